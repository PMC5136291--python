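"""Functional annotation of variants and the three filtering regimes.

Variant sets are filtered before testing by one of three regimes:

* ``nonsynonymous`` — protein-altering consequences (missense plus all
  loss-of-function terms);
* ``lof`` — loss-of-function only (stop gain/loss, splice donor/acceptor,
  frameshift);
* ``cadd`` — CADD phred-scaled deleteriousness score at or above a
  threshold (default 20, i.e. the top 1% most deleterious substitutions by
  CADD's construction), which admits deleterious intronic variation that
  consequence-based filters cannot see.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import SchemaError
from .geno_io import GenotypeMatrix, normalize_chrom

logger = logging.getLogger("pathkat.annotate")

__all__ = [
    "LOF_TERMS",
    "NONSYNONYMOUS_TERMS",
    "FilterRegime",
    "read_annotation_table",
    "consequence_class",
    "apply_regime",
]

LOF_TERMS = frozenset(
    {
        "stop_gained",
        "stop_lost",
        "splice_acceptor_variant",
        "splice_donor_variant",
        "frameshift_variant",
    }
)
# a loss-of-function change is also protein-altering
NONSYNONYMOUS_TERMS = frozenset({"missense_variant"}) | LOF_TERMS

_MODES = ("nonsynonymous", "lof", "cadd")

_REQUIRED_COLUMNS = ("chrom", "pos", "ref", "alt", "cadd_phred", "consequence")


@dataclass(frozen=True)
class FilterRegime:
    """Which functional filter to apply before collapsing variants."""

    mode: str = "cadd"
    cadd_threshold: float = 20.0

    def __post_init__(self):
        if self.mode not in _MODES:
            raise ValueError(f"mode must be one of {_MODES}, got {self.mode!r}")
        if not self.cadd_threshold > 0:
            raise ValueError("cadd_threshold must be positive")


def read_annotation_table(path) -> pd.DataFrame:
    """Read a per-variant annotation TSV.

    Requires a header with columns ``chrom, pos, ref, alt, cadd_phred,
    consequence``.  Empty CADD entries become NaN (score absent).  Duplicate
    variant keys resolve last-wins with a logged warning.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str})
    for col in _REQUIRED_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"annotation table {path} is missing column {col!r}")
    df["pos"] = df["pos"].astype(int)
    df["cadd_phred"] = pd.to_numeric(df["cadd_phred"], errors="coerce")
    neg = df["cadd_phred"] < 0
    if neg.any():
        raise SchemaError(f"annotation table {path} has negative cadd_phred values")
    df["chrom"] = df["chrom"].map(normalize_chrom)
    dup = df.duplicated(subset=["chrom", "pos", "ref", "alt"], keep="last")
    if dup.any():
        logger.warning(
            "stage=read_annotation_table duplicate_keys=%d (last wins)",
            int(dup.sum()),
        )
        df = df[~dup]
    return df.reset_index(drop=True)


def consequence_class(term: str) -> str:
    """Classify a VEP consequence term as ``lof``, ``nonsynonymous`` or ``other``.

    Matching is case-insensitive; unknown terms fall in ``other``.
    """
    if not term:
        raise ValueError("consequence term must be non-empty")
    t = term.strip().lower()
    if t in LOF_TERMS:
        return "lof"
    if t in NONSYNONYMOUS_TERMS:
        return "nonsynonymous"
    return "other"


def apply_regime(
    gm: GenotypeMatrix, annotations: pd.DataFrame, regime: FilterRegime
) -> GenotypeMatrix:
    """Keep only variants passing the regime's functional filter.

    Variants without an annotation entry are dropped with a logged count.
    Column selection only: dosage values are never altered.  An empty result
    is legitimate (downstream eligibility rules handle it).
    """
    key = pd.DataFrame(
        {
            "chrom": gm.variants["chrom"].map(normalize_chrom),
            "pos": gm.variants["pos"].astype(int),
            "ref": gm.variants["ref"],
            "alt": gm.variants["alt"],
        }
    )
    merged = key.merge(
        annotations, on=["chrom", "pos", "ref", "alt"], how="left", sort=False
    )
    unannotated = merged["consequence"].isna() & merged["cadd_phred"].isna()
    if unannotated.any():
        logger.warning(
            "stage=apply_regime unannotated_variants_dropped=%d",
            int(unannotated.sum()),
        )

    if regime.mode == "cadd":
        score = merged["cadd_phred"].to_numpy(dtype=float)
        keep = np.isfinite(score) & (score >= regime.cadd_threshold)
    else:
        classes = merged["consequence"].fillna("").map(
            lambda t: consequence_class(t) if t else "other"
        )
        if regime.mode == "lof":
            keep = (classes == "lof").to_numpy()
        else:
            keep = classes.isin(["lof", "nonsynonymous"]).to_numpy()
    keep &= ~unannotated.to_numpy()

    out = gm.subset_variants(np.flatnonzero(keep))
    logger.info(
        "stage=apply_regime mode=%s n_in=%d n_out=%d",
        regime.mode, gm.n_variants, out.n_variants,
    )
    return out
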