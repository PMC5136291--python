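"""Genotype I/O: VCF reading, per-variant statistics and variant-level QC.

Genotypes are held as a samples x variants dosage matrix in [0, 2] with
``numpy.nan`` marking missing calls.  Dosages are taken from the ``DS``
FORMAT field when present (imputed data carries its information there) and
from hard ``GT`` allele counts otherwise.  Multi-allelic records are
decomposed into one bi-allelic row per alternate allele; genotype calls
carrying a different alternate allele count as dosage 0 for the focal one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .errors import ConfigError, VcfParseError

logger = logging.getLogger("pathkat.geno_io")

__all__ = [
    "VariantKey",
    "GenotypeMatrix",
    "read_vcf",
    "variant_stats",
    "hwe_exact_p",
    "filter_variants",
    "normalize_chrom",
]


def normalize_chrom(chrom: str) -> str:
    """Strip a leading ``chr`` prefix so VCF/BED chromosome labels join."""
    return chrom[3:] if chrom.lower().startswith("chr") else chrom


class VariantKey(NamedTuple):
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str


@dataclass
class GenotypeMatrix:
    """Samples x variants dosage matrix with per-variant metadata.

    Attributes
    ----------
    samples : list of sample IDs, in VCF header order.
    variants : DataFrame with columns ``chrom, pos, ref, alt, info``;
        ``info`` is the imputation-quality score in [0, 1] or NaN when absent.
    dosage : float array of shape (n_samples, n_variants); entries in [0, 2]
        or NaN for missing calls.
    """

    samples: list[str]
    variants: pd.DataFrame
    dosage: np.ndarray

    def __post_init__(self):
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.shape != (len(self.samples), len(self.variants)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        finite = self.dosage[np.isfinite(self.dosage)]
        if finite.size and (finite.min() < -1e-9 or finite.max() > 2 + 1e-9):
            raise ValueError("non-missing dosages must lie in [0, 2]")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def keys(self) -> list[VariantKey]:
        return [
            VariantKey(c, int(p), r, a)
            for c, p, r, a in zip(
                self.variants["chrom"], self.variants["pos"],
                self.variants["ref"], self.variants["alt"],
            )
        ]

    def subset_variants(self, index: Sequence[int]) -> "GenotypeMatrix":
        idx = np.asarray(index, dtype=int)
        return GenotypeMatrix(
            samples=list(self.samples),
            variants=self.variants.iloc[idx].reset_index(drop=True),
            dosage=self.dosage[:, idx],
        )

    def subset_samples(self, index: Sequence[int]) -> "GenotypeMatrix":
        idx = np.asarray(index, dtype=int)
        return GenotypeMatrix(
            samples=[self.samples[i] for i in idx],
            variants=self.variants.copy(),
            dosage=self.dosage[idx, :],
        )


def _record_info_score(variant, info_key, info_fallback, alt_index):
    for key in (info_key, info_fallback):
        if key is None:
            continue
        try:
            val = variant.INFO.get(key)
        except Exception:  # pragma: no cover - htslib quirk safety
            val = None
        if val is None:
            continue
        if isinstance(val, (tuple, list)):
            val = val[alt_index] if alt_index < len(val) else val[0]
        try:
            return float(val)
        except (TypeError, ValueError):
            continue
    return np.nan


def read_vcf(
    path,
    sample_subset: Sequence[str] | None = None,
    info_key: str = "INFO",
    info_fallback: str = "R2",
) -> GenotypeMatrix:
    """Read a VCF (plain or bgzip) into a :class:`GenotypeMatrix`.

    ``DS`` dosages are preferred over ``GT`` hard calls when both are
    present.  ``sample_subset`` restricts (and errors on unknown) sample IDs;
    the imputation-quality INFO score is read from ``info_key`` with
    ``info_fallback`` as a secondary key, NaN when neither is present.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path), gts012=False, strict_gt=True)
    except Exception as exc:
        raise VcfParseError(f"cannot open VCF {path}: {exc}") from exc

    header_samples = list(vcf.samples)
    if sample_subset is not None:
        missing = [s for s in sample_subset if s not in header_samples]
        if missing:
            raise VcfParseError(
                f"sample IDs absent from VCF header: {missing}"
            )
        vcf = VCF(str(path), samples=list(sample_subset), strict_gt=True)

    samples = list(vcf.samples)
    n = len(samples)
    cols: list[np.ndarray] = []
    meta: list[tuple] = []
    record_no = 0
    try:
        for variant in vcf:
            record_no += 1
            alts = variant.ALT or []
            gt = None
            ds = None
            try:
                ds = variant.format("DS")
            except Exception:
                ds = None
            if ds is not None:
                ds = np.asarray(ds, dtype=float)
                if ds.ndim == 1:
                    ds = ds[:, None]
            if ds is None or ds.shape[1] < len(alts):
                gt = variant.genotype.array()  # (n, ploidy+1), -1 missing
            for k, alt in enumerate(alts):
                if ds is not None and k < ds.shape[1]:
                    col = ds[:, k].astype(float)
                    col[~np.isfinite(col)] = np.nan
                else:
                    alleles = gt[:, :-1]
                    missing = (alleles < 0).any(axis=1)
                    col = (alleles == k + 1).sum(axis=1).astype(float)
                    col[missing] = np.nan
                cols.append(col)
                meta.append(
                    (
                        variant.CHROM,
                        int(variant.POS),
                        variant.REF,
                        alt,
                        _record_info_score(variant, info_key, info_fallback, k),
                    )
                )
    except VcfParseError:
        raise
    except Exception as exc:
        raise VcfParseError(
            f"malformed VCF {path} at or near record {record_no + 1}: {exc}"
        ) from exc

    variants = pd.DataFrame(meta, columns=["chrom", "pos", "ref", "alt", "info"])
    dosage = (
        np.column_stack(cols) if cols else np.empty((n, 0), dtype=float)
    )
    dosage = np.clip(dosage, 0.0, 2.0, out=dosage) if dosage.size else dosage
    logger.info("stage=read_vcf n_samples=%d n_variants=%d", n, len(variants))
    return GenotypeMatrix(samples=samples, variants=variants, dosage=dosage)


def hwe_exact_p(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Two-sided exact test of Hardy-Weinberg genotype proportions.

    Sums, over every heterozygote count compatible with the observed allele
    counts, the conditional probabilities that do not exceed that of the
    observed configuration.  Monomorphic input returns 1.
    """
    counts = (int(n_hom_ref), int(n_het), int(n_hom_alt))
    if any(c < 0 for c in counts):
        raise ValueError("genotype counts must be non-negative")
    n = sum(counts)
    if n == 0:
        raise ValueError("at least one genotype count must be positive")
    n_alt = 2 * counts[2] + counts[1]
    n_minor = min(n_alt, 2 * n - n_alt)
    if n_minor == 0:
        return 1.0

    # het counts share the parity of the minor-allele total
    hets = np.arange(n_minor % 2, n_minor + 1, 2)
    hets = hets[(n_minor - hets) % 2 == 0]
    hets = hets[hets <= n_minor]
    n_minor_hom = (n_minor - hets) // 2
    n_major_hom = n - hets - n_minor_hom
    valid = n_major_hom >= 0
    hets, n_minor_hom, n_major_hom = hets[valid], n_minor_hom[valid], n_major_hom[valid]

    # log P(het = h | N, minor count) up to a shared constant
    logp = (
        hets * np.log(2.0)
        - gammaln(hets + 1)
        - gammaln(n_minor_hom + 1)
        - gammaln(n_major_hom + 1)
    )
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    observed = counts[1]
    p_obs = probs[hets == observed]
    if p_obs.size == 0:  # inconsistent configuration cannot occur from data
        raise ValueError("heterozygote count inconsistent with allele totals")
    p = probs[probs <= p_obs[0] * (1 + 1e-12)].sum()
    return float(min(p, 1.0))


def variant_stats(gm: GenotypeMatrix) -> pd.DataFrame:
    """Per-variant MAF, call rate and (hard calls only) HWE exact p-value.

    MAF is computed on non-missing entries; variants with zero non-missing
    calls get NaN MAF and are flagged for downstream exclusion.  The HWE test
    applies only to variants whose non-missing dosages are all integral.
    """
    if gm.n_variants == 0:
        return pd.DataFrame(columns=["maf", "call_rate", "hwe_p"])
    D = gm.dosage
    present = np.isfinite(D)
    n_called = present.sum(axis=0)
    alt_sum = np.nansum(D, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(n_called > 0, alt_sum / (2.0 * n_called), np.nan)
    maf = np.minimum(f, 1.0 - f)
    call_rate = n_called / gm.n_samples

    hwe_p = np.full(gm.n_variants, np.nan)
    for j in range(gm.n_variants):
        if n_called[j] == 0:
            continue
        col = D[present[:, j], j]
        rounded = np.rint(col)
        if np.max(np.abs(col - rounded)) > 1e-9:
            continue  # dosage data: exact HWE test does not apply
        n2 = int((rounded == 2).sum())
        n1 = int((rounded == 1).sum())
        n0 = int((rounded == 0).sum())
        hwe_p[j] = hwe_exact_p(n0, n1, n2)

    n_no_calls = int((n_called == 0).sum())
    if n_no_calls:
        logger.warning("stage=variant_stats n_zero_call_variants=%d", n_no_calls)
    return pd.DataFrame({"maf": maf, "call_rate": call_rate, "hwe_p": hwe_p})


def filter_variants(
    gm: GenotypeMatrix,
    stats: pd.DataFrame,
    max_maf: float,
    min_info: float | None = None,
    min_hwe_p: float | None = None,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Apply variant-level QC: rare-MAF, imputation-INFO and HWE filters.

    Boundary conventions follow the filters' definitions: MAF <= max_maf and
    INFO >= min_info are inclusive, HWE requires P strictly greater than
    ``min_hwe_p``.  Variants with undefined MAF (no calls) are always dropped.
    When the INFO filter is active, variants with absent INFO are dropped.
    Variants without an HWE p-value (non-integral dosages) pass the HWE
    filter with a logged warning: for dosage data the filter is assumed
    pre-applied upstream.

    Returns the filtered matrix and a report with one row per criterion
    (``criterion, n_removed, n_remaining``).
    """
    if not (0.0 < max_maf <= 0.5):
        raise ConfigError(f"max_maf must lie in (0, 0.5], got {max_maf}")
    if len(stats) != gm.n_variants:
        raise ValueError("stats not aligned to genotype matrix variants")

    keep = np.ones(gm.n_variants, dtype=bool)
    report_rows = []

    def _apply(criterion: str, mask_pass: np.ndarray):
        nonlocal keep
        removed = int((keep & ~mask_pass).sum())
        keep = keep & mask_pass
        report_rows.append(
            {"criterion": criterion, "n_removed": removed,
             "n_remaining": int(keep.sum())}
        )

    maf = stats["maf"].to_numpy(dtype=float)
    _apply("defined_maf", np.isfinite(maf))
    _apply("maf", np.isfinite(maf) & (maf <= max_maf))

    if min_info is not None:
        info = gm.variants["info"].to_numpy(dtype=float)
        _apply("info", np.isfinite(info) & (info >= min_info))

    if min_hwe_p is not None:
        hwe = stats["hwe_p"].to_numpy(dtype=float)
        undefined = ~np.isfinite(hwe)
        if undefined.any():
            logger.warning(
                "stage=filter_variants hwe_skipped_dosage_variants=%d "
                "(HWE filter assumed pre-applied upstream for dosage data)",
                int((keep & undefined).sum()),
            )
        _apply("hwe", undefined | (hwe > min_hwe_p))

    report = pd.DataFrame(report_rows)
    out = gm.subset_variants(np.flatnonzero(keep))
    logger.info(
        "stage=filter_variants n_in=%d n_out=%d", gm.n_variants, out.n_variants
    )
    return out, report
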