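"""Variant-to-gene and gene-to-pathway mapping.

The unit of association testing is a :class:`VariantSet`: a named list of
variant column indices into a (filtered) genotype matrix, at pathway, gene
or subnetwork level.  A set is eligible for kernel testing only when it
contains at least two variants; the number of eligible sets is the
denominator of the Bonferroni correction.

Coordinate frames: VCF positions are 1-based, gene regions (BED) are 0-based
half-open.  A variant at 1-based position ``p`` belongs to a gene iff
``p - 1`` lies in ``[start, end)`` — the single place where the conversion
happens.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import SchemaError
from .geno_io import GenotypeMatrix, normalize_chrom

logger = logging.getLogger("pathkat.genesets")

__all__ = [
    "VariantSet",
    "read_gmt",
    "read_gene_bed",
    "assign_variants_to_genes",
    "build_variant_sets",
]

MIN_SET_SIZE = 2  # eligibility: two or more variants after filtering


@dataclass(frozen=True)
class VariantSet:
    """A named collection of variant indices tested as one unit."""

    label: str
    level: str  # pathway | gene | subnetwork
    indices: tuple[int, ...]

    def __post_init__(self):
        if self.level not in ("pathway", "gene", "subnetwork"):
            raise ValueError(f"unknown set level {self.level!r}")
        idx = tuple(sorted(set(int(i) for i in self.indices)))
        object.__setattr__(self, "indices", idx)

    @property
    def n_variants(self) -> int:
        return len(self.indices)

    @property
    def eligible(self) -> bool:
        return self.n_variants >= MIN_SET_SIZE


def read_gmt(path) -> dict[str, set[str]]:
    """Read an MSigDB-dialect GMT file: name, description, member genes.

    The description field is preserved in parsing but unused.  Duplicate
    genes within a line are deduplicated with a logged note; a line with
    fewer than three fields (i.e. no genes) is a parse error.
    """
    pathways: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = [f.strip() for f in line.split("\t")]
            if len(fields) < 3:
                raise SchemaError(
                    f"{path}:{lineno}: GMT line needs name, description and "
                    f"at least one gene ({len(fields)} fields found)"
                )
            name = fields[0]
            genes = [g for g in fields[2:] if g]
            if not genes:
                raise SchemaError(f"{path}:{lineno}: pathway {name!r} has no genes")
            if name in pathways:
                raise SchemaError(f"{path}:{lineno}: duplicate pathway name {name!r}")
            gene_set = set(genes)
            if len(gene_set) < len(genes):
                logger.warning(
                    "stage=read_gmt pathway=%s duplicate_genes=%d",
                    name, len(genes) - len(gene_set),
                )
            pathways[name] = gene_set
    return pathways


def read_gene_bed(path) -> pd.DataFrame:
    """Read gene regions from a BED4+ file (chrom, start, end, name).

    Intervals are 0-based half-open; strand (and any further columns) is
    ignored — collapsing is strand-agnostic.  Empty or inverted intervals
    are record errors.
    """
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        usecols=[0, 1, 2, 3], names=["chrom", "start", "end", "symbol"],
        dtype={0: str, 3: str},
    )
    if df.shape[1] < 4:
        raise SchemaError(f"{path}: BED needs at least 4 columns")
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    bad = df["start"] >= df["end"]
    if bad.any():
        rows = (df.index[bad] + 1).tolist()
        raise SchemaError(f"{path}: empty/inverted interval at data row(s) {rows}")
    df["chrom"] = df["chrom"].map(normalize_chrom)
    return df.reset_index(drop=True)


def assign_variants_to_genes(
    gm: GenotypeMatrix, genes: pd.DataFrame
) -> dict[str, list[int]]:
    """Map each variant to every gene region overlapping it.

    Chromosome labels are harmonized by stripping a leading ``chr``.
    Overlapping genes each receive the variant (pathway union deduplicates).
    Unassigned variants are counted in a log line.
    """
    chroms = gm.variants["chrom"].map(normalize_chrom).to_numpy()
    pos0 = gm.variants["pos"].to_numpy(dtype=int) - 1  # to 0-based

    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for c in np.unique(chroms):
        mask = chroms == c
        idx = np.flatnonzero(mask)
        order = np.argsort(pos0[idx], kind="stable")
        by_chrom[c] = (pos0[idx][order], idx[order])

    gene_map: dict[str, list[int]] = {}
    assigned = np.zeros(gm.n_variants, dtype=bool)
    for row in genes.itertuples(index=False):
        entry = by_chrom.get(row.chrom)
        if entry is None:
            continue
        sorted_pos, orig_idx = entry
        lo = np.searchsorted(sorted_pos, row.start, side="left")
        hi = np.searchsorted(sorted_pos, row.end - 1, side="right")
        if hi > lo:
            hits = orig_idx[lo:hi]
            gene_map.setdefault(row.symbol, [])
            gene_map[row.symbol].extend(int(i) for i in hits)
            assigned[hits] = True
    for symbol in gene_map:
        gene_map[symbol] = sorted(set(gene_map[symbol]))
    n_unassigned = int((~assigned).sum())
    logger.info(
        "stage=assign_variants_to_genes n_genes_hit=%d n_unassigned_variants=%d",
        len(gene_map), n_unassigned,
    )
    return gene_map


def build_variant_sets(
    pathways: dict[str, set[str]] | None,
    gene_map: dict[str, list[int]],
    level: str,
) -> tuple[list[VariantSet], pd.DataFrame]:
    """Construct pathway- or gene-level variant sets with an eligibility report.

    A pathway's set is the deduplicated union of its member genes' variant
    indices.  Sets with fewer than two variants are retained in the report
    but marked ineligible; the eligible count is the Bonferroni denominator.
    Pathways whose genes are all absent from ``gene_map`` are excluded and
    logged.
    """
    sets: list[VariantSet] = []
    if level == "pathway":
        if pathways is None:
            raise ValueError("pathway level requires a pathway collection")
        n_empty = 0
        for name in pathways:
            members = pathways[name]
            indices: set[int] = set()
            found = False
            for g in members:
                if g in gene_map:
                    found = True
                    indices.update(gene_map[g])
            if not found:
                n_empty += 1
                continue
            sets.append(VariantSet(name, "pathway", tuple(indices)))
        if n_empty:
            logger.info(
                "stage=build_variant_sets pathways_without_mapped_genes=%d", n_empty
            )
    elif level == "gene":
        for g in sorted(gene_map):
            sets.append(VariantSet(g, "gene", tuple(gene_map[g])))
    else:
        raise ValueError(f"level must be 'pathway' or 'gene', got {level!r}")

    report = pd.DataFrame(
        {
            "set": [s.label for s in sets],
            "level": [s.level for s in sets],
            "n_variants": [s.n_variants for s in sets],
            "eligible": [s.eligible for s in sets],
        }
    )
    n_eligible = int(report["eligible"].sum()) if len(report) else 0
    logger.info(
        "stage=build_variant_sets level=%s n_sets=%d n_eligible=%d",
        level, len(sets), n_eligible,
    )
    return sets, report
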