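"""Synthetic input bundles with known causal structure.

Generates a complete, internally consistent set of pipeline inputs — VCF
genotypes, variant annotations, GMT pathways, BED gene regions, an
interaction edge list, a phenotype/covariate table and a truth manifest —
so every stage of the pipeline is testable without external data.

The statistical structure emulated: rare variants (binomial genotypes under
Hardy-Weinberg, low-frequency MAF spectrum) tiled across non-overlapping
gene regions on synthetic chromosomes; pathways partitioning genes; a
quantitative trait driven by a configurable causal pathway whose effects
are split across several genes with mixed signs, plus standard-normal
covariates ("principal components") and Gaussian noise; CADD-like
deleteriousness scores enriched among causal variants; and an interaction
graph in which one designated hub connects to all causal genes.

Defaults are scaled for desk-size experiments (n = 500): per-allele effects
are drawn with SD 1.5 trait-SD so that a causal pathway carrying a handful
of filter-surviving rare variants is reliably detectable — the same
signal-to-noise regime a cohort of thousands reaches with substantially
smaller effects.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

from .annotate import LOF_TERMS
from .errors import ConfigError

logger = logging.getLogger("pathkat.synthgen")

__all__ = ["SimSpec", "TruthManifest", "SyntheticBundle", "generate_bundle",
           "partition_cohorts", "CohortPartition"]

_OTHER_TERMS = (
    "intron_variant",
    "synonymous_variant",
    "3_prime_UTR_variant",
    "upstream_gene_variant",
)
_ALLELES = (("A", "G"), ("C", "T"), ("G", "A"), ("T", "C"))
_GENES_PER_CHROM = 30
_GENE_SLOT = 10_000  # bp per gene slot
_GENE_SPAN = 6_000   # gene footprint within the slot


@dataclass(frozen=True)
class SimSpec:
    """Study conditions for one synthetic bundle; the seed fixes everything."""

    n_samples: int = 500
    n_genes: int = 60
    genes_per_pathway: int = 5
    n_pathways: int = 12
    variants_per_gene: tuple[int, int] = (4, 8)
    maf_range: tuple[float, float] = (0.0005, 0.01)
    common_variant_fraction: float = 0.1
    common_maf_range: tuple[float, float] = (0.05, 0.3)
    causal_pathway: str = "PATHWAY_001"
    causal_gene_count: int = 5
    causal_variant_fraction: float = 0.5
    effect_size_sd: float = 1.5
    sign_mix: float = 0.5
    cadd_high_fraction_causal: float = 0.3
    cadd_high_fraction_null: float = 0.05
    missense_fraction: float = 0.15
    lof_fraction: float = 0.05
    n_covariates: int = 10
    covariate_effect_sd: float = 0.2
    noise_sd: float = 1.0
    missing_fraction: float = 0.0
    hwe_violation_fraction: float = 0.0
    ld_rho: float = 0.0
    emit_dosage: bool = False
    trait_name: str = "sbp"
    seed: int = 0

    def __post_init__(self):
        fracs = {
            "common_variant_fraction": self.common_variant_fraction,
            "causal_variant_fraction": self.causal_variant_fraction,
            "sign_mix": self.sign_mix,
            "cadd_high_fraction_causal": self.cadd_high_fraction_causal,
            "cadd_high_fraction_null": self.cadd_high_fraction_null,
            "missense_fraction": self.missense_fraction,
            "lof_fraction": self.lof_fraction,
            "missing_fraction": self.missing_fraction,
            "hwe_violation_fraction": self.hwe_violation_fraction,
        }
        for name, v in fracs.items():
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")
        for name in ("n_samples", "n_genes", "genes_per_pathway", "n_pathways",
                     "causal_gene_count", "n_covariates"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be at least 1")
        if self.causal_gene_count > self.genes_per_pathway:
            raise ConfigError(
                "causal_gene_count cannot exceed genes_per_pathway"
            )
        if self.n_pathways * self.genes_per_pathway > self.n_genes:
            raise ConfigError(
                "pathways partition genes: need n_genes >= "
                "n_pathways * genes_per_pathway"
            )
        if not (0.0 <= self.ld_rho < 1.0):
            raise ConfigError("ld_rho must lie in [0, 1)")
        names = [f"PATHWAY_{i + 1:03d}" for i in range(self.n_pathways)]
        if self.causal_pathway not in names:
            raise ConfigError(
                f"causal_pathway {self.causal_pathway!r} is not one of the "
                f"generated names PATHWAY_001..PATHWAY_{self.n_pathways:03d}"
            )


@dataclass
class TruthManifest:
    """Ground truth for the emitted bundle."""

    causal_variants: list[dict]
    causal_genes: list[str]
    causal_pathway: str
    covariate_coefficients: list[float]
    trait_name: str
    seed: int


@dataclass
class SyntheticBundle:
    """File paths plus the in-memory truth of one generated bundle."""

    out_dir: Path
    vcf: Path
    annotations: Path
    gmt: Path
    bed: Path
    edges: Path
    phenotypes: Path
    manifest_path: Path
    truth: TruthManifest
    samples: list[str]
    variants: pd.DataFrame  # chrom,pos,ref,alt,gene,maf,cadd_phred,consequence,beta
    dosage: np.ndarray      # truth matrix, NaN for emitted missing calls
    phenotype: np.ndarray
    covariates: np.ndarray
    pathways: dict[str, set[str]]
    genes: pd.DataFrame     # chrom,start,end,symbol


def _gene_layout(n_genes: int) -> pd.DataFrame:
    rows = []
    for i in range(n_genes):
        chrom = f"chrS{i // _GENES_PER_CHROM + 1}"
        start = (i % _GENES_PER_CHROM) * _GENE_SLOT
        rows.append((chrom, start, start + _GENE_SPAN, f"GENE_{i + 1:04d}"))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "symbol"])


def _draw_gene_genotypes(rng, n, mafs, ld_rho, hwe_mask):
    """Genotypes for one gene's variants: binomial, optionally with an
    exchangeable latent haplotype correlation, plus HWE-violating columns."""
    m = mafs.size
    if ld_rho > 0 and m > 1:
        thresh = norm.ppf(mafs)
        g = np.zeros((n, m))
        for _hap in range(2):
            shared = rng.standard_normal((n, 1))
            indep = rng.standard_normal((n, m))
            z = np.sqrt(ld_rho) * shared + np.sqrt(1 - ld_rho) * indep
            g += (z < thresh[None, :]).astype(float)
    else:
        g = rng.binomial(2, mafs[None, :], size=(n, m)).astype(float)
    for j in np.flatnonzero(hwe_mask):
        # strong homozygote excess (inbreeding F = 0.9): for rare alleles a
        # heterozygote deficit is what the exact test actually detects
        p = mafs[j]
        f_coef = 0.9
        p2 = p * p + f_coef * p * (1 - p)
        p1 = 2.0 * p * (1 - p) * (1 - f_coef)
        u = rng.random(n)
        g[:, j] = np.where(u < p2, 2.0, np.where(u < p2 + p1, 1.0, 0.0))
    return g


def generate_bundle(spec: SimSpec, out_dir) -> SyntheticBundle:
    """Write a complete input bundle under ``out_dir`` and return its truth.

    Deterministic given ``spec`` (byte-identical across invocations).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    n = spec.n_samples

    genes = _gene_layout(spec.n_genes)
    pathways: dict[str, set[str]] = {}
    gene_pathway = {}
    for p in range(spec.n_pathways):
        name = f"PATHWAY_{p + 1:03d}"
        members = set(
            genes["symbol"].iloc[
                p * spec.genes_per_pathway:(p + 1) * spec.genes_per_pathway
            ]
        )
        pathways[name] = members
        for g in members:
            gene_pathway[g] = name
    causal_genes = sorted(pathways[spec.causal_pathway])[: spec.causal_gene_count]
    causal_gene_set = set(causal_genes)

    # --- variants ---------------------------------------------------------
    lo, hi = spec.variants_per_gene
    rows = []
    for gi, grow in enumerate(genes.itertuples(index=False)):
        m_g = int(rng.integers(lo, hi + 1))
        in_causal_gene = grow.symbol in causal_gene_set
        for j in range(m_g):
            pos = grow.start + 100 * (j + 1)  # 1-based; inside [start, end)
            ref, alt = _ALLELES[j % len(_ALLELES)]
            is_common = (not in_causal_gene) and (
                rng.random() < spec.common_variant_fraction
            )
            if is_common:
                maf = rng.uniform(*spec.common_maf_range)
            else:
                maf = rng.uniform(*spec.maf_range)
            causal = (
                in_causal_gene
                and not is_common
                and rng.random() < spec.causal_variant_fraction
            )
            beta = 0.0
            if causal:
                sign = -1.0 if rng.random() < spec.sign_mix else 1.0
                beta = sign * abs(rng.normal(0.0, spec.effect_size_sd))
            high_frac = (
                spec.cadd_high_fraction_causal if causal
                else spec.cadd_high_fraction_null
            )
            if rng.random() < high_frac:
                cadd = rng.uniform(20.0, 40.0)
            else:
                cadd = rng.uniform(0.1, 19.9)
            u = rng.random()
            if u < spec.lof_fraction:
                conseq = sorted(LOF_TERMS)[int(rng.integers(len(LOF_TERMS)))]
            elif u < spec.lof_fraction + spec.missense_fraction:
                conseq = "missense_variant"
            else:
                conseq = _OTHER_TERMS[int(rng.integers(len(_OTHER_TERMS)))]
            hwe_bad = rng.random() < spec.hwe_violation_fraction
            rows.append(
                (grow.chrom, pos, ref, alt, grow.symbol, maf, cadd, conseq,
                 beta, causal, hwe_bad)
            )
    variants = pd.DataFrame(
        rows,
        columns=["chrom", "pos", "ref", "alt", "gene", "maf", "cadd_phred",
                 "consequence", "beta", "causal", "hwe_violation"],
    )
    m_total = len(variants)

    # --- genotypes (per gene block, order fixed) --------------------------
    dosage = np.empty((n, m_total))
    for sym, idx in variants.groupby("gene", sort=False).groups.items():
        idx = np.asarray(idx)
        dosage[:, idx] = _draw_gene_genotypes(
            rng, n,
            variants["maf"].to_numpy()[idx],
            spec.ld_rho,
            variants["hwe_violation"].to_numpy()[idx],
        )

    # --- phenotype --------------------------------------------------------
    covariates = rng.standard_normal((n, spec.n_covariates))
    gamma = rng.normal(0.0, spec.covariate_effect_sd, spec.n_covariates)
    beta_vec = variants["beta"].to_numpy()
    y = (
        dosage @ beta_vec
        + covariates @ gamma
        + rng.normal(0.0, spec.noise_sd, n)
    )

    # --- missingness (after phenotype so truth effects use full genotypes)
    if spec.missing_fraction > 0:
        miss = rng.random(dosage.shape) < spec.missing_fraction
        dosage = dosage.copy()
        dosage[miss] = np.nan

    samples = [f"S{i + 1:05d}" for i in range(n)]

    # --- serialize --------------------------------------------------------
    paths = {
        "vcf": out / "genotypes.vcf",
        "annotations": out / "annotations.tsv",
        "gmt": out / "pathways.gmt",
        "bed": out / "genes.bed",
        "edges": out / "edges.tsv",
        "phenotypes": out / "phenotypes.tsv",
        "manifest": out / "truth.json",
    }
    _write_vcf(paths["vcf"], samples, variants, dosage, genes,
               emit_dosage=spec.emit_dosage)
    ann = variants[["chrom", "pos", "ref", "alt", "cadd_phred", "consequence"]]
    ann = ann.copy()
    ann["cadd_phred"] = ann["cadd_phred"].map(lambda v: f"{v:.3f}")
    ann.to_csv(paths["annotations"], sep="\t", index=False)
    with open(paths["gmt"], "w") as fh:
        for name, members in pathways.items():
            fh.write("\t".join([name, "synthetic"] + sorted(members)) + "\n")
    genes.to_csv(paths["bed"], sep="\t", index=False, header=False)
    _write_edges(paths["edges"], rng, genes, causal_genes)
    pheno = pd.DataFrame({"sample_id": samples})
    pheno[spec.trait_name] = [f"{v:.8f}" for v in y]
    for c in range(spec.n_covariates):
        pheno[f"pc{c + 1}"] = [f"{v:.8f}" for v in covariates[:, c]]
    pheno.to_csv(paths["phenotypes"], sep="\t", index=False)

    causal_records = [
        {
            "chrom": r.chrom, "pos": int(r.pos), "ref": r.ref, "alt": r.alt,
            "gene": r.gene, "beta": float(r.beta),
        }
        for r in variants[variants["causal"]].itertuples(index=False)
    ]
    truth = TruthManifest(
        causal_variants=causal_records,
        causal_genes=causal_genes,
        causal_pathway=spec.causal_pathway,
        covariate_coefficients=[float(g) for g in gamma],
        trait_name=spec.trait_name,
        seed=spec.seed,
    )
    with open(paths["manifest"], "w") as fh:
        json.dump({"spec": asdict(spec), **asdict(truth)}, fh, indent=1,
                  sort_keys=True)

    logger.info(
        "stage=generate_bundle n_samples=%d n_variants=%d n_causal=%d",
        n, m_total, len(causal_records),
    )
    return SyntheticBundle(
        out_dir=out, truth=truth, samples=samples, variants=variants,
        dosage=dosage, phenotype=y, covariates=covariates,
        pathways=pathways, genes=genes,
        vcf=paths["vcf"], annotations=paths["annotations"], gmt=paths["gmt"],
        bed=paths["bed"], edges=paths["edges"], phenotypes=paths["phenotypes"],
        manifest_path=paths["manifest"],
    )


def _write_vcf(path, samples, variants, dosage, genes, emit_dosage,
               info_scores=None, sample_mask=None):
    cols = np.arange(len(samples))
    if sample_mask is not None:
        cols = np.flatnonzero(sample_mask)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in genes["chrom"].unique():
            fh.write(f"##contig=<ID={chrom},length=1000000>\n")
        if info_scores is not None:
            fh.write(
                '##INFO=<ID=INFO,Number=1,Type=Float,'
                'Description="Imputation quality score">\n'
            )
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if emit_dosage:
            fh.write(
                '##FORMAT=<ID=DS,Number=A,Type=Float,'
                'Description="Alternate allele dosage">\n'
            )
        header = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER",
                  "INFO", "FORMAT"] + [samples[i] for i in cols]
        fh.write("\t".join(header) + "\n")
        fmt = "GT:DS" if emit_dosage else "GT"
        gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
        for j, row in enumerate(variants.itertuples(index=False)):
            info = "."
            if info_scores is not None:
                info = f"INFO={info_scores[j]:.3f}"
            fields = [row.chrom, str(int(row.pos)), f"var{j + 1}", row.ref,
                      row.alt, ".", "PASS", info, fmt]
            for i in cols:
                d = dosage[i, j]
                if not np.isfinite(d):
                    fields.append("./." + (":." if emit_dosage else ""))
                    continue
                gt = gt_map[int(round(d))]
                fields.append(f"{gt}:{d:.4f}" if emit_dosage else gt)
            fh.write("\t".join(fields) + "\n")


def _write_edges(path, rng, genes, causal_genes):
    hub = causal_genes[0]
    edges = {}
    for g in causal_genes[1:]:
        edges[(hub, g)] = rng.uniform(600.0, 900.0)
    symbols = list(genes["symbol"])
    n_background = 2 * len(symbols)
    for _ in range(n_background):
        a, b = rng.choice(symbols, size=2, replace=False)
        key = (min(a, b), max(a, b))
        if key in edges or (key[1], key[0]) in edges:
            continue
        edges[key] = rng.uniform(150.0, 900.0)
    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b\texperimental_score\n")
        for (a, b), s in edges.items():
            fh.write(f"{a}\t{b}\t{s:.1f}\n")


@dataclass
class CohortPartition:
    """Disjoint discovery/replication sample subsets (+ optional degraded VCF)."""

    discovery_ids: list[str]
    replication_ids: list[str]
    discovery_list: Path
    replication_list: Path
    replication_vcf: Path | None
    info_scores: np.ndarray | None


def partition_cohorts(
    bundle: SyntheticBundle,
    fractions: tuple[float, float] = (0.5, 0.5),
    seed: int = 0,
    low_info_fraction: float | None = None,
    info_low_range: tuple[float, float] = (0.05, 0.39),
    info_high_range: tuple[float, float] = (0.4, 1.0),
) -> CohortPartition:
    """Split samples into disjoint discovery/replication subsets.

    With ``low_info_fraction`` set, a replication VCF is also written whose
    variants carry an imputation-quality INFO score: that fraction of
    variants draws from ``info_low_range`` (below the 0.4 QC bar), the rest
    from ``info_high_range``.
    """
    f1, f2 = fractions
    if f1 < 0 or f2 < 0 or f1 + f2 > 1.0 + 1e-12:
        raise ConfigError("fractions must be non-negative and sum to at most 1")
    rng = np.random.default_rng(seed)
    n = len(bundle.samples)
    order = rng.permutation(n)
    n1 = int(round(f1 * n))
    n2 = int(round(f2 * n))
    n2 = min(n2, n - n1)
    disc = sorted(bundle.samples[i] for i in order[:n1])
    repl = sorted(bundle.samples[i] for i in order[n1:n1 + n2])

    disc_path = bundle.out_dir / "discovery_samples.txt"
    repl_path = bundle.out_dir / "replication_samples.txt"
    disc_path.write_text("\n".join(disc) + "\n")
    repl_path.write_text("\n".join(repl) + "\n")

    repl_vcf = None
    info_scores = None
    if low_info_fraction is not None:
        if not (0.0 <= low_info_fraction <= 1.0):
            raise ConfigError("low_info_fraction must lie in [0, 1]")
        m = len(bundle.variants)
        low = rng.random(m) < low_info_fraction
        info_scores = np.where(
            low,
            rng.uniform(*info_low_range, m),
            rng.uniform(*info_high_range, m),
        )
        repl_vcf = bundle.out_dir / "genotypes_replication.vcf"
        _write_vcf(
            repl_vcf, bundle.samples, bundle.variants, bundle.dosage,
            bundle.genes, emit_dosage=False, info_scores=info_scores,
        )
    return CohortPartition(
        discovery_ids=disc, replication_ids=repl,
        discovery_list=disc_path, replication_list=repl_path,
        replication_vcf=repl_vcf, info_scores=info_scores,
    )
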