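"""End-to-end orchestration: discovery, gene scan, permutation, subnetworks,
replication.

The discovery pipeline reads genotypes, applies the rare-MAF and functional
filters, maps variants to genes and genes to pathway variant sets, fits a
per-trait null model on the covariates, kernel-tests every eligible set and
flags results against the Bonferroni threshold ``alpha / n_eligible`` where
the denominator is the number of sets with two or more surviving variants
under the active regime.  Replication reruns restricted to discovery hits
with imputation-quality (INFO >= 0.4) and Hardy-Weinberg (P > 5e-7) QC
switched on.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .annotate import FilterRegime, apply_regime, read_annotation_table
from .errors import ConfigError
from .geno_io import GenotypeMatrix, filter_variants, read_vcf, variant_stats
from .genesets import (
    VariantSet,
    assign_variants_to_genes,
    build_variant_sets,
    read_gene_bed,
    read_gmt,
)
from .kernel_test import (
    DEFAULT_RHO_GRID,
    NullModel,
    WeightSpec,
    beta_weights,
    fit_null,
    single_variant_scan,
    skat_o,
)
from .netdissect import hub_subnetwork, pathway_hubs, read_edge_list, test_subnetworks
from .permtest import derive_set_seed, permutation_test

logger = logging.getLogger("pathkat.pipeline")

__all__ = [
    "RunConfig",
    "bonferroni_threshold",
    "run_discovery",
    "run_gene_scan",
    "run_replication",
    "run_permutations",
    "run_subnetworks",
    "load_config",
]

REPLICATION_MIN_INFO = 0.4
REPLICATION_MIN_HWE_P = 5e-7


@dataclass
class RunConfig:
    """Inputs, filters and options for one pipeline run."""

    vcf: Path
    annotations: Path
    gmt: Path | None = None
    bed: Path | None = None
    edges: Path | None = None
    phenotypes: Path | None = None
    traits: tuple[str, ...] = ()
    covariates: tuple[str, ...] = tuple(f"pc{i}" for i in range(1, 11))
    regime: FilterRegime = field(default_factory=FilterRegime)
    maf_max: float = 0.01
    min_info: float | None = None
    min_hwe_p: float | None = None
    alpha: float = 0.05
    permutations: int = 0
    seed: int = 0
    sample_list: Path | None = None
    weights: WeightSpec = field(default_factory=WeightSpec)
    rho_grid: tuple[float, ...] = DEFAULT_RHO_GRID
    out_dir: Path | None = None

    def __post_init__(self):
        if not (0.0 < self.alpha < 1.0):
            raise ConfigError(f"alpha must lie in (0, 1), got {self.alpha}")
        for name in ("vcf", "annotations", "gmt", "bed", "edges",
                     "phenotypes", "sample_list"):
            p = getattr(self, name)
            if p is not None:
                p = Path(p)
                setattr(self, name, p)
                if not p.exists():
                    raise ConfigError(f"{name} path does not exist: {p}")
        if self.out_dir is not None:
            self.out_dir = Path(self.out_dir)

    def replication(self) -> "RunConfig":
        """Copy of this config with replication QC defaults activated."""
        import copy

        cfg = copy.copy(self)
        if cfg.min_info is None:
            cfg.min_info = REPLICATION_MIN_INFO
        if cfg.min_hwe_p is None:
            cfg.min_hwe_p = REPLICATION_MIN_HWE_P
        return cfg


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Family-wise threshold alpha / n_tests."""
    if n_tests < 1:
        raise ConfigError("n_tests must be at least 1")
    if not (0.0 < alpha < 1.0):
        raise ConfigError("alpha must lie in (0, 1)")
    return alpha / n_tests


def load_config(path) -> RunConfig:
    """Read a flat key-value TOML config into a RunConfig."""
    import tomllib

    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    regime_kwargs = {}
    if "filter" in raw:
        regime_kwargs["mode"] = raw.pop("filter")
    if "cadd_threshold" in raw:
        regime_kwargs["cadd_threshold"] = raw.pop("cadd_threshold")
    if regime_kwargs:
        raw["regime"] = FilterRegime(**regime_kwargs)
    for key in ("traits", "covariates"):
        if key in raw:
            raw[key] = tuple(raw[key])
    return RunConfig(**raw)


# ---------------------------------------------------------------------------


@dataclass
class LoadedInputs:
    gm: GenotypeMatrix            # post rare + regime filter, polymorphic
    stats: pd.DataFrame           # per-variant stats aligned to gm
    gene_map: dict[str, list[int]]
    filter_report: pd.DataFrame
    pheno: pd.DataFrame


def _read_sample_list(path) -> list[str]:
    return [s for s in Path(path).read_text().split() if s]


def load_inputs(config: RunConfig) -> LoadedInputs:
    """Shared input stage: genotypes, QC filters, regime, gene assignment."""
    subset = _read_sample_list(config.sample_list) if config.sample_list else None
    gm = read_vcf(config.vcf, sample_subset=subset)
    stats = variant_stats(gm)

    if config.min_info is not None and not np.isfinite(
        gm.variants["info"].to_numpy(dtype=float)
    ).any():
        raise ConfigError(
            "min_info filter requested but the VCF carries no imputation-"
            "quality INFO scores"
        )

    gm_rare, report = filter_variants(
        gm, stats, config.maf_max, config.min_info, config.min_hwe_p
    )
    ann = read_annotation_table(config.annotations)
    gm_f = apply_regime(gm_rare, ann, config.regime)

    # kernel weights need maf > 0: drop monomorphic survivors
    stats_f = variant_stats(gm_f)
    poly = stats_f["maf"].to_numpy(dtype=float) > 0
    n_mono = int((~poly).sum())
    if n_mono:
        logger.info("stage=load_inputs monomorphic_dropped=%d", n_mono)
        gm_f = gm_f.subset_variants(np.flatnonzero(poly))
        stats_f = stats_f.iloc[np.flatnonzero(poly)].reset_index(drop=True)
    report = pd.concat(
        [report, pd.DataFrame([
            {"criterion": "regime_and_polymorphic",
             "n_removed": gm_rare.n_variants - gm_f.n_variants,
             "n_remaining": gm_f.n_variants}
        ])],
        ignore_index=True,
    )

    genes = read_gene_bed(config.bed)
    gene_map = assign_variants_to_genes(gm_f, genes)

    if config.phenotypes is None:
        raise ConfigError("phenotype table path is required")
    pheno = pd.read_csv(config.phenotypes, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in pheno.columns:
        raise ConfigError("phenotype table needs a sample_id column")
    pheno = pheno.set_index("sample_id")
    return LoadedInputs(
        gm=gm_f, stats=variant_stats(gm_f), gene_map=gene_map,
        filter_report=report, pheno=pheno,
    )


def _trait_null(inputs: LoadedInputs, config: RunConfig, trait: str):
    """Null model for one trait on the complete-case sample subset."""
    cols = [trait, *config.covariates]
    missing_cols = [c for c in cols if c not in inputs.pheno.columns]
    if missing_cols:
        raise ConfigError(f"phenotype table lacks column(s) {missing_cols}")
    tab = inputs.pheno.reindex(inputs.gm.samples)[cols].apply(
        pd.to_numeric, errors="coerce"
    )
    complete = tab.notna().all(axis=1).to_numpy()
    n_dropped = int((~complete).sum())
    logger.info(
        "stage=trait_subset trait=%s n_in=%d n_complete=%d dropped=%d",
        trait, len(tab), int(complete.sum()), n_dropped,
    )
    rows = np.flatnonzero(complete)
    y = tab[trait].to_numpy(dtype=float)[rows]
    C = tab[list(config.covariates)].to_numpy(dtype=float)[rows]
    X = np.column_stack([np.ones(len(rows)), C])
    null = fit_null(y, X, column_names=["intercept", *config.covariates])
    return null, rows


def _test_sets(
    sets: list[VariantSet],
    inputs: LoadedInputs,
    null: NullModel,
    rows: np.ndarray,
    config: RunConfig,
    trait: str,
) -> pd.DataFrame:
    """SKAT-O over eligible sets for one trait; ineligible sets kept as rows."""
    maf = inputs.stats["maf"].to_numpy(dtype=float)
    records = []
    for vset in sets:
        rec = {
            "set": vset.label, "level": vset.level, "trait": trait,
            "n_variants": vset.n_variants, "eligible": vset.eligible,
            "p_skato": np.nan, "p_rho_0": np.nan, "p_rho_1": np.nan,
            "min_p_rho": np.nan,
        }
        if vset.eligible:
            idx = list(vset.indices)
            G = inputs.gm.dosage[np.ix_(rows, idx)]
            w = beta_weights(maf[idx], config.weights)
            try:
                res = skat_o(null, G, w, rho_grid=config.rho_grid,
                             label=vset.label)
            except Exception as exc:  # degenerate within the trait subset
                logger.warning(
                    "stage=test_sets set=%s trait=%s untestable: %s",
                    vset.label, trait, exc,
                )
                rec["eligible"] = False
            else:
                rec.update(
                    p_skato=res.p_skato, p_rho_0=res.p_skat,
                    p_rho_1=res.p_burden, min_p_rho=res.min_p_rho,
                )
        records.append(rec)
    return pd.DataFrame(records)


def _finalize(df: pd.DataFrame, alpha: float) -> tuple[pd.DataFrame, float, int]:
    n_eligible = int(df["eligible"].sum())
    if n_eligible == 0:
        logger.warning("stage=finalize no eligible sets; empty result")
        df["passes_bonferroni"] = False
        return df, np.nan, 0
    threshold = bonferroni_threshold(alpha, n_eligible)
    df["passes_bonferroni"] = df["eligible"] & (df["p_skato"] < threshold)
    return df, threshold, n_eligible


def _write_outputs(config: RunConfig, name: str, tables: dict[str, pd.DataFrame],
                   extra_manifest: dict):
    if config.out_dir is None:
        return
    config.out_dir.mkdir(parents=True, exist_ok=True)
    for fname, df in tables.items():
        df.to_csv(config.out_dir / fname, sep="\t", index=False,
                  float_format="%.10g")
    manifest = {
        "stage": name,
        "config": {
            k: (str(v) if isinstance(v, Path) else v)
            for k, v in asdict(config).items()
        },
        "versions": _library_versions(),
        **extra_manifest,
    }
    with open(config.out_dir / f"{name}_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True, default=str)


def _library_versions() -> dict[str, str]:
    import numpy, pandas, scipy

    return {
        "pathkat": __version__,
        "numpy": numpy.__version__,
        "scipy": scipy.__version__,
        "pandas": pandas.__version__,
    }


# ---------------------------------------------------------------------------


def run_discovery(config: RunConfig, inputs: LoadedInputs | None = None
                  ) -> pd.DataFrame:
    """Pathway-level discovery scan for every configured trait.

    Returns a table of (set, trait, n_variants, p_skato, per-rho endpoints,
    eligibility, passes_bonferroni); the Bonferroni threshold and the
    eligible count are stored in ``DataFrame.attrs``.
    """
    inputs = inputs or load_inputs(config)
    pathways = read_gmt(config.gmt)
    sets, elig = build_variant_sets(pathways, inputs.gene_map, "pathway")

    frames = []
    for trait in config.traits:
        null, rows = _trait_null(inputs, config, trait)
        frames.append(_test_sets(sets, inputs, null, rows, config, trait))
    df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    if len(df):
        df, threshold, n_eligible = _finalize(df, config.alpha)
    else:
        threshold, n_eligible = np.nan, 0
    df.attrs["bonferroni_threshold"] = threshold
    df.attrs["n_eligible"] = n_eligible
    logger.info(
        "stage=run_discovery n_sets=%d n_eligible=%d threshold=%.3g",
        len(sets), n_eligible, threshold if n_eligible else float("nan"),
    )
    _write_outputs(
        config, "discovery",
        {"pathway_results.tsv": df, "filter_report.tsv": inputs.filter_report,
         "eligibility.tsv": elig},
        {"bonferroni_threshold": threshold, "n_eligible": n_eligible},
    )
    return df


def run_gene_scan(config: RunConfig, target_pathway: str | None = None,
                  inputs: LoadedInputs | None = None) -> pd.DataFrame:
    """Genome-wide gene-level scan with a Manhattan-plot export.

    The export table carries (gene, chrom, midpoint, p, in_target_pathway)
    so the target pathway's genes can be highlighted.
    """
    inputs = inputs or load_inputs(config)
    sets, elig = build_variant_sets(None, inputs.gene_map, "gene")

    target_genes: set[str] = set()
    if target_pathway is not None:
        pathways = read_gmt(config.gmt)
        if target_pathway not in pathways:
            raise ConfigError(f"pathway {target_pathway!r} not in GMT")
        target_genes = pathways[target_pathway]

    frames = []
    for trait in config.traits:
        null, rows = _trait_null(inputs, config, trait)
        frames.append(_test_sets(sets, inputs, null, rows, config, trait))
    df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["set", "level", "trait", "n_variants", "eligible",
                 "p_skato", "p_rho_0", "p_rho_1", "min_p_rho"]
    )
    if len(df):
        df, threshold, n_eligible = _finalize(df, config.alpha)
    else:
        df["passes_bonferroni"] = pd.Series(dtype=bool)
        threshold, n_eligible = np.nan, 0
    df.attrs["bonferroni_threshold"] = threshold
    df.attrs["n_eligible"] = n_eligible

    # Manhattan export: gene midpoints from variant positions
    pos = inputs.gm.variants["pos"].to_numpy()
    chrom = inputs.gm.variants["chrom"].to_numpy()
    rows_out = []
    for rec in df.itertuples(index=False):
        idx = inputs.gene_map.get(rec.set, [])
        if not idx:
            continue
        rows_out.append({
            "gene": rec.set, "chrom": chrom[idx[0]],
            "midpoint": float(np.mean(pos[idx])),
            "trait": rec.trait, "p": rec.p_skato,
            "in_target_pathway": rec.set in target_genes,
        })
    manhattan = pd.DataFrame(rows_out, columns=[
        "gene", "chrom", "midpoint", "trait", "p", "in_target_pathway",
    ])
    _write_outputs(
        config, "gene_scan",
        {"gene_results.tsv": df, "manhattan.tsv": manhattan,
         "gene_eligibility.tsv": elig},
        {"bonferroni_threshold": threshold, "n_eligible": n_eligible,
         "target_pathway": target_pathway},
    )
    df.attrs["manhattan"] = manhattan
    return df


def run_replication(config: RunConfig, discovery_hits: list[str]
                    ) -> dict[str, pd.DataFrame]:
    """Replication of discovery hit pathways under imputation-era QC.

    Activates INFO >= 0.4 and HWE P > 5e-7 (unless already configured),
    re-tests each hit pathway, collapses the same variants per gene, and
    runs a single-variant scan over the hit pathways' variants.  An empty
    hit list yields empty tables.
    """
    cfg = config.replication()
    empty = {
        "pathways": pd.DataFrame(), "genes": pd.DataFrame(),
        "single_variants": pd.DataFrame(),
    }
    if not discovery_hits:
        logger.info("stage=run_replication no discovery hits; empty output")
        _write_outputs(cfg, "replication",
                       {f"replication_{k}.tsv": v for k, v in empty.items()},
                       {"hits": []})
        return empty

    inputs = load_inputs(cfg)
    pathways = read_gmt(cfg.gmt)
    missing = [h for h in discovery_hits if h not in pathways]
    if missing:
        raise ConfigError(f"discovery hit(s) not in GMT: {missing}")
    hit_pathways = {h: pathways[h] for h in discovery_hits}
    sets, _ = build_variant_sets(hit_pathways, inputs.gene_map, "pathway")

    hit_genes = sorted(set().union(*hit_pathways.values()))
    gene_map_hits = {
        g: inputs.gene_map[g] for g in hit_genes if g in inputs.gene_map
    }
    gene_sets, _ = build_variant_sets(None, gene_map_hits, "gene")
    hit_variant_idx = sorted(
        set().union(*[set(s.indices) for s in sets]) if sets else set()
    )

    path_frames, gene_frames, sv_frames = [], [], []
    for trait in cfg.traits:
        null, rows = _trait_null(inputs, cfg, trait)
        path_frames.append(_test_sets(sets, inputs, null, rows, cfg, trait))
        gene_frames.append(_test_sets(gene_sets, inputs, null, rows, cfg, trait))
        if hit_variant_idx:
            gm_sub = inputs.gm.subset_variants(hit_variant_idx)
            gm_sub = gm_sub.subset_samples(rows)
            sv = single_variant_scan(null, gm_sub)
            sv.insert(0, "trait", trait)
            sv_frames.append(sv)

    out = {
        "pathways": pd.concat(path_frames, ignore_index=True)
        if path_frames else pd.DataFrame(),
        "genes": pd.concat(gene_frames, ignore_index=True)
        if gene_frames else pd.DataFrame(),
        "single_variants": pd.concat(sv_frames, ignore_index=True)
        if sv_frames else pd.DataFrame(),
    }
    untestable = [
        s.label for s in sets if not s.eligible
    ]
    if untestable:
        logger.warning(
            "stage=run_replication untestable_hits=%s (<2 surviving variants)",
            untestable,
        )
    _write_outputs(cfg, "replication",
                   {f"replication_{k}.tsv": v for k, v in out.items()},
                   {"hits": list(discovery_hits), "untestable": untestable})
    return out


def run_permutations(config: RunConfig, labels: list[str], B: int | None = None,
                     inputs: LoadedInputs | None = None) -> pd.DataFrame:
    """Permutation validation for named pathway sets.

    Per-set seeds derive from the run seed and the set label, so results do
    not depend on iteration order.
    """
    inputs = inputs or load_inputs(config)
    B = B or config.permutations
    pathways = read_gmt(config.gmt)
    sets, _ = build_variant_sets(pathways, inputs.gene_map, "pathway")
    by_label = {s.label: s for s in sets}
    records = []
    for trait in config.traits:
        null, rows = _trait_null(inputs, config, trait)
        gm_rows = inputs.gm.subset_samples(rows)
        for label in labels:
            vset = by_label.get(label)
            if vset is None or not vset.eligible:
                logger.warning(
                    "stage=run_permutations set=%s ineligible_or_missing", label
                )
                continue
            res = permutation_test(
                vset, gm_rows, null.y, null.X, B,
                seed=derive_set_seed(config.seed, f"{trait}:{label}"),
                weights=config.weights, rho_grid=config.rho_grid,
            )
            records.append({
                "set": label, "trait": trait, "B": res.B,
                "observed_p": res.observed_p, "n_smaller": res.n_smaller,
                "empirical_p": res.empirical_p, "robust": res.robust,
                "seed": res.seed,
            })
    df = pd.DataFrame(records)
    _write_outputs(config, "permutation", {"permutation_results.tsv": df}, {})
    return df


def run_subnetworks(config: RunConfig, pathway: str, trait: str,
                    k_hubs: int = 3, min_score: float = 0.0,
                    inputs: LoadedInputs | None = None) -> pd.DataFrame:
    """Hub-subnetwork dissection of one pathway against one trait."""
    inputs = inputs or load_inputs(config)
    pathways = read_gmt(config.gmt)
    if pathway not in pathways:
        raise ConfigError(f"pathway {pathway!r} not in GMT")
    graph = read_edge_list(config.edges, min_score=min_score)
    genes = pathways[pathway]
    hubs = pathway_hubs(graph, genes, k=k_hubs)
    subnets = [hub_subnetwork(graph, h, genes) for h in hubs]

    null, rows = _trait_null(inputs, config, trait)
    gm_rows = inputs.gm.subset_samples(rows)
    results = test_subnetworks(
        subnets, inputs.gene_map, gm_rows, null,
        weights=config.weights, rho_grid=config.rho_grid,
    )
    records = []
    for sn, vset, res in results:
        records.append({
            "hub": sn.hub,
            "members": ",".join(sorted(sn.members)),
            "trait": trait,
            "n_variants": vset.n_variants,
            "eligible": res is not None,
            "p_skato": res.p_skato if res else np.nan,
            "p_rho_0": res.p_skat if res else np.nan,
            "p_rho_1": res.p_burden if res else np.nan,
        })
    df = pd.DataFrame(records)
    _write_outputs(config, "subnetworks", {"subnetwork_results.tsv": df},
                   {"pathway": pathway, "hubs": hubs})
    return df
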