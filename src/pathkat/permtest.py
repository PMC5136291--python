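"""Phenotype-shuffling permutation validation of kernel-test hits.

For each permutation the trait vector is randomly shuffled among
individuals (genotypes and covariates stay fixed), the null model is re-fit
on the shuffled trait and the full SKAT-O p-value is recomputed.  A hit is
*robust* when at most ``floor(10 B / 100000)`` permuted p-values fall
strictly below the observed one — the "no more than 10 in 100,000" rule,
scaled proportionally to the permutation count.

The empirical p-value uses the (n_smaller + 1) / (B + 1) correction; the
robustness decision uses the raw count.

Because genotypes and covariates are fixed, the per-rho null eigenvalues
and the omnibus conditioning structure are computed once and reused across
permutations (only the residuals and residual variance change), with
survival functions tabulated by monotone interpolation.  This is
numerically equivalent to a from-scratch recomputation per permutation.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass

import numpy as np

from .errors import ResourceError
from .geno_io import GenotypeMatrix
from .genesets import VariantSet
from .kernel_test import DEFAULT_RHO_GRID, SkatOTest, WeightSpec, beta_weights

logger = logging.getLogger("pathkat.permtest")

__all__ = [
    "PermutationResult",
    "permutation_test",
    "robustness_ceiling",
    "derive_set_seed",
]

MAX_PERMUTATIONS_DEFAULT = 1_000_000


def robustness_ceiling(n_permutations: int) -> int:
    """Largest tolerated count of smaller permuted p-values: floor(10 B / 1e5)."""
    return (10 * n_permutations) // 100_000


def derive_set_seed(master_seed: int, label: str) -> int:
    """Stable per-set seed from a master seed and the set label.

    Makes each set's permutation stream independent of iteration order.
    """
    ss = np.random.SeedSequence([int(master_seed), zlib.crc32(label.encode())])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass(frozen=True)
class PermutationResult:
    label: str
    B: int
    observed_p: float
    n_smaller: int
    empirical_p: float
    robust: bool
    seed: int


def _set_mafs(gm: GenotypeMatrix, indices) -> np.ndarray:
    D = gm.dosage[:, list(indices)]
    n_called = np.isfinite(D).sum(axis=0)
    f = np.nansum(D, axis=0) / (2.0 * n_called)
    return np.minimum(f, 1.0 - f)


def permutation_test(
    variant_set: VariantSet,
    gm: GenotypeMatrix,
    y,
    X,
    B: int,
    seed: int,
    weights: WeightSpec = WeightSpec(),
    rho_grid=DEFAULT_RHO_GRID,
    residual_permutation: bool = False,
    max_permutations: int = MAX_PERMUTATIONS_DEFAULT,
) -> PermutationResult:
    """Permutation validation of one variant set's SKAT-O association.

    ``residual_permutation=True`` shuffles null-model residuals around the
    fitted covariate means instead of raw trait values (preserving the
    trait-covariate link); the default follows the raw-phenotype shuffle.
    Fully reproducible given ``seed``.
    """
    if B < 1:
        raise ValueError("B must be at least 1")
    if B > max_permutations:
        raise ResourceError(
            f"B={B} exceeds the configured ceiling {max_permutations}; "
            "raise max_permutations to proceed"
        )
    y = np.asarray(y, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    G = gm.dosage[:, list(variant_set.indices)]
    w = beta_weights(_set_mafs(gm, variant_set.indices), weights)

    engine = SkatOTest(G, w, X, rho_grid=rho_grid, label=variant_set.label)
    engine.prepare_fast()
    observed_p = engine.test(y, fast=True).p_skato

    rng = np.random.default_rng(np.random.SeedSequence(int(seed)))
    if residual_permutation:
        Q, _ = np.linalg.qr(X)
        fitted = Q @ (Q.T @ y)
        resid0 = y - fitted

    n_smaller = 0
    for _ in range(B):
        if residual_permutation:
            y_perm = fitted + rng.permutation(resid0)
        else:
            y_perm = rng.permutation(y)
        p_perm = engine.test(y_perm, fast=True).p_skato
        if p_perm < observed_p:
            n_smaller += 1

    empirical_p = (n_smaller + 1) / (B + 1)
    robust = n_smaller <= robustness_ceiling(B)
    logger.info(
        "stage=permutation_test set=%s B=%d observed_p=%.3g n_smaller=%d robust=%s",
        variant_set.label, B, observed_p, n_smaller, robust,
    )
    return PermutationResult(
        label=variant_set.label, B=B, observed_p=float(observed_p),
        n_smaller=n_smaller, empirical_p=float(empirical_p),
        robust=bool(robust), seed=int(seed),
    )
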