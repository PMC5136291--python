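"""Quantitative-trait kernel association engine (SKAT, burden, SKAT-O).

The statistic family is indexed by ``rho`` in [0, 1].  With per-variant
scores ``S_j = g_j' r`` (``r`` the null-model residuals) and weights
``w_j``:

    Q_SKAT   = sum_j (w_j S_j)^2            (rho = 0)
    Q_burden = (sum_j w_j S_j)^2            (rho = 1)
    Q(rho)   = (1 - rho) Q_SKAT + rho Q_burden

Under the null, ``Q(rho)`` is a weighted sum of 1-df chi-squares whose
weights are the nonzero eigenvalues of
``sigma2 * R(rho)^{1/2} W G' P G W R(rho)^{1/2}`` with ``P`` the projector
off the covariate span and ``R(rho) = (1-rho) I + rho 11'``.  The combined
SKAT-O p-value takes the minimum p over a rho grid and accounts for the
grid search by one-dimensional integration over the shared burden-direction
component of the statistics.

Weights default to the Beta(1, 25) density of MAF (so rare variants are
up-weighted); pass ``WeightSpec(1, 1)`` for flat weights.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import integrate
from scipy.stats import beta as beta_dist
from scipy.stats import chi2 as chi2_dist
from scipy.stats import ncx2 as ncx2_dist
from scipy.stats import t as t_dist

from .errors import CollinearityError, DegenerateFitError, DegenerateSetError
from .geno_io import GenotypeMatrix
from .qforms import (
    P_FLOOR,
    SurvivalInterpolator,
    _liu_params,
    davies_pvalue,
    liu_quantile,
)

logger = logging.getLogger("pathkat.kernel_test")

__all__ = [
    "DEFAULT_RHO_GRID",
    "WeightSpec",
    "NullModel",
    "KernelTestResult",
    "fit_null",
    "beta_weights",
    "mean_impute",
    "q_statistic",
    "mixture_lambdas",
    "davies_pvalue",
    "skat_o",
    "SkatOTest",
    "single_variant_scan",
]

# canonical optimal-adjusted grid
DEFAULT_RHO_GRID = (0.0, 0.01, 0.04, 0.09, 0.16, 0.25, 0.5, 1.0)

# rho = 1 makes R(rho) rank one and the omnibus conditioning division
# (1 - rho) degenerate; values at or above _RHO_CAP are computed at the cap.
_RHO_CAP = 0.999

_EIG_REL_TOL = 1e-10


@dataclass(frozen=True)
class WeightSpec:
    """Beta-density MAF weighting: w_j = Beta(maf_j; a1, a2)."""

    a1: float = 1.0
    a2: float = 25.0

    def __post_init__(self):
        if self.a1 <= 0 or self.a2 <= 0:
            raise ValueError("Beta shape parameters must be positive")


@dataclass
class NullModel:
    """OLS fit of the trait on covariates; everything the score tests need."""

    y: np.ndarray
    X: np.ndarray
    alpha_hat: np.ndarray
    residuals: np.ndarray
    sigma2_hat: float
    _q_basis: np.ndarray = field(repr=False, default=None)

    @property
    def n(self) -> int:
        return self.y.shape[0]

    @property
    def k(self) -> int:
        return self.X.shape[1]

    def project(self, v: np.ndarray) -> np.ndarray:
        """v - X (X'X)^-1 X' v, for vectors or column-stacked matrices."""
        Q = self._q_basis
        return v - Q @ (Q.T @ v)


def fit_null(y, X, column_names=None) -> NullModel:
    """Ordinary least squares of the trait on the covariate matrix.

    ``X`` must include the intercept column.  Raises
    :class:`CollinearityError` naming the offending columns on rank
    deficiency and :class:`DegenerateFitError` on a (numerically) perfect
    fit.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-dimensional")
    n, k = X.shape
    if y.shape[0] != n:
        raise ValueError("y and X have inconsistent sample counts")
    if n <= k:
        raise ValueError(f"need n > k covariates, got n={n}, k={k}")
    if not (np.all(np.isfinite(y)) and np.all(np.isfinite(X))):
        raise ValueError("missing/non-finite values must be dropped upstream")

    if np.linalg.matrix_rank(X) < k:
        names = column_names or list(range(k))
        bad = []
        for j in range(k):
            others = np.delete(X, j, axis=1)
            if np.linalg.matrix_rank(others) == np.linalg.matrix_rank(X):
                bad.append(names[j])
        raise CollinearityError(bad or names)

    Q, R = np.linalg.qr(X)
    coef_rhs = Q.T @ y
    alpha = np.linalg.solve(R, coef_rhs)
    residuals = y - Q @ coef_rhs
    rss = float(residuals @ residuals)
    syy = float(np.sum((y - y.mean()) ** 2))
    if rss <= 1e-12 * max(syy, 1e-300):
        raise DegenerateFitError(
            "trait is (numerically) an exact linear function of the covariates"
        )
    sigma2 = rss / (n - k)
    return NullModel(
        y=y, X=X, alpha_hat=alpha, residuals=residuals,
        sigma2_hat=sigma2, _q_basis=Q,
    )


def beta_weights(mafs, spec: WeightSpec = WeightSpec()) -> np.ndarray:
    """Beta-density weights of MAF; defaults give w = 25 (1 - maf)^24."""
    maf = np.asarray(mafs, dtype=float).ravel()
    if np.any(~np.isfinite(maf)) or np.any(maf <= 0.0) or np.any(maf > 0.5):
        raise ValueError(
            "each maf must lie in (0, 0.5]; monomorphic variants must be "
            "pre-filtered"
        )
    return beta_dist.pdf(maf, spec.a1, spec.a2)


def mean_impute(G) -> np.ndarray:
    """Replace missing dosages with the per-variant mean dosage."""
    G = np.array(G, dtype=float, copy=True)
    if G.ndim == 1:
        G = G[:, None]
    mask = ~np.isfinite(G)
    if mask.any():
        with np.errstate(invalid="ignore"):
            col_means = np.nanmean(np.where(mask, np.nan, G), axis=0)
        col_means = np.where(np.isfinite(col_means), col_means, 0.0)
        G[mask] = np.broadcast_to(col_means, G.shape)[mask]
    return G


def _rho_half_transform(A: np.ndarray, rho: float) -> np.ndarray:
    """R(rho)^{1/2} A R(rho)^{1/2} using the closed-form square root.

    R(rho) = (1-rho) I + rho 11' has eigenvalues (1-rho) [multiplicity m-1]
    and (1-rho+m rho) [eigenvector 1], so
    R^{1/2} = c1 (I - J/m) + c2 J/m with J = 11'.
    """
    m = A.shape[0]
    if rho == 0.0:
        return A
    c1 = math.sqrt(1.0 - rho)
    c2 = math.sqrt(1.0 - rho + m * rho)
    d = (c2 - c1) / m
    row = A.sum(axis=0)
    total = row.sum()
    # (c1 I + d J) A (c1 I + d J)
    out = (c1 * c1) * A
    out += (c1 * d) * (row[None, :] + row[:, None])
    out += (d * d) * total
    return out


def _nonzero_eigvals(M: np.ndarray, scale: float | None = None) -> np.ndarray:
    """Nonzero spectrum of a PSD matrix; ``scale`` anchors the zero test
    (projection can leave only round-off residue, which must not count)."""
    lam = np.linalg.eigvalsh(M)
    lmax = lam.max(initial=0.0)
    floor = _EIG_REL_TOL * max(lmax, 0.0)
    if scale is not None:
        floor = max(floor, 1e-12 * scale)
    if lmax <= floor or lmax <= 0:
        raise DegenerateSetError("variant set carries no testable variation")
    return lam[lam > floor]


def q_statistic(null: NullModel, G, w, rho: float) -> float:
    """Q(rho) = (1-rho) * sum (w_j S_j)^2 + rho * (sum w_j S_j)^2."""
    if not (0.0 <= rho <= 1.0):
        raise ValueError("rho must lie in [0, 1]")
    G = mean_impute(G)
    if G.shape[1] == 0:
        raise DegenerateSetError("empty variant set")
    w = np.asarray(w, dtype=float).ravel()
    ws = w * (G.T @ null.residuals)
    return float((1.0 - rho) * np.sum(ws**2) + rho * np.sum(ws) ** 2)


def mixture_lambdas(null: NullModel, G, w, rho: float) -> np.ndarray:
    """Null-distribution eigenvalues of Q(rho): sigma2 * eig of Z(rho)'Z(rho).

    ``Z(rho) = P G diag(w) R(rho)^{1/2}`` with ``P`` the covariate projector.
    """
    if not (0.0 <= rho <= 1.0):
        raise ValueError("rho must lie in [0, 1]")
    G = mean_impute(G)
    if G.shape[1] == 0:
        raise DegenerateSetError("empty variant set")
    w = np.asarray(w, dtype=float).ravel()
    Zw = G * w
    scale = float(np.sum(Zw * Zw)) / G.shape[1]
    Z = null.project(Zw)
    A = Z.T @ Z
    if rho == 1.0:
        lam = np.array([float(A.sum())])
        if lam[0] <= 1e-12 * scale:
            raise DegenerateSetError("variant set carries no testable variation")
    else:
        lam = _nonzero_eigvals(_rho_half_transform(A, rho), scale=scale)
    return null.sigma2_hat * lam


@dataclass
class KernelTestResult:
    """Per-rho statistics plus the combined SKAT-O p-value."""

    label: str
    n_variants: int
    rho_grid: tuple[float, ...]
    rho_used: tuple[float, ...]  # grid after the 0.999 cap, as computed
    q_per_rho: np.ndarray
    p_per_rho: np.ndarray
    p_skato: float
    min_p_rho: float  # grid point attaining the minimum p
    lambda_diag: dict[float, np.ndarray]
    sigma2_hat: float
    converged: bool

    @property
    def p_skat(self) -> float:
        return float(self.p_per_rho[self.rho_grid.index(0.0)]) \
            if 0.0 in self.rho_grid else float("nan")

    @property
    def p_burden(self) -> float:
        return float(self.p_per_rho[self.rho_grid.index(1.0)]) \
            if 1.0 in self.rho_grid else float("nan")


class SkatOTest:
    """A variant set's kernel test with genotype-side structure precomputed.

    Everything that depends only on genotypes, weights and covariates (the
    projected weighted genotype matrix, per-rho eigenvalues, the omnibus
    conditioning decomposition) is computed once at construction; ``test``
    then evaluates the full SKAT-O p-value for any trait vector.  This makes
    phenotype permutation loops cheap while remaining numerically identical
    to a from-scratch recomputation, since only the residuals and the
    residual variance change.
    """

    def __init__(
        self,
        G,
        weights,
        X,
        rho_grid=DEFAULT_RHO_GRID,
        label: str = "",
        accuracy: float = 1e-9,
    ):
        G = mean_impute(G)
        n, m = G.shape
        if m == 0:
            raise DegenerateSetError("empty variant set")
        w = np.asarray(weights, dtype=float).ravel()
        if w.shape[0] != m:
            raise ValueError("weights not aligned to genotype columns")
        grid = tuple(float(r) for r in rho_grid)
        if any(not 0.0 <= r <= 1.0 for r in grid):
            raise ValueError("rho grid must lie in [0, 1]")
        self.label = label
        self.rho_grid = grid
        self.rho_used = tuple(min(r, _RHO_CAP) for r in grid)
        self.accuracy = accuracy
        self.n, self.m = n, m

        X = np.asarray(X, dtype=float)
        Qx, _ = np.linalg.qr(X)
        self._Qx = Qx
        self.k = X.shape[1]

        Zw = G * w
        scale = float(np.sum(Zw * Zw)) / m
        Z = Zw - Qx @ (Qx.T @ Zw)
        self._Z = Z
        A = Z.T @ Z
        self._lam_u = []  # unscaled eigenvalues per rho_used
        self._liu_u = []
        for r in self.rho_used:
            lam = _nonzero_eigvals(_rho_half_transform(A, r), scale=scale)
            self._lam_u.append(lam)
            self._liu_u.append(_liu_params(lam))

        # omnibus decomposition along the common burden direction
        zbar = Z.mean(axis=1)
        zz = float(zbar @ zbar)
        trace_scale = float(np.trace(A)) / m
        if m < 2 or zz <= 1e-12 * max(trace_scale, 1e-300):
            self._omnibus_ok = False
        else:
            self._omnibus_ok = True
            cof = (zbar @ Z) / zz
            Z2 = Z - np.outer(zbar, cof)
            A2 = Z2.T @ Z2
            lam_cond = np.linalg.eigvalsh(A2)
            lmax = lam_cond.max(initial=0.0)
            lam_cond = lam_cond[lam_cond > _EIG_REL_TOL * max(lmax, 1e-300)]
            if lam_cond.size == 0:
                # all variation lies along the burden direction
                self._omnibus_ok = False
            else:
                self._lam_cond = lam_cond
                self._mu_q = float(lam_cond.sum())
                var_remain = 4.0 * zz * float(cof @ A2 @ cof)
                var_q = 2.0 * float((lam_cond**2).sum()) + var_remain
                self._sd1 = math.sqrt(max(var_q - var_remain, 0.0) / var_q)
                self._tau = np.array(
                    [
                        (m * m * r + (1.0 - r) * float(np.sum(cof**2))) * zz
                        for r in self.rho_used
                    ]
                )
        self._fast_sf = None
        self._fast_cond = None

    # -- fast-path machinery -------------------------------------------------
    def prepare_fast(self, n_points: int = 257):
        """Tabulate the per-rho and conditional survival functions once."""
        if self._fast_sf is None:
            self._fast_sf = [
                SurvivalInterpolator(lam, n_points=n_points) for lam in self._lam_u
            ]
            if self._omnibus_ok:
                self._fast_cond = SurvivalInterpolator(
                    self._lam_cond, n_points=n_points
                )
        return self

    # -- evaluation ----------------------------------------------------------
    def _residuals(self, y):
        y = np.asarray(y, dtype=float).ravel()
        if y.shape[0] != self.n:
            raise ValueError("trait vector has wrong length")
        resid = y - self._Qx @ (self._Qx.T @ y)
        rss = float(resid @ resid)
        syy = float(np.sum((y - y.mean()) ** 2))
        if rss <= 1e-12 * max(syy, 1e-300):
            raise DegenerateFitError("perfect covariate fit; no residual variance")
        sigma2 = rss / (self.n - self.k)
        return resid, sigma2

    def _qmin_per_rho(self, t_min: float) -> np.ndarray:
        out = np.empty(len(self.rho_used))
        for i, pr in enumerate(self._liu_u):
            if pr.ncp > 0:
                x = float(ncx2_dist.isf(t_min, df=pr.df, nc=pr.ncp))
            else:
                x = float(chi2_dist.isf(t_min, df=pr.df))
            out[i] = (x - pr.mu_x) / pr.sigma_x * pr.sigma_q + pr.mu_q
        return out

    _X_HI = 60.0  # chi2_1 mass beyond: ~8e-15

    def _omnibus_p(self, t_min: float, fast: bool) -> tuple[float, bool]:
        """P(min over the grid of p_rho <= t_min) by conditioning on the
        shared burden component (1-df chi-square).

        The inner conditional CDF argument is a min of lines in the
        conditioning variable x; its envelope breakpoints and the crossing
        into the zero region are located exactly so the integrator never
        straddles a kink.
        """
        qmin = self._qmin_per_rho(t_min)
        one_minus_r = 1.0 - np.asarray(self.rho_used)
        a_lines = qmin / one_minus_r
        b_lines = self._tau / one_minus_r
        mu_q, sd1 = self._mu_q, self._sd1

        # F = 0 where sd1 * (hmin - mu_q) + mu_q <= 0
        h0 = mu_q * (1.0 - 1.0 / sd1) if sd1 > 0 else -np.inf
        with np.errstate(divide="ignore"):
            x_zero = np.where(b_lines > 0, (a_lines - h0) / b_lines, np.inf)
        x_hi = float(min(self._X_HI, max(np.min(x_zero), 0.0)))
        if x_hi <= 0.0:
            return 1.0, True

        # lower-envelope breakpoints: where the argmin line switches
        probe = np.linspace(0.0, x_hi, 1025)
        which = np.argmin(
            a_lines[:, None] - b_lines[:, None] * probe[None, :], axis=0
        )
        breaks = set()
        for pos in np.flatnonzero(np.diff(which)):
            i, j = which[pos], which[pos + 1]
            db = b_lines[j] - b_lines[i]
            if db != 0.0:
                x = (a_lines[j] - a_lines[i]) / db
                if 1e-12 < x < x_hi * (1 - 1e-12):
                    breaks.add(float(x))
        s_edges = np.sqrt(np.array(sorted({0.0, x_hi, *breaks})))

        def hmin(x):
            return np.min(a_lines[:, None] - b_lines[:, None] * x, axis=0)

        if fast:
            nodes, wts = np.polynomial.legendre.leggauss(24)
            mid = 0.5 * (s_edges[1:] + s_edges[:-1])
            half = 0.5 * (s_edges[1:] - s_edges[:-1])
            s = (mid[:, None] + half[:, None] * nodes[None, :]).ravel()
            x = s * s
            t_adj = sd1 * (hmin(x) - mu_q) + mu_q
            F = np.zeros_like(t_adj)
            pos = t_adj > 0
            F[pos] = 1.0 - self._fast_cond.sf(t_adj[pos])
            dens = math.sqrt(2.0 / math.pi) * np.exp(-0.5 * x)
            w_all = (half[:, None] * wts[None, :]).ravel()
            integral = float(np.sum(F * dens * w_all))
            return 1.0 - integral, True

        def integrand(s):
            x = s * s
            h = float(np.min(a_lines - b_lines * x))
            t_adj = sd1 * (h - mu_q) + mu_q
            if t_adj <= 0:
                return 0.0
            F = 1.0 - davies_pvalue(t_adj, self._lam_cond, accuracy=1e-6).pvalue
            return F * math.sqrt(2.0 / math.pi) * math.exp(-0.5 * x)

        interior = [float(s) for s in s_edges[1:-1]]
        out = integrate.quad(
            integrand, 0.0, float(s_edges[-1]),
            points=interior or None,
            epsabs=1e-8, epsrel=1e-6, limit=100, full_output=1,
        )
        integral = out[0]
        converged = len(out) < 4
        return 1.0 - integral, converged

    def test(self, y, fast: bool = False) -> KernelTestResult:
        """Full SKAT-O evaluation of this variant set against a trait vector."""
        if fast:
            self.prepare_fast()
        resid, sigma2 = self._residuals(y)
        ws = self._Z.T @ resid  # = w_j * S_j (residuals are X-orthogonal)
        q_s = float(np.sum(ws**2))
        q_b = float(np.sum(ws) ** 2)

        n_rho = len(self.rho_used)
        q_per_rho = np.empty(n_rho)
        p_per_rho = np.empty(n_rho)
        converged = True
        for i, r in enumerate(self.rho_used):
            q = (1.0 - r) * q_s + r * q_b
            q_per_rho[i] = q
            t = q / sigma2
            if fast:
                p_per_rho[i] = float(self._fast_sf[i](t))
            else:
                res = davies_pvalue(t, self._lam_u[i], accuracy=self.accuracy)
                p_per_rho[i] = res.pvalue
                converged &= res.converged
        i_min = int(np.argmin(p_per_rho))
        t_min = float(p_per_rho[i_min])

        if n_rho == 1:
            p_skato = t_min
        elif not self._omnibus_ok:
            p_skato = min(1.0, n_rho * t_min)
        else:
            # qmin inversion and integration on the sigma2-standardized scale
            p_o, ok = self._omnibus_p(t_min, fast)
            converged &= ok
            p_skato = p_o
        # the omnibus p is bounded by the min-p and its Bonferroni bound
        p_skato = min(max(p_skato, t_min, P_FLOOR), min(1.0, n_rho * t_min))

        lam_diag = {
            r: sigma2 * lam for r, lam in zip(self.rho_grid, self._lam_u)
        }
        return KernelTestResult(
            label=self.label,
            n_variants=self.m,
            rho_grid=self.rho_grid,
            rho_used=self.rho_used,
            q_per_rho=q_per_rho,
            p_per_rho=p_per_rho,
            p_skato=float(p_skato),
            min_p_rho=float(self.rho_grid[i_min]),
            lambda_diag=lam_diag,
            sigma2_hat=sigma2,
            converged=converged,
        )


def skat_o(
    null: NullModel,
    G,
    w,
    rho_grid=DEFAULT_RHO_GRID,
    label: str = "",
    accuracy: float = 1e-9,
) -> KernelTestResult:
    """SKAT-O for one variant set against a fitted null model."""
    engine = SkatOTest(G, w, null.X, rho_grid=rho_grid, label=label,
                       accuracy=accuracy)
    return engine.test(null.y)


def single_variant_scan(null: NullModel, gm: GenotypeMatrix) -> pd.DataFrame:
    """Per-variant OLS of the trait on dosage plus the null covariates.

    Effect, standard error and Wald (t) p-value per variant, computed by
    the Frisch-Waugh projection identity.  Monomorphic variants and variants
    collinear with the covariates are flagged with absent p-values.
    """
    G = mean_impute(gm.dosage)
    n, m = G.shape
    if n != null.n:
        raise ValueError("genotype matrix and null model sample counts differ")
    Gt = null.project(G)
    denom = np.sum(Gt**2, axis=0)
    num = Gt.T @ null.residuals
    raw_scale = np.sum(G**2, axis=0)

    mono = np.array([
        np.nanstd(gm.dosage[:, j]) == 0.0 for j in range(m)
    ])
    collinear = (~mono) & (denom <= 1e-10 * np.maximum(raw_scale, 1e-300))
    usable = ~(mono | collinear)

    beta = np.full(m, np.nan)
    se = np.full(m, np.nan)
    tstat = np.full(m, np.nan)
    pval = np.full(m, np.nan)
    df = null.n - null.k - 1
    rss_null = float(null.residuals @ null.residuals)
    with np.errstate(invalid="ignore", divide="ignore"):
        beta[usable] = num[usable] / denom[usable]
        rss_full = np.maximum(rss_null - num[usable] ** 2 / denom[usable], 0.0)
        sigma2 = rss_full / df
        se[usable] = np.sqrt(sigma2 / denom[usable])
        tstat[usable] = beta[usable] / se[usable]
        pval[usable] = 2.0 * t_dist.sf(np.abs(tstat[usable]), df)

    flag = np.where(mono, "monomorphic", np.where(collinear, "collinear", ""))
    out = gm.variants[["chrom", "pos", "ref", "alt"]].copy()
    out["beta"] = beta
    out["se"] = se
    out["t"] = tstat
    out["p"] = pval
    out["flag"] = flag
    return out
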