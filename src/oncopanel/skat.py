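"""Gene-based rare-variant association: burden, SKAT, and the optimal
unified test (SKAT-O), built from the score-test formulas.

Model
-----
For individuals i = 1..n with trait y and a gene's genotype matrix G
(n x m allele counts), variants are weighted by w_j = Beta-density(MAF_j;
a, b) — the convention that up-weights rare variants (a=1, b=25 by
default). With Z = G diag(w), null-model residuals r = y - mu, and score
vector s = Z' r, the family of statistics is

    Q_rho = (1 - rho) * s's  +  rho * (1's)^2 ,    rho in [0, 1],

which is the variance-component (SKAT) statistic at rho = 0 and the
squared weighted burden score at rho = 1. Under the null, s is
asymptotically N(0, K) with K = Z'VZ - Z'VX (X'VX)^-1 X'VZ (V the
per-individual variance of y given the null fit), so Q_rho is a mixture
of one-degree chi-squares with weights eig(R_rho^1/2 K R_rho^1/2). Tail
probabilities are computed by numerical inversion of the characteristic
function (Imhof/Davies-type integration, accuracy ~1e-9), with a
saddlepoint and then moment-matching (Liu-type) fallback; fallback use is
recorded in the result's method label.

SKAT-O takes the minimum p over a rho grid and converts it to one p-value
via the published one-dimensional integration that conditions on the
common component of the genotype matrix.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats

DEFAULT_RHO_GRID = (0.0, 0.01, 0.04, 0.09, 0.16, 0.25, 0.5, 1.0)


class NullModelError(ValueError):
    """Raised when the null trait model cannot be fitted."""


@dataclass
class SkatNullModel:
    """Fitted trait model under no genetic effect (intercept +/- covariates)."""

    trait_type: str
    y: np.ndarray
    mu: np.ndarray
    residuals: np.ndarray
    variance: np.ndarray           # per-individual Var(y_i) under the null
    design: np.ndarray             # n x p design matrix (includes intercept)
    dispersion: float | None = None

    @property
    def n(self) -> int:
        return len(self.y)


def fit_null(y, trait_type: str = "binary", covariates=None) -> SkatNullModel:
    """Fit the null model: logistic (IRLS) for binary, OLS for quantitative."""
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 10:
        raise NullModelError(f"need >= 10 individuals, got {n}")
    X = np.ones((n, 1))
    if covariates is not None:
        cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        if cov.shape[0] != n:
            cov = cov.T
        X = np.column_stack([X, cov])
    if trait_type == "binary":
        classes = np.unique(y)
        if not set(classes) <= {0.0, 1.0} or len(classes) < 2:
            raise NullModelError("binary trait must contain both classes coded 0/1")
        try:
            fit = sm.GLM(y, X, family=sm.families.Binomial()).fit(tol=1e-10, maxiter=200)
        except Exception as exc:  # separation / non-convergence
            raise NullModelError(f"logistic null model failed for binary trait: {exc}") from exc
        mu = np.asarray(fit.fittedvalues)
        if not fit.converged:
            raise NullModelError("logistic null model did not converge for binary trait")
        if np.any(mu < 1e-10) or np.any(mu > 1.0 - 1e-10):
            raise NullModelError("separation detected in logistic null model for binary trait")
        variance = mu * (1.0 - mu)
        return SkatNullModel("binary", y, mu, y - mu, variance, X)
    if trait_type == "quantitative":
        fit = sm.OLS(y, X).fit()
        mu = np.asarray(fit.fittedvalues)
        resid = y - mu
        dof = max(n - X.shape[1], 1)
        dispersion = float(resid @ resid / dof)
        variance = np.full(n, dispersion)
        return SkatNullModel("quantitative", y, mu, resid, variance, X, dispersion)
    raise ValueError(f"unknown trait_type {trait_type!r}")


def beta_weights(mafs, a: float = 1.0, b: float = 25.0) -> np.ndarray:
    """Beta-density MAF weights; strictly decreasing on (0, 0.5) for a=1, b=25."""
    mafs = np.asarray(mafs, dtype=float)
    if np.any(mafs < 0.0) or np.any(mafs > 1.0):
        raise ValueError("MAFs must lie in [0, 1]")
    return stats.beta.pdf(mafs, a, b)


# ---------------------------------------------------------------------------
# tail probability of a weighted chi-square mixture
# ---------------------------------------------------------------------------

_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(15)


def _imhof_sf(q: float, lambdas: np.ndarray, acc: float = 1e-6,
              max_panels: int = 30_000) -> tuple[float, float]:
    """P(sum lambda_j chi2_1 > q) by Imhof's characteristic-function inversion.

    The oscillatory integrand sin(theta(u)) / (u rho(u)) is integrated with
    a 15-point Gauss-Legendre rule per oscillation period (vectorized), up
    to a truncation point where the enveloped oscillation bound drops below
    ``acc``; the returned second element is the truncation error bound.
    """
    scale = lambdas.max()
    lam = lambdas / scale
    q = q / scale

    def log_env(u):
        return -np.log(u) - 0.25 * np.log1p((lam[:, None] * u) ** 2).sum(axis=0)

    # truncation point: cycle-cancellation bound (4/q) * envelope(U) <= acc * pi
    target = np.log(acc * np.pi * q / 4.0)
    upper = 16.0 / q + 4.0
    while log_env(np.array([upper]))[0] > target and upper < 1e9:
        upper *= 2.0
    width = min(4.0 * np.pi / q, 1.0)
    n_panels = int(min(np.ceil(upper / width), max_panels))
    edges = np.linspace(0.0, n_panels * width, n_panels + 1)
    half = width / 2.0
    u = (edges[:-1, None] + half) + half * _GL_NODES[None, :]
    u = u.ravel()
    theta = 0.5 * np.arctan(lam[:, None] * u).sum(axis=0) - 0.5 * q * u
    log_rho = 0.25 * np.log1p((lam[:, None] * u) ** 2).sum(axis=0)
    vals = np.sin(theta) * np.exp(-np.log(u) - log_rho)
    integral = half * float((vals.reshape(n_panels, 15) @ _GL_WEIGHTS).sum())
    trunc_err = 4.0 / (q * np.pi) * float(np.exp(log_env(np.array([edges[-1]]))[0]))
    return 0.5 + integral / np.pi, trunc_err


def _saddlepoint_sf(q: float, lambdas: np.ndarray) -> float:
    """Kuonen's saddlepoint approximation to the mixture tail probability."""
    lam = lambdas
    mean = lam.sum()
    if abs(q - mean) < 1e-10 * max(mean, 1.0):
        return 0.5

    def kprime_minus_q(t):
        return np.sum(lam / (1.0 - 2.0 * t * lam)) - q

    upper = 1.0 / (2.0 * lam.max()) - 1e-12
    lower = -1e4 / max(mean, 1.0)
    try:
        t = optimize.brentq(kprime_minus_q, lower, upper, xtol=1e-14)
    except ValueError:
        return np.nan
    k = -0.5 * np.sum(np.log1p(-2.0 * t * lam))
    k2 = 2.0 * np.sum(lam**2 / (1.0 - 2.0 * t * lam) ** 2)
    w = np.sign(t) * np.sqrt(max(2.0 * (t * q - k), 0.0))
    v = t * np.sqrt(k2)
    if w == 0.0 or v == 0.0:
        return 0.5
    return float(stats.norm.sf(w + np.log(v / w) / w))


def _liu_params(lambdas: np.ndarray) -> dict:
    """Moment-matched noncentral chi-square parameters (modified Liu et al.)."""
    c1, c2 = lambdas.sum(), (lambdas**2).sum()
    c3, c4 = (lambdas**3).sum(), (lambdas**4).sum()
    s1 = c3 / c2**1.5
    s2 = c4 / c2**2
    if s1**2 > s2:
        a = 1.0 / (s1 - np.sqrt(s1**2 - s2))
        delta = s1 * a**3 - a**2
        df = a**2 - 2.0 * delta
    else:
        delta = 0.0
        df = 1.0 / s2
        a = np.sqrt(df)
    return {"mu_q": c1, "sigma_q": np.sqrt(2.0 * c2), "df": df, "delta": delta,
            "mu_x": df + delta, "sigma_x": np.sqrt(2.0) * a}


def _liu_sf(q: float, lambdas: np.ndarray) -> float:
    p = _liu_params(lambdas)
    t_star = (q - p["mu_q"]) / p["sigma_q"]
    x = t_star * p["sigma_x"] + p["mu_x"]
    if p["delta"] > 0:
        return float(stats.ncx2.sf(x, df=p["df"], nc=p["delta"]))
    return float(stats.chi2.sf(x, df=p["df"]))


def _liu_quantile(prob_sf: float, lambdas: np.ndarray) -> float:
    """Upper quantile q with P(Q > q) = prob_sf under the Liu approximation."""
    p = _liu_params(lambdas)
    if p["delta"] > 0:
        x = stats.ncx2.isf(prob_sf, df=p["df"], nc=p["delta"])
    else:
        x = stats.chi2.isf(prob_sf, df=p["df"])
    return (x - p["mu_x"]) / p["sigma_x"] * p["sigma_q"] + p["mu_q"]


def chi2_mixture_sf(q: float, lambdas, acc: float = 1e-9) -> tuple[float, str]:
    """Tail probability of sum lambda_j chi2_1; returns (p, method used)."""
    lam = np.asarray(lambdas, dtype=float)
    lam = lam[lam > max(lam.max(initial=0.0), 0.0) * 1e-12]
    if lam.size == 0:
        return 1.0, "degenerate"
    if q <= 0:
        return 1.0, "exact"
    if lam.size == 1:
        return float(stats.chi2.sf(q / lam[0], df=1)), "exact"
    p, err = _imhof_sf(q, lam, max(acc, 1e-8))
    if np.isfinite(p) and p > max(1e-5, 10.0 * err) and p <= 1.0 + 1e-9:
        return float(min(p, 1.0)), "davies"
    # deep tail (or inversion failed): the saddlepoint is sharper there
    sp = _saddlepoint_sf(q, lam)
    if np.isfinite(sp) and 0.0 < sp <= 1.0:
        return sp, "saddlepoint"
    return _liu_sf(q, lam), "liu"


# ---------------------------------------------------------------------------
# SKAT-O
# ---------------------------------------------------------------------------

@dataclass
class SkatGeneInput:
    """One gene's genotypes with per-variant MAFs and weights."""

    genotypes: np.ndarray
    mafs: np.ndarray
    weights: np.ndarray

    @classmethod
    def from_genotypes(cls, genotypes, weights_beta: tuple[float, float] = (1.0, 25.0)):
        g = np.asarray(genotypes, dtype=float)
        if g.ndim != 2:
            raise ValueError("genotype matrix must be 2-D (individuals x variants)")
        mafs = g.sum(axis=0) / (2.0 * g.shape[0])
        mafs = np.minimum(mafs, 1.0 - mafs)
        return cls(g, mafs, beta_weights(mafs, *weights_beta))

    def validate(self, null: SkatNullModel) -> None:
        if self.genotypes.shape[0] != null.n:
            raise ValueError(
                f"genotypes have {self.genotypes.shape[0]} individuals, "
                f"null model has {null.n}")
        if self.genotypes.shape[1] != len(self.weights) or len(self.weights) != len(self.mafs):
            raise ValueError("weights/mafs inconsistent with genotype columns")
        if not np.all(np.isfinite(self.weights)) or np.any(self.weights < 0):
            raise ValueError("weights must be finite and non-negative")


@dataclass
class SkatOResult:
    gene: str
    p_value: float
    per_rho_p: dict[float, float] = field(default_factory=dict)
    best_rho: float = 0.0
    n_marker_all: int = 0
    n_marker_test: int = 0
    mac: int = 0
    m_carriers: int = 0
    method_label: str = "skat-o"


def _project_weighted(Z: np.ndarray, null: SkatNullModel) -> np.ndarray:
    """V^1/2 (Z - X (X'VX)^-1 X'VZ): the matrix whose Gram is Cov(score)."""
    v = null.variance
    X = null.design
    sv = np.sqrt(v)
    XtVX = X.T @ (v[:, None] * X)
    coef = np.linalg.solve(XtVX, X.T @ (v[:, None] * Z))
    return sv[:, None] * (Z - X @ coef)


def _rho_half(rho: float, m: int) -> np.ndarray:
    """Symmetric square root of R_rho = (1-rho) I + rho 11'."""
    base = np.sqrt(1.0 - rho)
    spike = (np.sqrt(1.0 - rho + m * rho) - base) / m
    return base * np.eye(m) + spike * np.ones((m, m))


def _positive_eigvals(mat: np.ndarray) -> np.ndarray:
    lam = np.linalg.eigvalsh((mat + mat.T) / 2.0)
    lam = lam[lam > max(lam.max(initial=0.0), 0.0) * 1e-10]
    return lam[::-1]


def skat_o_test(gene_input: SkatGeneInput | np.ndarray, null: SkatNullModel,
                rho_grid=DEFAULT_RHO_GRID, gene: str = "", acc: float = 1e-9) -> SkatOResult:
    """SKAT-O for one gene. rho=0 reduces exactly to SKAT, rho=1 to the
    weighted burden score test; the combined p comes from the minimum-p
    statistic over the grid via one-dimensional integration."""
    if not isinstance(gene_input, SkatGeneInput):
        gene_input = SkatGeneInput.from_genotypes(gene_input)
    gene_input.validate(null)
    G, w = gene_input.genotypes, gene_input.weights
    n, m = G.shape
    if m < 1:
        raise ValueError("need at least one variant")
    rho_grid = tuple(float(r) for r in rho_grid)
    mac = int(round(G.sum()))
    m_carriers = int((G.sum(axis=1) > 0).sum())
    base = SkatOResult(gene=gene, p_value=1.0, per_rho_p={r: 1.0 for r in rho_grid},
                       best_rho=rho_grid[0], n_marker_all=m, n_marker_test=m,
                       mac=mac, m_carriers=m_carriers)
    if mac == 0:
        warnings.warn(f"gene {gene or '<unnamed>'}: all-zero genotype matrix; p = 1",
                      stacklevel=2)
        base.method_label = "degenerate"
        return base

    Z = G * w
    s = Z.T @ null.residuals
    Z1 = _project_weighted(Z, null)
    K = Z1.T @ Z1
    if not np.any(np.diag(K) > 0):
        base.method_label = "degenerate"
        return base

    per_rho_p: dict[float, float] = {}
    per_rho_lam: dict[float, np.ndarray] = {}
    methods = set()
    ss, s_sum = float(s @ s), float(s.sum())
    for rho in rho_grid:
        q = (1.0 - rho) * ss + rho * s_sum**2
        rh = _rho_half(rho, m)
        lam = _positive_eigvals(rh @ K @ rh)
        per_rho_lam[rho] = lam
        p, method = chi2_mixture_sf(q, lam, acc)
        per_rho_p[rho] = p
        methods.add(method)

    best_rho = min(per_rho_p, key=lambda r: (per_rho_p[r], r))
    p_min = per_rho_p[best_rho]
    label = "+".join(sorted(methods))
    if m == 1 or len(rho_grid) == 1:
        return SkatOResult(gene, p_min, per_rho_p, best_rho, m, m, mac, m_carriers,
                           f"single:{label}")
    p_comb = _skat_o_combine(Z1, per_rho_p, per_rho_lam, rho_grid)
    if p_comb is None:
        p_comb = min(1.0, p_min * len(rho_grid))
        label += "+bonferroni"
    p_comb = float(np.clip(p_comb, p_min, min(1.0, p_min * len(rho_grid))))
    return SkatOResult(gene, p_comb, per_rho_p, best_rho, m, m, mac, m_carriers,
                       f"skat-o:{label}")


def _skat_o_combine(Z1: np.ndarray, per_rho_p: dict[float, float],
                    per_rho_lam: dict[float, np.ndarray], rho_grid) -> float | None:
    """Minimum-p combination over the rho grid (one-dimensional integration).

    Decomposes the projected genotypes into their column-mean direction
    (the burden component, a scaled chi2_1) and the remainder (a
    chi-square mixture); conditioning on the former reduces the joint
    survival probability to a single integral over chi2_1.
    """
    n, m = Z1.shape
    p_min = min(per_rho_p.values())
    rho_adj = np.minimum(np.asarray(rho_grid, dtype=float), 0.999)

    z_mean = Z1.mean(axis=1)
    zbar2 = float(z_mean @ z_mean)
    if zbar2 <= 0:
        return None
    cof = (z_mean @ Z1) / zbar2
    Zi1 = np.outer(z_mean, cof)
    Zi2 = Z1 - Zi1
    W22 = Zi2.T @ Zi2
    lam = _positive_eigvals(W22)
    if lam.size == 0:
        return None
    var_remain = 4.0 * float(np.sum((Zi1.T @ Zi1) * W22))
    mu_q = lam.sum()
    var_q = 2.0 * (lam**2).sum() + var_remain
    tau = (m**2 * rho_adj + float(cof @ cof) * (1.0 - rho_adj)) * zbar2

    # per-rho upper quantiles of Q_rho at p_min (moment-matched inversion)
    q_rho = np.array([_liu_quantile(p_min, per_rho_lam[rho]) for rho in rho_grid])
    sd_ratio = np.sqrt(max(var_q - var_remain, 0.0)) / np.sqrt(var_q)
    lam_sum_cap = lam.sum() * 1e4

    def conditional_cdf(x: float) -> float:
        qmin = np.min((q_rho - tau * x) / (1.0 - rho_adj))
        if qmin > lam_sum_cap:
            return 1.0
        q_std = (qmin - mu_q) * sd_ratio + mu_q
        surv, _ = chi2_mixture_sf(q_std, lam, acc=1e-6)
        return 1.0 - surv

    # integrate F(x) dchi2_1(x) over x in (0, 40); substituting x = t^2 turns
    # the chi2_1 density singularity into the smooth sqrt(2/pi) exp(-t^2/2)
    nodes, weights = np.polynomial.legendre.leggauss(64)
    t_hi = np.sqrt(40.0)
    t = 0.5 * t_hi * (nodes + 1.0)
    w = 0.5 * t_hi * weights
    try:
        vals = np.array([conditional_cdf(ti**2) for ti in t])
    except Exception:
        return None
    val = float(np.sum(w * vals * np.sqrt(2.0 / np.pi) * np.exp(-t**2 / 2.0)))
    p = 1.0 - val
    if not np.isfinite(p):
        return None
    return p


def burden_test(gene_input: SkatGeneInput | np.ndarray, null: SkatNullModel,
                gene: str = "") -> SkatOResult:
    """Weighted burden score test (the rho = 1 member of the family)."""
    return skat_o_test(gene_input, null, rho_grid=(1.0,), gene=gene)


def skat_test(gene_input: SkatGeneInput | np.ndarray, null: SkatNullModel,
              gene: str = "") -> SkatOResult:
    """Variance-component SKAT (the rho = 0 member of the family)."""
    return skat_o_test(gene_input, null, rho_grid=(0.0,), gene=gene)


def _permutation_p(G: np.ndarray, w: np.ndarray, null: SkatNullModel,
                   rho_grid, n_permutations: int, seed: int) -> tuple[float, float]:
    """Permutation p for the min-p statistic, using the fast moment-matched
    per-rho tails for both the observed and permuted statistics. Returns
    (p, minimum achievable p)."""
    rng = np.random.default_rng(seed)
    Z = G * w
    Z1 = _project_weighted(Z, null)
    K = Z1.T @ Z1
    m = G.shape[1]
    lam_by_rho = []
    for rho in rho_grid:
        rh = _rho_half(float(rho), m)
        lam_by_rho.append(_positive_eigvals(rh @ K @ rh))

    def min_p(resid: np.ndarray) -> float:
        s = Z.T @ resid
        ss, s_sum = float(s @ s), float(s.sum())
        best = 1.0
        for rho, lam in zip(rho_grid, lam_by_rho):
            q = (1.0 - rho) * ss + rho * s_sum**2
            best = min(best, _liu_sf(q, lam) if lam.size else 1.0)
        return best

    observed = min_p(null.residuals)
    hits = 1
    for _ in range(n_permutations):
        perm = rng.permutation(null.n)
        if min_p(null.residuals[perm]) <= observed:
            hits += 1
    return hits / (n_permutations + 1), 1.0 / (n_permutations + 1)


def skat_o_screen(classified: pd.DataFrame, calls: pd.DataFrame, patients: pd.DataFrame,
                  trait_axis: str, weights_beta: tuple[float, float] = (1.0, 25.0),
                  rho_grid=DEFAULT_RHO_GRID, n_tests: int = 409, alpha: float = 0.05,
                  n_permutations: int = 0, seed: int = 0,
                  min_p_asymptotic: float = 0.0) -> pd.DataFrame:
    """Per-gene SKAT-O screen against a dichotomized clinicopathological axis.

    Carrier status is encoded as one minor-allele copy (tumor-only data
    has no genotypes). Common variants are not excluded — they only
    receive lower weight — so ``n_marker_test`` equals ``n_marker_all``
    unless a variant has no carriers among the analyzed samples.
    Significance is flagged at the Bonferroni threshold ``alpha/n_tests``.
    When ``n_permutations`` > 0, a permutation p-value is computed as a
    small-sample safeguard and recorded alongside.
    """
    from .filtration import KEY, quality_filter
    from .profiling import dichotomize

    case = dichotomize(patients, trait_axis).dropna()
    if case.nunique() < 2:
        raise NullModelError(f"axis {trait_axis!r} has a single level in this cohort")
    sample_ids = list(case.index.astype(str))
    y = case.astype(bool).astype(float).to_numpy()
    null = fit_null(y, "binary")

    passing = quality_filter(calls)
    eligible = classified[classified["passed_quality"].astype(bool)
                          & ~classified["excluded_common"].astype(bool)]
    pairs = passing.merge(eligible[KEY + ["gene"]], on=KEY, how="inner")
    pairs = pairs[pairs["sample_id"].astype(str).isin(sample_ids)]
    sample_pos = {sid: i for i, sid in enumerate(sample_ids)}

    rows = []
    for gene, sub in pairs.groupby("gene", sort=True):
        variant_keys = sorted(set(map(tuple, sub[KEY].to_numpy())))
        n_all = int(eligible[eligible["gene"] == gene][KEY].drop_duplicates().shape[0])
        G = np.zeros((len(sample_ids), len(variant_keys)))
        col = {k: j for j, k in enumerate(variant_keys)}
        for row in sub.itertuples(index=False):
            G[sample_pos[str(row.sample_id)], col[(row.chrom, row.pos, row.ref, row.alt)]] = 1.0
        gi = SkatGeneInput.from_genotypes(G, weights_beta)
        res = skat_o_test(gi, null, rho_grid=rho_grid, gene=str(gene))
        perm_p, map_p = (np.nan, np.nan)
        if n_permutations > 0 and (min_p_asymptotic <= 0 or res.p_value < min_p_asymptotic):
            gene_seed = (seed + zlib.crc32(str(gene).encode())) % 2**31
            perm_p, map_p = _permutation_p(G, gi.weights, null, rho_grid,
                                           n_permutations, gene_seed)
        rows.append({
            "SetID": str(gene), "p_value": res.p_value,
            "n_marker_all": n_all, "n_marker_test": res.n_marker_test,
            "mac": res.mac, "m": res.m_carriers,
            "best_rho": res.best_rho, "method": res.method_label,
            "perm_p": perm_p, "perm_min_achievable_p": map_p,
            "significant": res.p_value < bonferroni(alpha, n_tests),
        })
    out = pd.DataFrame(rows, columns=[
        "SetID", "p_value", "n_marker_all", "n_marker_test", "mac", "m",
        "best_rho", "method", "perm_p", "perm_min_achievable_p", "significant",
    ])
    return out.sort_values(["p_value", "SetID"], ignore_index=True)


def bonferroni(alpha: float, m: int) -> float:
    from .association import bonferroni_threshold

    return bonferroni_threshold(alpha, m)
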