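"""Cohort association statistics, implemented from their definitions.

* Fisher's exact test (two-sided by probability ordering): the p-value is
  the sum of hypergeometric probabilities, over all 2x2 tables with the
  observed margins, of tables no more probable than the observed one
  (relative tolerance 1e-7 on the probability comparison — the convention
  of the widely used implementations).
* Pearson correlation of binary incidence vectors, which coincides with
  the phi coefficient of the 2x2 cross-table; two-sided p from the exact
  t transform with n-2 degrees of freedom.
* Minor allele frequency and the exact conditional Hardy-Weinberg test
  (enumeration of heterozygote counts given the allele counts, summing
  outcomes no more probable than the observed).
* Bonferroni threshold alpha / m.

For tumor-only presence/absence data there are no true genotypes: each
carrier is encoded as heterozygous (one minor-allele copy) and
non-carriers as zero — a stated convention mirroring what a PLINK run on
presence/absence calls would see, not a biological claim.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .profiling import AXIS_LEVELS, dichotomize

_P_FLOOR = 1e-300


def fisher_exact_2x2(table) -> tuple[float, float]:
    """Two-sided Fisher's exact test on a 2x2 count table.

    Returns ``(odds_ratio, p)``. The odds ratio is the sample odds ratio
    ``ad/bc`` (``inf`` when ``bc`` is zero with ``ad`` positive, NaN when a
    margin is empty). With an empty margin the table carries no
    information and p is 1.
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {t.shape}")
    if np.any(t < 0) or not np.issubdtype(t.dtype, np.integer) and np.any(t != np.floor(t)):
        raise ValueError("table entries must be non-negative integers")
    a, b = int(t[0, 0]), int(t[0, 1])
    c, d = int(t[1, 0]), int(t[1, 1])
    row1, col1, n = a + b, a + c, a + b + c + d
    if min(row1, col1, n - row1, n - col1) == 0 or n == 0:
        if b * c == 0 and a * d > 0:
            return (np.inf, 1.0)
        return (np.nan if a * d == 0 else a * d / (b * c), 1.0)
    odds = np.inf if b * c == 0 else (a * d) / (b * c)
    lo, hi = max(0, col1 - (n - row1)), min(row1, col1)
    support = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(support, n, row1, col1)
    p_obs = pmf[a - lo]
    p = float(pmf[pmf <= p_obs * (1.0 + 1e-7)].sum())
    return odds, min(p, 1.0)


def chi2_2x2(table, correction: bool = False) -> tuple[float, float]:
    """Pearson chi-square test on a 2x2 table (no continuity correction by default)."""
    t = np.asarray(table, dtype=float)
    if t.sum() == 0 or (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        return 0.0, 1.0
    stat, p, _, _ = stats.chi2_contingency(t, correction=correction)
    return float(stat), float(p)


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Family-wise significance threshold alpha / m."""
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha must lie in (0,1), got {alpha}")
    if m < 1:
        raise ValueError(f"m must be >= 1, got {m}")
    return alpha / m


def round_to_sig(x: float, digits: int = 1) -> float:
    """Round to ``digits`` significant figures (0.05/409 -> 0.0001)."""
    if x == 0 or not np.isfinite(x):
        return x
    from math import floor, log10
    return round(x, -int(floor(log10(abs(x)))) + digits - 1)


@dataclass
class CorrelationMatrix:
    """Pairwise gene co-occurrence correlation with significance stars."""

    genes: list[str]
    r: pd.DataFrame
    p: pd.DataFrame
    n: int
    excluded: list[str] = field(default_factory=list)
    star_levels: tuple[float, ...] = (0.05, 0.01, 0.001)

    def stars(self) -> pd.DataFrame:
        def star(p: float) -> str:
            if not np.isfinite(p):
                return ""
            return "***" if p < 0.001 else "**" if p < 0.01 else "*" if p < 0.05 else ""
        out = self.p.map(star)
        np.fill_diagonal(out.values, "")
        return out


def pearson_binary_correlation(matrix: pd.DataFrame) -> CorrelationMatrix:
    """Pearson correlation between the rows of a binary gene x sample matrix.

    Equals the phi coefficient of each pair's 2x2 cross-table. Genes with
    zero variance across samples are excluded and listed. Two-sided p from
    ``t = r sqrt((n-2)/(1-r^2))`` against Student's t with n-2 df.
    """
    n = matrix.shape[1]
    if n < 3:
        raise ValueError(f"need >= 3 samples, got {n}")
    values = matrix.to_numpy(dtype=float)
    variable = values.std(axis=1) > 0
    excluded = [str(g) for g in matrix.index[~variable]]
    kept = matrix.index[variable].astype(str).tolist()
    x = values[variable]
    if len(kept) == 0:
        empty = pd.DataFrame(index=kept, columns=kept, dtype=float)
        return CorrelationMatrix(kept, empty, empty.copy(), n, excluded)
    r = np.atleast_2d(np.corrcoef(x))
    r = np.clip(r, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r**2, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.maximum(p, _P_FLOOR)
    np.fill_diagonal(p, 1.0)
    r_df = pd.DataFrame(r, index=kept, columns=kept)
    p_df = pd.DataFrame(p, index=kept, columns=kept)
    return CorrelationMatrix(kept, r_df, p_df, n, excluded)


def maf_and_hwe(genotypes) -> tuple[float, float]:
    """Minor allele frequency and exact Hardy-Weinberg p for one variant.

    ``genotypes`` are per-sample minor-allele copy counts in {0,1,2};
    NaN / negative entries are treated as missing. Returns ``(nan, nan)``
    when everything is missing. The HWE p-value is the exact conditional
    test: enumerate all heterozygote counts compatible with the observed
    allele counts and sum the probabilities of outcomes no more probable
    than the observed one. Invariant to swapping the allele labels.
    """
    g = np.asarray(genotypes, dtype=float)
    g = g[np.isfinite(g) & (g >= 0)]
    if g.size == 0:
        return float("nan"), float("nan")
    if not np.all(np.isin(g, (0.0, 1.0, 2.0))):
        raise ValueError("genotypes must be allele copy counts in {0,1,2}")
    n = g.size
    n_alt = int(g.sum())
    p_alt = n_alt / (2 * n)
    maf = min(p_alt, 1.0 - p_alt)
    n_rare = min(n_alt, 2 * n - n_alt)
    obs_het = int((g == 1).sum())
    if n_rare == 0:
        return maf, 1.0
    probs = _hwe_het_distribution(n, n_rare)
    p_obs = probs.get(obs_het, 0.0)
    p = sum(v for v in probs.values() if v <= p_obs * (1.0 + 1e-12))
    return maf, float(min(p, 1.0))


def _hwe_het_distribution(n: int, n_rare: int) -> dict[int, float]:
    """P(#het = h | n diploid samples, n_rare rare alleles) for all feasible h."""
    from scipy.special import gammaln

    def logfact(k):
        return gammaln(k + 1)

    hets = range(n_rare % 2, n_rare + 1, 2)
    logs = {}
    for h in hets:
        hom_r = (n_rare - h) // 2
        hom_c = n - h - hom_r
        if hom_c < 0:
            continue
        logs[h] = (
            logfact(n) - logfact(h) - logfact(hom_r) - logfact(hom_c)
            + h * np.log(2.0)
            + logfact(n_rare) + logfact(2 * n - n_rare) - logfact(2 * n)
        )
    return {h: float(np.exp(v)) for h, v in logs.items()}


def carrier_genotypes(matrix_row) -> np.ndarray:
    """Presence/absence incidence encoded as heterozygous genotypes (0/1 copies)."""
    return np.asarray(matrix_row, dtype=float)


def variant_maf_hwe_table(classified: pd.DataFrame, calls: pd.DataFrame,
                          n_samples: int | None = None) -> pd.DataFrame:
    """Per-variant cohort MAF and HWE p under the carrier-as-het encoding."""
    from .filtration import KEY, quality_filter

    passing = quality_filter(calls)
    if n_samples is None:
        n_samples = int(calls["sample_id"].nunique()) if len(calls) else 0
    carriers = passing.groupby(KEY)["sample_id"].nunique()
    rows = []
    for key, n_car in carriers.items():
        geno = np.concatenate([np.ones(int(n_car)), np.zeros(n_samples - int(n_car))])
        maf, hwe_p = maf_and_hwe(geno)
        rows.append(dict(zip(KEY, key)) | {"n_carriers": int(n_car), "maf": maf, "hwe_p": hwe_p})
    return pd.DataFrame(rows, columns=KEY + ["n_carriers", "maf", "hwe_p"])


def association_screen(matrix: pd.DataFrame, patients: pd.DataFrame,
                       axes: tuple[str, ...] = ("stage_group", "site", "gender", "age_group"),
                       test: str = "fisher") -> pd.DataFrame:
    """Gene-by-axis 2x2 association tests on an incidence matrix.

    For each gene and axis, the table cross-classifies mutated status with
    the two-level contrast of the axis (samples outside the contrast or
    with missing values are dropped).
    """
    if test not in ("fisher", "chisq"):
        raise ValueError(f"unknown test {test!r}")
    rows = []
    for axis in axes:
        case = dichotomize(patients, axis).reindex(matrix.columns)
        in_contrast = case.notna()
        case_bool = case[in_contrast].astype(bool).to_numpy()
        sub = matrix.loc[:, in_contrast.to_numpy()]
        for gene in matrix.index:
            mutated = sub.loc[gene].to_numpy(dtype=bool)
            a = int((mutated & case_bool).sum())
            b = int((mutated & ~case_bool).sum())
            c = int((~mutated & case_bool).sum())
            d = int((~mutated & ~case_bool).sum())
            if test == "fisher":
                odds, p = fisher_exact_2x2([[a, b], [c, d]])
            else:
                _, p = chi2_2x2([[a, b], [c, d]])
                odds = np.inf if b * c == 0 and a * d > 0 else \
                    (np.nan if b * c == 0 else a * d / (b * c))
            rows.append({
                "gene": str(gene), "axis": axis,
                "case_level": AXIS_LEVELS[axis][0], "control_level": AXIS_LEVELS[axis][1],
                "mutated_case": a, "mutated_control": b,
                "wild_case": c, "wild_control": d,
                "odds_ratio": odds, "p_value": p, "test": test,
            })
    out = pd.DataFrame(rows)
    return out.sort_values(["axis", "p_value", "gene"], ignore_index=True)
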