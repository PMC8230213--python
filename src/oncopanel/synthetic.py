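"""Synthetic tumor-only panel cohorts with controlled cascade structure.

The generator emulates what a deep-coverage targeted cancer-panel run on
FFPE tumors produces *after* variant calling and annotation: per-sample
variant calls (depth, quality, VAF) plus a per-variant annotation table
carrying COSMIC/ICGC/Ensembl membership, FATHMM-based somatic/pathogenic
status, reported tissues, and SIFT/PolyPhen labels. Database flags are
realized *count-exactly* (a shuffled flag vector with exact tallies rather
than Bernoulli draws), so cascade regression tests are deterministic.

Somatic VAFs are drawn from a Beta(2,3) scaled onto (5, 95) percent — a
plausible tumor-only FFPE spread; the germline-suspect fraction of variants
is placed in the 49-51 or 99-100 percent bands that the downstream
heuristic flags. Clinicopathological features are drawn from configurable
marginal counts (independently across fields; only marginals are known).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from . import io as vio

TARGET_TISSUE = "large_intestine"
_OTHER_TISSUES = ("lung", "breast", "skin", "stomach", "liver", "prostate")


class CohortConfigError(ValueError):
    """Raised when a cohort configuration is internally inconsistent."""


@dataclass
class CascadeComposition:
    """Exact tallies the generated annotation table must realize.

    Defaults reproduce the reference cascade of a 409-gene colorectal
    cohort: 4256 variants, 483 absent from COSMIC of which 17 are in ICGC
    (466 novel against both), 561 confirmed somatic, 299 pathogenic of
    which 125 carry a prior large-intestine report (174 are first-time in
    that tissue), and the consequence / SIFT / PolyPhen tallies of the
    somatic set.
    """

    n_total: int = 4256
    n_absent_cosmic: int = 483
    n_of_those_in_icgc: int = 17
    n_confirmed_somatic: int = 561
    n_pathogenic: int = 299
    n_pathogenic_with_prior_large_intestine_report: int = 125
    n_pathogenic_outside_somatic: int = 0
    n_sift_deleterious: int = 130
    n_sift_tolerated: int = 111
    n_polyphen_damaging: int = 418
    n_polyphen_benign: int = 143
    n_germline_band: int = 69
    n_germline_maf_supported: int = 45
    consequence_counts: dict[str, int] = field(
        default_factory=lambda: {"synonymous": 240, "missense": 247, "other": 74}
    )

    def validate(self) -> None:
        def _need(cond: bool, msg: str) -> None:
            if not cond:
                raise CohortConfigError(msg)

        c = self
        n_in_cosmic = c.n_total - c.n_absent_cosmic
        _need(all(v >= 0 for v in dataclasses.asdict(c).values() if isinstance(v, int)),
              "all composition counts must be non-negative")
        _need(c.n_absent_cosmic <= c.n_total,
              f"n_absent_cosmic ({c.n_absent_cosmic}) exceeds n_total ({c.n_total})")
        _need(c.n_of_those_in_icgc <= c.n_absent_cosmic,
              f"n_of_those_in_icgc ({c.n_of_those_in_icgc}) exceeds "
              f"n_absent_cosmic ({c.n_absent_cosmic})")
        _need(c.n_confirmed_somatic <= n_in_cosmic,
              f"n_confirmed_somatic ({c.n_confirmed_somatic}) exceeds COSMIC rows ({n_in_cosmic})")
        _need(c.n_pathogenic_outside_somatic <= c.n_pathogenic,
              "n_pathogenic_outside_somatic exceeds n_pathogenic")
        _need(c.n_pathogenic - c.n_pathogenic_outside_somatic <= c.n_confirmed_somatic,
              f"n_pathogenic within somatic ({c.n_pathogenic - c.n_pathogenic_outside_somatic}) "
              f"exceeds n_confirmed_somatic ({c.n_confirmed_somatic})")
        _need(c.n_confirmed_somatic + c.n_pathogenic_outside_somatic <= n_in_cosmic,
              "somatic plus pathogenic-only rows exceed COSMIC rows")
        _need(c.n_pathogenic_with_prior_large_intestine_report <= c.n_pathogenic,
              f"n_pathogenic_with_prior_large_intestine_report "
              f"({c.n_pathogenic_with_prior_large_intestine_report}) exceeds "
              f"n_pathogenic ({c.n_pathogenic})")
        _need(c.n_sift_deleterious + c.n_sift_tolerated <= c.n_confirmed_somatic,
              "SIFT tallies exceed somatic count")
        _need(c.n_polyphen_damaging + c.n_polyphen_benign <= c.n_confirmed_somatic,
              "PolyPhen tallies exceed somatic count")
        _need(sum(c.consequence_counts.values()) <= c.n_confirmed_somatic,
              "consequence counts exceed somatic count")
        _need(set(c.consequence_counts) <= set(vio.CONSEQUENCES),
              f"unknown consequence in {sorted(c.consequence_counts)}")
        _need(c.n_germline_maf_supported <= c.n_germline_band,
              f"n_germline_maf_supported ({c.n_germline_maf_supported}) exceeds "
              f"n_germline_band ({c.n_germline_band})")
        _need(c.n_germline_band <= c.n_absent_cosmic,
              "germline-band variants are drawn among the novel set; "
              f"n_germline_band ({c.n_germline_band}) exceeds n_absent_cosmic ({c.n_absent_cosmic})")


def default_panel(n_genes: int = 409) -> list[str]:
    """Synthetic panel gene symbols G001..G409 (a real list may be supplied)."""
    width = len(str(n_genes))
    return [f"G{i:0{width}d}" for i in range(1, n_genes + 1)]


#: Clinicopathological marginal counts of the reference 95-patient cohort.
#: ``None`` keys are missing values (denominators differ per field).
TABLE1_MARGINALS: dict[str, dict[str | None, int]] = {
    "gender": {"male": 58, "female": 37},
    "overall_stage": {"I": 17, "II": 32, "III": 37, "IV": 8, None: 1},
    "t_stage": {"T1": 2, "T2": 18, "T3": 61, "T4": 13, None: 1},
    "n_stage": {"N0": 55, "N1": 33, "N2": 6, None: 1},
    "m_stage": {"M0": 90, "M1": 4, None: 1},
    "site": {"left_colon": 47, "right_colon": 30, "rectum": 13, None: 5},
}


@dataclass
class CohortConfig:
    """Knobs of the synthetic cohort; defaults mirror the reference study."""

    n_patients: int = 90
    panel_genes: Sequence[str] = field(default_factory=default_panel)
    variants_per_patient: float = 120.0
    somatic_vaf_beta: tuple[float, float] = (2.0, 3.0)
    somatic_vaf_range: tuple[float, float] = (5.0, 95.0)
    germline_fraction: float | None = None  # derived from composition when None
    composition: CascadeComposition = field(default_factory=CascadeComposition)
    clinicopath_marginals: dict[str, dict[str | None, int]] = field(
        default_factory=lambda: {k: dict(v) for k, v in TABLE1_MARGINALS.items()}
    )
    age_mean: float = 62.0
    age_sd: float = 14.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 0:
            raise CohortConfigError("n_patients must be non-negative")
        if self.germline_fraction is not None and not (0.0 <= self.germline_fraction <= 1.0):
            raise CohortConfigError("germline_fraction must lie in [0,1]")
        lo, hi = self.somatic_vaf_range
        if not (0.0 < lo < hi <= 100.0):
            raise CohortConfigError("somatic_vaf_range must be within (0,100]")
        self.composition.validate()


@dataclass
class Cohort:
    """In-memory synthetic cohort: three tables plus the generating config."""

    patients: pd.DataFrame
    calls: pd.DataFrame
    annotations: pd.DataFrame
    config: CohortConfig | None = None

    def write(self, directory: str | Path) -> dict[str, Path]:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = {
            "patients": directory / "patients.tsv",
            "annotations": directory / "annotations.tsv",
            "calls": directory / "calls.tsv",
        }
        vio.write_tsv(paths["patients"], self.patients)
        vio.write_tsv(paths["annotations"], self.annotations)
        vio.write_tsv(paths["calls"], self.calls)
        vcf_dir = directory / "vcf"
        vio.write_sample_vcfs(vcf_dir, self.calls)
        paths["vcf_dir"] = vcf_dir
        return paths


def _realize_counts(marginals: dict[str | None, int], n: int, rng: np.random.Generator) -> list:
    """Count-exact categorical vector of length n (largest-remainder scaling)."""
    cats = list(marginals.keys())
    counts = np.array([marginals[c] for c in cats], dtype=float)
    total = counts.sum()
    if total <= 0:
        return [None] * n
    scaled = counts * n / total
    base = np.floor(scaled).astype(int)
    remainder = n - base.sum()
    order = np.argsort(-(scaled - base))
    base[order[:remainder]] += 1
    values: list = []
    for cat, k in zip(cats, base):
        values.extend([cat] * int(k))
    rng.shuffle(values)
    return values


def generate_patients(config: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = config.n_patients
    width = max(3, len(str(n)))
    df = pd.DataFrame({"patient_id": [f"P{i:0{width}d}" for i in range(1, n + 1)]})
    ages = rng.normal(config.age_mean, config.age_sd, size=n)
    df["age_years"] = np.clip(np.round(ages, 1), 18.0, 100.0)
    for fld in ("gender", "t_stage", "n_stage", "m_stage", "overall_stage", "site"):
        df[fld] = _realize_counts(config.clinicopath_marginals[fld], n, rng)
    return df[vio.PATIENT_COLUMNS]


def table1_patients(seed: int = 0) -> pd.DataFrame:
    """The 95-patient clinicopathological table realized count-exactly."""
    cfg = CohortConfig(n_patients=95)
    return generate_patients(cfg, np.random.default_rng(seed))


_BASES = np.array(list("ACGT"))


def _variant_keys(n: int, rng: np.random.Generator) -> pd.DataFrame:
    chroms = [f"chr{i}" for i in range(1, 23)]
    chrom = np.repeat(chroms, int(np.ceil(n / len(chroms))))[:n]
    pos = np.concatenate([
        np.sort(rng.integers(10_000, 50_000_000, size=k)) + np.arange(k)  # strictly increasing
        for c in chroms if (k := int((chrom == c).sum()))
    ])
    ref_idx = rng.integers(0, 4, size=n)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n)) % 4
    return pd.DataFrame({
        "chrom": chrom, "pos": pos.astype(int),
        "ref": _BASES[ref_idx], "alt": _BASES[alt_idx],
    })


def _fill_exact(n: int, labels: list[tuple[str | None, int]], fill, rng: np.random.Generator) -> np.ndarray:
    """Array of length n with exact label counts, remainder `fill`, shuffled."""
    out = []
    for label, count in labels:
        out.extend([label] * count)
    out.extend([fill] * (n - len(out)))
    out = np.array(out, dtype=object)
    rng.shuffle(out)
    return out


def generate_annotations(config: CohortConfig, keys: pd.DataFrame,
                         rng: np.random.Generator) -> tuple[pd.DataFrame, dict[str, np.ndarray]]:
    """Annotation table realizing ``config.composition`` exactly.

    Returns the table plus index masks used when laying out calls
    (which variants are germline-band and which need >=2 carriers).
    """
    comp = config.composition
    n = comp.n_total
    ann = keys.copy()
    ann["gene"] = rng.choice(np.asarray(list(config.panel_genes), dtype=object), size=n)
    ann["exon"] = None
    ann["hgvs_c"] = None
    ann["hgvs_p"] = None

    idx = rng.permutation(n)
    novel = idx[: comp.n_absent_cosmic]
    cosmic = idx[comp.n_absent_cosmic:]
    icgc = novel[: comp.n_of_those_in_icgc]
    somatic = cosmic[: comp.n_confirmed_somatic]
    n_path_in = comp.n_pathogenic - comp.n_pathogenic_outside_somatic
    pathogenic = np.concatenate([
        somatic[:n_path_in],
        cosmic[comp.n_confirmed_somatic: comp.n_confirmed_somatic + comp.n_pathogenic_outside_somatic],
    ]).astype(int)
    prior_tissue = pathogenic[: comp.n_pathogenic_with_prior_large_intestine_report]

    in_cosmic = np.zeros(n, bool)
    in_cosmic[cosmic] = True
    flags = {name: np.zeros(n, bool) for name in
             ("in_icgc", "cosmic_confirmed_somatic", "cosmic_pathogenic", "ensembl_known")}
    flags["in_icgc"][icgc] = True
    flags["cosmic_confirmed_somatic"][somatic] = True
    flags["cosmic_pathogenic"][pathogenic] = True
    # previously catalogued germline-population variants rescued by COSMIC status
    rescued = cosmic[: comp.n_confirmed_somatic + comp.n_pathogenic_outside_somatic]
    flags["ensembl_known"][rng.choice(rescued, size=len(rescued) // 4, replace=False)] = True

    tissues = np.full(n, None, dtype=object)
    for i in cosmic:
        tissues[i] = rng.choice(_OTHER_TISSUES)
    tissues[pathogenic] = [rng.choice(_OTHER_TISSUES) for _ in pathogenic]
    tissues[prior_tissue] = [
        TARGET_TISSUE + ("," + rng.choice(_OTHER_TISSUES) if rng.random() < 0.4 else "")
        for _ in prior_tissue
    ]

    # consequence / SIFT / PolyPhen exact within the somatic set
    somatic_local = rng.permutation(comp.n_confirmed_somatic)
    consequence = np.array(
        rng.choice(["synonymous", "missense", "other"], size=n, p=[0.45, 0.45, 0.10]),
        dtype=object)
    conseq_somatic = _fill_exact(
        comp.n_confirmed_somatic, list(comp.consequence_counts.items()), "other", rng)
    consequence[somatic] = conseq_somatic
    sift = np.full(n, None, dtype=object)
    sift[somatic[somatic_local]] = _fill_exact(
        comp.n_confirmed_somatic,
        [("deleterious", comp.n_sift_deleterious), ("tolerated", comp.n_sift_tolerated)],
        None, rng)
    polyphen = np.full(n, None, dtype=object)
    n_prob = comp.n_polyphen_damaging // 2
    polyphen[somatic[rng.permutation(comp.n_confirmed_somatic)]] = _fill_exact(
        comp.n_confirmed_somatic,
        [("probably_damaging", n_prob),
         ("possibly_damaging", comp.n_polyphen_damaging - n_prob),
         ("benign", comp.n_polyphen_benign)],
        None, rng)

    germline_band = novel[rng.permutation(comp.n_absent_cosmic)[: comp.n_germline_band]]
    maf_supported = germline_band[: comp.n_germline_maf_supported]
    population_af = np.full(n, np.nan)
    population_af[maf_supported] = rng.uniform(0.01, 0.2, size=len(maf_supported))

    ann["consequence"] = consequence
    ann["in_cosmic"] = in_cosmic
    ann["cosmic_confirmed_somatic"] = flags["cosmic_confirmed_somatic"]
    ann["cosmic_pathogenic"] = flags["cosmic_pathogenic"]
    ann["cosmic_tissues"] = tissues
    ann["in_icgc"] = flags["in_icgc"]
    ann["ensembl_known"] = flags["ensembl_known"]
    ann["population_af"] = population_af
    ann["sift"] = sift
    ann["polyphen"] = polyphen
    masks = {
        "germline_band": np.isin(np.arange(n), germline_band),
        "maf_supported": np.isin(np.arange(n), maf_supported),
    }
    return ann[vio.ANNOTATION_COLUMNS], masks


def _band_vaf(rng: np.random.Generator, size: int) -> np.ndarray:
    """VAFs inside the germline-suspect bands with margin for depth rounding."""
    het = rng.random(size) < 0.8
    vaf = np.where(het, rng.uniform(49.2, 50.8, size), rng.uniform(99.2, 99.9, size))
    return vaf


# exclusion margins keep non-germline VAFs out of the suspect bands even
# after alt-depth rounding (max shift 100*0.5/301 ~ 0.17 at depth 301)
_BAND_AVOID = ((48.8, 51.2), (98.8, 100.0))


def _somatic_vaf(rng: np.random.Generator, size: int, a: float, b: float,
                 lo: float, hi: float) -> np.ndarray:
    """Beta-shaped somatic VAFs, rejection-sampled to stay off the germline bands."""
    vaf = lo + (hi - lo) * rng.beta(a, b, size=size)
    for _ in range(100):
        bad = np.zeros(size, dtype=bool)
        for blo, bhi in _BAND_AVOID:
            bad |= (vaf >= blo) & (vaf <= bhi)
        if not bad.any():
            break
        vaf[bad] = lo + (hi - lo) * rng.beta(a, b, size=int(bad.sum()))
    return vaf


def generate_calls(config: CohortConfig, patients: pd.DataFrame, annotations: pd.DataFrame,
                   masks: dict[str, np.ndarray], rng: np.random.Generator) -> pd.DataFrame:
    comp = config.composition
    n_var = len(annotations)
    n_pat = len(patients)
    total_calls = config.n_patients * config.variants_per_patient
    mean_carriers = max(1.0, total_calls / max(n_var, 1))

    n_carriers = 1 + rng.poisson(mean_carriers - 1.0, size=n_var)
    n_carriers = np.clip(n_carriers, 1, n_pat)
    # MAF-supported germline variants need cohort MAF > 1%: >= 2 carriers of 90
    min2 = max(2, int(np.ceil(0.01 * 2 * n_pat)) + 1) if n_pat else 2
    n_carriers[masks["maf_supported"]] = np.maximum(n_carriers[masks["maf_supported"]], min2)
    n_carriers[masks["germline_band"] & ~masks["maf_supported"]] = 1

    patient_ids = patients["patient_id"].to_numpy()
    a, b = config.somatic_vaf_beta
    lo, hi = config.somatic_vaf_range
    rows = []
    for i in range(n_var):
        carriers = rng.choice(patient_ids, size=int(n_carriers[i]), replace=False)
        k = len(carriers)
        if masks["germline_band"][i]:
            vafs = _band_vaf(rng, k)
        else:
            vafs = _somatic_vaf(rng, k, a, b, lo, hi)
        depth = rng.integers(301, 2001, size=k)
        alt_depth = np.clip(np.round(depth * vafs / 100.0), 1, depth).astype(int)
        qual = np.round(rng.uniform(50.5, 99.0, size=k), 1)
        key = annotations.iloc[i]
        for j, sample in enumerate(carriers):
            rows.append((
                sample, key["chrom"], int(key["pos"]), key["ref"], key["alt"],
                float(qual[j]), int(depth[j]), int(alt_depth[j]),
                100.0 * alt_depth[j] / depth[j],
            ))
    calls = pd.DataFrame(rows, columns=vio.CALL_COLUMNS)
    return calls.sort_values(["sample_id", "chrom", "pos", "ref", "alt"], ignore_index=True)


def generate_cohort(config: CohortConfig | None = None) -> Cohort:
    """Generate a full synthetic cohort; deterministic under ``config.seed``."""
    config = config if config is not None else CohortConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    if config.n_patients == 0:
        return Cohort(
            patients=pd.DataFrame(columns=vio.PATIENT_COLUMNS),
            calls=pd.DataFrame(columns=vio.CALL_COLUMNS),
            annotations=pd.DataFrame(columns=vio.ANNOTATION_COLUMNS),
            config=config,
        )
    patients = generate_patients(config, rng)
    keys = _variant_keys(config.composition.n_total, rng)
    annotations, masks = generate_annotations(config, keys, rng)
    calls = generate_calls(config, patients, annotations, masks, rng)
    return Cohort(patients=patients, calls=calls, annotations=annotations, config=config)


# ---------------------------------------------------------------------------
# simulation harnesses for the association machinery
# ---------------------------------------------------------------------------

def generate_skat_null(
    n_individuals: int,
    n_variants_per_gene: int,
    maf_spectrum: float | tuple[float, float] | Sequence[float] | Callable = (0.01, 0.10),
    trait: str = "binary",
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Genotypes and a trait drawn independently (the null model).

    ``maf_spectrum`` may be a point mass (float), a uniform range (2-tuple),
    a finite set of MAFs (sequence), or ``callable(rng, size)``.
    """
    if n_individuals < 10:
        raise ValueError("n_individuals must be >= 10")
    rng = np.random.default_rng(seed)
    if callable(maf_spectrum):
        mafs = np.asarray(maf_spectrum(rng, n_variants_per_gene), dtype=float)
    elif isinstance(maf_spectrum, tuple) and len(maf_spectrum) == 2:
        mafs = rng.uniform(*maf_spectrum, size=n_variants_per_gene)
    elif np.isscalar(maf_spectrum):
        mafs = np.full(n_variants_per_gene, float(maf_spectrum))
    else:
        mafs = rng.choice(np.asarray(maf_spectrum, dtype=float), size=n_variants_per_gene)
    if np.all(mafs <= 0.0):
        raise ValueError("degenerate maf_spectrum: all MAFs are zero")
    genotypes = rng.binomial(2, mafs, size=(n_individuals, n_variants_per_gene))
    if trait == "binary":
        y = rng.binomial(1, 0.5, size=n_individuals).astype(float)
        while y.sum() in (0, n_individuals):  # both classes required downstream
            y = rng.binomial(1, 0.5, size=n_individuals).astype(float)
    elif trait == "quantitative":
        y = rng.normal(0.0, 1.0, size=n_individuals)
    else:
        raise ValueError(f"unknown trait type {trait!r}")
    return genotypes, y


def inject_gene_association(cohort: Cohort, gene: str, trait: str,
                            odds_ratio: float, seed: int = 0,
                            baseline_rate: float = 0.25) -> Cohort:
    """Resample carrier status of pathogenic variants in ``gene`` so the
    population log-odds association with the dichotomized ``trait`` equals
    ``log(odds_ratio)``. Returns a new cohort; the input is not modified.
    """
    from .profiling import dichotomize  # deferred: profiling is downstream

    if odds_ratio <= 0:
        raise ValueError(f"odds_ratio must be positive, got {odds_ratio}")
    if gene not in set(cohort.annotations["gene"]):
        raise ValueError(f"gene {gene!r} not in panel annotations")
    rng = np.random.default_rng(seed)
    case = dichotomize(cohort.patients, trait)
    case = case.dropna()
    if case.nunique() < 2:
        raise ValueError(f"trait {trait!r} is constant; cannot inject an association")

    ann = cohort.annotations
    target = ann[(ann["gene"] == gene) & ann["cosmic_pathogenic"].astype(bool)]
    if target.empty:
        raise ValueError(f"gene {gene!r} has no pathogenic variants to resample")
    target_keys = set(map(tuple, target[["chrom", "pos", "ref", "alt"]].to_numpy()))

    p0 = baseline_rate  # carrier rate in the control stratum
    odds1 = odds_ratio * p0 / (1 - p0)
    p1 = odds1 / (1 + odds1)
    carrier = {
        pid: rng.random() < (p1 if bool(is_case) else p0)
        for pid, is_case in case.items()
    }

    calls = cohort.calls
    is_target = calls.apply(
        lambda r: (r["chrom"], r["pos"], r["ref"], r["alt"]) in target_keys, axis=1
    ) if len(calls) else pd.Series(False, index=calls.index)
    kept = calls[~is_target | calls["sample_id"].map(lambda s: carrier.get(s, False))]

    new_rows = []
    first = target.iloc[0]
    have = set(kept.loc[is_target.reindex(kept.index, fill_value=False), "sample_id"]) \
        if len(kept) else set()
    for pid, is_carrier in carrier.items():
        if is_carrier and pid not in have:
            depth = int(rng.integers(301, 2001))
            vaf = 5.0 + 90.0 * rng.beta(2, 3)
            alt_depth = int(np.clip(round(depth * vaf / 100.0), 1, depth))
            new_rows.append((
                pid, first["chrom"], int(first["pos"]), first["ref"], first["alt"],
                float(np.round(rng.uniform(50.5, 99.0), 1)), depth, alt_depth,
                100.0 * alt_depth / depth,
            ))
    calls_out = pd.concat(
        [kept, pd.DataFrame(new_rows, columns=vio.CALL_COLUMNS)], ignore_index=True
    ).sort_values(["sample_id", "chrom", "pos", "ref", "alt"], ignore_index=True)
    return Cohort(patients=cohort.patients.copy(), calls=calls_out,
                  annotations=cohort.annotations.copy(), config=cohort.config)
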