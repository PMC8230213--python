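"""The tumor-only variant filtration and classification cascade.

Stages, applied per cohort (one row per distinct variant key):

1. Quality gate: keep calls with coverage strictly greater than 300x and
   site quality strictly greater than 50 (both configurable).
2. Common-variant exclusion: variants previously catalogued in Ensembl are
   excluded unless rescued by COSMIC confirmed-somatic or pathogenic
   (FATHMM) status.
3. Novelty: a variant absent from COSMIC is novel-vs-COSMIC; if it is also
   absent from ICGC it is novel against both catalogues.
4. Tissue routing: a pathogenic variant with a prior report in the target
   tissue (large intestine) is tissue-specific; a pathogenic variant with
   no such report is a first-time observation in that tissue.
5. Germline heuristic: tumor-only data has no matched normal, so a variant
   is germline-suspect when any carrier's VAF falls in the 49-51% or
   99-100% bands; the suspicion is MAF-supported when the cohort minor
   allele frequency additionally exceeds 1%. Cohort MAF counts each
   carrier as one minor allele over 2 x n_samples chromosomes — a stated
   convention (there are no true genotypes), mirroring what a
   presence/absence PLINK encoding would see.
6. Damaging inclusion: SIFT deleterious and/or PolyPhen damaging
   (probably_ or possibly_) variants are flagged for downstream analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

KEY = ["chrom", "pos", "ref", "alt"]

CLASSIFIED_COLUMNS = KEY + [
    "gene", "consequence", "sift", "polyphen", "n_carriers",
    "passed_quality", "excluded_common", "novel_vs_cosmic", "in_icgc",
    "novel_vs_both", "confirmed_somatic", "pathogenic",
    "tissue_specific_pathogenic", "novel_in_target_tissue",
    "germline_suspect_vaf", "germline_suspect_maf_support",
    "damaging_included",
]

FLAG_COLUMNS = CLASSIFIED_COLUMNS[9:]


class OrphanCallError(ValueError):
    """Raised when calls reference variants missing from the annotation table."""


@dataclass
class FilterConfig:
    """Thresholds of the cascade; defaults follow the reference protocol."""

    min_coverage: int = 300          # strict: depth must exceed this
    min_quality: float = 50.0        # strict: QUAL must exceed this
    germline_vaf_bands: tuple[tuple[float, float], ...] = ((49.0, 51.0), (99.0, 100.0))
    germline_maf_threshold: float = 0.01   # strict: cohort MAF must exceed this
    target_tissue: str = "large_intestine"
    common_af_override: float | None = None  # optional population-AF (>x) exclusion

    def validate(self) -> None:
        if self.min_coverage < 0 or self.min_quality < 0:
            raise ValueError("thresholds must be non-negative")
        for lo, hi in self.germline_vaf_bands:
            if not (0.0 <= lo <= hi <= 100.0):
                raise ValueError(f"band ({lo},{hi}) not within [0,100]")
        bands = sorted(self.germline_vaf_bands)
        for (_, hi1), (lo2, _) in zip(bands, bands[1:]):
            if lo2 <= hi1:
                raise ValueError("germline VAF bands must be disjoint")
        if not (0.0 < self.germline_maf_threshold < 1.0):
            raise ValueError("germline_maf_threshold must lie in (0,1)")


def quality_filter(calls: pd.DataFrame, config: FilterConfig | None = None) -> pd.DataFrame:
    """Calls with depth > min_coverage and qual > min_quality (strict).

    Missing depth or quality fails the gate. Idempotent; never raises on
    content.
    """
    config = config or FilterConfig()
    if calls.empty:
        return calls.copy()
    depth = pd.to_numeric(calls["depth"], errors="coerce")
    qual = pd.to_numeric(calls["qual"], errors="coerce")
    keep = (depth > config.min_coverage) & (qual > config.min_quality)
    return calls[keep.fillna(False)].copy()


def _in_band(vaf: np.ndarray, bands) -> np.ndarray:
    hit = np.zeros(len(vaf), dtype=bool)
    for lo, hi in bands:
        hit |= (vaf >= lo) & (vaf <= hi)
    return hit


def classify(calls: pd.DataFrame, annotations: pd.DataFrame,
             config: FilterConfig | None = None,
             n_samples: int | None = None) -> pd.DataFrame:
    """Resolve every cascade flag for each distinct variant seen in ``calls``.

    The quality gate is applied internally; ``passed_quality`` records
    whether a variant retains at least one passing call, and carrier counts
    / VAF aggregation use passing calls only. Every variant key present in
    ``calls`` must have exactly one annotation row.
    """
    config = config or FilterConfig()
    config.validate()
    if n_samples is None:
        n_samples = int(calls["sample_id"].nunique()) if len(calls) else 0

    keys = calls[KEY].drop_duplicates()
    ann = annotations.drop_duplicates(subset=KEY)
    merged = keys.merge(ann, on=KEY, how="left", indicator=True)
    orphans = merged[merged["_merge"] == "left_only"]
    if len(orphans):
        orphan_keys = list(orphans[KEY].itertuples(index=False, name=None))
        raise OrphanCallError(
            f"{len(orphan_keys)} variant(s) lack annotation rows: {orphan_keys[:10]}"
        )
    merged = merged.drop(columns="_merge")

    passing = quality_filter(calls, config)
    grouped = passing.groupby(KEY, sort=False)
    carriers = grouped["sample_id"].nunique()
    band_hit = grouped["vaf_percent"].apply(
        lambda v: bool(_in_band(pd.to_numeric(v, errors="coerce").dropna().to_numpy(),
                                config.germline_vaf_bands).any())
    )
    key_index = pd.MultiIndex.from_frame(merged[KEY])
    n_carriers = carriers.reindex(key_index, fill_value=0).to_numpy()
    in_band = band_hit.reindex(key_index, fill_value=False).to_numpy(dtype=bool)

    out = merged[KEY + ["gene", "consequence", "sift", "polyphen"]].copy()
    out["n_carriers"] = n_carriers.astype(int)
    out["passed_quality"] = out["n_carriers"] > 0

    in_cosmic = merged["in_cosmic"].astype(bool).to_numpy()
    somatic = merged["cosmic_confirmed_somatic"].astype(bool).to_numpy()
    pathogenic = merged["cosmic_pathogenic"].astype(bool).to_numpy()
    ensembl = merged["ensembl_known"].astype(bool).to_numpy()
    icgc = merged["in_icgc"].astype(bool).to_numpy()

    excluded = ensembl & ~(somatic | pathogenic)
    if config.common_af_override is not None:
        pop_af = pd.to_numeric(merged["population_af"], errors="coerce").to_numpy()
        excluded |= (np.nan_to_num(pop_af) > config.common_af_override) & ~(somatic | pathogenic)
    out["excluded_common"] = excluded
    out["novel_vs_cosmic"] = ~in_cosmic
    out["in_icgc"] = icgc
    out["novel_vs_both"] = ~in_cosmic & ~icgc
    out["confirmed_somatic"] = somatic
    out["pathogenic"] = pathogenic

    tissues = merged["cosmic_tissues"].map(
        lambda t: frozenset() if pd.isna(t) or t == "" else
        frozenset(x.strip() for x in str(t).split(",")))
    in_target = tissues.map(lambda s: config.target_tissue in s).to_numpy(dtype=bool)
    out["tissue_specific_pathogenic"] = pathogenic & in_target
    out["novel_in_target_tissue"] = pathogenic & ~in_target

    maf = out["n_carriers"].to_numpy() / (2.0 * n_samples) if n_samples else np.zeros(len(out))
    out["germline_suspect_vaf"] = in_band
    out["germline_suspect_maf_support"] = in_band & (maf > config.germline_maf_threshold)

    sift_del = (merged["sift"] == "deleterious").to_numpy()
    poly_dmg = merged["polyphen"].isin(["probably_damaging", "possibly_damaging"]).to_numpy()
    out["damaging_included"] = sift_del | poly_dmg
    return out[CLASSIFIED_COLUMNS].reset_index(drop=True)


@dataclass
class CascadeCounts:
    """Tallies at every cascade node, on the post-quality variant set.

    Both the confirmed-somatic and the pathogenic sets are reported along
    with their intersection (their exact overlap is not a partition), and
    the pre-quality total is kept alongside the post-quality one.
    """

    n_total_all: int = 0
    n_total: int = 0
    n_excluded_common: int = 0
    n_novel_vs_cosmic: int = 0
    n_in_icgc_among_novel: int = 0
    n_novel_vs_both: int = 0
    n_confirmed_somatic: int = 0
    n_pathogenic: int = 0
    n_somatic_and_pathogenic: int = 0
    n_tissue_specific_pathogenic: int = 0
    n_novel_in_target_tissue: int = 0
    n_germline_suspect_vaf: int = 0
    n_germline_maf_supported: int = 0
    n_damaging_included: int = 0
    n_sift_deleterious_somatic: int = 0
    n_sift_tolerated_somatic: int = 0
    n_polyphen_damaging_somatic: int = 0
    n_polyphen_benign_somatic: int = 0
    consequence_counts_somatic: dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "consequence_counts_somatic"}
        d["consequence_counts_somatic"] = dict(self.consequence_counts_somatic)
        return d


def cascade_counts(classified: pd.DataFrame) -> CascadeCounts:
    """Count every cascade node; permutation-invariant, all-zero on empty."""
    if classified.empty:
        return CascadeCounts()
    passed = classified[classified["passed_quality"].astype(bool)]
    b = {c: passed[c].astype(bool) for c in FLAG_COLUMNS if c in passed}
    novel = passed["novel_vs_cosmic"].astype(bool)
    somatic = passed["confirmed_somatic"].astype(bool)
    pathogenic = passed["pathogenic"].astype(bool)
    som = passed[somatic]
    return CascadeCounts(
        n_total_all=int(len(classified)),
        n_total=int(len(passed)),
        n_excluded_common=int(passed["excluded_common"].astype(bool).sum()),
        n_novel_vs_cosmic=int(novel.sum()),
        n_in_icgc_among_novel=int((novel & passed["in_icgc"].astype(bool)).sum()),
        n_novel_vs_both=int(passed["novel_vs_both"].astype(bool).sum()),
        n_confirmed_somatic=int(somatic.sum()),
        n_pathogenic=int(pathogenic.sum()),
        n_somatic_and_pathogenic=int((somatic & pathogenic).sum()),
        n_tissue_specific_pathogenic=int(passed["tissue_specific_pathogenic"].astype(bool).sum()),
        n_novel_in_target_tissue=int(passed["novel_in_target_tissue"].astype(bool).sum()),
        n_germline_suspect_vaf=int(passed["germline_suspect_vaf"].astype(bool).sum()),
        n_germline_maf_supported=int(passed["germline_suspect_maf_support"].astype(bool).sum()),
        n_damaging_included=int(passed["damaging_included"].astype(bool).sum()),
        n_sift_deleterious_somatic=int((som["sift"] == "deleterious").sum()),
        n_sift_tolerated_somatic=int((som["sift"] == "tolerated").sum()),
        n_polyphen_damaging_somatic=int(
            som["polyphen"].isin(["probably_damaging", "possibly_damaging"]).sum()),
        n_polyphen_benign_somatic=int((som["polyphen"] == "benign").sum()),
        consequence_counts_somatic={
            k: int(v) for k, v in som["consequence"].value_counts().sort_index().items()
        },
    )
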