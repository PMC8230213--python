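"""Gene x sample incidence matrices and cohort descriptive tables.

A gene x sample matrix is binary: cell (g, s) is 1 iff sample ``s``
carries at least one variant in gene ``g`` meeting the named criterion
(``any``, ``somatic``, ``pathogenic``, ``tissue_specific_pathogenic``).
It is the substrate for recurrent-gene selection, clinicopathological
stratification, gene-level association screens, and co-occurrence
correlation.

Dichotomization conventions (used cohort-wide):

* age group: young iff age < 50 years (50.0 itself is old);
* stage group: early iff overall stage I-II, late iff III-IV;
* lymph node: N0 versus N1/N2; metastasis: M0 versus M1;
* site: left versus right for the two-level contrast (rectum and other
  fold into "other" and are dropped from the contrast); descriptive
  stratification keeps left/right/other separately.

Percentages always carry their field-specific non-missing denominators:
the reference cohort's printed table mixes denominators (95 patients
overall, 94 with stage, 90 with site), so every row here reports its own.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .filtration import KEY

CRITERIA = ("any", "somatic", "pathogenic", "tissue_specific_pathogenic")

STRATIFY_AXES = ("gender", "age_group", "stage_group", "site", "lymph_node", "metastasis")

#: For two-level contrasts: axis -> (case label, control label).
AXIS_LEVELS = {
    "gender": ("female", "male"),
    "age_group": ("young", "old"),
    "stage_group": ("late", "early"),
    "site": ("left", "right"),
    "lymph_node": ("involved", "N0"),
    "metastasis": ("M1", "M0"),
}


def axis_labels(patients: pd.DataFrame, axis: str) -> pd.Series:
    """Per-patient stratum labels for an axis (NaN where undetermined)."""
    idx = patients["patient_id"]
    if axis == "gender":
        lab = patients["gender"]
    elif axis == "age_group":
        age = pd.to_numeric(patients["age_years"], errors="coerce")
        lab = pd.Series(np.where(age < 50.0, "young", "old"), index=patients.index)
        lab[age.isna()] = np.nan
    elif axis == "stage_group":
        stage = patients["overall_stage"]
        lab = stage.map({"I": "early", "II": "early", "III": "late", "IV": "late"})
    elif axis == "site":
        lab = patients["site"].map({
            "left_colon": "left", "right_colon": "right", "rectum": "other", "other": "other",
        })
    elif axis == "lymph_node":
        lab = patients["n_stage"].map({"N0": "N0", "N1": "involved", "N2": "involved"})
    elif axis == "metastasis":
        lab = patients["m_stage"]
    else:
        raise ValueError(f"unknown axis {axis!r}; choose from {STRATIFY_AXES}")
    return pd.Series(lab.to_numpy(), index=idx, name=axis)


def dichotomize(patients: pd.DataFrame, axis: str) -> pd.Series:
    """Boolean case indicator per patient (NaN = not in the contrast)."""
    labels = axis_labels(patients, axis)
    case, control = AXIS_LEVELS[axis]
    out = pd.Series(np.nan, index=labels.index, dtype=object, name=axis)
    out[labels == case] = True
    out[labels == control] = False
    return out


def gene_sample_matrix(classified: pd.DataFrame, calls: pd.DataFrame,
                       criterion: str = "any") -> pd.DataFrame:
    """Binary gene x sample incidence under a named criterion.

    Variants failing the quality gate or excluded as common never count;
    ``tissue_specific_pathogenic`` deliberately excludes pathogenic
    variants with no prior target-tissue report (those are
    ``novel_in_target_tissue``). Duplicate identical call rows are
    idempotent (set semantics).
    """
    if criterion not in CRITERIA:
        raise ValueError(f"unknown criterion {criterion!r}; choose from {CRITERIA}")
    eligible = classified[classified["passed_quality"].astype(bool)
                          & ~classified["excluded_common"].astype(bool)]
    if criterion == "somatic":
        eligible = eligible[eligible["confirmed_somatic"].astype(bool)]
    elif criterion == "pathogenic":
        eligible = eligible[eligible["pathogenic"].astype(bool)]
    elif criterion == "tissue_specific_pathogenic":
        eligible = eligible[eligible["tissue_specific_pathogenic"].astype(bool)]

    samples = sorted(calls["sample_id"].astype(str).unique()) if len(calls) else []
    pairs = calls.merge(eligible[KEY + ["gene"]], on=KEY, how="inner")
    pairs = pairs[["gene", "sample_id"]].drop_duplicates()
    genes = sorted(eligible["gene"].astype(str).unique())
    matrix = pd.DataFrame(0, index=pd.Index(genes, name="gene"),
                          columns=pd.Index(samples, name="sample_id"), dtype=int)
    for gene, sample in pairs.itertuples(index=False):
        matrix.at[str(gene), str(sample)] = 1
    matrix.attrs["criterion"] = criterion
    return matrix


def select_recurrent_genes(matrix: pd.DataFrame, min_patients: int = 3) -> list[str]:
    """Genes mutated in at least ``min_patients`` samples under the matrix criterion."""
    row_sums = matrix.sum(axis=1)
    return sorted(row_sums.index[row_sums >= min_patients])


def gene_summary(classified: pd.DataFrame,
                 matrix_all: pd.DataFrame,
                 matrix_somatic: pd.DataFrame,
                 matrix_pathogenic: pd.DataFrame,
                 matrix_tissue_specific: pd.DataFrame | None = None,
                 top_k: int | None = None) -> pd.DataFrame:
    """Per-gene variant tallies and sample-percentage columns.

    Rows are ordered by the fraction of samples with >=1 pathogenic variant
    (descending), ties broken by somatic fraction then gene symbol —
    a stable, permutation-invariant ordering.
    """
    passed = classified[classified["passed_quality"].astype(bool)
                        & ~classified["excluded_common"].astype(bool)]
    g = passed.groupby("gene")
    summary = pd.DataFrame({
        "total_variants": g.size(),
        "novel_variants": g["novel_vs_cosmic"].sum().astype(int),
        "pathogenic_variants": g["pathogenic"].sum().astype(int),
        "somatic_variants": g["confirmed_somatic"].sum().astype(int),
        "tissue_specific_variants": g["tissue_specific_pathogenic"].sum().astype(int),
        "polyphen_damaging": g.apply(
            lambda d: int(d["polyphen"].isin(["probably_damaging", "possibly_damaging"]).sum()),
            include_groups=False),
        "sift_deleterious": g.apply(
            lambda d: int((d["sift"] == "deleterious").sum()), include_groups=False),
        "non_synonymous": g.apply(
            lambda d: int((d["consequence"] != "synonymous").sum()), include_groups=False),
    })

    def _pct(matrix: pd.DataFrame | None) -> pd.Series:
        if matrix is None or matrix.shape[1] == 0:
            return pd.Series(0.0, index=summary.index)
        frac = matrix.sum(axis=1) / matrix.shape[1]
        return frac.reindex(summary.index, fill_value=0.0)

    summary["pct_samples_pathogenic_all_tissue"] = _pct(matrix_pathogenic)
    summary["pct_samples_somatic"] = _pct(matrix_somatic)
    summary["pct_samples_tissue_specific"] = _pct(matrix_tissue_specific)
    summary = summary.sort_values(
        by=["pct_samples_pathogenic_all_tissue", "pct_samples_somatic", "gene"],
        ascending=[False, False, True],
        key=lambda col: col if col.name != "gene" else col.astype(str),
    )
    summary = summary.reset_index()
    return summary.head(top_k) if top_k else summary


def stratify(matrix: pd.DataFrame, patients: pd.DataFrame, axis: str) -> pd.DataFrame:
    """Per-gene mutated-sample counts by stratum of a clinicopathological axis.

    Strata partition the samples (a ``missing`` stratum keeps the partition
    exact when the axis value is unknown); stratum counts therefore sum to
    the matrix row sums.
    """
    known = set(patients["patient_id"].astype(str))
    unknown = [s for s in matrix.columns if str(s) not in known]
    if unknown:
        raise ValueError(f"samples without patient records: {unknown[:10]}")
    labels = axis_labels(patients, axis).reindex(matrix.columns).fillna("missing")
    strata = sorted(labels.unique())
    out = pd.DataFrame(
        {stratum: matrix.loc[:, (labels == stratum).to_numpy()].sum(axis=1)
         for stratum in strata},
    )
    out.index.name = "gene"
    out.attrs["axis"] = axis
    return out


def _pct_int(numer: int, denom: int) -> int:
    """Nearest-integer percent, half away from zero."""
    return int(np.floor(100.0 * numer / denom + 0.5)) if denom else 0


def cohort_summary(patients: pd.DataFrame) -> pd.DataFrame:
    """Descriptive clinicopathological table: n (%) per category.

    Every percentage uses the field's own non-missing denominator, which is
    reported alongside. Age is summarized as mean (sd). Fields that are
    missing for every patient are emitted as a single annotated row.
    """
    if patients.empty:
        raise ValueError("cohort_summary requires a nonempty patient table")
    rows: list[dict] = []
    age = pd.to_numeric(patients["age_years"], errors="coerce").dropna()
    if len(age):
        rows.append({"field": "age_years", "category": "mean (sd)",
                     "n": len(age), "denominator": len(age),
                     "value": f"{age.mean():.0f} ({age.std(ddof=1):.0f})", "pct": np.nan})
    field_order = {
        "gender": ["male", "female"],
        "overall_stage": ["I", "II", "III", "IV"],
        "t_stage": ["T1", "T2", "T3", "T4"],
        "n_stage": ["N0", "N1", "N2"],
        "m_stage": ["M0", "M1"],
        "site": ["left_colon", "right_colon", "rectum", "other"],
    }
    for fld, order in field_order.items():
        values = patients[fld].dropna()
        denom = len(values)
        if denom == 0:
            rows.append({"field": fld, "category": "(all missing)", "n": 0,
                         "denominator": 0, "value": "no non-missing values", "pct": np.nan})
            continue
        counts = values.value_counts()
        for cat in order:
            n = int(counts.get(cat, 0))
            if n == 0 and cat not in counts:
                continue
            rows.append({"field": fld, "category": cat, "n": n, "denominator": denom,
                         "value": f"{n} ({_pct_int(n, denom)}%)", "pct": _pct_int(n, denom)})
    return pd.DataFrame(rows, columns=["field", "category", "n", "denominator", "value", "pct"])
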