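"""Readers and writers for the formats the pipeline touches.

Conventions
-----------
* Coordinates are 1-based, inclusive, as in VCF. Indels are taken as given
  (no re-normalisation or left-alignment beyond what the caller produced).
* Variant identity is the ``(chrom, pos, ref, alt)`` tuple after
  multi-allelic splitting; annotation tables are joined on that key and must
  carry one gene per variant (canonical-transcript convention, resolved
  upstream).
* VAF (variant allele fraction) is stored on the *percent* scale, because
  the germline heuristic bands are defined on that scale (49-51 / 99-100).
* TSV files are tab-delimited UTF-8 with ``.`` for missing; enum-valued
  columns parse case-insensitively with spaces mapped to underscores.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pysam

MISSING = "."

CONSEQUENCES = ("synonymous", "missense", "stop_gained", "frameshift", "splice", "other")
SIFT_LEVELS = ("deleterious", "tolerated")
POLYPHEN_LEVELS = ("probably_damaging", "possibly_damaging", "benign")
GENDERS = ("male", "female")
T_STAGES = ("T1", "T2", "T3", "T4")
N_STAGES = ("N0", "N1", "N2")
M_STAGES = ("M0", "M1")
OVERALL_STAGES = ("I", "II", "III", "IV")
SITES = ("left_colon", "right_colon", "rectum", "other")

CALL_COLUMNS = [
    "sample_id", "chrom", "pos", "ref", "alt",
    "qual", "depth", "alt_depth", "vaf_percent",
]
ANNOTATION_COLUMNS = [
    "chrom", "pos", "ref", "alt", "gene", "exon", "hgvs_c", "hgvs_p",
    "consequence", "in_cosmic", "cosmic_confirmed_somatic", "cosmic_pathogenic",
    "cosmic_tissues", "in_icgc", "ensembl_known", "population_af",
    "sift", "polyphen",
]
PATIENT_COLUMNS = [
    "patient_id", "age_years", "gender", "t_stage", "n_stage", "m_stage",
    "overall_stage", "site",
]


class VcfParseError(ValueError):
    """Raised when a VCF cannot be parsed."""


class AnnotationValidationError(ValueError):
    """Raised when annotation rows violate their internal invariants."""


def _norm_enum(value, domain: Sequence[str], *, upper: bool = False):
    """Case-insensitive enum parsing; spaces/hyphens map to underscores."""
    if value is None or (isinstance(value, float) and np.isnan(value)) or value == MISSING or value == "":
        return None
    text = str(value).strip().replace(" ", "_").replace("-", "_")
    text = text.upper() if upper else text.lower()
    if text in domain:
        return text
    raise ValueError(f"value {value!r} not in domain {domain}")


@dataclass(frozen=True)
class VariantCall:
    """One called variant in one sample (tumor-only)."""

    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    qual: float | None = None
    depth: int | None = None
    alt_depth: int | None = None
    vaf_percent: float | None = None

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")
        if self.depth is not None and self.alt_depth is not None:
            if self.alt_depth > self.depth:
                raise ValueError(
                    f"alt_depth {self.alt_depth} > depth {self.depth} at {self.chrom}:{self.pos}"
                )
            if self.vaf_percent is not None and self.depth > 0:
                expected = 100.0 * self.alt_depth / self.depth
                if abs(expected - self.vaf_percent) > 0.5:
                    raise ValueError(
                        f"vaf_percent {self.vaf_percent} inconsistent with "
                        f"depths {self.alt_depth}/{self.depth} at {self.chrom}:{self.pos}"
                    )

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class VariantAnnotation:
    """Per-variant database and functional annotations (one gene per variant)."""

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    consequence: str = "other"
    exon: str | None = None
    hgvs_c: str | None = None
    hgvs_p: str | None = None
    in_cosmic: bool = False
    cosmic_confirmed_somatic: bool = False
    cosmic_pathogenic: bool = False
    cosmic_tissues: frozenset[str] = field(default_factory=frozenset)
    in_icgc: bool = False
    ensembl_known: bool = False
    population_af: float | None = None
    sift: str | None = None
    polyphen: str | None = None

    def __post_init__(self):
        object.__setattr__(self, "cosmic_tissues", frozenset(self.cosmic_tissues))
        if (self.cosmic_confirmed_somatic or self.cosmic_pathogenic) and not self.in_cosmic:
            raise AnnotationValidationError(
                f"COSMIC somatic/pathogenic status without in_cosmic at {self.key}"
            )
        if self.cosmic_tissues and not self.in_cosmic:
            raise AnnotationValidationError(
                f"cosmic_tissues nonempty without in_cosmic at {self.key}"
            )
        if self.population_af is not None and not (0.0 <= self.population_af <= 1.0):
            raise AnnotationValidationError(
                f"population_af {self.population_af} outside [0,1] at {self.key}"
            )

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class Patient:
    """Clinicopathological record for one patient; fields may be missing."""

    patient_id: str
    age_years: float | None = None
    gender: str | None = None
    t_stage: str | None = None
    n_stage: str | None = None
    m_stage: str | None = None
    overall_stage: str | None = None
    site: str | None = None

    def __post_init__(self):
        for attr, domain, upper in (
            ("gender", GENDERS, False), ("t_stage", T_STAGES, True),
            ("n_stage", N_STAGES, True), ("m_stage", M_STAGES, True),
            ("overall_stage", OVERALL_STAGES, True), ("site", SITES, False),
        ):
            value = getattr(self, attr)
            if value is not None:
                object.__setattr__(self, attr, _norm_enum(value, domain, upper=upper))
        if self.age_years is not None and self.age_years < 0:
            raise ValueError(f"age_years must be non-negative, got {self.age_years}")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path: str | Path) -> list[VariantCall]:
    """Read one tumor sample's VCF into a list of :class:`VariantCall`.

    Multi-allelic records are split into one call per ALT allele. VAF is
    taken from allele depths (``AD``) when available, else from an allele
    fraction field (``AF``); records with neither retain a missing VAF and
    trigger a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        vf = pysam.VariantFile(str(path))
    except (ValueError, OSError) as exc:
        raise VcfParseError(f"malformed VCF {path}: {exc}") from exc
    calls: list[VariantCall] = []
    with vf:
        sample_names = list(vf.header.samples)
        for rec in vf:
            for sample_name in sample_names or [path.stem]:
                fmt = rec.samples[sample_name] if sample_names else {}
                ad = fmt.get("AD") if sample_names else None
                dp = fmt.get("DP") if sample_names else None
                af = fmt.get("AF") if sample_names else None
                for alt_idx, alt in enumerate(rec.alts or ()):
                    depth = int(dp) if dp is not None else None
                    alt_depth = None
                    vaf = None
                    if ad is not None and len(ad) > alt_idx + 1 and ad[alt_idx + 1] is not None:
                        alt_depth = int(ad[alt_idx + 1])
                        if depth is None:
                            depth = int(sum(x for x in ad if x is not None))
                        if depth:
                            vaf = 100.0 * alt_depth / depth
                    elif af is not None:
                        af_val = af[alt_idx] if isinstance(af, tuple) else af
                        if af_val is not None:
                            vaf = 100.0 * float(af_val)
                    if vaf is None and alt_depth is None:
                        warnings.warn(
                            f"record {rec.chrom}:{rec.pos} in {path.name} lacks both "
                            "depth and fraction fields; VAF left missing",
                            stacklevel=2,
                        )
                    calls.append(VariantCall(
                        sample_id=sample_name,
                        chrom=rec.chrom, pos=rec.pos, ref=rec.ref, alt=alt,
                        qual=float(rec.qual) if rec.qual is not None else None,
                        depth=depth, alt_depth=alt_depth, vaf_percent=vaf,
                    ))
    return calls


def write_vcf(path: str | Path, calls: Iterable[VariantCall], sample_id: str | None = None) -> None:
    """Write a minimal VCF v4.2 for one sample with DP/AD/AF FORMAT fields."""
    calls = sorted(calls, key=lambda c: (c.chrom, c.pos, c.ref, c.alt))
    if sample_id is None:
        ids = {c.sample_id for c in calls}
        if len(ids) != 1:
            raise ValueError(f"expected exactly one sample, got {sorted(ids)}")
        sample_id = ids.pop()
    contigs = sorted({c.chrom for c in calls})
    lines = ["##fileformat=VCFv4.2"]
    lines += [f"##contig=<ID={contig}>" for contig in contigs]
    lines += [
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">',
        '##FORMAT=<ID=AF,Number=A,Type=Float,Description="Allele fraction">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample_id,
    ]
    for c in calls:
        qual = f"{c.qual:g}" if c.qual is not None else MISSING
        fmt_keys, fmt_vals = ["GT"], ["0/1"]
        if c.depth is not None:
            fmt_keys.append("DP")
            fmt_vals.append(str(c.depth))
        if c.depth is not None and c.alt_depth is not None:
            fmt_keys.append("AD")
            fmt_vals.append(f"{c.depth - c.alt_depth},{c.alt_depth}")
        if c.vaf_percent is not None:
            fmt_keys.append("AF")
            fmt_vals.append(f"{c.vaf_percent / 100.0:.6f}")
        lines.append("\t".join([
            c.chrom, str(c.pos), MISSING, c.ref, c.alt, qual, "PASS", MISSING,
            ":".join(fmt_keys), ":".join(fmt_vals),
        ]))
    Path(path).write_text("\n".join(lines) + "\n")


def write_sample_vcfs(directory: str | Path, calls: pd.DataFrame) -> list[Path]:
    """Write one VCF per sample from a calls table; returns the paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for sample_id, group in calls.groupby("sample_id", sort=True):
        path = directory / f"{sample_id}.vcf"
        write_vcf(path, frame_to_calls(group), sample_id=str(sample_id))
        paths.append(path)
    return paths


def read_vcf_dir(directory: str | Path) -> pd.DataFrame:
    """Read every ``*.vcf`` in a directory into one calls table."""
    frames = [calls_to_frame(read_vcf(p)) for p in sorted(Path(directory).glob("*.vcf"))]
    if not frames:
        return pd.DataFrame(columns=CALL_COLUMNS)
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# record <-> DataFrame conversion
# ---------------------------------------------------------------------------

def calls_to_frame(calls: Iterable[VariantCall]) -> pd.DataFrame:
    rows = [dataclasses.asdict(c) for c in calls]
    df = pd.DataFrame(rows, columns=CALL_COLUMNS)
    return df


def frame_to_calls(df: pd.DataFrame) -> list[VariantCall]:
    out = []
    for row in df.itertuples(index=False):
        out.append(VariantCall(
            sample_id=str(row.sample_id), chrom=str(row.chrom), pos=int(row.pos),
            ref=str(row.ref), alt=str(row.alt),
            qual=None if pd.isna(row.qual) else float(row.qual),
            depth=None if pd.isna(row.depth) else int(row.depth),
            alt_depth=None if pd.isna(row.alt_depth) else int(row.alt_depth),
            vaf_percent=None if pd.isna(row.vaf_percent) else float(row.vaf_percent),
        ))
    return out


def annotations_to_frame(annotations: Iterable[VariantAnnotation]) -> pd.DataFrame:
    rows = []
    for a in annotations:
        d = dataclasses.asdict(a)
        d["cosmic_tissues"] = ",".join(sorted(a.cosmic_tissues)) if a.cosmic_tissues else None
        rows.append(d)
    return pd.DataFrame(rows, columns=ANNOTATION_COLUMNS)


def frame_to_annotations(df: pd.DataFrame) -> list[VariantAnnotation]:
    out = []
    bad_keys = []
    for row in df.itertuples(index=False):
        tissues = row.cosmic_tissues
        if tissues is None or (isinstance(tissues, float) and np.isnan(tissues)) or tissues in (MISSING, ""):
            tissue_set: frozenset[str] = frozenset()
        else:
            tissue_set = frozenset(t.strip() for t in str(tissues).split(",") if t.strip())
        try:
            out.append(VariantAnnotation(
                chrom=str(row.chrom), pos=int(row.pos), ref=str(row.ref), alt=str(row.alt),
                gene=str(row.gene),
                consequence=_norm_enum(row.consequence, CONSEQUENCES) or "other",
                exon=None if pd.isna(row.exon) else str(row.exon),
                hgvs_c=None if pd.isna(row.hgvs_c) else str(row.hgvs_c),
                hgvs_p=None if pd.isna(row.hgvs_p) else str(row.hgvs_p),
                in_cosmic=_parse_flag(row.in_cosmic),
                cosmic_confirmed_somatic=_parse_flag(row.cosmic_confirmed_somatic),
                cosmic_pathogenic=_parse_flag(row.cosmic_pathogenic),
                cosmic_tissues=tissue_set,
                in_icgc=_parse_flag(row.in_icgc),
                ensembl_known=_parse_flag(row.ensembl_known),
                population_af=None if pd.isna(row.population_af) else float(row.population_af),
                sift=_norm_enum(row.sift, SIFT_LEVELS),
                polyphen=_norm_enum(row.polyphen, POLYPHEN_LEVELS),
            ))
        except AnnotationValidationError:
            bad_keys.append((str(row.chrom), int(row.pos), str(row.ref), str(row.alt)))
    if bad_keys:
        raise AnnotationValidationError(
            f"{len(bad_keys)} annotation rows violate invariants; offending keys: {bad_keys[:10]}"
        )
    return out


def patients_to_frame(patients: Iterable[Patient]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(p) for p in patients], columns=PATIENT_COLUMNS)


def frame_to_patients(df: pd.DataFrame) -> list[Patient]:
    out = []
    for row in df.itertuples(index=False):
        out.append(Patient(
            patient_id=str(row.patient_id),
            age_years=None if pd.isna(row.age_years) else float(row.age_years),
            gender=None if _is_missing(row.gender) else str(row.gender),
            t_stage=None if _is_missing(row.t_stage) else str(row.t_stage),
            n_stage=None if _is_missing(row.n_stage) else str(row.n_stage),
            m_stage=None if _is_missing(row.m_stage) else str(row.m_stage),
            overall_stage=None if _is_missing(row.overall_stage) else str(row.overall_stage),
            site=None if _is_missing(row.site) else str(row.site),
        ))
    return out


def _is_missing(value) -> bool:
    return value is None or (isinstance(value, float) and np.isnan(value)) or value in (MISSING, "")


_TRUE = {"1", "true", "yes", "t", "y"}
_FALSE = {"0", "false", "no", "f", "n", ".", "", "nan", "none"}


def _parse_flag(value) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return False
    text = str(value).strip().lower()
    if text in _TRUE:
        return True
    if text in _FALSE:
        return False
    raise ValueError(f"cannot parse flag value {value!r}")


# ---------------------------------------------------------------------------
# TSV
# ---------------------------------------------------------------------------

def _read_tsv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, na_values=[MISSING], keep_default_na=False)
    missing_cols = [c for c in required if c not in df.columns]
    if missing_cols:
        raise ValueError(f"{path}: missing required columns {missing_cols}")
    return df


def read_annotations(path: str | Path) -> pd.DataFrame:
    """Read and validate an annotation TSV; unknown columns are preserved."""
    df = _read_tsv(path, ANNOTATION_COLUMNS)
    df["pos"] = df["pos"].astype(int)
    df["population_af"] = pd.to_numeric(df["population_af"], errors="coerce")
    for col in ("in_cosmic", "cosmic_confirmed_somatic", "cosmic_pathogenic", "in_icgc", "ensembl_known"):
        df[col] = df[col].map(_parse_flag)
    df["consequence"] = df["consequence"].map(lambda v: _norm_enum(v, CONSEQUENCES) or "other")
    df["sift"] = df["sift"].map(lambda v: _norm_enum(v, SIFT_LEVELS))
    df["polyphen"] = df["polyphen"].map(lambda v: _norm_enum(v, POLYPHEN_LEVELS))
    validate_annotation_frame(df)
    return df


def validate_annotation_frame(df: pd.DataFrame) -> None:
    """Check the COSMIC-consistency invariants, listing offending keys."""
    has_tissue = df["cosmic_tissues"].notna() & (df["cosmic_tissues"].astype(str) != "")
    status = df["cosmic_confirmed_somatic"].astype(bool) | df["cosmic_pathogenic"].astype(bool)
    bad = (status | has_tissue) & ~df["in_cosmic"].astype(bool)
    if bad.any():
        keys = list(df.loc[bad, ["chrom", "pos", "ref", "alt"]].itertuples(index=False, name=None))
        raise AnnotationValidationError(
            f"{len(keys)} annotation rows carry COSMIC status or tissues without "
            f"in_cosmic; offending keys: {keys[:10]}"
        )


def read_patients(path: str | Path) -> pd.DataFrame:
    df = _read_tsv(path, PATIENT_COLUMNS)
    df["age_years"] = pd.to_numeric(df["age_years"], errors="coerce")
    for col, domain, upper in (
        ("gender", GENDERS, False), ("t_stage", T_STAGES, True), ("n_stage", N_STAGES, True),
        ("m_stage", M_STAGES, True), ("overall_stage", OVERALL_STAGES, True), ("site", SITES, False),
    ):
        df[col] = df[col].map(lambda v, d=domain, u=upper: _norm_enum(v, d, upper=u))
    return df


def write_tsv(path: str | Path, df: pd.DataFrame) -> None:
    """Write a TSV with '.' for missing values (round-trips with the readers)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, na_rep=MISSING)


def read_calls_tsv(path: str | Path) -> pd.DataFrame:
    df = _read_tsv(path, CALL_COLUMNS)
    df["pos"] = df["pos"].astype(int)
    for col in ("qual", "vaf_percent"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    for col in ("depth", "alt_depth"):
        df[col] = pd.to_numeric(df[col], errors="coerce").astype("Int64")
    return df


def write_classified(path: str | Path, classified: pd.DataFrame) -> None:
    write_tsv(path, classified)


def read_classified_tsv(path: str | Path) -> pd.DataFrame:
    """Read a classified-variant table written by :func:`write_classified`."""
    df = pd.read_csv(path, sep="\t", na_values=[MISSING], keep_default_na=False)
    df["pos"] = df["pos"].astype(int)
    flag_cols = [c for c in df.columns if c.startswith(("passed_", "excluded_", "novel_",
                 "in_icgc", "confirmed_", "pathogenic", "tissue_", "germline_", "damaging_"))]
    for col in flag_cols:
        df[col] = df[col].map(_parse_flag)
    for col in ("chrom", "ref", "alt", "gene"):
        df[col] = df[col].astype(str)
    return df


def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    """Read a gene x sample incidence matrix (first column = gene symbols)."""
    df = pd.read_csv(path, sep="\t")
    return df.set_index(df.columns[0]).astype(int)
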