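"""Reading and writing of regional-thickness and biomarker tables.

Two thickness dialects are supported:

* ``wide_tsv`` — one row per subject-visit, in the ``aparcstats2table``
  convention: ``lh_<region>_thickness`` / ``rh_<region>_thickness`` columns
  (the ``_thickness`` suffix is optional on read), plus covariate columns.
* ``long_csv`` — one row per subject-visit-hemisphere-region with columns
  ``subject, visit, hemi, region, thickness`` plus covariates.

Biomarkers travel in a separate one-row-per-subject CSV.  Missing values
are written as empty cells and accepted as empty, ``NA`` or ``NaN``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .regions import DESIKAN_KILLIANY_REGIONS, N_REGIONS

GROUPS = ("CTR", "AD", "FTD")
PHENOTYPES = ("none", "bvFTD", "nfvPPA", "svPPA")
FTD_PHENOTYPES = ("bvFTD", "nfvPPA", "svPPA")
SEXES = ("M", "F")

BIOMARKER_COLUMNS = (
    "csf_nfl",
    "csf_1433",
    "csf_ykl40",
    "plasma_ttau",
    "plasma_ptau",
    "plasma_nfl",
    "plasma_gfap",
    "plasma_uchl1",
)

_COVARIATE_COLUMNS = ("group", "phenotype", "sex", "age_at_mri", "age_of_onset")


@dataclass
class ThicknessRecord:
    """One subject-visit: 34 left + 34 right regional mean thicknesses (mm).

    ``lh_thickness`` and ``rh_thickness`` are ordered by the canonical
    Desikan-Killiany catalogue (:data:`cortasym.regions.DESIKAN_KILLIANY_REGIONS`).
    ``age_of_onset`` is NaN for controls; ``phenotype`` is ``"none"`` unless
    the diagnostic group is FTD.
    """

    subject_id: str
    visit: int
    group: str
    phenotype: str
    sex: str
    age_at_mri: float
    age_of_onset: float  # NaN when missing (always for CTR)
    lh_thickness: np.ndarray
    rh_thickness: np.ndarray

    def __post_init__(self) -> None:
        self.lh_thickness = np.asarray(self.lh_thickness, dtype=float)
        self.rh_thickness = np.asarray(self.rh_thickness, dtype=float)
        if self.visit < 1:
            raise ValueError(f"{self.subject_id}: visit must be >= 1, got {self.visit}")
        if self.group not in GROUPS:
            raise ValueError(f"{self.subject_id}: unknown group {self.group!r}")
        if self.phenotype not in PHENOTYPES:
            raise ValueError(f"{self.subject_id}: unknown phenotype {self.phenotype!r}")
        if (self.group == "FTD") != (self.phenotype in FTD_PHENOTYPES):
            raise ValueError(
                f"{self.subject_id}: phenotype {self.phenotype!r} inconsistent "
                f"with group {self.group!r}"
            )
        if self.sex not in SEXES:
            raise ValueError(f"{self.subject_id}: sex must be M or F, got {self.sex!r}")
        for hemi, values in (("lh", self.lh_thickness), ("rh", self.rh_thickness)):
            if values.shape != (N_REGIONS,):
                raise ValueError(
                    f"{self.subject_id}: {hemi} has {values.size} regions, "
                    f"expected {N_REGIONS}"
                )
            if not np.all(np.isfinite(values)) or np.any(values <= 0):
                raise ValueError(
                    f"{self.subject_id} visit {self.visit}: non-positive or "
                    f"non-finite {hemi} thickness value"
                )


@dataclass
class BiomarkerRecord:
    """Per-subject fluid biomarkers (pg/mL) and MMSE; NaN marks a missing value."""

    subject_id: str
    csf_nfl: float = math.nan
    csf_1433: float = math.nan
    csf_ykl40: float = math.nan
    plasma_ttau: float = math.nan
    plasma_ptau: float = math.nan
    plasma_nfl: float = math.nan
    plasma_gfap: float = math.nan
    plasma_uchl1: float = math.nan
    mmse: float = math.nan

    def __post_init__(self) -> None:
        for col in BIOMARKER_COLUMNS:
            v = getattr(self, col)
            if not math.isnan(v) and v < 0:
                raise ValueError(
                    f"{self.subject_id}: negative concentration for {col}: {v}"
                )
        if not math.isnan(self.mmse) and not 0 <= self.mmse <= 30:
            raise ValueError(
                f"{self.subject_id}: mmse must lie in [0, 30], got {self.mmse}"
            )


def _parse_optional_float(value) -> float:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return math.nan
    s = str(value).strip()
    if s == "" or s.lower() in {"na", "nan"}:
        return math.nan
    return float(s)


def _wide_region_columns(df: pd.DataFrame) -> dict[str, str]:
    """Map ``(hemi, region)`` keys like ``lh_insula`` to actual column names.

    Accepts both ``lh_<region>_thickness`` and ``lh_<region>`` headers,
    case-insensitively on the region label.
    """
    lookup: dict[str, str] = {}
    for col in df.columns:
        name = col.strip()
        low = name.lower()
        if not (low.startswith("lh_") or low.startswith("rh_")):
            continue
        core = low.removesuffix("_thickness")
        lookup[core] = name
    return lookup


def _records_from_wide(df: pd.DataFrame, path: str) -> list[ThicknessRecord]:
    lookup = _wide_region_columns(df)
    for hemi in ("lh", "rh"):
        for region in DESIKAN_KILLIANY_REGIONS:
            if f"{hemi}_{region}" not in lookup:
                raise ValueError(
                    f"{path}: missing thickness column for region {region!r} "
                    f"({hemi} hemisphere)"
                )
    records = []
    for idx, row in df.iterrows():
        sid = str(row["subject_id"])
        try:
            lh = np.array(
                [float(row[lookup[f"lh_{r}"]]) for r in DESIKAN_KILLIANY_REGIONS]
            )
            rh = np.array(
                [float(row[lookup[f"rh_{r}"]]) for r in DESIKAN_KILLIANY_REGIONS]
            )
        except (TypeError, ValueError) as exc:
            raise ValueError(
                f"{path}: non-numeric thickness in row for subject {sid!r} "
                f"(row {idx})"
            ) from exc
        records.append(
            ThicknessRecord(
                subject_id=sid,
                visit=int(row.get("visit", 1)),
                group=str(row["group"]),
                phenotype=str(row.get("phenotype", "none")),
                sex=str(row["sex"]),
                age_at_mri=float(row["age_at_mri"]),
                age_of_onset=_parse_optional_float(row.get("age_of_onset")),
                lh_thickness=lh,
                rh_thickness=rh,
            )
        )
    return records


def _records_from_long(df: pd.DataFrame, path: str) -> list[ThicknessRecord]:
    required = {"subject", "visit", "hemi", "region", "thickness"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: long CSV missing columns {sorted(missing)}")
    df = df.copy()
    df["region"] = df["region"].str.lower()
    records = []
    for (sid, visit), sub in df.groupby(["subject", "visit"], sort=True):
        arrays: dict[str, np.ndarray] = {}
        for hemi in ("lh", "rh"):
            hemi_rows = sub[sub["hemi"] == hemi]
            present = dict(zip(hemi_rows["region"], hemi_rows["thickness"]))
            values = np.empty(N_REGIONS)
            for i, region in enumerate(DESIKAN_KILLIANY_REGIONS):
                if region not in present:
                    raise ValueError(
                        f"{path}: subject {sid!r} visit {visit} is missing "
                        f"region {region!r} ({hemi})"
                    )
                try:
                    values[i] = float(present[region])
                except (TypeError, ValueError) as exc:
                    raise ValueError(
                        f"{path}: non-numeric thickness for subject {sid!r} "
                        f"visit {visit} region {region!r}"
                    ) from exc
            arrays[hemi] = values
        first = sub.iloc[0]
        records.append(
            ThicknessRecord(
                subject_id=str(sid),
                visit=int(visit),
                group=str(first["group"]),
                phenotype=str(first.get("phenotype", "none")),
                sex=str(first["sex"]),
                age_at_mri=float(first["age_at_mri"]),
                age_of_onset=_parse_optional_float(first.get("age_of_onset")),
                lh_thickness=arrays["lh"],
                rh_thickness=arrays["rh"],
            )
        )
    return records


def read_thickness_table(path, dialect: str = "wide_tsv") -> list[ThicknessRecord]:
    """Read thickness records from ``path``; region order is canonicalised.

    Parameters
    ----------
    path : str or Path
        Input table.
    dialect : {"wide_tsv", "long_csv"}
        Table layout (see module docstring).
    """
    path = Path(path)
    if dialect == "wide_tsv":
        df = pd.read_csv(path, sep="\t", dtype={"subject_id": str}, float_precision="round_trip")
        return _records_from_wide(df, str(path))
    if dialect == "long_csv":
        df = pd.read_csv(path, dtype={"subject": str, "region": str, "hemi": str}, float_precision="round_trip")
        return _records_from_long(df, str(path))
    raise ValueError(f"unknown dialect {dialect!r}")


def write_thickness_table(records: Iterable[ThicknessRecord], path, dialect: str = "wide_tsv") -> None:
    """Write records to ``path``; exact inverse of :func:`read_thickness_table`."""
    path = Path(path)
    records = list(records)
    if dialect == "wide_tsv":
        rows = []
        for rec in records:
            row: dict = {
                "subject_id": rec.subject_id,
                "visit": rec.visit,
                "group": rec.group,
                "phenotype": rec.phenotype,
                "sex": rec.sex,
                "age_at_mri": rec.age_at_mri,
                "age_of_onset": "" if math.isnan(rec.age_of_onset) else rec.age_of_onset,
            }
            for i, region in enumerate(DESIKAN_KILLIANY_REGIONS):
                row[f"lh_{region}_thickness"] = repr(float(rec.lh_thickness[i]))
                row[f"rh_{region}_thickness"] = repr(float(rec.rh_thickness[i]))
            rows.append(row)
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    elif dialect == "long_csv":
        rows = []
        for rec in records:
            for hemi, values in (("lh", rec.lh_thickness), ("rh", rec.rh_thickness)):
                for region, value in zip(DESIKAN_KILLIANY_REGIONS, values):
                    rows.append(
                        {
                            "subject": rec.subject_id,
                            "visit": rec.visit,
                            "hemi": hemi,
                            "region": region,
                            "thickness": repr(float(value)),
                            "group": rec.group,
                            "phenotype": rec.phenotype,
                            "sex": rec.sex,
                            "age_at_mri": rec.age_at_mri,
                            "age_of_onset": ""
                            if math.isnan(rec.age_of_onset)
                            else rec.age_of_onset,
                        }
                    )
        pd.DataFrame(rows).to_csv(path, index=False)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def read_biomarkers(path) -> list[BiomarkerRecord]:
    """Read the per-subject biomarker CSV; empty/NA cells become NaN, never 0."""
    df = pd.read_csv(path, dtype={"subject_id": str}, float_precision="round_trip")
    records = []
    for _, row in df.iterrows():
        kwargs = {"subject_id": str(row["subject_id"])}
        for col in (*BIOMARKER_COLUMNS, "mmse"):
            if col in df.columns:
                kwargs[col] = _parse_optional_float(row[col])
        records.append(BiomarkerRecord(**kwargs))
    return records


def write_biomarkers(records: Iterable[BiomarkerRecord], path) -> None:
    rows = []
    for rec in records:
        row = {"subject_id": rec.subject_id}
        for col in (*BIOMARKER_COLUMNS, "mmse"):
            v = getattr(rec, col)
            row[col] = "" if math.isnan(v) else repr(float(v))
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def covariate_table(records: Sequence[ThicknessRecord]) -> pd.DataFrame:
    """One row per subject-visit with the demographic covariates."""
    return pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in records],
            "visit": [r.visit for r in records],
            "group": [r.group for r in records],
            "phenotype": [r.phenotype for r in records],
            "sex": [r.sex for r in records],
            "age_at_mri": [r.age_at_mri for r in records],
            "age_of_onset": [r.age_of_onset for r in records],
        }
    )


def build_cohort_table(
    records: Sequence[ThicknessRecord],
    cai_table: pd.DataFrame,
    biomarkers: Sequence[BiomarkerRecord] | None = None,
) -> pd.DataFrame:
    """Merge covariates, per-visit asymmetry index and per-subject biomarkers.

    The result is the substrate of every downstream analysis: one row per
    subject-visit with columns ``subject_id, visit, group, phenotype, sex,
    age_at_mri, age_of_onset, cai`` plus biomarker columns and ``mmse``
    when biomarker records are supplied.
    """
    table = covariate_table(records).merge(
        cai_table[["subject_id", "visit", "cai"]], on=["subject_id", "visit"], how="left"
    )
    if biomarkers is not None:
        bio_df = pd.DataFrame(
            [
                {f.name: getattr(rec, f.name) for f in fields(BiomarkerRecord)}
                for rec in biomarkers
            ]
        )
        table = table.merge(bio_df, on="subject_id", how="left")
    return table
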