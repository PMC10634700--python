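"""Reading, validating and writing the tabular data model.

Three input tables drive every analysis:

* **cell table** — one row per segmented cell: ``cell_id``, ``region_id``,
  centroid coordinates ``x_um``/``y_um`` in microns (per-region frame), and
  one 0/1 positivity column per panel marker;
* **region metadata** — ``region_id``, ``patient_id``, treatment ``cohort``,
  histopathologic ``site`` and tissue ``area_mm2``;
* **patient table** — ``patient_id``, ``cohort`` and, for the treated cohort,
  disease-free survival ``dfs_months``.

All files are plain UTF-8 CSV with a header row; writers prepend a
``# spatialtme-schema: N`` comment line which readers skip. Positivity is
consumed as already-thresholded 0/1; intensity columns are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import COHORTS, SCHEMA_VERSION, SITES


class SchemaError(ValueError):
    """A required column is missing or an enumerated value is invalid."""


class ParseError(ValueError):
    """A cell-level value could not be interpreted (reported with row index)."""


_CELL_REQUIRED = ("cell_id", "region_id", "x_um", "y_um")
_REGION_REQUIRED = ("region_id", "patient_id", "cohort", "site", "area_mm2")
_PATIENT_REQUIRED = ("patient_id", "cohort")


def _read_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", dtype=str, keep_default_na=False)


def read_cell_table(path, marker_list: list[str]) -> pd.DataFrame:
    """Read a cell table, parsing marker positivity columns as booleans.

    Row order is preserved. A missing required column raises
    :class:`SchemaError` naming the column; a positivity value other than
    0/1 raises :class:`ParseError` citing the offending row index.
    """
    df = _read_csv(path)
    for col in list(_CELL_REQUIRED) + list(marker_list):
        if col not in df.columns:
            raise SchemaError(f"cell table is missing required column {col!r}")
    out = pd.DataFrame(
        {
            "cell_id": df["cell_id"].astype(str),
            "region_id": df["region_id"].astype(str),
            "x_um": pd.to_numeric(df["x_um"]).astype(float),
            "y_um": pd.to_numeric(df["y_um"]).astype(float),
        }
    )
    for marker in marker_list:
        vals = df[marker].str.strip()
        bad = ~vals.isin(["0", "1"])
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ParseError(
                f"non-0/1 positivity value {vals.iloc[row]!r} for marker "
                f"{marker!r} at row {row}"
            )
        out[marker] = vals == "1"
    if out["cell_id"].duplicated().any():
        dup = out.loc[out["cell_id"].duplicated(), "cell_id"].iloc[0]
        raise SchemaError(f"duplicate cell_id {dup!r}")
    if (out["x_um"] < 0).any() or (out["y_um"] < 0).any():
        raise ParseError("negative centroid coordinate in cell table")
    # Carry through optional derived columns when present.
    for extra in ("state", "barcode"):
        if extra in df.columns:
            out[extra] = df[extra].replace("", None)
    return out


def read_region_metadata(path) -> pd.DataFrame:
    """Read region metadata keyed (and indexed) by ``region_id``."""
    df = _read_csv(path)
    for col in _REGION_REQUIRED:
        if col not in df.columns:
            raise SchemaError(f"region table is missing required column {col!r}")
    if df["region_id"].duplicated().any():
        dup = df.loc[df["region_id"].duplicated(), "region_id"].iloc[0]
        raise SchemaError(f"duplicate region_id {dup!r}")
    bad_cohort = ~df["cohort"].isin(COHORTS)
    if bad_cohort.any():
        raise SchemaError(
            f"unknown cohort token {df.loc[bad_cohort, 'cohort'].iloc[0]!r}"
        )
    bad_site = ~df["site"].isin(SITES)
    if bad_site.any():
        raise SchemaError(
            f"unknown site token {df.loc[bad_site, 'site'].iloc[0]!r}"
        )
    area = pd.to_numeric(df["area_mm2"]).astype(float)
    if (area <= 0).any():
        raise SchemaError("area_mm2 must be positive for every region")
    out = pd.DataFrame(
        {
            "region_id": df["region_id"].astype(str),
            "patient_id": df["patient_id"].astype(str),
            "cohort": df["cohort"],
            "site": df["site"],
            "area_mm2": area,
        }
    ).set_index("region_id", drop=False)
    return out


def read_patient_table(path) -> pd.DataFrame:
    """Read the patient table (DFS months optional per patient)."""
    df = _read_csv(path)
    for col in _PATIENT_REQUIRED:
        if col not in df.columns:
            raise SchemaError(f"patient table is missing required column {col!r}")
    if df["patient_id"].duplicated().any():
        raise SchemaError("duplicate patient_id in patient table")
    bad_cohort = ~df["cohort"].isin(COHORTS)
    if bad_cohort.any():
        raise SchemaError(
            f"unknown cohort token {df.loc[bad_cohort, 'cohort'].iloc[0]!r}"
        )
    out = pd.DataFrame(
        {
            "patient_id": df["patient_id"].astype(str),
            "cohort": df["cohort"],
        }
    )
    if "dfs_months" in df.columns:
        out["dfs_months"] = pd.to_numeric(
            df["dfs_months"].replace("", np.nan)
        ).astype(float)
    else:
        out["dfs_months"] = np.nan
    if "dfs_label" in df.columns:
        out["dfs_label"] = df["dfs_label"].replace("", None)
    return out.set_index("patient_id", drop=False)


def write_table(df: pd.DataFrame, path) -> None:
    """Write any of the data-model tables with a schema-version comment.

    Boolean positivity columns are written as 0/1 so the readers' strict
    parse accepts a round trip.
    """
    out = df.copy()
    for col in out.columns:
        if out[col].dtype == bool:
            out[col] = out[col].astype(int)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"# spatialtme-schema: {SCHEMA_VERSION}\n")
        out.to_csv(fh, index=False, lineterminator="\n")


def write_feature_matrix(matrix: pd.DataFrame, path) -> None:
    """Write a region x feature matrix with a 2-row (family, key) header."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"# spatialtme-schema: {SCHEMA_VERSION}\n")
        matrix.to_csv(fh, index=True, index_label="region_id", lineterminator="\n")


def read_feature_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#", header=[0, 1], index_col=0)
    df.index = df.index.astype(str)
    df.index.name = "region_id"
    df.columns = pd.MultiIndex.from_tuples(
        [(f, k) for f, k in df.columns], names=["family", "key"]
    )
    return df


# ---------------------------------------------------------------------------
# Cross-table validation
# ---------------------------------------------------------------------------

@dataclass
class ValidationIssue:
    severity: str  # "error" | "warning"
    message: str


@dataclass
class ValidationReport:
    issues: list[ValidationIssue] = field(default_factory=list)

    @property
    def errors(self) -> list[ValidationIssue]:
        return [i for i in self.issues if i.severity == "error"]

    @property
    def warnings(self) -> list[ValidationIssue]:
        return [i for i in self.issues if i.severity == "warning"]

    def __bool__(self) -> bool:  # truthy when clean
        return not self.errors


def validate_dataset(
    cells: pd.DataFrame,
    regions: pd.DataFrame,
    patients: pd.DataFrame,
    require_dfs: bool = False,
) -> ValidationReport:
    """Cross-check the three tables; never raises, caller inspects severities."""
    report = ValidationReport()
    known_regions = set(regions["region_id"])
    orphan = sorted(set(cells["region_id"]) - known_regions)
    for rid in orphan:
        report.issues.append(
            ValidationIssue("error", f"cells reference unknown region {rid!r}")
        )
    populated = set(cells["region_id"])
    for rid in regions["region_id"]:
        if rid not in populated:
            report.issues.append(
                ValidationIssue("warning", f"region {rid!r} has no cells")
            )
    spans = regions.groupby("patient_id")["cohort"].nunique()
    for pid in spans.index[spans > 1]:
        report.issues.append(
            ValidationIssue("error", f"patient {pid!r} spans multiple cohorts")
        )
    if require_dfs:
        treated = patients[patients["cohort"] == "aCD40"]
        missing = treated.index[treated["dfs_months"].isna()]
        for pid in missing:
            report.issues.append(
                ValidationIssue(
                    "error", f"aCD40 patient {pid!r} lacks dfs_months"
                )
            )
    return report
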