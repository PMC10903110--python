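"""Containers and CSV round-trip IO for multiplex bead-array panel data.

A :class:`PanelDataset` holds replicate-level fluorescence (or interpolated
concentration) values for a sample × analyte panel, per-well bead counts, and
sample metadata (genotype, treatment, optional continuous response). A
:class:`CleanedMatrix` is the replicate-averaged sample × analyte matrix
produced by the cleaning pipeline, together with its exclusion audit log.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

GENOTYPES = ("APOE3", "APOE4")
TREATMENTS = ("vehicle", "abeta")

METADATA_COLUMNS = ("genotype", "treatment")


class PanelError(ValueError):
    """Raised for structurally invalid panel data."""


@dataclasses.dataclass
class PanelDataset:
    """Replicate-level panel measurements with sample metadata.

    Parameters
    ----------
    samples : pandas.DataFrame
        Indexed by sample id; columns ``genotype``, ``treatment`` and
        optionally ``response`` (a per-sample continuous value such as basal
        oxygen consumption rate, pmol O2/min/ug protein).
    analytes : list of str
        Ordered analyte names, shared by all samples.
    values : ndarray, shape (n_samples, n_analytes, max_replicates)
        Replicate measurements, NaN-padded where fewer replicates exist.
        Every (sample, analyte) cell must carry at least one finite value.
    bead_counts : ndarray or None
        Non-negative integer bead counts, same shape as ``values`` (NaN where
        no replicate exists).
    truth : dict or None
        For synthetic panels only: record of planted effects and outliers.
    bead_flags : pandas.DataFrame or None
        Populated by :func:`cytopls.cleaning.review_bead_counts`.
    """

    samples: pd.DataFrame
    analytes: list[str]
    values: np.ndarray
    bead_counts: np.ndarray | None = None
    truth: dict | None = None
    bead_flags: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise PanelError("values must be (n_samples, n_analytes, n_replicates)")
        n, m, _ = self.values.shape
        if n != len(self.samples):
            raise PanelError("values row count does not match sample metadata")
        if m != len(self.analytes):
            raise PanelError("values column count does not match analyte list")
        if not np.isfinite(self.values).any(axis=2).all():
            raise PanelError("every (sample, analyte) cell needs >=1 replicate value")
        finite = np.isfinite(self.values)
        if np.any(self.values[finite] < 0):
            raise PanelError("replicate values must be >= 0")
        if self.bead_counts is not None:
            self.bead_counts = np.asarray(self.bead_counts, dtype=float)
            if self.bead_counts.shape != self.values.shape:
                raise PanelError("bead_counts shape must match values")

    # -- convenience ------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_analytes(self) -> int:
        return self.values.shape[1]

    @property
    def max_replicates(self) -> int:
        return self.values.shape[2]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.samples.index)

    def replicate_count(self) -> int:
        """Total number of (finite) replicate measurements in the panel."""
        return int(np.isfinite(self.values).sum())

    def subset(self, sample_ids: list[str]) -> "PanelDataset":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return dataclasses.replace(
            self,
            samples=self.samples.loc[sample_ids],
            values=self.values[idx],
            bead_counts=None if self.bead_counts is None else self.bead_counts[idx],
            bead_flags=None,
        )


@dataclasses.dataclass
class CleanedMatrix:
    """Sample × analyte replicate means plus the exclusion audit trail.

    ``values[i, j]`` is the arithmetic mean of the retained replicates for
    cell (i, j); cells with zero retained replicates are NaN and listed in
    ``missing`` (never silently imputed). ``fraction_excluded`` is the number
    of outlier-excluded replicate measurements over the total replicate count.
    """

    values: pd.DataFrame
    n_replicates_used: pd.DataFrame
    exclusions: pd.DataFrame
    fraction_excluded: float
    missing: list[tuple[str, str]] = dataclasses.field(default_factory=list)
    dropped_analytes: list[str] = dataclasses.field(default_factory=list)

    @property
    def analytes(self) -> list[str]:
        return list(self.values.columns)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)


EXCLUSION_COLUMNS = ["sample_id", "analyte", "replicate", "value", "reason"]


def empty_exclusions() -> pd.DataFrame:
    return pd.DataFrame(columns=EXCLUSION_COLUMNS)


# ---------------------------------------------------------------------------
# CSV writers
# ---------------------------------------------------------------------------

def _wide_frame(panel: PanelDataset, cube: np.ndarray) -> pd.DataFrame:
    rows = []
    for i, sid in enumerate(panel.sample_ids):
        for r in range(panel.max_replicates):
            if not np.isfinite(panel.values[i, :, r]).any():
                continue
            rows.append([sid, r + 1, *cube[i, :, r]])
    return pd.DataFrame(rows, columns=["sample_id", "replicate", *panel.analytes])


def write_panel(panel: PanelDataset, out_dir: str | Path, sep: str = ",") -> dict:
    """Write a panel as wide CSVs: measurements, bead counts, metadata, truth.

    Returns the mapping of logical name to written path; all files round-trip
    through :func:`read_panel`.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {"measurements": out / "measurements.csv", "metadata": out / "metadata.csv"}
    _wide_frame(panel, panel.values).to_csv(paths["measurements"], index=False, sep=sep)
    meta = panel.samples.reset_index(names="sample_id")
    meta.to_csv(paths["metadata"], index=False, sep=sep)
    if panel.bead_counts is not None:
        paths["bead_counts"] = out / "bead_counts.csv"
        _wide_frame(panel, panel.bead_counts).to_csv(
            paths["bead_counts"], index=False, sep=sep
        )
    if panel.truth is not None:
        paths["truth"] = out / "truth.json"
        paths["truth"].write_text(json.dumps(_jsonable(panel.truth), indent=1, sort_keys=True))
    return paths


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


# ---------------------------------------------------------------------------
# CSV readers (wide and long dialects)
# ---------------------------------------------------------------------------

def read_panel(
    measurements: str | Path,
    metadata: str | Path,
    bead_counts: str | Path | None = None,
    truth: str | Path | None = None,
    sep: str = ",",
    decimal: str = ".",
) -> PanelDataset:
    """Read a wide-format panel (one row per sample-replicate)."""
    meas = pd.read_csv(measurements, sep=sep, decimal=decimal)
    meta = pd.read_csv(metadata, sep=sep, decimal=decimal).set_index("sample_id")
    for col in METADATA_COLUMNS:
        if col not in meta.columns:
            raise PanelError(f"metadata is missing required column '{col}'")
    analytes = [c for c in meas.columns if c not in ("sample_id", "replicate")]
    sample_ids = list(meta.index)
    max_rep = int(meas["replicate"].max())
    values = np.full((len(sample_ids), len(analytes), max_rep), np.nan)
    beads = None
    if bead_counts is not None:
        bead_df = pd.read_csv(bead_counts, sep=sep, decimal=decimal)
        beads = np.full_like(values, np.nan)
    for _, row in meas.iterrows():
        i = sample_ids.index(row["sample_id"])
        r = int(row["replicate"]) - 1
        values[i, :, r] = [row[a] for a in analytes]
    if beads is not None:
        for _, row in bead_df.iterrows():
            i = sample_ids.index(row["sample_id"])
            r = int(row["replicate"]) - 1
            beads[i, :, r] = [row[a] for a in analytes]
        beads[~np.isfinite(values)] = np.nan
    truth_dict = None
    if truth is not None and Path(truth).exists():
        truth_dict = json.loads(Path(truth).read_text())
    return PanelDataset(
        samples=meta, analytes=analytes, values=values, bead_counts=beads, truth=truth_dict
    )


def read_panel_long(
    path: str | Path,
    metadata: str | Path,
    sep: str = ",",
    decimal: str = ".",
    value_column: str = "value",
) -> PanelDataset:
    """Read a long-format panel.

    Expected columns: ``sample_id``, ``analyte``, ``replicate``, the designated
    ``value_column`` (fluorescence or interpolated concentration — the outlier
    rule is applied to whichever the caller designates), and optionally
    ``bead_count``.
    """
    long = pd.read_csv(path, sep=sep, decimal=decimal)
    meta = pd.read_csv(metadata, sep=sep, decimal=decimal).set_index("sample_id")
    for col in ("sample_id", "analyte", "replicate", value_column):
        if col not in long.columns:
            raise PanelError(f"long-format file is missing column '{col}'")
    analytes = list(pd.unique(long["analyte"]))
    sample_ids = list(meta.index)
    max_rep = int(long["replicate"].max())
    values = np.full((len(sample_ids), len(analytes), max_rep), np.nan)
    beads = np.full_like(values, np.nan) if "bead_count" in long.columns else None
    a_index = {a: j for j, a in enumerate(analytes)}
    s_index = {s: i for i, s in enumerate(sample_ids)}
    for _, row in long.iterrows():
        i, j, r = s_index[row["sample_id"]], a_index[row["analyte"]], int(row["replicate"]) - 1
        values[i, j, r] = row[value_column]
        if beads is not None:
            beads[i, j, r] = row["bead_count"]
    return PanelDataset(samples=meta, analytes=analytes, values=values, bead_counts=beads)


def write_cleaned(matrix: CleanedMatrix, out_dir: str | Path, sep: str = ",") -> dict:
    """Write cleaned values, replicate counts and the exclusion audit CSVs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "values": out / "cleaned_values.csv",
        "n_replicates": out / "n_replicates_used.csv",
        "exclusions": out / "exclusions.csv",
        "summary": out / "cleaning_summary.json",
    }
    matrix.values.to_csv(paths["values"], index_label="sample_id", sep=sep)
    matrix.n_replicates_used.to_csv(paths["n_replicates"], index_label="sample_id", sep=sep)
    matrix.exclusions.to_csv(paths["exclusions"], index=False, sep=sep)
    summary = {
        "fraction_excluded": matrix.fraction_excluded,
        "n_exclusions": int(len(matrix.exclusions)),
        "missing_cells": [list(c) for c in matrix.missing],
        "dropped_analytes": matrix.dropped_analytes,
    }
    paths["summary"].write_text(json.dumps(summary, indent=1, sort_keys=True))
    return paths
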