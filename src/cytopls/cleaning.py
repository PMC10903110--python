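"""Automated bead-array data cleaning: bead-count review, triplicate outlier
designation, replicate averaging, and low-prevalence analyte filtering.

The outlier rule operates on the measured scale supplied (fluorescence or
interpolated concentration) without transformation; it is covariant under
positive affine maps of the triplicate, so the designation never depends on
units or offset. Every removal is logged so the raw replicate multiset can be
reconstructed from retained ∪ excluded values for every cell.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .panel import (
    EXCLUSION_COLUMNS,
    CleanedMatrix,
    PanelDataset,
    empty_exclusions,
)

DEFAULT_MIN_BEADS = 35
DEFAULT_MIN_NONZERO_FRACTION = 0.25


class CleaningError(ValueError):
    """Raised for unusable inputs to the cleaning pipeline."""


def detect_triplicate_outlier(values, ratio: float = 2.0) -> int | None:
    """Designate at most one replicate of a triplicate as an outlier.

    Replicate ``x`` with companions ``y, z`` is the outlier iff its separation
    from the other two exceeds ``ratio`` times the distance between them:
    ``min(|x - y|, |x - z|) > ratio * |y - z|`` (strict; ties are retained;
    default ratio 2). With fewer than three finite values the rule is not
    applicable ("the other two" is undefined for a pair) and ``None`` is
    returned.
    """
    arr = np.asarray(values, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size != 3:
        return None
    for i in range(3):
        x = arr[i]
        y, z = arr[[j for j in range(3) if j != i]]
        if min(abs(x - y), abs(x - z)) > ratio * abs(y - z):
            return int(np.flatnonzero(np.isfinite(np.asarray(values, dtype=float)))[i])
    return None


def review_bead_counts(
    panel: PanelDataset,
    min_beads: int = DEFAULT_MIN_BEADS,
    strict: bool = False,
    require_beads: bool = True,
) -> PanelDataset:
    """Flag replicate wells whose bead count falls below ``min_beads``.

    Default behavior flags without removal; with ``strict=True`` the flagged
    replicates are masked out (recorded as low_bead_count exclusions by
    :func:`clean_panel`) before outlier detection. Missing bead counts are an
    error unless ``require_beads=False``.
    """
    if panel.bead_counts is None:
        if require_beads:
            raise CleaningError(
                "panel has no bead counts; pass require_beads=False (--no-bead-check) to skip review"
            )
        return dataclasses.replace(panel, bead_flags=pd.DataFrame(
            columns=["sample_id", "analyte", "replicate", "bead_count", "value", "removed"]
        ))
    low = (panel.bead_counts < min_beads) & np.isfinite(panel.values)
    rows = []
    for i, j, r in zip(*np.nonzero(low)):
        rows.append(
            [
                panel.sample_ids[i],
                panel.analytes[j],
                int(r),
                float(panel.bead_counts[i, j, r]),
                float(panel.values[i, j, r]),
                bool(strict),
            ]
        )
    flags = pd.DataFrame(
        rows, columns=["sample_id", "analyte", "replicate", "bead_count", "value", "removed"]
    )
    values = panel.values
    if strict and len(rows):
        values = panel.values.copy()
        values[low] = np.nan
    return dataclasses.replace(panel, values=values, bead_flags=flags)


def clean_panel(
    panel: PanelDataset,
    min_beads: int = DEFAULT_MIN_BEADS,
    strict_beads: bool = False,
    bead_check: bool = True,
) -> CleanedMatrix:
    """Bead-count review, per-triplicate outlier removal, replicate averaging.

    For every (sample, analyte) cell the triplicate rule designates at most
    one replicate for removal; the cleaned value is the arithmetic mean of
    the retained replicates. Cells left with zero retained replicates are
    reported as missing (NaN), never imputed. ``fraction_excluded`` counts
    outlier removals over the total number of replicate measurements.
    """
    total_reps = panel.replicate_count()
    reviewed = review_bead_counts(
        panel, min_beads=min_beads, strict=strict_beads, require_beads=bead_check
    )
    exclusions: list[list] = []
    if reviewed.bead_flags is not None and len(reviewed.bead_flags):
        for _, f in reviewed.bead_flags.iterrows():
            if f["removed"]:
                exclusions.append(
                    [f["sample_id"], f["analyte"], int(f["replicate"]), f["value"], "low_bead_count"]
                )

    vals = reviewed.values
    n, m, _ = vals.shape
    means = np.full((n, m), np.nan)
    used = np.zeros((n, m), dtype=int)
    missing: list[tuple[str, str]] = []
    n_outliers = 0
    for i in range(n):
        for j in range(m):
            cell = vals[i, j]
            finite = np.isfinite(cell)
            keep = finite.copy()
            out = detect_triplicate_outlier(cell)
            if out is not None:
                keep[out] = False
                n_outliers += 1
                exclusions.append(
                    [panel.sample_ids[i], panel.analytes[j], out, float(cell[out]), "outlier"]
                )
            if keep.any():
                means[i, j] = cell[keep].mean()
                used[i, j] = int(keep.sum())
            else:
                missing.append((panel.sample_ids[i], panel.analytes[j]))

    excl_df = (
        pd.DataFrame(exclusions, columns=EXCLUSION_COLUMNS) if exclusions else empty_exclusions()
    )
    return CleanedMatrix(
        values=pd.DataFrame(means, index=panel.samples.index, columns=panel.analytes),
        n_replicates_used=pd.DataFrame(used, index=panel.samples.index, columns=panel.analytes),
        exclusions=excl_df,
        fraction_excluded=n_outliers / total_reps if total_reps else 0.0,
        missing=missing,
    )


def filter_low_prevalence(
    matrix: CleanedMatrix,
    min_nonzero_fraction: float = DEFAULT_MIN_NONZERO_FRACTION,
) -> CleanedMatrix:
    """Drop analytes unless strictly more than ``min_nonzero_fraction`` of
    samples have non-zero values (missing cells count as not non-zero).

    Dropped analytes are appended to the audit log; dropping every analyte is
    an error.
    """
    vals = matrix.values
    nonzero_frac = ((vals != 0) & vals.notna()).mean(axis=0)
    keep = nonzero_frac > min_nonzero_fraction
    dropped = [a for a in vals.columns if not keep[a]]
    if not keep.any():
        raise CleaningError(
            f"all analytes have non-zero fraction <= {min_nonzero_fraction}; nothing to analyze"
        )
    return CleanedMatrix(
        values=vals.loc[:, keep],
        n_replicates_used=matrix.n_replicates_used.loc[:, keep],
        exclusions=matrix.exclusions,
        fraction_excluded=matrix.fraction_excluded,
        missing=matrix.missing,
        dropped_analytes=matrix.dropped_analytes + dropped,
    )
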