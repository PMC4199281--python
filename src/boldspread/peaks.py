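"""Subject/run-specific ROI peaks and within-group peak-location dispersion.

A peak is the voxel of extreme signed percent signal change within an ROI
(intersected with the brain mask): the maximum for activation, the minimum
for deactivation.  Letting the peak vary by subject respects individual
anatomy.  Dispersion quantifies within-group spatial consistency: for every
subject, the mean Euclidean mm distance between their peak and each
same-group peer's peak, averaged across conditions and across all regions of
a network, reported raw and log10-transformed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from boldspread.volumes import MaskVolume, StatVolume, check_same_grid, voxel_to_mm

__all__ = ["PeakRecord", "RoiError", "find_peak", "peak_table", "dispersion"]


class RoiError(ValueError):
    """Raised when an ROI cannot be analysed (e.g. empty ROI-within-brain)."""


@dataclass(frozen=True)
class PeakRecord:
    """Location and signed value of one ROI extremum."""

    subject_id: str
    run_id: str
    roi_label: str
    sign: str  # "activation" or "deactivation"
    index: tuple[int, int, int]
    mm: tuple[float, float, float]
    value: float


def find_peak(
    vol: StatVolume,
    roi: MaskVolume,
    brain: MaskVolume | None = None,
    sign: str = "activation",
) -> PeakRecord:
    """Locate the ROI extremum of a statistical map.

    Activation peaks are the argmax over ROI ∩ brain, deactivation peaks the
    argmin.  Ties are broken deterministically at the smallest linear voxel
    index in array-scan order (continuous data never ties in practice).
    """
    if sign not in ("activation", "deactivation"):
        raise ValueError(f"sign must be 'activation' or 'deactivation', got {sign!r}")
    check_same_grid(vol, roi)
    mask = roi.data
    if brain is not None:
        check_same_grid(vol, brain)
        mask = mask & brain.data
    if not mask.any():
        raise RoiError(f"ROI {roi.label!r} has no in-brain voxels")
    values = np.where(mask, vol.data, -np.inf if sign == "activation" else np.inf)
    flat = int(np.argmax(values) if sign == "activation" else np.argmin(values))
    index = tuple(int(i) for i in np.unravel_index(flat, vol.shape))
    return PeakRecord(
        subject_id=vol.subject_id,
        run_id=vol.run_id,
        roi_label=roi.label,
        sign=sign,
        index=index,  # type: ignore[arg-type]
        mm=tuple(voxel_to_mm(index, vol)),  # type: ignore[arg-type]
        value=float(vol.data[index]),
    )


def peak_table(peaks: list[PeakRecord]) -> pd.DataFrame:
    """Long table of peaks: one row per subject x run x ROI."""
    return pd.DataFrame(
        {
            "subject_id": p.subject_id,
            "run_id": p.run_id,
            "roi_label": p.roi_label,
            "sign": p.sign,
            "i": p.index[0],
            "j": p.index[1],
            "k": p.index[2],
            "x_mm": p.mm[0],
            "y_mm": p.mm[1],
            "z_mm": p.mm[2],
            "value": p.value,
        }
        for p in peaks
    )


def dispersion(
    peaks: pd.DataFrame,
    group_col: str = "group",
    network_col: str = "network",
    condition_cols: tuple[str, ...] = ("run_id",),
) -> pd.DataFrame:
    """Per-subject peak-location dispersion within each group and network.

    Within each (group, network, ROI, condition) cell the per-subject score is
    the mean Euclidean mm distance to every other subject's peak; scores are
    then averaged across conditions and ROIs, yielding one value per subject
    per network.  Returns columns ``subject_id, group, network,
    dispersion_mm, dispersion_log10`` (log10 of the mm value; 0 distances give
    -inf and are left to the caller).

    ``peaks`` needs columns ``subject_id, x_mm, y_mm, z_mm, roi_label`` plus
    the group/network/condition columns.  Raises when any cell has < 2
    subjects.
    """
    required = {"subject_id", "x_mm", "y_mm", "z_mm", "roi_label", group_col, network_col}
    missing = required - set(peaks.columns)
    if missing:
        raise ValueError(f"peaks table missing columns: {sorted(missing)}")

    cell_cols = [group_col, network_col, "roi_label", *condition_cols]
    rows = []
    for keys, cell in peaks.groupby(cell_cols, sort=True):
        if cell["subject_id"].duplicated().any():
            raise ValueError(f"duplicate subjects within cell {keys}")
        n = len(cell)
        if n < 2:
            raise ValueError(f"cell {keys} has {n} subject(s); need >= 2 for dispersion")
        coords = cell[["x_mm", "y_mm", "z_mm"]].to_numpy(dtype=float)
        diff = coords[:, None, :] - coords[None, :, :]
        dist = np.sqrt((diff**2).sum(axis=2))
        mean_to_peers = (dist.sum(axis=1)) / (n - 1)  # diagonal is 0
        keys = keys if isinstance(keys, tuple) else (keys,)
        for sid, d in zip(cell["subject_id"], mean_to_peers):
            rows.append(
                {
                    "subject_id": sid,
                    group_col: keys[0],
                    network_col: keys[1],
                    "dispersion_mm": d,
                }
            )
    per_cell = pd.DataFrame(rows)
    out = (
        per_cell.groupby(["subject_id", group_col, network_col], as_index=False)[
            "dispersion_mm"
        ].mean()
    )
    with np.errstate(divide="ignore"):
        out["dispersion_log10"] = np.log10(out["dispersion_mm"].to_numpy())
    return out.rename(columns={group_col: "group", network_col: "network"})
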