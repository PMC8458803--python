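"""Tube-based calibration of fitted S0 maps to absolute TSC, and ROI summaries.

The fitted ordinate at TE = 0 (S0) is proportional to tissue sodium content
but carries an arbitrary scanner scale.  Reference tubes of known
concentration imaged in the same field of view pin that scale: an ordinary
least-squares line ``s0 = slope * concentration + intercept`` is fitted to the
per-tube mean S0, and inverting it voxelwise yields the total sodium
concentration (TSC) map in mmol/L wet tissue.  ROI statistics are the mean
TSC over converged voxels plus the ROI volume as a percentage of the
intracranial volume (ICV).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "CalibrationModel",
    "TSCMap",
    "ROISummary",
    "tube_mean_signals",
    "fit_calibration",
    "apply_calibration",
    "roi_summary",
]


@dataclass(frozen=True)
class CalibrationModel:
    """Linear signal-to-concentration mapping fitted on the reference tubes."""

    slope: float  # signal units per (mmol/L)
    intercept: float  # signal units
    r_squared: float
    tube_means: tuple[tuple[float, float], ...]  # (known conc, mean fitted s0)


@dataclass
class TSCMap:
    """Calibrated concentration volume (mmol/L wet tissue)."""

    tsc_volume: np.ndarray
    voxel_size: float
    calibration: CalibrationModel
    n_clipped: int  # voxels whose calibrated value was negative, clipped to 0


@dataclass
class ROISummary:
    """Per-subject ROI means and ICV-normalized volumes."""

    subject_id: str
    group: str
    mean_tsc: dict[str, float]  # ROI -> mmol/L
    voxel_count: dict[str, int]
    normalized_volume: dict[str, float]  # ROI -> % of ICV


def tube_mean_signals(s0_map, labels, tube_concentrations, convergence_mask=None):
    """Mean fitted S0 per reference tube, ordered by ascending concentration.

    Parameters
    ----------
    s0_map : 3-D array of fitted S0.
    labels : 3-D integer label volume.
    tube_concentrations : mapping label_id -> known concentration (mmol/L).
    convergence_mask : optional 3-D bool array; only converged voxels enter
        the means.

    Returns
    -------
    list of (concentration, mean_s0), ascending in concentration.
    """
    s0_map = np.asarray(s0_map, dtype=float)
    labels = np.asarray(labels)
    out = []
    for label_id, conc in tube_concentrations.items():
        m = labels == label_id
        if not m.any():
            raise ValueError(f"tube label {label_id} absent from label volume")
        if convergence_mask is not None:
            m &= np.asarray(convergence_mask, dtype=bool)
        if not m.any():
            raise ValueError(f"tube label {label_id} has no converged voxels")
        out.append((float(conc), float(np.nanmean(s0_map[m]))))
    return sorted(out)


def fit_calibration(tube_data, force_zero_intercept: bool = False) -> CalibrationModel:
    """Ordinary least-squares line through the (concentration, mean S0) pairs.

    Requires at least three tubes with distinct concentrations.  With
    ``force_zero_intercept`` the line is constrained through the origin
    (ratio-style normalization).
    """
    tube_data = [(float(c), float(s)) for c, s in tube_data]
    conc = np.array([c for c, _ in tube_data])
    s0 = np.array([s for _, s in tube_data])
    if len(np.unique(conc)) < 3:
        raise ValueError("calibration needs >= 3 tubes with distinct concentrations")
    if force_zero_intercept:
        slope = float(conc @ s0 / (conc @ conc))
        intercept = 0.0
    else:
        slope, intercept = (float(v) for v in np.polyfit(conc, s0, 1))
    pred = slope * conc + intercept
    ss_res = float(np.sum((s0 - pred) ** 2))
    ss_tot = float(np.sum((s0 - s0.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else max(0.0, 1.0 - ss_res / ss_tot)
    return CalibrationModel(
        slope=slope, intercept=intercept, r_squared=r2, tube_means=tuple(sorted(tube_data))
    )


def apply_calibration(s0_map, model: CalibrationModel, voxel_size: float = 1.0) -> TSCMap:
    """Invert the calibration line voxelwise: ``tsc = (s0 - intercept)/slope``.

    Negative calibrated values (noise) are clipped to zero and counted;
    NaN voxels (unfitted) are preserved.
    """
    if model.slope <= 0:
        raise ValueError("calibration slope must be positive")
    s0_map = np.asarray(s0_map, dtype=float)
    tsc = (s0_map - model.intercept) / model.slope
    neg = tsc < 0
    n_clipped = int(np.count_nonzero(neg))
    tsc = np.where(neg, 0.0, tsc)
    return TSCMap(tsc_volume=tsc, voxel_size=voxel_size, calibration=model, n_clipped=n_clipped)


def roi_summary(
    tsc: TSCMap,
    labels,
    roi_labels: dict[str, int],
    icv_voxel_count: int,
    convergence_mask=None,
    subject_id: str = "subject",
    group: str = "NA",
) -> ROISummary:
    """Per-ROI mean TSC (over converged voxels) and ICV-normalized volume.

    ``normalized_volume = 100 * roi_voxel_count / icv_voxel_count`` (% of ICV);
    the volume uses all ROI voxels, the mean only converged ones.  An empty
    ``roi_labels`` mapping yields an empty summary.
    """
    if icv_voxel_count < 1:
        raise ValueError("icv_voxel_count must be >= 1")
    labels = np.asarray(labels)
    vol = np.asarray(tsc.tsc_volume, dtype=float)
    means, counts, nvols = {}, {}, {}
    for roi, label_id in roi_labels.items():
        m = labels == label_id
        n_anat = int(np.count_nonzero(m))
        if n_anat == 0:
            raise ValueError(f"ROI {roi!r} (label {label_id}) absent from label volume")
        if convergence_mask is not None:
            m &= np.asarray(convergence_mask, dtype=bool)
        if not m.any():
            raise ValueError(f"ROI {roi!r} has no converged voxels")
        means[roi] = float(np.nanmean(vol[m]))
        counts[roi] = n_anat
        nvols[roi] = 100.0 * n_anat / icv_voxel_count
    return ROISummary(
        subject_id=subject_id,
        group=group,
        mean_tsc=means,
        voxel_count=counts,
        normalized_volume=nvols,
    )
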