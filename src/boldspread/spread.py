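"""Radial decay of the BOLD signal around a peak: the spread measure.

The procedure, per subject x run x ROI:

1. average the signed percent signal change over spheres of radius 3..10 mm
   (1-mm steps) centred on the subject's peak, excluding out-of-brain voxels;
2. normalize each sphere mean by the 3-mm value, making the profile a
   proportion of the innermost sphere and hence independent of amplitude;
3. average the normalized profiles across runs (one pattern per ROI per
   subject);
4. convert consecutive spheres into *shell signals*: total signal
   V(r)·n(r) with analytic sphere volume V(r) = (4/3)πr³, differenced and
   divided by the shell volume — the mean normalized signal in the voxels
   uniquely added at each radius step;
5. fit shell signal against 1/r̄² (r̄ the shell midpoint radius) by ordinary
   least squares with intercept.  The slope is the decay/spread measure:
   larger slopes = faster decay = more focal response.

The fitted curve also yields d50, the distance at which the normalized signal
falls to 0.5, and the corresponding sphere volume v50 = (4/3)π·d50³.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from boldspread.peaks import PeakRecord, find_peak
from boldspread.volumes import MaskVolume, StatVolume, check_same_grid

__all__ = [
    "DEFAULT_RADII",
    "NormalizationError",
    "RadialProfile",
    "DecayFit",
    "sphere_volume",
    "sphere_mean",
    "radial_means",
    "normalize_profile",
    "shell_signals",
    "shell_midpoints",
    "fit_decay",
    "spread_pipeline",
]

#: sampling radii in mm, 3 mm (one voxel) to 10 mm in 1-mm steps
DEFAULT_RADII: tuple[float, ...] = (3.0, 4.0, 5.0, 6.0, 7.0, 8.0, 9.0, 10.0)

#: near-zero guard for the 3-mm normalization denominator (%)
NORMALIZATION_EPS = 1e-9


class NormalizationError(ValueError):
    """3-mm sphere mean too close to zero or of the wrong sign for the contrast."""


@dataclass(frozen=True)
class RadialProfile:
    """Sphere means, their normalized form, and derived shell signals."""

    radii: tuple[float, ...]
    means: tuple[float, ...]  # m(r), signed %
    normalized: tuple[float, ...]  # n(r) = m(r)/m(3); n(3) = 1
    shells: tuple[float, ...]  # s_k, one per consecutive radius pair


@dataclass(frozen=True)
class DecayFit:
    """OLS fit of shell signals on 1/r̄²: s = intercept + slope / r̄²."""

    slope: float  # decay/spread measure; larger = faster decay (more focal)
    intercept: float
    r_fit: float  # Pearson r between fitted and observed shells; NaN if degenerate
    d50: float  # mm at which fitted signal = 0.5; NaN when undefined
    v50: float  # (4/3)π d50³ mm³; NaN when d50 undefined
    n_shells: int

    @property
    def d50_defined(self) -> bool:
        return math.isfinite(self.d50)


def sphere_volume(radius: float) -> float:
    """Analytic sphere volume (4/3)πr³ in mm³."""
    return (4.0 / 3.0) * math.pi * radius**3


def _distance2_grid(vol: StatVolume, center_mm) -> np.ndarray:
    x, y, z = vol.axis_coords()
    cx, cy, cz = center_mm
    return (
        (x - cx)[:, None, None] ** 2
        + (y - cy)[None, :, None] ** 2
        + (z - cz)[None, None, :] ** 2
    )


def sphere_mean(
    vol: StatVolume,
    center_mm,
    radius: float,
    brain: MaskVolume | None = None,
) -> float:
    """Mean signal over in-brain voxels whose centers lie within ``radius`` mm.

    Membership is center-in-closed-ball: ``distance <= radius``.  Raises when
    the sphere contains no in-brain voxel.
    """
    if radius < max(vol.voxel_size):
        raise ValueError(
            f"radius {radius} mm below the largest voxel dimension "
            f"{max(vol.voxel_size)} mm; sphere could miss every voxel center"
        )
    mask = _distance2_grid(vol, center_mm) <= radius**2
    if brain is not None:
        check_same_grid(vol, brain)
        mask &= brain.data
    if not mask.any():
        raise ValueError(f"no in-brain voxels within {radius} mm of {tuple(center_mm)}")
    return float(vol.data[mask].mean())


def radial_means(
    vol: StatVolume,
    peak: PeakRecord,
    radii: tuple[float, ...] = DEFAULT_RADII,
    brain: MaskVolume | None = None,
) -> np.ndarray:
    """Sphere means m(r) at every sampling radius around one peak."""
    d2 = _distance2_grid(vol, peak.mm)
    if brain is not None:
        check_same_grid(vol, brain)
    out = np.empty(len(radii))
    for i, r in enumerate(radii):
        if r < max(vol.voxel_size):
            raise ValueError(f"radius {r} mm below the largest voxel dimension")
        mask = d2 <= r**2
        if brain is not None:
            mask &= brain.data
        if not mask.any():
            raise ValueError(f"no in-brain voxels within {r} mm of peak {peak.mm}")
        out[i] = vol.data[mask].mean()
    return out


def normalize_profile(
    means: np.ndarray,
    sign: str = "activation",
) -> np.ndarray:
    """Divide sphere means by the 3-mm (first-radius) value.

    The first element of ``means`` is the innermost-sphere mean m(3).  For
    activation profiles m(3) must be positive, for deactivation negative; a
    near-zero (|m(3)| <= 1e-9 %) or wrong-sign denominator raises
    :class:`NormalizationError` so the caller can exclude and log the record.
    """
    means = np.asarray(means, dtype=float)
    m3 = means[0]
    if abs(m3) <= NORMALIZATION_EPS:
        raise NormalizationError(f"3-mm sphere mean {m3:g} too close to zero to normalize")
    if sign == "activation" and m3 < 0:
        raise NormalizationError(f"3-mm sphere mean {m3:g} negative for an activation profile")
    if sign == "deactivation" and m3 > 0:
        raise NormalizationError(f"3-mm sphere mean {m3:g} positive for a deactivation profile")
    return means / m3


def shell_signals(normalized: np.ndarray, radii: tuple[float, ...] = DEFAULT_RADII) -> np.ndarray:
    """Mean normalized signal in the voxels uniquely added at each radius step.

    With analytic volumes V(r) = (4/3)πr³, the total signal in a sphere is
    V(r)·n(r); the shell signal for consecutive radii (r_k, r_{k+1}) is

        s_k = (V(r_{k+1})·n(r_{k+1}) − V(r_k)·n(r_k)) / (V(r_{k+1}) − V(r_k)),

    i.e. the average activation (or deactivation) in the added voxels relative
    to the 3-mm sphere's intensity.  A constant profile n ≡ 1 gives s_k ≡ 1.
    """
    normalized = np.asarray(normalized, dtype=float)
    radii_arr = np.asarray(radii, dtype=float)
    if len(normalized) != len(radii_arr):
        raise ValueError("normalized profile and radii must have equal length")
    if np.any(np.diff(radii_arr) <= 0):
        raise ValueError(f"radii must be strictly increasing, got {tuple(radii_arr)}")
    volumes = (4.0 / 3.0) * np.pi * radii_arr**3
    totals = volumes * normalized
    return np.diff(totals) / np.diff(volumes)


def shell_midpoints(radii: tuple[float, ...] = DEFAULT_RADII) -> np.ndarray:
    """Representative radius r̄_k of each shell: midpoint of its bounding radii."""
    radii_arr = np.asarray(radii, dtype=float)
    return (radii_arr[:-1] + radii_arr[1:]) / 2.0


def fit_decay(
    shells: np.ndarray,
    radii: tuple[float, ...] = DEFAULT_RADII,
    intercept: bool = True,
    abscissa: str = "midpoint",
) -> DecayFit:
    """Fit shell signals against inverse squared distance from the peak.

    Ordinary least squares of s_k on x_k = 1/r̄_k² (with intercept by
    default); r̄_k is the shell midpoint, or the outer bounding radius with
    ``abscissa="outer"``.  The slope is the spread measure.  ``r_fit`` is the
    Pearson correlation between fitted and observed shell signals (NaN when
    the observations are constant).  d50 solves intercept + slope/d² = 0.5,
    defined only for intercept < 0.5 and slope > 0.
    """
    shells = np.asarray(shells, dtype=float)
    radii_arr = np.asarray(radii, dtype=float)
    if len(shells) != len(radii_arr) - 1:
        raise ValueError("need one shell signal per consecutive radius pair")
    if len(shells) < 3:
        raise ValueError(f"need >= 3 shells to fit, got {len(shells)}")
    if abscissa == "midpoint":
        rbar = shell_midpoints(tuple(radii_arr))
    elif abscissa == "outer":
        rbar = radii_arr[1:]
    else:
        raise ValueError(f"abscissa must be 'midpoint' or 'outer', got {abscissa!r}")
    x = 1.0 / rbar**2
    if np.ptp(x) < 1e-15:
        raise ValueError("degenerate predictor: shell radii give constant 1/r̄²")

    if intercept:
        slope, a = np.polyfit(x, shells, 1)
    else:
        slope = float(x @ shells / (x @ x))
        a = 0.0
    fitted = a + slope * x
    if np.ptp(shells) < 1e-15 or np.ptp(fitted) < 1e-15:
        r_fit = float("nan")
    else:
        r_fit = float(stats.pearsonr(fitted, shells)[0])

    if slope > 0 and a < 0.5:
        d50 = math.sqrt(slope / (0.5 - a))
        v50 = sphere_volume(d50)
    else:
        d50 = v50 = float("nan")
    return DecayFit(
        slope=float(slope),
        intercept=float(a),
        r_fit=r_fit,
        d50=d50,
        v50=v50,
        n_shells=len(shells),
    )


def spread_pipeline(
    vols: list[StatVolume] | StatVolume,
    roi: MaskVolume,
    brain: MaskVolume | None = None,
    sign: str = "activation",
    radii: tuple[float, ...] = DEFAULT_RADII,
    peak_vols: list[StatVolume] | None = None,
    intercept: bool = True,
) -> tuple[list[PeakRecord], RadialProfile, DecayFit]:
    """Peak -> profile -> normalize -> run-average -> shells -> fit, for one ROI.

    ``vols`` holds one volume per run; normalized profiles are averaged across
    runs before shell-differencing and fitting, yielding one DecayFit per
    subject x ROI.  ``peak_vols`` optionally supplies separate maps (e.g. a
    smoothed analysis) on which to locate the peaks; by default peaks are
    found on the same volumes that are sampled.  Runs whose 3-mm mean fails
    the normalization sign/size check are excluded; if every run fails,
    :class:`NormalizationError` propagates.
    """
    if isinstance(vols, StatVolume):
        vols = [vols]
    if peak_vols is None:
        peak_vols = vols
    if len(peak_vols) != len(vols):
        raise ValueError("peak_vols must match vols run for run")

    peaks: list[PeakRecord] = []
    kept_norm: list[np.ndarray] = []
    kept_means: list[np.ndarray] = []
    errors: list[NormalizationError] = []
    for vol, pvol in zip(vols, peak_vols):
        peak = find_peak(pvol, roi, brain, sign)
        peaks.append(peak)
        means = radial_means(vol, peak, radii, brain)
        try:
            kept_norm.append(normalize_profile(means, sign))
        except NormalizationError as err:
            errors.append(err)
            continue
        kept_means.append(means)
    if not kept_norm:
        raise NormalizationError(
            f"all {len(vols)} run(s) excluded for ROI {roi.label!r}: {errors[-1]}"
        )

    normalized = np.mean(kept_norm, axis=0)
    means_avg = np.mean(kept_means, axis=0)
    shells = shell_signals(normalized, radii)
    profile = RadialProfile(
        radii=tuple(float(r) for r in radii),
        means=tuple(float(v) for v in means_avg),
        normalized=tuple(float(v) for v in normalized),
        shells=tuple(float(v) for v in shells),
    )
    fit = fit_decay(shells, radii, intercept=intercept)
    return peaks, profile, fit
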