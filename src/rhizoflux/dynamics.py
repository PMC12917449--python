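"""Uptake time-series analytics: compartment water contents, the
rhizosphere/bulk depletion ratio against its nighttime baseline, root
water uptake (RWU) rates, theta -> psi conversion, radial depletion
profiles and transition detection.

The central statistic is the depletion ratio d(theta_rhizo)/d(theta_bulk):
at night, when uptake is (nearly) zero and the compartments equilibrate,
it reflects only their relative retention; during transpiration a ratio
rising above that baseline signals preferential depletion of the
rhizosphere — the onset of supply limitation.  Ratios are computed from
windowed least-squares slopes rather than raw frame differences, with an
epsilon test on the bulk decrement so near-zero denominators are flagged
undefined instead of blowing up.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import distance_transform_edt
from scipy.signal import savgol_filter

from .hydraulics import SoilHydraulicParams, psi_of_theta
from .segmentation import MaskSet

__all__ = [
    "BaselineFit",
    "TransitionResult",
    "compartment_series",
    "night_baseline",
    "depletion_ratio",
    "rwu_series",
    "theta_to_psi",
    "radial_depletion_profile",
    "ratio_rwu_association",
    "detect_transition",
]


@dataclass(frozen=True)
class BaselineFit:
    """OLS fit of theta_rhizo on theta_bulk over nontranspiring frames.

    The slope is the expected drying trajectory without plant-driven
    fluxes; deviations above it in transpiring phases indicate active
    rhizosphere depletion.
    """

    slope: float
    intercept: float
    n_points: int
    residual_sd: float


@dataclass(frozen=True)
class TransitionResult:
    """Detected shift to rhizosphere-dominated uptake.

    ``psi_transition`` is the bulk water potential (kPa) of the first
    window of the earliest persistent exceedance run, or ``None``.  The
    estimate is indicative: the underlying shift is gradual, not a sharp
    change point.
    """

    psi_transition: float | None
    tau: float
    k_consecutive: int
    first_window_index: int | None = None


def compartment_series(theta_maps, masks: MaskSet, metadata, box) -> pd.DataFrame:
    """Reduce theta maps to per-frame compartment means and total water.

    Parameters
    ----------
    theta_maps : iterable of WaterContentMap
        One map per frame, aligned with ``metadata`` rows.
    masks : MaskSet
        Fixed masks; the rhizosphere compartment is the skeleton pixel set.
    metadata : DataFrame
        Columns ``time_min`` and ``light`` (0/1), one row per frame.
    box : RhizoboxSpec
        Supplies pixel area and path thickness for total water.

    Frames in which either compartment has no valid pixel are dropped.
    Returns a DataFrame with columns ``time_min, theta_rhizo, theta_bulk,
    total_water, light, n_rhizo, n_bulk``.
    """
    if not masks.rhizosphere.any() or not masks.bulk.any():
        raise ValueError("both compartment masks must be non-empty")
    cell = box.pixel_size**2 * box.path_thickness
    records = []
    for (_, meta), wmap in zip(metadata.iterrows(), theta_maps):
        rh = masks.rhizosphere & wmap.valid_mask
        bk = masks.bulk & wmap.valid_mask
        n_rh, n_bk = int(rh.sum()), int(bk.sum())
        if n_rh == 0 or n_bk == 0:
            continue
        records.append(
            {
                "time_min": float(meta["time_min"]),
                "theta_rhizo": float(wmap.theta[rh].mean()),
                "theta_bulk": float(wmap.theta[bk].mean()),
                "total_water": float(wmap.theta[wmap.valid_mask].sum() * cell),
                "light": int(meta["light"]),
                "n_rhizo": n_rh,
                "n_bulk": n_bk,
            }
        )
    df = pd.DataFrame.from_records(records)
    if len(df) and not df.time_min.is_monotonic_increasing:
        raise ValueError("frame timestamps must be strictly increasing")
    return df


def night_baseline(series: pd.DataFrame) -> BaselineFit:
    """Nighttime 1:1 drying baseline: OLS of theta_rhizo on theta_bulk
    restricted to light-off frames."""
    night = series[series.light == 0]
    if len(night) < 3:
        raise ValueError(f"need >= 3 night frames, got {len(night)}")
    x = night.theta_bulk.to_numpy()
    y = night.theta_rhizo.to_numpy()
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    sd = float(np.std(resid, ddof=min(2, len(night) - 1)))
    return BaselineFit(
        slope=float(slope), intercept=float(intercept), n_points=len(night), residual_sd=sd
    )


def _window_slope(t_min: np.ndarray, y: np.ndarray) -> float:
    """Least-squares slope of y against time (per minute)."""
    return float(np.polyfit(t_min, y, 1)[0])


def depletion_ratio(
    series: pd.DataFrame,
    window_min: float = 30.0,
    eps: float = 1e-4,
    soil: SoilHydraulicParams | None = None,
) -> pd.DataFrame:
    """Windowed depletion ratio d(theta_rhizo)/d(theta_bulk) for light-on
    frames.

    Consecutive light-on frames are grouped into non-overlapping windows of
    ``window_min`` minutes (at least 2 frames).  Within each window, the
    temporal change of each compartment is the least-squares slope of
    theta against time; the ratio is reported only where the bulk
    decrement over the window passes the epsilon test
    ``|dtheta_bulk * window| >= eps`` (``defined`` flag otherwise False).
    If ``soil`` is given, the bulk potential at the window midpoint is
    attached via the retention curve.

    Returns a DataFrame with columns ``time_min (window midpoint), ratio,
    dtheta_bulk, dtheta_rhizo (per minute), theta_bulk_mid, psi_bulk,
    defined, n_frames``.
    """
    day = series[series.light == 1].reset_index(drop=True)
    records = []
    if len(day):
        # split day frames into contiguous light periods, then tile windows
        gaps = np.flatnonzero(np.diff(day.time_min) > 2.1 * np.median(np.diff(day.time_min))
                              ) if len(day) > 1 else []
        blocks = np.split(np.arange(len(day)), np.asarray(gaps) + 1)
        for block in blocks:
            sub = day.iloc[block]
            t0 = sub.time_min.iloc[0]
            for w0 in np.arange(t0, sub.time_min.iloc[-1], window_min):
                win = sub[(sub.time_min >= w0) & (sub.time_min < w0 + window_min)]
                if len(win) < 2:
                    continue
                t = win.time_min.to_numpy()
                db = _window_slope(t, win.theta_bulk.to_numpy())
                dr = _window_slope(t, win.theta_rhizo.to_numpy())
                defined = abs(db * window_min) >= eps
                records.append(
                    {
                        "time_min": float(t.mean()),
                        "ratio": dr / db if defined else np.nan,
                        "dtheta_bulk": db,
                        "dtheta_rhizo": dr,
                        "theta_bulk_mid": float(win.theta_bulk.mean()),
                        "since_light_on_min": float(t.mean() - t0),
                        "defined": bool(defined),
                        "n_frames": len(win),
                    }
                )
    df = pd.DataFrame.from_records(
        records,
        columns=[
            "time_min", "ratio", "dtheta_bulk", "dtheta_rhizo",
            "theta_bulk_mid", "since_light_on_min", "defined", "n_frames",
        ],
    )
    if soil is not None and len(df):
        df["psi_bulk"] = theta_to_psi(df.theta_bulk_mid.to_numpy(), soil)
    else:
        df["psi_bulk"] = np.nan
    return df


def rwu_series(
    series: pd.DataFrame,
    diff_min: float = 15.0,
    sg_window: int = 9,
    sg_order: int = 2,
) -> tuple[pd.DataFrame, float]:
    """Root water uptake from the total-water time series.

    Total water is smoothed with a Savitzky-Golay filter (which reproduces
    polynomial trends up to ``sg_order`` exactly), then
    ``RWU(t) = -(W(t+diff) - W(t)) / diff`` on frames ``diff_min`` apart.
    Returns ``(DataFrame with time_min, rwu_cm3_h, light; mean RWU over
    light-on samples)`` — the transpiration-period average.
    """
    if sg_window % 2 == 0 or sg_window <= sg_order:
        raise ValueError("sg_window must be odd and greater than sg_order")
    if len(series) < sg_window:
        raise ValueError(f"series shorter than the smoothing window {sg_window}")
    t = series.time_min.to_numpy()
    cadence = np.median(np.diff(t))
    if diff_min < cadence - 1e-9:
        raise ValueError(f"diff_min {diff_min} below frame cadence {cadence}")
    lag = max(1, int(round(diff_min / cadence)))
    w = savgol_filter(series.total_water.to_numpy(), sg_window, sg_order)
    dt_min = t[lag:] - t[:-lag]
    rwu = -(w[lag:] - w[:-lag]) / dt_min * 60.0  # cm3 h-1
    out = pd.DataFrame(
        {
            "time_min": 0.5 * (t[lag:] + t[:-lag]),
            "rwu_cm3_h": rwu,
            "light": series.light.to_numpy()[:-lag],
        }
    )
    day = out[out.light == 1]
    mean_rwu = float(day.rwu_cm3_h.mean()) if len(day) else np.nan
    return out, mean_rwu


def theta_to_psi(theta, soil: SoilHydraulicParams):
    """Elementwise water potential (kPa) from water content.

    Values at or below residual / above saturation are clamped to the
    invertible range edges; the number of clamped entries is not an error
    (noisy maps legitimately graze the bounds) but they map to the dry
    floor / zero respectively.
    """
    theta = np.asarray(theta, dtype=float)
    lo = soil.theta_r + 1e-9 * (soil.theta_s - soil.theta_r)
    clamped = np.clip(theta, lo, soil.theta_s)
    return psi_of_theta(soil, clamped)


def radial_depletion_profile(
    theta_map_early: np.ndarray,
    theta_map_late: np.ndarray,
    skeleton: np.ndarray,
    pixel_size: float,
    dt_h: float,
    max_dist_cm: float = 0.4,
    bin_cm: float | None = None,
) -> pd.DataFrame:
    """Water-content change rate versus distance from the root skeleton.

    Distances come from the Euclidean distance transform of the skeleton;
    Delta-theta / Delta-t is averaged in radial bins out to
    ``max_dist_cm``.  Empty bins are flagged (count 0, NaN mean), never
    interpolated.

    Returns a DataFrame with columns ``dist_cm (bin center),
    dtheta_per_h, n_pixels``.
    """
    early = np.asarray(theta_map_early, dtype=float)
    late = np.asarray(theta_map_late, dtype=float)
    skeleton = np.asarray(skeleton, dtype=bool)
    if early.shape != late.shape or early.shape != skeleton.shape:
        raise ValueError("maps and skeleton must share one shape")
    if not skeleton.any():
        raise ValueError("skeleton is empty")
    if bin_cm is None:
        bin_cm = pixel_size
    dist = distance_transform_edt(~skeleton) * pixel_size
    rate = (late - early) / dt_h
    edges = np.arange(0.0, max_dist_cm + bin_cm, bin_cm)
    idx = np.digitize(dist.ravel(), edges) - 1
    rate_flat = rate.ravel()
    records = []
    for b in range(len(edges) - 1):
        sel = idx == b
        n = int(np.count_nonzero(sel))
        records.append(
            {
                "dist_cm": 0.5 * (edges[b] + edges[b + 1]),
                "dtheta_per_h": float(rate_flat[sel].mean()) if n else np.nan,
                "n_pixels": n,
            }
        )
    return pd.DataFrame.from_records(records)


def ratio_rwu_association(
    ratio_series: pd.DataFrame,
    rwu: pd.DataFrame,
    active_frac: float = 1.0 / 3.0,
    settle_min: float = 60.0,
) -> tuple[float, int]:
    """Spearman association between the depletion ratio and concurrent RWU.

    Defined ratio windows are paired with the nearest RWU sample and the
    rank correlation is evaluated over the *active transpiration period*:
    samples with RWU of at least ``active_frac`` of the run maximum, and
    at least ``settle_min`` minutes after lights-on.  The first hour of
    each light period is a transient — the overnight-refilled rhizosphere
    re-drains while gradients re-establish — and once uptake has collapsed
    below a third of its peak the plant has effectively shut down, leaving
    a slow equilibration tail in which the ratio is measurement noise.

    Returns ``(rho, n_pairs)``.
    """
    from scipy.stats import spearmanr

    defined = ratio_series[
        ratio_series.defined & (ratio_series.since_light_on_min >= settle_min)
    ].sort_values("time_min")
    merged = pd.merge_asof(
        defined, rwu.sort_values("time_min"), on="time_min", direction="nearest"
    )
    active = merged[merged.rwu_cm3_h >= active_frac * merged.rwu_cm3_h.max()]
    if len(active) < 3:
        return np.nan, len(active)
    rho = spearmanr(active.ratio, active.rwu_cm3_h).statistic
    return float(rho), len(active)


def detect_transition(
    ratio_series: pd.DataFrame,
    baseline: BaselineFit,
    tau: float = 1.5,
    k_consecutive: int = 3,
) -> TransitionResult:
    """First persistent exceedance of the nighttime baseline.

    Scans the (time-ordered) defined ratio windows for the earliest run of
    at least ``k_consecutive`` consecutive defined windows with
    ``ratio > tau * baseline.slope`` and returns the bulk potential of the
    run's first window.  An indicative estimate by construction: the
    underlying transition is gradual.
    """
    df = ratio_series[ratio_series.defined].reset_index(drop=True)
    run_start, run = None, 0
    for i in range(len(df)):
        if df.ratio.iloc[i] > tau * baseline.slope:
            if run == 0:
                run_start = i
            run += 1
            if run >= k_consecutive:
                return TransitionResult(
                    psi_transition=float(df.psi_bulk.iloc[run_start]),
                    tau=tau,
                    k_consecutive=k_consecutive,
                    first_window_index=int(run_start),
                )
        else:
            run, run_start = 0, None
    return TransitionResult(psi_transition=None, tau=tau, k_consecutive=k_consecutive)
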