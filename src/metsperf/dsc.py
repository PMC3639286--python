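"""DSC perfusion processing: signal -> ΔR2* -> bolus window -> baseline -> CBV.

The processing chain converts a 4D dynamic susceptibility contrast (DSC)
series into cerebral blood volume (CBV):

1. ``delta_r2star``:  ΔR2*(t) = -ln(S_t / S_0) / TE, with S_0 the mean signal
   over the pre-bolus baseline frames.  ΔR2* is proportional to the
   intravascular contrast concentration.
2. ``detect_bolus_fppm``:  a first-pass pharmacokinetic model (first-pass
   gamma-variate bolus plus a cumulative leakage term) is fitted to the whole
   ΔR2* curve; the bolus start/end are where the fitted first-pass component
   crosses 5% of its peak.  A threshold-on-smoothed-curve detector is the
   fallback when the fit does not converge.
3. ``correct_baseline``:  three-segment baseline - the pre-bolus trend is set
   to zero, a linear fit over the post-bolus frames models slow drift, and a
   straight line bridges the two segments under the bolus.
4. ``fit_gamma_variate``:  y(t) = K (t-t0)^α exp(-(t-t0)/β) for t > t0; CBV is
   the area under the fitted curve, K β^(α+1) Γ(α+1) in closed form.

All times are seconds; frame indices map to times through the acquisition
geometry's frame interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.optimize import curve_fit
from scipy.special import gammaln

from .errors import BaselineError
from .geometry import AcquisitionGeometry

# QC defaults (no field-standard values exist for these; all are
# overridable keyword arguments where they apply)
BOLUS_EDGE_FRACTION = 0.05      # bolus start/end at 5% of fitted peak
MIN_PEAK_SNR = 5.0              # peak must exceed 5x baseline noise SD
ALPHA_MAX = 20.0                # gamma-variate shape upper bound
BETA_MAX_S = 60.0               # gamma-variate time-constant upper bound (s)
CBV_QUADRATURE_RTOL = 1e-3      # closed form vs numeric area agreement


# ---------------------------------------------------------------------------
# containers


@dataclass
class DSCSeries:
    """A 4D DSC acquisition: signal (x, y, slice, frame) plus metadata."""

    signal: np.ndarray
    baseline_frames: np.ndarray
    geometry: AcquisitionGeometry
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        self.baseline_frames = np.asarray(self.baseline_frames, dtype=int)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.signal.ndim != 4:
            raise ValueError("signal must be 4D (x, y, slice, frame)")
        if self.baseline_frames.size < 5:
            raise ValueError("need at least 5 baseline frames")
        if self.mask.shape != self.signal.shape[:3]:
            raise ValueError("mask shape must match spatial signal shape")

    @property
    def frame_times(self) -> np.ndarray:
        return np.arange(self.signal.shape[-1]) * self.geometry.frame_interval_s


@dataclass
class BolusFit:
    """Gamma-variate bolus fit for one voxel or ROI curve."""

    K: float = np.nan
    alpha: float = np.nan
    beta: float = np.nan
    t0: float = np.nan
    cbv: float = np.nan                 # closed-form area K β^(α+1) Γ(α+1)
    cbv_quadrature: float = np.nan      # numeric cross-check of the area
    residual_norm: float = np.nan
    converged: bool = False

    def curve(self, t: np.ndarray) -> np.ndarray:
        return gamma_variate(np.asarray(t, float), self.K, self.alpha, self.beta, self.t0)


@dataclass
class BolusWindow:
    """Detected bolus extent (frame indices) and how it was obtained."""

    found: bool
    t_start: int = -1
    t_end: int = -1
    method: str = "none"                # "fppm" or "threshold"
    params: dict = field(default_factory=dict)


@dataclass
class CBVMap:
    """Per-voxel CBV values with a QC mask of failed/implausible fits."""

    values: np.ndarray                  # NaN where QC failed or outside mask
    qc_failed: np.ndarray               # True where the fit was rejected
    window: Optional[BolusWindow] = None


# ---------------------------------------------------------------------------
# ΔR2* transform


def delta_r2star(series: DSCSeries) -> np.ndarray:
    """ΔR2*(t) = -(1/TE) ln(S_t / S_0) per voxel, in s^-1.

    S_0 is the mean over the baseline frames.  Voxels with non-positive
    signal anywhere in the series (or non-positive S_0) get NaN at the
    offending frames rather than raising; downstream QC excludes them.
    """
    te = series.geometry.te_s
    s = series.signal
    s0 = s[..., series.baseline_frames].mean(axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = -np.log(s / s0[..., None]) / te
    out[~np.isfinite(out)] = np.nan
    bad = (s <= 0) | (s0[..., None] <= 0)
    out[bad] = np.nan
    return out


def delta_r2star_curve(signal: np.ndarray, baseline_frames: np.ndarray, te_s: float) -> np.ndarray:
    """1D convenience version of :func:`delta_r2star`."""
    signal = np.asarray(signal, float)
    s0 = signal[np.asarray(baseline_frames, int)].mean()
    with np.errstate(divide="ignore", invalid="ignore"):
        out = -np.log(signal / s0) / te_s
    out[~np.isfinite(out)] = np.nan
    return out


# ---------------------------------------------------------------------------
# model functions


def gamma_variate(t: np.ndarray, K: float, alpha: float, beta: float, t0: float) -> np.ndarray:
    """K (t-t0)^α exp(-(t-t0)/β) for t > t0, else 0."""
    t = np.asarray(t, dtype=float)
    tau = t - t0
    out = np.zeros_like(tau)
    pos = tau > 0
    with np.errstate(over="ignore"):
        out[pos] = K * tau[pos] ** alpha * np.exp(-tau[pos] / beta)
    return out


def gamma_variate_area(K: float, alpha: float, beta: float) -> float:
    """Closed-form area under the gamma-variate: K β^(α+1) Γ(α+1)."""
    return float(K * np.exp((alpha + 1.0) * np.log(beta) + gammaln(alpha + 1.0)))


def _gamma_variate_jac(t, K, alpha, beta, t0):
    """Analytic Jacobian of :func:`gamma_variate` wrt (K, α, β, t0)."""
    t = np.asarray(t, dtype=float)
    tau = t - t0
    out = np.zeros((t.size, 4))
    pos = tau > 1e-12
    taup = tau[pos]
    with np.errstate(over="ignore"):
        y = taup ** alpha * np.exp(-taup / beta)
    out[pos, 0] = y
    out[pos, 1] = K * y * np.log(taup)
    out[pos, 2] = K * y * taup / beta ** 2
    out[pos, 3] = K * y * (1.0 / beta - alpha / taup)
    return out


def _gamma_shape(t: np.ndarray, t0: float, alpha: float, beta: float) -> np.ndarray:
    """Peak-normalized gamma-variate (peak value 1 at t = t0 + αβ)."""
    tau = np.asarray(t, float) - t0
    out = np.zeros_like(tau)
    pos = tau > 0
    with np.errstate(over="ignore", invalid="ignore"):
        out[pos] = (tau[pos] / (alpha * beta)) ** alpha * np.exp(alpha - tau[pos] / beta)
    return out


def _fppm_model(t, c0, K, t0, alpha, beta, k_leak):
    """First-pass + leakage model: c0 + K g(t) + k_leak ∫ g dτ.

    g is the peak-normalized first-pass bolus; the cumulative term captures
    contrast retention / recirculation so the whole curve can be fitted.
    """
    g = _gamma_shape(t, t0, alpha, beta)
    leak = cumulative_trapezoid(g, t, initial=0.0)
    return c0 + K * g + k_leak * leak


# ---------------------------------------------------------------------------
# bolus extent detection


def _smooth(y: np.ndarray, w: int = 3) -> np.ndarray:
    kernel = np.ones(w) / w
    return np.convolve(np.nan_to_num(y, nan=0.0), kernel, mode="same")


def _threshold_window(curve, frame_times, baseline_frames, noise_sd, edge_fraction):
    """Fallback detector: crossings of a smoothed curve above a noise floor."""
    sm = _smooth(curve)
    base = float(np.nanmean(sm[baseline_frames]))
    peak_idx = int(np.nanargmax(sm))
    peak = sm[peak_idx] - base
    thr = base + max(edge_fraction * peak, 2.0 * noise_sd)
    above = sm > thr
    # walk outwards from the peak
    t_start = peak_idx
    while t_start > 0 and above[t_start - 1]:
        t_start -= 1
    t_end = peak_idx
    n = len(curve)
    while t_end < n - 1 and above[t_end + 1]:
        t_end += 1
    return t_start, t_end


def detect_bolus_fppm(
    curve: np.ndarray,
    frame_times: np.ndarray,
    baseline_frames: Optional[np.ndarray] = None,
    edge_fraction: float = BOLUS_EDGE_FRACTION,
    min_peak_snr: float = MIN_PEAK_SNR,
) -> BolusWindow:
    """Locate the bolus start/end frames on a ΔR2* curve.

    Fits the first-pass pharmacokinetic model to the whole curve and returns
    the frames where the fitted bolus component crosses ``edge_fraction`` of
    its peak.  Returns ``found=False`` when no bolus rises above
    ``min_peak_snr`` times the baseline noise SD.
    """
    curve = np.asarray(curve, dtype=float)
    frame_times = np.asarray(frame_times, dtype=float)
    n = curve.size
    if n < 30:
        raise ValueError("bolus detection needs at least 30 frames")
    if baseline_frames is None:
        baseline_frames = np.arange(min(10, n // 5))
    baseline_frames = np.asarray(baseline_frames, int)

    finite = np.isfinite(curve)
    if finite.sum() < 30:
        return BolusWindow(found=False)
    work = np.where(finite, curve, np.nanmedian(curve[finite]))

    noise_sd = float(np.nanstd(work[baseline_frames], ddof=1))
    sm = _smooth(work)
    base = float(np.nanmean(sm[baseline_frames]))
    peak_idx = int(np.nanargmax(sm))
    peak_amp = float(sm[peak_idx] - base)
    floor = max(min_peak_snr * noise_sd, 1e-12)
    if peak_amp < floor:
        return BolusWindow(found=False)

    dt = float(np.median(np.diff(frame_times)))
    # onset guess: last frame before the peak below 10% of the rise
    rise_thr = base + 0.1 * peak_amp
    onset = peak_idx
    while onset > 0 and sm[onset - 1] > rise_thr:
        onset -= 1
    t0_guess = frame_times[max(onset - 1, 0)]
    alpha0, K0 = 3.0, peak_amp
    beta0 = max((frame_times[peak_idx] - t0_guess) / alpha0, dt / 2)
    p0 = [base, K0, t0_guess, alpha0, beta0, 0.0]
    lb = [-np.inf, 0.0, t0_guess - 10 * dt, 0.2, dt / 10, -2 * K0 - 1e-9]
    ub = [np.inf, 10 * K0 + 1e-9, frame_times[peak_idx], ALPHA_MAX, BETA_MAX_S, 2 * K0 + 1e-9]
    p0 = np.clip(p0, lb, ub)

    try:
        popt, _ = curve_fit(_fppm_model, frame_times, work, p0=p0,
                            bounds=(lb, ub), maxfev=3000)
        c0, K, t0, alpha, beta, k_leak = popt
        dense = np.linspace(frame_times[0], frame_times[-1], 10 * n)
        bolus = K * _gamma_shape(dense, t0, alpha, beta)
        thr = edge_fraction * K
        above = np.flatnonzero(bolus >= thr)
        if K <= floor or above.size == 0:
            raise RuntimeError("degenerate FPPM fit")
        t_start_time = dense[above[0]]
        t_end_time = dense[above[-1]]
        t_start = int(np.searchsorted(frame_times, t_start_time, side="left"))
        t_end = int(min(np.searchsorted(frame_times, t_end_time, side="left"), n - 1))
        if not (0 <= t_start < t_end <= n - 1):
            raise RuntimeError("implausible FPPM bolus extent")
        return BolusWindow(
            found=True, t_start=t_start, t_end=t_end, method="fppm",
            params={"c0": c0, "K": K, "t0": t0, "alpha": alpha,
                    "beta": beta, "k_leak": k_leak},
        )
    except (RuntimeError, ValueError):
        t_start, t_end = _threshold_window(work, frame_times, baseline_frames,
                                           noise_sd, edge_fraction)
        if t_start >= t_end:
            return BolusWindow(found=False)
        return BolusWindow(found=True, t_start=int(t_start), t_end=int(t_end),
                           method="threshold", params={})


# ---------------------------------------------------------------------------
# three-segment baseline


def correct_baseline(curve: np.ndarray, frame_times: np.ndarray,
                     t_start: int, t_end: int):
    """Subtract a three-segment baseline from a ΔR2* curve.

    Segments: the pre-bolus trend (least-squares line over frames before
    ``t_start``; removing it sets the pre-bolus baseline to zero), a linear
    fit over the post-bolus frames (``t_end`` to the last frame), and the
    straight line connecting the two under the bolus.

    Returns ``(corrected_curve, segments)`` where ``segments`` records the
    fitted slopes/intercepts.
    """
    curve = np.asarray(curve, dtype=float)
    frame_times = np.asarray(frame_times, dtype=float)
    n = curve.size
    if not (0 <= t_start < t_end < n):
        raise BaselineError(f"bolus window [{t_start}, {t_end}] outside curve support")
    post = np.arange(t_end, n)
    if post.size < 3:
        raise BaselineError("fewer than 3 post-bolus frames")
    pre = np.arange(0, t_start)

    finite = np.isfinite(curve)
    if pre.size >= 2 and finite[pre].sum() >= 2:
        idx = pre[finite[pre]]
        pre_slope, pre_icpt = np.polyfit(frame_times[idx], curve[idx], 1)
    elif pre.size >= 1 and finite[pre].any():
        pre_slope, pre_icpt = 0.0, float(np.nanmean(curve[pre]))
    else:
        pre_slope, pre_icpt = 0.0, 0.0
    idx = post[finite[post]]
    if idx.size < 3:
        raise BaselineError("fewer than 3 finite post-bolus frames")
    post_slope, post_icpt = np.polyfit(frame_times[idx], curve[idx], 1)

    baseline = np.empty(n)
    baseline[:t_start] = pre_slope * frame_times[:t_start] + pre_icpt
    baseline[t_end:] = post_slope * frame_times[t_end:] + post_icpt
    y_a = pre_slope * frame_times[t_start] + pre_icpt
    y_b = post_slope * frame_times[t_end] + post_icpt
    span = frame_times[t_end] - frame_times[t_start]
    bridge_t = frame_times[t_start:t_end]
    baseline[t_start:t_end] = y_a + (y_b - y_a) * (bridge_t - frame_times[t_start]) / span

    segments = {
        "pre_slope": float(pre_slope), "pre_intercept": float(pre_icpt),
        "post_slope": float(post_slope), "post_intercept": float(post_icpt),
        "bridge_start": (float(frame_times[t_start]), float(y_a)),
        "bridge_end": (float(frame_times[t_end]), float(y_b)),
    }
    return curve - baseline, segments


# ---------------------------------------------------------------------------
# gamma-variate fit and CBV


def fit_gamma_variate(corrected: np.ndarray, frame_times: np.ndarray,
                      t_start: int, max_restarts: int = 2) -> BolusFit:
    """Nonlinear least-squares gamma-variate fit of a baseline-corrected curve.

    Initialization: t0 one frame before the detected bolus start; α and β
    from a log-linearization ln y = ln K + α ln τ - τ/β over the points above
    10% of the peak.  CBV is the closed-form area, cross-checked against
    trapezoidal quadrature.
    """
    corrected = np.asarray(corrected, dtype=float)
    frame_times = np.asarray(frame_times, dtype=float)
    finite = np.isfinite(corrected)
    if finite.sum() < 8:
        return BolusFit()
    t = frame_times[finite]
    y = corrected[finite]
    dt = float(np.median(np.diff(frame_times)))
    t_start = int(np.clip(t_start, 0, len(frame_times) - 1))
    t0_init = frame_times[t_start] - dt

    after = t >= frame_times[t_start]
    if not after.any() or np.nanmax(y[after]) <= 0:
        return BolusFit()
    peak = float(np.nanmax(y[after]))
    peak_time = float(t[after][int(np.nanargmax(y[after]))])

    # log-linearized moment initialization
    alpha0, beta0 = 3.0, max((peak_time - t0_init) / 3.0, dt / 2)
    sel = (t > t0_init) & (y > 0.1 * peak)
    if sel.sum() >= 4:
        tau = t[sel] - t0_init
        A = np.column_stack([np.ones_like(tau), np.log(tau), tau])
        try:
            coef, *_ = np.linalg.lstsq(A, np.log(y[sel]), rcond=None)
            a_hat, b_hat = coef[1], -1.0 / coef[2] if coef[2] < 0 else np.nan
            if np.isfinite(a_hat) and 0.1 < a_hat < 15 and np.isfinite(b_hat) and 0 < b_hat < BETA_MAX_S:
                alpha0, beta0 = float(a_hat), float(b_hat)
        except np.linalg.LinAlgError:
            pass
    K0 = peak / max(gamma_variate(np.array([t0_init + alpha0 * beta0]),
                                  1.0, alpha0, beta0, t0_init)[0], 1e-300)

    lb = [0.0, 1e-3, 1e-3, t0_init - 2 * dt]
    ub = [np.inf, ALPHA_MAX, BETA_MAX_S, t0_init + 3 * dt]
    rng = np.random.default_rng(0)
    p0 = np.clip([K0, alpha0, beta0, t0_init], lb, ub)
    for attempt in range(max_restarts + 1):
        try:
            popt, _ = curve_fit(gamma_variate, t, y, p0=p0, bounds=(lb, ub),
                                jac=_gamma_variate_jac, maxfev=4000)
            K, alpha, beta, t0 = (float(v) for v in popt)
            if K <= 0 or alpha >= ALPHA_MAX * 0.999 or beta >= BETA_MAX_S * 0.999:
                raise RuntimeError("parameter at bound")
            resid = y - gamma_variate(t, K, alpha, beta, t0)
            cbv = gamma_variate_area(K, alpha, beta)
            dense = np.linspace(t0, t0 + (alpha + 12.0) * beta, 4000)
            cbv_quad = float(np.trapezoid(gamma_variate(dense, K, alpha, beta, t0), dense))
            return BolusFit(K=K, alpha=alpha, beta=beta, t0=t0, cbv=cbv,
                            cbv_quadrature=cbv_quad,
                            residual_norm=float(np.linalg.norm(resid)),
                            converged=True)
        except (RuntimeError, ValueError):
            p0 = np.clip([K0 * rng.uniform(0.5, 2.0),
                          alpha0 * rng.uniform(0.7, 1.4),
                          beta0 * rng.uniform(0.7, 1.4),
                          t0_init], lb, ub)
    return BolusFit()


def fit_curve(curve: np.ndarray, frame_times: np.ndarray,
              window: BolusWindow) -> BolusFit:
    """Baseline-correct a ΔR2* curve over a detected window and fit the bolus."""
    if not window.found:
        return BolusFit()
    try:
        corrected, _ = correct_baseline(curve, frame_times, window.t_start, window.t_end)
    except BaselineError:
        return BolusFit()
    return fit_gamma_variate(corrected, frame_times, window.t_start)


def roi_curve(dr2s: np.ndarray, roi_mask: np.ndarray) -> np.ndarray:
    """Mean ΔR2* curve over an ROI (NaN voxels ignored frame-wise)."""
    vox = dr2s[roi_mask]
    if vox.size == 0:
        raise ValueError("empty ROI mask")
    with np.errstate(invalid="ignore"):
        return np.nanmean(vox, axis=0)


def compute_cbv_map(series: DSCSeries, mask: Optional[np.ndarray] = None,
                    per_voxel_detection: bool = False) -> CBVMap:
    """Run the full chain (ΔR2* -> bolus window -> baseline -> gamma fit) per voxel.

    By default the bolus window is detected once on the brain-mean curve and
    shared by all voxels (bolus timing is global in a DSC acquisition); pass
    ``per_voxel_detection=True`` to re-detect on every voxel curve.  Voxels
    with failed fits, negative areas, or closed-form/quadrature disagreement
    are QC-flagged and set to NaN.
    """
    mask = series.mask if mask is None else np.asarray(mask, bool)
    if mask.sum() == 0:
        raise ValueError("empty mask")
    dr2s = delta_r2star(series)
    times = series.frame_times
    mean_curve = roi_curve(dr2s, mask)
    window = detect_bolus_fppm(mean_curve, times, series.baseline_frames)

    values = np.full(mask.shape, np.nan)
    qc = np.zeros(mask.shape, dtype=bool)
    if not window.found:
        qc[mask] = True
        return CBVMap(values=values, qc_failed=qc, window=window)

    coords = np.argwhere(mask)
    for (i, j, k) in coords:
        curve = dr2s[i, j, k]
        win = window
        if per_voxel_detection:
            win = detect_bolus_fppm(curve, times, series.baseline_frames)
            if not win.found:
                qc[i, j, k] = True
                continue
        fit = fit_curve(curve, times, win)
        ok = (fit.converged and fit.cbv >= 0 and
              abs(fit.cbv - fit.cbv_quadrature) <= CBV_QUADRATURE_RTOL * max(fit.cbv, 1e-12))
        if ok:
            values[i, j, k] = fit.cbv
        else:
            qc[i, j, k] = True
    return CBVMap(values=values, qc_failed=qc, window=window)
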