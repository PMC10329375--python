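"""Airway closure detection and airway opening pressure (AOP) measurement.

Two detectors are provided:

* :func:`pcond_method` — the conductive-pressure method, run on a usual
  constant-flow (60 L/min) breath with an end-inspiratory occlusion.  The
  conductive pressure ``P_cond`` is the airway pressure at the early
  insufflation slope break minus set PEEP; the resistive pressure ``P_res``
  is peak minus plateau after at least 0.3 s of occlusion.  Airway closure
  is called when ``P_cond - P_res > 1 cmH2O`` and the opening pressure is
  then ``AOP = PEEP + (P_cond - P_res)``.

* :func:`standard_method` — the reference method, run on a low-flow
  (5 L/min) insufflation.  Closure shows as an abrupt change in slope on the
  time-pressure curve (the first, steep slope is the circuit compliance
  charging against the closed airway); the pressure at the slope break *is*
  the AOP.

The slope break is located by exhaustive-grid two-segment least-squares
fits — deterministic and reproducible, standing in for the visual reading
used at the bedside.  The low-flow method uses a continuous piecewise-linear
fit; the constant-flow method additionally models the exponential approach
of the pressure to its post-break ramp (the circuit-lung transient), which
a plain second line would mistake for part of the corner.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import math

import numpy as np

from .waveform import BreathWaveform

__all__ = [
    "DetectionConfig",
    "AOPResult",
    "BreakFit",
    "detect_onset",
    "detect_intrinsic_peep",
    "fit_slope_break",
    "fit_knee_exp",
    "measure_peak_plateau",
    "pcond_method",
    "standard_method",
]


@dataclass(frozen=True)
class DetectionConfig:
    """All detector constants, in one place.

    Attributes
    ----------
    closure_threshold:
        Minimum ``P_cond - P_res`` excess (cmH2O) to call airway closure.
    onset_flow_threshold:
        Flow (L/min) above which insufflation is considered started; must be
        sustained for at least 3 samples.
    break_window_s:
        Window after onset searched for the slope break on constant-flow
        breaths, s.  Kept short: the break of interest sits at the very
        beginning of insufflation, and a short window keeps later features
        of the pressure curve (e.g. a compliance inflection) out of the fit.
        The low-flow method always fits the full insufflation instead.
    plateau_window_s:
        Span averaged at the end of the occlusion to read the plateau, s.
    min_pause_s:
        Minimum occlusion length for a valid plateau, s.
    slope_ratio_min:
        Minimum slope1/slope2 for a qualifying break in the low-flow method.
        The first slope of a genuine closure is the circuit-compliance
        charging slope, roughly an order of magnitude above any lung slope;
        a bilinear PV curve only produces ratios near ``c_above/c_below``.
    sse_ratio_min:
        Minimum SSE(one segment)/SSE(two segments) for a qualifying break
        (an F-like goodness criterion) in the low-flow method.
    report_rounding:
        Resolution (cmH2O) at which AOP values are reported.
    smooth_samples:
        Width of an optional moving-average pre-filter applied to the
        pressure trace before fitting and peak reading (1, the default,
        disables it).  The estimators are least-squares fits that average
        noise on their own, and pre-smoothing blurs the very corner being
        located, so the filter is off unless the input is unusually noisy.
    occlusion_flow_threshold:
        |flow| (L/min) below which a sample counts as occluded.
    intrinsic_flow_threshold:
        |flow| (L/min) at the last pre-insufflation sample above which
        intrinsic PEEP is flagged.
    flow_correction:
        When set, ``P_res`` is rescaled by the ratio of the measured flow at
        the slope break to the measured end-insufflation flow, accounting
        for ventilators whose flow is not perfectly constant.
    """

    closure_threshold: float = 1.0
    onset_flow_threshold: float = 2.0
    break_window_s: float = 0.15
    plateau_window_s: float = 0.1
    min_pause_s: float = 0.3
    slope_ratio_min: float = 5.0
    sse_ratio_min: float = 5.0
    report_rounding: float = 1.0
    smooth_samples: int = 1
    occlusion_flow_threshold: float = 0.5
    intrinsic_flow_threshold: float = 2.0
    flow_correction: bool = False

    def __post_init__(self) -> None:
        if not self.closure_threshold > 0:
            raise ValueError("closure_threshold must be > 0")
        if self.min_pause_s < 0.3:
            raise ValueError("min_pause_s must be >= 0.3 s")
        if not self.slope_ratio_min > 1:
            raise ValueError("slope_ratio_min must be > 1")
        if self.smooth_samples < 1:
            raise ValueError("smooth_samples must be >= 1")


@dataclass
class AOPResult:
    """Outcome of either detection method on one breath."""

    method: str                       # "pcond" | "standard"
    closure_detected: bool
    set_peep: float
    aop: Optional[float] = None       # raw value, cmH2O; None when no closure
    p_cond: Optional[float] = None    # pcond method only
    p_res: Optional[float] = None     # pcond method only
    p_break: Optional[float] = None   # fitted pressure at the slope break
    peak: Optional[float] = None
    plateau: Optional[float] = None
    intrinsic_peep_flag: bool = False
    fit_sse_ratio: Optional[float] = None
    slope1: Optional[float] = None
    slope2: Optional[float] = None
    report_rounding: float = 1.0

    @property
    def aop_reported(self) -> Optional[float]:
        """AOP rounded to the reporting resolution (half-up), or ``None``."""
        if self.aop is None:
            return None
        res = self.report_rounding
        return float(np.floor(self.aop / res + 0.5) * res)

    def to_dict(self) -> dict:
        d = {
            "method": self.method,
            "closure_detected": self.closure_detected,
            "set_peep": self.set_peep,
            "aop": self.aop,
            "aop_reported": self.aop_reported,
            "p_cond": self.p_cond,
            "p_res": self.p_res,
            "p_break": self.p_break,
            "peak": self.peak,
            "plateau": self.plateau,
            "intrinsic_peep_flag": self.intrinsic_peep_flag,
            "fit_sse_ratio": self.fit_sse_ratio,
        }
        return d


@dataclass(frozen=True)
class BreakFit:
    """Result of a two-segment slope-break fit."""

    index: int          # breakpoint sample index into the waveform
    t_break: float
    p_break: float
    slope1: float
    slope2: float
    sse_ratio: float
    p_seg1_at_break: Optional[float] = None  # first-segment value at t_break
    sse: Optional[float] = None              # total SSE of the winning fit
    tau: Optional[float] = None              # time constant used, s


def _smooth(x: np.ndarray, k: int) -> np.ndarray:
    """Centred moving average of odd width ``k`` with edge padding."""
    if k <= 1:
        return x
    if k % 2 == 0:
        k += 1
    pad = k // 2
    xp = np.pad(x, pad, mode="edge")
    kernel = np.full(k, 1.0 / k)
    return np.convolve(xp, kernel, mode="valid")


def detect_onset(w: BreathWaveform, cfg: DetectionConfig = DetectionConfig()) -> int:
    """First sample where flow reaches the onset threshold for >= 3 samples."""
    thr = cfg.onset_flow_threshold / 60.0  # L/min -> L/s
    above = w.flow >= thr
    ok = above.copy()
    if ok.size >= 3:
        ok[:-2] = above[:-2] & above[1:-1] & above[2:]
        ok[-2:] = False
    idx = np.nonzero(ok)[0]
    if idx.size == 0:
        raise ValueError("no insufflation found (flow never sustained above threshold)")
    return int(idx[0])


def detect_intrinsic_peep(w: BreathWaveform,
                          cfg: DetectionConfig = DetectionConfig()) -> bool:
    """Flag intrinsic PEEP from residual end-expiratory flow.

    The sample inspected is the one immediately before insufflation onset;
    for records that begin at the onset (the simulator's convention) the
    breath is treated as cyclic and the last sample of the record — the end
    of the expiration — is used instead.
    """
    try:
        onset = detect_onset(w, cfg)
    except ValueError:
        return False
    i = onset - 1 if onset > 0 else w.n_samples - 1
    return bool(abs(w.flow[i]) * 60.0 > cfg.intrinsic_flow_threshold)


def fit_slope_break(w: BreathWaveform, onset: int, window_s: float,
                    cfg: DetectionConfig = DetectionConfig()) -> BreakFit:
    """Two-segment continuous piecewise-linear fit of paw against time.

    The breakpoint is searched exhaustively on the sample grid over
    ``[onset, onset + window_s]``; for each candidate the least-squares
    problem (value at the break plus the two slopes) is solved exactly and
    the candidate minimising the total SSE wins, earlier index on ties.
    ``sse_ratio`` compares a single straight line against the two-segment
    fit; values near 1 mean no break is present.
    """
    end = min(w.n_samples, onset + int(round(window_s * w.fs)) + 1)
    t = w.t[onset:end]
    p = _smooth(w.paw, cfg.smooth_samples)[onset:end]
    n = t.size
    if n < 6:
        raise ValueError(f"break window holds only {n} samples; need >= 6")

    # one-segment reference fit
    A1 = np.column_stack([np.ones(n), t - t[0]])
    coef1, res1, *_ = np.linalg.lstsq(A1, p, rcond=None)
    sse_one = float(res1[0]) if res1.size else float(np.sum((A1 @ coef1 - p) ** 2))

    best = None
    ones = np.ones(n)
    for j in range(2, n - 2):
        x = t - t[j]
        A = np.column_stack([ones, np.minimum(x, 0.0), np.maximum(x, 0.0)])
        coef, res, *_ = np.linalg.lstsq(A, p, rcond=None)
        sse = float(res[0]) if res.size else float(np.sum((A @ coef - p) ** 2))
        if best is None or sse < best[0] - 1e-15:
            best = (sse, j, coef)
    sse_two, j, coef = best
    a, b1, b2 = (float(c) for c in coef)

    if sse_one < 1e-12:  # straight or constant trace: no break to speak of
        ratio = 1.0
    elif sse_two < 1e-12:
        ratio = np.inf
    else:
        ratio = sse_one / sse_two
    return BreakFit(index=onset + j, t_break=float(t[j]), p_break=a,
                    slope1=b1, slope2=b2, sse_ratio=float(ratio))


#: time-constant grid (s) searched when no physical estimate is supplied
_TAU_GRID = (0.004, 0.008, 0.012, 0.018, 0.025, 0.035, 0.05)

#: clipping range for the physical time-constant estimate, s
_TAU_RANGE = (0.004, 0.06)


def fit_knee_exp(w: BreathWaveform, onset: int, window_s: float,
                 cfg: DetectionConfig = DetectionConfig(),
                 tau: Optional[float] = None,
                 p_res_hint: Optional[float] = None) -> BreakFit:
    """Slope-break fit using the physical response shape of the knee.

    For a linear lung behind a circuit compliance, the pressure after the
    break does not bend into the elastic ramp instantly: it approaches the
    ramp exponentially with time constant ``Rrs * Ccirc``.  Fitting a plain
    second line through that transient drags the fitted break pressure down
    by an amount that grows with the time constant.  This fit therefore
    models the window as a straight first segment followed by
    ``A + B*(t - tb) + C*exp(-(t - tb)/tau)`` with ``C <= 0`` (the corner
    is approached from below) and reports the *asymptote* value ``A`` at
    the breakpoint — the corner a human reader extrapolates by eye.

    The breakpoint is searched exhaustively on the sample grid.  ``tau``
    should be the physical time constant when an estimate is available
    (see :func:`pcond_method`); otherwise a small grid of plausible values
    is searched, which costs some variance on noisy traces.

    The grid breakpoint can land a few samples after the true corner (the
    first segment happily absorbs the start of the bend), in which case the
    reported asymptote includes that much of the second slope.  When
    ``p_res_hint`` — the measured peak-minus-plateau resistive pressure,
    which for this circuit-lung model equals the offset of the asymptote
    above the corner point — is given, the corner time is recovered as the
    intersection of the first-segment line with the asymptote shifted down
    by ``p_res_hint`` (falling back on the fitted exponential amplitude,
    which at the corner equals exactly that offset), and the asymptote is
    evaluated there instead.
    """
    end = min(w.n_samples, onset + int(round(window_s * w.fs)) + 1)
    t = w.t[onset:end]
    p = _smooth(w.paw, cfg.smooth_samples)[onset:end]
    n = t.size
    if n < 6:
        raise ValueError(f"break window holds only {n} samples; need >= 6")
    if tau is None:
        taus = _TAU_GRID
    elif np.isscalar(tau):
        taus = (float(tau),)
    else:
        taus = tuple(float(x) for x in tau)

    A1 = np.column_stack([np.ones(n), t - t[0]])
    coef1, res1, *_ = np.linalg.lstsq(A1, p, rcond=None)
    sse_one = float(res1[0]) if res1.size else float(np.sum((A1 @ coef1 - p) ** 2))

    best = None
    for j in range(2, n - 3):
        t1, p1 = t[:j], p[:j]
        X1 = np.column_stack([np.ones(j), t1 - t[j]])
        c1, r1, *_ = np.linalg.lstsq(X1, p1, rcond=None)
        sse1 = float(r1[0]) if r1.size else float(np.sum((X1 @ c1 - p1) ** 2))
        x = t[j:] - t[j]
        for tau_k in taus:
            X2 = np.column_stack([np.ones(x.size), x, np.exp(-x / tau_k)])
            c2, r2, *_ = np.linalg.lstsq(X2, p[j:], rcond=None)
            if c2[2] > 0:  # enforce approach from below: refit without the exp
                X0 = X2[:, :2]
                c0, r0, *_ = np.linalg.lstsq(X0, p[j:], rcond=None)
                c2 = np.array([c0[0], c0[1], 0.0])
                r2 = r0
            sse2 = float(r2[0]) if np.size(r2) else float(np.sum((X2 @ c2 - p[j:]) ** 2))
            sse = sse1 + sse2
            if best is None or sse < best[0] - 1e-15:
                best = (sse, j, c1, c2, tau_k)
    sse_two, j, c1, c2, tau_win = best
    slope1 = float(c1[1])
    a1 = float(c1[0])               # first-segment value at the breakpoint
    p_break = _corner_pressure(c2, a1, slope1, p_res_hint, tau_win,
                               max_back=(t[j] - t[0]) + 2.0 / w.fs)
    slope2 = float(c2[1])
    if sse_one < 1e-12:
        ratio = 1.0
    elif sse_two < 1e-12:
        ratio = np.inf
    else:
        ratio = sse_one / sse_two
    return BreakFit(index=onset + j, t_break=float(t[j]), p_break=p_break,
                    slope1=slope1, slope2=slope2, sse_ratio=float(ratio),
                    p_seg1_at_break=a1, sse=sse_two, tau=tau_win)


def _corner_pressure(c2, a1: float, slope1: float,
                     p_res_hint: Optional[float], tau: float,
                     max_back: float) -> float:
    """Asymptote value at the corner, given the two fitted segments.

    ``c2 = (A, B, C)`` is the post-break asymptote fit (value, slope,
    exponential amplitude, all at the breakpoint).  The corner sits where
    the first-segment line crosses the asymptote shifted down by the
    resistive offset; when that geometry is unusable the exponential
    amplitude provides the offset instead, and with no usable hint the
    asymptote at the breakpoint is returned unchanged.
    """
    A, B, amp = float(c2[0]), float(c2[1]), float(c2[2])
    if p_res_hint is None or not p_res_hint > 0.2:
        return A
    if slope1 > B + 100.0:
        dt = (A - p_res_hint - a1) / (slope1 - B)
        dt = float(np.clip(dt, -max_back, 0.05))
        return A + B * dt
    if amp < -1e-6:
        back = tau * math.log(max(p_res_hint / -amp, 1e-3))
        back = float(np.clip(back, 0.0, max_back))
        return A - B * back
    return A


def _charging_slope(w: BreathWaveform, onset: int, cfg: DetectionConfig) -> float:
    """Circuit charging slope, cmH2O/s, from raw early sample differences.

    The steepest consecutive-sample slope within the first ~60 ms of
    insufflation is circuit-dominated whether or not the airway is closed
    (lung flow starts at zero either way).
    """
    k = max(2, int(round(0.06 * w.fs)))
    seg = w.paw[onset:onset + k + 1]
    return float(np.max(np.diff(seg)) * w.fs)


def _occlusion_segment(w: BreathWaveform, onset: int,
                       cfg: DetectionConfig) -> Tuple[int, int]:
    """Indices ``(start, stop)`` of the end-inspiratory occlusion."""
    thr = cfg.occlusion_flow_threshold / 60.0
    i = onset
    n = w.n_samples
    while i < n and w.flow[i] > thr:
        i += 1
    start = i
    while i < n and abs(w.flow[i]) < thr:
        i += 1
    return start, i


def measure_peak_plateau(w: BreathWaveform,
                         cfg: DetectionConfig = DetectionConfig()) -> Tuple[float, float]:
    """Peak pressure of the insufflation and plateau of the occlusion.

    Peak is the maximum (lightly smoothed) airway pressure during
    insufflation; plateau is the mean pressure over the final
    ``plateau_window_s`` of the occlusion.  Raises when the occlusion is
    shorter than ``min_pause_s``.
    """
    onset = detect_onset(w, cfg)
    occ_start, occ_stop = _occlusion_segment(w, onset, cfg)
    pause = (occ_stop - occ_start) / w.fs
    if pause < cfg.min_pause_s:
        raise ValueError(
            f"occlusion too short: {pause:.2f} s < {cfg.min_pause_s} s; "
            "plateau (and resistive pressure) unavailable"
        )
    peak = _peak_pressure(w, onset, occ_start, cfg)
    k = max(1, int(round(cfg.plateau_window_s * w.fs)))
    plateau = float(np.mean(w.paw[occ_stop - k:occ_stop]))
    return peak, plateau


def _peak_pressure(w: BreathWaveform, onset: int, occ_start: int,
                   cfg: DetectionConfig) -> float:
    """Peak airway pressure at end-insufflation.

    The pressure ramps up to the very last insufflation instant, which in
    general falls between samples; a raw sample maximum therefore reads
    low by up to one sample's worth of ramp (and, under noise, rides the
    noise).  The end of the ramp is instead extrapolated from a straight
    fit of the (smoothed) pressure over the last ~80 ms of insufflation,
    excluding the samples blurred by the smoothing filter at the corner.
    Falls back to the sample maximum on very short insufflations.
    """
    psm = _smooth(w.paw, cfg.smooth_samples)
    guard = cfg.smooth_samples // 2
    stop = occ_start - guard
    k = int(round(0.08 * w.fs))
    start = stop - k
    if start < onset + 2 or stop - start < 3:
        return float(np.max(psm[onset:occ_start]))
    tt = w.t[start:stop]
    pp = psm[start:stop]
    coef = np.polyfit(tt, pp, 1)
    # insufflation runs through the whole last flow-on sampling interval
    t_end = w.t[occ_start - 1] + 1.0 / w.fs
    return float(np.polyval(coef, t_end))


def pcond_method(w: BreathWaveform, set_peep: float,
                 cfg: DetectionConfig = DetectionConfig()) -> AOPResult:
    """Conductive-pressure method on a usual constant-flow breath.

    ``P_cond`` is the fitted slope-break pressure minus set PEEP; ``P_res``
    is peak minus plateau.  Closure is called when their difference exceeds
    ``closure_threshold`` and the AOP is ``set_peep + (P_cond - P_res)``.
    An intrinsic-PEEP flag marks the result as unreliable (the measurement
    assumes no intrinsic PEEP); it does not change the computation.

    The slope-break fit is anchored on the physical time constant of the
    circuit-lung node, ``tau = Rrs * Ccirc``, estimated from the breath as
    raw peak-minus-plateau over the initial charging slope.  The fit window
    starts at ``break_window_s`` and is extended (up to 0.25 s) only when
    that time constant is long enough to need it — keeping later features
    of the pressure curve out of the fit whenever possible.
    """
    intrinsic = detect_intrinsic_peep(w, cfg)
    onset = detect_onset(w, cfg)
    peak, plateau = measure_peak_plateau(w, cfg)
    p_res_raw = peak - plateau
    slope_ct = _charging_slope(w, onset, cfg)
    occ_start, _ = _occlusion_segment(w, onset, cfg)
    q = float(w.flow[onset])
    vt = float(np.max(w.volume[onset:occ_start + 1]))

    # physical time constant of the knee transient (corrected first-order
    # for the circuit share of the delivered volume), and the fit window
    taus = None
    window_s = cfg.break_window_s
    if slope_ct > 50.0 and q > 0:
        taus = _tau_candidates(w, onset, slope_ct, p_res_raw, plateau,
                               set_peep, vt, q)
    fit = fit_knee_exp(w, onset, window_s, cfg, tau=taus, p_res_hint=p_res_raw)
    if fit.tau is not None and taus is not None:
        fit = _refine_knee_long_window(w, onset, window_s, occ_start, fit,
                                       fit.tau, p_res_raw, cfg)

    p_cond = fit.p_break - set_peep
    p_res = p_res_raw
    if cfg.flow_correction:
        q_break = float(w.flow[fit.index])
        q_end = float(w.flow[max(onset, occ_start - 1)])
        if q_end > 0:
            p_res = p_res * (q_break / q_end)
    detected = (p_cond - p_res) > cfg.closure_threshold
    aop = set_peep + (p_cond - p_res) if detected else None
    return AOPResult(
        method="pcond", closure_detected=bool(detected), set_peep=set_peep,
        aop=aop, p_cond=p_cond, p_res=p_res, p_break=fit.p_break,
        peak=peak, plateau=plateau, intrinsic_peep_flag=intrinsic,
        fit_sse_ratio=fit.sse_ratio, slope1=fit.slope1, slope2=fit.slope2,
        report_rounding=cfg.report_rounding,
    )


def _tau_candidates(w: BreathWaveform, onset: int, slope_ct: float,
                    p_res_raw: float, plateau: float, set_peep: float,
                    vt: float, q: float) -> Tuple[float, ...]:
    """Physical candidates for the knee time constant ``Rrs * Ceq``.

    Candidate A treats the steepest early interval as the pure circuit
    charging slope — exact when the airway starts closed, because the
    pre-opening pressure rise is a straight line.  Candidate B inverts the
    first-interval rise of the open-airway exponential — better when no
    closure phase exists, since then every early interval already bends.
    The knee fit itself arbitrates between them by residual.
    """
    ccirc_est = 1000.0 * q / slope_ct
    ctot0 = vt / max(plateau - set_peep, 1.0)
    circ_share = min(0.9, ccirc_est / max(ctot0, ccirc_est + 1e-9))
    tau_a = float(np.clip(p_res_raw / slope_ct / (1.0 - circ_share), *_TAU_RANGE))
    cands = [tau_a]
    h = 1.0 / w.fs
    dp1 = float(w.paw[onset + 1] - w.paw[onset]) if onset + 1 < w.n_samples else 0.0
    ramp = 1000.0 * q / max(ctot0, 1.0)
    p_inf = p_res_raw / (1.0 - circ_share)
    if p_inf > 0.5:
        arg = 1.0 - (dp1 - ramp * h) / p_inf
        if 0.05 < arg < 0.95:
            tau_b = float(np.clip(-h / math.log(arg), *_TAU_RANGE))
            if abs(tau_b - tau_a) > 1e-4:
                cands.append(tau_b)
    return tuple(cands)


def _fit_asymptote(w: BreathWaveform, j_abs: int, end_abs: int, tau: float):
    """Least-squares ``A + B*x + C*exp(-x/tau)`` (C <= 0) from sample ``j_abs``."""
    x = w.t[j_abs:end_abs] - w.t[j_abs]
    p = w.paw[j_abs:end_abs]
    X = np.column_stack([np.ones(x.size), x, np.exp(-x / tau)])
    c, r, *_ = np.linalg.lstsq(X, p, rcond=None)
    if c[2] > 0:
        c0, r0, *_ = np.linalg.lstsq(X[:, :2], p, rcond=None)
        c = np.array([c0[0], c0[1], 0.0])
        r = r0
    sse = float(r[0]) if np.size(r) else float(np.sum((X @ c - p) ** 2))
    return c, sse, x.size


def _refine_knee_long_window(w: BreathWaveform, onset: int, window_s: float,
                             occ_start: int, fit: BreakFit, tau: float,
                             p_res_hint: float, cfg: DetectionConfig) -> BreakFit:
    """Re-estimate the asymptote over a longer window when that is safe.

    The short window protects the fit from later curvature of the pressure
    ramp (a compliance inflection bends it upward mid-insufflation), at the
    price of a noisier asymptote.  This refinement refits the post-break
    model over up to 0.3 s and keeps the long-window estimate only when its
    per-sample residual is commensurate with the short window's — i.e. when
    the longer stretch of data is actually described by the same
    line-plus-exponential, which a mid-insufflation bend violates.
    """
    j_abs = fit.index
    end_short = min(w.n_samples, onset + int(round(window_s * w.fs)) + 1, occ_start)
    long_s = float(np.clip(0.10 + 5.0 * tau, window_s, 0.30))
    end_long = min(w.n_samples, onset + int(round(long_s * w.fs)) + 1, occ_start)
    if end_long - end_short < 3 or end_short - j_abs < 4:
        return fit
    c_s, sse_s, n_s = _fit_asymptote(w, j_abs, end_short, tau)
    c_l, sse_l, n_l = _fit_asymptote(w, j_abs, end_long, tau)
    dof_s = max(n_s - 3, 1)
    dof_l = max(n_l - 3, 1)
    # F-like check on the *added* stretch of data only: mean squared
    # residual of the extra samples against that of the short window
    ms_short = sse_s / dof_s
    ms_extra = (sse_l - sse_s) / max(n_l - n_s, 1)
    if ms_extra > 3.0 * ms_short + 0.01:
        return fit
    a1 = fit.p_seg1_at_break if fit.p_seg1_at_break is not None else float(c_l[0])
    p_break = _corner_pressure(
        c_l, a1, fit.slope1, p_res_hint, tau,
        max_back=(w.t[j_abs] - w.t[onset]) + 2.0 / w.fs)
    return BreakFit(index=fit.index, t_break=fit.t_break, p_break=p_break,
                    slope1=fit.slope1, slope2=float(c_l[1]),
                    sse_ratio=fit.sse_ratio, p_seg1_at_break=fit.p_seg1_at_break)


def standard_method(w: BreathWaveform, set_peep: float,
                    cfg: DetectionConfig = DetectionConfig()) -> AOPResult:
    """Standard low-flow method: the slope-break pressure is the AOP.

    The two-segment fit runs over the whole insufflation.  A break
    qualifies as airway closure when the fit is decisively better than a
    straight line (``sse_ratio``), the first slope dominates the second
    (circuit compliance against lung compliance) and the break pressure
    sits above PEEP by more than the closure threshold.

    The quality ratio is evaluated over a window local to the detected
    break rather than the whole insufflation: a genuine break lives in the
    first fraction of a several-second maneuver, and residuals summed over
    the long featureless remainder would dilute its evidence below any
    useful cutoff on noisy traces.
    """
    intrinsic = detect_intrinsic_peep(w, cfg)
    onset = detect_onset(w, cfg)
    occ_start, _ = _occlusion_segment(w, onset, cfg)
    window_s = (occ_start - onset) / w.fs
    fit = fit_slope_break(w, onset, window_s, cfg)
    peak = float(np.max(_smooth(w.paw, cfg.smooth_samples)[onset:occ_start]))
    if fit.slope2 <= 0:
        slope_ratio = np.inf if fit.slope1 > 0 else 0.0
    else:
        slope_ratio = fit.slope1 / fit.slope2
    local_s = min(window_s, max(1.0, 2.0 * (fit.t_break - w.t[onset])))
    sse_ratio = _local_sse_ratio(w, onset, fit.index, local_s, cfg)
    detected = (
        sse_ratio >= cfg.sse_ratio_min
        and slope_ratio >= cfg.slope_ratio_min
        and (fit.p_break - set_peep) > cfg.closure_threshold
    )
    return AOPResult(
        method="standard", closure_detected=bool(detected), set_peep=set_peep,
        aop=fit.p_break if detected else None, p_break=fit.p_break, peak=peak,
        intrinsic_peep_flag=intrinsic, fit_sse_ratio=sse_ratio,
        slope1=fit.slope1, slope2=fit.slope2,
        report_rounding=cfg.report_rounding,
    )


def _local_sse_ratio(w: BreathWaveform, onset: int, break_idx: int,
                     window_s: float, cfg: DetectionConfig) -> float:
    """One-segment over two-segment SSE near the break (fixed breakpoint)."""
    end = min(w.n_samples, onset + int(round(window_s * w.fs)) + 1)
    if break_idx <= onset + 1 or break_idx >= end - 2:
        return 1.0
    t = w.t[onset:end]
    p = _smooth(w.paw, cfg.smooth_samples)[onset:end]
    x = t - w.t[break_idx]
    A1 = np.column_stack([np.ones(x.size), x])
    c1, r1, *_ = np.linalg.lstsq(A1, p, rcond=None)
    sse_one = float(r1[0]) if r1.size else float(np.sum((A1 @ c1 - p) ** 2))
    A2 = np.column_stack([np.ones(x.size), np.minimum(x, 0.0), np.maximum(x, 0.0)])
    c2, r2, *_ = np.linalg.lstsq(A2, p, rcond=None)
    sse_two = float(r2[0]) if r2.size else float(np.sum((A2 @ c2 - p) ** 2))
    if sse_one < 1e-12:
        return 1.0
    if sse_two < 1e-12:
        return float(np.inf)
    return sse_one / sse_two
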