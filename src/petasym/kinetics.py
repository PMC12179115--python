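"""Simplified reference tissue model (SRTM) kinetics for dynamic PET.

The SRTM expresses a target-tissue time-activity curve (TAC) as a function of a
reference-tissue TAC::

    C_T(t) = R1 * C_R(t) + (k2 - R1 * k2a) * int_0^t C_R(s) exp(-k2a (t - s)) ds

with ``k2a = k2 / (1 + BP_ND)`` the apparent efflux rate.  The distribution
volume ratio is ``DVR = BP_ND + 1`` and ``R1 = K1/K1'`` is the tracer delivery
ratio.  All TACs are assumed decay-corrected; no decay term appears anywhere.

Fitting uses the basis-function method: for each candidate ``k2a`` on a search
grid the model is linear in ``(theta1, theta2) = (R1, k2 - R1*k2a)`` and is
solved by weighted linear least squares; the winning ``k2a`` is then refined by
golden-section search.  An independent multi-start nonlinear least-squares
fitter is provided as a brute-force cross-check.

The reference curve is treated as piecewise linear through the frame midpoints
(anchored at ``(0, 0)``); the convolution with the exponential is evaluated
analytically segment by segment, and model outputs are frame averages
(integrated over each frame), not midpoint samples, because frame durations
range from 5 s to 10 min.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "FrameSchedule",
    "TimeActivityCurve",
    "PiecewiseLinearCurve",
    "SRTMParams",
    "SRTMFit",
    "SUVValue",
    "make_frame_schedule",
    "manchester_schedule",
    "turku_schedule",
    "default_weights",
    "srtm_forward",
    "SRTMBasis",
    "fit_srtm_basis",
    "fit_srtm_nls_oracle",
    "compute_suv_window",
    "DEFAULT_K2A_GRID",
]

#: Default apparent-efflux search grid: 256 log-spaced values on [0.005, 1.0] /min,
#: bracketing plausible PK11195 kinetics with near-continuous resolution.
DEFAULT_K2A_GRID = np.geomspace(0.005, 1.0, 256)


@dataclass(frozen=True)
class FrameSchedule:
    """Ordered dynamic-PET frame boundaries in minutes, injection at t = 0.

    At most one frame (a pre-injection background frame) may start before 0.
    """

    starts: tuple[float, ...]
    ends: tuple[float, ...]

    def __post_init__(self) -> None:
        s = np.asarray(self.starts, dtype=float)
        e = np.asarray(self.ends, dtype=float)
        if s.ndim != 1 or s.shape != e.shape or s.size == 0:
            raise ValueError("starts and ends must be equal-length non-empty sequences")
        if np.any(e <= s):
            raise ValueError("every frame must have end > start")
        if np.any(s[1:] < e[:-1]):
            raise ValueError("frames must be non-overlapping and increasing")
        if np.count_nonzero(s < 0) > 1:
            raise ValueError("at most one frame may start before injection (t = 0)")

    @property
    def n_frames(self) -> int:
        return len(self.starts)

    @property
    def start_array(self) -> np.ndarray:
        return np.asarray(self.starts, dtype=float)

    @property
    def end_array(self) -> np.ndarray:
        return np.asarray(self.ends, dtype=float)

    @property
    def durations(self) -> np.ndarray:
        return self.end_array - self.start_array

    @property
    def midpoints(self) -> np.ndarray:
        return 0.5 * (self.start_array + self.end_array)

    @property
    def post_injection(self) -> np.ndarray:
        """Boolean mask of frames acquired after injection."""
        return self.start_array >= 0.0

    @property
    def post_duration(self) -> float:
        """Total covered post-injection time in minutes."""
        return float(self.durations[self.post_injection].sum())


def make_frame_schedule(
    spec: Sequence[tuple[int, float]], background_min: float | None = None
) -> FrameSchedule:
    """Build a contiguous schedule from ``(count, duration_minutes)`` blocks.

    Frames start at t = 0; an optional background frame of ``background_min``
    minutes is placed immediately before injection.
    """
    starts: list[float] = []
    ends: list[float] = []
    if background_min is not None:
        if background_min <= 0:
            raise ValueError("background duration must be positive")
        starts.append(-float(background_min))
        ends.append(0.0)
    t = 0.0
    for count, duration in spec:
        if count <= 0 or duration <= 0:
            raise ValueError("frame counts and durations must be positive")
        for _ in range(int(count)):
            starts.append(t)
            t += float(duration)
            ends.append(t)
    if not starts:
        raise ValueError("empty frame specification")
    return FrameSchedule(tuple(starts), tuple(ends))


def manchester_schedule() -> FrameSchedule:
    """18-frame schedule: ~6 min background, then 15 s, 5 s, 10 s, 30 s,
    4x1 min, 7x5 min, 2x10 min (60 min post-injection)."""
    spec = [
        (1, 15 / 60),
        (1, 5 / 60),
        (1, 10 / 60),
        (1, 30 / 60),
        (4, 1.0),
        (7, 5.0),
        (2, 10.0),
    ]
    return make_frame_schedule(spec, background_min=6.0)


def turku_schedule() -> FrameSchedule:
    """17-frame schedule: 2x15 s, 3x30 s, 3x1 min, 7x5 min, 2x10 min."""
    spec = [(2, 15 / 60), (3, 30 / 60), (3, 1.0), (7, 5.0), (2, 10.0)]
    return make_frame_schedule(spec)


@dataclass
class TimeActivityCurve:
    """Decay-corrected concentration (kBq/mL) per frame of a schedule."""

    schedule: FrameSchedule
    values: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size != self.schedule.n_frames:
            raise ValueError("need exactly one value per frame")
        if not np.all(np.isfinite(v)):
            raise ValueError("TAC values must be finite")
        self.values = v

    def with_values(self, values: np.ndarray, label: str | None = None) -> "TimeActivityCurve":
        return TimeActivityCurve(self.schedule, values, self.label if label is None else label)


@dataclass(frozen=True)
class SRTMParams:
    """SRTM parameters: delivery ratio R1, efflux k2 (1/min), binding BP_ND."""

    r1: float
    k2: float
    bp_nd: float

    def __post_init__(self) -> None:
        if self.bp_nd <= -1.0:
            raise ValueError("BP_ND must exceed -1 (k2a undefined otherwise)")

    @property
    def dvr(self) -> float:
        return self.bp_nd + 1.0

    @property
    def k2a(self) -> float:
        return self.k2 / (1.0 + self.bp_nd)


@dataclass(frozen=True)
class SRTMFit:
    params: SRTMParams
    wrss: float
    weights: tuple[float, ...]
    grid_index: int
    boundary_flag: bool
    degenerate_flag: bool = False
    n_iter: int = 0

    @property
    def dvr(self) -> float:
        return self.params.dvr


@dataclass(frozen=True)
class SUVValue:
    """Standardized uptake value (dimensionless, tissue density 1 g/mL)."""

    value: float
    window: tuple[float, float]

    def __post_init__(self) -> None:
        if self.window[1] <= self.window[0]:
            raise ValueError("SUV window end must exceed its start")


@dataclass(frozen=True)
class PiecewiseLinearCurve:
    """Continuous reference curve: piecewise linear through (nodes, values).

    The curve is 0 for t < nodes[0] and held constant after nodes[-1].
    """

    nodes: tuple[float, ...]
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        t = np.asarray(self.nodes, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.ndim != 1 or t.shape != v.shape or t.size < 2:
            raise ValueError("need at least two (node, value) pairs")
        if np.any(np.diff(t) <= 0):
            raise ValueError("nodes must be strictly increasing")

    @classmethod
    def from_tac(cls, tac: TimeActivityCurve) -> "PiecewiseLinearCurve":
        """Interpolant through post-injection frame midpoints, anchored at (0, 0)
        and held constant from the last midpoint to the last frame end."""
        sched = tac.schedule
        post = sched.post_injection
        mids = sched.midpoints[post]
        vals = tac.values[post]
        nodes = np.concatenate([[0.0], mids, [sched.end_array[-1]]])
        values = np.concatenate([[0.0], vals, [vals[-1]]])
        return cls(tuple(nodes), tuple(values))

    def __call__(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return np.where(
            t < self.nodes[0], 0.0, np.interp(t, self.nodes, self.values)
        )


class _FrameIntegrator:
    """Shared machinery: segment-analytic integrals of a piecewise-linear curve
    and of its exponential convolution, aggregated to frame averages."""

    def __init__(self, curve: PiecewiseLinearCurve, schedule: FrameSchedule):
        post = schedule.post_injection
        starts = schedule.start_array[post]
        ends = schedule.end_array[post]
        if ends[-1] > curve.nodes[-1] + 1e-9:
            raise ValueError("reference curve must cover [0, last frame end]")
        b = np.union1d(np.asarray(curve.nodes), np.concatenate([starts, ends]))
        b = b[(b >= 0.0) & (b <= ends[-1] + 1e-12)]
        self.b = b
        self.u = curve(b)
        self.h = np.diff(b)
        self.post = post
        self.durations = ends - starts
        # cumulative-integral lookup indices for each post frame
        self.i0 = np.searchsorted(b, starts)
        self.i1 = np.searchsorted(b, ends)
        seg_int_c = self.h * 0.5 * (self.u[:-1] + self.u[1:])
        self.cum_int_c = np.concatenate([[0.0], np.cumsum(seg_int_c)])
        self.seg_int_c = seg_int_c
        self.n_frames = schedule.n_frames

    def frame_avg_curve(self) -> np.ndarray:
        """Frame averages of the curve itself (0 for background frames)."""
        out = np.zeros(self.n_frames)
        out[self.post] = (self.cum_int_c[self.i1] - self.cum_int_c[self.i0]) / self.durations
        return out

    def frame_avg_conv(self, lams: np.ndarray) -> np.ndarray:
        """Frame averages of I(t) = int_0^t C(s) exp(-lam (t-s)) ds.

        Returns an array of shape (n_frames, len(lams)); background frames are 0.
        """
        lams = np.atleast_1d(np.asarray(lams, dtype=float))
        if np.any(lams <= 0):
            raise ValueError("convolution rates must be positive")
        h = self.h[:, None]
        lam = lams[None, :]
        u0 = self.u[:-1, None]
        slope = ((self.u[1:] - self.u[:-1]) / self.h)[:, None]
        g = -np.expm1(-lam * h) / lam  # (1 - e^{-lam h}) / lam
        c = u0 * g + slope * (h - g) / lam
        # closed-form scan: I_k = exp(-lam b_k) * sum_{j<k} c_j exp(lam b_{j+1})
        scaled = c * np.exp(lam * self.b[1:, None])
        cum = np.cumsum(scaled, axis=0)
        i_at = np.zeros((self.b.size, lams.size))
        i_at[1:] = np.exp(-lam * self.b[1:, None]) * cum
        # per-segment integral of I from the ODE: int I = (int C - dI) / lam
        seg_int_i = (self.seg_int_c[:, None] - np.diff(i_at, axis=0)) / lam
        cum_i = np.concatenate([np.zeros((1, lams.size)), np.cumsum(seg_int_i, axis=0)])
        out = np.zeros((self.n_frames, lams.size))
        out[self.post] = (cum_i[self.i1] - cum_i[self.i0]) / self.durations[:, None]
        return out


def default_weights(schedule: FrameSchedule, uniform: bool = False) -> np.ndarray:
    """Per-frame fit weights: frame duration in minutes (variance ~ 1/duration
    under the frame-noise model) or uniform; background frames always 0."""
    post = schedule.post_injection
    w = np.where(post, 1.0 if uniform else schedule.durations, 0.0)
    return w.astype(float)


def srtm_forward(
    params: SRTMParams,
    ref: TimeActivityCurve | PiecewiseLinearCurve,
    schedule: FrameSchedule,
) -> TimeActivityCurve:
    """Frame-averaged SRTM model output for a reference input.

    When ``ref`` is a measured TAC its frame values are used directly for the
    ``R1 * C_R`` term (they already are frame averages) and its midpoint
    interpolant for the convolution term; a continuous curve is integrated
    analytically for both terms.
    """
    lam = params.k2a
    if lam <= 0:
        raise ValueError("k2a must be positive")
    if isinstance(ref, TimeActivityCurve):
        if ref.schedule != schedule:
            raise ValueError("reference TAC schedule does not match the target schedule")
        curve = PiecewiseLinearCurve.from_tac(ref)
        integ = _FrameIntegrator(curve, schedule)
        r_term = np.where(schedule.post_injection, ref.values, 0.0)
    else:
        curve = ref
        integ = _FrameIntegrator(curve, schedule)
        r_term = integ.frame_avg_curve()
    conv = integ.frame_avg_conv(np.array([lam]))[:, 0]
    vals = params.r1 * r_term + (params.k2 - params.r1 * lam) * conv
    return TimeActivityCurve(schedule, vals, label="srtm_forward")


def _degenerate_params(r1: float, lam: float) -> SRTMParams:
    """Parameters on the degenerate ridge theta2 = 0 (target proportional to
    reference): every k2a fits, but the ridge relation k2 = R1*k2a pins
    BP_ND = R1 - 1 (hence DVR = R1) uniquely.  An all-zero target reports 0."""
    if abs(r1) < 1e-12:
        return SRTMParams(0.0, 0.0, 0.0)
    bp = max(r1 - 1.0, -0.999)
    return SRTMParams(r1=r1, k2=r1 * lam, bp_nd=bp)


def _golden_section_min(f, a: float, b: float, tol: float = 1e-6, max_iter: int = 80):
    """Golden-section minimisation of f on [a, b]; returns (x, f(x), n_iter)."""
    invphi = (math.sqrt(5.0) - 1.0) / 2.0
    x1 = b - invphi * (b - a)
    x2 = a + invphi * (b - a)
    f1, f2 = f(x1), f(x2)
    it = 2
    while (b - a) > tol and it < max_iter:
        if f1 <= f2:
            b, x2, f2 = x2, x1, f1
            x1 = b - invphi * (b - a)
            f1 = f(x1)
        else:
            a, x1, f1 = x1, x2, f2
            x2 = a + invphi * (b - a)
            f2 = f(x2)
        it += 1
    return (x1, f1, it) if f1 <= f2 else (x2, f2, it)


class SRTMBasis:
    """Precomputed basis-function fitter for one reference TAC.

    Building the basis (the convolution columns over the whole ``k2a`` grid) is
    the expensive part; reuse one instance to fit many targets sharing the same
    reference and schedule.
    """

    def __init__(
        self,
        ref: TimeActivityCurve,
        grid: np.ndarray | None = None,
        weights: np.ndarray | None = None,
    ):
        self.ref = ref
        self.schedule = ref.schedule
        grid = DEFAULT_K2A_GRID if grid is None else np.asarray(grid, dtype=float)
        if grid.ndim != 1 or grid.size < 2 or np.any(grid <= 0) or np.any(np.diff(grid) <= 0):
            raise ValueError("k2a grid must be positive, sorted and of length >= 2")
        self.grid = grid
        if weights is None:
            weights = default_weights(self.schedule)
        weights = np.asarray(weights, dtype=float)
        if weights.shape != (self.schedule.n_frames,) or np.any(weights < 0):
            raise ValueError("weights must be non-negative, one per frame")
        self.weights = weights
        post = self.schedule.post_injection
        if int(post.sum()) < 3:
            raise ValueError("need at least 3 post-injection frames")
        self.post = post
        self._curve = PiecewiseLinearCurve.from_tac(ref)
        self._integ = _FrameIntegrator(self._curve, self.schedule)
        self.basis = self._integ.frame_avg_conv(grid)[post]  # (n_post, n_grid)
        self.r = ref.values[post]
        self.w = weights[post]
        # grid-independent normal-equation pieces
        self._a11 = float(np.sum(self.w * self.r * self.r))
        self._wr = self.w * self.r

    def _column(self, lam: float) -> np.ndarray:
        return self._integ.frame_avg_conv(np.array([lam]))[self.post, 0]

    def _solve(self, y: np.ndarray, col: np.ndarray):
        """Weighted 2-parameter LLS of y on (r, col); returns (t1, t2, wrss)."""
        a12 = float(np.sum(self._wr * col))
        a22 = float(np.sum(self.w * col * col))
        b1 = float(np.sum(self._wr * y))
        b2 = float(np.sum(self.w * col * y))
        det = self._a11 * a22 - a12 * a12
        if det <= 0 or not np.isfinite(det):
            t1 = b1 / self._a11 if self._a11 > 0 else 0.0
            t2 = 0.0
        else:
            t1 = (a22 * b1 - a12 * b2) / det
            t2 = (self._a11 * b2 - a12 * b1) / det
        wrss = float(np.sum(self.w * y * y) - t1 * b1 - t2 * b2)
        return t1, t2, max(wrss, 0.0)

    def fit(self, target: TimeActivityCurve | np.ndarray, refine: bool = True) -> SRTMFit:
        if isinstance(target, TimeActivityCurve):
            if target.schedule != self.schedule:
                raise ValueError("target and reference schedules differ")
            y = target.values[self.post]
        else:
            y = np.asarray(target, dtype=float)
            if y.shape == (self.schedule.n_frames,):
                y = y[self.post]
            elif y.shape != (int(self.post.sum()),):
                raise ValueError("target values have wrong length")
        wtuple = tuple(self.weights)
        yscale = float(np.sum(self.w * y * y))
        if yscale == 0.0:
            params = SRTMParams(0.0, 0.0, 0.0)
            return SRTMFit(params, 0.0, wtuple, 0, False, degenerate_flag=True)

        # grid sweep, vectorised over k2a
        a12 = self._wr @ self.basis
        a22 = self.w @ (self.basis * self.basis)
        b1 = float(np.sum(self._wr * y))
        b2 = (self.w * y) @ self.basis
        det = self._a11 * a22 - a12 * a12
        good = det > 0
        t1 = np.where(good, (a22 * b1 - a12 * b2) / np.where(good, det, 1.0), 0.0)
        t2 = np.where(good, (self._a11 * b2 - a12 * b1) / np.where(good, det, 1.0), 0.0)
        wrss = np.sum(self.w[:, None] * y[:, None] ** 2, axis=0) - t1 * b1 - t2 * b2
        wrss = np.maximum(wrss, 0.0)
        idx = int(np.argmin(wrss))
        boundary = idx in (0, self.grid.size - 1)
        lam = float(self.grid[idx])
        th1, th2, best = float(t1[idx]), float(t2[idx]), float(wrss[idx])
        n_iter = 0

        if refine and not boundary:
            lo = math.log(self.grid[idx - 1])
            hi = math.log(self.grid[idx + 1])

            def objective(loglam: float) -> float:
                _, _, w_ = self._solve(y, self._column(math.exp(loglam)))
                return w_

            xbest, fbest, n_iter = _golden_section_min(objective, lo, hi, tol=1e-7)
            if fbest <= best:
                lam = math.exp(xbest)
                th1, th2, best = self._solve(y, self._column(lam))

        degenerate = abs(th2) <= 1e-7 * max(abs(th1) * lam, 1e-300)
        if degenerate:
            params = _degenerate_params(th1, lam)
        else:
            k2 = th2 + th1 * lam
            params = SRTMParams(r1=th1, k2=k2, bp_nd=k2 / lam - 1.0)
        return SRTMFit(params, best, wtuple, idx, boundary, degenerate, n_iter)


def fit_srtm_basis(
    target: TimeActivityCurve,
    ref: TimeActivityCurve,
    grid: np.ndarray | None = None,
    weights: np.ndarray | None = None,
    refine: bool = True,
) -> SRTMFit:
    """Basis-function SRTM fit of one target TAC against a reference TAC."""
    return SRTMBasis(ref, grid=grid, weights=weights).fit(target, refine=refine)


def fit_srtm_nls_oracle(
    target: TimeActivityCurve,
    ref: TimeActivityCurve,
    weights: np.ndarray | None = None,
    init: SRTMParams | None = None,
) -> SRTMFit:
    """Direct multi-start weighted nonlinear least squares on (R1, k2, k2a).

    Slow brute-force reference fitter used to cross-check the basis method.
    Raises ``RuntimeError`` if no start converges.
    """
    from scipy.optimize import least_squares

    if target.schedule != ref.schedule:
        raise ValueError("target and reference schedules differ")
    schedule = target.schedule
    if weights is None:
        weights = default_weights(schedule)
    weights = np.asarray(weights, dtype=float)
    post = schedule.post_injection
    y = target.values[post]
    r = ref.values[post]
    sw = np.sqrt(weights[post])
    integ = _FrameIntegrator(PiecewiseLinearCurve.from_tac(ref), schedule)

    def model(p: np.ndarray) -> np.ndarray:
        r1, k2, lam = p
        conv = integ.frame_avg_conv(np.array([lam]))[post, 0]
        return r1 * r + (k2 - r1 * lam) * conv

    def residuals(p: np.ndarray) -> np.ndarray:
        return sw * (model(p) - y)

    starts: list[np.ndarray] = []
    if init is not None:
        starts.append(np.array([init.r1, init.k2, init.k2a]))
    for lam0 in (0.02, 0.05, 0.12, 0.3, 0.7):
        for dvr0 in (1.0, 1.5):
            starts.append(np.array([1.0, lam0 * dvr0, lam0]))
    bounds = ([0.0, 1e-5, 1.2e-3], [10.0, 3.0, 1.5])
    best = None
    for x0 in starts:
        try:
            sol = least_squares(
                residuals, x0, bounds=bounds, xtol=1e-14, ftol=1e-14, gtol=1e-14
            )
        except Exception:
            continue
        if not sol.success:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise RuntimeError("SRTM NLS oracle failed to converge from every start")
    r1, k2, lam = best.x
    wrss = float(2.0 * best.cost)
    degenerate = abs(k2 - r1 * lam) <= 1e-7 * max(abs(r1) * lam, 1e-300)
    if degenerate:
        params = _degenerate_params(r1, lam)
    else:
        params = SRTMParams(r1=r1, k2=k2, bp_nd=k2 / lam - 1.0)
    grid_index = int(np.argmin(np.abs(DEFAULT_K2A_GRID - lam)))
    return SRTMFit(
        params, wrss, tuple(weights), grid_index, False, degenerate, int(best.nfev)
    )


def compute_suv_window(
    tac: TimeActivityCurve,
    injected_activity_mbq: float,
    body_weight_kg: float,
    window: tuple[float, float] = (40.0, 60.0),
) -> SUVValue:
    """Windowed standardized uptake value.

    The mean concentration over the window is the overlap-weighted average of
    the frames intersecting it; SUV = mean [kBq/mL] * weight [kg] / activity
    [MBq], dimensionless under an assumed tissue density of 1 g/mL.
    """
    if injected_activity_mbq <= 0 or body_weight_kg <= 0:
        raise ValueError("injected activity and body weight must be positive")
    lo, hi = window
    if hi <= lo:
        raise ValueError("window end must exceed window start")
    starts = tac.schedule.start_array
    ends = tac.schedule.end_array
    overlap = np.minimum(ends, hi) - np.maximum(starts, lo)
    overlap = np.maximum(overlap, 0.0)
    total = overlap.sum()
    if total <= 0:
        raise ValueError("SUV window does not overlap any frame")
    mean_conc = float(np.sum(overlap * tac.values) / total)
    return SUVValue(mean_conc * body_weight_kg / injected_activity_mbq, (lo, hi))
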