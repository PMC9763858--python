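"""Molecule counting: photobleach calibration, stoichiometry, periodicity.

A track's initial intensity ``I0`` is the ordinary-least-squares line through
its first five intensities extrapolated back to the first laser-exposed frame;
dividing by the characteristic single-fluorophore brightness ``I_1`` gives the
assembly stoichiometry.  ``I_1`` is calibrated two independent ways — the
modal brightness of foci after sufficient photobleaching, and the modal
interval of stepwise-photobleaching steps resolved with a Chung-Kennedy
edge-preserving filter — which must agree.

The stoichiometry distribution is summarised as a Gaussian KDE of kernel sd
0.6 molecules (the total single-molecule uncertainty), and the oligomer
periodicity as the modal peak of a KDE over nearest-neighbour intervals of the
sorted stoichiometries.  Intervals below the kernel width are sub-resolution
and are excluded from the interval KDE by default (config-exposed; see
docs/methods.md for the reasoning).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._kde import gaussian_kde, kde_mode, silverman_bandwidth
from .config import RunConfig
from .detect import Focus, _disk_offsets
from .errors import CalibrationError, ParameterError
from .io import ImageStack
from .track import Track

__all__ = [
    "CalibrationResult", "PeriodicityResult",
    "chung_kennedy_filter", "detect_steps",
    "single_fluorophore_brightness", "initial_track_intensity",
    "track_stoichiometry", "stoichiometry_kde", "periodicity",
    "extract_trace", "postbleach_knee",
]


@dataclass
class CalibrationResult:
    """Unitary fluorophore brightness estimate."""

    I1: float
    method: str                 # modal_postbleach | step_intervals | external_standard
    support: int                # foci or steps used

    def __post_init__(self) -> None:
        if self.I1 <= 0:
            raise CalibrationError("calibrated I_1 must be positive")


@dataclass
class PeriodicityResult:
    """Modal nearest-neighbour stoichiometry interval and its error."""

    interval: float             # molecules
    error: float
    error_alt: float            # alternative reading of the error formula
    grid: np.ndarray = field(repr=False)
    density: np.ndarray = field(repr=False)
    n_tracks: int = 0
    n_intervals: int = 0
    n_under_peak: int = 0


# ---------------------------------------------------------------------------
# Chung-Kennedy filtering and step detection
# ---------------------------------------------------------------------------

def chung_kennedy_filter(trace: np.ndarray, window: int = 5,
                         exponent: float = 2.0) -> np.ndarray:
    """Edge-preserving smoother for stepwise photobleaching traces.

    Output_t combines the means of the ``window`` samples strictly before and
    strictly after t, weighted by the inverse variance of each window raised
    to ``exponent`` — so the window that straddles a step (high variance) is
    suppressed and edges survive smoothing.  Truncated windows are used at the
    trace ends; if both windows have zero variance the weights fall back to
    equal.
    """
    trace = np.asarray(trace, dtype=float)
    n = trace.size
    if n <= 2 * window:
        raise ParameterError("trace must be longer than twice the window")
    out = np.empty(n)
    for t in range(n):
        back = trace[max(0, t - window):t]
        fwd = trace[t + 1:t + 1 + window]
        if back.size == 0:
            out[t] = fwd.mean()
            continue
        if fwd.size == 0:
            out[t] = back.mean()
            continue
        vb = back.var()
        vf = fwd.var()
        if vb == 0.0 and vf == 0.0:
            wb = wf = 1.0
        else:
            # var^-p with a guard: a zero-variance window dominates entirely
            wb = np.inf if vb == 0.0 else vb ** (-exponent)
            wf = np.inf if vf == 0.0 else vf ** (-exponent)
            if np.isinf(wb) and np.isinf(wf):
                wb = wf = 1.0
            elif np.isinf(wb):
                out[t] = back.mean()
                continue
            elif np.isinf(wf):
                out[t] = fwd.mean()
                continue
        out[t] = (wf * fwd.mean() + wb * back.mean()) / (wf + wb)
    return out


def detect_steps(filtered: np.ndarray, min_step: float,
                 window: int = 5,
                 raw: np.ndarray | None = None) -> list[tuple[int, float]]:
    """Downward intensity steps in a Chung-Kennedy-filtered trace.

    Candidate change points are found where the two-sided window difference of
    the filtered trace drops below ``-min_step / 2``; within each candidate
    run the position is the sample with the largest single-sample drop
    (position = first index of the new plateau).  Plateau levels are medians
    of the raw trace (or the filtered trace if no raw trace is given) between
    change points; only level drops exceeding ``min_step`` are reported.

    Returns ``(position, size)`` pairs with size > 0 for a downward step.
    """
    filtered = np.asarray(filtered, dtype=float)
    n = filtered.size
    if min_step <= 0:
        raise ParameterError("min_step must be positive")
    level_src = np.asarray(raw, dtype=float) if raw is not None else filtered

    # two-sided window difference
    w = max(1, int(window))
    d = np.full(n, np.nan)
    for t in range(w, n - w + 1):
        d[t] = filtered[t:t + w].mean() - filtered[t - w:t].mean()
    cand = np.where(d < -min_step / 2.0)[0]

    # group consecutive candidates into runs; locate each step inside its run
    positions: list[int] = []
    if cand.size:
        run_start = cand[0]
        prev = cand[0]
        runs = []
        for c in cand[1:]:
            if c == prev + 1:
                prev = c
                continue
            runs.append((run_start, prev))
            run_start = prev = c
        runs.append((run_start, prev))
        diffs = np.diff(filtered)   # diffs[t-1] = f[t] - f[t-1]
        for lo, hi in runs:
            seg = diffs[max(lo - 1, 0):hi]      # drops landing at lo..hi
            if seg.size == 0:
                positions.append(int(lo))
                continue
            t = int(np.argmin(seg)) + max(lo - 1, 0) + 1
            positions.append(t)

    # plateau medians between change points; merge sub-threshold changes
    def plateau_steps(pos: list[int]) -> list[tuple[int, float]]:
        bounds = [0] + pos + [n]
        levels = [float(np.median(level_src[a:b]))
                  for a, b in zip(bounds[:-1], bounds[1:])]
        return [(p, levels[i] - levels[i + 1]) for i, p in enumerate(pos)]

    pos = sorted(set(positions))
    while True:
        steps = plateau_steps(pos)
        weak = [p for p, size in steps if abs(size) < min_step]
        if not weak:
            break
        pos = [p for p in pos if p not in weak]
    return [(p, size) for p, size in plateau_steps(pos) if size >= min_step]


# ---------------------------------------------------------------------------
# calibration of the unitary brightness
# ---------------------------------------------------------------------------

def extract_trace(stack: ImageStack, x: float, y: float,
                  radius: int = 8, bg_box: int = 17) -> np.ndarray:
    """Background-corrected integrated intensity at a fixed position over time.

    Uses the same disk/annulus geometry as spot fitting; suited to immobile
    assemblies whose position is known from tracking.
    """
    h, w = stack.shape
    half = bg_box // 2
    cx, cy = int(round(x)), int(round(y))
    cx = min(max(cx, half), w - half - 1)
    cy = min(max(cy, half), h - half - 1)
    win = stack.frames[:, cy - half:cy + half + 1, cx - half:cx + half + 1]
    yy, xx = np.mgrid[-half:half + 1, -half:half + 1]
    disk = xx * xx + yy * yy <= radius * radius
    from .detect import robust_background

    annulus = win[:, ~disk]
    bg = np.array([robust_background(a)[0] for a in annulus])
    return win[:, disk].sum(axis=1) - bg * int(disk.sum())


def postbleach_knee(stack: ImageStack, fraction: float = 0.25) -> int:
    """First frame where total background-corrected intensity falls below
    ``fraction`` of its initial value ("sufficient photobleaching").

    The per-frame background is taken as the median pixel (foci are sparse).
    """
    frames = stack.frames
    med = np.median(frames, axis=(1, 2))
    total = frames.sum(axis=(1, 2)) - med * frames.shape[1] * frames.shape[2]
    t0 = stack.t0_frame
    ref = total[t0]
    if ref <= 0:
        raise CalibrationError("no initial in-mask intensity")
    below = np.where(total[t0:] < fraction * ref)[0]
    if below.size == 0:
        raise CalibrationError("stack never photobleaches below the knee")
    return int(below[0] + t0)


def single_fluorophore_brightness(
    *,
    method: str,
    postbleach_intensities: np.ndarray | None = None,
    traces: list[np.ndarray] | None = None,
    min_step: float | None = None,
    ck_window: int = 5,
    ck_exponent: float = 2.0,
    kernel_width: float | None = None,
    external_value: float | None = None,
) -> CalibrationResult:
    """Estimate the characteristic brightness ``I_1`` of a single fluorophore.

    ``modal_postbleach`` takes the modal peak of a KDE over focus intensities
    collected after the photobleach knee; ``step_intervals`` takes the modal
    size of downward photobleaching steps extracted from intensity traces with
    the Chung-Kennedy filter; ``external_standard`` passes a supplied value
    through.  Fewer than 10 supporting foci/steps raises
    :class:`CalibrationError`.
    """
    if method == "external_standard":
        if external_value is None or external_value <= 0:
            raise CalibrationError("external standard needs a positive value")
        return CalibrationResult(external_value, method, support=0)

    if method == "modal_postbleach":
        vals = np.asarray(postbleach_intensities, dtype=float).ravel() \
            if postbleach_intensities is not None else np.empty(0)
        vals = vals[vals > 0]
        if vals.size < 10:
            raise CalibrationError(
                f"only {vals.size} post-bleach foci; need >= 10")
        bw = kernel_width if kernel_width else silverman_bandwidth(vals)
        grid = np.linspace(0.0, float(vals.max()) * 1.2, 2048)
        mode, _ = kde_mode(vals, bw, grid)
        return CalibrationResult(mode, method, support=int(vals.size))

    if method == "step_intervals":
        if not traces:
            raise CalibrationError("step_intervals needs intensity traces")
        if min_step is None or min_step <= 0:
            raise CalibrationError("step_intervals needs a positive min_step")
        # only steps towards the end of the photobleach are reliably unitary:
        # early in a bright trace, molecules bleach faster than the filter
        # window resolves and drops merge into multi-molecule cascades
        level_cap = 6.0 * min_step
        sizes: list[float] = []
        for tr in traces:
            if tr.size <= 2 * ck_window:
                continue
            filt = chung_kennedy_filter(tr, ck_window, ck_exponent)
            for pos, s in detect_steps(filt, min_step, ck_window, raw=tr):
                pre_level = float(np.median(tr[max(0, pos - 10):pos]))
                if pre_level < level_cap:
                    sizes.append(s)
        if len(sizes) < 10:
            raise CalibrationError(f"only {len(sizes)} bleach steps; need >= 10")
        arr = np.asarray(sizes)
        bw = kernel_width if kernel_width else silverman_bandwidth(arr)
        grid = np.linspace(0.0, float(arr.max()) * 1.2, 2048)
        mode, _ = kde_mode(arr, bw, grid)
        return CalibrationResult(mode, method, support=len(sizes))

    raise ParameterError(f"unknown calibration method {method!r}")


# ---------------------------------------------------------------------------
# per-track stoichiometry
# ---------------------------------------------------------------------------

def initial_track_intensity(track: Track, n_extrap: int = 5,
                            t0_frame: int = 0) -> float | None:
    """OLS line through the first ``n_extrap`` intensities, evaluated at the
    first laser-exposed frame.

    A positive slope cannot arise from photobleaching, so the mean of the
    points is used instead.  Length-1 tracks have no defined I0 (None).
    """
    if track.length < 2:
        return None
    k = min(n_extrap, track.length)
    t = track.frames[:k].astype(float)
    y = track.intensities[:k]
    slope, intercept = np.polyfit(t, y, 1)
    if slope > 0:
        return float(y.mean())
    return float(intercept + slope * t0_frame)


def track_stoichiometry(track: Track, calibration: CalibrationResult,
                        max_start_frame: int = 10,
                        n_extrap: int = 5, t0_frame: int = 0) -> float | None:
    """S = I0 / I_1 for tracks starting within the first ``max_start_frame``
    frames of laser exposure; later tracks (undercounted by photobleaching)
    and tracks without an I0 are excluded (None).
    """
    track.I0 = initial_track_intensity(track, n_extrap, t0_frame)
    if track.I0 is None or track.start_frame - t0_frame >= max_start_frame:
        track.excluded = True
        track.stoichiometry = None
        return None
    track.excluded = False
    track.stoichiometry = track.I0 / calibration.I1
    return track.stoichiometry


# ---------------------------------------------------------------------------
# distribution and periodicity
# ---------------------------------------------------------------------------

def stoichiometry_kde(values: np.ndarray, kernel_width: float = 0.6,
                      grid_pitch: float = 0.05
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian KDE (sd = ``kernel_width`` molecules) of stoichiometries on a
    grid of pitch <= ``grid_pitch`` spanning [0, max(S) + 3]."""
    values = np.asarray(values, dtype=float).ravel()
    if values.size == 0:
        raise ParameterError("no stoichiometry values")
    hi = float(values.max()) + 3.0
    grid = np.arange(0.0, hi + grid_pitch, grid_pitch)
    return grid, gaussian_kde(values, kernel_width, grid)


def _kde_peaks(values: np.ndarray, kernel_width: float,
               grid_pitch: float) -> np.ndarray:
    """Positions of the local maxima of the stoichiometry KDE."""
    hi = float(values.max()) + 3.0 * kernel_width
    grid = np.arange(0.0, hi + grid_pitch, grid_pitch)
    dens = gaussian_kde(values, kernel_width, grid)
    interior = (dens[1:-1] > dens[2:]) & (dens[1:-1] >= dens[:-2])
    return grid[1:-1][interior]


def periodicity(values: np.ndarray, kernel_width: float = 0.6,
                min_interval: float | None = None,
                n_extrap: int = 5, grid_pitch: float = 0.01,
                alt_error: bool = False,
                intervals_from: str = "peaks") -> PeriodicityResult:
    """Modal nearest-neighbour stoichiometry interval (the oligomer period).

    The stoichiometries are sorted and nearest-neighbour intervals taken; a
    Gaussian KDE (sd = ``kernel_width`` molecules) of the intervals is built
    and its modal peak quoted as the periodicity.

    ``intervals_from`` selects what "neighbouring stoichiometries" means:

    * ``"peaks"`` (default) — intervals between the local maxima of the
      stoichiometry KDE.  When every underlying stoichiometry level holds at
      most one track the KDE peaks are the individual values and this reduces
      exactly to the sorted-value form; when levels hold several tracks the
      value form degenerates (within-level spacings shrink the intervals
      below the true period) while peak positions remain unbiased estimates
      of the levels.
    * ``"values"`` — the literal consecutive differences of the sorted
      values, with sub-resolution intervals (below ``min_interval``, default
      one kernel width) excluded.

    The quoted error is ``kernel_width * sqrt(mean(S) / n_extrap) /
    n_under_peak`` where ``n_under_peak`` counts intervals within one kernel
    width of the peak; ``error_alt`` carries the alternative reading with the
    peak count inside the square root.
    """
    values = np.sort(np.asarray(values, dtype=float).ravel())
    if values.size < 3:
        raise ParameterError("periodicity needs at least 3 stoichiometries")
    if min_interval is None:
        min_interval = kernel_width
    if intervals_from == "peaks":
        peaks = _kde_peaks(values, kernel_width, grid_pitch)
        if len(peaks) >= 2:
            kept = np.diff(peaks)
        else:       # single unresolved peak: fall back to the value form
            kept = np.diff(values)
            kept = kept[kept >= min_interval]
    elif intervals_from == "values":
        intervals = np.diff(values)
        kept = intervals[intervals >= min_interval]
    else:
        raise ParameterError(f"unknown intervals_from {intervals_from!r}")
    if kept.size == 0:
        raise ParameterError("no intervals at or above the resolution limit")
    hi = float(kept.max()) + 3.0 * kernel_width
    grid = np.arange(0.0, hi + grid_pitch, grid_pitch)
    dens = gaussian_kde(kept, kernel_width, grid)
    peak = float(grid[int(np.argmax(dens))])
    # harmonic disambiguation: when neighbouring occupancy levels merge, their
    # spacing doubles; substantial interval density at half the modal value
    # marks the half as the fundamental period
    half = peak / 2.0
    if half >= kernel_width:
        d_half = dens[int(np.argmin(np.abs(grid - half)))]
        d_peak = dens[int(np.argmin(np.abs(grid - peak)))]
        if d_half >= 0.6 * d_peak:
            peak = half
    n_under = int(np.sum(np.abs(kept - peak) <= kernel_width))
    n_under = max(n_under, 1)
    base = kernel_width * np.sqrt(values.mean() / n_extrap)
    err = float(base / n_under)
    err_alt = float(kernel_width * np.sqrt(values.mean() / (n_extrap * n_under)))
    return PeriodicityResult(
        interval=peak,
        error=err_alt if alt_error else err,
        error_alt=err_alt,
        grid=grid,
        density=dens,
        n_tracks=int(values.size),
        n_intervals=int(kept.size),
        n_under_peak=n_under,
    )
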