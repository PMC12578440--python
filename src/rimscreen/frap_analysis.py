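"""FRAP recovery-curve processing and exponential fitting.

Pipeline for fluorescence recovery after photobleaching at a cellular
structure: a region is bleached to below 50% of its starting intensity,
then imaged over time together with an unbleached reference cell and an
empty background region in the same field.  Processing order:

1. bleach-depth validation (first post-bleach / mean pre-bleach < 0.5),
2. background subtraction and acquisition-photobleaching correction
   using the reference cell: corrected(t) = (bleached - background) x
   R(0)/R(t), with R(t) the background-subtracted reference and R(0)
   its pre-bleach mean,
3. normalization: mean pre-bleach -> 100%, first post-bleach -> 0%,
4. 3-point rolling average over post-bleach frames (no partial windows),
5. least-squares fit of y = m1 + m2*exp(-m3*x) on post-bleach data with
   time 0 at the first post-bleach frame; half-time t1/2 = ln2/m3.

m3 is the off-rate (1/s).  For a recovering trace m2 is negative and
m1 is the recovery plateau (mobile fraction on the percent scale).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "FrapTrace",
    "FrapFit",
    "FrapError",
    "validate_bleach",
    "correct_trace",
    "normalize",
    "rolling_average",
    "fit_recovery",
    "analyze_trace",
    "read_trace_tsv",
    "write_trace_tsv",
]

M3_BOUNDS = (1e-6, 1e3)  # off-rate search range, 1/s
N_RESTARTS = 5


class FrapError(ValueError):
    pass


@dataclass
class FrapTrace:
    """One FRAP acquisition: bleached ROI, reference ROI (unbleached
    cell) and background ROI (empty space), frame times in seconds.

    The bleach happens between frames ``n_pre`` and ``n_pre + 1``; the
    first post-bleach frame defines time zero for fitting.
    """

    times: np.ndarray
    bleached: np.ndarray
    reference: np.ndarray
    background: np.ndarray
    n_pre: int
    interval: float | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.bleached = np.asarray(self.bleached, dtype=float)
        self.reference = np.asarray(self.reference, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        n = len(self.times)
        if not (len(self.bleached) == len(self.reference) == len(self.background) == n):
            raise FrapError("trace columns must have equal length")
        if self.n_pre < 1:
            raise FrapError("need at least one pre-bleach frame")
        if self.n_pre >= n:
            raise FrapError("no post-bleach frames")
        if np.any(np.diff(self.times) <= 0):
            raise FrapError("times must be strictly increasing")

    @property
    def post_times(self) -> np.ndarray:
        """Post-bleach times relative to the first post-bleach frame."""
        return self.times[self.n_pre:] - self.times[self.n_pre]


@dataclass
class FrapFit:
    m1: float
    m2: float
    m3: float
    t_half: float
    residual_sse: float
    converged: bool

    def to_dict(self) -> dict:
        return {
            "m1": self.m1,
            "m2": self.m2,
            "m3_per_s": self.m3,
            "t_half_s": self.t_half,
            "residual_sse": self.residual_sse,
            "converged": self.converged,
        }


def validate_bleach(trace: FrapTrace) -> tuple[bool, float]:
    """Bleach depth = first post-bleach / mean pre-bleach intensity
    (background-subtracted); the bleach passes when depth < 0.5."""
    pre = trace.bleached[: trace.n_pre] - trace.background[: trace.n_pre]
    pre_mean = float(np.mean(pre))
    if pre_mean <= 0:
        raise FrapError("mean pre-bleach intensity does not exceed background")
    first_post = float(trace.bleached[trace.n_pre] - trace.background[trace.n_pre])
    depth = first_post / pre_mean
    return depth < 0.5, depth


def correct_trace(trace: FrapTrace) -> np.ndarray:
    """Background subtraction plus acquisition-photobleach correction.

    corrected(t) = (bleached(t) - background(t)) * R(0)/R(t), with
    R(t) = reference(t) - background(t) and R(0) the mean of R over the
    pre-bleach frames.  Deterministic; raises if the reference does not
    exceed background at any frame.
    """
    r = trace.reference - trace.background
    bad = np.nonzero(r <= 0)[0]
    if bad.size:
        raise FrapError(
            f"reference signal does not exceed background at frame {bad[0]}"
        )
    r0 = float(np.mean(r[: trace.n_pre]))
    return (trace.bleached - trace.background) * (r0 / r)


def normalize(corrected: np.ndarray, n_pre: int) -> np.ndarray:
    """Rescale so the pre-bleach mean is exactly 100% and the first
    post-bleach frame exactly 0%."""
    corrected = np.asarray(corrected, dtype=float)
    if n_pre < 1 or n_pre >= len(corrected):
        raise FrapError("n_pre out of range")
    pre_mean = float(np.mean(corrected[:n_pre]))
    first_post = float(corrected[n_pre])
    denom = pre_mean - first_post
    if denom == 0:
        raise FrapError("pre-bleach mean equals first post-bleach value")
    return 100.0 * (corrected - first_post) / denom


def rolling_average(
    values: Sequence[float],
    times: Sequence[float] | None = None,
    window: int = 3,
) -> np.ndarray | tuple[np.ndarray, np.ndarray]:
    """Centered moving mean over consecutive post-bleach points.

    Only full windows are produced, so the output is shortened to
    ``len(values) - window + 1`` points; with ``times`` given, each
    smoothed value is timestamped at the window's central frame.
    """
    values = np.asarray(values, dtype=float)
    if window > len(values):
        raise FrapError(f"window {window} exceeds {len(values)} post-bleach frames")
    if window < 1:
        raise FrapError("window must be >= 1")
    smoothed = np.convolve(values, np.ones(window) / window, mode="valid")
    if times is None:
        return smoothed
    times = np.asarray(times, dtype=float)
    half = (window - 1) // 2
    return smoothed, times[half: half + len(smoothed)]


def _exp_model(params: np.ndarray, t: np.ndarray) -> np.ndarray:
    m1, m2, m3 = params
    return m1 + m2 * np.exp(-m3 * t)


def fit_recovery(times: Sequence[float], values: Sequence[float]) -> FrapFit:
    """Least-squares fit of y = m1 + m2*exp(-m3*x) with m3 > 0.

    Initialization: m1 = last value, m2 = first - last, m3 = 3/span.
    On non-convergence the fit restarts from five log-spaced m3 values;
    deterministic throughout.  t1/2 = ln2/m3.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if len(t) != len(y):
        raise FrapError("times and values differ in length")
    if len(t) < 4:
        raise FrapError("need at least 4 post-bleach points to fit")
    span = t[-1] - t[0]
    if span <= 0:
        raise FrapError("degenerate time axis")

    lo = [-np.inf, -np.inf, M3_BOUNDS[0]]
    hi = [np.inf, np.inf, M3_BOUNDS[1]]

    def solve(m3_init: float):
        x0 = np.array([y[-1], y[0] - y[-1], m3_init])
        return least_squares(
            lambda p: _exp_model(p, t) - y, x0, bounds=(lo, hi), method="trf"
        )

    inits = [3.0 / span] + list(
        np.logspace(math.log10(1e-4), math.log10(1e2), N_RESTARTS)
    )
    best = None
    for m3_init in inits:
        res = solve(m3_init)
        if best is None or res.cost < best.cost:
            best = res
        if res.success and res.cost < 1e-12 * max(1.0, float(np.sum(y**2))):
            best = res
            break
    if best is None or not best.success:
        raise FrapError(f"exponential fit did not converge: {getattr(best, 'message', '')}")
    m1, m2, m3 = (float(v) for v in best.x)
    return FrapFit(
        m1=m1,
        m2=m2,
        m3=m3,
        t_half=math.log(2) / m3,
        residual_sse=float(2 * best.cost),
        converged=bool(best.success),
    )


def analyze_trace(trace: FrapTrace, window: int = 3) -> tuple[FrapFit, dict]:
    """Full pipeline: validate bleach, correct, normalize, smooth the
    post-bleach frames, fit.  Returns the fit plus a processing record
    (bleach depth, smoothed curve, parameters used)."""
    passed, depth = validate_bleach(trace)
    corrected = correct_trace(trace)
    norm = normalize(corrected, trace.n_pre)
    post = norm[trace.n_pre:]
    smoothed, sm_times = rolling_average(post, trace.post_times, window=window)
    fit = fit_recovery(sm_times, smoothed)
    record = {
        "bleach_passed": passed,
        "bleach_depth": depth,
        "window": window,
        "n_pre": trace.n_pre,
        "n_post": len(post),
        "smoothed_times_s": sm_times.tolist(),
        "smoothed_values_pct": smoothed.tolist(),
    }
    return fit, record


# ---------------------------------------------------------------------------
# TSV I/O: columns time_s, bleached, reference, background with a
# '# n_pre=<int>' header line.
# ---------------------------------------------------------------------------


def read_trace_tsv(path: str | Path) -> FrapTrace:
    path = Path(path)
    n_pre = None
    rows = []
    header_seen = False
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            if "n_pre=" in line:
                n_pre = int(line.split("n_pre=")[1].split()[0])
            continue
        if not header_seen and line.lower().startswith("time"):
            header_seen = True
            continue
        rows.append([float(x) for x in line.split("\t")])
    if n_pre is None:
        raise FrapError(f"{path}: missing '# n_pre=<int>' header")
    data = np.asarray(rows, dtype=float)
    if data.ndim != 2 or data.shape[1] != 4:
        raise FrapError(f"{path}: expected 4 columns time_s, bleached, reference, background")
    return FrapTrace(
        times=data[:, 0], bleached=data[:, 1],
        reference=data[:, 2], background=data[:, 3], n_pre=n_pre,
    )


def write_trace_tsv(trace: FrapTrace, path: str | Path) -> None:
    path = Path(path)
    lines = [f"# n_pre={trace.n_pre}", "time_s\tbleached\treference\tbackground"]
    for t, b, r, g in zip(trace.times, trace.bleached, trace.reference, trace.background):
        lines.append(f"{t:.6g}\t{b:.10g}\t{r:.10g}\t{g:.10g}")
    path.write_text("\n".join(lines) + "\n")
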