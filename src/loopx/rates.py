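"""Loop-extrusion rates and per-experiment looping statistics.

The loop growth curve (loop kbp vs time) is smoothed with a second-order
Savitzky-Golay filter (50-point window) only to locate a monotone 5-s
fitting window after loop initiation; the extrusion rate k (kbp/s) comes
from an ordinary least-squares line f(t) = k*t + c on the *raw* curve
within that window.  Experiments are summarised as the fraction of
tethers with at least one loop and compared with the Wilcoxon rank-sum
test; rates are compared with Welch's t-test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.signal import savgol_filter

from .stats import rank_sum_test, welch_t_test
from .tracking import DnaPartitionSeries

__all__ = [
    "LoopGrowthCurve",
    "RateEstimate",
    "LoopingSummary",
    "WindowNotFoundError",
    "choose_fit_window",
    "fit_rate",
    "fraction_looped",
    "compare_fractions",
    "compare_rates",
]

SAVGOL_ORDER = 2
SAVGOL_WINDOW = 50


class WindowNotFoundError(RuntimeError):
    """No monotone fitting window exists; the event is excluded."""


@dataclass
class LoopGrowthCurve:
    """Loop size (kbp) against time (s) for one extrusion event."""

    time: np.ndarray
    loop_kbp: np.ndarray
    savgol_order: int = SAVGOL_ORDER
    savgol_window: int = SAVGOL_WINDOW

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.loop_kbp = np.asarray(self.loop_kbp, dtype=float)
        if self.time.shape != self.loop_kbp.shape:
            raise ValueError("time and loop_kbp must align")
        if self.time.size >= 2 and not np.all(np.diff(self.time) > 0):
            raise ValueError("time must be strictly increasing")

    @classmethod
    def from_partition(cls, series: DnaPartitionSeries, **kw) -> "LoopGrowthCurve":
        """Build from a DNA partition, dropping edge/invalid frames."""
        m = series.valid
        return cls(time=series.time[m], loop_kbp=series.loop_kbp[m], **kw)

    @property
    def smoothed(self) -> np.ndarray:
        """Savitzky-Golay smoothed curve (window shrunk to fit if needed)."""
        n = self.loop_kbp.size
        window = self.savgol_window
        if window > n:
            window = n if n % 2 == 1 else n - 1
            warnings.warn(
                f"Savitzky-Golay window shrunk to {window} points "
                f"(series has {n})",
                stacklevel=2,
            )
        if window % 2 == 0:
            window -= 1
        if window <= self.savgol_order:
            return self.loop_kbp.copy()
        return savgol_filter(self.loop_kbp, window, self.savgol_order)


@dataclass
class RateEstimate:
    """Linear-fit loop-extrusion rate over a 5-s window."""

    k: float  # kbp/s
    c: float  # kbp intercept
    window: tuple[float, float]
    r_squared: float
    n_points: int


def choose_fit_window(
    curve: LoopGrowthCurve,
    window_s: float = 5.0,
    monotone_tol: float = 0.5,
    init_threshold: float = 1.0,
    sustain: int = 3,
    min_growth: float = 1.0,
    on_slipback: str = "reselect",
) -> tuple[float, float]:
    """Earliest monotone ``window_s`` window after loop initiation.

    Initiation is the first point where the smoothed loop exceeds
    ``init_threshold`` kbp for ``sustain`` consecutive points.  Candidate
    windows ``[t0, t0 + window_s]`` are scanned from there; a window
    qualifies when the smoothed curve never drops by more than
    ``monotone_tol`` kbp between consecutive points inside it *and* shows
    at least ``min_growth`` kbp of net growth (the loop must actually be
    increasing, not merely holding its size).

    ``on_slipback="exclude"`` raises as soon as the *first* candidate
    window fails (the event slips back within the initial window);
    ``"reselect"`` keeps scanning later start points.
    """
    if on_slipback not in ("reselect", "exclude"):
        raise ValueError("on_slipback must be 'reselect' or 'exclude'")
    t = curve.time
    sm = curve.smoothed
    if t.size < 3:
        raise WindowNotFoundError("curve too short")

    above = sm > init_threshold
    init_idx = None
    run = 0
    for i, a in enumerate(above):
        run = run + 1 if a else 0
        if run >= min(sustain, t.size):
            init_idx = i - run + 1
            break
    if init_idx is None:
        raise WindowNotFoundError(
            f"no sustained loop above {init_threshold} kbp; event excluded"
        )

    first = True
    for start in range(init_idx, t.size):
        t0 = t[start]
        mask = (t >= t0) & (t <= t0 + window_s + 1e-9)
        if mask.sum() < 3:
            break
        seg = sm[mask]
        if np.all(np.diff(seg) >= -monotone_tol) and seg[-1] - seg[0] >= min_growth:
            return (float(t0), float(t0 + window_s))
        if first and on_slipback == "exclude":
            raise WindowNotFoundError(
                "loop slips back within the initial window; event excluded"
            )
        first = False
    raise WindowNotFoundError("no monotone fitting window found; event excluded")


def fit_rate(curve: LoopGrowthCurve, window: tuple[float, float]) -> RateEstimate:
    """OLS line on the *raw* loop sizes within ``window``.

    Smoothing never enters the fit; it only selected the window.
    """
    t0, t1 = window
    mask = (curve.time >= t0 - 1e-9) & (curve.time <= t1 + 1e-9)
    if mask.sum() < 3:
        raise ValueError(f"fewer than 3 raw points in window {window}")
    res = stats.linregress(curve.time[mask], curve.loop_kbp[mask])
    return RateEstimate(
        k=float(res.slope),
        c=float(res.intercept),
        window=(float(t0), float(t1)),
        r_squared=float(res.rvalue**2),
        n_points=int(mask.sum()),
    )


@dataclass
class LoopingSummary:
    """Looping activity of one experiment (one field of tethers)."""

    n_tethers: int
    n_looped: int
    experiment_id: str | None = None
    acquisition_span: float = 1000.0  # s, includes the initial 100 s of flow

    def __post_init__(self):
        if not (0 <= self.n_looped <= self.n_tethers):
            raise ValueError("0 <= n_looped <= n_tethers required")

    @property
    def fraction_looped(self) -> float:
        return self.n_looped / self.n_tethers

    def to_dict(self) -> dict:
        return {
            "experiment_id": self.experiment_id,
            "n_tethers": self.n_tethers,
            "n_looped": self.n_looped,
            "fraction_looped": self.fraction_looped,
            "acquisition_span_s": self.acquisition_span,
        }


def fraction_looped(
    tether_results,
    experiment_id: str | None = None,
    acquisition_span: float = 1000.0,
) -> LoopingSummary:
    """Fraction of doubly-tethered DNAs with at least one loop event.

    ``tether_results`` is a per-tether boolean list (loop detected or
    not); the order of tethers is irrelevant.
    """
    flags = [bool(b) for b in tether_results]
    if not flags:
        raise ValueError("tether_results must be non-empty")
    return LoopingSummary(
        n_tethers=len(flags),
        n_looped=sum(flags),
        experiment_id=experiment_id,
        acquisition_span=acquisition_span,
    )


def _two_or_pairwise(groups, test):
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for g in groups:
        if g.size == 0:
            raise ValueError("groups must be non-empty")
    if len(groups) == 2:
        return test(groups[0], groups[1])
    return {
        (i, j): test(groups[i], groups[j])
        for i in range(len(groups))
        for j in range(i + 1, len(groups))
    }


def compare_fractions(groups):
    """Wilcoxon rank-sum comparison of per-experiment looped fractions.

    Two groups: returns ``(W, p)``.  More: dict of pairwise results
    keyed by group-index pairs.
    """
    return _two_or_pairwise(groups, rank_sum_test)


def compare_rates(groups):
    """Welch's t-test comparison of loop-extrusion rate groups."""
    return _two_or_pairwise(groups, welch_t_test)
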