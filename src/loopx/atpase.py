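"""ATPase rates from phosphate-sensor time courses and DNA fold-stimulation.

The EnzChek-style readout reports free phosphate (uM, after calibration)
accumulating linearly while the enzyme turns over in steady state.  The
rate is the OLS slope over a linear window, normalised by the enzyme
concentration to ATP per condensin per minute; DNA stimulation is
expressed as the fold change over the rate without DNA.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .stats import welch_t_test

__all__ = [
    "PhosphateTrace",
    "AtpaseRate",
    "FoldStimulationCurve",
    "estimate_rate",
    "fold_stimulation",
    "compare_conditions",
]


@dataclass
class PhosphateTrace:
    """One phosphate-release time course.

    ``time`` in seconds (strictly increasing), ``signal`` in uM phosphate
    (apply a calibration factor upstream for raw absorbance),
    ``enzyme_conc`` and ``dna_conc`` in nM.
    """

    time: np.ndarray
    signal: np.ndarray
    enzyme_conc: float
    dna_conc: float = 0.0
    condition: str | None = None

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.time.shape != self.signal.shape:
            raise ValueError("time and signal must have the same length")
        if self.time.size >= 2 and not np.all(np.diff(self.time) > 0):
            raise ValueError("time must be strictly increasing")
        if self.enzyme_conc <= 0:
            raise ValueError("enzyme_conc must be > 0")


@dataclass
class AtpaseRate:
    """Estimated ATPase rate for one trace.

    ``slope`` is in uM phosphate per minute; ``rate`` is the same slope
    normalised by enzyme concentration, in ATP*condensin^-1*min^-1.
    """

    slope: float
    slope_se: float
    rate: float
    rate_se: float
    r_squared: float
    window: tuple[float, float]
    n_points: int
    linearity_ok: bool


def _ols(t_min: np.ndarray, y: np.ndarray):
    """Slope/intercept/r^2/slope-SE; constant y counts as a perfect fit."""
    n = t_min.size
    slope, intercept = np.polyfit(t_min, y, 1)
    pred = slope * t_min + intercept
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    if n > 2:
        sxx = float(np.sum((t_min - t_min.mean()) ** 2))
        se = np.sqrt(ss_res / (n - 2) / sxx) if sxx > 0 else np.nan
    else:
        se = np.nan
    return float(slope), r2, float(se)


def estimate_rate(
    trace: PhosphateTrace,
    window: tuple[float, float] | None = None,
    r2_min: float = 0.99,
    min_points: int = 5,
) -> AtpaseRate:
    """OLS slope over the steady-state window, enzyme-normalised.

    With no explicit ``window`` (seconds), the longest suffix window
    whose fit reaches ``r2_min`` is used: candidate start points are
    scanned from the beginning of the trace, so an initial lag phase is
    skipped automatically.  If no window qualifies the full trace is
    fitted and the result flagged ``linearity_ok=False``.
    """
    t, y = trace.time, trace.signal
    if window is not None:
        mask = (t >= window[0]) & (t <= window[1])
        if mask.sum() < min_points:
            raise ValueError(f"fewer than {min_points} points in window {window}")
        tw, yw = t[mask], y[mask]
        slope, r2, se = _ols(tw / 60.0, yw)
        ok = r2 >= r2_min
    else:
        if t.size < min_points:
            raise ValueError(f"trace has fewer than {min_points} points")
        chosen = None
        for start in range(t.size - min_points + 1):
            slope, r2, se = _ols(t[start:] / 60.0, y[start:])
            if r2 >= r2_min:
                # keep shedding lag points while the fit still improves
                while start < t.size - min_points:
                    s2, r2b, se2 = _ols(t[start + 1 :] / 60.0, y[start + 1 :])
                    if r2b <= r2 + 1e-12:
                        break
                    start, slope, r2, se = start + 1, s2, r2b, se2
                chosen = (start, slope, r2, se)
                break
        if chosen is None:
            slope, r2, se = _ols(t / 60.0, y)
            tw, yw, ok = t, y, False
        else:
            start, slope, r2, se = chosen
            tw, yw, ok = t[start:], y[start:], True
    rate = slope * 1000.0 / trace.enzyme_conc  # uM/min -> nM/min, / nM enzyme
    rate_se = se * 1000.0 / trace.enzyme_conc if np.isfinite(se) else np.nan
    return AtpaseRate(
        slope=slope,
        slope_se=se,
        rate=rate,
        rate_se=rate_se,
        r_squared=r2,
        window=(float(tw[0]), float(tw[-1])),
        n_points=int(tw.size),
        linearity_ok=bool(ok),
    )


@dataclass
class FoldStimulationCurve:
    """Fold change of the ATPase rate over the DNA-free baseline."""

    dna_concs: np.ndarray
    fold: np.ndarray
    fold_se: np.ndarray

    def as_dict(self) -> dict:
        return {float(c): float(f) for c, f in zip(self.dna_concs, self.fold)}


def fold_stimulation(rates_by_dna: dict) -> FoldStimulationCurve:
    """Divide the rate at each DNA concentration by the DNA-free rate.

    ``rates_by_dna`` maps DNA concentration (nM) to an
    :class:`AtpaseRate`.  The baseline (key 0) must be present with a
    positive rate; its fold is exactly 1.  Relative uncertainties of
    numerator and baseline propagate in quadrature.
    """
    keys = sorted(rates_by_dna)
    if 0 not in rates_by_dna and 0.0 not in rates_by_dna:
        raise ValueError("baseline rate at dna_conc=0 is required")
    base = rates_by_dna[0 if 0 in rates_by_dna else 0.0]
    if not (base.rate > 0):
        raise ValueError("baseline rate must be > 0")
    rel0 = (base.rate_se / base.rate) if np.isfinite(base.rate_se) else 0.0
    folds, ses = [], []
    for k in keys:
        r = rates_by_dna[k]
        if k == 0:
            folds.append(1.0)
            ses.append(0.0)
            continue
        f = r.rate / base.rate
        rel = (r.rate_se / r.rate) if (np.isfinite(r.rate_se) and r.rate != 0) else 0.0
        folds.append(f)
        ses.append(abs(f) * np.hypot(rel, rel0))
    return FoldStimulationCurve(
        dna_concs=np.asarray(keys, dtype=float),
        fold=np.asarray(folds),
        fold_se=np.asarray(ses),
    )


def compare_conditions(group_a, group_b):
    """Welch's unpaired two-tailed t-test between two groups of rates."""
    return welch_t_test(group_a, group_b)
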