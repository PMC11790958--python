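"""Equilibrium fluorescence-polarisation binding and competition analysis.

The binding model is the exact (ligand-depletion) solution of the 1:1
mass-action equilibrium, required because the fluorescent peptide probe
concentration (typically 0.1 uM) is not negligible against the measured
dissociation constants (2.8-17.7 uM):

    FP = (FPmax / 2[Pep]) * (([C]+[Pep]+Kd) - sqrt(([C]+[Pep]+Kd)^2 - 4[C][Pep]))

where [C] is the receptor (condensin/HAWK) concentration and [Pep] the
probe concentration, both in uM, and FP is the polarisation change in mP.
The bracketed term is exactly the bound-probe concentration, so FP/FPmax
is the bound fraction of the probe.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats
from scipy.optimize import curve_fit

__all__ = [
    "fp_model",
    "TitrationData",
    "BindingFit",
    "fit_kd",
    "CompetitionResult",
    "analyze_competition",
]


def fp_model(c, pep: float, kd: float, fp_max: float):
    """Exact ligand-depletion FP value in mP.

    Parameters
    ----------
    c :
        Receptor concentration(s), uM (scalar or array, >= 0).
    pep :
        Probe concentration, uM (> 0).
    kd :
        Dissociation constant, uM (> 0).
    fp_max :
        Maximal FP change, mP.

    The discriminant is clamped at zero against floating-point round-off
    (it is non-negative analytically for kd > 0).
    """
    if pep <= 0:
        raise ValueError("probe concentration must be > 0 (division by [Pep])")
    if kd <= 0:
        raise ValueError("kd must be > 0")
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise ValueError("receptor concentrations must be >= 0")
    s = c + pep + kd
    disc = np.maximum(s * s - 4.0 * c * pep, 0.0)
    out = (fp_max / (2.0 * pep)) * (s - np.sqrt(disc))
    return out if out.ndim else float(out)


@dataclass
class TitrationData:
    """FP titration: one probe, replicate mP readings per receptor conc."""

    probe_conc: float
    receptor_concs: np.ndarray
    readings: np.ndarray  # (n_concs, n_replicates)

    def __post_init__(self):
        self.receptor_concs = np.asarray(self.receptor_concs, dtype=float)
        self.readings = np.atleast_2d(np.asarray(self.readings, dtype=float))
        if self.probe_conc <= 0:
            raise ValueError("probe_conc must be > 0")
        if self.readings.shape[0] != self.receptor_concs.size:
            raise ValueError("one row of readings per receptor concentration")

    @property
    def means(self) -> np.ndarray:
        return self.readings.mean(axis=1)

    @property
    def sds(self) -> np.ndarray:
        if self.readings.shape[1] < 2:
            return np.zeros(self.receptor_concs.size)
        return self.readings.std(axis=1, ddof=1)

    @property
    def n_replicates(self) -> int:
        return self.readings.shape[1]


@dataclass
class BindingFit:
    """Fitted (Kd, FPmax) of the exact binding model with asymptotic SEs."""

    kd: float
    fp_max: float
    kd_se: float
    fp_max_se: float
    residuals: np.ndarray
    converged: bool
    message: str = ""

    def __repr__(self):  # pragma: no cover - cosmetic
        return (
            f"BindingFit(kd={self.kd:.3g} +/- {self.kd_se:.2g} uM, "
            f"fp_max={self.fp_max:.3g} +/- {self.fp_max_se:.2g} mP, "
            f"converged={self.converged})"
        )


KD_BOUNDS = (1e-4, 1e4)


def fit_kd(data: TitrationData, weighted: bool = True, use_means: bool = True) -> BindingFit:
    """Least-squares fit of (Kd, FPmax) to a titration.

    By default the fit runs on per-concentration replicate means with
    inverse-variance weights (standard error of the mean); pass
    ``weighted=False`` for an unweighted fit or ``use_means=False`` to fit
    every raw reading.  Initialisation: Kd at the mid-titration (geometric
    mean) concentration, FPmax at the maximum observed mean; Kd bounded to
    (1e-4, 1e4) uM.  Non-convergence is flagged, never silent.
    """
    concs = data.receptor_concs
    if np.unique(concs).size < 4:
        raise ValueError("need at least 4 distinct receptor concentrations")
    if not np.all(np.isfinite(data.readings)):
        raise ValueError("readings must be finite")

    if use_means:
        x, y = concs, data.means
        sem = data.sds / np.sqrt(data.n_replicates)
        sigma = sem if (weighted and np.all(sem > 0)) else None
    else:
        x = np.repeat(concs, data.n_replicates)
        y = data.readings.ravel()
        sigma = None

    pos = concs[concs > 0]
    kd0 = float(np.exp(np.mean(np.log(pos)))) if pos.size else 1.0
    kd0 = float(np.clip(kd0, *KD_BOUNDS))
    fp0 = max(float(y.max()), 1e-6)

    def model(c, kd, fp_max):
        return fp_model(c, data.probe_conc, kd, fp_max)

    try:
        popt, pcov = curve_fit(
            model,
            x,
            y,
            p0=[kd0, fp0],
            sigma=sigma,
            bounds=([KD_BOUNDS[0], 1e-9], [KD_BOUNDS[1], 1e7]),
            maxfev=10000,
        )
    except RuntimeError as exc:  # no convergence
        return BindingFit(
            kd=np.nan,
            fp_max=np.nan,
            kd_se=np.nan,
            fp_max_se=np.nan,
            residuals=np.full_like(np.asarray(y, float), np.nan),
            converged=False,
            message=str(exc),
        )
    perr = np.sqrt(np.diag(pcov))
    resid = y - model(x, *popt)
    return BindingFit(
        kd=float(popt[0]),
        fp_max=float(popt[1]),
        kd_se=float(perr[0]),
        fp_max_se=float(perr[1]),
        residuals=resid,
        converged=True,
    )


@dataclass
class CompetitionResult:
    """Background-subtracted condition summaries and pairwise t-tests."""

    labels: list
    means: np.ndarray
    sds: np.ndarray
    ns: np.ndarray
    p_values: dict  # (label_i, label_j) -> two-tailed p

    def summary(self, label) -> tuple[float, float, int]:
        i = self.labels.index(label)
        return float(self.means[i]), float(self.sds[i]), int(self.ns[i])


def analyze_competition(conditions: dict, backgrounds: dict) -> CompetitionResult:
    """Background-subtract competition FP readings and compare conditions.

    Parameters
    ----------
    conditions :
        Mapping label -> replicate mP readings (e.g. probe+receptor,
        probe+receptor+competitor).
    backgrounds :
        Mapping label -> matched background readings (probe with the
        corresponding peptide buffer), subtracted replicate-wise.

    Pairwise p-values use the unpaired two-tailed Student's t-test
    (conditions here share the replicate structure of a single plate).
    """
    labels = list(conditions)
    subtracted = {}
    for lab in labels:
        if lab not in backgrounds:
            raise ValueError(f"no background readings for condition {lab!r}")
        r = np.asarray(conditions[lab], dtype=float)
        b = np.asarray(backgrounds[lab], dtype=float)
        if r.shape != b.shape:
            raise ValueError(
                f"replicate structure mismatch for condition {lab!r}: "
                f"{r.shape} readings vs {b.shape} backgrounds"
            )
        if r.size < 2:
            raise ValueError("need n >= 2 replicates per condition")
        subtracted[lab] = r - b

    means = np.array([subtracted[lab].mean() for lab in labels])
    sds = np.array([subtracted[lab].std(ddof=1) for lab in labels])
    ns = np.array([subtracted[lab].size for lab in labels])
    p_values = {}
    for a, b in combinations(labels, 2):
        t, p = stats.ttest_ind(subtracted[a], subtracted[b], equal_var=True)
        p_values[(a, b)] = float(p)
    return CompetitionResult(labels=labels, means=means, sds=sds, ns=ns, p_values=p_values)
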