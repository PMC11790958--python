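"""Ground-truthed synthetic data for every stage of the analysis.

Three generators live here:

* :func:`simulate_tether_movie` — fluorescence image series of a single
  surface-tethered, doubly-anchored 48.5-kbp lambda-DNA molecule with
  programmable loop-extrusion events, returned together with the exact
  per-frame DNA partition (ground truth).
* :func:`simulate_fp_plate` — fluorescence-polarisation titration plates
  drawn from the exact ligand-depletion binding model with Gaussian
  replicate noise.
* :func:`simulate_atpase_trace` — phosphate-sensor time courses with a
  linear accumulation signal.

All randomness in a call flows from a single integer seed through one
``numpy.random.Generator`` instance, so identical configurations are
bit-reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .fp import TitrationData, fp_model
from .atpase import PhosphateTrace

__all__ = [
    "LoopEvent",
    "TetherSimConfig",
    "GroundTruth",
    "simulate_tether_movie",
    "simulate_experiment",
    "simulate_fp_plate",
    "simulate_atpase_trace",
]

#: total length of the lambda-phage substrate in kbp
LAMBDA_KBP = 48.5


# --------------------------------------------------------------------------
# tether movies
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class LoopEvent:
    """A single loop-extrusion event on one tether.

    Parameters
    ----------
    t_start :
        Time (s) at which extrusion starts.
    rate :
        Extrusion rate in kbp/s (>= 0).
    anchor_pos :
        Fractional position of the loop anchor along the tether, 0 = top
        attachment point, 1 = bottom.
    max_loop :
        Plateau loop size in kbp; extrusion stops there.
    slippage :
        Optional shrinkage rate (kbp/s) applied after the plateau is
        reached; ``None`` means the loop holds its plateau size.
    """

    t_start: float
    rate: float
    anchor_pos: float = 0.5
    max_loop: float = 30.0
    slippage: float | None = None

    def loop_kbp_at(self, t: float) -> float:
        """Ground-truth loop size (kbp) at time ``t`` seconds."""
        if t < self.t_start or self.rate < 0:
            return 0.0
        grown = self.rate * (t - self.t_start)
        if grown <= self.max_loop:
            return grown
        if self.slippage is None:
            return self.max_loop
        t_plateau = self.t_start + (self.max_loop / self.rate if self.rate > 0 else 0.0)
        return max(0.0, self.max_loop - self.slippage * (t - t_plateau))

    def end_time(self, horizon: float) -> float:
        """Time at which the loop is gone again (``horizon`` if never)."""
        if self.slippage is None or self.slippage <= 0 or self.rate <= 0:
            return horizon
        t_plateau = self.t_start + self.max_loop / self.rate
        return min(horizon, t_plateau + self.max_loop / self.slippage)


@dataclass(frozen=True)
class TetherSimConfig:
    """Configuration of a synthetic single-tether movie.

    The tether is rendered as a vertical fluorescent line between its two
    anchor points.  A loop event condenses ``loop_kbp`` of DNA into a
    compact bright blob of ``loop_extent_px`` rows at the anchor
    position; the remaining (slack) DNA always spans the full distance
    from each attachment point to the blob, so its linear density drops
    as the loop grows while the blob's intensity share equals its DNA
    share.  The ideal image is blurred with a Gaussian PSF, scaled to
    photons and degraded with noise.

    Frames represent offset- and background-corrected photon counts;
    ``background_mean`` adds a uniform stray-light pedestal when nonzero.
    """

    n_frames: int = 100
    frame_interval: float = 1.0
    tether_length_px: int = 100
    axis_col: int = 16
    frame_shape: tuple[int, int] = (120, 33)
    total_dna: float = LAMBDA_KBP
    loop_events: tuple[LoopEvent, ...] = ()
    psf_sigma: float = 0.8
    loop_extent_px: int = 7
    background_mean: float = 0.0
    noise_model: str = "poisson"  # "poisson" | "gaussian"
    gaussian_sd: float = 0.0
    read_noise_sd: float = 2.0
    photons_per_kbp: float = 300.0
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "loop_events", tuple(self.loop_events))
        self.validate()

    @property
    def duration(self) -> float:
        return self.n_frames * self.frame_interval

    @property
    def tether_top_row(self) -> int:
        return (self.frame_shape[0] - self.tether_length_px) // 2

    def validate(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")
        if self.total_dna <= 0:
            raise ValueError("total_dna must be > 0")
        nrow, ncol = self.frame_shape
        if self.tether_length_px > nrow:
            raise ValueError("tether does not fit inside frame_shape")
        if not (0 <= self.axis_col < ncol):
            raise ValueError("axis_col outside frame")
        if self.background_mean < 0:
            raise ValueError("background_mean must be >= 0")
        if self.noise_model not in ("poisson", "gaussian"):
            raise ValueError(f"unknown noise_model {self.noise_model!r}")
        if self.gaussian_sd < 0 or self.read_noise_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if self.photons_per_kbp <= 0:
            raise ValueError("photons_per_kbp must be > 0")
        intervals = []
        anchor_margin = self.loop_extent_px / (2.0 * self.tether_length_px)
        for ev in self.loop_events:
            if ev.rate < 0:
                raise ValueError("event rate must be >= 0")
            if not (0.0 <= ev.anchor_pos <= 1.0):
                raise ValueError("anchor_pos must lie in [0, 1]")
            if not (anchor_margin <= ev.anchor_pos <= 1.0 - anchor_margin):
                raise ValueError(
                    "anchor_pos places the loop blob off the tether "
                    f"(needs {anchor_margin:.3f} <= anchor_pos <= "
                    f"{1 - anchor_margin:.3f} for loop_extent_px="
                    f"{self.loop_extent_px})"
                )
            if not (0.0 <= ev.t_start < self.duration):
                raise ValueError("t_start must fall within the acquisition")
            if ev.max_loop > self.total_dna:
                raise ValueError("loop DNA exceeds the substrate total")
            intervals.append((ev.t_start, ev.end_time(self.duration)))
        intervals.sort()
        for (s0, e0), (s1, _e1) in zip(intervals, intervals[1:]):
            if s1 < e0:
                raise ValueError(
                    "loop events overlap in time; the single-loop model "
                    "allows at most one concurrent loop per tether"
                )

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["loop_events"] = [dataclasses.asdict(ev) for ev in self.loop_events]
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "TetherSimConfig":
        d = json.loads(text)
        d["loop_events"] = tuple(LoopEvent(**ev) for ev in d.get("loop_events", []))
        d["frame_shape"] = tuple(d["frame_shape"])
        return cls(**d)


@dataclass
class GroundTruth:
    """Exact per-frame DNA partition behind a synthetic movie.

    ``up_kbp + loop_kbp + down_kbp == total_dna`` holds exactly at every
    frame; ``loop_center_row`` is NaN on frames without a loop.
    """

    time: np.ndarray
    up_kbp: np.ndarray
    loop_kbp: np.ndarray
    down_kbp: np.ndarray
    loop_center_row: np.ndarray
    total_dna: float
    has_loop: bool

    def to_json(self) -> str:
        return json.dumps(
            {
                "total_dna": self.total_dna,
                "has_loop": self.has_loop,
                "time": self.time.tolist(),
                "up_kbp": self.up_kbp.tolist(),
                "loop_kbp": self.loop_kbp.tolist(),
                "down_kbp": self.down_kbp.tolist(),
                "loop_center_row": [
                    None if math.isnan(v) else v for v in self.loop_center_row
                ],
            },
            indent=2,
        )


def _segment_mass(n_rows: int, a: float, b: float, mass: float) -> np.ndarray:
    """kbp per pixel row for ``mass`` kbp spread uniformly over rows [a, b)."""
    if b <= a or mass <= 0:
        return np.zeros(n_rows)
    rows = np.arange(n_rows)
    overlap = np.clip(np.minimum(b, rows + 1.0) - np.maximum(a, rows), 0.0, 1.0)
    return (mass / (b - a)) * overlap


def ideal_frame_components(
    config: TetherSimConfig, frame: int
) -> tuple[np.ndarray, np.ndarray]:
    """Noise-free (line, punctum) images in photon counts for one frame.

    The two components sum to the pre-noise expected frame minus the
    background pedestal; the punctum carries exactly
    ``loop_kbp/total_dna`` of the total rendered intensity.
    """
    t = frame * config.frame_interval
    event = None
    loop = 0.0
    for ev in config.loop_events:
        lk = ev.loop_kbp_at(t)
        if lk > 0:
            event, loop = ev, lk
            break

    n_rows, n_cols = config.frame_shape
    r0 = config.tether_top_row
    r1 = r0 + config.tether_length_px

    punctum = np.zeros(n_rows)
    if event is None or loop <= 0:
        line = _segment_mass(n_rows, r0, r1, config.total_dna)
    else:
        anchor = event.anchor_pos
        up = anchor * (config.total_dna - loop)
        down = config.total_dna - loop - up
        r_loop = r0 + anchor * config.tether_length_px
        half = config.loop_extent_px / 2.0
        # slack DNA always spans anchor-to-blob; only its density changes
        line = _segment_mass(n_rows, r0, r_loop - half, up)
        line += _segment_mass(n_rows, r_loop + half, r1, down)
        punctum = _segment_mass(n_rows, r_loop - half, r_loop + half, loop)

    def render(profile: np.ndarray) -> np.ndarray:
        img = np.zeros((n_rows, n_cols))
        img[:, config.axis_col] = profile
        img = gaussian_filter1d(img, config.psf_sigma, axis=0, mode="constant")
        img = gaussian_filter1d(img, config.psf_sigma, axis=1, mode="constant")
        return img * config.photons_per_kbp

    return render(line), render(punctum)


def simulate_tether_movie(config: TetherSimConfig):
    """Render a tether movie and its exact ground truth.

    Returns
    -------
    (ImageSeries, GroundTruth)
        Frames are float photon counts (noise applied last); the ground
        truth holds the analytic DNA partition, conserved exactly.
    """
    from .kymo import ImageSeries  # local import to avoid a cycle

    config.validate()
    rng = np.random.default_rng(config.seed)
    n_rows, n_cols = config.frame_shape

    times = np.arange(config.n_frames) * config.frame_interval
    loop_kbp = np.zeros(config.n_frames)
    center = np.full(config.n_frames, np.nan)
    anchors = np.full(config.n_frames, 0.5)
    for i, t in enumerate(times):
        for ev in config.loop_events:
            lk = ev.loop_kbp_at(t)
            if lk > 0:
                loop_kbp[i] = lk
                anchors[i] = ev.anchor_pos
                center[i] = config.tether_top_row + ev.anchor_pos * config.tether_length_px
                break
    up_kbp = anchors * (config.total_dna - loop_kbp)
    down_kbp = config.total_dna - loop_kbp - up_kbp

    frames = np.empty((config.n_frames, n_rows, n_cols))
    for i in range(config.n_frames):
        line, punctum = ideal_frame_components(config, i)
        expected = line + punctum + config.background_mean
        if config.noise_model == "poisson":
            noisy = rng.poisson(expected).astype(float)
            if config.read_noise_sd > 0:
                noisy += rng.normal(0.0, config.read_noise_sd, expected.shape)
        else:
            noisy = expected + (
                rng.normal(0.0, config.gaussian_sd, expected.shape)
                if config.gaussian_sd > 0
                else 0.0
            )
        # offset-subtracted counts keep negative read-noise excursions;
        # clipping would rectify the noise and bias intensity ratios
        frames[i] = noisy

    series = ImageSeries(frames=frames, frame_interval=config.frame_interval)
    truth = GroundTruth(
        time=times,
        up_kbp=up_kbp,
        loop_kbp=loop_kbp,
        down_kbp=down_kbp,
        loop_center_row=center,
        total_dna=config.total_dna,
        has_loop=bool(config.loop_events),
    )
    return series, truth


def simulate_experiment(
    n_tethers: int,
    prop_looped: float,
    rate: float = 1.0,
    seed: int = 0,
    n_frames: int = 80,
    config: TetherSimConfig | None = None,
):
    """Simulate one loop-extrusion experiment of ``n_tethers`` tethers.

    Exactly ``round(prop_looped * n_tethers)`` tethers receive a single
    loop event (randomised start time and anchor position); the rest stay
    unlooped.  Yields ``(ImageSeries, GroundTruth)`` pairs in tether order.

    Tether identities are shuffled so looped tethers are not a prefix.
    """
    if n_tethers < 1:
        raise ValueError("n_tethers must be >= 1")
    if not (0.0 <= prop_looped <= 1.0):
        raise ValueError("prop_looped must lie in [0, 1]")
    base = config or TetherSimConfig(n_frames=n_frames)
    rng = np.random.default_rng(seed)
    n_looped = int(round(prop_looped * n_tethers))
    looped = np.zeros(n_tethers, dtype=bool)
    looped[rng.permutation(n_tethers)[:n_looped]] = True

    duration = base.n_frames * base.frame_interval
    out = []
    for i in range(n_tethers):
        events: tuple[LoopEvent, ...] = ()
        if looped[i]:
            t_start = rng.uniform(5.0, max(5.0 + 1e-6, duration - 40.0))
            anchor = rng.uniform(0.3, 0.7)
            events = (LoopEvent(t_start=t_start, rate=rate, anchor_pos=anchor),)
        cfg = dataclasses.replace(
            base, loop_events=events, seed=int(rng.integers(0, 2**31 - 1))
        )
        out.append(simulate_tether_movie(cfg))
    return out


# --------------------------------------------------------------------------
# FP titration plates
# --------------------------------------------------------------------------

def simulate_fp_plate(
    kd: float,
    fp_max: float,
    probe_conc: float,
    receptor_concs,
    noise_sd: float = 2.0,
    n_replicates: int = 3,
    seed: int = 0,
) -> TitrationData:
    """Draw an FP titration plate from the exact quadratic binding model.

    Each receptor concentration gets ``n_replicates`` readings equal to
    the closed-form model value plus i.i.d. Gaussian noise of ``noise_sd``
    mP (one entry per technical replicate; plates read multiple times
    can be represented by passing replicates x reads as n_replicates).
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    receptor_concs = np.asarray(receptor_concs, dtype=float)
    if np.any(receptor_concs < 0):
        raise ValueError("receptor concentrations must be >= 0")
    rng = np.random.default_rng(seed)
    model = fp_model(receptor_concs, probe_conc, kd, fp_max)
    readings = np.tile(model[:, None], (1, n_replicates))
    if noise_sd > 0:
        readings = readings + rng.normal(0.0, noise_sd, readings.shape)
    return TitrationData(
        probe_conc=probe_conc, receptor_concs=receptor_concs, readings=readings
    )


# --------------------------------------------------------------------------
# ATPase traces
# --------------------------------------------------------------------------

def simulate_atpase_trace(
    rate: float,
    enzyme_conc: float = 50.0,
    duration: float = 20.0,
    sampling: float = 30.0,
    noise_sd: float = 0.05,
    seed: int = 0,
    dna_conc: float = 0.0,
    condition: str | None = None,
) -> PhosphateTrace:
    """Linear phosphate-release time course with Gaussian noise.

    Parameters
    ----------
    rate :
        True phosphate production rate in uM/min.
    enzyme_conc :
        Enzyme concentration in nM (default 50 nM as used for condensin I).
    duration, sampling :
        Trace length in minutes and sampling interval in seconds.
    noise_sd :
        Gaussian noise on the signal, uM.
    """
    if rate < 0:
        raise ValueError("rate must be >= 0")
    if duration <= 0:
        raise ValueError("duration must be > 0")
    if sampling <= 0:
        raise ValueError("sampling must be > 0")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration * 60.0 + sampling / 2, sampling)
    signal = rate * t / 60.0
    if noise_sd > 0:
        signal = signal + rng.normal(0.0, noise_sd, t.shape)
    return PhosphateTrace(
        time=t,
        signal=signal,
        enzyme_conc=enzyme_conc,
        dna_conc=dna_conc,
        condition=condition,
    )
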