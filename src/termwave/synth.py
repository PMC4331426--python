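"""Synthetic microelectrode-array recordings and wave-feature tables.

Every pipeline stage can be exercised without clinical data: a plane wave
of prescribed speed, width, direction and reverberation time is written
onto the 10x10 grid as a time-shifted template per electrode (shift =
projection of the electrode position on the propagation direction divided
by the speed) plus seeded white Gaussian noise.  The template mimics the
complex-regime pulse morphology: a raised-cosine crest of the requested
width, a trailing depression and a single delayed positive lobe (the
reverberation), with the lobe timed so the z-score reverberation rule
recovers the requested tau.  Ground truth is embedded in the recording's
metadata and round-trips through file I/O.
"""
from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .lfp import ArrayRecording
from .simulate import SimulationResult, measure_sim_features

__all__ = [
    "SynthSpec",
    "waveform_template",
    "synth_plane_wave_recording",
    "synth_from_simulation",
    "synth_feature_table",
]


@dataclass(frozen=True)
class SynthSpec:
    """Ground-truth description of one synthetic plane wave."""

    speed: float  # um/ms
    width: float  # um
    direction: float = 0.0  # deg
    tau: float | None = None  # ms, reverberation time; None = no lobe
    amplitude: float = 4.0  # crest height in noise-SD units
    noise_sd: float = 1.0
    fs: float = 5000.0  # Hz
    duration: float | None = None  # ms; default sized to fit wave + reverberation
    n_rows: int = 10
    n_cols: int = 10
    pitch: float = 400.0  # um
    depression_frac: float = 0.3  # depression depth / crest
    lobe_frac: float = 0.2  # reverberation lobe height / crest
    seed: int = 0

    def __post_init__(self) -> None:
        if self.speed <= 0 or self.width <= 0:
            raise ValueError("speed and width must be positive")
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    @property
    def crest_ms(self) -> float:
        return self.width / self.speed


def _raised_cosine(t: np.ndarray, t0: float, dur: float) -> np.ndarray:
    """Unit raised-cosine bump supported on [t0, t0+dur]."""
    ph = (t - t0) / dur
    out = np.zeros_like(t)
    inside = (ph >= 0) & (ph <= 1)
    out[inside] = 0.5 * (1.0 - np.cos(2.0 * math.pi * ph[inside]))
    return out


def _flat_top(t: np.ndarray, t0: float, ramp: float, hold: float) -> np.ndarray:
    """Unit flat-top bump: cosine rise over ``ramp``, hold, cosine fall."""
    out = np.zeros_like(t)
    ph = (t - t0) / ramp
    rising = (ph >= 0) & (ph < 1)
    out[rising] = 0.5 * (1.0 - np.cos(math.pi * ph[rising]))
    out[(t >= t0 + ramp) & (t < t0 + ramp + hold)] = 1.0
    ph2 = (t - t0 - ramp - hold) / ramp
    falling = (ph2 >= 0) & (ph2 <= 1)
    out[falling] = 0.5 * (1.0 + np.cos(math.pi * ph2[falling]))
    return out


#: detection threshold (z units) the template geometry is tuned to
_Z_CREST = 2.5
_Z_REV = 0.5


def waveform_template(spec: SynthSpec, t_ms: np.ndarray, t_arrival: float) -> np.ndarray:
    """Noise-free voltage template for one electrode (arrival at t_arrival).

    Crest: flat-top bump whose extent above the 2.5 z detection threshold
    equals width/speed (the quantity the pipeline's width rule measures).
    Depression: inverted raised cosine (depth ``depression_frac`` x crest)
    immediately after.  Reverberation: positive lobe of height
    ``lobe_frac`` x crest timed so the z-threshold rule (main wave recedes
    below 0.5 z, lobe rises above and recedes again) yields tau.
    """
    A = spec.amplitude
    t_above = spec.crest_ms  # target extent above the crest threshold, ms
    ramp = min(10.0, 0.3 * t_above)
    # fraction of the cosine ramp spent above the crest threshold
    frac_above = 1.0 - math.acos(1.0 - 2.0 * _Z_CREST / A) / math.pi if A > _Z_CREST else 0.0
    hold = max(1.0, t_above - 2.0 * frac_above * ramp)
    y = A * _flat_top(t_ms, t_arrival, ramp, hold)
    t_fall = t_arrival + ramp + hold  # start of the falling ramp
    # falling ramp crosses the reverberation threshold (0.5 z) at:
    ph_rev = math.acos(2.0 * _Z_REV / A - 1.0) / math.pi
    t_end = t_fall + ph_rev * ramp
    d_dep = max(15.0, 0.4 * t_above)
    if spec.tau is not None:
        d_dep = min(d_dep, 0.6 * spec.tau)
    y -= spec.depression_frac * A * _raised_cosine(t_ms, t_fall + ramp, d_dep)
    if spec.tau is not None:
        lobe_h = spec.lobe_frac * A
        if lobe_h <= _Z_REV:
            raise ValueError("reverberation lobe must exceed the 0.5 z threshold")
        d_lobe = max(10.0, 0.3 * spec.tau)
        # lobe recedes below 0.5 z at its late crossing phase
        ph_lobe = 1.0 - math.acos(1.0 - 2.0 * _Z_REV / lobe_h) / (2.0 * math.pi)
        t_lobe_start = t_end + spec.tau - ph_lobe * d_lobe
        y += lobe_h * _raised_cosine(t_ms, t_lobe_start, d_lobe)
    return y


def synth_plane_wave_recording(spec: SynthSpec) -> ArrayRecording:
    """Render a plane wave onto the array with seeded Gaussian noise.

    Each electrode's trace is the template delayed by the projection of
    its position onto the propagation direction divided by the speed; the
    noise-free component is identical across seeds.  Raises if the wave
    (including the reverberation) does not fit in the duration.
    """
    rows = np.arange(spec.n_rows)
    cols = np.arange(spec.n_cols)
    cc, rr = np.meshgrid(cols, rows)
    x = cc * spec.pitch
    y = rr * spec.pitch
    th = math.radians(spec.direction)
    proj = x * math.cos(th) + y * math.sin(th)
    proj = proj - proj.min()
    delays = proj / spec.speed  # ms

    t_start = 100.0  # quiet baseline before the wave enters
    # tail long enough that the wave is a small fraction of the window (the
    # z-score normalization must stay noise-dominated)
    tail = 300.0 + (spec.tau or 0.0) + 12.0 * spec.crest_ms
    duration = spec.duration or (t_start + delays.max() + spec.crest_ms + tail)
    n = int(round(duration * spec.fs / 1000.0))
    t_ms = np.arange(n) * 1000.0 / spec.fs
    needed = t_start + delays.max() + spec.crest_ms + (spec.tau or 0.0) + 50.0
    if duration < needed:
        raise ValueError(
            f"wave transit ({needed:.0f} ms) exceeds the recording duration ({duration:.0f} ms)"
        )

    rng = np.random.default_rng(spec.seed)
    v = np.empty((n, spec.n_rows, spec.n_cols))
    for r in range(spec.n_rows):
        for c in range(spec.n_cols):
            v[:, r, c] = waveform_template(spec, t_ms, t_start + delays[r, c])
    # the pipeline z-scores over the analysis window, so the wave inflates its
    # own normalization; scale the template so the post-z-score crest height
    # equals the requested amplitude
    if spec.noise_sd > 0:
        s = v[:, 0, 0] / spec.amplitude  # unit-peak template shape
        m1, v1 = float(s.mean()), float(s.var())
        margin = (1.0 - m1) ** 2 - v1 * spec.amplitude**2
        if margin <= 0:
            raise ValueError("recording too short to reach the requested z amplitude; "
                             "increase duration")
        v *= spec.noise_sd / math.sqrt(margin)
    v += spec.noise_sd * rng.standard_normal(v.shape)
    return ArrayRecording(
        voltage=v, sampling_rate=spec.fs, pitch=spec.pitch,
        meta={"ground_truth": asdict(spec), "kind": "synthetic_plane_wave"},
    )


def synth_from_simulation(
    result: SimulationResult,
    direction: float = 0.0,
    *,
    fs: float = 5000.0,
    noise_sd: float = 0.0,
    amplitude: float = 4.0,
    n_rows: int = 10,
    n_cols: int = 10,
    pitch: float = 400.0,
    seed: int = 0,
) -> ArrayRecording:
    """Sample a 1-D simulated field onto the array along a direction.

    Each electrode reads the simulated u at the spatial coordinate given
    by the projection of its position onto the direction (the array is
    placed around mid-domain), resampled to ``fs`` and scaled so the crest
    has the requested amplitude in noise-SD-equivalent units; seeded noise
    is added on top.  Ground-truth features from the simulation's own
    measurement are embedded in the metadata.
    """
    feats = measure_sim_features(result)
    if not feats.is_wave:
        raise ValueError("simulation contains no propagating wave")
    rows = np.arange(n_rows)
    cols = np.arange(n_cols)
    cc, rr = np.meshgrid(cols, rows)
    th = math.radians(direction)
    proj = cc * pitch * math.cos(th) + rr * pitch * math.sin(th)
    x0 = 0.45 * result.grid.length
    t_grid = result.t
    n = int(round((t_grid[-1] - t_grid[0]) * fs / 1000.0))
    t_ms = t_grid[0] + np.arange(n) * 1000.0 / fs
    scale = amplitude / max(1e-12, float(result.u.max()))
    v = np.empty((n, n_rows, n_cols))
    for r in range(n_rows):
        for c in range(n_cols):
            xi = x0 + proj[r, c]
            i1 = min(result.grid.n_points - 1, int(xi / result.grid.dx))
            frac = xi / result.grid.dx - i1
            i2 = min(result.grid.n_points - 1, i1 + 1)
            trace = (1 - frac) * result.u[:, i1] + frac * result.u[:, i2]
            v[:, r, c] = scale * np.interp(t_ms, t_grid, trace)
    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        v += noise_sd * rng.standard_normal(v.shape)
    return ArrayRecording(
        voltage=v, sampling_rate=fs, pitch=pitch,
        meta={
            "kind": "synthetic_from_simulation",
            "direction": direction,
            "ground_truth": {
                "speed": feats.speed, "width": feats.width,
                "reverberation_time": feats.reverberation_time,
            },
        },
    )


def synth_feature_table(
    ranges: dict,
    n_waves: int,
    seed: int = 0,
) -> pd.DataFrame:
    """Uniform wave-feature draws emulating a per-seizure summary table.

    ``ranges`` maps ``speed``, ``width``, ``tau`` to (min, max) pairs in
    um/ms, um and ms respectively; draws are i.i.d. uniform and
    reproducible by seed.
    """
    for key in ("speed", "width", "tau"):
        lo, hi = ranges[key]
        if lo > hi:
            raise ValueError(f"range for {key} has min > max: {ranges[key]}")
    rng = np.random.default_rng(seed)
    rows = {
        "wave_id": np.arange(n_waves),
        "speed_um_per_ms": rng.uniform(*ranges["speed"], n_waves),
        "width_um": rng.uniform(*ranges["width"], n_waves),
        "tau_ms": rng.uniform(*ranges["tau"], n_waves),
    }
    return pd.DataFrame(rows)


#: wave-feature ranges of the first analyzed seizure (speeds um/ms, widths um,
#: reverberation times ms)
PATIENT1_SEIZURE1_RANGES = {"speed": (82.0, 389.0), "width": (1891.0, 4841.0), "tau": (29.0, 161.0)}
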