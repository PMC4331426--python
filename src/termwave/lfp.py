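"""Plane-wave detection and characterization in microelectrode-array LFP.

The pipeline mirrors the clinical analysis protocol: recordings from a
10x10 array (400 um pitch) are bandpass filtered 2-50 Hz (fourth-order
Butterworth, zero-phase), downsampled to 5000 Hz and z-scored per channel
over the analysis window.  Spatial gradients between adjacent electrodes
yield, at every sample, a magnitude-weighted histogram of gradient angles;
a wave event is timed by the center channel's z-score crossing 2.5, its
direction by the histogram peak, and its span (t_initial, t_final) by the
occupancy of +-20 degree windows around the incoming and outgoing
directions.  One-dimensional paths of 10 electrodes parallel to the
propagation direction then provide replicate estimates of speed (median of
the 45 pairwise onset-delay estimates per path), width (threshold
transition behind the last electrode) and reverberation time (z-score
excursion after the primary wave), summarized with small-sample t
confidence intervals.

Convention: gradient vectors are reported as computed (pointing uphill);
propagation angles are taken from the descent direction (-grad), which
points from the approaching crest toward the quiescent tissue ahead, so a
wave traveling at angle theta produces a histogram peak near theta at
onset and near theta+180 after passage.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal, stats

__all__ = [
    "ArrayRecording",
    "WaveEvent",
    "Path",
    "PathSet",
    "WaveFeatures",
    "preprocess_lfp",
    "zscore",
    "gradient_field",
    "angle_histogram",
    "detect_wave_events",
    "build_paths",
    "path_speed",
    "path_width",
    "path_reverberation",
    "summarize_wave",
    "analyze_recording",
]


@dataclass
class ArrayRecording:
    """Voltage from a rows x cols microelectrode array.

    ``voltage`` has shape (n_samples, n_rows, n_cols) in arbitrary units;
    ``mask`` marks live electrodes (False = dead channel).  Electrode (r, c)
    sits at position (x, y) = (c * pitch, r * pitch).
    """

    voltage: np.ndarray
    sampling_rate: float  # Hz
    pitch: float = 400.0  # um
    mask: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        v = np.asarray(self.voltage, dtype=float)
        if v.ndim != 3:
            raise ValueError("voltage must be (time, rows, cols)")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be > 0")
        self.voltage = v
        if self.mask is None:
            self.mask = np.ones(v.shape[1:], dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != v.shape[1:]:
                raise ValueError("mask shape must match the electrode grid")

    @property
    def n_samples(self) -> int:
        return self.voltage.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.voltage.shape[1:]

    @property
    def times_ms(self) -> np.ndarray:
        return np.arange(self.n_samples) * 1000.0 / self.sampling_rate


def preprocess_lfp(
    raw: np.ndarray,
    fs_in: float,
    *,
    band: tuple[float, float] = (2.0, 50.0),
    fs_out: float = 5000.0,
    pitch: float = 400.0,
) -> ArrayRecording:
    """Bandpass filter (fourth-order Butterworth, zero phase) and decimate.

    ``raw`` is (time, rows, cols) at ``fs_in`` Hz.  Channels that are all
    NaN are masked out; the output is sampled at ``fs_out`` Hz.
    """
    raw = np.asarray(raw, dtype=float)
    if fs_in < 2.0 * band[1]:
        raise ValueError(f"fs_in={fs_in} Hz is below twice the upper band edge {band[1]} Hz")
    mask = ~np.all(np.isnan(raw), axis=0)
    work = np.where(np.isnan(raw), 0.0, raw)
    sos = signal.butter(4, band, btype="bandpass", fs=fs_in, output="sos")
    filt = signal.sosfiltfilt(sos, work, axis=0)
    if fs_out < fs_in:
        up = int(round(fs_out))
        down = int(round(fs_in))
        g = math.gcd(up, down)
        filt = signal.resample_poly(filt, up // g, down // g, axis=0)
        fs = fs_in * (up // g) / (down // g)
    else:
        fs = fs_in
    return ArrayRecording(voltage=filt, sampling_rate=fs, pitch=pitch, mask=mask)


def zscore(rec: ArrayRecording) -> np.ndarray:
    """Per-channel z-score over the full analysis window (masked -> NaN)."""
    v = rec.voltage
    mu = v.mean(axis=0)
    sd = v.std(axis=0)
    sd = np.where(sd > 0, sd, np.inf)
    z = (v - mu) / sd
    z[:, ~rec.mask] = np.nan
    return z


def _smooth(z: np.ndarray, fs: float, smooth_ms: float) -> np.ndarray:
    """Boxcar-average z along time; all threshold reads use this view.

    A few milliseconds of averaging suppresses sample-level noise
    crossings of the z thresholds without moving the crossing times of the
    2-50 Hz signal content.
    """
    w = int(round(smooth_ms * fs / 1000.0))
    if w <= 1:
        return z
    kernel = np.ones(w) / w
    flat = z.reshape(z.shape[0], -1)
    out = np.empty_like(flat)
    for j in range(flat.shape[1]):
        col = flat[:, j]
        if np.all(np.isnan(col)):
            out[:, j] = col
        else:
            out[:, j] = np.convolve(col, kernel, mode="same")
    return out.reshape(z.shape)


# ---------------------------------------------------------------------------
# gradients and angle histograms
# ---------------------------------------------------------------------------


def gradient_field(rec: ArrayRecording, t_index: int, *, use_z: np.ndarray | None = None):
    """Central-difference voltage gradient per interior electrode.

    Returns ``(gx, gy, magnitude, angle_deg)`` arrays over the grid with
    NaN where a needed neighbor is missing.  x increases with column index,
    y with row index; the gradient points uphill.
    """
    v = use_z if use_z is not None else rec.voltage
    if not (0 <= t_index < v.shape[0]):
        raise IndexError(f"t_index {t_index} outside the record")
    frame = np.where(rec.mask, v[t_index], np.nan)
    gx = np.full(rec.shape, np.nan)
    gy = np.full(rec.shape, np.nan)
    gx[:, 1:-1] = (frame[:, 2:] - frame[:, :-2]) / (2.0 * rec.pitch)
    gy[1:-1, :] = (frame[2:, :] - frame[:-2, :]) / (2.0 * rec.pitch)
    mag = np.hypot(gx, gy)
    ang = np.degrees(np.arctan2(gy, gx)) % 360.0
    return gx, gy, mag, ang


def angle_histogram(angles_deg, magnitudes, n_bins: int = 36):
    """Magnitude-weighted histogram of gradient angles over [0, 360).

    Returns ``(bin_centers, weights, peak_angle)``; ``peak_angle`` is None
    when every magnitude is zero (empty-histogram flag).
    """
    a = np.asarray(angles_deg, dtype=float).ravel()
    m = np.asarray(magnitudes, dtype=float).ravel()
    ok = np.isfinite(a) & np.isfinite(m)
    a, m = a[ok] % 360.0, m[ok]
    if a.size == 0:
        raise ValueError("no valid vectors")
    edges = np.linspace(0.0, 360.0, n_bins + 1)
    w, _ = np.histogram(a, bins=edges, weights=m)
    centers = 0.5 * (edges[:-1] + edges[1:])
    if w.sum() == 0:
        return centers, w, None
    return centers, w, float(centers[int(np.argmax(w))])


def _window_weight(angles, mags, center_deg: float, halfwidth: float) -> float:
    """Total gradient magnitude with angle within +-halfwidth of center."""
    a = np.asarray(angles, dtype=float).ravel()
    m = np.asarray(mags, dtype=float).ravel()
    ok = np.isfinite(a) & np.isfinite(m)
    d = np.abs((a[ok] - center_deg + 180.0) % 360.0 - 180.0)
    return float(m[ok][d <= halfwidth].sum())


# ---------------------------------------------------------------------------
# event detection
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class WaveEvent:
    """One plane-wave passage across the array."""

    t0: float  # ms: center-channel threshold crossing
    theta0: float  # deg: propagation direction estimate at onset
    theta1: float  # deg: theta0 + 180 (mod 360)
    t_initial: float  # ms
    t_final: float  # ms
    ambiguous: bool = False

    def __post_init__(self) -> None:
        if not (self.t_initial <= self.t0 <= self.t_final):
            raise ValueError("event must satisfy t_initial <= t0 <= t_final")


def _center_signal(z: np.ndarray) -> np.ndarray:
    """Mean z-score of the four central electrodes (even grid has no center)."""
    nr, nc = z.shape[1:]
    r0, c0 = (nr - 1) // 2, (nc - 1) // 2
    rows = [r0] if nr % 2 else [r0, r0 + 1]
    cols = [c0] if nc % 2 else [c0, c0 + 1]
    block = z[:, rows][:, :, cols]
    return np.nanmean(block.reshape(z.shape[0], -1), axis=1)


def detect_wave_events(
    rec: ArrayRecording,
    *,
    z_threshold: float = 2.5,
    angle_halfwidth: float = 20.0,
    n_bins: int = 36,
    refractory_ms: float = 50.0,
    window_frac: float = 0.25,
    max_span_ms: float = 1000.0,
    smooth_ms: float = 5.0,
) -> list[WaveEvent]:
    """Detect plane-wave events and their directions and time spans.

    t0: upward crossings of the center-channel z-score through the
    threshold (events closer than the refractory gap are merged).  The
    propagation direction theta0 is the peak of the magnitude-weighted
    histogram of descent angles at t0; a peak is flagged ambiguous when a
    second bin comes within 5% of its weight.  Scanning backward (forward)
    from t0, t_initial (t_final) delimit the span during which the angle
    window around theta0 (theta1) holds at least ``window_frac`` of the
    total gradient weight.
    """
    z = _smooth(zscore(rec), rec.sampling_rate, smooth_ms)
    dt_ms = 1000.0 / rec.sampling_rate
    center = _center_signal(z)
    above = center >= z_threshold
    crossings = np.flatnonzero(above[1:] & ~above[:-1]) + 1
    merged: list[int] = []
    for i in crossings:
        if not merged or (i - merged[-1]) * dt_ms > refractory_ms:
            merged.append(int(i))

    events: list[WaveEvent] = []
    for i0 in merged:
        _gx, _gy, mag, ang = gradient_field(rec, i0, use_z=z)
        desc = (ang + 180.0) % 360.0
        try:
            _c, w, peak = angle_histogram(desc, mag, n_bins=n_bins)
        except ValueError:
            continue
        if peak is None:
            continue
        ws = np.sort(w)[::-1]
        ambiguous = bool(len(ws) > 1 and ws[1] >= 0.95 * ws[0])
        theta0 = peak
        theta1 = (theta0 + 180.0) % 360.0

        def frac_in_window(i: int, center_deg: float) -> float:
            _gx2, _gy2, m2, a2 = gradient_field(rec, i, use_z=z)
            d2 = (a2 + 180.0) % 360.0
            tot = np.nansum(m2)
            if tot == 0:
                return 0.0
            return _window_weight(d2, m2, center_deg, angle_halfwidth) / tot

        max_back = int(max_span_ms / dt_ms)
        i_init = i0
        for i in range(i0, max(0, i0 - max_back) - 1, -1):
            if frac_in_window(i, theta0) >= window_frac:
                i_init = i
            else:
                break
        i_fin = i0
        for i in range(i0, min(z.shape[0], i0 + max_back)):
            if frac_in_window(i, theta1) >= window_frac or i <= i0 + 1:
                i_fin = i
            elif i > i0 + int(5.0 / dt_ms):
                break
        events.append(
            WaveEvent(
                t0=i0 * dt_ms, theta0=theta0, theta1=theta1,
                t_initial=i_init * dt_ms, t_final=max(i_fin * dt_ms, i0 * dt_ms),
                ambiguous=ambiguous,
            )
        )
    return events


# ---------------------------------------------------------------------------
# one-dimensional paths
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Path:
    """Ordered electrodes along a grid line; the last is farthest downstream."""

    electrodes: tuple[tuple[int, int], ...]  # (row, col), ordered along propagation
    step_um: float  # inter-electrode distance (pitch or pitch*sqrt(2))
    complete: bool  # full 10 electrodes

    @property
    def length_um(self) -> float:
        return (len(self.electrodes) - 1) * self.step_um

    @property
    def last_electrode(self) -> tuple[int, int]:
        return self.electrodes[-1]


@dataclass(frozen=True)
class PathSet:
    direction_deg: float  # grid direction actually used
    paths: tuple[Path, ...]


# (drow, dcol) steps along the propagation direction; positions follow
# (x, y) = (col*pitch, row*pitch) so theta -> (drow, dcol) = (sin, cos)
_GRID_DIRS = {0.0: (0, 1), 45.0: (1, 1), 90.0: (1, 0), 135.0: (1, -1),
              180.0: (0, -1), 225.0: (-1, -1), 270.0: (-1, 0), 315.0: (-1, 1)}


def build_paths(
    event: WaveEvent,
    rec: ArrayRecording,
    *,
    min_length: int = 10,
    degraded_min: int = 6,
) -> PathSet:
    """All maximal grid-parallel electrode lines nearest the wave direction.

    The grid family (axis or diagonal) closest to theta0 is selected; each
    returned path is ordered along the propagation direction so its last
    electrode is reached last by the wave.  Lines interrupted by masked
    channels are split; pieces shorter than ``degraded_min`` are dropped,
    pieces shorter than ``min_length`` are flagged incomplete.
    """
    nr, nc = rec.shape
    angles = np.array(sorted(_GRID_DIRS))
    d = np.abs((angles - event.theta0 + 180.0) % 360.0 - 180.0)
    theta = float(angles[int(np.argmin(d))])
    drow, dcol = _GRID_DIRS[theta]
    step = rec.pitch * (math.sqrt(2.0) if drow != 0 and dcol != 0 else 1.0)

    # enumerate maximal lines in direction (drow, dcol): start from cells with
    # no predecessor
    paths: list[Path] = []
    for r in range(nr):
        for c in range(nc):
            pr, pc = r - drow, c - dcol
            if 0 <= pr < nr and 0 <= pc < nc:
                continue  # not a line start
            line = []
            rr, cc = r, c
            while 0 <= rr < nr and 0 <= cc < nc:
                line.append((rr, cc))
                rr += drow
                cc += dcol
            # split at masked electrodes
            piece: list[tuple[int, int]] = []
            pieces = []
            for e in line:
                if rec.mask[e]:
                    piece.append(e)
                else:
                    if piece:
                        pieces.append(piece)
                    piece = []
            if piece:
                pieces.append(piece)
            for pc_ in pieces:
                if len(pc_) >= degraded_min:
                    paths.append(Path(
                        electrodes=tuple(pc_), step_um=step,
                        complete=len(pc_) >= min_length,
                    ))
    return PathSet(direction_deg=theta, paths=tuple(paths))


# ---------------------------------------------------------------------------
# per-path feature estimates
# ---------------------------------------------------------------------------


def _event_slice(rec: ArrayRecording, event: WaveEvent, margin_ms: float = 100.0):
    dt_ms = 1000.0 / rec.sampling_rate
    i0 = max(0, int((event.t_initial - margin_ms) / dt_ms))
    i1 = min(rec.n_samples, int((event.t_final + margin_ms) / dt_ms) + 1)
    return i0, i1


def path_speed(
    path: Path,
    rec: ArrayRecording,
    event: WaveEvent,
    *,
    onset_sd: float = 1.0,
    min_onsets: int = 6,
    smooth_ms: float = 5.0,
) -> float | None:
    """Median of all pairwise onset-delay speed estimates along a path.

    Onset per electrode: first crossing of mean + ``onset_sd`` standard
    deviations (z = 1) within the event window.  All C(n,2) electrode
    pairs contribute distance/delay estimates; zero-delay pairs are
    excluded and the median taken.  Returns None (path rejected) when
    fewer than ``min_onsets`` electrodes have onsets.
    """
    z = _smooth(zscore(rec), rec.sampling_rate, smooth_ms)
    dt_ms = 1000.0 / rec.sampling_rate
    i0, i1 = _event_slice(rec, event)
    onsets = []
    for pos, e in enumerate(path.electrodes):
        trace = z[i0:i1, e[0], e[1]]
        idx = np.flatnonzero(trace >= onset_sd)
        if idx.size:
            onsets.append((pos * path.step_um, (i0 + idx[0]) * dt_ms))
    if len(onsets) < min_onsets:
        return None
    speeds = []
    for i in range(len(onsets)):
        for j in range(i + 1, len(onsets)):
            dxm = onsets[j][0] - onsets[i][0]
            dtm = onsets[j][1] - onsets[i][1]
            if dtm != 0.0:
                speeds.append(abs(dxm / dtm))
    if not speeds:
        return None
    return float(np.median(speeds))


def path_width(
    path: Path,
    rec: ArrayRecording,
    event: WaveEvent,
    *,
    z_threshold: float = 2.5,
    smooth_ms: float = 5.0,
) -> tuple[float, bool] | None:
    """Wave width along a path, with a lower-bound flag.

    At the moment the last electrode's z-score first exceeds the
    threshold, walk back along the path to the first electrode below
    threshold; the distance from the last electrode to that transition is
    the width.  If every electrode is above threshold the width saturates
    at the path extent and is flagged as a lower bound.  Returns None when
    the last electrode never crosses (path rejected).
    """
    z = _smooth(zscore(rec), rec.sampling_rate, smooth_ms)
    i0, i1 = _event_slice(rec, event)
    last = path.last_electrode
    trace = z[i0:i1, last[0], last[1]]
    idx = np.flatnonzero(trace >= z_threshold)
    if idx.size == 0:
        return None
    it = i0 + idx[0]
    frame = z[it]
    n = len(path.electrodes)
    for back in range(1, n):
        e = path.electrodes[n - 1 - back]
        if frame[e[0], e[1]] < z_threshold:
            return back * path.step_um, False
    return path.length_um, True


def path_reverberation(
    path: Path,
    rec: ArrayRecording,
    event: WaveEvent,
    *,
    rev_threshold: float = 0.5,
    horizon_ms: float = 500.0,
    smooth_ms: float = 5.0,
) -> float | None:
    """Mean reverberation time over the path's electrodes.

    Per electrode: after the primary wave, the z-score first falls below
    the reverberation threshold (0.5) at t_end; tau is the further time
    until the next suprathreshold excursion recedes below the threshold
    again.  Electrodes with no such excursion within the horizon are
    skipped; None when no electrode yields a value.
    """
    z = _smooth(zscore(rec), rec.sampling_rate, smooth_ms)
    dt_ms = 1000.0 / rec.sampling_rate
    i_start = int(event.t0 / dt_ms)
    i_max = min(rec.n_samples, i_start + int((horizon_ms + event.t_final - event.t0) / dt_ms))
    taus = []
    for e in path.electrodes:
        trace = z[i_start:i_max, e[0], e[1]]
        above = trace >= rev_threshold
        if not above.any():
            continue
        i_peak = int(np.flatnonzero(above)[0])
        below = np.flatnonzero(~above[i_peak:])
        if below.size == 0:
            continue
        i_end = i_peak + int(below[0])
        rise = np.flatnonzero(above[i_end:])
        if rise.size == 0:
            continue
        i_rise = i_end + int(rise[0])
        fall = np.flatnonzero(~above[i_rise:])
        if fall.size == 0:
            continue
        tau = (int(fall[0]) + i_rise - i_end) * dt_ms
        if tau <= horizon_ms:
            taus.append(tau)
    return float(np.mean(taus)) if taus else None


# ---------------------------------------------------------------------------
# wave-level summary
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class WaveFeatures:
    """Per-wave feature summary with small-sample t confidence intervals."""

    speeds: tuple[float, ...]
    widths: tuple[float, ...]
    width_lower_bound: tuple[bool, ...]
    taus: tuple[float, ...]
    mean_speed: float | None
    mean_width: float | None
    mean_tau: float | None
    speed_ci: tuple[float, float] | None
    width_ci: tuple[float, float] | None


def _t_ci(values: np.ndarray, conf: float = 0.90) -> tuple[float, float] | None:
    n = len(values)
    if n < 2:
        return None
    m = float(np.mean(values))
    s = float(np.std(values, ddof=1))
    half = stats.t.ppf(0.5 + conf / 2.0, n - 1) * s / math.sqrt(n)
    return (m - half, m + half)


def summarize_wave(
    speeds,
    widths,
    taus,
    *,
    width_lower_bound=None,
    exclude_lower_bounds: bool = False,
) -> WaveFeatures:
    """Means across paths and 90% t confidence intervals for speed/width.

    The CI is mean +- t_{0.95, n-1} * s/sqrt(n) with n the number of
    paths.  With a single path the mean is reported and the CI undefined.
    Lower-bound widths are flagged; optionally excluded from the width CI.
    """
    speeds = tuple(float(s) for s in speeds if s is not None)
    wl = tuple(bool(b) for b in (width_lower_bound or [False] * len(widths)))
    widths_all = [(float(w), b) for w, b in zip(widths, wl) if w is not None]
    taus = tuple(float(t) for t in taus if t is not None)
    w_for_ci = [w for w, b in widths_all if not (exclude_lower_bounds and b)]
    return WaveFeatures(
        speeds=speeds,
        widths=tuple(w for w, _ in widths_all),
        width_lower_bound=tuple(b for _, b in widths_all),
        taus=taus,
        mean_speed=float(np.mean(speeds)) if speeds else None,
        mean_width=float(np.mean([w for w, _ in widths_all])) if widths_all else None,
        mean_tau=float(np.mean(taus)) if taus else None,
        speed_ci=_t_ci(np.array(speeds)) if len(speeds) >= 2 else None,
        width_ci=_t_ci(np.array(w_for_ci)) if len(w_for_ci) >= 2 else None,
    )


def analyze_recording(rec: ArrayRecording, **detect_kwargs) -> pd.DataFrame:
    """End-to-end: detect events, build paths, estimate and summarize.

    Returns one row per wave with columns matching the solver's feature
    table schema (``wave_id``, ``speed_um_per_ms``, ``width_um``,
    ``tau_ms``) plus direction, CI bounds and path counts.
    """
    rows = []
    for i, ev in enumerate(detect_wave_events(rec, **detect_kwargs)):
        ps = build_paths(ev, rec)
        usable = [p for p in ps.paths if p.complete] or list(ps.paths)
        speeds, widths, lbs, taus = [], [], [], []
        for p in usable:
            s = path_speed(p, rec, ev)
            if s is not None:
                speeds.append(s)
            wres = path_width(p, rec, ev)
            if wres is not None:
                widths.append(wres[0])
                lbs.append(wres[1])
            tau = path_reverberation(p, rec, ev)
            if tau is not None:
                taus.append(tau)
        summ = summarize_wave(speeds, widths, taus, width_lower_bound=lbs)
        rows.append(
            {
                "wave_id": i,
                "t0_ms": ev.t0,
                "direction_deg": ev.theta0,
                "speed_um_per_ms": summ.mean_speed,
                "width_um": summ.mean_width,
                "width_lower_bound": any(summ.width_lower_bound),
                "tau_ms": summ.mean_tau,
                "n_paths": len(usable),
                "speed_ci_lo": summ.speed_ci[0] if summ.speed_ci else np.nan,
                "speed_ci_hi": summ.speed_ci[1] if summ.speed_ci else np.nan,
                "width_ci_lo": summ.width_ci[0] if summ.width_ci else np.nan,
                "width_ci_hi": summ.width_ci[1] if summ.width_ci else np.nan,
            }
        )
    return pd.DataFrame(rows)
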