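"""From raw envelopes (or raw EMG plus wrist kinematics) to the pooled,
averaged, normalized phasic activation matrix that synergy extraction
consumes.

Pipeline, in order: optional raw-EMG envelope formation (30 Hz high-pass,
rectification, 10 Hz low-pass), movement-phase detection from wrist speed
(5% of per-repetition peak speed), segment padding (0.3 s on each side),
linear-ramp tonic removal with clipping at zero, resampling of each padded
phase to 100 samples, averaging across repetitions and a single global-max
normalization.  All filters are Butterworth applied zero-phase
(forward-backward), so the effective order doubles but onset timing is not
shifted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, sosfiltfilt

__all__ = [
    "PreprocessConfig",
    "PhaseSegment",
    "PooledActivations",
    "lowpass_filter",
    "highpass_filter",
    "process_raw_emg",
    "detect_phases",
    "remove_tonic",
    "resample_phase",
    "average_and_normalize",
    "pool_envelope_set",
]

logger = logging.getLogger("musyn.preprocess")


@dataclass
class PreprocessConfig:
    """Tunable preprocessing parameters (defaults are the standard values
    for fast point-to-point reaching envelopes).

    Attributes
    ----------
    envelope_lp_order, envelope_lp_fc:
        Butterworth low-pass applied to activation envelopes (7th order,
        10 Hz).
    emg_hp_fc:
        High-pass cut-off for raw EMG before rectification (30 Hz).
    kin_lp_order, kin_lp_fc:
        Low-pass for kinematic signals (3rd order, 6 Hz).
    speed_frac:
        Onset/offset threshold as a fraction of the per-repetition peak
        wrist speed (0.05).
    pad_s:
        Padding added before onset and after offset so complete bursts are
        captured despite electromechanical delay (0.3 s).
    T:
        Samples per resampled movement phase (100).
    n_edge_s:
        Span of the edge windows whose means anchor the tonic ramp (0.1 s).
    min_run_s:
        Minimum supra-threshold run duration; shorter runs are treated as
        noise spikes and discarded (0.1 s).
    """

    envelope_lp_order: int = 7
    envelope_lp_fc: float = 10.0
    emg_hp_order: int = 7
    emg_hp_fc: float = 30.0
    kin_lp_order: int = 3
    kin_lp_fc: float = 6.0
    speed_frac: float = 0.05
    pad_s: float = 0.3
    T: int = 100
    n_edge_s: float = 0.1
    min_run_s: float = 0.1
    r2_mean: str = "row"


@dataclass
class PhaseSegment:
    """A movement phase located in a recording: 0-based half-open sample
    intervals, before and after the +/-0.3 s padding."""

    onset_idx: int
    offset_idx: int
    direction_label: str = ""
    padded_onset_idx: int = 0
    padded_offset_idx: int = 0
    overlaps_previous: bool = False

    def __post_init__(self) -> None:
        if not (self.padded_onset_idx <= self.onset_idx < self.offset_idx
                <= self.padded_offset_idx):
            raise ValueError(
                "require padded_onset <= onset < offset <= padded_offset, got "
                f"{self.padded_onset_idx}, {self.onset_idx}, "
                f"{self.offset_idx}, {self.padded_offset_idx}"
            )


@dataclass
class PooledActivations:
    """The M x (K*T) matrix fed to factorization: per-muscle phasic
    activations, phases concatenated, repetitions averaged, globally
    normalized so the maximum entry is 1."""

    matrix: np.ndarray
    muscle_names: list[str]
    phase_labels: list[str]
    T: int = 100
    normalization_constant: float = 1.0
    all_zero: bool = False

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        M, N = self.matrix.shape
        if len(self.muscle_names) != M:
            raise ValueError(f"{len(self.muscle_names)} names for {M} rows")
        if N != len(self.phase_labels) * self.T:
            raise ValueError(
                f"matrix has {N} columns, expected K*T = "
                f"{len(self.phase_labels)} * {self.T}"
            )

    def phase_block(self, k: int) -> np.ndarray:
        return self.matrix[:, k * self.T:(k + 1) * self.T]


# ---------------------------------------------------------------------------
# Filtering and envelope formation
# ---------------------------------------------------------------------------

def _butter_sos(order: int, fc: float, fs: float, btype: str):
    if not 0 < fc < fs / 2:
        raise ValueError(f"cut-off {fc} Hz must lie in (0, Nyquist={fs / 2} Hz)")
    return butter(order, fc, btype=btype, fs=fs, output="sos")


def lowpass_filter(x: np.ndarray, order: int, fc: float, fs: float) -> np.ndarray:
    """Zero-phase Butterworth low-pass (forward-backward; DC gain 1)."""
    sos = _butter_sos(order, fc, fs, "lowpass")
    return sosfiltfilt(sos, np.asarray(x, dtype=float), axis=-1)


def highpass_filter(x: np.ndarray, order: int, fc: float, fs: float) -> np.ndarray:
    """Zero-phase Butterworth high-pass."""
    sos = _butter_sos(order, fc, fs, "highpass")
    return sosfiltfilt(sos, np.asarray(x, dtype=float), axis=-1)


def process_raw_emg(x: np.ndarray, fs: float, cfg: PreprocessConfig | None = None) -> np.ndarray:
    """Raw EMG to nonnegative envelope: high-pass at 30 Hz, full-wave
    rectification, low-pass at 10 Hz; tiny negative ringing from the final
    low-pass is clipped at zero."""
    cfg = cfg or PreprocessConfig()
    if fs <= 2 * cfg.emg_hp_fc:
        raise ValueError(f"sampling rate {fs} Hz too low for a {cfg.emg_hp_fc} Hz high-pass")
    hp = highpass_filter(x, cfg.emg_hp_order, cfg.emg_hp_fc, fs)
    rect = np.abs(hp)
    env = lowpass_filter(rect, cfg.envelope_lp_order, cfg.envelope_lp_fc, fs)
    return np.clip(env, 0.0, None)


# ---------------------------------------------------------------------------
# Phase detection
# ---------------------------------------------------------------------------

def detect_phases(
    wrist_speed: np.ndarray,
    fs: float,
    frac: float = 0.05,
    pad_s: float = 0.3,
    min_run_s: float = 0.1,
    labels: list[str] | None = None,
) -> list[PhaseSegment]:
    """Locate movement phases as supra-threshold runs of wrist speed.

    The threshold is ``frac`` times the peak speed of this repetition
    (detection is therefore invariant to uniform speed scaling).  Onset is
    the first sample of a run, offset the first sample after it; runs
    shorter than ``min_run_s`` are discarded as noise spikes.  Padded
    indices extend ``pad_s`` on each side, clamped to the recording.
    """
    speed = np.asarray(wrist_speed, dtype=float)
    if not 0 < frac < 1:
        raise ValueError("frac must be in (0, 1)")
    peak = speed.max(initial=0.0)
    if peak <= 0:
        return []
    thr = frac * peak
    above = speed > thr
    # run boundaries of the boolean mask
    edges = np.flatnonzero(np.diff(np.concatenate(([False], above, [False])).astype(int)))
    starts, stops = edges[::2], edges[1::2]
    pad = int(round(pad_s * fs))
    min_run = int(round(min_run_s * fs))
    segments: list[PhaseSegment] = []
    prev_padded_end = -1
    for i, (a, b) in enumerate(zip(starts, stops)):
        if b - a < min_run:
            logger.info("discarding supra-threshold run [%d, %d): shorter than %.3g s",
                        a, b, min_run_s)
            continue
        seg = PhaseSegment(
            onset_idx=int(a), offset_idx=int(b),
            direction_label=(labels[len(segments)] if labels else f"phase{len(segments)}"),
            padded_onset_idx=int(max(0, a - pad)),
            padded_offset_idx=int(min(len(speed), b + pad)),
            overlaps_previous=bool(max(0, a - pad) < prev_padded_end),
        )
        prev_padded_end = seg.padded_offset_idx
        segments.append(seg)
    return segments


# ---------------------------------------------------------------------------
# Tonic removal, resampling, pooling
# ---------------------------------------------------------------------------

def remove_tonic(segment: np.ndarray, n_edge: int) -> np.ndarray:
    """Subtract a linear-ramp tonic component from a padded phase segment.

    The ramp runs from the mean of the first ``n_edge`` samples to the
    mean of the last ``n_edge`` samples; negative residuals from the
    subtraction are set to zero so the result stays nonnegative.  Works on
    a 1-D signal or a (muscles x samples) matrix.
    """
    seg = np.asarray(segment, dtype=float)
    n = seg.shape[-1]
    if n_edge < 1 or n < 2 * n_edge:
        raise ValueError(f"segment of {n} samples too short for edge windows of {n_edge}")
    start = seg[..., :n_edge].mean(axis=-1, keepdims=True)
    end = seg[..., -n_edge:].mean(axis=-1, keepdims=True)
    # anchor the line at the centers of the edge windows so that a signal
    # that is itself a perfect ramp cancels exactly
    t0 = (n_edge - 1) / 2.0
    t1 = (n - 1) - t0
    slope = (end - start) / (t1 - t0)
    ramp = start + slope * (np.arange(n) - t0)
    return np.clip(seg - ramp, 0.0, None)


def resample_phase(segment: np.ndarray, T: int = 100) -> np.ndarray:
    """Resample a phase segment to ``T`` samples by endpoint-preserving
    linear interpolation (segments are short and nonperiodic, so FFT
    resampling is inappropriate)."""
    seg = np.asarray(segment, dtype=float)
    if T < 2:
        raise ValueError("T must be >= 2")
    n = seg.shape[-1]
    if n < 2:
        raise ValueError("segment must have at least 2 samples")
    old = np.linspace(0.0, 1.0, n)
    new = np.linspace(0.0, 1.0, T)
    if seg.ndim == 1:
        return np.interp(new, old, seg)
    return np.vstack([np.interp(new, old, row) for row in seg])


def average_and_normalize(
    repetitions: list[np.ndarray],
    muscle_names: list[str],
    phase_labels: list[str],
    T: int = 100,
) -> PooledActivations:
    """Average phase-resampled envelope matrices entrywise across
    repetitions, then divide by the single global maximum so the largest
    entry of the pooled matrix is exactly 1.

    All-zero data cannot be normalized; it is returned unscaled and
    flagged.
    """
    if not repetitions:
        raise ValueError("no repetitions given")
    shapes = {rep.shape for rep in map(np.asarray, repetitions)}
    if len(shapes) != 1:
        raise ValueError(f"repetitions have inconsistent shapes: {sorted(shapes)}")
    mean = np.mean([np.asarray(r, dtype=float) for r in repetitions], axis=0)
    peak = float(mean.max(initial=0.0))
    if peak <= 0:
        logger.warning("pooled data is all zero; skipping normalization")
        return PooledActivations(mean, muscle_names, phase_labels, T,
                                 normalization_constant=1.0, all_zero=True)
    return PooledActivations(mean / peak, muscle_names, phase_labels, T,
                             normalization_constant=peak)


def pool_envelope_set(env_set, cfg: PreprocessConfig | None = None) -> PooledActivations:
    """Run the per-phase pipeline (tonic removal, resampling) on every
    repetition of an :class:`~musyn.synthetic.EnvelopeSet` and pool.

    Uses the raw variable-length padded segments when the set carries
    them, otherwise the fixed-grid matrices (already K*T wide).
    """
    cfg = cfg or PreprocessConfig()
    K = len(env_set.phase_labels)
    reps_out: list[np.ndarray] = []
    if env_set.raw_segments is not None:
        n_edge = max(1, int(round(cfg.n_edge_s * env_set.fs)))
        for rep_segments in env_set.raw_segments:
            blocks = []
            for seg in rep_segments:
                phasic = remove_tonic(seg, n_edge=n_edge)
                blocks.append(resample_phase(phasic, T=cfg.T))
            reps_out.append(np.hstack(blocks))
    else:
        for rep in env_set.reps:
            T_in = rep.shape[1] // K
            n_edge = max(1, int(round(cfg.n_edge_s / (env_set.phase_duration_s / T_in))))
            blocks = []
            for k in range(K):
                seg = rep[:, k * T_in:(k + 1) * T_in]
                phasic = remove_tonic(seg, n_edge=n_edge)
                blocks.append(resample_phase(phasic, T=cfg.T))
            reps_out.append(np.hstack(blocks))
    return average_and_normalize(reps_out, list(env_set.muscle_names),
                                 list(env_set.phase_labels), T=cfg.T)
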