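"""Ground-truth synthetic datasets for multi-directional reaching.

The generator emulates the structure the synergy pipeline assumes: a small
set of nonnegative unit-norm spatial synergies, smooth phasic bursts per
movement phase whose amplitude is cosine-tuned to each synergy's preferred
movement direction, an additive linear-ramp tonic (anti-gravity) component
per muscle and phase, and nonnegative (truncated Gaussian) noise across
repetitions.  A nested scenario places a 12-muscle "standard" recording
set inside a 32-muscle "high-density" set, with extra synergies loading on
the muscles only the dense set records — the configuration in which a
denser montage reveals one additional synergy while the shared ones keep
their structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "STANDARD_MUSCLES",
    "EXTRA_MUSCLES",
    "PHASE_LABELS",
    "GroundTruth",
    "NestedScenarioConfig",
    "EnvelopeSet",
    "GenerationError",
    "gen_synergies",
    "gen_group_synergies",
    "cosine_tuning",
    "gen_coefficients",
    "synthesize_repetitions",
    "nested_scenario",
    "perturb_synergy",
]

#: the 12 superficial upper-limb muscles of a standard bipolar montage
STANDARD_MUSCLES = [
    "DA", "DM", "DP", "INFRA", "TMAJ", "PT2",
    "TL", "TLat", "BL", "BS", "BRD", "PT",
]

#: the 20 deep / multi-head muscles added in the high-density configuration
EXTRA_MUSCLES = [
    "SUPRA", "SUBSC", "TMIN", "PT1", "PT3", "LAT1", "LAT2", "LAT3",
    "CORB", "TMed", "ANC", "SUP", "BRA", "ECRL", "ECRB", "ECU",
    "FCR", "FCU", "PL", "PQ",
]

_DIRECTIONS = ["N", "NE", "E", "SE", "S", "SW", "W", "NW"]
_DIR_ANGLE = {d: np.pi / 2 - i * np.pi / 4 for i, d in enumerate(_DIRECTIONS)}

#: 16 point-to-point phases: center-out and back for each cardinal target
PHASE_LABELS = [lab for d in _DIRECTIONS for lab in (f"O->{d}", f"{d}->O")]


class GenerationError(RuntimeError):
    """Generation failed to satisfy a structural constraint within the
    allotted number of redraws."""


def phase_angles(labels: list[str]) -> np.ndarray:
    """Movement direction (rad) of each phase; return movements point
    opposite to their target."""
    angles = []
    for lab in labels:
        src, _, dst = lab.partition("->")
        if src == "O":
            angles.append(_DIR_ANGLE[dst])
        else:
            angles.append(_DIR_ANGLE[src] + np.pi)
    return np.asarray(angles)


@dataclass
class GroundTruth:
    """Everything needed to synthesize and to score recovery.

    ``W_true`` has nonnegative unit-norm columns (M x S); ``C_true``
    (S x K*T) is built from per-phase Gaussian bursts whose parameters
    (``tuning`` amplitudes, ``burst_centers``, ``burst_width``) are stored
    so the same bursts can be evaluated on any time grid.  ``tonic_levels``
    (M x K x 2) holds per-muscle start/end levels of the linear tonic ramp.
    """

    W_true: np.ndarray
    C_true: np.ndarray
    tuning: np.ndarray
    burst_centers: np.ndarray
    burst_width: float
    tonic_levels: np.ndarray
    noise_sigma: float
    n_reps: int
    seed: int
    muscle_names: list[str]
    phase_labels: list[str] = field(default_factory=lambda: list(PHASE_LABELS))
    T: int = 100

    def __post_init__(self) -> None:
        M, S = self.W_true.shape
        norms = np.linalg.norm(self.W_true, axis=0)
        if not np.allclose(norms, 1.0, atol=1e-12):
            raise ValueError("W_true columns must have unit Euclidean norm")
        if np.any(self.W_true < 0) or np.any(self.C_true < 0):
            raise ValueError("W_true and C_true must be nonnegative")
        if len(set(self.muscle_names)) != M:
            raise ValueError(f"need {M} distinct muscle names")

    @property
    def M(self) -> int:
        return self.W_true.shape[0]

    @property
    def S_true(self) -> int:
        return self.W_true.shape[1]

    @property
    def K(self) -> int:
        return len(self.phase_labels)

    def ideal(self) -> np.ndarray:
        """Noise- and tonic-free composition ``W_true @ C_true``."""
        return self.W_true @ self.C_true

    def to_dict(self) -> dict:
        return {
            "W_true": self.W_true.tolist(),
            "C_true": self.C_true.tolist(),
            "tonic_levels": self.tonic_levels.tolist(),
            "noise_sigma": self.noise_sigma,
            "n_reps": self.n_reps,
            "seed": self.seed,
            "muscle_names": list(self.muscle_names),
            "phase_labels": list(self.phase_labels),
            "T": self.T,
        }


@dataclass
class NestedScenarioConfig:
    """Configuration of the 12-in-32 nested-montage scenario.

    ``S_shared`` synergies load almost entirely (a fraction ``1 - leak``
    of squared norm, 98% by default) on the 12 standard muscles,
    ``S_extra`` on the 20 added muscles, so the dense montage carries
    structure the standard one cannot see.
    """

    standard_muscles: list[str] = field(default_factory=lambda: list(STANDARD_MUSCLES))
    extra_muscles: list[str] = field(default_factory=lambda: list(EXTRA_MUSCLES))
    S_shared: int = 3
    S_extra: int = 1
    noise_sigma: float = 0.05
    tonic_max: float = 0.1
    leak: float = 0.02
    n_reps: int = 8
    seed: int = 0
    # burst and tuning geometry (see module docs): sharp direction tuning,
    # prime-mover bursts just before mid-phase, delayed stabilization
    # bursts for the extra synergies, slightly stronger extra recruitment
    tuning_exponent: float = 4.0
    burst_width: float = 0.09
    shared_center: float = 0.45
    extra_center: float = 0.78
    center_jitter: float = 0.05
    extra_amp: float = 1.4

    def __post_init__(self) -> None:
        if set(self.standard_muscles) & set(self.extra_muscles):
            raise ValueError("standard and extra muscle sets must be disjoint")
        if len(self.standard_muscles) != 12 or len(self.extra_muscles) != 20:
            raise ValueError("expected 12 standard and 20 extra muscles")
        if self.S_shared + self.S_extra > 12:
            raise ValueError("S_shared + S_extra must be <= 12")


@dataclass
class EnvelopeSet:
    """Per-repetition envelope matrices with their raw-length variants.

    ``reps`` holds ``n_reps`` matrices of shape M x (K*T) on the fixed
    100-sample-per-phase grid.  ``raw_segments`` (when present) holds, per
    repetition, one M x L matrix per padded movement phase at the native
    sampling rate — the input the preprocessing pipeline consumes.
    """

    reps: list[np.ndarray]
    muscle_names: list[str]
    phase_labels: list[str]
    T: int = 100
    fs: float = 1000.0
    phase_duration_s: float = 1.0
    raw_segments: list[list[np.ndarray]] | None = None

    def subset(self, muscle_names: list[str]) -> "EnvelopeSet":
        """Row-subset view: the same recordings restricted to a smaller
        montage (identical to having recorded only those muscles)."""
        idx = [self.muscle_names.index(m) for m in muscle_names]
        return EnvelopeSet(
            reps=[rep[idx] for rep in self.reps],
            muscle_names=list(muscle_names),
            phase_labels=list(self.phase_labels),
            T=self.T, fs=self.fs, phase_duration_s=self.phase_duration_s,
            raw_segments=None if self.raw_segments is None else
            [[seg[idx] for seg in rep] for rep in self.raw_segments],
        )


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------

def gen_synergies(
    M: int, S: int, sparsity: float = 0.5, seed: int = 0,
    max_sim: float = 0.8, max_tries: int = 500,
) -> np.ndarray:
    """Draw S nonnegative unit-norm synergy columns over M muscles.

    ``sparsity`` is the fraction of muscles zeroed per synergy.  Columns
    are redrawn until every pairwise cosine similarity is at most
    ``max_sim`` so the synergies are mutually distinguishable.
    """
    if not 1 <= S <= M:
        raise ValueError(f"order S={S} must satisfy 1 <= S <= M={M}")
    if not 0 <= sparsity < 1:
        raise ValueError("sparsity must be in [0, 1)")
    rng = np.random.default_rng(seed)
    n_zero = min(int(round(sparsity * M)), M - 1)
    for _ in range(max_tries):
        W = rng.uniform(0.0, 1.0, size=(M, S))
        for j in range(S):
            if n_zero:
                W[rng.choice(M, size=n_zero, replace=False), j] = 0.0
            if not W[:, j].any():  # keep at least one active muscle
                W[rng.integers(M), j] = 1.0
        W /= np.linalg.norm(W, axis=0)
        if S == 1 or np.max(np.triu(W.T @ W, k=1)) <= max_sim:
            return W
    raise GenerationError(
        f"could not draw {S} synergies with pairwise similarity <= {max_sim} "
        f"in {max_tries} tries"
    )


def cosine_tuning(
    preferred_angles: np.ndarray,
    labels: list[str] | None = None,
    amplitude: float = 1.0,
    exponent: float = 1.0,
) -> np.ndarray:
    """Half-rectified cosine direction tuning: synergy i is recruited with
    amplitude ``amplitude * max(0, cos(phase_angle - preferred_i))**exponent``
    — the standard tuning model for reaching; ``exponent > 1`` narrows the
    tuning so each synergy is recruited mainly near its preferred
    direction."""
    labels = labels if labels is not None else PHASE_LABELS
    angles = phase_angles(labels)
    pref = np.atleast_1d(np.asarray(preferred_angles, dtype=float))
    base = np.clip(np.cos(angles[None, :] - pref[:, None]), 0.0, None)
    return amplitude * base**exponent


def gen_group_synergies(M: int, S: int, seed: int = 0) -> np.ndarray:
    """Direction-grouped synergies: partition the M muscles into S
    disjoint groups and give each synergy random loads on its own group
    only.

    Disjoint supports make the synergies mutually orthogonal, the
    structure of functionally segregated muscle groups (e.g., flexor
    versus extensor compartments); used by the nested scenario so that no
    lower-order factorization can merge two synergies cheaply.
    """
    if not 1 <= S <= M:
        raise ValueError(f"order S={S} must satisfy 1 <= S <= M={M}")
    rng = np.random.default_rng(seed)
    groups = np.array_split(rng.permutation(M), S)
    W = np.zeros((M, S))
    for j, g in enumerate(groups):
        W[g, j] = rng.uniform(0.2, 1.0, size=len(g))
        W[:, j] /= np.linalg.norm(W[:, j])
    return W


def _burst(grid: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((grid - center) / width) ** 2)


def gen_coefficients(
    S: int, K: int, T: int = 100,
    tuning: np.ndarray | None = None,
    seed: int = 0,
    center_jitter: float = 0.1,
    width: float = 0.15,
    base_centers: np.ndarray | float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Temporal coefficients: one smooth Gaussian burst per phase per
    synergy, scaled by the synergy's tuning for that phase's direction.

    ``tuning`` is an (S, K) array of nonnegative amplitudes (all ones by
    default).  Burst centers sit at ``base_centers`` (a scalar or one
    value per synergy, as a fraction of the phase — late centers model
    delayed stabilization bursts) with a seeded jitter of at most
    ``center_jitter``; ``width`` is the burst standard deviation as a
    fraction of the phase, small enough that bursts vanish at the padded
    segment edges.

    Returns ``(C, centers)`` where ``C`` is S x (K*T) and ``centers`` the
    (S, K) burst centers in normalized phase time, so the identical bursts
    can be re-evaluated on a raw-length grid.
    """
    if tuning is None:
        tuning = np.ones((S, K))
    tuning = np.asarray(tuning, dtype=float)
    if tuning.shape != (S, K):
        raise ValueError(f"tuning must be ({S}, {K}), got {tuning.shape}")
    if np.any(tuning < 0):
        raise ValueError("tuning amplitudes must be nonnegative")
    rng = np.random.default_rng(seed)
    base = np.broadcast_to(np.atleast_1d(np.asarray(base_centers, dtype=float)), (S,))
    centers = base[:, None] + rng.uniform(-center_jitter, center_jitter, size=(S, K))
    grid = np.linspace(0.0, 1.0, T)
    C = np.zeros((S, K * T))
    for i in range(S):
        for k in range(K):
            C[i, k * T:(k + 1) * T] = tuning[i, k] * _burst(grid, centers[i, k], width)
    return C, centers


def synthesize_repetitions(gt: GroundTruth, fs: float = 1000.0,
                           phase_duration_s: float = 1.0) -> EnvelopeSet:
    """Compose noisy repetition envelopes from a ground truth.

    Each repetition is ``W_true @ C_true`` plus the per-phase linear tonic
    ramps plus Gaussian noise, clipped at zero (the truncation keeps
    envelopes nonnegative); repetitions differ only in the noise draw.
    Raw-length variants of every padded phase are generated at ``fs`` from
    the same burst and ramp parameters, so running the preprocessing
    pipeline on them reproduces the fixed-grid composition up to
    interpolation error.
    """
    M, S, K, T = gt.M, gt.S_true, gt.K, gt.T
    ideal = gt.ideal()
    # fixed-grid tonic: per-phase ramp between the stored start/end levels
    ramp01 = np.arange(T) / (T - 1)
    tonic = np.zeros((M, K * T))
    for k in range(K):
        start, end = gt.tonic_levels[:, k, 0], gt.tonic_levels[:, k, 1]
        tonic[:, k * T:(k + 1) * T] = start[:, None] + (end - start)[:, None] * ramp01

    rng = np.random.default_rng(np.random.SeedSequence([gt.seed, 2**20]))
    reps, raw_all = [], []
    L = max(2, int(round(fs * phase_duration_s)))
    raw_grid = np.linspace(0.0, 1.0, L)
    raw_ramp = raw_grid
    for _ in range(gt.n_reps):
        noise = rng.normal(0.0, gt.noise_sigma, size=(M, K * T)) if gt.noise_sigma > 0 \
            else np.zeros((M, K * T))
        reps.append(np.clip(ideal + tonic + noise, 0.0, None))
        segments = []
        for k in range(K):
            C_raw = np.zeros((S, L))
            for i in range(S):
                C_raw[i] = gt.tuning[i, k] * _burst(raw_grid, gt.burst_centers[i, k],
                                                   gt.burst_width)
            start, end = gt.tonic_levels[:, k, 0], gt.tonic_levels[:, k, 1]
            seg = gt.W_true @ C_raw + start[:, None] + (end - start)[:, None] * raw_ramp
            if gt.noise_sigma > 0:
                seg = seg + rng.normal(0.0, gt.noise_sigma, size=(M, L))
            segments.append(np.clip(seg, 0.0, None))
        raw_all.append(segments)
    return EnvelopeSet(
        reps=reps, muscle_names=list(gt.muscle_names),
        phase_labels=list(gt.phase_labels), T=T, fs=fs,
        phase_duration_s=phase_duration_s, raw_segments=raw_all,
    )


def _embed(w_main: np.ndarray, n_other: int, leak: float,
           rng: np.random.Generator, main_first: bool) -> np.ndarray:
    """Embed unit-norm loads into a larger montage with a ``leak``
    fraction of squared norm spilling onto the other muscle group."""
    spill = rng.uniform(0.0, 1.0, size=n_other)
    spill /= np.linalg.norm(spill)
    main = np.sqrt(1.0 - leak) * w_main
    other = np.sqrt(leak) * spill
    return np.concatenate([main, other]) if main_first else np.concatenate([other, main])


def nested_scenario(
    cfg: NestedScenarioConfig | None = None,
) -> tuple[EnvelopeSet, EnvelopeSet, GroundTruth]:
    """Build the nested 12-in-32 muscle dataset.

    Shared synergies load ``1 - leak`` (98% by default) of their squared
    norm on the 12 standard muscles; each extra synergy loads the same
    fraction on the 20 added muscles.  Synergies recruit disjoint muscle
    groups (:func:`gen_group_synergies`), are sharply cosine-tuned with
    preferred directions spread evenly over the reach directions (extra
    synergies interleaved midway), and prime-mover bursts peak just before
    mid-phase while the extra synergies burst late in the phase, as
    stabilizing forearm activity does.  Each synergy therefore contributes
    comparable, poorly compressible variance, and a factorization of the
    dense view needs one more component than the standard view.  Returns
    ``(full_32, standard_12_view, ground_truth)`` where the 12-muscle view
    is exactly the corresponding rows of the 32-muscle data.
    """
    cfg = cfg or NestedScenarioConfig()
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    n_std, n_ext = len(cfg.standard_muscles), len(cfg.extra_muscles)
    S = cfg.S_shared + cfg.S_extra

    W_std = gen_group_synergies(n_std, cfg.S_shared, seed=cfg.seed)
    cols = [_embed(W_std[:, j], n_ext, cfg.leak, rng, main_first=True)
            for j in range(cfg.S_shared)]
    if cfg.S_extra:
        W_ext = gen_group_synergies(n_ext, cfg.S_extra, seed=cfg.seed + 104729)
        cols += [_embed(W_ext[:, j], n_std, cfg.leak, rng, main_first=False)
                 for j in range(cfg.S_extra)]
    W = np.column_stack(cols)

    # preferred directions: shared synergies evenly spaced, extras midway
    shared_pref = 2 * np.pi * np.arange(cfg.S_shared) / max(cfg.S_shared, 1)
    extra_pref = shared_pref[:cfg.S_extra] + np.pi / max(cfg.S_shared, 1)
    pref = np.concatenate([shared_pref, extra_pref[:cfg.S_extra]])
    tuning = cosine_tuning(pref, exponent=cfg.tuning_exponent)
    tuning[cfg.S_shared:] *= cfg.extra_amp
    K = len(PHASE_LABELS)
    base_centers = np.array([cfg.shared_center] * cfg.S_shared
                            + [cfg.extra_center] * cfg.S_extra)
    C, centers = gen_coefficients(
        S, K, T=100, tuning=tuning, seed=cfg.seed,
        center_jitter=cfg.center_jitter, width=cfg.burst_width,
        base_centers=base_centers,
    )

    muscle_names = list(cfg.standard_muscles) + list(cfg.extra_muscles)
    tonic = np.zeros((n_std + n_ext, K, 2))
    if cfg.tonic_max > 0:
        tonic = rng.uniform(0.0, cfg.tonic_max, size=(n_std + n_ext, K, 2))
    gt = GroundTruth(
        W_true=W, C_true=C, tuning=tuning, burst_centers=centers,
        burst_width=cfg.burst_width, tonic_levels=tonic, noise_sigma=cfg.noise_sigma,
        n_reps=cfg.n_reps, seed=cfg.seed, muscle_names=muscle_names,
    )
    full = synthesize_repetitions(gt)
    view = full.subset(list(cfg.standard_muscles))
    return full, view, gt


def perturb_synergy(W: np.ndarray, col: int, fraction: float, seed: int = 0) -> np.ndarray:
    """Replace a fraction of one synergy's loads with random values and
    renormalize — a controllable structural perturbation for
    simulated-vs-experimental style comparisons."""
    if not 0 <= fraction <= 1:
        raise ValueError("fraction must be in [0, 1]")
    W = np.array(W, dtype=float, copy=True)
    M = W.shape[0]
    rng = np.random.default_rng(seed)
    n = int(round(fraction * M))
    if n:
        idx = rng.choice(M, size=n, replace=False)
        W[idx, col] = rng.uniform(0.0, W[:, col].max(initial=1.0), size=n)
    norm = np.linalg.norm(W[:, col])
    if norm > 0:
        W[:, col] /= norm
    return W
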