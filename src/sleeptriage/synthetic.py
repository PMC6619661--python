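"""Synthetic polysomnography: Markov hypnograms, stage-realistic signals,
EDF fixtures, and a simulated disagreeing scorer.

Every generator is a pure function of its parameters and a seed, so the whole
staging/reliability pipeline is testable without any recorded data. The
signal model is deliberately simple — per-stage mixtures of gated sinusoids
over pink background noise — but reproduces the discriminative structure the
stager relies on:

* **W** — sustained 8–13 Hz alpha runs and the highest chin-EMG tone;
* **N1** — low-amplitude theta, moderate tone;
* **N2** — theta background with ≥ 0.5 s spindle bursts (11–16 Hz) and some
  sub-75 µV delta;
* **N3** — high-amplitude slow waves (> 75 µV peak-to-peak, ≥ 50% duty);
* **R** — EMG atonia (lowest tone; the residual is slow baseline wander, so
  the EMG mean frequency collapses) and intermittent slow EOG deflections.

Epochs adjacent to a stage transition are synthesized as a weighted blend of
the two neighboring stage archetypes. This emulates the gradual feature drift
real recordings show at stage boundaries — slow-wave-related features hover
near the N2/N3 criterion exactly where human scorers disagree — which is the
phenomenon the reliability triage exists to catch.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from .io import Hypnogram, Recording, Channel, STAGES, write_edf, write_hypnogram

# ---------------------------------------------------------------------------
# archetypes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Component:
    """A gated sinusoid: ``amp`` µV at ``freq`` Hz, active for ``duty`` of the
    epoch in bursts of ``burst_seconds``; each burst's amplitude carries a
    lognormal jitter of sigma ``amp_jitter`` (0 = none)."""

    freq: float
    amp: float
    duty: float = 1.0
    burst_seconds: float = 2.0
    amp_jitter: float = 0.0


@dataclass(frozen=True)
class StageArchetype:
    """Waveform recipe for one sleep stage.

    NREM stages N2/N3 additionally carry a slow-wave ``delta`` template and
    an ``nrem_depth`` in [0, 1]; the delta amplitude and duty are continuous
    functions of depth (see :func:`delta_for_depth`), so the slow-wave
    features vary smoothly across the N2/N3 continuum rather than jumping
    between two fixed recipes. The EOG of NREM epochs mixes in a fraction
    ``eog_delta_coupling`` of an (independently phased) delta render —
    frontal slow waves bleed into the EOG electrodes.
    """

    eeg: tuple[Component, ...]
    eog: tuple[Component, ...]
    emg_tone: float            # broadband (white) chin-EMG amplitude, µV
    emg_slow: Component        # residual slow baseline (dominates under atonia)
    noise_sigma: float = 3.0   # pink-noise background on EEG/EOG, µV
    eog_noise_sigma: float = 14.0  # broadband EOG noise, µV (electrode/EMG pickup)
    nrem_depth: float | None = None
    delta: Component | None = None
    eog_delta_coupling: float = 0.4


#: slow-wave peak-to-peak amplitude (µV) and duty as functions of NREM depth
DELTA_PP_RANGE = (40.0, 125.0)   # pp = 40 + 85·depth: straddles the 75 µV cut
DELTA_DUTY_RANGE = (0.20, 0.85)  # duty = 0.20 + 0.65·depth


def delta_for_depth(depth: float, template: Component) -> Component:
    """Slow-wave component at a given NREM depth (µV p-p and duty ramps)."""
    pp = DELTA_PP_RANGE[0] + (DELTA_PP_RANGE[1] - DELTA_PP_RANGE[0]) * depth
    duty = DELTA_DUTY_RANGE[0] + (DELTA_DUTY_RANGE[1] - DELTA_DUTY_RANGE[0]) * depth
    return replace(template, amp=pp / 2.0, duty=duty)


def default_archetypes() -> dict[str, StageArchetype]:
    """Default per-stage recipes (see module docstring for the rationale)."""
    slow = Component(freq=2.0, amp=2.0)
    delta = Component(freq=1.2, amp=0.0, duty=0.0, burst_seconds=2.5,
                      amp_jitter=0.05)
    return {
        "W": StageArchetype(
            eeg=(Component(10.0, 30.0, duty=0.9, burst_seconds=3.0),),
            eog=(Component(0.8, 40.0, duty=0.3, burst_seconds=1.5),),
            emg_tone=30.0, emg_slow=slow),
        "N1": StageArchetype(
            eeg=(Component(5.0, 25.0, duty=0.8, burst_seconds=3.0),),
            eog=(Component(0.5, 30.0, duty=0.5, burst_seconds=2.0),),
            emg_tone=12.0, emg_slow=slow),
        "N2": StageArchetype(
            eeg=(Component(5.5, 15.0, duty=0.85, burst_seconds=3.0),
                 Component(13.5, 35.0, duty=0.30, burst_seconds=1.0)),  # spindles
            eog=(Component(0.6, 4.0, duty=0.3, burst_seconds=2.0),),
            emg_tone=10.0, emg_slow=slow,
            nrem_depth=0.28, delta=delta),
        "N3": StageArchetype(
            eeg=(Component(5.5, 12.0, duty=0.6, burst_seconds=3.0),
                 Component(13.5, 12.0, duty=0.1, burst_seconds=1.0)),  # trace
            eog=(Component(1.0, 3.0, duty=0.3, burst_seconds=2.5),),
            emg_tone=8.0, emg_slow=slow,
            nrem_depth=0.90, delta=delta),
        "R": StageArchetype(
            eeg=(Component(5.5, 22.0, duty=0.8, burst_seconds=3.0),),
            eog=(Component(0.7, 60.0, duty=0.4, burst_seconds=1.5),),  # REMs
            emg_tone=2.0, emg_slow=Component(2.0, 5.0)),
    }


# ---------------------------------------------------------------------------
# hypnogram generation
# ---------------------------------------------------------------------------

@dataclass
class TransitionModel:
    """Row-stochastic 5×5 stage transition matrix plus initial distribution."""

    matrix: np.ndarray
    initial: np.ndarray = field(
        default_factory=lambda: np.array([1.0, 0.0, 0.0, 0.0, 0.0]))

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.initial = np.asarray(self.initial, dtype=float)
        if self.matrix.shape != (5, 5):
            raise ValueError(f"transition matrix must be 5x5, got {self.matrix.shape}")
        if np.any(self.matrix < 0) or np.any(self.initial < 0):
            raise ValueError("negative probabilities")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("transition matrix rows must sum to 1")
        if not np.isclose(self.initial.sum(), 1.0, atol=1e-9):
            raise ValueError("initial distribution must sum to 1")

    def stationary(self) -> np.ndarray:
        """Stationary distribution via the left eigenvector at eigenvalue 1."""
        vals, vecs = np.linalg.eig(self.matrix.T)
        k = int(np.argmin(np.abs(vals - 1.0)))
        v = np.real(vecs[:, k])
        return v / v.sum()


def default_transition_model() -> TransitionModel:
    """Sleep-like chain: long stage runs (all self-transitions ≥ 0.85), most
    traffic through N2, with N2↔N3 deepening cycles, brief W/N1 arousals and
    consolidated REM periods."""
    m = np.array([
        # W     N1     N2     N3     R
        [0.930, 0.055, 0.015, 0.000, 0.000],   # W
        [0.030, 0.850, 0.100, 0.000, 0.020],   # N1
        [0.010, 0.015, 0.905, 0.050, 0.020],   # N2
        [0.002, 0.003, 0.060, 0.930, 0.005],   # N3
        [0.015, 0.015, 0.060, 0.005, 0.905],   # R
    ])
    return TransitionModel(matrix=m)


def generate_hypnogram(n_epochs: int, model: TransitionModel | None = None,
                       seed: int = 0) -> Hypnogram:
    """Sample a hypnogram from the Markov chain; identical for identical seeds."""
    if n_epochs < 1:
        raise ValueError("n_epochs must be >= 1")
    model = model or default_transition_model()
    rng = np.random.default_rng(seed)
    stages = np.empty(n_epochs, dtype=int)
    stages[0] = rng.choice(5, p=model.initial)
    for i in range(1, n_epochs):
        stages[i] = rng.choice(5, p=model.matrix[stages[i - 1]])
    return Hypnogram([STAGES[s] for s in stages])


# ---------------------------------------------------------------------------
# signal synthesis
# ---------------------------------------------------------------------------

def _pink_noise(n: int, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """1/f-shaped noise, unit-normalized then scaled to ``sigma``."""
    if sigma <= 0:
        return np.zeros(n)
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0)
    scale = np.ones_like(f)
    scale[1:] = 1.0 / np.sqrt(f[1:] / f[1])
    x = np.fft.irfft(spec * scale, n)
    return sigma * x / max(np.std(x), 1e-12)


def _render_component(c: Component, n: int, fs: float,
                      rng: np.random.Generator) -> np.ndarray:
    t = np.arange(n) / fs
    wave = c.amp * np.sin(2 * np.pi * c.freq * t + rng.uniform(0, 2 * np.pi))
    if c.duty >= 1.0 and c.amp_jitter <= 0:
        return wave
    if c.duty <= 0.0:
        return np.zeros(n)
    if c.duty >= 1.0:
        mask = np.ones(n, dtype=bool)
    else:
        period = c.burst_seconds / c.duty
        offset = rng.uniform(0, period)
        mask = ((t + offset) % period) < c.burst_seconds
    gain = mask.astype(float)
    if c.amp_jitter > 0:
        # per-burst lognormal amplitude jitter
        edges = np.flatnonzero(np.diff(np.concatenate([[0], mask.view(np.int8), [0]])))
        for start, stop in zip(edges[::2], edges[1::2]):
            gain[start:stop] *= rng.lognormal(0.0, c.amp_jitter)
    return wave * gain


def _render_background(arch: StageArchetype, n: int, fs: float,
                       rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Non-slow-wave, noise-free part of an epoch (rhythms + EMG)."""
    eeg = sum((_render_component(c, n, fs, rng) for c in arch.eeg),
              start=np.zeros(n))
    eog = sum((_render_component(c, n, fs, rng) for c in arch.eog),
              start=np.zeros(n))
    emg = (arch.emg_tone * rng.standard_normal(n)
           + _render_component(arch.emg_slow, n, fs, rng))
    return {"EEG": eeg, "EOG": eog, "EMG": emg}


def _render_delta(arch: StageArchetype, depth: float | None, n: int, fs: float,
                  rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Slow-wave component at ``depth`` plus its EOG bleed-through."""
    if arch.delta is None or depth is None:
        return {"EEG": np.zeros(n), "EOG": np.zeros(n)}
    dcomp = delta_for_depth(float(np.clip(depth, 0.0, 1.0)), arch.delta)
    return {"EEG": _render_component(dcomp, n, fs, rng),
            "EOG": arch.eog_delta_coupling * _render_component(dcomp, n, fs, rng)}


def _render_noise(arch: StageArchetype, n: int,
                  rng: np.random.Generator) -> dict[str, np.ndarray]:
    return {"EEG": _pink_noise(n, arch.noise_sigma, rng),
            "EOG": (_pink_noise(n, arch.noise_sigma, rng)
                    + arch.eog_noise_sigma * rng.standard_normal(n))}


def _render_epoch(arch: StageArchetype, n: int, fs: float,
                  rng: np.random.Generator, depth: float | None = None,
                  ) -> dict[str, np.ndarray]:
    """Render one epoch of all three roles from an archetype.

    ``depth`` overrides the archetype's ``nrem_depth`` for NREM stages; the
    slow-wave component and its EOG bleed-through scale with it.
    """
    bg = _render_background(arch, n, fs, rng)
    delta = _render_delta(arch, depth if depth is not None else arch.nrem_depth,
                          n, fs, rng)
    noise = _render_noise(arch, n, rng)
    return {"EEG": bg["EEG"] + delta["EEG"] + noise["EEG"],
            "EOG": bg["EOG"] + delta["EOG"] + noise["EOG"],
            "EMG": bg["EMG"]}


def _distance_to_transition(stages: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """Per-epoch distance to the nearest differing-stage epoch and that
    epoch's stage index; distance = len when the hypnogram is uniform."""
    y = np.asarray(stages)
    n = y.size
    dist = np.full(n, n, dtype=int)
    other = np.full(n, -1, dtype=int)
    stage_idx = {s: i for i, s in enumerate(STAGES)}
    last = -1
    for i in range(n):
        if i > 0 and y[i] != y[i - 1]:
            last = i - 1
        if last >= 0:
            dist[i], other[i] = i - last, stage_idx[y[last]]
    nxt = -1
    for i in range(n - 1, -1, -1):
        if i < n - 1 and y[i] != y[i + 1]:
            nxt = i + 1
        if nxt >= 0 and nxt - i < dist[i]:
            dist[i], other[i] = nxt - i, stage_idx[y[nxt]]
    return dist, other


def synthesize_recording(h: Hypnogram,
                         archetypes: dict[str, StageArchetype] | None = None,
                         fs: float = 256.0, seed: int = 0,
                         blend_base: float = 0.42, blend_radius: int = 2,
                         depth_jitter: float = 0.03,
                         ) -> Recording:
    """Render a multi-channel PSG recording realizing a hypnogram.

    Channels: C3-M2, C4-M1 (EEG), EOG-L, EOG-R, EMG Chin, all at ``fs``.
    Epochs within ``blend_radius`` of a stage transition drift toward the
    stage across the boundary with weight ``blend_base / 2**(d-1)`` at
    distance ``d``, as feature values do in real recordings. Between the two
    NREM-depth stages (N2↔N3) the drift acts on the continuous depth
    parameter — slow-wave amplitude and duty ramp through the 75 µV scoring
    criterion — while for all other stage pairs the rendered waveforms are
    mixed directly. Each epoch's depth also carries a small jitter (σ 0.05).
    """
    archetypes = archetypes or default_archetypes()
    missing = sorted(set(h.stages) - set(archetypes))
    if missing:
        raise ValueError(f"no archetype for stage(s) {missing}")
    rng = np.random.default_rng(seed)
    spe = int(round(h.epoch_seconds * fs))
    n = len(h)

    dist, other = _distance_to_transition(h.stages)
    buf = {name: np.empty(n * spe) for name in
           ("C3-M2", "C4-M1", "EOG-L", "EOG-R", "EMG Chin")}
    for i, stage in enumerate(h.stages):
        arch = archetypes[stage]
        d = int(dist[i])
        w = blend_base * 0.85 ** (d - 1) if 1 <= d <= blend_radius else 0.0
        neigh = archetypes[STAGES[other[i]]] if (w > 0 and other[i] >= 0) else None

        depth = arch.nrem_depth
        nrem_pair = (depth is not None and neigh is not None
                     and neigh.nrem_depth is not None)
        if depth is not None:
            if nrem_pair:
                depth = (1 - w) * depth + w * neigh.nrem_depth
            depth += rng.normal(0.0, depth_jitter)

        def render(rng_):
            if nrem_pair:
                # N2<->N3: slow waves ramp with depth, background cross-fades
                bg_o = _render_background(arch, spe, fs, rng_)
                bg_n = _render_background(neigh, spe, fs, rng_)
                delta = _render_delta(arch, depth, spe, fs, rng_)
                noise = _render_noise(arch, spe, rng_)
                return {
                    "EEG": ((1 - w) * bg_o["EEG"] + w * bg_n["EEG"]
                            + delta["EEG"] + noise["EEG"]),
                    "EOG": ((1 - w) * bg_o["EOG"] + w * bg_n["EOG"]
                            + delta["EOG"] + noise["EOG"]),
                    "EMG": (1 - w) * bg_o["EMG"] + w * bg_n["EMG"],
                }
            out = _render_epoch(arch, spe, fs, rng_, depth)
            if neigh is not None:
                nb = _render_epoch(neigh, spe, fs, rng_)
                for k in out:
                    out[k] = (1 - w) * out[k] + w * nb[k]
            return out

        own = render(rng)
        own2 = render(rng)
        sl = slice(i * spe, (i + 1) * spe)
        buf["C3-M2"][sl] = own["EEG"]
        buf["C4-M1"][sl] = own2["EEG"]
        buf["EOG-L"][sl] = own["EOG"]
        buf["EOG-R"][sl] = own2["EOG"]
        buf["EMG Chin"][sl] = own["EMG"]

    roles = {"C3-M2": "EEG", "C4-M1": "EEG", "EOG-L": "EOG",
             "EOG-R": "EOG", "EMG Chin": "EMG"}
    return Recording(channels=[
        Channel(label=k, role=roles[k], fs=fs, samples=v) for k, v in buf.items()
    ])


# ---------------------------------------------------------------------------
# disagreeing scorer
# ---------------------------------------------------------------------------

def simulate_disagreeing_scorer(truth: Hypnogram, p_near: float, p_far: float,
                                near_radius: int = 2, seed: int = 0) -> Hypnogram:
    """Simulate a second scorer whose errors cluster at stage transitions.

    Epochs within ``near_radius`` of a stage change are relabeled with
    probability ``p_near`` to the stage on the other side of the nearest
    transition (the typical boundary-call disagreement); all other epochs are
    relabeled with probability ``p_far``. Deterministic under ``seed``.
    """
    if not (0.0 <= p_far <= p_near <= 1.0):
        raise ValueError(f"need 0 <= p_far <= p_near <= 1, got {p_far}, {p_near}")
    rng = np.random.default_rng(seed)
    dist, other = _distance_to_transition(truth.stages)
    stages = list(truth.stages)
    for i in range(len(stages)):
        p = p_near if dist[i] <= near_radius else p_far
        if p > 0 and rng.random() < p:
            if other[i] >= 0:
                stages[i] = STAGES[other[i]]
            else:  # uniform hypnogram: any other stage
                choices = [s for s in STAGES if s != stages[i]]
                stages[i] = choices[rng.integers(len(choices))]
    return Hypnogram(stages, epoch_seconds=truth.epoch_seconds)


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

def make_fixture(n_epochs: int, seed: int, out_dir,
                 archetypes: dict[str, StageArchetype] | None = None,
                 model: TransitionModel | None = None,
                 fs: float = 256.0) -> dict[str, Path]:
    """Write a complete synthetic fixture: EDF + truth hypnogram + manifest.

    Returns the paths keyed ``edf``, ``hypnogram``, ``manifest``. The same
    seed reproduces byte-identical hypnogram files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    h = generate_hypnogram(n_epochs, model, seed=seed)
    rec = synthesize_recording(h, archetypes, fs=fs, seed=seed + 1)
    paths = {"edf": out_dir / f"fixture_{seed}.edf",
             "hypnogram": out_dir / f"fixture_{seed}_truth.csv",
             "manifest": out_dir / f"fixture_{seed}_manifest.yaml"}
    write_edf(rec, paths["edf"])
    write_hypnogram(h, paths["hypnogram"])
    with open(paths["manifest"], "w") as f:
        yaml.safe_dump({"n_epochs": n_epochs, "seed": seed, "fs": fs,
                        "channels": [c.label for c in rec.channels]}, f)
    return paths
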