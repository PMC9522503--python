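"""Synthetic labeled polysomnography: Markov hypnograms + stage-colored EEG.

The generator reproduces the two statistical properties the classification
pipeline exploits, without any physiological realism claims:

* **Hypnogram structure** — stages evolve as a first-order Markov chain with
  strong self-transitions.  The default chain puts 0.897 mass on the diagonal,
  matching the same-label adjacency fraction observed in overnight
  single-channel EEG scoring on the Sleep-EDF-2013 corpus, with the remaining
  mass spread along plausible sleep-architecture routes (W<->N1, N1->N2,
  N2<->N3, N2<->REM favored).
* **Spectral separability** — each stage emits band-limited oscillations with
  randomized phase over a 1/f (pink) noise floor: alpha for Wake, low-amplitude
  theta for N1, theta plus sigma-band spindle activity for N2, high-amplitude
  delta for N3, and mixed low-amplitude theta for REM.  Stages are therefore
  separable in the time-frequency domain by construction.

Signals are synthesized in the frequency domain (Gaussian spectral bumps plus
a ``1/f^exponent`` floor, random phases, inverse real FFT), which gives exact
band-limited content at 3000-sample epochs cheaply.

A single seed drives a whole dataset; per-recording streams are derived with
``np.random.SeedSequence(spawn_key)`` so that adding recordings never perturbs
earlier ones.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from .preprocessing import DEFAULT_SAMPLING_RATE, EPOCH_SECONDS
from .stages import N_STAGES, STAGES, encode_stages


@dataclasses.dataclass
class StageMarkovModel:
    """First-order Markov chain over the 5 stages (order W, N1, N2, N3, REM)."""

    transition: np.ndarray  # (5, 5) row-stochastic
    initial: np.ndarray  # (5,) distribution

    def __post_init__(self) -> None:
        self.transition = np.asarray(self.transition, dtype=float)
        self.initial = np.asarray(self.initial, dtype=float)
        validate_stochastic(self.transition, name="transition")
        if self.initial.shape != (N_STAGES,) or np.any(self.initial < 0):
            raise ValueError("initial must be a non-negative 5-vector")
        if abs(self.initial.sum() - 1.0) > 1e-9:
            raise ValueError("initial distribution must sum to 1")


@dataclasses.dataclass
class StageSignalTemplate:
    """Spectral recipe for one stage: oscillations over 1/f noise.

    ``oscillations`` is a list of ``(center_hz, bandwidth_hz, rel_amplitude)``;
    ``amplitude_scale`` sets the overall RMS in microvolts.
    """

    stage: str
    oscillations: list[tuple[float, float, float]]
    noise_exponent: float = 1.0
    amplitude_scale: float = 30.0

    def __post_init__(self) -> None:
        nyquist = DEFAULT_SAMPLING_RATE / 2
        for center, bw, amp in self.oscillations:
            if amp < 0:
                raise ValueError(f"{self.stage}: negative oscillation amplitude")
            if not 0 < center < nyquist:
                raise ValueError(f"{self.stage}: center {center} Hz outside (0, Nyquist)")
            if bw <= 0:
                raise ValueError(f"{self.stage}: bandwidth must be positive")


def validate_stochastic(matrix: np.ndarray, name: str = "matrix") -> None:
    """Raise if ``matrix`` is not 5x5 row-stochastic with non-negative entries."""
    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape != (N_STAGES, N_STAGES):
        raise ValueError(f"{name} must be 5x5, got {matrix.shape}")
    if np.any(matrix < 0):
        raise ValueError(f"{name} has negative entries")
    rowsum = matrix.sum(axis=1)
    bad = np.nonzero(np.abs(rowsum - 1.0) > 1e-9)[0]
    if bad.size:
        raise ValueError(
            f"{name} row {bad[0]} ({STAGES[bad[0]]}) sums to {rowsum[bad[0]]:.6f}, not 1"
        )


def default_transition(self_mass: float = 0.897) -> np.ndarray:
    """Default stage-transition matrix.

    Diagonal mass ``self_mass`` (0.897: the observed fraction of adjacent
    epoch pairs sharing a label); off-diagonal mass follows typical sleep
    architecture, scaled so each row sums to 1.
    """
    # off-diagonal proportions, rows/cols in order W, N1, N2, N3, REM
    off = np.array(
        [
            [0.0, 0.080, 0.010, 0.003, 0.010],  # W: mostly into N1
            [0.030, 0.0, 0.060, 0.003, 0.010],  # N1: down into N2
            [0.010, 0.020, 0.0, 0.050, 0.023],  # N2: deepen to N3 or REM
            [0.005, 0.003, 0.090, 0.0, 0.005],  # N3: lighten back to N2
            [0.020, 0.040, 0.040, 0.003, 0.0],  # REM: wake or light sleep
        ]
    )
    off = off / off.sum(axis=1, keepdims=True) * (1.0 - self_mass)
    return off + np.eye(N_STAGES) * self_mass


def default_initial() -> np.ndarray:
    """Default initial stage distribution: nights begin mostly awake."""
    return np.array([0.6, 0.2, 0.1, 0.05, 0.05])


def default_markov_model(self_mass: float = 0.897) -> StageMarkovModel:
    return StageMarkovModel(default_transition(self_mass), default_initial())


def default_templates() -> dict[str, StageSignalTemplate]:
    """Textbook stage signatures: (center Hz, bandwidth Hz, rel. amplitude)."""
    return {
        "W": StageSignalTemplate("W", [(10.0, 2.0, 1.0)], amplitude_scale=30.0),
        "N1": StageSignalTemplate("N1", [(5.5, 1.5, 0.5)], amplitude_scale=20.0),
        "N2": StageSignalTemplate(
            "N2", [(5.5, 1.5, 0.6), (13.0, 1.0, 0.8)], amplitude_scale=25.0
        ),
        "N3": StageSignalTemplate("N3", [(1.2, 0.8, 2.0)], amplitude_scale=60.0),
        "REM": StageSignalTemplate(
            "REM", [(5.5, 1.5, 0.4), (20.0, 3.0, 0.2)], amplitude_scale=15.0
        ),
    }


def sample_hypnogram(
    model: StageMarkovModel, n_epochs: int, seed: int | np.random.Generator
) -> np.ndarray:
    """Draw a stage-code sequence of length ``n_epochs`` from the chain."""
    if n_epochs < 1:
        raise ValueError("n_epochs must be >= 1")
    rng = np.random.default_rng(seed)
    # cumulative rows let each step be a single searchsorted
    cum_tr = np.cumsum(model.transition, axis=1)
    out = np.empty(n_epochs, dtype=np.int64)
    u = rng.random(n_epochs)
    out[0] = np.searchsorted(np.cumsum(model.initial), u[0], side="right")
    for t in range(1, n_epochs):
        out[t] = np.searchsorted(cum_tr[out[t - 1]], u[t], side="right")
    return np.clip(out, 0, N_STAGES - 1)


def synthesize_epoch(
    stage: int | str,
    templates: dict[str, StageSignalTemplate] | None = None,
    sampling_rate: float = DEFAULT_SAMPLING_RATE,
    seed: int | np.random.Generator = 0,
    n_samples: int | None = None,
) -> np.ndarray:
    """Synthesize one raw epoch for ``stage`` (microvolts, length 3000).

    Frequency-domain synthesis: amplitude spectrum = 1/f^exponent floor plus a
    Gaussian bump per oscillation, phases uniform, inverse rFFT, then scaled
    to the template's RMS amplitude.
    """
    templates = templates if templates is not None else default_templates()
    name = STAGES[stage] if isinstance(stage, (int, np.integer)) else str(stage)
    if name not in templates:
        raise KeyError(f"no signal template for stage {name!r}")
    tpl = templates[name]
    rng = np.random.default_rng(seed)
    n = n_samples or int(round(sampling_rate * EPOCH_SECONDS))
    freqs = np.fft.rfftfreq(n, d=1.0 / sampling_rate)
    amp = np.zeros_like(freqs)
    nonzero = freqs > 0
    amp[nonzero] = freqs[nonzero] ** (-tpl.noise_exponent / 2.0)  # pink floor
    # bump height is relative to the pink floor at 1 Hz (amplitude 1)
    for center, bw, rel in tpl.oscillations:
        sigma = bw / 2.0
        amp += rel * np.exp(-0.5 * ((freqs - center) / sigma) ** 2)
    phases = rng.uniform(0, 2 * np.pi, freqs.size)
    spectrum = amp * np.exp(1j * phases)
    spectrum[0] = 0.0
    x = np.fft.irfft(spectrum, n=n)
    rms = np.sqrt(np.mean(x**2))
    if rms > 0:
        x = x / rms * tpl.amplitude_scale
    return x


@dataclasses.dataclass
class SyntheticRecording:
    """One synthetic night: signals ``(n_epochs, 3000)`` + stage codes."""

    recording_id: str
    subject_id: str
    signals: np.ndarray
    labels: np.ndarray


def generate_recording(
    recording_id: str,
    subject_id: str,
    n_epochs: int,
    model: StageMarkovModel,
    templates: dict[str, StageSignalTemplate] | None,
    seed_seq: np.random.SeedSequence,
    sampling_rate: float = DEFAULT_SAMPLING_RATE,
) -> SyntheticRecording:
    rng = np.random.default_rng(seed_seq)
    labels = sample_hypnogram(model, n_epochs, rng)
    n = int(round(sampling_rate * EPOCH_SECONDS))
    signals = np.empty((n_epochs, n))
    for i, code in enumerate(labels):
        signals[i] = synthesize_epoch(
            int(code), templates, sampling_rate=sampling_rate, seed=rng
        )
    return SyntheticRecording(recording_id, subject_id, signals, labels)


def generate_dataset(
    n_recordings: int = 20,
    epochs_per_recording: int = 200,
    model: StageMarkovModel | None = None,
    templates: dict[str, StageSignalTemplate] | None = None,
    seed: int = 0,
    recordings_per_subject: int = 1,
    sampling_rate: float = DEFAULT_SAMPLING_RATE,
) -> list[SyntheticRecording]:
    """Generate a labeled synthetic dataset.

    Deterministic under a fixed seed; recording ``i`` uses the sub-stream
    ``SeedSequence(seed, spawn_key=(i,))``, so regenerating with more
    recordings leaves earlier recordings bit-identical.
    """
    if n_recordings < 1 or epochs_per_recording < 1:
        raise ValueError("n_recordings and epochs_per_recording must be >= 1")
    model = model if model is not None else default_markov_model()
    templates = templates if templates is not None else default_templates()
    recordings = []
    for i in range(n_recordings):
        sub = np.random.SeedSequence(entropy=seed, spawn_key=(i,))
        subject = f"s{i // recordings_per_subject:03d}"
        recordings.append(
            generate_recording(
                recording_id=f"rec{i:03d}",
                subject_id=subject,
                n_epochs=epochs_per_recording,
                model=model,
                templates=templates,
                seed_seq=sub,
                sampling_rate=sampling_rate,
            )
        )
    return recordings


def dataset_arrays(
    recordings: Sequence[SyntheticRecording],
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Stack a dataset into ``(X, y, groups, subjects)`` flat arrays."""
    X = np.concatenate([r.signals for r in recordings])
    y = np.concatenate([r.labels for r in recordings])
    groups = np.concatenate(
        [np.full(r.signals.shape[0], r.recording_id, dtype=object) for r in recordings]
    )
    subjects = np.concatenate(
        [np.full(r.signals.shape[0], r.subject_id, dtype=object) for r in recordings]
    )
    return X, y, groups, subjects
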