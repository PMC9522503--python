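"""Epoch preprocessing: standardization and filter-bank log-power spectrograms.

A 30 s single-channel EEG epoch sampled at 100 Hz (3000 samples) is turned
into the two representations the neural branches consume:

* a standardized time series ``(x - mu) / sigma`` for the temporal branch, and
* a short-time Fourier log-power spectrogram for the spectral branch:
  2 s Hamming window, 50% overlap, 256-point FFT, giving 29 frames x 129
  frequency bins, then reduced to 29 x 20 by a bank of triangular frequency
  filters.

Standardization statistics can be taken per recording (default; preserves
relative amplitude between stages within a night) or per epoch.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from scipy import signal as _signal
from sklearn.base import BaseEstimator, TransformerMixin

from .stages import stage_code

#: Default log floor: log(power + LOG_FLOOR) avoids -inf on silent frames.
LOG_FLOOR = 1e-10

DEFAULT_SAMPLING_RATE = 100.0
EPOCH_SECONDS = 30.0


@dataclasses.dataclass
class EpochRecord:
    """One 30 s labeled EEG epoch — the atomic unit of sleep scoring.

    ``samples`` are raw microvolts; ``label`` (optional) is a stage code;
    ``recording_id``/``index`` locate the epoch within its recording.
    """

    samples: np.ndarray
    label: int | None = None
    recording_id: str = ""
    index: int = 0
    sampling_rate: float = DEFAULT_SAMPLING_RATE

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        expected = int(round(self.sampling_rate * EPOCH_SECONDS))
        if self.samples.ndim != 1 or self.samples.size != expected:
            raise ValueError(
                f"epoch {self.recording_id!r}[{self.index}]: expected "
                f"{expected} samples, got shape {self.samples.shape}"
            )
        if self.label is not None:
            self.label = stage_code(self.label)


@dataclasses.dataclass
class StandardizedEpoch:
    """Z-scored epoch samples (dimensionless)."""

    samples: np.ndarray
    standardization_scope: str = "per_epoch"


@dataclasses.dataclass
class Spectrogram:
    """Time x frequency log-power matrix for one epoch."""

    values: np.ndarray  # (n_frames, n_bins) log-power
    frame_times: np.ndarray  # seconds, frame centers
    bin_freqs: np.ndarray  # Hz
    log_floor: float = LOG_FLOOR

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclasses.dataclass
class FilterBank:
    """Non-negative (n_filters x n_bins) weight matrix of triangular filters."""

    weights: np.ndarray
    bin_freqs: np.ndarray
    freq_range: tuple[float, float]

    @property
    def n_filters(self) -> int:
        return self.weights.shape[0]

    @property
    def n_bins(self) -> int:
        return self.weights.shape[1]


class DegenerateEpochError(ValueError):
    """Raised for epochs that cannot be standardized (zero variance)."""


def standardize_epoch(
    epoch: EpochRecord | np.ndarray,
    mu: float,
    sigma: float,
    *,
    scope: str = "per_epoch",
) -> StandardizedEpoch:
    """Apply ``(samples - mu) / sigma``.

    ``mu`` and ``sigma`` must be computed according to the configured scope
    (per-epoch or per-recording); ``sigma <= 0`` (a flat signal) raises
    :class:`DegenerateEpochError` naming the offending epoch.
    """
    if isinstance(epoch, EpochRecord):
        samples, where = epoch.samples, f"{epoch.recording_id!r}[{epoch.index}]"
    else:
        samples, where = np.asarray(epoch, dtype=float), "<array>"
    if not sigma > 0:
        raise DegenerateEpochError(
            f"epoch {where}: standard deviation {sigma} is not positive "
            "(flat signal cannot be standardized)"
        )
    return StandardizedEpoch((samples - mu) / sigma, standardization_scope=scope)


def standardize_signals(
    X: np.ndarray, *, scope: str = "per_recording", groups: np.ndarray | None = None
) -> np.ndarray:
    """Standardize an ``(n_epochs, n_samples)`` array of raw epochs.

    ``scope='per_epoch'`` z-scores each row independently;
    ``scope='per_recording'`` pools the statistics over all rows sharing the
    same ``groups`` entry (all rows, if ``groups`` is None).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError(f"expected (n_epochs, n_samples), got shape {X.shape}")
    if scope == "per_epoch":
        mu = X.mean(axis=1, keepdims=True)
        sd = X.std(axis=1, keepdims=True)
        if np.any(sd <= 0):
            bad = int(np.argmax(sd.ravel() <= 0))
            raise DegenerateEpochError(f"epoch [{bad}] has zero variance")
        return (X - mu) / sd
    if scope == "per_recording":
        out = np.empty_like(X)
        if groups is None:
            groups = np.zeros(X.shape[0], dtype=int)
        groups = np.asarray(groups)
        for g in np.unique(groups):
            mask = groups == g
            mu, sd = X[mask].mean(), X[mask].std()
            if sd <= 0:
                raise DegenerateEpochError(f"recording {g!r} has zero variance")
            out[mask] = (X[mask] - mu) / sd
        return out
    raise ValueError(f"unknown standardization scope: {scope!r}")


def compute_log_spectrogram(
    std_epoch: StandardizedEpoch | np.ndarray,
    window_sec: float = 2.0,
    overlap: float = 0.5,
    nfft: int = 256,
    sampling_rate: float = DEFAULT_SAMPLING_RATE,
    log_floor: float = LOG_FLOOR,
) -> Spectrogram:
    """STFT log-power spectrogram of one epoch.

    Hamming window (symmetric), no padding: frame count is
    ``floor((L - W) / H) + 1`` with hop ``H = W * (1 - overlap)``; bin count is
    ``nfft / 2 + 1``.  For 3000 samples at defaults this is 29 x 129.
    Values are ``log(power + log_floor)``.
    """
    x = std_epoch.samples if isinstance(std_epoch, StandardizedEpoch) else std_epoch
    x = np.asarray(x, dtype=float)
    nperseg = int(round(window_sec * sampling_rate))
    if nfft < nperseg:
        raise ValueError(f"nfft ({nfft}) must be >= window samples ({nperseg})")
    if x.shape[-1] < nperseg:
        raise ValueError(
            f"epoch length {x.shape[-1]} shorter than one window ({nperseg})"
        )
    noverlap = int(round(nperseg * overlap))
    freqs, times, power = _signal.spectrogram(
        x,
        fs=sampling_rate,
        window=_signal.windows.hamming(nperseg, sym=True),
        noverlap=noverlap,
        nfft=nfft,
        detrend=False,
        scaling="spectrum",
        mode="psd",
        axis=-1,
    )
    values = np.log(np.moveaxis(power, -2, -1) + log_floor)
    return Spectrogram(values, frame_times=times, bin_freqs=freqs, log_floor=log_floor)


def build_filterbank(
    n_filters: int = 20,
    n_bins: int = 129,
    freq_range: tuple[float, float] = (0.5, 49.0),
    sampling_rate: float = DEFAULT_SAMPLING_RATE,
    nfft: int = 256,
) -> FilterBank:
    """Bank of triangular filters with linearly spaced centers.

    Filter edges are ``n_filters + 2`` points evenly spaced over
    ``freq_range``; filter *i* rises over ``(edge[i], edge[i+1])`` and falls
    over ``(edge[i+1], edge[i+2])`` — adjacent filters overlap by 50%.  Each
    row is normalized to unit sum.
    """
    if n_filters >= n_bins:
        raise ValueError(f"n_filters ({n_filters}) must be < n_bins ({n_bins})")
    if n_filters < 1:
        raise ValueError("n_filters must be >= 1")
    bin_freqs = np.arange(n_bins) * (sampling_rate / nfft)
    lo, hi = freq_range
    edges = np.linspace(lo, hi, n_filters + 2)
    weights = np.zeros((n_filters, n_bins))
    for i in range(n_filters):
        left, center, right = edges[i], edges[i + 1], edges[i + 2]
        rising = (bin_freqs - left) / (center - left)
        falling = (right - bin_freqs) / (right - center)
        weights[i] = np.clip(np.minimum(rising, falling), 0.0, None)
        total = weights[i].sum()
        if total <= 0:
            raise ValueError(
                f"filter {i} covers no frequency bin; widen freq_range or "
                "reduce n_filters"
            )
        weights[i] /= total
    return FilterBank(weights, bin_freqs=bin_freqs, freq_range=(lo, hi))


def apply_filterbank(spec: Spectrogram, bank: FilterBank) -> Spectrogram:
    """Reduce a spectrogram's frequency axis through a filter bank.

    Filters act on *linear* power (recovered from the stored log values), and
    the result is re-logged with the same floor, so an identity-like bank
    returns the input unchanged.
    """
    if spec.values.shape[-1] != bank.n_bins:
        raise ValueError(
            f"spectrogram has {spec.values.shape[-1]} bins but the bank "
            f"expects {bank.n_bins}"
        )
    linear = np.clip(np.exp(spec.values) - spec.log_floor, 0.0, None)
    reduced = np.log(linear @ bank.weights.T + spec.log_floor)
    center_freqs = bank.weights @ bank.bin_freqs
    return Spectrogram(
        reduced,
        frame_times=spec.frame_times,
        bin_freqs=center_freqs,
        log_floor=spec.log_floor,
    )


class EpochStandardizer(TransformerMixin, BaseEstimator):
    """Transformer z-scoring raw epochs, per recording or per epoch.

    Stateless between fit and transform: the statistics are a property of the
    data being transformed (each night is standardized with its own mean/SD),
    so ``fit`` only validates input.
    """

    def __init__(self, scope: str = "per_recording"):
        self.scope = scope

    def fit(self, X, y=None, **fit_params):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError(f"expected (n_epochs, n_samples), got {X.shape}")
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X, groups: np.ndarray | None = None) -> np.ndarray:
        return standardize_signals(np.asarray(X, dtype=float), scope=self.scope, groups=groups)


class SpectrogramTransformer(TransformerMixin, BaseEstimator):
    """Transformer mapping raw epochs ``(n, 3000)`` to filter-bank log-power
    spectrograms ``(n, 29, 20)`` (or ``(n, 29, 129)`` with ``apply_bank=False``).
    """

    def __init__(
        self,
        window_sec: float = 2.0,
        overlap: float = 0.5,
        nfft: int = 256,
        sampling_rate: float = DEFAULT_SAMPLING_RATE,
        n_filters: int = 20,
        freq_range: tuple[float, float] = (0.5, 49.0),
        log_floor: float = LOG_FLOOR,
        apply_bank: bool = True,
    ):
        self.window_sec = window_sec
        self.overlap = overlap
        self.nfft = nfft
        self.sampling_rate = sampling_rate
        self.n_filters = n_filters
        self.freq_range = freq_range
        self.log_floor = log_floor
        self.apply_bank = apply_bank

    def fit(self, X=None, y=None):
        n_bins = self.nfft // 2 + 1
        self.filterbank_ = build_filterbank(
            n_filters=self.n_filters,
            n_bins=n_bins,
            freq_range=self.freq_range,
            sampling_rate=self.sampling_rate,
            nfft=self.nfft,
        )
        return self

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "filterbank_"):
            self.fit()
        X = np.atleast_2d(np.asarray(X, dtype=float))
        spec = compute_log_spectrogram(
            X,
            window_sec=self.window_sec,
            overlap=self.overlap,
            nfft=self.nfft,
            sampling_rate=self.sampling_rate,
            log_floor=self.log_floor,
        )
        if not self.apply_bank:
            return spec.values
        return apply_filterbank(spec, self.filterbank_).values


def segment_epochs(
    x: np.ndarray,
    sampling_rate: float = DEFAULT_SAMPLING_RATE,
    epoch_seconds: float = EPOCH_SECONDS,
) -> np.ndarray:
    """Cut a continuous signal into consecutive 30 s epochs (drop remainder)."""
    x = np.asarray(x, dtype=float).ravel()
    n = int(round(sampling_rate * epoch_seconds))
    n_epochs = x.size // n
    if n_epochs == 0:
        raise ValueError(f"signal of {x.size} samples holds no {epoch_seconds} s epoch")
    return x[: n_epochs * n].reshape(n_epochs, n)


def read_edf_epochs(
    path: str,
    channel: str = "EEG Fpz-Cz",
    sampling_rate: float = DEFAULT_SAMPLING_RATE,
    trim: tuple[int, int] | None = None,
) -> np.ndarray:
    """Read one EEG channel from an EDF/EDF+ recording as 30 s epochs.

    Optional path for real polysomnography data; requires :mod:`mne`.  ``trim``
    gives (first, last+1) epoch indices of the in-bed period to keep — trimming
    indices are supplied by the caller, never inferred.
    """
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "reading EDF files requires the optional dependency 'mne' "
            "(pip install sleepstager[edf])"
        ) from exc
    raw = mne.io.read_raw_edf(path, include=[channel], preload=True, verbose="error")
    if channel not in raw.ch_names:
        raise ValueError(f"channel {channel!r} not found in {path}")
    if abs(raw.info["sfreq"] - sampling_rate) > 1e-6:
        raw = raw.resample(sampling_rate, verbose="error")
    data = raw.get_data(picks=[channel])[0] * 1e6  # volts -> microvolts
    epochs = segment_epochs(data, sampling_rate=sampling_rate)
    if trim is not None:
        epochs = epochs[trim[0] : trim[1]]
    return epochs
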