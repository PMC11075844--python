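"""Surface-EMG conditioning: band-pass, powerline notch, rectification.

The chain reproduces the standard gait-EMG recipe: a 30-300 Hz sixth-order
Butterworth band-pass to remove motion artifact and high-frequency noise, a
60 Hz notch against powerline interference, and full-wave rectification to
expose the neural-drive envelope. Filters are applied forward-backward
(zero phase) by default so that phase-coupling structure, which the
downstream bicoherence stage measures, is not distorted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal
from sklearn.base import BaseEstimator, TransformerMixin

from .records import EmgRecord

__all__ = [
    "FilterConfig",
    "bandpass_filter",
    "notch_filter",
    "rectify",
    "preprocess_chain",
    "EmgPreprocessor",
]


@dataclass(frozen=True)
class FilterConfig:
    """Filter-chain parameters.

    ``band_order`` is the overall band-pass order (even, >= 2); the notch is
    a second-order IIR with -3 dB bandwidth ``notch_freq / notch_q``. Set
    ``notch_freq`` to 0 to disable the notch and ``rectify`` to False to
    stop before rectification. ``zero_phase`` selects forward-backward
    application, which doubles the effective attenuation.
    """

    band_low: float = 30.0
    band_high: float = 300.0
    band_order: int = 6
    notch_freq: float = 60.0
    notch_q: float = 30.0
    zero_phase: bool = True
    rectify: bool = True

    def validate(self, fs: float) -> None:
        if not 0 < self.band_low < self.band_high:
            raise ValueError(
                f"need 0 < band_low < band_high, got {self.band_low}, {self.band_high}"
            )
        if self.band_high >= fs / 2:
            raise ValueError(
                f"band_high = {self.band_high} Hz violates Nyquist at fs = {fs} Hz"
            )
        if self.band_order < 2 or self.band_order % 2:
            raise ValueError(f"band_order must be even and >= 2, got {self.band_order}")
        if self.notch_freq and self.notch_freq >= fs / 2:
            raise ValueError(
                f"notch_freq = {self.notch_freq} Hz violates Nyquist at fs = {fs} Hz"
            )
        if self.notch_q <= 0:
            raise ValueError("notch_q must be positive")


def design_bandpass(config: FilterConfig, fs: float) -> np.ndarray:
    """Second-order sections of the Butterworth band-pass.

    A band-pass of overall order ``band_order`` has ``band_order / 2``
    analogue pole pairs, i.e. ``scipy.signal.butter(band_order // 2, ...)``.
    """
    config.validate(fs)
    return signal.butter(
        config.band_order // 2,
        [config.band_low, config.band_high],
        btype="bandpass",
        fs=fs,
        output="sos",
    )


def design_notch(config: FilterConfig, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """(b, a) of the second-order IIR notch."""
    config.validate(fs)
    return signal.iirnotch(config.notch_freq, config.notch_q, fs=fs)


def _min_length(sos: np.ndarray) -> int:
    # sosfiltfilt needs > 3 * (number of second-order sections * 2) samples
    return 3 * (sos.shape[0] * 2) + 1


def bandpass_filter(record: EmgRecord, config: FilterConfig = FilterConfig()) -> EmgRecord:
    """Butterworth band-pass; zero-phase when ``config.zero_phase``."""
    sos = design_bandpass(config, record.fs)
    if len(record) < _min_length(sos):
        raise ValueError(
            f"signal of length {len(record)} too short for the filter "
            f"(need >= {_min_length(sos)} samples)"
        )
    if config.zero_phase:
        y = signal.sosfiltfilt(sos, record.samples)
    else:
        y = signal.sosfilt(sos, record.samples)
    return record.with_samples(y)


def notch_filter(record: EmgRecord, config: FilterConfig = FilterConfig()) -> EmgRecord:
    """Second-order IIR notch at ``config.notch_freq``; identity if disabled."""
    if not config.notch_freq:
        return record.with_samples(record.samples.copy())
    b, a = design_notch(config, record.fs)
    if config.zero_phase:
        y = signal.filtfilt(b, a, record.samples)
    else:
        y = signal.lfilter(b, a, record.samples)
    return record.with_samples(y)


def rectify(record: EmgRecord) -> EmgRecord:
    """Full-wave rectification: sample-wise absolute value."""
    return record.with_samples(np.abs(record.samples))


def preprocess_chain(record: EmgRecord, config: FilterConfig = FilterConfig()) -> EmgRecord:
    """Band-pass, then notch, then (optionally) rectify. Input unmodified."""
    config.validate(record.fs)
    out = bandpass_filter(record, config)
    out = notch_filter(out, config)
    if config.rectify:
        out = rectify(out)
    return out


class EmgPreprocessor(TransformerMixin, BaseEstimator):
    """Sklearn-style transformer applying the EMG filter chain row-wise.

    Operates on a 2-D array of shape (n_signals, n_samples) sampled at
    ``fs``. Stateless; ``fit`` only validates the configuration.

    Parameters mirror :class:`FilterConfig`.
    """

    def __init__(
        self,
        fs: float = 1500.0,
        band_low: float = 30.0,
        band_high: float = 300.0,
        band_order: int = 6,
        notch_freq: float = 60.0,
        notch_q: float = 30.0,
        zero_phase: bool = True,
        rectify: bool = True,
    ):
        self.fs = fs
        self.band_low = band_low
        self.band_high = band_high
        self.band_order = band_order
        self.notch_freq = notch_freq
        self.notch_q = notch_q
        self.zero_phase = zero_phase
        self.rectify = rectify

    def _config(self) -> FilterConfig:
        return FilterConfig(
            band_low=self.band_low,
            band_high=self.band_high,
            band_order=self.band_order,
            notch_freq=self.notch_freq,
            notch_q=self.notch_q,
            zero_phase=self.zero_phase,
            rectify=self.rectify,
        )

    def fit(self, X, y=None):
        self._config().validate(self.fs)
        self.n_features_in_ = np.asarray(X, dtype=float).shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        config = self._config()
        config.validate(self.fs)
        out = np.empty_like(X)
        for i, row in enumerate(X):
            rec = EmgRecord(samples=row, fs=self.fs)
            out[i] = preprocess_chain(rec, config).samples
        return out
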