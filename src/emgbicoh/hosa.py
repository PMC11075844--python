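"""Higher-order spectral analysis: direct bispectrum and bicoherence.

The bispectrum of a zero-mean signal is the Fourier transform of its
third-order cumulant: a complex function B(f1, f2) that is identically zero
for Gaussian processes and non-zero where triples of Fourier components at
f1, f2 and f1+f2 are phase-coupled. The direct estimator segments the
signal, windows and FFTs each segment, and averages the triple product
X(f1) X(f2) X*(f1+f2) across segments:

    b(f1, f2)  = (1/K) sum_k  Xk(f1) Xk(f2) conj(Xk(f1+f2))
    p12(f1,f2) = (1/K) sum_k |Xk(f1) Xk(f2)|^2
    p3(f1,f2)  = (1/K) sum_k |Xk(f1+f2)|^2

The bicoherence is the normalized magnitude

    bic(f1, f2) = |b| / sqrt(p12 * p3)

which by the Cauchy-Schwarz inequality over segments lies in [0, 1]: it is
1 when the triple-product phase is constant across segments (full quadratic
phase coupling) and tends to 0 as 1/sqrt(K) for independent phases. Index
arithmetic is on the full nfft grid with wrap-around, the convention of the
classic MATLAB higher-order spectra toolbox whose ``bicoher`` routine this
estimator mirrors.

A deliberately naive triple-loop estimator (:func:`bicoherence_bruteforce`)
serves as an independent oracle for the vectorized path on tiny inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import fft as sp_fft
from scipy import signal as sp_signal
from sklearn.base import BaseEstimator, TransformerMixin

from .records import EmgRecord

__all__ = [
    "HosaParams",
    "BispectrumEstimate",
    "BicoherenceMap",
    "EstimationError",
    "segment_signal",
    "bispectrum_direct",
    "bicoherence",
    "bicoherence_bruteforce",
    "average_maps",
    "BicoherenceEstimator",
]


class EstimationError(RuntimeError):
    """The input cannot support a meaningful spectral estimate."""


@dataclass(frozen=True)
class HosaParams:
    """Direct-method estimation parameters.

    At the default fs = 1500 Hz, nfft = seg_len = 128 gives ~11.7 Hz
    frequency bins — coarse but sufficient to localize coupling inside the
    30-300 Hz EMG band — while a 5 s walking trial yields ~115
    half-overlapped segments. Estimator noise scales as 1/sqrt(K), and for
    short per-trial records the variance of the coupling estimate, not
    frequency resolution, is what limits downstream class contrast: longer
    segments sharpen the grid but leave too few independent realizations
    per trial for stable per-trial maps.
    The Hann window controls leakage; ``denom_floor`` masks bins whose
    normalization denominator is below ``denom_floor`` times the maximum
    denominator, avoiding 0/0 at empty bins.
    """

    nfft: int = 128
    seg_len: int = 128
    overlap_frac: float = 0.5
    window: str = "hann"
    denom_floor: float = 1e-12

    def validate(self) -> None:
        if self.seg_len > self.nfft:
            raise ValueError(
                f"seg_len ({self.seg_len}) must not exceed nfft ({self.nfft})"
            )
        if not 0.0 <= self.overlap_frac < 1.0:
            raise ValueError(f"overlap_frac must be in [0, 1), got {self.overlap_frac}")
        if self.denom_floor <= 0:
            raise ValueError("denom_floor must be positive")

    def get_window(self) -> np.ndarray:
        if self.window in ("rect", "boxcar", "rectangular"):
            return np.ones(self.seg_len)
        return sp_signal.get_window(self.window, self.seg_len)


@dataclass
class BispectrumEstimate:
    """Raw direct-method accumulators on the full (nfft x nfft) grid."""

    b: np.ndarray            # complex, segment-averaged triple products
    p12: np.ndarray          # mean |X(f1) X(f2)|^2
    p3: np.ndarray           # mean |X(f1+f2)|^2
    n_segments: int
    freqs: np.ndarray        # Hz per bin, FFT ordering
    params: HosaParams


@dataclass
class BicoherenceMap:
    """Normalized bicoherence in [0, 1] over the bifrequency grid.

    ``mask`` is True where the normalization denominator is informative;
    masked-out bins hold 0.
    """

    values: np.ndarray
    mask: np.ndarray
    freqs: np.ndarray
    n_segments: int
    params: HosaParams = field(default_factory=HosaParams)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def nearest_bin(self, f: float) -> int:
        """Index of the FFT bin closest to frequency ``f`` (Hz)."""
        return int(np.argmin(np.abs(self.freqs - f)))

    def at(self, f1: float, f2: float) -> float:
        """Bicoherence at the bin pair nearest (f1, f2)."""
        return float(self.values[self.nearest_bin(f1), self.nearest_bin(f2)])


def segment_signal(record: EmgRecord, params: HosaParams) -> np.ndarray:
    """Slice into overlapping, mean-subtracted, windowed segments.

    Returns an array of shape (K, seg_len) with
    K = floor((N - seg_len) / step) + 1 and
    step = round(seg_len * (1 - overlap_frac)).
    """
    params.validate()
    x = record.samples
    n = x.size
    if n < params.seg_len:
        raise ValueError(
            f"signal of length {n} shorter than seg_len; need >= {params.seg_len}"
        )
    step = max(1, int(round(params.seg_len * (1.0 - params.overlap_frac))))
    k = (n - params.seg_len) // step + 1
    win = params.get_window()
    segs = np.empty((k, params.seg_len))
    for i in range(k):
        seg = x[i * step : i * step + params.seg_len]
        segs[i] = (seg - seg.mean()) * win
    return segs


def _sum_index(nfft: int) -> np.ndarray:
    idx = np.arange(nfft)
    return (idx[:, None] + idx[None, :]) % nfft


def bispectrum_direct(segments: np.ndarray, params: HosaParams) -> BispectrumEstimate:
    """Segment-averaged triple products and their normalization terms."""
    params.validate()
    segments = np.atleast_2d(np.asarray(segments, dtype=float))
    k = segments.shape[0]
    if k < 2:
        raise EstimationError(f"need at least 2 segments for averaging, got {k}")
    nfft = params.nfft
    sum_idx = _sum_index(nfft)
    b = np.zeros((nfft, nfft), dtype=complex)
    p12 = np.zeros((nfft, nfft))
    p3 = np.zeros((nfft, nfft))
    for seg in segments:
        X = sp_fft.fft(seg, nfft)
        outer = np.multiply.outer(X, X)
        Xs = X[sum_idx]
        b += outer * np.conj(Xs)
        p12 += np.abs(outer) ** 2
        p3 += np.abs(Xs) ** 2
    b /= k
    p12 /= k
    p3 /= k
    freqs = np.fft.fftfreq(nfft) * nfft  # bin units; scaled by fs/nfft by callers
    return BispectrumEstimate(
        b=b, p12=p12, p3=p3, n_segments=k, freqs=freqs, params=params
    )


def _normalize(est: BispectrumEstimate, fs: float) -> BicoherenceMap:
    denom = est.p12 * est.p3
    floor = est.params.denom_floor * denom.max()
    mask = denom >= floor
    values = np.zeros_like(denom)
    np.divide(np.abs(est.b), np.sqrt(denom, where=mask, out=np.ones_like(denom)),
              where=mask, out=values)
    values[~mask] = 0.0
    freqs = np.fft.fftfreq(est.b.shape[0], d=1.0 / fs)
    return BicoherenceMap(
        values=values,
        mask=mask,
        freqs=freqs,
        n_segments=est.n_segments,
        params=est.params,
    )


def bicoherence(record: EmgRecord, params: HosaParams = HosaParams()) -> BicoherenceMap:
    """Direct-method bicoherence of one record."""
    if not np.any(record.samples):
        raise EstimationError("degenerate signal: all samples are zero")
    segments = segment_signal(record, params)
    if segments.shape[0] < 2:
        raise EstimationError(
            f"signal yields only {segments.shape[0]} segment(s); need >= 2"
        )
    est = bispectrum_direct(segments, params)
    return _normalize(est, record.fs)


def bicoherence_bruteforce(
    record: EmgRecord, params: HosaParams = HosaParams()
) -> BicoherenceMap:
    """Triple-loop reference estimator; intended for tiny inputs only.

    Same contract as :func:`bicoherence`, computed with explicit Python
    loops over segments and bin pairs and a naive DFT, with no shared code
    on the numerical path.
    """
    if not np.any(record.samples):
        raise EstimationError("degenerate signal: all samples are zero")
    params.validate()
    x = record.samples
    n = x.size
    if n < params.seg_len:
        raise ValueError(
            f"signal of length {n} shorter than seg_len; need >= {params.seg_len}"
        )
    step = max(1, int(round(params.seg_len * (1.0 - params.overlap_frac))))
    k = (n - params.seg_len) // step + 1
    if k < 2:
        raise EstimationError(f"signal yields only {k} segment(s); need >= 2")
    nfft = params.nfft
    win = params.get_window()
    # naive per-segment DFT
    spectra = []
    for i in range(k):
        seg = x[i * step : i * step + params.seg_len]
        mean = sum(seg) / len(seg)
        seg = [(v - mean) * w for v, w in zip(seg, win)]
        X = []
        for f in range(nfft):
            acc = 0j
            for t_i, v in enumerate(seg):
                acc += v * np.exp(-2j * np.pi * f * t_i / nfft)
            X.append(acc)
        spectra.append(X)
    b = np.zeros((nfft, nfft), dtype=complex)
    p12 = np.zeros((nfft, nfft))
    p3 = np.zeros((nfft, nfft))
    for f1 in range(nfft):
        for f2 in range(nfft):
            f3 = (f1 + f2) % nfft
            for X in spectra:
                triple = X[f1] * X[f2] * np.conj(X[f3])
                b[f1, f2] += triple
                p12[f1, f2] += abs(X[f1] * X[f2]) ** 2
                p3[f1, f2] += abs(X[f3]) ** 2
    b /= k
    p12 /= k
    p3 /= k
    denom = p12 * p3
    floor = params.denom_floor * denom.max()
    values = np.zeros((nfft, nfft))
    mask = np.zeros((nfft, nfft), dtype=bool)
    for f1 in range(nfft):
        for f2 in range(nfft):
            if denom[f1, f2] >= floor:
                mask[f1, f2] = True
                values[f1, f2] = abs(b[f1, f2]) / np.sqrt(denom[f1, f2])
    freqs = np.fft.fftfreq(nfft, d=1.0 / record.fs)
    return BicoherenceMap(
        values=values, mask=mask, freqs=freqs, n_segments=k, params=params
    )


def average_maps(maps: list[BicoherenceMap]) -> BicoherenceMap:
    """Element-wise mean of maps on a common grid; masks are ANDed.

    This is how the pooled "all muscles" condition is formed: one averaged
    map per trial across the per-muscle maps.
    """
    if not maps:
        raise ValueError("need at least one map")
    first = maps[0]
    for m in maps[1:]:
        if m.values.shape != first.values.shape or not np.allclose(
            m.freqs, first.freqs
        ):
            raise ValueError("maps must share the same bifrequency grid")
    values = np.mean([m.values for m in maps], axis=0)
    mask = np.logical_and.reduce([m.mask for m in maps])
    return BicoherenceMap(
        values=values,
        mask=mask,
        freqs=first.freqs.copy(),
        n_segments=min(m.n_segments for m in maps),
        params=first.params,
    )


class BicoherenceEstimator(TransformerMixin, BaseEstimator):
    """Sklearn-style transformer: signals -> bicoherence maps.

    ``transform`` maps an array of shape (n_signals, n_samples) to an array
    of bicoherence values of shape (n_signals, nfft, nfft). Masked bins are
    zero. Use :meth:`transform_maps` to keep full :class:`BicoherenceMap`
    objects (mask, frequency axis, segment count).
    """

    def __init__(
        self,
        fs: float = 1500.0,
        nfft: int = 128,
        seg_len: int = 128,
        overlap_frac: float = 0.5,
        window: str = "hann",
        denom_floor: float = 1e-12,
    ):
        self.fs = fs
        self.nfft = nfft
        self.seg_len = seg_len
        self.overlap_frac = overlap_frac
        self.window = window
        self.denom_floor = denom_floor

    def _params(self) -> HosaParams:
        return HosaParams(
            nfft=self.nfft,
            seg_len=self.seg_len,
            overlap_frac=self.overlap_frac,
            window=self.window,
            denom_floor=self.denom_floor,
        )

    def fit(self, X, y=None):
        self._params().validate()
        return self

    def transform_maps(self, X) -> list[BicoherenceMap]:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        params = self._params()
        return [
            bicoherence(EmgRecord(samples=row, fs=self.fs), params) for row in X
        ]

    def transform(self, X) -> np.ndarray:
        return np.stack([m.values for m in self.transform_maps(X)])
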