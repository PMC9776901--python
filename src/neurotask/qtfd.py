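"""Quadratic time-frequency representations and feature reduction.

The pipeline represents each EEG segment by a quadratic time-frequency
distribution (QTFD).  The chain is: real segment ``s(t)`` -> analytic
signal ``a(t) = s(t) + j H[s](t)`` -> pseudo Wigner-Ville distribution
(WVD)

    WVD_a(t, f) = integral a(t + tau/2) a*(t - tau/2) e^{-j 2 pi tau f} dtau

-> Choi-Williams distribution (CWD), which multiplies the ambiguity
function (the 2-D Fourier dual of the WVD over (doppler, lag)) by the
exponential kernel

    K(phi, tau) = exp(-(phi * tau)^2 / alpha^2)

before transforming to the (time, frequency) plane.  The kernel equals 1
at the ambiguity-plane axes, so auto-terms (which concentrate there) are
preserved, while cross-terms of multicomponent signals (which sit away
from the axes) are attenuated; ``alpha`` controls the suppression
strength and the CWD converges to the WVD as ``alpha -> inf``.

Discretization notes
--------------------
* Pseudo-WVD: integer lags ``m`` correspond to ``tau = 2 m / fs``, so a
  length-``n_fbins`` DFT over the lag axis yields frequencies
  ``f_k = k fs / (2 n_fbins)`` covering ``[0, fs/2)`` — valid for
  analytic input.  A Hann lag window of odd length (centre weight 1)
  limits lag support; ``n_fbins >= window_len`` avoids lag aliasing.
* The grid is scaled so the frequency sum of each interior time slice
  equals ``|a(t)|^2`` (the WVD time marginal).
* In the CWD kernel, doppler is in cycles/sample and lag in samples, so
  ``alpha`` is dimensionless; the default ``alpha = 1`` gives strong
  cross-term suppression at EEG band separations while leaving
  auto-terms intact.

The TFR grid is finally reduced to a fixed-length trial feature vector:
energy integrated over (frequency band x time bin) cells, averaged over
channels, ``log(1 + x)`` compressed and min-max scaled to [0, 1] — the
range the Bernoulli deep-belief-network input layer expects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.fft
import scipy.signal

__all__ = [
    "AnalyticSegment",
    "CWKernelParams",
    "TFRGrid",
    "FeatureScaler",
    "analytic_signal",
    "wigner_ville",
    "choi_williams",
    "segment_channels",
    "extract_features",
    "trial_features",
    "trial_feature_matrix",
    "DEFAULT_BAND_EDGES",
]

#: Standard EEG band edges (Hz): delta, theta, alpha, low beta, high beta, gamma.
DEFAULT_BAND_EDGES = (0.5, 4.0, 8.0, 12.0, 18.0, 26.0, 40.0)


@dataclass
class AnalyticSegment:
    """Complex analytic signal of one real segment; real part equals the input."""

    values: np.ndarray
    fs: float

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class CWKernelParams:
    """Discretization and kernel parameters for the quadratic TFRs.

    ``alpha_kernel`` is the Choi-Williams cross-term suppression
    parameter (the WVD limit is ``alpha_kernel -> inf``); ``window_len``
    the odd pseudo-WVD lag-window length in samples; ``n_fbins`` the
    number of frequency bins on ``[0, fs/2)``.
    """

    alpha_kernel: float = 1.0
    window_len: int = 127
    n_fbins: int = 256

    def __post_init__(self) -> None:
        if self.alpha_kernel <= 0:
            raise ValueError("alpha_kernel must be positive")
        if self.window_len < 3 or self.window_len % 2 == 0:
            raise ValueError("window_len must be odd and >= 3")
        if self.n_fbins < self.window_len:
            raise ValueError("n_fbins must be >= window_len (lag aliasing)")


@dataclass
class TFRGrid:
    """Real (n_time, n_freq) energy matrix with axis vectors in s and Hz."""

    values: np.ndarray
    times: np.ndarray
    freqs: np.ndarray
    kind: str  # {"wvd", "cwd"}

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.times), len(self.freqs)):
            raise ValueError("axis lengths do not match the value matrix")
        if not np.isfinite(self.values).all():
            raise ValueError("TFR grid contains non-finite entries")


def analytic_signal(segment: np.ndarray, fs: float) -> AnalyticSegment:
    """One-sided-spectrum analytic signal via the FFT Hilbert transform."""
    segment = np.asarray(segment)
    if np.iscomplexobj(segment):
        raise TypeError("analytic_signal expects a real-valued segment")
    if segment.ndim != 1 or len(segment) < 4:
        raise ValueError("segment must be 1-D with at least 4 samples")
    return AnalyticSegment(scipy.signal.hilbert(segment.astype(np.float64)), fs)


def _lag_autocorr(batch: np.ndarray, params: CWKernelParams) -> np.ndarray:
    """Windowed instantaneous autocorrelation for a batch of segments.

    ``batch`` is (B, n_samples) complex; returns ``r[b, l, n] =
    w[m] a[n+m] a*[n-m]`` with FFT-ordered lag rows (l = m for m >= 0,
    l = n_fbins + m for m < 0) and time columns.  Out-of-range products
    are zero-padded.
    """
    b, n = batch.shape
    if params.window_len > n:
        raise ValueError("window_len exceeds the segment length")
    half = params.window_len // 2
    win = scipy.signal.windows.hann(params.window_len, sym=True)
    win = win / win[half]  # centre weight 1 keeps the time marginal exact
    r = np.zeros((b, params.n_fbins, n), dtype=complex)
    r[:, 0] = (batch * np.conj(batch)) * win[half]
    for m in range(1, half + 1):
        # prod[:, t] = a[t+m] a*[t-m], defined for t in [m, n-1-m]
        prod = np.zeros((b, n), dtype=complex)
        prod[:, m:n - m] = batch[:, 2 * m:] * np.conj(batch[:, :n - 2 * m])
        r[:, m] = prod * win[half + m]
        r[:, params.n_fbins - m] = np.conj(prod) * win[half - m]
    return r


def _tfr_batch(batch: np.ndarray, params: CWKernelParams,
               kind: str) -> np.ndarray:
    """(B, n_time, n_freq) grids for a batch of analytic segments."""
    r = _lag_autocorr(batch, params)
    if kind == "cwd":
        n = batch.shape[1]
        # ambiguity function: DFT over the time axis
        amb = scipy.fft.fft(r, axis=2, overwrite_x=True)
        doppler = np.fft.fftfreq(n)  # cycles / sample
        half = params.window_len // 2
        lags = np.fft.fftfreq(params.n_fbins, d=1.0 / params.n_fbins)
        lags = np.where(np.abs(lags) <= half, lags, 0.0)  # signed lag m
        amb *= np.exp(-np.outer(lags, doppler) ** 2
                      / params.alpha_kernel ** 2)[None]
        r = scipy.fft.ifft(amb, axis=2, overwrite_x=True)
    spec = scipy.fft.fft(r, axis=1, overwrite_x=True)  # over lag -> frequency
    return np.real(spec).swapaxes(1, 2) / params.n_fbins


def _axes(n_samples: int, fs: float,
          params: CWKernelParams) -> tuple[np.ndarray, np.ndarray]:
    times = np.arange(n_samples) / fs
    # integer lag m corresponds to tau = 2m/fs, hence the factor 2
    freqs = np.arange(params.n_fbins) * fs / (2 * params.n_fbins)
    return times, freqs


def wigner_ville(a: AnalyticSegment, params: CWKernelParams) -> TFRGrid:
    """Discrete pseudo-WVD with a Hann lag window."""
    values = _tfr_batch(np.asarray(a.values)[None], params, "wvd")[0]
    times, freqs = _axes(len(a), a.fs, params)
    return TFRGrid(values, times, freqs, "wvd")


def choi_williams(a: AnalyticSegment, params: CWKernelParams) -> TFRGrid:
    """Choi-Williams distribution via exponential-kernel ambiguity filtering."""
    values = _tfr_batch(np.asarray(a.values)[None], params, "cwd")[0]
    times, freqs = _axes(len(a), a.fs, params)
    return TFRGrid(values, times, freqs, "cwd")


def segment_channels(trial: np.ndarray, fs: float, win_len: float,
                     hop: float) -> list[list[np.ndarray]]:
    """Half-open sliding windows per channel.

    Returns one list of 1-D segments per channel;
    ``floor((T - win_len)/hop) + 1`` segments each.
    """
    trial = np.atleast_2d(np.asarray(trial, dtype=np.float64))
    if trial.shape[0] < trial.shape[1]:
        raise ValueError("trial must be sample-major (time on the first axis)")
    if hop <= 0:
        raise ValueError("hop must be positive")
    n_samples = trial.shape[0]
    n_win = int(round(win_len * fs))
    n_hop = int(round(hop * fs))
    if n_win > n_samples:
        raise ValueError("win_len exceeds the trial duration")
    n_segments = (n_samples - n_win) // n_hop + 1
    out = []
    for ch in range(trial.shape[1]):
        x = trial[:, ch]
        out.append([x[i * n_hop:i * n_hop + n_win].copy()
                    for i in range(n_segments)])
    return out


@dataclass
class FeatureScaler:
    """Min-max scaling to [0, 1], frozen on a training feature matrix.

    ``mode="global"`` (default) uses a single min/max over the whole
    training matrix, preserving the relative energy scale between
    components — a cell that carries little energy on every training
    trial stays small.  ``mode="per_component"`` rescales each component
    to its own training range; note this equalizes low- and high-energy
    cells, which can bury the class contrast under noise components once
    the DBN compresses the vector.  Values outside the training range
    (routine for out-of-class test trials) are clipped, keeping the
    output inside the [0, 1] interval the Bernoulli DBN input expects.
    """

    mode: str = "global"
    min_: np.ndarray = field(default_factory=lambda: np.empty(0))
    max_: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        if self.mode not in ("global", "per_component"):
            raise ValueError("mode must be 'global' or 'per_component'")

    def fit(self, features: np.ndarray) -> "FeatureScaler":
        features = np.atleast_2d(features)
        if self.mode == "global":
            self.min_ = np.full(features.shape[1], features.min())
            self.max_ = np.full(features.shape[1], features.max())
        else:
            self.min_ = features.min(axis=0)
            self.max_ = features.max(axis=0)
        return self

    def transform(self, features: np.ndarray) -> np.ndarray:
        span = np.where(self.max_ > self.min_, self.max_ - self.min_, 1.0)
        scaled = (features - self.min_) / span
        return np.clip(scaled, 0.0, 1.0)


def extract_features(grids: list[TFRGrid], band_edges=DEFAULT_BAND_EDGES,
                     n_time_bins: int = 5) -> np.ndarray:
    """Reduce one trial's per-channel TFR grids to a raw feature vector.

    Per channel, positive TFR energy is integrated into
    ``(len(band_edges) - 1) x n_time_bins`` cells (contiguous time
    chunks), cells are averaged across channels and ``log1p``
    compressed.  Min-max scaling to [0, 1] is a separate, train-set-only
    step (:class:`FeatureScaler`).
    """
    band_edges = np.asarray(band_edges, dtype=float)
    if (np.diff(band_edges) <= 0).any():
        raise ValueError("band_edges must be strictly increasing")
    n_bands = len(band_edges) - 1
    cells = np.zeros((n_bands, n_time_bins))
    for grid in grids:
        energy = np.clip(grid.values, 0.0, None)  # auto-term (positive) energy
        band_idx = np.searchsorted(band_edges, grid.freqs, side="right") - 1
        for b in range(n_bands):
            col = energy[:, band_idx == b].sum(axis=1)
            for t, chunk in enumerate(np.array_split(col, n_time_bins)):
                cells[b, t] += chunk.sum()
    cells /= max(len(grids), 1)
    return np.log1p(cells).ravel()


def trial_features(trial: np.ndarray, fs: float, params: CWKernelParams,
                   win_len: float = 1.0, hop: float = 1.0,
                   band_edges=DEFAULT_BAND_EDGES, n_time_bins: int = 5,
                   kind: str = "cwd") -> np.ndarray:
    """Full per-trial reduction: segment -> analytic -> CWD -> band/time cells."""
    per_channel = segment_channels(trial, fs, win_len, hop)
    n_channels, n_segments = len(per_channel), len(per_channel[0])
    batch = np.stack([scipy.signal.hilbert(seg)
                      for segments in per_channel for seg in segments])
    values = _tfr_batch(batch, params, kind)
    _, freqs = _axes(batch.shape[1], fs, params)
    seg_times, _ = _axes(batch.shape[1], fs, params)
    grids = []
    for ch in range(n_channels):
        rows = values[ch * n_segments:(ch + 1) * n_segments]
        times = np.concatenate([seg_times + k * hop for k in range(n_segments)])
        grids.append(TFRGrid(np.vstack(rows), times, freqs, kind))
    return extract_features(grids, band_edges, n_time_bins)


def trial_feature_matrix(trialset, params: CWKernelParams | None = None,
                         win_len: float = 1.0, hop: float = 1.0,
                         band_edges=DEFAULT_BAND_EDGES,
                         n_time_bins: int = 5) -> np.ndarray:
    """Raw (pre-scaling) feature matrix for every trial in a TrialSet."""
    if params is None:
        params = CWKernelParams()
    rows = [trial_features(seg, trialset.fs, params, win_len, hop,
                           band_edges, n_time_bins)
            for seg, _ in trialset.trials]
    return np.vstack(rows)
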