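"""Multichannel Wiener filter (MWF) artifact removal.

EEG artifacts such as electrode glitches and blinks are spatially
focused and much larger than the neural background.  The MWF estimates
the artifact component from second-order statistics: a covariance matrix
``Ryy`` over artifact-contaminated samples and ``Rvv`` over clean
samples.  A generalized eigenvalue decomposition (GEVD) of the pair
``Ryy v = lambda Rvv v`` diagonalizes both; components whose generalized
eigenvalue exceeds one carry more power during artifact segments than
during clean ones, and the artifact covariance is approximated by a
low-rank reconstruction from those components.  The resulting spatial
Wiener filter ``W = Ryy^{-1} (Ryy - Rvv_hat)`` estimates the artifact
signal, which is subtracted samplewise.

The filter is spatial only (no delay taps) — the covariances stay
``n_channels`` square and the per-recording fit is cheap.  Artifact
segments can be supplied by the caller or marked automatically with a
robust amplitude threshold (:func:`mark_artifacts`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .signal_io import Recording

__all__ = ["MWFModel", "mark_artifacts", "fit_mwf", "apply_mwf"]

#: Eigenvalue floor used to keep both covariance matrices positive definite.
_EIG_FLOOR = 1e-10


@dataclass
class MWFModel:
    """Fitted spatial Wiener filter.

    ``W`` acts on channel (row) vectors: the artifact estimate for sample
    ``y`` is ``W @ y``.  ``gevd_values`` are the generalized eigenvalues
    sorted descending; ``rank`` is the number of retained components.
    """

    W: np.ndarray
    rank: int
    gevd_values: np.ndarray

    @property
    def n_channels(self) -> int:
        return self.W.shape[0]


def mark_artifacts(rec: Recording, z_threshold: float = 5.0,
                   window_len: float = 0.5) -> np.ndarray:
    """Flag high-amplitude windows with a per-channel robust z-score.

    The recording is tiled into non-overlapping ``window_len``-second
    windows; for every window and channel the peak absolute amplitude is
    taken, z-scored robustly per channel (median/MAD across windows), and
    the whole window is masked when any channel exceeds ``z_threshold``.
    """
    if z_threshold <= 0:
        raise ValueError("z_threshold must be positive")
    n_win = int(round(window_len * rec.fs))
    if rec.n_samples < n_win:
        raise ValueError("recording is shorter than one marking window")
    n_windows = rec.n_samples // n_win
    peaks = np.empty((n_windows, rec.n_channels))
    for w in range(n_windows):
        seg = rec.data[w * n_win:(w + 1) * n_win]
        peaks[w] = np.abs(seg).max(axis=0)
    med = np.median(peaks, axis=0)
    mad = np.median(np.abs(peaks - med), axis=0)
    scale = 1.4826 * mad + 1e-12
    z = (peaks - med) / scale
    flagged = (z > z_threshold).any(axis=1)
    mask = np.zeros(rec.n_samples, dtype=bool)
    for w in np.flatnonzero(flagged):
        mask[w * n_win:(w + 1) * n_win] = True
    return mask


def _symmetrized_cov(x: np.ndarray) -> np.ndarray:
    c = np.cov(x, rowvar=False)
    c = np.atleast_2d(c)
    c = 0.5 * (c + c.T)
    # clip tiny/negative eigenvalues so the GEVD is well-posed
    vals, vecs = np.linalg.eigh(c)
    vals = np.clip(vals, _EIG_FLOOR, None)
    return (vecs * vals) @ vecs.T


def fit_mwf(rec: Recording, mask: np.ndarray,
            rank_rule: str = "eig_gt_one") -> MWFModel:
    """Fit the spatial MWF from artifact-masked vs clean samples.

    ``rank_rule`` is either ``"eig_gt_one"`` (retain GEVD components whose
    generalized eigenvalue exceeds 1 — artifact power above clean power)
    or ``"fixed:r"`` for a fixed retained rank ``r``.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != (rec.n_samples,):
        raise ValueError("mask length must equal the number of samples")
    c = rec.n_channels
    n_art, n_clean = int(mask.sum()), int((~mask).sum())
    if n_art < 10 * c or n_clean < 10 * c:
        raise ValueError(
            f"need >= {10 * c} artifact and clean samples each "
            f"(got {n_art} artifact, {n_clean} clean)"
        )
    Ryy = _symmetrized_cov(rec.data[mask])
    Rvv = _symmetrized_cov(rec.data[~mask])

    # GEVD: Ryy V = Rvv V diag(lam);  V^T Rvv V = I
    lam, V = scipy.linalg.eigh(Ryy, Rvv)
    order = np.argsort(lam)[::-1]
    lam, V = lam[order], V[:, order]

    if rank_rule == "eig_gt_one":
        keep = lam > 1.0
    elif rank_rule.startswith("fixed:"):
        r = int(rank_rule.split(":", 1)[1])
        if not 0 <= r <= c:
            raise ValueError(f"fixed rank must be in [0, {c}]")
        keep = np.zeros(c, dtype=bool)
        keep[:r] = True
    else:
        raise ValueError(f"unknown rank_rule {rank_rule!r}")

    # W = Ryy^{-1} (Ryy - Rvv_hat) = V diag((lam-1)/lam on kept, else 0) V^{-1}
    gains = np.where(keep, (lam - 1.0) / lam, 0.0)
    Vinv = np.linalg.inv(V)
    W = (V * gains) @ Vinv
    return MWFModel(W=W, rank=int(keep.sum()), gevd_values=lam)


def apply_mwf(rec: Recording, model: MWFModel) -> Recording:
    """Subtract the filter's artifact estimate; shape and metadata unchanged."""
    if rec.n_channels != model.n_channels:
        raise ValueError(
            f"recording has {rec.n_channels} channels, filter expects "
            f"{model.n_channels}"
        )
    artifact = rec.data @ model.W.T
    return Recording(rec.data - artifact, rec.fs, list(rec.channel_labels),
                     list(rec.markers) if rec.markers else None)
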