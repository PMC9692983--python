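"""Robust fusion of candidate raw signals into one respiratory signal.

Not every candidate signal in an observation matrix is driven by
respiration — some contain motion artifacts or pure noise.  Fusion proceeds
in two stages:

1. **Correlation gating**: respiratory activity is assumed to induce high
   mutual correlation among the signals that observe it.  Each signal is
   scored by its mean correlation with all signals (including itself,
   ``rho_mu_i = sum_j rho_ji / n``) and only the best ``keep`` columns are
   retained.
2. **Moving-window PCA**: within a sliding window (default 30 s, hop one
   sample) the retained signals are mean-centered and their first principal
   component direction is estimated.  Because a principal direction is only
   defined up to sign, the coefficient signs are aligned from window to
   window using the sign of each coefficient column's sum, which removes
   the sign-flip discontinuities a naive moving PCA produces.  The fused
   sample is the projection of the current (centered) observation row onto
   the aligned first principal direction.
"""

from __future__ import annotations

import warnings

import numpy as np

from .signals import RespiratorySignal
from .video_extract import ObservationMatrix

__all__ = ["select_top_correlated", "fuse_moving_pca", "fuse_observations"]


def select_top_correlated(O: ObservationMatrix, keep: int = 5) -> ObservationMatrix:
    """Keep the ``keep`` columns with the largest mean correlation.

    Zero-variance columns (undefined correlation) are scored ``-inf`` and
    excluded.  If ``keep`` exceeds the number of columns, all columns are
    returned with a warning.
    """
    X = O.values[O.frame_valid]
    n = O.n_signals
    if n < 1:
        raise ValueError("observation matrix has no columns")
    if keep > n:
        warnings.warn(f"keep={keep} exceeds n={n}; returning all columns")
        keep = n

    sd = X.std(axis=0)
    score = np.full(n, -np.inf)
    ok = sd > 1e-12
    if ok.sum() >= 1:
        with np.errstate(invalid="ignore"):
            rho = np.corrcoef(X[:, ok].T)
        rho = np.atleast_2d(rho)
        # mean over all n signals as defined; absent (zero-variance)
        # partners contribute nothing
        score[ok] = np.nansum(rho, axis=1) / n
    order = np.argsort(score)[::-1]
    sel = [i for i in order[:keep] if np.isfinite(score[i])]
    if not sel:
        raise ValueError("no column with finite correlation score")
    sel = np.sort(sel)
    return ObservationMatrix(
        values=O.values[:, sel],
        fs=O.fs,
        source_kind=O.source_kind,
        frame_valid=O.frame_valid.copy(),
    )


def _window_pca(Wc: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Full PCA loading matrix (columns = components) of a centered window."""
    U, S, Vt = np.linalg.svd(Wc, full_matrices=False)
    return Vt.T, S


def fuse_moving_pca(
    Omax: ObservationMatrix,
    window_length: float = 30.0,
    align_signs: bool = True,
) -> RespiratorySignal:
    """Fuse an observation matrix into one signal via moving-window PCA.

    ``align_signs=False`` disables the window-to-window sign correction and
    exists only to demonstrate/ablate the discontinuities it prevents.
    The trailing ``wl - 1`` samples reuse the last complete window's
    principal direction.  Windows with (numerically) constant data produce
    zero samples flagged invalid.
    """
    X = Omax.values
    m, n = X.shape
    fs = Omax.fs
    wl = int(round(window_length * fs))
    if wl < 2:
        raise ValueError("window must span at least 2 samples")
    if m < wl:
        raise ValueError(f"signal length {m} shorter than window {wl}")

    s = np.zeros(m)
    valid = np.ones(m, dtype=bool)
    prev_C: np.ndarray | None = None
    last_mu: np.ndarray | None = None
    last_c1: np.ndarray | None = None

    def colsign(C: np.ndarray) -> np.ndarray:
        cs = np.sign(C.sum(axis=0))
        cs[cs == 0] = 1.0  # tie-break toward +1
        return cs

    for k in range(m - wl + 1):
        W = X[k : k + wl]
        mu = W.mean(axis=0)
        Wc = W - mu
        if float(np.abs(Wc).max(initial=0.0)) < 1e-12:
            s[k] = 0.0
            valid[k] = False
            continue
        C, S = _window_pca(Wc)
        if align_signs:
            if prev_C is not None:
                D = colsign(C) * colsign(prev_C)
                C = C * D[None, :]
            prev_C = C
        s[k] = (X[k] - mu) @ C[:, 0]
        last_mu, last_c1 = mu, C[:, 0]

    if last_c1 is None:
        return RespiratorySignal(samples=s, fs=fs, valid=np.zeros(m, dtype=bool))
    for k in range(m - wl + 1, m):
        s[k] = (X[k] - last_mu) @ last_c1

    valid &= Omax.frame_valid
    return RespiratorySignal(samples=s, fs=fs, valid=valid)


def fuse_observations(
    O: ObservationMatrix,
    keep: int = 5,
    window_length: float = 30.0,
) -> RespiratorySignal:
    """Correlation gating followed by moving-window PCA fusion."""
    return fuse_moving_pca(select_top_correlated(O, keep=keep), window_length=window_length)
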