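"""Windowed comparison features and correlation-based selection.

The classical (non-end-to-end) pipeline: component mixing (a pluggable
matrix, identity by default, standing in for a statistically independent
decomposition), short rectangular windows over each epoch, per-window
spectral and summary-statistic features — including a circular
autocorrelation computed through the FFT (Wiener-Khinchin),

    ACF(w) = iFFT(|FFT(w)|^2)

— and feature selection by Pearson correlation with a continuous target
under a Bonferroni-corrected significance level plus an |r| floor.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sstats
from statsmodels.tsa.stattools import levinson_durbin

logger = logging.getLogger(__name__)

__all__ = [
    "WindowPlan",
    "FeatureTable",
    "SelectionRule",
    "plan_windows",
    "acf",
    "window_features",
    "assemble_features",
    "select_features",
    "DEFAULT_KINDS",
]

DEFAULT_KINDS = (
    "mean",
    "abs_mean",
    "quadratic_mean",
    "nonzero_mean",
    "nonzero_abs_mean",
    "nonzero_quadratic_mean",
    "variance",
    "skewness",
    "kurtosis",
    "rms",
    "log_energy",
)


@dataclass(frozen=True)
class WindowPlan:
    """Rectangular analysis windows: lengths in milliseconds."""

    window_length: float = 50.0
    overlap: float = 25.0

    def __post_init__(self):
        if not (0 < self.overlap < self.window_length):
            raise ValueError("need 0 < overlap < window_length")

    @property
    def hop(self) -> float:
        return self.window_length - self.overlap


@dataclass(frozen=True)
class SelectionRule:
    """Bonferroni-corrected Pearson selection."""

    alpha: float = 1e-5
    r_min: float = 0.2

    def __post_init__(self):
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if not (0 <= self.r_min < 1):
            raise ValueError("r_min must be in [0, 1)")


@dataclass
class FeatureTable:
    matrix: np.ndarray  # (n_trials, n_features)
    names: list
    provenance: dict

    def __post_init__(self):
        if len(self.names) != self.matrix.shape[1]:
            raise ValueError("names must match matrix columns")
        if len(set(self.names)) != len(self.names):
            raise ValueError("feature names must be unique")


def plan_windows(epoch_length: float, plan: WindowPlan) -> np.ndarray:
    """(start, end) pairs in ms for rectangular windows over an epoch.

    hop = window_length - overlap; count = floor((epoch - window)/hop) + 1,
    so a 2000 ms epoch at 50/25 ms yields 79 windows.
    """
    if epoch_length < plan.window_length:
        raise ValueError("epoch shorter than window")
    count = int(np.floor((epoch_length - plan.window_length) / plan.hop)) + 1
    starts = np.arange(count) * plan.hop
    return np.stack([starts, starts + plan.window_length], axis=1)


def acf(window) -> np.ndarray:
    """Circular autocorrelation through the FFT: iFFT(|FFT(w)|^2)."""
    w = np.asarray(window, dtype=np.float64)
    if w.size == 0:
        raise ValueError("empty window")
    return np.fft.ifft(np.abs(np.fft.fft(w)) ** 2).real


def _lpc(w: np.ndarray, order: int) -> np.ndarray:
    """LPC coefficients via the autocorrelation (Levinson-Durbin) method."""
    if np.allclose(w, w[0]):
        return np.zeros(order)
    _, arcoefs, *_ = levinson_durbin(w - w.mean(), nlags=order, isacov=False)
    return np.asarray(arcoefs, dtype=np.float64)


def window_features(
    window, kinds=DEFAULT_KINDS, n_fft: int = 8, lpc_order: int = 4, fft_mode: str = "truncate"
) -> dict:
    """Named features of one window.

    Scalar kinds are the summary statistics; "fft" yields ``n_fft // 2 + 1``
    magnitude bins (the window truncated, or zero-padded, to ``n_fft``
    samples per ``fft_mode``); "lpc" yields ``lpc_order`` linear-predictive
    coefficients; "acf" yields the circular autocorrelation sequence.
    """
    w = np.asarray(window, dtype=np.float64)
    if w.size == 0:
        raise ValueError("empty window")
    out = {}
    nz = w[w != 0]
    for kind in kinds:
        if kind == "mean":
            out[kind] = float(w.mean())
        elif kind == "abs_mean":
            out[kind] = float(np.abs(w).mean())
        elif kind == "quadratic_mean" or kind == "rms":
            out[kind] = float(np.sqrt(np.mean(w**2)))
        elif kind == "nonzero_mean":
            out[kind] = float(nz.mean()) if nz.size else 0.0
        elif kind == "nonzero_abs_mean":
            out[kind] = float(np.abs(nz).mean()) if nz.size else 0.0
        elif kind == "nonzero_quadratic_mean":
            out[kind] = float(np.sqrt(np.mean(nz**2))) if nz.size else 0.0
        elif kind == "variance":
            out[kind] = float(w.var())
        elif kind in ("skewness", "kurtosis"):
            if np.allclose(w, w[0]):
                # moment ratios undefined for a constant window
                logger.warning("%s of a constant window set to 0", kind)
                out[kind] = 0.0
            else:
                fn = sstats.skew if kind == "skewness" else sstats.kurtosis
                out[kind] = float(fn(w))
        elif kind == "log_energy":
            out[kind] = float(np.log(np.sum(w**2) + 1e-20))
        elif kind == "fft":
            seg = w[:n_fft] if fft_mode == "truncate" else w
            mags = np.abs(np.fft.rfft(seg, n=n_fft))
            for i, m in enumerate(mags):
                out[f"fft{i}"] = float(m)
        elif kind == "lpc":
            for i, c in enumerate(_lpc(w, lpc_order)):
                out[f"lpc{i}"] = float(c)
        elif kind == "acf":
            for i, v in enumerate(acf(w)):
                out[f"acf{i}"] = float(v)
        else:
            raise ValueError(f"unknown feature kind {kind!r}")
    return out


def assemble_features(
    ts,
    plan: WindowPlan,
    kinds=DEFAULT_KINDS,
    mixing: np.ndarray = None,
    n_fft: int = 8,
    lpc_order: int = 4,
) -> FeatureTable:
    """Per-trial feature table across components and windows.

    ``mixing`` (C x M) maps channels to components before windowing
    (identity by default; a statistically independent decomposition can be
    injected here).  Column names are ``c{component}_w{window}_{kind}``.
    """
    if not kinds:
        raise ValueError("no feature kinds requested")
    data = ts.data  # (n, T, C)
    if mixing is not None:
        mixing = np.asarray(mixing, dtype=np.float64)
        if mixing.shape[0] != data.shape[2]:
            raise ValueError("mixing matrix rows must equal channel count")
        data = data @ mixing
    n, T, M = data.shape
    windows_ms = plan_windows(T / ts.sampling_rate * 1000.0, plan)
    idx = np.round(windows_ms / 1000.0 * ts.sampling_rate).astype(int)
    rows, names = [], None
    for i in range(n):
        feats = {}
        for m in range(M):
            for wi, (a, b) in enumerate(idx):
                vals = window_features(data[i, a:b, m], kinds, n_fft, lpc_order)
                for k, v in vals.items():
                    feats[f"c{m}_w{wi}_{k}"] = v
        if names is None:
            names = list(feats)
        rows.append([feats[k] for k in names])
    matrix = np.asarray(rows, dtype=np.float64) if rows else np.empty((0, 0))
    bad = ~np.isfinite(matrix)
    if bad.any():
        logger.warning("imputing %d non-finite feature values with 0", int(bad.sum()))
        matrix[bad] = 0.0
    prov = {
        "kinds": list(kinds),
        "window_ms": plan.window_length,
        "overlap_ms": plan.overlap,
        "n_components": M,
        "n_windows": len(idx),
    }
    return FeatureTable(matrix, names or [], prov)


def select_features(table: FeatureTable, target, rule: SelectionRule = SelectionRule()):
    """Columns passing Bonferroni-corrected Pearson significance and |r| floor.

    A column is selected when its Pearson p-value < alpha / n_features and
    |r| > r_min.  Constant columns are excluded with a warning (undefined r).
    Returns (selected_indices, r_values, p_values).
    """
    y = np.asarray(target, dtype=np.float64)
    X = table.matrix
    if X.shape[0] < 3:
        raise ValueError("need at least 3 trials")
    if len(y) != X.shape[0]:
        raise ValueError("target length mismatch")
    n_feat = X.shape[1]
    rs = np.full(n_feat, np.nan)
    ps = np.full(n_feat, np.nan)
    for j in range(n_feat):
        col = X[:, j]
        if np.allclose(col, col[0]):
            logger.warning("constant feature column %r excluded", table.names[j])
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r, p = sstats.pearsonr(col, y)
        rs[j], ps[j] = r, p
    thresh = rule.alpha / max(n_feat, 1)
    selected = np.flatnonzero((ps < thresh) & (np.abs(rs) > rule.r_min))
    return selected, rs, ps
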