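"""Per-epoch feature extraction from MODWT coefficients.

Five feature families are computed for every 10-s epoch:

* wavelet variance (VA) and interquartile range (IQR) per channel and
  retained layer — spectral power / dispersion at that scale;
* Pearson correlation (PCC) and Hoeffding's D per unordered channel
  pair and retained layer — linear and general inter-channel
  dependence, i.e. synchronization at that scale;
* permutation entropy (PE) per channel on the raw (untransformed)
  epoch — ordinal-pattern complexity of the time series.

All wavelet-coefficient statistics are computed on the non-boundary
coefficients ``t >= L_j - 1`` only, so circular wrap-around artefacts
never enter a feature.  With 16 channels (120 unordered pairs) and
``j`` retained layers the feature count is ``16*j*2 + 120*j*2 + 16 =
272*j + 16``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import factorial

import numpy as np
import pandas as pd
from scipy import stats

from .modwt import WaveletFilter, get_filter, max_level, modwt_decompose
from .preprocess import Epoch

__all__ = [
    "FeatureConfig",
    "wavelet_variance",
    "wavelet_pcc",
    "wavelet_iqr",
    "hoeffding_d",
    "permutation_entropy",
    "retained_layers_for",
    "extract_epoch_features",
    "build_feature_table",
    "feature_count",
    "METADATA_COLUMNS",
]

METADATA_COLUMNS = ("subject_id", "label")


def _nonboundary(w: np.ndarray, Lj: int) -> np.ndarray:
    core = np.asarray(w, dtype=float)[..., Lj - 1 :]
    if core.shape[-1] < 1:
        raise ValueError(f"no non-boundary coefficients: N < Lj = {Lj}")
    return core


def wavelet_variance(w: np.ndarray, Lj: int) -> float:
    """Boundary-excluded wavelet variance: mean square of ``w[t]`` over
    ``t = Lj-1 .. N-1`` (the ``M_j = N - Lj + 1`` wrap-free coefficients).

    Wavelet coefficients have zero mean by construction (the wavelet
    filter sums to zero), so the mean square estimates the variance at
    that scale.
    """
    core = _nonboundary(w, Lj)
    return float(np.mean(core**2))


def wavelet_pcc(wx: np.ndarray, wy: np.ndarray, Lj: int) -> float:
    """Pearson correlation of two coefficient series over the
    non-boundary region, NaN if either series is constant there."""
    cx = _nonboundary(wx, Lj)
    cy = _nonboundary(wy, Lj)
    if cx.shape != cy.shape:
        raise ValueError("coefficient series differ in length")
    if cx.size < 2:
        raise ValueError("need at least two non-boundary coefficients")
    dx = cx - cx.mean()
    dy = cy - cy.mean()
    denom = np.sqrt((dx**2).sum() * (dy**2).sum())
    if denom == 0:
        return float("nan")
    return float(np.clip((dx * dy).sum() / denom, -1.0, 1.0))


def wavelet_iqr(w: np.ndarray, Lj: int) -> float:
    """Interquartile range (P75 - P25, linear-interpolation quantiles)
    of the non-boundary coefficients."""
    core = _nonboundary(w, Lj)
    if core.size < 2:
        raise ValueError("need at least two non-boundary coefficients")
    p75, p25 = np.percentile(core, [75, 25])
    return float(p75 - p25)


def _bivariate_u(x: np.ndarray) -> np.ndarray:
    """u(x_i - x_j) matrix with u(t>0)=1, u(0)=1/2, u(t<0)=0."""
    gt = (x[:, None] > x[None, :]).astype(np.float64)
    eq = (x[:, None] == x[None, :]).astype(np.float64)
    return gt + 0.5 * eq


def _hoeffding_from_ranks(r: np.ndarray, s: np.ndarray, q: np.ndarray) -> float:
    n = len(r)
    d1 = np.sum((q - 1.0) * (q - 2.0))
    d2 = np.sum((r - 1.0) * (r - 2.0) * (s - 1.0) * (s - 2.0))
    d3 = np.sum((r - 2.0) * (s - 2.0) * (q - 1.0))
    num = (n - 2) * (n - 3) * d1 + d2 - 2 * (n - 2) * d3
    den = n * (n - 1) * (n - 2) * (n - 3) * (n - 4)
    return float(30.0 * num / den)


def hoeffding_d(x: np.ndarray, y: np.ndarray) -> float:
    """Hoeffding's D statistic of dependence, scaled by 30.

    A rank statistic sensitive to any form of bivariate dependence (not
    only monotone); 1 for perfect functional dependence on untied data,
    near 0 under independence (it may be slightly negative).  Ties are
    handled with midranks: the bivariate rank ``Q_i`` counts points in
    the lower-left quadrant of point i, ties weighted by halves.
    Requires at least 5 pairs.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError("x and y must be the same length")
    n = len(x)
    if n < 5:
        raise ValueError("Hoeffding's D requires at least 5 pairs")
    r = stats.rankdata(x)
    s = stats.rankdata(y)
    ux = _bivariate_u(x)
    uy = _bivariate_u(y)
    # diagonal contributes u(0)*u(0) = 1/4 but the sum excludes j = i
    q = 1.0 + (ux * uy).sum(axis=1) - 0.25
    return _hoeffding_from_ranks(r, s, q)


def _hoeffding_all_pairs(data: np.ndarray) -> np.ndarray:
    """Hoeffding's D for every pair of rows of ``data`` (k x n).

    Batched form of :func:`hoeffding_d`: the quadrant counts Q for all
    row pairs are obtained as per-sample Gram matrices of the stacked
    u-matrices, so the cost is one (n,k,n)x(n,n,k) batched product
    instead of k^2/2 separate double loops.
    """
    data = np.asarray(data, dtype=float)
    k, n = data.shape
    if n < 5:
        raise ValueError("Hoeffding's D requires at least 5 samples")
    ranks = np.vstack([stats.rankdata(row) for row in data])
    u = np.empty((k, n, n), dtype=np.float32)
    for c in range(k):
        rc = ranks[c]
        u[c] = (rc[:, None] > rc[None, :]).astype(np.float32)
        ties = rc[:, None] == rc[None, :]
        if ties.sum() > n:  # off-diagonal ties present
            u[c] += 0.5 * ties.astype(np.float32)
        else:
            u[c][np.diag_indices(n)] = 0.5
    # G[i, a, b] = sum_j u[a, i, j] * u[b, i, j]
    b = u.transpose(1, 0, 2)  # (n, k, n)
    g = (b @ b.transpose(0, 2, 1)).astype(np.float64)  # (n, k, k)
    q = 1.0 + g.transpose(1, 2, 0) - 0.25  # (k, k, n)

    p1 = (ranks - 1.0) * (ranks - 2.0)
    d1 = ((q - 1.0) * (q - 2.0)).sum(axis=2)
    d2 = p1 @ p1.T
    d3 = np.einsum("ai,bi,abi->ab", ranks - 2.0, ranks - 2.0, q - 1.0)
    num = (n - 2) * (n - 3) * d1 + d2 - 2 * (n - 2) * d3
    den = n * (n - 1) * (n - 2) * (n - 3) * (n - 4)
    return 30.0 * num / den


def permutation_entropy(x: np.ndarray, m: int = 3, tau: int = 1) -> float:
    """Normalized permutation entropy of a series, in [0, 1].

    Shannon entropy of the empirical distribution of ordinal patterns
    of ``m`` samples at delay ``tau``, normalized by ``ln m!``; 0 for a
    strictly monotone series (a single pattern), 1 when all ``m!``
    patterns are equally frequent.  Ties within a window are ordered by
    occurrence (stable sort).
    """
    x = np.asarray(x, dtype=float).ravel()
    if m < 2:
        raise ValueError("embedding dimension m must be >= 2")
    if tau < 1:
        raise ValueError("delay tau must be >= 1")
    n_windows = len(x) - (m - 1) * tau
    if n_windows < 2:
        raise ValueError(f"series too short for m={m}, tau={tau}")
    idx = np.arange(n_windows)[:, None] + tau * np.arange(m)[None, :]
    patterns = np.argsort(x[idx], axis=1, kind="stable")
    codes = patterns @ (m ** np.arange(m))
    counts = np.bincount(codes)
    p = counts[counts > 0] / n_windows
    return float(-(p * np.log(p)).sum() / np.log(float(factorial(m))))


@dataclass(frozen=True)
class FeatureConfig:
    """Options for per-epoch feature extraction.

    ``exclude_layers = 4`` drops that many layers before retaining the
    rest; ``exclude_from = "shallow"`` drops the shallowest (highest
    frequency) layers, ``"deep"`` the deepest.  ``pe_m``/``pe_tau`` are
    the permutation-entropy embedding dimension and delay.
    """

    exclude_layers: int = 4
    exclude_from: str = "shallow"
    pe_m: int = 3
    pe_tau: int = 1

    def __post_init__(self):
        if self.exclude_from not in ("shallow", "deep"):
            raise ValueError("exclude_from must be 'shallow' or 'deep'")


def retained_layers_for(n_samples: int, filt: WaveletFilter | str, config: FeatureConfig | None = None) -> list[int]:
    """Layers kept for feature extraction: all levels up to the maximum
    depth, minus the excluded ones (default: the 4 shallowest)."""
    cfg = config or FeatureConfig()
    if isinstance(filt, str):
        filt = get_filter(filt)
    jmax = max_level(n_samples, filt.width)
    if cfg.exclude_layers >= jmax:
        raise ValueError(f"cannot exclude {cfg.exclude_layers} of {jmax} layers")
    if cfg.exclude_from == "shallow":
        return list(range(cfg.exclude_layers + 1, jmax + 1))
    return list(range(1, jmax - cfg.exclude_layers + 1))


def feature_count(n_channels: int, n_layers: int) -> int:
    """Feature-vector length: ``C*j*2 + C(C-1)/2*j*2 + C`` (VA+IQR per
    channel-layer, PCC+D per pair-layer, PE per channel)."""
    n_pairs = n_channels * (n_channels - 1) // 2
    return n_channels * n_layers * 2 + n_pairs * n_layers * 2 + n_channels


def extract_epoch_features(
    epoch: Epoch,
    filt: WaveletFilter | str = "la8",
    retained_layers: list[int] | None = None,
    config: FeatureConfig | None = None,
) -> dict[str, float]:
    """Compute the full named feature vector for one epoch.

    Returns an ordered mapping ``feature name -> value`` with
    deterministic naming: ``VA_ch{c}_layer{j}``, ``IQR_ch{c}_layer{j}``,
    ``PCC_ch{a}_ch{b}_layer{j}``, ``D_ch{a}_ch{b}_layer{j}`` and
    ``PE_ch{c}`` with 1-based channel indices.
    """
    cfg = config or FeatureConfig()
    if isinstance(filt, str):
        filt = get_filter(filt)
    layers = retained_layers or retained_layers_for(epoch.n_samples, filt, cfg)
    if not layers:
        raise ValueError("no retained layers")
    jmax = max_level(epoch.n_samples, filt.width)
    if min(layers) < 1 or max(layers) > jmax:
        raise ValueError(f"retained layers {layers} outside 1..{jmax}")

    decomp = modwt_decompose(epoch.data, filt, J=max(layers))
    n_ch = epoch.n_channels
    pairs = list(combinations(range(n_ch), 2))
    out: dict[str, float] = {}
    for j in layers:
        Lj = int(decomp.Lj[j - 1])
        w = decomp.W[:, j - 1, :]  # (channels, N)
        core = w[:, Lj - 1 :]
        for c in range(n_ch):
            out[f"VA_ch{c + 1}_layer{j}"] = wavelet_variance(w[c], Lj)
        for c in range(n_ch):
            out[f"IQR_ch{c + 1}_layer{j}"] = wavelet_iqr(w[c], Lj)
        centered = core - core.mean(axis=1, keepdims=True)
        norms = np.sqrt((centered**2).sum(axis=1))
        if core.shape[1] >= 5:
            d_mat = _hoeffding_all_pairs(core)
        else:
            d_mat = None
        for a, b in pairs:
            denom = norms[a] * norms[b]
            rho = float(np.clip((centered[a] * centered[b]).sum() / denom, -1, 1)) if denom > 0 else float("nan")
            out[f"PCC_ch{a + 1}_ch{b + 1}_layer{j}"] = rho
        for a, b in pairs:
            out[f"D_ch{a + 1}_ch{b + 1}_layer{j}"] = (
                float(d_mat[a, b]) if d_mat is not None else float("nan")
            )
    for c in range(n_ch):
        out[f"PE_ch{c + 1}"] = permutation_entropy(epoch.data[c], cfg.pe_m, cfg.pe_tau)
    return out


def build_feature_table(
    epochs: list[Epoch],
    filt: WaveletFilter | str = "la8",
    config: FeatureConfig | None = None,
    retained_layers: list[int] | None = None,
) -> pd.DataFrame:
    """Assemble the epochs x features table with subject/label metadata.

    One row per epoch; undefined feature values (e.g. correlation with
    a constant channel) are imputed with the column median so row
    counts stay stable, and a column that is undefined everywhere is
    dropped.
    """
    if not epochs:
        raise ValueError("no epochs supplied")
    shapes = {e.data.shape for e in epochs}
    if len(shapes) > 1:
        raise ValueError(f"inconsistent epoch shapes: {shapes}")
    rows = [extract_epoch_features(e, filt, retained_layers, config) for e in epochs]
    table = pd.DataFrame(rows)
    all_nan = table.columns[table.isna().all()]
    if len(all_nan):
        table = table.drop(columns=all_nan)
    table = table.fillna(table.median())
    meta = pd.DataFrame(
        {
            "subject_id": [e.subject_id for e in epochs],
            "label": [e.label for e in epochs],
        }
    )
    return pd.concat([meta, table], axis=1)
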