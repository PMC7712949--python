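"""Maximal-overlap discrete wavelet transform (MODWT).

The MODWT is an undecimated, shift-equivariant variant of the discrete
wavelet transform: every coefficient series keeps the length N of the
input, so it is defined for any sample size, and circular (mod-N)
boundary handling makes it exactly shift-equivariant.  Filters are the
standard DWT pairs renormalized by ``2**(1/2)`` per level, which gives
the energy decomposition ``||x||^2 = sum_j ||W_j||^2 + ||V_J||^2``.

Six wavelet families are provided: Haar, the Daubechies extremal-phase
filters of widths 4/6/8 (D4, D6, D8), the least-asymmetric filter of
width 8 (LA8) and the Coiflet of width 6 (C6).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "WaveletFilter",
    "ModwtDecomposition",
    "FILTER_NAMES",
    "get_filter",
    "max_level",
    "equivalent_filters",
    "modwt_decompose",
    "mra_reconstruct",
]

# Unit-energy DWT scaling filters g (sum = sqrt(2)), standard published
# values (Daubechies extremal phase; least asymmetric; Coiflet).  The
# wavelet filter h is derived from g through the quadrature-mirror
# relation h_l = (-1)^l g_{L-1-l}, so the QMF identity holds exactly.
_SCALING: dict[str, tuple[float, ...]] = {
    "haar": (
        0.7071067811865476,
        0.7071067811865476,
    ),
    "d4": (
        0.4829629131445341,
        0.8365163037378079,
        0.2241438680420134,
        -0.1294095225512604,
    ),
    "d6": (
        0.3326705529500826,
        0.8068915093110925,
        0.4598775021184915,
        -0.1350110200102546,
        -0.0854412738820267,
        0.0352262918857095,
    ),
    "d8": (
        0.2303778133088965,
        0.7148465705529157,
        0.6308807679298589,
        -0.0279837694168599,
        -0.1870348117190931,
        0.0308413818355607,
        0.0328830116668852,
        -0.0105974017850690,
    ),
    "la8": (
        0.0322231006040427,
        -0.0126039672620378,
        -0.0992195435768472,
        0.2978577956052774,
        0.8037387518059161,
        0.4976186676320155,
        -0.0296355276459985,
        -0.0757657147892733,
    ),
    "c6": (
        -0.0727326195125264,
        0.3378976624574818,
        0.8525720202116004,
        0.3848648468648578,
        -0.0727326195125264,
        -0.0156557281357920,
    ),
}

_ALIASES = {"haar": "haar", "d4": "d4", "d6": "d6", "d8": "d8", "la8": "la8", "c6": "c6"}

FILTER_NAMES = ("haar", "d4", "d6", "d8", "la8", "c6")


@dataclass(frozen=True)
class WaveletFilter:
    """A MODWT wavelet/scaling filter pair.

    ``h_tilde`` (wavelet, high-pass) sums to 0 and has energy 1/2;
    ``g_tilde`` (scaling, low-pass) sums to 1.  Both are the unit-level
    DWT filters divided by sqrt(2).
    """

    name: str
    h_tilde: np.ndarray = field(repr=False)
    g_tilde: np.ndarray = field(repr=False)

    @property
    def width(self) -> int:
        return len(self.h_tilde)

    # kept for symmetry with the common L notation
    @property
    def L(self) -> int:
        return len(self.h_tilde)


def get_filter(name: str) -> WaveletFilter:
    """Return the MODWT filter pair for one of the six supported families.

    Parameters
    ----------
    name
        One of ``haar, d4, d6, d8, la8, c6`` (case-insensitive).
    """
    key = str(name).lower()
    if key not in _SCALING:
        raise ValueError(
            f"unknown wavelet filter {name!r}; choose from {', '.join(FILTER_NAMES)}"
        )
    g = np.asarray(_SCALING[key], dtype=float)
    L = len(g)
    # QMF relation on the DWT filters, then renormalize for the MODWT.
    h = np.array([(-1.0) ** l * g[L - 1 - l] for l in range(L)])
    sqrt2 = np.sqrt(2.0)
    return WaveletFilter(name=key, h_tilde=h / sqrt2, g_tilde=g / sqrt2)


def level_filter_width(j: int, L: int) -> int:
    """Width ``L_j = (2**j - 1)(L - 1) + 1`` of the level-j equivalent filter."""
    return (2**j - 1) * (L - 1) + 1


def max_level(n_samples: int, filter_width: int) -> int:
    """Deepest decomposition level whose equivalent filter fits the series.

    Returns the largest j such that ``L_j = (2**j - 1)(L - 1) + 1 <= N``,
    i.e. the deepest layer at which at least one coefficient is free of
    circular wrap-around.  For a 10-s epoch at 125 Hz (N = 1250) this
    gives 10 layers for Haar, 8 for D4 and 7 for the width-6/8 filters.
    """
    N = int(n_samples)
    L = int(filter_width)
    if L < 2:
        raise ValueError("filter width must be at least 2")
    if N < L:
        raise ValueError(f"series of length {N} shorter than filter width {L}")
    j = 1
    while level_filter_width(j + 1, L) <= N:
        j += 1
    return j


@dataclass
class ModwtDecomposition:
    """MODWT coefficients of a single series.

    Attributes
    ----------
    W : ndarray, shape (J, N)
        Wavelet coefficient series, one row per layer ``j = 1..J``.
    V_J : ndarray, shape (N,)
        Scaling coefficients at the deepest layer.
    Lj : ndarray, shape (J,)
        Equivalent-filter widths; coefficients with ``t < Lj - 1`` are
        boundary coefficients affected by circular wrap-around.
    """

    W: np.ndarray
    V_J: np.ndarray
    Lj: np.ndarray
    filter: WaveletFilter
    J: int

    @property
    def N(self) -> int:
        return self.V_J.shape[-1]


def modwt_decompose(x: np.ndarray, filt: WaveletFilter | str, J: int | None = None) -> ModwtDecomposition:
    """Decompose a series (or stack of series) by the MODWT pyramid.

    Parameters
    ----------
    x
        Input series, shape ``(N,)`` or ``(..., N)``; the transform is
        applied along the last axis with circular boundary handling.
    filt
        A :class:`WaveletFilter` or one of the six filter names.
    J
        Number of layers; defaults to ``max_level(N, L)``.

    Notes
    -----
    Implemented by the pyramid recursion: at stage j the stage-(j-1)
    scaling coefficients are filtered with the base filters upsampled by
    ``2**(j-1)`` (zeros inserted between taps), which is algebraically
    identical to circular convolution with the level-j equivalent filter.
    """
    if isinstance(filt, str):
        filt = get_filter(filt)
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("empty input series")
    N = x.shape[-1]
    if N < 2:
        raise ValueError("need at least two samples")
    L = filt.width
    jmax = max_level(N, L)
    if J is None:
        J = jmax
    if not 1 <= J <= jmax:
        raise ValueError(f"J={J} outside the valid range 1..{jmax} for N={N}, L={L}")

    h, g = filt.h_tilde, filt.g_tilde
    V = x
    W_layers = np.empty(x.shape[:-1] + (J, N)) if x.ndim > 1 else np.empty((J, N))
    for j in range(1, J + 1):
        step = 2 ** (j - 1)
        Wj = np.zeros_like(V)
        Vj = np.zeros_like(V)
        for l in range(L):
            shifted = np.roll(V, step * l, axis=-1)
            Wj += h[l] * shifted
            Vj += g[l] * shifted
        if x.ndim > 1:
            W_layers[..., j - 1, :] = Wj
        else:
            W_layers[j - 1] = Wj
        V = Vj

    Lj = np.array([level_filter_width(j, L) for j in range(1, J + 1)])
    return ModwtDecomposition(W=W_layers, V_J=V, Lj=Lj, filter=filt, J=J)


def equivalent_filters(filt: WaveletFilter | str, J: int) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Explicit level-j equivalent filters ``(h_j, g_j)`` for j = 1..J.

    Built by convolving the running scaling filter with the base pair
    upsampled by ``2**(j-1)``; level-j filters have width
    ``(2**j - 1)(L - 1) + 1``.  Used for direct single-pass evaluation of
    the transform and for the multi-resolution inverse.
    """
    if isinstance(filt, str):
        filt = get_filter(filt)
    h, g = filt.h_tilde, filt.g_tilde
    hs: list[np.ndarray] = [h.copy()]
    gs: list[np.ndarray] = [g.copy()]
    for j in range(2, J + 1):
        step = 2 ** (j - 1)
        up_h = np.zeros(step * (len(h) - 1) + 1)
        up_g = np.zeros_like(up_h)
        up_h[::step] = h
        up_g[::step] = g
        hs.append(np.convolve(gs[-1], up_h))
        gs.append(np.convolve(gs[-1], up_g))
    return hs, gs


def _circular_correlate(coeff: np.ndarray, taps: np.ndarray) -> np.ndarray:
    """y_t = sum_l taps_l * coeff_{(t+l) mod N}, vectorized over leading axes."""
    N = coeff.shape[-1]
    padded = np.zeros(coeff.shape[:-1] + (N,))
    padded[..., : len(taps)] = taps
    return np.fft.irfft(np.conj(np.fft.rfft(padded)) * np.fft.rfft(coeff), n=N)


def mra_reconstruct(decomp: ModwtDecomposition) -> tuple[np.ndarray, np.ndarray]:
    """Multi-resolution analysis: per-layer details and the final smooth.

    Returns ``(D, A_J)`` where ``D`` stacks the detail series of layers
    1..J along the same axis as ``decomp.W`` and ``A_J`` is the smooth.
    The additive identity ``x = sum_j D_j + A_J`` holds to floating-point
    accuracy.
    """
    hs, gs = equivalent_filters(decomp.filter, decomp.J)
    D = np.empty_like(decomp.W)
    for j in range(decomp.J):
        Wj = decomp.W[..., j, :] if decomp.W.ndim > 2 else decomp.W[j]
        Dj = _circular_correlate(Wj, hs[j])
        if decomp.W.ndim > 2:
            D[..., j, :] = Dj
        else:
            D[j] = Dj
    A = _circular_correlate(decomp.V_J, gs[decomp.J - 1])
    return D, A
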