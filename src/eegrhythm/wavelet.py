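"""Discrete wavelet machinery: Mallat cascade, 4-level wavelet-packet trees,
frequency ordering of packet leaves, and rhythm-band reconstruction.

The transform is an iterated two-channel orthogonal filter bank with
periodized boundary handling, so coefficient counts halve exactly at each
level and Parseval's identity holds to machine precision.  A full packet
tree (both the approximation and the detail branch split at every node)
taken to level 4 at fs = 128 Hz yields 16 leaves of 4 Hz bandwidth each.

Raw packet-tree nodes come out in natural (Paley) order, in which the
high-pass branches are spectrally inverted by downsampling aliasing; the
Gray-code permutation implemented by :func:`frequency_order` restores a
frequency-monotone leaf index, which is what the rhythm-band map below is
defined over.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import numpy as np
import pywt

__all__ = [
    "BANDS",
    "BandMap",
    "InsufficientDataError",
    "PacketTree",
    "WaveletSpec",
    "default_band_map",
    "dwt_mallat",
    "frequency_order",
    "natural_order",
    "reconstruct_band",
    "reconstruct_leaves",
    "subband_width_hz",
    "wpt_decompose",
]

#: Canonical rhythm-band order used throughout the package.
BANDS: Tuple[str, ...] = ("delta", "theta", "alpha", "beta")


class InsufficientDataError(ValueError):
    """Signal too short for the requested decomposition depth."""


# ---------------------------------------------------------------------------
# Wavelet specification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WaveletSpec:
    """An orthogonal wavelet as a pair of conjugate quadrature filters.

    ``lo``/``hi`` are the synthesis (scaling/wavelet) filters; analysis uses
    their correlation form, so a single pair fully determines the orthogonal
    transform.  ``levels`` is the default decomposition depth.
    """

    name: str
    lo: np.ndarray
    hi: np.ndarray
    levels: int = 4

    @classmethod
    def from_name(cls, name: str = "db5", levels: int = 4) -> "WaveletSpec":
        w = pywt.Wavelet(name)
        if not w.orthogonal:
            raise ValueError(f"wavelet {name!r} is not orthogonal")
        return cls(
            name=name,
            lo=np.asarray(w.rec_lo, dtype=float),
            hi=np.asarray(w.rec_hi, dtype=float),
            levels=levels,
        )

    @property
    def filter_length(self) -> int:
        return int(self.lo.size)


def db5(levels: int = 4) -> WaveletSpec:
    """The Daubechies-5 wavelet (10-tap filters), the package default."""
    return WaveletSpec.from_name("db5", levels=levels)


# ---------------------------------------------------------------------------
# One filter-bank stage, periodized
# ---------------------------------------------------------------------------

def _analysis_step(x: np.ndarray, filt: np.ndarray) -> np.ndarray:
    """Circular correlation with ``filt`` followed by dyadic downsampling."""
    full = np.zeros_like(x)
    for n in range(filt.size):
        full += filt[n] * np.roll(x, -n)
    return full[::2]


def _synthesis_step(coef: np.ndarray, filt: np.ndarray) -> np.ndarray:
    """Dyadic upsampling followed by circular convolution with ``filt``."""
    up = np.zeros(2 * coef.size, dtype=float)
    up[::2] = coef
    out = np.zeros_like(up)
    for n in range(filt.size):
        out += filt[n] * np.roll(up, n)
    return out


def _split(x: np.ndarray, spec: WaveletSpec) -> Tuple[np.ndarray, np.ndarray]:
    if x.size % 2:
        raise InsufficientDataError(
            f"cannot split odd-length block of {x.size} samples"
        )
    return _analysis_step(x, spec.lo), _analysis_step(x, spec.hi)


def _merge(a: np.ndarray, d: np.ndarray, spec: WaveletSpec) -> np.ndarray:
    return _synthesis_step(a, spec.lo) + _synthesis_step(d, spec.hi)


def _pad_to_multiple(x: np.ndarray, block: int) -> np.ndarray:
    rem = x.size % block
    if rem == 0:
        return x
    return np.concatenate([x, np.zeros(block - rem)])


# ---------------------------------------------------------------------------
# Mallat multiresolution decomposition
# ---------------------------------------------------------------------------

def dwt_mallat(
    signal: Sequence[float],
    spec: WaveletSpec | None = None,
    depth: int = 4,
) -> Tuple[np.ndarray, List[np.ndarray]]:
    """Split a signal into its depth-``N`` approximation and detail components.

    Returns ``(f_N, [d_1, ..., d_N])`` where every component is reconstructed
    back to the original signal length, so the pyramid identity

        f_0 = f_N + d_N + d_{N-1} + ... + d_1

    holds pointwise to numerical precision: the approximation carries the
    low-frequency residue and each detail carries one octave of structure.
    """
    if depth < 1:
        raise ValueError(f"depth must be >= 1, got {depth}")
    spec = spec or db5()
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1:
        raise ValueError("dwt_mallat expects a 1-D signal")
    if x.size < 2**depth:
        raise InsufficientDataError(
            f"need at least 2**{depth} = {2**depth} samples, got {x.size}"
        )
    n = x.size
    padded = _pad_to_multiple(x, 2**depth)

    approx = padded
    detail_coeffs: List[np.ndarray] = []
    for _ in range(depth):
        approx, d = _split(approx, spec)
        detail_coeffs.append(d)

    def lift(coef: np.ndarray, level: int, is_detail: bool) -> np.ndarray:
        out = _synthesis_step(coef, spec.hi if is_detail else spec.lo)
        for _ in range(level - 1):
            out = _synthesis_step(out, spec.lo)
        return out[:n]

    f_n = lift(approx, depth, is_detail=False)
    details = [
        lift(d, lev, is_detail=True)
        for lev, d in enumerate(detail_coeffs, start=1)
    ]
    return f_n, details


# ---------------------------------------------------------------------------
# Wavelet-packet decomposition
# ---------------------------------------------------------------------------

@dataclass
class PacketTree:
    """Full wavelet-packet coefficient tree in natural (Paley) node order.

    ``coeffs[(m, i)]`` holds the coefficients of node *i* at level *m*;
    level ``levels`` has ``2**levels`` leaves.  ``n_samples`` is the length
    of the analysed signal before zero-padding to a dyadic-compatible
    length; reconstructions are truncated back to it.
    """

    coeffs: Dict[Tuple[int, int], np.ndarray]
    levels: int
    n_samples: int
    fs: float
    spec: WaveletSpec = field(repr=False)

    @property
    def n_leaves(self) -> int:
        return 2**self.levels

    def leaf(self, natural_index: int) -> np.ndarray:
        return self.coeffs[(self.levels, natural_index)]

    def leaf_by_frequency(self, frequency_index: int) -> np.ndarray:
        return self.leaf(natural_order(self.levels, frequency_index))

    def leaf_energies_by_frequency(self) -> np.ndarray:
        """Coefficient energy of each leaf, in frequency order."""
        return np.array(
            [float(np.sum(self.leaf_by_frequency(k) ** 2))
             for k in range(self.n_leaves)]
        )


def wpt_decompose(
    signal: Sequence[float],
    spec: WaveletSpec | None = None,
    levels: int = 4,
    fs: float = 128.0,
) -> PacketTree:
    """Decompose a signal into a complete ``levels``-deep packet tree.

    Both children of every node are computed, so the bottom level tiles
    [0, fs/2) into ``2**levels`` equal-width subbands.  The signal is
    zero-padded to the next multiple of ``2**levels`` samples (periodized
    transform); the pad carries no energy.
    """
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1:
        raise ValueError("wpt_decompose expects a 1-D signal")
    if x.size < 2**levels:
        raise InsufficientDataError(
            f"need at least 2**{levels} = {2**levels} samples, got {x.size}"
        )
    spec = spec or db5(levels)
    padded = _pad_to_multiple(x, 2**levels)

    coeffs: Dict[Tuple[int, int], np.ndarray] = {(0, 0): padded}
    for lev in range(levels):
        for i in range(2**lev):
            a, d = _split(coeffs[(lev, i)], spec)
            coeffs[(lev + 1, 2 * i)] = a
            coeffs[(lev + 1, 2 * i + 1)] = d
    return PacketTree(
        coeffs=coeffs, levels=levels, n_samples=x.size, fs=fs, spec=spec
    )


def frequency_order(level: int, natural_index: int) -> int:
    """Frequency-ordered position of a natural (Paley) packet node.

    Downsampling mirrors the spectrum of every high-pass branch, so the
    natural leaf index is not frequency-monotone; the binary-reflected
    Gray code undoes the accumulated mirrorings.  Leaf ``k`` in frequency
    order spans ``[k*df, (k+1)*df)`` with ``df = fs / 2**(level+1)``.
    """
    _check_node_index(level, natural_index)
    f = natural_index
    n = natural_index
    while n:
        n >>= 1
        f ^= n
    return f


def natural_order(level: int, frequency_index: int) -> int:
    """Inverse of :func:`frequency_order` (the Gray code itself)."""
    _check_node_index(level, frequency_index)
    return frequency_index ^ (frequency_index >> 1)


def _check_node_index(level: int, index: int) -> None:
    if level < 0:
        raise ValueError(f"level must be >= 0, got {level}")
    if not 0 <= index < 2**level:
        raise ValueError(
            f"node index {index} out of range for level {level} "
            f"(expected 0..{2**level - 1})"
        )


def subband_width_hz(fs: float = 128.0, levels: int = 4) -> float:
    """Bandwidth of one packet leaf: fs/2 divided into 2**levels tiles."""
    return fs / 2.0 / 2**levels


# ---------------------------------------------------------------------------
# Rhythm-band map and band reconstruction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BandMap:
    """Assignment of frequency-ordered packet leaves to rhythm bands.

    ``leaves`` maps a band name to the frequency-order leaf indices that are
    summed (for energies) or kept (for reconstruction); ``edges_hz`` carries
    the nominal physiological band edges, which are narrower than the 4 Hz
    leaf tiling actually computed.
    """

    leaves: Mapping[str, Tuple[int, ...]]
    edges_hz: Mapping[str, Tuple[float, float]]
    levels: int = 4

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for band, idx in self.leaves.items():
            overlap = seen.intersection(idx)
            if overlap:
                raise ValueError(
                    f"leaf indices {sorted(overlap)} assigned to more than "
                    f"one band (second assignment: {band!r})"
                )
            seen.update(idx)

    @property
    def bands(self) -> Tuple[str, ...]:
        return tuple(self.leaves)

    def leaf_set(self, band: str) -> Tuple[int, ...]:
        try:
            return tuple(self.leaves[band])
        except KeyError:
            raise ValueError(
                f"unknown band {band!r}; known bands: {list(self.leaves)}"
            ) from None


def default_band_map(levels: int = 4) -> BandMap:
    """The four-rhythm leaf assignment over a 16-leaf, 4 Hz tiling.

    delta -> leaf 0 (0-4 Hz), theta -> leaf 1 (4-8 Hz), alpha -> leaf 2
    (8-12 Hz), beta -> leaves 3..7 (12-32 Hz).  Leaves 8..15 (32-64 Hz) are
    outside every rhythm band and are treated as residual.  The nominal
    edges are the conventional physiological definitions, which the 4 Hz
    tiling can only approximate.
    """
    if levels != 4:
        raise ValueError("the default band map is defined for 4 levels")
    return BandMap(
        leaves={
            "delta": (0,),
            "theta": (1,),
            "alpha": (2,),
            "beta": (3, 4, 5, 6, 7),
        },
        edges_hz={
            "delta": (0.5, 3.5),
            "theta": (4.0, 7.0),
            "alpha": (8.0, 13.0),
            "beta": (14.0, 30.0),
        },
        levels=levels,
    )


def reconstruct_leaves(
    tree: PacketTree, frequency_indices: Iterable[int]
) -> np.ndarray:
    """Invert the packet transform keeping only the given frequency-ordered
    leaves; every other leaf is zeroed.  Output has ``tree.n_samples``
    samples."""
    keep = {natural_order(tree.levels, k) for k in frequency_indices}
    level_nodes: Dict[int, np.ndarray] = {}
    for i in range(tree.n_leaves):
        c = tree.leaf(i)
        level_nodes[i] = c if i in keep else np.zeros_like(c)
    for lev in range(tree.levels, 0, -1):
        level_nodes = {
            i: _merge(level_nodes[2 * i], level_nodes[2 * i + 1], tree.spec)
            for i in range(2 ** (lev - 1))
        }
    return level_nodes[0][: tree.n_samples]


def reconstruct_band(tree: PacketTree, band_map: BandMap, band: str) -> np.ndarray:
    """Time-domain rhythm signal of one band: inverse transform with all
    leaves outside the band's set zeroed."""
    return reconstruct_leaves(tree, band_map.leaf_set(band))


def extract_rhythms(
    tree: PacketTree, band_map: BandMap | None = None
) -> Dict[str, np.ndarray]:
    """All four rhythm-band signals of one channel epoch, keyed by band."""
    band_map = band_map or default_band_map(tree.levels)
    return {b: reconstruct_band(tree, band_map, b) for b in band_map.bands}
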