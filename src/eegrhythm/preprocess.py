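"""Denoising: common average re-referencing and wavelet low-pass at 30 Hz.

Two steps, applied in this order.  First each channel is re-referenced to
the instantaneous mean over all eight channels (common average reference,
CAR), which removes common-mode signal such as reference drift.  Second,
each channel is passed through a 4-level db5 wavelet-packet filter that
zeroes every 4 Hz subband lying entirely above 30 Hz; the 28-32 Hz leaf
straddles the cut and is kept, because the beta band as mapped onto the
packet tiling extends through that leaf.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .record_io import Epoch
from .wavelet import (
    InsufficientDataError,
    WaveletSpec,
    db5,
    reconstruct_leaves,
    wpt_decompose,
)

__all__ = [
    "ReferencedEpoch",
    "common_average_reference",
    "preprocess_epoch",
    "wavelet_lowpass_30",
]

#: Frequency-ordered leaves kept by the low-pass: 0..7 cover 0-32 Hz.
_KEPT_LEAVES = tuple(range(8))


@dataclass
class ReferencedEpoch(Epoch):
    """An epoch after common average re-referencing.

    ``reference_series`` is the per-sample channel mean that was subtracted;
    the re-referenced channels sum to zero at every sample by construction.
    """

    reference_series: np.ndarray = None  # type: ignore[assignment]


def common_average_reference(epoch: Epoch) -> ReferencedEpoch:
    """Subtract the instantaneous 8-channel mean from every channel.

    The input epoch is not modified.  Raises ``ValueError`` naming the first
    offending sample if any voltage is NaN or infinite.
    """
    v = epoch.voltages
    finite = np.isfinite(v)
    if not finite.all():
        bad = int(np.flatnonzero(~finite.all(axis=1))[0])
        raise ValueError(f"non-finite voltage at sample {bad}")
    reference = v.mean(axis=1)
    return ReferencedEpoch(
        tester_id=epoch.tester_id,
        event_id=epoch.event_id,
        task_label=epoch.task_label,
        voltages=v - reference[:, None],
        fs=epoch.fs,
        reference_series=reference,
    )


def wavelet_lowpass_30(
    signal: np.ndarray, fs: float = 128.0, spec: WaveletSpec | None = None
) -> np.ndarray:
    """Remove content above 30 Hz from one channel by subband zeroing.

    The signal is decomposed into the 16-leaf level-4 packet tree; the
    frequency-ordered leaves covering 32 Hz and above are zeroed and the
    signal reconstructed to its original length.  Only defined for
    fs = 128 Hz, where the leaves are 4 Hz wide.
    """
    if fs != 128.0:
        raise ValueError(f"the 30 Hz subband cut is defined for fs=128, got {fs}")
    x = np.asarray(signal, dtype=float)
    if x.size < 16:
        raise InsufficientDataError(
            f"need at least 16 samples for a 4-level decomposition, got {x.size}"
        )
    tree = wpt_decompose(x, spec=spec or db5(), levels=4, fs=fs)
    return reconstruct_leaves(tree, _KEPT_LEAVES)


def preprocess_epoch(
    epoch: Epoch, spec: WaveletSpec | None = None
) -> ReferencedEpoch:
    """Full denoising for one epoch: CAR then per-channel 30 Hz low-pass."""
    ref = common_average_reference(epoch)
    spec = spec or db5()
    filtered = np.column_stack([
        wavelet_lowpass_30(ref.voltages[:, c], fs=epoch.fs, spec=spec)
        for c in range(ref.voltages.shape[1])
    ])
    ref.voltages = filtered
    return ref
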