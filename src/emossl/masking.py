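"""Contiguous-block timestep masking for the self-supervised pretext task.

A single contiguous block of timesteps (default 30, about 10% of a typical
clip) is selected uniformly at random and every one of the 74 features in
those rows is replaced by the sentinel value -30, which lies far outside the
standardized data range.  The original clip is kept as the reconstruction
target; the model is pre-trained to recover it from the masked copy.

Clips shorter than the block length are masked over max(1, floor(0.10 * T))
rows so the roughly-10% coverage is preserved.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_model import FeatureSequence

MASK_LEN = 30
SENTINEL = -30.0


@dataclass
class MaskedPair:
    """(masked input, original target) plus the mask location."""

    input: np.ndarray
    target: np.ndarray
    mask_start: int
    mask_len: int


def effective_mask_len(n_timesteps: int, mask_len: int = MASK_LEN) -> int:
    """Block length actually masked: ``mask_len`` when the clip is long
    enough, otherwise max(1, floor(0.10 * T))."""
    if n_timesteps >= mask_len:
        return mask_len
    return max(1, int(np.floor(0.10 * n_timesteps)))


def mask_clip(
    seq: FeatureSequence | np.ndarray,
    rng: np.random.Generator,
    mask_len: int = MASK_LEN,
    sentinel: float = SENTINEL,
) -> MaskedPair:
    """Mask one contiguous block of a clip.

    The starting timestep is drawn uniformly from the valid range
    {0, ..., T - L}; all 74 columns of the L selected rows are set to the
    sentinel.  The target is the untouched original.
    """
    values = seq.values if isinstance(seq, FeatureSequence) else np.asarray(seq)
    T = values.shape[0]
    if T < 1:
        raise ValueError("cannot mask an empty clip")
    L = effective_mask_len(T, mask_len)
    start = int(rng.integers(0, T - L + 1))
    masked = values.copy()
    masked[start : start + L, :] = sentinel
    return MaskedPair(input=masked, target=values.copy(), mask_start=start, mask_len=L)
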