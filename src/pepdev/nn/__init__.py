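def _tune_allocator() -> None:
    # Training churns through many ~MB-sized temporaries; glibc serves those
    # with mmap/munmap by default, which dominates wall time with syscalls.
    # Raising M_MMAP_THRESHOLD keeps them on the heap.  Best-effort.
    try:
        import ctypes

        ctypes.CDLL("libc.so.6").mallopt(-3, 512 * 1024 * 1024)  # M_MMAP_THRESHOLD
    except Exception:
        pass


_tune_allocator()

from .autodiff import Tensor, concatenate, constant
from .layers import (
    Adam,
    Conv1d,
    FeedForward,
    LayerNorm,
    Linear,
    Module,
    MultiHeadAttention,
    attention_bias,
    masked_mean,
    sinusoidal_positions,
)

__all__ = [
    "Tensor",
    "concatenate",
    "constant",
    "Adam",
    "Conv1d",
    "FeedForward",
    "LayerNorm",
    "Linear",
    "Module",
    "MultiHeadAttention",
    "attention_bias",
    "masked_mean",
    "sinusoidal_positions",
]
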