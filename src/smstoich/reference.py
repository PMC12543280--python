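"""Reference constants of the worm-lysate training corpus this protocol targets.

These published class counts describe the manually labeled trace corpora
the classification protocol was developed against.  They are bookkeeping
inputs (e.g., for inverse-class-frequency weights at the real corpus's
imbalance); the traces themselves are not distributed.
"""

from __future__ import annotations

__all__ = [
    "FARRED_TRAINING_CLASS_COUNTS",
    "GREEN_TRAINING_CLASS_COUNTS",
]

#: Manually labeled far-red traces per class (rejected / 1-step / 2-step /
#: 3-and-higher-step), pooled over two biological replicates.
FARRED_TRAINING_CLASS_COUNTS: dict[str, int] = {
    "rejected": 12_563,
    "1-step": 10_926,
    "2-step": 5_053,
    "3plus": 1_593,
}

#: Manually labeled green traces per class (rejected / 1-step), one
#: biological replicate.
GREEN_TRAINING_CLASS_COUNTS: dict[str, int] = {
    "rejected": 4_329,
    "1-step": 9_444,
}
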