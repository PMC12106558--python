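"""Shared helpers for the test suite."""

import numpy as np

from petuq import ActivityPhantom, DosePair


def make_toy_pairs(images, drf: int = 1) -> list[DosePair]:
    """Wrap raw (fd, ld) image arrays into DosePair objects for the trainer."""
    pairs = []
    for k, (fd, ld) in enumerate(images):
        phantom = ActivityPhantom(image=np.asarray(fd, dtype=float))
        pairs.append(
            DosePair(fd=phantom, ld=np.asarray(ld, dtype=float), drf=drf, seed=k, phantom_id=k)
        )
    return pairs
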