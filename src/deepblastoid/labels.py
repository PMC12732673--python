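"""Morphological class labels for microwell blastoid images.

Five classes describe what a trained embryologist sees in a single
brightfield microwell tile:

* ``A`` — well-formed cavity and an inner cell mass (ICM) enclosed by a
  complete circular trophectoderm (TE) ring.
* ``B`` — cavity present but no ICM.
* ``C`` — ICM present but the TE ring is irregular or broken.
* ``D`` — no cavity; the structure appears as cellular debris.
* ``W`` — empty microwell (no foreground structure at all).

The canonical integer encoding is A=0, B=1, C=2, D=3, W=4 and is used
everywhere a label has to become an array index.
"""

from __future__ import annotations

import enum
from typing import Iterable, Sequence

import numpy as np

__all__ = ["ClassLabel", "CLASS_NAMES", "N_CLASSES", "encode_labels", "decode_labels"]


class ClassLabel(enum.IntEnum):
    """The five microwell morphology classes, ordered by their integer code."""

    A = 0
    B = 1
    C = 2
    D = 3
    W = 4

    @classmethod
    def from_any(cls, value: "ClassLabel | str | int") -> "ClassLabel":
        """Coerce a name ('A'..'W'), code (0..4) or ClassLabel to a ClassLabel."""
        if isinstance(value, cls):
            return value
        if isinstance(value, str):
            try:
                return cls[value.upper()]
            except KeyError:
                raise ValueError(f"unknown class label {value!r}; expected one of A,B,C,D,W")
        if isinstance(value, (int, np.integer)):
            try:
                return cls(int(value))
            except ValueError:
                raise ValueError(f"class code {value} outside 0..4")
        raise TypeError(f"cannot interpret {value!r} as a class label")


CLASS_NAMES: tuple[str, ...] = tuple(lbl.name for lbl in ClassLabel)
N_CLASSES: int = len(ClassLabel)


def encode_labels(labels: Iterable["ClassLabel | str | int"]) -> np.ndarray:
    """Map labels in any accepted form to the integer codes 0..4."""
    return np.array([int(ClassLabel.from_any(l)) for l in labels], dtype=np.int64)


def decode_labels(codes: Sequence[int]) -> list[str]:
    """Map integer codes back to the class names."""
    return [ClassLabel(int(c)).name for c in codes]
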