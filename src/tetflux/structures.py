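"""Enumeration and encoding of the candidate TET participation structures.

Each of the three oxidation reactions (mdC->hmdC, hmdC->fdC, fdC->cadC)
can be driven by any non-empty subset of {TET1, TET2, TET3}: 7 options per
reaction, hence 7**3 = 343 candidate structures.

The canonical enumeration order is lexicographic ascending over the triple
of per-reaction bitmasks (TET1 = least significant bit), so the TET1-only
structure ``(1, 1, 1)`` comes first and the full structure ``(7, 7, 7)``
is last, at index :data:`FULL_STRUCTURE_INDEX` = 342. The order is
arbitrary but stable, which is what downstream tie-breaking needs.
"""

from __future__ import annotations

from .errors import ValidationError
from .model import TETS, ModelStructure

__all__ = [
    "N_STRUCTURES",
    "N_OPTIONS_PER_REACTION",
    "FULL_STRUCTURE_INDEX",
    "enumerate_structures",
    "encode",
    "decode",
    "describe",
]

N_OPTIONS_PER_REACTION = 7
N_STRUCTURES = N_OPTIONS_PER_REACTION**3
FULL_STRUCTURE_INDEX = N_STRUCTURES - 1


def enumerate_structures() -> list[ModelStructure]:
    """All 343 structures in canonical (ascending-bitmask) order."""
    return [
        ModelStructure.from_masks(m1, m2, m3)
        for m1 in range(1, 8)
        for m2 in range(1, 8)
        for m3 in range(1, 8)
    ]


def encode(structure: ModelStructure) -> int:
    """Canonical index of a structure, an integer in [0, 342]."""
    m1, m2, m3 = structure.masks
    return (m1 - 1) * 49 + (m2 - 1) * 7 + (m3 - 1)


def decode(code: int) -> ModelStructure:
    """Inverse of :func:`encode`."""
    code = int(code)
    if not 0 <= code < N_STRUCTURES:
        raise ValidationError(f"structure code must be in [0, {N_STRUCTURES - 1}], got {code}")
    m1, rest = divmod(code, 49)
    m2, m3 = divmod(rest, 7)
    return ModelStructure.from_masks(m1 + 1, m2 + 1, m3 + 1)


def describe(structure: ModelStructure) -> str:
    """Fixed-width dot-pattern row, reaction-major, TET1..TET3 within reaction.

    Example: the full structure renders as ``"• • • | • • • | • • •"``.
    """
    groups = []
    for r in range(3):
        ind = structure.indicator(r)
        groups.append(" ".join("•" if ind[i] else "_" for i in range(len(TETS))))
    return " | ".join(groups)
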