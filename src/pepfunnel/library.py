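"""Combinatorial peptide library built from a motif under a residue-class scheme.

Each of the 20 standard residues belongs to exactly one of six physicochemical
classes (acidic, basic, hydrophobic/aliphatic, aromatic, polar-uncharged,
unique).  A motif of length *L* seeds a library: at every position the motif
residue may be replaced by any member of its own class (including itself), so
the library is the Cartesian product of the per-position classes.  For the
acetyl-CoA synthetase 2 nucleotide-pocket motif GEPDTYWQ this yields
2*2*2*2*5*3*3*5 = 3600 distinct 8-mers.

Enumeration order is deterministic: positions vary rightmost-fastest and class
members are taken in the order the scheme lists them.
"""

from __future__ import annotations

import itertools
from collections.abc import Iterator
from dataclasses import dataclass, field

from ._scales import STANDARD_RESIDUES

__all__ = [
    "InvalidSequenceError",
    "ResidueClassScheme",
    "MotifSpec",
    "PeptideSeq",
    "build_default_scheme",
    "library_size",
    "enumerate_pcs",
    "is_member",
    "validate_sequence",
]


class InvalidSequenceError(ValueError):
    """Raised when a sequence contains a non-standard residue code."""


def validate_sequence(sequence: str) -> str:
    """Return the uppercased sequence, rejecting non-standard residues.

    Ambiguity codes (B, Z, X) and the rare residues (U, O) are rejected: the
    class scheme is defined only over the 20 standard codes.
    """
    seq = sequence.upper()
    if not seq:
        raise InvalidSequenceError("empty sequence")
    bad = sorted(set(seq) - set(STANDARD_RESIDUES))
    if bad:
        raise InvalidSequenceError(
            f"non-standard residue code(s) {bad!r} in sequence {sequence!r}"
        )
    return seq


@dataclass(frozen=True)
class PeptideSeq:
    """A peptide over the 20 standard residues with an optional id."""

    sequence: str
    id: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", validate_sequence(self.sequence))

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ResidueClassScheme:
    """Ordered partition of the 20 standard residues into named classes."""

    classes: tuple[tuple[str, tuple[str, ...]], ...]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for name, members in self.classes:
            overlap = seen & set(members)
            if overlap:
                raise ValueError(f"residues {sorted(overlap)} in more than one class")
            seen.update(members)
        if seen != set(STANDARD_RESIDUES):
            missing = sorted(set(STANDARD_RESIDUES) - seen)
            extra = sorted(seen - set(STANDARD_RESIDUES))
            raise ValueError(
                f"classes must partition the 20 standard residues "
                f"(missing {missing}, extra {extra})"
            )

    @property
    def class_names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.classes)

    def class_of(self, residue: str) -> str:
        """Name of the class containing ``residue``."""
        residue = residue.upper()
        for name, members in self.classes:
            if residue in members:
                return name
        raise InvalidSequenceError(f"non-standard residue {residue!r}")

    def members_of(self, residue: str) -> tuple[str, ...]:
        """All residues sharing a class with ``residue`` (in scheme order)."""
        residue = residue.upper()
        for _, members in self.classes:
            if residue in members:
                return members
        raise InvalidSequenceError(f"non-standard residue {residue!r}")


def build_default_scheme() -> ResidueClassScheme:
    """The six-class scheme: acidic, basic, hydrophobic/aliphatic, aromatic,
    polar-uncharged, unique."""
    return ResidueClassScheme(
        classes=(
            ("acidic", ("D", "E")),
            ("basic", ("R", "H", "K")),
            ("hydrophobic_aliphatic", ("A", "I", "L", "M", "V")),
            ("aromatic", ("F", "W", "Y")),
            ("polar_uncharged", ("N", "C", "Q", "S", "T")),
            ("unique", ("G", "P")),
        )
    )


@dataclass(frozen=True)
class MotifSpec:
    """A template motif plus the class scheme that defines its variants."""

    motif: str
    scheme: ResidueClassScheme = field(default_factory=build_default_scheme)

    def __post_init__(self) -> None:
        object.__setattr__(self, "motif", validate_sequence(self.motif))

    def position_classes(self) -> list[tuple[str, ...]]:
        """Per-position allowed residues (the class of each motif residue)."""
        return [self.scheme.members_of(r) for r in self.motif]


def library_size(motif: MotifSpec) -> int:
    """Number of distinct class-consistent variants of the motif.

    Equals the product over positions of the size of the class containing the
    motif residue at that position (the original residue counts as one of its
    own substitutes).
    """
    size = 1
    for members in motif.position_classes():
        size *= len(members)
    return size


def _iter_pcs(motif: MotifSpec) -> Iterator[str]:
    for combo in itertools.product(*motif.position_classes()):
        yield "".join(combo)


def enumerate_pcs(motif: MotifSpec, id_prefix: str = "PCS") -> list[PeptideSeq]:
    """Enumerate every class-consistent variant of the motif.

    Returns ``library_size(motif)`` distinct peptides, each the motif's length,
    ids ``PCS1..PCSn`` by enumeration index (1-based).  The motif itself is a
    member.  Order is deterministic: rightmost position fastest, class members
    in scheme order.
    """
    return [
        PeptideSeq(seq, id=f"{id_prefix}{i}")
        for i, seq in enumerate(_iter_pcs(motif), start=1)
    ]


def is_member(seq: PeptideSeq | str, motif: MotifSpec) -> bool:
    """True iff ``seq`` has the motif's length and every residue belongs to
    the class of the motif residue at that position."""
    sequence = seq.sequence if isinstance(seq, PeptideSeq) else validate_sequence(seq)
    if len(sequence) != len(motif.motif):
        return False
    scheme = motif.scheme
    return all(
        scheme.class_of(r) == scheme.class_of(m)
        for r, m in zip(sequence, motif.motif)
    )
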