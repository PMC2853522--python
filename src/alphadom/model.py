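"""Core data model for alpha-satellite higher-order repeat (HOR) analysis.

All coordinates are 0-based, half-open.  Sequences are uppercase DNA over
``{A, C, G, T, N}``; alignment states additionally allow ``-`` for a
deletion relative to the consensus coordinate system.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .errors import ValidationError

DNA_ALPHABET = frozenset("ACGTN")
STATE_ORDER = "ACGT-"  # fixed tie-break order for majority calls


def validate_dna(sequence: str, label: str = "sequence") -> str:
    """Uppercase *sequence* and verify it only uses ``{A,C,G,T,N}``.

    ``U`` is rejected: the pipeline is DNA-only and silent RNA→DNA
    conversion would mask sample mix-ups.
    """
    seq = sequence.upper()
    if not seq:
        raise ValidationError(f"{label}: empty sequence")
    bad = set(seq) - DNA_ALPHABET
    if bad:
        raise ValidationError(
            f"{label}: illegal characters {sorted(bad)} (DNA over ACGTN expected)"
        )
    return seq


@dataclass(frozen=True)
class SequenceRecord:
    """A named DNA sequence with free-text provenance."""

    id: str
    sequence: str
    source: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", validate_dna(self.sequence, self.id))

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class RepeatAnnotationRow:
    """One positioned repeat unit (monomer or HOR) on an array sequence."""

    array_id: str
    start: int
    end: int
    unit_kind: str  # "monomer" | "hor"
    unit_index: int
    complete: bool = True

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"annotation {self.array_id}:{self.unit_index}: bad interval "
                f"[{self.start}, {self.end})"
            )
        if self.unit_kind not in ("monomer", "hor"):
            raise ValidationError(f"unknown unit_kind {self.unit_kind!r}")


@dataclass(frozen=True)
class MonomerCall:
    """A single ~171-bp alpha-satellite monomer located on the array."""

    start: int
    end: int
    identity_to_consensus: float
    index: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class HORUnit:
    """One higher-order repeat unit: a block of k consecutive monomers."""

    start: int
    end: int
    monomer_span: tuple[int, int]  # [first_monomer_index, last_monomer_index]
    complete: bool
    mean_identity: Optional[float] = None
    index: int = 0

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class HORPhasing:
    """A phased decomposition of the monomer tiling into k-monomer units."""

    k: int
    anchor_offset: int
    units: list[HORUnit]

    @property
    def complete_units(self) -> list[HORUnit]:
        return [u for u in self.units if u.complete]


@dataclass
class Consensus:
    """Majority consensus of a set of repeat copies, with per-column support."""

    sequence: str
    support: np.ndarray  # fraction of copies matching each column, in (0, 1]

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ArrayAlignment:
    """Repeat copies projected onto consensus columns.

    ``matrix`` holds one single-character state per (copy, column) drawn
    from ``{A,C,G,T,N,-}``; insertions relative to the consensus are kept
    out of the matrix so column arithmetic stays trivial.
    """

    copy_ids: list[str]
    matrix: np.ndarray  # dtype '<U1', shape (n_copies, n_columns)
    consensus: str  # per-column consensus state
    insertions: list[tuple[str, int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype="<U1")
        if self.matrix.ndim != 2:
            raise ValidationError("alignment matrix must be 2-D")
        if len(self.copy_ids) != self.matrix.shape[0]:
            raise ValidationError("copy_ids / matrix row count mismatch")
        if len(self.consensus) != self.matrix.shape[1]:
            raise ValidationError("consensus length / column count mismatch")

    @property
    def n_copies(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_columns(self) -> int:
        return self.matrix.shape[1]

    def row(self, copy_id: str) -> str:
        i = self.copy_ids.index(copy_id)
        return "".join(self.matrix[i])

    def rows(self) -> Iterable[tuple[str, str]]:
        for i, cid in enumerate(self.copy_ids):
            yield cid, "".join(self.matrix[i])


@dataclass(frozen=True)
class Variant:
    """One copy's deviation from the consensus state at one column."""

    copy_id: str
    column: int
    alt_state: str  # one of {A,C,G,T,-}


@dataclass(frozen=True)
class DVNGroup:
    """A diagnostic variant nucleotide: an alternate state shared by >= 2 copies."""

    column: int
    alt_state: str
    carriers: frozenset[str]

    def __post_init__(self) -> None:
        if len(self.carriers) < 2:
            raise ValidationError("a DVN requires at least 2 carriers")


@dataclass
class VariantPartition:
    """Variants split into shared DVNs and sporadic singletons."""

    dvns: list[DVNGroup]
    sporadic: list[Variant]

    @property
    def dvn_columns(self) -> int:
        """Number of distinct consensus positions bearing at least one DVN."""
        return len({g.column for g in self.dvns})

    @property
    def n_variants(self) -> int:
        return sum(len(g.carriers) for g in self.dvns) + len(self.sporadic)


@dataclass(frozen=True)
class CenpBBoxCall:
    """Best CENP-B box match within one monomer."""

    monomer_index: int
    offset: int
    n_essential_matches: int
    intact: bool
    present: bool


@dataclass
class HaplotypeMatrix:
    """Copies x DVN-groups binary carrier matrix."""

    copy_ids: list[str]
    matrix: np.ndarray  # int8, shape (n_copies, n_dvn_groups)
    dvns: list[DVNGroup]
    ordered: bool = True  # True when row order is array order

    @property
    def n_copies(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_groups(self) -> int:
        return self.matrix.shape[1]


@dataclass(frozen=True)
class Domain:
    """A contiguous run of copies homogenised onto a common DVN haplotype."""

    first_copy: int
    last_copy: int  # inclusive, in array order
    defining_dvns: frozenset[int]  # indices into HaplotypeMatrix.dvns

    @property
    def size(self) -> int:
        return self.last_copy - self.first_copy + 1


@dataclass
class DomainMap:
    """Ordered segmentation of array copies into domains / barriers / unassigned."""

    domains: list[Domain]
    barriers: list[tuple[int, int]] = field(default_factory=list)
    unassigned: list[int] = field(default_factory=list)
    n_copies: int = 0

    def covered(self) -> set[int]:
        out: set[int] = set()
        for d in self.domains:
            out.update(range(d.first_copy, d.last_copy + 1))
        for a, b in self.barriers:
            out.update(range(a, b + 1))
        out.update(self.unassigned)
        return out

    def domain_of(self, copy_index: int) -> Optional[int]:
        for i, d in enumerate(self.domains):
            if d.first_copy <= copy_index <= d.last_copy:
                return i
        return None


@dataclass(frozen=True)
class ConversionTract:
    """A run of foreign-domain DVNs on one copy, attributed to a donor domain."""

    copy_id: str
    column_start: int
    column_end: int  # half-open
    donor_domain: int
    n_dvns: int


@dataclass(frozen=True)
class DuplicatePair:
    """Two adjacent, near-identical copies — the signature of a fresh unequal crossover."""

    first_copy: int
    second_copy: int
    identity: float
    n_private_dvns: int

    def __post_init__(self) -> None:
        if self.second_copy != self.first_copy + 1:
            raise ValidationError("duplicate pairs must be adjacent copies")


@dataclass
class SetComparison:
    """Joint-frame comparison of two repeat sets (homologues, CENP-A vs bulk)."""

    shared_dvns: int
    private_a: int
    private_b: int
    newick: str
    intermingling_index: float
    intermingling_raw: float
    intermingling_pvalue: float
    n_a: int = 0
    n_b: int = 0

    @property
    def total_dvns(self) -> int:
        return self.shared_dvns + self.private_a + self.private_b
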