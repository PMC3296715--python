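"""Core domain types shared across the numt pipeline.

Coordinates are 0-based half-open everywhere inside the package; conversion
to 1-based inclusive (GFF3) happens only at serialization boundaries.
Circular mitochondrial coordinates are normalized to ``[0, L)``; an interval
that spans the origin is stored as two sub-intervals flagged origin-spanning.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

DNA_ALPHABET = set("ACGTN")
_BASE_TO_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_CODE_TO_BASE = np.array(list("ACGTN"))

# translation table for reverse complement, case preserving
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement, preserving softmask case."""
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode DNA (case-insensitive) as uint8 codes A,C,G,T,N -> 0..4."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, 4, dtype=np.uint8)
    for base, code in (("A", 0), ("C", 1), ("G", 2), ("T", 3)):
        out[arr == ord(base)] = code
    return out


def decode(codes: np.ndarray) -> str:
    return "".join(_CODE_TO_BASE[codes])


def mask_array(seq: str) -> np.ndarray:
    """Boolean array, True where the residue is softmasked (lowercase)."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return (arr >= ord("a")) & (arr <= ord("z"))


class FormatError(ValueError):
    """Malformed input file or record."""


class ValidationError(ValueError):
    """Input violates a domain invariant."""


@dataclass
class GenomeSequence:
    """A nuclear scaffold or mitochondrial genome.

    Attributes
    ----------
    id : str
        Record identifier (unique within a file).
    residues : str
        DNA over ``{A,C,G,T,N}``; lowercase marks softmasked positions.
        Masking never changes residue identity, only case.
    topology : str
        ``"linear"`` or ``"circular"``; circular is reserved for
        mitochondrial genomes.
    """

    id: str
    residues: str
    topology: str = "linear"

    def __post_init__(self) -> None:
        if len(self.residues) == 0:
            raise ValidationError(f"sequence {self.id!r} is empty")
        if self.topology not in ("linear", "circular"):
            raise ValidationError(f"bad topology {self.topology!r}")
        bad = set(self.residues.upper()) - DNA_ALPHABET
        if bad:
            raise FormatError(
                f"record {self.id!r} contains non-IUPAC characters: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    def fragment(self, start: int, end: int) -> str:
        """Residues of ``[start, end)``; wraps the origin when circular."""
        n = len(self.residues)
        if self.topology == "circular":
            start %= n
            end = end % n if end % n or end == 0 else n
            if end <= start:
                return self.residues[start:] + self.residues[:end]
        return self.residues[start:end]


@dataclass
class MitoInterval:
    """Interval on a (possibly circular) mitochondrial genome.

    ``origin_spanning`` intervals are stored as ``[start, L) + [0, end)``.
    """

    start: int
    end: int
    origin_spanning: bool = False

    def length(self, mito_length: Optional[int] = None) -> int:
        if self.origin_spanning:
            if mito_length is None:
                raise ValueError("mito_length required for origin-spanning interval")
            return (mito_length - self.start) + self.end
        return self.end - self.start


@dataclass
class Fragment:
    """One aligned numt fragment: nuclear interval <-> mito origin."""

    nuc_start: int
    nuc_end: int
    mito_start: int
    mito_end: int
    strand: str  # "+" or "-"
    identity: float  # gap-excluded identity fraction in (0, 1]

    def nuc_length(self) -> int:
        return self.nuc_end - self.nuc_start

    def mito_length(self) -> int:
        return self.mito_end - self.mito_start


@dataclass
class NumtAnnotation:
    """A merged numt: one insertion locus possibly in several fragments.

    ``total_numt_length`` sums fragment nuclear lengths, excluding
    interrupting sequence and internal duplications, matching the
    length convention of the per-species summary tables.
    """

    numt_id: str
    species: str
    scaffold: str
    fragments: list  # list[Fragment], sorted by nuc_start

    def __post_init__(self) -> None:
        self.fragments = sorted(self.fragments, key=lambda f: f.nuc_start)

    @property
    def span(self) -> tuple:
        return (self.fragments[0].nuc_start, self.fragments[-1].nuc_end)

    @property
    def total_numt_length(self) -> int:
        """Fragment-sum length, counting duplicated mito coverage once."""
        # collapse fragments covering the same mito bases (internal
        # duplications) so repeated sequence is counted once
        ivs = sorted((f.mito_start, f.mito_end) for f in self.fragments)
        total = 0
        cur_s, cur_e = ivs[0]
        for s, e in ivs[1:]:
            if s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                total += cur_e - cur_s
                cur_s, cur_e = s, e
        total += cur_e - cur_s
        return total

    @property
    def mito_interval(self) -> tuple:
        return (
            min(f.mito_start for f in self.fragments),
            max(f.mito_end for f in self.fragments),
        )


@dataclass
class RearrangementEvent:
    """One gross post-insertion mutation within a numt."""

    numt_id: str
    type: str  # interruption | deletion | inversion | internal_duplication
    size: int
    nuc_interval: Optional[tuple] = None
    mito_interval: Optional[tuple] = None


@dataclass
class Hsp:
    """Ungapped high-scoring segment pair from the seed-and-extend search."""

    query_start: int
    query_end: int
    subject_start: int
    subject_end: int
    strand: str
    score: int
    bit_score: float
    e_value: float
    identity: float = 1.0

    def __post_init__(self) -> None:
        if self.query_end - self.query_start != self.subject_end - self.subject_start:
            raise ValidationError("ungapped HSP intervals must have equal length")


@dataclass
class LinkedHit:
    """Chain of colinear same-strand HSPs within the separation limit."""

    hsps: list
    subject_id: str
    query_id: str
    combined_score: int = 0
    combined_e_value: float = 0.0

    def __post_init__(self) -> None:
        self.hsps = sorted(self.hsps, key=lambda h: h.subject_start)
        if not self.combined_score:
            self.combined_score = sum(h.score for h in self.hsps)

    @property
    def strand(self) -> str:
        return self.hsps[0].strand

    @property
    def subject_interval(self) -> tuple:
        return (self.hsps[0].subject_start, self.hsps[-1].subject_end)

    @property
    def query_interval(self) -> tuple:
        return (
            min(h.query_start for h in self.hsps),
            max(h.query_end for h in self.hsps),
        )


@dataclass
class PlacementResult:
    """Exhaustive branch placement of one numt on the species tree."""

    numt_id: str
    branch_loglik: dict  # branch label -> maximized log-likelihood
    best_branch: str
    significance_set: list  # branch labels not significantly worse at alpha
    age_window: tuple  # (t_min, t_max) in My
    density: dict  # branch label -> weight, sums to 1 over the window
    low_information: bool = False


@dataclass
class HomologyVerdict:
    """Paralog/ortholog call for a numt pair or group."""

    numt_ids: tuple
    relation: str  # paralog | ortholog | unresolved
    delta_loglik: float
    p_value: float
    synteny_confirmed: str = "untestable"  # yes | no | untestable


@dataclass
class TruthRecord:
    """Ground truth for one simulated numt copy."""

    numt_id: str
    species: str  # leaf where the record is observed ('' once deleted)
    insertion_branch: str  # label of branch where the founding event happened
    insertion_time_my: float
    mito_start: int
    mito_end: int  # may exceed mito length for origin-spanning copies
    strand: str
    scaffold: str = ""
    nuc_start: int = -1
    nuc_end: int = -1
    parent_numt_id: Optional[str] = None
    deleted: bool = False
    rearrangements: list = field(default_factory=list)  # [(type, size), ...]


@dataclass
class RateInputs:
    """Inputs of the insertion/duplication rate estimators."""

    n_insertions: float  # density-weighted insertion count on the branch set
    total_time_my: float  # summed branch durations T
    n_duplications: float  # Dp, one per paralog set by default
    mean_numts_per_genome: float  # N
    per_branch: dict = field(default_factory=dict)  # label -> (N_i, T)


@dataclass
class RateEstimates:
    insertion_rate: float  # insertions / My
    duplication_rate: float  # duplications / numt / My
    deletion_rate: float  # deletions / numt / My
    half_life_my: float  # ln 2 / deletion rate
    per_branch: dict = field(default_factory=dict)
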