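"""Shared record types used across the workbench stages.

Coordinates are 0-based half-open on the forward strand throughout the
package. BED output keeps this convention; GFF3 output converts to 1-based
inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

IUPAC = set("ACGTRYSWKMBDHVN")


@dataclass
class SequenceRecord:
    """A named nucleotide sequence with a circular/linear topology flag."""

    id: str
    seq: str
    circular: bool = False

    def __post_init__(self) -> None:
        self.seq = self.seq.upper()
        bad = set(self.seq) - IUPAC
        if bad:
            raise ValueError(
                f"record {self.id!r} contains non-IUPAC characters: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class SeedHit:
    """One local alignment of a probe/consensus against the genome."""

    contig: str
    start: int
    end: int
    strand: str  # '+' or '-'
    identity: float  # percent, 0..100
    score: float

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"hit span empty: [{self.start}, {self.end})")
        if not 0.0 <= self.identity <= 100.0:
            raise ValueError(f"identity out of range: {self.identity}")

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class ORF:
    """A maximal stop-to-stop reading frame on one strand.

    Coordinates are on the forward strand of the contig; ``length`` is the
    nucleotide length of the stop-free segment.
    """

    contig: str
    start: int
    end: int
    strand: str
    frame: int  # 0, 1, 2 relative to the span scanned

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class LTRElement:
    """A candidate LTR retroelement.

    ``ltr5_span`` precedes ``ltr3_span`` on the forward strand of the contig.
    Solo elements carry only ``ltr5_span``; the internal span and ORF fields
    are absent for them.
    """

    contig: str
    strand: str
    ltr5_span: tuple[int, int]
    ltr3_span: tuple[int, int] | None = None
    internal_span: tuple[int, int] | None = None
    ltr_pair_identity: float | None = None
    orf_span: tuple[int, int] | None = None
    orf_length: int = 0
    class_label: str = "candidate"  # intact | degenerate | solo | candidate

    @property
    def start(self) -> int:
        return self.ltr5_span[0]

    @property
    def end(self) -> int:
        return self.ltr3_span[1] if self.ltr3_span else self.ltr5_span[1]

    @property
    def is_solo(self) -> bool:
        return self.ltr3_span is None


@dataclass
class ConsensusLTR:
    """Majority-rule consensus of a set of LTR copies."""

    seq: str
    support: int
    column_majority: list[float] = field(default_factory=list)


@dataclass
class AlignmentRecord:
    """One read-to-reference alignment, PAF-compatible.

    Target coordinates may lie on a doubled circular reference, i.e. in
    [0, 2L); ``canonicalize`` folds them back onto [0, L).
    """

    query: str
    query_length: int
    query_start: int
    query_end: int
    target: str
    target_start: int
    target_end: int
    strand: str
    matches: int
    block_length: int
    mapq: int = 60
    clip_left: int = 0
    clip_right: int = 0
    query_seq: str | None = None  # retained by the internal aligner for pileups

    def __post_init__(self) -> None:
        if self.matches > self.block_length:
            raise ValueError("matches exceed block length")

    @property
    def identity(self) -> float:
        return 100.0 * self.matches / self.block_length if self.block_length else 0.0


@dataclass
class CanonicalPlacement:
    """A read's placement folded onto circular coordinates [0, L).

    Origin-spanning reads have exactly two intervals, [s, L) then [0, e).
    """

    read: str
    read_length: int
    intervals: list[tuple[int, int]]
    origin_spanning: bool
    strand: str = "+"

    @property
    def start(self) -> int:
        return self.intervals[0][0]

    @property
    def aligned_span(self) -> int:
        return sum(e - s for s, e in self.intervals)


@dataclass
class RepeatBlock:
    """A maximal tandem array: unit length, copy number, consensus unit."""

    start: int
    end: int
    unit_length: int
    copy_number: float
    unit_consensus: str = ""

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass
class CoverageAnomaly:
    """A run of excess coverage coinciding with read clipping."""

    start: int
    end: int
    fold_enrichment: float
    clipped_fraction: float


@dataclass
class VariantSite:
    """A pileup site with a non-reference allele above threshold."""

    pos: int
    ref_base: str
    alt_base: str
    depth: int
    alt_fraction: float


COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVNacgtryswkmbdhvn",
                           "TGCAYRSWMKVHDBNtgcayrswmkvhdbn")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (IUPAC-aware)."""
    return seq.translate(COMPLEMENT)[::-1]
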