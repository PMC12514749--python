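"""Domain types shared across the simulation and detection stages.

Coordinate conventions
----------------------
All genomic coordinates are 1-based and inclusive. Exons are stored in
*transcript* order: exon 1 is the 5'-most exon of the mRNA, so for a
'-'-strand gene the genomic start coordinates strictly decrease with the
exon number. Junction breakpoints follow the dominant chimeric-junction
dialect: the donor position is the last transcribed base before the
junction and the acceptor position is the first transcribed base after it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

EN_DASH = "–"  # the junction-label separator, as in "16–9"

EVENT_TYPES = ("canonical", "exon_skip", "kdd", "fusion", "truncation", "unclassified")


class ValidationError(ValueError):
    """Raised when a domain object violates one of its invariants."""


# ---------------------------------------------------------------------------
# gene models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneSpec:
    """Blueprint for one toy gene inside a :class:`GenomeSpec`.

    ``kinase_domain_exons`` / ``autoinhibitory_exons`` are inclusive
    transcript-order exon-number ranges, e.g. ``(11, 18)`` for a BRAF-like
    kinase domain, or ``None`` when the gene carries no such annotation.
    """

    symbol: str
    strand: str
    n_exons: int
    exon_length: int = 160
    intron_length: int = 60
    kinase_domain_exons: Optional[tuple[int, int]] = None
    autoinhibitory_exons: Optional[tuple[int, int]] = None
    chrom: Optional[str] = None
    start: Optional[int] = None

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValidationError(f"{self.symbol}: strand must be '+' or '-'")
        if self.n_exons < 1 or self.exon_length < 1 or self.intron_length < 1:
            raise ValidationError(f"{self.symbol}: exon/intron lengths and counts must be positive")
        for name, rng in (("kinase_domain_exons", self.kinase_domain_exons),
                          ("autoinhibitory_exons", self.autoinhibitory_exons)):
            if rng is not None:
                lo, hi = rng
                if not (1 <= lo <= hi <= self.n_exons):
                    raise ValidationError(
                        f"{self.symbol}: {name} {rng} outside 1..{self.n_exons}")

    @property
    def footprint(self) -> int:
        return self.n_exons * self.exon_length + (self.n_exons - 1) * self.intron_length


@dataclass(frozen=True)
class GenomeSpec:
    n_chromosomes: int
    chrom_length: int
    genes: tuple[GeneSpec, ...]
    seed: int = 42

    def __post_init__(self) -> None:
        if self.n_chromosomes < 1 or self.chrom_length < 1:
            raise ValidationError("need at least one chromosome of positive length")
        symbols = [g.symbol for g in self.genes]
        if len(symbols) != len(set(symbols)):
            raise ValidationError("gene symbols must be unique")

    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chromosomes)]


@dataclass(frozen=True)
class GeneModel:
    """A strand-aware multi-exon gene with transcript-ordered exons."""

    symbol: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]  # transcript order, 1-based inclusive
    kinase_domain_exons: Optional[tuple[int, int]] = None
    autoinhibitory_exons: Optional[tuple[int, int]] = None

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValidationError(f"{self.symbol}: strand must be '+' or '-'")
        if not self.exons:
            raise ValidationError(f"{self.symbol}: gene needs at least one exon")
        for s, e in self.exons:
            if not (1 <= s <= e):
                raise ValidationError(f"{self.symbol}: bad exon interval ({s}, {e})")
        starts = [s for s, _ in self.exons]
        ordered = all(a < b for a, b in zip(starts, starts[1:])) if self.strand == "+" \
            else all(a > b for a, b in zip(starts, starts[1:]))
        if len(self.exons) > 1 and not ordered:
            raise ValidationError(
                f"{self.symbol}: exon genomic starts must be strictly "
                f"{'increasing' if self.strand == '+' else 'decreasing'} in transcript order")
        ivals = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(ivals, ivals[1:]):
            if s2 <= e1:
                raise ValidationError(f"{self.symbol}: overlapping exons ({s1},{e1}) and ({s2},{e2})")

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    def exon(self, number: int) -> tuple[int, int]:
        if not 1 <= number <= self.n_exons:
            raise ValidationError(f"{self.symbol}: exon {number} outside 1..{self.n_exons}")
        return self.exons[number - 1]

    def boundary3(self, number: int) -> int:
        """Genomic coordinate of the transcript-3' (last transcribed) base of an exon."""
        s, e = self.exon(number)
        return e if self.strand == "+" else s

    def boundary5(self, number: int) -> int:
        """Genomic coordinate of the transcript-5' (first transcribed) base of an exon."""
        s, e = self.exon(number)
        return s if self.strand == "+" else e

    def span(self) -> tuple[int, int]:
        return min(s for s, _ in self.exons), max(e for _, e in self.exons)


# ---------------------------------------------------------------------------
# truth events
# ---------------------------------------------------------------------------

def event_label(event_type: str, gene5: str, gene3: str,
                donor_exon: int, acceptor_exon: int) -> str:
    """Build the exon-junction label, e.g. ``KIAA1549::BRAF 16–9``.

    Intragenic labels keep the junction reading order donor–acceptor,
    so a kinase-domain duplication of exons 10..17 reads ``KDD FGFR1 17–10``.
    """
    pair = f"{donor_exon}{EN_DASH}{acceptor_exon}"
    if event_type == "fusion":
        return f"{gene5}::{gene3} {pair}"
    if event_type == "kdd":
        return f"KDD {gene5} {pair}"
    if event_type == "exon_skip":
        return f"SKIP {gene5} {pair}"
    if event_type == "canonical":
        return f"{gene5} {pair}"
    raise ValidationError(f"no label grammar for event type {event_type!r}")


@dataclass(frozen=True)
class TruthEvent:
    """A simulated ground-truth structural event.

    Genomic breakpoint fields are filled in by
    :func:`junctionscope.simulate.make_event_transcript`.
    """

    event_type: str
    gene5: str
    gene3: str
    donor_exon: int
    acceptor_exon: int
    label: str = ""
    chrom_don: Optional[str] = None
    pos_don: Optional[int] = None
    strand_don: Optional[str] = None
    chrom_acc: Optional[str] = None
    pos_acc: Optional[int] = None
    strand_acc: Optional[str] = None

    def __post_init__(self) -> None:
        if self.event_type not in ("fusion", "kdd", "exon_skip"):
            raise ValidationError(f"unknown truth event type {self.event_type!r}")
        if self.event_type == "fusion" and self.gene5 == self.gene3:
            raise ValidationError("fusion requires two different genes")
        if self.event_type == "kdd":
            if self.gene5 != self.gene3:
                raise ValidationError("kdd is intragenic (gene5 == gene3)")
            if self.acceptor_exon > self.donor_exon:
                raise ValidationError("kdd requires acceptor_exon <= donor_exon")
        if self.event_type == "exon_skip":
            if self.gene5 != self.gene3:
                raise ValidationError("exon_skip is intragenic (gene5 == gene3)")
            if self.acceptor_exon < self.donor_exon + 2:
                raise ValidationError("exon_skip requires acceptor_exon >= donor_exon + 2")
        if not self.label:
            object.__setattr__(self, "label", event_label(
                self.event_type, self.gene5, self.gene3,
                self.donor_exon, self.acceptor_exon))

    def with_breakpoints(self, **kw) -> "TruthEvent":
        return replace(self, **kw)

    @property
    def read_tag(self) -> str:
        """ASCII id embedded in simulated read names for truth tracking."""
        return (f"{self.event_type}:{self.gene5}:{self.gene3}:"
                f"{self.donor_exon}:{self.acceptor_exon}")


@dataclass(frozen=True)
class ReadSimParams:
    read_length: int = 100
    fragment_mean: int = 250
    fragment_sd: float = 30.0
    depth: float = 50.0
    ffpe_degradation: float = 0.0
    substitution_rate: float = 0.0
    seed: int = 42

    def __post_init__(self) -> None:
        if self.read_length < 1 or self.fragment_mean < 1:
            raise ValidationError("read_length and fragment_mean must be positive")
        if self.read_length > self.fragment_mean:
            raise ValidationError("read_length must not exceed fragment_mean")
        for name in ("ffpe_degradation", "substitution_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1], got {v}")
        if self.depth < 0:
            raise ValidationError("depth must be non-negative")


# ---------------------------------------------------------------------------
# junctions and classified events
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChimericJunction:
    """One donor→acceptor breakpoint pair with read support.

    ``pos_don`` is the last transcribed base of the donor segment,
    ``pos_acc`` the first transcribed base of the acceptor segment.
    """

    chrom_don: str
    pos_don: int
    strand_don: str
    chrom_acc: str
    pos_acc: int
    strand_acc: str
    split_reads: int = 0
    spanning_pairs: int = 0

    def __post_init__(self) -> None:
        if self.pos_don < 1 or self.pos_acc < 1:
            raise ValidationError("junction coordinates are 1-based (>= 1)")
        if self.split_reads < 0 or self.spanning_pairs < 0:
            raise ValidationError("support counts must be non-negative")
        if self.strand_don not in "+-" or self.strand_acc not in "+-":
            raise ValidationError("strands must be '+' or '-'")


@dataclass(frozen=True)
class AnnotatedJunction:
    junction: ChimericJunction
    don_gene: Optional[str] = None
    acc_gene: Optional[str] = None
    don_exon: Optional[int] = None
    acc_exon: Optional[int] = None
    don_boundary_offset: Optional[int] = None
    acc_boundary_offset: Optional[int] = None


@dataclass(frozen=True)
class StructuralEvent:
    event_type: str
    gene5: Optional[str]
    gene3: Optional[str]
    donor_exon: Optional[int]
    acceptor_exon: Optional[int]
    label: str
    split_reads: int
    spanning_pairs: int
    # None encodes "n/a" (event types where the flag has no meaning)
    kinase_domain_retained: Optional[bool] = None
    autoinhibitory_lost: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.event_type not in EVENT_TYPES:
            raise ValidationError(f"unknown event type {self.event_type!r}")

    @property
    def total_support(self) -> int:
        return self.split_reads + self.spanning_pairs


@dataclass(frozen=True)
class DetectorConfig:
    """Thresholds for junction-to-event calling.

    The defaults (2 split reads, no pair requirement, 3 total) are the
    package's declared defaults: they pass pristine simulations while
    rejecting single-read decoys, and every one is configurable.
    """

    boundary_tolerance: int = 5
    min_split_reads: int = 2
    min_spanning_pairs: int = 0
    min_total_support: int = 3

    def __post_init__(self) -> None:
        for name in ("boundary_tolerance", "min_split_reads",
                     "min_spanning_pairs", "min_total_support"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
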