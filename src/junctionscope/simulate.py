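"""Synthetic genomes, event transcripts and paired-end reads.

The generator builds small random genomes whose gene geometries mimic the
kinase genes recurrently rearranged in pediatric low-grade glioma: a
BRAF-like gene whose N-terminal autoinhibitory exons precede the kinase
domain, an FGFR1-like gene whose kinase-domain exons can be internally
tandem-duplicated, a MET-like gene with a skippable internal exon, and the
usual 5' fusion partners. Event transcripts are exact exon concatenations,
so every downstream stage (mapping, junction extraction, classification)
can be tested against known truth without any external data.

Determinism: every operation takes a seed and produces byte-identical
output for identical inputs.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .models import (ChimericJunction, GeneModel, GenomeSpec, ReadSimParams,
                     TruthEvent, ValidationError)

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_UNIQ_K = 31          # exon sequences may not share any 31-mer
_GENE_GAP = 1000      # intergenic spacer between placed gene footprints
_MIN_OVERHANG = 31    # bases required on each side for a read to count as
                      # junction-crossing (matches the toy mapper's seed length)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return rng.choice(_BASES, size=n).tobytes().decode()


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def _kmers(seq: str, k: int = _UNIQ_K) -> set[str]:
    if len(seq) < k:
        return {seq}
    return {seq[i:i + k] for i in range(len(seq) - k + 1)}


# ---------------------------------------------------------------------------
# genome construction
# ---------------------------------------------------------------------------

def _place_genes(spec: GenomeSpec) -> list[tuple[str, int]]:
    """Assign (chrom, genomic start) per gene; explicit placements win."""
    names = spec.chrom_names()
    cursor = {c: _GENE_GAP + 1 for c in names}
    placed = []
    for i, g in enumerate(spec.genes):
        chrom = g.chrom if g.chrom is not None else names[i % len(names)]
        if chrom not in cursor:
            raise ValidationError(f"{g.symbol}: unknown chromosome {chrom!r}")
        start = g.start if g.start is not None else cursor[chrom]
        end = start + g.footprint - 1
        if end > spec.chrom_length:
            raise ValidationError(
                f"{g.symbol}: footprint {start}-{end} exceeds chromosome "
                f"length {spec.chrom_length}")
        placed.append((chrom, start))
        cursor[chrom] = max(cursor[chrom], end + _GENE_GAP + 1)
    # overlap check, naming both offenders
    by_chrom: dict[str, list[tuple[int, int, str]]] = {}
    for g, (chrom, start) in zip(spec.genes, placed):
        by_chrom.setdefault(chrom, []).append((start, start + g.footprint - 1, g.symbol))
    for chrom, spans in by_chrom.items():
        spans.sort()
        for (s1, e1, n1), (s2, e2, n2) in zip(spans, spans[1:]):
            if s2 <= e1:
                raise ValidationError(
                    f"gene footprints overlap on {chrom}: {n1} ({s1}-{e1}) "
                    f"and {n2} ({s2}-{e2})")
    return placed


def build_toy_genome(spec: GenomeSpec) -> tuple[dict[str, str], dict[str, GeneModel]]:
    """Generate chromosome sequences and strand-aware gene models.

    Exon sequences are rejection-resampled so that no two exons anywhere in
    the genome share a 31-mer, which makes split mapping with a 31-bp seed
    unambiguous on the toy genome.
    """
    rng = np.random.default_rng(spec.seed)
    placements = _place_genes(spec)
    chroms = {c: list(_random_seq(rng, spec.chrom_length))
              for c in spec.chrom_names()}
    seen_kmers: set[str] = set()
    models: dict[str, GeneModel] = {}
    for g, (chrom, gstart) in zip(spec.genes, placements):
        # genomic exon blocks, ascending
        blocks = []
        pos = gstart
        for _ in range(g.n_exons):
            blocks.append((pos, pos + g.exon_length - 1))
            pos += g.exon_length + g.intron_length
        # transcript order: '+' reads blocks forward, '-' backwards
        tx_blocks = tuple(blocks if g.strand == "+" else blocks[::-1])
        for s, e in tx_blocks:
            for _ in range(1000):
                exon_seq = _random_seq(rng, g.exon_length)
                kmers = _kmers(exon_seq) | _kmers(_revcomp(exon_seq))
                if not (kmers & seen_kmers):
                    seen_kmers |= kmers
                    break
            else:  # pragma: no cover - astronomically unlikely
                raise ValidationError(f"{g.symbol}: could not sample a unique exon sequence")
            genomic_seq = exon_seq if g.strand == "+" else _revcomp(exon_seq)
            chroms[chrom][s - 1:e] = genomic_seq
        models[g.symbol] = GeneModel(
            symbol=g.symbol, chrom=chrom, strand=g.strand, exons=tx_blocks,
            kinase_domain_exons=g.kinase_domain_exons,
            autoinhibitory_exons=g.autoinhibitory_exons)
    return {c: "".join(s) for c, s in chroms.items()}, models


def exon_sequence(genome: Mapping[str, str], model: GeneModel, number: int) -> str:
    """Transcript-orientation sequence of one exon."""
    s, e = model.exon(number)
    raw = genome[model.chrom][s - 1:e]
    return raw if model.strand == "+" else _revcomp(raw)


# ---------------------------------------------------------------------------
# event transcripts
# ---------------------------------------------------------------------------

def make_event_transcript(genome: Mapping[str, str],
                          models: Mapping[str, GeneModel],
                          truth: TruthEvent) -> tuple[str, TruthEvent]:
    """Build the chimeric mRNA for a truth event and fill in its breakpoints.

    fusion: exons 1..donor of the 5' gene then exons acceptor..last of the
    3' gene (the 3' gene typically contributing the kinase domain);
    kdd: exons 1..donor then acceptor..last of the same gene, duplicating
    the acceptor..donor span; exon_skip: all exons except
    donor+1..acceptor-1. The junction breakpoints are the genomic
    coordinates of the donor exon's last and the acceptor exon's first
    transcribed base.
    """
    g5 = models.get(truth.gene5)
    g3 = models.get(truth.gene3)
    if g5 is None or g3 is None:
        missing = truth.gene5 if g5 is None else truth.gene3
        raise ValidationError(f"unknown gene {missing!r} in truth event {truth.label!r}")
    if not 1 <= truth.donor_exon <= g5.n_exons:
        raise ValidationError(
            f"{truth.label}: donor exon {truth.donor_exon} outside 1..{g5.n_exons}")
    if not 1 <= truth.acceptor_exon <= g3.n_exons:
        raise ValidationError(
            f"{truth.label}: acceptor exon {truth.acceptor_exon} outside 1..{g3.n_exons}")

    head = [exon_sequence(genome, g5, i) for i in range(1, truth.donor_exon + 1)]
    tail = [exon_sequence(genome, g3, i) for i in range(truth.acceptor_exon, g3.n_exons + 1)]
    transcript = "".join(head) + "".join(tail)
    filled = truth.with_breakpoints(
        chrom_don=g5.chrom, pos_don=g5.boundary3(truth.donor_exon), strand_don=g5.strand,
        chrom_acc=g3.chrom, pos_acc=g3.boundary5(truth.acceptor_exon), strand_acc=g3.strand)
    return transcript, filled


def junction_offset(genome: Mapping[str, str], models: Mapping[str, GeneModel],
                    truth: TruthEvent) -> int:
    """Transcript length contributed by the donor side (the junction sits
    between base ``offset`` and ``offset + 1``, 1-based)."""
    g5 = models[truth.gene5]
    return sum(len(exon_sequence(genome, g5, i)) for i in range(1, truth.donor_exon + 1))


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------

def simulate_reads(transcript: str, truth: TruthEvent, params: ReadSimParams,
                   junction_pos: Optional[int] = None,
                   min_overhang: int = _MIN_OVERHANG,
                   ) -> tuple[list[tuple[SeqRecord, SeqRecord]], dict]:
    """Sample paired-end reads uniformly over an event transcript.

    At degradation 0 the pair count is Poisson with mean
    ``depth * len / (2 * read_length)``. FFPE-like degradation ``d`` acts
    twice: it shifts the effective fragment mean down to
    ``fragment_mean * (1 - 0.5 d)``, and it nicks fragments at a per-base
    rate ``0.005 d`` — a nicked fragment fails library conversion and is
    lost — so the usable pair yield, and with it the junction-spanning
    read yield, falls as degradation rises. Returns the read pairs plus a
    truth sidecar recording, per event, how many individual reads cross
    the junction with at least ``min_overhang`` aligned bases on each
    side — exactly the reads a 31-mer-seeded split mapper can recover.
    """
    rng = np.random.default_rng(params.seed)
    L = len(transcript)
    if params.depth > 0 and L < params.fragment_mean:
        raise ValidationError(
            f"transcript ({L} bp) shorter than fragment_mean "
            f"({params.fragment_mean} bp); use smaller fragments")
    mean_pairs = params.depth * L / (2 * params.read_length)
    n_pairs = int(rng.poisson(mean_pairs)) if mean_pairs > 0 else 0
    eff_mean = params.fragment_mean * (1.0 - 0.5 * params.ffpe_degradation)
    nick_rate = 0.005 * params.ffpe_degradation

    pairs: list[tuple[SeqRecord, SeqRecord]] = []
    n_crossing = 0
    jpos = junction_pos
    for i in range(n_pairs):
        frag = int(round(rng.normal(eff_mean, params.fragment_sd)))
        frag = max(params.read_length, min(frag, L))
        if nick_rate > 0 and rng.random() > np.exp(-nick_rate * frag):
            continue  # fragment nicked during fixation: lost from the library
        start = int(rng.integers(0, L - frag + 1))
        end = start + frag
        r1 = transcript[start:start + params.read_length]
        r2 = _revcomp(transcript[end - params.read_length:end])
        if params.substitution_rate > 0:
            r1 = _mutate(rng, r1, params.substitution_rate)
            r2 = _mutate(rng, r2, params.substitution_rate)
        if jpos is not None:
            for s, e in ((start, start + params.read_length),
                         (end - params.read_length, end)):
                if s + min_overhang <= jpos <= e - min_overhang:
                    n_crossing += 1
        name = f"{truth.read_tag}:pair{i:06d}"
        pairs.append((_fastq_record(f"{name}/1", r1),
                      _fastq_record(f"{name}/2", r2)))
    sidecar = {"label": truth.label, "event_type": truth.event_type,
               "n_pairs": n_pairs, "n_crossing_reads": n_crossing,
               "chrom_don": truth.chrom_don, "pos_don": truth.pos_don,
               "chrom_acc": truth.chrom_acc, "pos_acc": truth.pos_acc}
    return pairs, sidecar


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hits:
        choices = [b for b in b"ACGT" if bytes([b]) != arr[i]]
        arr[i] = bytes([rng.choice(choices)])
    return arr.tobytes().decode()


def _fastq_record(name: str, seq: str) -> SeqRecord:
    rec = SeqRecord(Seq(seq), id=name, description="")
    rec.letter_annotations["phred_quality"] = [40] * len(seq)
    return rec


# ---------------------------------------------------------------------------
# truth-junction emission (detector testing without a mapper)
# ---------------------------------------------------------------------------

def emit_truth_junctions(truths: Sequence[TruthEvent],
                         models: Mapping[str, GeneModel],
                         chrom_lengths: Mapping[str, int],
                         n_decoys: int = 0,
                         support_range: tuple[int, int] = (5, 20),
                         seed: int = 0,
                         tolerance: int = 5) -> list[ChimericJunction]:
    """One junction record per truth event plus unambiguous decoys.

    Decoy coordinates are drawn uniformly but rejected unless both sides
    sit at least ``tolerance + 1`` bases from every exon boundary, so a
    detector run at that tolerance must leave them unassigned.
    """
    rng = np.random.default_rng(seed)
    lo, hi = support_range
    if lo < 1 or hi < lo:
        raise ValidationError("support_range must be (lo, hi) with 1 <= lo <= hi")
    junctions = []
    for t in truths:
        if t.pos_don is None or t.pos_acc is None:
            raise ValidationError(
                f"{t.label}: breakpoints not filled in (run make_event_transcript first)")
        junctions.append(ChimericJunction(
            chrom_don=t.chrom_don, pos_don=t.pos_don, strand_don=t.strand_don,
            chrom_acc=t.chrom_acc, pos_acc=t.pos_acc, strand_acc=t.strand_acc,
            split_reads=int(rng.integers(lo, hi + 1)),
            spanning_pairs=int(rng.integers(0, hi + 1))))
    boundaries = {}
    for m in models.values():
        pts = boundaries.setdefault(m.chrom, [])
        for s, e in m.exons:
            pts.extend((s, e))
    chrom_names = sorted(chrom_lengths)
    for _ in range(n_decoys):
        sides = []
        while len(sides) < 2:
            chrom = chrom_names[int(rng.integers(0, len(chrom_names)))]
            pos = int(rng.integers(1, chrom_lengths[chrom] + 1))
            near = min((abs(pos - b) for b in boundaries.get(chrom, [])), default=tolerance + 1)
            if near >= tolerance + 1:
                sides.append((chrom, pos, "+-"[int(rng.integers(0, 2))]))
        (cd, pd_, sd), (ca, pa, sa) = sides
        junctions.append(ChimericJunction(
            chrom_don=cd, pos_don=pd_, strand_don=sd,
            chrom_acc=ca, pos_acc=pa, strand_acc=sa,
            split_reads=int(rng.integers(lo, hi + 1)),
            spanning_pairs=int(rng.integers(0, hi + 1))))
    return junctions
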