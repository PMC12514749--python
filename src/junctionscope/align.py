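"""Self-contained split-read mapping and chimeric-junction extraction.

The toy mapper is an exact k-mer-seed, ungapped-extension aligner for the
synthetic genomes produced by :mod:`junctionscope.simulate`, whose
exon-uniqueness guarantee makes 31-mer seeds unambiguous. A read crossing
one junction yields a primary plus a supplementary alignment; reads whose
seeds hit more than one locus are dropped and counted. Output is standard
SAM (written and re-read with pysam) so the extraction step also works on
externally produced split alignments.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Iterable, Mapping, Optional, Sequence

import pysam

from .models import ChimericJunction
from .simulate import _revcomp

DEFAULT_K = 31
_AMBIGUOUS = ("*", -1)

# genomic window within which a non-split mate may support a junction as
# one half of a spanning pair
SPANNING_WINDOW = 500


class _Segment:
    """One ungapped match of part of a read, in original read orientation."""

    __slots__ = ("chrom", "ref_start", "ref_end", "strand", "q_start", "q_end")

    def __init__(self, chrom: str, ref_start: int, ref_end: int, strand: str,
                 q_start: int, q_end: int):
        self.chrom = chrom          # 0-based
        self.ref_start = ref_start  # 0-based inclusive
        self.ref_end = ref_end      # 0-based exclusive
        self.strand = strand
        self.q_start = q_start      # read coordinates, 0-based half-open
        self.q_end = q_end


def build_index(genome: Mapping[str, str], k: int = DEFAULT_K) -> dict:
    """Forward-strand k-mer index; duplicated k-mers are marked ambiguous."""
    index: dict[str, tuple[str, int]] = {}
    for chrom, seq in genome.items():
        for i in range(len(seq) - k + 1):
            kmer = seq[i:i + k]
            index[kmer] = _AMBIGUOUS if kmer in index else (chrom, i)
    return index


_COMP = str.maketrans("ACGT", "TGCA")


def _seed_at(seq: str, i: int, genome: Mapping[str, str], index: dict,
             k: int) -> Optional[tuple]:
    """Resolve the seed starting at read position ``i``; ``None`` = no hit,
    ``_AMBIGUOUS`` = multi-locus hit."""
    kmer = seq[i:i + k]
    fwd = index.get(kmer)
    rev = index.get(kmer.translate(_COMP)[::-1])
    if fwd == _AMBIGUOUS or rev == _AMBIGUOUS or (fwd and rev):
        return _AMBIGUOUS
    if fwd:
        return (*fwd, "+")
    if rev:
        return (*rev, "-")
    return None


def _extend(seq: str, i: int, hit: tuple, genome: Mapping[str, str], k: int,
            back_limit: int = 0) -> _Segment:
    """Ungapped extension of a seed hit, forward and back to ``back_limit``."""
    chrom, p, strand = hit
    ref = genome[chrom]
    L = len(seq)
    j = i + k
    if strand == "+":
        while j < L and p + (j - i) < len(ref) and seq[j] == ref[p + (j - i)]:
            j += 1
        b = i
        while b > back_limit and p - (i - b) - 1 >= 0 \
                and seq[b - 1] == ref[p - (i - b) - 1]:
            b -= 1
        return _Segment(chrom, p - (i - b), p + (j - i), "+", b, j)
    # seq[i] pairs with ref position p+k-1 on the minus strand
    while j < L and p + k - 1 - (j - i) >= 0 \
            and seq[j] == ref[p + k - 1 - (j - i)].translate(_COMP):
        j += 1
    b = i
    while b > back_limit and p + k - 1 + (i - b) + 1 < len(ref) \
            and seq[b - 1] == ref[p + k + (i - b)].translate(_COMP):
        b -= 1
    return _Segment(chrom, p + k - (j - i), p + k + (i - b), "-", b, j)


def _map_segments(seq: str, genome: Mapping[str, str], index: dict,
                  k: int) -> Optional[list[_Segment]]:
    """Greedy left-to-right split mapping; ``None`` marks an ambiguous seed.

    When extension overruns a junction through micro-homology and leaves a
    remainder shorter than the seed, the remainder is rescued with an
    end-anchored seed whose overlap with the first segment is trimmed, so
    a read with at least ``k`` matchable bases on each side of one
    junction is always recovered as a split pair.
    """
    L = len(seq)
    segments: list[_Segment] = []
    i = 0
    while i + k <= L and not segments:
        hit = _seed_at(seq, i, genome, index, k)
        if hit is _AMBIGUOUS:
            return None
        if hit is None:
            i += 1
            continue
        segments.append(_extend(seq, i, hit, genome, k))
    if not segments or segments[0].q_end == L:
        return segments
    first = segments[0]
    # second segment: scan the remainder; if too short, anchor at the read end
    i = first.q_end
    while i + k <= L:
        hit = _seed_at(seq, i, genome, index, k)
        if hit is _AMBIGUOUS:
            return None
        if hit is not None:
            segments.append(_extend(seq, i, hit, genome, k, back_limit=first.q_end))
            return segments
        i += 1
    if L - first.q_end < k and L >= k:
        hit = _seed_at(seq, L - k, genome, index, k)
        if hit is _AMBIGUOUS:
            return None
        if hit is not None:
            seg2 = _extend(seq, L - k, hit, genome, k, back_limit=first.q_end)
            if seg2.q_start >= first.q_end and (seg2.chrom, seg2.ref_start,
                                                seg2.strand) != (first.chrom,
                                                                 first.ref_start,
                                                                 first.strand):
                segments.append(seg2)
    return segments


def _to_sam_record(seg: _Segment, seq: str, qname: str, header: pysam.AlignmentHeader,
                   is_read1: bool, supplementary: bool,
                   other: Optional[_Segment]) -> pysam.AlignedSegment:
    L = len(seq)
    a = pysam.AlignedSegment(header)
    a.query_name = qname
    a.reference_name = seg.chrom
    a.reference_start = seg.ref_start
    a.mapping_quality = 60
    a.is_paired = True
    a.is_read1 = is_read1
    a.is_read2 = not is_read1
    a.is_supplementary = supplementary
    m = seg.q_end - seg.q_start
    if seg.strand == "+":
        a.is_reverse = False
        stored = seq
        lead, trail = seg.q_start, L - seg.q_end
    else:
        a.is_reverse = True
        stored = _revcomp(seq)
        lead, trail = L - seg.q_end, seg.q_start
    cigar = []
    if lead:
        cigar.append((4, lead))
    cigar.append((0, m))
    if trail:
        cigar.append((4, trail))
    a.cigartuples = cigar
    a.query_sequence = stored
    a.query_qualities = pysam.qualitystring_to_array("I" * L)
    if other is not None:
        ocig = f"{other.q_end - other.q_start}M"
        a.set_tag("SA", f"{other.chrom},{other.ref_start + 1},{other.strand},{ocig},60,0;")
    return a


def toy_map_reads(pairs: Sequence[tuple], genome: Mapping[str, str],
                  out_sam: str, k: int = DEFAULT_K) -> dict:
    """Map paired reads against a toy genome, writing SAM.

    ``pairs`` holds ``(SeqRecord, SeqRecord)`` tuples as produced by
    :func:`junctionscope.simulate.simulate_reads` (read ids carry ``/1``
    and ``/2`` suffixes, which are stripped for SAM). Returns mapping
    statistics; ambiguous or unmappable reads are dropped and counted.
    """
    index = build_index(genome, k)
    header = pysam.AlignmentHeader.from_dict({
        "HD": {"VN": "1.6", "SO": "queryname"},
        "SQ": [{"SN": c, "LN": len(genome[c])} for c in sorted(genome)],
        "PG": [{"ID": "junctionscope-toymap", "PN": "junctionscope"}],
    })
    stats = {"pairs": len(pairs), "mapped_reads": 0, "split_reads": 0,
             "dropped_ambiguous": 0, "dropped_unmapped": 0}
    with pysam.AlignmentFile(out_sam, "w", header=header) as out:
        for r1, r2 in pairs:
            qname = r1.id.rsplit("/", 1)[0]
            for rec, is_read1 in ((r1, True), (r2, False)):
                seq = str(rec.seq).upper()
                segs = _map_segments(seq, genome, index, k)
                if segs is None:
                    stats["dropped_ambiguous"] += 1
                    continue
                if not segs:
                    stats["dropped_unmapped"] += 1
                    continue
                stats["mapped_reads"] += 1
                if len(segs) == 2:
                    stats["split_reads"] += 1
                    out.write(_to_sam_record(segs[0], seq, qname, header,
                                             is_read1, False, segs[1]))
                    out.write(_to_sam_record(segs[1], seq, qname, header,
                                             is_read1, True, segs[0]))
                else:
                    out.write(_to_sam_record(segs[0], seq, qname, header,
                                             is_read1, False, None))
    return stats


# ---------------------------------------------------------------------------
# junction extraction
# ---------------------------------------------------------------------------

def _orig_query_interval(aln: pysam.AlignedSegment) -> tuple[int, int]:
    """Aligned read interval in original read orientation (0-based half-open)."""
    L = aln.infer_read_length()
    qs, qe = aln.query_alignment_start, aln.query_alignment_end
    if aln.is_reverse:
        return L - qe, L - qs
    return qs, qe


def extract_chimeric_junctions(sam_path: str,
                               spanning_window: int = SPANNING_WINDOW,
                               ) -> tuple[list[ChimericJunction], dict]:
    """Aggregate split alignments into supported chimeric junctions.

    ``split_reads`` counts reads whose two segments flank an identical
    breakpoint pair (the donor position being the last transcribed base of
    the read-upstream segment). ``spanning_pairs`` counts non-split pairs
    whose mates fall on opposite sides of an already-evidenced junction
    within ``spanning_window`` bases. Malformed supplementary groups (more
    than two segments for one read) are skipped and counted.
    """
    by_read: dict[tuple[str, bool], list] = defaultdict(list)
    with pysam.AlignmentFile(sam_path, "r") as sam:
        for aln in sam:
            if aln.is_unmapped:
                continue
            by_read[(aln.query_name, aln.is_read1)].append(aln)

    support: dict[tuple, int] = defaultdict(int)
    nonsplit: dict[tuple[str, bool], tuple] = {}
    stats = {"malformed_skipped": 0, "split_reads_seen": 0}
    for key, alns in by_read.items():
        if len(alns) == 1:
            a = alns[0]
            nonsplit[key] = (a.reference_name, a.reference_start + 1, a.reference_end)
            continue
        if len(alns) != 2:
            stats["malformed_skipped"] += 1
            continue
        alns.sort(key=lambda a: _orig_query_interval(a)[0])
        don, acc = alns
        strand_d = "-" if don.is_reverse else "+"
        strand_a = "-" if acc.is_reverse else "+"
        pos_don = don.reference_end if strand_d == "+" else don.reference_start + 1
        pos_acc = acc.reference_start + 1 if strand_a == "+" else acc.reference_end
        key = (don.reference_name, pos_don, strand_d,
               acc.reference_name, pos_acc, strand_a)
        # mate 2 is sequenced antisense to the transcript: its junction
        # reads acceptor→donor, so flip it back into transcript orientation
        if don.is_read2:
            flip = {"+": "-", "-": "+"}
            key = (key[3], key[4], flip[key[5]], key[0], key[1], flip[key[2]])
        support[key] += 1
        stats["split_reads_seen"] += 1

    junctions = {k: [n, 0] for k, n in support.items()}

    # spanning pairs: both mates non-split, on opposite sides of a junction
    mates: dict[str, list] = defaultdict(list)
    for (qname, _), loc in nonsplit.items():
        mates[qname].append(loc)
    for qname, locs in mates.items():
        if len(locs) != 2:
            continue
        for key, counts in junctions.items():
            cd, pd_, sd, ca, pa, sa = key
            hits_don = [_on_donor_side(loc, cd, pd_, sd, spanning_window) for loc in locs]
            hits_acc = [_on_acceptor_side(loc, ca, pa, sa, spanning_window) for loc in locs]
            if (hits_don[0] and hits_acc[1]) or (hits_don[1] and hits_acc[0]):
                counts[1] += 1

    out = [ChimericJunction(chrom_don=k[0], pos_don=k[1], strand_don=k[2],
                            chrom_acc=k[3], pos_acc=k[4], strand_acc=k[5],
                            split_reads=v[0], spanning_pairs=v[1])
           for k, v in sorted(junctions.items())]
    return out, stats


def _on_donor_side(loc: tuple, chrom: str, pos: int, strand: str, window: int) -> bool:
    c, s, e = loc
    if c != chrom:
        return False
    if strand == "+":  # transcript-upstream of the breakpoint = genomically left
        return e <= pos and s >= pos - window
    return s >= pos and e <= pos + window


def _on_acceptor_side(loc: tuple, chrom: str, pos: int, strand: str, window: int) -> bool:
    c, s, e = loc
    if c != chrom:
        return False
    if strand == "+":
        return s >= pos and e <= pos + window
    return e <= pos and s >= pos - window
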