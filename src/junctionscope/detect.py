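"""Classification of chimeric junctions into structural events.

This is the analysis core: each donor→acceptor junction is assigned exon
context against strand-aware gene models and then classified by a fixed
rule order into canonical splice, exon skip, kinase-domain duplication
(acceptor exon at or before the donor exon of the same gene), fusion
(different genes, 5'→3' orientation), truncation (one side in a gene, the
other not) or unclassified. Fusions and duplications additionally carry
domain flags: whether the 3' partner's kinase domain is retained intact
and whether its autoinhibitory domain is lost — the functional reading
behind BRAF-fusion activation in pilocytic astrocytoma.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .io import REPORT_COLUMNS
from .models import (AnnotatedJunction, ChimericJunction, DetectorConfig,
                     GeneModel, StructuralEvent, event_label)


# ---------------------------------------------------------------------------
# exon-context assignment
# ---------------------------------------------------------------------------

def _match_boundary(chrom: str, pos: int, strand: str,
                    models: Mapping[str, GeneModel], side: str,
                    tolerance: int) -> tuple[Optional[str], Optional[int], Optional[int]]:
    """Nearest matching exon boundary within tolerance, or all-``None``.

    ``side`` selects the boundary kind: the donor side must hit an exon's
    transcript-3' boundary, the acceptor side a transcript-5' boundary.
    Signed offsets are measured along the transcript direction, so a donor
    position 3 bp inside its exon has offset -3. Ties break to the nearer
    boundary, then the lexicographically smaller gene symbol, then the
    lower exon number.
    """
    best = None
    for symbol in sorted(models):
        m = models[symbol]
        if m.chrom != chrom or m.strand != strand:
            continue
        sign = 1 if m.strand == "+" else -1
        for number in range(1, m.n_exons + 1):
            boundary = m.boundary3(number) if side == "donor" else m.boundary5(number)
            offset = sign * (pos - boundary)
            if abs(offset) > tolerance:
                continue
            key = (abs(offset), symbol, number)
            if best is None or key < best[0]:
                best = (key, symbol, number, offset)
    if best is None:
        return None, None, None
    _, symbol, number, offset = best
    return symbol, number, offset


def assign_exon_context(junction: ChimericJunction,
                        models: Mapping[str, GeneModel],
                        cfg: DetectorConfig = DetectorConfig()) -> AnnotatedJunction:
    """Attach gene/exon context to both sides of a junction.

    A side that matches no exon boundary within ``cfg.boundary_tolerance``
    keeps ``None`` fields — an unmatched side is a value, not an error.
    """
    don_gene, don_exon, don_off = _match_boundary(
        junction.chrom_don, junction.pos_don, junction.strand_don,
        models, "donor", cfg.boundary_tolerance)
    acc_gene, acc_exon, acc_off = _match_boundary(
        junction.chrom_acc, junction.pos_acc, junction.strand_acc,
        models, "acceptor", cfg.boundary_tolerance)
    return AnnotatedJunction(junction=junction,
                             don_gene=don_gene, acc_gene=acc_gene,
                             don_exon=don_exon, acc_exon=acc_exon,
                             don_boundary_offset=don_off, acc_boundary_offset=acc_off)


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def classify_event(a: AnnotatedJunction,
                   models: Mapping[str, GeneModel]) -> StructuralEvent:
    """Apply the event taxonomy to an annotated junction.

    Rule order: (1) both sides in the same gene — acceptor = donor + 1 is
    a canonical splice, acceptor >= donor + 2 an exon skip, acceptor <=
    donor a kinase-domain duplication; (2) both sides assigned but in
    different genes — a fusion with the donor gene as 5' partner; (3)
    exactly one side assigned — truncation; (4) neither — unclassified.
    Exactly one type applies to every junction.
    """
    j = a.junction
    support = dict(split_reads=j.split_reads, spanning_pairs=j.spanning_pairs)
    if a.don_gene is not None and a.acc_gene is not None:
        d, acc = a.don_exon, a.acc_exon
        if a.don_gene == a.acc_gene:
            if acc == d + 1:
                etype = "canonical"
            elif acc >= d + 2:
                etype = "exon_skip"
            else:
                etype = "kdd"
            return StructuralEvent(
                event_type=etype, gene5=a.don_gene, gene3=a.acc_gene,
                donor_exon=d, acceptor_exon=acc,
                label=event_label(etype, a.don_gene, a.acc_gene, d, acc), **support)
        return StructuralEvent(
            event_type="fusion", gene5=a.don_gene, gene3=a.acc_gene,
            donor_exon=d, acceptor_exon=acc,
            label=event_label("fusion", a.don_gene, a.acc_gene, d, acc), **support)
    if a.don_gene is not None or a.acc_gene is not None:
        gene = a.don_gene if a.don_gene is not None else a.acc_gene
        return StructuralEvent(
            event_type="truncation",
            gene5=a.don_gene, gene3=a.acc_gene,
            donor_exon=a.don_exon, acceptor_exon=a.acc_exon,
            label=f"truncat. {gene}", **support)
    return StructuralEvent(event_type="unclassified", gene5=None, gene3=None,
                           donor_exon=None, acceptor_exon=None,
                           label="unclassified", **support)


def assess_domain_retention(e: StructuralEvent,
                            models: Mapping[str, GeneModel]) -> StructuralEvent:
    """Set kinase/autoinhibitory domain flags on fusions and duplications.

    For a fusion, the 3' gene's kinase domain is retained iff all of its
    kinase exons lie at or after the acceptor exon, and the autoinhibitory
    domain is lost iff that range lies entirely before the acceptor exon.
    For a duplication, the kinase domain counts as retained (duplicated
    intact) iff the duplicated span covers the whole kinase-exon range.
    Other event types keep both flags as n/a.
    """
    if e.event_type not in ("fusion", "kdd"):
        return e
    g3 = models[e.gene3]
    kin = g3.kinase_domain_exons
    auto = g3.autoinhibitory_exons
    retained: Optional[bool] = None
    lost: Optional[bool] = None
    if e.event_type == "fusion":
        if kin is not None:
            retained = kin[0] >= e.acceptor_exon
        if auto is not None:
            lost = auto[1] < e.acceptor_exon
    else:  # kdd: duplicated span is [acceptor_exon, donor_exon]
        if kin is not None:
            retained = e.acceptor_exon <= kin[0] and kin[1] <= e.donor_exon
    return StructuralEvent(
        event_type=e.event_type, gene5=e.gene5, gene3=e.gene3,
        donor_exon=e.donor_exon, acceptor_exon=e.acceptor_exon, label=e.label,
        split_reads=e.split_reads, spanning_pairs=e.spanning_pairs,
        kinase_domain_retained=retained, autoinhibitory_lost=lost)


# ---------------------------------------------------------------------------
# filtering and end-to-end detection
# ---------------------------------------------------------------------------

def filter_events(events: Iterable[StructuralEvent],
                  cfg: DetectorConfig = DetectorConfig()) -> list[StructuralEvent]:
    """Support-threshold filter; non-findings never reach the report.

    Canonical splice junctions are the transcript's own structure and
    unclassified junctions carry no exon context; neither is reported.
    The kept set shrinks monotonically as any threshold rises.
    """
    kept = []
    for e in events:
        if e.event_type in ("canonical", "unclassified"):
            continue
        if e.split_reads < cfg.min_split_reads:
            continue
        if e.spanning_pairs < cfg.min_spanning_pairs:
            continue
        if e.total_support < cfg.min_total_support:
            continue
        kept.append(e)
    return kept


_FLAG = {True: "true", False: "false", None: "na"}


def events_to_frame(events: Sequence[StructuralEvent]) -> pd.DataFrame:
    rows = [{
        "event_type": e.event_type, "gene5": e.gene5 or "", "gene3": e.gene3 or "",
        "donor_exon": e.donor_exon if e.donor_exon is not None else "",
        "acceptor_exon": e.acceptor_exon if e.acceptor_exon is not None else "",
        "label": e.label, "split_reads": e.split_reads,
        "spanning_pairs": e.spanning_pairs,
        "kinase_domain_retained": _FLAG[e.kinase_domain_retained],
        "autoinhibitory_lost": _FLAG[e.autoinhibitory_lost],
    } for e in events]
    return pd.DataFrame(rows, columns=REPORT_COLUMNS)


def detect(junctions: Iterable[ChimericJunction],
           models: Mapping[str, GeneModel],
           cfg: DetectorConfig = DetectorConfig()) -> pd.DataFrame:
    """Full junction→event pipeline returning the sorted report table.

    Junctions that classify to the same event (same genes, exons and label
    — breakpoint jitter within the boundary tolerance) are aggregated with
    summed support before filtering. Report rows are ordered by
    (event_type, gene5, gene3, total support descending, label) for
    deterministic output.
    """
    events = []
    for j in junctions:
        e = classify_event(assign_exon_context(j, models, cfg), models)
        events.append(assess_domain_retention(e, models))
    merged: dict[tuple, StructuralEvent] = {}
    for e in events:
        key = (e.event_type, e.gene5, e.gene3, e.donor_exon, e.acceptor_exon, e.label)
        prev = merged.get(key)
        if prev is None:
            merged[key] = e
        else:
            merged[key] = StructuralEvent(
                event_type=e.event_type, gene5=e.gene5, gene3=e.gene3,
                donor_exon=e.donor_exon, acceptor_exon=e.acceptor_exon,
                label=e.label,
                split_reads=prev.split_reads + e.split_reads,
                spanning_pairs=prev.spanning_pairs + e.spanning_pairs,
                kinase_domain_retained=e.kinase_domain_retained,
                autoinhibitory_lost=e.autoinhibitory_lost)
    kept = filter_events(merged.values(), cfg)
    kept.sort(key=lambda e: (e.event_type, e.gene5 or "", e.gene3 or "",
                             -e.total_support, e.label))
    return events_to_frame(kept)
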