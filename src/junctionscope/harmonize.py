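"""Parsing, normalization and consensus of heterogeneous fusion-caller output.

Three dialects are supported: an Arriba-style TSV (gene1/gene2 with
``chrom:pos`` breakpoints and strand columns), a STAR-Fusion-style TSV
(``A--B`` fusion names with ``chr:pos:strand`` breakpoints) and an
anchored-multiplex-PCR-style CSV ("archer-like") that reports exon labels
and a GSP2-control unique-start-sites QC metric. Reports are normalized
(gene aliases, 5'→3' order preserved), matched across callers by ordered
gene pair plus breakpoint proximity or exon label, and reduced to
consensus calls under union / majority / intersection policies.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from math import ceil
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .models import EN_DASH, ValidationError

CALLERS = ("arriba_like", "starfusion_like", "archer_like")

QC_MIN_UNIQUE_START_SITES = 10  # pass requires strictly more than this


def qc_flag(unique_start_sites: int) -> bool:
    """Anchored-PCR QC rule: the GSP2 control must show more than 10
    unique RNA start sites. Failing samples keep their calls but flagged —
    fusions are still detectable in degraded libraries."""
    if unique_start_sites < 0:
        raise ValidationError("unique_start_sites must be >= 0")
    return unique_start_sites > QC_MIN_UNIQUE_START_SITES


@dataclass(frozen=True)
class Breakpoint:
    chrom: str
    pos: int
    strand: Optional[str] = None


@dataclass(frozen=True)
class CallerReport:
    """One normalized fusion record from one caller."""

    caller: str
    gene5: str
    gene3: str
    bp5: Optional[Breakpoint] = None
    bp3: Optional[Breakpoint] = None
    exon_label: Optional[str] = None
    support: Mapping[str, int] = field(default_factory=dict)
    confidence: Optional[str] = None
    qc_pass: Optional[bool] = None
    sample: Optional[str] = None

    def __post_init__(self) -> None:
        if self.caller not in CALLERS + ("other",):
            raise ValidationError(f"unknown caller {self.caller!r}")
        if not ((self.bp5 and self.bp3) or self.exon_label):
            raise ValidationError(
                f"{self.gene5}::{self.gene3}: need breakpoints or an exon label")


@dataclass(frozen=True)
class ParseIssue:
    row: int
    column: str
    message: str


@dataclass
class ParseResult:
    reports: list[CallerReport]
    errors: list[ParseIssue]


class FormatError(ValidationError):
    """A caller file is missing mandatory columns or is otherwise unreadable."""


# ---------------------------------------------------------------------------
# parsers (each dialect is defined bit-exactly by its writer below)
# ---------------------------------------------------------------------------

_ARRIBA_COLUMNS = ["gene1", "gene2", "strand1", "strand2",
                   "breakpoint1", "breakpoint2", "type",
                   "split_reads", "discordant_mates", "confidence"]
_STARFUSION_COLUMNS = ["FusionName", "JunctionReadCount", "SpanningFragCount",
                       "LeftBreakpoint", "RightBreakpoint"]
_ARCHER_COLUMNS = ["sample", "gene5", "gene3", "exon5", "exon3",
                   "breakpoint5", "breakpoint3", "reads", "unique_start_sites"]


def _require_columns(df: pd.DataFrame, required: Sequence[str], path: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing mandatory columns: {', '.join(missing)}")


def _parse_chrom_pos(text: str) -> tuple[str, int]:
    chrom, _, pos = str(text).rpartition(":")
    if not chrom or not pos.isdigit():
        raise ValueError(f"malformed breakpoint {text!r} (want chrom:pos)")
    return chrom, int(pos)


def parse_arriba_like(path: str) -> ParseResult:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    df.columns = [c.lstrip("#") for c in df.columns]
    _require_columns(df, _ARRIBA_COLUMNS[:7] + ["confidence"], path)
    reports, errors = [], []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            c5, p5 = _parse_chrom_pos(row.breakpoint1)
            c3, p3 = _parse_chrom_pos(row.breakpoint2)
        except ValueError as exc:
            errors.append(ParseIssue(row=i, column="breakpoint1/breakpoint2",
                                     message=str(exc)))
            continue
        reports.append(CallerReport(
            caller="arriba_like", gene5=row.gene1, gene3=row.gene2,
            bp5=Breakpoint(c5, p5, row.strand1 or None),
            bp3=Breakpoint(c3, p3, row.strand2 or None),
            support={"split_reads": int(row.split_reads or 0),
                     "discordant_mates": int(row.discordant_mates or 0)},
            confidence=row.confidence or None))
    return ParseResult(reports, errors)


def parse_starfusion_like(path: str) -> ParseResult:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    df.columns = [c.lstrip("#") for c in df.columns]
    _require_columns(df, _STARFUSION_COLUMNS, path)
    reports, errors = [], []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        name = row.FusionName
        if "--" not in name:
            errors.append(ParseIssue(row=i, column="FusionName",
                                     message=f"no '--' separator in {name!r}"))
            continue
        gene5, gene3 = name.split("--", 1)
        try:
            bp5 = _parse_bp_with_strand(row.LeftBreakpoint)
            bp3 = _parse_bp_with_strand(row.RightBreakpoint)
        except ValueError as exc:
            errors.append(ParseIssue(row=i, column="LeftBreakpoint/RightBreakpoint",
                                     message=str(exc)))
            continue
        reports.append(CallerReport(
            caller="starfusion_like", gene5=gene5, gene3=gene3, bp5=bp5, bp3=bp3,
            support={"split_reads": int(row.JunctionReadCount or 0),
                     "spanning_pairs": int(row.SpanningFragCount or 0)}))
    return ParseResult(reports, errors)


def _parse_bp_with_strand(text: str) -> Breakpoint:
    parts = str(text).split(":")
    if len(parts) != 3 or not parts[1].isdigit() or parts[2] not in "+-":
        raise ValueError(f"malformed breakpoint {text!r} (want chr:pos:strand)")
    return Breakpoint(parts[0], int(parts[1]), parts[2])


def parse_archer_like(path: str) -> ParseResult:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(df, _ARCHER_COLUMNS, path)
    reports, errors = [], []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        bp5 = bp3 = None
        try:
            if row.breakpoint5:
                bp5 = Breakpoint(*_parse_chrom_pos(row.breakpoint5))
            if row.breakpoint3:
                bp3 = Breakpoint(*_parse_chrom_pos(row.breakpoint3))
            uss = int(row.unique_start_sites)
        except ValueError as exc:
            errors.append(ParseIssue(row=i, column="breakpoint5/breakpoint3/unique_start_sites",
                                     message=str(exc)))
            continue
        label = None
        if row.exon5 and row.exon3:
            label = f"{row.exon5}{EN_DASH}{row.exon3}"
        reports.append(CallerReport(
            caller="archer_like", gene5=row.gene5, gene3=row.gene3,
            bp5=bp5, bp3=bp3, exon_label=label,
            support={"reads": int(row.reads or 0), "unique_start_sites": uss},
            qc_pass=qc_flag(uss), sample=row.sample or None))
    return ParseResult(reports, errors)


# ---------------------------------------------------------------------------
# writers (round-trip partners of the parsers)
# ---------------------------------------------------------------------------

def write_arriba_like(reports: Iterable[CallerReport], path: str) -> None:
    rows = [{"gene1": r.gene5, "gene2": r.gene3,
             "strand1": r.bp5.strand or "", "strand2": r.bp3.strand or "",
             "breakpoint1": f"{r.bp5.chrom}:{r.bp5.pos}",
             "breakpoint2": f"{r.bp3.chrom}:{r.bp3.pos}",
             "type": "translocation" if r.bp5.chrom != r.bp3.chrom else "deletion/read-through",
             "split_reads": r.support.get("split_reads", 0),
             "discordant_mates": r.support.get("discordant_mates", 0),
             "confidence": r.confidence or ""} for r in reports]
    pd.DataFrame(rows, columns=_ARRIBA_COLUMNS).to_csv(path, sep="\t", index=False)


def write_starfusion_like(reports: Iterable[CallerReport], path: str) -> None:
    rows = [{"FusionName": f"{r.gene5}--{r.gene3}",
             "JunctionReadCount": r.support.get("split_reads", 0),
             "SpanningFragCount": r.support.get("spanning_pairs", 0),
             "LeftBreakpoint": f"{r.bp5.chrom}:{r.bp5.pos}:{r.bp5.strand}",
             "RightBreakpoint": f"{r.bp3.chrom}:{r.bp3.pos}:{r.bp3.strand}"}
            for r in reports]
    pd.DataFrame(rows, columns=_STARFUSION_COLUMNS).to_csv(path, sep="\t", index=False)


def write_archer_like(reports: Iterable[CallerReport], path: str) -> None:
    rows = []
    for r in reports:
        exon5 = exon3 = ""
        if r.exon_label and EN_DASH in r.exon_label:
            exon5, exon3 = r.exon_label.split(EN_DASH, 1)
        rows.append({"sample": r.sample or "", "gene5": r.gene5, "gene3": r.gene3,
                     "exon5": exon5, "exon3": exon3,
                     "breakpoint5": f"{r.bp5.chrom}:{r.bp5.pos}" if r.bp5 else "",
                     "breakpoint3": f"{r.bp3.chrom}:{r.bp3.pos}" if r.bp3 else "",
                     "reads": r.support.get("reads", 0),
                     "unique_start_sites": r.support.get("unique_start_sites", 0)})
    pd.DataFrame(rows, columns=_ARCHER_COLUMNS).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# alias normalization
# ---------------------------------------------------------------------------

class AliasTable:
    """Symbol → canonical-symbol map; canonical symbols map to themselves."""

    def __init__(self, mapping: Mapping[str, str]):
        for sym, canon in mapping.items():
            resolved = mapping.get(canon, canon)
            if resolved != canon:
                raise ValidationError(
                    f"alias table not idempotent: {sym} -> {canon} -> {resolved}")
        self._map = dict(mapping)

    def canonical(self, symbol: str) -> str:
        return self._map.get(symbol, symbol)

    @classmethod
    def default(cls) -> "AliasTable":
        text = resources.files("junctionscope.data").joinpath("aliases.tsv").read_text()
        mapping = {}
        for line in text.splitlines()[1:]:
            if line.strip():
                sym, canon = line.split("\t")
                mapping[sym] = canon
        return cls(mapping)


def normalize(report: CallerReport, aliases: AliasTable) -> CallerReport:
    """Canonicalize gene symbols; the 5'/3' order is never touched
    (fusion direction is meaningful — reciprocal pairs are distinct)."""
    return replace(report, gene5=aliases.canonical(report.gene5),
                   gene3=aliases.canonical(report.gene3))


# ---------------------------------------------------------------------------
# cross-caller matching and consensus
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConsensusEvent:
    gene5: str
    gene3: str
    key_label: str
    per_caller: Mapping[str, bool]
    n_callers_detected: int
    status: str
    span_warning: bool = False

    def __post_init__(self) -> None:
        if self.n_callers_detected < 1:
            raise ValidationError("a consensus event needs at least one detection")
        concordant = all(self.per_caller.values())
        if (self.status == "concordant") != concordant:
            raise ValidationError("status inconsistent with per-caller flags")

    def __hash__(self) -> int:
        return hash((self.gene5, self.gene3, self.key_label,
                     tuple(sorted(self.per_caller.items())),
                     self.n_callers_detected, self.status, self.span_warning))


def _reports_match(a: CallerReport, b: CallerReport, bp_tolerance: int) -> bool:
    if (a.gene5, a.gene3) != (b.gene5, b.gene3):
        return False
    if a.bp5 and a.bp3 and b.bp5 and b.bp3:
        return (a.bp5.chrom == b.bp5.chrom and a.bp3.chrom == b.bp3.chrom
                and abs(a.bp5.pos - b.bp5.pos) <= bp_tolerance
                and abs(a.bp3.pos - b.bp3.pos) <= bp_tolerance)
    return a.exon_label is not None and a.exon_label == b.exon_label


def match_events(reports: Sequence[CallerReport], bp_tolerance: int = 10,
                 callers: Optional[Sequence[str]] = None) -> list[ConsensusEvent]:
    """Cluster caller reports into consensus events.

    Two reports match iff they share the ordered gene pair and either both
    breakpoint pairs agree within ``bp_tolerance`` bases or (when
    breakpoints are unavailable) their exon labels are equal. Matching is
    closed transitively, so a cluster may chain breakpoints farther apart
    than the tolerance; such clusters carry ``span_warning``. The result
    is deterministic and independent of input report order.
    """
    reports = sorted(reports, key=_report_sort_key)
    compared = tuple(callers) if callers is not None else tuple(
        sorted({r.caller for r in reports}))
    parent = list(range(len(reports)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(reports)):
        for j in range(i + 1, len(reports)):
            if _reports_match(reports[i], reports[j], bp_tolerance):
                parent[find(i)] = find(j)

    clusters: dict[int, list[CallerReport]] = {}
    for i in range(len(reports)):
        clusters.setdefault(find(i), []).append(reports[i])

    events = []
    for members in clusters.values():
        detected = {c: any(r.caller == c for r in members) for c in compared}
        rep = members[0]
        label = rep.exon_label or (
            f"{rep.bp5.chrom}:{rep.bp5.pos}|{rep.bp3.chrom}:{rep.bp3.pos}"
            if rep.bp5 and rep.bp3 else "")
        span = 0
        positions5 = [m.bp5.pos for m in members if m.bp5]
        positions3 = [m.bp3.pos for m in members if m.bp3]
        if positions5 and positions3:
            span = max(max(positions5) - min(positions5),
                       max(positions3) - min(positions3))
        events.append(ConsensusEvent(
            gene5=rep.gene5, gene3=rep.gene3, key_label=label,
            per_caller=detected, n_callers_detected=len({m.caller for m in members}),
            status="concordant" if all(detected.values()) else "discordant",
            span_warning=span > bp_tolerance))
    events.sort(key=lambda e: (e.gene5, e.gene3, e.key_label))
    return events


def _report_sort_key(r: CallerReport):
    return (r.gene5, r.gene3, r.caller,
            r.bp5.pos if r.bp5 else -1, r.bp3.pos if r.bp3 else -1,
            r.exon_label or "")


POLICIES = ("union", "majority", "intersection")


def consensus_policy(events: Sequence[ConsensusEvent], policy: str,
                     n_callers: Optional[int] = None) -> list[ConsensusEvent]:
    """Reduce consensus events to a final call set.

    union keeps anything one caller saw; majority needs ceil(k/2) of the k
    compared callers; intersection needs all of them.
    """
    if policy not in POLICIES:
        raise ValidationError(f"unknown policy {policy!r}; want one of {POLICIES}")
    if not events:
        return []
    k = n_callers if n_callers is not None else max(len(e.per_caller) for e in events)
    need = {"union": 1, "majority": ceil(k / 2), "intersection": k}[policy]
    return [e for e in events if e.n_callers_detected >= need]


def consensus_to_frame(events: Sequence[ConsensusEvent]) -> pd.DataFrame:
    callers = sorted({c for e in events for c in e.per_caller}) if events else []
    rows = []
    for e in events:
        row = {"gene5": e.gene5, "gene3": e.gene3, "key": e.key_label,
               "n_callers": e.n_callers_detected, "status": e.status,
               "span_warning": str(e.span_warning).lower()}
        for c in callers:
            row[c] = "detected" if e.per_caller.get(c) else "missed"
        rows.append(row)
    cols = ["gene5", "gene3", "key"] + callers + ["n_callers", "status", "span_warning"]
    return pd.DataFrame(rows, columns=cols)
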