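"""Readers and writers for the standard formats the pipeline touches.

FASTA and FASTQ go through Biopython, GFF3 reading through gffutils, and
tabular files through pandas. Transcript-order exon numbers are carried in
a GFF3 ``exon_number`` attribute so files stay standard (rows sorted by
genomic start) while preserving exon-junction numbering semantics.
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping, Optional, Sequence

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .models import ChimericJunction, GeneModel, ValidationError

JUNCTION_COLUMNS = ["chrom_don", "pos_don", "strand_don",
                    "chrom_acc", "pos_acc", "strand_acc",
                    "split_reads", "spanning_pairs"]

REPORT_COLUMNS = ["event_type", "gene5", "gene3", "donor_exon", "acceptor_exon",
                  "label", "split_reads", "spanning_pairs",
                  "kinase_domain_retained", "autoinhibitory_lost"]


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def write_genome(sequences: Mapping[str, str], path: str) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="")
               for name, seq in sequences.items()]
    SeqIO.write(records, path, "fasta")


def read_genome(path: str) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def write_annotation(models: Iterable[GeneModel], path: str) -> None:
    """Write gene models as GFF3, one ``gene`` row plus its ``exon`` rows.

    Rows are sorted by (chrom, genomic start); for '-'-strand genes the
    exons therefore appear in ascending genomic order even though their
    transcript-order numbers descend.
    """
    rows = []
    for m in models:
        lo, hi = m.span()
        attrs = [f"ID=gene:{m.symbol}", f"Name={m.symbol}"]
        if m.kinase_domain_exons:
            attrs.append("kinase_domain_exons=%d-%d" % m.kinase_domain_exons)
        if m.autoinhibitory_exons:
            attrs.append("autoinhibitory_exons=%d-%d" % m.autoinhibitory_exons)
        rows.append((m.chrom, lo, hi, m.strand, "gene", ";".join(attrs)))
        for number, (s, e) in enumerate(m.exons, start=1):
            attrs = [f"ID=exon:{m.symbol}.{number}", f"Parent=gene:{m.symbol}",
                     f"exon_number={number}"]
            rows.append((m.chrom, s, e, m.strand, "exon", ";".join(attrs)))
    rows.sort(key=lambda r: (r[0], r[1], r[4] != "gene", r[2]))
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom, start, end, strand, ftype, attrs in rows:
            fh.write(f"{chrom}\tjunctionscope\t{ftype}\t{start}\t{end}\t.\t{strand}\t.\t{attrs}\n")


def _parse_range(text: str) -> tuple[int, int]:
    lo, hi = text.split("-")
    return int(lo), int(hi)


def read_annotation(path: str) -> dict[str, GeneModel]:
    """Load gene models back from GFF3 (inverse of :func:`write_annotation`)."""
    db = gffutils.create_db(path, dbfn=":memory:", force=True,
                            keep_order=True, merge_strategy="error")
    models: dict[str, GeneModel] = {}
    for gene in db.features_of_type("gene"):
        symbol = gene.attributes["Name"][0]
        exons = {}
        for exon in db.children(gene, featuretype="exon"):
            number = int(exon.attributes["exon_number"][0])
            exons[number] = (exon.start, exon.end)
        ordered = tuple(exons[i] for i in sorted(exons))
        kin = gene.attributes.get("kinase_domain_exons")
        auto = gene.attributes.get("autoinhibitory_exons")
        models[symbol] = GeneModel(
            symbol=symbol, chrom=gene.seqid, strand=gene.strand, exons=ordered,
            kinase_domain_exons=_parse_range(kin[0]) if kin else None,
            autoinhibitory_exons=_parse_range(auto[0]) if auto else None,
        )
    return models


# ---------------------------------------------------------------------------
# FASTQ
# ---------------------------------------------------------------------------

def write_fastq_pairs(pairs: Sequence[tuple[SeqRecord, SeqRecord]],
                      path_r1: str, path_r2: str) -> None:
    SeqIO.write([p[0] for p in pairs], path_r1, "fastq")
    SeqIO.write([p[1] for p in pairs], path_r2, "fastq")


def read_fastq(path: str) -> list[SeqRecord]:
    return list(SeqIO.parse(path, "fastq"))


# ---------------------------------------------------------------------------
# chimeric-junction TSV and event report TSV
# ---------------------------------------------------------------------------

def write_junctions(junctions: Iterable[ChimericJunction], path: str,
                    header_lines: Optional[Sequence[str]] = None) -> None:
    df = pd.DataFrame([{
        "chrom_don": j.chrom_don, "pos_don": j.pos_don, "strand_don": j.strand_don,
        "chrom_acc": j.chrom_acc, "pos_acc": j.pos_acc, "strand_acc": j.strand_acc,
        "split_reads": j.split_reads, "spanning_pairs": j.spanning_pairs,
    } for j in junctions], columns=JUNCTION_COLUMNS)
    _write_tsv(df, path, header_lines)


def read_junctions(path: str) -> list[ChimericJunction]:
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in JUNCTION_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"junction file {path} lacks columns: {', '.join(missing)}")
    return [ChimericJunction(
        chrom_don=str(r.chrom_don), pos_don=int(r.pos_don), strand_don=str(r.strand_don),
        chrom_acc=str(r.chrom_acc), pos_acc=int(r.pos_acc), strand_acc=str(r.strand_acc),
        split_reads=int(r.split_reads), spanning_pairs=int(r.spanning_pairs),
    ) for r in df.itertuples()]


def _write_tsv(df: pd.DataFrame, path: str,
               header_lines: Optional[Sequence[str]] = None) -> None:
    with open(path, "w") as fh:
        for line in header_lines or ():
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)


def write_report(df: pd.DataFrame, path: str,
                 header_lines: Optional[Sequence[str]] = None) -> None:
    _write_tsv(df, path, header_lines)


def read_report(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def ensure_dir(path: str) -> str:
    os.makedirs(path, exist_ok=True)
    return path
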