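"""Default toy genome and truth-event set.

The gene roster mirrors the recurrent pLGG players: a 19-exon KIAA1549-like
5' partner, an 18-exon BRAF-like gene on the '-' strand with its
autoinhibitory domain in exons 1-6 and kinase domain in exons 11-18,
FGFR1/FGFR2-like receptor kinases whose kinase-domain exons (10-17) can be
internally duplicated, a MET-like gene with a skippable exon 14, NTRK-like
kinases, and the common 5' fusion partners. The default truth set holds 20
distinct events: the nine observed KIAA1549::BRAF exon-exon junctions, six
further fusions, two kinase-domain duplications and three exon skips.
"""

from __future__ import annotations

from .models import GeneSpec, GenomeSpec, TruthEvent

DEFAULT_SEED = 42

_GENES = (
    # chr1
    GeneSpec("KIAA1549L", "+", 19, chrom="chr1"),
    GeneSpec("BRAFL", "-", 18, kinase_domain_exons=(11, 18),
             autoinhibitory_exons=(1, 6), chrom="chr1"),
    GeneSpec("PAG1L", "+", 10, chrom="chr1"),
    GeneSpec("TAX1BP1L", "+", 10, chrom="chr1"),
    # chr2
    GeneSpec("FGFR1L", "-", 18, kinase_domain_exons=(10, 17), chrom="chr2"),
    GeneSpec("FGFR2L", "-", 18, kinase_domain_exons=(10, 17), chrom="chr2"),
    GeneSpec("SHTN1L", "+", 12, chrom="chr2"),
    GeneSpec("TACC1L", "+", 13, chrom="chr2"),
    # chr3
    GeneSpec("METL", "+", 21, kinase_domain_exons=(15, 21), chrom="chr3"),
    GeneSpec("NTRK2L", "+", 20, kinase_domain_exons=(13, 20), chrom="chr3"),
    GeneSpec("NTRK3L", "-", 20, kinase_domain_exons=(13, 20), chrom="chr3"),
    GeneSpec("NACC2L", "+", 8, chrom="chr3"),
    GeneSpec("ETV6L", "+", 8, chrom="chr3"),
)


def default_genome_spec(seed: int = DEFAULT_SEED) -> GenomeSpec:
    return GenomeSpec(n_chromosomes=3, chrom_length=30_000, genes=_GENES, seed=seed)


def default_truth_events() -> list[TruthEvent]:
    """The 20-event simulation fixture (all breakpoint-distinct)."""
    kiaa_braf = [(16, 9), (15, 9), (16, 11), (15, 11), (13, 11),
                 (13, 9), (10, 9), (17, 11), (19, 9)]
    events = [TruthEvent("fusion", "KIAA1549L", "BRAFL", d, a) for d, a in kiaa_braf]
    events += [
        TruthEvent("fusion", "PAG1L", "BRAFL", 5, 9),
        TruthEvent("fusion", "TAX1BP1L", "BRAFL", 5, 9),
        TruthEvent("fusion", "FGFR2L", "SHTN1L", 17, 7),
        TruthEvent("fusion", "FGFR1L", "TACC1L", 17, 7),
        TruthEvent("fusion", "NACC2L", "NTRK2L", 5, 13),
        TruthEvent("fusion", "ETV6L", "NTRK3L", 5, 15),
        TruthEvent("kdd", "FGFR1L", "FGFR1L", 17, 10),
        TruthEvent("kdd", "FGFR2L", "FGFR2L", 17, 10),
        TruthEvent("exon_skip", "METL", "METL", 13, 15),
        TruthEvent("exon_skip", "METL", "METL", 10, 13),
        TruthEvent("exon_skip", "NTRK2L", "NTRK2L", 11, 13),
    ]
    return events
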