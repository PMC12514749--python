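"""Detector behaviour: toy mapping, junction extraction, classification."""

import pysam
import pytest
from hypothesis import given
from hypothesis import strategies as st

import junctionscope.io as jio
from junctionscope.align import extract_chimeric_junctions, toy_map_reads
from junctionscope.detect import (assess_domain_retention, assign_exon_context,
                                  classify_event, detect, filter_events)
from junctionscope.models import (AnnotatedJunction, ChimericJunction,
                                  DetectorConfig, GeneModel, ReadSimParams,
                                  StructuralEvent, TruthEvent)
from junctionscope.simulate import (_revcomp, emit_truth_junctions,
                                    exon_sequence, junction_offset,
                                    make_event_transcript, simulate_reads)


def _record(name, seq):
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord
    rec = SeqRecord(Seq(seq), id=name, description="")
    rec.letter_annotations["phred_quality"] = [40] * len(seq)
    return rec


def _junction_for(models, gene5, donor, gene3, acceptor, split=10, pairs=2):
    g5, g3 = models[gene5], models[gene3]
    return ChimericJunction(
        chrom_don=g5.chrom, pos_don=g5.boundary3(donor), strand_don=g5.strand,
        chrom_acc=g3.chrom, pos_acc=g3.boundary5(acceptor), strand_acc=g3.strand,
        split_reads=split, spanning_pairs=pairs)


class TestToyMapper:
    def test_read_within_one_exon_maps_uniquely(self, tmp_path, genome, models):
        m = models["METL"]
        seq = exon_sequence(genome, m, 5)[:100]
        sam = str(tmp_path / "one.sam")
        stats = toy_map_reads([(_record("r/1", seq), _record("r/2", _revcomp(seq)))],
                              genome, sam)
        assert stats["split_reads"] == 0 and stats["mapped_reads"] == 2
        alns = list(pysam.AlignmentFile(sam, "r"))
        assert len(alns) == 2
        assert all(not a.is_supplementary for a in alns)

    def test_junction_read_yields_clipped_alignment_pair(self, tmp_path, genome, models):
        tx, t = make_event_transcript(
            genome, models, TruthEvent("fusion", "KIAA1549L", "BRAFL", 16, 9))
        j = junction_offset(genome, models, t)
        read = tx[j - 50:j + 50]  # 50 bp on each side of the junction
        sam = str(tmp_path / "split.sam")
        toy_map_reads([(_record("r/1", read), _record("r/2", _revcomp(read)))],
                      genome, sam)
        alns = [a for a in pysam.AlignmentFile(sam, "r") if a.is_read1]
        assert len(alns) == 2
        assert sum(a.is_supplementary for a in alns) == 1
        clips = [a.query_length - a.query_alignment_length for a in alns]
        assert sorted(clips) == [50, 50]  # the two clips partition the read

    def test_no_reads_gives_header_only_sam(self, tmp_path, genome):
        sam = str(tmp_path / "empty.sam")
        stats = toy_map_reads([], genome, sam)
        assert stats["mapped_reads"] == 0
        assert list(pysam.AlignmentFile(sam, "r")) == []


class TestJunctionExtraction:
    def test_seven_crossing_reads_aggregate_to_one_junction(
            self, tmp_path, genome, models):
        tx, t = make_event_transcript(
            genome, models, TruthEvent("fusion", "PAG1L", "BRAFL", 5, 9))
        j = junction_offset(genome, models, t)
        pairs = [( _record(f"r{i}/1", tx[j - 60 + i:j + 40 + i]),
                   _record(f"r{i}/2", _revcomp(tx[j + 40 + i:j + 140 + i])))
                 for i in range(7)]
        sam = str(tmp_path / "seven.sam")
        toy_map_reads(pairs, genome, sam)
        junctions, _ = extract_chimeric_junctions(sam)
        chimeric = [x for x in junctions
                    if (x.chrom_don, x.pos_don) == (t.chrom_don, t.pos_don)]
        assert len(chimeric) == 1
        assert chimeric[0].split_reads == 7
        assert (chimeric[0].pos_acc, chimeric[0].strand_acc) == (t.pos_acc, t.strand_acc)

    def test_no_chimeric_reads_gives_empty_set(self, tmp_path, genome, models):
        seq = exon_sequence(genome, models["METL"], 3)[:100]
        sam = str(tmp_path / "plain.sam")
        toy_map_reads([(_record("r/1", seq), _record("r/2", _revcomp(seq)))],
                      genome, sam)
        junctions, _ = extract_chimeric_junctions(sam)
        assert junctions == []

    def test_split_support_is_conserved_per_event(self, tmp_path, genome, models):
        """Every junction-crossing read the simulator emits is recovered as
        split support at (or within micro-homology jitter of) the truth
        breakpoint pair."""
        events = [TruthEvent("fusion", "KIAA1549L", "BRAFL", 16, 9),
                  TruthEvent("kdd", "FGFR1L", "FGFR1L", 17, 10),
                  TruthEvent("exon_skip", "METL", "METL", 13, 15)]
        pairs, sidecars, filled = [], [], []
        for i, tr in enumerate(events):
            tx, t = make_event_transcript(genome, models, tr)
            ev, sc = simulate_reads(tx, t, ReadSimParams(depth=40, seed=300 + i),
                                    junction_pos=junction_offset(genome, models, t))
            pairs += ev
            sidecars.append(sc)
            filled.append(t)
        sam = str(tmp_path / "cons.sam")
        toy_map_reads(pairs, genome, sam)
        junctions, _ = extract_chimeric_junctions(sam)
        for t, sc in zip(filled, sidecars):
            got = sum(j.split_reads for j in junctions
                      if j.chrom_don == t.chrom_don and j.chrom_acc == t.chrom_acc
                      and abs(j.pos_don - t.pos_don) <= 30
                      and abs(j.pos_acc - t.pos_acc) <= 30)
            assert got == sc["n_crossing_reads"]


class TestExonContext:
    def test_exact_boundary_offset_zero(self, models):
        j = _junction_for(models, "KIAA1549L", 16, "BRAFL", 9)
        a = assign_exon_context(j, models)
        assert (a.don_gene, a.don_exon, a.don_boundary_offset) == ("KIAA1549L", 16, 0)
        assert (a.acc_gene, a.acc_exon, a.acc_boundary_offset) == ("BRAFL", 9, 0)

    @pytest.mark.parametrize("strand_gene", ["KIAA1549L", "BRAFL"])
    def test_donor_inside_exon_has_negative_offset(self, models, strand_gene):
        m = models[strand_gene]
        boundary = m.boundary3(7)
        pos = boundary - 3 if m.strand == "+" else boundary + 3
        j = ChimericJunction(chrom_don=m.chrom, pos_don=pos, strand_don=m.strand,
                             chrom_acc="chr3", pos_acc=99999, strand_acc="+",
                             split_reads=1)
        a = assign_exon_context(j, models)
        assert (a.don_gene, a.don_exon, a.don_boundary_offset) == (strand_gene, 7, -3)

    def test_decoy_far_from_boundaries_stays_unassigned(self, models, genome, truths):
        lens = {c: len(s) for c, s in genome.items()}
        decoys = emit_truth_junctions(truths[:1], models, lens,
                                      n_decoys=10, seed=3)[1:]
        for d in decoys:
            a = assign_exon_context(d, models)
            assert a.don_gene is None and a.acc_gene is None

    def test_equidistant_boundaries_take_lower_exon(self):
        # exons [1,4] and [9,12]: donor boundaries 4 and 12; position 8 is
        # 4 bases from both -> lower exon number wins
        gm = {"TIE": GeneModel("TIE", "chrX", "+", ((1, 4), (9, 12)))}
        j = ChimericJunction(chrom_don="chrX", pos_don=8, strand_don="+",
                             chrom_acc="chrX", pos_acc=1000, strand_acc="+",
                             split_reads=1)
        a = assign_exon_context(j, gm, DetectorConfig(boundary_tolerance=5))
        assert (a.don_exon, a.don_boundary_offset) == (1, 4)

    def test_cross_gene_tie_prefers_nearer_then_smaller_symbol(self):
        gm = {"AAA": GeneModel("AAA", "chrX", "+", ((1, 10),)),
              "BBB": GeneModel("BBB", "chrX", "+", ((14, 20),))}
        j = ChimericJunction(chrom_don="chrX", pos_don=12, strand_don="+",
                             chrom_acc="chrX", pos_acc=1000, strand_acc="+",
                             split_reads=1)
        a = assign_exon_context(j, gm, DetectorConfig(boundary_tolerance=5))
        assert a.don_gene == "AAA"  # |12-10| = 2 beats nothing nearer


def _oracle_type(gene_d, exon_d, gene_a, exon_a):
    """Brute-force taxonomy: direct restatement of the event definitions."""
    if gene_d == gene_a:
        if exon_a == exon_d + 1:
            return "canonical"
        if exon_a >= exon_d + 2:
            return "exon_skip"
        return "kdd"
    return "fusion"


class TestClassification:
    @pytest.mark.parametrize("g5,d,g3,a,etype,label", [
        ("METL", 13, "METL", 15, "exon_skip", "SKIP METL 13–15"),
        ("FGFR1L", 17, "FGFR1L", 10, "kdd", "KDD FGFR1L 17–10"),
        ("KIAA1549L", 16, "BRAFL", 9, "fusion", "KIAA1549L::BRAFL 16–9"),
        ("METL", 4, "METL", 5, "canonical", "METL 4–5"),
    ])
    def test_taxonomy_examples(self, models, g5, d, g3, a, etype, label):
        j = _junction_for(models, g5, d, g3, a)
        e = classify_event(assign_exon_context(j, models), models)
        assert (e.event_type, e.label) == (etype, label)

    def test_single_sided_junction_is_truncation(self, models):
        m = models["BRAFL"]
        j = ChimericJunction(chrom_don=m.chrom, pos_don=m.boundary3(5),
                             strand_don=m.strand, chrom_acc="chr2",
                             pos_acc=29_999, strand_acc="+", split_reads=4)
        e = classify_event(assign_exon_context(j, models), models)
        assert e.event_type == "truncation"
        assert e.label == "truncat. BRAFL"

    def test_exhaustive_agreement_with_taxonomy_oracle(self, three_gene_toy):
        """Every donor/acceptor exon-boundary pair of the 3-gene toy
        annotation (both orders) classifies exactly as the brute-force
        taxonomy oracle says; off-boundary positions are unclassified."""
        genome, models = three_gene_toy
        gene_exons = [(g, i) for g in sorted(models)
                      for i in range(1, models[g].n_exons + 1)]
        checked = 0
        for gd, ed in gene_exons:
            for ga, ea in gene_exons:
                j = _junction_for(models, gd, ed, ga, ea)
                e = classify_event(assign_exon_context(j, models), models)
                assert e.event_type == _oracle_type(gd, ed, ga, ea), (gd, ed, ga, ea)
                assert (e.gene5, e.gene3) == (gd, ga)
                assert (e.donor_exon, e.acceptor_exon) == (ed, ea)
                checked += 1
        assert checked == 19 * 19
        # off-boundary decoys: shift both sides beyond tolerance
        for gd, ed in gene_exons[::3]:
            m = models[gd]
            j = ChimericJunction(
                chrom_don=m.chrom,
                pos_don=m.boundary3(ed) + (25 if m.strand == "+" else -25),
                strand_don=m.strand, chrom_acc=m.chrom,
                pos_acc=m.boundary5(ed) - (25 if m.strand == "+" else -25),
                strand_acc=m.strand, split_reads=5)
            e = classify_event(assign_exon_context(j, models), models)
            assert e.event_type == "unclassified"

    def test_every_junction_gets_exactly_one_type(self, models, genome, truths):
        lens = {c: len(s) for c, s in genome.items()}
        junctions = emit_truth_junctions(truths, models, lens, n_decoys=10, seed=5)
        for j in junctions:
            e = classify_event(assign_exon_context(j, models), models)
            assert e.event_type in ("canonical", "exon_skip", "kdd", "fusion",
                                    "truncation", "unclassified")


class TestDomainFlags:
    def test_braf_like_fusion_keeps_kinase_loses_autoinhibition(self, models):
        # BRAF-like: kinase exons 11-18, autoinhibitory 1-6, acceptor exon 9
        j = _junction_for(models, "KIAA1549L", 16, "BRAFL", 9)
        e = assess_domain_retention(
            classify_event(assign_exon_context(j, models), models), models)
        assert e.kinase_domain_retained is True
        assert e.autoinhibitory_lost is True

    def test_acceptor_inside_kinase_domain_breaks_it(self, models):
        j = _junction_for(models, "KIAA1549L", 16, "BRAFL", 13)
        e = assess_domain_retention(
            classify_event(assign_exon_context(j, models), models), models)
        assert e.kinase_domain_retained is False

    @pytest.mark.parametrize("donor,acceptor,retained", [
        (17, 10, True),   # span 10-17 covers kinase exons 10-17
        (16, 10, False),  # span 10-16 clips the last kinase exon
        (17, 12, False),  # span 12-17 starts inside the domain
    ])
    def test_kdd_retention_requires_full_domain_coverage(
            self, models, donor, acceptor, retained):
        j = _junction_for(models, "FGFR1L", donor, "FGFR1L", acceptor)
        e = assess_domain_retention(
            classify_event(assign_exon_context(j, models), models), models)
        assert e.event_type == "kdd"
        assert e.kinase_domain_retained is retained

    def test_skip_events_keep_flags_not_applicable(self, models):
        j = _junction_for(models, "METL", 13, "METL", 15)
        e = assess_domain_retention(
            classify_event(assign_exon_context(j, models), models), models)
        assert e.kinase_domain_retained is None
        assert e.autoinhibitory_lost is None


def _event(etype="fusion", split=5, pairs=2):
    return StructuralEvent(event_type=etype, gene5="A", gene3="B",
                           donor_exon=2, acceptor_exon=3, label="A::B 2–3",
                           split_reads=split, spanning_pairs=pairs)


class TestFiltering:
    def test_below_min_split_removed(self):
        assert filter_events([_event(split=1)], DetectorConfig()) == []

    def test_all_canonical_input_reports_nothing(self, models):
        events = [classify_event(assign_exon_context(
            _junction_for(models, "METL", i, "METL", i + 1), models), models)
            for i in range(1, 6)]
        assert all(e.event_type == "canonical" for e in events)
        assert filter_events(events, DetectorConfig(min_split_reads=0,
                                                    min_total_support=0)) == []

    @given(st.lists(st.tuples(st.integers(0, 12), st.integers(0, 12)), max_size=30),
           st.integers(0, 8), st.integers(0, 8), st.integers(0, 8),
           st.integers(0, 4), st.integers(0, 4), st.integers(0, 4))
    def test_reported_set_shrinks_as_thresholds_rise(
            self, supports, ms, mp, mt, ds, dp, dt):
        events = [_event(split=s, pairs=p) for s, p in supports]
        lo = DetectorConfig(min_split_reads=ms, min_spanning_pairs=mp,
                            min_total_support=mt)
        hi = DetectorConfig(min_split_reads=ms + ds, min_spanning_pairs=mp + dp,
                            min_total_support=mt + dt)
        assert set(filter_events(events, hi)) <= set(filter_events(events, lo))


class TestDetect:
    def test_recovers_all_truth_events_with_exact_labels(
            self, models, genome, truths):
        lens = {c: len(s) for c, s in genome.items()}
        junctions = emit_truth_junctions(truths, models, lens, n_decoys=5, seed=7)
        report = detect(junctions, models)
        assert len(report) == 20
        assert set(report["label"]) == {t.label for t in truths}

    def test_empty_input_empty_report(self, models):
        report = detect([], models)
        assert len(report) == 0
        assert list(report.columns) == jio.REPORT_COLUMNS

    def test_decoys_only_input_reports_nothing(self, models, genome, truths):
        lens = {c: len(s) for c, s in genome.items()}
        decoys = emit_truth_junctions(truths[:1], models, lens,
                                      n_decoys=15, seed=9)[1:]
        assert len(detect(decoys, models)) == 0

    def test_report_sorted_by_type_genes_support(self, models, genome, truths):
        lens = {c: len(s) for c, s in genome.items()}
        junctions = emit_truth_junctions(truths, models, lens, seed=13)
        report = detect(junctions, models)
        keys = [(r.event_type, r.gene5, r.gene3,
                 -(r.split_reads + r.spanning_pairs), r.label)
                for r in report.itertuples()]
        assert keys == sorted(keys)
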