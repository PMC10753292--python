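"""Gene-model parsing, exon groups, ASE enumeration and reference I/O."""

import gzip
import json

import pytest
from hypothesis import given, settings, strategies as st

from splicequant import reference as R
from splicequant import simdata
from splicequant.benchmarks import brute_force_events


def write_gtf(tmp_path, lines, name="toy.gtf"):
    p = tmp_path / name
    p.write_text("\n".join(lines) + "\n")
    return p


def gtf_exon(chrom, start1, end1, strand, gene, tx):
    return (f"{chrom}\tsrc\texon\t{start1}\t{end1}\t.\t{strand}\t.\t"
            f'gene_id "{gene}"; transcript_id "{tx}";')


class TestParseGeneModels:
    def test_one_based_to_half_open_conversion(self, tmp_path):
        gtf = write_gtf(tmp_path, [gtf_exon("chr1", 101, 200, "+", "G", "T1")])
        (model,) = R.parse_gene_models(gtf)
        assert model.transcripts == (("T1", ((100, 200),)),)

    def test_intron_is_gap_between_consecutive_exons(self, tmp_path):
        gtf = write_gtf(tmp_path, [
            gtf_exon("chr1", 101, 200, "+", "G", "T1"),
            gtf_exon("chr1", 301, 400, "+", "G", "T1"),
        ])
        (model,) = R.parse_gene_models(gtf)
        (_tid, exons) = model.transcripts[0]
        assert model.introns(exons) == [(200, 300)]

    def test_overlapping_exons_within_transcript_rejected(self, tmp_path):
        gtf = write_gtf(tmp_path, [
            gtf_exon("chr1", 101, 200, "+", "G", "T1"),
            gtf_exon("chr1", 151, 250, "+", "G", "T1"),
        ])
        with pytest.raises(R.GtfFormatError, match="overlapping exons"):
            R.parse_gene_models(gtf)

    def test_missing_transcript_id_names_line(self, tmp_path):
        gtf = write_gtf(tmp_path, [
            'chr1\tsrc\texon\t101\t200\t.\t+\t.\tgene_id "G";',
        ])
        with pytest.raises(R.GtfFormatError, match="line 1"):
            R.parse_gene_models(gtf)

    def test_unknown_strand_dropped_with_warning(self, tmp_path, caplog):
        gtf = write_gtf(tmp_path, [
            gtf_exon("chr1", 101, 200, "+", "G", "T1"),
            'chr1\tsrc\texon\t301\t400\t.\t.\t.\tgene_id "G2"; transcript_id "T2";',
        ])
        with caplog.at_level("WARNING"):
            models = R.parse_gene_models(gtf)
        assert [m.gene_id for m in models] == ["G"]
        assert any("unknown strand" in r.message for r in caplog.records)

    def test_unreadable_file_raises_io_error(self, tmp_path):
        with pytest.raises(OSError):
            R.parse_gene_models(tmp_path / "absent.gtf")

    def test_abutting_exons_fused_so_introns_are_nonempty(self, tmp_path, caplog):
        gtf = write_gtf(tmp_path, [
            gtf_exon("chr1", 101, 200, "+", "G", "T1"),
            gtf_exon("chr1", 201, 300, "+", "G", "T1"),
        ])
        with caplog.at_level("WARNING"):
            (model,) = R.parse_gene_models(gtf)
        assert model.transcripts == (("T1", ((100, 300),)),)


class TestExonGroups:
    def make_gene(self, exon_sets, strand="+"):
        return R.GeneModel(
            gene_id="G", chrom="c", strand=strand,
            transcripts=tuple((f"T{i}", tuple(ex)) for i, ex in enumerate(exon_sets)),
        )

    def test_overlap_components(self):
        g = self.make_gene([[(100, 200)], [(150, 250)], [(300, 400)]])
        spans = [grp.span for grp in R.build_exon_groups(g)]
        assert spans == [(100, 250), (300, 400)]

    def test_abutting_half_open_exons_do_not_merge(self):
        g = self.make_gene([[(100, 200)], [(200, 300)]])
        assert [grp.span for grp in R.build_exon_groups(g)] == [(100, 200), (200, 300)]

    def test_multi_isoform_locus_collapses_to_two_flanking_groups(self, multi_isoform_ref):
        _scenario, ref = multi_isoform_ref
        spans = sorted(g.span for g in ref.groups.values())
        assert spans == [(800, 1200), (2000, 2400)]

    def test_partition_covers_all_spliced_exons(self):
        g = self.make_gene([[(0, 50), (100, 150)], [(0, 60), (100, 150), (200, 260)]])
        groups = R.build_exon_groups(g)
        exons = {e for _, ex in g.transcripts for e in ex}
        for e in exons:
            containing = [grp for grp in groups
                          if grp.span[0] <= e[0] and e[1] <= grp.span[1]]
            assert len(containing) == 1
        for a in groups:
            for b in groups:
                if a is not b:
                    assert a.span[1] <= b.span[0] or b.span[1] <= a.span[0]


class TestAnnotation:
    def test_skipped_exon_event_structure(self):
        g = R.GeneModel(
            gene_id="G", chrom="c", strand="+",
            transcripts=(
                ("TA", ((100, 200), (500, 600))),
                ("TB", ((100, 200), (300, 350), (500, 600))),
            ),
        )
        events = [e for e in R.annotate_ases([g]) if e.type == "SE"]
        (e,) = events
        assert e.region == (300, 350)
        assert set(e.inc_junctions) == {(200, 300), (350, 500)}
        assert e.exc_junctions == ((200, 500),)
        assert e.tandem

    def test_retained_intron_detected_from_spanning_exon(self):
        g = R.GeneModel(
            gene_id="G", chrom="c", strand="+",
            transcripts=(
                ("A", ((100, 200), (300, 400))),
                ("RI", ((100, 400),)),
            ),
        )
        (e,) = [e for e in R.annotate_ases([g]) if e.type == "IR"]
        assert e.region == (200, 300)
        assert e.uses_intron_depth and e.exc_junctions == ((200, 300),)

    def test_single_transcript_gene_yields_no_events(self):
        g = R.GeneModel(gene_id="G", chrom="c", strand="+",
                        transcripts=(("T", ((0, 10), (20, 30))),))
        assert R.annotate_ases([g]) == []

    def test_all_introns_mode_annotates_unretained_introns(self):
        g = R.GeneModel(gene_id="G", chrom="c", strand="+",
                        transcripts=(("T", ((0, 10), (20, 30))),
                                     ("U", ((0, 10), (25, 30))),))
        assert not [e for e in R.annotate_ases([g]) if e.type == "IR"]
        ir = [e for e in R.annotate_ases([g], all_introns=True) if e.type == "IR"]
        assert {e.region for e in ir} == {(10, 20), (10, 25)}

    def test_enumeration_matches_brute_force_on_named_scenarios(self):
        for name in simdata.SCENARIOS:
            s = simdata.make_scenario(name)
            for model in s.models:
                got = {
                    (e.type, tuple(sorted(e.inc_junctions)), tuple(sorted(e.exc_junctions)))
                    for e in R.annotate_ases([model])
                    if e.type in ("IR", "SE", "MXE", "A5SS", "A3SS")
                }
                want = {
                    (t, tuple(sorted(i)), tuple(sorted(x)))
                    for t, i, x in brute_force_events(model)
                }
                assert got == want, name

    def test_deterministic_event_ids(self, multi_isoform_ref):
        scenario, ref = multi_isoform_ref
        again = R.annotate_ases(scenario.models)
        assert [e.event_id for e in again] == [e.event_id for e in ref.events]


class TestPolarity:
    def test_exon_inclusion_isoform_is_included(self):
        e = R.ASEvent(event_id="x", type="SE", gene_id="G", chrom="c", strand="+",
                      region=(300, 350),
                      inc_junctions=((200, 500),),
                      exc_junctions=((200, 300), (350, 500)))
        fixed = R.assign_polarity(e)
        assert set(fixed.inc_junctions) == {(200, 300), (350, 500)}

    @pytest.mark.parametrize("strand,expected_inc", [
        # plus strand: first intron is the left one; (100,400) vs (100,200)
        ("+", ((100, 200), (260, 600))),
        # minus strand: first intron is the right one; (450,600) vs (260,600)
        ("-", ((100, 400), (450, 600))),
    ])
    def test_mxe_included_isoform_has_shorter_first_intron(self, strand, expected_inc):
        e = R.ASEvent(event_id="x", type="MXE", gene_id="G", chrom="c", strand=strand,
                      region=(200, 450),
                      inc_junctions=((100, 400), (450, 600)),
                      exc_junctions=((100, 200), (260, 600)))
        fixed = R.assign_polarity(e)
        assert set(fixed.inc_junctions) == set(expected_inc)

    def test_degenerate_tie_breaks_to_smaller_coordinates(self, caplog):
        e = R.ASEvent(event_id="x", type="AFE", gene_id="G", chrom="c", strand="+",
                      region=(0, 500),
                      inc_junctions=((200, 600),),
                      exc_junctions=((100, 500),))
        fixed = R.assign_polarity(e)
        assert fixed.inc_junctions == ((100, 500),)


class TestReferenceIO:
    def test_round_trip_is_lossless(self, multi_isoform_ref, tmp_path):
        scenario, ref = multi_isoform_ref
        groups = [g for m in ref.models for g in R.build_exon_groups(m)]
        R.write_reference(ref.events, groups, ref.models, tmp_path / "again")
        ref2 = R.load_reference(tmp_path / "again")
        assert ref2.events == ref.events
        assert ref2.groups == ref.groups
        assert ref2.models == ref.models

    def test_same_models_write_byte_identical_bundles(self, multi_isoform_ref, tmp_path):
        scenario, _ = multi_isoform_ref
        scenario.build_reference(tmp_path / "a")
        scenario.build_reference(tmp_path / "b")
        for name in ("events.tsv.gz", "exon_groups.bed.gz", "models.tsv.gz", "meta.json"):
            assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()

    def test_version_mismatch_rejected(self, multi_isoform_ref, tmp_path):
        scenario, _ = multi_isoform_ref
        scenario.build_reference(tmp_path / "ref")
        meta = json.loads((tmp_path / "ref" / "meta.json").read_text())
        meta["format_version"] = "999"
        (tmp_path / "ref" / "meta.json").write_text(json.dumps(meta))
        with pytest.raises(R.ReferenceFormatError, match="version"):
            R.load_reference(tmp_path / "ref")

    def test_empty_event_list_round_trips(self, tmp_path):
        R.write_reference([], [], [], tmp_path / "empty")
        ref = R.load_reference(tmp_path / "empty")
        assert ref.events == [] and ref.models == []


@st.composite
def random_gene(draw):
    n_tx = draw(st.integers(2, 4))
    strand = draw(st.sampled_from("+-"))
    bounds = draw(st.lists(st.integers(1, 300), min_size=12, max_size=12,
                           unique=True).map(sorted))
    bounds = [10 * b for b in bounds]
    txs = []
    for t in range(n_tx):
        idx = sorted(draw(st.sets(st.integers(0, 5), min_size=2, max_size=4)))
        exons = tuple((bounds[2 * i], bounds[2 * i + 1]) for i in idx)
        txs.append((f"T{t}", exons))
    return R.GeneModel(gene_id="H", chrom="c", strand=strand, transcripts=tuple(txs))


@settings(max_examples=60, deadline=None, derandomize=True)
@given(random_gene())
def test_enumeration_matches_brute_force_on_random_genes(model):
    """Property: pairwise brute-force comparison reproduces the annotation."""
    got = {
        (e.type, tuple(sorted(e.inc_junctions)), tuple(sorted(e.exc_junctions)))
        for e in R.annotate_ases([model])
        if e.type in ("IR", "SE", "MXE", "A5SS", "A3SS")
    }
    want = {
        (t, tuple(sorted(i)), tuple(sorted(x)))
        for t, i, x in brute_force_events(model)
    }
    assert got == want
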