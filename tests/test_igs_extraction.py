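import numpy as np
import pytest
from Bio.Seq import Seq
from hypothesis import given, settings
from hypothesis import strategies as st

from igscluster.annotation_io import (GeneRecord, GenomeAnnotation,
                                      TranscriptionUnit)
from igscluster.igs_extraction import (SDS_MOTIFS, SDSHit, choose_window_length,
                                       coding_fraction, compute_igrs,
                                       compute_rigrs, detect_sds, extract_igs,
                                       extract_igs_records,
                                       extract_upstream_window)

from conftest import random_dna
from oracles import scan_sds_reference


def _tu(gene_id):
    return TranscriptionUnit(gene_id, (gene_id,), gene_id)


class TestComputeIgrs:
    def test_forward_gap(self, two_gene_annotation):
        regions = compute_igrs(two_gene_annotation, [_tu("gB")])
        assert regions[0].length == 200

    def test_minus_strand_scans_higher_coordinates(self):
        rng = np.random.default_rng(0)
        genes = [GeneRecord("gA", "-", 0, 300), GeneRecord("gB", "-", 500, 800)]
        ann = GenomeAnnotation("r", random_dna(rng, 1000), "circular", genes)
        # lead gA (TSC 299) looks upstream towards gB's start at 500
        regions = compute_igrs(ann, [_tu("gA")])
        assert regions[0].length == 200

    def test_circular_wrap(self):
        rng = np.random.default_rng(1)
        genes = [GeneRecord("gA", "+", 100, 400), GeneRecord("gB", "+", 600, 900)]
        ann = GenomeAnnotation("r", random_dna(rng, 1000), "circular", genes)
        # previous + coding end for gA is gB's end at 900: (100 - 900) mod 1000
        regions = compute_igrs(ann, [_tu("gA")])
        assert regions[0].length == 200

    def test_single_gene_strand_wraps_to_own_far_side(self):
        rng = np.random.default_rng(2)
        genes = [GeneRecord("gA", "+", 100, 400)]
        ann = GenomeAnnotation("r", random_dna(rng, 1000), "circular", genes)
        regions = compute_igrs(ann, [_tu("gA")])
        assert regions[0].length == 700  # (100 - 400) mod 1000


class TestComputeRigrs:
    def test_simple_gap(self):
        rng = np.random.default_rng(3)
        genes = [GeneRecord("gA", "+", 0, 300), GeneRecord("gB", "+", 500, 800)]
        ann = GenomeAnnotation("r", random_dna(rng, 1000), "linear", genes)
        regions = compute_rigrs(ann)
        assert [r.length for r in regions] == [200]

    def test_overlap_contributes_zero(self):
        rng = np.random.default_rng(4)
        genes = [GeneRecord("gA", "+", 0, 300), GeneRecord("gB", "-", 250, 600)]
        ann = GenomeAnnotation("r", random_dna(rng, 1000), "linear", genes)
        regions = compute_rigrs(ann)
        assert [r.length for r in regions] == [0]

    def test_three_genes_circular_gives_three_gaps(self):
        rng = np.random.default_rng(5)
        genes = [GeneRecord("gA", "+", 0, 100), GeneRecord("gB", "-", 200, 300),
                 GeneRecord("gC", "+", 500, 700)]
        ann = GenomeAnnotation("r", random_dna(rng, 1000), "circular", genes)
        regions = compute_rigrs(ann)
        assert len(regions) == 3
        assert [r.length for r in regions] == [100, 200, 300]

    def test_igr_at_least_rigr_on_simulated_genome(self, simulated):
        _, annotation, tus, _ = simulated
        igrs = {r.anchor: r.length for r in compute_igrs(annotation, tus)}
        rigrs = compute_rigrs(annotation)
        # the strand-aware IGR can cross opposite-strand genes, so it is
        # never shorter than the smallest strand-agnostic gap at the locus
        assert min(igrs.values()) >= 0
        assert np.mean(list(igrs.values())) >= np.mean([r.length for r in rigrs])


class TestChooseWindowLength:
    def test_mean_minus_sd(self):
        # mean 250, population sd 50 -> 200
        assert choose_window_length([200, 300]) == 200

    def test_constant_lengths(self):
        assert choose_window_length([300, 300, 300]) == 300

    def test_small_sample(self):
        # mean 100, population sd 8.165 -> round(91.835) = 92
        assert choose_window_length([90, 100, 110]) == 92

    def test_override_wins(self):
        assert choose_window_length([90, 100, 110], override=200) == 200

    def test_all_zero_is_an_error(self):
        with pytest.raises(ValueError):
            choose_window_length([0, 0, 0])


class TestExtractUpstreamWindow:
    def test_forward(self, two_gene_annotation):
        w = extract_upstream_window(_tu("gB"), two_gene_annotation, 200)
        assert w == two_gene_annotation.sequence[300:500]

    def test_reverse_complement(self):
        rng = np.random.default_rng(6)
        seq = random_dna(rng, 1000)
        ann = GenomeAnnotation("r", seq, "circular",
                               [GeneRecord("gM", "-", 100, 400)])
        w = extract_upstream_window(_tu("gM"), ann, 200)
        assert w == str(Seq(seq[400:600]).reverse_complement())

    def test_circular_wrap_through_origin(self):
        rng = np.random.default_rng(7)
        seq = random_dna(rng, 1000)
        ann = GenomeAnnotation("r", seq, "circular",
                               [GeneRecord("gW", "+", 50, 350)])
        w = extract_upstream_window(_tu("gW"), ann, 200)
        assert w == seq[850:] + seq[:50]

    def test_linear_truncation_returns_none(self):
        rng = np.random.default_rng(8)
        ann = GenomeAnnotation("r", random_dna(rng, 1000), "linear",
                               [GeneRecord("gL", "+", 50, 350)])
        assert extract_upstream_window(_tu("gL"), ann, 200) is None


class TestDetectSds:
    def test_consensus_at_canonical_offset(self):
        window = "C" * 188 + "AGGAGG" + "C" * 6  # first base 12 bp upstream
        hit = detect_sds(window)
        assert (hit.motif, hit.offset) == ("AGGAGG", 12)

    def test_motif_outside_search_region_falls_back_to_submotif(self):
        # AGGAGG starts 30 bp upstream (outside the 25-bp region);
        # GGA starts 8 bp upstream and wins
        window = "C" * 170 + "AGGAGG" + "C" * 16 + "GGA" + "C" * 5
        hit = detect_sds(window)
        assert (hit.motif, hit.offset) == ("GGA", 8)

    def test_pyrimidine_tail_has_no_hit(self, rng):
        window = random_dna(rng, 175) + "".join(rng.choice(["C", "T"], 25))
        assert detect_sds(window) is None

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=150, deadline=None, derandomize=True)
    def test_matches_exhaustive_reference_scan(self, seed):
        """Longest motif always wins; ties go to the hit nearest the TSC."""
        r = np.random.default_rng(seed)
        # GA-rich alphabet makes motif collisions frequent
        window = "".join(r.choice(list("AGGAC"), size=30))
        hit = detect_sds(window, search_len=25)
        ref = scan_sds_reference(window, SDS_MOTIFS, 25)
        if ref is None:
            assert hit is None
        else:
            assert (hit.motif, hit.offset) == ref


class TestExtractIgs:
    def test_no_sds_takes_last_175(self, rng):
        window = random_dna(rng, 200)
        assert extract_igs(window, None, 200) == window[25:]

    def test_offset_12(self, rng):
        window = random_dna(rng, 200)
        igs = extract_igs(window, SDSHit("AGGAGG", 12), 200)
        assert igs == window[13:188]

    def test_maximal_offset_25(self, rng):
        window = random_dna(rng, 200)
        igs = extract_igs(window, SDSHit("AGGAGG", 25), 200)
        assert igs == window[:175]


class TestCodingFraction:
    def test_fully_coding(self, two_gene_annotation):
        assert coding_fraction(0, 300, two_gene_annotation) == 1.0

    def test_pure_intergenic(self, two_gene_annotation):
        assert coding_fraction(320, 480, two_gene_annotation) == 0.0

    def test_half_overlap(self, two_gene_annotation):
        assert coding_fraction(200, 400, two_gene_annotation) == 0.5


class TestExtractionOnSimulatedGenome:
    def test_all_igs_have_fixed_length(self, simulated):
        _, annotation, tus, _ = simulated
        records, log = extract_igs_records(annotation, tus)
        assert log.n_igs == len(tus)
        assert {len(r.sequence) for r in records} == {175}

    def test_planted_consensus_recovered_exactly(self, simulated):
        """Planted AGGAGG has no closer decoy (C/T spacer), so offset and
        motif must round-trip exactly; unplanted units must stay empty."""
        _, annotation, tus, truth = simulated
        records, _ = extract_igs_records(annotation, tus)
        planted = {t.tu_id: t for t in truth.tus}
        for r in records:
            t = planted[r.tu_id]
            if t.sds_motif == "AGGAGG":
                assert (r.sds_motif, r.sds_offset) == (t.sds_motif, t.sds_offset)
            elif t.sds_motif is None:
                assert r.sds_motif is None

    def test_detected_fraction_at_least_planted(self):
        from igscluster.synthetic_fixtures import FixtureSpec, simulate_genome
        spec = FixtureSpec(n_genes=80, sds_probability=1.0, rng_seed=11)
        annotation, tus, _ = simulate_genome(spec)
        _, log = extract_igs_records(annotation, tus)
        assert log.sds_fraction == 1.0
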