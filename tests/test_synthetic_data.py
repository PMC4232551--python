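"""Generator determinism, geometry guarantees and full-pipeline truth recovery."""

import numpy as np
import pytest

from cuparray import (
    build_single_locus,
    classify_repeat_type,
    copy_number_from_depth,
    copy_number_from_fragment,
    generate_array_strain,
    generate_depth_track,
    generate_junction_cases,
    infer_unit_length,
    insilico_pcr,
    map_junction,
    virtual_digest,
)
from cuparray.synthetic_data import DEFAULT_CONFIG, ZERO_DIVERGENCE


class TestSingleLocus:
    def test_probe_fragment_is_exactly_single_copy_size(self, single_locus):
        locus, truth = single_locus
        cup1 = locus.feature("CUP1")
        frags = virtual_digest(locus.sequence, probe=(cup1.start, cup1.end))
        probe = [f for f in frags if f.contains_probe]
        assert len(probe) == 1 and probe[0].length == 5200
        assert truth.expected_probe_fragment_bp == 5200

    def test_no_internal_ecori_site(self, single_locus):
        locus, _ = single_locus
        inner = locus.sequence[locus.left_ecoRI : locus.right_ecoRI - 1]
        # the only GAATTC inside the fragment is the partial right-site overlap
        assert inner.count("GAATTC") == 0

    def test_deterministic_per_seed(self):
        a, _ = build_single_locus(seed=21)
        b, _ = build_single_locus(seed=21)
        c, _ = build_single_locus(seed=22)
        assert a.sequence == b.sequence
        assert a.sequence != c.sequence

    def test_annotation_invariants_hold(self, single_locus):
        locus, _ = single_locus
        locus.validate()
        cup1 = locus.feature("CUP1")
        assert cup1.length == 186  # 61 codons plus stop, minus strand


class TestArrayStrains:
    def test_single_copy_strain_equals_base_locus(self):
        strain = generate_array_strain(3, 1, seed=6, divergence=ZERO_DIVERGENCE)
        locus, _ = build_single_locus(6)
        assert strain.sequence == locus.sequence

    def test_byte_identical_outputs_per_seed(self, tmp_path):
        s1 = generate_array_strain(2, 4, seed=19)
        s2 = generate_array_strain(2, 4, seed=19)
        assert s1.sequence == s2.sequence
        assert s1.truth.to_json() == s2.truth.to_json()
        paths = s1.write(tmp_path)
        assert paths["fasta"].read_bytes() == paths["fasta"].read_bytes()

    def test_truth_log_records_genesis_events(self):
        strain = generate_array_strain(4, 5, seed=8)
        kinds = [e["kind"] for e in strain.truth.events]
        assert kinds == ["NHEJ_dup"] + ["unequal_CO"] * 3

    def test_unit_length_recovered_at_zero_divergence(self):
        strain = generate_array_strain(1, 2, seed=7, divergence=ZERO_DIVERGENCE)
        span = strain.truth.repeat_span
        res = infer_unit_length(strain.sequence[span[0] : span[1]])
        assert res.unit_len == 1998

    def test_divergence_leaves_fragment_lengths_alone(self):
        strain = generate_array_strain(5, 7, seed=23)  # default divergence rates
        assert sum(strain.truth.n_substitutions.values()) > 0
        frags = virtual_digest(strain.sequence, probe=strain.truth.features["CUP1_copy1"][:2])
        probe = [f for f in frags if f.contains_probe]
        assert probe[0].length == strain.truth.expected_probe_fragment_bp

    def test_outward_primers_silent_on_any_single_copy_type(self):
        for type_id in (1, 2, 3, 4, 5):
            strain = generate_array_strain(type_id, 1, seed=5, divergence=ZERO_DIVERGENCE)
            fwd, rev = DEFAULT_CONFIG.primer_pair(strain.sequence, "outward")
            assert insilico_pcr(strain.sequence, fwd, rev) == []

    def test_unknown_type_rejected(self):
        with pytest.raises(ValueError):
            generate_array_strain(6, 2, seed=1)


class TestJunctionCases:
    def test_truth_labels_recovered_exactly_without_mismatches(self):
        cases = generate_junction_cases(seed=31, n_cases=100)
        hits = 0
        for case in cases:
            call = map_junction(case.junction, case.distal_ref, case.proximal_ref)
            hits += (
                call.microhomology_len == case.true_microhomology
                and call.inserted_seq == case.true_insert
            )
        assert hits == 100

    def test_blunt_case_maps_to_zero_zero(self):
        cases = generate_junction_cases(seed=2, n_cases=50, mh_range=(0, 0), ins_range=(0, 0))
        for case in cases:
            call = map_junction(case.junction, case.distal_ref, case.proximal_ref)
            assert (call.microhomology_len, call.inserted_seq) == (0, "")

    def test_snp_cases_still_map_with_mismatch_recorded(self):
        cases = generate_junction_cases(seed=41, n_cases=100, mismatch_rate=1.0)
        recovered = 0
        for case in cases:
            assert case.snp_offsets
            call = map_junction(case.junction, case.distal_ref, case.proximal_ref)
            if (
                call.microhomology_len == case.true_microhomology
                and call.inserted_seq == case.true_insert
                and case.snp_offsets[0] in call.mismatch_positions
            ):
                recovered += 1
        assert recovered >= 95

    def test_homopolymer_expansions_flagged(self):
        cases = generate_junction_cases(
            seed=9, n_cases=60, mh_range=(0, 0), ins_range=(3, 8), homopolymer_prob=1.0
        )
        for case in cases:
            assert case.homopolymer_expansion
            call = map_junction(case.junction, case.distal_ref, case.proximal_ref)
            assert call.inserted_seq == case.true_insert
            assert call.homopolymer_expansion


class TestDepthTracks:
    def test_single_copy_track_reads_one(self):
        _, truth = build_single_locus(seed=14)
        depth = generate_depth_track(truth, mean_coverage=30, seed=14)
        copies, n = copy_number_from_depth(depth, (1500, 2500), [(200, 1200), (4000, 5000)])
        assert n == 1 and copies == pytest.approx(1.0, abs=0.1)

    @pytest.mark.parametrize("true_n", [2, 18])
    def test_repeat_span_reads_copy_number(self, true_n):
        strain = generate_array_strain(3, true_n, seed=16)
        depth = generate_depth_track(strain.truth, mean_coverage=30, seed=16)
        p, d = strain.truth.breaks
        copies, n = copy_number_from_depth(depth, (p, d), [(200, 1200), (4000, 5000)])
        assert n == true_n

    def test_subunit_coverage_warns(self):
        _, truth = build_single_locus(seed=1)
        with pytest.warns(UserWarning, match="coverage"):
            generate_depth_track(truth, mean_coverage=0.5, seed=1)


class TestFullPipelineRecovery:
    @pytest.mark.parametrize(
        "type_id,n", [(1, 2), (2, 3), (3, 7), (4, 5), (5, 14), (3, 18), (2, 1)]
    )
    def test_every_truth_field_recovered(self, type_id, n):
        """Digest -> copy number, period -> type, junction -> classification."""
        seed = 100 + 10 * type_id + n
        strain = generate_array_strain(type_id, n, seed=seed)  # default divergence
        truth = strain.truth
        unit_bp = truth.exact_unit_len

        # restriction route
        cup1_key = "CUP1" if n == 1 else "CUP1_copy1"
        frags = virtual_digest(strain.sequence, probe=truth.features[cup1_key][:2])
        probe = [f for f in frags if f.contains_probe][0]
        assert probe.length == truth.expected_probe_fragment_bp
        est = copy_number_from_fragment(probe.length / 1000, 5.2, unit_bp / 1000)
        assert est == n

        if n == 1:
            return  # no repeat structure to infer on a single copy

        # period route
        span = truth.repeat_span
        res = infer_unit_length(strain.sequence[span[0] : span[1]])
        assert res.unit_len == unit_bp
        assert classify_repeat_type(res.unit_len) == type_id

        # junction route, against the undiverged single-copy references
        locus, _ = build_single_locus(seed)
        p, d = truth.breaks
        jpos = truth.junction_positions[0]
        ins = truth.junction_insert
        window = strain.sequence[jpos - 60 : jpos + len(ins) + 60]
        call = map_junction(window, locus.sequence[d - 300 : d + 300], locus.sequence[p - 300 : p + 300])
        assert call.classification == "nonhomologous"
        assert call.microhomology_len <= 3
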