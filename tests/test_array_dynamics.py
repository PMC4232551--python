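"""NHEJ duplication, unequal crossover, contractions and marker-loss screens."""

import itertools

import numpy as np
import pytest

from cuparray import (
    ArrayState,
    LocusMap,
    contract_array,
    infer_unit_length,
    map_junction,
    nhej_duplicate,
    simulate_marker_loss,
    unequal_crossover,
)
from cuparray import build_single_locus


def _toy_locus(seed: int = 4) -> LocusMap:
    """100 bp locus with junction-determining bases pinned around breaks 30/50."""
    rng = np.random.default_rng(seed)
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    arr = bases[rng.integers(0, 4, 100)]
    # matched extensions must stop exactly at the breaks, with the adjacent
    # base mismatching too so the stop cannot be absorbed as an isolated SNP
    for target, other in ((50, 30), (51, 31)):
        if arr[target] == arr[other]:
            arr[target] = bases[(int(np.searchsorted(bases, arr[target])) + 1) % 4]
    for target, other in ((29, 49), (28, 48)):
        if arr[target] == arr[other]:
            arr[target] = bases[(int(np.searchsorted(bases, arr[target])) + 1) % 4]
    return LocusMap(sequence=arr.tobytes().decode(), name="toy")


class TestNhejDuplicate:
    def test_product_lengths_conserve_sequence(self):
        locus = _toy_locus()
        dup, deletion = nhej_duplicate(locus, 30, 50)
        assert len(dup.sequence) == 120 and len(deletion.sequence) == 80
        assert len(dup.sequence) + len(deletion.sequence) == 2 * len(locus.sequence)
        assert dup.sequence == locus.sequence[:50] + locus.sequence[30:]
        assert deletion.sequence == locus.sequence[:30] + locus.sequence[50:]

    def test_junction_mapping_recovers_the_breaks(self):
        locus = _toy_locus()
        dup, _ = nhej_duplicate(locus, 30, 50)
        junction = dup.sequence[30:70]  # 20 bp either side of the new junction
        call = map_junction(junction, locus.sequence, locus.sequence)
        assert (call.microhomology_len, call.inserted_seq) == (0, "")
        assert call.distal_match[1] == 50  # prefix ends at the distal break
        assert call.proximal_match[0] == 30  # suffix starts at the proximal break

    def test_insertion_lengthens_only_the_duplication(self):
        locus = _toy_locus()
        dup, deletion = nhej_duplicate(locus, 30, 50, insertion="TAC")
        assert len(dup.sequence) == 123 and len(deletion.sequence) == 80

    def test_microhomology_precondition_checked(self):
        locus = _toy_locus()
        seq = locus.sequence
        compatible = seq[:50] + seq[30:33] + seq[53:]
        ok = LocusMap(sequence=compatible, name="mh")
        nhej_duplicate(ok, 30, 50, microhomology_used=3)  # identical 3-mers: fine
        with pytest.raises(ValueError, match="identical"):
            nhej_duplicate(locus, 30, 50, microhomology_used=5)

    def test_breaks_outside_locus_rejected(self):
        locus = _toy_locus()
        with pytest.raises(ValueError):
            nhej_duplicate(locus, 30, 100)
        with pytest.raises(ValueError):
            nhej_duplicate(locus, 50, 30)

    def test_type1_spec_creates_two_copy_array_with_insert(self):
        locus, _ = build_single_locus(seed=2)
        dup, _ = nhej_duplicate(locus, 1350, 3347, insertion="A")
        span = dup.sequence[1350 : 3347 + 1998 + 1]
        res = infer_unit_length(span)
        assert res.unit_len == 1998
        junction = dup.sequence[3347 - 60 : 3347 + 1 + 60]
        call = map_junction(
            junction, locus.sequence[3047:3647], locus.sequence[1050:1650]
        )
        assert call.inserted_seq == "A" and call.microhomology_len == 0


class TestUnequalCrossover:
    def test_fig7_style_collapse_to_single_unmarked_copy(self):
        a = ArrayState.make(14, marker_unit=6)
        b = ArrayState.make(14, marker_unit=6)
        gained, lost = unequal_crossover(a, b, offset_k=13, crossover_j=13)
        assert gained.n == 27 and lost.n == 1
        assert gained.marker_count == 2 and lost.marker_count == 0

    def test_offset_emptying_an_array_rejected(self):
        a, b = ArrayState.make(5), ArrayState.make(3)
        with pytest.raises(ValueError):
            unequal_crossover(a, b, offset_k=3)
        with pytest.raises(ValueError):
            unequal_crossover(a, b, offset_k=0)

    def test_matches_exhaustive_enumeration_for_three_unit_sisters(self):
        a = ArrayState.make(3, marker_unit=1)
        b = ArrayState.make(3, marker_unit=1)
        observed = set()
        for k in (1, 2):
            for j in range(k, min(b.n, a.n + k) + 1):
                gained, lost = unequal_crossover(a, b, k, crossover_j=j)
                observed.add((gained.units, lost.units))
        # brute force: all splices b[:j] + a[j-k:] / a[:j-k] + b[j:]
        expected = set()
        for k in (1, 2):
            for j in range(k, 3 + 1):
                if j - k <= 3:
                    expected.add((b.units[:j] + a.units[j - k :], a.units[: j - k] + b.units[j:]))
        assert observed == expected
        for gained_units, lost_units in observed:
            assert len(gained_units) + len(lost_units) == 6
            assert sum(gained_units) + sum(lost_units) == 2

    def test_conservation_over_random_events(self):
        rng = np.random.default_rng(77)
        for _ in range(500):
            na, nb = int(rng.integers(1, 20)), int(rng.integers(2, 20))
            a = ArrayState(tuple(bool(x) for x in rng.integers(0, 2, na)))
            b = ArrayState(tuple(bool(x) for x in rng.integers(0, 2, nb)))
            k = int(rng.integers(1, b.n))
            gained, lost = unequal_crossover(a, b, k, rng=rng)
            assert gained.n + lost.n == a.n + b.n
            assert gained.marker_count + lost.marker_count == a.marker_count + b.marker_count


class TestContractions:
    def test_collapse_to_single_copy(self):
        res = contract_array(ArrayState.make(14), "SSA", k_lost=13)
        assert res.state.n == 1 and res.excised_units is None

    def test_smallest_contraction(self):
        res = contract_array(ArrayState.make(2), "popout", k_lost=1, excise_start=0)
        assert res.state.n == 1 and len(res.excised_units) == 1

    def test_marker_within_excised_span_is_lost(self):
        res = contract_array(ArrayState.make(14, marker_unit=5), "popout", 7, excise_start=3)
        assert res.marker_lost and res.state.marker_count == 0
        assert len(res.excised_units) == 7 and sum(res.excised_units) == 1

    def test_marker_outside_span_survives(self):
        res = contract_array(ArrayState.make(14, marker_unit=0), "SSA", 7, excise_start=3)
        assert not res.marker_lost and res.state.marker_count == 1

    def test_excising_everything_rejected(self):
        with pytest.raises(ValueError):
            contract_array(ArrayState.make(5), "popout", k_lost=5)


class TestMarkerLossScreen:
    def test_zero_rate_means_zero_events(self):
        tally = simulate_marker_loss(14, 6, 0.0, n_divisions=10**4, seed=1)
        assert tally.n_events == 0 and tally.single_copy_fraction is None

    def test_forced_full_contraction_always_single_copy(self):
        tally = simulate_marker_loss(
            14, 6, 1.0, n_divisions=2000, seed=2, event_size_distribution={13: 1.0}
        )
        assert tally.single_copy_fraction == 1.0

    def test_uniform_event_size_gives_one_in_thirteen(self):
        # conditional on detection, P(single copy) = P(k = 13) = 1/13
        tally = simulate_marker_loss(14, 6, 1.0, n_divisions=10**5, seed=3)
        assert tally.n_marker_loss == tally.n_events
        p = 1 / 13
        sigma = (p * (1 - p) / tally.n_events) ** 0.5
        assert abs(tally.single_copy_fraction - p) < 4 * sigma

    def test_identical_seed_identical_tally(self):
        t1 = simulate_marker_loss(14, 6, 0.3, n_divisions=5000, seed=9)
        t2 = simulate_marker_loss(14, 6, 0.3, n_divisions=5000, seed=9)
        assert t1 == t2

    def test_invalid_distribution_rejected(self):
        with pytest.raises(ValueError):
            simulate_marker_loss(
                14, 6, 0.5, n_divisions=100, seed=0, event_size_distribution={13: 0.7}
            )
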