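from dataclasses import replace
from itertools import product

import numpy as np

import pytest

from pedrecomb.crossover_calling import (call_events, call_family,
                                         count_transmissions,
                                         deduplicate_events,
                                         find_informative_markers,
                                         phase_family,
                                         pretreat_double_recombinants,
                                         reduced_family_counts)
from pedrecomb.pedio import (MISSING, GenotypeMatrix, NuclearFamily,
                             extract_nuclear_families)
from pedrecomb.synthetic_data import ChromosomeConfig, SimConfig, simulate_cohort

from .conftest import make_family_matrix
from .oracles import min_recombinant_total


def _total_called(transmitted) -> int:
    """Called event total (no pretreat/dedup) on a toy transmitted matrix."""
    fam, gm = make_family_matrix(transmitted)
    return sum(len(call_events(t)) for t in phase_family(fam, "mum", gm))


class TestInformativeMarkers:
    def test_het_by_hom_is_informative_for_het_parent(self):
        fam, gm = make_family_matrix(np.zeros((2, 3)), co_parent_dosage=0)
        assert len(find_informative_markers(fam, "mum", gm)[1]) == 3
        assert find_informative_markers(fam, "dad", gm) == {}

    def test_double_het_uninformative(self):
        fam, gm = make_family_matrix(np.zeros((2, 3)))
        calls = gm.calls.copy()
        calls[1, 0] = 1  # father het at marker 1
        gm = GenotypeMatrix(gm.markers, gm.samples, calls)
        idx = find_informative_markers(fam, "mum", gm)[1]
        assert 1 not in idx and len(idx) == 2

    def test_missing_child_drops_marker(self):
        fam, gm = make_family_matrix(np.zeros((2, 3)))
        calls = gm.calls.copy()
        calls[2, 2] = MISSING
        gm = GenotypeMatrix(gm.markers, gm.samples, calls)
        assert 2 not in find_informative_markers(fam, "mum", gm)[1]

    def test_mendel_inconsistent_child_drops_marker(self):
        fam, gm = make_family_matrix(np.zeros((2, 3)), co_parent_dosage=2)
        calls = gm.calls.copy()
        calls[0, 2] = 0  # child lacks the obligate paternal allele
        gm = GenotypeMatrix(gm.markers, gm.samples, calls)
        assert 0 not in find_informative_markers(fam, "mum", gm)[1]


class TestPhasing:
    def test_single_switch_in_one_child(self):
        t = np.array([[0, 0, 0, 0, 0],
                      [0, 0, 0, 1, 1],
                      [0, 0, 0, 0, 0]])
        fam, gm = make_family_matrix(t)
        tracks = phase_family(fam, "mum", gm)
        events = call_events(tracks[0])
        assert len(events) == 1
        assert events.iloc[0]["child_id"] == "kid1"
        assert (events.iloc[0]["left_bp"], events.iloc[0]["right_bp"]) == \
            (300_000, 400_000)

    def test_identical_children_no_events(self):
        t = np.tile([0, 1, 0, 1], (3, 1))  # same alleles -> same haplotype
        assert _total_called(t) == 0

    def test_simultaneous_switch_attributed_to_reference(self):
        # both non-reference children appear to switch at the same interval:
        # parsimony says the reference child recombined
        t = np.array([[0, 0, 0, 0],
                      [0, 0, 1, 1],
                      [0, 0, 1, 1]])
        fam, gm = make_family_matrix(t)
        events = call_events(phase_family(fam, "mum", gm)[0])
        assert len(events) == 1
        assert events.iloc[0]["child_id"] == "kid0"

    def test_fewer_than_two_children_rejected(self):
        fam, gm = make_family_matrix(np.zeros((2, 3)))
        solo = NuclearFamily("dad", "mum", ("kid0",))
        with pytest.raises(ValueError):
            phase_family(solo, "mum", gm)

    def test_total_invariant_to_reference_rotation(self):
        rng = np.random.default_rng(17)
        for _ in range(25):
            t = rng.integers(0, 2, size=(rng.integers(3, 5), 8))
            totals = set()
            for shift in range(t.shape[0]):
                totals.add(_total_called(np.roll(t, shift, axis=0)))
            assert len(totals) == 1


class TestOracleEquivalence:
    """Called totals must equal the exhaustive minimum-recombinant solution
    for every enumerable toy family (<= 4 children, <= 12 markers)."""

    @pytest.mark.parametrize("n_children,n_markers",
                             [(2, 5), (3, 4), (4, 3)])
    def test_exhaustive_enumeration(self, n_children, n_markers):
        for bits in product((0, 1), repeat=n_children * n_markers):
            t = np.array(bits).reshape(n_children, n_markers)
            assert _total_called(t) == min_recombinant_total(t), t

    def test_randomized_larger_families(self):
        rng = np.random.default_rng(99)
        for _ in range(250):
            n_children = rng.integers(2, 5)
            n_markers = rng.integers(2, 13)
            t = rng.integers(0, 2, size=(n_children, n_markers))
            assert _total_called(t) == min_recombinant_total(t), t


class TestPretreatment:
    def test_tight_blip_removed(self):
        # ...H1 H2 H1... with flanks 200 kb apart
        t = np.array([[0, 0, 0, 0], [0, 1, 0, 0], [0, 0, 0, 0]])
        fam, gm = make_family_matrix(t)
        track = pretreat_double_recombinants(phase_family(fam, "mum", gm)[0])
        assert track.removed_positions == (200_000,)
        assert len(call_events(track)) == 0

    def test_wide_double_retained(self):
        # H1 H2 H2 H1 spanning 5 Mb: two markers support the switch
        t = np.array([[0, 0, 0, 0], [0, 1, 1, 0], [0, 0, 0, 0]])
        positions = np.array([1, 2_500_000, 3_000_000, 5_500_000])
        fam, gm = make_family_matrix(t, positions=positions)
        track = pretreat_double_recombinants(phase_family(fam, "mum", gm)[0])
        assert track.removed_positions == ()
        assert len(call_events(track)) == 2  # both real switches kept

    def test_iterates_to_fixpoint(self):
        # removing kid2's blip leaves kid1 with a newly-exposed blip
        t = np.array([[0, 0, 0, 0], [0, 1, 1, 0], [0, 0, 1, 0],
                      [0, 0, 0, 0]])
        positions = np.array([100_000, 200_000, 300_000, 400_000])
        fam, gm = make_family_matrix(t, positions=positions)
        track = pretreat_double_recombinants(phase_family(fam, "mum", gm)[0])
        assert len(track.removed_positions) == 2
        assert len(call_events(track)) == 0


def test_wide_double_event_count():
    t = np.array([[0, 0, 0, 0], [0, 1, 1, 0], [0, 0, 0, 0]])
    positions = np.array([1, 2_500_000, 3_000_000, 5_500_000])
    fam, gm = make_family_matrix(t, positions=positions)
    track = pretreat_double_recombinants(phase_family(fam, "mum", gm)[0])
    events = call_events(track)
    assert len(events) == 2
    assert set(events["child_id"]) == {"kid1"}


class TestDeduplication:
    def test_shared_events_removed_entirely(self):
        t = np.array([[0, 0, 0, 0],
                      [0, 0, 1, 1],
                      [0, 0, 1, 1],
                      [0, 0, 0, 0]])
        fam, gm = make_family_matrix(t)
        events = call_events(phase_family(fam, "mum", gm)[0])
        kept = deduplicate_events(events)
        shared = events[events["n_children_sharing"] >= 2]
        assert len(shared) == 2  # kid1+kid2 share the same interval
        assert len(kept) == 0

    def test_mixed_fixture_counts(self):
        # 3 shared events (one interval, 3 children) + 4 unique -> 4 remain
        t = np.array([[0, 0, 1, 1, 0, 0],   # ref: 2 events (via attribution)
                      [1, 0, 1, 1, 0, 1],
                      [0, 1, 1, 1, 0, 0],
                      [0, 0, 1, 1, 1, 1]])
        fam, gm = make_family_matrix(t)
        events = call_events(phase_family(fam, "mum", gm)[0])
        kept = deduplicate_events(events)
        assert len(events) - len(kept) == int(
            (events["n_children_sharing"] >= 2).sum())
        assert (kept["n_children_sharing"] == 1).all()

    def test_unique_event_kept(self):
        t = np.array([[0, 0, 0], [0, 0, 1], [0, 0, 0]])
        fam, gm = make_family_matrix(t)
        events = deduplicate_events(call_events(phase_family(fam, "mum", gm)[0]))
        assert len(events) == 1


class TestReducedFamilies:
    def test_subset_counting(self):
        # 4 children -> C(4,3)=4 subsets, each child in C(3,2)=3
        t = np.array([[0, 0, 0, 0],
                      [0, 0, 0, 1],
                      [0, 1, 1, 1],
                      [0, 0, 1, 1]])
        fam, gm = make_family_matrix(t)
        counts = reduced_family_counts(fam, "mum", gm)
        assert set(counts) == set(fam.child_ids)
        # each is a mean over 3 subsets -> multiples of 1/3
        for v in counts.values():
            assert abs(v * 3 - round(v * 3)) < 1e-9

    def test_no_shared_events_matches_standard_counts(self):
        # switches in distinct intervals: no dedup inside any subset
        t = np.array([[0, 0, 0, 0, 0],
                      [1, 0, 0, 0, 0],
                      [0, 0, 1, 1, 1],
                      [0, 0, 0, 0, 1]])
        fam, gm = make_family_matrix(t)
        events = call_family(fam, gm)
        standard = {c: int((events["child_id"] == c).sum())
                    for c in fam.child_ids}
        unbiased = reduced_family_counts(fam, "mum", gm)
        assert unbiased == {c: float(v) for c, v in standard.items()}

    def test_three_children_passthrough(self):
        t = np.array([[0, 0, 0], [0, 0, 1], [0, 0, 0]])
        fam, gm = make_family_matrix(t)
        counts = reduced_family_counts(fam, "mum", gm)
        assert counts == {"kid0": 0.0, "kid1": 1.0, "kid2": 0.0}


class TestCohortCounting:
    def test_records_only_for_three_plus_children(self, small_cohort):
        _, ped, gm, _ = small_cohort
        fams = extract_nuclear_families(ped, genotyped=set(gm.samples))
        events, records = count_transmissions(fams, gm, ped)
        assert (records.groupby("parent_id")["child_id"].count() == 3).all()
        two_child = NuclearFamily(fams[0].father_id, fams[0].mother_id,
                                  fams[0].child_ids[:2])
        ev2, rec2 = count_transmissions([two_child], gm, ped)
        assert len(rec2) == 0
        assert (~ev2["assigned"]).all()

    def test_totals_equal_per_chromosome_sums(self, small_cohort):
        _, ped, gm, _ = small_cohort
        fams = extract_nuclear_families(ped, genotyped=set(gm.samples))
        _, records = count_transmissions(fams, gm, ped)
        chrom_cols = [c for c in records.columns if c.startswith("chr")]
        assert (records[chrom_cols].sum(axis=1)
                == records["total_count"]).all()

    def test_missing_age_is_reported_with_pair(self, small_cohort):
        _, ped, gm, _ = small_cohort
        fams = extract_nuclear_families(ped, genotyped=set(gm.samples))
        stripped = replace(ped, parental_ages={})
        with pytest.raises(KeyError, match="parent="):
            count_transmissions(fams[:1], gm, stripped)


def test_detection_rate_on_dense_clean_data():
    """On error-free data with dense markers, nearly every true crossover is
    recovered by an event whose interval contains it, and no event lacks a
    matching true crossover."""
    cfg = SimConfig(
        n_families=15, children_per_family=3,
        chromosomes=[ChromosomeConfig(30_000_000, a_maternal=1.5,
                                      a_paternal=1.5)],
        snps_per_chromosome=3000, seed=42)
    ped, gm, truth = simulate_cohort(cfg)
    fams = extract_nuclear_families(ped, genotyped=set(gm.samples))
    events, _ = count_transmissions(fams, gm, ped, unique_only=False,
                                    reduced=False)
    matched = 0
    for r in truth.itertuples():
        sub = events[(events["parent_id"] == r.parent_id)
                     & (events["child_id"] == r.child_id)
                     & (events["chrom"] == r.chrom)
                     & (events["left_bp"] <= r.pos_bp)
                     & (events["right_bp"] >= r.pos_bp)]
        matched += len(sub) > 0
    assert matched / len(truth) >= 0.95
    assert len(events) <= len(truth)  # no spurious events without error
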