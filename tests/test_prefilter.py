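import numpy as np
import pytest

from rmatrace.chem import MASS_CYS
from rmatrace.peaklist_io import ConfigError, Role, SampleEntry, SampleTable
from rmatrace.prefilter import (
    FilterConfig,
    blank_filter,
    intensity_filter,
    mass_floor_filter,
    merge_duplicates,
)
from tests.conftest import make_peak
from tests.oracles import brute_force_merge_groups


class TestIntensityFilter:
    def test_above_both_floors_kept(self, samples_lub):
        peak = make_peak("a", 200.0, 5.0, areas={"S1": 26_000})
        assert intensity_filter([peak], samples_lub) == [peak]

    def test_floor_is_strict(self, samples_lub):
        peak = make_peak("a", 200.0, 5.0, areas={"S1": 25_000})
        assert intensity_filter([peak], samples_lub) == []

    def test_labeled_floor_must_hold_even_with_strong_control(self, samples_lub):
        peak = make_peak("a", 200.0, 5.0, areas={"S2": 100_000, "S1": 10_000})
        assert intensity_filter([peak], samples_lub) == []

    def test_blank_area_cannot_satisfy_any_floor(self, samples_lub):
        peak = make_peak("a", 200.0, 5.0, areas={"B1": 900_000, "S1": 16_000})
        assert intensity_filter([peak], samples_lub) == []

    def test_requires_labeled_sample(self):
        samples = SampleTable([SampleEntry("B1", Role.blank)])
        with pytest.raises(ConfigError):
            intensity_filter([], samples)


class TestBlankFilter:
    def test_fourfold_kept(self, samples_lub):
        peak = make_peak("a", 200.0, 5.0, areas={"S1": 121_000, "B1": 30_000})
        assert blank_filter([peak], samples_lub) == [peak]

    def test_below_fourfold_removed(self, samples_lub):
        peak = make_peak("a", 200.0, 5.0, areas={"S1": 100_000, "B1": 30_000})
        assert blank_filter([peak], samples_lub) == []

    def test_no_blank_samples_is_identity(self):
        samples = SampleTable([SampleEntry("S1", Role.labeled_mix)])
        peaks = [make_peak("a", 200.0, 5.0, areas={"S1": 10})]
        assert blank_filter(peaks, samples) == peaks

    def test_undetected_in_blanks_passes(self, samples_lub):
        peak = make_peak("a", 200.0, 5.0, areas={"S1": 10})
        assert blank_filter([peak], samples_lub) == [peak]


class TestMassFloor:
    @pytest.mark.parametrize("mass,kept", [
        (119.90, False),
        (120.00, True),  # boundary inclusive: "less than 120" removed
        (MASS_CYS, True),
    ])
    def test_floor(self, mass, kept):
        peaks = mass_floor_filter([make_peak("a", mass, 5.0)])
        assert bool(peaks) is kept


class TestMergeDuplicates:
    def test_within_ppm_and_tight_rt_merges_and_sums(self, samples_lub):
        a = make_peak("a", 250.0000, 5.00, areas={"S1": 30_000, "S2": 10_000})
        b = make_peak("b", 250.0100, 5.08, areas={"S1": 5_000, "S2": 2_000})
        (merged,) = merge_duplicates([a, b], samples_lub)
        assert merged.areas == {"S1": 35_000, "S2": 12_000}
        # mass/RT come from the member with the larger total area
        assert merged.neutral_mass == 250.0000
        assert merged.rt == 5.00
        assert "merged" in merged.annotations

    def test_beyond_50ppm_not_merged(self, samples_lub):
        a = make_peak("a", 250.0000, 5.00, areas={"S1": 1})
        b = make_peak("b", 250.0200, 5.00, areas={"S1": 1})  # 80 ppm
        assert len(merge_duplicates([a, b], samples_lub)) == 2

    @pytest.mark.parametrize("profile_b,expect_merged", [
        ((10.0, 20.0, 30.0, 40.0), True),   # r = 1 >= 0.9
        ((40.0, 10.0, 35.0, 20.0), False),  # decorrelated
    ])
    def test_loose_rt_requires_correlation(self, samples_multi, profile_b,
                                           expect_merged):
        profile_a = {"L1": 100.0, "L2": 200.0, "L3": 300.0, "L4": 400.0}
        a = make_peak("a", 250.0000, 5.00, areas=profile_a)
        b = make_peak("b", 250.0050, 5.15,
                      areas=dict(zip(["L1", "L2", "L3", "L4"], profile_b)))
        n = len(merge_duplicates([a, b], samples_multi))
        assert (n == 1) is expect_merged

    def test_fewer_than_three_shared_samples_fails_correlation_branch(
        self, samples_multi
    ):
        a = make_peak("a", 250.0000, 5.00, areas={"L1": 1.0, "L2": 2.0})
        b = make_peak("b", 250.0050, 5.15, areas={"L1": 1.0, "L2": 2.0})
        assert len(merge_duplicates([a, b], samples_multi)) == 2

    def test_cross_polarity_never_merges(self, samples_lub):
        a = make_peak("a", 250.0, 5.0, "positive", {"S1": 1})
        b = make_peak("b", 250.0, 5.0, "negative", {"S1": 1})
        assert len(merge_duplicates([a, b], samples_lub)) == 2

    def test_conserves_total_area_per_sample(self, sim_small):
        peaks, samples, _ = sim_small
        merged = merge_duplicates(peaks, samples)
        for sample in [e.sample_id for e in samples.entries]:
            before = sum(p.areas.get(sample, 0.0) for p in peaks)
            after = sum(p.areas.get(sample, 0.0) for p in merged)
            assert after == pytest.approx(before, rel=1e-12)

    def test_idempotent(self, sim_small):
        peaks, samples, _ = sim_small
        once = merge_duplicates(peaks, samples)
        twice = merge_duplicates(once, samples)
        assert [(p.peak_id, p.neutral_mass, p.areas) for p in twice] == \
               [(p.peak_id, p.neutral_mass, p.areas) for p in once]

    def test_transitive_closure_matches_brute_force(self, samples_multi):
        """Random tables with planted near-duplicate chains: merge groups
        equal the all-pairs flooding oracle."""
        rng = np.random.default_rng(5)
        for _ in range(5):
            peaks = []
            base_masses = rng.uniform(150, 800, 40)
            for i, m in enumerate(base_masses):
                rt = float(rng.uniform(1, 12))
                n_dups = int(rng.integers(1, 4))
                for d in range(n_dups):
                    mass = m * (1 + rng.normal(0, 15e-6))
                    areas = {
                        s: float(rng.lognormal(10, 0.5))
                        for s in ["L1", "L2", "L3", "L4"]
                        if rng.random() < 0.9
                    }
                    peaks.append(make_peak(
                        f"p{i}_{d}", float(mass),
                        rt + float(rng.normal(0, 0.08)), "negative", areas
                    ))
            merged = merge_duplicates(peaks, samples_multi)
            expected_groups = brute_force_merge_groups(peaks, samples_multi)
            assert len(merged) == len(expected_groups)
            # each merged peak's area total equals the sum over one oracle group
            totals = sorted(round(p.total_area(), 6) for p in merged)
            peak_by_id = {p.peak_id: p for p in peaks}
            oracle_totals = sorted(
                round(sum(peak_by_id[i].total_area() for i in g), 6)
                for g in expected_groups
            )
            assert totals == oracle_totals


def test_filters_commute_and_return_subsets(sim_small):
    peaks, samples, _ = sim_small
    config = FilterConfig()
    a = blank_filter(intensity_filter(peaks, samples, config), samples, config)
    b = intensity_filter(blank_filter(peaks, samples, config), samples, config)
    assert [p.peak_id for p in a] == [p.peak_id for p in b]
    ids = {p.peak_id for p in peaks}
    assert {p.peak_id for p in a} <= ids
    assert {p.peak_id for p in mass_floor_filter(peaks, config)} <= ids
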