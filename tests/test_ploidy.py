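"""FACS classification, coverage windows, copy-number and segdup calls."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from yeastpop.ploidy import (
    FACS_RANGES,
    ChromosomeCall,
    CoverageProfile,
    FacsReadout,
    assign_ploidy,
    call_chromosome_copy_numbers,
    classify_facs,
    detect_segmental_duplications,
    find_facs_peaks,
    validate_with_allele_balance,
    window_coverage,
)
from yeastpop.simulate import SimulationConfig, simulate_coverage, simulate_population


class TestClassifyFacs:
    @pytest.mark.parametrize(
        "g1,g2,expected",
        [
            (100, 200, 1),
            (200, 400, 2),
            (300, 600, 3),
            (400, 800, 4),
            (500, 950, 5),
            (140, 290, None),  # matches neither the 1n G2 nor the 2n G1 range
        ],
    )
    def test_printed_ranges(self, g1, g2, expected):
        assert classify_facs(FacsReadout(g1, g2)) == expected

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            classify_facs(FacsReadout(0, 200))

    @settings(derandomize=True, max_examples=200)
    @given(st.floats(1, 1000), st.floats(1, 1200))
    def test_total_lookup(self, g1, g2):
        """Pure lookup: a single matching (G1, G2) range pair gives that
        ploidy, anything else is ambiguous."""
        matches = [
            p for p, ((a, b), (c, d)) in FACS_RANGES.items()
            if a <= g1 <= b and c <= g2 <= d
        ]
        expected = matches[0] if len(matches) == 1 else None
        assert classify_facs(FacsReadout(g1, g2)) == expected


class TestFacsPeaks:
    def test_two_gaussian_modes_recovered(self, rng):
        events = pd.DataFrame(
            {
                "fl2a": np.concatenate(
                    [rng.normal(200, 15, 3000), rng.normal(400, 20, 1500)]
                ),
                "fsch": rng.normal(500, 30, 4500),
            }
        )
        r = find_facs_peaks(events)
        assert not r.ambiguous
        assert r.g1_value == pytest.approx(200, abs=15)
        assert r.g2_value == pytest.approx(400, abs=20)

    def test_saturated_events_rejected(self):
        events = pd.DataFrame({"fl2a": np.full(500, 1000.0), "fsch": np.full(500, 1000.0)})
        with pytest.raises(ValueError):
            find_facs_peaks(events)

    def test_single_mode_is_ambiguous(self, rng):
        events = pd.DataFrame(
            {"fl2a": rng.normal(300, 10, 2000), "fsch": rng.normal(500, 30, 2000)}
        )
        assert find_facs_peaks(events).ambiguous


class TestWindowCoverage:
    def test_constant_depth(self):
        track = pd.DataFrame(
            {"chrom": "chr1", "pos": np.arange(0, 5000, 250), "depth": 30.0}
        )
        profile = window_coverage(track, {"chr1": 5000})
        assert np.allclose(profile.windows["chr1"], 30.0)
        assert profile.genome_median == 30.0

    def test_window_count_is_ceil(self):
        track = pd.DataFrame({"chrom": "chr1", "pos": [0, 2500], "depth": 10.0})
        profile = window_coverage(track, {"chr1": 2500})
        assert len(profile.windows["chr1"]) == 3

    def test_one_elevated_chromosome_leaves_median(self):
        frames = []
        for i in range(10):
            depth = 45.0 if i == 0 else 30.0
            frames.append(
                pd.DataFrame(
                    {"chrom": f"chr{i}", "pos": np.arange(0, 50_000, 500), "depth": depth}
                )
            )
        track = pd.concat(frames)
        profile = window_coverage(track, {f"chr{i}": 50_000 for i in range(10)})
        assert profile.genome_median == 30.0

    def test_empty_track_rejected(self):
        with pytest.raises(ValueError):
            window_coverage(pd.DataFrame(columns=["chrom", "pos", "depth"]), {"c": 1000})


def _flat_profile(ratios: dict[str, float], median: float = 30.0, n_win: int = 100):
    windows = {c: np.full(n_win, median * r) for c, r in ratios.items()}
    return CoverageProfile(
        windows=windows,
        chromosome_lengths={c: n_win * 1000 for c in ratios},
        genome_median=median,
    )


class TestCopyNumberCalls:
    def test_euploid_diploid(self):
        calls = call_chromosome_copy_numbers(_flat_profile({"a": 1.0, "b": 1.0}), 2)
        assert all(c.copy_number == 2 and not c.aneuploid for c in calls)

    def test_trisomy_from_ratio(self):
        calls = call_chromosome_copy_numbers(_flat_profile({"a": 1.5, "b": 1.0}), 2)
        byname = {c.chromosome: c for c in calls}
        assert byname["a"].copy_number == 3 and byname["a"].aneuploid
        assert byname["b"].copy_number == 2

    def test_invariant_under_depth_rescaling(self):
        p1 = _flat_profile({"a": 1.5, "b": 1.0}, median=30)
        p2 = _flat_profile({"a": 1.5, "b": 1.0}, median=30)
        for c in p2.windows:
            p2.windows[c] = p2.windows[c] * 3.7
        p2.genome_median *= 3.7
        c1 = call_chromosome_copy_numbers(p1, 2)
        c2 = call_chromosome_copy_numbers(p2, 2)
        assert [c.copy_number for c in c1] == [c.copy_number for c in c2]

    def test_disomy_in_simulated_triploid(self):
        cfg = SimulationConfig(
            seed=21, n_isolates=12, ploidy_distribution={3: 1.0},
            aneuploidy_rate=0.25, chromosome_lengths=(600_000,) * 6,
        )
        genotypes, truth = simulate_population(cfg)
        coverage, _ = simulate_coverage(genotypes, truth, cfg)
        checked = 0
        for i, iso in enumerate(truth.isolates):
            calls = call_chromosome_copy_numbers(coverage[iso], 3)
            for c, call in enumerate(calls):
                if truth.chromosome_cn[i, c] == 2 and not any(
                    d[0] == c for d in truth.segdups[i]
                ):
                    assert call.copy_number == 2 and call.aneuploid
                    checked += 1
        assert checked >= 1

    def test_zero_median_rejected(self):
        p = _flat_profile({"a": 1.0})
        p.genome_median = 0.0
        with pytest.raises(ValueError):
            call_chromosome_copy_numbers(p, 2)


class TestAlleleBalance:
    def test_disomy_consistent(self, rng):
        calls = [ChromosomeCall("a", 1.0, 2, False)]
        fracs = {"a": rng.binomial(60, 0.5, 200) / 60}
        out = validate_with_allele_balance(fracs, calls)
        assert out[0].allele_balance_support == "consistent"

    def test_trisomy_modes_consistent(self, rng):
        calls = [ChromosomeCall("a", 1.5, 3, True)]
        third = rng.binomial(60, 1 / 3, 100) / 60
        two_thirds = rng.binomial(60, 2 / 3, 100) / 60
        out = validate_with_allele_balance({"a": np.concatenate([third, two_thirds])}, calls)
        assert out[0].allele_balance_support == "consistent"

    def test_trisomy_called_as_disomy_is_inconsistent(self, rng):
        cfg = SimulationConfig(
            seed=33, n_isolates=4, ploidy_distribution={3: 1.0}, aneuploidy_rate=0.0,
            chromosome_lengths=(800_000,) * 2,
        )
        genotypes, truth = simulate_population(cfg)
        _, depths = simulate_coverage(genotypes, truth, cfg)
        df = depths[truth.isolates[0]]
        het = df[df["code"] == 1]
        fracs = {
            chrom: (sub["alt_depth"] / sub["dp"]).to_numpy()
            for chrom, sub in het.groupby("chrom")
        }
        calls = [ChromosomeCall(c, 1.0, 2, False) for c in fracs]  # wrong CN on purpose
        out = validate_with_allele_balance(fracs, calls)
        assert all(c.allele_balance_support == "inconsistent" for c in out)

    def test_few_sites_no_data(self):
        calls = [ChromosomeCall("a", 1.0, 2, False)]
        out = validate_with_allele_balance({"a": np.array([0.5] * 3)}, calls)
        assert out[0].allele_balance_support == "no_data"


class TestSegmentalDuplications:
    def test_uniform_chromosome_is_empty(self):
        p = _flat_profile({"a": 1.0}, n_win=200)
        calls = call_chromosome_copy_numbers(p, 2)
        assert detect_segmental_duplications(p, calls, 2) == []

    def test_short_blip_below_min_segment_ignored(self):
        p = _flat_profile({"a": 1.0}, n_win=200)
        p.windows["a"][100:105] = 45.0  # 5-kb blip at 1.5x
        calls = call_chromosome_copy_numbers(p, 2)
        assert detect_segmental_duplications(p, calls, 2) == []

    def test_noiseless_duplication_recovered_exactly(self):
        p = _flat_profile({"a": 1.0, "b": 1.0}, n_win=300)
        p.windows["a"][100:150] = 45.0  # 50-kb segment at CN 3 on a CN-2 chromosome
        calls = call_chromosome_copy_numbers(p, 2)
        dups = detect_segmental_duplications(p, calls, 2)
        assert len(dups) == 1
        d = dups[0]
        assert (d.chromosome, d.start, d.end, d.copy_number) == ("a", 100_000, 150_000, 3)

    def test_planted_duplication_recovered_within_one_window(self):
        # deep, near-Poisson coverage so boundary windows are classifiable
        cfg = SimulationConfig(
            seed=13, n_isolates=20, mean_depth=200.0, depth_dispersion=10_000.0,
        )
        genotypes, truth = simulate_population(cfg)
        coverage, _ = simulate_coverage(genotypes, truth, cfg)
        checked = 0
        for i, iso in enumerate(truth.isolates):
            if not truth.segdups[i]:
                continue
            calls = call_chromosome_copy_numbers(coverage[iso], int(truth.ploidy[i]))
            dups = detect_segmental_duplications(coverage[iso], calls, int(truth.ploidy[i]))
            for c, s, e, cn in truth.segdups[i]:
                chrom = truth.chromosomes[c]
                match = [
                    d for d in dups
                    if d.chromosome == chrom
                    and abs(d.start - (s // 1000) * 1000) <= 1000
                    and abs(d.end - (e // 1000) * 1000) <= 1000
                ]
                assert match, (iso, (chrom, s, e, cn), dups)
                assert match[0].copy_number == cn
                checked += 1
        assert checked >= 3


class TestAssignPloidy:
    def test_facs_with_consistent_balance(self, rng):
        fracs = rng.binomial(60, 0.5, 300) / 60
        call = assign_ploidy("x", 2, fracs)
        assert call.ploidy == 2 and call.facs_evidence

    def test_ambiguous_facs_resolved_by_triploid_modes(self, rng):
        fracs = np.concatenate(
            [rng.binomial(90, 1 / 3, 200) / 90, rng.binomial(90, 2 / 3, 200) / 90]
        )
        call = assign_ploidy("x", None, fracs)
        assert call.ploidy == 3 and call.allele_balance_evidence

    def test_conflicting_evidence_is_ambiguous(self, rng):
        # FACS says diploid but genome-wide modes are tetraploid-like
        k = rng.choice([1, 2, 3], 600)
        fracs = rng.binomial(100, k / 4, 600) / 100
        call = assign_ploidy("x", 2, fracs)
        assert call.ploidy is None
        assert call.conflict and call.facs_evidence and call.allele_balance_evidence

    def test_no_evidence_rejected(self):
        with pytest.raises(ValueError):
            assign_ploidy("x", None, None)
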