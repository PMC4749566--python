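"""Null models, empirical p-values, fold ratios, cut-off selection, plateau."""
import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import binom

from corefit import (
    Compendium,
    GeneSetCollection,
    RankedProfile,
    SyntheticSpec,
    empirical_p,
    fold_ratio,
    fuzzy_intersect,
    extract_signatures,
    generate_compendium,
    plateau_scan,
    probe_permutation_null,
    refine_cutoff_by_enrichment,
    resampling_null,
    scan_cutoffs,
    select_cutoff,
    support_counts,
)
from corefit.calibrate import CutoffScan, NullDistribution, _find_plateau
from corefit.profiles import ProbeGeneMap

from conftest import random_compendium


def null_from(values, **kw):
    defaults = dict(null_kind="resampling", n=5, k_min=3, f=0.2, seed=0)
    defaults.update(kw)
    return NullDistribution(np.asarray(values), **defaults)


class TestEmpiricalP:
    def test_observed_beats_all_999_draws(self):
        null = null_from(np.zeros(999))
        assert empirical_p(5, null) == pytest.approx(1 / 1000)

    def test_observed_below_all_draws(self):
        null = null_from(np.full(99, 10))
        assert empirical_p(1, null) == 1.0

    def test_observed_at_median(self):
        values = np.arange(1, 202)  # 1..201, median 101
        null = null_from(values)
        # counting oracle: 101 of 201 draws are >= 101
        assert empirical_p(101, null) == (1 + 101) / 202

    def test_add_one_keeps_p_positive_and_superuniform_bound(self):
        null = null_from([3])
        assert 0 < empirical_p(100, null) <= 1


class TestFoldRatio:
    def test_paper_style_signal_to_noise(self):
        # 108 observed vs a null averaging 32 → 3.375, "close to 3"
        null = null_from(np.full(1000, 32))
        assert fold_ratio(108, null) == pytest.approx(3.375)

    def test_observed_equal_to_null_mean(self):
        assert fold_ratio(7.0, null_from([7, 7, 7])) == 1.0

    def test_zero_null_flagged_infinite(self):
        assert math.isinf(fold_ratio(4, null_from([0, 0, 0])))

    def test_scale_free_under_draw_duplication(self):
        values = np.array([1, 4, 2, 9, 0])
        assert fold_ratio(6, null_from(values)) == pytest.approx(
            fold_ratio(6, null_from(np.tile(values, 2)))
        )


class TestResamplingNull:
    def test_degenerate_background(self):
        prof = tuple(f"P{i:03d}" for i in range(50))
        background = Compendium(
            [RankedProfile(f"d{i}", prof) for i in range(6)]
        )
        nulls = resampling_null(background, n=4, k_min=4, f=0.2, b=25, seed=3)
        tail = int(0.2 * 50)
        assert (nulls["up"].cardinalities == tail).all()
        assert (nulls["down"].cardinalities == tail).all()

    def test_b_one_and_reproducibility(self):
        rng = np.random.default_rng(0)
        background = random_compendium(rng, 60, 12)
        one = resampling_null(background, n=5, k_min=2, f=0.2, b=1, seed=9)
        assert one["down"].b == 1
        again = resampling_null(background, n=5, k_min=2, f=0.2, b=1, seed=9)
        assert (one["down"].cardinalities == again["down"].cardinalities).all()

    def test_matches_bruteforce_with_same_seed(self):
        """Independent re-implementation consuming the identical RNG stream."""
        rng = np.random.default_rng(4)
        background = random_compendium(rng, 40, 20)
        got = resampling_null(background, n=5, k_min=5, f=0.2, b=30, seed=123)

        oracle_rng = np.random.default_rng(123)
        sigs = extract_signatures(background, 0.2)
        expected = []
        for _ in range(30):
            rows = oracle_rng.choice(len(background), size=5, replace=False)
            chosen = [sigs[r] for r in rows]
            inter_up = frozenset.intersection(*[s.up_set for s in chosen])
            expected.append(len(inter_up))
        assert list(got["up"].cardinalities) == expected

    def test_n_larger_than_background_rejected(self):
        rng = np.random.default_rng(1)
        background = random_compendium(rng, 30, 4)
        with pytest.raises(ValueError, match="cannot draw"):
            resampling_null(background, n=5, k_min=2, b=2, seed=0)


class TestProbePermutationNull:
    def test_mean_matches_binomial_expectation(self):
        # after independent permutation, P(probe in a tail) = t/U exactly,
        # independently across profiles: support ~ Binomial(N, t/U)
        rng = np.random.default_rng(2)
        comp = random_compendium(rng, 100, 6)
        k = 2
        nulls = probe_permutation_null(comp, k_min=k, f=0.2, b=400, seed=5)
        expected = 100 * binom.sf(k - 1, 6, 0.2)
        got = nulls["down"].mean
        sd = math.sqrt(400)  # crude: per-draw sd is a few probes
        assert abs(got - expected) < 5 * expected / sd + 2

    def test_identical_profiles_agreement_destroyed(self):
        probes = tuple(f"P{i:03d}" for i in range(100))
        comp = Compendium([RankedProfile(f"d{i}", probes) for i in range(5)])
        nulls = probe_permutation_null(comp, k_min=5, f=0.2, b=100, seed=8)
        sigs = extract_signatures(comp, 0.2)
        observed = len(frozenset.intersection(*[s.down_set for s in sigs]))
        assert observed == 20
        assert nulls["down"].mean < observed / 10

    def test_single_draw_reproducible(self):
        rng = np.random.default_rng(3)
        comp = random_compendium(rng, 50, 4)
        a = probe_permutation_null(comp, k_min=2, b=1, seed=77)
        b = probe_permutation_null(comp, k_min=2, b=1, seed=77)
        assert (a["up"].cardinalities == b["up"].cardinalities).all()


def constructed_scan(rows):
    table = pd.DataFrame(rows)
    return CutoffScan(table=table, n=int(table["k"].max()), f=0.2,
                      b=1000, null_kind="resampling", seed=0)


def scan_rows(direction, ks, observed, null_mean, p):
    return [
        {"direction": direction, "k": k, "observed": o, "null_mean": m,
         "fold": o / max(m, 1e-3), "p": pv}
        for k, o, m, pv in zip(ks, observed, null_mean, p)
    ]


class TestSelectCutoff:
    def base_rows(self):
        # k = 6..11; ks 8..11 clear fold 3 and p < 0.05 on calibrated nulls
        rows = scan_rows(
            "down",
            ks=[6, 7, 8, 9, 10, 11],
            observed=[300, 180, 108, 60, 40, 30],
            null_mean=[200, 90, 32, 12, 8, 5],
            p=[0.4, 0.2, 0.001, 0.001, 0.002, 0.01],
        )
        rows += scan_rows("up", ks=[6, 7, 8, 9, 10, 11],
                          observed=[10] * 6, null_mean=[30] * 6, p=[1.0] * 6)
        return rows

    def test_maximal_passing_k(self):
        sel = select_cutoff(constructed_scan(self.base_rows()))
        assert sel.by_direction["down"] == 11
        assert sel.by_direction["up"] is None

    def test_exactly_one_passing_k(self):
        rows = scan_rows("down", ks=[1, 2, 3], observed=[50, 40, 30],
                         null_mean=[45, 12, 25], p=[0.8, 0.01, 0.5])
        rows += scan_rows("up", ks=[1, 2, 3], observed=[1, 1, 1],
                          null_mean=[45, 30, 25], p=[1, 1, 1])
        assert select_cutoff(constructed_scan(rows)).by_direction["down"] == 2

    def test_degenerate_null_is_not_evaluable(self):
        # fold explodes when the chance expectation is ~0; such k must not win
        rows = scan_rows("down", ks=[8, 9, 10], observed=[108, 50, 20],
                         null_mean=[32, 0.05, 0.0], p=[0.001, 0.001, 0.001])
        rows += scan_rows("up", ks=[8, 9, 10], observed=[0, 0, 0],
                          null_mean=[32, 0.05, 0.0], p=[1, 1, 1])
        assert select_cutoff(constructed_scan(rows)).by_direction["down"] == 8

    def test_no_selection_is_valid(self):
        rows = scan_rows("down", ks=[1, 2], observed=[10, 10],
                         null_mean=[10, 10], p=[0.5, 0.5])
        rows += scan_rows("up", ks=[1, 2], observed=[10, 10],
                          null_mean=[10, 10], p=[0.5, 0.5])
        sel = select_cutoff(constructed_scan(rows))
        assert sel.by_direction == {"up": None, "down": None}


class TestRefineByEnrichment:
    def make_world(self):
        # gene sets in which only the k ≤ 9 cores are enriched
        probes = [f"P{i:02d}" for i in range(40)]
        probe_map = ProbeGeneMap({p: "G" + p[1:] for p in probes})
        universe = {"G" + p[1:] for p in probes}
        sets = GeneSetCollection({"PATH": frozenset({"G00", "G01", "G02", "G03"})})
        table_stub = support_counts(extract_signatures(
            Compendium([RankedProfile("d", tuple(probes)),
                        RankedProfile("e", tuple(reversed(probes)))]), 0.25))
        from corefit import FitResult

        def fit_with_core(core):
            return FitResult(up_core=frozenset(), down_core=frozenset(core),
                             k_min=1, n_signatures=2, table=table_stub)

        fits = {
            8: fit_with_core({"P00", "P01", "P02", "P03"}),   # all in PATH
            9: fit_with_core({"P00", "P01", "P02"}),          # still enriched
            10: fit_with_core({"P20", "P21", "P22"}),         # no PATH overlap
        }
        rows = scan_rows("down", ks=[8, 9, 10], observed=[40, 30, 20],
                         null_mean=[10, 6, 4], p=[0.001] * 3)
        rows += scan_rows("up", ks=[8, 9, 10], observed=[0] * 3,
                          null_mean=[10, 6, 4], p=[1.0] * 3)
        return constructed_scan(rows), fits, sets, probe_map, universe

    def test_maximal_enriched_k_wins(self):
        scan, fits, sets, probe_map, universe = self.make_world()
        sel = refine_cutoff_by_enrichment(scan, fits, sets, probe_map, universe)
        assert sel.by_direction["down"] == 9 and sel.refined

    def test_all_enriched_keeps_max_k(self):
        scan, fits, sets, probe_map, universe = self.make_world()
        fits[10] = fits[9]
        sel = refine_cutoff_by_enrichment(scan, fits, sets, probe_map, universe)
        assert sel.by_direction["down"] == 10

    def test_none_enriched_falls_back_flagged(self):
        scan, fits, sets, probe_map, universe = self.make_world()
        for k in fits:
            fits[k] = fits[10] if k != 10 else fits[k]
        fits[8] = fits[9] = fits[10]
        sel = refine_cutoff_by_enrichment(scan, fits, sets, probe_map, universe)
        assert not sel.refined
        assert "fell back" in sel.rationale
        assert sel.by_direction["down"] == 10  # the base maximal rule

    def test_empty_collection_rejected(self):
        scan, fits, sets, probe_map, universe = self.make_world()
        with pytest.raises(ValueError):
            refine_cutoff_by_enrichment(
                scan, fits, GeneSetCollection({}), probe_map, universe)


class TestPlateau:
    def test_rule_on_constructed_curve(self):
        assert _find_plateau([5, 6, 7, 8, 9, 10],
                             [30, 18, 12, 10, 10, 10], 0.02) == 8

    def test_no_plateau_on_steep_curve(self):
        assert _find_plateau([2, 3, 4], [100, 50, 25], 0.02) is None

    def test_constant_curve_plateaus_at_min_n(self):
        assert _find_plateau([2, 3, 4], [7, 7, 7], 0.02) == 2

    def test_scan_runs_and_flags(self):
        rng = np.random.default_rng(6)
        background = random_compendium(rng, 80, 30)
        curve = plateau_scan(background, theta=0.7, n_range=range(2, 9),
                             f=0.2, b=60, seed=11)
        assert list(curve.table["n"]) == list(range(2, 9))
        assert (curve.table["mean_cardinality"] >= 0).all()
        if curve.plateau_n is not None:
            flagged = curve.table[curve.table["is_plateau"]]["n"].min()
            assert flagged == curve.plateau_n


class TestPipelineNullSoundness:
    def test_pvalues_superuniform_on_pure_noise(self):
        """Mini version of the calibration soundness check (50 runs)."""
        ps = []
        for seed in range(50):
            spec = SyntheticSpec(
                universe_size=200, n_correctors=5, n_background=30,
                n_core_down=0, n_core_up=0, n_moa_clusters=0,
                background_module_size=0, seed=10_000 + seed,
            )
            comp, truth = generate_compendium(spec)
            corr = comp.subset(truth.corrector_ids)
            bg = comp.subset(truth.background_ids)
            table = support_counts(extract_signatures(corr, 0.2))
            observed = len(fuzzy_intersect(table, 2).down_core)
            nulls = resampling_null(bg, n=5, k_min=2, f=0.2, b=79, seed=seed)
            ps.append(empirical_p(observed, nulls["down"]))
        ps = np.sort(ps)
        d_plus = np.max(np.arange(1, 51) / 50 - ps)
        assert d_plus < 1.52 / math.sqrt(50)  # one-sided KS, alpha ~ 0.01


def test_scan_cutoffs_consistent_with_single_k_nulls(small_correctors,
                                                     small_background):
    scan = scan_cutoffs(small_correctors, small_background, b=150, seed=21)
    nulls = resampling_null(small_background, n=len(small_correctors),
                            k_min=3, b=150, seed=21)
    row = scan.table[(scan.table.direction == "down") & (scan.table.k == 3)].iloc[0]
    assert row["null_mean"] == pytest.approx(nulls["down"].mean)
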