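"""Unit tests for triplet extraction, the branch-length mixture and summaries."""

import math

import numpy as np
import pytest

from discordia import synthetic_data as sd
from discordia import triplet_mixture as tm


# ---------------------------------------------------------------------------
# extract_triplet
# ---------------------------------------------------------------------------

class TestExtractTriplet:
    def test_direct_read_off(self):
        obs = tm.extract_triplet(
            "(((A:1.0,B:1.0):0.5,C:1.5):1.0,O:2.5);", ["A", "B", "C"], "O"
        )
        assert obs.topology == ("A", "B")
        assert obs.t == pytest.approx(0.5)

    def test_pruning_sums_internal_path(self):
        # removing D merges two internal edges of 0.1 into the cherry branch
        tree = "((((A:1,C:1):0.1,D:5):0.1,B:1.2):1.0,O:2.5);"
        obs = tm.extract_triplet(tree, ["A", "B", "C"], "O")
        assert obs.topology == ("A", "C")
        assert obs.t == pytest.approx(0.2)

    def test_extra_taxa_elsewhere_are_ignored(self):
        tree = "(((((A:1.0,C:1.0):0.2,B:1.2):0.4,(D:0.5,E:0.5):1.1):0.6,O:2.2):0.1,F:2.3);"
        obs = tm.extract_triplet(tree, ["A", "B", "C"], "O")
        assert obs.topology == ("A", "C")
        assert obs.t == pytest.approx(0.2)

    def test_star_triplet_unresolved(self):
        obs = tm.extract_triplet("((A:1,B:1,C:1):1,O:2);", ["A", "B", "C"], "O")
        assert obs.topology is None

    def test_missing_taxon_raises(self):
        with pytest.raises(tm.MissingTaxonError):
            tm.extract_triplet("((A:1,B:1):1,O:2);", ["A", "B", "C"], "O")

    def test_matches_simulator_ground_truth(self):
        cfg = sd.MscConfig(t2=0.8, n_loci=150, seed=42)
        trees, truth = sd.simulate_triplet_loci(cfg)
        obs, skipped = tm.extract_triplets(trees, cfg.taxa, cfg.outgroup)
        assert skipped == 0
        for got, want in zip(obs, truth):
            assert got.topology == want.topology
            assert got.t == pytest.approx(want.t, rel=1e-6)

    def test_subst_scale_scales_tree_lengths(self):
        a = sd.simulate_triplet_loci(sd.MscConfig(t2=0.8, n_loci=40, seed=9))
        b = sd.simulate_triplet_loci(
            sd.MscConfig(t2=0.8, n_loci=40, seed=9, subst_scale=2.0)
        )
        oa, _ = tm.extract_triplets(a[0], ("A", "B", "C"), "O")
        ob, _ = tm.extract_triplets(b[0], ("A", "B", "C"), "O")
        for x, y in zip(oa, ob):
            assert y.t == pytest.approx(2.0 * x.t, rel=1e-6)


# ---------------------------------------------------------------------------
# tallies
# ---------------------------------------------------------------------------

class TestTally:
    def test_counts_and_percentages(self):
        obs = (
            [tm.TripletObservation("x", ("A", "B"), 1.0)] * 761
            + [tm.TripletObservation("x", ("A", "C"), 1.0)] * 411
            + [tm.TripletObservation("x", ("B", "C"), 1.0)] * 302
        )
        tally = tm.tally_topologies(obs)
        assert tally.total == 1474
        assert tally.percent_rounded(("A", "B")) == 52
        assert tally.percent(("A", "B")) == pytest.approx(100 * 761 / 1474)

    def test_single_observation_is_100_percent(self):
        tally = tm.tally_topologies([tm.TripletObservation("x", ("A", "B"), 1.0)])
        assert tally.percent(("A", "B")) == pytest.approx(100.0)

    def test_empty_input(self):
        tally = tm.tally_topologies([])
        assert tally.total == 0 and tally.counts == {}


# ---------------------------------------------------------------------------
# fits
# ---------------------------------------------------------------------------

class TestIlsOnlyFit:
    def test_hand_computed_example(self):
        fit = tm.fit_ils_only([1.0, 2.0, 3.0])
        assert fit.lambda_ == pytest.approx(2.0)
        assert fit.lnl == pytest.approx(3 * math.log(0.5) - 3, abs=1e-10)
        assert fit.bic == pytest.approx(math.log(3) + 10.158883, abs=1e-4)

    def test_mle_consistency(self):
        t = np.random.default_rng(0).exponential(5.0, 10000)
        fit = tm.fit_ils_only(t)
        assert abs(fit.lambda_ - 5.0) < 3 * 5.0 / math.sqrt(10000)

    @pytest.mark.parametrize("c", [0.5, 2.0, 7.3])
    def test_scale_equivariance(self, c):
        t = np.random.default_rng(1).exponential(1.0, 200)
        base, scaled = tm.fit_ils_only(t), tm.fit_ils_only(c * t)
        assert scaled.lambda_ == pytest.approx(c * base.lambda_)
        assert scaled.lnl == pytest.approx(base.lnl - 200 * math.log(c))

    def test_degenerate_input_raises(self):
        with pytest.raises(ValueError):
            tm.fit_ils_only([0.0, 0.0, 0.0])


class TestMixtureFit:
    def test_recovers_planted_weight_single_seed(self):
        t = sd.sample_mixture_lengths(sd.MixtureTruth(pi=0.3, lam=1.0, c=2.0, n=2000, seed=1))
        fit = tm.fit_mixture_em(t)
        assert abs(fit.pi - 0.3) < 0.1
        assert abs(fit.c - 2.0) < 0.3

    def test_nested_model_limit_on_pure_exponential(self):
        t = sd.sample_mixture_lengths(sd.MixtureTruth(pi=1.0, lam=1.0, n=500, seed=2))
        exp_fit = tm.fit_ils_only(t)
        mix = tm.fit_mixture_em(t)
        assert mix.lnl >= exp_fit.lnl - 1e-9
        # the mixture may soak up a little noise but stays close to nested
        assert mix.lnl - exp_fit.lnl < 10.0

    def test_all_shifted_boundary(self):
        t = sd.sample_mixture_lengths(sd.MixtureTruth(pi=0.0, lam=1.0, c=2.0, n=2000, seed=3))
        fit = tm.fit_mixture_em(t)
        assert fit.c <= t.min() + 1e-9
        assert abs(fit.c - 2.0) < 0.3
        assert fit.pi < 0.1

    def test_lnl_trace_monotone(self):
        t = sd.sample_mixture_lengths(sd.MixtureTruth(pi=0.4, lam=2.0, c=3.0, n=800, seed=4))
        fit = tm.fit_mixture_em(t)
        trace = np.array(fit.lnl_trace)
        assert np.all(np.diff(trace) >= -1e-7)

    @pytest.mark.parametrize("c_scale", [0.5, 3.5])
    def test_scale_equivariance(self, c_scale):
        t = sd.sample_mixture_lengths(sd.MixtureTruth(pi=0.4, lam=1.0, c=2.0, n=1000, seed=5))
        base = tm.fit_mixture_em(t)
        scaled = tm.fit_mixture_em(c_scale * t)
        assert scaled.pi == pytest.approx(base.pi, abs=1e-6)
        assert scaled.lambda_ == pytest.approx(c_scale * base.lambda_, rel=1e-6)
        assert scaled.c == pytest.approx(c_scale * base.c, rel=1e-5)

    def test_too_few_values_raises(self):
        with pytest.raises(ValueError):
            tm.fit_mixture_em([1.0] * 9)


class TestClassify:
    @pytest.mark.parametrize(
        "bic1,bic2,expected",
        [
            (-100.0, -85.0, tm.ILS_ONLY),
            (-85.0, -100.0, tm.MIXTURE),
            (-100.0, -95.0, tm.INDISTINGUISHABLE),
        ],
    )
    def test_delta_bic_rule(self, bic1, bic2, expected):
        cls, delta = tm.classify_topology(bic1, bic2)
        assert cls == expected
        assert delta == pytest.approx(bic2 - bic1)

    def test_fit_topology_nesting_invariant(self):
        t = sd.sample_mixture_lengths(sd.MixtureTruth(pi=0.5, lam=1.0, c=3.0, n=400, seed=6))
        fit = tm.fit_topology(t)
        assert fit.lnl2 >= fit.lnl1 - 1e-9
        assert fit.classification == tm.MIXTURE
        assert fit.ils_weight == pytest.approx(fit.pi)

    def test_zero_branches_excluded_but_counted(self):
        t = np.concatenate([np.zeros(5), np.random.default_rng(7).exponential(1.0, 100)])
        fit = tm.fit_topology(t)
        assert fit.n == 105
        assert fit.n_zero_excluded == 5


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def _fake_fit(classification, pi=1.0):
    return tm.MixtureFit(
        n=100, lambda1=1.0, lnl1=-100.0, bic1=205.0, pi=pi, lambda2=1.0,
        c=0.0, lnl2=-100.0, bic2=220.0, delta_bic=15.0,
        classification=classification,
    )


class TestSummaries:
    def test_all_ils_weights_one(self):
        counts = {("A", "B"): 761, ("A", "C"): 400, ("B", "C"): 313}
        fits = {
            ("A", "C"): _fake_fit(tm.ILS_ONLY),
            ("B", "C"): _fake_fit(tm.ILS_ONLY),
        }
        s = tm.summarize_triplet(counts, fits, ("A", "B"))
        assert s.n_total == 1474
        assert s.n_discordant == 713
        assert s.ils_loci_estimate == pytest.approx(713.0)
        assert s.ils_percent == pytest.approx(100.0)
        assert not s.introgression_flag

    def test_weighted_mixture_topology(self):
        counts = {("A", "B"): 761, ("A", "C"): 400, ("B", "C"): 313}
        fits = {
            ("A", "C"): _fake_fit(tm.MIXTURE, pi=0.9045),
            ("B", "C"): _fake_fit(tm.ILS_ONLY),
        }
        s = tm.summarize_triplet(counts, fits, ("A", "B"))
        assert s.ils_loci_estimate == pytest.approx(0.9045 * 400 + 313)
        assert s.introgression_flag

    def test_species_topology_never_flags(self):
        counts = {("A", "B"): 50, ("A", "C"): 30, ("B", "C"): 20}
        fits = {
            ("A", "B"): _fake_fit(tm.MIXTURE, pi=0.5),
            ("A", "C"): _fake_fit(tm.ILS_ONLY),
            ("B", "C"): _fake_fit(tm.ILS_ONLY),
        }
        s = tm.summarize_triplet(counts, fits, ("A", "B"))
        assert not s.introgression_flag

    def test_no_discordant_loci(self):
        s = tm.summarize_triplet({("A", "B"): 10}, {}, ("A", "B"))
        assert s.ils_percent is None

    def test_count_conservation(self):
        counts = {("A", "B"): 761, ("A", "C"): 411, ("B", "C"): 302}
        s = tm.summarize_triplet(counts, {}, ("A", "B"))
        assert s.counts[("A", "B")] + s.n_discordant == s.n_total

    def test_summarize_all_percentages(self):
        base = dict(taxa=("A", "B", "C"), outgroup="O", species_topology=("A", "B"))
        flagged = [tm.TripletSummary(**base, introgression_flag=True) for _ in range(17)]
        clean = [tm.TripletSummary(**base) for _ in range(43)]
        study = tm.summarize_all(flagged + clean)
        assert study.introgression_percent == pytest.approx(28.33)
        study0 = tm.summarize_all(clean)
        assert study0.introgression_percent == 0.0

    def test_triplet_combinations(self):
        combos = tm.triplet_combinations(["d", "b", "a", "c"])
        assert len(combos) == 4
        assert ("a", "b", "c") in combos


class TestPipeline:
    def test_analyze_triplet_end_to_end(self):
        cfg = sd.MscConfig(t2=1.5, n_loci=400, seed=11)
        trees, _ = sd.simulate_triplet_loci(cfg)
        s = tm.analyze_triplet(trees, cfg.taxa, cfg.outgroup)
        assert s.species_topology == ("A", "B")
        assert s.n_total <= 400
        assert s.ils_percent is not None
        table = tm.fits_table(s)
        assert set(table["topology"]) == {"A-B", "A-C", "B-C"}
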