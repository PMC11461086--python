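"""Likelihood assignment: frequencies, lnL arithmetic, downsampling, tests."""

import numpy as np
import pytest

from paleopop import assign, simdata
from paleopop.containers import MISSING, PseudohaploidCalls, make_labels
from paleopop.simdata import SimConfig
from tests.conftest import toy_matrix


def _calls(rows, prefix="T"):
    c = np.asarray(rows, dtype=np.int8)
    m = toy_matrix(np.zeros((1, c.shape[1]), dtype=np.int8))
    return PseudohaploidCalls(
        samples=np.array([f"{prefix}{i + 1}" for i in range(c.shape[0])],
                         dtype=object),
        sites=m.sites, calls=c)


class TestPopFrequencies:
    def test_smoothed_frequency_arithmetic(self):
        # two diploids with dosages (1,1): (2 + 0.5)/(4 + 1) = 0.5
        m = toy_matrix([[1], [1]])
        labels = make_labels(m.samples, "A", "modern")
        f = assign.pop_allele_frequencies(m, labels, smoothing=0.5)
        assert f.row("A")[0] == pytest.approx(0.5)

    def test_monomorphic_reference_never_exactly_zero(self):
        # 25 diploids all dosage 0: 0.5/51
        m = toy_matrix(np.zeros((25, 1), dtype=np.int8))
        labels = make_labels(m.samples, "A", "modern")
        f = assign.pop_allele_frequencies(m, labels, smoothing=0.5)
        assert f.row("A")[0] == pytest.approx(0.5 / 51)
        assert 0.0 < f.row("A")[0] < 1.0

    def test_leave_one_out_drops_the_carrier(self):
        m = toy_matrix([[2], [0], [0]])
        labels = make_labels(m.samples, "A", "modern")
        full = assign.pop_allele_frequencies(m, labels)
        loo = assign.pop_allele_frequencies(m, labels, leave_out="S1")
        assert full.row("A")[0] == pytest.approx(2.5 / 7)
        assert loo.row("A")[0] == pytest.approx(0.5 / 5)

    def test_zero_called_site_flagged_uninformative(self):
        m = toy_matrix([[MISSING], [MISSING]])
        labels = make_labels(m.samples, "A", "modern")
        f = assign.pop_allele_frequencies(m, labels)
        assert f.row("A")[0] == pytest.approx(0.5)
        assert not f.informative("A")[0]


class TestSampleOptimizedVariantSet:
    def test_toy_counts(self):
        """10 panel sites: 4 fail MAF, target misses 2 others -> 4 remain."""
        rng = np.random.default_rng(0)
        d = rng.integers(0, 2, size=(10, 10)).astype(np.int8)  # ~MAF 0.25
        d[:, :4] = 0  # monomorphic: MAF 0 < 0.1
        panel = toy_matrix(d)
        calls = np.zeros((1, 10), dtype=np.int8)
        calls[0, 4:6] = MISSING
        target = _calls(calls)
        sites = assign.sample_optimized_variant_set(target, "T1", panel,
                                                    min_maf=0.1,
                                                    max_missing=0.1)
        assert list(sites) == [6, 7, 8, 9]

    def test_fully_genotyped_target_keeps_filtered_panel(self):
        d = np.array([[0, 1], [1, 1], [2, 1], [1, 0]], dtype=np.int8)
        panel = toy_matrix(d)
        target = _calls([[0, 1]])
        sites = assign.sample_optimized_variant_set(target, "T1", panel)
        assert list(sites) == [0, 1]

    def test_empty_target_warns_and_returns_nothing(self):
        panel = toy_matrix([[0, 1], [1, 1]])
        target = _calls([[MISSING, MISSING]])
        with pytest.warns(UserWarning, match="no usable sites"):
            sites = assign.sample_optimized_variant_set(target, "T1", panel)
        assert len(sites) == 0


class TestSampleLoglik:
    def test_two_site_arithmetic(self):
        """Observed alleles at frequencies 0.9 and 0.8: ln .9 + ln .8."""
        freqs = assign.PopFrequencies(
            populations=["A"], sites=None,
            freq=np.array([[0.9, 0.8]]),
            n_called_alleles=np.array([[10, 10]]), smoothing=0.5)
        res = assign.sample_loglik(np.array([1, 1], dtype=np.int8), freqs,
                                   "A", np.array([0, 1]))
        assert res.sum_lnl == pytest.approx(np.log(0.9) + np.log(0.8))
        assert res.sum_lnl == pytest.approx(-0.3285, abs=1e-4)
        assert res.normalized == pytest.approx(-0.16425, abs=1e-4)
        assert res.n_used == 2

    def test_high_frequency_limit_approaches_zero(self):
        freqs = assign.PopFrequencies(
            populations=["A"], sites=None,
            freq=np.array([[1 - 1e-9] * 5]),
            n_called_alleles=np.array([[10] * 5]), smoothing=1e-9)
        res = assign.sample_loglik(np.ones(5, dtype=np.int8), freqs, "A",
                                   np.arange(5))
        assert res.normalized == pytest.approx(0.0, abs=1e-6)
        assert res.normalized <= 0.0

    def test_each_site_strictly_decreases_the_sum(self):
        freqs = assign.PopFrequencies(
            populations=["A"], sites=None,
            freq=np.array([[0.6, 0.7, 0.2]]),
            n_called_alleles=np.array([[10, 10, 10]]), smoothing=0.5)
        calls = np.array([1, 1, 0], dtype=np.int8)
        prev = 0.0
        for k in (1, 2, 3):
            s = assign.sample_loglik(calls, freqs, "A", np.arange(k)).sum_lnl
            assert s < prev
            prev = s

    def test_uncalled_sites_skipped_and_counted(self):
        freqs = assign.PopFrequencies(
            populations=["A"], sites=None,
            freq=np.array([[0.5, 0.5]]),
            n_called_alleles=np.array([[10, 10]]), smoothing=0.5)
        res = assign.sample_loglik(np.array([1, MISSING], dtype=np.int8),
                                   freqs, "A", np.array([0, 1]))
        assert res.n_used == 1 and res.n_skipped == 1

    def test_zero_usable_sites_is_an_error(self):
        freqs = assign.PopFrequencies(
            populations=["A"], sites=None, freq=np.array([[0.5]]),
            n_called_alleles=np.array([[10]]), smoothing=0.5)
        with pytest.raises(ValueError, match="zero usable"):
            assign.sample_loglik(np.array([MISSING], dtype=np.int8), freqs,
                                 "A", np.array([0]))


class TestDownsampling:
    def _setup(self, n_sites=400, seed=13):
        rng = np.random.default_rng(seed)
        freqs = assign.PopFrequencies(
            populations=["A"], sites=None,
            freq=rng.uniform(0.1, 0.9, (1, n_sites)),
            n_called_alleles=np.full((1, n_sites), 50), smoothing=0.5)
        calls = (rng.random(n_sites) < freqs.freq[0]).astype(np.int8)
        return freqs, calls

    def test_exhaustive_draw_has_zero_variance(self):
        freqs, calls = self._setup(100)
        dist = assign.downsample_loglik(calls, freqs, "A", np.arange(100),
                                        n_sites_per_draw=100, n_draws=10,
                                        rng=1)
        assert dist.draws.var() == 0.0

    def test_draw_mean_tracks_full_set_value(self):
        freqs, calls = self._setup(400)
        full = assign.sample_loglik(calls, freqs, "A", np.arange(400))
        dist = assign.downsample_loglik(calls, freqs, "A", np.arange(400),
                                        n_sites_per_draw=200, n_draws=100,
                                        rng=2)
        se = dist.draws.std(ddof=1) / np.sqrt(dist.n_draws)
        assert abs(dist.mean() - full.normalized) < 3 * se + 1e-12

    def test_same_seed_identical_draw_vectors(self):
        freqs, calls = self._setup(300)
        a = assign.downsample_loglik(calls, freqs, "A", np.arange(300),
                                     n_draws=20, rng=7)
        b = assign.downsample_loglik(calls, freqs, "A", np.arange(300),
                                     n_draws=20, rng=7)
        assert np.array_equal(a.draws, b.draws)

    def test_insufficient_sites_refused(self):
        freqs, calls = self._setup(100)
        with pytest.raises(ValueError, match="cannot draw"):
            assign.downsample_loglik(calls, freqs, "A", np.arange(100),
                                     n_sites_per_draw=200)

    def test_draw_variance_decreases_with_draw_size(self):
        freqs, calls = self._setup(1000)
        variances = []
        for n in (50, 200, 500):
            dist = assign.downsample_loglik(calls, freqs, "A",
                                            np.arange(1000),
                                            n_sites_per_draw=n, n_draws=200,
                                            rng=3)
            variances.append(dist.draws.var())
        assert variances[0] > variances[1] > variances[2]


class TestZTest:
    def _dist(self, mean):
        return assign.LnLDistribution(sample_id="t", population="A",
                                      draws=np.full(10, mean),
                                      n_sites_per_draw=200, n_draws=10,
                                      seed=None)

    def test_target_at_reference_mean(self):
        ref = np.array([-0.4, -0.5, -0.6, -0.45, -0.55])
        rep = assign.assignment_z_test(self._dist(ref.mean()), ref)
        assert rep.z == pytest.approx(0.0)
        assert rep.p == pytest.approx(0.5)

    def test_target_at_reference_q10_in_quantile_mode(self):
        ref = np.array([-0.4, -0.5, -0.6, -0.45, -0.55])
        q10 = np.quantile(ref, 0.10)
        rep = assign.assignment_z_test(self._dist(q10), ref,
                                       reference_point="q10")
        assert rep.z == pytest.approx(0.0)
        assert rep.p == pytest.approx(0.5)

    def test_degenerate_reference_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            assign.assignment_z_test(self._dist(-0.5), np.full(5, -0.5))

    def test_deficit_gives_small_one_sided_p(self):
        ref = np.array([-0.40, -0.41, -0.39, -0.42, -0.38])
        rep = assign.assignment_z_test(self._dist(-0.50), ref)
        assert rep.z < -3 and rep.p < 1e-3


class TestWilcoxon:
    def test_exact_extreme_case(self):
        u, p = assign.wilcoxon_rank_sum([1, 2, 3], [4, 5, 6],
                                        alternative="less")
        assert u == 0.0
        assert p == pytest.approx(0.05)  # 1 / C(6,3)

    def test_identical_samples_two_sided_p_one(self):
        x = [1.0, 2.0, 3.0, 4.0]
        _, p = assign.wilcoxon_rank_sum(x, x)
        assert p == pytest.approx(1.0)

    def test_normal_approximation_close_to_exact_at_n8(self):
        rng = np.random.default_rng(5)
        x = rng.normal(0, 1, 8)
        y = rng.normal(0.5, 1, 8)
        from scipy.stats import mannwhitneyu
        p_exact = mannwhitneyu(x, y, method="exact").pvalue
        p_asym = mannwhitneyu(x, y, method="asymptotic").pvalue
        _, p_pkg = assign.wilcoxon_rank_sum(x, y)
        assert p_pkg == pytest.approx(p_exact)
        assert abs(p_asym - p_exact) < 0.01

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            assign.wilcoxon_rank_sum([], [1.0])


class TestSelfAssignment:
    def test_members_assign_to_own_population_at_high_fst(self):
        """LOO-scored members pick their own population at F_ST 0.05."""
        correct = 0
        reps = 20
        for seed in range(reps):
            cfg = SimConfig(n_per_pop=25, n_sites=5000, fst_river=1e-4,
                            fst_season=0.05, seed=seed)
            panel, labels = simdata.simulate_nuclear_panel(cfg)
            james = panel.select_samples(
                list(labels.loc[labels.population.isin(["JRS", "JRF"]),
                                "sample_id"]))
            rng = np.random.default_rng([seed, 60])
            sid = james.samples[seed % 25]  # a JRS member
            row = simdata.pseudohaploidize(
                james.dosages[james.sample_index(sid)], rng)
            target = PseudohaploidCalls(
                samples=np.array(["t"], dtype=object), sites=james.sites,
                calls=row[None, :])
            sites = assign.sample_optimized_variant_set(target, "t", james)
            own = assign.downsample_loglik(
                row, assign.pop_allele_frequencies(
                    james, labels, populations=["JRS"], leave_out=sid),
                "JRS", sites, n_draws=25, rng=rng).mean()
            other = assign.downsample_loglik(
                row, assign.pop_allele_frequencies(
                    james, labels, populations=["JRF"]),
                "JRF", sites, n_draws=25, rng=rng).mean()
            correct += own > other
        assert correct >= int(0.9 * reps)

    def test_degraded_ancestral_target_shows_mean_deficit(self):
        """At the study's missingness the Z direction is negative on average."""
        zs = []
        for seed in range(12):
            cfg = SimConfig(n_per_pop=25, n_sites=45603, seed=seed)
            panel, labels = simdata.simulate_nuclear_panel(cfg)
            james = panel.select_samples(
                list(labels.loc[labels.population.isin(["JRS", "JRF"]),
                                "sample_id"]))
            anc = simdata.degrade_to_ancient(panel, labels, cfg)
            anc = PseudohaploidCalls(samples=anc.samples, sites=james.sites,
                                     calls=anc.calls)
            reports = assign.assign_target(anc, "ANC001", james, labels,
                                           n_draws=50, rng=[seed, 61])
            zs.extend(r.z for r in reports)
        assert np.mean(zs) < 0.0
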