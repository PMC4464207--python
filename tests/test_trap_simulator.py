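"""Event-driven and mean-field simulators against their exact oracles."""

import numpy as np
import pytest
from scipy import stats

import lipotrap as lt
from lipotrap.errors import DomainError, ValidationError


def make_config(r0, lam_in, lam_out=0.0, n=1, max_events=1_000_000, seed=0):
    return lt.SimConfig(
        r0=r0,
        flux=lt.FluxParams(lam_in=lam_in, lam_out=lam_out),
        n_liposomes=n,
        max_events=max_events,
        seed=seed,
    )


class TestFluxParams:
    def test_net_flux(self):
        assert lt.FluxParams(2.0, 0.5).net == 1.5

    def test_semi_permeability_enforced(self):
        with pytest.raises(ValidationError):
            lt.FluxParams(1.0, 2.0)
        with pytest.raises(ValidationError):
            lt.FluxParams(1.0, -0.5)


class TestSingleTrajectory:
    def test_no_flux_no_trapping(self):
        tr = lt.simulate_liposome_exact(make_config(2.0, 0.0), np.random.default_rng(0))
        assert tr.n_final == 0
        assert tr.event_kinds == ("closure",)
        assert not tr.censored

    def test_no_flux_closure_times_exponential(self):
        cfg = make_config(2.0, 0.0, n=3000, seed=1)
        ens = lt.simulate_ensemble_exact(cfg)
        assert np.all(ens.counts == 0)
        ks = stats.kstest(ens.taus, "expon", args=(0, 1 / 2.0)).statistic
        assert ks < 1.36 / np.sqrt(3000)

    def test_event_bookkeeping_with_outflux(self):
        cfg = make_config(1.0, 3.0, lam_out=2.0, seed=5)
        for i in range(20):
            tr = lt.simulate_liposome_exact(cfg, np.random.default_rng((5, i)))
            assert np.all(np.diff(tr.event_times) > 0)
            kinds = tr.event_kinds
            assert kinds.count("closure") <= 1
            if not tr.censored:
                assert kinds[-1] == "closure"
                assert tr.tau == tr.event_times[-1]
            assert tr.n_final == kinds.count("influx") - kinds.count("outflux")
            # running count never negative; frozen after closure
            counts = tr.count_at(np.linspace(0, tr.event_times[-1] * 1.5, 64))
            assert np.all(counts >= 0)
            assert counts[-1] == tr.n_final

    def test_censoring_flagged_not_raised(self):
        tr = lt.simulate_liposome_exact(
            make_config(1e-9, 10.0, max_events=5), np.random.default_rng(2)
        )
        assert tr.censored and tr.tau is None


class TestEnsembleExact:
    def test_deterministic_given_seed(self):
        cfg = make_config(1.0, 1.0, n=500, seed=42)
        a = lt.simulate_ensemble_exact(cfg)
        b = lt.simulate_ensemble_exact(cfg)
        np.testing.assert_array_equal(a.taus, b.taus)
        np.testing.assert_array_equal(a.counts, b.counts)

    def test_half_of_trajectories_trap_nothing(self):
        """At r0 = lam_in = 1 the embedded chain closes from N=0 with odds 1:1."""
        cfg = make_config(1.0, 1.0, n=20_000, seed=7)
        ens = lt.simulate_ensemble_exact(cfg)
        p0 = np.mean(ens.counts == 0)
        se = np.sqrt(0.25 / 20_000)
        assert abs(p0 - 0.5) < 4 * se

    @pytest.mark.parametrize("r0", [1.0, 2.0])
    def test_matches_embedded_chain_pmf(self, r0):
        """Observed N_inf frequencies track the exact birth-chain pmf."""
        n = 100_000
        cfg = make_config(r0, 1.0, n=n, seed=11)
        ens = lt.simulate_ensemble_exact(cfg)
        for k in range(4):
            p = lt.exact_trapped_pmf_birth(k, r0, 1.0)
            se = np.sqrt(p * (1 - p) / n)
            assert abs(np.mean(ens.counts == k) - p) < 4 * se

    @pytest.mark.parametrize("ratio, seed", [(0.5, 4), (2.5, 5)])
    def test_tail_exponent_follows_rate_ratio(self, ratio, seed):
        """Tail MLE of the full stochastic chain lands near mu = 1 + r0/lam."""
        cfg = make_config(ratio, 1.0, n=100_000, max_events=100_000, seed=seed)
        ens = lt.simulate_ensemble_exact(cfg)
        fit = lt.fit_powerlaw_mle(lt.CountSample(ens.counts), n_min=10)
        assert abs(fit.estimate - (1.0 + ratio)) <= 0.15

    def test_zero_net_flux_mean_closure_time(self):
        """lam_in = lam_out leaves no drift; mean tau matches a frozen reference."""
        cfg = make_config(1.0, 5.0, lam_out=5.0, n=5000, seed=8)
        ens = lt.simulate_ensemble_exact(cfg)
        # reference mean from an independent long-run of the same Markov model
        ref = make_config(1.0, 5.0, lam_out=5.0, n=5000, seed=1008)
        ref_mean = lt.simulate_ensemble_exact(ref).taus.mean()
        pooled_se = ens.taus.std(ddof=1) / np.sqrt(5000)
        assert abs(ens.taus.mean() - ref_mean) < 6 * pooled_se

    def test_censored_trajectories_counted(self):
        cfg = make_config(1e-9, 10.0, n=50, max_events=10, seed=3)
        ens = lt.simulate_ensemble_exact(cfg)
        assert ens.n_censored == 50
        assert len(ens.taus) == 0


class TestExactPmfBirth:
    @pytest.mark.parametrize(
        "n, expected", [(0, 0.5), (1, 1 / 6), (2, 1 / 12)]
    )
    def test_unit_rates_values(self, n, expected):
        assert lt.exact_trapped_pmf_birth(n, 1.0, 1.0) == pytest.approx(expected)

    @pytest.mark.parametrize("r0, lam", [(1.0, 1.0), (1.3, 1.0), (2.0, 0.5)])
    def test_sums_to_one_with_tail_bound(self, r0, lam):
        k = np.arange(0, 2_000_000)
        total = lt.exact_trapped_pmf_birth(k, r0, lam).sum()
        # remaining tail is bounded by the survival of the truncation point
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_no_influx_point_mass(self):
        assert lt.exact_trapped_pmf_birth(0, 1.0, 0.0) == 1.0
        assert lt.exact_trapped_pmf_birth(3, 1.0, 0.0) == 0.0

    def test_negative_count_rejected(self):
        with pytest.raises(DomainError):
            lt.exact_trapped_pmf_birth(-1, 1.0, 1.0)


class TestMeanField:
    def test_inversion_boundary(self, jam_params):
        assert lt.sample_closure_time_meanfield(jam_params, 1.0) == 0.0

    def test_inversion_closed_form(self):
        tau = lt.sample_closure_time_meanfield(lt.RateParams(2.0, 1.0), 0.25)
        assert tau == pytest.approx(1.0)

    def test_inversion_exponential_limit(self):
        tau = lt.sample_closure_time_meanfield(lt.RateParams(1.0, 0.0), np.exp(-1.0))
        assert tau == pytest.approx(1.0)

    def test_u_outside_unit_interval_rejected(self, jam_params):
        for bad in (0.0, -0.5, 1.5):
            with pytest.raises(DomainError):
                lt.sample_closure_time_meanfield(jam_params, bad)

    def test_closure_times_follow_survival_law(self, jam_params):
        """KS distance of sampled taus to the analytic SPF below the 5% value."""
        n = 10_000
        ens = lt.simulate_ensemble_meanfield(jam_params, n, seed=9)
        cdf = lambda t: 1.0 - lt.survival_powerlaw(t, jam_params)
        ks = stats.ks_1samp(ens.taus, cdf).statistic
        assert ks < 1.36 / np.sqrt(n)

    def test_no_influx_counts_zero_times_exponential(self):
        ens = lt.simulate_ensemble_meanfield(lt.RateParams(1.0, 0.0), 2000, seed=10)
        assert np.all(ens.counts == 0)
        ks = stats.kstest(ens.taus, "expon").statistic
        assert ks < 1.36 / np.sqrt(2000)

    def test_count_modes(self, jam_params):
        cont = lt.simulate_ensemble_meanfield(jam_params, 5000, seed=3, count_mode="continuous")
        floor = lt.simulate_ensemble_meanfield(jam_params, 5000, seed=3, count_mode="floor")
        pois = lt.simulate_ensemble_meanfield(jam_params, 5000, seed=3, count_mode="poisson")
        np.testing.assert_allclose(cont.counts, jam_params.lam * cont.taus)
        np.testing.assert_array_equal(floor.counts, np.floor(cont.counts))
        assert np.all(pois.counts == np.floor(pois.counts))
        with pytest.raises(ValidationError):
            lt.simulate_ensemble_meanfield(jam_params, 10, seed=3, count_mode="bogus")

    def test_continuous_counts_have_exact_exponent_law(self, jam_params):
        """N = lam*tau draws follow the shifted-Pareto law with mu = 1 + r0/lam."""
        ens = lt.simulate_ensemble_meanfield(jam_params, 10_000, seed=12)
        dist = lt.exponent_from_rates(jam_params)
        ks = lt.ks_statistic(lt.CountSample(ens.counts, continuous=True), dist)
        assert ks < 1.36 / np.sqrt(10_000)


class TestOccupancyStats:
    def test_counting_process_mean_and_variance(self):
        """With closure switched off the inside count is a Poisson process."""
        cfg = make_config(1e-9, 2.0, n=400, max_events=400, seed=13)
        trs = lt.simulate_trajectories(cfg)
        grid = np.array([0.0, 5.0, 20.0])
        df = lt.ensemble_occupancy_stats(trs, grid)
        assert df["mean_n"].iloc[0] == 0.0 and df["var_n"].iloc[0] == 0.0
        for row in (1, 2):
            t = grid[row]
            mean = df["mean_n"].iloc[row]
            se = np.sqrt(2.0 * t / 400)
            assert abs(mean - 2.0 * t) < 4 * se
            assert df["var_n"].iloc[row] == pytest.approx(mean, rel=0.3)

    def test_empirical_hazard_tracks_averaged_rate(self, jam_params):
        """Diagnostic: hazard among survivors vs r0/(1+lam t), reported not asserted
        to high precision (the averaged rate ignores survivorship bias)."""
        cfg = make_config(1.3, 1.0, n=20_000, seed=14)
        trs = lt.simulate_trajectories(cfg)
        grid = np.linspace(0.0, 2.0, 9)
        df = lt.ensemble_occupancy_stats(trs, grid)
        expected = lt.hazard_inverse_linear(grid[:-1], jam_params)
        observed = df["hazard"].to_numpy()[:-1]
        assert np.all(np.isfinite(observed))
        # same order of magnitude and decreasing trend
        assert observed[0] > observed[-1]
        assert np.all(np.abs(observed / expected - 1.0) < 0.5)

    def test_times_beyond_all_closures_are_nan(self):
        cfg = make_config(5.0, 0.0, n=10, seed=15)
        trs = lt.simulate_trajectories(cfg)
        far = max(tr.tau for tr in trs) + 10.0
        df = lt.ensemble_occupancy_stats(trs, np.array([0.0, far]))
        assert np.isnan(df["mean_n"].iloc[1])


class TestEnsembleIO:
    def test_csv_round_trip(self, tmp_path, jam_params):
        ens = lt.simulate_ensemble_meanfield(jam_params, 50, seed=21)
        path = tmp_path / "ens.csv"
        lt.write_ensemble_csv(ens, path)
        assert path.read_text().splitlines()[0] == "tau,n_trapped"
        back = lt.read_ensemble_csv(path)
        np.testing.assert_allclose(back.taus, ens.taus)
        np.testing.assert_allclose(back.counts, ens.counts)
        assert back.seed == 21 and back.n_censored == 0
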