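"""Chain construction, stationary laws, sampling and cohort generation."""

import numpy as np
import pytest

from scanpath_ais.simulate import (
    CohortConfig,
    MarkovChainSpec,
    build_chain,
    simulate_cohort,
    simulate_scanpath,
    stationary_distribution,
)


class TestBuildChain:
    def test_zero_coupling_is_iid(self):
        base = np.array([0.5, 0.3, 0.2])
        chain = build_chain(3, (1,), 0.0, base)
        assert np.allclose(chain.cond, np.tile(base, (3, 1)))
        assert chain.active_lags == ()

    def test_full_coupling_single_lag_is_cycle(self):
        chain = build_chain(8, (1,), 1.0)
        # row for x_{t-1} = s is a point mass on s % 8 + 1
        for s in range(1, 9):
            row = chain.cond[chain.tuple_code((s,))]
            assert row[s % 8] == 1.0

    def test_conditional_depends_only_on_active_lags(self):
        chain = build_chain(4, (2,), 0.5)
        cond = chain.cond.reshape(4, 4, 4)  # [x_{t-2}-1, x_{t-1}-1, next]
        assert np.abs(cond - cond[:, :1, :]).max() == 0.0
        assert np.abs(cond - cond[:1, :, :]).max() > 0.1

    def test_repeat_map_preserves_marginal(self):
        base = np.array([0.05, 0.05, 0.1, 0.1, 0.35, 0.05, 0.05, 0.25])
        for lags in [(1,), (2,), (2, 4)]:
            chain = build_chain(8, lags, 0.7, base, map_kind="repeat")
            pi = stationary_distribution(chain, k=chain.order)
            # marginal of the most recent symbol
            marg = pi.reshape(-1, 8).sum(axis=0) if chain.order > 1 else pi
            marg = np.bincount(
                np.arange(8**chain.order) % 8, weights=pi, minlength=8
            )
            assert np.abs(marg - base).max() < 1e-10

    @pytest.mark.parametrize("bad_rho", [-0.1, 1.1])
    def test_invalid_rho(self, bad_rho):
        with pytest.raises(ValueError):
            build_chain(4, (1,), bad_rho)

    def test_rows_normalize(self, rng):
        chain = build_chain(5, (1, 3), 0.4, rng.dirichlet(np.ones(5)))
        assert np.allclose(chain.cond.sum(axis=1), 1.0, atol=1e-12)


class TestStationaryDistribution:
    def test_iid_spec_gives_base_product(self):
        base = np.array([0.6, 0.4])
        chain = build_chain(2, (), 0.0, base)
        pi = stationary_distribution(chain)
        assert np.allclose(pi, base)

    def test_deterministic_cycle_is_uniform(self):
        chain = build_chain(8, (1,), 1.0)
        pi = stationary_distribution(chain)
        assert np.allclose(pi, 1 / 8)

    def test_fixed_point_of_random_ergodic_chain(self, rng):
        chain = build_chain(4, (1, 2), 0.5, rng.dirichlet(np.ones(4)))
        pi = stationary_distribution(chain)
        from scanpath_ais.simulate import _lifted_transition

        P = _lifted_transition(chain, chain.order)
        assert np.abs(pi @ P - pi).max() < 1e-10
        assert (pi >= 0).all()
        assert pi.sum() == pytest.approx(1.0, abs=1e-12)


class TestSimulateScanpath:
    def test_cycle_spec_produces_exact_orbit(self):
        chain = build_chain(8, (1,), 1.0)
        path = simulate_scanpath(chain, 24, seed=1)
        diffs = (np.diff(path.symbols) - 1) % 8
        assert (diffs == 0).all()

    def test_same_seed_same_sequence(self):
        chain = build_chain(8, (1, 3), 0.6)
        a = simulate_scanpath(chain, 500, seed=42)
        b = simulate_scanpath(chain, 500, seed=42)
        assert (a.symbols == b.symbols).all()

    def test_lag_one_transition_frequencies_converge(self):
        chain = build_chain(3, (1,), 0.6, np.array([0.5, 0.3, 0.2]))
        path = simulate_scanpath(chain, 100_000, seed=2)
        x = path.symbols
        for s in range(1, 4):
            nxt = x[1:][x[:-1] == s]
            freq = np.bincount(nxt - 1, minlength=3) / nxt.size
            assert np.abs(freq - chain.cond[s - 1]).max() < 0.01

    def test_marginal_matches_analytic_stationary(self):
        chain = build_chain(4, (2,), 0.7, np.array([0.4, 0.3, 0.2, 0.1]), map_kind="repeat")
        path = simulate_scanpath(chain, 100_000, seed=3)
        emp = np.bincount(path.symbols - 1, minlength=4) / path.n
        pi = stationary_distribution(chain)
        marg = np.bincount(np.arange(16) % 4, weights=pi, minlength=4)
        assert 0.5 * np.abs(emp - marg).sum() <= 0.01  # total variation

    def test_uniform_init_with_burn_in(self):
        chain = build_chain(4, (1,), 0.5)
        path = simulate_scanpath(chain, 100, seed=4, init="uniform")
        assert path.n == 100


class TestSimulateCohort:
    def test_default_cohort_structure(self):
        cohort = simulate_cohort(seed=0)
        manifest = cohort.manifest["participants"]
        assert len(manifest) == 11
        lag_sets = [tuple(v["true_lags"]) for v in manifest.values()]
        assert sum(1 for s in lag_sets if s and max(s) > 1) == 4
        assert sum(1 for s in lag_sets if s == (1,)) == 6
        assert sum(1 for s in lag_sets if s == ()) == 1
        ev = cohort.events
        for pid, grp in ev.groupby("participant"):
            assert len(grp) == 12
            assert (grp["onset"] < grp["lane_change"]).all()
            assert (grp["lane_change"] < grp["end"]).all()
            assert sorted(grp["difficulty"].value_counts()) == [6, 6]
            assert (grp["onset"].to_numpy()[1:] >= grp["end"].to_numpy()[:-1]).all()

    def test_all_order_one_config(self):
        cfg = CohortConfig(n_participants=3, lag_sets=((1,), (1,), (1,)))
        cohort = simulate_cohort(cfg, seed=1)
        assert all(
            v["true_lags"] == [1] for v in cohort.manifest["participants"].values()
        )

    def test_fixation_counts_center_on_study_mean(self):
        cfg = CohortConfig(
            n_participants=24,
            lag_sets=tuple([(1,)] * 24),
        )
        cohort = simulate_cohort(cfg, seed=2)
        counts = cohort.fixations.groupby("participant").size()
        se = 74.0 / np.sqrt(len(counts))
        assert abs(counts.mean() - 866.0) < 3 * se + 5

    def test_baseline_fixations_concentrate_on_two_aois(self):
        cohort = simulate_cohort(seed=3)
        fx, ev = cohort.participant_tables("P01")
        # fixations outside trials are baseline-style driving
        in_trial = np.zeros(len(fx), dtype=bool)
        for _, tr in ev.iterrows():
            in_trial |= (fx["onset"] >= tr["onset"]) & (fx["onset"] <= tr["end"])
        share = fx.loc[~in_trial, "aoi"].isin([5, 8]).mean()
        assert share > 0.5

    def test_writes_csv_round_trip(self, tmp_path):
        cfg = CohortConfig(n_participants=2, lag_sets=((1,), ()))
        cohort = simulate_cohort(cfg, seed=4)
        cohort.write(tmp_path)
        assert (tmp_path / "fixations.csv").exists()
        assert (tmp_path / "events.csv").exists()
        assert (tmp_path / "manifest.json").exists()
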