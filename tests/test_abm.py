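"""Spatial ABM: diffusion, Hill response, step mechanics, replicated runs."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from probisim import abm


def quiet_params(**kw):
    """Params with growth, secretion and starvation switched off."""
    defaults = dict(
        growth_r={"A": 0.0, "B": 0.0, "C": 0.0, "P": 0.0},
        secretion_m1=0.0, secretion_m2=0.0,
        decay_m1=0.0, decay_m2=0.0,
        starvation=False, cross_feed_gain=0.0,
    )
    defaults.update(kw)
    return abm.ABMParams(**defaults)


class TestDiffuse:
    def test_uniform_field_unchanged(self):
        f = np.full((20, 20), 3.7)
        out = abm.diffuse(f, 1e-6, 172.8, 0.01)
        np.testing.assert_allclose(out, f, rtol=1e-12)

    def test_mass_conserved_on_random_field(self, rng):
        f = rng.random((40, 40)) * 100
        out = abm.diffuse(f, 1e-6, 172.8, 0.01)
        assert out.sum() == pytest.approx(f.sum(), rel=1e-9)

    def test_impulse_matches_brute_force_stencil(self):
        D, dt, h = 1e-6, 172.8, 0.01
        n_sub = int(np.ceil(D * dt / h**2 / abm.STABILITY_LIMIT))
        f = np.zeros((21, 21))
        f[10, 10] = 1.0
        got = abm.diffuse(f, D, dt, h)

        # independent per-cell reference with explicit neighbor clamping
        a = (D * dt / h**2) / n_sub
        ref = f.copy()
        for _ in range(n_sub):
            new = np.empty_like(ref)
            for i in range(21):
                for j in range(21):
                    up = ref[max(i - 1, 0), j]
                    dn = ref[min(i + 1, 20), j]
                    lf = ref[i, max(j - 1, 0)]
                    rt = ref[i, min(j + 1, 20)]
                    new[i, j] = ref[i, j] + a * (up + dn + lf + rt - 4 * ref[i, j])
            ref = new
        np.testing.assert_allclose(got, ref, atol=1e-15)

    def test_substep_count_at_defaults(self):
        coeff = 1e-6 * 172.8 / 0.01**2
        assert int(np.ceil(coeff / abm.STABILITY_LIMIT)) == 7

    def test_non_finite_field_rejected(self):
        f = np.zeros((12, 12))
        f[0, 0] = np.nan
        with pytest.raises(abm.ABMError, match="non-finite"):
            abm.diffuse(f, 1e-6, 172.8, 0.01)


class TestHillResponse:
    def test_zero_concentration_gives_zero(self):
        assert abm.hill_response(0.0, 10.0, 2.0) == 0.0

    def test_half_saturation_identity(self):
        assert abm.hill_response(10.0, 10.0, 2.0) == pytest.approx(0.5)

    @given(st.floats(0.01, 1e4), st.floats(0.01, 1e4))
    def test_strictly_increasing_with_supremum_one(self, c1, c2):
        lo, hi = sorted((c1, c2))
        f_lo = abm.hill_response(lo, 10.0, 2.0)
        f_hi = abm.hill_response(hi, 10.0, 2.0)
        assert 0.0 <= f_lo <= f_hi < 1.0
        if hi > lo:
            assert f_hi > f_lo

    def test_negative_concentration_rejected(self):
        with pytest.raises(abm.ABMError, match="negative"):
            abm.hill_response(-1.0, 10.0, 2.0)


class TestInitWorld:
    def test_empty_world(self):
        cfg = abm.GridConfig(width=15, height=15,
                             seed_layout={"A": 0, "B": 0, "C": 0, "P": 0})
        w = abm.init_world(cfg, abm.ABMParams(), seed=0)
        assert all(w.population(t) == 0 for t in abm.AGENT_TYPES)
        assert w.m1.sum() == 0 and w.m2.sum() == 0

    def test_same_seed_gives_identical_worlds(self):
        cfg = abm.GridConfig(width=20, height=20)
        a = abm.init_world(cfg, abm.ABMParams(), seed=11)
        b = abm.init_world(cfg, abm.ABMParams(), seed=11)
        for t in abm.AGENT_TYPES:
            np.testing.assert_array_equal(a.agents[t]["pos"], b.agents[t]["pos"])

    def test_layout_capacity_enforced(self):
        cfg = abm.GridConfig(width=10, height=10, seed_layout={"A": 5000})
        with pytest.raises(abm.ABMError, match="capacity"):
            abm.init_world(cfg, abm.ABMParams(), seed=0)

    def test_uniform_placement_chi_square(self):
        # aggregate placements over 100 seeds on a 20x20 grid
        cfg = abm.GridConfig(width=20, height=20,
                             seed_layout={"A": 200, "B": 0, "C": 0, "P": 0})
        totals = np.zeros(400)
        for s in range(100):
            w = abm.init_world(cfg, abm.ABMParams(), seed=s)
            totals += np.bincount(w.agents["A"]["pos"], minlength=400)
        _, p = stats.chisquare(totals)
        assert p > 0.001


class TestStep:
    def test_no_deaths_below_threshold(self, small_grid):
        par = quiet_params()
        w = abm.init_world(small_grid, par, seed=1)
        n0 = w.population("P")
        abm.step(w, par)
        assert w.population("P") == n0

    def test_geometric_kill_law_within_binomial_bounds(self):
        cfg = abm.GridConfig(width=40, height=40,
                             seed_layout={"A": 0, "B": 0, "C": 0, "P": 1000})
        par = quiet_params()
        w = abm.init_world(cfg, par, seed=5)
        w.m1[:] = par.theta_m1 * 2  # uniformly above threshold, no decay
        for _ in range(10):
            abm.step(w, par)
        p_surv = 0.8**10
        lo, hi = stats.binom.ppf([0.005, 0.995], 1000, p_surv)
        assert lo <= w.population("P") <= hi

    def test_biofilm_flag_transitions_exactly_at_threshold(self):
        cfg = abm.GridConfig(width=12, height=12,
                             seed_layout={"A": 0, "B": 0, "C": 0, "P": 0})
        par = quiet_params()
        for occupancy, expect in ((19, False), (20, True)):
            w = abm.init_world(cfg, par, seed=0)
            w.agents["A"]["pos"] = np.full(occupancy, 7, dtype=np.int64)
            w.agents["A"]["energy"] = np.full(occupancy, par.energy_init)
            abm.step(w, par)
            assert bool(w.biofilm.reshape(-1)[7]) is expect

    def test_metabolite_mass_balance_per_step(self, small_grid):
        par = abm.ABMParams()
        w = abm.init_world(small_grid, par, seed=3)
        for _ in range(5):
            before = w.m1.sum()
            abm.step(w, par)
            # secretion follows the growth stage, so the secreting count is
            # the post-step Type A population (no A deaths occur here)
            n_a = w.population("A")
            expected = (before + n_a * par.secretion_m1) * (1 - par.decay_m1)
            assert w.m1.sum() == pytest.approx(expected, rel=1e-9)

    def test_ratio_threshold_mode_runs(self, small_grid):
        par = quiet_params(threshold_mode="ratio", theta_m1=0.5)
        w = abm.init_world(small_grid, par, seed=2)
        w.m1[:] = 10.0
        w.m2[:] = 1.0  # ratio 10 > 0.5 -> pathogens exposed
        n0 = w.population("P")
        abm.step(w, par)
        assert w.population("P") < n0

    def test_starvation_kills_after_energy_runs_out_except_biofilm(self):
        cfg = abm.GridConfig(width=12, height=12,
                             seed_layout={"A": 0, "B": 0, "C": 0, "P": 0})
        par = quiet_params(starvation=True, energy_init=3.0)
        w = abm.init_world(cfg, par, seed=0)
        w.nutrient[:] = 0.0
        w.agents["B"]["pos"] = np.array([5, 30], dtype=np.int64)
        w.agents["B"]["energy"] = np.full(2, par.energy_init)
        w.biofilm.reshape(-1)[30] = True  # second agent sits on biofilm
        for _ in range(4):
            abm.step(w, par)
        assert list(w.agents["B"]["pos"]) == [30]


class TestRun:
    def test_identical_seed_identical_result(self, small_grid):
        par = abm.ABMParams()
        a = abm.run_one(small_grid, par, seed=9, n_iterations=30)
        b = abm.run_one(small_grid, par, seed=9, n_iterations=30)
        np.testing.assert_array_equal(a.populations, b.populations)
        np.testing.assert_array_equal(
            abm.dominance_heatmap(a), abm.dominance_heatmap(b)
        )

    def test_no_pathogens_seeded_excluded_at_step_zero(self):
        cfg = abm.GridConfig(width=15, height=15,
                             seed_layout={"A": 20, "B": 20, "C": 10, "P": 0})
        summ = abm.run(cfg, abm.ABMParams(), n_replicates=3,
                       n_iterations=5, seed_base=0)
        assert summ.exclusion_probability == 1.0
        assert summ.exclusion_steps() == [0, 0, 0]

    def test_no_antagonism_means_no_exclusion(self, small_grid):
        par = abm.ABMParams(p_kill=0.0)
        summ = abm.run(small_grid, par, n_replicates=3,
                       n_iterations=60, seed_base=1)
        assert summ.exclusion_probability == 0.0

    def test_timestep_bookkeeping_defaults_give_24h(self):
        assert abm.ABMParams().simulated_hours == pytest.approx(24.0)


class TestSpatialSummaries:
    def test_single_type_world_dominates_every_occupied_patch(self):
        cfg = abm.GridConfig(width=15, height=15,
                             seed_layout={"A": 0, "B": 60, "C": 0, "P": 0})
        r = abm.run_one(cfg, quiet_params(), seed=4, n_iterations=1)
        hm = abm.dominance_heatmap(r)
        occupied = r.final_counts["B"] > 0
        assert set(np.unique(hm[occupied])) == {abm.HEATMAP_CODES["B"]}
        assert set(np.unique(hm[~occupied])) == {abm.HEATMAP_CODES["none"]}

    def test_heatmap_partitions_the_grid(self, small_grid):
        r = abm.run_one(small_grid, abm.ABMParams(), seed=2, n_iterations=10)
        hm = abm.dominance_heatmap(r)
        assert hm.size == small_grid.n_patches
        assert set(np.unique(hm)) <= set(abm.HEATMAP_CODES.values())

    def test_halo_extreme_boundary_placement(self):
        cfg = abm.GridConfig(width=20, height=20,
                             seed_layout={"A": 0, "B": 0, "C": 0, "P": 0})
        r = abm.run_one(cfg, quiet_params(), seed=0, n_iterations=1)
        counts_a = np.zeros((20, 20), dtype=int)
        counts_a[0, :] = 5          # all A on the top edge
        counts_b = np.zeros((20, 20), dtype=int)
        counts_b[8:12, 8:12] = 5    # B in the interior
        r.final_counts = {"A": counts_a, "B": counts_b,
                          "C": np.zeros((20, 20), int), "P": np.zeros((20, 20), int)}
        assert abm.halo_metric(r, 0.2) > 10

    def test_halo_null_near_one_for_uniform_mixing(self):
        cfg = abm.GridConfig(width=40, height=40,
                             seed_layout={"A": 300, "B": 500, "C": 400, "P": 200})
        ratios = []
        for s in range(20):
            w = abm.init_world(cfg, abm.ABMParams(), seed=s)
            r = abm.ABMResult(
                populations=np.zeros((1, 4), dtype=np.int64),
                exclusion_step=None,
                final_counts={t: w.counts(t) for t in abm.AGENT_TYPES},
                biofilm=w.biofilm, seed=s, n_iterations=0, timestep_s=172.8,
            )
            ratios.append(abm.halo_metric(r, 0.2))
        assert np.median(ratios) == pytest.approx(1.0, abs=0.15)

    def test_halo_undefined_for_empty_region(self):
        cfg = abm.GridConfig(width=15, height=15,
                             seed_layout={"A": 0, "B": 0, "C": 0, "P": 0})
        r = abm.run_one(cfg, quiet_params(), seed=0, n_iterations=1)
        assert abm.halo_metric(r) is None


class TestSensitivityScan:
    def test_single_cell_grid_equals_plain_run(self, small_grid):
        par = abm.ABMParams()
        table = abm.sensitivity_scan(small_grid, par, {"p_kill": [0.2]},
                                     n_replicates=2, n_iterations=40, seed_base=0)
        direct = abm.run(small_grid, par, n_replicates=2,
                         n_iterations=40, seed_base=0)
        assert len(table) == 1
        assert table["exclusion_probability"].iloc[0] == direct.exclusion_probability

    def test_exclusion_non_decreasing_in_kill_probability(self, small_grid):
        # low thresholds so the kill condition is binding early
        par = abm.ABMParams(theta_m1=5.0, theta_m2=5.0)
        table = abm.sensitivity_scan(
            small_grid, par, {"p_kill": [0.0, 0.1, 0.4]},
            n_replicates=4, n_iterations=120, seed_base=3,
        )
        probs = table.sort_values("p_kill")["exclusion_probability"].to_numpy()
        assert np.all(np.diff(probs) >= 0)

    def test_diffusion_swept_over_admissible_range(self, small_grid):
        table = abm.sensitivity_scan(
            small_grid, abm.ABMParams(), {"diffusion": [1e-7, 1e-6, 1e-5]},
            n_replicates=1, n_iterations=10, seed_base=0,
        )
        assert len(table) == 3
        assert table["exclusion_probability"].between(0, 1).all()
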