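"""Derived quantities: densities, validation error, profiles, statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from scaffoldsim import run_replicates, run_simulation
from scaffoldsim.analysis import (
    compare_groups,
    density_series,
    dispersion_ratio,
    edge_core_contrast,
    manhattan_distance_grid,
    mape,
    radial_profile,
    replay_counts,
    shell_spread,
    stiffness_summary,
)

from conftest import make_config


class TestDensitySeries:
    def test_density_starts_at_one(self, tiny_config):
        res = run_simulation(tiny_config)
        ds = density_series(res)
        assert ds["density"].iloc[0] == 1.0

    def test_extinct_population_reaches_and_stays_at_zero(self):
        # certain death and degradation wipe the population out
        cfg = make_config(
            total_hours=6.0,
            rule_lines=["die: P -> D, 1.0", "clear: D -> empty, 1.0"],
        )
        res = run_simulation(cfg)
        ds = density_series(res)
        assert ds["density"].iloc[1] == 0.0
        assert (ds["density"].iloc[1:] == 0.0).all()

    def test_matches_event_log_replay_exactly(self, tiny_config):
        """Independent replay of the event log reproduces every recorded
        per-type count (brute-force bookkeeping oracle)."""
        res = run_simulation(tiny_config)
        replayed = replay_counts(res)
        recorded = res.timeseries[["iteration", "n_P", "n_Q", "n_D"]].astype(int)
        pd.testing.assert_frame_equal(replayed, recorded.reset_index(drop=True))


class TestMape:
    def test_identity_and_formula(self):
        assert np.allclose(mape([1.0, 2.0], [1.0, 2.0]), 0.0)
        assert mape([1.25], [1.0])[0] == pytest.approx(0.25)

    def test_absolute_error_is_symmetric(self):
        assert mape([0.5], [1.0])[0] == mape([1.5], [1.0])[0] == pytest.approx(0.5)

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            mape([1.0], [0.0])
        with pytest.raises(ValueError):
            mape([1.0, 2.0], [1.0])  # mismatched points


class TestRadialProfile:
    @pytest.fixture(scope="class")
    def results(self):
        cfg = make_config(total_hours=12.0, snapshot_hours=(0.0, 12.0))
        return run_replicates(cfg, 3, base_seed=2)

    def test_initial_fields_are_flat_at_one(self, results):
        for qty in ("glucose", "oxygen", "young_modulus"):
            prof = radial_profile(results, qty, hours=[0.0])
            assert np.allclose(prof["value"], 1.0, atol=1e-12)

    def test_bins_partition_the_lattice(self, results):
        prof = radial_profile(results, "young_modulus", hours=[0.0])
        assert prof["n_voxels"].sum() == 5**3

    def test_constructed_field_reproduces_bin_centers(self):
        """A field equal to the Manhattan distance has bin means within half
        a bin width of the bin label (constructed-field oracle)."""
        cfg = make_config(total_hours=1.0, snapshot_hours=(0.0, 1.0))
        res = run_simulation(cfg)
        dist = manhattan_distance_grid(cfg.n_layers, cfg.voxel_size)
        for h in res.snapshots:
            res.snapshots[h]["young_modulus"] = dist
        prof = radial_profile([res], "young_modulus", hours=[1.0], normalize=False)
        for _, row in prof.iterrows():
            assert abs(row["value"] - (row["distance_bin"] + 0.5)) <= 0.5

    def test_unknown_quantity_rejected(self, results):
        with pytest.raises(ValueError):
            radial_profile(results, "ph")


class TestStiffnessSummary:
    def synthetic_results(self, means, spatial_sd, seed=0):
        """Stand-in results with prescribed per-replicate mean and spatial
        spread of the final stiffness field (synthetic variance model)."""
        from scaffoldsim.engine import SimulationResult
        from scaffoldsim.seeding import ScaleFactor

        rng = np.random.default_rng(seed)
        out = []
        for m in means:
            field = m + spatial_sd * rng.standard_normal((6, 6, 6))
            out.append(
                SimulationResult(
                    timeseries=pd.DataFrame({"iteration": [0], "hour": [0.0]}),
                    snapshots={240.0: {"young_modulus": field}},
                    events=pd.DataFrame(),
                    config_hash="x",
                    seed=0,
                    scale=ScaleFactor(0.0, 1, 1.0),
                    cell_types={"P": "proliferant"},
                    initial_living=1,
                    final_state=None,
                )
            )
        return out

    def test_untouched_scaffold_reports_initial_stiffness(self):
        cfg = make_config(total_hours=4.0, parameters={"lox": 0.0})
        results = run_replicates(cfg, 3, base_seed=0)
        for mode in ("pooled", "per_scaffold"):
            summ = stiffness_summary(results, mode)
            assert summ.mean == pytest.approx(47.0)
            assert summ.dispersion == pytest.approx(0.0, abs=1e-12)

    def test_identical_replicates_have_zero_per_scaffold_ci(self):
        results = self.synthetic_results([50.0, 50.0, 50.0], spatial_sd=0.0)
        summ = stiffness_summary(results, "per_scaffold")
        assert summ.ci_low == summ.ci_high == summ.mean == pytest.approx(50.0)

    def test_dispersion_ratio_matches_variance_decomposition(self):
        """Known between-replicate and within-replicate variances reproduce
        the pooled/per-scaffold ratio predicted by the closed form."""
        between_sd, within_sd, n_rep = 0.5, 6.0, 40
        rng = np.random.default_rng(3)
        means = 50.0 + between_sd * rng.standard_normal(n_rep)
        results = self.synthetic_results(means, spatial_sd=within_sd, seed=4)
        ratio = dispersion_ratio(results)
        # pooled variance = within^2 + between^2; the sd of replicate means
        # adds a within^2 / n_voxels sampling term on top of between^2
        n_vox = 6**3
        expected = np.sqrt(within_sd**2 + between_sd**2) / np.sqrt(
            between_sd**2 + within_sd**2 / n_vox
        )
        assert ratio == pytest.approx(expected, rel=0.15)

    def test_single_replicate_rejected_in_per_scaffold_mode(self):
        results = self.synthetic_results([50.0], spatial_sd=1.0)
        with pytest.raises(ValueError):
            stiffness_summary(results, "per_scaffold")

    def test_edge_core_contrast_sign_convention(self):
        """A field increasing with center distance yields a positive
        edge-core contrast; shell_spread sees the same range."""
        results = self.synthetic_results([47.0], spatial_sd=0.0)
        dist = manhattan_distance_grid(6, 1.0)
        results[0].snapshots[240.0]["young_modulus"] = 47.0 + dist
        contrast = edge_core_contrast(results, core_max_mm=3.0, edge_min_mm=6.0)
        assert contrast > 0
        # the radial bands of an increasing field also spread
        assert shell_spread(results, band_edges_mm=(3.0, 6.0)) > 0


class TestCompareGroups:
    def test_identical_samples_have_zero_h(self):
        h, p = compare_groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert h == pytest.approx(0.0)

    def test_separated_samples_reject_equality(self):
        h, p = compare_groups([47.0] * 30 + [47.1, 46.9], [58.0] * 30 + [57.9, 58.1])
        assert p < 1e-6

    def test_all_tied_input_flagged(self):
        with pytest.raises(ValueError):
            compare_groups([5.0, 5.0], [5.0, 5.0])

    def test_matches_rank_based_brute_force(self):
        """H computed from first principles (rank sums with tie correction)
        agrees with the library statistic on a small fixed sample."""
        a = [1.2, 3.4, 0.5, 2.2]
        b = [4.1, 2.8, 5.0]
        pooled = np.array(a + b)
        ranks = stats.rankdata(pooled)
        n, na = len(pooled), len(a)
        ra, rb = ranks[:na].sum(), ranks[na:].sum()
        h_brute = 12 / (n * (n + 1)) * (ra**2 / na + rb**2 / (n - na)) - 3 * (n + 1)
        h, _ = compare_groups(a, b)
        assert h == pytest.approx(h_brute, rel=1e-12)
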