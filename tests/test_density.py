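"""Density synthesis, masking, correlation and occupancy-scan tests."""

import math

import numpy as np
import pandas as pd
import pytest

from ligandqc import (
    Atom,
    DensityGrid,
    MaskSpec,
    ReflectionSet,
    UndefinedCorrelationError,
    ZeroResidualError,
    calc_model_map,
    correlation,
    diff_map_correlation,
    effective_resolution,
    ligand_grid_points,
    mask_radius,
    occupancy_scan,
    qq_data,
    render_observed_map,
)
from ligandqc.density import B_TO_U2, DEFAULT_OCC_GRID, GridSpec

from conftest import brute_force_points


def _atom(pos, element="C", b=20.0, occ=1.0, name="C1"):
    return Atom(name, element, pos, occ=occ, b=b, comp_id="LIG", chain="B", seq_id=1)


SMALL = GridSpec(np.array([-4.0, -4.0, -4.0]), 0.5, (17, 17, 17))


class TestModelMap:
    def test_linearity_in_occupancy(self):
        g1 = calc_model_map([_atom([0, 0, 0], occ=0.4)], SMALL)
        g2 = calc_model_map([_atom([0, 0, 0], occ=0.8)], SMALL)
        assert np.allclose(g2.values, 2.0 * g1.values)

    def test_peak_at_atom_node(self):
        g = calc_model_map([_atom([0, 0, 0])], SMALL)
        assert np.unravel_index(np.argmax(g.values), g.dims) == (8, 8, 8)

    def test_gaussian_mass_integral(self):
        # sum * spacing^3 should recover occ * Z within 2%
        for el, z in [("C", 6), ("O", 8)]:
            g = calc_model_map([_atom([0.1, -0.2, 0.05], element=el, occ=0.7, b=25.0)], SMALL)
            mass = g.values.sum() * SMALL.spacing**3
            assert mass == pytest.approx(0.7 * z, rel=0.02)

    def test_empty_atom_list_zero_grid(self):
        g = calc_model_map([], SMALL)
        assert not g.values.any()

    def test_omit_removes_contribution(self):
        a1, a2 = _atom([-1, 0, 0], name="C1"), _atom([1, 0, 0], name="C2")
        full = calc_model_map([a1, a2], SMALL)
        omitted = calc_model_map([a1, a2], SMALL, omit=[a2])
        only1 = calc_model_map([a1], SMALL)
        assert np.allclose(omitted.values, only1.values)
        assert not np.allclose(full.values, only1.values)

    def test_outside_grid_warns(self):
        with pytest.warns(UserWarning, match="outside grid"):
            calc_model_map([_atom([50, 50, 50])], SMALL)


class TestMaskRadius:
    def test_zero_b_gives_base_radius(self):
        for el, r0 in [("C", 1.7), ("N", 1.6), ("O", 1.5), ("S", 1.8), ("P", 1.8)]:
            assert mask_radius(el, 0.0) == pytest.approx(r0)

    def test_hand_evaluated_formula(self):
        # carbon, B=30, r0=1.7, c_b=3.0: r = 1.7 + 3*sqrt(30/(8*pi^2))
        expected = 1.7 + 3.0 * math.sqrt(30.0 / (8 * math.pi**2))
        assert mask_radius("C", 30.0) == pytest.approx(expected, abs=1e-12)

    def test_strictly_increasing_in_b(self):
        radii = [mask_radius("C", b) for b in (0, 10, 20, 40, 80)]
        assert all(x < y for x, y in zip(radii, radii[1:]))

    def test_doubling_b_increment(self):
        b = 24.0
        inc = mask_radius("C", 2 * b) - mask_radius("C", b)
        expected = 3.0 * (math.sqrt(2) - 1) * math.sqrt(b * B_TO_U2)
        assert inc == pytest.approx(expected, abs=1e-12)

    def test_unknown_element_default(self):
        with pytest.warns(UserWarning):
            assert mask_radius("Xx", 0.0) == pytest.approx(1.7)


class TestLigandGridPoints:
    def test_no_environment_all_inside(self):
        lig = [_atom([0, 0, 0], b=0.0)]
        pts = ligand_grid_points(SMALL, lig, [])
        assert pts == brute_force_points(SMALL, lig, [])

    def test_coincident_env_atom_masks_everything(self):
        lig = [_atom([0, 0, 0], b=0.0)]
        env = [_atom([0, 0, 0], b=0.0, name="CE")]
        with pytest.raises(ValueError, match="fully masked"):
            ligand_grid_points(SMALL, lig, env)

    def test_matches_brute_force_on_toy(self, toy, toy_env):
        _, _, lig = toy
        grid = GridSpec.around_atoms(lig.atoms, spacing=0.7, margin=3.0)
        assert ligand_grid_points(grid, lig.atoms, toy_env) == brute_force_points(
            grid, lig.atoms, toy_env
        )

    @pytest.mark.parametrize("seed", range(50))
    def test_brute_force_oracle_random(self, seed):
        """Mask equals the all-grid-points double loop on random cases."""
        rng = np.random.default_rng(seed)
        grid = GridSpec(np.array([-3.0, -3.0, -3.0]), 0.8, (9, 9, 9))
        elements = ["C", "N", "O", "S"]
        lig = [
            _atom(rng.uniform(-2, 2, 3), element=elements[rng.integers(4)],
                  b=float(rng.uniform(5, 60)), name=f"L{i}")
            for i in range(rng.integers(1, 4))
        ]
        env = [
            _atom(rng.uniform(-4, 4, 3), element=elements[rng.integers(4)],
                  b=float(rng.uniform(5, 60)), name=f"E{i}")
            for i in range(rng.integers(0, 4))
        ]
        spec = MaskSpec(neighbour_radius_inflation=float(rng.uniform(0, 0.5)))
        try:
            got = ligand_grid_points(grid, lig, env, spec)
        except ValueError:
            assert brute_force_points(grid, lig, env, spec) == set()
            return
        assert got == brute_force_points(grid, lig, env, spec)


def _grid_from(values):
    return DensityGrid(np.zeros(3), 1.0, np.asarray(values, dtype=float))


class TestCorrelation:
    PTS = {(0, 0, 0), (1, 0, 0), (2, 0, 0), (3, 0, 0), (4, 0, 0)}

    def test_self_correlation_one(self):
        g = _grid_from(np.arange(5.0).reshape(5, 1, 1))
        assert correlation(g, g, self.PTS) == pytest.approx(1.0, abs=1e-12)

    def test_negation_minus_one(self):
        g = _grid_from(np.arange(5.0).reshape(5, 1, 1))
        h = _grid_from(-np.arange(5.0).reshape(5, 1, 1))
        assert correlation(g, h, self.PTS) == pytest.approx(-1.0, abs=1e-12)

    def test_textbook_pearson(self):
        # independent hand computation of Pearson r for two 5-value lists
        a = np.array([1.0, 2.0, 4.0, 5.0, 8.0])
        b = np.array([2.0, 3.0, 3.0, 6.0, 7.0])
        am, bm = a - a.mean(), b - b.mean()
        expected = float(np.sum(am * bm) / np.sqrt(np.sum(am**2) * np.sum(bm**2)))
        ga = _grid_from(a.reshape(5, 1, 1))
        gb = _grid_from(b.reshape(5, 1, 1))
        assert correlation(ga, gb, self.PTS) == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_raises(self):
        g = _grid_from(np.ones((5, 1, 1)))
        h = _grid_from(np.arange(5.0).reshape(5, 1, 1))
        with pytest.raises(UndefinedCorrelationError):
            correlation(g, h, self.PTS)

    def test_scale_offset_invariance(self):
        rng = np.random.default_rng(0)
        a = _grid_from(rng.normal(size=(5, 1, 1)))
        b = _grid_from(rng.normal(size=(5, 1, 1)))
        base = correlation(a, b, self.PTS)
        for alpha, beta in [(2.5, 1.0), (-3.0, -7.0), (0.1, 100.0)]:
            scaled = _grid_from(alpha * b.values + beta)
            assert correlation(a, scaled, self.PTS) == pytest.approx(
                math.copysign(1, alpha) * base, abs=1e-10
            )

    def test_symmetry(self):
        rng = np.random.default_rng(1)
        a = _grid_from(rng.normal(size=(5, 1, 1)))
        b = _grid_from(rng.normal(size=(5, 1, 1)))
        assert correlation(a, b, self.PTS) == pytest.approx(correlation(b, a, self.PTS))

    def test_incompatible_grids_raise(self):
        a = _grid_from(np.zeros((5, 1, 1)))
        b = DensityGrid(np.zeros(3), 2.0, np.zeros((5, 1, 1)))
        with pytest.raises(ValueError):
            correlation(a, b, self.PTS)


class TestDiffMapCorrelation:
    def _setup(self, true_occ, model_occ, toy, toy_grid):
        s, _, lig = toy
        obs = render_observed_map(s, lig, true_occ, 0.0, toy_grid, seed=0)
        lig_keys = lig.atom_keys()
        env_map = calc_model_map([a for a in s.atoms if a.key() not in lig_keys], toy_grid)
        model_lig = calc_model_map(
            [Atom(a.name, a.element, a.pos, model_occ, a.b, comp_id=a.comp_id,
                  chain=a.chain, seq_id=a.seq_id) for a in lig.atoms],
            toy_grid,
        )
        diff = obs - env_map - model_lig
        from ligandqc import neighbourhood

        pts = ligand_grid_points(toy_grid, lig.atoms, neighbourhood(s, lig, 4.0))
        return diff, model_lig, pts

    def test_exact_model_raises_zero_residual(self, toy, toy_grid):
        diff, model_lig, pts = self._setup(1.0, 1.0, toy, toy_grid)
        with pytest.raises(ZeroResidualError):
            diff_map_correlation(diff, model_lig, pts)

    def test_over_occupied_model_negative(self, toy, toy_grid):
        diff, model_lig, pts = self._setup(0.5, 1.0, toy, toy_grid)
        assert diff_map_correlation(diff, model_lig, pts) < 0

    def test_under_occupied_model_positive(self, toy, toy_grid):
        diff, model_lig, pts = self._setup(1.0, 0.5, toy, toy_grid)
        assert diff_map_correlation(diff, model_lig, pts) > 0


class TestQQData:
    def test_normal_samples_track_diagonal(self):
        rng = np.random.default_rng(42)
        qq = qq_data(rng.normal(size=10_000), n_quantiles=100)
        # central 98% of quantiles
        sel = (qq.theoretical > -2.33) & (qq.theoretical < 2.33)
        assert np.max(np.abs(qq.observed[sel] - qq.theoretical[sel])) < 0.1

    def test_constant_input_errors(self):
        with pytest.raises(ValueError, match="zero variance"):
            qq_data(np.ones(1000), n_quantiles=10)

    def test_observed_sorted_and_standardized(self):
        rng = np.random.default_rng(7)
        qq = qq_data(5.0 + 3.0 * rng.normal(size=5000), n_quantiles=50)
        assert np.all(np.diff(qq.observed) >= 0)
        assert abs(np.median(qq.observed)) < 0.1  # standardization recentres

    def test_too_few_values_raises(self):
        with pytest.raises(ValueError):
            qq_data(np.arange(5.0), n_quantiles=10)


def _refl(n_obs, n_missing, F=100.0, sigF=0.0, d_min=2.0):
    df = pd.DataFrame(
        {
            "F": [F] * n_obs + [0.0] * n_missing,
            "sigF": [sigF] * n_obs + [0.0] * n_missing,
            "observed": [True] * n_obs + [False] * n_missing,
        }
    )
    return ReflectionSet(df, d_min)


class TestEffectiveResolution:
    def test_complete_perfect_data(self):
        assert effective_resolution(_refl(1000, 0)) == pytest.approx(2.0)

    def test_half_missing(self):
        assert effective_resolution(_refl(500, 500)) == pytest.approx(2.0 * 2 ** (1 / 3))

    def test_noise_never_decreases(self):
        vals = [effective_resolution(_refl(800, 200, sigF=s)) for s in (0, 20, 50, 100)]
        assert all(x <= y for x, y in zip(vals, vals[1:]))
        assert all(v >= 2.0 for v in vals)

    def test_duplication_invariant(self):
        r1 = _refl(300, 100, sigF=30.0)
        r2 = ReflectionSet(pd.concat([r1.records, r1.records], ignore_index=True), r1.d_min)
        assert effective_resolution(r1) == pytest.approx(effective_resolution(r2))

    def test_no_observed_raises(self):
        with pytest.raises(ValueError):
            effective_resolution(_refl(0, 10))

    def test_csv_roundtrip(self, tmp_path):
        r = _refl(100, 20, sigF=10.0)
        p = tmp_path / "refl.csv"
        df = r.records.copy()
        df["d_min"] = r.d_min
        df.to_csv(p, index=False)
        assert effective_resolution(ReflectionSet.from_csv(p)) == pytest.approx(
            effective_resolution(r)
        )


class TestOccupancyScan:
    def test_default_grid(self):
        assert len(DEFAULT_OCC_GRID) == 21
        assert DEFAULT_OCC_GRID[0] == 0.0 and DEFAULT_OCC_GRID[-1] == 1.0
        assert np.allclose(np.diff(DEFAULT_OCC_GRID), 0.05)

    @pytest.mark.parametrize("q_true", [0.30, 0.50, 0.65, 0.80])
    def test_zero_crossing_brackets_truth(self, toy, toy_grid, q_true):
        s, _, lig = toy
        obs = render_observed_map(s, lig, q_true, 0.0, toy_grid, seed=0)
        scan = occupancy_scan(s, lig, obs, toy_grid)
        cc = {q: c for q, _, c in scan}
        below = [q for q, c in cc.items() if c is not None and c > 0 and q < 1]
        above = [q for q, c in cc.items() if c is not None and c < 0]
        lo, hi = max(below), min(above)
        assert lo < q_true + 1e-9 < hi + 1e-9
        assert hi - lo <= 0.10 + 1e-9  # sign change within one step of truth

    def test_self_consistent_cc_direct_unity(self, toy, toy_grid):
        s, _, lig = toy
        obs = render_observed_map(s, lig, 1.0, 0.0, toy_grid, seed=0)
        scan = occupancy_scan(s, lig, obs, toy_grid)
        cc_dir = dict((q, c) for q, c, _ in scan)[1.0]
        assert cc_dir == pytest.approx(1.0, abs=1e-9)

    def test_matches_naive_recomputation(self, toy, toy_grid):
        """The linear-in-occupancy shortcut equals rebuilding the model
        map from scratch at each trial occupancy."""
        from dataclasses import replace

        s, _, lig = toy
        obs = render_observed_map(s, lig, 0.65, 0.0, toy_grid, seed=0)
        scan = occupancy_scan(s, lig, obs, toy_grid, occupancies=(0.3, 0.9))
        from ligandqc import neighbourhood

        pts = ligand_grid_points(toy_grid, lig.atoms, neighbourhood(s, lig, 4.0))
        lig_keys = lig.atom_keys()
        env_atoms = [a for a in s.atoms if a.key() not in lig_keys]
        for q, cc_dir, cc_diff in scan:
            model_lig = calc_model_map([replace(a, occ=q) for a in lig.atoms], toy_grid)
            env_map = calc_model_map(env_atoms, toy_grid)
            direct = obs - env_map
            diff = direct - model_lig
            assert cc_dir == pytest.approx(correlation(direct, model_lig, pts), abs=1e-9)
            assert cc_diff == pytest.approx(diff_map_correlation(diff, model_lig, pts), abs=1e-9)

    def test_bad_occupancy_rejected(self, toy, toy_grid):
        s, _, lig = toy
        obs = render_observed_map(s, lig, 0.5, 0.0, toy_grid, seed=0)
        with pytest.raises(ValueError):
            occupancy_scan(s, lig, obs, toy_grid, occupancies=(0.5, 1.2))


class TestGridIO:
    def test_npz_roundtrip(self, tmp_path):
        g = DensityGrid(np.array([1.0, 2.0, 3.0]), 0.5, np.random.default_rng(0).normal(size=(4, 5, 6)))
        p = tmp_path / "g.npz"
        g.to_npz(p)
        g2 = DensityGrid.from_npz(p)
        assert g.compatible(g2) and np.allclose(g.values, g2.values)

    def test_ccp4_roundtrip(self, tmp_path):
        g = DensityGrid(np.zeros(3), 0.5, np.random.default_rng(1).normal(size=(8, 8, 8)))
        p = tmp_path / "g.ccp4"
        g.to_ccp4(p)
        g2 = DensityGrid.from_ccp4(p)
        assert g2.dims == g.dims
        assert g2.spacing == pytest.approx(g.spacing, rel=1e-5)
        assert np.allclose(g.values, g2.values, atol=1e-5)
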