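"""Growth loop, scenarios, sweeps: structure and determinism.

The emergent-behaviour checks on full-size runs (lobe formation, LEC
regulation, the anisotropy and mutant regimes) live in
``test_acceptance.py``; here short, small-template runs exercise the
machinery.
"""

import numpy as np
import pytest

from puzzlecell import (
    SimulationParams,
    generate_tissue,
    grow,
    run_scenario,
    step,
    sweep,
    validate,
)
from puzzlecell.simulator import scenario_params


def short_params(**kw) -> SimulationParams:
    kw.setdefault("n_steps", 5)
    return SimulationParams(**kw)


class TestGrow:
    def test_isotropic_scaling_relaxes_walls(self, small_tissue):
        t = small_tissue.copy()
        p = short_params(g_x=1.05, g_y=1.05)
        before = t.nodes.copy()
        grow(t, p)
        np.testing.assert_allclose(t.nodes[: len(before)], before * 1.05)
        for (i, j), rest in t.rest_lengths.items():
            assert rest == pytest.approx(float(np.hypot(*(t.nodes[j] - t.nodes[i]))))

    def test_anisotropic_scaling(self, small_tissue):
        t = small_tissue.copy()
        grow(t, short_params(g_x=1.08, g_y=1.0))
        w = t.nodes[:, 0].max() - t.nodes[:, 0].min()
        h = t.nodes[:, 1].max() - t.nodes[:, 1].min()
        assert w == pytest.approx(1.08 * 40.0, rel=1e-6)
        assert h == pytest.approx(40.0, rel=1e-6)

    def test_springs_keep_reference_length(self, small_tissue, default_params):
        from puzzlecell import place_connections

        t = small_tissue.copy()
        p = default_params.updated(min_micro=5.0)
        place_connections(t, p)
        refs = [s.ref_length for s in t.springs]
        grow(t, p)
        assert [s.ref_length for s in t.springs] == refs

    def test_shrinkage_rejected(self, small_tissue):
        with pytest.raises(ValueError):
            grow(small_tissue.copy(), SimulationParams(g_x=1.0).updated(g_x=0.99))


class TestStep:
    def test_no_restriction_keeps_affine_shapes(self):
        t = generate_tissue(seed=4, n_cells=9, width=45, height=45)
        p = short_params(k_m=0.0)
        for si in range(p.n_steps):
            t, df = step(t, p, si)
        assert validate(t) == []
        inner = df[df["interior"]]
        np.testing.assert_allclose(inner["lobeyness"], 1.0, atol=0.01)

    def test_emits_one_record_per_cell(self, small_tissue, default_params):
        t = small_tissue.copy()
        _, df = step(t, default_params, 0)
        assert len(df) == t.n_cells
        assert set(df["cell_id"]) == set(range(t.n_cells))

    def test_topology_constant(self):
        t = generate_tissue(seed=4, n_cells=9, width=45, height=45)
        n_cells = t.n_cells
        adjacency = {
            tuple(sorted(own)) for own in t.edges().values() if len(own) == 2
        }
        p = short_params()
        for si in range(p.n_steps):
            t, _ = step(t, p, si)
        assert t.n_cells == n_cells
        assert {
            tuple(sorted(own)) for own in t.edges().values() if len(own) == 2
        } == adjacency


class TestScenarios:
    def test_unknown_scenario_rejected(self):
        with pytest.raises(ValueError):
            run_scenario("warp", SimulationParams(n_steps=1))

    def test_presets(self, default_params):
        aniso = scenario_params("anisotropic", default_params)
        assert aniso.g_y == 1.0 and aniso.g_x > 1.0
        none = scenario_params("no_restriction", default_params)
        assert none.k_m == 0.0
        spk = scenario_params("spk1", default_params)
        assert spk.spk1_mode
        assert spk.k_m > default_params.k_m
        assert spk.k_s > default_params.k_s
        assert spk.reset_period > default_params.reset_period
        grad = scenario_params("gradient", default_params, width=100.0)
        gy = grad.g_y(np.array([0.0, 100.0]))
        assert gy[0] == pytest.approx(1.0)
        assert gy[1] == pytest.approx(grad.g_x)

    def test_gradient_growth_is_continuous_in_material_x(self, default_params):
        grad = scenario_params("gradient", default_params, width=100.0)
        xs = np.linspace(0, 100, 51)
        gy = grad.g_y(xs)
        assert np.all(np.diff(gy) >= 0)
        assert np.all(np.abs(np.diff(gy)) < 0.01)

    def test_run_returns_metrics_and_final_tissue(self, tmp_path):
        run = run_scenario(
            "isotropic", short_params(n_steps=3), n_cells=9,
            width=45, height=45, out_dir=tmp_path, snapshot_every=2,
        )
        assert validate(run.tissue) == []
        assert set(run.metrics["step"]) == {0, 1, 2, 3}
        assert (tmp_path / "metrics.csv").exists()
        assert (tmp_path / "final_tissue.json").exists()
        assert (tmp_path / "final_tissue.svg").exists()
        assert (tmp_path / "run_log.json").exists()
        assert (tmp_path / "tissue_step0002.svg").exists()


class TestDeterminism:
    def test_identical_seed_gives_identical_metrics(self, tmp_path):
        outs = []
        for sub in ("a", "b"):
            run_scenario(
                "isotropic", short_params(n_steps=4, seed=11), n_cells=9,
                width=45, height=45, out_dir=tmp_path / sub,
            )
            outs.append((tmp_path / sub / "metrics.csv").read_bytes())
        assert outs[0] == outs[1]

    def test_spk1_switch_alone_changes_nothing_until_inhibition_matters(self):
        # with the convexity threshold so high that no node is ever
        # inhibited, the spk1 flag has no other effect: bit-identical steps
        t0 = generate_tissue(seed=2, n_cells=9, width=45, height=45)
        wt, _ = step(t0.copy(), short_params(kappa_convex=100.0), 0)
        mut, _ = step(t0.copy(), short_params(kappa_convex=100.0, spk1_mode=True), 0)
        np.testing.assert_array_equal(wt.nodes, mut.nodes)


class TestSweep:
    def test_unknown_parameter_rejected(self):
        with pytest.raises(ValueError):
            sweep("gravity", [1.0], SimulationParams(n_steps=1))

    def test_no_restriction_end_of_km_sweep_is_unlobed(self):
        base = short_params(n_steps=4)
        table = sweep("k_m", [0.0, base.k_m], base, n_cells=9, width=45, height=45)
        assert list(table["value"]) == [0.0, base.k_m]
        assert table.loc[0, "mean_lobeyness"] == pytest.approx(1.0, abs=0.01)

    def test_isotropy_maps_growth_factors(self):
        base = short_params(n_steps=1)
        table = sweep("isotropy", [0.0, 1.0], base, n_cells=9, width=45, height=45)
        assert len(table) == 2
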