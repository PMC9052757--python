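"""Generators: potentials, samplers, planted ensembles, binding traces."""
import numpy as np
import pytest

from allostate import fel, synthdata as sd
from allostate._util import kt_kcal, wrap_angle
from allostate.binding import detect_binding_events
from allostate.states import classify_binding_phase

KT300 = kt_kcal(300.0)


class TestTripleWell:
    def test_well_centres_are_local_minima(self, triple_well):
        for lab, c in zip(triple_well.labels, triple_well.centers):
            m = np.array(triple_well.minima[lab])
            assert np.all(np.abs(wrap_angle(m - c)) <= 5.0)
            u_min = triple_well.energy(m)
            for _ in range(50):
                probe = m + np.random.default_rng(0).uniform(-5, 5, size=2)
                assert triple_well.energy(probe) >= u_min - 1e-9

    def test_exact_periodicity(self, triple_well, rng):
        pts = rng.uniform(-180, 180, size=(50, 2))
        u = triple_well.energy(pts)
        shifted = triple_well.energy(pts + np.array([360.0, 0.0]))
        np.testing.assert_allclose(u, shifted, atol=1e-12)
        shifted2 = triple_well.energy(pts + np.array([0.0, -720.0]))
        np.testing.assert_allclose(u, shifted2, atol=1e-12)

    def test_recorded_barriers_near_4kt_and_8kt(self, triple_well):
        b1 = triple_well.true_barriers[("inactive", "unblocked")]
        b2 = triple_well.true_barriers[("inactive", "active")]
        assert b1 / KT300 == pytest.approx(4.0, abs=0.05)
        assert b2 / KT300 == pytest.approx(8.0, abs=0.05)

    def test_recorded_barrier_is_dense_grid_self_consistent(self,
                                                            triple_well):
        grid = triple_well.dense_grid(resolution=1.0)
        res = fel.barrier_between(grid, triple_well._well_box("inactive"),
                                  triple_well._well_box("active"))
        assert res.barrier == pytest.approx(
            triple_well.true_barriers[("inactive", "active")], abs=0.05)

    def test_gradient_matches_finite_differences(self, triple_well, rng):
        pts = rng.uniform(-180, 180, size=(20, 2))
        grad = triple_well.gradient(pts)
        eps = 1e-5
        for d in range(2):
            step = np.zeros(2)
            step[d] = eps
            fd = (triple_well.energy(pts + step)
                  - triple_well.energy(pts - step)) / (2 * eps)
            np.testing.assert_allclose(grad[:, d], fd, atol=1e-6)


class TestLangevin:
    def test_zero_noise_limit_stays_at_minimum(self, coarse_triple_well):
        m = np.array(coarse_triple_well.minima["inactive"])
        params = sd.LangevinParams(kt=1e-12, diffusion=1e-8, dt=0.001,
                                   n_steps=500, x0=tuple(m))
        series = sd.langevin_sample(coarse_triple_well, params)
        # relaxes to the analytic minimum (within the 2° grid refinement of
        # the recorded one) and stays there
        np.testing.assert_allclose(series.values[-1], m, atol=2.0)
        np.testing.assert_allclose(series.values[-1], series.values[-50],
                                   atol=1e-3)

    def test_harmonic_well_variance_matches_closed_form(self):
        """Long-run variance in a quadratic well is kT/k (batched means)."""
        width = 30.0
        pot = sd.ModelPotential(
            centers=np.array([[0.0]]), widths=np.array([[width]]),
            depths=np.array([50.0]), labels=["well"], cv_names=("x",),
            grid_resolution=2.0)
        # curvature at the minimum of -d exp(κ(cosΔ-1)) is d·κ·(π/180)²
        kappa = (180.0 / (np.pi * width)) ** 2
        k_spring = 50.0 * kappa * (np.pi / 180.0) ** 2
        params = sd.LangevinParams(kt=KT300, diffusion=500.0, dt=0.002,
                                   n_steps=60_000, x0=(0.0,), seed=9)
        series = sd.langevin_sample(pot, params)
        x = series.values[5000:, 0]
        target_var = KT300 / k_spring
        batches = x.reshape(11, -1)
        batch_vars = batches.var(axis=1)
        sem = batch_vars.std(ddof=1) / np.sqrt(len(batch_vars))
        assert x.var() == pytest.approx(target_var, abs=3 * sem + 0.05 * target_var)

    def test_seed_determinism(self, coarse_triple_well):
        params = sd.LangevinParams(n_steps=500, seed=42)
        a = sd.langevin_sample(coarse_triple_well, params)
        b = sd.langevin_sample(coarse_triple_well, params)
        assert np.array_equal(a.values, b.values)

    def test_excessive_drift_raises(self):
        pot = sd.ModelPotential(
            centers=np.array([[0.0]]), widths=np.array([[10.0]]),
            depths=np.array([500.0]), labels=["deep"], cv_names=("x",),
            grid_resolution=5.0)
        params = sd.LangevinParams(kt=0.1, diffusion=5000.0, dt=0.5,
                                   n_steps=100, x0=(15.0,))
        with pytest.raises(ValueError, match="smaller timestep"):
            sd.langevin_sample(pot, params)

    @staticmethod
    def _in_box(x, potential, label, half_width=40.0):
        box = potential._well_box(label, half_width=half_width)
        inside = np.ones(len(x), dtype=bool)
        for a, name in enumerate(potential.cv_names):
            lo, hi = box[name]
            d = (wrap_angle(x[:, a]) - wrap_angle(lo)) % 360.0
            inside &= d <= (hi - lo)
        return inside

    def test_boltzmann_populations_on_triple_well(self, triple_well):
        """Basin occupancies match analytic Boltzmann weights within 3σ.

        σ comes from 20 block means of the basin indicator, which absorbs
        the trajectory autocorrelation (effective-sample-size correction).
        """
        params = sd.LangevinParams(n_steps=400_000, dt=0.002,
                                   diffusion=2000.0, seed=17,
                                   x0=(-130.0, -70.0))
        series = sd.langevin_sample(triple_well, params)
        x = series.values
        grid = triple_well.dense_grid(resolution=1.0)
        w = np.exp(-grid.values / KT300)
        prob = w / w.sum()
        in_a = self._in_box(x, triple_well, "inactive")
        in_b = self._in_box(x, triple_well, "unblocked")
        analytic = [
            prob[fel._region_mask(grid, triple_well._well_box(lab, 40.0))].sum()
            for lab in ("inactive", "unblocked")]
        p_exp = analytic[1] / (analytic[0] + analytic[1])
        p_obs = in_b.sum() / (in_a.sum() + in_b.sum())
        block_p = []
        for idx in np.array_split(np.arange(len(x)), 20):
            na, nb = in_a[idx].sum(), in_b[idx].sum()
            if na + nb:
                block_p.append(nb / (na + nb))
        sem = np.std(block_p, ddof=1) / np.sqrt(len(block_p))
        assert abs(p_obs - p_exp) < 3 * sem


@pytest.fixture(scope="module")
def short_run():
    pot = sd.make_triple_well()
    params = sd.LangevinParams(n_steps=20_000, seed=5)
    return sd.wtmetad_sample(pot, params, pace=200, n_walkers=4)


class TestWtMetad:
    def test_first_hill_height_is_h0(self, short_run):
        _series, hills = short_run
        first = min(hills, key=lambda h: (h.times[0] if len(h) else np.inf))
        assert first.heights[0] == pytest.approx(0.5)

    def test_heights_tempered_below_h0(self, short_run):
        _series, hills = short_run
        for h in hills:
            assert np.all(h.heights <= 0.5 + 1e-12)
            assert h.heights[-1] < 0.5  # bias has accumulated

    def test_tempering_e_fold_identity(self):
        """At accumulated bias (γ-1)kT the deposited height is h₀/e."""
        gamma, kt = 10.0, KT300
        grid = sd._BiasGrid(ndim=2, bins=90)
        target_v = (gamma - 1.0) * kt
        # fill the grid with a uniform bias of exactly (γ-1) kT
        grid.v[:] = target_v
        h = 0.5 * np.exp(-grid.value(np.array([10.0, 10.0]))
                         / ((gamma - 1.0) * kt))
        assert h == pytest.approx(0.5 / np.e)

    def test_seed_determinism(self):
        pot = sd.make_triple_well()
        params = sd.LangevinParams(n_steps=2000, seed=3)
        a = sd.wtmetad_sample(pot, params, pace=100, n_walkers=2)
        b = sd.wtmetad_sample(pot, params, pace=100, n_walkers=2)
        np.testing.assert_array_equal(a[1][0].centers, b[1][0].centers)
        np.testing.assert_array_equal(a[1][1].heights, b[1][1].heights)

    def test_gamma_validation(self):
        pot = sd.make_triple_well()
        with pytest.raises(ValueError, match="γ"):
            sd.wtmetad_sample(pot, sd.LangevinParams(n_steps=10), gamma=1.0)

    def test_double_well_barrier_recovery(self):
        """End-to-end on a 1D double well with a known barrier."""
        pot = sd.make_double_well_1d()
        true = pot.true_barriers[("left", "right")]
        params = sd.LangevinParams(n_steps=400_000, x0=(-120.0,), seed=11)
        _series, hills = sd.wtmetad_sample(pot, params, pace=250,
                                           n_walkers=4)
        spec = fel.GridSpec.dihedral(pot.cv_names, bins=144)
        grid = fel.fel_from_bias(fel.bias_from_hills(hills, spec))
        res = fel.barrier_between(grid, pot._well_box("left"),
                                  pot._well_box("right"))
        assert abs(res.barrier - true) < 0.5 * KT300


class TestPlantedEnsemble:
    def test_seed_determinism(self):
        spec = sd.PlantedNetworkSpec(seed=6, n_frames=50)
        a = sd.planted_ensemble(spec)
        b = sd.planted_ensemble(spec)
        assert np.array_equal(a.frames, b.frames)

    def test_correlation_target_is_psd_unit_diagonal(self):
        r = sd.PlantedNetworkSpec().correlation_target()
        np.testing.assert_allclose(np.diag(r), 1.0, atol=1e-12)
        assert np.linalg.eigvalsh(r).min() > -1e-9

    def test_amplitude_invariance_of_correlations(self):
        from allostate.network import correlation_matrix

        small = sd.planted_ensemble(
            sd.PlantedNetworkSpec(seed=2, amplitude=0.5, n_frames=2000))
        large = sd.planted_ensemble(
            sd.PlantedNetworkSpec(seed=2, amplitude=1.0, n_frames=2000))
        c_small = correlation_matrix(small, align=False).values
        c_large = correlation_matrix(large, align=False).values
        np.testing.assert_allclose(c_small, c_large, atol=0.05)

    def test_null_case_no_path_stands_out(self):
        from allostate.network import (contact_adjacency, correlation_matrix,
                                       spm)

        spec = sd.PlantedNetworkSpec(rho_path=0.1)
        path = spec.planted_path()
        pedges = set(tuple(sorted(e)) for e in zip(path[:-1], path[1:]))
        full = 0
        for seed in range(5):
            ens = sd.planted_ensemble(
                sd.PlantedNetworkSpec(seed=seed, rho_path=0.1,
                                      n_frames=2000))
            res = spm(correlation_matrix(ens), contact_adjacency(ens))
            full += pedges <= set(res.top_edges(len(path)))
        assert full == 0

    def test_topology_written_and_readable(self, tmp_path):
        from allostate import trajio

        spec = sd.PlantedNetworkSpec(seed=1, n_frames=20)
        ens = sd.planted_ensemble(spec, topology_path=tmp_path / "p.pdb")
        model = trajio.load_structure(tmp_path / "p.pdb")
        assert model.n_atoms == 2 * spec.n_per_subunit
        assert set(a.chain for a in model.atoms) == {"A", "B"}

    def test_invalid_rho_ordering(self):
        with pytest.raises(ValueError, match="rho"):
            sd.PlantedNetworkSpec(rho_path=0.1, rho_bg=0.5)


class TestBindingTrace:
    def test_unbound_schedule_stays_above_recognition(self):
        series, labels = sd.binding_trace(0, [("unbound", 100)])
        d = series.column("d_nuc")
        assert len(d) == 100
        # 14 Å target with σ = 0.3: crossing 12 Å is a >6σ event
        assert np.all(d > 12.0)
        assert set(labels) == {"inactive-OxH"}

    def test_full_schedule_yields_one_productive_event(self):
        series, labels = sd.binding_trace(1, [
            ("unbound", 100), ("recognition", 80), ("captured", 100),
            ("catalytic", 80), ("unbound", 50)])
        d = series.column("d_nuc")
        phases = classify_binding_phase(d, labels)
        events = detect_binding_events(d, phases, min_capture_frames=10)
        assert len(events) == 1
        assert events[0].productive

    def test_empty_schedule_empty_series(self):
        series, labels = sd.binding_trace(0, [])
        assert len(series) == 0
        assert len(labels) == 0

    def test_infeasible_schedule_raises(self):
        with pytest.raises(ValueError, match="infeasible"):
            sd.binding_trace(0, [("unbound", 10), ("catalytic", 10)])

    def test_seed_determinism(self):
        a, _ = sd.binding_trace(7, [("unbound", 30), ("recognition", 20)])
        b, _ = sd.binding_trace(7, [("unbound", 30), ("recognition", 20)])
        assert np.array_equal(a.values, b.values)


def test_generated_files_readable_by_trajio(tmp_path):
    """Every generator output round-trips through the I/O layer cleanly."""
    from allostate import trajio

    pot = sd.make_triple_well()
    series, hills = sd.wtmetad_sample(
        pot, sd.LangevinParams(n_steps=2000, seed=1), pace=200, n_walkers=2)
    for w, (s, h) in enumerate(zip(series, hills)):
        trajio.write_colvar(s, tmp_path / f"w{w}.colvar")
        trajio.write_hills(h, tmp_path / f"w{w}.hills")
        back_cv = trajio.read_colvar(tmp_path / f"w{w}.colvar")
        back_h = trajio.read_hills(tmp_path / f"w{w}.hills", walker_id=w)
        np.testing.assert_allclose(back_cv.values, s.values, atol=1e-6)
        np.testing.assert_allclose(back_h.heights, h.heights, atol=1e-8)
        assert back_h.cv_periods == [360.0, 360.0]
    ens = sd.planted_ensemble(
        sd.PlantedNetworkSpec(seed=0, n_frames=10),
        topology_path=tmp_path / "top.pdb")
    trajio.write_trajectory(ens, tmp_path / "traj.dcd")
    model = trajio.load_structure(tmp_path / "top.pdb")
    back = trajio.load_trajectory(tmp_path / "traj.dcd", model)
    assert back.n_frames == 10
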