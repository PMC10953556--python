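"""Vertex monolayer: mesh building, energy, relaxation, ablation, defects."""

import numpy as np
import pytest

from yapflow import vertex as vx


class TestBuildMonolayer:
    def test_unjittered_cells_are_hexagons(self, mesh64):
        assert {len(c) for c in mesh64.cells} == {6}

    def test_seed_determinism(self):
        a = vx.build_monolayer(36, jitter=0.3, seed=7)
        b = vx.build_monolayer(36, jitter=0.3, seed=7)
        assert np.array_equal(a.vertices, b.vertices)
        assert a.cells == b.cells

    def test_interior_vertex_coordination_three(self):
        mesh = vx.build_monolayer(36, jitter=0.25, seed=2)
        counts = mesh.vertex_cells()
        for v, cells in counts.items():
            if not mesh.pinned[v]:
                assert len(cells) == 3

    def test_euler_relation_holds(self, mesh64):
        mesh64.check_euler()

    def test_too_few_cells_raise(self):
        with pytest.raises(ValueError):
            vx.build_monolayer(3)


class TestEnergyAndGradient:
    def test_reference_configuration_zero_energy(self, mesh64):
        p = vx.VertexParams(Gamma=0.0, Lambda=0.0)
        assert vx.energy(mesh64, p) == pytest.approx(0.0, abs=1e-10)

    def test_translation_invariance(self, mesh64):
        p = vx.VertexParams()
        m = mesh64.copy()
        m.fiber_stress[:] = 0.5
        e0 = vx.energy(m, p)
        m.vertices = m.vertices + np.array([3.7, -1.2])
        assert vx.energy(m, p) == pytest.approx(e0, rel=1e-12)

    def test_gradient_matches_finite_differences(self):
        mesh = vx.build_monolayer(36, jitter=0.2, seed=4)
        mesh.fiber_stress[:] = 0.6
        p = vx.VertexParams()
        grad = vx.energy_gradient(mesh, p)
        h = 1e-6
        rng = np.random.default_rng(0)
        for vi in rng.choice(len(mesh.vertices), 8, replace=False):
            for k in (0, 1):
                up, dn = mesh.copy(), mesh.copy()
                up.vertices[vi, k] += h
                dn.vertices[vi, k] -= h
                fd = (vx.energy(up, p) - vx.energy(dn, p)) / (2 * h)
                assert fd == pytest.approx(grad[vi, k], rel=1e-6, abs=1e-9)


class TestRelax:
    def test_equilibrium_mesh_unchanged(self, mesh64):
        m = mesh64.copy()
        m.fiber_stress[:] = 0.6            # uniform lattice is an equilibrium
        relaxed = vx.relax(m)
        assert np.abs(relaxed.vertices - m.vertices).max() == 0.0

    def test_energy_descent_and_gradient_tolerance(self):
        mesh = vx.build_monolayer(64, jitter=0.25, seed=5)
        mesh.fiber_stress[:] = 0.5
        p = vx.VertexParams()
        e0 = vx.energy(mesh, p)
        relaxed = vx.relax(mesh, p)
        assert vx.energy(relaxed, p) <= e0
        gnorm = np.linalg.norm(vx.energy_gradient(relaxed, p)[~relaxed.pinned])
        assert gnorm < 1e-6


class TestAblation:
    def test_no_stress_no_recoil(self, recoil_sweep):
        svals, angles = recoil_sweep
        assert svals[0] == 0.0
        assert angles[0] < 0.01

    def test_recoil_monotone_and_linear(self, recoil_sweep):
        svals, angles = recoil_sweep
        x, y = np.array(svals[1:]), np.array(angles[1:])
        assert np.all(np.diff(angles) >= 0)
        slope, intercept = np.polyfit(x, y, 1)
        pred = slope * x + intercept
        r2 = 1 - np.sum((y - pred) ** 2) / np.sum((y - y.mean()) ** 2)
        assert slope > 0 and r2 >= 0.9

    def test_axis_invariant(self, mesh64):
        interior = np.nonzero(~mesh64.boundary_cells())[0]
        res = vx.ablate_and_recoil(mesh64, int(interior[0]), 0.5)
        assert res.opening_short_axis <= res.opening_long_axis
        assert 0.0 <= res.recoil_angle <= 1.0

    def test_boundary_cell_rejected(self, mesh64):
        bcell = int(np.nonzero(mesh64.boundary_cells())[0][0])
        with pytest.raises(ValueError):
            vx.ablate_and_recoil(mesh64, bcell, 0.5)


class TestCapHeterogeneity:
    def test_fraction_limits(self, mesh64):
        assert not vx.assign_cap_heterogeneity(mesh64, 0.0, seed=1).has_cap.any()
        assert vx.assign_cap_heterogeneity(mesh64, 1.0, seed=1).has_cap.all()

    def test_capped_count_within_binomial_interval(self, mesh64):
        frac = 0.3
        total = sum(vx.assign_cap_heterogeneity(mesh64, frac, seed=s).has_cap.sum()
                    for s in range(100))
        n = 100 * mesh64.n_cells
        sd = (n * frac * (1 - frac)) ** 0.5
        assert abs(total - n * frac) < 1.96 * sd

    def test_bad_fraction_raises(self, mesh64):
        with pytest.raises(ValueError):
            vx.assign_cap_heterogeneity(mesh64, 1.5)


class TestStrainField:
    def test_homogeneous_field_uniform(self, monolayer_pair):
        hom, _ = monolayer_pair
        field = vx.nuclear_strain_field(hom)
        assert np.var(field) < 1e-10

    def test_heterogeneous_variance_larger(self, monolayer_pair):
        hom, het = monolayer_pair
        assert (np.var(vx.nuclear_strain_field(het))
                > np.var(vx.nuclear_strain_field(hom)))

    def test_capped_cell_strain_below_uncapped_paired(self, monolayer_pair):
        _, het = monolayer_pair
        interior = ~het.boundary_cells()
        i = int(np.nonzero(het.has_cap & interior)[0][0])
        alt = het.copy()
        alt.has_cap[i] = False
        alt.cap_strength[i] = 0.0
        alt = vx.relax(alt)
        assert (vx.nuclear_strain_field(het)[i]
                < vx.nuclear_strain_field(alt)[i])

    def test_unrelaxed_mesh_rejected(self, mesh64):
        with pytest.raises(ValueError):
            vx.nuclear_strain_field(mesh64)


class TestDefects:
    def test_uniform_director_no_defects(self, mesh64):
        rel = mesh64.copy()
        rel.relaxed = True
        d = vx.detect_defects(rel, director=np.zeros(mesh64.n_cells))
        assert len(d.charges) == 0

    def test_constructed_plus_half_detected_once(self, mesh64):
        centroids = np.array([mesh64.cell_polygon(i).mean(axis=0)
                              for i in range(mesh64.n_cells)])
        center = centroids.mean(axis=0) + 0.13
        theta = 0.5 * np.arctan2(centroids[:, 1] - center[1],
                                 centroids[:, 0] - center[0])
        rel = mesh64.copy()
        rel.relaxed = True
        d = vx.detect_defects(rel, director=theta)
        assert list(d.charges) == [0.5]
        assert d.total_charge == pytest.approx(
            vx.boundary_winding(rel, theta), abs=1e-9)

    def test_total_charge_equals_boundary_winding(self, monolayer_pair):
        _, het = monolayer_pair
        d = vx.detect_defects(het)
        assert d.charges.size > 0
        assert set(np.abs(d.charges)) <= {0.5}

    def test_too_few_cells_raise(self):
        mesh = vx.build_monolayer(9, seed=0)
        with pytest.raises(ValueError):
            vx.detect_defects(mesh)
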