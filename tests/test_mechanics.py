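import numpy as np
import pytest

from mechanotaxis import (MechanicsParams, active_forces, area_drag_forces,
                          build_disk_mesh, compute_geometry, hill,
                          membrane_passive_forces, relax_interior,
                          step_membrane)
from mechanotaxis.mesh import CellMesh, IntegrityError, _canonical


def ring_mesh(n=24, radius=5.0, scale=1.0):
    th = 2 * np.pi * np.arange(n) / n
    membrane = scale * radius * np.c_[np.cos(th), np.sin(th)]
    tri = _canonical(np.array([[0, 1, 2]]))
    return CellMesh(membrane=membrane, interior=np.zeros((1, 2)),
                    triangles=tri, reference_angles=np.zeros((1, 3)))


def ring_params(n=24, radius=5.0, **kw):
    rest = 2 * radius * np.sin(np.pi / n)
    defaults = dict(mu=1.0, k=0.5, eta_m=0.2, rest_edge_length=rest,
                    dt_mech=1.0, c_drag=0.0, k_perim=0.0)
    defaults.update(kw)
    return MechanicsParams(**defaults)


class TestPassiveForces:
    def test_rest_ring_is_force_free(self):
        mesh = ring_mesh()
        p = ring_params()
        f = membrane_passive_forces(mesh, mesh.membrane.copy(), p)
        assert np.abs(f).max() < 1e-12

    def test_hooke_on_stretched_pair(self):
        # isolate one spring by looking at a uniformly dilated ring: each
        # edge is stretched by the same δ and pulls its end nodes with k·δ
        # along the edge; the two contributions at a node add symmetrically
        mesh = ring_mesh(scale=1.1)
        p = ring_params()
        f = membrane_passive_forces(mesh, mesh.membrane.copy(), p)
        delta = mesh.segment_lengths[0] - p.rest_edge_length
        # net inward force at node 0: 2·k·δ·sin(π/n) along -r̂
        expected = 2 * p.k * delta * np.sin(np.pi / 24)
        r_hat = mesh.membrane[0] / np.hypot(*mesh.membrane[0])
        assert f[0] @ r_hat == pytest.approx(-expected, rel=1e-9)

    def test_dilated_ring_points_inward_and_sums_to_zero(self):
        mesh = ring_mesh(scale=1.2)
        p = ring_params()
        f = membrane_passive_forces(mesh, mesh.membrane.copy(), p)
        radial = (f * mesh.membrane).sum(axis=1)
        assert np.all(radial < 0)
        assert np.abs(f.sum(axis=0)).max() < 1e-9

    def test_viscous_force_opposes_elongation(self):
        mesh = ring_mesh(scale=1.0)
        prev = mesh.membrane * 0.95  # edges just elongated
        p = ring_params(k=0.0, eta_m=0.5)
        f = membrane_passive_forces(mesh, prev, p)
        radial = (f * mesh.membrane).sum(axis=1)
        assert np.all(radial < 0)

    def test_zero_length_edge_rejected(self):
        mesh = ring_mesh()
        mesh.membrane[1] = mesh.membrane[0]
        with pytest.raises(IntegrityError):
            membrane_passive_forces(mesh, mesh.membrane.copy(), ring_params())


class TestActiveForces:
    def test_hill_limits(self):
        assert hill(np.array([0.0]), 2.0, 2.0)[0] == 0.0
        assert hill(np.array([2.0]), 2.0, 2.0)[0] == pytest.approx(0.5)
        assert hill(np.array([1e9]), 2.0, 2.0)[0] == pytest.approx(1.0, abs=1e-9)

    def test_zero_fields_give_zero_force(self):
        mesh = ring_mesh()
        z = np.zeros(24)
        f = active_forces(mesh, z, z, ring_params())
        assert np.abs(f).max() == 0.0

    def test_saturation_bounds_force(self):
        mesh = ring_mesh()
        p = ring_params(f_pro_max=1.0, f_cont_max=0.0, force_smooth_passes=0)
        pip3 = np.zeros(24)
        pip3[0] = 1e9
        f = active_forces(mesh, pip3, np.zeros(24), p)
        mags = np.hypot(f[:, 0], f[:, 1])
        assert mags.max() == pytest.approx(p.f_pro_max, rel=1e-6)
        assert np.all(mags <= p.f_pro_max + 1e-12)

    def test_protrusion_points_outward(self):
        mesh = ring_mesh()
        p = ring_params(force_smooth_passes=0)
        pip3 = np.ones(24)
        pip3[3] = 5.0
        f = active_forces(mesh, pip3, np.zeros(24), p)
        assert f[3] @ mesh.membrane[3] > 0

    def test_negative_concentration_rejected(self):
        mesh = ring_mesh()
        bad = -np.ones(24)
        with pytest.raises(IntegrityError):
            active_forces(mesh, bad, np.zeros(24), ring_params())


class TestAreaDragForces:
    def test_at_target_no_force(self):
        mesh = ring_mesh()
        geom = compute_geometry(mesh)
        p = ring_params(k_area=0.05, c_drag=0.0)
        f = area_drag_forces(mesh, np.zeros((24, 2)), np.zeros((1, 2)),
                             geom.area, p, geom)
        assert np.abs(f).max() < 1e-12

    def test_deficit_pushes_outward_with_zero_sum(self):
        mesh = ring_mesh()
        geom = compute_geometry(mesh)
        p = ring_params(k_area=0.05, c_drag=0.0)
        f = area_drag_forces(mesh, np.zeros((24, 2)), np.zeros((1, 2)),
                             geom.area / 0.9, p, geom)
        radial = (f * mesh.membrane).sum(axis=1)
        assert np.all(radial > 0)
        # pressure on a closed contour sums to exactly zero
        assert np.abs(f.sum(axis=0)).max() < 1e-12

    def test_rigid_translation_has_zero_drag(self):
        mesh = ring_mesh()
        geom = compute_geometry(mesh)
        p = ring_params(k_area=0.0, c_drag=0.5)
        v = np.full((24, 2), 1.3)
        v_int = np.full((1, 2), 1.3)
        f = area_drag_forces(mesh, v, v_int, geom.area, p, geom)
        assert np.abs(f).max() < 1e-12


class TestStepMembrane:
    def test_zero_force_no_motion(self):
        mesh = ring_mesh()
        new, used = step_membrane(mesh, np.zeros((24, 2)), None, ring_params())
        assert np.array_equal(new, mesh.membrane)
        assert used == 1.0

    def test_overdamped_displacement(self):
        mesh = ring_mesh()
        p = ring_params(mu=2.0)
        f = np.zeros((24, 2))
        f[5] = [0.1, 0.0]
        new, used = step_membrane(mesh, f, None, p)
        assert used == 1.0
        assert new[5] - mesh.membrane[5] == pytest.approx([0.05, 0.0])

    def test_displacement_cap_halves_step(self):
        mesh = ring_mesh()
        p = ring_params()
        f = np.zeros((24, 2))
        f[5] = [100.0, 0.0]
        new, used = step_membrane(mesh, f, None, p)
        assert used < 1.0
        moved = np.hypot(*(new[5] - mesh.membrane[5]))
        assert moved <= 0.2 * mesh.segment_lengths.mean() + 1e-12

    def test_perturbed_ring_relaxes_with_decreasing_energy(self):
        rng = np.random.default_rng(1)
        mesh = ring_mesh()
        mesh.membrane += 0.1 * rng.standard_normal((24, 2))
        p = ring_params(k=0.3, eta_m=0.0, dt_mech=0.25)
        prev = mesh.membrane.copy()
        energies = []
        import dataclasses
        for _ in range(100):
            f = membrane_passive_forces(mesh, prev, p)
            v = f / p.mu
            energies.append(float((v ** 2).sum()))
            prev = mesh.membrane
            new, _ = step_membrane(mesh, f, None, p, dt=p.dt_mech)
            mesh = dataclasses.replace(mesh, membrane=new)
        energies = np.array(energies)
        # overall descent (allow tiny numerical wiggles between neighbors)
        assert energies[-1] < 1e-3 * energies[0]
        assert np.all(np.diff(np.maximum.accumulate(-energies)) >= 0)


class TestRelaxInterior:
    def test_square_single_node_at_centroid(self, square_mesh):
        out = relax_interior(square_mesh)
        assert out[0] == pytest.approx([0.5, 0.5], abs=1e-10)

    def test_affine_equivariance(self, disk_mesh):
        import dataclasses
        base = relax_interior(disk_mesh)
        A = np.array([[1.3, 0.2], [-0.1, 0.8]])
        b = np.array([2.0, -1.0])
        mapped = dataclasses.replace(
            disk_mesh, membrane=disk_mesh.membrane @ A.T + b)
        out = relax_interior(mapped)
        assert np.allclose(out, base @ A.T + b, atol=1e-8)

    def test_idempotence(self, disk_mesh):
        import dataclasses
        once = relax_interior(disk_mesh)
        relaxed = dataclasses.replace(disk_mesh, interior=once)
        twice = relax_interior(relaxed, x0=once)
        assert np.abs(twice - once).max() < 1e-10

    def test_matches_jacobi_iteration(self):
        from mechanotaxis.mesh import unique_edges
        mesh = build_disk_mesh(6.0, 16, 30, seed=2)
        out = relax_interior(mesh)
        # 1000-iteration Jacobi oracle on the same adjacency
        tri = mesh.full_triangles
        e = unique_edges(tri)
        n = 16 + 30
        nbrs = [[] for _ in range(n)]
        for a, b in e:
            nbrs[a].append(b)
            nbrs[b].append(a)
        pos = mesh.points.copy()
        for _ in range(1000):
            new = pos.copy()
            for i in range(16, n):
                new[i] = pos[nbrs[i]].mean(axis=0)
            pos = new
        assert np.abs(out - pos[16:]).max() < 1e-6

    def test_residual_is_zero_net_spring(self, disk_mesh):
        from mechanotaxis.mesh import unique_edges
        out = relax_interior(disk_mesh)
        pts = np.vstack([disk_mesh.membrane, out])
        e = unique_edges(disk_mesh.full_triangles)
        resid = np.zeros_like(pts)
        for a, b in e:
            resid[a] += pts[b] - pts[a]
            resid[b] += pts[a] - pts[b]
        assert np.abs(resid[disk_mesh.n_membrane:]).max() < 1e-8
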