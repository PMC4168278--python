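"""Stimulation metrics: thresholded volume/depth, Ohm's law, sweeps."""

import numpy as np
import pytest

from sucsim import (
    BoundaryConditions,
    MCTConfig,
    StimulationMetrics,
    convert_mode,
    effective_depth,
    effective_volume,
    estimate_impedance,
    metrics_at,
    output_current_ma,
    solve_potential,
    sweep_metrics,
    total_drive_current,
)
from sucsim.geometry import GM, WM
from sucsim.fem import PotentialSolution

MCT = 2.5


def synthetic_solution(mesh, jmag):
    """Solution carrying only a prescribed |J| field (for metric tests)."""
    m = mesh.num_tets
    return PotentialSolution(
        V=np.zeros(mesh.num_nodes),
        E=np.zeros((m, 3)),
        J=np.zeros((m, 3)),
        jmag=np.asarray(jmag, dtype=float),
        residual=0.0,
        v0=1.0,
    )


class TestEffectiveVolume:
    def test_uniformly_suprathreshold_gives_eligible_volume(self, small_mesh):
        sol = synthetic_solution(small_mesh, np.full(small_mesh.num_tets, 2 * MCT))
        eligible = np.isin(small_mesh.region_labels, [GM, WM])
        expected = small_mesh.tet_volumes()[eligible].sum() * 1e-3
        assert effective_volume(sol, small_mesh) == pytest.approx(expected, rel=1e-12)

    def test_uniformly_subthreshold_gives_zero(self, small_mesh):
        sol = synthetic_solution(small_mesh, np.full(small_mesh.num_tets, 0.9 * MCT))
        assert effective_volume(sol, small_mesh) == 0.0

    def test_threshold_is_inclusive(self, small_mesh):
        sol = synthetic_solution(small_mesh, np.full(small_mesh.num_tets, MCT))
        assert effective_volume(sol, small_mesh) > 0.0

    def test_radial_field_matches_brute_force_enumeration(self, small_mesh, small_spec):
        """|J|(r) = MCT (r0/r)^2 around the contact centre: suprathreshold
        set is the r <= r0 ball; check against per-element enumeration."""
        r0 = 6.0
        center = np.array(
            [0.5 * small_spec.extent_x, 0.5 * small_spec.extent_y, small_spec.extent_z]
        )
        cent = small_mesh.centroids()
        r = np.linalg.norm(cent - center, axis=1)
        jmag = MCT * (r0 / np.maximum(r, 1e-9)) ** 2
        sol = synthetic_solution(small_mesh, jmag)
        got = effective_volume(sol, small_mesh)

        # independent brute-force oracle: python loop over elements
        expected = 0.0
        vols = small_mesh.tet_volumes()
        for e in range(small_mesh.num_tets):
            if small_mesh.region_labels[e] not in (GM, WM):
                continue
            if np.linalg.norm(cent[e] - center) <= r0:
                expected += vols[e]
        assert got == pytest.approx(expected * 1e-3, rel=1e-12)

    def test_monotone_in_threshold(self, small_mesh):
        rng = np.random.default_rng(7)
        sol = synthetic_solution(small_mesh, rng.uniform(0, 5, small_mesh.num_tets))
        vols = [
            effective_volume(sol, small_mesh, MCTConfig(mct=m)) for m in (1.0, 2.5, 4.0)
        ]
        assert vols[0] >= vols[1] >= vols[2]


class TestEffectiveDepth:
    def test_suprathreshold_ball_gives_its_radius(self, small_mesh, small_spec):
        center = np.array(
            [0.5 * small_spec.extent_x, 0.5 * small_spec.extent_y, small_spec.extent_z]
        )
        r = np.linalg.norm(small_mesh.centroids() - center, axis=1)
        sol = synthetic_solution(small_mesh, np.where(r <= 5.0, 2 * MCT, 0.0))
        depth = effective_depth(sol, small_mesh, center)
        # one element diameter of slack at h = 1 mm
        assert depth == pytest.approx(0.5, abs=0.2)

    def test_all_subthreshold_gives_zero(self, small_mesh, small_spec):
        center = (0.5 * small_spec.extent_x, 0.5 * small_spec.extent_y, small_spec.extent_z)
        sol = synthetic_solution(small_mesh, np.zeros(small_mesh.num_tets))
        assert effective_depth(sol, small_mesh, center) == 0.0

    def test_ray_missing_mesh_errors(self, small_mesh):
        sol = synthetic_solution(small_mesh, np.ones(small_mesh.num_tets))
        with pytest.raises(ValueError):
            effective_depth(sol, small_mesh, (-50.0, -50.0, 100.0), (0.0, 0.0, 1.0))

    def test_agrees_with_dense_ray_marching_oracle(self, small_mesh, small_spec):
        """Compare against 0.01 mm marching with independent point location."""
        rng = np.random.default_rng(11)
        cent = small_mesh.centroids()
        jmag = 2.0 + 2.0 * np.sin(cent[:, 0]) * np.cos(0.7 * cent[:, 2]) + rng.normal(
            0, 0.05, small_mesh.num_tets
        )
        center = np.array(
            [0.5 * small_spec.extent_x, 0.5 * small_spec.extent_y, small_spec.extent_z]
        )
        sol = synthetic_solution(small_mesh, jmag)
        got = effective_depth(sol, small_mesh, center)

        # oracle: dense samples + nearest-centroid candidate containment
        from scipy.spatial import cKDTree

        tree = cKDTree(cent)
        direction = np.array([0.0, 0.0, -1.0])
        ts = np.arange(0.0, small_spec.extent_z + 0.01, 0.01)
        pts = center[None, :] + ts[:, None] * direction[None, :]
        _, cands = tree.query(pts, k=24)
        deepest = 0.0
        verts = small_mesh.nodes[small_mesh.tets]
        import numpy.linalg as la

        A = np.concatenate([np.ones((small_mesh.num_tets, 4, 1)), verts], axis=2)
        Ainv = la.inv(np.transpose(A, (0, 2, 1)))
        for t, p, cc in zip(ts, pts, cands):
            lam = Ainv[cc] @ np.concatenate([[1.0], p])
            inside = np.all(lam >= -1e-9, axis=1)
            if not inside.any():
                continue
            e = cc[np.argmax(inside)]
            if jmag[e] >= MCT:
                deepest = t
        h_elem = np.cbrt(6 * small_mesh.tet_volumes().max())
        assert abs(got * 10.0 - deepest) <= 2.0 * h_elem  # mm


class TestOhmsLaw:
    @pytest.mark.parametrize(
        "impedance,printed_ma",
        [(111.7, 8.95), (136.4, 7.33), (89.9, 11.12), (348.4, 2.87)],
    )
    def test_published_impedances_reproduce_printed_currents(self, impedance, printed_ma):
        assert output_current_ma(1.0, impedance) == pytest.approx(printed_ma, abs=0.005)

    def test_impedance_from_current(self):
        assert estimate_impedance(1.0, 8.95e-3) == pytest.approx(111.7, abs=0.05)

    def test_nonpositive_current_rejected(self):
        with pytest.raises(ValueError):
            estimate_impedance(1.0, 0.0)

    def test_metrics_self_consistency_enforced(self):
        with pytest.raises(ValueError):
            StimulationMetrics("voltage", 1.0, 0.0, 0.0, impedance=100.0, output_current=5.0)


class TestConvertAndSweep:
    def test_voltage_mode_doubles_field(self, small_solution):
        sol, _ = small_solution
        assert convert_mode(sol, "voltage", 2.0) == pytest.approx(2.0)

    def test_current_mode_identity(self, small_solution):
        sol, _ = small_solution
        i_1v_ma = 1000.0 * total_drive_current(sol)
        assert convert_mode(sol, "current", i_1v_ma) == pytest.approx(1.0, rel=1e-12)

    def test_current_metrics_equal_voltage_metrics_at_ohms_law_pair(
        self, small_solution, small_mesh
    ):
        sol, patch = small_solution
        i_1v = total_drive_current(sol)
        z = estimate_impedance(1.0, i_1v)
        i_ma = 4.0
        v_equiv = i_ma * z / 1000.0
        m_i = metrics_at(sol, small_mesh, "current", i_ma, patch.center)
        m_v = metrics_at(sol, small_mesh, "voltage", v_equiv, patch.center)
        assert m_i.effective_volume == pytest.approx(m_v.effective_volume, rel=1e-12)
        assert m_i.effective_depth == pytest.approx(m_v.effective_depth, rel=1e-12)

    def test_nonpositive_amplitude_rejected(self, small_solution):
        sol, _ = small_solution
        with pytest.raises(ValueError):
            convert_mode(sol, "voltage", 0.0)

    def test_sweep_columns_monotone_in_amplitude(self, small_solution, small_mesh):
        sol, patch = small_solution
        table = sweep_metrics(sol, small_mesh, patch.center)
        for mode, group in table.groupby("mode"):
            g = group.sort_values("amplitude")
            assert (g["effective_volume_cm3"].diff().dropna() >= 0).all()
            assert (g["effective_depth_cm"].diff().dropna() >= 0).all()

    def test_sweep_rescaling_matches_brute_force_resolve(self, small_solution, small_mesh):
        """Rescaled 1 V solve vs an honest re-solve at 2 V."""
        sol, patch = small_solution
        m2 = metrics_at(sol, small_mesh, "voltage", 2.0, patch.center)
        bc2 = BoundaryConditions(drives=[(patch, 2.0)], reference=sol.bc.reference)
        sol2 = solve_potential(sol.system, bc2)
        v2 = effective_volume(sol2, small_mesh)
        d2 = effective_depth(sol2, small_mesh, patch.center)
        assert m2.effective_volume == pytest.approx(v2, rel=1e-6, abs=1e-9)
        assert m2.effective_depth == pytest.approx(d2, rel=1e-6, abs=1e-9)

    def test_effective_volume_bounded_by_eligible_volume(self, small_solution, small_mesh):
        sol, patch = small_solution
        eligible = np.isin(small_mesh.region_labels, [GM, WM])
        bound = small_mesh.tet_volumes()[eligible].sum() * 1e-3
        table = sweep_metrics(sol, small_mesh, patch.center)
        assert (table["effective_volume_cm3"] <= bound + 1e-12).all()

    def test_grid_sizes_match_protocol(self, small_solution, small_mesh):
        sol, patch = small_solution
        table = sweep_metrics(sol, small_mesh, patch.center)
        assert (table["mode"] == "voltage").sum() == 10
        assert (table["mode"] == "current").sum() == 8
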