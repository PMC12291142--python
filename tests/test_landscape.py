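"""Minima, constrained optimization, NEB paths, MECI and environments."""

import numpy as np
import pytest

from photospawn.landscape import (LandscapeError, StationaryPoint,
                                  compare_environments, find_default_minimum,
                                  neb_mep, optimize_meci, optimize_minimum)
from photospawn.model import ConstantCouplingModel, DiabaticModel, ModelError
from photospawn.units import EV_TO_KCAL


class PolyModel2D(ConstantCouplingModel):
    """One polynomial surface + a far-away spectator (for NEB benchmarks)."""

    def __init__(self, fn, grad, hess):
        self.n_dims = 2
        self.n_diab = 2
        self.pair = (0, 1)
        self.lam = 0.0
        self.masses = np.ones(2)
        self._fn, self._grad, self._hess = fn, grad, hess

    def diabats(self, Q, hessian=False):
        B = len(Q)
        V = np.empty((B, 2))
        dV = np.zeros((B, 2, 2))
        V[:, 0] = self._fn(Q)
        V[:, 1] = 100.0
        dV[:, 0] = self._grad(Q)
        if not hessian:
            return V, dV, None
        d2V = np.zeros((B, 2, 2, 2))
        d2V[:, 0] = self._hess(Q)
        return V, dV, d2V


def _quadratic_bowl(k1=0.8, k2=0.3, c=(1.0, -2.0)):
    c = np.asarray(c)

    def fn(Q):
        return 0.5 * k1 * (Q[:, 0] - c[0]) ** 2 + 0.5 * k2 * (Q[:, 1] - c[1]) ** 2

    def grad(Q):
        g = np.zeros_like(Q)
        g[:, 0] = k1 * (Q[:, 0] - c[0])
        g[:, 1] = k2 * (Q[:, 1] - c[1])
        return g

    def hess(Q):
        H = np.zeros((len(Q), 2, 2))
        H[:, 0, 0] = k1
        H[:, 1, 1] = k2
        return H

    return PolyModel2D(fn, grad, hess)


class TestMinima:
    def test_quadratic_bowl_analytic(self):
        m = _quadratic_bowl()
        pt = optimize_minimum(m, 0, np.array([3.0, 3.0]))
        assert np.allclose(pt.q, [1.0, -2.0], atol=1e-6)
        assert pt.energy == pytest.approx(0.0, abs=1e-8)
        assert all(s > 0 for s in pt.hessian_signs)

    def test_frozen_coordinate_conditional_minimum(self):
        m = _quadratic_bowl()
        pt = optimize_minimum(m, 0, np.array([0.25, 3.0]),
                              constraint_mask=[True, False])
        assert pt.q[0] == 0.25            # held exactly
        assert pt.q[1] == pytest.approx(-2.0, abs=1e-6)

    def test_packaged_basins(self, model):
        gaps = {}
        for lab in ("LE_low", "LE_high", "CT"):
            pt = find_default_minimum(model, lab)
            assert pt.character == lab
            gaps[lab] = pt.gap
        assert 2.5 <= gaps["LE_low"] <= 2.8
        assert gaps["CT"] == pytest.approx(1.0, abs=0.1)
        assert gaps["LE_high"] > gaps["LE_low"]

    def test_post_spawn_snapshots_reach_known_basins(self, model, rng):
        # S1 optimizations from perturbed snapshots converge only to the
        # three packaged basins
        seen = set()
        for lab in ("LE_low", "LE_high", "CT"):
            base = find_default_minimum(model, lab).q
            for _ in range(3):
                q0 = base + rng.normal(0, 0.12, model.n_dims)
                pt = optimize_minimum(model, 1, q0, local_radius=2.0)
                assert pt.character in {"LE_low", "LE_high", "CT"}
                seen.add(pt.character)
        assert seen == {"LE_low", "LE_high", "CT"}

    def test_wrong_dimension_rejected(self, model):
        with pytest.raises(ModelError):
            optimize_minimum(model, 1, np.zeros(3))


class TestNEB:
    def test_harmonic_valley_straight_path(self):
        m = _quadratic_bowl(k1=0.0001, k2=0.5, c=(0.0, 0.0))
        # two "minima" along the nearly flat direction; the MEP is straight
        a = StationaryPoint(np.array([-2.0, 0.0]), 0, 0.0002, 0.0, "LE",
                            (1, 1), None, 0.0)
        b = StationaryPoint(np.array([2.0, 0.0]), 0, 0.0002, 0.0, "LE",
                            (1, 1), None, 0.0)
        path = neb_mep(m, 0, a, b, n_images=10, climbing=False)
        assert np.abs(path.images[:, 1]).max() < 1e-6
        assert path.barrier == pytest.approx(0.0, abs=1e-6)

    def test_quartic_double_well_barrier(self):
        a_, b_ = 0.4, 1.3

        def fn(Q):
            return a_ * (Q[:, 0] ** 2 - b_**2) ** 2 + 0.5 * Q[:, 1] ** 2

        def grad(Q):
            g = np.zeros_like(Q)
            g[:, 0] = 4 * a_ * Q[:, 0] * (Q[:, 0] ** 2 - b_**2)
            g[:, 1] = Q[:, 1]
            return g

        def hess(Q):
            H = np.zeros((len(Q), 2, 2))
            H[:, 0, 0] = 12 * a_ * Q[:, 0] ** 2 - 4 * a_ * b_**2
            H[:, 1, 1] = 1.0
            return H

        m = PolyModel2D(fn, grad, hess)
        lo = optimize_minimum(m, 0, np.array([-b_, 0.1]))
        hi = optimize_minimum(m, 0, np.array([b_, -0.1]))
        path = neb_mep(m, 0, lo, hi, n_images=16, climbing=True)
        assert path.barrier == pytest.approx(a_ * b_**4, rel=0.01)

    def test_image_doubling_invariance(self, model):
        a = find_default_minimum(model, "LE_high")
        b = find_default_minimum(model, "CT")
        p1 = neb_mep(model, 1, a, b, n_images=14)
        p2 = neb_mep(model, 1, a, b, n_images=28)
        assert p2.barrier == pytest.approx(p1.barrier, rel=0.01, abs=2e-4)

    def test_endpoint_surface_mismatch(self, model):
        a = find_default_minimum(model, "LE_low")
        b = find_default_minimum(model, "LE_high")
        bad = StationaryPoint(b.q, 2, b.energy, b.gap, "LE", (1,), None, 0.0)
        with pytest.raises(ModelError):
            neb_mep(model, 1, a, bad)


class TestMECI:
    def test_shifted_paraboloids_closed_form(self):
        # V1 = (x^2+y^2)/2, V2 = ((x-2)^2 + y^2)/2 + 0.1, zero coupling:
        # seam x = (4 - 0.2)/4 = 1.05 - 0.05... solve V1 = V2:
        # x = (4 + 0.2) / 4 = 1.05; minimal mean energy on the seam at y = 0
        def v1(Q):
            return 0.5 * (Q[:, 0] ** 2 + Q[:, 1] ** 2)

        def v2(Q):
            return 0.5 * ((Q[:, 0] - 2.0) ** 2 + Q[:, 1] ** 2) + 0.1

        class TwoParab(ConstantCouplingModel):
            n_dims, n_diab, pair, lam = 2, 2, (0, 1), 0.0
            masses = np.ones(2)

            def diabats(self, Q, hessian=False):
                B = len(Q)
                V = np.column_stack([v1(Q), v2(Q)])
                dV = np.zeros((B, 2, 2))
                dV[:, 0, 0] = Q[:, 0]
                dV[:, 0, 1] = Q[:, 1]
                dV[:, 1, 0] = Q[:, 0] - 2.0
                dV[:, 1, 1] = Q[:, 1]
                d2V = None
                if hessian:
                    d2V = np.zeros((B, 2, 2, 2))
                    d2V[:, :, 0, 0] = 1.0
                    d2V[:, :, 1, 1] = 1.0
                return V, dV, d2V

        m = TwoParab()
        x_seam = 1.05
        meci = optimize_meci(m, 0, 1, np.array([0.8, 0.4]), gap_tol=1e-5)
        assert np.allclose(meci.q, [x_seam, 0.0], atol=1e-4)
        assert meci.mean_energy == pytest.approx(
            0.5 * x_seam**2, abs=1e-6)
        assert meci.residual_gap <= 1e-5

    def test_packaged_model_residual_gap(self, model):
        q0 = np.zeros(model.n_dims)
        ref = float(model.evaluate(q0).energies[2])
        meci = optimize_meci(model, 1, 2, q0, ref_energy=ref)
        assert meci.converged
        assert meci.residual_gap <= 1e-3
        # the seam bottom lies below the vertical S2 energy
        assert meci.e_rel < 0


class TestEnvironments:
    def test_zero_eps_identical(self, model, rng):
        d = model.to_dict()
        d["eps_env"] = 0.0
        m0 = DiabaticModel.from_dict(d)
        ct = find_default_minimum(m0, "CT")
        snaps = [ct.q + rng.normal(0, 0.05, m0.n_dims) for _ in range(4)]
        df, _ = compare_environments(m0, snaps)
        good = df[df["ok"]]
        assert len(good) >= 2
        assert (good["protein_gap"] - good["vacuum_sp_gap"]).abs().max() < 1e-6
        assert (good["protein_character"] == good["vacuum_sp_character"]).all()

    def test_two_level_flip_threshold(self, model):
        # at a geometry where vacuum CT sits just below LE, the S1 character
        # flips from LE (protein) to CT (vacuum) once eps_env exceeds the
        # local diabatic splitting
        from photospawn.model import toggle_environment
        pt = find_default_minimum(model, "LE_high")
        V, _, _ = model.diabats(pt.q[None])
        local_gap = float(V[0, 2] - V[0, 1])   # CT above LE in protein
        assert local_gap > 0
        d = model.to_dict()
        for shrink in (local_gap + 0.1, local_gap - 0.1):
            # vacuum removes eps_env from the CT diabat: the S1 character at
            # this geometry flips exactly when eps_env exceeds the local
            # protein-mode LE/CT splitting
            d["eps_env"] = shrink
            m = DiabaticModel.from_dict(d)
            # rebuild so that protein-mode diabats match the packaged model
            d2 = dict(d)
            d2["ct_e0"] = model.ct_e0 + model.eps_env - shrink
            m = DiabaticModel.from_dict(d2)
            vac_m = toggle_environment(m, "vacuum")
            evp = m.evaluate(pt.q)
            evv = vac_m.evaluate(pt.q)
            char_p = "CT" if evp.weights[1][2] >= evp.weights[1][1] else "LE"
            char_v = "CT" if evv.weights[1][2] >= evv.weights[1][1] else "LE"
            assert char_p == "LE"
            assert char_v == ("CT" if shrink > local_gap else "LE")

    def test_majorities_on_packaged_model(self, model, rng):
        le = find_default_minimum(model, "LE_high")
        lo = find_default_minimum(model, "LE_low")
        ct = find_default_minimum(model, "CT")
        snaps = []
        for base, n in ((le.q, 4), (lo.q, 4), (ct.q, 3)):
            for _ in range(n):
                snaps.append(base + rng.normal(0, 0.08, model.n_dims))
        df, summary = compare_environments(model, snaps)
        assert summary["protein_le_fraction"] > 0.5
        assert summary["vacuum_sp_ct_fraction"] > 0.5
        assert summary["vacuum_opt_ct_fraction"] == 1.0
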