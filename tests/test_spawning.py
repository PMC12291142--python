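"""Frozen-Gaussian machinery, spawning logic, stochastic selection and
population accounting."""

import numpy as np
import pytest

from photospawn.model import InitialCondition, ModelError
from photospawn.spawning import (SpawnBundle, SpawnConfig,
                                 TrajectoryBasisFunction, bootstrap_populations,
                                 make_bundle, overlap, overlap_matrix,
                                 propagate_bundle, make_child,
                                 state_populations, step_amplitudes,
                                 step_centroid, stochastic_select, tbf_weights)
from photospawn.archive import RunArchive
from photospawn.units import HBAR

from oracles import TwoStateModel, linear_crossing, overlap_by_quadrature


def _tbf(i, state, q, p, alpha, gamma=0.0):
    return TrajectoryBasisFunction(id=i, state=state, q=np.atleast_1d(q),
                                   p=np.atleast_1d(p),
                                   alpha=np.atleast_1d(alpha), gamma=gamma)


class TestOverlap:
    def test_identical_is_one(self):
        a = _tbf(0, 0, [0.3, -1.0], [0.5, 0.2], [0.7, 0.3], gamma=0.4)
        assert overlap(a, a) == pytest.approx(1.0)

    def test_closed_form_displacement(self):
        # alpha = 0.5, equal momenta, dq = 2 -> |S| = exp(-alpha dq^2 / 2)
        a = _tbf(0, 0, 0.0, 0.3, 0.5)
        b = _tbf(1, 0, 2.0, 0.3, 0.5)
        assert abs(overlap(a, b)) == pytest.approx(np.exp(-1.0), rel=1e-12)

    def test_matches_quadrature(self, rng):
        for _ in range(8):
            alpha = rng.uniform(0.2, 2.0, 2)
            a = _tbf(0, 0, rng.normal(0, 1, 2), rng.normal(0, 1, 2), alpha,
                     gamma=rng.normal())
            b = _tbf(1, 0, rng.normal(0, 1, 2), rng.normal(0, 1, 2), alpha,
                     gamma=rng.normal())
            assert abs(overlap(a, b) - overlap_by_quadrature(a, b)) < 1e-8

    def test_width_mismatch_rejected(self):
        a = _tbf(0, 0, 0.0, 0.0, 0.5)
        b = _tbf(1, 0, 0.0, 0.0, 0.7)
        with pytest.raises(ModelError):
            overlap(a, b)


class TestCentroidStep:
    def test_harmonic_period(self, model):
        # bath-free variant of the packaged model: S0 is harmonic along q1;
        # recover the period to <= 0.1% over 10 periods
        from photospawn.model import DiabaticModel
        d = model.to_dict()
        d["bath_omegas"] = d["bath_couple"] = d["bath_c"] = []
        d["bath_ct_shift"] = []
        d["mass_q"] = list(d["mass_q"][:2]) if d.get("mass_q") else []
        model = DiabaticModel.from_dict(d)
        om = np.sqrt(model.kg[0] / model.masses[0])
        period = 2 * np.pi / om
        tbf = _tbf(0, 0, np.zeros(model.n_dims), np.zeros(model.n_dims),
                   np.ones(model.n_dims))
        tbf.q[0] = 0.05
        dt = 0.05
        n = int(round(10 * period / dt))
        qs = []
        for _ in range(n):
            tbf, _, _ = step_centroid(tbf, model, dt)
            qs.append(tbf.q[0])
        qs = np.array(qs)
        # measure the period from the autocorrelation peak spacing
        zeros = np.flatnonzero(np.diff(np.sign(qs)) < 0)
        measured = np.mean(np.diff(zeros)) * dt
        assert measured == pytest.approx(period, rel=1e-3)

    def test_flat_surface_uniform_motion(self):
        m = TwoStateModel(lambda x: 0 * x, lambda x: 0 * x + 5.0, 0.0,
                          mass=2.0)
        tbf = _tbf(0, 0, 0.0, 1.2, 0.5)
        e0 = 1.2**2 / 4.0
        for _ in range(100):
            tbf, _, _ = step_centroid(tbf, m, 0.1)
        assert tbf.q[0] == pytest.approx(1.2 / 2.0 * 10.0, rel=1e-12)
        assert tbf.p[0] == pytest.approx(1.2)

    def test_energy_drift_second_order(self, model):
        # anharmonic S1 surface: halving dt reduces the energy error ~4x
        q0 = np.zeros(model.n_dims)
        q0[0] = 1.5
        errs = []
        for dt in (0.4, 0.2):
            tbf = _tbf(0, 1, q0.copy(), np.zeros(model.n_dims),
                       np.ones(model.n_dims))
            ev = model.evaluate(tbf.q)
            e0 = ev.energies[1]
            n = int(round(40.0 / dt))
            worst = 0.0
            for _ in range(n):
                tbf, _, ev1 = step_centroid(tbf, model, dt)
                e = (ev1.energies[0, 1]
                     + (tbf.p**2 / (2 * model.masses)).sum())
                worst = max(worst, abs(e - e0))
            errs.append(worst)
        assert errs[0] / errs[1] > 2.5


class TestAmplitudes:
    def test_single_tbf_constant_modulus(self):
        S = np.eye(1, dtype=complex)
        H = np.array([[1.3 + 0j]])
        Sd = np.zeros((1, 1), dtype=complex)
        bundle = SpawnBundle(model=None, tbfs=[], c=np.array([1.0 + 0j]))
        step_amplitudes(bundle, 10.0, (S, Sd, H), (S, Sd, H), n_substeps=500)
        assert abs(abs(bundle.c[0]) - 1.0) < 1e-6

    def test_rabi_oscillation(self):
        # constant coupling V between two degenerate basis states:
        # complete population transfer after t = pi hbar / (2 V)
        V = 0.02
        S = np.eye(2, dtype=complex)
        H = np.array([[0.0, V], [V, 0.0]], dtype=complex)
        Sd = np.zeros((2, 2), dtype=complex)
        bundle = SpawnBundle(model=None, tbfs=[],
                             c=np.array([1.0 + 0j, 0.0 + 0j]))
        t_half = np.pi * HBAR / (2 * V)
        n = 200
        for _ in range(n):
            step_amplitudes(bundle, t_half / n, (S, Sd, H), (S, Sd, H),
                            n_substeps=5)
        assert abs(bundle.c[1]) ** 2 == pytest.approx(1.0, abs=1e-8)
        assert abs(bundle.c[0]) ** 2 == pytest.approx(0.0, abs=1e-8)


class TestSpawning:
    def test_no_coupling_no_spawns(self):
        m = TwoStateModel(lambda x: 0.05 * x, lambda x: -0.05 * x, 0.0,
                          mass=50.0)
        ic = InitialCondition([-10.0], [10.0], state=1)
        cfg = SpawnConfig(dt=0.25, horizon=50.0)
        arch = propagate_bundle(make_bundle(m, ic, cfg), cfg)
        assert not any(e["type"] == "spawn" for e in arch.events)
        assert arch.populations[-1][1] == pytest.approx(1.0, abs=1e-9)

    def test_downhill_child_conserves_energy(self):
        m = linear_crossing(0.05, -0.05, 0.02, mass=50.0)
        parent = _tbf(0, 1, 0.0, 10.0, 3.0)
        dvec = np.array([1.0])
        child = make_child(m, parent, (parent.q, parent.p, 0.0, 0, dvec, 0.0),
                           child_id=1)
        e_par = (m.evaluate(parent.q).energies[1]
                 + (parent.p**2 / (2 * m.masses)).sum())
        e_ch = (m.evaluate(child.q).energies[0]
                + (child.p**2 / (2 * m.masses)).sum())
        assert e_ch == pytest.approx(e_par, abs=1e-8)

    def test_upward_spawn_rejected_without_kinetic_energy(self):
        m = linear_crossing(0.05, -0.05, 0.02, mass=50.0)
        parent = _tbf(0, 0, -10.0, 0.5, 3.0)  # lower state, tiny momentum
        dvec = np.array([1.0])
        child = make_child(m, parent, (parent.q, parent.p, 0.0, 1, dvec, 0.0),
                           child_id=1)
        assert child is None


class TestSelection:
    def _two_group_bundle(self, w1=0.7, seed=0):
        alpha = np.array([0.5])
        a = _tbf(0, 0, 0.0, 0.0, alpha)
        b = _tbf(1, 0, 50.0, 0.0, alpha)   # far away: decoupled
        c = np.array([np.sqrt(w1), np.sqrt(1 - w1)], dtype=complex)
        return SpawnBundle(model=None, tbfs=[a, b], c=c,
                           rng=np.random.default_rng(seed))

    def test_single_component_unchanged(self):
        alpha = np.array([0.5])
        a = _tbf(0, 0, 0.0, 0.0, alpha)
        b = _tbf(1, 0, 0.5, 0.0, alpha)
        bundle = SpawnBundle(model=None, tbfs=[a, b],
                             c=np.array([0.8 + 0j, 0.6 + 0j]),
                             rng=np.random.default_rng(0))
        _, did = stochastic_select(bundle, SpawnConfig())
        assert not did
        assert all(t.alive for t in bundle.tbfs)

    def test_selection_frequencies_binomial(self):
        n, w1 = 1000, 0.7
        hits = 0
        for k in range(n):
            bundle = self._two_group_bundle(w1, seed=k)
            stochastic_select(bundle, SpawnConfig())
            if bundle.tbfs[0].alive:
                hits += 1
        sigma = np.sqrt(n * w1 * (1 - w1))
        assert abs(hits - n * w1) < 3 * sigma

    def test_renormalized_to_unit_population(self):
        bundle = self._two_group_bundle(0.3, seed=5)
        stochastic_select(bundle, SpawnConfig())
        pops = state_populations(bundle, n_states=2)
        assert pops.sum() == pytest.approx(1.0, abs=1e-12)


class TestPopulations:
    def test_orthogonal_tbfs_square_moduli(self):
        alpha = np.array([0.5])
        tbfs = [_tbf(0, 0, 0.0, 0.0, alpha), _tbf(1, 1, 40.0, 0.0, alpha)]
        c = np.array([0.6 + 0j, 0.8 + 0j])
        bundle = SpawnBundle(model=None, tbfs=tbfs, c=c)
        pops = state_populations(bundle, n_states=2)
        assert pops[0] == pytest.approx(0.36, abs=1e-10)
        assert pops[1] == pytest.approx(0.64, abs=1e-10)
        assert pops.sum() == pytest.approx(1.0, abs=1e-10)

    def test_overlapping_pair_quadratic_form(self):
        alpha = np.array([0.5])
        a = _tbf(0, 0, 0.0, 0.0, alpha)
        b = _tbf(1, 0, 1.0, 0.0, alpha)
        ca, cb = 0.5 + 0.1j, 0.3 - 0.2j
        bundle = SpawnBundle(model=None, tbfs=[a, b], c=np.array([ca, cb]))
        S = overlap(a, b)
        expect = (abs(ca) ** 2 + abs(cb) ** 2
                  + 2 * np.real(np.conj(ca) * S * cb))
        pops = state_populations(bundle, n_states=1)
        assert pops[0] == pytest.approx(expect, abs=1e-12)


def _toy_archive(pop_curve, ic_id):
    T = len(pop_curve)
    pops = np.zeros((T, 3))
    pops[:, 2] = pop_curve
    pops[:, 1] = 1 - pop_curve
    z = np.zeros((T, 1))
    return RunArchive(
        times=np.arange(T, dtype=float), populations=pops, norm=np.ones(T),
        tbf_q=np.zeros((T, 1, 1)), tbf_p=np.zeros((T, 1, 1)),
        tbf_state=np.ones((T, 1), dtype=int), tbf_weight=np.ones((T, 1)),
        tbf_dipole=z + 30.0, tbf_donor=z, tbf_gap=z + 1.0, tbf_energy=z,
        tbf_parent=np.array([-1]), tbf_spawn_time=np.zeros(1),
        meta={"ic_id": ic_id})


class TestBootstrap:
    def test_identical_runs_zero_band(self):
        curve = np.exp(-np.arange(20) / 3.0)
        runs = [_toy_archive(curve, i) for i in range(4)]
        out = bootstrap_populations(runs, n_boot=200, seed=1)
        assert np.allclose(out.lower[2], out.upper[2])
        assert np.allclose(out.mean[2], curve)

    def test_two_extreme_runs(self):
        runs = [_toy_archive(np.zeros(5), 0), _toy_archive(np.ones(5), 1)]
        out = bootstrap_populations(runs, n_boot=2000, seed=2, level=0.999)
        assert np.allclose(out.mean[2], 0.5)
        assert np.allclose(out.lower[2], 0.0)
        assert np.allclose(out.upper[2], 1.0)

    def test_coverage_near_nominal(self):
        # synthetic per-IC curves with known mean: the 95% band should
        # cover the truth at roughly the nominal rate
        rng = np.random.default_rng(7)
        cover = 0
        reps = 400
        for _ in range(reps):
            runs = [_toy_archive(np.full(3, np.clip(rng.normal(0.5, 0.1),
                                                    0, 1)), i)
                    for i in range(12)]
            out = bootstrap_populations(runs, n_boot=300,
                                        seed=int(rng.integers(2**31)))
            if out.lower[2][0] <= 0.5 <= out.upper[2][0]:
                cover += 1
        assert 0.85 <= cover / reps <= 0.99


def test_seed_determinism_bit_identical(model, fc300):
    ics = [fc300[0], fc300[1]]
    for ic in ics:
        ic = ic
    sel = [InitialCondition(ic.q, ic.p, state=2) for ic in ics]
    from photospawn.spawning import run_ssaims
    cfg = SpawnConfig(horizon=20.0)
    a = run_ssaims(sel, model, cfg, runs_per_ic=1, base_seed=3)
    b = run_ssaims(sel, model, cfg, runs_per_ic=1, base_seed=3)
    for x, y in zip(a, b):
        assert np.array_equal(x.populations, y.populations)
        assert np.array_equal(x.tbf_q, y.tbf_q, equal_nan=True)
        assert x.events == y.events
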