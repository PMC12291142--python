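"""Electronic-structure evaluation, environment toggle, FC sampling and
calibration plumbing of the diabatic model."""

import numpy as np
import pytest

from photospawn.model import (CalibrationError, Constraint, DiabaticModel,
                              ModelError, calibrate_model, default_model,
                              eval_electronic_structure,
                              evaluate_constraints, sample_fc_ensemble,
                              toggle_environment)
from photospawn.units import KB

from oracles import TwoStateModel


def test_adiabatic_ordering_and_weights(model, rng):
    Q = rng.normal(0.0, 2.0, (200, model.n_dims))
    out = model.evaluate_batch(Q)
    assert np.all(np.diff(out.energies, axis=1) >= 0)
    # weights are a partition of unity per state
    assert np.allclose(out.weights.sum(axis=2), 1.0, atol=1e-12)
    # donor charge equals the CT weight
    assert np.allclose(out.donor_charge, out.weights[:, :, 2])


def test_uncoupled_degeneracy_and_splitting():
    # flat degenerate diabats: splitting 0 without coupling, 2*lam with
    m0 = TwoStateModel(lambda x: 0.0 * x, lambda x: 0.0 * x, 0.0)
    ev = m0.evaluate(np.zeros(1))
    assert ev.energies[1] - ev.energies[0] == pytest.approx(0.0, abs=1e-14)
    assert ev.singular  # coupling flagged at the exact degeneracy
    m1 = TwoStateModel(lambda x: 0.0 * x, lambda x: 0.0 * x, 0.05)
    ev = m1.evaluate(np.zeros(1))
    assert ev.energies[1] - ev.energies[0] == pytest.approx(0.10, abs=1e-12)


def test_ct_asymptote(model):
    # deep in the CT well the S1 dipole approaches the CT diabat value
    q = np.zeros(model.n_dims)
    q[0], q[1] = model.ct_center
    if model.n_dims > 2:
        q[2:] = model._bc * q[[0, 1]][model._bm] + model._bshift
    ev = model.evaluate(q)
    assert abs(ev.dipoles[1] - model.mu_ct) / model.mu_ct < 0.01
    assert ev.donor_charge[1] > 0.99


def test_gradients_match_finite_differences(model, rng):
    Q = rng.normal(0.0, 1.5, (100, model.n_dims))
    out = model.evaluate_batch(Q)
    h = 2e-5
    for k in range(model.n_dims):
        dq = np.zeros(model.n_dims)
        dq[k] = h
        fd = (model.evaluate_batch(Q + dq).energies
              - model.evaluate_batch(Q - dq).energies) / (2 * h)
        assert np.abs(fd - out.gradients[:, :, k]).max() < 1e-6


def test_nac_antisymmetry_and_cap(model, rng):
    Q = rng.normal(0.0, 1.5, (50, model.n_dims))
    out = model.evaluate_batch(Q)
    d12 = out.nac_between(1, 2)
    d21 = out.nac_between(2, 1)
    assert np.allclose(d12, -d21)
    assert np.all(np.linalg.norm(out.nac, axis=1) <= model.nac_cap + 1e-9)


def test_dimension_mismatch_rejected(model):
    with pytest.raises(ModelError):
        eval_electronic_structure(model, np.zeros(model.n_dims + 1))


def test_environment_toggle(model, rng):
    vac = toggle_environment(model, "vacuum")
    prot = toggle_environment(vac, "protein")
    Q = rng.normal(0.0, 2.0, (50, model.n_dims))
    Vv, _, _ = vac.diabats(Q)
    Vp, _, _ = prot.diabats(Q)
    # only the CT diabat shifts, by exactly eps_env, at every geometry
    assert np.allclose(Vp[:, 2] - Vv[:, 2], model.eps_env)
    assert np.allclose(Vp[:, :2], Vv[:, :2])
    # ground-state properties are mode-invariant
    assert np.allclose(vac.evaluate_batch(Q).energies[:, 0],
                       prot.evaluate_batch(Q).energies[:, 0])
    with pytest.raises(ModelError):
        toggle_environment(model, "gas")


def test_environment_shift_bounded_in_adiabats(model, rng):
    # the CT-dominant adiabat rises by at most eps_env under the toggle
    vac = toggle_environment(model, "vacuum")
    Q = rng.normal(0.0, 2.0, (50, model.n_dims))
    ep = model.evaluate_batch(Q).energies
    ev = vac.evaluate_batch(Q).energies
    diff = ep - ev
    assert np.all(diff >= -1e-10)
    assert np.all(diff <= model.eps_env + 1e-10)


def test_zero_eps_env_identical():
    d = default_model().to_dict()
    d["eps_env"] = 0.0
    m = DiabaticModel.from_dict(d)
    v = toggle_environment(m, "vacuum")
    Q = np.random.default_rng(0).normal(0, 2, (20, m.n_dims))
    assert np.allclose(m.evaluate_batch(Q).energies,
                       v.evaluate_batch(Q).energies)


def test_fc_sampler_equipartition(model):
    ics = sample_fc_ensemble(model, 10000, 300.0, seed=4)
    Q = np.array([ic.q for ic in ics])
    P = np.array([ic.p for ic in ics])
    kT = KB * 300.0
    # position variance of the reaction coordinates matches kT/k (the
    # bath-coupled marginals integrate out exactly for the harmonic S0)
    for dim, k in zip((0, 1), model.kg):
        assert Q[:, dim].var() == pytest.approx(kT / k, rel=0.05)
    # kinetic energy per degree of freedom
    ke = (P**2 / (2 * model.masses)).mean(axis=0)
    assert np.allclose(ke, kT / 2, rtol=0.06)


def test_fc_sampler_seed_reproducible(model):
    a = sample_fc_ensemble(model, 20, 300.0, seed=9)
    b = sample_fc_ensemble(model, 20, 300.0, seed=9)
    for x, y in zip(a, b):
        assert np.array_equal(x.q, y.q) and np.array_equal(x.p, y.p)
    c = sample_fc_ensemble(model, 20, 300.0, seed=10)
    assert not np.array_equal(a[0].q, c[0].q)


def test_fc_sampler_input_validation(model):
    with pytest.raises(ModelError):
        sample_fc_ensemble(model, 0, 300.0, seed=1)
    with pytest.raises(ModelError):
        sample_fc_ensemble(model, 5, -10.0, seed=1)


def test_model_roundtrip(tmp_path, model):
    path = tmp_path / "m.toml"
    model.to_toml(path)
    again = DiabaticModel.from_toml(path)
    Q = np.random.default_rng(1).normal(0, 1, (10, model.n_dims))
    assert np.allclose(model.evaluate_batch(Q).energies,
                       again.evaluate_batch(Q).energies)
    with pytest.raises(ModelError):
        DiabaticModel.from_dict({"no_such_param": 1.0})


def test_calibrate_single_offset_exact():
    # one constraint, one linear parameter: solved essentially exactly
    m = default_model()
    ev0 = m.evaluate(np.zeros(m.n_dims))
    target = float(ev0.energies[2] - ev0.energies[0]) + 0.1
    fitted = calibrate_model(
        [Constraint("vertical_gap_s2", target, 1e-5)],
        model=m, free_params=("ct_e0",), max_iter=300)
    ev = fitted.evaluate(np.zeros(fitted.n_dims))
    assert ev.energies[2] - ev.energies[0] == pytest.approx(target, abs=1e-4)


def test_calibrate_contradictory_constraints_fail():
    with pytest.raises(CalibrationError) as err:
        calibrate_model(
            [Constraint("vertical_gap_s2", 1.0, 0.01),
             Constraint("vertical_gap_s2", 3.0, 0.01)],
            free_params=("ct_e0",), max_iter=60)
    assert err.value.residuals


def test_default_constraints_satisfied(model):
    # direct re-evaluation of the shipped parameter set against the static
    # calibration targets, independently of any optimizer
    constraints = [
        Constraint("gap_le_low", 2.65, 0.15),
        Constraint("gap_ct", 1.0, 0.1),
        Constraint("barrier_le_low_le_high", 6.0, 0.5),
        Constraint("barrier_le_high_ct", 0.6, 0.2),
        Constraint("barrier_ct_le_high", 5.0, 0.0, kind="ge"),
    ]
    res = evaluate_constraints(model, constraints)
    assert all(ok for _, ok in res.values()), res
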