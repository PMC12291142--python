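"""Frozen-Gaussian multiple-spawning propagator with stochastic selection.

The nuclear wavefunction on each electronic state is expanded in trajectory
basis functions (TBFs): frozen Gaussians whose centroids follow classical
trajectories on the occupied adiabatic surface.  When a TBF traverses a
region of strong nonadiabatic coupling (|d_IJ . v| above threshold) a child
TBF is spawned on the partner state at the coupling maximum, and the complex
amplitudes are propagated by the time-dependent Schroedinger equation in the
moving, nonorthogonal TBF basis.

Stochastic selection (the overlap-based flavor): whenever the live TBFs
split into groups that are mutually decoupled (negligible overlap and
off-diagonal Hamiltonian), one group is drawn with probability equal to its
Mulliken population, the others are discarded, and the survivor is
renormalized to unit population.  Averaging over selection seeds recovers
the fully coupled multiple-spawning dynamics at a bounded basis size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.sparse.csgraph import connected_components
from scipy.sparse import csr_matrix

from .archive import RunArchive
from .model import InitialCondition, ModelError
from .units import HBAR

__all__ = [
    "TrajectoryBasisFunction", "SpawnBundle", "SpawnConfig",
    "PopulationCurve", "PropagationError", "SelectionError",
    "overlap", "overlap_matrix", "step_centroid", "step_amplitudes",
    "check_spawn", "stochastic_select", "state_populations", "run_ssaims",
    "bootstrap_populations", "default_widths",
]

log = logging.getLogger(__name__)


class PropagationError(RuntimeError):
    pass


class SelectionError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# TBFs and bundles
# ---------------------------------------------------------------------------


@dataclass
class TrajectoryBasisFunction:
    """One frozen-Gaussian basis element.

    chi(x) = prod_k (2 a_k / pi)^(1/4)
             exp(-a_k (x_k - q_k)^2 + i p_k (x_k - q_k) / hbar) * exp(i g / hbar)
    """

    id: int
    state: int
    q: np.ndarray
    p: np.ndarray
    alpha: np.ndarray
    gamma: float = 0.0
    parent: int = -1
    t_spawn: float = 0.0
    alive: bool = True
    # spawn-monitor state
    armed: bool = False
    blocked: bool = False
    best_lambda: float = 0.0
    best_snapshot: tuple | None = None
    last_spawn_t: float = -1e30

    def __post_init__(self):
        self.q = np.asarray(self.q, dtype=float)
        self.p = np.asarray(self.p, dtype=float)
        self.alpha = np.asarray(self.alpha, dtype=float)
        if np.any(self.alpha <= 0):
            raise ModelError("Gaussian widths must be positive")


def default_widths(model, scale=5.5):
    """Frozen-Gaussian widths a_k = scale * m_k w_k / (2 hbar).

    The base value is the ground-state width of each harmonic S0 mode; the
    default scale narrows the basis functions relative to that, which
    benchmarks against exact grid propagation show is needed to resolve the
    narrow coupling zones of this model's crossing seams."""
    H = model.evaluate_batch(np.zeros((1, model.n_dims)), hessian=True).hessians[0][0]
    k = np.maximum(np.diag(H), 1e-6)
    om = np.sqrt(k / model.masses)
    return scale * model.masses * om / (2.0 * HBAR)


@dataclass
class SpawnConfig:
    dt: float = 0.25                 # fs, nuclear step
    horizon: float = 500.0           # fs
    n_substeps: int = 10             # electronic sub-steps per nuclear step
    spawn_threshold: float = 0.01    # fs^-1, effective coupling |d.v|
    spawn_drop: float = 0.25         # fractional drop off the maximum
    overlap_threshold: float = 1e-3  # decoupling |S_ab|
    h_threshold: float = 1e-7        # decoupling |H_ab| (eV)
    max_tbfs: int = 10
    spawn_mode: str = "peak"         # "peak": spawn at the local coupling
                                     # maximum and rewind the bundle to the
                                     # entry of the region; "entry": spawn
                                     # directly on entering it
    gap_spawn_max: float = 0.2       # eV, gap gate for entry-mode spawning
    spawn_cooldown: float = 2.0      # fs, per-TBF pause between entry spawns
    rewind_span: float = 10.0        # fs of history kept for spawn rewinds
    rewind_pre: float = 1.0          # fs rewound before the arming time
    width_scale: float = 5.5         # TBF width scale (see default_widths)
    child_overlap_max: float = 0.9   # skip spawns nearly parallel to a live TBF
    record_stride: int = 2
    cond_max: float = 1e8            # overlap condition number before Tikhonov
    select_every: int = 1            # steps between decoupling checks
    gap_refine: float = 0.4          # eV; refine the nuclear step when any
                                     # TBF's pair gap is below this
    refine_factor: int = 5           # micro-steps per refined nuclear step
    min_weight_spawn: float = 0.02   # parents below this weight do not spawn
    prune_weight: float = 0.05       # drop TBFs persistently below this weight
    prune_after: float = 30.0        # fs a TBF may stay below prune_weight
    merge_overlap: float = 0.6       # coalesce same-state TBFs above this |S|
    merge_after: float = 50.0        # fs before coalescence switches on


@dataclass
class SpawnBundle:
    model: object
    tbfs: list
    c: np.ndarray                   # complex amplitudes of *live* TBFs
    time: float = 0.0
    rng: np.random.Generator = None
    run_seed: int | None = None
    ic_id: int | None = None
    events: list = field(default_factory=list)

    @property
    def live(self):
        return [t for t in self.tbfs if t.alive]

    def amplitude_index(self, tbf):
        return self.live.index(tbf)


# ---------------------------------------------------------------------------
# Gaussian matrix elements
# ---------------------------------------------------------------------------


def _pair_params(Qa, Pa, Ga, Qb, Pb, Gb, alpha):
    """Complex pairwise quantities for frozen-Gaussian integrals.

    Inputs are (N, d) arrays (bra a, ket b) and shared widths (d,).
    Returns nuclear overlap S_nuc (N, N) and the complex product-Gaussian
    center z0 (N, N, d).
    """
    dq = Qb[None, :, :] - Qa[:, None, :]
    dp = Pb[None, :, :] - Pa[:, None, :]
    Pm = 0.5 * (Pa[:, None, :] + Pb[None, :, :])
    Qm = 0.5 * (Qa[:, None, :] + Qb[None, :, :])
    expo = (-0.5 * alpha * dq**2 - dp**2 / (8.0 * alpha * HBAR**2)
            - 1j * Pm * dq / HBAR).sum(axis=2)
    # widths alpha here are the exponent parameters a_k of each Gaussian;
    # the product Gaussian has center z0 with an imaginary momentum shift
    z0 = Qm + 1j * dp / (4.0 * alpha[None, None, :] * HBAR)
    phase = (Gb[None, :] - Ga[:, None]) / HBAR
    S = np.exp(expo + 1j * phase)
    return S, z0


def overlap(a: TrajectoryBasisFunction, b: TrajectoryBasisFunction):
    """Closed-form overlap <a|b> of two frozen Gaussians (same widths)."""
    if a.q.shape != b.q.shape:
        raise ModelError("TBF dimensionalities differ")
    if not np.allclose(a.alpha, b.alpha):
        raise ModelError("TBF widths differ")
    S, _ = _pair_params(a.q[None], a.p[None], np.array([a.gamma]),
                        b.q[None], b.p[None], np.array([b.gamma]), a.alpha)
    return complex(S[0, 0])


def overlap_matrix(tbfs, with_state_delta=True):
    if not tbfs:
        return np.zeros((0, 0), dtype=complex)
    alpha = tbfs[0].alpha
    Q = np.array([t.q for t in tbfs])
    P = np.array([t.p for t in tbfs])
    G = np.array([t.gamma for t in tbfs])
    S, _ = _pair_params(Q, P, G, Q, P, G, alpha)
    if with_state_delta:
        st = np.array([t.state for t in tbfs])
        S = np.where(st[:, None] == st[None, :], S, 0.0)
    return S


def _bundle_matrices(bundle: SpawnBundle, config: SpawnConfig, ev=None):
    """Overlap S, its time derivative Sdot, and Hamiltonian H for live TBFs.

    Potential elements use the bra-ket-averaged second-order (saddle-point)
    expansion about the two centroids; interstate elements use the
    nonadiabatic coupling at the centroid midpoint contracted with the
    momentum operator.
    """
    model = bundle.model
    tbfs = bundle.live
    N = len(tbfs)
    d = model.n_dims
    alpha = tbfs[0].alpha
    masses = model.masses
    Q = np.array([t.q for t in tbfs])
    P = np.array([t.p for t in tbfs])
    G = np.array([t.gamma for t in tbfs])
    st = np.array([t.state for t in tbfs])

    Snuc, z0 = _pair_params(Q, P, G, Q, P, G, alpha)
    same = st[:, None] == st[None, :]
    S = np.where(same, Snuc, 0.0)

    if ev is None or getattr(ev, "hessians", None) is None:
        ev = model.evaluate_batch(Q, hessian=True)
    E = ev.energies[np.arange(N), st]
    grad = ev.gradients[np.arange(N), st]    # (N, d)
    hess = ev.hessians[np.arange(N), st]     # (N, d, d)

    # --- moments (ratios to S_nuc) -------------------------------------
    # <p_k> / S for ket b
    pk = P[None, :, :] + 2j * HBAR * alpha * (z0 - Q[None, :, :])
    # <p_k^2> / S
    pk2 = (alpha * HBAR**2 + P[None, :, :] ** 2
           + 4j * HBAR * alpha * P[None, :, :] * (z0 - Q[None, :, :])
           - 4.0 * HBAR**2 * alpha**2 * (z0 - Q[None, :, :]) ** 2)
    T = (pk2 / (2.0 * masses)).sum(axis=2)   # kinetic ratio

    # --- same-state potential: bra-ket averaged 2nd-order Taylor -------
    def quad_about(center, gval, gvec, hmat, which):
        # center: (N, d) expansion points belonging to bra (axis 0) or ket
        if which == "bra":
            c = center[:, None, :]
            g = gvec[:, None, :]
            h = hmat[:, None, :, :]
            v0 = gval[:, None]
        else:
            c = center[None, :, :]
            g = gvec[None, :, :]
            h = hmat[None, :, :, :]
            v0 = gval[None, :]
        dz = z0 - c
        lin = (g * dz).sum(axis=2)
        quad_diag = (np.einsum("...kk->...k", h) / (4.0 * alpha)).sum(axis=2)
        quad_full = np.einsum("abk,abkl,abl->ab", dz, np.broadcast_to(
            h, (z0.shape[0], z0.shape[1], d, d)), dz)
        return v0 + lin + 0.5 * (quad_full + quad_diag)

    Vavg = 0.5 * (quad_about(Q, E, grad, hess, "bra")
                  + quad_about(Q, E, grad, hess, "ket"))
    H = np.where(same, Snuc * (T + Vavg), 0.0)

    # --- interstate (nonadiabatic) elements ----------------------------
    diff = ~same & (np.abs(Snuc) > 1e-10)
    iu, ju = np.nonzero(diff)
    if len(iu):
        mids = 0.5 * (Q[iu] + Q[ju])
        mev = model.evaluate_batch(mids, light=True)
        for n, (a, b) in enumerate(zip(iu, ju)):
            i_s, j_s = st[a], st[b]
            dvec = np.zeros(d)
            if {i_s, j_s} == {int(mev.pair_lo[n]), int(mev.pair_up[n])}:
                dvec = mev.nac[n] if (i_s == mev.pair_lo[n]) else -mev.nac[n]
                # dvec = d_{I_a, I_b}
            H[a, b] = -1j * HBAR * Snuc[a, b] * (
                dvec / masses * pk[a, b]).sum()
    H = 0.5 * (H + H.conj().T)

    # --- Sdot: <a | d/dt b> --------------------------------------------
    qdot = P / masses
    pdot = -grad
    gdot = (P**2 / (2.0 * masses)).sum(axis=1) - E
    dq_b = 2.0 * alpha * (z0 - Q[None, :, :]) - 1j * P[None, :, :] / HBAR
    dp_b = 1j * (z0 - Q[None, :, :]) / HBAR
    Sdot = Snuc * ((qdot[None, :, :] * dq_b).sum(axis=2)
                   + (pdot[None, :, :] * dp_b).sum(axis=2)
                   + 1j * gdot[None, :] / HBAR)
    Sdot = np.where(same, Sdot, 0.0)
    return S, Sdot, H, ev


# ---------------------------------------------------------------------------
# propagation
# ---------------------------------------------------------------------------


def step_centroid(tbf: TrajectoryBasisFunction, model, dt, force=None,
                  energy=None):
    """Velocity-Verlet step on the TBF's surface; advances the phase by the
    classical Lagrangian increment (trapezoidal)."""
    if not tbf.alive:
        raise PropagationError(f"TBF {tbf.id} is dead")
    if dt <= 0:
        raise ModelError("dt must be positive")
    m = model.masses
    if force is None or energy is None:
        ev0 = model.evaluate_batch(tbf.q[None])
        force = -ev0.gradients[0, tbf.state]
        energy = ev0.energies[0, tbf.state]
    lag0 = (tbf.p**2 / (2 * m)).sum() - energy
    p_half = tbf.p + 0.5 * dt * force
    q_new = tbf.q + dt * p_half / m
    ev1 = model.evaluate_batch(q_new[None])
    f_new = -ev1.gradients[0, tbf.state]
    p_new = p_half + 0.5 * dt * f_new
    e1 = ev1.energies[0, tbf.state]
    lag1 = (p_new**2 / (2 * m)).sum() - e1
    out = replace(tbf, q=q_new, p=p_new,
                  gamma=tbf.gamma + 0.5 * dt * (lag0 + lag1))
    out.best_snapshot = tbf.best_snapshot
    return out, f_new, ev1


def step_amplitudes(bundle: SpawnBundle, dt, mats0, mats1, n_substeps=20,
                    cond_max=1e8):
    """Advance amplitudes through one nuclear step.

    RK4 on i hbar (S cdot + Sdot c) = H c with (S, Sdot, H) linearly
    interpolated between the matrices at the step endpoints; the overlap is
    Tikhonov-regularized when ill-conditioned.
    """
    c = bundle.c.astype(complex)
    S0, Sd0, H0 = mats0
    S1, Sd1, H1 = mats1
    h = dt / n_substeps
    reg = 0.0
    cond = np.linalg.cond(S1) if len(S1) > 1 else 1.0
    if cond > cond_max:
        log.warning("ill-conditioned overlap (cond=%.2e); regularizing", cond)
        reg = 1e-10

    def deriv(c, f):
        S = S0 + f * (S1 - S0)
        Sd = Sd0 + f * (Sd1 - Sd0)
        H = H0 + f * (H1 - H0)
        rhs = (-1j / HBAR) * (H @ c) - Sd @ c
        if reg:
            S = S + reg * np.eye(len(S))
        return np.linalg.solve(S, rhs)

    t = 0.0
    for _ in range(n_substeps):
        f0 = t / dt
        fm = (t + 0.5 * h) / dt
        f1 = (t + h) / dt
        k1 = deriv(c, f0)
        k2 = deriv(c + 0.5 * h * k1, fm)
        k3 = deriv(c + 0.5 * h * k2, fm)
        k4 = deriv(c + h * k3, f1)
        c = c + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        t += h
    bundle.c = c
    return bundle


def state_populations(bundle: SpawnBundle, n_states=None, S=None):
    """Mulliken population per electronic state: sum_ab Re(c_a* S_ab c_b)."""
    tbfs = bundle.live
    if n_states is None:
        n_states = bundle.model.n_diab
    pops = np.zeros(n_states)
    if not tbfs:
        return pops
    if S is None:
        S = overlap_matrix(tbfs)
    c = bundle.c
    M = np.real(np.conj(c)[:, None] * S * c[None, :])
    st = np.array([t.state for t in tbfs])
    for s in range(n_states):
        sel = st == s
        pops[s] = M[np.ix_(sel, sel)].sum()
    return pops


def tbf_weights(bundle: SpawnBundle, S=None):
    """Per-TBF Mulliken weight Re(c_a* sum_b S_ab c_b) for live TBFs."""
    tbfs = bundle.live
    if not tbfs:
        return np.zeros(0)
    if S is None:
        S = overlap_matrix(tbfs)
    return np.real(np.conj(bundle.c) * (S @ bundle.c))


# ---------------------------------------------------------------------------
# spawning
# ---------------------------------------------------------------------------


def effective_coupling(model, tbf, precomputed=None):
    """Lambda = |d_IJ . v| (fs^-1) and the partner state at the centroid.

    ``precomputed`` may carry (pair_lo, pair_up, nac_vector) from a batched
    evaluation at the TBF's geometry to avoid re-evaluation."""
    if precomputed is None:
        out = model.evaluate_batch(tbf.q[None])
        lo, up, nac = int(out.pair_lo[0]), int(out.pair_up[0]), out.nac[0]
    else:
        lo, up, nac = precomputed
    if tbf.state == lo:
        partner, dvec = up, nac
    elif tbf.state == up:
        partner, dvec = lo, -nac
    else:
        return 0.0, None, None
    lam = abs(float((dvec * tbf.p / model.masses).sum()))
    return lam, partner, dvec


def check_spawn(tbf: TrajectoryBasisFunction, model, config: SpawnConfig,
                time=0.0, precomputed=None, gap=None):
    """Update the spawn monitor of one TBF; return a spawn decision or None.

    Arms when the effective coupling exceeds the threshold, tracks its
    maximum, and triggers at the local maximum (detected by a fractional
    drop); the returned decision carries the phase-space point of the
    maximum so the child can be placed there.
    """
    if not tbf.alive:
        raise PropagationError(f"TBF {tbf.id} is dead")
    lam, partner, dvec = effective_coupling(model, tbf, precomputed)
    if partner is None:
        return None
    if tbf.blocked:
        if lam < config.spawn_threshold:
            tbf.blocked = False
            return None
        if (config.spawn_mode == "peak" and partner is not None
                and time - tbf.last_spawn_t >= config.spawn_cooldown):
            # an upper-state TBF lingering in the coupling region keeps
            # feeding children (downward flux); lower-state TBFs transfer
            # their character adiabatically and need no trains
            if gap is None:
                out = model.evaluate_batch(tbf.q[None])
                lo, up = int(out.pair_lo[0]), int(out.pair_up[0])
                gap = float(out.energies[0, up] - out.energies[0, lo])
            lo_partner = partner < tbf.state
            if gap <= config.gap_spawn_max and lo_partner:
                tbf.last_spawn_t = time
                return (tbf.q.copy(), tbf.p.copy(), tbf.gamma, partner,
                        dvec.copy(), time, time)
        return None
    if gap is None:
        out = model.evaluate_batch(tbf.q[None])
        lo, up = int(out.pair_lo[0]), int(out.pair_up[0])
        gap = float(out.energies[0, up] - out.energies[0, lo])
    if config.spawn_mode == "entry":
        # stateless trigger with a per-TBF cooldown; duplicate children are
        # suppressed downstream by the child-overlap check
        if (lam > config.spawn_threshold and gap <= config.gap_spawn_max
                and time - tbf.last_spawn_t >= config.spawn_cooldown):
            tbf.last_spawn_t = time
            return (tbf.q.copy(), tbf.p.copy(), tbf.gamma, partner,
                    dvec.copy(), time)
        return None
    if not tbf.armed:
        if lam > config.spawn_threshold:
            tbf.armed = True
            tbf.arm_time = time
            tbf.best_lambda = lam
            tbf.best_snapshot = (tbf.q.copy(), tbf.p.copy(), tbf.gamma,
                                 partner, dvec.copy(), time, time)
        return None
    if lam > tbf.best_lambda:
        tbf.best_lambda = lam
        tbf.best_snapshot = (tbf.q.copy(), tbf.p.copy(), tbf.gamma,
                             partner, dvec.copy(), time,
                             getattr(tbf, "arm_time", time))
        return None
    if lam < tbf.best_lambda * (1.0 - config.spawn_drop) \
            or lam < config.spawn_threshold:
        snap = tbf.best_snapshot
        tbf.armed = False
        tbf.blocked = True
        tbf.last_spawn_t = time
        tbf.best_lambda = 0.0
        tbf.best_snapshot = None
        return snap
    return None


def make_child(model, tbf, snapshot, child_id):
    """Build the spawned TBF at the coupling maximum, rescaling the momentum
    along the coupling vector to conserve total energy; returns None if the
    kinetic energy along d_IJ cannot bridge an upward gap."""
    q, p, gamma, partner, dvec, t_max = snapshot[:6]
    out = model.evaluate_batch(q[None])
    dE = float(out.energies[0, partner] - out.energies[0, tbf.state])
    m = model.masses
    norm = np.linalg.norm(dvec)
    if norm < 1e-14:
        return None
    u = dvec / norm
    pu = float((p * u / m).sum() * 1.0)
    # solve (p + k u)^2/2m = p^2/2m - dE along u (masses equal per dim here
    # in mass-weighted coordinates; general masses via the u/m metric)
    a2 = float((u * u / (2 * m)).sum())
    disc = pu**2 - 4 * a2 * dE
    if disc < 0:
        return None
    k1 = (-pu + np.sqrt(disc)) / (2 * a2)
    k2 = (-pu - np.sqrt(disc)) / (2 * a2)
    kappa = k1 if abs(k1) <= abs(k2) else k2
    child = TrajectoryBasisFunction(
        id=child_id, state=partner, q=q.copy(), p=p + kappa * u,
        alpha=tbf.alpha, gamma=gamma, parent=tbf.id, t_spawn=t_max)
    return child


# ---------------------------------------------------------------------------
# stochastic selection
# ---------------------------------------------------------------------------


def stochastic_select(bundle: SpawnBundle, config: SpawnConfig, S=None,
                      H=None):
    """Overlap-based stochastic selection of one decoupled TBF group."""
    tbfs = bundle.live
    if not tbfs:
        raise SelectionError("no live TBFs")
    if S is None:
        S = overlap_matrix(tbfs)
    N = len(tbfs)
    st = np.array([t.state for t in tbfs])
    same = st[:, None] == st[None, :]
    adj = same & (np.abs(S) > config.overlap_threshold)
    if H is not None:
        # cross-state pairs are orthogonal (S = 0); their coupling lives in
        # the off-diagonal Hamiltonian (NAC) elements
        adj |= (~same) & (np.abs(H) > config.h_threshold)
    np.fill_diagonal(adj, True)
    n_comp, labels = connected_components(csr_matrix(adj), directed=False)
    if n_comp <= 1:
        return bundle, False
    M = np.real(np.conj(bundle.c)[:, None] * S * bundle.c[None, :])
    pops = np.array([M[np.ix_(labels == g, labels == g)].sum()
                     for g in range(n_comp)])
    pops = np.clip(pops, 0.0, None)
    if pops.sum() <= 0:
        raise SelectionError("all group populations are zero")
    probs = pops / pops.sum()
    g = bundle.rng.choice(n_comp, p=probs)
    keep = labels == g
    newc = bundle.c[keep] / np.sqrt(pops[g])
    for t, k in zip(tbfs, keep):
        if not k:
            t.alive = False
    bundle.c = newc
    bundle.events.append({
        "type": "selection", "time": bundle.time,
        "n_groups": int(n_comp), "chosen": int(g),
        "probs": [float(x) for x in probs]})
    return bundle, True


# ---------------------------------------------------------------------------
# the SSAIMS driver
# ---------------------------------------------------------------------------


def _snapshot(bundle):
    blob = []
    for t in bundle.tbfs:
        blob.append((t.id, t.state, t.q.copy(), t.p.copy(), t.gamma,
                     t.parent, t.t_spawn, t.alive, t.armed, t.blocked,
                     t.best_lambda, t.best_snapshot, t.last_spawn_t,
                     getattr(t, "low_since", None)))
    return (bundle.time, blob, bundle.c.copy())


def _restore(bundle, snap):
    time, blob, c = snap
    tbfs = []
    for (i, st, q, p, g, par, ts, alive, armed, blocked, bl, bs, lst,
         lows) in blob:
        t = TrajectoryBasisFunction(id=i, state=st, q=q.copy(), p=p.copy(),
                                    alpha=bundle.tbfs[0].alpha, gamma=g,
                                    parent=par, t_spawn=ts, alive=alive)
        t.armed, t.blocked = armed, blocked
        t.best_lambda, t.best_snapshot, t.last_spawn_t = bl, bs, lst
        t.low_since = lows
        tbfs.append(t)
    bundle.tbfs = tbfs
    bundle.time = time
    bundle.c = c.copy()


def _back_propagate(model, child, t_from, t_to, dt=0.15):
    """Classical time-reversed propagation of a TBF on its surface."""
    q, p = child.q.copy(), -child.p.copy()
    gamma = child.gamma
    m = model.masses
    t = t_from
    while t > t_to + 1e-9:
        h = min(dt, t - t_to)
        ev = model.evaluate_batch(q[None])
        f = -ev.gradients[0, child.state]
        lag0 = (p**2 / (2 * m)).sum() - ev.energies[0, child.state]
        ph = p + 0.5 * h * f
        q = q + h * ph / m
        ev1 = model.evaluate_batch(q[None])
        p = ph + 0.5 * h * (-ev1.gradients[0, child.state])
        lag1 = (p**2 / (2 * m)).sum() - ev1.energies[0, child.state]
        gamma += 0.5 * h * (lag0 + lag1)   # gamma runs backward in real time
        t -= h
    out = replace(child, q=q, p=-p, gamma=child.gamma
                  - (gamma - child.gamma))
    out.best_snapshot = None
    return out


def propagate_bundle(bundle: SpawnBundle, config: SpawnConfig,
                     record=True):
    """Propagate one bundle to the horizon, recording a RunArchive.

    Spawning follows the classic multiple-spawning prescription: when a
    TBF's effective coupling passes through a local maximum, a child is
    placed at the maximum with an energy-conserving momentum shift and the
    whole bundle is rewound to the moment the coupling region was entered,
    so parent and child traverse the interaction region together.  The
    nuclear step is refined while any TBF sits close to the seam.
    """
    model = bundle.model
    rec_dt = config.dt * config.record_stride
    n_rec = int(round(config.horizon / rec_dt)) + 1
    Nmax = config.max_tbfs
    d = model.n_dims
    Sstates = model.n_diab

    times = np.zeros(n_rec)
    pops = np.zeros((n_rec, Sstates))
    norms = np.zeros(n_rec)
    cap = [Nmax]
    tq = np.full((n_rec, Nmax, d), np.nan)
    tp = np.full((n_rec, Nmax, d), np.nan)
    tst = np.full((n_rec, Nmax), -1, dtype=int)
    tw = np.full((n_rec, Nmax), np.nan)
    tdip = np.full((n_rec, Nmax), np.nan)
    tdon = np.full((n_rec, Nmax), np.nan)
    tgap = np.full((n_rec, Nmax), np.nan)
    ten = np.full((n_rec, Nmax), np.nan)
    parents = np.full(Nmax, -1, dtype=int)
    spawn_t = np.full(Nmax, np.nan)

    def grow(arr, fill, axis=1):
        pad = [(0, 0)] * arr.ndim
        pad[axis] = (0, arr.shape[axis])
        return np.pad(arr, pad, constant_values=fill)

    def ensure_capacity(n_id):
        nonlocal tq, tp, tst, tw, tdip, tdon, tgap, ten, parents, spawn_t
        while n_id >= cap[0]:
            tq, tp = grow(tq, np.nan), grow(tp, np.nan)
            tst = grow(tst, -1)
            tw, tdip, tdon = grow(tw, np.nan), grow(tdip, np.nan), grow(tdon, np.nan)
            tgap, ten = grow(tgap, np.nan), grow(ten, np.nan)
            parents = grow(parents, -1, axis=0)
            spawn_t = grow(spawn_t, np.nan, axis=0)
            cap[0] *= 2

    for t in bundle.tbfs:
        parents[t.id] = t.parent
        spawn_t[t.id] = t.t_spawn

    def record_frame(k, S, ev):
        live = bundle.live
        times[k] = bundle.time
        pops[k] = state_populations(bundle, Sstates, S)
        norms[k] = float(np.real(np.conj(bundle.c) @ S @ bundle.c))
        tq[k] = np.nan
        tp[k] = np.nan
        tst[k] = -1
        for arr in (tw, tdip, tdon, tgap, ten):
            arr[k] = np.nan
        w = tbf_weights(bundle, S)
        for n, t in enumerate(live):
            j = t.id
            tq[k, j] = t.q
            tp[k, j] = t.p
            tst[k, j] = t.state
            tw[k, j] = w[n]
            if ev.dipoles is not None:
                tdip[k, j] = ev.dipoles[n, t.state]
            if ev.donor_charge is not None:
                tdon[k, j] = ev.donor_charge[n, t.state]
            tgap[k, j] = ev.energies[n, 1] - ev.energies[n, 0]
            ten[k, j] = ev.energies[n, t.state] + float(
                (t.p**2 / (2 * model.masses)).sum())

    from collections import deque
    buffer = deque(maxlen=int(round(config.rewind_span / config.dt)) + 2)
    no_rewind_until = -1e30

    S0, Sd0, H0, ev0 = _bundle_matrices(bundle, config)
    record_frame(0, S0, ev0)
    krec_done = 0

    while bundle.time < config.horizon - 1e-9:
        buffer.append(_snapshot(bundle))
        live = bundle.live
        idx = np.arange(len(live))
        gaps = (ev0.energies[idx, ev0.pair_up]
                - ev0.energies[idx, ev0.pair_lo])
        n_div = (config.refine_factor if np.any(gaps < config.gap_refine)
                 else 1)
        dt_eff = config.dt / n_div
        rewound = False
        for _ in range(n_div):
            live = bundle.live
            st = [t.state for t in live]
            idx = np.arange(len(live))
            m = model.masses
            Q = np.array([t.q for t in live])
            P = np.array([t.p for t in live])
            E0 = ev0.energies[idx, st]
            F0 = -ev0.gradients[idx, st]
            lag0 = (P**2 / (2 * m)).sum(axis=1) - E0
            Ph = P + 0.5 * dt_eff * F0
            Qn = Q + dt_eff * Ph / m
            evn = model.evaluate_batch(Qn, hessian=True)
            F1 = -evn.gradients[idx, st]
            Pn = Ph + 0.5 * dt_eff * F1
            lag1 = (Pn**2 / (2 * m)).sum(axis=1) - evn.energies[idx, st]
            for n, t in enumerate(live):
                t.q = Qn[n]
                t.p = Pn[n]
                t.gamma += 0.5 * dt_eff * (lag0[n] + lag1[n])
            bundle.time += dt_eff

            S1, Sd1, H1, ev1 = _bundle_matrices(bundle, config, ev=evn)
            step_amplitudes(bundle, dt_eff, (S0, Sd0, H0), (S1, Sd1, H1),
                            max(config.n_substeps // n_div, 4),
                            config.cond_max)

            # spawn checks
            wts = tbf_weights(bundle, S1)
            for n, t in enumerate(list(bundle.live)):
                pre = (int(ev1.pair_lo[n]), int(ev1.pair_up[n]), ev1.nac[n])
                pgap = float(ev1.energies[n, ev1.pair_up[n]]
                             - ev1.energies[n, ev1.pair_lo[n]])
                decision = check_spawn(t, model, config, time=bundle.time,
                                       precomputed=pre, gap=pgap)
                if decision is None:
                    continue
                if len(bundle.live) >= config.max_tbfs:
                    bundle.events.append({"type": "spawn-skipped-maxtbf",
                                          "time": bundle.time,
                                          "parent": t.id})
                    continue
                if wts[n] < config.min_weight_spawn:
                    bundle.events.append({"type": "spawn-skipped-weight",
                                          "time": bundle.time,
                                          "parent": t.id})
                    continue
                child = make_child(model, t, decision,
                                   child_id=len(bundle.tbfs))
                if child is None:
                    bundle.events.append({"type": "spawn-rejected",
                                          "time": bundle.time,
                                          "parent": t.id})
                    continue
                dup = any(o.state == child.state
                          and abs(overlap(o, child)) > config.child_overlap_max
                          for o in bundle.live)
                if dup:
                    bundle.events.append({"type": "spawn-skipped-duplicate",
                                          "time": bundle.time,
                                          "parent": t.id})
                    continue
                arm_time = decision[6] if len(decision) > 6 else decision[5]
                t_back = max(arm_time - config.rewind_pre, buffer[0][0])
                if bundle.time > no_rewind_until and t_back < child.t_spawn:
                    # rewind the bundle to the entry of the coupling region
                    snap = None
                    for s in reversed(buffer):
                        if s[0] <= t_back + 1e-9:
                            snap = s
                            break
                    if snap is None:
                        snap = buffer[0]
                    no_rewind_until = bundle.time
                    child = _back_propagate(model, child, child.t_spawn,
                                            snap[0])
                    _restore(bundle, snap)
                    for other in bundle.tbfs:
                        other.blocked = True
                        other.armed = False
                        other.best_snapshot = None
                    child.blocked = True
                    bundle.tbfs.append(child)
                    ensure_capacity(child.id)
                    parents[child.id] = child.parent
                    spawn_t[child.id] = child.t_spawn
                    bundle.c = np.concatenate([bundle.c, [0.0 + 0.0j]])
                    bundle.events.append(
                        {"type": "spawn", "time": child.t_spawn,
                         "parent": child.parent, "child": child.id,
                         "state": child.state, "rewound_to": snap[0]})
                    rewound = True
                    break
                # in-place spawn (no rewind available/allowed)
                child.blocked = True
                bundle.tbfs.append(child)
                ensure_capacity(child.id)
                parents[child.id] = child.parent
                spawn_t[child.id] = child.t_spawn
                bundle.c = np.concatenate([bundle.c, [0.0 + 0.0j]])
                bundle.events.append({"type": "spawn", "time": bundle.time,
                                      "parent": child.parent,
                                      "child": child.id,
                                      "state": child.state})
                S1, Sd1, H1, ev1 = _bundle_matrices(bundle, config)
                wts = tbf_weights(bundle, S1)
            if rewound:
                break
            S0, Sd0, H0, ev0 = S1, Sd1, H1, ev1
        if rewound:
            S0, Sd0, H0, ev0 = _bundle_matrices(bundle, config)
            continue

        # coalescence: nearly parallel same-state TBFs are merged (the
        # dominant member absorbs the partner's projection) to keep the
        # basis compact and the surviving-branch count meaningful; only
        # after the nonadiabatic transfer window to leave it untouched
        live = bundle.live
        if len(live) > 1 and bundle.time > config.merge_after:
            Sfull = overlap_matrix(live)
            w = tbf_weights(bundle, Sfull)
            merged = False
            for a in range(len(live)):
                if not live[a].alive:
                    continue
                for b in range(a + 1, len(live)):
                    if not live[b].alive:
                        continue
                    if live[a].state != live[b].state:
                        continue
                    if abs(Sfull[a, b]) <= config.merge_overlap:
                        continue
                    keep, kill = (a, b) if w[a] >= w[b] else (b, a)
                    bundle.c[keep] = (bundle.c[keep]
                                      + Sfull[keep, kill] * bundle.c[kill])
                    live[kill].alive = False
                    merged = True
            if merged:
                keep_mask = np.array([t.alive for t in live])
                bundle.c = bundle.c[keep_mask]
                S0, Sd0, H0, ev0 = _bundle_matrices(bundle, config)
                norm = float(np.real(np.conj(bundle.c) @ S0 @ bundle.c))
                if norm > 0:
                    bundle.c /= np.sqrt(norm)
                bundle.events.append({"type": "merge", "time": bundle.time})

        # dead-weight pruning
        live = bundle.live
        if len(live) > 1:
            w = tbf_weights(bundle, S0)
            now = bundle.time
            drop = []
            for n, t in enumerate(live):
                if w[n] >= config.prune_weight:
                    t.low_since = None
                else:
                    if getattr(t, "low_since", None) is None:
                        t.low_since = now
                    elif now - t.low_since >= config.prune_after:
                        drop.append(n)
            if drop and len(drop) < len(live):
                keep = np.ones(len(live), dtype=bool)
                keep[drop] = False
                for n in drop:
                    live[n].alive = False
                bundle.c = bundle.c[keep]
                S0, Sd0, H0, ev0 = _bundle_matrices(bundle, config)
                norm = float(np.real(np.conj(bundle.c) @ S0 @ bundle.c))
                if norm > 0:
                    bundle.c /= np.sqrt(norm)
                bundle.events.append({"type": "prune", "time": now,
                                      "n_dropped": len(drop)})

        # stochastic selection
        if bundle.rng is not None:
            bundle, did = stochastic_select(bundle, config, S=S0, H=H0)
            if did:
                S0, Sd0, H0, ev0 = _bundle_matrices(bundle, config)

        k = int(round(bundle.time / rec_dt))
        if abs(k * rec_dt - bundle.time) < 1e-6 and 0 < k < n_rec:
            record_frame(k, S0, ev0)
            krec_done = max(krec_done, k)

    arch = RunArchive(
        times=times[:krec_done + 1], populations=pops[:krec_done + 1],
        norm=norms[:krec_done + 1], tbf_q=tq[:krec_done + 1],
        tbf_p=tp[:krec_done + 1], tbf_state=tst[:krec_done + 1],
        tbf_weight=tw[:krec_done + 1], tbf_dipole=tdip[:krec_done + 1],
        tbf_donor=tdon[:krec_done + 1], tbf_gap=tgap[:krec_done + 1],
        tbf_energy=ten[:krec_done + 1],
        tbf_parent=parents, tbf_spawn_time=spawn_t,
        events=bundle.events,
        meta={"ic_id": bundle.ic_id, "run_seed": bundle.run_seed,
              "dt": config.dt, "horizon": config.horizon},
    )
    return arch



def make_bundle(model, ic: InitialCondition, config: SpawnConfig, seed=None,
                widths=None, ic_id=None):
    """Initial bundle: one unit-amplitude TBF vertically promoted to the
    IC's electronic state (no explicit laser coupling)."""
    if widths is None:
        widths = default_widths(model, scale=config.width_scale)
    state = ic.state if ic.state is not None else model.n_diab - 1
    root = TrajectoryBasisFunction(id=0, state=state, q=ic.q.copy(),
                                   p=ic.p.copy(), alpha=widths)
    rng = None if seed is None else np.random.default_rng(seed)
    return SpawnBundle(model=model, tbfs=[root],
                       c=np.array([1.0 + 0.0j]), rng=rng, run_seed=seed,
                       ic_id=ic_id)


def run_ssaims(ics, model, config: SpawnConfig = None, runs_per_ic=5,
               base_seed=0):
    """SSAIMS campaign: every IC is propagated with ``runs_per_ic``
    independent stochastic-selection seeds; returns one archive per run."""
    config = config or SpawnConfig()
    widths = default_widths(model, scale=config.width_scale)
    archives = []
    for i, ic in enumerate(ics):
        for r in range(runs_per_ic):
            seed = (base_seed * 100003 + i * 1009 + r * 7 + 1) % (2**31)
            bundle = make_bundle(model, ic, config, seed=seed, widths=widths,
                                 ic_id=i)
            try:
                arch = propagate_bundle(bundle, config)
            except (PropagationError, np.linalg.LinAlgError) as exc:
                log.error("run ic=%d seed=%d failed: %s", i, seed, exc)
                arch = RunArchive(
                    times=np.zeros(1), populations=np.zeros((1, model.n_diab)),
                    norm=np.zeros(1), tbf_q=np.zeros((1, 1, model.n_dims)),
                    tbf_p=np.zeros((1, 1, model.n_dims)),
                    tbf_state=np.full((1, 1), -1), tbf_weight=np.zeros((1, 1)),
                    tbf_dipole=np.zeros((1, 1)), tbf_donor=np.zeros((1, 1)),
                    tbf_gap=np.zeros((1, 1)), tbf_energy=np.zeros((1, 1)),
                    tbf_parent=np.full(1, -1), tbf_spawn_time=np.zeros(1),
                    meta={"ic_id": i, "run_seed": seed, "error": str(exc)},
                    truncated=True)
            archives.append(arch)
    return archives


# ---------------------------------------------------------------------------
# bootstrap population statistics
# ---------------------------------------------------------------------------


@dataclass
class PopulationCurve:
    times: np.ndarray        # (T,)
    mean: np.ndarray         # (S, T)
    lower: np.ndarray        # (S, T)
    upper: np.ndarray        # (S, T)
    n_boot: int
    level: float = 0.95


def bootstrap_populations(runs, n_boot=1000, seed=0, level=0.95):
    """Bootstrap the per-state population curves by resampling ICs.

    Initial conditions (not individual selection runs) are resampled with
    replacement; each replicate averages all runs of the drawn ICs.
    """
    runs = [r for r in runs if not r.truncated]
    if not runs:
        raise ModelError("no (complete) runs to bootstrap")
    ics = sorted({r.meta["ic_id"] for r in runs})
    by_ic = {i: [r for r in runs if r.meta["ic_id"] == i] for i in ics}
    times = runs[0].times
    # per-IC mean curves
    ic_curves = np.array([
        np.mean([r.populations for r in by_ic[i]], axis=0) for i in ics])
    rng = np.random.default_rng(seed)
    mean = ic_curves.mean(axis=0)
    if len(ics) == 1 or n_boot < 2:
        lo = hi = mean
    else:
        draws = rng.integers(0, len(ics), size=(n_boot, len(ics)))
        boot = ic_curves[draws].mean(axis=1)        # (n_boot, T, S)
        q = (1.0 - level) / 2.0
        lo = np.quantile(boot, q, axis=0)
        hi = np.quantile(boot, 1.0 - q, axis=0)
    return PopulationCurve(times=times, mean=mean.T, lower=lo.T, upper=hi.T,
                           n_boot=n_boot, level=level)
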