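"""Born-Oppenheimer trajectory dynamics on a single adiabatic surface.

NVE (velocity-Verlet) continuations of TBF centroids after nonadiabatic
decay, thermostatted (Langevin, NVT) stability runs from optimized minima,
and the hysteresis detector for LE<->CT character transitions based on the
excited-state dipole moment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import InitialCondition, ModelError
from .units import KB

__all__ = [
    "AdiabaticTrajectory", "TransitionEvent",
    "run_nve", "run_nve_batch", "run_nvt_langevin",
    "detect_character_transitions",
]

LE_MAX_DIPOLE = 20.0   # Debye; below: locally excited character
CT_MIN_DIPOLE = 25.0   # Debye; above: charge-transfer character
DEFAULT_DWELL = 10.0   # fs


@dataclass
class AdiabaticTrajectory:
    times: np.ndarray         # (T,) fs
    q: np.ndarray             # (T, d)
    p: np.ndarray             # (T, d)
    energy: np.ndarray        # (T,) total classical energy, eV
    gap: np.ndarray           # (T,) S_n - S0 gap, eV
    dipole: np.ndarray        # (T,) Debye
    donor_charge: np.ndarray  # (T,)
    surface: int
    ensemble: str             # "NVE" | "NVT"
    ic: InitialCondition | None = None
    meta: dict = field(default_factory=dict)
    truncated: bool = False

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({
            "time_fs": self.times, "energy_eV": self.energy,
            "gap_eV": self.gap, "dipole_D": self.dipole,
            "donor_charge": self.donor_charge,
            **{f"q{k}": self.q[:, k] for k in range(self.q.shape[1])},
        })


def _record(model, surface, Q):
    out = model.evaluate_batch(Q)
    return (out.energies[:, surface],
            out.energies[:, surface] - out.energies[:, 0],
            out.dipoles[:, surface], out.donor_charge[:, surface],
            -out.gradients[:, surface])


def run_nve_batch(ics, model, surface, horizon, dt=0.25, record_stride=2):
    """Velocity-Verlet NVE trajectories for a batch of ICs (vectorized)."""
    if horizon <= 0 or dt <= 0:
        raise ModelError("horizon and dt must be positive")
    W = len(ics)
    Q = np.array([ic.q for ic in ics], dtype=float)
    P = np.array([ic.p for ic in ics], dtype=float)
    m = model.masses
    n_steps = int(round(horizon / dt))
    n_rec = n_steps // record_stride + 1
    T = np.zeros(n_rec)
    qs = np.zeros((n_rec, W, Q.shape[1]))
    ps = np.zeros_like(qs)
    en = np.zeros((n_rec, W))
    gp = np.zeros((n_rec, W))
    dip = np.zeros((n_rec, W))
    don = np.zeros((n_rec, W))

    e, g, d_, dc, F = _record(model, surface, Q)
    T[0], qs[0], ps[0] = 0.0, Q, P
    en[0] = e + (P**2 / (2.0 * m)).sum(axis=1)
    gp[0], dip[0], don[0] = g, d_, dc
    k = 1
    for step in range(1, n_steps + 1):
        Ph = P + 0.5 * dt * F
        Q = Q + dt * Ph / m
        e, g, d_, dc, F = _record(model, surface, Q)
        P = Ph + 0.5 * dt * F
        if step % record_stride == 0:
            T[k] = step * dt
            qs[k], ps[k] = Q, P
            en[k] = e + (P**2 / (2.0 * m)).sum(axis=1)
            gp[k], dip[k], don[k] = g, d_, dc
            k += 1
    trajs = []
    for w in range(W):
        trajs.append(AdiabaticTrajectory(
            times=T.copy(), q=qs[:, w], p=ps[:, w], energy=en[:, w],
            gap=gp[:, w], dipole=dip[:, w], donor_charge=don[:, w],
            surface=surface, ensemble="NVE", ic=ics[w]))
    return trajs


def run_nve(ic, model, surface, horizon, dt=0.25, record_stride=2):
    """NVE trajectory from one initial condition."""
    return run_nve_batch([ic], model, surface, horizon, dt, record_stride)[0]


def run_nvt_langevin(ic, model, surface, temperature, friction=1e-3,
                     horizon=900.0, dt=0.25, seed=0, record_stride=2,
                     resample_velocities=True):
    """Langevin (BAOAB) trajectory at the target temperature.

    Initial velocities are Maxwell-Boltzmann at ``temperature`` (from
    ``seed``) unless ``resample_velocities`` is False.  ``friction`` is in
    fs^-1 (default 1 ps^-1).
    """
    if temperature <= 0 or friction <= 0:
        raise ModelError("temperature and friction must be positive")
    rng = np.random.default_rng(seed)
    m = model.masses
    kT = KB * temperature
    Q = np.atleast_2d(ic.q).astype(float).copy()
    if resample_velocities:
        P = rng.standard_normal(Q.shape) * np.sqrt(kT * m)
    else:
        P = np.atleast_2d(ic.p).astype(float).copy()
    n_steps = int(round(horizon / dt))
    n_rec = n_steps // record_stride + 1
    T = np.zeros(n_rec)
    qs = np.zeros((n_rec,) + Q.shape[1:])
    ps = np.zeros_like(qs)
    en = np.zeros(n_rec)
    gp = np.zeros(n_rec)
    dip = np.zeros(n_rec)
    don = np.zeros(n_rec)
    c1 = np.exp(-friction * dt)
    c2 = np.sqrt((1.0 - c1**2) * kT * m)

    e, g, d_, dc, F = _record(model, surface, Q)
    T[0], qs[0], ps[0] = 0.0, Q[0], P[0]
    en[0] = e[0] + (P**2 / (2 * m)).sum()
    gp[0], dip[0], don[0] = g[0], d_[0], dc[0]
    k = 1
    for step in range(1, n_steps + 1):
        P = P + 0.5 * dt * F
        Q = Q + 0.5 * dt * P / m
        P = c1 * P + c2 * rng.standard_normal(P.shape)
        Q = Q + 0.5 * dt * P / m
        e, g, d_, dc, F = _record(model, surface, Q)
        P = P + 0.5 * dt * F
        if step % record_stride == 0:
            T[k] = step * dt
            qs[k], ps[k] = Q[0], P[0]
            en[k] = e[0] + (P**2 / (2 * m)).sum()
            gp[k], dip[k], don[k] = g[0], d_[0], dc[0]
            k += 1
    return AdiabaticTrajectory(
        times=T, q=qs, p=ps, energy=en, gap=gp, dipole=dip, donor_charge=don,
        surface=surface, ensemble="NVT", ic=ic,
        meta={"temperature": temperature, "friction": friction, "seed": seed})


@dataclass
class TransitionEvent:
    time: float
    direction: str     # "LE->CT" or "CT->LE"


def detect_character_transitions(traj_or_series, le_max=LE_MAX_DIPOLE,
                                 ct_min=CT_MIN_DIPOLE, dwell=DEFAULT_DWELL,
                                 times=None):
    """Hysteresis + dwell detector of LE<->CT transitions in a dipole series.

    A transition is recorded when the dipole leaves one side's band, enters
    the other's, and stays there for at least ``dwell`` fs; the 20-25 D band
    is ambiguous and never triggers by itself.  Returns (events, final
    label); the final label is taken from the last unambiguous excursion
    (``"ambiguous"`` if there is none).
    """
    if le_max >= ct_min:
        raise ModelError("le_max must be below ct_min")
    if isinstance(traj_or_series, AdiabaticTrajectory):
        dip = traj_or_series.dipole
        times = traj_or_series.times
    else:
        dip = np.asarray(traj_or_series, dtype=float)
        if times is None:
            times = np.arange(len(dip), dtype=float)
    if len(dip) == 0:
        raise ModelError("empty dipole series")

    label = np.where(dip <= le_max, -1, np.where(dip >= ct_min, 1, 0))
    events = []
    current = 0          # -1 LE, +1 CT, 0 unknown
    cand = 0
    cand_t = 0.0
    for t, lab in zip(times, label):
        if lab == 0:
            continue
        if current == 0:
            # first unambiguous stretch establishes the initial character
            if cand == lab:
                if t - cand_t >= dwell:
                    current = lab
            else:
                cand, cand_t = lab, t
                if dwell <= 0:
                    current = lab
            continue
        if lab == current:
            cand = 0
            continue
        if cand == lab:
            if t - cand_t >= dwell:
                events.append(TransitionEvent(
                    time=cand_t,
                    direction="LE->CT" if lab > 0 else "CT->LE"))
                current = lab
                cand = 0
        else:
            cand, cand_t = lab, t
    final = {1: "CT", -1: "LE", 0: "ambiguous"}[current if current else cand]
    if current == 0 and cand == 0:
        final = "ambiguous"
    return events, final
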