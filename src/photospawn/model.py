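"""Analytic diabatic model of the donor-acceptor (FAD / tryptophan) complex.

The electronic structure of the chromophore-donor unit is represented by three
diabatic states:

* ``G``  — electronic ground state, harmonic in all coordinates;
* ``LE`` — locally excited state on the flavin: bright (carries the
  ground-state transition dipole), low permanent dipole, a double well along
  the intramolecular distortion coordinate ``q1`` producing a high- and a
  low-energy LE minimum;
* ``CT`` — intermolecular charge-transfer (radical-pair) state: dark, large
  permanent dipole, displaced along the donor-acceptor / solvation coordinate
  ``q2`` with a Marcus-like parabola toward the Franck-Condon side and a
  steep confining wall beyond its minimum.

Only LE and CT are electronically coupled (constant, Condon coupling
``lambda``); G is uncoupled from both, so there is no radiative/nonadiabatic
S1->S0 channel in the model.  A switchable environment term destabilizes the
CT diabat by ``eps_env`` in "protein" mode, encoding the protein
electrostatics that favor local excitation over charge separation.

Besides the two reaction coordinates the model carries an optional harmonic
bath, bilinearly coupled to q1/q2 and *identical on all three diabats*: it
exchanges vibrational energy with the reaction coordinates (dissipation /
thermal activation) without affecting any electronic observable (gaps,
characters, dipoles) at a given geometry.

Coordinates are abstract mass-weighted dimensionless reaction coordinates;
all masses are 1 in internal units (see :mod:`photospawn.units`).
"""

from __future__ import annotations

import dataclasses
import io
import tomllib
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .units import HBAR, KB, osc_strength

__all__ = [
    "ConstantCouplingModel",
    "DiabaticModel",
    "ElectronicStateEval",
    "StateBatch",
    "InitialCondition",
    "ModelError",
    "CalibrationError",
    "Constraint",
    "eval_electronic_structure",
    "sample_fc_ensemble",
    "calibrate_model",
    "toggle_environment",
    "load_model",
    "default_model",
    "ics_to_frame",
    "ics_from_frame",
]


class ModelError(ValueError):
    """Invalid model input (dimension mismatch, bad mode, ...)."""


class CalibrationError(RuntimeError):
    """Raised when a constraint set cannot be satisfied."""

    def __init__(self, message, residuals=None):
        super().__init__(message)
        self.residuals = residuals or {}


# ---------------------------------------------------------------------------
# Generic constant-coupling diabatic framework (one coupled pair)
# ---------------------------------------------------------------------------


@dataclass
class StateBatch:
    """Vectorized electronic-structure results at a batch of geometries.

    Adiabatic states are sorted by energy at every geometry.  ``pair_lo`` /
    ``pair_up`` give, per geometry, the sorted indices of the two adiabats
    that originate from the coupled diabatic pair; the nonadiabatic coupling
    vector ``nac`` couples exactly those two states (antisymmetric:
    d[up,lo] = -d[lo,up] = -nac).
    """

    q: np.ndarray            # (B, d)
    energies: np.ndarray     # (B, S)
    gradients: np.ndarray    # (B, S, d)
    weights: np.ndarray      # (B, S, n_diab)
    nac: np.ndarray          # (B, d)   between pair_lo and pair_up
    pair_lo: np.ndarray      # (B,) int
    pair_up: np.ndarray      # (B,) int
    dipoles: np.ndarray | None = None       # (B, S) Debye
    osc: np.ndarray | None = None           # (B, S) from the ground state
    donor_charge: np.ndarray | None = None  # (B, S)
    delta_e: np.ndarray | None = None       # (B,) E_CT^lowest - E_LE^lowest
    singular: np.ndarray | None = None      # (B,) bool, NAC magnitude capped

    def __len__(self):
        return self.q.shape[0]

    def nac_between(self, i, j):
        """NAC vectors d_ij for the requested sorted-state pair (B, d)."""
        d = np.zeros_like(self.nac)
        fwd = (self.pair_lo == i) & (self.pair_up == j)
        bwd = (self.pair_lo == j) & (self.pair_up == i)
        d[fwd] = self.nac[fwd]
        d[bwd] = -self.nac[bwd]
        return d


@dataclass
class ElectronicStateEval:
    """Electronic structure at a single geometry (see :class:`StateBatch`)."""

    q: np.ndarray
    energies: np.ndarray
    gradients: np.ndarray
    weights: np.ndarray
    nac: np.ndarray
    pair_lo: int
    pair_up: int
    dipoles: np.ndarray
    osc: np.ndarray
    donor_charge: np.ndarray
    delta_e: float
    singular: bool

    @property
    def gap(self):
        """S0-S1 energy gap in eV."""
        return float(self.energies[1] - self.energies[0])


class ConstantCouplingModel:
    """Diabatic potentials plus one constantly-coupled pair of diabats.

    Subclasses provide :meth:`diabats` (values, gradients and optionally
    Hessians of the diabatic surfaces) and the class handles the closed-form
    two-level adiabatic transformation: energies, analytic gradients,
    nonadiabatic coupling, diabatic weights and adiabatic Hessians.  Using
    the closed form (rather than a numerical eigensolver) keeps the mixing
    angle globally smooth, so NAC signs are continuous along trajectories.
    """

    n_dims: int
    n_diab: int
    pair: tuple[int, int]
    lam: float
    masses: np.ndarray
    nac_cap: float = 1.0e3

    # diabatic observables; subclasses may override
    mu_diab: np.ndarray | None = None        # permanent dipoles (Debye)
    tdm_ground: np.ndarray | None = None     # transition dipoles from G (a.u.)
    ground_index: int = 0
    donor_diab: np.ndarray | None = None     # donor charge per diabat
    le_index: int | None = None
    ct_index: int | None = None

    # -- subclass API ------------------------------------------------------
    def diabats(self, Q, hessian=False):
        """Return (V, dV, d2V) with shapes (B,n), (B,n,d), (B,n,d,d)."""
        raise NotImplementedError

    # -- adiabatic machinery ----------------------------------------------
    def _check(self, Q):
        Q = np.atleast_2d(np.asarray(Q, dtype=float))
        if Q.shape[1] != self.n_dims:
            raise ModelError(
                f"geometry has {Q.shape[1]} dimensions, model has {self.n_dims}"
            )
        return Q

    def evaluate_batch(self, Q, hessian=False, light=False):
        Q = self._check(Q)
        B, d = Q.shape
        i, j = self.pair
        V, dV, d2V = self.diabats(Q, hessian=hessian)

        m = 0.5 * (V[:, i] + V[:, j])
        delta = 0.5 * (V[:, i] - V[:, j])
        dm = 0.5 * (dV[:, i] + dV[:, j])
        ddelta = 0.5 * (dV[:, i] - dV[:, j])
        lam = self.lam
        r2 = delta**2 + lam**2
        r = np.sqrt(r2)

        e_lo = m - r
        e_up = m + r
        # mixing angle theta = 0.5*atan2(lam, delta); upper = (cos, sin),
        # lower = (-sin, cos) in the (i, j) diabatic basis
        theta = 0.5 * np.arctan2(lam, delta)
        c2, s2 = np.cos(theta) ** 2, np.sin(theta) ** 2

        # NAC d_{lo,up} = grad(theta) = -lam * grad(delta) / (2 r^2)
        singular = r2 < 1e-24
        safe_r2 = np.where(singular, 1.0, r2)
        nac = -lam * ddelta / (2.0 * safe_r2[:, None])
        norm = np.linalg.norm(nac, axis=1)
        over = norm > self.nac_cap
        capped = over | (singular & (lam == 0.0))
        if np.any(over):
            nac[over] *= (self.nac_cap / norm[over])[:, None]
        if lam == 0.0:
            # exact uncoupled degeneracy: coupling undefined, report capped 0
            nac[singular] = 0.0

        with np.errstate(invalid="ignore"):
            dr = np.where(r[:, None] > 0, delta[:, None] / np.where(r[:, None] > 0, r[:, None], 1.0), 0.0) * ddelta
        g_lo = dm - dr
        g_up = dm + dr

        # assemble all states: spectators + pair
        spect = [a for a in range(self.n_diab) if a not in (i, j)]
        S = self.n_diab
        energies = np.empty((B, S))
        grads = np.empty((B, S, d))
        weights = np.zeros((B, S, self.n_diab))
        # pre-sort ordering: [spectators..., lo, up]
        for k, a in enumerate(spect):
            energies[:, k] = V[:, a]
            grads[:, k] = dV[:, a]
            weights[:, k, a] = 1.0
        energies[:, -2] = e_lo
        energies[:, -1] = e_up
        grads[:, -2] = g_lo
        grads[:, -1] = g_up
        weights[:, -2, i] = s2
        weights[:, -2, j] = c2
        weights[:, -1, i] = c2
        weights[:, -1, j] = s2

        order = np.argsort(energies, axis=1, kind="stable")
        bidx = np.arange(B)[:, None]
        energies = energies[bidx, order]
        grads = grads[bidx, order]
        weights = weights[bidx, order]
        inv = np.argsort(order, axis=1)
        pair_lo = inv[:, S - 2]
        pair_up = inv[:, S - 1]

        out = StateBatch(
            q=Q, energies=energies, gradients=grads, weights=weights,
            nac=nac, pair_lo=pair_lo, pair_up=pair_up, singular=capped,
        )
        self._observables(out, theta, light=light)
        if hessian:
            out.hessians = self._hessians(Q, V, dV, d2V, delta, ddelta, r, order)
        return out

    def _hessians(self, Q, V, dV, d2V, delta, ddelta, r, order):
        i, j = self.pair
        B, d = Q.shape
        d2m = 0.5 * (d2V[:, i] + d2V[:, j])
        d2delta = 0.5 * (d2V[:, i] - d2V[:, j])
        lam = self.lam
        r = np.maximum(r, 1e-12)
        outer = ddelta[:, :, None] * ddelta[:, None, :]
        corr = (delta / r)[:, None, None] * d2delta + (lam**2 / r**3)[:, None, None] * outer
        h_lo = d2m - corr
        h_up = d2m + corr
        spect = [a for a in range(self.n_diab) if a not in (i, j)]
        H = np.empty((B, self.n_diab, d, d))
        for k, a in enumerate(spect):
            H[:, k] = d2V[:, a]
        H[:, -2] = h_lo
        H[:, -1] = h_up
        return H[np.arange(B)[:, None], order]

    def _observables(self, out: StateBatch, theta, light=False):
        if self.mu_diab is not None:
            out.dipoles = out.weights @ self.mu_diab
        if self.donor_diab is not None:
            out.donor_charge = out.weights @ self.donor_diab
        if light:
            return
        if self.tdm_ground is not None:
            # signed adiabatic coefficients from the smooth mixing angle
            B, S = out.energies.shape
            i, j = self.pair
            coef = np.zeros((B, S, self.n_diab))
            ct, st = np.cos(theta), np.sin(theta)
            bidx = np.arange(B)
            spect = [a for a in range(self.n_diab) if a not in (i, j)]
            # reconstruct per-sorted-state coefficients
            coef[bidx, out.pair_lo, i] = -st
            coef[bidx, out.pair_lo, j] = ct
            coef[bidx, out.pair_up, i] = ct
            coef[bidx, out.pair_up, j] = st
            for a in spect:
                k = np.argmax(out.weights[:, :, a], axis=1)
                coef[bidx, k, a] = 1.0
            tdm = coef @ self.tdm_ground
            g = np.argmax(out.weights[:, :, self.ground_index], axis=1)
            gaps = out.energies - out.energies[bidx, g][:, None]
            out.osc = np.where(gaps > 0, osc_strength(np.abs(gaps), tdm), 0.0)
        if self.le_index is not None and self.ct_index is not None:
            w_le = out.weights[:, :, self.le_index]
            w_ct = out.weights[:, :, self.ct_index]
            excited = (w_le + w_ct) > 0.5  # not ground-dominant
            big = 1e30
            e_le = np.where(excited & (w_le >= w_ct), out.energies, big).min(axis=1)
            e_ct = np.where(excited & (w_ct > w_le), out.energies, big).min(axis=1)
            out.delta_e = np.where((e_le < big) & (e_ct < big), e_ct - e_le, np.nan)

    def evaluate(self, q, hessian=False) -> ElectronicStateEval:
        out = self.evaluate_batch(np.atleast_2d(q), hessian=hessian)
        ev = ElectronicStateEval(
            q=out.q[0], energies=out.energies[0], gradients=out.gradients[0],
            weights=out.weights[0], nac=out.nac[0],
            pair_lo=int(out.pair_lo[0]), pair_up=int(out.pair_up[0]),
            dipoles=None if out.dipoles is None else out.dipoles[0],
            osc=None if out.osc is None else out.osc[0],
            donor_charge=None if out.donor_charge is None else out.donor_charge[0],
            delta_e=np.nan if out.delta_e is None else float(out.delta_e[0]),
            singular=bool(out.singular[0]),
        )
        if hessian:
            ev.hessians = out.hessians[0]
        return ev

    # convenience: energy/gradient of one surface (for optimizers/dynamics)
    def surface(self, Q, state):
        out = self.evaluate_batch(Q)
        return out.energies[:, state], out.gradients[:, state]


# ---------------------------------------------------------------------------
# The calibrated three-state donor-acceptor model
# ---------------------------------------------------------------------------

_STATES = ("G", "LE", "CT")


@dataclass
class DiabaticModel(ConstantCouplingModel):
    """Parametrized G/LE/CT model with environment toggle and harmonic bath.

    Diabatic surfaces (q1, q2 reaction coordinates, x_j bath)::

        V_G  = kg1/2 q1^2 + kg2/2 q2^2                             + V_bath
        V_LE = poly4(q1)  + k2/2 q2^2                              + V_bath
        V_CT = e0 + eps_env?[protein] + k1/2 (q1-w1)^2
               + k2/2 (q2-w2)^2 + w4 * max(q2-w2, 0)^4            + V_bath^CT
        V_bath^X = sum_j omega_j^2/2 (x_j - c_j q_{m_j} - b_j[X=CT])^2

    The CT-only bath displacements b_j realize Marcus-type solvation: the
    polarization modes relax to different equilibria once the electron has
    transferred, which (i) adds slow solvation broadening to the LE/CT gap
    and (ii) dephases LE/CT electronic coherence during the nonadiabatic
    dynamics.

    The CT profile along q2 is a soft Marcus-like parabola on the
    Franck-Condon side (small CT reorganization energy) with a steep
    one-sided quartic wall beyond its minimum; the wall keeps the S0-S1 gap
    at the charge-separated minimum near 1 eV under thermal motion and
    enforces the global gap floor.
    """

    name: str = "fwd-mimic"
    environment: str = "protein"
    kg: tuple = (0.085, 0.0064)
    le_poly: tuple = (3.25, -0.6, 0.2, 0.1, 0.02)   # c0..c4 along q1
    le_k2: float = 0.0064
    ct_e0: float = 2.0
    ct_k1: float = 0.05
    ct_center: tuple = (-0.8, 24.0)
    ct_k2: float = 0.0018
    ct_wall4: float = 0.01
    lam: float = 0.07
    eps_env: float = 0.9
    mu_g: float = 5.0
    mu_le: float = 8.0
    mu_ct: float = 31.0
    tdm_le: float = 1.6
    bath_omegas: tuple = ()
    bath_couple: tuple = ()
    bath_c: tuple = ()
    bath_ct_shift: tuple = ()        # CT-diabat displacement of each mode
    mass_q: tuple = ()               # per-dimension inertia (default all 1)
    nac_cap: float = 1.0e3

    n_diab: int = 3
    pair: tuple = (1, 2)    # LE-CT coupled block
    ground_index: int = 0
    le_index: int = 1
    ct_index: int = 2

    def __post_init__(self):
        if self.environment not in ("protein", "vacuum"):
            raise ModelError(f"unknown environment mode {self.environment!r}")
        if self.lam < 0:
            raise ModelError("coupling lambda must be >= 0")
        if not (self.mu_ct > self.mu_le >= 0):
            raise ModelError("dipoles must satisfy mu_CT > mu_LE >= 0")
        for k in (*self.kg, self.le_k2, self.ct_k1, self.ct_k2):
            if k <= 0:
                raise ModelError("force constants must be positive")
        nb = len(self.bath_omegas)
        if not self.bath_ct_shift:
            self.bath_ct_shift = tuple(0.0 for _ in range(nb))
        if not (len(self.bath_couple) == len(self.bath_c)
                == len(self.bath_ct_shift) == nb):
            raise ModelError("inconsistent bath specification")
        self.n_dims = 2 + nb
        if self.mass_q:
            if len(self.mass_q) != self.n_dims:
                raise ModelError("mass_q must cover all dimensions")
            self.masses = np.asarray(self.mass_q, dtype=float)
        else:
            self.masses = np.ones(self.n_dims)
        self.mu_diab = np.array([self.mu_g, self.mu_le, self.mu_ct])
        self.tdm_ground = np.array([0.0, self.tdm_le, 0.0])
        self.donor_diab = np.array([0.0, 0.0, 1.0])
        self._bw = np.asarray(self.bath_omegas, dtype=float)
        self._bm = np.asarray(self.bath_couple, dtype=int)
        self._bc = np.asarray(self.bath_c, dtype=float)
        self._bshift = np.asarray(self.bath_ct_shift, dtype=float)

    # -- diabatic surfaces -------------------------------------------------
    def diabats(self, Q, hessian=False):
        B, d = Q.shape
        q1, q2 = Q[:, 0], Q[:, 1]
        nb = len(self._bw)
        V = np.empty((B, 3))
        dV = np.zeros((B, 3, d))

        kg1, kg2 = self.kg
        c0, c1, c2, c3, c4 = self.le_poly
        w1, w2 = self.ct_center
        k2c, w4 = self.ct_k2, self.ct_wall4
        s = q2 - w2
        sp = np.maximum(s, 0.0)
        eps = self.eps_env if self.environment == "protein" else 0.0

        V[:, 0] = 0.5 * kg1 * q1**2 + 0.5 * kg2 * q2**2
        V[:, 1] = c0 + q1 * (c1 + q1 * (c2 + q1 * (c3 + q1 * c4))) + 0.5 * self.le_k2 * q2**2
        V[:, 2] = (self.ct_e0 + eps + 0.5 * self.ct_k1 * (q1 - w1) ** 2
                   + 0.5 * k2c * s**2 + w4 * sp**4)

        dV[:, 0, 0] = kg1 * q1
        dV[:, 0, 1] = kg2 * q2
        dV[:, 1, 0] = c1 + q1 * (2 * c2 + q1 * (3 * c3 + q1 * 4 * c4))
        dV[:, 1, 1] = self.le_k2 * q2
        dV[:, 2, 0] = self.ct_k1 * (q1 - w1)
        dV[:, 2, 1] = k2c * s + 4.0 * w4 * sp**3

        if nb:
            x = Q[:, 2:]
            disp = x - self._bc[None, :] * Q[:, self._bm]
            dispc = disp - self._bshift[None, :]
            for state, dsp in ((0, disp), (1, disp), (2, dispc)):
                V[:, state] += 0.5 * np.sum(self._bw**2 * dsp**2, axis=1)
                fb = (self._bw**2)[None, :] * dsp
                dV[:, state, 2:] += fb
                for mm in (0, 1):
                    sel = self._bm == mm
                    if np.any(sel):
                        dV[:, state, mm] += -np.sum(
                            fb[:, sel] * self._bc[sel][None, :], axis=1)

        if not hessian:
            return V, dV, None

        d2V = np.zeros((B, 3, d, d))
        d2V[:, 0, 0, 0] = kg1
        d2V[:, 0, 1, 1] = kg2
        d2V[:, 1, 0, 0] = 2 * c2 + q1 * (6 * c3 + 12 * c4 * q1)
        d2V[:, 1, 1, 1] = self.le_k2
        d2V[:, 2, 0, 0] = self.ct_k1
        d2V[:, 2, 1, 1] = k2c + 12.0 * w4 * sp**2
        if nb:
            for jb, (w, m, c) in enumerate(zip(self._bw, self._bm, self._bc)):
                k = w**2
                d2V[:, :, 2 + jb, 2 + jb] += k
                d2V[:, :, 2 + jb, m] += -k * c
                d2V[:, :, m, 2 + jb] += -k * c
                d2V[:, :, m, m] += k * c**2
        return V, dV, d2V

    # -- serialization -----------------------------------------------------
    _TOML_FIELDS = (
        "name", "environment", "kg", "le_poly", "le_k2", "ct_e0", "ct_k1",
        "ct_center", "ct_k2", "ct_wall4", "lam", "eps_env", "mu_g",
        "mu_le", "mu_ct", "tdm_le", "bath_omegas", "bath_couple", "bath_c",
        "bath_ct_shift", "mass_q", "nac_cap",
    )

    def to_dict(self):
        out = {}
        for f in self._TOML_FIELDS:
            v = getattr(self, f)
            out[f] = list(v) if isinstance(v, (tuple, list, np.ndarray)) else v
        return out

    def to_toml(self, path):
        lines = ["[model]"]
        for k, v in self.to_dict().items():
            if isinstance(v, str):
                lines.append(f'{k} = "{v}"')
            elif isinstance(v, list):
                lines.append(f"{k} = [{', '.join(repr(float(x)) if not isinstance(x, int) or k not in ('bath_couple',) else repr(int(x)) for x in v)}]")
            else:
                lines.append(f"{k} = {v!r}")
        text = "\n".join(lines) + "\n"
        with open(path, "w") as fh:
            fh.write(text)

    @classmethod
    def from_dict(cls, d):
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ModelError(f"unknown model parameters: {sorted(unknown)}")
        d = {k: tuple(v) if isinstance(v, list) else v for k, v in d.items()}
        return cls(**d)

    @classmethod
    def from_toml(cls, path_or_bytes):
        if isinstance(path_or_bytes, bytes):
            data = tomllib.load(io.BytesIO(path_or_bytes))
        else:
            with open(path_or_bytes, "rb") as fh:
                data = tomllib.load(fh)
        return cls.from_dict(data.get("model", data))

    # parameter access by dotted name, e.g. "lam" or "le_poly[2]"
    def get_param(self, name):
        if "[" in name:
            base, idx = name[:-1].split("[")
            return float(getattr(self, base)[int(idx)])
        return float(getattr(self, name))

    def with_params(self, updates: dict) -> "DiabaticModel":
        d = self.to_dict()
        for name, val in updates.items():
            if "[" in name:
                base, idx = name[:-1].split("[")
                d[base] = list(d[base])
                d[base][int(idx)] = float(val)
            else:
                d[name] = float(val)
        return DiabaticModel.from_dict(d)


def load_model(path) -> DiabaticModel:
    return DiabaticModel.from_toml(path)


def default_model() -> DiabaticModel:
    """The shipped calibrated model (frozen output of :func:`calibrate_model`)."""
    data = resources.files("photospawn").joinpath("data/fwd_mimic.toml").read_bytes()
    return DiabaticModel.from_toml(data)


def toggle_environment(model: DiabaticModel, mode: str) -> DiabaticModel:
    """Return a copy of ``model`` in ``protein`` or ``vacuum`` mode."""
    if mode not in ("protein", "vacuum"):
        raise ModelError(f"unknown environment mode {mode!r}")
    d = model.to_dict()
    d["environment"] = mode
    return DiabaticModel.from_dict(d)


def eval_electronic_structure(model, q, hessian=False) -> ElectronicStateEval:
    """Adiabatic energies, gradients, couplings and observables at ``q``."""
    return model.evaluate(np.asarray(q, dtype=float), hessian=hessian)


# ---------------------------------------------------------------------------
# Initial conditions / Franck-Condon sampling
# ---------------------------------------------------------------------------


@dataclass
class InitialCondition:
    q: np.ndarray
    p: np.ndarray
    state: int | None = None
    provenance: str = "FC-sampled"
    seed: int | None = None

    def __post_init__(self):
        self.q = np.asarray(self.q, dtype=float)
        self.p = np.asarray(self.p, dtype=float)
        if self.q.shape != self.p.shape:
            raise ModelError("q and p dimensions differ")


def ics_to_frame(ics):
    import pandas as pd

    d = len(ics[0].q)
    rows = []
    for k, ic in enumerate(ics):
        row = {"index": k, "state": -1 if ic.state is None else ic.state,
               "provenance": ic.provenance, "seed": ic.seed}
        row.update({f"q{i}": ic.q[i] for i in range(d)})
        row.update({f"p{i}": ic.p[i] for i in range(d)})
        rows.append(row)
    return pd.DataFrame(rows)


def ics_from_frame(df):
    d = sum(c.startswith("q") and c[1:].isdigit() for c in df.columns)
    out = []
    for _, row in df.iterrows():
        st = int(row["state"])
        out.append(InitialCondition(
            q=np.array([row[f"q{i}"] for i in range(d)]),
            p=np.array([row[f"p{i}"] for i in range(d)]),
            state=None if st < 0 else st,
            provenance=str(row.get("provenance", "FC-sampled")),
            seed=None if row.get("seed") is None else int(row["seed"]),
        ))
    return out


def _langevin_baoab(force, q0, p0, dt, n_steps, friction, kT, masses, rng,
                    callback=None):
    """BAOAB Langevin integrator, vectorized over walkers (W, d)."""
    q, p = q0.copy(), p0.copy()
    f = force(q)
    c1 = np.exp(-friction * dt)
    c2 = np.sqrt((1.0 - c1**2) * kT * masses)
    for step in range(n_steps):
        p += 0.5 * dt * f
        q += 0.5 * dt * p / masses
        p = c1 * p + c2 * rng.standard_normal(p.shape)
        q += 0.5 * dt * p / masses
        f = force(q)
        p += 0.5 * dt * f
        if callback is not None:
            callback(step, q, p)
    return q, p


def sample_fc_ensemble(model, n, temperature, seed, *, dt=0.25, friction=0.05,
                       burn_fs=1500.0, stride_fs=150.0, wigner=False):
    """Sample ``n`` thermal initial conditions on the ground surface.

    Classical Langevin (BAOAB) dynamics on S0 at the target temperature,
    run as a bank of independent walkers with stride sampling along each
    chain; zero-point motion is not included unless ``wigner=True``, which
    instead draws from the finite-temperature Wigner distribution of the
    (harmonic) ground surface.
    """
    if n < 1:
        raise ModelError("n must be >= 1")
    if temperature <= 0:
        raise ModelError("temperature must be positive")
    kT = KB * temperature
    rng = np.random.default_rng(seed)
    d = model.n_dims
    masses = model.masses

    if wigner:
        H = model.evaluate_batch(np.zeros((1, d)), hessian=True).hessians[0][0]
        w2, modes = np.linalg.eigh(H / np.sqrt(np.outer(masses, masses)))
        om = np.sqrt(np.maximum(w2, 1e-12))
        coth = 1.0 / np.tanh(HBAR * om / (2.0 * kT))
        sq = np.sqrt(HBAR / (2.0 * om) * coth)
        sp = np.sqrt(HBAR * om / 2.0 * coth)
        xi = rng.standard_normal((n, d)) * sq
        pi = rng.standard_normal((n, d)) * sp
        Q = xi @ modes.T * np.sqrt(masses)
        P = pi @ modes.T * np.sqrt(masses)
        return [InitialCondition(Q[k], P[k], provenance="FC-sampled", seed=seed)
                for k in range(n)]

    n_chains = min(n, 400)
    per = -(-n // n_chains)
    stride = max(1, int(round(stride_fs / dt)))
    burn = int(round(burn_fs / dt))

    def force(Qw):
        return -model.evaluate_batch(Qw).gradients[:, 0, :]

    q = np.zeros((n_chains, d))
    p = rng.standard_normal((n_chains, d)) * np.sqrt(kT * masses)
    samples = []

    def cb(step, Qw, Pw):
        if step >= burn and (step - burn) % stride == 0 and len(samples) < per:
            samples.append((Qw.copy(), Pw.copy()))

    _langevin_baoab(force, q, p, dt, burn + per * stride, friction, kT,
                    masses, rng, callback=cb)
    ics = []
    for Qw, Pw in samples:
        for w in range(n_chains):
            ics.append(InitialCondition(Qw[w], Pw[w], provenance="FC-sampled",
                                        seed=seed))
    return ics[:n]


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------


@dataclass
class Constraint:
    """One calibration target: a named model property with tolerance."""

    prop: str
    target: float
    tol: float
    kind: str = "eq"      # eq | le | ge
    weight: float = 1.0


def _property_registry():
    # deferred imports: landscape/spectroscopy depend on model
    from . import landscape as ls
    from . import spectroscopy as sp

    def vertical(model, state):
        ev = model.evaluate(np.zeros(model.n_dims))
        return float(ev.energies[state] - ev.energies[0])

    def min_gap(model, label):
        pt = ls.find_default_minimum(model, label)
        return pt.gap

    def min_energy(model, label):
        return ls.find_default_minimum(model, label).energy

    def barrier(model, a, b):
        pa = ls.find_default_minimum(model, a)
        pb = ls.find_default_minimum(model, b)
        path = ls.neb_mep(model, 1, pa, pb, n_images=14)
        return path.barrier_kcal

    def bright_fraction(model, n=300, seed=2025, temperature=300.0):
        ics = sample_fc_ensemble(model, n, temperature, seed)
        recs = sp.vertical_excitations(ics, model)
        return 100.0 * np.mean([r.bright_s2 for r in recs])

    def spectrum_max(model, n=300, seed=2025, temperature=300.0):
        ics = sample_fc_ensemble(model, n, temperature, seed)
        recs = sp.vertical_excitations(ics, model)
        spec = sp.absorption_spectrum(recs)
        return spec.peak_energy

    return {
        "vertical_gap_s1": lambda m: vertical(m, 1),
        "vertical_gap_s2": lambda m: vertical(m, 2),
        "gap_le_low": lambda m: min_gap(m, "LE_low"),
        "gap_le_high": lambda m: min_gap(m, "LE_high"),
        "gap_ct": lambda m: min_gap(m, "CT"),
        "s1_energy_le_low": lambda m: min_energy(m, "LE_low"),
        "s1_energy_le_high": lambda m: min_energy(m, "LE_high"),
        "s1_energy_ct": lambda m: min_energy(m, "CT"),
        "barrier_le_low_le_high": lambda m: barrier(m, "LE_low", "LE_high"),
        "barrier_le_high_ct": lambda m: barrier(m, "LE_high", "CT"),
        "barrier_ct_le_high": lambda m: barrier(m, "CT", "LE_high"),
        "bright_s2_fraction": bright_fraction,
        "spectrum_max": spectrum_max,
    }


def evaluate_constraints(model, constraints):
    """Direct re-evaluation of each constraint; returns {prop: (value, ok)}."""
    reg = _property_registry()
    out = {}
    for c in constraints:
        try:
            v = float(reg[c.prop](model))
        except KeyError:
            raise ModelError(f"unknown calibration property {c.prop!r}")
        if c.kind == "eq":
            ok = abs(v - c.target) <= c.tol
        elif c.kind == "le":
            ok = v <= c.target + c.tol
        elif c.kind == "ge":
            ok = v >= c.target - c.tol
        else:
            raise ModelError(f"unknown constraint kind {c.kind!r}")
        out[c.prop] = (v, ok)
    return out


def calibrate_model(constraints, model=None, free_params=(), max_iter=200,
                    verbose=False):
    """Derivative-free local search tuning ``free_params`` to the constraints.

    Starts from ``model`` (default: the shipped parameter set) and minimizes
    the weighted excess residual with Nelder-Mead; returns a model whose
    *direct re-evaluation* satisfies every constraint within tolerance, else
    raises :class:`CalibrationError` reporting the worst residual.
    """
    from scipy.optimize import minimize

    model = model or default_model()
    reg = _property_registry()
    for c in constraints:
        if c.prop not in reg:
            raise ModelError(f"unknown calibration property {c.prop!r}")

    def residuals(m):
        res = {}
        for c in constraints:
            v = reg[c.prop](m)
            if c.kind == "eq":
                r = abs(v - c.target) / c.tol
            elif c.kind == "le":
                r = max(0.0, v - c.target) / c.tol
            else:
                r = max(0.0, c.target - v) / c.tol
            res[c.prop] = c.weight * r
        return res

    if not free_params:
        res = residuals(model)
        if max(res.values()) <= 1.0:
            return model
        raise CalibrationError(
            f"constraints unsatisfied with no free parameters; worst "
            f"{max(res, key=res.get)} residual {max(res.values()):.3g}x tol",
            residuals=res)

    x0 = np.array([model.get_param(p) for p in free_params])
    scale = np.where(np.abs(x0) > 1e-6, np.abs(x0), 1.0)

    def cost(x):
        m = model.with_params(dict(zip(free_params, x * scale)))
        try:
            r = residuals(m)
        except Exception:
            return 1e6
        return sum(v**2 for v in r.values())

    best = minimize(cost, x0 / scale, method="Nelder-Mead",
                    options={"maxiter": max_iter, "xatol": 1e-6, "fatol": 1e-10})
    fitted = model.with_params(dict(zip(free_params, best.x * scale)))
    res = residuals(fitted)
    if verbose:
        for k, v in res.items():
            print(f"  {k}: {v:.3f} x tol")
    if max(res.values()) > 1.0:
        worst = max(res, key=res.get)
        raise CalibrationError(
            f"calibration failed: {worst} residual {res[worst]:.3g}x tolerance "
            f"after {max_iter} iterations", residuals=res)
    return fitted
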