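"""Independent numerical oracles used by the test suite.

* simple one-dimensional two-state diabatic models built on the package's
  constant-coupling framework;
* an exact split-operator grid propagator for 1-D two-state problems (the
  reference for multiple-spawning population transfer);
* brute-force quadrature of frozen-Gaussian overlaps.

These implementations share no code path with the propagator they check:
the split-operator works on a spatial grid in the diabatic representation,
the quadrature integrates wavefunctions numerically.
"""

import numpy as np

from photospawn.model import ConstantCouplingModel
from photospawn.units import HBAR


class TwoStateModel(ConstantCouplingModel):
    """1-D pair of diabatic potentials with constant coupling."""

    def __init__(self, v1, v2, lam, mass=1.0, d2v1=None, d2v2=None):
        self.n_dims = 1
        self.n_diab = 2
        self.pair = (0, 1)
        self.lam = lam
        self.masses = np.array([mass])
        self._v = (v1, v2)
        self._d2 = (d2v1, d2v2)

    def diabats(self, Q, hessian=False):
        x = Q[:, 0]
        B = len(x)
        V = np.empty((B, 2))
        dV = np.empty((B, 2, 1))
        h = 1e-5
        for i, v in enumerate(self._v):
            V[:, i] = v(x)
            dV[:, i, 0] = (v(x + h) - v(x - h)) / (2 * h)
        if not hessian:
            return V, dV, None
        d2V = np.empty((B, 2, 1, 1))
        for i, v in enumerate(self._v):
            if self._d2[i] is not None:
                d2V[:, i, 0, 0] = self._d2[i](x)
            else:
                d2V[:, i, 0, 0] = (v(x + h) - 2 * V[:, i] + v(x - h)) / h**2
        return V, dV, d2V


def linear_crossing(slope1=0.005, slope2=-0.005, lam=0.002, mass=2000.0):
    """Tully-like single avoided crossing (units: eV, fs, dimensionless x)."""
    return TwoStateModel(lambda x: slope1 * x, lambda x: slope2 * x, lam,
                         mass=mass,
                         d2v1=lambda x: 0.0 * x, d2v2=lambda x: 0.0 * x)


def split_operator_populations(model: TwoStateModel, q0, p0, alpha,
                               init_adiabat, t_final, dt=0.1,
                               x_span=None, n_grid=4096):
    """Exact grid propagation of a Gaussian wavepacket; returns the final
    adiabatic populations (lower, upper)."""
    m = model.masses[0]
    lam = model.lam
    if x_span is None:
        width = 1.0 / np.sqrt(alpha)
        travel = abs(p0) / m * t_final
        x_span = (q0 - 10 * width - 2 * travel, q0 + 10 * width + 2 * travel)
    x = np.linspace(*x_span, n_grid)
    dx = x[1] - x[0]
    k = 2 * np.pi * np.fft.fftfreq(n_grid, dx)

    V1 = model._v[0](x)
    V2 = model._v[1](x)

    # adiabatic transformation at each grid point
    delta = 0.5 * (V1 - V2)
    theta = 0.5 * np.arctan2(lam, delta)
    # upper = (cos, sin), lower = (-sin, cos) in the diabatic basis
    ct, st = np.cos(theta), np.sin(theta)

    phi = (2 * alpha / np.pi) ** 0.25 * np.exp(
        -alpha * (x - q0) ** 2 + 1j * p0 * (x - q0) / HBAR)
    psi = np.empty((2, n_grid), dtype=complex)
    if init_adiabat == 1:   # upper
        psi[0] = ct * phi
        psi[1] = st * phi
    else:
        psi[0] = -st * phi
        psi[1] = ct * phi

    # propagators
    Tk = np.exp(-1j * (HBAR * k**2 / (2 * m)) * dt / 2)
    mbar = 0.5 * (V1 + V2)
    r = np.sqrt(delta**2 + lam**2)
    # exp(-i V dt / hbar) for V = mbar I + delta sz + lam sx
    ph = np.exp(-1j * mbar * dt / HBAR)
    cosr = np.cos(r * dt / HBAR)
    sinr = np.sin(r * dt / HBAR)
    safe_r = np.where(r > 0, r, 1.0)
    u11 = ph * (cosr - 1j * delta / safe_r * sinr)
    u22 = ph * (cosr + 1j * delta / safe_r * sinr)
    u12 = ph * (-1j * lam / safe_r * sinr)

    n_steps = int(round(t_final / dt))
    for _ in range(n_steps):
        psi = np.fft.ifft(Tk * np.fft.fft(psi, axis=1), axis=1)
        a, b = psi[0].copy(), psi[1].copy()
        psi[0] = u11 * a + u12 * b
        psi[1] = u12 * a + u22 * b
        psi = np.fft.ifft(Tk * np.fft.fft(psi, axis=1), axis=1)

    lower = -st * psi[0] + ct * psi[1]
    upper = ct * psi[0] + st * psi[1]
    p_lo = float(np.sum(np.abs(lower) ** 2) * dx)
    p_up = float(np.sum(np.abs(upper) ** 2) * dx)
    return p_lo, p_up


def overlap_by_quadrature(a, b, n=20001, nsig=12.0):
    """Numerical quadrature of <a|b> for frozen-Gaussian TBFs (any dims)."""
    val = 1.0 + 0.0j
    for k in range(len(a.q)):
        al = a.alpha[k]
        lo = min(a.q[k], b.q[k]) - nsig / np.sqrt(al)
        hi = max(a.q[k], b.q[k]) + nsig / np.sqrt(al)
        x = np.linspace(lo, hi, n)
        fa = (2 * al / np.pi) ** 0.25 * np.exp(
            -al * (x - a.q[k]) ** 2 + 1j * a.p[k] * (x - a.q[k]) / HBAR)
        fb = (2 * al / np.pi) ** 0.25 * np.exp(
            -al * (x - b.q[k]) ** 2 + 1j * b.p[k] * (x - b.q[k]) / HBAR)
        val *= np.trapezoid(np.conj(fa) * fb, x)
    return val * np.exp(1j * (b.gamma - a.gamma) / HBAR)
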