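"""Post-processing analytics for spawning and adiabatic campaigns.

Amplitude-weighted dipole-time distribution maps (the time evolution of the
excited-state dipole over all TBFs), LE/CT classification of TBFs from
their dipole series, the electron-transfer quantum yield, exponential
lifetime fits of population curves, and decay-completion times.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .model import ModelError
from .spawning import PopulationCurve

__all__ = [
    "DipoleMap", "CharacterSummary", "FitResult",
    "dipole_time_distribution", "classify_tbf_character", "quantum_yield",
    "fit_lifetime", "decay_completion_time", "character_summary",
]

DIPOLE_SIGMA = 1.91   # Debye, map convolution width
TIME_SIGMA = 0.75     # fs
LE_MAX = 20.0         # Debye
CT_MIN = 25.0         # Debye


@dataclass
class DipoleMap:
    times: np.ndarray       # (T,)
    dipoles: np.ndarray     # (M,)
    density: np.ndarray     # (M, T)
    sigma_dipole: float
    sigma_time: float

    def mass_per_time(self):
        """Integral of the density over the dipole axis at each time."""
        return np.trapezoid(self.density, self.dipoles, axis=0)


@dataclass
class FitResult:
    tau: float | None
    sigma: float | None
    ok: bool
    reason: str = ""


@dataclass
class CharacterSummary:
    n_le: int
    n_ct: int
    n_ambiguous: int
    yield_ct: float
    lifetime: FitResult | None = None

    @property
    def counts(self):
        return {"LE": self.n_le, "CT": self.n_ct,
                "ambiguous": self.n_ambiguous}


def dipole_time_distribution(archives, sigma_dipole=DIPOLE_SIGMA,
                             sigma_time=TIME_SIGMA, dipole_grid=None,
                             states=None):
    """Amplitude-weighted 2-D (dipole, time) density over all TBFs.

    Every TBF contributes a 2-D Gaussian ridge along its dipole series,
    weighted by its time-dependent Mulliken weight; the map is averaged
    over the archives (independent runs).
    """
    if sigma_dipole <= 0 or sigma_time <= 0:
        raise ModelError("convolution widths must be positive")
    archives = list(archives)
    if not archives:
        raise ModelError("no archives")
    times = archives[0].times
    if dipole_grid is None:
        dipole_grid = np.arange(0.0, 40.0 + 1e-9, 0.25)
    M, T = len(dipole_grid), len(times)
    dens = np.zeros((M, T))
    dt_frame = times[1] - times[0] if T > 1 else 1.0
    half = max(1, int(np.ceil(4 * sigma_time / dt_frame)))
    tker = np.exp(-0.5 * (np.arange(-half, half + 1) * dt_frame / sigma_time) ** 2)
    tker /= tker.sum()
    for arch in archives:
        for n in range(arch.n_tbfs):
            livemask = arch.tbf_state[:, n] >= 0
            if states is not None:
                livemask &= np.isin(arch.tbf_state[:, n], states)
            idx = np.flatnonzero(livemask)
            if len(idx) == 0:
                continue
            mu = arch.tbf_dipole[idx, n]
            if np.any(np.isnan(mu)):
                raise ModelError(f"missing dipole series for TBF {n}")
            w = np.clip(arch.tbf_weight[idx, n], 0.0, None)
            ridge = np.exp(-0.5 * ((dipole_grid[:, None] - mu[None, :])
                                   / sigma_dipole) ** 2)
            ridge *= w[None, :] / (sigma_dipole * np.sqrt(2 * np.pi))
            sub = np.zeros((M, T))
            sub[:, idx] = ridge
            # convolve along time
            dens += np.apply_along_axis(
                lambda row: np.convolve(row, tker, mode="same"), 1, sub)
    dens /= len(archives)
    return DipoleMap(times=times, dipoles=dipole_grid, density=dens,
                     sigma_dipole=sigma_dipole, sigma_time=sigma_time)


def classify_tbf_character(dipole_series, weights=None, le_max=LE_MAX,
                           ct_min=CT_MIN):
    """Final LE/CT label of a TBF from the last unambiguous dipole frame."""
    if le_max >= ct_min:
        raise ModelError("le_max must be below ct_min")
    mu = np.asarray(dipole_series, dtype=float)
    mu = mu[~np.isnan(mu)]
    if mu.size == 0:
        raise ModelError("empty dipole series")
    unamb = np.flatnonzero((mu <= le_max) | (mu >= ct_min))
    if len(unamb) == 0:
        return "ambiguous"
    return "CT" if mu[unamb[-1]] >= ct_min else "LE"


def quantum_yield(n_le, n_ct, n_ambiguous=0):
    """Electron-transfer quantum yield: CT / (CT + LE), ambiguous excluded."""
    if n_le < 0 or n_ct < 0:
        raise ModelError("counts must be nonnegative")
    if n_le + n_ct == 0:
        raise ModelError("no labeled TBFs")
    return n_ct / (n_ct + n_le)


def character_summary(archives, surface=1, le_max=LE_MAX, ct_min=CT_MIN,
                      min_weight=0.01):
    """Classify the surviving TBFs on ``surface`` at the end of each run.

    TBFs alive at the final frame but carrying less than ``min_weight`` of
    Mulliken population are not counted as surviving wavepacket branches.
    """
    n_le = n_ct = n_amb = 0
    for arch in archives:
        if arch.truncated:
            continue
        for n in arch.survivors():
            if arch.tbf_state[-1, n] != surface:
                continue
            if arch.tbf_weight[-1, n] < min_weight:
                continue
            lab = classify_tbf_character(arch.tbf_dipole[:, n],
                                         le_max=le_max, ct_min=ct_min)
            if lab == "CT":
                n_ct += 1
            elif lab == "LE":
                n_le += 1
            else:
                n_amb += 1
    y = quantum_yield(n_le, n_ct) if (n_le + n_ct) else float("nan")
    return CharacterSummary(n_le=n_le, n_ct=n_ct, n_ambiguous=n_amb,
                            yield_ct=y)


def fit_lifetime(curve: PopulationCurve, state, p_floor=0.01,
                 bootstrap_curves=None):
    """Single-exponential lifetime of one state's population decay.

    Fits P(t) = exp(-t/tau) from t = 0 to the first crossing of ``p_floor``
    (or the horizon); the uncertainty is the standard deviation of the same
    fit over bootstrap replicate curves when provided.
    """
    t = curve.times
    p = curve.mean[state]
    if p[-1] >= p[0] - 1e-12 or p[0] <= 0:
        return FitResult(None, None, False, "population does not decay")

    def fit_one(pp):
        below = np.flatnonzero(pp < p_floor)
        end = t[below[0]] if len(below) else t[-1]
        mask = t <= end
        popt, _ = curve_fit(lambda tt, tau: np.exp(-tt / tau),
                            t[mask], pp[mask], p0=[max(t[1], 1.0)],
                            maxfev=10000)
        return float(popt[0])

    tau = fit_one(p)
    sigma = None
    if bootstrap_curves is not None:
        taus = []
        for bc in bootstrap_curves:
            try:
                taus.append(fit_one(bc))
            except RuntimeError:
                continue
        if taus:
            sigma = float(np.std(taus))
    return FitResult(tau=tau, sigma=sigma, ok=True)


def decay_completion_time(curve: PopulationCurve, state, threshold=0.10):
    """First time the mean population of ``state`` drops below ``threshold``
    (linear interpolation between frames); (None, horizon) if never."""
    if not (0 < threshold <= 1):
        raise ModelError("threshold must be in (0, 1]")
    t = curve.times
    p = curve.mean[state]
    if p[0] < threshold:
        return 0.0, True
    below = np.flatnonzero(p < threshold)
    if len(below) == 0:
        return float(t[-1]), False
    k = below[0]
    t0, t1 = t[k - 1], t[k]
    p0, p1 = p[k - 1], p[k]
    return float(t0 + (p0 - threshold) / (p0 - p1) * (t1 - t0)), True
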