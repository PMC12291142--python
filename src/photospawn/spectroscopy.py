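"""Ensemble vertical excitations, absorption spectra and state-character
statistics over a Franck-Condon ensemble.

The bright transitions are those to LE-dominant adiabats (the ground-to-LE
transition carries the whole transition dipole); CT-dominant adiabats are
dark.  ``delta_e`` is the energy of the lowest CT-dominant adiabat minus the
lowest LE-dominant one — its sign marks the ordering of the two characters,
and geometries with ``delta_e`` near zero sit close to the LE/CT crossing
seam.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import InitialCondition, ModelError

__all__ = [
    "VerticalExcitationRecord", "Spectrum",
    "vertical_excitations", "absorption_spectrum", "bright_s2_subset",
    "records_to_frame",
]

DEFAULT_FWHM = 0.15  # eV, Gaussian broadening (full width at half maximum)


@dataclass
class VerticalExcitationRecord:
    ic_id: int
    gaps: np.ndarray          # (n_excited,) eV, from S0
    osc: np.ndarray           # (n_excited,)
    dipoles: np.ndarray       # (n_excited,) Debye
    donor_charge: np.ndarray  # (n_excited,)
    characters: tuple         # per excited state: "LE" | "CT"
    delta_e: float            # eV
    bright_s2: bool


@dataclass
class Spectrum:
    energies: np.ndarray
    intensity: np.ndarray
    per_state: np.ndarray     # (n_excited, n_grid) contribution breakdown
    fwhm: float

    @property
    def peak_energy(self):
        return float(self.energies[np.argmax(self.intensity)])

    @property
    def integral(self):
        return float(np.trapezoid(self.intensity, self.energies))


def vertical_excitations(ics, model):
    """Per-IC vertical excitation table for all excited adiabats."""
    if not ics:
        raise ModelError("empty IC list")
    Q = np.array([ic.q for ic in ics])
    out = model.evaluate_batch(Q)
    n_exc = out.energies.shape[1] - 1
    recs = []
    for b in range(len(ics)):
        w = out.weights[b]
        gaps = out.energies[b, 1:] - out.energies[b, 0]
        chars = tuple(
            "CT" if w[s, model.ct_index] >= w[s, model.le_index] else "LE"
            for s in range(1, n_exc + 1))
        bright = (n_exc >= 2 and chars[1] == "LE"
                  and out.osc[b, 2] > out.osc[b, 1])
        recs.append(VerticalExcitationRecord(
            ic_id=b, gaps=gaps, osc=out.osc[b, 1:],
            dipoles=out.dipoles[b, 1:], donor_charge=out.donor_charge[b, 1:],
            characters=chars, delta_e=float(out.delta_e[b]),
            bright_s2=bool(bright)))
    return recs


def records_to_frame(records):
    import pandas as pd
    rows = []
    for r in records:
        for s in range(len(r.gaps)):
            rows.append({
                "ic": r.ic_id, "state": s + 1, "gap_eV": r.gaps[s],
                "osc_strength": r.osc[s], "dipole_D": r.dipoles[s],
                "donor_charge": r.donor_charge[s],
                "character": r.characters[s], "delta_e_eV": r.delta_e,
                "bright_s2": r.bright_s2,
            })
    return pd.DataFrame(rows)


def absorption_spectrum(records, fwhm=DEFAULT_FWHM, e_min=None, e_max=None,
                        n_grid=2000):
    """Ensemble absorption spectrum: oscillator-strength-weighted Gaussians.

    Each vertical transition contributes a normalized Gaussian of the given
    FWHM centered at its gap, weighted by its oscillator strength; the sum
    is averaged over ICs, so the spectrum integral equals the mean total
    oscillator strength.
    """
    if not records:
        raise ModelError("no vertical-excitation records")
    if fwhm <= 0:
        raise ModelError("broadening width must be positive")
    sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    gaps = np.array([r.gaps for r in records])     # (N, S)
    osc = np.array([r.osc for r in records])
    if e_min is None:
        e_min = gaps.min() - 4 * fwhm
    if e_max is None:
        e_max = gaps.max() + 4 * fwhm
    grid = np.linspace(e_min, e_max, n_grid)
    norm = 1.0 / (sigma * np.sqrt(2.0 * np.pi))
    per_state = np.zeros((gaps.shape[1], n_grid))
    for s in range(gaps.shape[1]):
        g = np.exp(-0.5 * ((grid[None, :] - gaps[:, s, None]) / sigma) ** 2)
        per_state[s] = norm * np.mean(osc[:, s, None] * g, axis=0)
    return Spectrum(energies=grid, intensity=per_state.sum(axis=0),
                    per_state=per_state, fwhm=fwhm)


def bright_s2_subset(records, fwhm=DEFAULT_FWHM, **kw):
    """Records whose S2 is a bright LE state above a darker S1, + spectrum."""
    subset = [r for r in records if r.bright_s2]
    spec = absorption_spectrum(subset, fwhm=fwhm, **kw) if subset else None
    return subset, spec
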