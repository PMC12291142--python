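"""Unit system and physical constants.

Internal units throughout the package:

* energy      eV
* time        fs
* coordinates mass-weighted, dimensionless (masses absorbed; effective mass
              1 eV fs^2 per squared coordinate unit)
* dipoles     Debye
* transition dipoles  atomic units (e * a0)

With these choices ``hbar`` = 0.6582119 eV fs exactly, and momenta carry
units of (eV fs) per coordinate unit so that p^2 / (2 m) is an energy.
"""

HBAR = 0.6582119  # eV fs
KB = 8.617333262e-5  # eV / K
HARTREE_EV = 27.211386245988  # eV per Hartree
EV_TO_KCAL = 23.0605  # kcal/mol per eV


def osc_strength(gap_ev: float, tdm_au: float):
    """Oscillator strength f = (2/3) * dE * |mu|^2 in atomic units.

    ``gap_ev`` is the transition energy in eV, ``tdm_au`` the transition
    dipole in atomic units; both may be arrays.
    """
    return (2.0 / 3.0) * (gap_ev / HARTREE_EV) * tdm_au**2
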