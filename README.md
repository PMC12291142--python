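# photospawn

Multiple-spawning nonadiabatic dynamics, ensemble spectroscopy and
excited-state landscape analysis on a calibrated locally-excited /
charge-transfer (LE/CT) model of the first photoinduced electron-transfer
(ET) step in a plant cryptochrome.

## The problem

Blue-light absorption by the flavin (FAD) cofactor of a cryptochrome
triggers electron transfer from a nearby tryptophan, creating the
radical pair that starts signalling. Two routes compete:

* an **ultrafast nonadiabatic route** — thermal fluctuations put a bright,
  locally-excited (LE) S2 above a dark charge-transfer (CT) S1 in part of
  the ground-state ensemble; photoexcitation to that S2 decays through the
  S2/S1 crossing seam within femtoseconds, leaving part of the population
  on the charge-separated state;
* a **slower adiabatic route** — population excited to a bright LE S1
  crosses the S1 barrier between the LE minima and the CT minimum.

Simulating this with multireference QM/MM electronic structure is a
supercomputer campaign. This package reproduces the *mechanism* at desk
scale: the QM/MM surfaces are replaced by a calibrated three-state
(G/LE/CT) diabatic model over two reaction coordinates plus a harmonic
bath, and every method layer — frozen-Gaussian multiple spawning with
stochastic selection (SSAIMS), Born–Oppenheimer NVE/NVT dynamics,
vertical-excitation spectra, nudged-elastic-band paths, crossing-point
optimization — is a faithful implementation of the corresponding
production method. It is aimed at method developers and students of
nonadiabatic dynamics who want a complete, inspectable, seconds-to-minutes
version of this class of study.

## The model and methods in brief

Adiabatic states come from the 3×3 diabatic Hamiltonian with constant
LE–CT coupling λ,

    H = diag(V_G, V_LE, V_CT) + λ (|LE⟩⟨CT| + h.c.),

with V_LE a quartic double well along the flavin distortion coordinate
(minima `LE_high`, `LE_low`), V_CT a Marcus-like displaced well along the
donor–acceptor coordinate, and a switchable protein term ε_env that
destabilizes CT. The nuclear wavefunction is expanded in trajectory basis
functions (TBFs) — frozen Gaussians on classical trajectories — with
amplitudes propagated by the Schrödinger equation in the moving basis;
children are spawned at nonadiabatic-coupling maxima with bundle rewind,
and decoupled TBF groups are pruned by population-weighted stochastic
selection. The electron-transfer quantum yield is the CT fraction
(dipole > 25 D) of the S1 TBFs surviving at 500 fs; the S2 lifetime is a
single-exponential fit to the bootstrap-mean S2 population. Details and
all numerical choices: `docs/methods.md`.

## Worked example

```python
import numpy as np
from photospawn import (default_model, sample_fc_ensemble,
                        vertical_excitations, absorption_spectrum)
from photospawn.pipeline import select_bright_s2_ics
from photospawn.spawning import SpawnConfig, run_ssaims, bootstrap_populations
from photospawn.analysis import character_summary, fit_lifetime

model = default_model()
ics = sample_fc_ensemble(model, 300, 300.0, seed=11)
recs = vertical_excitations(ics, model)
print(f"bright-S2 fraction: {100*np.mean([r.bright_s2 for r in recs]):.1f} %")
print(f"spectrum maximum:   {absorption_spectrum(recs).peak_energy:.2f} eV")

sel = select_bright_s2_ics(ics, recs, 15)
runs = run_ssaims(sel, model, SpawnConfig(), runs_per_ic=5, base_seed=1)
curve = bootstrap_populations(runs, 1000, seed=3)
summ = character_summary(runs)
print(f"surviving S1 TBFs:  {summ.n_le} LE / {summ.n_ct} CT "
      f"-> ET yield {100*summ.yield_ct:.0f} %")
print(f"S2 lifetime:        {fit_lifetime(curve, state=2).tau:.2f} fs")
```

Output from the packaged model (exact TBF counts vary with the seed):

    bright-S2 fraction: 36.0 %
    spectrum maximum:   3.25 eV
    surviving S1 TBFs:  54 LE / 27 CT -> ET yield 33 %
    S2 lifetime:        3.15 fs

The bright-S2 fraction is the share of thermal geometries whose S2 is a
bright LE state above a dark CT S1 — the doorway to the nonadiabatic ET
route; the yield is the fraction of surviving S1 wavepacket branches that
ended charge-separated.

A command-line interface mirrors the library
(`photospawn {sample,spectrum,spawn,nve,nvt,analyze,landscape,pipeline}`);
`photospawn pipeline --seed 1 --out runs/` executes the whole campaign and
writes tabular artifacts plus a hashed manifest.

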