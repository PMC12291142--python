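"""End-to-end campaign orchestration.

Reproduces the full study on the packaged (or a user-supplied) model:

1. thermal Franck-Condon sampling on S0;
2. vertical excitations, absorption spectrum, bright-S2 subset;
3. SSAIMS nonadiabatic campaign from bright-S2 initial conditions;
4. NVE continuations on S1 from the surviving TBF centroids;
5. NVT stability runs from the optimized CT minimum;
6. S1 NVE campaign from bright-S1 FC initial conditions;
7. population / character / lifetime / dipole-map analysis;
8. landscape characterization (minima, NEB paths, MECI, environments).

Every stage derives its RNG seed from the global seed and the stage name;
all artifacts are written below ``out_root`` together with a manifest
(file list, SHA-256 hashes, seeds).
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np

from . import analysis as an
from . import landscape as ls
from . import spectroscopy as sp
from .adiabatic import run_nve_batch, run_nvt_langevin, detect_character_transitions
from .archive import RunArchive
from .config import PipelineConfig
from .model import (DiabaticModel, InitialCondition, default_model,
                    ics_to_frame, load_model, sample_fc_ensemble,
                    toggle_environment)
from .spawning import SpawnConfig, bootstrap_populations, run_ssaims

log = logging.getLogger(__name__)

__all__ = ["run_pipeline", "select_bright_s2_ics", "select_bright_s1_ics",
           "surviving_s1_ics"]


def select_bright_s2_ics(ics, records, n, delta_e_center=-0.35):
    """The SSAIMS launch set: bright-S2 ICs (LE-dominant S2 brighter than
    S1) nearest the given ordering gap, promoted to S2.

    These are geometries photoexcited just above the LE/CT crossing seam;
    the window center controls how far above the seam the packet starts.
    """
    bright = [i for i, r in enumerate(records) if r.bright_s2]
    bright.sort(key=lambda i: abs(records[i].delta_e - delta_e_center))
    out = []
    for i in bright[:n]:
        ic = InitialCondition(ics[i].q.copy(), ics[i].p.copy(), state=2,
                              provenance="FC-sampled", seed=ics[i].seed)
        out.append(ic)
    return out


def select_bright_s1_ics(ics, records, n):
    """FC ICs with a bright LE-dominant S1 (the dominant population),
    promoted to S1, for the adiabatic-ET campaign."""
    idx = [i for i, r in enumerate(records)
           if r.characters[0] == "LE" and r.osc[0] > r.osc[1]]
    out = []
    for i in idx[:n]:
        out.append(InitialCondition(ics[i].q.copy(), ics[i].p.copy(),
                                    state=1, provenance="FC-sampled",
                                    seed=ics[i].seed))
    return out


def surviving_s1_ics(archives):
    """Initial conditions for NVE continuations: position and momentum of
    every S1 TBF surviving at the end of each SSAIMS run."""
    out = []
    for arch in archives:
        if arch.truncated:
            continue
        for n in arch.survivors():
            if arch.tbf_state[-1, n] != 1:
                continue
            out.append(InitialCondition(
                arch.tbf_q[-1, n].copy(), arch.tbf_p[-1, n].copy(), state=1,
                provenance="TBF-centroid"))
    return out


def _sha(path):
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig):
    """Execute all stages; returns the manifest dict (also written to disk).

    A stage failure marks the stage failed in the manifest and skips its
    dependents rather than aborting the rest.
    """
    out = Path(config.out_root)
    out.mkdir(parents=True, exist_ok=True)
    model = (default_model() if config.model_path is None
             else load_model(config.model_path))
    cb, ab, lb = config.campaign, config.analysis, config.landscape
    manifest = {"seed": config.seed, "stages": {}, "files": {}}

    def register(name, path):
        manifest["files"][name] = {"path": str(path), "sha256": _sha(path)}

    def stage(name, deps=()):
        def deco(fn):
            def run(results):
                for dep in deps:
                    if manifest["stages"].get(dep, {}).get("status") != "ok":
                        manifest["stages"][name] = {
                            "status": "skipped", "reason": f"dependency {dep}"}
                        return None
                seed = config.stage_seed(name)
                try:
                    value = fn(results, seed)
                except Exception as exc:   # noqa: BLE001 - stage isolation
                    log.exception("stage %s failed", name)
                    manifest["stages"][name] = {"status": "failed",
                                                "error": str(exc)}
                    return None
                manifest["stages"][name] = {"status": "ok", "seed": seed}
                return value
            return (name, run)
        return deco

    results = {}

    @stage("fc_sampling")
    def _fc(results, seed):
        ics = sample_fc_ensemble(model, cb.n_ics, cb.temperature, seed)
        ics_to_frame(ics).to_csv(out / "fc_ensemble.csv", index=False)
        register("fc_ensemble", out / "fc_ensemble.csv")
        return ics

    @stage("spectroscopy", deps=("fc_sampling",))
    def _spec(results, seed):
        recs = sp.vertical_excitations(results["fc_sampling"], model)
        sp.records_to_frame(recs).to_csv(out / "vertical_excitations.csv",
                                         index=False)
        spec = sp.absorption_spectrum(recs, fwhm=ab.spectrum_fwhm)
        subset, sub_spec = sp.bright_s2_subset(recs, fwhm=ab.spectrum_fwhm)
        np.savetxt(out / "spectrum.tsv",
                   np.column_stack([spec.energies, spec.intensity]),
                   header="energy_eV intensity")
        with open(out / "spectrum_meta.json", "w") as fh:
            json.dump({"fwhm_eV": spec.fwhm, "peak_eV": spec.peak_energy,
                       "n_bright_s2": len(subset),
                       "bright_fraction": len(subset) / len(recs)}, fh,
                      indent=1)
        for n in ("vertical_excitations.csv", "spectrum.tsv",
                  "spectrum_meta.json"):
            register(n, out / n)
        return recs

    @stage("ssaims", deps=("fc_sampling", "spectroscopy"))
    def _ssaims(results, seed):
        sel = select_bright_s2_ics(results["fc_sampling"],
                                   results["spectroscopy"], cb.n_select,
                                   cb.ic_delta_e_center)
        scfg = SpawnConfig(dt=cb.dt, horizon=cb.horizon,
                           spawn_threshold=cb.spawn_threshold,
                           overlap_threshold=cb.overlap_threshold,
                           max_tbfs=cb.max_tbfs)
        arcs = run_ssaims(sel, model, scfg, runs_per_ic=cb.runs_per_ic,
                          base_seed=seed)
        adir = out / "ssaims"
        adir.mkdir(exist_ok=True)
        for k, a in enumerate(arcs):
            a.to_hdf5(adir / f"run_{k:03d}.h5")
        register("ssaims_run0", adir / "run_000.h5")
        return arcs

    @stage("population_analysis", deps=("ssaims",))
    def _pop(results, seed):
        arcs = results["ssaims"]
        curve = bootstrap_populations(arcs, ab.n_boot, seed=seed)
        summ = an.character_summary(arcs, surface=1, le_max=ab.le_max,
                                    ct_min=ab.ct_min)
        fit = an.fit_lifetime(curve, state=2)
        t10, reached = an.decay_completion_time(curve, state=2)
        dmap = an.dipole_time_distribution(
            arcs, sigma_dipole=ab.sigma_dipole, sigma_time=ab.sigma_time)
        np.savetxt(out / "dipole_map.tsv", dmap.density)
        payload = {
            "counts": summ.counts, "quantum_yield": summ.yield_ct,
            "tau_fs": fit.tau, "tau_sigma_fs": fit.sigma,
            "t_below_0.1_fs": t10, "decay_completed": reached,
            "seed": seed,
        }
        with open(out / "character_summary.json", "w") as fh:
            json.dump(payload, fh, indent=1)
        register("character_summary", out / "character_summary.json")
        register("dipole_map", out / "dipole_map.tsv")
        return {"curve": curve, "summary": summ, "fit": fit, "t10": t10}

    @stage("post_ssaims_nve", deps=("ssaims",))
    def _nve_post(results, seed):
        ics = surviving_s1_ics(results["ssaims"])
        trajs = run_nve_batch(ics, model, surface=1,
                              horizon=cb.nve_horizon, dt=cb.dt)
        rows = []
        for k, tr in enumerate(trajs):
            ev, final = detect_character_transitions(
                tr, le_max=ab.le_max, ct_min=ab.ct_min, dwell=ab.dwell)
            rows.append({"traj": k, "final": final, "n_events": len(ev),
                         "min_gap_eV": float(tr.gap.min())})
        import pandas as pd
        pd.DataFrame(rows).to_csv(out / "post_ssaims_nve.csv", index=False)
        register("post_ssaims_nve", out / "post_ssaims_nve.csv")
        return trajs

    @stage("nvt_ct_stability")
    def _nvt(results, seed):
        ct = ls.find_default_minimum(model, "CT")
        ic = InitialCondition(ct.q, np.zeros_like(ct.q), state=1,
                              provenance="optimized-minimum")
        rows = []
        for k in range(cb.n_nvt):
            tr = run_nvt_langevin(ic, model, 1, cb.temperature,
                                  friction=cb.nvt_friction,
                                  horizon=cb.nvt_horizon, dt=cb.dt,
                                  seed=seed + k)
            rows.append({"run": k, "mean_gap_eV": float(tr.gap.mean()),
                         "min_gap_eV": float(tr.gap.min()),
                         "mean_dipole_D": float(tr.dipole.mean()),
                         "final": detect_character_transitions(
                             tr, ab.le_max, ab.ct_min, ab.dwell)[1]})
        import pandas as pd
        pd.DataFrame(rows).to_csv(out / "nvt_ct_stability.csv", index=False)
        register("nvt_ct_stability", out / "nvt_ct_stability.csv")
        return rows

    @stage("fc_s1_nve", deps=("fc_sampling", "spectroscopy"))
    def _nve_fc(results, seed):
        sel = select_bright_s1_ics(results["fc_sampling"],
                                   results["spectroscopy"], cb.n_nve)
        trajs = run_nve_batch(sel, model, surface=1, horizon=cb.nve_horizon,
                              dt=cb.dt)
        rows = []
        for k, tr in enumerate(trajs):
            ev, final = detect_character_transitions(
                tr, le_max=ab.le_max, ct_min=ab.ct_min, dwell=ab.dwell)
            rows.append({"traj": k, "final": final,
                         "le_to_ct": any(e.direction == "LE->CT" for e in ev),
                         "min_gap_eV": float(tr.gap.min())})
        import pandas as pd
        pd.DataFrame(rows).to_csv(out / "fc_s1_nve.csv", index=False)
        register("fc_s1_nve", out / "fc_s1_nve.csv")
        return rows

    @stage("landscape")
    def _land(results, seed):
        pts = {lab: ls.find_default_minimum(model, lab)
               for lab in ("LE_low", "LE_high", "CT")}
        p1 = ls.neb_mep(model, 1, pts["LE_low"], pts["LE_high"],
                        n_images=lb.n_images, climbing=lb.climbing)
        p2 = ls.neb_mep(model, 1, pts["LE_high"], pts["CT"],
                        n_images=lb.n_images, climbing=lb.climbing)
        p1.to_frame().to_csv(out / "mep_lelow_lehigh.csv", index=False)
        p2.to_frame().to_csv(out / "mep_lehigh_ct.csv", index=False)
        rng = np.random.default_rng(seed)
        fc = sample_fc_ensemble(model, lb.n_meci_points, cb.temperature,
                                seed)
        mecis = []
        for ic in fc:
            anchor = ls.optimize_minimum(model, 0, ic.q, local_radius=3.0)
            ref = float(model.evaluate(anchor.q).energies[2])
            meci = ls.optimize_meci(model, 1, 2, anchor.q, ref_energy=ref)
            mecis.append({"e_rel_eV": meci.e_rel, "gap_eV": meci.gap,
                          "residual_gap_eV": meci.residual_gap})
        payload = {
            "minima": {lab: {"q": list(p.q), "energy_eV": p.energy,
                             "gap_eV": p.gap} for lab, p in pts.items()},
            "barrier_lelow_lehigh_kcal": p1.barrier_kcal,
            "barrier_lehigh_ct_kcal": p2.barrier_kcal,
            "barrier_ct_lehigh_kcal":
                (p2.energies.max() - p2.energies[-1]) * 23.0605,
            "meci": mecis,
        }
        with open(out / "landscape.json", "w") as fh:
            json.dump(payload, fh, indent=1)
        register("landscape", out / "landscape.json")
        return payload

    @stage("environment_comparison", deps=("post_ssaims_nve",))
    def _env(results, seed):
        trajs = results["post_ssaims_nve"]
        rng = np.random.default_rng(seed)
        snaps = []
        for _ in range(lb.n_env_snapshots):
            tr = trajs[rng.integers(len(trajs))]
            snaps.append(tr.q[rng.integers(len(tr.q))])
        df, summary = ls.compare_environments(model, snaps)
        df.to_csv(out / "environment_comparison.csv", index=False)
        with open(out / "environment_summary.json", "w") as fh:
            json.dump(summary, fh, indent=1)
        register("environment_comparison", out / "environment_comparison.csv")
        return summary

    stages = [_fc, _spec, _ssaims, _pop, _nve_post, _nvt, _nve_fc, _land,
              _env]
    for name, run in stages:
        log.info("stage %s", name)
        value = run(results)
        if value is not None:
            results[name] = value

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
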