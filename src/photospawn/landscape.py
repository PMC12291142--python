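"""Excited-state landscape characterization.

Stationary points (free and constrained), nudged-elastic-band minimum-energy
paths with barriers and S0-S1 gap profiles, minimal-energy conical
intersection (MECI) optimization by a smoothed gap penalty, and the
protein-versus-vacuum comparison of S1 minima.

On the default model the S1 surface carries three basins: two locally
excited minima (``LE_high`` close to the Franck-Condon region, ``LE_low``
displaced along the intramolecular coordinate with a lower emission gap) and
one charge-transfer minimum (``CT``) displaced along the donor-acceptor
coordinate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .model import DiabaticModel, ModelError, toggle_environment
from .units import EV_TO_KCAL

__all__ = [
    "StationaryPoint", "MEPPath", "MECIPoint", "LandscapeError",
    "optimize_minimum", "neb_mep", "optimize_meci", "compare_environments",
    "find_default_minimum", "basin_label",
]


class LandscapeError(RuntimeError):
    pass


@dataclass
class StationaryPoint:
    q: np.ndarray
    surface: int
    energy: float
    gap: float
    character: str           # LE_low | LE_high | CT | LE | G
    hessian_signs: tuple
    constraint_mask: np.ndarray | None
    grad_norm: float


@dataclass
class MEPPath:
    images: np.ndarray       # (N+1, d)
    energies: np.ndarray     # (N+1,) surface energy, eV
    gaps: np.ndarray         # (N+1,) S0-S1 gap, eV
    surface: int
    spring: float
    climbing: bool

    @property
    def barrier(self):
        """Barrier relative to the path start, eV."""
        return float(self.energies.max() - self.energies[0])

    @property
    def barrier_kcal(self):
        return self.barrier * EV_TO_KCAL

    @property
    def arc_length(self):
        seg = np.linalg.norm(np.diff(self.images, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(seg)])

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({
            "image": np.arange(len(self.energies)),
            "arc_length": self.arc_length,
            "energy_eV": self.energies,
            "gap_eV": self.gaps,
        })


@dataclass
class MECIPoint:
    q: np.ndarray
    states: tuple
    mean_energy: float
    gap: float
    residual_gap: float      # gap above the model's minimal attainable splitting
    e_rel: float | None      # mean energy minus a reference FC S2 energy
    converged: bool


# ---------------------------------------------------------------------------
# minima
# ---------------------------------------------------------------------------


def optimize_minimum(model, surface, q0, constraint_mask=None, tol=1e-7,
                     max_iter=500, local_radius=None) -> StationaryPoint:
    """Quasi-Newton minimization on one adiabatic surface.

    ``constraint_mask`` marks coordinates held exactly fixed (True = frozen).
    ``local_radius`` bounds the search inside a box around the starting
    basin; excited-state minima here can be separated by sub-kcal/mol
    barriers that an unconstrained quasi-Newton step may overshoot.
    """
    q0 = np.asarray(q0, dtype=float).copy()
    if q0.shape != (model.n_dims,):
        raise ModelError("starting geometry has wrong dimensionality")
    if constraint_mask is None:
        mask = np.zeros(model.n_dims, dtype=bool)
    else:
        mask = np.asarray(constraint_mask, dtype=bool)
    free = ~mask

    def fg(x):
        q = q0.copy()
        q[free] = x
        out = model.evaluate_batch(q[None])
        return out.energies[0, surface], out.gradients[0, surface][free]

    # short capped gradient descent keeps the search inside the local basin
    # (excited-state minima can be separated by sub-kcal/mol barriers)
    x = q0[free].copy()
    for _ in range(60):
        e, g = fg(x)
        gn = np.linalg.norm(g)
        if gn < 1e-6:
            break
        step = -g * min(0.5, 0.15 / gn)
        x = x + step
    bounds = None
    if local_radius is not None:
        bounds = [(xi - local_radius, xi + local_radius) for xi in x]
    for _ in range(3):
        res = minimize(fg, x, jac=True, method="L-BFGS-B", bounds=bounds,
                       options={"maxiter": max_iter, "gtol": tol,
                                "ftol": 1e-15})
        x = res.x
        if np.linalg.norm(fg(x)[1]) < 1e-5:
            break
        for _ in range(40):   # extra descent breaks flat-region stalls
            e, g = fg(x)
            gn = np.linalg.norm(g)
            if gn < 1e-7:
                break
            x = x - g * min(0.5, 0.05 / gn)
    q = q0.copy()
    q[free] = x
    ev = model.evaluate(q, hessian=True)
    gnorm = float(np.linalg.norm(ev.gradients[surface][free]))
    if gnorm > 1e-3:
        raise LandscapeError(
            f"minimization did not converge (|g| = {gnorm:.2e})")
    H = ev.hessians[surface][np.ix_(free, free)]
    eigs = np.linalg.eigvalsh(H) if H.size else np.array([])
    signs = tuple(int(np.sign(e)) for e in eigs)
    return StationaryPoint(
        q=q, surface=surface, energy=float(ev.energies[surface]),
        gap=float(ev.energies[surface] - ev.energies[0]),
        character=basin_label(model, q, surface),
        hessian_signs=signs, constraint_mask=mask if mask.any() else None,
        grad_norm=gnorm,
    )


def _le_poly_minima(model: DiabaticModel):
    """Positions of the two LE-diabat minima and the saddle along q1."""
    c = np.asarray(model.le_poly)
    dcoef = np.array([c[1], 2 * c[2], 3 * c[3], 4 * c[4]])
    roots = np.roots(dcoef[::-1])
    roots = np.sort(roots[np.abs(roots.imag) < 1e-8].real)
    if len(roots) != 3:
        raise LandscapeError("LE diabat does not have a double well")
    lo, saddle, hi = roots  # positions, ascending in q1
    def f(x):
        return np.polynomial.polynomial.polyval(x, c)
    mins = sorted([lo, hi], key=f)   # [deeper, shallower] in LE energy
    return {"LE_low": mins[0], "LE_high": mins[1], "saddle": saddle}


def _bath_relaxed(model, q1, q2):
    q = np.zeros(model.n_dims)
    q[0], q[1] = q1, q2
    if model.n_dims > 2:
        q[2:] = model._bc * q[[0, 1]][model._bm]
    return q


def basin_label(model, q, surface):
    """Character label of one adiabatic state at ``q``.

    LE-dominant S1 points are split into LE_low / LE_high by the LE-diabat
    saddle along q1; CT-dominant points are labeled CT.
    """
    ev = model.evaluate(np.asarray(q, dtype=float))
    w = ev.weights[surface]
    dom = int(np.argmax(w))
    if dom == model.ground_index:
        return "G"
    if w[model.ct_index] >= w[model.le_index]:   # ties toward CT
        return "CT"
    try:
        pts = _le_poly_minima(model)
    except LandscapeError:
        return "LE"
    return "LE_low" if (q[0] - pts["saddle"]) * (pts["LE_low"] - pts["saddle"]) > 0 \
        else "LE_high"


def find_default_minimum(model: DiabaticModel, label, surface=1):
    """Optimize the named S1 basin (LE_low | LE_high | CT) of the model."""
    if label == "CT":
        q0 = _bath_relaxed(model, *model.ct_center)
    else:
        pts = _le_poly_minima(model)
        q0 = _bath_relaxed(model, pts[label], 0.0)
    pt = optimize_minimum(model, surface, q0, local_radius=1.0)
    if pt.character != label:
        raise LandscapeError(
            f"optimization from the {label} guess converged to {pt.character}")
    return pt


# ---------------------------------------------------------------------------
# NEB
# ---------------------------------------------------------------------------


def _fire(x0, force_fn, fixed_ends, max_steps=16000, fmax=2e-4, dt=0.08,
          max_disp=0.05):
    """QuickMin band relaxation: per-image projected-velocity descent.

    Each image carries its own velocity, projected onto its force direction
    and zeroed when it opposes the force; per-image steps are capped, which
    keeps one runaway image from stalling the whole band.
    """
    x = x0.copy()
    v = np.zeros_like(x)
    for _ in range(max_steps):
        f = force_fn(x)
        f[0] = 0.0
        f[-1] = 0.0
        if np.abs(f).max() < fmax:
            return x, True
        fn2 = np.sum(f * f, axis=-1, keepdims=True)
        proj = np.sum(v * f, axis=-1, keepdims=True)
        v = np.where(proj > 0, proj * f / np.maximum(fn2, 1e-30), 0.0)
        v += dt * f
        step = dt * v
        norms = np.linalg.norm(step, axis=-1, keepdims=True)
        step *= np.minimum(1.0, max_disp / np.maximum(norms, 1e-30))
        x = x + step
    return x, False


def neb_mep(model, surface, end_a: StationaryPoint, end_b: StationaryPoint,
            n_images=20, k_spring=None, climbing=True, max_steps=4000,
            fmax=2e-4) -> MEPPath:
    """Nudged-elastic-band minimum-energy path between two converged minima.

    Improved-tangent NEB with an optional climbing image; ``k_spring``
    defaults to an auto-scale set by the energy span of the straight path.
    """
    if end_a.surface != end_b.surface or end_a.surface != surface:
        raise ModelError("NEB endpoints must lie on the requested surface")
    d = model.n_dims
    N = n_images + 1
    t = np.linspace(0.0, 1.0, N)[:, None]
    band = (1 - t) * end_a.q[None] + t * end_b.q[None]

    if k_spring is None:
        E0 = model.evaluate_batch(band).energies[:, surface]
        span = max(E0.max() - E0.min(), 0.05)
        L = np.linalg.norm(end_b.q - end_a.q)
        k_spring = 2.0 * span / max((L / n_images) ** 2, 1e-6) / n_images

    climb_idx = [None]

    def forces(band):
        E, G = model.surface(band, surface)
        F = -G
        tau = np.zeros_like(band)
        # improved (energy-weighted) tangents
        for i in range(1, N - 1):
            dp = band[i + 1] - band[i]
            dm = band[i] - band[i - 1]
            if E[i + 1] > E[i] > E[i - 1]:
                tau[i] = dp
            elif E[i + 1] < E[i] < E[i - 1]:
                tau[i] = dm
            else:
                dEmax = max(abs(E[i + 1] - E[i]), abs(E[i - 1] - E[i]))
                dEmin = min(abs(E[i + 1] - E[i]), abs(E[i - 1] - E[i]))
                if E[i + 1] > E[i - 1]:
                    tau[i] = dp * dEmax + dm * dEmin
                else:
                    tau[i] = dp * dEmin + dm * dEmax
            tau[i] /= max(np.linalg.norm(tau[i]), 1e-30)
        Fout = np.zeros_like(band)
        for i in range(1, N - 1):
            fpar = np.dot(F[i], tau[i])
            fperp = F[i] - fpar * tau[i]
            fspring = k_spring * (np.linalg.norm(band[i + 1] - band[i])
                                  - np.linalg.norm(band[i] - band[i - 1]))
            if climbing and climb_idx[0] == i:
                Fout[i] = F[i] - 2.0 * fpar * tau[i]
            else:
                Fout[i] = fperp + fspring * tau[i]
        return Fout, E

    # stage 1: plain NEB to roughly converge the path
    def f_plain(b):
        return forces(b)[0]

    band, _ = _fire(band, f_plain, True, max_steps=max_steps, fmax=5 * fmax)
    if climbing:
        E = model.evaluate_batch(band).energies[:, surface]
        climb_idx[0] = int(np.argmax(E[1:-1])) + 1
        band, ok = _fire(band, f_plain, True, max_steps=max_steps, fmax=fmax)
        if not ok:
            # narrowly-avoided crossings leave a sharp ridge that the
            # climbing image cannot track; refine the highest image with a
            # Newton saddle search on the analytic Hessian instead
            E = model.evaluate_batch(band).energies[:, surface]
            k = int(np.argmax(E[1:-1])) + 1
            try:
                band[k] = _newton_saddle(model, surface, band[k])
            except LandscapeError:
                pass   # keep the relaxed band maximum
            climb_idx[0] = None
    if np.linalg.norm(np.diff(band, axis=0), axis=1).max() < 1e-10:
        raise LandscapeError("NEB band collapsed")

    out = model.evaluate_batch(band)
    return MEPPath(images=band, energies=out.energies[:, surface],
                   gaps=out.energies[:, surface] - out.energies[:, 0],
                   surface=surface, spring=float(k_spring), climbing=climbing)


# ---------------------------------------------------------------------------
# MECI
# ---------------------------------------------------------------------------


def _newton_saddle(model, surface, q0, max_iter=80, gtol=1e-8):
    """Newton search for the first-order saddle nearest ``q0``."""
    q = np.asarray(q0, dtype=float).copy()
    for _ in range(max_iter):
        ev = model.evaluate(q, hessian=True)
        g = ev.gradients[surface]
        if np.linalg.norm(g) < gtol:
            break
        H = ev.hessians[surface]
        w, V = np.linalg.eigh(H)
        w = np.where(np.abs(w) < 1e-8, 1e-8, w)
        step = -V @ ((V.T @ g) / w)
        n = np.linalg.norm(step)
        if n > 0.1:
            step *= 0.1 / n
        q = q + step
    ev = model.evaluate(q, hessian=True)
    if np.linalg.norm(ev.gradients[surface]) > 1e-6:
        raise LandscapeError("saddle refinement did not converge")
    if int((np.linalg.eigvalsh(ev.hessians[surface]) < -1e-6).sum()) != 1:
        raise LandscapeError("saddle refinement found a non-first-order point")
    return q


def min_pair_gap(model):
    """Smallest adiabatic splitting attainable between the coupled pair."""
    return 2.0 * float(model.lam)


def optimize_meci(model, state_i, state_j, q0, ref_energy=None, gap_tol=1e-3,
                  sigma0=2.0, sigma_growth=6.0, max_cycles=16,
                  local_radius=1.5) -> MECIPoint:
    """Minimal-energy crossing point of two adiabats by a smoothed penalty.

    Minimizes the mean pair energy plus a quadratic penalty on the squared
    gap in excess of the model's minimal attainable splitting (2*lambda for
    a Condon-coupled pair, zero for uncoupled surfaces); the penalty weight
    grows geometrically until the residual gap is within ``gap_tol``.

    The search is local (a trust box of ``local_radius`` around the start),
    matching how crossing-point optimizers behave in practice: from a
    Franck-Condon starting geometry it converges to the adjacent funnel of
    the seam rather than sliding to the seam's global bottom.
    """
    if state_j <= state_i:
        raise ModelError("state_j must be above state_i")
    floor = min_pair_gap(model)
    q = np.asarray(q0, dtype=float).copy()
    sigma = sigma0
    for _ in range(max_cycles):
        def fg(x):
            out = model.evaluate_batch(x[None])
            e = out.energies[0]
            g = out.gradients[0]
            gap = e[state_j] - e[state_i]
            mean = 0.5 * (e[state_j] + e[state_i])
            dmean = 0.5 * (g[state_j] + g[state_i])
            dgap = g[state_j] - g[state_i]
            pen = gap**2 - floor**2
            val = mean + sigma * pen
            grad = dmean + sigma * 2.0 * gap * dgap
            return val, grad

        bounds = None
        if local_radius is not None:
            q_anchor = np.asarray(q0, dtype=float)
            bounds = [(xi - local_radius, xi + local_radius)
                      for xi in q_anchor]
        res = minimize(fg, q, jac=True, method="L-BFGS-B", bounds=bounds,
                       options={"maxiter": 400, "gtol": 1e-9, "ftol": 1e-15})
        q = res.x
        out = model.evaluate(q)
        gap = float(out.energies[state_j] - out.energies[state_i])
        if gap - floor <= gap_tol:
            mean = 0.5 * float(out.energies[state_j] + out.energies[state_i])
            return MECIPoint(
                q=q, states=(state_i, state_j), mean_energy=mean, gap=gap,
                residual_gap=gap - floor,
                e_rel=None if ref_energy is None else mean - ref_energy,
                converged=True)
        sigma *= sigma_growth
    raise LandscapeError(
        f"MECI penalty loop stalled with residual gap {gap - floor:.2e} eV")


# ---------------------------------------------------------------------------
# environment comparison
# ---------------------------------------------------------------------------


def compare_environments(model: DiabaticModel, snapshots, constraint_mask=None,
                         surface=1):
    """Protein-vs-vacuum characterization of S1 minima.

    For each snapshot geometry: constrained optimization on S1 in protein
    mode, vacuum single-point at the identical optimized geometry, and a
    fully free optimization in vacuum.  Returns a pandas DataFrame (one row
    per snapshot) and a summary dict with majority characters.
    """
    import pandas as pd

    protein = toggle_environment(model, "protein")
    vacuum = toggle_environment(model, "vacuum")
    if constraint_mask is None:
        # surrogate of the frozen QM/MM boundary: bath coordinates fixed
        constraint_mask = np.zeros(model.n_dims, dtype=bool)
        constraint_mask[2:] = True
    rows = []
    for k, q in enumerate(snapshots):
        try:
            popt = optimize_minimum(protein, surface, q, constraint_mask,
                                    local_radius=2.0)
            ev_vac = vacuum.evaluate(popt.q)
            vac_char = ("CT" if ev_vac.weights[surface][model.ct_index]
                        >= ev_vac.weights[surface][model.le_index] else "LE")
            fopt = optimize_minimum(vacuum, surface, q)
            rows.append({
                "snapshot": k,
                "protein_character": "CT" if popt.character == "CT" else "LE",
                "protein_gap": popt.gap,
                "vacuum_sp_character": vac_char,
                "vacuum_sp_gap": float(ev_vac.energies[surface] - ev_vac.energies[0]),
                "vacuum_opt_character": "CT" if fopt.character == "CT" else "LE",
                "vacuum_opt_gap": fopt.gap,
                "ok": True,
            })
        except LandscapeError as exc:  # pragma: no cover - defensive
            rows.append({"snapshot": k, "ok": False, "error": str(exc)})
    df = pd.DataFrame(rows)
    good = df[df["ok"]]
    summary = {
        "n": int(len(good)),
        "protein_le_fraction": float((good["protein_character"] == "LE").mean()),
        "vacuum_sp_ct_fraction": float((good["vacuum_sp_character"] == "CT").mean()),
        "vacuum_opt_ct_fraction": float((good["vacuum_opt_character"] == "CT").mean()),
    }
    return df, summary
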