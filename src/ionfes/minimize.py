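"""Inherent-structure analysis: quenching configurations to local minima.

Finite-temperature configurations are quenched on the potential-energy
surface by steepest descent (backtracking Armijo line search) followed by
Polak-Ribiere conjugate gradient with automatic restarts, stopping when the
maximum force component drops below the threshold (default 1e-4 reduced
force units, i.e. 10 x 10^-5 kBT per length unit).  Both the max-component
and the Euclidean force norms are reported, since a "force threshold" can
reasonably mean either.

The solvers operate on plain (fun, grad) callables; system-level wrappers
flatten the free coordinates of a ToySystem and recompute the coordination
number on the quenched geometry so the U-vs-CN scatter of the
potential-energy landscape can be assembled.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .cvs import CVSpec, coordination_number
from .potentials import EnergyModel, ToySystem

FORCE_TOL = 1e-4  # reduced kBT / length


@dataclass
class QuenchRecord:
    """Outcome of quenching one configuration to its nearest minimum."""

    source_id: str
    u_final: float
    cn_final: float
    n_sd_steps: int
    n_cg_steps: int
    converged: bool
    max_force_final: float
    force_norm_final: float


def steepest_descent(fun, grad, x0, max_steps: int = 500, force_tol: float = FORCE_TOL,
                     step0: float = 0.05, armijo: float = 1e-4,
                     shrink: float = 0.5) -> tuple[np.ndarray, dict]:
    """Steepest descent with backtracking Armijo line search.

    Energy is non-increasing at every accepted step.  Returns the final
    point and an info dict (n_steps, converged, max_force).  Step-size
    underflow without progress flags non-convergence and returns the
    partial result.
    """
    x = np.array(x0, dtype=float)
    f = fun(x)
    if not np.isfinite(f):
        raise ValueError("starting energy is not finite")
    g = grad(x)
    step = step0
    n = 0
    for n in range(1, max_steps + 1):
        gmax = np.max(np.abs(g))
        if gmax <= force_tol:
            return x, {"n_steps": n - 1, "converged": True, "max_force": float(gmax)}
        d = -g
        gd = float(np.dot(g.ravel(), d.ravel()))
        alpha = step
        while True:
            x_new = x + alpha * d
            f_new = fun(x_new)
            if np.isfinite(f_new) and f_new <= f + armijo * alpha * gd:
                break
            alpha *= shrink
            if alpha < 1e-16:
                return x, {"n_steps": n, "converged": False,
                           "max_force": float(np.max(np.abs(g)))}
        x, f = x_new, f_new
        g = grad(x)
        # grow the trial step after easy acceptance, shrink memory otherwise
        step = min(alpha / shrink, 1.0)
    return x, {"n_steps": n, "converged": bool(np.max(np.abs(g)) <= force_tol),
               "max_force": float(np.max(np.abs(g)))}


def conjugate_gradient(fun, grad, x0, force_tol: float = FORCE_TOL,
                       max_steps: int = 1000) -> tuple[np.ndarray, dict]:
    """Polak-Ribiere(+) conjugate gradient with secant line searches.

    The line search solves phi'(alpha) = grad(x + alpha d) . d = 0 by secant
    iteration (exact in one step on quadratics, hence CG terminates in at
    most dim iterations there), with an Armijo backtracking fallback; a
    failed search restarts along the steepest-descent direction.
    """
    x = np.array(x0, dtype=float)
    f = fun(x)
    if not np.isfinite(f):
        raise ValueError("starting energy is not finite")
    g = grad(x)
    d = -g
    n_iter = 0
    for n_iter in range(1, max_steps + 1):
        gmax = np.max(np.abs(g))
        if gmax <= force_tol:
            return x, {"n_steps": n_iter - 1, "converged": True, "max_force": float(gmax)}
        gd0 = float(np.dot(g.ravel(), d.ravel()))
        if gd0 >= 0:  # not a descent direction: restart
            d = -g
            gd0 = -float(np.dot(g.ravel(), g.ravel()))
        alpha = _secant_line_search(fun, grad, x, d, f, gd0)
        if alpha is None:
            # line search failed; restart with plain steepest descent
            x, info = steepest_descent(fun, grad, x, max_steps=5,
                                       force_tol=force_tol)
            f, g = fun(x), grad(x)
            d = -g
            continue
        x_new = x + alpha * d
        g_new = grad(x_new)
        beta = float(np.dot(g_new.ravel(), (g_new - g).ravel())
                     / np.dot(g.ravel(), g.ravel()))
        beta = max(0.0, beta)  # PR+ automatic restart
        d = -g_new + beta * d
        x, f, g = x_new, fun(x_new), g_new
    return x, {"n_steps": n_iter, "converged": bool(np.max(np.abs(g)) <= force_tol),
               "max_force": float(np.max(np.abs(g)))}


def _secant_line_search(fun, grad, x, d, f0, gd0, max_secant: int = 8):
    """Return alpha approximately zeroing phi'(a) = grad(x + a d) . d, or None."""
    def dphi(a):
        return float(np.dot(grad(x + a * d).ravel(), d.ravel()))

    a_prev, g_prev = 0.0, gd0
    a = min(1.0, 2.0 * abs(f0) / max(abs(gd0), 1e-300)) if f0 != 0 else 1.0
    a = max(min(a, 1.0), 1e-12)
    for _ in range(max_secant):
        g_a = dphi(a)
        if abs(g_a) <= 1e-2 * abs(gd0) or g_a == g_prev:
            break
        a_next = a - g_a * (a - a_prev) / (g_a - g_prev)
        if not np.isfinite(a_next) or a_next <= 0:
            break
        a_prev, g_prev = a, g_a
        a = a_next
    f_a = fun(x + a * d)
    if np.isfinite(f_a) and f_a <= f0 + 1e-4 * a * gd0:
        return a
    # Armijo backtracking fallback
    alpha = a
    for _ in range(40):
        alpha *= 0.5
        f_a = fun(x + alpha * d)
        if np.isfinite(f_a) and f_a <= f0 + 1e-4 * alpha * gd0:
            return alpha
    return None


def system_objective(system: ToySystem):
    """(fun, grad, unpack) over the flattened free coordinates of a system."""
    model = EnergyModel(system, check_overlap=False)
    free = np.flatnonzero(~system.frozen)
    base = np.array(system.positions, dtype=float)

    def unpack(z):
        pos = base.copy()
        pos[free] = z.reshape(-1, 3)
        return pos

    def fun(z):
        return model.energy_forces(unpack(z))[0]

    def grad(z):
        _, f = model.energy_forces(unpack(z))
        return -f[free].ravel()

    return fun, grad, unpack


def quench(system: ToySystem, cv: CVSpec | None = None, source_id: str = "",
           sd_steps: int = 200, force_tol: float = FORCE_TOL,
           cg_steps: int = 2000) -> tuple[ToySystem, QuenchRecord]:
    """Quench a system to its nearest minimum (steepest descent, then CG)."""
    fun, grad, unpack = system_objective(system)
    z0 = system.positions[~system.frozen].ravel()
    z1, sd_info = steepest_descent(fun, grad, z0, max_steps=sd_steps,
                                   force_tol=force_tol)
    z2, cg_info = conjugate_gradient(fun, grad, z1, force_tol=force_tol,
                                     max_steps=cg_steps)
    pos = unpack(z2)
    g = grad(z2)
    cn = coordination_number(pos, cv)[0] if cv is not None else float("nan")
    rec = QuenchRecord(source_id=source_id, u_final=float(fun(z2)), cn_final=cn,
                       n_sd_steps=sd_info["n_steps"], n_cg_steps=cg_info["n_steps"],
                       converged=bool(cg_info["converged"]),
                       max_force_final=float(np.max(np.abs(g))),
                       force_norm_final=float(np.linalg.norm(g)))
    return system.with_positions(pos), rec


def strip_solvent(system: ToySystem, cv: CVSpec | None = None):
    """Remove all solvent_oxygen particles, remapping bonds and CV indices."""
    keep = [i for i, r in enumerate(system.roles) if r != "solvent_oxygen"]
    remap = {old: new for new, old in enumerate(keep)}
    bonds = [(remap[i], remap[j], bp) for i, j, bp in system.bonds
             if i in remap and j in remap]
    sub = ToySystem(
        positions=system.positions[keep],
        roles=[system.roles[i] for i in keep],
        charges=system.charges[keep],
        masses=system.masses[keep],
        bonds=bonds,
        pair_table=dict(system.pair_table),
        tether_k=system.tether_k[keep],
        tether_centers=system.tether_centers[keep],
        frozen=system.frozen[keep],
    )
    if cv is None:
        return sub, None
    members = tuple(remap[i] for i in cv.member_particles if i in remap)
    cv2 = replace(cv, center_particle=remap[cv.center_particle],
                  member_particles=members)
    return sub, cv2


def inherent_structure_scan(frames: np.ndarray, system: ToySystem, cv: CVSpec,
                            strip_solvent_first: bool = True,
                            force_tol: float = FORCE_TOL,
                            source_prefix: str = "frame") -> pd.DataFrame:
    """Quench each sampled frame and tabulate U vs CN at the minima.

    Mirrors the inherent-structure protocol: solvent particles are removed
    (by default) before optimizing the total potential energy, and the
    coordination number is recomputed on each quenched geometry.  Individual
    quench failures are recorded (converged=False) and the scan continues.
    """
    rows = []
    for t, frame in enumerate(np.asarray(frames, dtype=float)):
        sys_t = system.with_positions(frame)
        cv_t = cv
        if strip_solvent_first:
            sys_t, cv_t = strip_solvent(sys_t, cv)
        _, rec = quench(sys_t, cv_t, source_id=f"{source_prefix}_{t}",
                        force_tol=force_tol)
        rows.append(rec.__dict__)
    return pd.DataFrame(rows)
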