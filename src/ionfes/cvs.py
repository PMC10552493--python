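"""Coordination-number collective variables and geometric observables.

The coordination number of an ion with a set of candidate oxygen atoms is a
smooth count

    CN = sum_i s(d_i),      s(d) = [1 - (d/r0)^n] / [1 - (d/r0)^m],

where ``d_i`` are ion-member distances, ``r0`` is the characteristic cutoff
of the rational switching function, and ``m > n`` (default 6/12, for which
``s(d) = 1/(1 + (d/r0)^6)`` globally).  The removable singularity at
``d = r0`` is handled by its analytic limit ``n/m``.  Two CV families are
used: ligand-oxygen coordination (r0 = 5 reduced by convention) and
solvent-oxygen coordination (r0 = 2.5).

Also here: sharp (step-function) partial coordination curves n(r) and
ion-O-X chelate angles measured at the oxygen vertex.  The sharp curves and
the smooth switch are deliberately distinct observables and never mixed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .potentials import DomainError

#: below this center-member distance the CV gradient is singular
_D_GUARD = 1e-8
#: half-width of the series expansion window around d = r0
_SING_TOL = 1e-6


@dataclass(frozen=True)
class SwitchingParams:
    """Rational switching function parameters: cutoff r0, exponents n < m."""

    r0: float
    n_exp: int = 6
    m_exp: int = 12

    def __post_init__(self) -> None:
        if self.r0 <= 0:
            raise ValueError("r0 must be positive")
        if not (self.m_exp > self.n_exp >= 1):
            raise ValueError("exponents must satisfy m_exp > n_exp >= 1")


@dataclass(frozen=True)
class CVSpec:
    """A coordination-number CV: one center (the ion) and member particles."""

    center_particle: int
    member_particles: tuple[int, ...]
    switching: SwitchingParams
    label: str = "cv"

    def __post_init__(self) -> None:
        members = tuple(int(i) for i in self.member_particles)
        object.__setattr__(self, "member_particles", members)
        if not members:
            raise ValueError("member list must be non-empty")
        if self.center_particle in members:
            raise ValueError("center particle must not be a member")


@dataclass
class CVSeries:
    """Per-frame time series of a primary CV (plus optional secondary CV)
    from one umbrella window; ``center``/``k`` are the window's harmonic
    bias parameters (``None`` for unbiased runs)."""

    time: np.ndarray
    primary: np.ndarray
    secondary: np.ndarray | None = None
    center: float | None = None
    k: float | None = None
    label: str = "cv_ligand"
    secondary_label: str = "cv_water"

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.primary = np.asarray(self.primary, dtype=float)
        if self.secondary is not None:
            self.secondary = np.asarray(self.secondary, dtype=float)
            if self.secondary.shape != self.primary.shape:
                raise ValueError("secondary CV must match primary length")
        if self.time.shape != self.primary.shape:
            raise ValueError("time must match primary length")

    def __len__(self) -> int:
        return self.primary.size

    def sliced(self, start: int, stop: int | None = None) -> "CVSeries":
        sl = slice(start, stop)
        return CVSeries(self.time[sl], self.primary[sl],
                        None if self.secondary is None else self.secondary[sl],
                        self.center, self.k, self.label, self.secondary_label)


def switch(d, p: SwitchingParams):
    """Switching weight s(d) in (0, 1]; s(0)=1, s(r0)=n/m, decay (r0/d)^(m-n)."""
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise DomainError("distance must be non-negative")
    s, _ = _switch_and_deriv(d, p)
    return s if s.ndim else float(s)


def switch_deriv(d, p: SwitchingParams):
    """ds/dd of the switching function."""
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise DomainError("distance must be non-negative")
    _, ds = _switch_and_deriv(d, p)
    return ds if ds.ndim else float(ds)


def _switch_and_deriv(d: np.ndarray, p: SwitchingParams) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(d, dtype=float) / p.r0
    n, m = p.n_exp, p.m_exp
    u = x - 1.0
    near = np.abs(u) < _SING_TOL
    xs = np.where(near, 0.5, x)  # safe evaluation point away from the pole
    xn = xs**n
    xm = xs**m
    den = 1.0 - xm
    s = (1.0 - xn) / den
    # ds/dx = [-n x^(n-1) (1 - x^m) + m x^(m-1) (1 - x^n)] / (1 - x^m)^2
    dsdx = (-n * xs ** (n - 1) * den + m * xs ** (m - 1) * (1.0 - xn)) / (den * den)
    # first-order Taylor expansion around the removable singularity at x = 1:
    # s = n/m * (1 + (n - m)/2 u + O(u^2)),  s'(1) = n(n - m)/(2m)
    s_near = (n / m) * (1.0 + 0.5 * (n - m) * u)
    dsdx_near = n * (n - m) / (2.0 * m)
    s = np.where(near, s_near, s)
    dsdx = np.where(near, dsdx_near, dsdx)
    return s, dsdx / p.r0


def coordination_number(frame: np.ndarray, spec: CVSpec) -> tuple[float, np.ndarray]:
    """Smooth coordination number and its analytic per-particle gradient.

    Returns ``(value, grad)`` with ``grad`` of shape (N, 3).  Gradients sum
    to zero over particles (translational invariance).  A member coincident
    with the center raises :class:`DomainError`.
    """
    frame = np.asarray(frame, dtype=float)
    members = np.array(spec.member_particles, dtype=int)
    d = frame[members] - frame[spec.center_particle]
    r = np.sqrt(np.einsum("ij,ij->i", d, d))
    if np.any(r < _D_GUARD):
        raise DomainError("member coincident with the CV center")
    s, dsdr = _switch_and_deriv(r, spec.switching)
    grad = np.zeros_like(frame)
    gm = (dsdr / r)[:, None] * d
    np.add.at(grad, members, gm)
    grad[spec.center_particle] -= gm.sum(axis=0)
    return float(np.sum(s)), grad


def cv_values(frames: np.ndarray, spec: CVSpec) -> np.ndarray:
    """Coordination-number values over a (T, N, 3) trajectory (no gradients)."""
    frames = np.asarray(frames, dtype=float)
    d = frames[:, spec.member_particles, :] - frames[:, [spec.center_particle], :]
    r = np.sqrt(np.einsum("tij,tij->ti", d, d))
    if np.any(r < _D_GUARD):
        raise DomainError("member coincident with the CV center")
    s, _ = _switch_and_deriv(r, spec.switching)
    return s.sum(axis=1)


def chelate_angles(frame: np.ndarray, triplets) -> np.ndarray:
    """Angles (degrees) at the oxygen vertex of (ion, O, X) triplets.

    The angle is between the O->ion and O->X vectors, matching the
    ion-oxygen-X reading order.  Degenerate (zero-length) arms raise
    :class:`DomainError`.
    """
    frame = np.asarray(frame, dtype=float)
    out = np.empty(len(triplets))
    for t, (ion, o, x) in enumerate(triplets):
        if len({ion, o, x}) != 3:
            raise DomainError("triplet particles must be distinct")
        a = frame[ion] - frame[o]
        b = frame[x] - frame[o]
        na, nb = np.linalg.norm(a), np.linalg.norm(b)
        if na < _D_GUARD or nb < _D_GUARD:
            raise DomainError("zero-length vector in angle triplet")
        c = np.clip(np.dot(a, b) / (na * nb), -1.0, 1.0)
        out[t] = np.degrees(np.arccos(c))
    return out


def partial_coordination_curve(traj: np.ndarray, center: int, members,
                               r_grid: np.ndarray) -> np.ndarray:
    """Sharp partial coordination number n(r): the mean over frames of the
    count of members within distance r of the center, on an ascending grid.

    This is the step-function count of the radial-shell analysis, distinct
    from the smooth switching-function CV.
    """
    traj = np.asarray(traj, dtype=float)
    if traj.ndim != 3 or traj.shape[0] == 0:
        raise ValueError("trajectory must be a non-empty (T, N, 3) array")
    r_grid = np.asarray(r_grid, dtype=float)
    if np.any(np.diff(r_grid) < 0):
        raise ValueError("r_grid must be sorted ascending")
    members = np.asarray(members, dtype=int)
    d = traj[:, members, :] - traj[:, [center], :]
    r = np.sqrt(np.einsum("tij,tij->ti", d, d))
    counts = (r[:, :, None] <= r_grid[None, None, :]).sum(axis=1)
    return counts.mean(axis=0)
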