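"""Nonbonded and bonded interaction models for toy ion-chelator systems.

The central object is the 12-6-4 pair potential

    U(r) = C12/r^12 - C6/r^6 - C4/r^4 + q/r,

a Lennard-Jones form augmented with an attractive ``C4/r^4`` term that mimics
the charge-induced-dipole interaction of highly charged cations (Zr4+ here),
plus a point-charge Coulomb term.  Everything is expressed in reduced units:
energies in kBT, lengths in Angstrom-like units, masses of 1.  The pair
potential is plainly truncated at the cutoff (no switching, no long-range
correction) -- a deliberate simplification documented in docs/methods.md.

``ToySystem`` bundles particle positions, roles, charges, bonds, an optional
isotropic harmonic tether per particle (the stand-in for a periodic box) and a
role-pair interaction table.  ``EnergyModel`` compiles a system into flat
arrays for fast repeated energy/force evaluation inside the integrator and
the minimizers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: Distances below this guard are treated as particle overlap and raised as
#: an explicit error instead of returning a silently enormous energy.
R_MIN_GUARD = 1e-3

ROLES = ("ion", "ligand_oxygen", "backbone", "solvent_oxygen")


class DomainError(ValueError):
    """Input outside the mathematical domain of an operation."""


class OverlapError(RuntimeError):
    """Two interacting particles closer than ``R_MIN_GUARD``."""


@dataclass(frozen=True)
class PairParams:
    """Coefficients of the truncated 12-6-4 + Coulomb pair potential.

    ``q_product`` is the dimensionless product of the two charges times the
    (reduced) Coulomb constant; ``cutoff`` is the plain truncation radius.
    """

    c12: float = 0.0
    c6: float = 0.0
    c4: float = 0.0
    q_product: float = 0.0
    cutoff: float = 11.0

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        if min(self.c12, self.c6, self.c4) < 0:
            raise ValueError("c12, c6, c4 must be non-negative")
        attractive = self.c6 > 0 or self.c4 > 0 or self.q_product < 0
        if attractive and self.c12 <= 0:
            raise ValueError("attractive terms require c12 > 0 to prevent collapse")


@dataclass(frozen=True)
class BondParams:
    """Harmonic bond, E = k_bond/2 (r - r_eq)^2."""

    k_bond: float
    r_eq: float

    def __post_init__(self) -> None:
        if self.k_bond <= 0 or self.r_eq <= 0:
            raise ValueError("k_bond and r_eq must be positive")


def pair_key(role_a: str, role_b: str) -> tuple[str, str]:
    """Canonical (sorted) key for the role-pair interaction table."""
    return tuple(sorted((role_a, role_b)))  # type: ignore[return-value]


def pair_energy(r, p: PairParams):
    """12-6-4 + Coulomb pair energy at separation ``r`` (scalar or array).

    Exactly zero for ``r >= cutoff``.  Raises :class:`DomainError` for
    non-positive separations.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise DomainError("pair separation must be positive")
    inv2 = 1.0 / (r * r)
    inv4 = inv2 * inv2
    inv6 = inv4 * inv2
    u = p.c12 * inv6 * inv6 - p.c6 * inv6 - p.c4 * inv4 + p.q_product / r
    u = np.where(r >= p.cutoff, 0.0, u)
    return u if u.ndim else float(u)


def pair_dudr(r, p: PairParams):
    """dU/dr of the pair potential (zero beyond the cutoff)."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise DomainError("pair separation must be positive")
    inv = 1.0 / r
    inv2 = inv * inv
    inv5 = inv2 * inv2 * inv
    inv7 = inv5 * inv2
    inv13 = inv7 * inv5 * inv
    dudr = -12.0 * p.c12 * inv13 + 6.0 * p.c6 * inv7 + 4.0 * p.c4 * inv5 - p.q_product * inv2
    dudr = np.where(r >= p.cutoff, 0.0, dudr)
    return dudr if dudr.ndim else float(dudr)


def lj_124_from_well(r_star: float, depth: float, c4: float = 0.0,
                     q_product: float = 0.0, cutoff: float = 11.0) -> PairParams:
    """Build PairParams whose pure 12-6 part has its minimum at ``r_star``
    with depth ``depth`` (the c4/Coulomb terms shift the true minimum)."""
    c6 = 2.0 * depth * r_star**6
    c12 = depth * r_star**12
    return PairParams(c12=c12, c6=c6, c4=c4, q_product=q_product, cutoff=cutoff)


@dataclass
class ToySystem:
    """A desk-scale particle system: one ion plus chelator/solvent beads.

    positions : (N, 3) array, reduced lengths.
    roles     : per-particle label from :data:`ROLES`.
    charges   : bookkeeping charges (the pair_table carries the actual
                Coulomb prefactors).
    bonds     : list of ``(i, j, BondParams)``.
    pair_table: role-pair -> PairParams; absent pairs do not interact.
    tether_k / tether_centers : optional isotropic harmonic confinement per
                particle (k = 0 disables); replaces a periodic box.
    frozen    : particles excluded from dynamics/minimization.
    """

    positions: np.ndarray
    roles: list[str]
    charges: np.ndarray
    masses: np.ndarray
    bonds: list[tuple[int, int, BondParams]] = field(default_factory=list)
    pair_table: dict[tuple[str, str], PairParams] = field(default_factory=dict)
    tether_k: np.ndarray | None = None
    tether_centers: np.ndarray | None = None
    frozen: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        n = self.positions.shape[0]
        if self.positions.shape != (n, 3):
            raise ValueError("positions must be (N, 3)")
        self.charges = np.asarray(self.charges, dtype=float)
        self.masses = np.asarray(self.masses, dtype=float)
        if self.tether_k is None:
            self.tether_k = np.zeros(n)
        self.tether_k = np.asarray(self.tether_k, dtype=float)
        if self.tether_centers is None:
            self.tether_centers = np.zeros((n, 3))
        self.tether_centers = np.asarray(self.tether_centers, dtype=float)
        if self.frozen is None:
            self.frozen = np.zeros(n, dtype=bool)
        self.frozen = np.asarray(self.frozen, dtype=bool)
        self.validate()

    @property
    def n_particles(self) -> int:
        return self.positions.shape[0]

    def validate(self) -> None:
        n = self.n_particles
        if len(self.roles) != n or self.charges.shape != (n,) or self.masses.shape != (n,):
            raise ValueError("roles, charges, masses must match the particle count")
        for role in self.roles:
            if role not in ROLES:
                raise ValueError(f"unknown role {role!r}")
        if self.roles.count("ion") != 1:
            raise ValueError("exactly one particle must have role 'ion'")
        if np.any(self.masses <= 0):
            raise ValueError("all masses must be positive")
        for i, j, _ in self.bonds:
            if i == j:
                raise ValueError("bond graph must have no self-bonds")
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError("bond index out of range")
        for key in self.pair_table:
            if key != pair_key(*key):
                raise ValueError(f"pair_table key {key} is not in canonical sorted order")

    @property
    def ion_index(self) -> int:
        return self.roles.index("ion")

    def indices_of(self, role: str) -> np.ndarray:
        return np.array([i for i, r in enumerate(self.roles) if r == role], dtype=int)

    def with_positions(self, positions: np.ndarray) -> "ToySystem":
        return replace(self, positions=np.array(positions, dtype=float))


class EnergyModel:
    """System compiled to flat arrays for fast energy/force evaluation.

    ``check_overlap=False`` disables the overlap guard (the minimizers rely
    on large-but-finite energies to reject bad line-search trials).
    """

    def __init__(self, system: ToySystem, check_overlap: bool = True):
        self.system = system
        self.check_overlap = check_overlap
        n = system.n_particles
        pi, pj = [], []
        c12, c6, c4, qp, cut = [], [], [], [], []
        for i in range(n):
            for j in range(i + 1, n):
                params = system.pair_table.get(pair_key(system.roles[i], system.roles[j]))
                if params is None:
                    continue
                # bonded pairs are excluded from the nonbonded sum
                if any({i, j} == {a, b} for a, b, _ in system.bonds):
                    continue
                pi.append(i)
                pj.append(j)
                c12.append(params.c12)
                c6.append(params.c6)
                c4.append(params.c4)
                qp.append(params.q_product)
                cut.append(params.cutoff)
        self.pi = np.array(pi, dtype=int)
        self.pj = np.array(pj, dtype=int)
        self.c12 = np.array(c12)
        self.c6 = np.array(c6)
        self.c4 = np.array(c4)
        self.qp = np.array(qp)
        self.cut = np.array(cut)
        self.bi = np.array([b[0] for b in system.bonds], dtype=int)
        self.bj = np.array([b[1] for b in system.bonds], dtype=int)
        self.bk = np.array([b[2].k_bond for b in system.bonds])
        self.br = np.array([b[2].r_eq for b in system.bonds])
        self.tk = system.tether_k
        self.tc = system.tether_centers
        self.frozen = system.frozen
        self.free = ~system.frozen

    def energy_forces(self, x: np.ndarray) -> tuple[float, np.ndarray]:
        """Potential energy and analytic forces (-grad U) at positions x."""
        f = np.zeros_like(x)
        u = 0.0
        if self.pi.size:
            d = x[self.pi] - x[self.pj]
            r = np.sqrt(np.einsum("ij,ij->i", d, d))
            if self.check_overlap and np.any(r < R_MIN_GUARD):
                k = int(np.argmin(r))
                raise OverlapError(
                    f"particles {self.pi[k]} and {self.pj[k]} overlap (r={r[k]:.2e})"
                )
            r = np.maximum(r, R_MIN_GUARD * 1e-3)  # last-resort finiteness guard
            inv = 1.0 / r
            inv2 = inv * inv
            inv4 = inv2 * inv2
            inv6 = inv4 * inv2
            live = r < self.cut
            upair = self.c12 * inv6 * inv6 - self.c6 * inv6 - self.c4 * inv4 + self.qp * inv
            u += float(np.sum(upair[live]))
            dudr = (-12.0 * self.c12 * inv6 * inv6 + 6.0 * self.c6 * inv6
                    + 4.0 * self.c4 * inv4 - self.qp * inv) * inv
            dudr = np.where(live, dudr, 0.0)
            fv = (-dudr * inv)[:, None] * d
            np.add.at(f, self.pi, fv)
            np.subtract.at(f, self.pj, fv)
        if self.bi.size:
            d = x[self.bi] - x[self.bj]
            r = np.sqrt(np.einsum("ij,ij->i", d, d))
            r = np.maximum(r, R_MIN_GUARD * 1e-3)
            dr = r - self.br
            u += float(np.sum(0.5 * self.bk * dr * dr))
            fv = (-(self.bk * dr) / r)[:, None] * d
            np.add.at(f, self.bi, fv)
            np.subtract.at(f, self.bj, fv)
        if np.any(self.tk > 0):
            dx = x - self.tc
            u += float(0.5 * np.sum(self.tk * np.einsum("ij,ij->i", dx, dx)))
            f -= self.tk[:, None] * dx
        f[self.frozen] = 0.0
        return u, f


def total_energy_forces(system: ToySystem) -> tuple[float, np.ndarray]:
    """Total potential energy and per-particle forces of a ToySystem."""
    return EnergyModel(system).energy_forces(system.positions)


def bias_energy_force(cv_value: float, dcv_dx: np.ndarray, center: float,
                      k: float) -> tuple[float, np.ndarray]:
    """Harmonic umbrella bias U = k/2 (s - s0)^2 and its force contribution.

    ``dcv_dx`` is the (N, 3) gradient of the collective variable; the force
    is ``-k (s - s0) * dcv_dx``.
    """
    if k < 0:
        raise ValueError("spring constant must be non-negative")
    ds = cv_value - center
    return 0.5 * k * ds * ds, (-k * ds) * dcv_dx
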