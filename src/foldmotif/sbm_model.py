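"""The coarse-grained C-alpha structure-based (Go) model.

One bead per residue at the C-alpha position.  The potential is

    V = sum_bonds K_r (r - r0)^2
      + sum_angles K_theta (theta - theta0)^2
      + sum_dihedrals [ K_phi1 (1 - cos(phi - phi0)) + K_phi3 (1 - cos 3(phi - phi0)) ]
      + sum_contacts eps1 [ 5 (sigma_ij / r)^12 - 6 (sigma_ij / r)^10 ]
      + sum_non-contacts eps2 (sigma_rep / r)^12

with r0, theta0, phi0 and sigma_ij measured from the native structure, so
every bonded term and every contact is at its minimum in the folded state.
Non-native pairs feel only the short-range repulsion.  Defaults: K_r = 100,
K_theta = 20, K_phi1 = 1, K_phi3 = 0.5, eps1 = eps2 = 1 (all in units of the
base energy scale epsilon = 1 kcal/mol) and sigma_rep = 4.0 A.

Internally everything is in reduced units (length A, energy epsilon, mass 1,
k_B = 1); epsilon in kcal/mol is applied only when reporting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .contact_maps import ContactMap
from .structures_io import CalphaStructure

__all__ = [
    "SBMParameters",
    "SBMTopology",
    "build_topology",
    "potential_energy",
    "naive_potential_energy",
    "forces",
    "measure_dihedral",
    "write_topology_tsv",
]


@dataclass
class SBMParameters:
    """Force-field constants, as multiples of the base energy scale epsilon."""

    epsilon_kcal_per_mol: float = 1.0
    k_r: float = 100.0          # per A^2
    k_theta: float = 20.0       # per rad^2
    k_phi1: float = 1.0
    k_phi3: float = 0.5
    eps1: float = 1.0           # contact well depth
    eps2: float = 1.0           # repulsion prefactor
    sigma_rep: float = 4.0      # A
    min_separation_repulsion: int = 3

    def __post_init__(self) -> None:
        for name in ("epsilon_kcal_per_mol", "k_r", "k_theta", "k_phi1",
                     "k_phi3", "eps1", "eps2", "sigma_rep"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def scaled(self, lam: float) -> "SBMParameters":
        """All epsilon-type constants scaled by ``lam`` (energy unit change)."""
        return SBMParameters(
            epsilon_kcal_per_mol=self.epsilon_kcal_per_mol * lam,
            k_r=self.k_r, k_theta=self.k_theta, k_phi1=self.k_phi1,
            k_phi3=self.k_phi3, eps1=self.eps1, eps2=self.eps2,
            sigma_rep=self.sigma_rep,
            min_separation_repulsion=self.min_separation_repulsion)


@dataclass
class SBMTopology:
    """Native geometry + interaction lists ready for the numeric kernels."""

    native_coords: np.ndarray       # (n, 3)
    bond_r0: np.ndarray             # (n-1,)
    angle_theta0: np.ndarray        # (n-2,)
    dihedral_phi0: np.ndarray       # (n-3,)
    contact_i: np.ndarray
    contact_j: np.ndarray
    contact_sigma: np.ndarray
    repulsive_i: np.ndarray
    repulsive_j: np.ndarray
    params: SBMParameters = field(default_factory=SBMParameters)
    name: str = ""

    @property
    def n_residues(self) -> int:
        return len(self.native_coords)

    @property
    def n_contacts(self) -> int:
        return len(self.contact_i)

    def kernel_args(self) -> tuple:
        p = self.params
        return (self.bond_r0, self.angle_theta0, self.dihedral_phi0,
                self.contact_i, self.contact_j, self.contact_sigma,
                self.repulsive_i, self.repulsive_j,
                p.k_r, p.k_theta, p.k_phi1, p.k_phi3, p.eps1, p.eps2,
                p.sigma_rep)

    def with_params(self, params: SBMParameters) -> "SBMTopology":
        return SBMTopology(self.native_coords, self.bond_r0, self.angle_theta0,
                           self.dihedral_phi0, self.contact_i, self.contact_j,
                           self.contact_sigma, self.repulsive_i,
                           self.repulsive_j, params, self.name)


def measure_dihedral(p0, p1, p2, p3) -> float:
    """Signed (IUPAC) dihedral of four points, radians in (-pi, pi]."""
    b1 = np.asarray(p1, float) - p0
    b2 = np.asarray(p2, float) - p1
    b3 = np.asarray(p3, float) - p2
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    return float(math.atan2(np.dot(m1, n2), np.dot(n1, n2)))


def build_topology(backbone: CalphaStructure | np.ndarray, cmap: ContactMap,
                   params: SBMParameters | None = None, name: str = ""
                   ) -> SBMTopology:
    """Measure native geometry and assemble the interaction lists.

    An n-residue chain gets n-1 bonds, n-2 angles and n-3 dihedrals.  Three
    collinear consecutive beads make the middle angle undefined and raise.
    Contact pairs are excluded from the repulsive list, as are pairs closer
    in sequence than ``min_separation_repulsion``.
    """
    params = params or SBMParameters()
    x = backbone if isinstance(backbone, np.ndarray) else backbone.coords
    x = np.asarray(x, float)
    n = len(x)
    if cmap.n_residues != n:
        raise ValueError(
            f"contact map indexes {cmap.n_residues} residues, backbone has {n}")
    ci, cj, sig = cmap.arrays()
    if len(ci) and (cj - ci).min() < 3:
        bad = int(np.argmin(cj - ci))
        raise ValueError(
            f"contact ({ci[bad]}, {cj[bad]}) violates the minimum sequence "
            "separation of 3")

    bond_r0 = np.linalg.norm(np.diff(x, axis=0), axis=1)
    theta0 = np.empty(n - 2)
    for a in range(n - 2):
        u = x[a] - x[a + 1]
        v = x[a + 2] - x[a + 1]
        cross = np.linalg.norm(np.cross(u, v))
        if cross < 1e-8 * np.linalg.norm(u) * np.linalg.norm(v):
            raise ValueError(
                f"residues ({a}, {a + 1}, {a + 2}) are collinear; the native "
                "angle is undefined")
        theta0[a] = math.atan2(cross, float(np.dot(u, v)))
    phi0 = np.array([measure_dihedral(x[t], x[t + 1], x[t + 2], x[t + 3])
                     for t in range(n - 3)])

    pairs = set(zip(ci.tolist(), cj.tolist()))
    sep = params.min_separation_repulsion
    rep = [(i, j) for i in range(n) for j in range(i + sep, n)
           if (i, j) not in pairs]
    ri = np.array([p[0] for p in rep], dtype=np.int64)
    rj = np.array([p[1] for p in rep], dtype=np.int64)
    return SBMTopology(
        native_coords=x.copy(), bond_r0=bond_r0, angle_theta0=theta0,
        dihedral_phi0=phi0, contact_i=ci.astype(np.int64),
        contact_j=cj.astype(np.int64), contact_sigma=sig.astype(float),
        repulsive_i=ri, repulsive_j=rj, params=params,
        name=name or getattr(backbone, "name", ""))


def potential_energy(topology: SBMTopology, coords: np.ndarray
                     ) -> tuple[float, dict[str, float]]:
    """Total potential energy and per-term breakdown, in units of epsilon."""
    x = np.ascontiguousarray(coords, dtype=float)
    if x.shape != (topology.n_residues, 3):
        raise ValueError(f"coords must be ({topology.n_residues}, 3)")
    _check_overlap(topology, x)
    eb, ea, ed, ec, er, _ = _kernels.energy_forces(x, *topology.kernel_args())
    breakdown = {"bond": eb, "angle": ea, "dihedral": ed,
                 "contact": ec, "repulsive": er}
    return eb + ea + ed + ec + er, breakdown


def forces(topology: SBMTopology, coords: np.ndarray) -> np.ndarray:
    """Analytic forces (negative potential gradient), epsilon per Angstrom."""
    x = np.ascontiguousarray(coords, dtype=float)
    if x.shape != (topology.n_residues, 3):
        raise ValueError(f"coords must be ({topology.n_residues}, 3)")
    _check_overlap(topology, x)
    *_, f = _kernels.energy_forces(x, *topology.kernel_args())
    return f


def _check_overlap(topology: SBMTopology, x: np.ndarray) -> None:
    for ii, jj in ((topology.contact_i, topology.contact_j),
                   (topology.repulsive_i, topology.repulsive_j)):
        if len(ii):
            d2 = ((x[ii] - x[jj]) ** 2).sum(axis=1)
            if d2.min() < 1e-12:
                k = int(np.argmin(d2))
                raise ValueError(
                    f"beads {ii[k]} and {jj[k]} overlap (r = 0)")


def naive_potential_energy(topology: SBMTopology, coords: np.ndarray) -> float:
    """Straightforward scalar-loop evaluation of the same potential.

    Deliberately written term by term with plain ``math`` calls and an
    independent dihedral construction; used as a cross-check of the compiled
    kernel, never for production evaluation.
    """
    p = topology.params
    x = [tuple(map(float, row)) for row in np.asarray(coords, float)]
    n = len(x)

    def sub(a, b):
        return (a[0] - b[0], a[1] - b[1], a[2] - b[2])

    def dot(a, b):
        return a[0] * b[0] + a[1] * b[1] + a[2] * b[2]

    def cross(a, b):
        return (a[1] * b[2] - a[2] * b[1],
                a[2] * b[0] - a[0] * b[2],
                a[0] * b[1] - a[1] * b[0])

    def norm(a):
        return math.sqrt(dot(a, a))

    e = 0.0
    for b in range(n - 1):
        r = norm(sub(x[b + 1], x[b]))
        e += p.k_r * (r - topology.bond_r0[b]) ** 2
    for a in range(n - 2):
        u = sub(x[a], x[a + 1])
        v = sub(x[a + 2], x[a + 1])
        theta = math.acos(max(-1.0, min(1.0, dot(u, v) / (norm(u) * norm(v)))))
        e += p.k_theta * (theta - topology.angle_theta0[a]) ** 2
    for t in range(n - 3):
        b1 = sub(x[t + 1], x[t])
        b2 = sub(x[t + 2], x[t + 1])
        b3 = sub(x[t + 3], x[t + 2])
        n1 = cross(b1, b2)
        n2 = cross(b2, b3)
        cosphi = dot(n1, n2) / (norm(n1) * norm(n2))
        cosphi = max(-1.0, min(1.0, cosphi))
        phi = math.acos(cosphi)
        if dot(n1, b3) > 0.0:
            phi = -phi
        d = phi - topology.dihedral_phi0[t]
        e += p.k_phi1 * (1.0 - math.cos(d)) + p.k_phi3 * (1.0 - math.cos(3 * d))
    for i, j, s in zip(topology.contact_i, topology.contact_j,
                       topology.contact_sigma):
        r = norm(sub(x[int(j)], x[int(i)]))
        e += p.eps1 * (5.0 * (s / r) ** 12 - 6.0 * (s / r) ** 10)
    for i, j in zip(topology.repulsive_i, topology.repulsive_j):
        r = norm(sub(x[int(j)], x[int(i)]))
        e += p.eps2 * (p.sigma_rep / r) ** 12
    return e


def write_topology_tsv(topology: SBMTopology, path) -> None:
    """Serialize the topology as sectioned TSV (bonds / angles / dihedrals /
    contacts), mirroring common SBM topology layouts."""
    with open(path, "w") as fh:
        fh.write(f"# sbm topology: {topology.name}\n")
        fh.write(f"# epsilon_kcal_per_mol\t{topology.params.epsilon_kcal_per_mol}\n")
        fh.write("[bonds]\ti\tj\tr0_angstrom\n")
        for b, r0 in enumerate(topology.bond_r0):
            fh.write(f"\t{b}\t{b + 1}\t{r0:.6f}\n")
        fh.write("[angles]\ti\tj\tk\ttheta0_rad\n")
        for a, t0 in enumerate(topology.angle_theta0):
            fh.write(f"\t{a}\t{a + 1}\t{a + 2}\t{t0:.6f}\n")
        fh.write("[dihedrals]\ti\tj\tk\tl\tphi0_rad\n")
        for t, p0 in enumerate(topology.dihedral_phi0):
            fh.write(f"\t{t}\t{t + 1}\t{t + 2}\t{t + 3}\t{p0:.6f}\n")
        fh.write("[contacts]\ti\tj\tsigma_ij_angstrom\n")
        for i, j, s in zip(topology.contact_i, topology.contact_j,
                           topology.contact_sigma):
            fh.write(f"\t{i}\t{j}\t{s:.6f}\n")
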