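"""Building the function-less folding motif (FM) of a structural family.

Given a structural alignment of functionally diverse members of one fold,
the FM is the consensus scaffold: alignment columns occupied by a residue in
more than half of the members become FM positions; the FM backbone starts as
the per-column average of the superposed member coordinates; the FM contact
map keeps the contacts shared (through the alignment) by at least a support
threshold of members, the threshold picked so the FM's packing fraction
(contacts per residue) brackets the family median.  Averaged coordinates do
not respect virtual C-alpha bond geometry, so the raw backbone is relaxed
under a stiffened SBM whose bond lengths are all reset to the canonical
3.8 A: loops move, the core stays put.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass, field

import numpy as np

from .contact_maps import Contact, ContactMap, packing_fraction
from .structures_io import GAP, CalphaStructure, StructuralAlignment

__all__ = [
    "OccupancyProfile",
    "FoldingMotif",
    "occupancy_curve",
    "select_positions",
    "average_coordinates",
    "consensus_contact_map",
    "choose_support_threshold",
    "check_adjacency",
    "relax_backbone",
    "build_folding_motif",
]


@dataclass
class OccupancyProfile:
    """Per-column member counts and the cumulative residues-at-support curve.

    ``k_curve[k]`` (k = 1..K) is the number of columns occupied by at least
    k members; it is non-increasing, and a flat stretch around the chosen
    support means the FM length is insensitive to the exact cutoff.
    """

    counts: np.ndarray               # per alignment column
    k_curve: np.ndarray              # index 0 unused; k_curve[k] for k>=1
    n_members: int

    def at_least(self, k: int) -> int:
        return int(self.k_curve[k])


@dataclass
class FoldingMotif:
    backbone: CalphaStructure
    contact_map: ContactMap
    position_provenance: list[dict]          # per FM residue
    contact_support: dict[tuple[int, int], int]
    support_threshold: int
    occupancy_fraction: float
    adjacency_violations: list[tuple[int, int]] = field(default_factory=list)
    raw_backbone: CalphaStructure | None = None

    @property
    def n_residues(self) -> int:
        return len(self.backbone)


def occupancy_curve(alignment: StructuralAlignment) -> OccupancyProfile:
    """How many columns survive as the required member support k grows."""
    counts = alignment.occupancy()
    K = alignment.n_members
    k_curve = np.zeros(K + 1, dtype=int)
    for k in range(1, K + 1):
        k_curve[k] = int((counts >= k).sum())
    return OccupancyProfile(counts=counts, k_curve=k_curve, n_members=K)


def implied_support(n_members: int, occupancy_fraction: float) -> int:
    """Smallest member count satisfying 'more than fraction of K'."""
    return int(np.floor(occupancy_fraction * n_members)) + 1


def select_positions(alignment: StructuralAlignment,
                     occupancy_fraction: float = 0.5) -> np.ndarray:
    """Columns where strictly more than ``occupancy_fraction`` of the members
    hold a residue (for 13 members at 50%: 7 or more), in alignment order."""
    if not 0.0 < occupancy_fraction < 1.0:
        raise ValueError("occupancy_fraction must be in (0, 1)")
    counts = alignment.occupancy()
    need = implied_support(alignment.n_members, occupancy_fraction)
    cols = np.flatnonzero(counts >= need)
    if len(cols) == 0:
        raise ValueError(
            f"no column reaches occupancy > {occupancy_fraction:.0%} "
            f"({need} of {alignment.n_members} members); lower the threshold")
    return cols


def average_coordinates(alignment: StructuralAlignment,
                        selected_columns: np.ndarray,
                        name: str = "FM") -> CalphaStructure:
    """Raw FM backbone: per selected column, the mean of the superposed
    C-alpha coordinates over the members holding a residue there."""
    coords = np.empty((len(selected_columns), 3))
    for t, col in enumerate(selected_columns):
        row = alignment.columns[col]
        members = np.flatnonzero(row != GAP)
        if len(members) == 0:
            raise ValueError(f"column {col} has no residues to average")
        pts = np.array([alignment.superposed[m][row[m]] for m in members])
        coords[t] = pts.mean(axis=0)
    return CalphaStructure(name=name, chain="A", coords=coords,
                           res_numbers=np.arange(1, len(coords) + 1))


def consensus_contact_map(alignment: StructuralAlignment,
                          wt_maps: list[ContactMap],
                          selected_columns: np.ndarray,
                          support_threshold: int,
                          backbone: CalphaStructure | None = None,
                          min_separation: int = 3
                          ) -> tuple[ContactMap, dict[tuple[int, int], int]]:
    """FM contacts: pairs of FM positions whose aligned residues are in
    contact in at least ``support_threshold`` members.

    Support is counted on the full alignment; sigma_ij is measured on
    ``backbone`` (the relaxed FM in the full pipeline).  Returns the map and
    the per-contact support counts.
    """
    K = alignment.n_members
    if support_threshold > K:
        raise ValueError(f"support threshold {support_threshold} exceeds "
                         f"member count {K}")
    if len(wt_maps) != K:
        raise ValueError("need one contact map per member")
    pair_sets = [m.pairs for m in wt_maps]
    cols = alignment.columns[selected_columns]        # (n_fm, K)
    n_fm = len(selected_columns)
    support: dict[tuple[int, int], int] = {}
    for p in range(n_fm):
        for q in range(p + min_separation, n_fm):
            count = 0
            for k in range(K):
                a = cols[p, k]
                b = cols[q, k]
                if a != GAP and b != GAP:
                    pair = (a, b) if a < b else (b, a)
                    if pair in pair_sets[k]:
                        count += 1
            if count >= support_threshold:
                support[(p, q)] = count
    contacts = []
    for (p, q), _count in sorted(support.items()):
        if backbone is not None:
            sigma = float(np.linalg.norm(backbone.coords[p] - backbone.coords[q]))
        else:
            sigma = 1.0    # placeholder until a backbone exists
        contacts.append(Contact(p, q, sigma))
    cmap = ContactMap(contacts, n_fm,
                      provenance=f"consensus:support>={support_threshold}",
                      min_separation=min_separation)
    return cmap, support


def choose_support_threshold(alignment: StructuralAlignment,
                             wt_maps: list[ContactMap],
                             selected_columns: np.ndarray,
                             candidates: list[int]) -> list[dict]:
    """Rank candidate support thresholds by how close the resulting FM
    packing fraction lands to the median WT packing fraction.

    Returns one dict per candidate, sorted best first, with the bracketing
    pair (nearest above / below the median) marked.
    """
    if not candidates:
        raise ValueError("need at least one candidate threshold")
    median_pf = float(np.median([packing_fraction(m) for m in wt_maps]))
    rows = []
    for thr in candidates:
        cmap, _ = consensus_contact_map(alignment, wt_maps, selected_columns,
                                        thr)
        pf = packing_fraction(cmap)
        rows.append({"threshold": thr, "packing_fraction": pf,
                     "n_contacts": len(cmap),
                     "distance_to_median": abs(pf - median_pf),
                     "median_wt_packing_fraction": median_pf,
                     "bracket": ""})
    above = [r for r in rows if r["packing_fraction"] >= median_pf]
    below = [r for r in rows if r["packing_fraction"] < median_pf]
    if above:
        min(above, key=lambda r: r["distance_to_median"])["bracket"] = "above"
    if below:
        min(below, key=lambda r: r["distance_to_median"])["bracket"] = "below"
    rows.sort(key=lambda r: r["distance_to_median"])
    return rows


def check_adjacency(selected_columns: np.ndarray,
                    alignment: StructuralAlignment) -> list[tuple[int, int]]:
    """Verify each consecutive FM pair is backbone-connected in >= 1 member.

    Returns the violating FM position pairs (empty = the FM backbone is
    everywhere supported by at least one WT backbone).
    """
    cols = alignment.columns[selected_columns]
    violations = []
    for t in range(len(selected_columns) - 1):
        ok = False
        for k in range(alignment.n_members):
            a = cols[t, k]
            b = cols[t + 1, k]
            if a != GAP and b != GAP and b - a == 1:
                ok = True
                break
        if not ok:
            violations.append((t, t + 1))
    return violations


def relax_backbone(raw_fm: CalphaStructure, fm_contacts: ContactMap,
                   bond_target: float = 3.8,
                   temperature: float = 0.2,
                   n_steps: int = 50_000,
                   timestep: float = 0.0005,
                   seed: int = 0) -> tuple[CalphaStructure, dict]:
    """Drive the averaged FM backbone to canonical virtual-bond geometry.

    The relaxation potential is the SBM measured on the raw FM with every
    bond length parameter reset to ``bond_target`` and the dihedral and
    contact constants stiffened to the angle constant (K_phi1 = eps1 = eps2
    = 20, K_phi3 = 10 via the fixed 0.5 ratio), so bonds snap to 3.8 A while
    angles, dihedrals and contacts hold the raw geometry.  A short
    low-temperature Langevin run is followed by a gradient-descent polish.
    Residue count and order never change.
    """
    from scipy.optimize import minimize

    from . import _kernels
    from .sampling import SimulationConfig, run_langevin
    from .sbm_model import SBMParameters, build_topology

    if len(raw_fm) < 4:
        raise ValueError("relaxation needs >= 4 residues")
    params = SBMParameters(k_phi1=20.0, k_phi3=10.0, eps1=20.0, eps2=20.0)
    topo = build_topology(raw_fm, fm_contacts, params, name=f"{raw_fm.name}:relax")
    before = topo.bond_r0.copy()
    topo.bond_r0 = np.full_like(topo.bond_r0, bond_target)

    cfg = SimulationConfig(temperature=temperature, n_steps=n_steps,
                           timestep=timestep, save_interval=max(n_steps // 10, 1),
                           seed=seed)
    traj = run_langevin(topo, cfg, x0=raw_fm.coords)
    x = traj.final_coords

    args = topo.kernel_args()

    def fun(flat):
        eb, ea, ed, ec, er, f = _kernels.energy_forces(
            flat.reshape(-1, 3), *args)
        return eb + ea + ed + ec + er, -f.ravel()

    res = minimize(fun, x.ravel(), jac=True, method="L-BFGS-B",
                   options={"maxiter": 2000})
    coords = res.x.reshape(-1, 3)
    # remove the rigid-body drift picked up during the dynamics so that
    # reported displacements are internal rearrangement only
    from .structures_io import kabsch

    R, t = kabsch(coords, raw_fm.coords)
    coords = coords @ R.T + t
    bonds_after = np.linalg.norm(np.diff(coords, axis=0), axis=1)
    if not np.isfinite(res.fun):
        raise RuntimeError("relaxation diverged; reduce the timestep")
    relaxed = CalphaStructure(
        name=raw_fm.name, chain=raw_fm.chain, coords=coords,
        res_numbers=raw_fm.res_numbers.copy(),
        ins_codes=list(raw_fm.ins_codes), res_names=list(raw_fm.res_names))
    diagnostics = {
        "bond_std_before": float(before.std()),
        "bond_std_after": float(bonds_after.std()),
        "bond_mean_after": float(bonds_after.mean()),
        "displacement": np.linalg.norm(coords - raw_fm.coords, axis=1),
    }
    if diagnostics["bond_std_after"] > max(diagnostics["bond_std_before"],
                                           0.02):
        _warnings.warn("relaxation did not tighten the bond-length "
                       "distribution", stacklevel=2)
    return relaxed, diagnostics


def build_folding_motif(alignment: StructuralAlignment,
                        wt_maps: list[ContactMap],
                        occupancy_fraction: float = 0.5,
                        support_threshold: int = 4,
                        relax: bool = True,
                        seed: int = 0,
                        name: str = "FM") -> FoldingMotif:
    """Full pipeline: positions -> averaged backbone -> relaxation ->
    consensus contacts with sigma measured on the final backbone."""
    cols = select_positions(alignment, occupancy_fraction)
    raw = average_coordinates(alignment, cols, name=name)
    pre_map, support = consensus_contact_map(alignment, wt_maps, cols,
                                             support_threshold, backbone=raw)
    if relax and len(raw) >= 4:
        backbone, _diag = relax_backbone(raw, pre_map, seed=seed)
    else:
        backbone = raw
    cmap, support = consensus_contact_map(alignment, wt_maps, cols,
                                          support_threshold, backbone=backbone)
    counts = alignment.occupancy()
    provenance = [{"column": int(c), "occupancy": int(counts[c])}
                  for c in cols]
    violations = check_adjacency(cols, alignment)
    if violations:
        _warnings.warn(f"{len(violations)} consecutive FM pair(s) are not "
                       "backbone-connected in any member", stacklevel=2)
    return FoldingMotif(backbone=backbone, contact_map=cmap,
                        position_provenance=provenance,
                        contact_support=support,
                        support_threshold=support_threshold,
                        occupancy_fraction=occupancy_fraction,
                        adjacency_violations=violations,
                        raw_backbone=raw)
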