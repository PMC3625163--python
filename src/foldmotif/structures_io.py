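"""Reading protein structures and managing multiple structural alignments.

The unit of work is a C-alpha trace (:class:`CalphaStructure`): one bead per
residue at the position of the C-alpha atom, with the residue's heavy atoms
kept alongside for contact-map computation.  Multiple traces are related by a
:class:`StructuralAlignment`, either imported from an external structural
aligner (superposed PDB files plus a column table) or computed by a builtin
progressive aligner.  The builtin aligner is a convenience with no claim of
equivalence to STAMP-class tools; quantitative consensus work should import a
reference alignment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GAP",
    "CalphaStructure",
    "StructuralAlignment",
    "ImportPayload",
    "read_structure",
    "write_backbone",
    "align_structures",
    "load_column_table",
    "kabsch",
]

#: Sentinel used in alignment columns for "this member has no residue here".
GAP = -1


@dataclass
class CalphaStructure:
    """Ordered C-alpha trace of one protein chain.

    Residues are indexed internally 0..n-1 (contiguous); author numbering
    (``res_numbers`` + ``ins_codes``) is preserved for reporting, since the
    literature quotes residues in author numbering.
    """

    name: str
    chain: str
    coords: np.ndarray                      # (n, 3) C-alpha positions, Angstrom
    res_numbers: np.ndarray                 # (n,) author residue numbers
    ins_codes: list[str] = field(default_factory=list)
    res_names: list[str] = field(default_factory=list)
    heavy_coords: list[np.ndarray] | None = None   # per residue (k, 3)
    heavy_elements: list[list[str]] | None = None
    skipped_residues: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.res_numbers = np.asarray(self.res_numbers, dtype=int)
        n = len(self.coords)
        if n < 2:
            raise ValueError(f"{self.name}: need >= 2 residues, got {n}")
        if self.coords.shape != (n, 3):
            raise ValueError("coords must be (n, 3)")
        if not self.ins_codes:
            self.ins_codes = [""] * n
        if not self.res_names:
            self.res_names = ["GLY"] * n
        if len(self.res_numbers) != n or len(self.ins_codes) != n:
            raise ValueError("residue id arrays must match coords length")
        ids = self.res_ids
        if len(set(ids)) != n:
            raise ValueError(f"{self.name}: residue ids are not unique")

    def __len__(self) -> int:
        return len(self.coords)

    @property
    def res_ids(self) -> list[str]:
        """Author residue identifiers, number + insertion code (e.g. ``52A``)."""
        return [f"{n}{c}" for n, c in zip(self.res_numbers, self.ins_codes)]

    def index_of(self, res_id: str) -> int:
        try:
            return self.res_ids.index(res_id)
        except ValueError:
            raise KeyError(f"{self.name}: no residue with id {res_id!r}") from None


@dataclass
class ImportPayload:
    """External alignment: superposed copies of the members + a column table.

    ``superposed`` must contain the same residues as the structures handed to
    :func:`align_structures`, with coordinates already rigidly superposed.
    ``columns`` holds one row per alignment column, one author residue id (or
    ``-`` for a gap) per member.
    """

    superposed: list[CalphaStructure]
    columns: list[list[str]]


@dataclass
class StructuralAlignment:
    """Column-indexed correspondence between members of a structure family."""

    members: list[CalphaStructure]
    columns: np.ndarray              # (n_cols, K) internal residue index or GAP
    superposed: list[np.ndarray]     # per member (n_i, 3) coords after rigid fit

    def __post_init__(self) -> None:
        self.columns = np.asarray(self.columns, dtype=int)
        K = len(self.members)
        if K < 2:
            raise ValueError("alignment needs >= 2 members")
        if self.columns.ndim != 2 or self.columns.shape[1] != K:
            raise ValueError("columns must be (n_cols, n_members)")
        for m in range(K):
            col = self.columns[:, m]
            used = col[col != GAP]
            if np.any(np.diff(used) <= 0):
                raise ValueError(
                    f"member {self.members[m].name}: residue order not "
                    "monotonic down the columns"
                )
            if len(set(used.tolist())) != len(used):
                raise ValueError(
                    f"member {self.members[m].name}: residue in > 1 column"
                )
            if len(used) and (used.min() < 0 or used.max() >= len(self.members[m])):
                raise ValueError("column index out of range")

    @property
    def n_columns(self) -> int:
        return self.columns.shape[0]

    @property
    def n_members(self) -> int:
        return len(self.members)

    def member_index(self, member: str | int) -> int:
        if isinstance(member, (int, np.integer)):
            return int(member)
        for k, m in enumerate(self.members):
            if m.name == member:
                return k
        raise KeyError(f"no member named {member!r}; members: "
                       f"{[m.name for m in self.members]}")

    def occupancy(self) -> np.ndarray:
        """Per-column count of members holding a residue (not a gap)."""
        return (self.columns != GAP).sum(axis=1)

    def correspondence(self, source: str | int, target: str | int) -> dict[int, int]:
        """Map source internal residue index -> target internal index, via
        shared columns.  Residues aligned to a gap in the target are absent."""
        s = self.member_index(source)
        t = self.member_index(target)
        out: dict[int, int] = {}
        for row in self.columns:
            if row[s] != GAP and row[t] != GAP:
                out[int(row[s])] = int(row[t])
        return out


# ---------------------------------------------------------------------------
# PDB reading / writing (biotite-backed)
# ---------------------------------------------------------------------------

def read_structure(path, chain: str | None = None,
                   residue_range: tuple[int, int] | None = None,
                   name: str | None = None) -> CalphaStructure:
    """Read one chain of a PDB file into a C-alpha trace.

    altLoc conflicts are resolved by keeping the highest-occupancy conformer
    (ties broken by file order).  Hydrogens are dropped; HETATM records are
    ignored except selenomethionine (MSE), which is treated as a residue.
    Residues lacking a C-alpha are skipped with a warning and recorded in
    ``skipped_residues``.  ``residue_range`` is inclusive, in author numbering.
    """
    from biotite.structure.io.pdb import PDBFile

    pdbfile = PDBFile.read(str(path))
    atoms = pdbfile.get_structure(model=1, altloc="occupancy")
    keep = ~atoms.hetero | (atoms.res_name == "MSE")
    atoms = atoms[keep]
    chains = sorted(set(atoms.chain_id.tolist()))
    if chain is None:
        chain = chains[0]
    if chain not in chains:
        raise ValueError(
            f"chain {chain!r} not found in {path}; available chains: {chains}"
        )
    atoms = atoms[atoms.chain_id == chain]
    if residue_range is not None:
        lo, hi = residue_range
        atoms = atoms[(atoms.res_id >= lo) & (atoms.res_id <= hi)]
    if atoms.array_length() == 0:
        raise ValueError(f"empty selection for chain {chain!r} in {path}")

    # group atoms by residue, in order of appearance
    res_keys: list[tuple[int, str]] = []
    seen: set[tuple[int, str]] = set()
    ins = atoms.ins_code if "ins_code" in atoms.get_annotation_categories() else None
    for a in range(atoms.array_length()):
        key = (int(atoms.res_id[a]), str(ins[a]) if ins is not None else "")
        if key not in seen:
            seen.add(key)
            res_keys.append(key)

    coords, nums, icodes, names = [], [], [], []
    heavy_xyz: list[np.ndarray] = []
    heavy_el: list[list[str]] = []
    skipped: list[str] = []
    for num, icode in res_keys:
        if ins is not None:
            mask = (atoms.res_id == num) & (ins == icode)
        else:
            mask = atoms.res_id == num
        sub = atoms[mask]
        heavy = sub[(sub.element != "H") & (sub.element != "D")]
        ca = heavy[heavy.atom_name == "CA"]
        if ca.array_length() == 0:
            skipped.append(f"{num}{icode}")
            continue
        coords.append(ca.coord[0])
        nums.append(num)
        icodes.append(icode)
        names.append(str(sub.res_name[0]))
        heavy_xyz.append(np.array(heavy.coord, dtype=float))
        heavy_el.append([str(e) for e in heavy.element])
    if skipped:
        warnings.warn(
            f"{path}: {len(skipped)} residue(s) without C-alpha skipped: "
            f"{skipped[:10]}", stacklevel=2)
    if not coords:
        raise ValueError(f"no residues with C-alpha in selection of {path}")
    return CalphaStructure(
        name=name or str(path),
        chain=chain,
        coords=np.array(coords),
        res_numbers=np.array(nums),
        ins_codes=icodes,
        res_names=names,
        heavy_coords=heavy_xyz,
        heavy_elements=heavy_el,
        skipped_residues=skipped,
    )


def write_backbone(structure: CalphaStructure, path) -> None:
    """Write the C-alpha trace as a PDB file (one CA ATOM record per residue).

    Round-trips through :func:`read_structure` to PDB precision (1e-3 A);
    author numbering and insertion codes are preserved verbatim.
    """
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    n = len(structure)
    arr = struc.AtomArray(n)
    arr.coord = structure.coords.astype(np.float32)
    arr.chain_id[:] = structure.chain or "A"
    arr.res_id = structure.res_numbers
    arr.ins_code = np.array(structure.ins_codes, dtype="U1")
    arr.res_name = np.array(structure.res_names, dtype="U5")
    arr.atom_name[:] = "CA"
    arr.element[:] = "C"
    arr.hetero[:] = False
    pdbfile = PDBFile()
    pdbfile.set_structure(arr)
    pdbfile.write(str(path))


# ---------------------------------------------------------------------------
# Rigid-body superposition
# ---------------------------------------------------------------------------

def kabsch(mobile: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rigid fit: returns (R, t) with R @ x + t mapping
    ``mobile`` onto ``target`` (proper rotation, no reflection)."""
    P = np.asarray(mobile, float)
    Q = np.asarray(target, float)
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    H = (P - cp).T @ (Q - cq)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cq - R @ cp
    return R, t


def _pair_align(ref: np.ndarray, mob: np.ndarray, d0: float = 4.0,
                match_cutoff: float = 8.0, max_iter: int = 50):
    """Iterative monotone correspondence + rigid fit between two C-alpha sets.

    Returns (pairs, R, t, rmsd) where pairs is a list of (ref_idx, mob_idx)
    and R, t superpose ``mob`` onto ``ref``.  Raises if the correspondence
    does not stabilise within ``max_iter`` sweeps.
    """
    n, m = len(ref), len(mob)
    k = min(n, m)
    R, t = kabsch(mob[:k], ref[:k])
    prev: list[tuple[int, int]] | None = None
    for it in range(max_iter):
        x = mob @ R.T + t
        d2 = ((ref[:, None, :] - x[None, :, :]) ** 2).sum(axis=2)
        score = 1.0 / (1.0 + d2 / d0 ** 2)
        # monotone (Needleman-Wunsch, zero gap penalty) best correspondence
        F = np.zeros((n + 1, m + 1))
        for i in range(1, n + 1):
            Fi, Fim = F[i], F[i - 1]
            for j in range(1, m + 1):
                Fi[j] = max(Fim[j - 1] + score[i - 1, j - 1], Fim[j], Fi[j - 1])
        pairs: list[tuple[int, int]] = []
        i, j = n, m
        while i > 0 and j > 0:
            if F[i, j] == F[i - 1, j - 1] + score[i - 1, j - 1]:
                if d2[i - 1, j - 1] < match_cutoff ** 2:
                    pairs.append((i - 1, j - 1))
                i, j = i - 1, j - 1
            elif F[i, j] == F[i - 1, j]:
                i -= 1
            else:
                j -= 1
        pairs.reverse()
        if len(pairs) < 3:
            raise ValueError("builtin alignment found < 3 corresponding residues")
        ri = np.array([p[0] for p in pairs])
        mi = np.array([p[1] for p in pairs])
        R, t = kabsch(mob[mi], ref[ri])
        if pairs == prev:
            x = mob @ R.T + t
            rmsd = float(np.sqrt(((ref[ri] - x[mi]) ** 2).sum(axis=1).mean()))
            return pairs, R, t, rmsd
        prev = pairs
    raise ValueError(f"builtin alignment failed to converge in {max_iter} iterations")


def _star_alignment(structures: list[CalphaStructure]) -> StructuralAlignment:
    """Progressive star alignment: every member is pairwise aligned to the
    first, and columns are merged on the reference residues.  Insertions of
    different members relative to the reference occupy separate columns."""
    ref = structures[0]
    K = len(structures)
    n0 = len(ref)
    match: list[dict[int, int]] = [dict((i, i) for i in range(n0))]
    transforms: list[tuple[np.ndarray, np.ndarray]] = [(np.eye(3), np.zeros(3))]
    for s in structures[1:]:
        pairs, R, t, _ = _pair_align(ref.coords, s.coords)
        match.append(dict(pairs))
        transforms.append((R, t))

    # member residues not matched to the reference, grouped by the reference
    # position they fall after (-1 = before the first matched residue)
    inserts: list[dict[int, list[int]]] = []
    for k in range(K):
        matched = match[k]
        inv = {v: r for r, v in matched.items()}      # member idx -> ref idx
        ins: dict[int, list[int]] = {}
        last_ref = -1
        for j in range(len(structures[k])):
            if j in inv:
                last_ref = inv[j]
            else:
                ins.setdefault(last_ref, []).append(j)
        inserts.append(ins)

    rows: list[list[int]] = []

    def emit_inserts(after_ref: int) -> None:
        for k in range(K):
            for j in inserts[k].get(after_ref, []):
                row = [GAP] * K
                row[k] = j
                rows.append(row)

    emit_inserts(-1)
    for r in range(n0):
        row = [match[k].get(r, GAP) for k in range(K)]
        rows.append(row)
        emit_inserts(r)

    superposed = [structures[k].coords @ transforms[k][0].T + transforms[k][1]
                  for k in range(K)]
    return StructuralAlignment(list(structures), np.array(rows, dtype=int),
                               superposed)


def align_structures(structures: list[CalphaStructure], mode: str = "builtin",
                     import_payload: ImportPayload | None = None
                     ) -> StructuralAlignment:
    """Build a :class:`StructuralAlignment` of >= 2 structures.

    ``mode="import"`` takes columns and superposed coordinates verbatim from
    an external aligner's output (:class:`ImportPayload`); this is the
    reference path for quantitative work.  ``mode="builtin"`` runs the
    progressive star aligner.
    """
    if len(structures) < 2:
        raise ValueError("need >= 2 structures to align")
    if mode == "builtin":
        return _star_alignment(structures)
    if mode != "import":
        raise ValueError(f"unknown mode {mode!r}")
    if import_payload is None:
        raise ValueError("import mode requires an ImportPayload")
    payload = import_payload
    if len(payload.superposed) != len(structures):
        raise ValueError("payload member count does not match structures")
    K = len(structures)
    cols = np.full((len(payload.columns), K), GAP, dtype=int)
    for k, (s, sup) in enumerate(zip(structures, payload.superposed)):
        if s.res_ids != sup.res_ids:
            bad = next(
                (a for a, b in zip(s.res_ids, sup.res_ids) if a != b),
                f"length {len(s)} vs {len(sup)}")
            raise ValueError(
                f"member {s.name}: superposed payload residue mismatch at "
                f"{bad!r}")
    for c, row in enumerate(payload.columns):
        if len(row) != K:
            raise ValueError(f"column {c}: {len(row)} fields for {K} members")
        for k, rid in enumerate(row):
            if rid == "-" or rid == "":
                continue
            try:
                cols[c, k] = structures[k].index_of(rid)
            except KeyError:
                raise ValueError(
                    f"member {structures[k].name}: column table names residue "
                    f"{rid!r} not present in the structure") from None
    superposed = [np.array(sup.coords, float) for sup in payload.superposed]
    return StructuralAlignment(list(structures), cols, superposed)


def load_column_table(path) -> list[list[str]]:
    """Read an alignment column table: one row per column, tab-separated
    author residue ids, ``-`` for a gap.  Lines starting with ``#`` are
    comments."""
    rows: list[list[str]] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            rows.append(line.split("\t"))
    return rows
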