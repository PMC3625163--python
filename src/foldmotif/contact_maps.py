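"""Native contact maps: computation, transformation and partitioning.

A native contact is an unordered residue pair (i, j), i < j, whose heavy
atoms approach within a cutoff in the folded structure; the associated length
scale ``sigma_ij`` is the native C-alpha--C-alpha distance, which sets the
minimum of the 10--12 contact potential in the structure-based model.  The
default criterion (any heavy-atom pair < 4.5 A, sequence separation >= 3) is
a pluggable stand-in for atomic contact analyses such as CSU; lists produced
by external tools can be imported verbatim from TSV so that published counts
are reproduced exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .structures_io import CalphaStructure, StructuralAlignment

__all__ = [
    "Contact",
    "ContactMap",
    "ContactParams",
    "compute_contact_map",
    "packing_fraction",
    "loop_length",
    "split_by_loop_length",
    "project_contacts",
    "contact_set_ops",
    "select_hub_contacts",
    "cluster_contacts",
    "read_contacts_tsv",
    "write_contacts_tsv",
    "BETA_TREFOIL_WT_COUNTS",
]

#: Published (residue count, contact count) pairs for the 13 functionally
#: diverse beta-trefoil chains used to construct the folding motif.  The
#: contact counts come from atomic contact analysis of the deposited
#: structures; the ratio contacts/residues is the packing fraction.
BETA_TREFOIL_WT_COUNTS: dict[str, tuple[int, int]] = {
    "2AFG": (129, 374),
    "6I1B": (153, 430),
    "1T9F": (178, 532),
    "1SR4": (154, 367),
    "1DQG": (134, 388),
    "1UPS": (131, 380),
    "1JLY": (153, 457),
    "1WBA": (171, 499),
    "1DFQ": (193, 528),
    "1DFC": (119, 347),
    "1HCD": (118, 324),
    "1TTU": (161, 428),
    "1WD4": (162, 481),
}


@dataclass(frozen=True)
class Contact:
    """Unordered native residue pair with its native C-alpha distance (A)."""

    i: int
    j: int
    sigma_ij: float

    def __post_init__(self) -> None:
        if self.i >= self.j:
            raise ValueError(f"contact requires i < j, got ({self.i}, {self.j})")
        if self.sigma_ij <= 0:
            raise ValueError("sigma_ij must be positive")

    @property
    def pair(self) -> tuple[int, int]:
        return (self.i, self.j)


@dataclass
class ContactMap:
    """Symmetric set of native contacts over ``n_residues`` beads.

    Stored as i < j pairs; duplicates are rejected.  ``min_separation`` is
    the smallest allowed |i - j| (default 3, the C-alpha SBM convention).
    """

    contacts: list[Contact]
    n_residues: int
    provenance: str = ""
    min_separation: int = 3

    def __post_init__(self) -> None:
        pairs = [c.pair for c in self.contacts]
        if len(set(pairs)) != len(pairs):
            raise ValueError("duplicate contacts")
        for c in self.contacts:
            if c.j - c.i < self.min_separation:
                raise ValueError(
                    f"contact {c.pair} violates min_separation="
                    f"{self.min_separation}")
            if c.j >= self.n_residues:
                raise ValueError(f"contact {c.pair} out of range "
                                 f"(n_residues={self.n_residues})")
        self.contacts = sorted(self.contacts, key=lambda c: c.pair)

    def __len__(self) -> int:
        return len(self.contacts)

    def __iter__(self):
        return iter(self.contacts)

    @property
    def pairs(self) -> set[tuple[int, int]]:
        return {c.pair for c in self.contacts}

    def sigma(self, i: int, j: int) -> float:
        for c in self.contacts:
            if c.pair == (i, j):
                return c.sigma_ij
        raise KeyError((i, j))

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(i, j, sigma) as flat arrays, for numeric kernels."""
        if not self.contacts:
            z = np.zeros(0)
            return z.astype(int), z.astype(int), z
        i = np.array([c.i for c in self.contacts])
        j = np.array([c.j for c in self.contacts])
        s = np.array([c.sigma_ij for c in self.contacts])
        return i, j, s


@dataclass
class ContactParams:
    heavy_atom_cutoff: float = 4.5     # A, any-heavy-atom criterion
    min_separation: int = 3
    calpha_cutoff: float = 6.5         # A, fallback when no heavy atoms


def compute_contact_map(structure: CalphaStructure,
                        params: ContactParams | None = None) -> ContactMap:
    """Contact map of a single structure.

    (i, j) is a contact iff any heavy-atom pair between residues i and j is
    within ``heavy_atom_cutoff`` and j - i >= ``min_separation``; sigma_ij is
    always the native C-alpha distance.  Structures without stored heavy
    atoms fall back to a C-alpha distance criterion with a warning.
    """
    import warnings

    params = params or ContactParams()
    n = len(structure)
    ca = structure.coords
    contacts: list[Contact] = []
    if structure.heavy_coords is None:
        warnings.warn(
            f"{structure.name}: no heavy atoms stored, falling back to "
            f"C-alpha cutoff {params.calpha_cutoff} A", stacklevel=2)
        d = np.linalg.norm(ca[:, None, :] - ca[None, :, :], axis=2)
        for i in range(n):
            for j in range(i + params.min_separation, n):
                if d[i, j] < params.calpha_cutoff:
                    contacts.append(Contact(i, j, float(d[i, j])))
    else:
        from scipy.spatial import cKDTree

        flat = np.concatenate(structure.heavy_coords, axis=0)
        owner = np.concatenate(
            [np.full(len(h), r) for r, h in enumerate(structure.heavy_coords)])
        tree = cKDTree(flat)
        pairs = tree.query_pairs(params.heavy_atom_cutoff, output_type="ndarray")
        ri = owner[pairs[:, 0]]
        rj = owner[pairs[:, 1]]
        lo = np.minimum(ri, rj)
        hi = np.maximum(ri, rj)
        mask = hi - lo >= params.min_separation
        for i, j in sorted(set(zip(lo[mask].tolist(), hi[mask].tolist()))):
            sigma = float(np.linalg.norm(ca[i] - ca[j]))
            contacts.append(Contact(i, j, sigma))
    return ContactMap(contacts, n, provenance=f"computed:{structure.name}",
                      min_separation=params.min_separation)


def packing_fraction(cmap: ContactMap) -> float:
    """Total number of contacts divided by the total number of residues."""
    if cmap.n_residues <= 0:
        raise ValueError("n_residues must be positive")
    return len(cmap) / cmap.n_residues


def loop_length(contact: Contact | tuple[int, int]) -> int:
    """Number of backbone residues separating the two contacting residues."""
    i, j = contact.pair if isinstance(contact, Contact) else contact
    return j - i - 1


def split_by_loop_length(contacts: list[Contact] | ContactMap, n_low: int
                         ) -> tuple[list[Contact], list[Contact]]:
    """Split contacts into short-range (lowest ``n_low`` loop lengths) and
    long-range groups.  Ties are broken by ascending (i, j) so the split is
    deterministic."""
    items = list(contacts)
    if not 0 <= n_low <= len(items):
        raise ValueError(f"n_low={n_low} out of range for {len(items)} contacts")
    ordered = sorted(items, key=lambda c: (loop_length(c), c.i, c.j))
    return ordered[:n_low], ordered[n_low:]


def project_contacts(source_map: ContactMap, alignment: StructuralAlignment,
                     source_member: str | int, target_member: str | int,
                     target_structure: CalphaStructure | None = None
                     ) -> ContactMap:
    """Project a contact map onto another backbone through an alignment.

    A source contact survives iff both of its residues align to non-gap
    residues of the target; it is re-indexed to the target and sigma_ij is
    re-measured on the target backbone (the hybrid is simulated as a model of
    the target geometry).  Pairs falling below the target map's minimum
    sequence separation are dropped.
    """
    corr = alignment.correspondence(source_member, target_member)
    tgt = target_structure or alignment.members[
        alignment.member_index(target_member)]
    contacts: list[Contact] = []
    for c in source_map:
        if c.i in corr and c.j in corr:
            p, q = sorted((corr[c.i], corr[c.j]))
            if q - p < source_map.min_separation:
                continue
            sigma = float(np.linalg.norm(tgt.coords[p] - tgt.coords[q]))
            contacts.append(Contact(p, q, sigma))
    src_name = getattr(source_map, "provenance", "") or str(source_member)
    return ContactMap(contacts, len(tgt),
                      provenance=f"projected:{src_name}->{tgt.name}",
                      min_separation=source_map.min_separation)


def contact_set_ops(a: ContactMap, b: ContactMap,
                    correspondence: dict[int, int] | None = None
                    ) -> dict[str, list[Contact]]:
    """Partition two maps into {only_a, only_b, common}.

    ``correspondence`` maps a-indices to b-indices (e.g. from
    ``StructuralAlignment.correspondence``); identity if omitted.  An
    a-contact touching a residue with no correspondent goes to ``only_a``
    (and symmetrically for b).  ``common`` is reported in a's indexing.
    """
    if correspondence is None:
        correspondence = {i: i for i in range(a.n_residues)}
    b_pairs = b.pairs
    mapped_pairs: set[tuple[int, int]] = set()
    only_a, common = [], []
    for c in a:
        if c.i in correspondence and c.j in correspondence:
            p, q = sorted((correspondence[c.i], correspondence[c.j]))
            if (p, q) in b_pairs:
                common.append(c)
                mapped_pairs.add((p, q))
                continue
        only_a.append(c)
    only_b = [c for c in b if c.pair not in mapped_pairs]
    return {"only_a": only_a, "only_b": only_b, "common": common}


def select_hub_contacts(contacts: list[Contact] | ContactMap,
                        min_degree: int = 3) -> list[Contact]:
    """Contacts having at least one residue that participates in
    >= ``min_degree`` contacts of the input set (degree computed once on the
    full input, not iteratively)."""
    if min_degree < 1:
        raise ValueError("min_degree must be >= 1")
    items = list(contacts)
    degree: dict[int, int] = {}
    for c in items:
        degree[c.i] = degree.get(c.i, 0) + 1
        degree[c.j] = degree.get(c.j, 0) + 1
    return [c for c in items
            if degree[c.i] >= min_degree or degree[c.j] >= min_degree]


def cluster_contacts(contacts: list[Contact] | ContactMap
                     ) -> list[dict]:
    """Connected components of the graph whose nodes are contacts and whose
    edges join contacts sharing a residue.

    Returns one dict per cluster: {"contacts": [...], "residues": sorted
    residue indices}, largest cluster first.
    """
    import networkx as nx

    items = list(contacts)
    if not items:
        raise ValueError("empty contact set")
    g = nx.Graph()
    g.add_nodes_from(range(len(items)))
    by_res: dict[int, list[int]] = {}
    for idx, c in enumerate(items):
        by_res.setdefault(c.i, []).append(idx)
        by_res.setdefault(c.j, []).append(idx)
    for nodes in by_res.values():
        for a, b in zip(nodes, nodes[1:]):
            g.add_edge(a, b)
    clusters = []
    for comp in nx.connected_components(g):
        cs = [items[idx] for idx in sorted(comp)]
        residues = sorted({r for c in cs for r in c.pair})
        clusters.append({"contacts": cs, "residues": residues})
    clusters.sort(key=lambda cl: (-len(cl["contacts"]), cl["residues"]))
    return clusters


# ---------------------------------------------------------------------------
# TSV interchange (author numbering, so external contact lists import cleanly)
# ---------------------------------------------------------------------------

def write_contacts_tsv(cmap: ContactMap, structure: CalphaStructure, path) -> None:
    ids = structure.res_ids
    with open(path, "w") as fh:
        fh.write("i_author\tj_author\tsigma_ij_angstrom\tsource\n")
        for c in cmap:
            fh.write(f"{ids[c.i]}\t{ids[c.j]}\t{c.sigma_ij:.4f}\t"
                     f"{cmap.provenance}\n")


def read_contacts_tsv(path, structure: CalphaStructure,
                      min_separation: int = 3) -> ContactMap:
    """Import a contact list (e.g. produced by an external atomic-contact
    tool) in author numbering.  sigma_ij, if blank, is re-measured from the
    structure's C-alpha coordinates."""
    contacts: list[Contact] = []
    with open(path) as fh:
        header = fh.readline()
        if not header.lower().startswith("i_author"):
            raise ValueError(f"{path}: expected contact TSV header")
        for line in fh:
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            i = structure.index_of(fields[0])
            j = structure.index_of(fields[1])
            i, j = min(i, j), max(i, j)
            if len(fields) > 2 and fields[2]:
                sigma = float(fields[2])
            else:
                sigma = float(np.linalg.norm(
                    structure.coords[i] - structure.coords[j]))
            contacts.append(Contact(i, j, sigma))
    return ContactMap(contacts, len(structure), provenance=f"tsv:{path}",
                      min_separation=min_separation)
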