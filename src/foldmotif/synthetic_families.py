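"""Synthetic fold families and toy folders: download-free, ground-truthed.

Two kinds of fixture generators live here.  ``make_family`` emulates what a
structural family looks like to the folding-motif pipeline: a shared
structural core, per-member decoy loop insertions ("functional"
decorations), occasional core deletions, coordinate noise and a random
rigid-body pose, with the generator's own bookkeeping exposed as a
ground-truth alignment.  ``make_ideal_fold`` / ``make_toy_twostate`` build
small bead chains whose SBMs fold two-state at desk scale, standing in for
the beta-trefoil simulations when exercising the sampling and landscape
machinery.

Insertions are placed as out-of-plane excursion bulges so that they perturb
neither core contacts nor core geometry — loops decorating a conserved fold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .contact_maps import Contact, ContactMap
from .structures_io import GAP, CalphaStructure, StructuralAlignment

__all__ = [
    "FamilySpec",
    "SyntheticFamily",
    "make_ideal_fold",
    "make_family",
    "make_toy_twostate",
]

BOND = 3.8            # canonical virtual C-alpha bond length, A
STRAND_SEP = 5.4      # cross-strand C-alpha pairing distance, A


@dataclass
class FamilySpec:
    """Study conditions for a synthetic family.

    Defaults mirror the folding-motif study design: 13 members, two decoy
    insertion sites each present in a minority (at most 6) of the members so
    the >50% occupancy rule must reject them, 0.3 A coordinate noise, and a
    random rigid pose per member.
    """

    n_members: int = 13
    insertion_sites: tuple[int, ...] = (5, 12)   # after this core position
    insertion_length: tuple[int, int] = (3, 6)   # inclusive range
    max_members_with_insertion: int = 6
    deletion_probability: float = 0.0
    noise_sigma: float = 0.3                     # A, isotropic
    random_pose: bool = True
    seed: int = 0
    max_retries: int = 50

    def __post_init__(self) -> None:
        if not 0.0 <= self.deletion_probability <= 1.0:
            raise ValueError("deletion_probability must be in [0, 1]")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.n_members < 2:
            raise ValueError("need >= 2 members")


@dataclass
class SyntheticFamily:
    members: list[CalphaStructure]
    alignment: StructuralAlignment          # ground truth, pre-superposed
    contact_maps: list[ContactMap]
    core_columns: np.ndarray                # alignment columns that are core
    insertion_columns: np.ndarray
    spec: FamilySpec = field(default_factory=FamilySpec)


#: Out-of-plane zig-zag half-amplitude of idealized strands (keeps
#: consecutive bead triples from being collinear).
ZIG = 0.5
_RISE = np.sqrt(BOND ** 2 - (2 * ZIG) ** 2)    # along-strand spacing


def _strand_coords(x0: float, y: float, direction: float, length: int
                   ) -> np.ndarray:
    out = np.zeros((length, 3))
    for k in range(length):
        out[k] = (x0 + direction * _RISE * k, y, ZIG * (-1) ** k)
    return out


def _zigzag_sheet(strand_lengths: list[int]
                  ) -> tuple[np.ndarray, list[list[int]]]:
    """Antiparallel strands at STRAND_SEP spacing joined by exact-bond
    two-bead turns; returns coordinates and per-strand bead indices."""
    c = (STRAND_SEP - BOND) / 2.0
    a = np.sqrt(BOND ** 2 - c ** 2 - ZIG ** 2)
    coords: list[np.ndarray] = []
    strands: list[list[int]] = []
    y = 0.0
    direction = 1.0
    x0 = 0.0
    idx = 0
    for s, L in enumerate(strand_lengths):
        block = _strand_coords(x0, y, direction, L)
        strands.append(list(range(idx, idx + L)))
        coords.extend(block)
        idx += L
        if s < len(strand_lengths) - 1:
            tip = block[-1, 0]
            coords.append(np.array([tip + direction * a, y + c, 0.0]))
            coords.append(np.array([tip + direction * a,
                                    y + STRAND_SEP - c, 0.0]))
            idx += 2
            y += STRAND_SEP
            x0 = tip
            direction = -direction
    return np.array(coords), strands


def _pair_strands(x: np.ndarray, strands: list[list[int]],
                  min_loop_sep: int) -> list[tuple[int, int]]:
    contacts = []
    for sa, sb in zip(strands, strands[1:]):
        for i in sa:
            for j in sb:
                lo, hi = min(i, j), max(i, j)
                if abs(x[i, 0] - x[j, 0]) < 0.5 * _RISE \
                        and hi - lo >= min_loop_sep:
                    contacts.append((lo, hi))
    return sorted(set(contacts))


def _hairpin(n: int) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Two-strand hairpin, all bonds exactly BOND.

    Strands of h = n//2 - 1 beads plus a two-bead turn; designed contacts
    pair the strands, (i, n-1-i) with j - i >= 6 (the two tightest turn
    pairs are left to the bonded terms).
    """
    if n < 10:
        raise ValueError("hairpin needs n >= 10")
    h = n // 2 - 1
    x, strands = _zigzag_sheet([h, n - h - 2])
    return x, _pair_strands(x, strands, min_loop_sep=6)


def _meander(n: int) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Three antiparallel strands (a beta-meander): two hairpin turns."""
    per = (n - 4) // 3
    extra = (n - 4) - 3 * per
    lens = [per + (1 if k < extra else 0) for k in range(3)]
    x, strands = _zigzag_sheet(lens)
    return x, _pair_strands(x, strands, min_loop_sep=5)


def make_ideal_fold(n: int, style: str = "hairpin", seed: int = 0
                    ) -> tuple[CalphaStructure, ContactMap]:
    """Idealized self-avoiding C-alpha chain with designed native contacts.

    Styles: ``hairpin`` (two strands; clean two-state under the SBM),
    ``helix-like`` (regular helix, local i/i+4 contacts), ``compact-random``
    (seeded self-avoiding collapse with distance-based contacts).
    """
    if n < 10:
        raise ValueError("need n >= 10 beads")
    rng = np.random.default_rng(seed)
    if style == "hairpin":
        x, pairs = _hairpin(n)
    elif style == "helix-like":
        # rise and radius chosen for 3.8 A along-chain spacing
        turns_per_bead = 2 * np.pi / 3.6
        radius = 2.3
        chord = 2 * radius * np.sin(turns_per_bead / 2)
        rise = np.sqrt(BOND ** 2 - chord ** 2)
        t = np.arange(n)
        x = np.stack([radius * np.cos(turns_per_bead * t),
                      radius * np.sin(turns_per_bead * t),
                      rise * t], axis=1)
        pairs = [(i, i + 4) for i in range(n - 4)]
    elif style == "compact-random":
        x = _self_avoiding_collapse(n, rng)
        d = np.linalg.norm(x[:, None] - x[None, :], axis=2)
        pairs = [(i, j) for i in range(n) for j in range(i + 3, n)
                 if d[i, j] < 6.5]
    else:
        raise ValueError(f"unknown style {style!r}")
    structure = CalphaStructure(
        name=f"{style}-{n}-s{seed}", chain="A", coords=x,
        res_numbers=np.arange(1, n + 1))
    d = np.linalg.norm(x[:, None] - x[None, :], axis=2)
    cmap = ContactMap([Contact(i, j, float(d[i, j])) for i, j in pairs], n,
                      provenance=f"designed:{style}")
    return structure, cmap


def _self_avoiding_collapse(n: int, rng: np.random.Generator) -> np.ndarray:
    """Biased self-avoiding walk with fixed bond length, drawn toward the
    centroid so the chain stays compact."""
    x = [np.zeros(3), np.array([BOND, 0.0, 0.0])]
    for _ in range(2, n):
        centroid = np.mean(x, axis=0)
        for _attempt in range(500):
            step = rng.normal(size=3)
            pull = centroid - x[-1]
            if np.linalg.norm(pull) > 1e-9:
                step = step + 0.8 * pull / np.linalg.norm(pull)
            step = BOND * step / np.linalg.norm(step)
            cand = x[-1] + step
            d = np.linalg.norm(np.array(x[:-1]) - cand, axis=1)
            if d.min() > 3.9:
                x.append(cand)
                break
        else:
            raise RuntimeError("self-avoiding walk got stuck")
    return np.array(x)


def _bulge_loop(anchor_a: np.ndarray, anchor_b: np.ndarray, length: int,
                outward: np.ndarray) -> np.ndarray:
    """Arc of ``length`` beads bridging two anchors, bowed out along
    ``outward`` so the loop stays clear of the core."""
    ts = np.linspace(0.0, 1.0, length + 2)[1:-1]
    base = anchor_a[None, :] + ts[:, None] * (anchor_b - anchor_a)[None, :]
    bulge = np.sin(np.pi * ts)[:, None] * outward[None, :] * (2.0 + 0.9 * length)
    return base + bulge


def make_family(template: CalphaStructure, template_map: ContactMap,
                spec: FamilySpec | None = None) -> SyntheticFamily:
    """Decorate a template core into a family with known ground truth.

    Each member is the template core (minus sampled deletions) with decoy
    bulge loops inserted at the spec's sites, Gaussian coordinate noise, and
    a random rigid pose.  The returned alignment's superposed coordinates
    are the pre-pose (noisy) coordinates, i.e. a perfect aligner's output;
    column bookkeeping marks core vs insertion columns.  Member contact maps
    are the template contacts surviving deletions (sigma re-measured per
    member) plus loop-local contacts.
    """
    spec = spec or FamilySpec()
    rng = np.random.default_rng(spec.seed)
    n_core = len(template)
    K = spec.n_members
    lo_len, hi_len = spec.insertion_length

    # which members carry which insertion, and how long
    ins_members: dict[int, dict[int, int]] = {}
    for site in spec.insertion_sites:
        if not 0 <= site < n_core - 1:
            raise ValueError(f"insertion site {site} out of range")
        n_with = int(rng.integers(1, spec.max_members_with_insertion + 1))
        chosen = rng.choice(K, size=n_with, replace=False)
        ins_members[site] = {int(m): int(rng.integers(lo_len, hi_len + 1))
                             for m in chosen}

    # deletions per member (resampled if they disconnect the chain: no two
    # adjacent core deletions and never a terminal residue)
    deletions: list[set[int]] = []
    for _m in range(K):
        for _try in range(spec.max_retries):
            dels = {i for i in range(1, n_core - 1)
                    if rng.random() < spec.deletion_probability}
            if all(i + 1 not in dels for i in dels):
                deletions.append(dels)
                break
        else:
            raise RuntimeError("could not sample a connected deletion pattern")

    centroid = template.coords.mean(axis=0)
    members: list[CalphaStructure] = []
    maps: list[ContactMap] = []
    # per member: map core position -> member internal index (or None)
    core_to_member: list[list[int | None]] = []
    # per site: per member, list of member indices of inserted beads
    ins_to_member: dict[int, list[list[int]]] = {s: [[] for _ in range(K)]
                                                 for s in spec.insertion_sites}

    for m in range(K):
        coords: list[np.ndarray] = []
        kinds: list[tuple[str, int, int]] = []   # ("core", pos) / ("ins", site, rank)
        for pos in range(n_core):
            if pos in deletions[m]:
                continue
            coords.append(template.coords[pos].copy())
            kinds.append(("core", pos, 0))
            if pos in ins_members and m in ins_members[pos] \
                    and (pos + 1) not in deletions[m]:
                L = ins_members[pos][m]
                outward = template.coords[pos] - centroid
                outward = outward / max(np.linalg.norm(outward), 1e-9)
                loop = _bulge_loop(template.coords[pos],
                                   template.coords[pos + 1], L, outward)
                for r in range(L):
                    coords.append(loop[r])
                    kinds.append(("ins", pos, r))
        arr = np.array(coords)
        arr = arr + rng.normal(scale=spec.noise_sigma, size=arr.shape)
        pre_pose = arr.copy()

        if spec.random_pose:
            # uniform random rotation via QR of a Gaussian matrix
            q, r = np.linalg.qr(rng.normal(size=(3, 3)))
            q *= np.sign(np.diag(r))
            if np.linalg.det(q) < 0:
                q[:, 0] = -q[:, 0]
            arr = arr @ q.T + rng.uniform(-50, 50, size=3)

        member = CalphaStructure(
            name=f"member{m:02d}", chain="A", coords=arr,
            res_numbers=np.arange(1, len(arr) + 1))
        members.append(member)
        member.superposed_truth = pre_pose          # ground-truth overlay

        c2m: list[int | None] = [None] * n_core
        for idx, (kind, a, b) in enumerate(kinds):
            if kind == "core":
                c2m[a] = idx
            else:
                ins_to_member[a][m].append(idx)
        core_to_member.append(c2m)

        # member contact map: surviving template contacts + loop-local pairs
        contacts: list[Contact] = []
        for c in template_map:
            ia = c2m[c.i]
            ja = c2m[c.j]
            if ia is None or ja is None:
                continue
            p, q_ = min(ia, ja), max(ia, ja)
            if q_ - p < template_map.min_separation:
                continue
            sigma = float(np.linalg.norm(pre_pose[p] - pre_pose[q_]))
            contacts.append(Contact(p, q_, sigma))
        for site in spec.insertion_sites:
            beads = ins_to_member[site][m]
            for ai in range(len(beads)):
                for aj in range(ai + 1, len(beads)):
                    p, q_ = beads[ai], beads[aj]
                    if q_ - p < 3:
                        continue
                    d = float(np.linalg.norm(pre_pose[p] - pre_pose[q_]))
                    if d < 6.5:
                        contacts.append(Contact(p, q_, d))
        maps.append(ContactMap(sorted(set(contacts), key=lambda c: c.pair),
                               len(arr), provenance=f"synthetic:{member.name}"))

    # ground-truth columns: walk core positions; after each, the insertion
    # block of that site (shared across members, padded with gaps)
    rows: list[list[int]] = []
    kinds_of_row: list[str] = []
    for pos in range(n_core):
        rows.append([c2m[pos] if c2m[pos] is not None else GAP
                     for c2m in core_to_member])
        kinds_of_row.append("core")
        if pos in ins_members:
            block = max((len(ins_to_member[pos][m]) for m in range(K)),
                        default=0)
            for r in range(block):
                row = []
                for m in range(K):
                    beads = ins_to_member[pos][m]
                    row.append(beads[r] if r < len(beads) else GAP)
                rows.append(row)
                kinds_of_row.append("insertion")

    superposed = [mem.superposed_truth for mem in members]
    alignment = StructuralAlignment(members, np.array(rows, dtype=int),
                                    superposed)
    kinds_arr = np.array(kinds_of_row)
    return SyntheticFamily(
        members=members, alignment=alignment, contact_maps=maps,
        core_columns=np.flatnonzero(kinds_arr == "core"),
        insertion_columns=np.flatnonzero(kinds_arr == "insertion"),
        spec=spec)


def make_toy_twostate(seed: int = 0, n: int = 30,
                      near_band: tuple[int, int] = (3, 6),
                      far_band: int = 18):
    """Desk-scale two-state folder: a 30-bead hairpin with a deferred
    distal contact band.

    The chain is a two-strand hairpin whose native contacts come in two
    bands of sequence separation: a near-turn band (``near_band``, formed
    already in the compact denatured state, anchoring the strands) and a
    distal band (separation >= ``far_band``).  The rungs in between carry
    no contacts, so progressing from the turn-anchored denatured state to
    the folded hairpin requires ordering an unrewarded stretch of ladder —
    a free-energy barrier crossed by local zippering, which keeps the
    kinetics fast.  Near its folding temperature the model exchanges
    between the two basins on the 10^4-step scale, which is what the
    landscape machinery needs; designs whose every pairing step is
    rewarded melt continuously at this size, and designs rewarded only at
    the distal ends have barriers whose crossing from a fully disordered
    coil is too slow to sample (see the methods note, including why the
    fully extended coil is not part of the sampled denatured ensemble).
    """
    from .sbm_model import SBMParameters, build_topology

    h = n // 2 - 1
    x, strands = _zigzag_sheet([h, n - h - 2])
    pairs = []
    for i in strands[0]:
        for j in strands[1]:
            sep = j - i
            if abs(x[i, 0] - x[j, 0]) < 1.5 * _RISE and \
                    (near_band[0] <= sep <= near_band[1] or sep >= far_band):
                pairs.append((i, j))
    d = np.linalg.norm(x[:, None] - x[None, :], axis=2)
    cmap = ContactMap([Contact(i, j, float(d[i, j]))
                       for i, j in sorted(pairs)], n,
                      provenance="designed:toy-twostate")
    structure = CalphaStructure(name=f"toy-twostate-s{seed}", chain="A",
                                coords=x, res_numbers=np.arange(1, n + 1))
    return build_topology(structure, cmap, SBMParameters(),
                          name=structure.name)
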