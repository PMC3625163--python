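"""Free-energy profiles, barrier heights, route maps and backtracking.

All free energies are -ln of a weighted Q histogram, i.e. in units of k_B T
at the sample's target temperature; at T_f this is the scaled free energy
F / k_B T_f used to compare folding barriers across models (a higher barrier
implies a slower folder).  Route maps give per-contact formation
probabilities inside a narrow Q window; a contact whose formation
probability drops substantially as folding progresses is backtracking.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass, field

import numpy as np

from .sampling import FORMATION_FACTOR, WeightedSample
from .sbm_model import SBMTopology

__all__ = [
    "FreeEnergyProfile",
    "RouteMap",
    "BacktrackingEvent",
    "free_energy_profile",
    "natural_q_bins",
    "profile_on_natural_bins",
    "barrier_height",
    "route_map",
    "route_maps_on_grid",
    "detect_backtracking",
    "write_profile_tsv",
    "write_route_map_tsv",
]

#: Barrier changes below ~2 k_B T are within the roughness of the folding
#: funnel and are reported as residual rather than significant.
RESIDUAL_BARRIER_CHANGE = 2.0


@dataclass
class FreeEnergyProfile:
    """F(Q) on a fixed grid; NaN where no frames fell."""

    bin_edges: np.ndarray
    free_energy: np.ndarray          # shifted so the global minimum is 0
    probabilities: np.ndarray        # normalized over visited bins
    temperature: float
    basins: list[float] = field(default_factory=list)   # basin Q positions
    barrier_q: float = float("nan")
    undersampled: list[float] = field(default_factory=list)

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def value_at(self, q: float) -> float:
        # side="right" matches np.histogram's half-open bin convention
        k = int(np.clip(np.searchsorted(self.bin_edges, q, side="right") - 1,
                        0, len(self.free_energy) - 1))
        return float(self.free_energy[k])


def _find_basins(centers: np.ndarray, F: np.ndarray,
                 min_separation: float = 0.2,
                 smooth_window: int = 3,
                 min_prominence: float = 0.15) -> tuple[list[float], float]:
    """Two-basin detection on the smoothed profile.

    Among all pairs of local minima at least ``min_separation`` apart in Q,
    keep the pair with the most prominent intervening barrier (the maximum
    of F between them minus the shallower well) — a topographic criterion
    that is robust to noise dimples inside a single broad basin and to
    profiles tilted away from T_f, where the minor basin is shallow.
    Pairs whose best prominence falls below ``min_prominence`` (k_BT) do
    not count as two states at all; the default floor sits at the bin-level
    statistical noise of a well-sampled profile, so ripples on a plateau do
    not masquerade as a folding barrier (callers that must be certain a
    barrier is real, like the folding-temperature search, apply their own
    stricter prominence and population filters on top).  Returns ([basin Q
    positions], barrier-top Q).
    """
    ok = np.isfinite(F)
    c = centers[ok]
    f = F[ok]
    if len(f) < 3:
        return ([float(c[np.argmin(f)])] if len(f) else []), float("nan")
    pad = smooth_window // 2
    fs = np.convolve(np.pad(f, pad, mode="edge"),
                     np.ones(smooth_window) / smooth_window, mode="valid")
    minima = [k for k in range(len(fs))
              if (k == 0 or fs[k] <= fs[k - 1])
              and (k == len(fs) - 1 or fs[k] < fs[k + 1])]
    if not minima:
        minima = [int(np.argmin(fs))]
    best = None
    for a_i, a in enumerate(minima):
        for b in minima[a_i + 1:]:
            if c[b] - c[a] < min_separation:
                continue
            top = int(a + np.argmax(f[a:b + 1]))
            prominence = f[top] - max(fs[a], fs[b])
            if prominence < min_prominence:
                continue
            if best is None or prominence > best[0]:
                best = (prominence, a, b, top)
    if best is None:
        k = int(np.argmin(fs))
        return [float(c[k])], float("nan")
    _, a, b, top = best
    return [float(c[a]), float(c[b])], float(c[top])


def free_energy_profile(sample: WeightedSample, n_bins: int = 40,
                        q_range: tuple[float, float] = (0.0, 1.0)
                        ) -> FreeEnergyProfile:
    """F(Q) = -ln(weighted histogram), minimum shifted to zero.

    Q is discrete (multiples of 1/m for m native contacts); when the bin
    count does not divide the level count, bins alternate between holding
    one and two levels and the raw histogram acquires a spurious +-ln(2)
    sawtooth.  Choose ``n_bins`` equal to the number of native contacts to
    put exactly one Q level in each bin (edges fall on the midpoints
    between levels).  Interior bins of the visited range that received no
    frames are flagged as undersampled.
    """
    if not np.isclose(sample.weights.sum(), 1.0, atol=1e-8):
        raise ValueError("sample weights must be normalized")
    edges = np.linspace(q_range[0], q_range[1], n_bins + 1)
    hist, _ = np.histogram(sample.q, bins=edges, weights=sample.weights)
    visited = hist > 0
    if not visited.any():
        raise ValueError("no frames inside the Q range")
    F = np.full(n_bins, np.nan)
    F[visited] = -np.log(hist[visited])
    F -= np.nanmin(F)
    centers = 0.5 * (edges[:-1] + edges[1:])
    lo, hi = np.flatnonzero(visited)[[0, -1]]
    undersampled = [float(centers[k]) for k in range(lo, hi + 1)
                    if not visited[k]]
    if undersampled:
        _warnings.warn(
            f"{len(undersampled)} interior Q bin(s) unvisited "
            "(undersampled profile)", stacklevel=2)
    basins, barrier_q = _find_basins(centers, F)
    return FreeEnergyProfile(bin_edges=edges, free_energy=F,
                             probabilities=hist, temperature=sample.temperature,
                             basins=basins, barrier_q=barrier_q,
                             undersampled=undersampled)


def natural_q_bins(n_contacts: int) -> tuple[int, tuple[float, float]]:
    """(n_bins, q_range) placing each discrete Q level k/m at a bin center,
    eliminating the level-aliasing sawtooth of arbitrary binning."""
    m = int(n_contacts)
    half = 0.5 / m
    return m + 1, (-half, 1.0 + half)


def profile_on_natural_bins(sample: WeightedSample,
                            n_contacts: int) -> FreeEnergyProfile:
    """Free-energy profile binned on the discrete Q grid of a topology."""
    n_bins, q_range = natural_q_bins(n_contacts)
    return free_energy_profile(sample, n_bins=n_bins, q_range=q_range)


def barrier_height(profile: FreeEnergyProfile) -> float:
    """Scaled barrier: max F between the basins minus the unfolded-basin F.

    The unfolded basin is the lower-Q one; at T_f, where the basins are
    equal, the choice of reference basin does not matter.  Invariant under
    adding a constant to F.
    """
    if len(profile.basins) < 2:
        raise ValueError("profile has a single basin; no barrier defined")
    return float(profile.value_at(profile.barrier_q)
                 - profile.value_at(profile.basins[0]))


@dataclass
class RouteMap:
    """Per-contact formation probability in a window |Q - center| <= hw."""

    q_center: float
    q_halfwidth: float
    contact_i: np.ndarray
    contact_j: np.ndarray
    probabilities: np.ndarray
    n_frames: int
    effective_frames: float

    def probability(self, i: int, j: int) -> float:
        for a, b, p in zip(self.contact_i, self.contact_j, self.probabilities):
            if (a, b) == (i, j):
                return float(p)
        raise KeyError((i, j))


def route_map(sample: WeightedSample, topology: SBMTopology, q_center: float,
              q_halfwidth: float = 0.025,
              formation_factor: float = FORMATION_FACTOR) -> RouteMap:
    """Weighted per-contact formation probabilities near one Q value.

    Needs coordinate-saving runs.  An empty window raises, naming the
    nearest populated Q; fewer than 100 effective frames earns a warning.
    """
    mask = np.abs(sample.q - q_center) <= q_halfwidth
    if not mask.any():
        near = float(sample.q[np.argmin(np.abs(sample.q - q_center))])
        raise ValueError(
            f"no frames with |Q - {q_center}| <= {q_halfwidth}; nearest "
            f"populated Q is {near:.3f}")
    idx = np.flatnonzero(mask)
    w = sample.weights[idx]
    wsum = w.sum()
    if wsum <= 0:
        raise ValueError("window has zero total weight")
    ess = float(wsum ** 2 / np.sum(w ** 2))
    if ess < 100:
        _warnings.warn(
            f"route map window at Q={q_center} has only {ess:.0f} effective "
            "frames", stacklevel=2)
    coords = sample.coords(idx)
    d = np.linalg.norm(coords[:, topology.contact_j, :]
                       - coords[:, topology.contact_i, :], axis=2)
    formed = d < formation_factor * topology.contact_sigma[None, :]
    prob = (w[:, None] * formed).sum(axis=0) / wsum
    return RouteMap(q_center=q_center, q_halfwidth=q_halfwidth,
                    contact_i=topology.contact_i.copy(),
                    contact_j=topology.contact_j.copy(),
                    probabilities=prob, n_frames=int(mask.sum()),
                    effective_frames=ess)


def route_maps_on_grid(sample: WeightedSample, topology: SBMTopology,
                       centers: np.ndarray | None = None,
                       q_halfwidth: float = 0.025) -> list[RouteMap]:
    """Route maps over a Q grid (default 0.05 .. 0.95 step 0.05), skipping
    windows with no frames."""
    if centers is None:
        centers = np.arange(0.05, 0.951, 0.05)
    maps = []
    for qc in centers:
        try:
            maps.append(route_map(sample, topology, float(qc), q_halfwidth))
        except ValueError:
            continue
    return maps


@dataclass
class BacktrackingEvent:
    i: int
    j: int
    drop: float
    q_rise: float        # window where the formation probability peaked
    q_drop: float        # later window where it had fallen the most


def detect_backtracking(route_maps: list[RouteMap],
                        drop_threshold: float = 0.25
                        ) -> list[BacktrackingEvent]:
    """Contacts that form early and then break as folding progresses.

    A contact is flagged iff its formation probability drops by more than
    ``drop_threshold`` between some pair of windows Q1 < Q2; the maximal
    drop and its Q interval are reported.  Needs >= 5 windows spanning both
    basins.
    """
    if len(route_maps) < 5:
        raise ValueError("need >= 5 Q windows to assess backtracking")
    maps = sorted(route_maps, key=lambda m: m.q_center)
    qs = np.array([m.q_center for m in maps])
    P = np.stack([m.probabilities for m in maps])       # (windows, contacts)
    events: list[BacktrackingEvent] = []
    for c in range(P.shape[1]):
        p = P[:, c]
        run_max = np.maximum.accumulate(p)
        drops = run_max - p
        k2 = int(np.argmax(drops))
        if drops[k2] > drop_threshold:
            k1 = int(np.argmax(p[:k2 + 1]))
            events.append(BacktrackingEvent(
                i=int(maps[0].contact_i[c]), j=int(maps[0].contact_j[c]),
                drop=float(drops[k2]), q_rise=float(qs[k1]),
                q_drop=float(qs[k2])))
    events.sort(key=lambda e: -e.drop)
    return events


def write_profile_tsv(profile: FreeEnergyProfile, path) -> None:
    with open(path, "w") as fh:
        fh.write("Q_bin\tF_scaled\n")
        for c, f in zip(profile.bin_centers, profile.free_energy):
            if np.isfinite(f):
                fh.write(f"{c:.4f}\t{f:.6f}\n")


def write_route_map_tsv(rmap: RouteMap, structure, path) -> None:
    ids = structure.res_ids if structure is not None else None
    with open(path, "w") as fh:
        fh.write("i_author\tj_author\tprobability\tq_center\n")
        for i, j, p in zip(rmap.contact_i, rmap.contact_j, rmap.probabilities):
            a = ids[i] if ids else str(i)
            b = ids[j] if ids else str(j)
            fh.write(f"{a}\t{b}\t{p:.4f}\t{rmap.q_center:.3f}\n")
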