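"""Two-point RIL linkage analysis and map construction.

Markers are grouped by a recombination-fraction/LOD graph, co-segregating
markers are collapsed into haplotype bins, bins are ordered by minimising
the total count of crossover events over the family (a greedy insertion
build refined by exhaustive permutation of a sliding window), leftover
markers are placed by a LOD-exclusion rule, and segregation distortion is
tested against the Mendelian 1:1 expectation.

The observed fraction R of recombinant lines between two loci in a selfed
RIL family overestimates the per-meiosis recombination fraction r because
recombinants accumulate over generations; the two are related by
R = 2r / (1 + 2r), inverted here before applying the Kosambi map function
d = 25 ln((1 + 2r) / (1 - 2r)).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

__all__ = [
    "TwoPointResult",
    "LinkageGroup",
    "LinkageMap",
    "two_point",
    "pairwise_tables",
    "ril_correct",
    "kosambi",
    "kosambi_inverse",
    "group_markers",
    "bin_haplotypes",
    "order_markers",
    "order_objective",
    "place_markers",
    "segregation_chisq",
    "double_co_scan",
    "build_linkage_map",
]


# ---------------------------------------------------------------------------
# Two-point statistics

@dataclass(frozen=True)
class TwoPointResult:
    n_informative: int
    n_recombinant: int
    R: float                 # observed recombinant fraction among RILs
    lod: float               # log10 likelihood ratio vs independent assortment
    r: float                 # corrected per-meiosis recombination fraction
    distance_cm: float       # Kosambi distance
    defined: bool = True


def _lod_from_counts(k: int, n: int) -> float:
    """LOD of linkage vs R = 0.5 from recombinant count k of n informative."""
    if n == 0:
        return 0.0
    R = k / n
    lod = 0.0
    if k > 0:
        lod += k * np.log10(R / 0.5)
    if n - k > 0:
        lod += (n - k) * np.log10((1.0 - R) / 0.5)
    return float(lod)


def two_point(gi: np.ndarray, gj: np.ndarray) -> TwoPointResult:
    """Two-point analysis of a marker pair from genotype codes.

    Lines heterozygous or missing at either marker are excluded; R is the
    fraction of informative lines whose homozygous classes differ.
    """
    gi = np.asarray(gi)
    gj = np.asarray(gj)
    inf_mask = ((gi == 0) | (gi == 1)) & ((gj == 0) | (gj == 1))
    n = int(inf_mask.sum())
    if n == 0:
        return TwoPointResult(0, 0, np.nan, 0.0, np.nan, np.nan, defined=False)
    k = int(np.sum(gi[inf_mask] != gj[inf_mask]))
    R = k / n
    r = ril_correct(R) if R < 1.0 else 0.5
    d = kosambi(r) if r < 0.5 else np.inf
    return TwoPointResult(n, k, R, _lod_from_counts(k, n), r, d)


def pairwise_tables(genotypes: np.ndarray):
    """All-pairs informative counts N and recombinant counts D.

    ``genotypes`` is (n_lines, m) coded 0/1/2/-1.  Returns (N, D) as (m, m)
    integer matrices over lines homozygous at both markers of a pair.
    """
    a = (genotypes == 0).astype(np.float64)
    b = (genotypes == 1).astype(np.float64)
    hom = a + b
    N = hom.T @ hom
    D = a.T @ b + b.T @ a
    return N.astype(np.int64), D.astype(np.int64)


def ril_correct(R: float) -> float:
    """Per-meiosis recombination fraction from the observed RIL fraction.

    Inverse of R = 2r / (1 + 2r) for RILs by selfing; capped at 0.5.
    """
    R = float(R)
    if not 0.0 <= R < 1.0:
        raise ValueError("R must be in [0, 1)")
    return min(R / (2.0 - 2.0 * R), 0.5)


def kosambi(r: float) -> float:
    """Kosambi map distance (cM); infinite (unlinked) at r >= 0.5."""
    r = float(r)
    if r < 0.0:
        raise ValueError("r must be non-negative")
    if r >= 0.5:
        return np.inf
    return 25.0 * np.log((1.0 + 2.0 * r) / (1.0 - 2.0 * r))


def kosambi_inverse(d: float) -> float:
    """Recombination fraction at Kosambi distance d cM."""
    e = np.exp(4.0 * d / 100.0)
    return float((e - 1.0) / (2.0 * (e + 1.0)))


# ---------------------------------------------------------------------------
# Grouping and binning

def group_markers(genotypes: np.ndarray, rf_cutoff: float = 0.2,
                  min_lod: float = 6.0, tables=None) -> list[list[int]]:
    """Partition markers into linkage groups.

    Groups are connected components of the graph whose edges join marker
    pairs with corrected r <= rf_cutoff and LOD >= min_lod.  Singleton
    components (markers unlinked to everything) come back as one-element
    groups.  Groups are ordered by size, largest first.
    """
    m = genotypes.shape[1]
    N, D = tables if tables is not None else pairwise_tables(genotypes)
    with np.errstate(invalid="ignore", divide="ignore"):
        R = np.where(N > 0, D / np.maximum(N, 1), np.nan)
        r = np.where(R < 1.0, R / (2.0 - 2.0 * R), 0.5)
        logR = np.where(D > 0, np.log10(np.maximum(R, 1e-300) / 0.5), 0.0)
        log1R = np.where(N - D > 0, np.log10(np.maximum(1.0 - R, 1e-300) / 0.5), 0.0)
        lod = D * logR + (N - D) * log1R
    adj = (N > 0) & (r <= rf_cutoff) & (lod >= min_lod)
    np.fill_diagonal(adj, False)
    n_comp, labels = connected_components(csr_matrix(adj), directed=False)
    groups = [[] for _ in range(n_comp)]
    for j in range(m):
        groups[labels[j]].append(j)
    groups.sort(key=lambda g: (-len(g), g[0]))
    return groups


def bin_haplotypes(group: list[int], genotypes: np.ndarray,
                   marker_ids=None) -> list[dict]:
    """Collapse recombinationally indistinguishable markers into bins.

    Two markers merge when their non-missing calls never conflict, i.e. no
    line exhibits a recombinant or inconsistent pair.  Merging is the
    transitive closure of that relation.  Each bin's representative is its
    member with the fewest missing calls (ties broken by input order).
    Returns a list of {"representative", "members"} dicts, members as
    marker indices.
    """
    idx = np.asarray(group)
    sub = genotypes[:, idx]
    conflict = np.zeros((len(idx), len(idx)), dtype=bool)
    codes = [(sub == c).astype(np.float64) for c in (0, 1, 2)]
    for ci in range(3):
        for cj in range(3):
            if ci != cj:
                conflict |= (codes[ci].T @ codes[cj]) > 0
    n_comp, labels = connected_components(csr_matrix(~conflict), directed=False)
    missing_counts = np.sum(sub < 0, axis=0)
    bins = []
    for comp in range(n_comp):
        members = np.flatnonzero(labels == comp)
        rep = members[np.argmin(missing_counts[members])]
        bins.append({
            "representative": int(idx[rep]),
            "members": [int(idx[m]) for m in members],
        })
    bins.sort(key=lambda b: b["representative"])
    return bins


# ---------------------------------------------------------------------------
# Ordering

def order_objective(order, D: np.ndarray) -> int:
    """Total crossover events implied by an order: sum of adjacent recombinant counts."""
    o = np.asarray(order)
    return int(D[o[:-1], o[1:]].sum())


def _greedy_build(markers, D):
    order = list(markers[:2])
    for c in markers[2:]:
        best_cost, best_slot = None, 0
        for s in range(len(order) + 1):
            if s == 0:
                delta = D[c, order[0]]
            elif s == len(order):
                delta = D[order[-1], c]
            else:
                a, b = order[s - 1], order[s]
                delta = D[a, c] + D[c, b] - D[a, b]
            if best_cost is None or delta < best_cost:
                best_cost, best_slot = delta, s
        order.insert(best_slot, c)
    return order


def _ripple(order, D, window, max_passes):
    order = list(order)
    m = len(order)
    w = min(window, m)
    perms = list(itertools.permutations(range(w)))
    for _ in range(max_passes):
        improved = False
        for start in range(0, m - w + 1):
            seg = order[start:start + w]
            left = order[start - 1] if start > 0 else None
            right = order[start + w] if start + w < m else None

            def cost(arrangement):
                c = int(D[np.array(arrangement[:-1]), np.array(arrangement[1:])].sum())
                if left is not None:
                    c += D[left, arrangement[0]]
                if right is not None:
                    c += D[arrangement[-1], right]
                return c

            base = cost(seg)
            best, best_seg = base, seg
            for p in perms:
                cand = [seg[i] for i in p]
                c = cost(cand)
                if c < best:
                    best, best_seg = c, cand
            if best < base:
                order[start:start + w] = best_seg
                improved = True
        if not improved:
            break
    return order


def order_markers(markers: list[int], D: np.ndarray, window: int = 5,
                  max_passes: int = 50, marker_ids=None) -> list[int]:
    """Order markers by minimising the total crossover count.

    Greedy insertion builds an initial order; ripple passes exhaustively
    permute every sliding window of ``window`` loci, accepting strict
    improvements, until a full pass finds none.  Orientation is normalised
    so the first locus sorts before the last (by id when given, else index).
    """
    if len(markers) < 2:
        return list(markers)
    order = _greedy_build(list(markers), D)
    order = _ripple(order, D, window, max_passes)
    key = (lambda j: marker_ids[j]) if marker_ids is not None else (lambda j: j)
    if key(order[0]) > key(order[-1]):
        order.reverse()
    return order


def map_positions(order: list[int], N: np.ndarray, D: np.ndarray) -> np.ndarray:
    """Cumulative Kosambi cM along an ordered group from adjacent pairs."""
    cm = [0.0]
    for a, b in zip(order[:-1], order[1:]):
        n, k = N[a, b], D[a, b]
        if n == 0:
            step = 0.0
        else:
            r = ril_correct(min(k / n, 0.999))
            step = kosambi(r) if r < 0.5 else 0.0
        cm.append(cm[-1] + step)
    return np.asarray(cm)


# ---------------------------------------------------------------------------
# Placement of leftover markers

def _slot_lod(c, order, s, N, D):
    """Summed two-point LOD of candidate c with the loci flanking slot s."""
    neighbors = []
    if s > 0:
        neighbors.append(order[s - 1])
    if s < len(order):
        neighbors.append(order[s])
    return sum(_lod_from_counts(int(D[c, y]), int(N[c, y])) for y in neighbors)


def place_markers(leftovers: list[int], order: list[int], N: np.ndarray,
                  D: np.ndarray, lod_exclusion: float = 3.0):
    """Try to place leftover markers into an ordered frame.

    A marker co-segregating with a frame locus (zero recombinants over a
    positive informative count) is attached at that locus.  Otherwise every
    insertion slot is scored by the summed two-point LOD with its flanking
    loci; the marker is placed only when the best slot beats the second
    best by at least ``lod_exclusion`` (markers compatible with several
    positions stay unplaced, as forcing them would inflate the map).
    Returns (placements, unplaced): placements maps marker -> slot index.
    """
    placements, unplaced = {}, []
    for c in leftovers:
        co = [y for y in order if N[c, y] > 0 and D[c, y] == 0]
        if co:
            placements[c] = order.index(co[0])
            continue
        scores = sorted((_slot_lod(c, order, s, N, D)
                         for s in range(len(order) + 1)), reverse=True)
        if len(scores) >= 2 and scores[0] - scores[1] >= lod_exclusion:
            best_slot = int(np.argmax([_slot_lod(c, order, s, N, D)
                                       for s in range(len(order) + 1)]))
            placements[c] = best_slot
        else:
            unplaced.append(c)
    return placements, unplaced


# ---------------------------------------------------------------------------
# Segregation distortion and double crossovers

def segregation_chisq(genotypes: np.ndarray, marker_ids=None, alpha: float = 0.05,
                      bonferroni: bool = False):
    """Chi-square test of 1:1 segregation at every marker.

    Heterozygous and missing calls are excluded.  Returns a list of dicts
    (marker, n_a, n_b, chisq, p, distorted, favored).  The significance
    level is per-marker by default; ``bonferroni`` divides alpha by the
    marker count.
    """
    g = np.asarray(genotypes)
    n_a = np.sum(g == 0, axis=0)
    n_b = np.sum(g == 1, axis=0)
    n = n_a + n_b
    with np.errstate(invalid="ignore", divide="ignore"):
        chisq = np.where(n > 0, (n_a - n_b) ** 2 / np.maximum(n, 1), np.nan)
    p = stats.chi2.sf(chisq, df=1)
    level = alpha / g.shape[1] if bonferroni else alpha
    out = []
    for j in range(g.shape[1]):
        out.append({
            "marker": marker_ids[j] if marker_ids is not None else j,
            "n_a": int(n_a[j]),
            "n_b": int(n_b[j]),
            "chisq": float(chisq[j]) if n[j] > 0 else np.nan,
            "p": float(p[j]) if n[j] > 0 else np.nan,
            "distorted": bool(n[j] > 0 and p[j] < level),
            "favored": "A" if n_a[j] > n_b[j] else ("B" if n_b[j] > n_a[j] else "-"),
        })
    return out


def distortion_runs(reports: list[dict]) -> list[dict]:
    """Maximal runs of consecutive distorted markers sharing a favored parent."""
    runs, i, n = [], 0, len(reports)
    while i < n:
        if not reports[i]["distorted"]:
            i += 1
            continue
        fav, j = reports[i]["favored"], i
        while j + 1 < n and reports[j + 1]["distorted"] and reports[j + 1]["favored"] == fav:
            j += 1
        runs.append({"start": i, "end": j, "length": j - i + 1, "favored": fav})
        i = j + 1
    return runs


def double_co_scan(order: list[int], cm: np.ndarray, genotypes: np.ndarray,
                   window_cm: float = 25.0):
    """Flag apparent double crossovers along an ordered group.

    A (line, locus) pair is flagged when the locus's homozygous call
    differs from the shared call of both flanking loci and the flanking
    span is within ``window_cm``.  Lines missing or heterozygous at any of
    the three loci are skipped.  Returns (flags, n_markers_flagged).
    """
    flags = []
    g = genotypes
    for t in range(1, len(order) - 1):
        a, b, c = order[t - 1], order[t], order[t + 1]
        if cm[t + 1] - cm[t - 1] > window_cm:
            continue
        ga, gb, gc = g[:, a], g[:, b], g[:, c]
        ok = np.isin(ga, (0, 1)) & np.isin(gb, (0, 1)) & np.isin(gc, (0, 1))
        hit = ok & (ga == gc) & (gb != ga)
        for line in np.flatnonzero(hit):
            flags.append((int(line), b))
    return flags, len({locus for _, locus in flags})


# ---------------------------------------------------------------------------
# Whole-map construction

@dataclass
class LinkageGroup:
    group_id: int
    loci: list[int]              # ordered representative marker indices
    cm: np.ndarray               # cumulative Kosambi positions
    bins: dict                   # representative -> list of member indices
    placements: dict = field(default_factory=dict)
    unplaced: list = field(default_factory=list)

    @property
    def length_cm(self) -> float:
        return float(self.cm[-1]) if len(self.cm) else 0.0

    @property
    def n_markers(self) -> int:
        return sum(len(m) for m in self.bins.values())


@dataclass
class LinkageMap:
    groups: list[LinkageGroup]
    marker_ids: list[str]
    unassigned: list[int] = field(default_factory=list)

    @property
    def total_cm(self) -> float:
        return sum(g.length_cm for g in self.groups)

    @property
    def n_loci(self) -> int:
        return sum(len(g.loci) for g in self.groups)


def build_linkage_map(genotypes: np.ndarray, marker_ids=None, rf_cutoff: float = 0.2,
                      min_lod: float = 6.0, window: int = 5,
                      lod_exclusion: float = 3.0,
                      frame_informative_fraction: float = 170.0 / 188.0,
                      min_group_size: int = 2) -> LinkageMap:
    """Group, bin, order and place markers into a complete linkage map.

    Bins whose representative is genotyped in at least
    ``frame_informative_fraction`` of the lines form the ordering frame;
    the rest are placed afterwards under the LOD-exclusion rule.  When a
    group has fewer than two such bins the frame falls back to all bins.
    Groups smaller than ``min_group_size`` are reported as unassigned.
    """
    if marker_ids is None:
        marker_ids = [f"m{j}" for j in range(genotypes.shape[1])]
    N, D = pairwise_tables(genotypes)
    raw_groups = group_markers(genotypes, rf_cutoff, min_lod, tables=(N, D))
    n_lines = genotypes.shape[0]
    groups, unassigned = [], []
    gid = 0
    for markers in raw_groups:
        if len(markers) < min_group_size:
            unassigned.extend(markers)
            continue
        gid += 1
        bins = bin_haplotypes(markers, genotypes, marker_ids)
        reps = [b["representative"] for b in bins]
        presence = {j: np.sum(genotypes[:, j] >= 0) / n_lines for j in reps}
        frame = [j for j in reps if presence[j] >= frame_informative_fraction]
        # the informativeness pre-filter only helps when most markers are
        # near-complete; with uniform missingness it would starve the frame
        if len(frame) < max(2, len(reps) // 2):
            frame = reps
        order = order_markers(frame, D, window=window, marker_ids=marker_ids)
        leftovers = [j for j in reps if j not in frame]
        placements, unplaced = place_markers(leftovers, order, N, D, lod_exclusion)
        # inserted markers become loci at their slot, keeping the frame order
        full = list(order)
        for c, slot in sorted(placements.items(), key=lambda kv: -kv[1]):
            full.insert(slot, c)
        cm = map_positions(full, N, D)
        bin_map = {b["representative"]: b["members"] for b in bins}
        groups.append(LinkageGroup(gid, full, cm, bin_map, placements, unplaced))
    return LinkageMap(groups, list(marker_ids), unassigned)
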