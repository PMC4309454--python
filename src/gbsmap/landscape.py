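"""Recombination landscape: genetic vs physical map analysis.

Anchors an ordered linkage map to physical marker coordinates, computes
the piecewise first derivative of genetic against physical position
(dcM/dMb, the local recombination rate), demarcates the pericentromeric
region of each chromosome as the longest run of near-zero-rate segments
(< 1 cM/Mb by default), calls recombination hotspots as runs of
high-rate segments, and summarises each chromosome as recombinational
p-arm / pericentromere / q-arm with cM, Mb and average cM/Mb — the shape
of a published comparison table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AnchoredChromosome",
    "AnchoredMap",
    "RecProfile",
    "HotspotCall",
    "anchor_map",
    "coverage",
    "derivative_profile",
    "call_pcenr",
    "call_hotspots",
    "arm_summary",
    "summarize_arms_from_spans",
    "pericentromere_genome_percent",
]

RATE_CAP = 1e6   # cM/Mb assigned to zero-Mb spans with nonzero cM


@dataclass
class AnchoredChromosome:
    chromosome: str
    loci: list[str]              # retained loci in map order (after orientation)
    cm: np.ndarray
    mb: np.ndarray
    flipped: bool
    discrepancies: list = field(default_factory=list)   # (locus, reason)


@dataclass
class AnchoredMap:
    chromosomes: list[AnchoredChromosome]

    def __getitem__(self, name: str) -> AnchoredChromosome:
        for c in self.chromosomes:
            if c.chromosome == name:
                return c
        raise KeyError(name)


def _monotone_filter(mb: np.ndarray, tol_mb: float):
    """Indices of the longest non-decreasing subsequence; others checked
    against the local trend and flagged when off by more than tol_mb."""
    n = len(mb)
    best_len = np.ones(n, dtype=int)
    prev = np.full(n, -1)
    for i in range(n):
        for j in range(i):
            if mb[j] <= mb[i] and best_len[j] + 1 > best_len[i]:
                best_len[i] = best_len[j] + 1
                prev[i] = j
    end = int(np.argmax(best_len))
    keep = []
    while end >= 0:
        keep.append(end)
        end = prev[end]
    keep = sorted(keep)
    keep_set = set(keep)
    outliers = []
    for i in range(n):
        if i in keep_set:
            continue
        lo = max((k for k in keep if k < i), default=None)
        hi = min((k for k in keep if k > i), default=None)
        anchors = [mb[k] for k in (lo, hi) if k is not None]
        trend = float(np.interp(i, [k for k in (lo, hi) if k is not None], anchors))
        if abs(mb[i] - trend) > tol_mb:
            outliers.append(i)
        else:
            keep_set.add(i)
    return sorted(keep_set), outliers


def anchor_map(map_table: pd.DataFrame, positions: pd.DataFrame,
               trend_tolerance_mb: float = 5.0) -> AnchoredMap:
    """Join a linkage map to physical marker positions.

    ``map_table`` needs columns group, locus, cm; ``positions`` needs
    marker, chromosome, position_bp (1-based).  Each group is assigned the
    chromosome holding the majority of its anchored loci; loci on another
    chromosome are flagged wrong-chromosome, loci breaking the monotone
    cM-vs-bp trend by more than ``trend_tolerance_mb`` are flagged
    out-of-trend; both are excluded from downstream profiles.  Orientation
    is flipped when cM runs against bp (Spearman correlation negative).
    """
    pos = positions.set_index("marker")
    out = []
    for gid, sub in map_table.groupby("group", sort=True):
        sub = sub.sort_values("cm", kind="stable")
        anchored = sub[sub["locus"].isin(pos.index)]
        if len(anchored) < 2:
            raise ValueError(f"group {gid!r} has fewer than 2 anchored loci")
        chroms = pos.loc[anchored["locus"], "chromosome"]
        majority = chroms.value_counts().idxmax()
        discrepancies = [(locus, "wrong-chromosome")
                         for locus, c in zip(anchored["locus"], chroms) if c != majority]
        same = anchored[np.asarray(chroms == majority)]
        cm = same["cm"].to_numpy(dtype=float)
        mb = (pos.loc[same["locus"], "position_bp"].to_numpy(dtype=float) - 1.0) / 1e6
        loci = list(same["locus"])

        rho = stats.spearmanr(cm, mb).statistic if len(cm) > 2 else np.corrcoef(cm, mb)[0, 1]
        flipped = bool(rho < 0)
        if flipped:
            cm = cm[::-1].copy()
            mb = mb[::-1].copy()
            loci = loci[::-1]
            cm = cm.max() - cm if len(cm) else cm
            # re-sort ascending in cM after reflection
            order = np.argsort(cm, kind="stable")
            cm, mb = cm[order], mb[order]
            loci = [loci[i] for i in order]

        keep, outliers = _monotone_filter(mb, trend_tolerance_mb)
        discrepancies += [(loci[i], "out-of-trend") for i in outliers]
        cm = cm[keep]
        mb = mb[keep]
        loci = [loci[i] for i in keep]
        out.append(AnchoredChromosome(str(majority), loci, cm, mb, flipped, discrepancies))
    return AnchoredMap(out)


def coverage(anchored: AnchoredMap, chrom_lengths_mb: dict[str, float]):
    """Physical span of retained loci as a percentage of chromosome length.

    Returns (per-chromosome dict, genome-wide percent).  Chromosomes with a
    single retained locus contribute zero span.
    """
    per, total_span, total_len = {}, 0.0, 0.0
    for c in anchored.chromosomes:
        L = float(chrom_lengths_mb[c.chromosome])
        span = float(c.mb.max() - c.mb.min()) if len(c.mb) >= 2 else 0.0
        per[c.chromosome] = 100.0 * span / L
        total_span += span
        total_len += L
    return per, 100.0 * total_span / total_len if total_len else np.nan


@dataclass
class RecProfile:
    chromosome: str
    start_mb: np.ndarray
    end_mb: np.ndarray
    rate: np.ndarray            # cM/Mb
    capped: np.ndarray          # True where a zero-Mb span was capped

    @property
    def genetic_span_cm(self) -> float:
        return float(np.sum(self.rate[~self.capped] * (self.end_mb - self.start_mb)[~self.capped]))


def derivative_profile(chrom: AnchoredChromosome, smooth: int = 0) -> RecProfile:
    """Piecewise recombination rate between consecutive distinct loci.

    rate_i = (cM_{i+1} - cM_i) / (Mb_{i+1} - Mb_i).  Coincident physical
    positions with differing cM get a capped, flagged rate.  ``smooth``
    (odd, >= 3) applies a running-median filter over that many segments;
    off by default.
    """
    if len(chrom.cm) < 2:
        raise ValueError("need at least 2 retained loci for a profile")
    cm, mb = chrom.cm, chrom.mb
    keep = np.concatenate([[True], (np.diff(mb) != 0) | (np.diff(cm) != 0)])
    cm, mb = cm[keep], mb[keep]
    dcm = np.diff(cm)
    dmb = np.diff(mb)
    capped = dmb <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        rate = np.where(capped, np.where(dcm > 0, RATE_CAP, 0.0), dcm / np.where(dmb > 0, dmb, 1.0))
    rate = np.maximum(rate, 0.0)
    if smooth and smooth >= 3:
        from scipy.signal import medfilt
        rate = medfilt(rate, kernel_size=smooth if smooth % 2 else smooth + 1)
    return RecProfile(chrom.chromosome, mb[:-1], mb[1:], rate, capped)


def call_pcenr(profile: RecProfile, rate_threshold: float = 1.0,
               min_span_mb: float = 3.0, merge_gap_mb: float = 2.0):
    """Demarcate the pericentromeric region from a rate profile.

    Candidate regions are maximal runs of consecutive segments with rate
    below the threshold; two runs separated by a single above-threshold
    segment narrower than ``merge_gap_mb`` are merged.  The longest merged
    run spanning at least ``min_span_mb`` is returned as (start_mb, end_mb);
    None when no run qualifies (a one-armed, telocentric-looking profile).
    """
    below = profile.rate < rate_threshold
    runs = []
    i = 0
    while i < len(below):
        if below[i]:
            j = i
            while j + 1 < len(below) and below[j + 1]:
                j += 1
            runs.append([i, j])
            i = j + 1
        else:
            i += 1
    # merge across single narrow above-threshold separators
    merged = []
    for run in runs:
        if merged:
            prev = merged[-1]
            sep_first, sep_last = prev[1] + 1, run[0] - 1
            if sep_first == sep_last:
                sep_w = profile.end_mb[sep_first] - profile.start_mb[sep_first]
                if sep_w < merge_gap_mb:
                    prev[1] = run[1]
                    continue
        merged.append(run)
    best = None
    for i0, i1 in merged:
        span = profile.end_mb[i1] - profile.start_mb[i0]
        if span >= min_span_mb and (best is None or span > best[2]):
            best = (float(profile.start_mb[i0]), float(profile.end_mb[i1]), float(span))
    return (best[0], best[1]) if best else None


@dataclass(frozen=True)
class HotspotCall:
    chromosome: str
    start_mb: float
    end_mb: float
    peak_rate: float
    flank_left: str
    flank_right: str


def call_hotspots(profile: RecProfile, hotspot_threshold: float = 10.0,
                  loci=None) -> list[HotspotCall]:
    """Maximal runs of segments at or above the hotspot rate threshold.

    Calls are sorted by peak rate, descending.  ``loci`` (the retained
    locus names in order) labels the flanking markers when provided.
    """
    hot = (profile.rate >= hotspot_threshold) & ~profile.capped
    calls = []
    i = 0
    while i < len(hot):
        if hot[i]:
            j = i
            while j + 1 < len(hot) and hot[j + 1]:
                j += 1
            peak = float(profile.rate[i:j + 1].max())
            left = loci[i] if loci is not None else ""
            right = loci[j + 1] if loci is not None else ""
            calls.append(HotspotCall(profile.chromosome, float(profile.start_mb[i]),
                                     float(profile.end_mb[j]), peak, left, right))
            i = j + 1
        else:
            i += 1
    calls.sort(key=lambda h: -h.peak_rate)
    return calls


def summarize_arms_from_spans(spans: pd.DataFrame, decimals: int = 1) -> pd.DataFrame:
    """Derived arm-summary cells from cM/Mb spans.

    ``spans`` has one row per chromosome with columns: chromosome,
    total_cm, total_mb, p_cm, p_mb, peri_cm, peri_mb, q_cm, q_mb (any may
    be NaN).  Adds avg cM/Mb per region and the pericentromere's percent
    of the chromosome, rounded to ``decimals``.
    """
    out = spans.copy()

    def ratio(a, b):
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where((b > 0) & np.isfinite(a), a / b, np.nan)

    out["p_rate"] = np.round(ratio(out["p_cm"], out["p_mb"]), decimals)
    out["peri_rate"] = np.round(ratio(out["peri_cm"], out["peri_mb"]), decimals)
    out["q_rate"] = np.round(ratio(out["q_cm"], out["q_mb"]), decimals)
    out["peri_pct"] = np.round(100.0 * ratio(out["peri_mb"], out["total_mb"]), decimals)
    return out


def pericentromere_genome_percent(spans: pd.DataFrame) -> float:
    """Pericentromeric Mb as a percent of total Mb, over chromosomes with a call."""
    has = spans["peri_mb"].notna()
    return float(100.0 * spans.loc[has, "peri_mb"].sum() / spans.loc[has, "total_mb"].sum())


def arm_summary(anchored: AnchoredMap, pcenr_calls: dict[str, tuple | None],
                chrom_lengths_mb: dict[str, float], min_arm_span_mb: float = 1.0,
                decimals: int = 1) -> pd.DataFrame:
    """Per-chromosome p-arm / pericentromere / q-arm decomposition.

    Arm spans are measured between retained loci: the p-arm runs from the
    first locus to the pericentromere start, the q-arm from its end to the
    last locus.  Chromosomes without a pericentromere call get an NA row;
    arms narrower than ``min_arm_span_mb`` are reported NA and flagged.
    """
    rows = []
    for c in anchored.chromosomes:
        peri = pcenr_calls.get(c.chromosome)
        total_cm = float(c.cm[-1] - c.cm[0])
        total_mb = float(chrom_lengths_mb[c.chromosome])
        row = {"chromosome": c.chromosome, "total_cm": round(total_cm, decimals),
               "total_mb": total_mb,
               "p_cm": np.nan, "p_mb": np.nan, "peri_cm": np.nan, "peri_mb": np.nan,
               "q_cm": np.nan, "q_mb": np.nan, "flag": ""}
        if peri is not None:
            lo, hi = peri
            cm_lo = float(np.interp(lo, c.mb, c.cm))
            cm_hi = float(np.interp(hi, c.mb, c.cm))
            p_mb = lo - float(c.mb[0])
            q_mb = float(c.mb[-1]) - hi
            row.update(peri_cm=round(cm_hi - cm_lo, decimals), peri_mb=round(hi - lo, decimals))
            if p_mb >= min_arm_span_mb:
                row.update(p_cm=round(cm_lo - float(c.cm[0]), decimals), p_mb=round(p_mb, decimals))
            else:
                row["p_mb"] = round(p_mb, decimals)
                row["flag"] = "p-arm-below-min-span"
            if q_mb >= min_arm_span_mb:
                row.update(q_cm=round(float(c.cm[-1]) - cm_hi, decimals), q_mb=round(q_mb, decimals))
            else:
                row["q_mb"] = round(q_mb, decimals)
                row["flag"] = (row["flag"] + ";" if row["flag"] else "") + "q-arm-below-min-span"
        rows.append(row)
    spans = pd.DataFrame(rows)
    return summarize_arms_from_spans(spans, decimals=decimals)
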