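"""Synthetic genome models: recombination-rate tracks, chromosomes, marker panels.

A genome here is a set of chromosomes, each carrying a piecewise-constant
recombination-rate profile (cM/Mb).  The profile is both the simulator's
ground truth for crossover placement and the quantity the landscape module
tries to recover from mapped data.  The default preset mimics a common-bean
style genome: 11 chromosomes of 32-60 Mb, a recombinationally suppressed
pericentromeric block covering the middle ~45% of each chromosome
(~0.25 cM/Mb), freely recombining arms (~3 cM/Mb), and a handful of narrow
hotspots per arm with rates up to ~34 cM/Mb.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RateTrack",
    "ChromosomeModel",
    "GenomeModel",
    "MarkerPanel",
    "build_genome",
    "build_marker_panel",
    "bean_preset",
    "small_preset",
]


class ConfigError(ValueError):
    """Invalid landscape / simulation configuration."""


@dataclass(frozen=True)
class RateTrack:
    """Piecewise-constant recombination rate (cM/Mb) along one chromosome.

    Bins are contiguous, non-overlapping and cover [0, length) Mb.
    """

    starts: np.ndarray   # Mb
    ends: np.ndarray     # Mb
    rates: np.ndarray    # cM/Mb

    def __post_init__(self):
        starts = np.asarray(self.starts, dtype=float)
        ends = np.asarray(self.ends, dtype=float)
        rates = np.asarray(self.rates, dtype=float)
        object.__setattr__(self, "starts", starts)
        object.__setattr__(self, "ends", ends)
        object.__setattr__(self, "rates", rates)
        if len(starts) == 0:
            raise ConfigError("empty rate track")
        if np.any(rates < 0):
            raise ConfigError("negative recombination rate")
        if starts[0] != 0.0 or np.any(ends <= starts):
            raise ConfigError("malformed track bins")
        if np.any(starts[1:] != ends[:-1]):
            raise ConfigError("track bins must be contiguous")

    @property
    def length_mb(self) -> float:
        return float(self.ends[-1])

    @property
    def genetic_length_cm(self) -> float:
        """Integral of rate over the chromosome: Sum(rate * width) in cM."""
        return float(np.sum(self.rates * (self.ends - self.starts)))

    def cumulative_cm(self, pos_mb) -> np.ndarray:
        """Genetic position (cM) of physical position(s) pos_mb."""
        pos = np.atleast_1d(np.asarray(pos_mb, dtype=float))
        cum = np.concatenate([[0.0], np.cumsum(self.rates * (self.ends - self.starts))])
        idx = np.clip(np.searchsorted(self.ends, pos, side="right"), 0, len(self.rates) - 1)
        return cum[idx] + self.rates[idx] * (pos - self.starts[idx])

    def inverse_cumulative_cm(self, cm) -> np.ndarray:
        """Physical position (Mb) at genetic position(s) cm; inverse of cumulative_cm."""
        cm = np.atleast_1d(np.asarray(cm, dtype=float))
        cum = np.concatenate([[0.0], np.cumsum(self.rates * (self.ends - self.starts))])
        idx = np.clip(np.searchsorted(cum[1:], cm, side="right"), 0, len(self.rates) - 1)
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(self.rates[idx] > 0, (cm - cum[idx]) / self.rates[idx], 0.0)
        return self.starts[idx] + frac


def _build_track(length_mb, base_rate, pericentromere, peri_rate, hotspots) -> RateTrack:
    """Overlay pericentromere and hotspot intervals on a constant baseline."""
    edges = {0.0, float(length_mb)}
    if pericentromere is not None:
        lo, hi = map(float, pericentromere)
        if not (0.0 <= lo < hi <= length_mb):
            raise ConfigError("pericentromere interval not nested in chromosome")
        edges.update((lo, hi))
    spans = []
    for center, width, peak in hotspots:
        lo = float(center) - float(width) / 2.0
        hi = float(center) + float(width) / 2.0
        if not (0.0 <= lo and hi <= length_mb):
            raise ConfigError("hotspot outside chromosome")
        if peak < base_rate:
            raise ConfigError("hotspot rate below baseline")
        edges.update((lo, hi))
        spans.append((lo, hi, float(peak)))
    cuts = np.array(sorted(edges))
    starts, ends = cuts[:-1], cuts[1:]
    rates = np.full(len(starts), float(base_rate))
    if pericentromere is not None:
        lo, hi = map(float, pericentromere)
        rates[(starts >= lo) & (ends <= hi)] = float(peri_rate)
    for lo, hi, peak in spans:
        rates[(starts >= lo) & (ends <= hi)] = peak
    return RateTrack(starts, ends, rates)


@dataclass(frozen=True)
class ChromosomeModel:
    name: str
    length_mb: float
    track: RateTrack
    pericentromere: tuple[float, float] | None = None   # (start, end) Mb
    hotspots: tuple = ()                                # (center, width, peak) Mb/cM-per-Mb

    @property
    def genetic_length_cm(self) -> float:
        return self.track.genetic_length_cm


@dataclass(frozen=True)
class GenomeModel:
    chromosomes: tuple[ChromosomeModel, ...]

    def __getitem__(self, name: str) -> ChromosomeModel:
        for c in self.chromosomes:
            if c.name == name:
                return c
        raise KeyError(name)

    @property
    def total_mb(self) -> float:
        return sum(c.length_mb for c in self.chromosomes)

    @property
    def pericentromeric_fraction(self) -> float:
        """Fraction of physical genome inside pericentromeric intervals."""
        peri = sum(c.pericentromere[1] - c.pericentromere[0]
                   for c in self.chromosomes if c.pericentromere is not None)
        return peri / self.total_mb

    @property
    def peak_hotspot_rate(self) -> float:
        peaks = [h[2] for c in self.chromosomes for h in c.hotspots]
        return max(peaks) if peaks else 0.0


@dataclass(frozen=True)
class MarkerPanel:
    """Codominant SNP markers at known physical positions.

    positions are 1-based bp; within a chromosome they are strictly
    increasing.  allele_a / allele_b are the two parental bases.
    """

    ids: tuple[str, ...]
    chromosomes: tuple[str, ...]
    positions_bp: tuple[int, ...]
    alleles_a: tuple[str, ...]
    alleles_b: tuple[str, ...]

    def __post_init__(self):
        by_chrom: dict[str, int] = {}
        for chrom, pos, a, b in zip(self.chromosomes, self.positions_bp,
                                    self.alleles_a, self.alleles_b):
            if a == b:
                raise ConfigError("marker alleles must differ")
            if chrom in by_chrom and pos <= by_chrom[chrom]:
                raise ConfigError("marker positions must be strictly increasing")
            by_chrom[chrom] = pos

    def __len__(self) -> int:
        return len(self.ids)

    def on_chromosome(self, name: str) -> np.ndarray:
        """Indices of markers on the given chromosome, in position order."""
        return np.flatnonzero(np.asarray(self.chromosomes) == name)

    def positions_mb(self) -> np.ndarray:
        return (np.asarray(self.positions_bp, dtype=float) - 1.0) / 1e6


# ---------------------------------------------------------------------------
# Presets

# Chromosome physical lengths (Mb) of a bean-like 11-chromosome genome.
_BEAN_MB = (52.2, 49.9, 52.3, 45.9, 40.8, 31.9, 51.7, 59.6, 37.4, 43.2, 51.5)

# Hotspot templates per chromosome: (arm fraction along chromosome, width Mb, peak cM/Mb).
# One dominant peak (34 cM/Mb) on Pv02's p-arm; medium peaks elsewhere.
_BEAN_HOTSPOTS = {
    1: ((0.08, 0.8, 12.0), (0.90, 0.8, 16.0)),
    2: ((0.05, 0.5, 34.0), (0.14, 0.8, 12.0), (0.82, 0.8, 14.0), (0.93, 0.8, 10.0)),
    3: ((0.88, 1.0, 15.0),),
    4: ((0.10, 0.9, 18.0), (0.88, 0.7, 9.0)),
    5: ((0.09, 0.8, 13.0), (0.91, 0.8, 11.0)),
    6: ((0.86, 1.0, 15.0),),
    7: ((0.07, 0.8, 11.0), (0.92, 0.8, 13.0)),
    8: ((0.06, 0.9, 14.0), (0.90, 0.9, 16.0)),
    9: ((0.12, 1.0, 15.0),),
    10: ((0.08, 0.8, 12.0), (0.91, 0.8, 14.0)),
    11: ((0.09, 0.8, 13.0), (0.90, 0.8, 12.0)),
}


def bean_preset(peri_fraction: float = 0.45, base_rate: float = 3.0,
                peri_rate: float = 0.25) -> dict:
    """Configuration dict for the default bean-like 11-chromosome genome."""
    chroms = []
    for i, mb in enumerate(_BEAN_MB, start=1):
        half = peri_fraction / 2.0
        peri = (round(mb * (0.5 - half), 3), round(mb * (0.5 + half), 3))
        hs = [(round(f * mb, 3), w, p) for f, w, p in _BEAN_HOTSPOTS[i]]
        chroms.append({
            "name": f"Pv{i:02d}",
            "length_mb": mb,
            "base_rate": base_rate,
            "pericentromere": peri,
            "peri_rate": peri_rate,
            "hotspots": hs,
        })
    return {"chromosomes": chroms}


def small_preset() -> dict:
    """A 3-chromosome miniature of the bean preset, for quick end-to-end runs."""
    cfg = bean_preset()
    small = cfg["chromosomes"][:3]
    for c in small:
        c["length_mb"] = round(c["length_mb"] / 3.0, 3)
        c["pericentromere"] = tuple(round(x / 3.0, 3) for x in c["pericentromere"])
        c["hotspots"] = [(round(c0 / 3.0, 3), min(w, c["length_mb"] / 20.0), p)
                         for c0, w, p in c["hotspots"]]
    return {"chromosomes": small}


def build_genome(config: dict, seed: int | None = None) -> GenomeModel:
    """Build a GenomeModel from a landscape configuration.

    The configuration holds one entry per chromosome with keys
    ``name, length_mb, base_rate, pericentromere, peri_rate, hotspots``.
    ``seed`` is accepted for interface symmetry; the preset genomes are
    deterministic.
    """
    chroms = []
    for c in config["chromosomes"]:
        length = float(c["length_mb"])
        if length <= 0:
            raise ConfigError("chromosome length must be positive")
        peri = c.get("pericentromere")
        peri = tuple(map(float, peri)) if peri is not None else None
        hotspots = tuple((float(a), float(b), float(p)) for a, b, p in c.get("hotspots", ()))
        track = _build_track(length, float(c.get("base_rate", 3.0)), peri,
                             float(c.get("peri_rate", 0.25)), hotspots)
        chroms.append(ChromosomeModel(str(c["name"]), length, track, peri, hotspots))
    return GenomeModel(tuple(chroms))


def _density_track(chrom: ChromosomeModel, outside: float, hotspot: float):
    """Piecewise marker-density multipliers: 1 inside the pericentromere,
    ``outside`` on the arms, ``outside * hotspot`` within hotspot spans."""
    cuts = {0.0, chrom.length_mb}
    if chrom.pericentromere is not None:
        cuts.update(chrom.pericentromere)
    spans = []
    for center, width, _ in chrom.hotspots:
        lo, hi = center - width / 2.0, center + width / 2.0
        cuts.update((lo, hi))
        spans.append((lo, hi))
    edges = np.array(sorted(cuts))
    dens = np.full(len(edges) - 1, outside)
    if chrom.pericentromere is not None:
        lo, hi = chrom.pericentromere
        dens[(edges[:-1] >= lo) & (edges[1:] <= hi)] = 1.0
    for lo, hi in spans:
        dens[(edges[:-1] >= lo) & (edges[1:] <= hi)] = outside * hotspot
    return edges, dens


def build_marker_panel(genome: GenomeModel, n_markers: int = 520,
                       outside_density_multiple: float = 5.0,
                       hotspot_density_multiple: float = 3.0,
                       seed: int | None = None,
                       min_spacing_bp: int = 100_000,
                       markers_per_hotspot: int = 3) -> MarkerPanel:
    """Place SNP markers on a genome with restriction-site-like arm bias.

    Marker density outside the pericentromere is ``outside_density_multiple``
    times the density inside, emulating the bias of a methylation-sensitive
    restriction enzyme toward gene-rich chromosome arms; hotspot spans, which
    coincide with gene-rich sequence, get a further
    ``hotspot_density_multiple`` on top of the arm density.  Positions are
    drawn from the resulting piecewise density; parental alleles are drawn
    uniformly from distinct bases.

    ``min_spacing_bp`` floors the spacing between tags, and every hotspot
    span is guaranteed ``markers_per_hotspot`` markers (edges and midpoint
    are added when sampling leaves fewer) so each simulated hotspot is
    delimited by mapped loci, as the gene-rich sequence context of real
    hotspots makes likely.
    """
    if n_markers <= 0:
        raise ConfigError("n_markers must be positive")
    rng = np.random.default_rng(seed)
    # Per-chromosome expected marker mass proportional to integral of density.
    tracks = [_density_track(c, outside_density_multiple, hotspot_density_multiple)
              for c in genome.chromosomes]
    masses = np.array([float(np.sum(d * np.diff(e))) for e, d in tracks])
    counts = rng.multinomial(n_markers, masses / masses.sum())
    bases = np.array(list("ACGT"))
    ids, chrom_col, pos_col, aa, ab = [], [], [], [], []
    for c, (edges, dens), k in zip(genome.chromosomes, tracks, counts):
        if k == 0:
            continue
        w = dens * np.diff(edges)
        cum = np.concatenate([[0.0], np.cumsum(w)])
        u = rng.uniform(0.0, cum[-1], size=k)
        idx = np.clip(np.searchsorted(cum[1:], u, side="right"), 0, len(dens) - 1)
        mb = edges[idx] + (u - cum[idx]) / dens[idx]
        # guarantee markers delimiting every hotspot span
        for center, width, _ in c.hotspots:
            lo, hi = center - width / 2.0, center + width / 2.0
            inside = np.sort(mb[(mb >= lo) & (mb <= hi)])
            want = [lo + 1e-3, (lo + hi) / 2.0, hi - 1e-3][:max(markers_per_hotspot, 0)]
            need = max(markers_per_hotspot - len(inside), 0)
            if need:
                pad = sorted(want, key=lambda p: -min([abs(p - x) for x in inside],
                                                      default=np.inf))[:need]
                mb = np.concatenate([mb, pad])
        bp = np.unique(np.round(mb * 1e6).astype(np.int64) + 1)
        # enforce minimal spacing between tags
        keep = [0]
        for j in range(1, len(bp)):
            if bp[j] - bp[keep[-1]] >= min_spacing_bp:
                keep.append(j)
        bp = bp[keep]
        for j, p in enumerate(bp):
            pair = rng.choice(4, size=2, replace=False)
            ids.append(f"{c.name}_m{j + 1:04d}")
            chrom_col.append(c.name)
            pos_col.append(int(p))
            aa.append(bases[pair[0]])
            ab.append(bases[pair[1]])
    return MarkerPanel(tuple(ids), tuple(chrom_col), tuple(pos_col), tuple(aa), tuple(ab))
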