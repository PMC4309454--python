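"""Forward simulation of selfed RIL families and GBS-like read data.

The simulator produces the study design the downstream analysis assumes:
an F1 between two fully homozygous parents is propagated by single seed
descent for a configurable number of selfing generations (default F11),
crossovers per meiosis follow a Poisson process whose intensity along each
chromosome is the genome's recombination-rate track (no interference), and
sequencing is emulated as fixed-length restriction-site tags with inline
barcodes, over-dispersed per-site depth, dropout, and uniform base error.

Genotype codes throughout: 0 = parent-A homozygote, 1 = parent-B homozygote,
2 = heterozygote, -1 = missing.  Text form: A / B / H / -.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genome import ChromosomeModel, ConfigError, GenomeModel, MarkerPanel, RateTrack

__all__ = [
    "RILPopulation",
    "DepthModel",
    "SimulatedReads",
    "sample_crossovers",
    "sample_gamete",
    "simulate_rils",
    "simulate_reads",
    "make_barcodes",
    "CODE_TO_CHAR",
    "CHAR_TO_CODE",
]

CODE_TO_CHAR = {0: "A", 1: "B", 2: "H", -1: "-"}
CHAR_TO_CODE = {v: k for k, v in CODE_TO_CHAR.items()}

PARENT_A = "ParentA"
PARENT_B = "ParentB"


@dataclass
class RILPopulation:
    """Genotypes of n RILs at m markers, plus provenance."""

    generation: int
    line_names: list[str]
    marker_ids: list[str]
    genotypes: np.ndarray          # (n_lines, n_markers) int8

    @property
    def n_lines(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_markers(self) -> int:
        return self.genotypes.shape[1]

    def het_fraction(self) -> float:
        called = self.genotypes >= 0
        return float(np.sum(self.genotypes == 2) / max(np.sum(called), 1))

    def missing_fraction(self) -> float:
        return float(np.mean(self.genotypes < 0))


def sample_crossovers(track: RateTrack, rng: np.random.Generator) -> np.ndarray:
    """Crossover positions (Mb) of one meiosis on one chromosome.

    The count is Poisson with mean equal to the genetic length in Morgans;
    positions are i.i.d. draws from the normalised rate density.
    """
    total_cm = track.genetic_length_cm
    if total_cm <= 0:
        return np.empty(0)
    k = rng.poisson(total_cm / 100.0)
    if k == 0:
        return np.empty(0)
    u = rng.uniform(0.0, total_cm, size=k)
    return np.sort(track.inverse_cumulative_cm(u))


def sample_gamete(track: RateTrack, hap1: np.ndarray, hap2: np.ndarray,
                  marker_mb: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One recombined gamete, evaluated at the marker positions.

    hap1/hap2 are the parental-origin vectors of the two homologs at
    ``marker_mb``.  The gamete follows one homolog and switches to the other
    at each crossover; the starting homolog is chosen at random.
    """
    xo = sample_crossovers(track, rng)
    start = rng.integers(2)
    if xo.size == 0:
        return (hap1 if start == 0 else hap2).copy()
    parity = (np.searchsorted(xo, marker_mb, side="right") + start) % 2
    return np.where(parity == 0, hap1, hap2)


def _parse_distortion(distortion_loci, marker_ids):
    """Map marker id -> (favored allele code, viability weight)."""
    table = {}
    if not distortion_loci:
        return table
    index = {mid: j for j, mid in enumerate(marker_ids)}
    for mid, (favored, weight) in distortion_loci.items():
        if mid not in index:
            raise ConfigError(f"unknown distortion locus {mid!r}")
        if not (0.0 < weight <= 1.0):
            raise ConfigError("distortion weight must be in (0, 1]")
        code = CHAR_TO_CODE[favored] if isinstance(favored, str) else int(favored)
        if code not in (0, 1):
            raise ConfigError("favored allele must be A or B")
        table[index[mid]] = (code, float(weight))
    return table


def simulate_rils(genome: GenomeModel, panel: MarkerPanel, n_lines: int = 188,
                  generations: int = 11, distortion_loci: dict | None = None,
                  seed: int | None = None, missing_rate: float = 0.0) -> RILPopulation:
    """Simulate an F_g RIL family by single seed descent.

    Each line descends from a uniform F1 through ``generations - 1`` rounds
    of self-fertilisation, one offspring kept per round.  Transmission-ratio
    distortion, if requested, acts as a gametic viability weight: a gamete
    carrying the disfavored allele at a named locus survives with the given
    probability, applied independently each generation.  ``missing_rate``
    masks genotype calls at random, a shorthand for read-level dropout when
    the sequencing layer is not being exercised.
    """
    if generations < 2:
        raise ConfigError("generations must be >= 2")
    if not (0.0 <= missing_rate < 1.0):
        raise ConfigError("missing_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    distortion = _parse_distortion(distortion_loci, panel.ids)

    mb_all = panel.positions_mb()
    chrom_idx = {c.name: panel.on_chromosome(c.name) for c in genome.chromosomes}
    genotypes = np.empty((n_lines, len(panel)), dtype=np.int8)

    for c in genome.chromosomes:
        idx = chrom_idx[c.name]
        if idx.size == 0:
            continue
        mb = mb_all[idx]
        local_distortion = {int(np.searchsorted(idx, j)): fw
                            for j, fw in distortion.items() if j in set(idx)}

        for line in range(n_lines):
            h1 = np.zeros(idx.size, dtype=np.int8)
            h2 = np.ones(idx.size, dtype=np.int8)
            for _ in range(generations - 1):
                g1 = _viable_gamete(c.track, h1, h2, mb, rng, local_distortion)
                g2 = _viable_gamete(c.track, h1, h2, mb, rng, local_distortion)
                h1, h2 = g1, g2
            geno = h1 + h2            # 0=AA, 2=BB, 1=het
            genotypes[line, idx] = np.where(geno == 1, 2, np.where(geno == 2, 1, 0))

    if missing_rate > 0:
        mask = rng.random(genotypes.shape) < missing_rate
        genotypes[mask] = -1

    names = [f"RIL{i + 1:03d}" for i in range(n_lines)]
    return RILPopulation(generations, names, list(panel.ids), genotypes)


def _viable_gamete(track, h1, h2, mb, rng, distortion, max_tries=1000):
    for _ in range(max_tries):
        g = sample_gamete(track, h1, h2, mb, rng)
        ok = True
        for j, (favored, weight) in distortion.items():
            if g[j] != favored and rng.random() > weight:
                ok = False
                break
        if ok:
            return g
    return g  # pragma: no cover - pathological weights


# ---------------------------------------------------------------------------
# Read simulation

@dataclass(frozen=True)
class DepthModel:
    """Per-(line, site) read-depth distribution.

    ``fixed`` makes depth a constant equal to ``mean``.  Otherwise depth is
    zero with probability ``dropout`` (library dropout of a tag) and, when
    retained, negative-binomial with the given mean and dispersion (Poisson
    when ``dispersion`` is None).  GBS missingness is dominated by the
    dropout mass; the over-dispersion mimics uneven amplification.
    """

    mean: float = 8.0
    dispersion: float | None = 2.0
    dropout: float = 0.2
    fixed: bool = False

    def sample(self, rng: np.random.Generator, size) -> np.ndarray:
        if self.fixed:
            return np.full(size, int(round(self.mean)), dtype=np.int64)
        if self.dispersion is None:
            depth = rng.poisson(self.mean, size=size)
        else:
            r = self.dispersion
            p = r / (r + self.mean)
            depth = rng.negative_binomial(r, p, size=size)
        if self.dropout > 0:
            depth = np.where(rng.random(size) < self.dropout, 0, depth)
        return depth

    def zero_probability(self) -> float:
        """Probability of zero reads at a site (dropout plus count mass at 0)."""
        if self.fixed:
            return 0.0 if round(self.mean) > 0 else 1.0
        if self.dispersion is None:
            p0 = np.exp(-self.mean)
        else:
            r = self.dispersion
            p0 = (r / (r + self.mean)) ** r
        return self.dropout + (1.0 - self.dropout) * p0


@dataclass
class SimulatedReads:
    """GBS tag reads plus the exact per-site base tally that produced them."""

    reads: list                      # (read id, sequence, quality string)
    entities: list[str]              # parents (if present) then RIL lines
    counts: np.ndarray               # (n_entities, n_markers, 4) tallies of emitted bases
    tags: list[str]                  # per-marker 101-base tag (parent-A allele at snp_offset)
    snp_offset: int
    barcodes: dict[str, str]

    @property
    def n_reads(self) -> int:
        return len(self.reads)


_BASES = np.array(list("ACGT"))
_BASE_INDEX = {b: i for i, b in enumerate("ACGT")}


def make_barcodes(names, length: int = 6, seed: int | None = None) -> dict[str, str]:
    """Unique fixed-length (hence prefix-free) barcodes for each name."""
    rng = np.random.default_rng(seed)
    seen, out = set(), {}
    for name in names:
        while True:
            bc = "".join(rng.choice(_BASES, size=length))
            if bc not in seen:
                seen.add(bc)
                out[name] = bc
                break
    return out


def _make_tags(panel: MarkerPanel, tag_length: int, snp_offset: int,
               rng: np.random.Generator) -> list[str]:
    """One random tag per marker carrying the parent-A allele at snp_offset."""
    tags = []
    for a in panel.alleles_a:
        t = rng.choice(_BASES, size=tag_length)
        t[snp_offset] = a
        tags.append("".join(t))
    return tags


def simulate_reads(population: RILPopulation, panel: MarkerPanel,
                   depth: DepthModel | None = None, error_rate: float = 0.001,
                   barcodes: dict[str, str] | None = None, seed: int | None = None,
                   tag_length: int = 101, snp_offset: int = 50,
                   include_parents: bool = False, parent_depth: int = 10,
                   quality_char: str = "I") -> SimulatedReads:
    """Emit GBS-like tag reads for a RIL population.

    Every marker owns one ``tag_length``-base tag; a read is the line's
    barcode followed by the tag carrying that line's allele at
    ``snp_offset``, with substitution errors at ``error_rate`` per base.
    Heterozygous genotypes transmit either allele per read with equal
    probability; missing genotypes emit no reads.  When ``include_parents``
    is set, the two parents are emitted first at constant ``parent_depth``.
    The returned tally is the exact census of emitted bases at each SNP
    position (errors included).
    """
    depth = depth or DepthModel()
    rng = np.random.default_rng(seed)
    tags = _make_tags(panel, tag_length, snp_offset, rng)

    entities = []
    geno_rows = []
    if include_parents:
        entities += [PARENT_A, PARENT_B]
        geno_rows.append(np.zeros(len(panel), dtype=np.int8))
        geno_rows.append(np.ones(len(panel), dtype=np.int8))
    entities += list(population.line_names)
    geno_rows += [population.genotypes[i] for i in range(population.n_lines)]

    if barcodes is None:
        barcodes = make_barcodes(entities, seed=seed)
    missing = [e for e in entities if e not in barcodes]
    if missing:
        raise ConfigError(f"no barcode for {missing[:3]}")
    if len(set(barcodes[e] for e in entities)) < len(entities):
        raise ConfigError("barcode collision")
    bcs = sorted(barcodes[e] for e in entities)
    for i in range(len(bcs) - 1):
        if bcs[i + 1].startswith(bcs[i]):
            raise ConfigError("barcode table is not prefix-free")

    n_parents = 2 if include_parents else 0
    depths = np.empty((len(entities), len(panel)), dtype=np.int64)
    if n_parents:
        depths[:n_parents] = parent_depth
    depths[n_parents:] = depth.sample(rng, (len(entities) - n_parents, len(panel)))

    allele_codes = np.array([[_BASE_INDEX[a], _BASE_INDEX[b]]
                             for a, b in zip(panel.alleles_a, panel.alleles_b)])
    tag_arrays = [np.frombuffer(t.encode(), dtype=np.uint8) for t in tags]
    base_bytes = np.frombuffer(b"ACGT", dtype=np.uint8)

    reads = []
    counts = np.zeros((len(entities), len(panel), 4), dtype=np.int32)
    qual = quality_char * tag_length
    for ei, (entity, geno) in enumerate(zip(entities, geno_rows)):
        bc = barcodes[entity]
        bc_qual = quality_char * len(bc)
        for mj in range(len(panel)):
            g = geno[mj]
            d = depths[ei, mj]
            if g < 0 or d == 0:
                continue
            if g == 2:
                allele_per_read = allele_codes[mj, rng.integers(2, size=d)]
            else:
                allele_per_read = np.full(d, allele_codes[mj, g])
            for ri in range(d):
                seq = tag_arrays[mj].copy()
                seq[snp_offset] = base_bytes[allele_per_read[ri]]
                if error_rate > 0:
                    err = np.flatnonzero(rng.random(tag_length) < error_rate)
                    if err.size:
                        shift = rng.integers(1, 4, size=err.size)
                        cur = np.searchsorted(base_bytes, seq[err])
                        seq[err] = base_bytes[(cur + shift) % 4]
                emitted = seq[snp_offset]
                counts[ei, mj, int(np.searchsorted(base_bytes, emitted))] += 1
                rid = f"{entity}:{panel.ids[mj]}:{ri}"
                reads.append((rid, bc + seq.tobytes().decode(), bc_qual + qual))
    return SimulatedReads(reads, entities, counts, tags, snp_offset, dict(barcodes))
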