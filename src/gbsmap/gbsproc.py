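"""Reference-free GBS read processing and SNP calling.

The pipeline mirrors a three-stage design: (1) adapter and 3' quality
trimming plus exact-barcode filtering, (2) demultiplexing and construction
of a unique-read parental reference (identical reads collapsed, redundancy
below a floor discarded, survivors concatenated with an N spacer so every
base owns a unique coordinate), (3) per-line read assignment, homozygous
base calling at a strict frequency threshold, parental SNP detection with
deletion-artifact resolution, an informativeness filter over the RIL
family, and selection of a single SNP per tag.

No alignment against an external genome is performed: reads are matched to
the unique reference by Hamming distance, which is exact for fixed-length
restriction tags.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .simpop import CHAR_TO_CODE, CODE_TO_CHAR, PARENT_A, PARENT_B

__all__ = [
    "TagRead",
    "UniqueReference",
    "SNPRecord",
    "quality_trim",
    "demultiplex",
    "build_reference",
    "assign_reads",
    "call_base",
    "call_track",
    "detect_parental_snps",
    "resolve_deletions",
    "filter_informative",
    "select_one_per_read",
    "run_pipeline",
    "PipelineResult",
]

_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")
_BASE_INDEX = {b: i for i, b in enumerate("ACGT")}
_BASES = "ACGT"


@dataclass
class TagRead:
    id: str
    sequence: str
    quality: str            # Phred+33
    line: str | None = None
    discard: bool = False

    def __post_init__(self):
        if len(self.sequence) != len(self.quality):
            raise ValueError("sequence/quality length mismatch")


def quality_trim(read: TagRead, q_threshold: int = 20,
                 adapter: str | None = None) -> TagRead:
    """Trim adapter then low-quality 3' tail from a read.

    If the adapter (or a 3'-terminal prefix of it, down to 5 bases) is found
    as a suffix of the read, it is removed first.  Quality trimming then
    truncates at the 3'-most base whose Phred score is below the threshold,
    discarding that base and everything 3' of it.  A read trimmed to nothing
    is flagged for discard.
    """
    seq, qual = read.sequence, read.quality
    if adapter:
        if seq.endswith(adapter):
            seq, qual = seq[: -len(adapter)], qual[: -len(adapter)]
        else:
            for k in range(min(len(adapter), len(seq)) - 1, 4, -1):
                if seq.endswith(adapter[:k]):
                    seq, qual = seq[:-k], qual[:-k]
                    break
    scores = np.frombuffer(qual.encode(), dtype=np.uint8).astype(int) - 33
    low = np.flatnonzero(scores < q_threshold)
    if low.size:
        cut = int(low[-1])
        seq, qual = seq[:cut], qual[:cut]
    out = TagRead(read.id, seq, qual, read.line, read.discard)
    if not seq:
        out.discard = True
    return out


def demultiplex(reads, barcode_table: dict[str, str]):
    """Split reads by exact 5' barcode; strip the barcode.

    ``barcode_table`` maps line name -> barcode.  The barcode set must be
    prefix-free, so an exact-prefix match is unambiguous; reads matching no
    barcode are discarded.  Returns (per-line read lists, discard count).
    """
    barcodes = sorted(barcode_table.values())
    for i in range(len(barcodes) - 1):
        if barcodes[i + 1].startswith(barcodes[i]):
            raise ValueError("barcode table is not prefix-free")
    if len(set(barcode_table.values())) < len(barcode_table):
        raise ValueError("duplicate barcode")
    by_barcode = {bc: line for line, bc in barcode_table.items()}
    lengths = sorted({len(b) for b in barcodes})
    out: dict[str, list[TagRead]] = {line: [] for line in barcode_table}
    discarded = 0
    for read in reads:
        hit = None
        for L in lengths:
            line = by_barcode.get(read.sequence[:L])
            if line is not None:
                hit = (line, L)
                break
        if hit is None:
            discarded += 1
            continue
        line, L = hit
        out[line].append(TagRead(read.id, read.sequence[L:], read.quality[L:], line))
    return out, discarded


@dataclass
class UniqueReference:
    """Unique parental reads concatenated with an N spacer.

    ``offsets[i]`` is the coordinate of the first base of read i in the
    concatenated sequence; non-spacer coordinates map bijectively to
    (read index, within-read position).
    """

    reads: list[str]
    multiplicities: list[int]
    spacer: int = 200

    def __post_init__(self):
        self.offsets = []
        pos = 0
        for r in self.reads:
            self.offsets.append(pos)
            pos += len(r) + self.spacer
        self.total_span = pos - self.spacer if self.reads else 0

    def coordinate(self, read_index: int, within: int) -> int:
        if not 0 <= within < len(self.reads[read_index]):
            raise IndexError("position outside read")
        return self.offsets[read_index] + within

    def locate(self, coordinate: int) -> tuple[int, int]:
        """Inverse map: coordinate -> (read index, within-read position)."""
        i = int(np.searchsorted(self.offsets, coordinate, side="right")) - 1
        within = coordinate - self.offsets[i]
        if within >= len(self.reads[i]):
            raise IndexError("coordinate falls in spacer")
        return i, within

    def sequence(self) -> str:
        return ("N" * self.spacer).join(self.reads)


def build_reference(reads, min_redundancy: int = 4, spacer: int = 200) -> UniqueReference:
    """Collapse identical parental reads into a unique-read reference.

    Reads flagged for discard are ignored; groups seen fewer than
    ``min_redundancy`` times are excluded to keep sequencing errors out of
    the reference.  Survivors are ordered by descending multiplicity then
    sequence, for determinism.
    """
    counts = Counter(r.sequence for r in reads if not r.discard and r.sequence)
    survivors = [(seq, n) for seq, n in counts.items() if n >= min_redundancy]
    if not survivors:
        raise ValueError("no reference reads survive the redundancy filter")
    survivors.sort(key=lambda kv: (-kv[1], kv[0]))
    return UniqueReference([s for s, _ in survivors], [n for _, n in survivors], spacer)


def _read_matrix(seqs: list[str]) -> np.ndarray:
    return np.frombuffer("".join(seqs).encode(), dtype=np.uint8).reshape(len(seqs), -1)


def assign_reads(reads, reference: UniqueReference, max_mismatch: int = 3) -> dict[int, np.ndarray]:
    """Tally per-coordinate base counts for one line's reads.

    Each read is matched to the unique reference read with the fewest
    mismatches (Hamming distance over the overlap from the 5' end); ties and
    distances above ``max_mismatch`` leave the read unassigned.  Returns a
    map read-index -> (read length, 4) count array.
    """
    by_len: dict[int, list[int]] = {}
    for i, r in enumerate(reference.reads):
        by_len.setdefault(len(r), []).append(i)
    matrices = {L: _read_matrix([reference.reads[i] for i in idx])
                for L, idx in by_len.items()}
    counts = {i: np.zeros((len(r), 4), dtype=np.int32)
              for i, r in enumerate(reference.reads)}
    base_lut = np.full(256, -1, dtype=np.int8)
    for b, i in _BASE_INDEX.items():
        base_lut[ord(b)] = i

    for read in reads:
        if read.discard or not read.sequence:
            continue
        q = np.frombuffer(read.sequence.encode(), dtype=np.uint8)
        best, second, best_ref = max_mismatch + 1, max_mismatch + 1, -1
        for L, idx in by_len.items():
            if len(q) > L:
                continue
            d = np.count_nonzero(matrices[L][:, : len(q)] != q, axis=1)
            order = np.argsort(d, kind="stable")[:2]
            for o in order:
                dist = int(d[o])
                if dist < best:
                    best, second, best_ref = dist, best, idx[o]
                elif dist < second:
                    second = dist
        if best <= max_mismatch and best < second:
            codes = base_lut[q]
            valid = codes >= 0
            np.add.at(counts[best_ref], (np.arange(len(q))[valid], codes[valid]), 1)
    return counts


def call_base(count_vector, min_depth: int = 4,
              homozygous_threshold: float = 0.95) -> str | None:
    """Homozygous base call from a 4-vector of base counts.

    Returns the majority base when its frequency strictly exceeds the
    threshold and total depth reaches ``min_depth``; otherwise None
    (heterozygous or ambiguous positions are unusable in a selfed RIL
    family and are treated as missing).
    """
    counts = np.asarray(count_vector)
    total = int(counts.sum())
    if total < min_depth:
        return None
    i = int(np.argmax(counts))
    if counts[i] / total > homozygous_threshold:
        return _BASES[i]
    return None


def call_track(counts: dict[int, np.ndarray], min_depth: int = 4,
               homozygous_threshold: float = 0.95) -> dict[int, list[str | None]]:
    """Base calls for every (reference read, position) of one line."""
    return {
        i: [call_base(c[p], min_depth, homozygous_threshold) for p in range(len(c))]
        for i, c in counts.items()
    }


@dataclass
class SNPRecord:
    coordinate: int                 # unique reference coordinate
    read_index: int
    within_read: int
    allele_a: str                   # parent-A base
    allele_b: str                   # parent-B base
    classification: str             # "transition" | "transversion"
    quality: float = 0.0
    presence_fraction: float = 0.0
    filter_status: str = "PASS"
    calls: dict = field(default_factory=dict)    # line -> code (0/1/2/-1)

    @staticmethod
    def classify(a: str, b: str) -> str:
        same_family = ({a, b} <= _PURINES) or ({a, b} <= _PYRIMIDINES)
        return "transition" if same_family else "transversion"


def detect_parental_snps(parent_a_track, parent_b_track, reference: UniqueReference,
                         quality_counts=None):
    """Compare parental call tracks position by position.

    Positions where both parents are called and differ become SNP records;
    positions where exactly one parent is missing are returned separately as
    deletion candidates (read index, position, called parent, base) for
    :func:`resolve_deletions`.  The record quality is the summed parental
    read depth at the position when count data are supplied.
    """
    snps, candidates = [], []
    for i in range(len(reference.reads)):
        ta = parent_a_track.get(i)
        tb = parent_b_track.get(i)
        n = len(reference.reads[i])
        for p in range(n):
            a = ta[p] if ta else None
            b = tb[p] if tb else None
            if a is not None and b is not None and a != b:
                q = 0.0
                if quality_counts is not None:
                    qa, qb = quality_counts
                    q = float(qa[i][p].sum() + qb[i][p].sum())
                snps.append(SNPRecord(reference.coordinate(i, p), i, p, a, b,
                                      SNPRecord.classify(a, b), quality=q))
            elif (a is None) != (b is None):
                candidates.append((i, p, "A" if a is not None else "B", a or b))
    return snps, candidates


def resolve_deletions(candidate, line_calls: dict[str, str | None],
                      presence_threshold: float = 0.85):
    """Classify an apparent parental deletion from RIL evidence.

    If the position is called in more than ``presence_threshold`` of the RIL
    family, the missing parent is a sampling artifact: two segregating bases
    make it a real SNP (the absent parent's allele is the base the called
    parent does not carry), a single base makes it uninformative.  Low
    presence means the tag itself is unreliable.  Returns
    ("real_snp", inferred allele) | ("ignored", None) | ("artifact", None).
    """
    read_index, pos, called_parent, called_base = candidate
    calls = [b for b in line_calls.values() if b is not None]
    presence = len(calls) / max(len(line_calls), 1)
    if presence <= presence_threshold:
        return "artifact", None
    bases = sorted(set(calls))
    if len(bases) < 2:
        return "ignored", None
    others = [b for b in bases if b != called_base]
    if called_base not in bases or not others:
        return "artifact", None
    # inferred allele of the missing parent: the non-reference segregating base
    return "real_snp", max(others, key=lambda b: calls.count(b))


def filter_informative(records: list[SNPRecord], n_lines: int,
                       presence_threshold: float = 0.85) -> list[SNPRecord]:
    """Flag SNPs genotyped in fewer than ceil(threshold * n) lines.

    All records are retained in the database; failures get filter status
    ``LOW_PRESENCE`` and are excluded from mapping downstream.
    """
    need = int(np.ceil(presence_threshold * n_lines))
    for rec in records:
        called = sum(1 for v in rec.calls.values() if v >= 0)
        rec.presence_fraction = called / n_lines if n_lines else 0.0
        if called < need:
            rec.filter_status = "LOW_PRESENCE"
        elif rec.filter_status == "LOW_PRESENCE":
            rec.filter_status = "PASS"
    return [r for r in records if r.filter_status == "PASS"]


def select_one_per_read(records: list[SNPRecord]) -> list[SNPRecord]:
    """Keep the highest-quality SNP of each reference read (tie: lowest coordinate)."""
    best: dict[int, SNPRecord] = {}
    for rec in records:
        cur = best.get(rec.read_index)
        if cur is None or (rec.quality, -rec.coordinate) > (cur.quality, -cur.coordinate):
            best[rec.read_index] = rec
    return sorted(best.values(), key=lambda r: r.coordinate)


# ---------------------------------------------------------------------------
# End-to-end pipeline

@dataclass
class PipelineResult:
    reference: UniqueReference
    records: list[SNPRecord]          # all SNPs with filter status
    passing: list[SNPRecord]          # informative, one per read
    line_names: list[str]
    n_input_reads: int
    n_demultiplexed: int
    n_discarded: int

    def genotype_matrix(self) -> np.ndarray:
        """(n_lines, n_passing_snps) int8 matrix of A/B/H/missing codes."""
        out = np.full((len(self.line_names), len(self.passing)), -1, dtype=np.int8)
        for j, rec in enumerate(self.passing):
            for i, line in enumerate(self.line_names):
                out[i, j] = rec.calls.get(line, -1)
        return out


def run_pipeline(reads, barcode_table: dict[str, str],
                 parent_a: str = PARENT_A, parent_b: str = PARENT_B,
                 q_threshold: int = 20, adapter: str | None = None,
                 min_redundancy: int = 4, spacer: int = 200,
                 max_mismatch: int = 3, min_depth: int = 4,
                 homozygous_threshold: float = 0.95,
                 presence_threshold: float = 0.85) -> PipelineResult:
    """Run trimming, demultiplexing, reference building and SNP calling.

    ``reads`` may be TagRead objects or (id, sequence, quality) tuples.
    The reference is built from parent A's reads; both parents are then
    called against it, SNPs detected, apparent deletions resolved with RIL
    evidence, the informativeness filter applied, and one SNP kept per tag.
    """
    tagged = [r if isinstance(r, TagRead) else TagRead(*r[:3]) for r in reads]
    n_input = len(tagged)
    trimmed = [quality_trim(r, q_threshold, adapter) for r in tagged]
    kept = [r for r in trimmed if not r.discard]
    per_line, discarded = demultiplex(kept, barcode_table)
    discarded += n_input - len(kept)
    n_demux = sum(len(v) for v in per_line.values())

    for parent in (parent_a, parent_b):
        if parent not in per_line:
            raise ValueError(f"missing parental reads for {parent!r}")
    reference = build_reference(per_line[parent_a], min_redundancy, spacer)

    ril_names = [n for n in barcode_table if n not in (parent_a, parent_b)]
    counts = {line: assign_reads(per_line[line], reference, max_mismatch)
              for line in barcode_table}
    tracks = {line: call_track(counts[line], min_depth, homozygous_threshold)
              for line in barcode_table}

    snps, candidates = detect_parental_snps(
        tracks[parent_a], tracks[parent_b], reference,
        quality_counts=(counts[parent_a], counts[parent_b]))

    for cand in candidates:
        i, p, called_parent, called_base = cand
        line_calls = {line: tracks[line].get(i, [None] * len(reference.reads[i]))[p]
                      for line in ril_names}
        status, inferred = resolve_deletions(cand, line_calls)
        if status != "real_snp":
            continue
        a_base = called_base if called_parent == "A" else inferred
        b_base = inferred if called_parent == "A" else called_base
        q = float(counts[parent_a][i][p].sum() + counts[parent_b][i][p].sum())
        snps.append(SNPRecord(reference.coordinate(i, p), i, p, a_base, b_base,
                              SNPRecord.classify(a_base, b_base), quality=q))
    snps.sort(key=lambda r: r.coordinate)

    for rec in snps:
        for line in ril_names:
            base = tracks[line].get(rec.read_index,
                                    [None] * len(reference.reads[rec.read_index]))[rec.within_read]
            if base == rec.allele_a:
                rec.calls[line] = 0
            elif base == rec.allele_b:
                rec.calls[line] = 1
            else:
                rec.calls[line] = -1

    informative = filter_informative(snps, len(ril_names), presence_threshold)
    passing = select_one_per_read(informative)
    return PipelineResult(reference, snps, passing, ril_names,
                          n_input, n_demux, discarded)
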