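"""File formats: FASTQ, genotype/marker/map TSV, BED tracks, run configs.

All tabular outputs are plain TSV with ``#``-prefixed header lines carrying
provenance (package version and a hash of the generating configuration);
readers skip those lines.  Genotypes are coded A/B/H/- in text form.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__
from .genome import MarkerPanel
from .simpop import CHAR_TO_CODE, CODE_TO_CHAR, RILPopulation

__all__ = [
    "config_hash",
    "load_config",
    "provenance_header",
    "write_fastq",
    "read_fastq",
    "write_genotypes",
    "read_genotypes",
    "write_marker_positions",
    "read_marker_positions",
    "write_map",
    "read_map",
    "write_profile",
    "write_bed",
    "write_table",
]


def config_hash(config: dict) -> str:
    """Stable short hash of a configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def provenance_header(config: dict | None = None) -> list[str]:
    lines = [f"# gbsmap {__version__}"]
    if config is not None:
        lines.append(f"# config_hash {config_hash(config)}")
    return lines


def write_fastq(reads, path) -> None:
    """Write (id, sequence, quality-string) triples as Sanger FASTQ."""
    records = []
    for rid, seq, qual in reads:
        rec = SeqRecord(Seq(seq), id=rid, description="")
        rec.letter_annotations["phred_quality"] = [ord(c) - 33 for c in qual]
        records.append(rec)
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fastq")


def read_fastq(path):
    """Read FASTQ into (id, sequence, quality-string) triples."""
    out = []
    for rec in SeqIO.parse(str(path), "fastq"):
        qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
        out.append((rec.id, str(rec.seq), qual))
    return out


def _write_tsv(df: pd.DataFrame, path, config=None) -> None:
    with open(path, "w") as fh:
        for line in provenance_header(config):
            fh.write(line + "\n")
        df.to_csv(fh, sep="\t", index=False)


def _read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


write_table = _write_tsv


def write_genotypes(population: RILPopulation, path, config=None) -> None:
    """Genotype matrix TSV: one row per marker, one A/B/H/- column per line."""
    df = pd.DataFrame({"marker": population.marker_ids})
    for i, name in enumerate(population.line_names):
        df[name] = [CODE_TO_CHAR[int(c)] for c in population.genotypes[i, :]]
    _write_tsv(df, path, config)


def read_genotypes(path) -> RILPopulation:
    df = _read_tsv(path)
    markers = list(df["marker"])
    lines = [c for c in df.columns if c != "marker"]
    geno = np.empty((len(lines), len(markers)), dtype=np.int8)
    for i, name in enumerate(lines):
        geno[i, :] = [CHAR_TO_CODE[v] for v in df[name]]
    return RILPopulation(0, lines, markers, geno)


def write_marker_positions(panel: MarkerPanel, path, config=None) -> None:
    df = pd.DataFrame({
        "marker": panel.ids,
        "chromosome": panel.chromosomes,
        "position_bp": panel.positions_bp,
        "allele_a": panel.alleles_a,
        "allele_b": panel.alleles_b,
    })
    _write_tsv(df, path, config)


def read_marker_positions(path) -> pd.DataFrame:
    return _read_tsv(path)


def write_map(map_df: pd.DataFrame, path, config=None) -> None:
    """Map TSV: group, locus, cm, bin_members (comma-joined), status."""
    _write_tsv(map_df, path, config)


def read_map(path) -> pd.DataFrame:
    return _read_tsv(path)


def write_profile(profiles, path, config=None) -> None:
    rows = []
    for p in profiles:
        for s, e, r in zip(p.start_mb, p.end_mb, p.rate):
            rows.append({"chromosome": p.chromosome, "start_mb": s, "end_mb": e,
                         "rate_cm_per_mb": r})
    _write_tsv(pd.DataFrame(rows), path, config)


def write_bed(intervals, path) -> None:
    """BED (0-based half-open, Mb converted to bp) from (chrom, start_mb, end_mb, name, score)."""
    with open(path, "w") as fh:
        for chrom, start_mb, end_mb, name, score in intervals:
            fh.write(f"{chrom}\t{int(round(start_mb * 1e6))}\t{int(round(end_mb * 1e6))}"
                     f"\t{name}\t{score:g}\n")
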