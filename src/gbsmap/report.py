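"""Summary reporting: per-group map statistics and simple pipeline arithmetic."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .linkmap import LinkageMap

__all__ = [
    "group_summary",
    "map_totals",
    "average_interlocus_distance",
    "percent_reduction",
    "reference_genome_percent",
]


def group_summary(linkage_map: LinkageMap, decimals: int = 2) -> pd.DataFrame:
    """Per-group cM length, total marker count, unique locus count, and
    average inter-locus distance (cM per unique locus)."""
    rows = []
    for g in linkage_map.groups:
        n_loci = len(g.loci)
        rows.append({
            "group": g.group_id,
            "cm": round(g.length_cm, 1),
            "total_markers": g.n_markers,
            "unique_loci": n_loci,
            "avg_interlocus_cm": round(g.length_cm / n_loci, decimals) if n_loci else np.nan,
        })
    return pd.DataFrame(rows)


def map_totals(group_cm, n_loci: int, decimals: int = 2) -> dict:
    """Totals over linkage groups: summed cM and average inter-locus distance."""
    total = float(np.sum(np.asarray(group_cm, dtype=float)))
    return {
        "total_cm": round(total, 1),
        "n_loci": int(n_loci),
        "avg_interlocus_cm": round(total / n_loci, decimals) if n_loci else np.nan,
    }


def average_interlocus_distance(total_cm: float, n_loci: int, decimals: int = 2) -> float:
    """Average marker spacing: total map length over unique locus count."""
    return round(float(total_cm) / int(n_loci), decimals)


def percent_reduction(before: float, after: float, decimals: int = 1) -> float:
    """Percent reduction from ``before`` to ``after``."""
    return round(100.0 * (before - after) / before, decimals)


def reference_genome_percent(n_reads: int, read_length_bp: int,
                             genome_mb: float, decimals: int = 2) -> float:
    """Unique-read reference span as a percent of a genome size."""
    return round(100.0 * n_reads * read_length_bp / (genome_mb * 1e6), decimals)
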