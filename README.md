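# gbsmap

Reference-free genotyping-by-sequencing (GBS) SNP calling, recombinant
inbred line (RIL) linkage mapping, and recombination-landscape analysis —
with a forward simulator of selfed RIL families so the whole pipeline can
be validated end to end against known ground truth.

## The problem

Linkage maps built from GBS data in species without (or predating) a
reference genome require an ad hoc pipeline: demultiplexing barcoded
restriction-site tags, building a unique-read reference from the parents,
calling homozygous SNPs in a nearly fully inbred family, and assembling a
map from two-point recombination fractions. Aligning the resulting genetic
map to physical coordinates then exposes the recombination landscape:
broad pericentromeric regions where crossing over is suppressed, and
narrow hotspots where the local rate reaches tens of cM/Mb.

`gbsmap` implements that pipeline for selfed RIL families (F~g~ by single
seed descent), plus the analyses layered on top:

- **simpop** — genomes as piecewise-constant recombination-rate tracks
  (cM/Mb), arm-biased marker panels, F11 RIL genotypes via Poisson
  crossover meioses (no interference), and GBS-like reads with barcodes,
  over-dispersed depth, dropout and base error.
- **gbsproc** — quality/adapter trimming, exact-barcode demultiplexing,
  unique-read reference (redundancy ≥ 4, reads joined by a 200-N spacer),
  Hamming-distance read assignment, homozygous calling (base frequency
  > 0.95, depth ≥ 4), parental SNP detection with deletion-artifact
  resolution, an ≥ 85 %-of-lines informativeness filter, and one SNP kept
  per tag.
- **linkmap** — two-point analysis with the selfed-RIL correction
  R = 2r/(1+2r), Kosambi distances d = 25 ln((1+2r)/(1−2r)), grouping at a
  recombination-fraction cutoff of 0.2, haplotype binning, marker ordering
  by minimum crossover count (greedy build + window-5 ripple), LOD-3
  placement of leftovers, 1:1 segregation χ² tests, and double-crossover
  flagging.
- **markerdist** — Poisson goodness-of-fit test of marker distribution
  over fixed cM intervals (1, 2.5, 5, 10, 20, 40 cM).
- **landscape** — anchoring the map to physical positions, dcM/dMb
  profiles, pericentromere demarcation (< 1 cM/Mb rule), hotspot calls,
  coverage, and per-chromosome p-arm / pericentromere / q-arm summaries.
- **cli** — a `gbsmap` command with `simulate`, `process-reads`,
  `call-snps`, `map`, `disttest`, `landscape`, `report` and `all`
  subcommands over the documented TSV/FASTQ/BED formats.

## Worked example

```python
import pandas as pd
from gbsmap import genome, simpop, linkmap, landscape, report

g = genome.build_genome(genome.bean_preset(), seed=0)
panel = genome.build_marker_panel(g, n_markers=520, seed=1001)
pop = simpop.simulate_rils(g, panel, n_lines=188, generations=11,
                           seed=2001, missing_rate=0.15)
lm = linkmap.build_linkage_map(pop.genotypes, list(panel.ids))
print(f"linkage groups: {len(lm.groups)}")
print(f"unique loci: {lm.n_loci}, total map length: {lm.total_cm:.1f} cM")

rows = [{"group": grp.group_id, "locus": panel.ids[l], "cm": c}
        for grp in lm.groups for l, c in zip(grp.loci, grp.cm)]
pos = pd.DataFrame({"marker": panel.ids, "chromosome": panel.chromosomes,
                    "position_bp": panel.positions_bp})
anchored = landscape.anchor_map(pd.DataFrame(rows), pos)
_, cov = landscape.coverage(anchored, {c.name: c.length_mb
                                       for c in g.chromosomes})
print(f"physical coverage: {cov:.2f} %")
```

Output:

```
linkage groups: 11
unique loci: 419, total map length: 1068.6 cM
physical coverage: 96.77 %
```

The 11 linkage groups match the 11 simulated chromosomes; 419 unique loci
remain after binning co-segregating markers out of the 520 simulated. On
the same run the landscape module recovers a pericentromeric genome
fraction of 44.1 % (truth: 45 %) and a peak hotspot rate of 35.9 cM/Mb
(truth: 34 cM/Mb).

The same pipeline runs from the shell on self-contained synthetic data:

```sh
gbsmap all --seed 7 --config examples/tiny.yaml --out-dir out/
```

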