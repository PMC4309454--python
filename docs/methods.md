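# Methods

## Genome and recombination model

A chromosome is modelled as a physical interval (Mb) carrying a
piecewise-constant recombination-rate track in cM/Mb. The genetic length
of a chromosome is the integral Σ rate × width; by construction the track
is both the simulator's crossover density and the quantity the landscape
analysis estimates. The default ("bean") preset has 11 chromosomes of
31.9–59.6 Mb (516.4 Mb total), a pericentromeric block covering the middle
45 % of each chromosome at 0.25 cM/Mb, arms at 3 cM/Mb, and one to four
rectangular hotspots per chromosome with peak rates of 9–34 cM/Mb and
widths of 0.5–1.0 Mb. The single 34 cM/Mb hotspot is 0.5 Mb wide so that
its genetic span (17 cM) remains linkable at the standard grouping cutoff
(recombination fraction 0.2); wider hotspots at that rate would open map
gaps that no two-point method can bridge.

Meiosis places a Poisson number of crossovers per chromosome (mean equal
to the genetic length in Morgans) at positions drawn i.i.d. from the
normalised rate density — no crossover interference. A gamete follows one
homolog and switches at each crossover, with a random starting phase.
RILs descend from a uniform F1 through g − 1 rounds of self-fertilisation
(single seed descent, one offspring per round; default g = 11, so the
expected residual heterozygosity is 2⁻¹⁰ ≈ 0.1 %). Transmission-ratio
distortion, when configured, is a gametic viability weight: a gamete
carrying the disfavored allele at a named locus survives with probability
w ∈ (0, 1], applied independently every generation. This is the simplest
mechanism that produces contiguous distorted tracts along a chromosome.

## Marker panels

Markers are placed from a piecewise density that is 1 inside the
pericentromere, 5× on the arms (the restriction-enzyme bias of
methylation-sensitive GBS libraries toward gene-rich arms), and a further
3× within hotspot spans, since recombination hotspots concentrate in
gene-rich, restriction-site-rich sequence. Two deliberate regularisations:

- a 100 kb spacing floor — closer tag pairs are recombinationally
  indistinguishable at n = 188 (≲ 0.3 cM apart) and would be binned
  anyway, while their tiny physical spans otherwise produce unbounded
  noise in dcM/dMb;
- every hotspot span is guaranteed at least three markers (edges and
  midpoint added if sampling leaves fewer). A simulated hotspot without
  delimiting loci is unobservable in principle, so leaving this to chance
  only adds runs in which the truth cannot be recovered by any method.

Default panel size is 520 markers.

## Read simulation

Each marker owns a random 101-base tag with the SNP at offset 50. A read
is the line's inline 5' barcode plus the tag carrying that line's allele,
with independent substitution errors per base. Per-(line, site) depth is
zero with probability `dropout` (tag dropout, the dominant cause of GBS
missingness) and otherwise negative-binomial (default mean 8, dispersion
2) to mimic uneven amplification; a fixed-depth mode supports exactness
tests. Heterozygous genotypes emit either allele per read with equal
probability. The returned count table is the exact census of emitted
bases, so callers can be tested against it without re-parsing FASTQ.

What the generator does *not* emulate: restriction-site sequence context,
paired ends, indels, quality-score decay along reads, PCR duplicates with
shared errors, or reference-genome artifacts. Passing tests therefore
validate the pipeline's logic and statistics, not its robustness to every
real-data pathology.

## SNP calling

Trimming removes a configured adapter suffix, then truncates at the
3'-most base with Phred quality below 20 (the single-cut rule keeps
everything 5' of the last low-quality base). Demultiplexing requires an
exact barcode prefix over a prefix-free table. The reference collapses
identical parent-A reads, discards groups with redundancy < 4 (sequencing
errors rarely recur identically), and concatenates survivors with 200 Ns
so every base has a unique coordinate (the spacer length is a parameter;
200 follows the primary description of the procedure). Reads are assigned
to the unique reference read at minimum Hamming distance (≤ 3; ties
unassigned) — exact-match alignment is appropriate because synthetic tags
are fixed-length, which is why no external aligner is used. A position is
called homozygous only when one base exceeds 95 % frequency at depth ≥ 4
(the depth floor mirrors the redundancy rule; heterozygous calls are
useless in a ~99.9 % homozygous family and are treated as missing).

Sites where exactly one parent is called are resolved with RIL evidence:
called in > 85 % of lines and segregating for two bases → real SNP with
the absent parent's allele inferred; present but monomorphic → ignored;
poorly covered → artifact. SNPs genotyped in fewer than ⌈0.85 n⌉ lines
are flagged and excluded from mapping, and only the highest-quality SNP
per tag is kept (quality = summed parental depth; ties broken by lowest
coordinate). Both 85 % thresholds are applied to genotype calls, not raw
read presence.

## Linkage mapping

Two-point analysis counts recombinants over lines homozygous at both
markers. Because recombinants accumulate over selfing generations, the
observed fraction R relates to the per-meiosis fraction r by
R = 2r/(1 + 2r) (inverted before mapping); distances use the Kosambi
function d = 25 ln((1+2r)/(1−2r)).

Grouping takes connected components of the graph with edges where
corrected r ≤ 0.2 and LOD ≥ `min_lod`. The LOD default (6.0) was
calibrated on the preset study conditions: at LOD 3 the ~10⁵
between-chromosome pairs yield a spurious linking edge roughly every
eighth run (n = 188, 15 % missing), while LOD ≥ 8 starts splitting
chromosomes at wide marker gaps; 6.0 recovered 11/11 groups in 60/60
calibration runs. Markers whose calls never conflict (zero observed
recombinants) are merged into bins represented by the member with fewest
missing calls. Ordering minimises the summed adjacent recombinant count
(a crossover-counting criterion) with greedy insertion followed by
exhaustive permutation of a sliding window of five loci until no
improvement; orientation is normalised by the terminal locus ids. A
well-genotyped frame (presence ≥ 170/188 ≈ 0.90) is ordered first when at
least half the bins qualify — under uniform missingness the cut would
otherwise starve the frame, so it falls back to all bins. Leftovers are
placed by summed two-point LOD against flanking loci, only when the best
insertion slot beats the second best by ≥ 3 (markers compatible with
several positions stay unplaced rather than inflate the map). Segregation
is tested per marker by χ² against 1:1 at α = 0.05 without multiplicity
correction (a Bonferroni switch exists); distorted runs are reported with
their favored parent. Double crossovers are flagged where a locus
disagrees with both flanking loci within a 25 cM window.

## Marker-distribution test

Each linkage group is cut independently from 0 cM into half-open
intervals of fixed length; a marker exactly at a group's end joins the
final partial bin. Counts across all groups are compared with a Poisson
law whose mean is the per-interval average: expected category frequencies
are pooled from the top until each reaches 5, and the χ² statistic uses
df = categories − 2 (one for totals, one for the estimated mean). Under
uniform random placement the test's type-I error at α = 0.05 measures
0.05–0.07 over 1000 replicates; arm-clustered placement (45 % of each
group suppressed 5×) is rejected at p ≪ 0.001 for all interval lengths
from 5 to 40 cM.

## Landscape analysis

Anchoring joins map loci to physical positions by marker id, assigns each
group to the chromosome holding its majority, orients it by the Spearman
sign of cM against bp, and flags discrepancies: loci on the wrong
chromosome, and loci off the monotone bp trend (longest non-decreasing
subsequence) by more than 5 Mb. Flagged loci are excluded from profiles.
The recombination profile is the slope ΔcM/ΔMb between consecutive
retained loci (zero-span segments are capped and flagged; optional
running-median smoothing is off by default). The pericentromere is the
longest run of segments below 1 cM/Mb — runs separated by a single
above-threshold segment narrower than 2 Mb are bridged — provided it
spans ≥ 3 Mb; otherwise the chromosome is reported without a call, as
happens for acrocentric-looking profiles. Hotspots are maximal runs at
≥ 10 cM/Mb (the threshold is a knob; reported peaks, not the cutoff, are
the scientific result). Arm summaries report cM, Mb and average cM/Mb for
p-arm, pericentromere and q-arm, the pericentromere's percent of the
chromosome, and flag arms narrower than 1 Mb instead of guessing.

## Recovery performance and problem sizes

Under the preset conditions (188 F11 lines, 520 markers, 15 % missing
calls — the low end of typical GBS missingness, appropriate because
mapped markers must pass the 85 % presence filter), twenty seeded
end-to-end runs recover 11 linkage groups in every run; pericentromere
calls are made for 219 of 220 chromosome-runs with a mean absolute
boundary error of ~1.2 Mb against a mean flanking-marker spacing of
~7 Mb at the true transitions; mean physical coverage is ~97 %; and the
mean called peak hotspot rate is within a few percent of the simulated
34 cM/Mb (single-run peaks scatter roughly ±30 % because the maximum of
noisy slope estimates is upward-biased). The one missed pericentromere
call arose when ordering noise collapsed a pericentromere to a single
retained segment whose pooled rate marginally exceeded 1 cM/Mb — an
inherent resolution limit at this marker density, not a bug.

Exactness tests use a 3-chromosome miniature (40 lines, ~60 markers,
fixed depth, zero error); the identity between called genotypes and
simulated truth is asserted at homozygous truth sites, since the caller
by design never emits heterozygous calls and residual F11 heterozygotes
are correctly reported missing. Ordering optimality is checked against
exhaustive permutation on 8-marker instances (50 random replicates of
200 lines). These sizes keep the full suite under a minute while leaving
every statistical check adequately powered.

## Known limitations

- Ordering within pericentromeres is essentially unidentifiable (almost
  no recombinants); downstream analyses tolerate, rather than fix, the
  resulting local shuffles via out-of-trend exclusion.
- Two-point placement cannot resolve a marker equally linked to two
  adjacent slots of the frame; such markers are left unplaced.
- The Poisson goodness-of-fit χ² is slightly anti-conservative at large
  interval lengths, where few intervals support the asymptotics.
- No interference model is offered; observed double-crossover counts in
  real data are expected to fall below this simulator's.
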