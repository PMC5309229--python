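# Methods

## The model

A P-type PPR protein is modelled as an ordered array of repeats, each
contributing one position of an RNA recognition site. Repeat boundaries
are consumed as input (1-based inclusive protein coordinates), never
predicted: upstream annotation (PPR databases, HMM scans) is a separate
problem with its own error modes, and mis-set boundaries shift the
specificity residues. The two specificity residues of repeat *i* are the
5th residue of the annotated span and its final residue; using the final
residue (rather than a fixed position 35) handles 30/35/37/38-aa repeat
variants uniformly, which matters because the inter-repeat loop residue is
what contacts the base. The leading short repeat (label `P0` by default)
does not contribute to recognition and is excluded.

The PPR code is degenerate and empirically characterized, so it is data,
not code: a TSV mapping each residue pair to a probability vector over
(A, C, G, U). Pairs absent from the table fall back to the uniform vector
with a logged warning — an unknown pair carries no information, and
failing hard would make every novel repeat a crash. The packaged default
table is this package's own transcription of the canonical published
pair→base associations (T/N→A, T/D→G, S/N→A, N/D→U, N/S→C,
N/N→pyrimidine, S/D→purine, N/T→pyrimidine, A/D→no preference) with
representative probability masses; because published weighting schemes
differ numerically, any quantitative claim should state the table used,
and the table is a swappable input everywhere.

The PWM is the row-wise stack of the looked-up vectors. The IUPAC
consensus includes at each position every base with probability ≥ τ;
τ defaults to 0.25 so that a uniform row reads `N` and a balanced
two-base row reads its two-letter code (R/Y/...), matching how degenerate
binding sites are conventionally printed. τ is restricted to (0, 0.5] —
above 0.5 two equal bases could both be dropped.

## Scanning and p-values

Windows are scored with the standard log2 odds against a 0-order
background (uniform by default; the empirical composition of the scanned
set is available as an option). Zero PWM cells are replaced by a
pseudo-probability ε = 1e-4 before the ratio, bounding scores. Windows
containing N are skipped rather than scored or rejected.

P-values are exact under the background model: the null distribution of
the window score is built by per-position convolution on an integer score
grid (the classic motif-scanner dynamic program), and a hit's p-value is
the upper-tail mass at its grid score. Numerical choices:

- Nominal resolution is 10,000 bins over the achievable score range; the
  grid is internally oversampled 500× so per-cell rounding error stays
  far below one nominal bin.
- Scanning computes each window's grid score from the same integer cell
  matrix as the null table, so scan p-values are exactly the discretized
  tail (byte-identical reruns).
- Real-valued queries (`ScoreDistribution.pvalue`) are mapped to the grid
  with a floor(L/2)+1-step conservative margin, because per-cell rounding
  can displace a window's grid score by up to (L+1)/2 steps below the
  rounded sum; without the margin a probability atom belonging in the
  tail could be dropped. Consequence: reported p-values are never
  anti-conservative, and agree with exhaustive enumeration to ~1e-3
  except for distinct windows whose true scores differ by less than a
  few parts in 10⁷ of the score range (no fixed discretization can
  separate those).
- Circular sequences are scanned with windows wrapping the origin (the
  end coordinate wraps back into [1, length]); reverse-strand hits score
  the reverse complement and are reported in forward coordinates.
- No multiple-testing correction is applied; the reporting threshold
  (default p ≤ 0.01) is a raw per-window p-value, as is conventional for
  single-motif scans of candidate regions.

## RIP-chip enrichment

The two-color model: pellet RNA (Cy5, F635) against supernatant RNA
(Cy3, F532) on replicate-spotted tiling arrays, one treatment experiment
(tagged protein) and one mock (untagged extract). Analysis is on log2
ratios of background-subtracted intensities; a spot is invalid — a
status, never an exception — if manually flagged, if its F532 foreground
does not exceed background, or if the Cy5 numerator is non-positive
(negative numerators are invalidated, not clamped, because a clamped
value would fabricate a finite ratio).

Normalization is per-array median centering of the valid log2 ratios:
the minimal defensible correction for dye/loading offsets, deliberately
isolated in one function so loess/print-tip alternatives can be swapped.
It is idempotent, and the ratio-scale values remain recoverable.

Per fragment and experiment, valid spots are pooled across the replicate
arrays before taking the median (with the default layout of 12 spots ×
2 arrays, 24 spots per experiment); the differential is the treatment
median minus the mock median. A fragment is retained only if **both**
experiments keep ≥ `min_pass` spots (default 13, i.e. more than half of
24); excluded fragments carry no differential and appear as gaps in the
genome-order plot rather than zeros. Ranking of enrichment peaks breaks
ties by genome position (ascending) for determinism. Known-artifact
fragments (spurious recurrent peaks) are handled by a user-supplied
blacklist of fragment ids, never by an automatic rule.

## Footprint co-mapping

Printed footprint coordinate pairs may run descending (transcript
orientation); they are normalized to ascending closed intervals, keeping
a `descending_input` flag as an orientation hint only — no strand is
assigned, since footprint records carry none. Co-mapping requires ≥ 1
shared base between the hit and footprint intervals and best overlapping
p-value ≤ threshold; containment of the best hit is reported separately.
Overlap rather than containment is the criterion because footprints
(29–41 nt) are longer than a 14-nt site — containment is the expected
case, overlap the safe one. Intervals are closed and 1-based internally;
BED export converts to 0-based half-open as (start−1, end], GFF3 stays
1-based inclusive.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the statistical structure the analysis assumes,
with one RNG stream per artifact (spawned from the master seed, so
regenerating one artifact does not shift the others; all outputs are
byte-identical under the same seed and config):

- a code table whose pairs prefer one base with mass `code_sharpness`
  (default 0.9; 1.0 gives deterministic rows; ≤ 0.25 is rejected as
  uninformative);
- a repeat protein shaped like a CRP1-type array: one 30-aa leading
  repeat plus 35-aa repeats (default 15 total → 14 scoring pairs), with
  specificity residues drawn from the generated table's pair set;
- a uniform-background genome (default 24 kb — a chloroplast-scale
  problem reduced ~6× to keep test runs fast) with PWM-sampled sites
  planted at the centers of the spiked fragments, plus an optional
  origin-straddling site on circular genomes;
- footprints extending each site by random flanks to a total length
  drawn from 29–41 nt (the in-vivo footprint range);
- a spotted-array dataset: 120 fragments tiling the genome, 2 arrays per
  experiment, 12 spots per fragment per array, Gaussian log2 spot noise
  (sd 0.3 — log-normal on the intensity scale), 4 spiked fragments with
  effect 2.0 log2 units on treatment arrays, manual-flag failures at
  rate 0.02. Intensities are back-computed from each spot's target ratio
  around a fixed Cy3 net signal, so stage-level ground truth is exact.

Not emulated: scanner/hybridization physics (saturation, spatial print-tip
effects), sequence-composition bias in the genome background, correlated
spot failures, and real PPR-code uncertainty. Passing tests therefore
demonstrate that the estimators recover known structure under the assumed
noise model — not that the defaults match any particular instrument.

## Design choices that were genuinely open

- **Alignment statistics**: published identity/similarity values for
  protein pairs come from tools whose column conventions are unstated.
  The utility documents its own: denominator = columns with at least one
  residue (double-gap columns dropped), similarity = identity or shared
  membership in a ClustalW-style strong group. Values from other
  conventions (e.g. local-alignment spans) will differ by a few points.
- **Protein mass** uses average (not monoisotopic) residue masses plus
  one water (18.0153 Da); unknown residues (X) contribute a placeholder
  110 Da and flag the result approximate.
- **Pooling vs averaging replicate arrays**: spots are pooled across an
  experiment's arrays before the median, matching the "24 replicate
  spots over two arrays" layout; per-array medians-of-medians would
  weight arrays equally instead and is not what the exclusion rule's
  spot counts imply.
- **Scan strand default is "given"**: candidate regions are sense-strand
  RNAs; both-strand scanning is a flag meant for genome-wide runs.
- **Consensus comparison of the shipped ortholog pair lists** is a
  pipeline-mechanics test: the lists are synthetic reconstructions (the
  real per-repeat residues are in a non-machine-readable annotation
  figure), so a mismatch there indicates shipped-data drift, not a
  scoring bug.

## Problem sizes

Default test and acceptance runs use the 24 kb genome / 120 fragment
configuration (≈ 11,500 spots per dataset), 20 seeds × 3 effect sizes for
spike recovery at a reduced 20-fragment layout, and exhaustive-enumeration
cross-checks for PWM lengths ≤ 6 (≤ 4096 windows). These sizes were chosen
so the full suite completes in well under a minute while keeping every
statistical check comfortably powered (e.g. the differential's standard
error at 24 + 24 spots and sd 0.3 is ≈ 0.11 log2 units, against a spike
effect of 2.0).

## Known limitations

- The default code table is qualitative: letters are right by
  construction, probability masses are representative. Refitting the code
  from protein–RNA pairs is out of scope.
- Footprint records are linear intervals; a footprint spanning a circular
  origin is not representable (the generator skips wrap sites when
  emitting footprints).
- The scanner's null model is 0-order; higher-order backgrounds and
  q-value/FDR machinery are out of scope.
- RIP-chip significance testing is deliberately absent: the method
  reports differential median ratios, and the QC rule plus ranking are
  the published decision procedure.
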