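# Methods

`ssrbridge` harmonizes microsatellite (SSR) allele sizes for grape
phylloxera (*Daktulosphaira vitifoliae*) across three genotyping
platforms: the original polyacrylamide gels whose allele names define the
historic clonal genotypes (G1, G4, G7, G19, G20, G30, G38), fluorescent
capillary electrophoresis, and whole-genome short-read sequencing.  The
same biological allele reports a different number on each platform —
universal primer tails inflate capillary sizes by 15–18 bp, platform-
specific migration shifts add up to ~3 bp, flanking indels move fragment
length without changing repeat count, and one locus was mis-scored in the
original gel work — so raw sizes cannot be compared across studies without
an explicit calibration and accounting model.  This note records that
model, its assumptions, and the choices made where the design was open.

## Capillary calibration

A raw capillary fragment size decomposes as

    raw = amplified_length + tail_length + locus_offset + jitter,

with `tail_length` the constant universal-tail addition (15–18 bp per
locus), `locus_offset` a whole-bp platform shift, and `jitter` sub-bp
measurement noise (~0.15 bp SD between replicate sizings of one allele).
Calibration proceeds in three steps:

1. **Tail subtraction** removes the known tail length.
2. **Offset estimation** from control samples of known genotype: the
   per-locus offset is the integer nearest the mean of
   (historic − tail-subtracted observed) over all control allele
   observations, homozygotes counted twice, half-integers rounded away
   from zero.  On the packaged reference table this yields the published
   adjustments: +3 bp for the poly-A locus Dvit5, 0 for Dvit1, and no
   adjustment for the two DVSSR loci.
3. **Binning**: each historic allele becomes a *bin* with a float center
   (the mean calibrated size of the control observations carrying it) and
   an integer historic *name*.  A measured size snaps to the nearest
   center within a ±1 bp tolerance; sizes outside every bin get a
   provisional bin named by their rounded size and an `off_bin` flag.
   Equidistant centers resolve to the lower name with a `bin_tie` flag.

Separating the bin center from the bin name is essential, not cosmetic:
a single per-locus integer offset cannot close the calibration on the
reference data, because one locus's two alleles shift by −2.5 and −0.7 bp
(a 1.9 bp spread that no integer offset brings jointly within ±1 bp of the
historic names), and the DVSSR4 allele migrating at 251 bp keeps its
historic name "250".  Bin centers absorb per-allele shifts exactly the way
fragment-analysis bin panels do in practice, while the integer offset
remains the interpretable, reportable platform adjustment.

**Artifact filtering** precedes calling.  Cross-dye pull-up: a peak within
0.5 bp of a ≥10×-taller peak in a different dye of the same sample is
removed.  Homopolymer stutter: at single-base-motif loci, a peak 1–2 bp
below a ≥2×-taller retained peak is removed (window 0.5–2.5 bp to admit
jitter), descending by height so ladders collapse onto the true peak.
Surviving peaks under 20% of the locus maximum are dropped (distant
stutter products), and the two tallest peaks remain; one survivor is a
homozygote, zero is ND.  None of these thresholds comes from measured
data; they are conservative fragment-analysis defaults and all are
configurable (`ArtifactConfig`).

## Read-level genotyping

A read is usable when longer than 50 bp, mean base quality above 20, and
free of runs of ≥5 N.  A *spanning* read contains both 15-mer flank
anchors (the last 15 bp of the 5′ flank, the first 15 bp of the 3′ flank)
in the same orientation — matched exactly, in either the read or its
reverse complement, which also fixes the read's strand.  The tract between
the anchors gives the observed repeat length; a tract that is not a clean
motif tiling is flagged as carrying a flank/tract artifact.

The stutter model is per-read: with probability `p_stutter` the observed
tract is shifted by `m` motif units, contracted with probability `p_down`,
with `m` geometric — P(m) = step·(1−step)^(m−1), so `step` is the stopping
probability and 1/step the mean magnitude (defaults 0.05 / 0.8 / 0.9, i.e.
~1.1 units per stutter event).  Parameters are re-estimated per locus by
method of moments from the spanning reads, taking the two most frequent
tract lengths as putative alleles: `p_stutter` is the off-allele fraction,
`p_down` the contraction fraction with add-one smoothing (so a single
off-allele read cannot collapse the direction estimate to 0 or 1), `step`
the inverse mean magnitude.  Below 20 spanning observations the defaults
are returned with a warning.

The genotype is the allele pair maximizing the likelihood in which each
spanning read is either on-allele (probability 1−p_stutter, halved per
allele) or a stutter product of one allele; the posterior is computed over
all candidate pairs within ±10 motif units of the observed lengths under a
flat prior.  A call is retained only if it passes, in order: at least 2
spanning reads; posterior > 0.90; artifact fraction (stutter-discordant or
flank-artifact reads) ≤ 15%; and a bias screen at p > 0.01.  ND calls name
the failing filter.

The bias screen is the Fisher exact association test on the strand ×
allele 2×2 table, plus an allele-balance test of the two allele read
counts against an even split at the same depth.  The allele-balance
component is what rejects stutter-absorbed calls — when a stutter pile is
promoted to allele status the "het" shows grossly imbalanced support — and
is the main guard at homopolymer loci.  A strand-balance marginal test
exists behind `include_strand_marginal=True` but is off by default: an
exact test on randomly oriented reads rejects ~1% of genuinely unbiased
calls at the fixed 0.01 cutoff, which is incompatible with near-perfect
retention of clean calls.

**Homopolymer behaviour.**  Poly-A tracts stutter per read an order of
magnitude more than di/trinucleotide repeats.  At 30% per-read stutter the
artifact-fraction and bias filters remove ~95% of calls at a poly-A-like
locus (measured over seeded replicates whose genotypes, like the published
poly-A genotypes, are homozygous or ≥2 bp apart) — reproducing as a
behaviour the empirical finding that no strain could be sequence-genotyped
at the poly-A locus.  The one configuration a heavy-stutter locus *can*
survive QC is a heterozygote whose alleles differ by exactly one unit,
where stutter from each allele lands mostly on its sister; that
configuration does not occur in the reference genotype table.

## Flank-indel decomposition

Observed allele sequences are globally aligned to the original reference
clone with affine gaps (match +2, mismatch −3, gap open −6, extend −1 —
conventional values, configurable; ambiguous N matches anything at zero
score, so the known N-flanked artifact in one published reference does not
score as a substitution).  Every indel is left-normalized to its leftmost
equivalent position — the same canonicalization variant callers use — and
classified by the reference region containing that position: forward
primer footprint, 5′ flank, repeat run, 3′ flank, reverse primer
footprint.  An indel whose canonical position falls on a region boundary
is additionally flagged `ambiguous`: a flank indel of motif length
adjacent to the repeat is mathematically indistinguishable from a
repeat-unit change (size homoplasy).  The signed region deltas sum to the
total length difference exactly, by construction and by property test.

The platform arithmetic follows from one mechanism: PCR overwrites primer
binding sites with the primer sequence, so primer-footprint indels are
length-neutral on amplified platforms but visible to direct sequencing:

    sequenced_delta  = delta_total
    amplified_delta  = delta_total − delta_primers

The canonical worked case is a locus with one −1 bp deletion inside the
forward primer footprint and a second −1 bp deletion on the 3′ flank:
amplified platforms see −1, sequencing sees −2.

**Explanation ledger.**  For a platform pair, the attributed discrepancy
is the difference of expected shifts — polyacrylamide anchored at 0 (its
names define the historic scale), capillary at `amplified_delta`,
sequencing at `sequenced_delta`, both plus any registered historic scoring
correction (one locus's historic names are 2 bp above the sequence-true
sizes, an error in the original gel scoring).  Verdicts: |residual| <
0.5 bp → explained; non-zero attribution with a ≥0.5 bp residual →
partial; no sequence data → undetermined; otherwise unexplained.  This
mechanical rule reproduces the published verdicts for every locus except
one gel-vs-capillary cell, where the published prose accounting is
internally loose (two −2 bp deletions plus one primer-restored base cannot
simultaneously give a 0.0 gel-vs-capillary and −2.0 gel-vs-sequencing
discrepancy); the rule yields "partial" there and the residual ~1 bp
remains unaccounted, consistent with the published suggestion of
dye-shift effects, which this package deliberately does not model.

## Concordance statistics

Per genotype and locus, allele pairs are sorted ascending and paired
positionally; homozygotes contribute two observations; ND skips the
genotype.  The per-locus statistic is the observation-weighted mean signed
difference, computed exactly in integer tenths (fixture sizes carry one
decimal) and rounded half away from zero to 1 dp only at presentation —
observation weighting is load-bearing: unique-allele weighting does not
reproduce the published per-locus means.  Grand statistics per platform
pair are the unweighted mean and sample SD (n−1) over the *rounded*
per-locus means, which is how the published summary row was evidently
computed from its own table.  Loci without measured polyacrylamide data
(the two DVSSR loci, whose platform-1 entries are published expected
sizes) are N/A for gel comparisons; their allele accounting is taken over
the capillary-vs-sequencing comparison, making the unique-allele total 30.

**Documented data corrections.**  The packaged genotype table transcribes
the published values verbatim.  Two cells carry documented corrections,
applied only where stated: (a) one genotype's capillary entry at the
trinucleotide locus reads 205.4/202.4 against a homozygous 205/205
reference genotype — read as homozygous 202.4 (suspected transposition),
it reproduces the published per-locus means (−2.6, +1.6) and the published
capillary-vs-sequencing grand average (+0.2) that the verbatim value
cannot; the verbatim result (−2.4, +1.3, +0.1) is pinned in the test suite
as a documented expected failure.  (b) one genotype's sequencing call at
the dinucleotide locus includes a 171 bp allele attributed to a
preferentially sequenced stutter band (one unit short of 173); the
correction is used for genotype matching only — the published concordance
statistics require the verbatim 171 and are computed from it.

## Genotype matching

A query profile matches a reference genotype at a locus when the
unordered allele pairs are identical after calibration to historic names;
ND loci are excluded; at least 4 loci must be scored (the historically
smallest panel).  The verdict is `unique_match` only when exactly one
reference matches at every compared locus; multiple full matches are
`ambiguous`, never auto-resolved.  An optional `fuzzy` tolerance (bp per
allele) serves uncalibrated float queries.  On the packaged table, all
seven genotypes self-match uniquely from their capillary profiles (8/8
loci, after calibration estimated from the table itself) and from their
sequencing profiles (4–7 loci scored, after the documented corrections).

## Synthetic data

The generator produces a complete, truth-annotated copy of each data
shape so every stage is testable without external downloads:

- **Panel/sequences**: loci are pure tandem repeats (motif classes
  mirroring the real panel: dinucleotides, one trinucleotide, one poly-A)
  inside unique random flanks whose outermost 20 bp are the primer
  footprints; flank ends are constrained so the planted tract is the
  maximal repeat run.  Loci sharing a dye are staggered ≥80 bp apart so
  their allele ranges never overlap in a simulated capillary lane.  Named
  indel patterns mirroring each observed flanking-variant configuration
  can be planted into every strain allele while the reference keeps the
  unmutated flanks.
- **Capillary peaks**: size = amplified length + tail + planted whole-bp
  offset (|offset| ≤ 3) + N(0, 0.15 bp) jitter (the within-allele spread
  seen in replicate sizings); poly-A loci grow satellite ladders at −1 and
  −2 bp with heights decaying ×0.4 per step; optional cross-dye pull-up
  ghosts at ~1/20 height.  Allele peak heights are drawn U(1500, 2800) —
  within a factor of 2, as replicate amplification of one template gives —
  so true alleles are never mistaken for each other's stutter.
- **Reads**: 150 bp reads with per-read stutter from the geometric model,
  Bernoulli(0.5) strand orientation, constant Q30 qualities.  `coverage`
  is the target spanning-read depth per chromosome, so homozygotes get
  double depth, as in real diploid sequencing.  Reads from molecules
  shorter than 150 bp are whole-molecule reads.

What the generator does **not** emulate: substitution sequencing errors,
quality-score variation, PCR duplicates, mapping ambiguity against a full
genome, and real inter-locus amplification competition.  Passing tests
therefore demonstrate the correctness of the calibration/QC/decomposition
logic under the stated noise model, not robustness to every artifact of
real instruments.

## Numerical conventions

- Rounding is half away from zero, applied at offset estimation,
  provisional-bin naming, and 1-dp presentation; statistics over the
  1-decimal fixture are computed in exact integer tenths (`Fraction`) so
  ties like −3.25 round deterministically to −3.3.
- Coordinates are 0-based half-open throughout.
- Repeat detection considers motif lengths 1–6, requires ≥3 copies and
  ≥6 bp, maximizes run length with ties to shorter motif then leftmost
  start, and reports motifs as their lexicographically least rotation.
- Fisher's exact test is two-sided by hypergeometric-probability summation
  (via scipy); a zero margin returns p = 1.0.

## Problem sizes

The default verification runs use: 10,000 random strings (≤40 bp) for
repeat-finder/oracle equivalence; 10,000 planted-indel pairs for
decomposition conservation and region recovery; every 2×2 table with
margins ≤ 15 for Fisher/enumeration agreement; 100 seeded replicates for
read-genotyper recovery at 40× and for capillary end-to-end identity
recovery; 50 qualifying replicates for the homopolymer failure rate.

## Known limitations

- Primer sequences, per-dye tail lengths and most motifs in the packaged
  panel are synthetic placeholders consistent with the published
  constraints (the appendix with the exact sequences is not
  redistributed); sequence-level analyses against the real GenBank
  references therefore run on mirrored synthetic constructs, and the
  panel's primers should not be used to analyze real data without
  replacement.
- The per-locus offset is a single integer; per-allele sub-bp variation is
  carried entirely by bin centers.  A per-allele offset refinement would
  be the next step if bins drift across instruments.
- Residual ~1 bp capillary-vs-sequencing discrepancies at the two
  FAM-labelled loci are reported as unaccounted; dye-shift correction is
  deliberately out of scope.
- The simplified spanning-read genotyper stands in for HMM-based callers;
  the published QC filter set is implemented verbatim, but stutter-model
  parameters are not comparable to an HMM's.
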