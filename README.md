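# ssrbridge

Cross-platform microsatellite (SSR) allele-size harmonization for grape
phylloxera (*Daktulosphaira vitifoliae*) genotyping.

Phylloxera clonal lineages — the genotypes that drive rootstock choice and
quarantine decisions — are defined by their combinations of SSR alleles
across a standard marker panel (Dvit1–Dvit6, DVSSR3, DVSSR4).  Those
allele *names* were fixed two decades ago on polyacrylamide gels, and the
same biological allele reports a different size on every newer platform:
fluorescent capillary fragments carry a 15–18 bp universal primer tail and
a platform shift of up to 3 bp, while whole-genome sequencing measures the
exact base-pair length, exposing flanking indels and historic scoring
errors that fragment analysis silently absorbs.  `ssrbridge` implements
the full desk-side pipeline for keeping these datasets compatible:

- **panel/IO** — the eight-locus marker panel data model, TSV genotype
  tables, CSV peak tables, FASTA/FASTQ; ships the published
  seven-genotype, three-platform allele-size table as a fixture;
- **capillary calibration** — tail subtraction, control-based integer
  offset estimation, named allele bins with ±1 bp tolerance, pull-up and
  stutter artifact filters;
- **sequence repeat typing** — tandem-repeat detection, primer-based
  amplicon extraction, and a spanning-read genotyper with a geometric
  stutter model and the strict published QC filters (posterior > 90%,
  ≤ 15% artifact reads, ≥ 2 spanning reads, Fisher bias p > 0.01);
- **flank decomposition** — global alignment of observed alleles to the
  original reference clones, left-normalized indels classified by region
  (primer footprint / 5′ flank / repeat / 3′ flank), and the
  amplified-vs-sequenced length arithmetic (PCR restores primer-footprint
  indels; sequencing sees them);
- **cross-platform concordance** — the per-locus and grand mean/SD
  discrepancy table with its explanation ledger;
- **genotype matching** — exact multilocus assignment of calibrated
  profiles to the reference clonal genotypes;
- **synthetic data** — truth-annotated simulators for allele sequences,
  capillary peak tables and stutter-noised reads, so every stage is
  testable end to end without downloads.

## Worked example

Recompute the cross-platform discrepancy table from the packaged
reference genotypes (the `--corrected` flag applies the one documented
transcription correction; see `docs/methods.md`):

```bash
$ ssrbridge concord --corrected
Locus   Alleles (n)  Platforms 1 and 2  Platforms 1 and 3  Platforms 2 and 3
Dvit1   4            +0.0 bp            -2.0 bp            -2.0 bp
Dvit2   3            -3.2 bp            -3.0 bp            +0.2 bp
Dvit3   2            -2.2 bp            -2.1 bp            +0.3 bp
Dvit4   4            -3.3 bp            -2.0 bp            +1.3 bp
Dvit5   7            -3.0 bp            ND                 ND
Dvit6   4            -2.6 bp            -1.0 bp            +1.6 bp
DVSSR3  2            N/A                N/A                -0.1 bp
DVSSR4  4            N/A                N/A                -0.2 bp
Av      30           -2.4 bp (±1.2)     -2.0 bp (±0.7)     +0.2 bp (±1.2)
```

Reading the table: platform 1 is the original polyacrylamide scoring,
platform 2 capillary (tail-subtracted), platform 3 sequencing.  Each cell
is the observation-weighted mean signed allele-size difference in bp —
e.g. capillary sizes at Dvit5 sit 3.0 bp below the historic names, so the
calibration adds +3 bp at that locus; Dvit5's sequencing cells are ND
because its poly-A repeat defeats read-level genotyping; the DVSSR loci
have no measured polyacrylamide history (N/A) but agree between capillary
and sequencing to within 0.2 bp.  The grand rows summarize per-locus
means: capillary needs locus-specific whole-bp adjustments against the
historic scale (−2.4 ± 1.2 bp), while capillary and sequencing agree
almost exactly (+0.2 ± 1.2 bp).

The same from Python, plus calibration and genotype assignment:

```python
import ssrbridge as sb
from ssrbridge.panel import MATCHING_CORRECTIONS

panel = sb.load_marker_panel()
profiles = sb.apply_corrections(sb.load_genotype_table(), MATCHING_CORRECTIONS)
poly = {p.sample_id: p for p in profiles if p.platform == "polyacrylamide"}
cap = {p.sample_id: p for p in profiles if p.platform == "capillary"}

ref = sb.ReferencePanel(profiles=poly)
model = sb.calibrate_from_profiles(cap, ref, panel)
print({n: lc.offset for n, lc in model.loci.items()})
# {'Dvit1': 0, 'Dvit2': 3, 'Dvit3': 2, 'Dvit4': 3, 'Dvit5': 3, 'Dvit6': 3,
#  'DVSSR3': 0, 'DVSSR4': -1}

res = sb.match_profile(sb.calibrate_profile(cap["G4"], model), ref)
print(res.verdict, res.best.genotype, res.best.loci_matching)
# unique_match G4 8
```

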