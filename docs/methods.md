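# Methods

## The dosage model

A competitor-calibrated iPLEX assay measures, for each interrogated
fragment, two MALDI-TOF peak intensities: the genomic template and a
synthetic competitor differing by a single base, co-amplified with the
same primers from a known two-copy-equivalent input. The per-fragment raw
ratio `r = I_temp / I_comp` is therefore proportional to template copy
number and independent of the fragment's amplification efficiency,
extension efficiency and crystallization/ionization behaviour, all of
which multiply both peaks. A second calibration divides by the aggregate
raw ratio of the diploid internal reference fragments (RNaseP, EIF2C1,
ALB) in the same multiplex well, cancelling sample-level input and
well-level reaction effects:

```
TR(T) = r(T) / agg_i r(R_i),    E[TR] ≈ copy_number / 2
```

Assumptions: the reference genes are copy-number-neutral in every sample;
competitor input is matched to two genomic copies; within-well effects are
shared between targets and references; peak intensities are ratio-scale
(positive, multiplicative noise).

### Parameters

| parameter | default | meaning |
|---|---|---|
| `deletion_max` | 0.65 | TR at or below → deletion (inclusive) |
| `duplication_min` | 1.30 | TR at or above → duplication (inclusive) |
| `norm` | `mean` | reference aggregation: arithmetic mean; `median` and `geomean` selectable |
| `min_intensity` | 0 | peaks below this are flagged `low_intensity`; 0 accepts any positive peak |
| `min_fragments` | 1 | minimum run length for a reported event |
| calibration `k` | 5 | cutoffs at mean ± k·sd of diploid-control TR |

The arithmetic mean is the default reference aggregate because it matches
the usual description of double calibration in iPLEX dosage assays; the
choice is exposed rather than hidden since the aggregation is not uniquely
determined by the assay design. Normalization is within-well by default
(references are co-amplified with their well's targets and share its
reaction-level effects); a pooled mode exists for panels without per-well
references. TR is implemented as the ratio-of-ratios above rather than
the allele-fraction form `I_temp/(I_temp+I_comp)` because ratio-of-ratios
makes the copy-number mapping exact (TR = c/2 for noiseless input).

### QC and degenerate inputs

A fragment with a zero competitor peak is uncallable (`missing_peak`); a
reference fragment with a zero template peak cannot report diploid dosage
and is likewise excluded from the normalizer. If every reference in a
well fails QC, that well's targets are flagged `no_reference`; a sample
with no usable reference anywhere raises a structured "uncallable sample"
error. A target with zero template but a valid competitor peak is a
genuine homozygous-deletion signal: TR = 0, called deletion. The public
`call_fragment` rejects non-positive TR values as arguments; the zero-TR
case arises only inside the pipeline where its provenance is known.

### Cutoff calibration

`calibrate_cutoffs` places cutoffs at `mean ± k·sd` of ≥ 20
diploid-control TR values (k = 5 by default: with a diploid TR spread of
≈ 0.05–0.07 this lands near the shipped 0.65/1.30 defaults, which remain
the out-of-the-box cutoffs — calibration is opt-in). When CNV-positive
standards are supplied and the k-rule fails to separate them from the
controls, the cutoff falls back to the midpoint between the controls'
0.1%/99.9% quantile and the nearest standard, provided that midpoint
separates the label sets; otherwise calibration fails loudly, listing the
overlapping values. Returned cutoffs must classify every standard
correctly and satisfy `0 < deletion_max < 1 < duplication_min`.

## Event merging

Within a gene, fragments are ordered by an explicit `order_index` (exon
labels are opaque strings — a large exon may be subdivided, e.g.
`ex11_part3` — so exon number alone cannot order fragments). Maximal runs
of consecutive fragments sharing the same non-normal call form one event;
a deletion run adjacent to a duplication run yields two events; genes are
hard boundaries; a `no_call` fragment splits a run and is surfaced as a QC
gap rather than imputed. Labels: `exon a deletion` (one exon fully
covered), `exon a-b deletion` (full span), `part of exon a deletion`
(strict subset of a subdivided exon); a mixed partial span falls back to
`exon a-b … (partial)`. A sample is CNV-positive iff it carries ≥ 1
event. Single-fragment events are reported by default (`min_fragments=1`);
requiring ≥ 2 concordant fragments is available but not default, since a
single-exon deletion is a real and reportable genotype.

## Simulator

The generator draws, per sample × fragment:

* shared efficiency `a ~ LogNormal(0, σ_eff²)` (default σ_eff = 0.3),
  multiplying both peaks — TR must be invariant to it, which the tests
  verify (the competitor's design property);
* template dosage = true copy number (default 2; 0–4 supported), reduced
  by an allele-dropout fraction δ ∈ [0,1] when the fragment carries a
  primer-site SNV artifact (δ = 1 models complete dropout of one allele;
  the competitor is untouched, as its primer sites carry no variant);
* competitor dosage = 2 always;
* independent multiplicative noise `exp(ε), ε ~ Normal(0, σ_noise²)` on
  each peak (default σ_noise = 0.05, giving a diploid TR spread of
  ≈ 0.07–0.08 including normalizer noise, consistent with ±0.35 cutoffs
  sitting several standard deviations out);
* with probability `missing_peak_prob` the competitor peak is zeroed.

Noise is multiplicative lognormal because peak heights are positive and
ratio-scale. Identical seeds give bit-identical tables. Wells are
simulated independently; real inter-well correlation structure is not
modelled. The simulator does not emulate raw spectra, adduct peaks,
extension chemistry, sample degradation or tumor-content mosaicism —
passing tests demonstrate the calling algebra and its failure modes, not
instrument-level performance on real spectra.

The study-shaped cohort (`make_study_fixture`) contains 293 samples on a
four-well BRCA1/BRCA2 panel (54 target fragments; BRCA2 exon 11 split
into five): 8 true carriers (two BRCA1 exon 1-2 deletions, one exon 1
deletion, one exon 1-2 duplication, one exon 5-10 deletion, one BRCA2
exon 17-18 deletion, two partial BRCA2 exon 11 deletions), 4 artifact
samples with δ = 1 dropout on one fragment each, and 281 plain diploid
samples. At zero noise the pipeline flags exactly the 12 positive-calling
samples, reproducing the assay's confusion structure (8 TP / 4 FP / 281
TN / 0 FN). At the default noise level sensitivity remains 100% across
seeded replicates, while the duplication cutoff sits only ≈ 4 standard
deviations above the diploid TR distribution, so a 293 × 54 batch
accrues a handful of fragment-level duplication false positives — the
zero-noise run, not the noisy one, is the reference condition for the
confusion structure.

## Evaluation

Sample-level scoring is primary (positive = carries ≥ 1 event);
fragment-level mode scores (sample, fragment) keys against true copy
numbers for power studies. Sensitivity = 100·tp/(tp+fn), specificity =
100·tn/(tn+fp); a zero denominator yields an explicit *undefined* marker,
never a silent 0 or NaN. Display values round half-up to one decimal
(281/285 → 98.6) with full precision retained internally.

## Breakpoints and mechanism

Coordinates are HGVS-style `g.<start>_<end>(del|dup)`, 1-based inclusive,
thousands separators tolerated; BED inputs are 0-based half-open; the
single conversion point is `g_to_bed_pos`. Event size is
`end − start + 1`.

Junction homology for a deletion is the number of alternative breakpoint
placements producing an identical mutant molecule, minus one — computed
as the sum of the maximal rightward and leftward junction identity
extensions, and verified in the tests against a brute-force enumeration
of shifted placements. A tandem-duplication junction admits the same
sliding argument, so both kinds share the computation (the duplication
path is exercised only on synthetic constructs).

Mechanism classification: NAHR when homology ≥ 30 bp or both breakpoints
fall in repeat elements of the same family (any Alu subfamily counts as
family "Alu"); NHEJ when homology ≤ 3 bp without repeat support; MMEJ in
between; *ambiguous* when same-family repeat evidence coexists with ≤ 3 bp
junction identity. The 30/3 bp thresholds are configurable: Alu-mediated
NAHR junctions typically show tens of base pairs of identity while
end-joining leaves at most a few, but published mechanism assignments
rarely state numeric criteria, so the defaults are an explicit design
choice rather than a community constant. Repeat annotation takes
RepeatMasker-style BED intervals; a breakpoint inside several intervals is
assigned to the one with the largest overlap with the variant span, then
to the earliest in the file.

Primer screening flags any primer interval containing a variant with
minor allele frequency `min(AF, 1−AF)` above 0.5% (configurable), reading
AF from a VCF INFO field or a plain TSV; variants without a frequency are
skipped and counted in a warning.

## Problem sizes

The default test suite simulates cohorts of ≤ 293 samples × 66 fragments
and verifies the homology computation on 1000 random deletions in random
sequences of ≤ 120 bp; the acceptance script runs the 293-sample cohort
once at zero noise and 20 times at default noise. These sizes exercise
every code path while keeping a full run in the seconds-to-a-minute
range.

## Known limitations

* The TR statistic assumes high-quality germline input; low tumor purity
  or degraded DNA shifts dosages continuously and is out of scope.
* Artifact and duplication calls are statistically asymmetric: on a
  multiplicative scale the 1.30 cutoff is closer to the diploid
  distribution than 0.65, so noisy batches lose specificity before
  sensitivity.
* Panel files do not carry primer sequences or masses; vendor exports
  must be converted to the long-format intensity TSV.
* Mechanism labels are heuristics over homology and repeat annotation;
  they do not substitute for junction sequencing.
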