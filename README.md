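# masscnv

Semi-quantitative copy-number variation (CNV) calling for
competitor-calibrated MALDI-TOF (iPLEX single-base-extension) dosage
assays, built around BRCA1/BRCA2 exon panels.

Large genomic rearrangements — multi-kb exon-level deletions and
duplications — account for a substantial share of pathogenic BRCA1/BRCA2
variants but are invisible to conventional point-mutation PCR assays.
A mass-spectrometric dosage assay interrogates every exon with a
multiplexed PCR + single-base-extension reaction, co-amplifying each
genomic fragment with a *competitor* oligonucleotide (identical but for one
base, same primers, known input copies) and with fragments of three
internal diploid reference genes (RNaseP, EIF2C1, ALB). `masscnv`
implements the data-analysis half of that workflow: Target Ratio
computation, cutoff-based calling, exon-range event merging, cutoff
calibration, diagnostic evaluation, a cohort simulator with known truth,
and breakpoint/mechanism characterization of the resulting rearrangements.

## The dosage statistic

For a target fragment *T* with template and competitor peak intensities
*I*<sub>temp</sub> and *I*<sub>comp</sub>, and reference fragments
*R*<sub>1..k</sub> co-amplified in the same multiplex well,

```
r(f)  = I_temp(f) / I_comp(f)                 (competitor calibration)
TR(T) = r(T) / mean_i r(R_i)                  (reference-gene calibration)
```

The competitor ratio cancels each fragment's private amplification and
extension efficiency; the reference-gene aggregate cancels sample- and
well-level effects. With competitor input matched to two genomic copies,
TR estimates copy number / 2: heterozygous deletions sit near 0.5, diploid
fragments near 1.0, duplications near 1.5. Fragments with **TR ≤ 0.65**
are called deletions and **TR ≥ 1.30** duplications (both boundaries
inclusive); maximal runs of consecutive same-call fragments within a gene
become one event (e.g. `exon 5-10 deletion`, `part of exon 11 deletion`).

The known failure mode of such assays is an SNV under a primer binding
site: it suppresses amplification of one genomic allele but not the
competitor (whose primer sites are identical to the reference sequence),
producing a TR near 0.5 that mimics a heterozygous deletion. The
simulator models this artifact explicitly, and `masscnv primer-check`
screens primer intervals against a population variant table (flagging any
primer containing a variant with minor allele frequency > 0.5%).

## Worked example

```python
import masscnv as m

panel = m.brca_fixture_panel()                     # 4-well BRCA1/BRCA2 panel
df, truth = m.make_study_fixture(seed=0, sigma_noise=0.0, sigma_efficiency=0.0)
res = m.TargetRatioModel(df, panel).fit()
print(res.summary())
```

```
Target Ratio copy-number calling
================================================
Panel:              brca-fixture (54 targets, 12 references)
Samples:            293
Cutoffs:            deletion TR <= 0.65, duplication TR >= 1.3
Normalization:      mean (within-well)
CNV-positive:       12
CNV-negative:       281
No-call fragments:  0
------------------------------------------------
Events:
  S001  BRCA1  exon 1-2 deletion  (n=2, mean TR=0.50)
  S002  BRCA1  exon 1 deletion  (n=1, mean TR=0.50)
  ...
  S011  BRCA2  part of exon 11 deletion  (n=2, mean TR=0.50)
  S012  BRCA2  part of exon 11 deletion  (n=2, mean TR=0.50)
```

The cohort contains 8 true CNV carriers and 4 allele-dropout artifact
samples; the assay flags all 12 as positive. Scoring against truth:

```python
cm = m.confusion(res.status_map(), truth.status_map())
print(cm)                      # ConfusionMatrix(tp=8, fp=4, tn=281, fn=0)
print(m.metrics(cm).display()) # {'sensitivity': 100.0, 'specificity': 98.6,
                               #  'ppv': 66.7, 'npv': 100.0}
```

Sensitivity is 100% (no carrier missed); specificity 98.6% — the four
false positives are exactly the artifact samples, diploid in truth but
indistinguishable from heterozygous deletions at the intensity level.

Breakpoint characterization works from coordinate strings and a reference
sequence:

```python
v = m.parse_hgvs_g("g.61,101_98,034del")
m.event_size(v)                      # 36934
hom, placements = m.junction_homology(v, reference_sequence)
m.classify_mechanism(hom, "AluSx", "AluSz")   # "NAHR"
```

## Command line

```sh
masscnv make-fixture --seed 0 --out-prefix fx            # synthetic cohort + truth
masscnv call --panel fx.panel.json --intensities fx.intensities.tsv --out-prefix out
masscnv evaluate --calls out.calls.tsv --truth fx.truth_samples.tsv --out metrics.json
masscnv simulate --config sim.yaml --seed 42 --out-prefix sim
masscnv breakpoints --ref ref.fa --variant "g.61,101_98,034del" --repeats repeats.bed
masscnv primer-check --primers primers.bed --variants common.vcf --maf-max 0.005
```

Exit codes: 0 success, 1 validation error, 2 I/O error.

### File formats

* **panel.json** — `{"name", "reference_genes", "pooled_normalization",
  "fragments": [{"fragment_id", "gene", "exon_label", "role"
  (target|reference), "well", "order_index" (targets only)}]}`; YAML
  accepted. Every well containing targets must contain a reference
  fragment unless `pooled_normalization` is true.
* **intensities.tsv** — long format, header `sample_id fragment_id
  intensity_template intensity_competitor`, one row per sample×fragment.
* **calls.tsv / events.tsv** — per-fragment TR values and calls; merged
  exon-range events. TR written with 4 decimals.
* **BED** inputs (repeats, primers) are 0-based half-open; coordinate
  strings are 1-based inclusive.

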