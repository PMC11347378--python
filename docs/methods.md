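# Methods

## The screen model

The package models a dual-fluorescence depletion screen in primary
hematopoietic stem and progenitor cells (HSPCs). Cas9-GFP⁺ cells and
wild-type GFP⁻ cells are mixed at a fixed ratio ρ (1:1 for the arrayed in
vitro arm, 3:2 for the pooled transplantation arm), transduced with one
guide per well at efficiency τ (mCherry marks transduction), and read out
either by flow cytometry (in vitro, day 2 and day 7) or by sorting each
reconstituted blood lineage into GFP⁺/GFP⁻ fractions and deep-sequencing the
integrated spacer barcodes (in vivo, eight weeks post transplant). Because
edited and wild-type cells share every well, mouse, and lineage, each
measurement is normalized to its own internal control; the scores are
therefore robust to well-to-well transduction differences and to global
engraftment variation.

### Growth and editing

A transduced Cas9⁺ cell is edited with probability `e` (gene-level editing
efficiency, default 0.9 — the efficiency measured for validated guides in
this system). Editing is applied before the first division; the unknown
editing-time distribution is absorbed into `e` rather than modeled as a
separate delay, which would not be identifiable from endpoint data.

An edited cell's growth is governed by a relative fitness `w ≥ 0`: expected
surviving offspring per division is `2w` (w = 1 neutral, w = 0.5 no net
growth, w = 0 extinction within one division). Over `D` divisions a neutral
subpopulation multiplies by `2^D` and an edited one by `(2w)^D`. Growth noise
is Poisson around this branching-process expectation — at the 10⁴–10⁶ cell
scale of these experiments the full per-cell branching variance is dominated
by the sampling stages, and the Poisson approximation keeps the simulator
effectively instantaneous. Apoptosis is not modeled as a separate channel
(no apoptotic signal is seen in this system); death is absorbed into `w`.

With the defaults (e = 0.9, w = 0.5, D = 5 by day 7), the expected GFP⁺
fraction within the transduced gate is (0.9·1 + 0.1·32)/(4.1 + 32) ≈ 0.114
versus 0.5 in the untransduced gate, giving an expected sur/pro score of
log2(0.114/0.5) ≈ −2.14 — comfortably below the −1 hit threshold, which is
what makes a 3-guide screen at this scale sensitive.

### Stage structure of the in vivo arm

1. **Input library.** Per-guide frequencies are a symmetric Dirichlet draw
   with concentration 150 per guide — chosen so a 45-guide library stays
   within a few percent of uniform, matching the 2–9% per-guide range
   reported for real pooled inputs. Concentrations ≥ 10⁶ short-circuit to
   the exact uniform limit.
2. **Pooling.** Transduced cells from all wells are pooled; the pool is a
   multinomial over (guide × Cas9 status × edited status) with the Cas9
   split ρ and per-gene editing `e`.
3. **Transplantation bottleneck.** Each mouse's graft (5×10⁴ cells,
   3×10⁴ Cas9⁺ / 2×10⁴ Cas9⁻ at the 3:2 mix) is drawn *without replacement*
   from the remaining pool — a multivariate hypergeometric draw, so cell
   counts are conserved exactly and coverage (~500 cells/guide) emerges from
   the design numbers rather than being a separate knob.
4. **Lineage expansion.** Each output lineage expands by a factor `E`
   (default 10³). Calendar time is not modeled: only relative guide
   composition matters to the scores, so eight weeks of reconstitution is
   summarized as `D = log2 E` effective divisions, with edited cells
   expanding `(2w)^D`. `E` is a free parameter because the true in vivo
   division count between transplant and readout is unknown.
5. **Sorting.** Each lineage is sorted into GFP⁺ and GFP⁻ fractions at a
   configurable depth (default 2×10⁴ cells), again hypergeometrically.
6. **Sequencing.** Reads per sorted sample are Dirichlet-multinomial with
   mean proportional to sorted-cell frequencies and concentration `1/ρ_PCR`
   (ρ_PCR = 0 degenerates to a pure multinomial). The default
   ρ_PCR = 10⁻⁴ (concentration 10⁴) gives ~7% per-guide CV at 2% guide
   frequency, consistent with the high replicate correlations such screens
   report; larger ρ_PCR values are available to stress-test scoring. An
   optional FASTQ emitter writes anchored amplicon reads with per-base
   substitution errors for end-to-end tests of the counting stage.

Every simulation can write a *truth fixture* (gene, lineage, w, e) so that
recovery of planted effects is testable without bookkeeping by the caller.

### Division-tracking dye model

For proliferation assays, founder cells are dye-labeled at day 0 and divide
at 1.25 divisions/day (so unperturbed cells reach division 5 by day 4, as
observed for control guides). Edited cells complete one or two free
divisions (a Bernoulli split around a delay of 1.5 divisions, reflecting
editing completing during the first cell cycles) and then continue each
division with probability `max(2w − 1, 0)`; a cell that fails to continue is
arrested at its current dye peak. Histograms report fractions of the *final*
population, so a founder that completed k divisions contributes 2^k cells —
with w = 0.5 the transduced histogram concentrates on divisions 1–2 while
the untransduced histogram is unchanged, reproducing the arrest phenotype
qualitatively. The delay parameter is this package's own modeling choice;
endpoint dye data cannot distinguish it from a continuous editing-time
distribution.

## Barcode counting

Spacer extraction anchors on the fixed vector sequence 5′ of the spacer
(≤ 1 substitution, small offset window) and takes the following 20-mer.
Assignment is exact-match first, then single-mismatch rescue *only when the
nearest library spacer is unique*; equidistant ties are counted as ambiguous
and excluded, as are unassigned reads. The packaged synthetic libraries are
generated with pairwise spacer Hamming distance ≥ 3, which makes Hamming-1
rescue provably unambiguous. Default anchors follow the common U6/scaffold
amplicon design and must be reconfigured for other layouts. Reads are
processed single-end, forward orientation; demultiplexing, adapter trimming
and quality filtering are out of scope.

## Scoring choices

* **Fraction-ratio sur/pro score.** The score is the ratio of within-gate
  GFP⁺ *fractions*, not of raw mCherry⁺GFP⁺/mCherry⁻GFP⁺ event counts: the
  raw-count ratio depends directly on the per-well transduction rate
  (20–60%), which would contradict the observed near-zero day-2 scores for
  every guide. The literal raw-ratio form is available behind a flag, and an
  optional day-2 anchoring mode subtracts the earliest timepoint's score per
  guide.
* **Pseudocount α = 0.5** wherever a log ratio is formed (gate fractions and
  CPM), so all scores are finite by construction. CPM normalization with
  α = 0 raises on an all-zero sample instead of dividing by zero.
* **Gene aggregation** is the mean of the gene's guides (median optional);
  with three guides per gene the mean is the natural low-variance choice.
* **Hit rule**: score < −1 log2 in *every* replicate (replicate-mean mode
  optional); enrichment calls (score > +1) use the mirrored rule and are
  off by default.

## QC

The QC report checks: input-library evenness against the expected band
(default 2–9%); per-sample fraction of guides recovered; GFP⁺/GFP⁻ lineage
ratios against the design mix and the mCherry⁺ fraction against the design
transduction rate (25% relative tolerance); and replicate Pearson
correlations per context. The evenness band is compared at its printed
precision (whole percent): reported ranges like "2–9%" are rounded values,
and a 45-guide Dirichlet-150 library legitimately produces minima of ~1.7%
that round to 2%. The comparison therefore rounds frequencies to whole
percent before applying the bounds.

## Set statistics

Target sets are the genes at or above the nearest-rank 90th percentile of a
binding-score ranking, with ties at the cutoff included (interpolating
quantile definitions were rejected because set membership should not depend
on scores that only shift the interpolated cutoff). Overlap significance is
the one-sided hypergeometric upper tail — the standard Venn-enrichment test;
the universe size must be supplied explicitly because the p-value depends
strongly on it and no default (e.g. "all annotated genes") is defensible
across experiments. Venn region counts are exact for 2–3 sets. Whether a
percentile cutoff should be taken per cell type before a union or on pooled
scores is left to the caller: the operation takes one score map per call.

## Problem sizes and determinism

Simulated checks use 20 seeds per scenario, 10⁴ FACS events per well,
2×10⁴-cell sorts and 5×10⁵-read sequencing depth — the design's own scale,
at which every suite and the acceptance script complete in seconds. All
randomness flows from one root seed through named stage streams
(`stage_rng`), so identical seed + configuration reproduces every output
bit-for-bit while stages remain individually reproducible.

## Known limitations

* A transduced cell carries exactly one guide (infection is kept below 30%
  for this reason); multi-integration is not modeled.
* Engraftment/homing kinetics, immune rejection, and calendar-time dynamics
  are summarized by the per-lineage expansion factor.
* The synthetic libraries carry the real screens' gene panels but synthetic
  spacers; real guide sequences are not publicly deposited.
* Passing tests demonstrate correct recovery of effects *under this
  generative model* (Poisson growth noise, Dirichlet-multinomial sequencing);
  real screens add PCR jackpotting, index hopping and gating drift that the
  generator does not emulate, so QC on real data remains essential.
* No p-value/FDR machinery for hit calling: the fixed −1 log2 threshold with
  replicate agreement is the intended decision rule at 3 guides/gene; rank
  aggregation and copy-number correction are out of scope.
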