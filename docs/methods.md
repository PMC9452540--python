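# Methods

## IsomiR assignment

Reads are collapsed to distinct sequences and assigned by an exact match of
a central motif of each mature miRNA — by default 13 nt starting at
`floor((L − 13)/2)` (0-based) of the mature sequence. Anchoring on the
middle of the read makes assignment insensitive to 5′/3′ end variability
while forbidding internal mismatches. The motif length is configurable;
13 nt keeps the false-anchor probability negligible (4⁻¹³ per position)
while leaving several nucleotides of end slack on a 20–23-nt miRNA.

When motifs of several distinct miRNAs occur in one read, the read goes to
the candidate whose anchored mature sequence disagrees with the read at the
fewest positions; residual ties are counted as ambiguous and excluded from
profiles rather than split fractionally, which avoids double counting at
the cost of slightly undercounting cross-homologous families. Paralogous
loci that produce an identical mature sequence are a single catalog entry
with multiple loci: counts are never split across paralogs, but the
templated-tail check consults every locus. Reads outside 16–35 nt are
counted as filtered. Input is assumed adapter- and UMI-trimmed; qualities
are ignored.

## Tail classification

All coordinates are relative to the annotated mature 3′ end. Walking
3′-ward from the motif along the mature sequence:

* reads that stop at the annotated end with nothing appended are
  **canonical**; reads that stop short are **trimmed**;
* an extension beyond the annotated end that fully matches the downstream
  genomic context at **any** locus is **ambiguous** (templated) — it may be
  a Drosha/Dicer cleavage variant, so it is deliberately kept separate from
  tailing evidence (conservative toward templated origin);
* any other extension is a **non-templated (NT) tail**;
* reads that diverge from the mature body before the annotated end and
  continue are **trimmed + tailed** and count as NT with the post-divergence
  suffix as the tail.

Partially templated extensions (first base genomic, later bases not) count
as NT with the *full* extension as the tail: the templating rule compares
the extension to the genome as a whole. The alternative — crediting the
genomic prefix to the genome and keeping only the post-mismatch suffix —
is available as the `nt_suffix_only` switch, off by default.

Tails longer than `max_tail_len` (default 8 nt; stored context must cover
it, default 20 nt) are flagged and excluded from nucleotide-identity and
category statistics while still counting toward NT prevalence. Observed
tails are short — nearly half are single nucleotides — so the cap loses
essentially nothing and guards against chimeric artifacts.

Tail categories: mono-A/C/G/U; the four A/U dinucleotides (AA, UU, AU,
UA); everything else is mixed. A coarse 3-way label (homogeneous U tail,
homogeneous A tail, Mixed) supports length × identity decompositions.

## Per-condition metrics

Abundance is RPM (reads per million assigned miRNA reads). Per-miRNA
metrics: end-status fractions (partition of the miRNA's reads); NT-tail
percentage; nucleotide identity within NT tails (nucleotide-weighted, so a
UU tail contributes two U); per-letter NT percentages defined as prevalence
× identity; mono-tail rates; abundance-weighted mean read length. Top-N
summaries (default N = 200, optionally split as top N/2 per arm) select
miRNAs by mean RPM across all conditions being compared — the set is fixed
within a comparison — and average per-miRNA percentages **unweighted**
across miRNAs, reported as mean ± standard error over N miRNAs. Replicates
are profiled separately and averaged at the summary level.

The spike-in misread estimator matches reads to spike-in references by an
exact anchor over the first 12 reference positions that are *not* queried
(an anchor overlapping a queried position would silently drop converted
reads and bias the rate low), then reports per position the fraction of
covering reads showing G at a known-A position.

## Differential tailing and regulation

Fold-changes use replicate-pooled counts with a 0.5-read pseudocount;
isomiRs (or miRNAs) below an RPM floor (1 RPM for isomiR tables, 10 RPM
for per-miRNA percentage and abundance comparisons) in every condition are
excluded. Cumulative curves report, per isomiR class (canonical /
ambiguous / NT), the fraction of isomiRs with fold-change ≤ each threshold,
with 25 log2-spaced thresholds in [1/8, 8] by default. Heatmap values are
100 × fold-change capped at 100 (rendered "≥100"); identical conditions
give 100 everywhere.

Percentage fold-changes of per-miRNA NT-U (or NT-A) use an epsilon of 0.05
percentage points to regularize ratios of small percentages. The
enzyme-sensitivity consensus ranks miRNAs by uridylation decrease
(ascending fold-change) in two independent knockout comparisons and
intersects the two top-100 lists. Terminal-nucleotide composition of a
miRNA set is tested per letter against the background frequency with a
two-sided binomial test — a simple calibrated choice where the original
analysis reports composition only. Wilcoxon comparisons use the two-sided
rank-sum (unpaired) or signed-rank (paired) test; no multiple-testing
correction is applied by default since raw p-values are the quantity of
record, with Benjamini–Hochberg available downstream of the returned
p-values.

Regulation calls: a miRNA is consensus **up** (negatively regulated by the
enzymes) when abundance log2FC ≥ +0.2 in every knockout comparison and
≤ −0.2 on rescue; **down** is the mirror. The ±0.2 threshold is symmetric
and inclusive. Whether every rescue or any rescue must revert is
configurable (`require_all_rescues`, default all). An expression floor of
mean RPM ≥ 10 suppresses unreliable calls on lowly expressed miRNAs.

## The simulator

The generator emulates AGO-loaded mature miRNAs and their 3′ modification:

* **expression** — log-normal per-miRNA weights (σ = 1.5), fixed across
  conditions;
* **end heterogeneity** — 5′ trimming (0/1/2 nt with probabilities
  0.85/0.12/0.03) and 3′ offsets (−2…+2 with probabilities
  0.03/0.12/0.75/0.08/0.02); positive offsets are *templated* extensions
  copied from a locus' downstream context and create ambiguous isomiRs;
* **enzymes** — an adenylase (A 0.85, G 0.10, U 0.045, C 0.005; base rate
  0.13), a dominant uridylase (U 0.97; base rate 0.13; substrate bias ×2
  for G-ending, ×0.5 for U/C-ending miRNAs), and a minor uridylase (U 0.97;
  base rate 0.032; arm bias ×3 on 3p, ×0.3 on 5p — a proxy for tails
  inherited from precursor processing, which only 3p miRNAs retain).
  Each enzyme carries per-miRNA log-normal sensitivities (σ = 0.8,
  normalized to mean 1) shared across conditions. Per read, each active
  enzyme contributes rate = base × substrate bias × arm bias × sensitivity;
  the tail event fires with probability 1 − Π(1 − rateₑ) and the enzyme is
  drawn proportionally. Tail length is geometric with P(len = 1) = 0.5,
  capped at 6; letters are i.i.d. from the enzyme's propensity. When no
  uridylase is active the adenylase rate is multiplied by a competition
  factor (2.4), modelling improved 3′-end access;
* **misreads** — position-independent substitutions (default 2×10⁻⁴ per
  base) plus a dedicated A→G channel (default 10⁻⁴), applied after the
  truth labels are recorded.

Base rates and the competition factor were calibrated once so that the
wild-type truth NT fraction sits at ≈0.18 of reads — the regime reported
for AGO-bound miRNAs — and so that the uridylase double knockout maintains
total tailing through adenylation compensation while only the triple
knockout shortens reads. These defaults are calibration aids, not claims;
every parameter is exposed in `ExperimentDesign`.

Each read is emitted with a truth row holding the generative event
(miRNA, offsets, enzyme, appended tail) and the classification labels the
annotated-end rule implies for the constructed read, so pipeline output can
be scored read by read. Determinism: all draws derive from the design seed
via `numpy` seed sequences; a condition × replicate library is
byte-reproducible.

### Controlled recovery designs

Per-miRNA NT probability is only identifiable when an appended tail cannot
coincide with the genomic context: an appended U in front of a downstream U
is, by definition, ambiguous. The recovery design therefore rewrites every
downstream context to start with C, uses a single enzyme that never appends
C, and disables 3′ offsets, making the truth NT probability exactly the
configured per-miRNA tailing probability. The verification then checks that
the measured per-miRNA NT count falls within the 99% binomial interval of
the configured probability for ≥95% of miRNAs at 2×10⁵ reads. The misread
recovery design runs spike-in references through the same generator with
only the A→G channel enabled.

## Verification scope and problem sizes

The verification suite runs entirely on simulated data: oracle equivalence
(assignment against an all-(miRNA, offset) scan; classification against an
exhaustive (locus, split point) enumerator), conservation and partition
invariants, parameter recovery, effect directions on a 200-miRNA,
10⁵-reads-per-library knockout panel with two replicates, terminal-G
enrichment of the consensus sensitive set, planted regulation-call
recovery, and Wilcoxon type-I calibration over 1,000 null draws. These
sizes keep the whole suite around half a minute while leaving per-miRNA
counts in the hundreds-to-thousands range typical of small-RNA libraries.

For the knockout weighted-length check, the double-knockout median delta is
≈0 *by construction* (compensated tailing), so its empirical sign
fluctuates within ±0.01 nt between seeds; the check therefore asserts
"substantial shortening only in the triple knockout" as
median(TKO) < −0.2 nt, median(DKO) > −0.05 nt, and median(DKO) >
median(TKO), rather than the sign of a noise-dominated median.

## What the simulation does not capture

Real libraries add ligation and PCR biases, UMI structure, adapter
artifacts, quality-dependent error profiles, cross-mapping among miRNA
families with shared central motifs, SNPs/editing (internal mismatches are
discarded here, not modelled), and pre-miRNA-level regulation (the LIN28
axis, precursor degradation kinetics). Tails are applied only to mature
reads; precursor-inherited 3p tailing is approximated by an arm-biased
enzyme rather than hairpin simulation. Passing recovery tests therefore
demonstrates correctness of the measurement machinery under the stated
generative model, not robustness to library chemistry. The original
study's printed numbers derive from its deposited sequencing libraries;
reanalysis of those accessions is supported by the same pipeline
(FASTQ/collapsed-FASTA input, miRBase-style references) but is not part of
the desk-scale verification.
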