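# Methods

## Library model

A site-saturated library is defined by a reference coding sequence, an
inclusive residue range (default 50–134, i.e. 85 positions), and a codon
alphabet allowed as substitutions at each position (default: all 64 codons;
NNK available by name, or any explicit codon list). Residue numbering is
that of the precursor protein, so variant names like `A55K` index codons of
the CDS directly. Every (position, alternative codon) pair with the
alternative differing from the reference codon is one codon variant; codon
variants are classified at the amino-acid level by standard-genetic-code
translation into synonymous, missense, or nonsense, and counts are
aggregated over synonymous encodings of the same residue variant before
scoring. Reference codons inside the saturated range may not be stop
codons.

The shipped default CDS (`synthetic_rcsf_cds`) is a **synthetic stand-in**:
the residues named in the motivating mutant analyses (the lipidated Cys16,
Thr53, Ala55, Gly60, Pro62, Arg64, Cys74, Asn78, His107, the
Cys109/Cys118/Cys124 disulfide partners, Ser127, Thr132) are pinned at
their published positions so that the corresponding variant names exist in
the default library; all other residues are arbitrary but fixed. Analyses
of real data should supply the real CDS via the library JSON.

## Read assignment

Reads are assumed trimmed to the saturated region. A read identical to the
reference is wild type; a read differing at exactly one codon whose
alternative codon is in the alphabet is that codon variant; everything else
is rejected with a reason code (length mismatch, ambiguous base, codon not
in alphabet, ≥2 differing codons). The single-mutant rule reflects the
library's construction — one mutated codon per molecule — so multi-codon
differences indicate sequencing error or template recombination and are
never partially assigned. No base-quality model is applied; pre-tabulated
count tables are accepted as an alternative input. Strand orientation is
the caller's responsibility (`revcomp` flag).

The per-sample `total_reads` recorded in the table is the normalisation
denominator. When counting from FASTQ it equals assigned + rejected reads;
when counts are supplied pre-tabulated, whatever total the table records is
used as-is.

## Enrichment scoring

Read fraction: `f = reads_sum / total_reads`. Per replicate pair,
`log2FC = log2(f_sel / f_ctrl)`. Dropout floor: selected fractions below
`floor_reads / total_sel` (default `floor_reads = 2`) are raised to that
floor and flagged. The floor is interpreted as a detection threshold, so a
single read — below the threshold — is floored to 2 as well; this makes the
per-replicate score exactly `log2((max(c_sel, 2)/N_sel) / (c_ctrl/N_ctrl))`.
The floor uses each replicate's own total. Variants with zero control reads
in a given replicate contribute no score in that replicate (NaN, excluded
from the mean); variants with zero control reads in *every* replicate are
emitted with a `control_dropout` flag and no score, and are excluded from
hit calling — flooring the control side would manufacture large apparent
enrichments from absence of evidence.

Replicate combination: arithmetic mean of the finite per-replicate scores
(default), or `combine="pooled"` — counts summed over replicates first,
one log2 ratio, floor applied to the pooled selected count. The mean is
symmetric and standard for enrichment screens; the pooled mode exists
because published per-variant tables do not always state the combination
rule.

## Hit calling

* Enriched: missense variants with combined log2FC ≥ cutoff (default 1.0).
  Synonymous and nonsense variants are reported in class statistics but are
  never hits.
* Depleted: missense variants at or below the **upper Tukey fence**
  (q3 + 1.5·IQR) of the nonsense-class log2FC distribution. The nonsense
  class is the empirical "no signaling" reference; a value drawn from that
  distribution itself lies inside the fence with probability ≈0.996 under
  normality, so genuinely nonsense-like variants are recovered essentially
  always while clearly functional variants (far above the fence) are not.
  A stricter `median + 0.5·IQR` rule is available (`rule="median_iqr"`),
  but note that by order statistics alone it rejects ~25–30% of values
  drawn from the reference distribution itself, which is hard to reconcile
  with "indistinguishable from nonsense"; it is therefore not the default.
  The rule and its parameters are recorded in output metadata.
* Codon summary: hits grouped by position; a position is `proline_only`
  when every hit substitution there is proline.
* Cross-screen filter: depleted set minus proline substitutions minus the
  inner-membrane screen's hit set.

## Group statistics

Quartiles use linear interpolation between order statistics
(`numpy.percentile`, default mode). The one-way ANOVA F across variant
classes is `scipy.stats.f_oneway` (between-group over within-group mean
square; F = 0 for identical groups, +inf when within-group variance is
zero). Pairwise comparisons are Welch t-tests of each class against a
reference class (default synonymous) with Bonferroni adjustment. ANOVA
requires every present class to have ≥2 scored members and at least two
such classes.

## Simulator

The generator emulates the three screen designs:

| screen | selection | fitness map | G | inoculum |
|---|---|---|---|---|
| LOF_IM | signaling toxic under lipoprotein-transport depletion | w = 1 − s_tox·min(a, 1), s_tox = 0.9 | 11 | 1e5 cells/mL |
| GOF_OM | growth on lactose ∝ reporter expression | w = w0 + k·a, w0 = 0.2, k = 0.8 | 11 | 1e5 cells/mL |
| LOF_OM | same map, shorter outgrowth | w = 0.2 + 0.8·a | 6 | 1e7 cells/mL |

Activities `a` are abstract signaling levels: WT and synonymous variants
have a = 1; nonsense variants a = 0, except truncations at the two most
C-terminal library positions, which keep a = 1 (removing the last residues
leaves a functional protein). Missense activities come from a
neutral-majority mixture — point mass at 1 (probability 0.75), a
loss-of-function tail uniform on (0, 0.6) (0.20), a gain-of-function tail
uniform on (1.2, 2.0) (0.05) — chosen so that most substitutions are
tolerated, a substantial minority impair signaling, and strong activators
are rare, as in typical saturation screens of a signaling domain; planted
effects override any default. `s_tox = 0.9` makes WT signaling near-lethal
under the toxicity selection without driving growth exactly to zero;
`w0 = 0.2` gives signaling-null cells low but nonzero growth on lactose
(basal reporter leakage), with w = 1 for WT at a = 1.

Control cultures have w = 1 for every variant. Growth is deterministic
exponential doubling over G generations, computed in log space (no
overflow, exact frequency ratios); there is no death term, lag phase, or
carrying-capacity kinetics — saturation is represented by stopping at G.
Stochasticity enters twice per culture: a multinomial founder draw of
inoculum_density × 10 mL cells from the (uniform by default) library pool,
and a multinomial sequencing draw at the configured depth (default 10⁶
reads/sample). Replicate random streams are spawned from the master seed,
so identical configurations give byte-identical output tables.

What the generator does **not** model: PCR jackpots and amplification
noise, codon-level sequencing error (counts are produced at amino-acid
resolution; a codon-resolved mode would split frequencies uniformly over
encodings), strand artefacts, variable per-sample depth, fitness
interactions between variants, and — importantly — any distinction between
inner- and outer-membrane signaling: activity is one scalar, so a variant
defective at the OM is equally defective at the IM. Passing tests therefore
demonstrate that the analysis recovers planted effects under multinomial
sampling noise, not that it is robust to the full error structure of real
amplicon data, and the cross-screen candidate set is typically empty under
defaults unless screen-specific activity profiles are supplied.

With deterministic fractions the pipeline satisfies
`log2FC_i − log2FC_j = G·(w_i − w_j)` exactly; the test suite verifies this
to 1e-9 relative error and uses it as the simulator's analytic anchor.

## Problem sizes and runtime choices

The default library (85 positions × 63 alternative codons → 1777 amino-acid
variants) at depth 10⁶ with triplicate cultures simulates and scores in
well under a second, so tests and the acceptance script run the full design
rather than a scaled-down one. The planted-recovery analysis uses 150
planted missense activities uniform on (0.1, 2.0) under the 6-generation
design, where depleted variants stay above the dropout floor and rank
recovery is informative across the whole activity range.

## Known limitations

* The depletion rule is an operationalisation; the underlying publications
  typically judge "indistinguishable from nonsense" visually. Both provided
  rules are configurable and recorded in outputs.
* Whether published per-variant scores are replicate means or pooled-count
  ratios is often unstated; both are implemented (mean is the default).
* The enrichment cutoff is applied to the combined score, not per
  replicate, matching one-number-per-variant reporting.
* FASTQ ingestion assumes trimmed, full-region, single-orientation reads;
  adapter trimming, paired-end merging and quality filtering are upstream
  concerns.
* Reporter and band normalisations are ratio utilities on measured values;
  no densitometry is performed. Replicate summaries default to mean ± SD
  (n−1); SEM is available.
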