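# Methods

## Sequon model

A predicted N-glycosylation site is the tripeptide consensus N-x-Z with
x ≠ proline, where Z names the motif class: S or T (canonical), C (part of
the quoted consensus but weakly evidenced), or V (proposed). Only the
x ≠ P constraint is enforced; no constraint is applied at the +2 residue
beyond the class letter itself, and proline at +3 does not disqualify a
site. An unknown residue `X` at any of the three positions disqualifies
the site, since a sequon cannot be asserted from unknown residues.
Coordinates are 1-based and index the Asn, matching conventional
protein-site reporting (e.g. "N227"). Overlapping sequons (as in `NNSS`)
are each reported. NxS/NxT is the default class set; NxC/NxV are opt-in
because their presence alone is weak evidence of surface N-glycosylation —
the enrichment module exists to make that contrast measurable.

## Canonical-isoform correspondence

Splice-event coordinates are not recoverable from two protein sequences,
so coordinate correspondence is computed by global (end-to-end) pairwise
alignment: BLOSUM62, affine gaps with open 11 / extend 1 (first gap
residue −11, each further residue −1), via Biopython's `PairwiseAligner`.
Among co-optimal tracebacks the aligner's first enumeration is taken;
this is deterministic for fixed inputs, which is what reproducibility
requires — the specific tie-break convention is otherwise immaterial
because ties only arise in repeat regions where no convention is
biologically privileged.

Classification operates on Asn coordinates only:

* **retained** — the canonical Asn aligns to the *same absolute* isoform
  coordinate and a valid sequon exists there;
* **shifted** — a valid sequon exists at a *different* aligned coordinate;
* **lost** — the Asn falls in an alignment gap, or the aligned position no
  longer completes a sequon (e.g. the x position became proline);
* **gained** — an isoform sequon whose Asn is not matched by any
  canonical sequon.

The x and +2 residues may differ under retained/shifted as long as a valid
sequon exists at the aligned Asn: sites are identified by their Asn.
Terminal truncations are handled by the global alignment's end gaps.
Every sequon of both sequences appears in exactly one classification, so
per pair retained + shifted + lost equals the canonical sequon count —
this conservation identity is asserted in tests for every simulated pair.

Summaries count sites per canonical-isoform pair (`total_differing_sites`
= shifted + lost + gained over pairs, i.e. a site×isoform tally) and also
report a deduplicated site count and protein-level tallies deduplicated by
canonical id, since both conventions appear in practice when multiple
isoforms per canonical exist.

## Surface annotation

SPC (surface prediction consensus) scores are integers 0–4 consumed from
a user-supplied table; 3–4 is the high-confidence surface set. Missing
genes are marked missing and excluded by the filter rather than scored 0,
because score 0 is not evidence of intracellular localization
(GPI-anchored and extracellular-matrix proteins also score 0). Gene
symbols match exactly first, then case-insensitively. Topology
annotations (TM counts, signal peptides) are consumed from an external
predictor's output, never computed.

## Motif enrichment null

The null preserves what composition-based confounding would otherwise
fake: each protein's own length and residue composition. Every
permutation shuffles each sequence's residues uniformly; the expected
count is the permutation mean and the p-value is two-sided empirical with
add-one correction, p = (1 + #{|c_b − E| ≥ |obs − E|}) / (B + 1), which
never returns 0. An i.i.d. closed form,
E = Σ_seqs (L−2)·f_N·(1−f_P−f_X)·f_Z, is provided alongside and is used in
tests as the independent check (the without-replacement exact form
(L−2)·n_N·n_Z·(L−2−n_P)/(L(L−1)(L−2)) arbitrates the permutation mean on a
single sequence). Calibration is verified empirically: under the null the
rejection rate at α = 0.05 sits near 4% across 500 datasets — slightly
conservative, as expected for a discrete two-sided statistic with ties.

Set membership for the surface-vs-intracellular contrast is SPC ≥ 3
versus SPC = 0; a GPI/ECM exclusion list can be supplied for the
intracellular set (default empty).

## Differential expression and volcano gates

The significance call under study is threshold-level — raw p < 0.05
together with |log2FC| > 4 against the day-15 reference — so the test is
deliberately simple and fully in-package: Welch's two-sided t-test on
log2(count + 1) across replicates, fold change from group means,
log2FC = log2(mean_day + c) − log2(mean_ref + c) with pseudocount c = 1.
Genes with fewer than 10 total counts are excluded before testing
(expression floor). No multiple-testing correction enters the significance
flag (a BH-adjusted column is emitted for users). Groups with fewer than
two replicates, or with zero variance in both groups, get a missing
p-value and are never called significant — a zero-variance "p = 1" would
manufacture confidence from degenerate data.

Library-size (CPM) normalization is available (`VolcanoConfig.cpm`) but
off by default: the fold-change gate is defined on the count scale, and
when library composition shifts between days (e.g. strong planted or real
fold changes in a nontrivial fraction of genes), CPM rescales every
gene's fold change — a 16-fold change at 10% affected genes measures as
roughly log2FC 2.7 after CPM — and contaminates null genes with the
compensating shift. Users comparing libraries of genuinely different
depth should enable it knowingly.

Power at the gate boundary: an effect of exactly 16-fold has true
|log2FC| = 4, sitting *on* the > 4 gate. With three replicates the
estimator is approximately normal around 4, so each day-versus-reference
comparison passes the gate about half the time, and across the three
comparisons (which share the reference group's noise) total detection is
capped near 3/4. This is a property of thresholding at the effect size,
not of the test; effects clearly above the gate (32-fold) are recovered at
≈99% with ≤1% of null genes flagged.

Evidence profiles max-normalize replicate-averaged transcript counts and
raw PSM spectral counts (no length normalization — spectral counts are the
semi-quantitative unit) to [0, 1] per protein per modality; an all-zero
profile is marked undetected rather than divided by zero. Concordance is
the sign of the Spearman correlation over shared timepoints (missing below
three timepoints), with a discordance flag when one modality is
undetected while the other exceeds a floor — the signature of proteins
seen robustly by only one technique.

## Synthetic data

The generator emulates the study design: canonical proteomes (default 300
proteins in the analysis scripts; lengths ~N(400, 120²) truncated at 50;
uniform residue composition unless a table is supplied; NxS/T sequons
planted at 0.005 per residue on top of the composition's natural rate),
splice isoforms (one event each, drawn from internal deletion 0.4 /
insertion 0.2 / terminal truncation 0.2 / segment substitution 0.2, sizes
6–45 residues), negative-binomial counts for days 15/30/45/60 in
triplicate (per-gene baselines lognormal around mean 200, dispersion 0.1,
a configurable fraction of genes with a planted fold applied to all
post-reference days), PSM tables with late-onset detection (25% of
proteins undetectable before a random onset day), and SPC scores drawn
from a distribution weighted toward 0 with ~25% high-confidence mass.
All generators are pure functions of (config, seed); byte-identical
reruns are asserted in tests.

Ground-truth sequon labels come from the known event coordinates, not
from alignment, giving an alignment-free oracle for the classifier. A
label is flagged *ambiguous* when its triplet lies within three residues
of a gap junction — where co-optimal alignments can slide — and, for
segment substitutions, anywhere inside the substituted window, because a
random-vs-random residue window can admit gappy co-optimal realignments
that break the identity mapping. At default settings ~2% of labels are
ambiguous; the classifier matches the oracle on 100% of unambiguous
labels and >99.9% overall.

What the generator does **not** emulate: real amino-acid composition
bias, homology and repeat structure (which would raise alignment
ambiguity), frameshift consequences of splicing beyond terminal
truncation, nonsense-mediated decay, correlated gene-gene expression, or
MS detectability physics. Passing tests therefore demonstrate that the
machinery is correct and calibrated under known conditions, not that
real-data classifications are error-free where alignments are genuinely
ambiguous.

## Numerical and degenerate-input choices

* Empty sequences, duplicate ids, isoforms without a canonical parent,
  negative counts, invalid SPC scores, and event/probability configs that
  do not normalize are rejected with errors, not coerced.
* `'*'` stop characters in FASTA input are stripped with a warning.
* Sequon scanning of a sequence shorter than 3 residues returns no sites;
  closed-form expected counts treat L < 3 as contributing 0.
* An enrichment expected count of 0 reports a missing ratio rather than
  dividing by zero.
* All randomness flows from explicit seeds; independent generator streams
  are derived per stage so stages can be rerun in isolation.

## Problem sizes in tests and the acceptance script

Tests exercise 1000 random sequences for scanner-oracle equivalence, 500
simulated pairs per splice-event type for classifier recovery, 500
datasets × 199 permutations for enrichment calibration, and 5000-gene
count matrices for volcano calibration; the acceptance script uses 200
pairs per event type and 300 calibration datasets. These sizes hold the
Monte-Carlo error of every reported rate well inside the asserted bands
while keeping the full run in the tens of seconds.
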