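# Methods

`cubkit` analyzes codon usage bias in sets of viral coding sequences
stratified by host of origin. This note records the statistical models the
package implements, the defaults and why, what the synthetic generator does
and does not emulate, and the numerical conventions at the edges.

## Input model

A corpus is a set of in-frame CDSs (one FASTA record per coding region per
isolate) joined to an isolate metadata table (id, accession, host,
recombinant flag). Validation enforces: length a positive multiple of 3, no
characters outside A/C/G/T after U→T normalization, no internal stop in
frame 0. A single terminal stop is trimmed and never counted. The length
check runs before ambiguity handling, so an out-of-frame record is reported
as a frame error even if it also contains ambiguity codes. The default
ambiguity policy drops whole codons containing non-ACGT characters and
records the dropped count per sequence (`reject_record` is available);
codon-level dropping keeps the remaining codons in frame, which is what
every downstream statistic needs. Recombination *detection* is out of
scope: recombinant status is an input flag, and the grouped analyses run on
the non-recombinant subset by default because recombination mixes codon
signatures from different donor backgrounds.

Internally everything is DNA-alphabet; tables that mirror the conventional
RNA spelling of codons (the RSCU matrix) convert T→U at the presentation
layer only.

## Statistics

**Composition.** Overall A/C/G/U(=T)%, AU%, GC% over the full trimmed CDS;
A3/C3/G3/U3 and GC3 over third codon positions; GC1/GC2 over positions 1
and 2; GC12 = (GC1+GC2)/2 exactly. Group summaries report the unweighted
mean over sequences and the sample SD (n−1 denominator), labelled as such;
singleton groups get SD 0 plus a flag. Pooled, length-weighted aggregation
is deliberately not the default: sequences, not nucleotides, are the
sampling units in a host-stratified comparison.

**Dinucleotide relative abundance.** ρ(xy) = f(xy)/(f(x)·f(y)) with
observed dinucleotide frequencies from all overlapping positions within
each CDS (pairs never span record boundaries) and mononucleotide
frequencies from the same sequence. ρ(CG) ≪ 1 is the classical CpG
suppression signal. Frame-restricted modes (positions 1–2, 2–3, and the
3–1 bridge between codons) are provided because bridge-position CpG is the
mutable fraction under synonymous change. ρ is flagged undefined, not 0,
when a mononucleotide is absent.

**Codon pair score / bias.** For consecutive codons A,B encoding amino
acids x,y:

    CPS(AB) = ln [ F(AB) · F(x) · F(y) ] / [ F(A) · F(B) · F(xy) ]

with all F terms raw counts over the analyzed corpus itself (the count
scale cancels in the ratio). Conditioning on the amino-acid pair separates
codon-pair preference from amino-acid-pair preference. No external
reference corpus is used — expected pair frequencies come from the same
corpus, the only option when no host mRNA reference is supplied; the
formula is stamped into the run manifest. Per-sequence CPB is the
unweighted mean CPS of that sequence's consecutive pairs; the corpus CPB
is the unweighted mean over sequences. Pairs with zero expected count are
flagged and excluded, with the exclusion count reported. Met and Trp
codons participate (the statistic conditions on amino acids, not on
synonymous families); stop codons cannot occur in validated CDSs.

**RSCU.** Counts are taken over the 59 informative codons: the three stops
and the single-codon amino acids Met (ATG) and Trp (TGG) are excluded,
leaving 18 families (nine 2-fold, Ile 3-fold, five 4-fold, Leu/Ser/Arg
6-fold). RSCU_ij = n_i·g_ij/Σ_j g_ij. A family with zero observations is
undefined — reported as NaN, never 0, since 0 would assert active
avoidance. Representation classes use strict inequalities: RSCU > 1.6
over-represented, < 0.6 under-represented, boundaries inclusive-neutral.
Group-level RSCU pools codon counts per group and then computes one RSCU
(the standard heatmap treatment — one value per host×region cell), rather
than averaging per-sequence RSCUs.

**ENC.** Wright's estimator. Per family with n ≥ 2 observations,
F = (nΣp̂² − 1)/(n − 1); ENC = 2 + 9/F̄₂ + 1/F̄₃ + 5/F̄₄ + 3/F̄₆ with class
means over usable families. Six-fold amino acids are single families
(matching the 59-codon/18-family framing); a 2+4 split is not implemented.
Repairs: a missing 3-fold class mean (Ile unobserved or a single count) is
replaced by (F̄₂+F̄₄)/2; any other missing or zero class mean makes ENC
undefined (NaN, with the class diagnostics retained) rather than infinite.
Finite-sample excursions above 61 are clamped to 61 and flagged. The
theoretical range is 20 (one codon per family) to 61 (uniform usage).
Composition-corrected variants (ENC′) are out of scope.

**ENC-plot.** Observed ENC against s = GC3 (proportion scale), with the
mutation-only null curve ENC_exp(s) = 2 + s + 29/(s² + (1−s)²). The
relative deviation (expected − observed)/expected is emitted per point;
positive deviations (points below the curve) indicate forces beyond
composition, conventionally translational selection.

**PR2.** x = G3/(G3+C3), y = A3/(A3+T3) over the assessed third positions.
Default site policy restricts to the eight codon boxes whose third
position is fully synonymous (the five 4-fold families plus the 4-fold
sub-boxes of Leu/Ser/Arg) — the classical parity formulation, since only
fully degenerate sites make the mutation-equilibrium prediction A=T, G=C
cleanly. An `all`-third-positions mode is provided and the policy used is
stamped on outputs. A zero denominator yields an undefined coordinate with
a flag.

**Neutrality plot.** Ordinary least squares of GC12 on GC3 across
sequences ([0,1] scale internally; ×100 for plots), with Pearson r and its
exact two-sided p-value (t-transform, n−2 df; no multiple-testing
correction). The force partition is mutation% = |slope|·100 and
selection% = 100 − mutation%, summing to 100 exactly. Note one published
analysis of this virus pairs a slope of −0.136 with a mutation pressure of
14.6%; the arithmetic rule gives 13.6%, and this package implements the
rule rather than matching the printed figure. Fits need ≥ 3 sequences and
nonzero GC3 variance; otherwise they are flagged undefined.

**CAI.** Sharp–Li relative adaptiveness from a host codon usage table
(Kazusa/CUTG counts or per-thousand — the scale cancels in the
within-family ratio): w = usage/max usage per family, so max w = 1 in each
family. Codons the host never uses get a floor w = 0.01 (configurable,
stamped in the manifest) instead of 0, which would zero the geometric mean;
an entirely unused family is an error. CAI = exp(mean log w) over a gene's
scored codons (Met/Trp/stops excluded, consistent with the 59-codon set);
log-space computation makes 10k-codon genes safe from underflow. Host
ranking orders reference hosts by mean CAI over all sequences, ties broken
by host name. Whole-organism Kazusa tables are used as-is; no
expression-weighted reference set is constructed, and no eCAI significance
testing is offered.

## Synthetic corpora

The generator produces in-frame, stop-free CDS corpora organized as
pseudo-isolates × coding regions. Defaults mirror the host-stratified
study design the package targets: 46 isolates (18 "citrus" / 26
"Actinidia" / 2 "Malus") × 3 regions, 500 codons per CDS, uniform
amino-acid composition over the 18 scored amino acids (an A/U-rich
preference preset is included for demos).

* **selection** regime: one preference table per corpus (given explicitly,
  or drawn per family from a symmetric Dirichlet whose concentration sets
  bias strength — smaller ⇒ sharper preference ⇒ lower ENC); every
  sequence draws codons i.i.d. from it.
* **mutation** regime: each sequence gets its own GC bias g ~
  Uniform(0.3, 0.7); nucleotides are i.i.d. with P(G)=P(C)=g/2,
  P(A)=P(T)=(1−g)/2 (Sueoka's mutation-equilibrium picture, applied
  strand-symmetrically), and stop codons are redrawn. Renormalizing the
  61-codon distribution is exactly the per-codon rejection scheme; it
  perturbs realized composition slightly, which the recovery tolerances
  absorb.
* **mixed** interpolates the two codon distributions with a weight.

CpG suppression multiplies the probability of any codon choice creating a
CG — inside the codon or across the junction with the previous codon — by
a factor in (0,1] and renormalizes, making the draw a Markov chain on the
previous codon's final base.

Determinism: every sequence's substream is seeded by (corpus seed, isolate
counter, region index), so corpora are bit-reproducible and independent of
generation order.

**What the generator does not emulate**, and hence what passing recovery
tests do not show about real data: phylogenetic correlation between
isolates (sequences are i.i.d. given the regime — real isolates share
ancestry and their effective sample size is smaller), amino-acid
composition differences between genes, within-sequence heterogeneity
(domains, structural RNA elements), and genuine host-specific tRNA-pool
selection. Recovery tests validate the estimators, not the biology.

A note on the selection regime and the neutrality slope: because one
codon's bases contribute to GC12 and GC3 of the same sequence, per-sequence
GC12 and GC3 covary even with a fixed preference table, and the regression
slope converges to a small preference-dependent constant (spread ≈ ±0.1
across Dirichlet draws) rather than exactly 0. The seeded recovery checks
therefore fix the corpus seed; "slope near zero under selection" is an
ensemble-level statement, not a per-corpus identity.

## Problem sizes and numerical conventions

Recovery experiments run at 200 sequences × 500 codons (neutrality and
PR2), 67 × 500 (≈100 kb, CpG odds), and pooled 10–20k codons (RSCU/ENC
convergence) — sizes at which the binomial sampling bands are a few
percent and the whole suite completes in seconds. Oracle-equivalence
checks compare against brute-force recomputations at 1e-9 relative (1e-6
for ENC, whose class-repair path accumulates a few more roundings).
Statistical assertions on random draws use 4σ CLT bands at the stated
sizes. Floats in TSV outputs are fixed at 4 decimals so repeated runs are
byte-identical; every run writes a JSON manifest recording the config,
formula variants, and thresholds that produced it.

## Known limitations

* ENC′ (background-composition-corrected ENC), codon-pair deoptimization
  design, and dN/dS-based selection tests are not implemented.
* CAI reproduction against published host rankings depends on the exact
  Kazusa table version per host; the package takes the supplied tables as
  ground truth.
* The per-sequence CPB of short sequences averages few pairs and is noisy;
  corpus CPB is the stable summary.
* One reported usage contradiction in the motivating system (whether Cys
  prefers TGT or TGC in the citrus polyprotein group) is a property of the
  external data, not resolvable here; the package simply reports per-group
  RSCU.
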