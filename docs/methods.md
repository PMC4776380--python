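# Methods

This note describes the models and procedures `effectorkit` implements,
the assumptions behind them, the parameters that matter, and the
numerical choices made where the design was genuinely open. It states
no empirical result that the test suite or `scripts/acceptance.py` does
not itself compute.

## Differential expression

**Normalisation.** Between-library scaling uses the trimmed mean of
M-values (TMM). The reference library is the one whose upper quartile
of depth-scaled counts lies closest to the mean upper quartile. For
each other library, per-transcript log-ratios M and log-abundances A
are computed against the reference over transcripts non-zero in both
libraries; the most extreme 30% of M on each side and 5% of A on each
side are trimmed, and the surviving M-values are averaged with
inverse-approximate-variance (delta-method binomial) weights. Factors
are rescaled to geometric mean 1. Because the precision weights retain
a weak dependence on absolute depth, the factors are invariant to
global depth rescaling of a library only to ≈0.1% — a property shared
by any inverse-variance-weighted TMM.

**TMM-FPKM.** FPKM = count × 10⁹ / (effective library size × transcript
length in bp), with effective size = column sum × TMM factor.

**Exact test.** Counts are equalised to the geometric-mean effective
library size and summed within tissue. A single common NB dispersion φ
is estimated by method of moments with a ratio-of-sums estimator,
φ̂ = Σ(v − m) / Σ m² over per-tissue sample moments (floored at 0) —
stabler than averaging per-transcript ratios at 3 replicates.
Conditional on the two group totals' sum T, the head total follows a
negative hypergeometric law with sizes nᵢ/φ, independent of the common
mean; at φ = 0 this degenerates to Binomial(T, n₁/(n₁+n₂)). The
two-sided p-value sums conditional probabilities of all outcomes no
more probable than the observed one. Calls are made at raw p < α
(default 0.001) with direction from the sign of the log₂ fold change;
no fold-change floor and no FDR correction are applied. Ties at p = α
are not called. All-zero transcripts report p = 1, not-significant.

This is a deliberate, documented simplification of the full
quantile-adjusted conditional ML machinery of dedicated DE packages:
with a raw-p threshold, a common dispersion, and three biological
replicates per tissue, the conditional exact test reproduces the
operating characteristics that matter here — the acceptance suite
verifies the type-I rate at p < 0.001 sits inside its binomial 99%
confidence band on a 10,000-transcript null, and that 8-fold-biased
transcripts at mean 500 are recovered with recall ≥ 0.95.

## Effector classification

A transcript is a *putative effector* when head-upregulated, with a
predicted signal peptide and no transmembrane domain; body-upregulated
secreted transcripts are *other secreted proteins*; everything else
(including secreted-but-TM) is unclassified. "Upregulated" means the
exact-test direction only. Secretion/TM/NLS/Pfam/database-hit
annotations are consumed as inputs — the package never runs predictors.
ORF completeness is classified from start/stop codon presence
(complete / 5′-partial / 3′-partial / internal). Repeat motifs are
counted greedily left-to-right, non-overlapping, with a configurable
per-occurrence substitution allowance (an overlapping mode exists
behind a flag); the longest run of back-to-back matches is reported
because tandem copy number is the biologically meaningful quantity for
repeat-bearing effectors such as C002.

## Similarity clustering

Edges with e-value ≤ 1e-35 enter an undirected graph weighted by
−log₁₀(e-value); an e-value of exactly 0 maps to weight 200 (the
standard stream-transform convention for e-value-weighted graphs).
Reciprocal hits merge keeping the larger weight; hit-less sequences
enter as singletons.

Markov clustering is implemented directly: self-loops at each node's
maximum incident weight (1 for isolated nodes), column normalisation,
then repeated expansion (matrix squaring), inflation (entrywise power,
default 6, renormalised) and pruning of entries below 1e-5, until the
largest entry change falls below 1e-8 or 200 iterations (a
non-convergent run is interpreted as-is with a warning). Clusters are
read off the attractor structure: rows with nonzero diagonal are
attractors, attractors sharing column support form cluster cores, and
each node joins its attractors' component; the rare overlapping node
joins the component containing the lexicographically smallest attractor
id, keeping the output deterministic. Prune threshold, tolerance and
iteration cap are desk-scale numerical choices; inflation 6 and the
1e-35 edge threshold are the pipeline's operating point. The
implementation is cross-checked against an independently coded
reference MCL on small fixtures and random graphs.

*Core* clusters contain a candidate effector and are represented by at
least 5 of the 8 aphid datasets (outgroup datasets do not count).
*Pioneer* clusters contain a candidate effector, every member lacks
both a database hit at e-value ≤ 1e-5 and a Pfam-A domain, and the
members' datasets are confined to a single species or genus (a supplied
genus mapping decides this). Published candidate-effector id lists may
be supplied as plain-text files to widen the effector flag.

## RBBH orthology

Per ordered dataset pair, a query's best hit is the highest-bitscore
hit passing identity ≥ 70% and query coverage ≥ 50% (coverage = 100 ×
alignment length / query length, assessed on the query side; a
symmetric mode exists behind a flag). Bitscores are compared after
rounding to one decimal — the granularity of common BLAST output — and
a query whose rounded top score is tied between subjects contributes
nothing: recent duplicates produce ties, and silently picking one would
fabricate a 1:1 orthologue. A pair is emitted only when each sequence
is the other's unique best. Pairs from all dataset combinations are
written as abc edges (query, hit, e-value; the smaller of the two
directional e-values) and grouped with the same MCL engine at
inflation 6, rather than plain connected components, so group
granularity matches the similarity clustering.

## Selection screen

Protein alignments are back-translated codon-by-codon onto their CDS
(standard genetic code; trailing stop codons dropped; any
translation mismatch is an error naming the sequence and column).
Trimming removes user-specified codon regions first (e.g. a
hypervariable repeat region) and then every codon column containing a
gap in any row — a deterministic replacement for manual alignment
curation.

NG86 dN/dS: per codon, each position contributes the fraction of its
three single-nucleotide changes that are synonymous (changes to stop
codons count as nonsynonymous, so synonymous + nonsynonymous sites = 3
per codon); site counts are averaged over the two sequences. Codon
pairs differing at k positions are resolved by averaging step counts
over all k! minimal mutational pathways with equal weights, excluding
pathways through intermediate stop codons (if all are blocked, all are
used). Proportions are Jukes–Cantor corrected,
d = −(3/4)·ln(1 − 4p/3); p ≥ 3/4 raises a saturation error, except the
corner case of wholly synonymous divergence beyond the limit (possible
only for very short sequences), which reports dS = ∞ and ω = 0 since
the ratio is then unambiguous. ω is undefined at dS = 0; such pairs are
excluded from group aggregation, and a dS = 0, dN > 0 group counts as
flagged only under an explicit option. Groups aggregate pairwise ω by
the **median**; a group is flagged as under candidate positive
selection when the aggregate exceeds 1. Pathway-averaged counts are
verified to 1e-12 against an exhaustive enumeration oracle over all
sense-codon pairs and random 50-codon sequences.

The screen is a pairwise counting method, not a maximum-likelihood
codon model: it has no transition/transversion or codon-frequency
parameters and no site-level inference. For the binary ω > 1 screen on
closely related sequences this is adequate and dependency-free; users
needing branch- or site-level resolution should export the trimmed
codon alignments to an ML codon-model package.

## Synthetic data generator

The generator emulates the pipeline's study conditions: 8 aphid-like
datasets (three genotypes of one species plus five relatives, with a
genus mapping), 30 gene families of 120 codons, each present in a
dataset with probability 0.9, evolved from a random stop-free root
along a **star phylogeny** (each dataset independently diverges from
the root) with branch scale 0.05 proposed substitutions per nucleotide
site — about 10% pairwise nucleotide divergence, congener-scale.
Families are well separated (random roots share only ~6% protein
identity), so cluster recovery has an unambiguous truth.

Codon evolution is acceptance–rejection on single-nucleotide proposals:
Poisson(t × length) proposals per branch at uniform positions,
stop-creating proposals rejected, synonymous proposals accepted with
probability min(1, 1/ω) and nonsynonymous with min(1, ω). The realized
nonsynonymous/synonymous rate ratio therefore equals ω in both regimes
— suppressing synonymous changes when ω > 1 is what lets an ω = 3
family actually show dN/dS > 1 to a counting estimator, which a scheme
that only boosts nonsynonymous acceptance (capped at 1) cannot do.
This is a transparent stand-in for a full parametric codon model, not a
replica of one: it has no transition/transversion bias and no codon
frequencies, which is exactly why NG86's equal-weight pathway averaging
is the matching estimator.

Twenty percent of families are effectors (signal peptide, no TM, NLS
with probability 0.4, family-level labels); a quarter of effector
families are pioneers — no database hit, no Pfam-A domain, and presence
restricted to one genus. Non-effector families receive a signal peptide
with probability 0.15 and a TM domain with probability 0.2. Counts are
negative binomial with dispersion 0.1 around a lognormal body mean
(median 500), three replicates per tissue, and an 8-fold head bias for
effector transcripts — a strong but realistic salivary-gland enrichment
that the calling rule should recover essentially completely at
p < 0.001. An optional `omega_effector` override evolves effector
families at elevated ω, mirroring the selection contrast the screen is
built to detect; optional duplications copy a gene within a dataset to
exercise RBBH tie rejection.

Similarity edges stand in for an all-vs-all BLASTP: percent identity is
computed position-wise after equal-length truncation (the generator
produces no indels), bitscore = identity% × length / 10, e-value =
10^(−bitscore/2) floored at 1e-180, edges below 20% identity omitted.
The e-value formula is arbitrary but strictly monotone in identity, so
thresholding and MCL weighting are well defined.

**What the generator does not emulate** — and hence what passing tests
do not show about real data: indels and alignment error, amino-acid
substitution preferences, assembly artefacts and chimeric transcripts,
isoform redundancy, unequal library depths, batch effects,
misannotated secretion signals, and paralogy beyond the simple recent
duplication. Real repertoires will be noisier at every stage; the
synthetic results certify the machinery, not field performance.
The real study design has separate head/body libraries per dataset;
the generator emits a single 3+3 count matrix covering all transcripts,
which is equivalent for a per-transcript test.

## Reporting conventions

Percentages are rounded half-away-from-zero at the requested precision
(consistent with all reproduced printed percentages, e.g. 49/430 →
11.4%, 3/390 → 0.8%, 4590/28542 → 16%, 6306/28542 → 22%). One
published ORF-completeness figure (2241/28542 printed as 7.6%) is
internally inconsistent (it computes to 7.9%) and is deliberately not
reproduced. Configuration is a flat key=value file; CLI flags override
it; every threshold applied is logged.

## Problem sizes

Tests and the acceptance script run at desk scale, chosen to finish in
minutes while keeping the statistical checks meaningful: 10,000
transcripts for the DE null calibration, 200 replicates per ω regime
(300 codons, total branch length 0.2), 30 families × 8 datasets
(~200 sequences) for end-to-end recovery, and ≤10-node fixtures plus
randomised small graphs for MCL oracle equivalence.
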