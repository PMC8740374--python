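# Methods

`somaspike` is a desk-scale pipeline for studying how learning-based somatic
mutation callers should be *built*: how synthetic tumor–normal training data
is constructed by spiking mutations into normal alignments, how tumor purity
and coverage are titrated by read mixing, how training sets are composed from
spike-in and real-truth sources, and how call sets are scored against a
tiered truth set with a coverage/purity-aware adjudication rule. Everything
runs on a single CPU in minutes over small synthetic genomes; the point is
the machinery and its statistical behavior, not genome-scale throughput.

## Synthetic substrate

**Reference.** Contigs are i.i.d. bases with a configurable GC fraction
(default 0.45). This is deliberately structureless: no repeats, no mapping
ambiguity. Consequences are noted under Limitations.

**Germline background.** SNVs and INDELs (1–10 bp) are dropped i.i.d. per
base (defaults 10⁻³ and 10⁻⁴ per bp), het:hom 2:1, with affected spans
(padded 1 bp) kept disjoint so truth bookkeeping is unambiguous. Germline
het sites matter downstream: they are the main source of realistic
non-somatic candidates (alt fraction ≈ 0.5 in both tumor and normal).

**Reads.** Paired-end reads (100 bp, fragments ≈ N(300, 30), capped at the
contig) are emitted pre-aligned at their true origin with simple CIGARs — no
aligner runs, which keeps the pipeline deterministic and dependency-free.
Each fragment carries a het germline variant with probability 1/2 (hom: 1),
applied to both mates; sites are unlinked (no haplotype structure).
Sequencing errors are i.i.d. substitutions (default 2×10⁻³); correct bases
get Phred 37, error bases a uniform Phred 10–30, so base quality is
informative but imperfect — some errors pass the scan's bq ≥ 15 filter, as
in real data. Mean depth over interior positions lands within 10% of the
target; edge positions are shallower.

## Spiking and damage

Somatic sites are chosen uniformly, avoiding germline spans and each other
(padded spans plus 2 bp spacing, so downstream exact matching is never
ambiguous). Default density is 400 SNVs + 95 INDELs per Mb, preserving the
≈4.2:1 SNV:INDEL ratio of the full-scale constructions this emulates. Target
VAFs are drawn from Beta(α=2, β=5) (mean 2/7 ≈ 0.286); Beta(2, 18)
(mean 0.10) emulates a low-purity tumor. An optional substitution-signature
restriction (e.g. C>T with its G>A complement) emulates skewed mutation
spectra.

Spiking is **fragment-level**: each fragment overlapping a site is
independently made a carrier with probability equal to the site's target
VAF, and both mates are edited — overlapping mates always agree, as a real
mutated molecule would read out. SNVs are base substitutions; insertions
splice bases into the read (CIGAR `I`); deletions remove the covered bases
(CIGAR `D`). A deletion running off a read's 3′ end soft-clips the tail;
a read starting inside a deleted span has its head soft-clipped and its
position advanced. Reads are never dropped and positions of other reads are
never touched (no re-alignment); the realism cost — slightly short reads
around deletions — is accepted. Re-deriving truth alleles by pileup majority
at VAF = 1.0 sites reproduces the plan exactly (tested).

FFPE-like damage is modeled as per-read, single-strand C>T flips at a
configurable per-cytosine rate (cap 0.05), with a replayable artifact log.
Because hits are independent per read, artifact allele fractions stay low —
the signature of deamination noise rather than true variants. Damage
preserves base qualities, which is what makes artifacts genuinely confusable
with low-VAF mutations.

## Titration

Purity-P, coverage-C samples are built by sampling fragments without
replacement from tagged tumor and normal pools (expected tumor-origin
fraction P, expected depth C); origin tags make realized purity auditable.
Contaminated normals (e.g. 95% normal + 5% tumor) use the same machinery.
In a titration grid each pool is split in half up front so no fragment
appears in both members of one pair. When purity and coverage both change,
purity is applied first, then thinning — one documented order so seeds
reproduce. Mixing linearity (mean observed VAF ≈ purity × target VAF,
regression slope within [0.9, 1.1]) is an acceptance property.

## Candidate scanning and features

Scanning follows the standard alignment-scan preprocessing thresholds:
`scan_maf 0.01` (cheap prefilter on unfiltered counts — its precedence
relative to the final AF test is not specified upstream, so prefilter
semantics are our documented choice), `min_mapq 10`, `snp_min_af 0.03`,
`snp_min_bq 15`, `snp_min_ao 3`, `ins_min_af 0.02`, `del_min_af 0.02`,
`max_dp 100000` (depth thinning, inert at desk scale). All boundaries are
inclusive. INDEL candidates are anchored at the base preceding the event
(VCF convention).

Each candidate becomes a 21-channel × 15-column matrix centered on the site
(encoding id `pileup-v1`): reference one-hot (4), tumor base + gap counts
(5), normal base + gap counts (5), tumor/normal mean base quality and mean
mapping quality (4), an edge mask, and derived tumor/normal non-reference
count tracks (2) — the last two exist so a *linear* model can express
"alt-supporting evidence" without interaction terms. External-caller flags,
when supplied, append constant channels and change the encoding id; models
refuse stores with a different encoding. Tumor count channels sum to the
column's (quality-filtered) depth, checked against an independent pileup.

## Genome split, gray zone, strategies

High-confidence regions are tiled into blocks (92 kb at full scale; 10 kb in
the desk-scale studies so a 200-kb genome yields ~20 assignable blocks),
blocks are randomly assigned train/eval at the train fraction (exact count,
rounded half-up; the last partial block participates normally), and a 5-bp
segment centered on each gray-zone mutation — low-confidence calls plus
unclassified calls above 30% VAF — is removed from the train side only.

Training sets are composed three ways: `spike_only` (all spike-source
candidates), `gt_real` (real-source candidates restricted to train regions),
and `combined` (all real candidates plus a uniform per-candidate 10%
subsample of spike candidates, without replacement; subsample size is
⌊0.1·n + 0.5⌋). A leakage guard — no training candidate locus inside the
eval regions — is a hard assertion at training time for every strategy; at
desk scale both sources share one synthetic genome, so spike candidates are
also confined to train regions.

**Classifier.** The harness is pluggable behind `TrainedModel` (predicts a
probability simplex over {non-somatic, somatic-SNV, somatic-INDEL}); the
reference implementation is multinomial logistic regression over
standardized flattened feature matrices with balanced class weights (lbfgs,
C = 1, deterministic under fixed seed). A linear model is enough to expose
composition effects, trains in seconds, and keeps the suite
accelerator-free; the upstream CNN architecture is deliberately out of
scope. Calls are candidates with P(somatic) ≥ 0.5 (configurable), typed by
the argmax somatic class, QUAL = −10·log₁₀(1 − p).

## Evaluation

Truth = HighConf + MedConf tiers. Calls and truth are normalized (INDELs
left-aligned and parsimony-trimmed; idempotent; records disagreeing with the
reference are flagged, never silently rewritten) and matched exactly on
(contig, pos, ref, alt) inside the eval regions. Unmatched truth → FN.
Unmatched calls are *private* and adjudicated: blacklisted if they match a
supplied blacklist; otherwise FP iff d ≥ 3CP/50 (boundary inclusive), where
d is the tumor alt support at the call and C, P the replicate's coverage and
purity; otherwise excluded — below the truth set's detection floor
(3 supporting reads at 50× and full purity) the call's somatic status cannot
be ascertained. d is measured with the scan's quality filters (mapq ≥ 10,
bq ≥ 15); upstream practice is unstated, so this is configurable.
Excluded/blacklisted calls enter no numerator or denominator; undefined
metrics are reported as explicit `None`, never NaN.

Stratification: VAF bins (edges 5/10/20/50/100%, configurable — the exact
published bin boundaries are not printed, so these follow the ranges the
analyses emphasize, with a `<5%` catch-all so the scheme partitions), signed
INDEL size (deletions negative; SNVs in their own stratum), and BED region
sets (non-partitioning: a call counts in every overlapping set, plus
"outside"). Partitioning schemes conserve totals (tested). The private-FN
comparison generalizes the 11-of-21 recurrence rule to ⌈r·R⌉ of R
replicates and reports each caller's private recurrent FN set with its
truth-VAF distribution.

The whole adjudication + metrics path is checked integer-exactly against an
independent brute-force set-arithmetic implementation on randomized fixtures
(≤ 500 variants, 20+ fixtures).

## Strategy-comparison study conditions

The composition study uses, per seed: one 200-kb genome; one clean spike
pair (Beta(2,5) VAFs) and one "real" pair with a shifted signature —
Beta(2,18) VAFs (low-purity-like spectrum) plus FFPE C>T damage at rate
0.005 in the tumor reads; 400 SNV + 95 INDEL spikes per pair; 50× coverage;
10-kb blocks, half held out. 50× matters: there the d ≥ 3CP/50 exclusion
floor equals the truth set's 3-read limit, so low-support artifact calls are
actually adjudicated as FPs instead of being excluded, and precision is
sensitive to whether a model has learned to reject sample-specific noise.
Under these conditions the combined model trades recall for a substantially
higher precision (it has seen artifact-like negatives; the spike-only model
has not) and its held-out F1 meets or beats spike-only in ≥ 4 of 5 seeds —
a soft, stochastic check by construction, not a theorem; individual seeds
can and do go the other way.

## Determinism and seeds

Every operation takes an explicit seed; no code touches global random state.
Pipelines fan one base seed out by stable stage-name hashing
(`derive_seed(seed, *stage_names)`, SHA-256 → 31 bits), so adding a stage
never perturbs earlier stages' streams. Same seed ⇒ byte-identical SAM
output, identical candidate stores, identical metrics.

## Problem sizes

Defaults throughout the tests and analysis scripts are 80–600 kb genomes at
50–160× — small enough that the full suite runs in a few minutes on one
CPU, large enough that the binomial/regression acceptance checks have the
statistical power they claim (e.g. ≥ 200 spiked sites for VAF recovery,
~500 truth sites per strategy-comparison seed).

## Limitations

* The structureless reference has no repeats or segmental duplications, so
  region-stratified evaluation is exercised on synthetic BEDs, and mapping
  ambiguity — a major real-world FP source — is absent entirely.
* Insert sizes and quality profiles are stylized, not instrument-derived;
  PCR duplicates and coverage waves are not modeled.
* INDEL spiking does not re-align; reads shorten slightly around deletions.
* Spiked haplotypes are unphased and germline sites unlinked.
* The logistic reference classifier cannot express feature interactions; it
  bounds from below what a CNN-class model would see, and composition
  effects measured here should be read as directional, not as effect-size
  predictions for genome-scale data.
* Passing tests demonstrate the machinery's correctness and the designed
  statistical behaviors on this synthetic substrate; they do not certify
  performance on real tumor data.
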