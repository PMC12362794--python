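# Methods

This note documents the models, parameter choices and numerical decisions
behind `puftyper`, and what the synthetic study conditions do and do not
establish about real sequencing data.

## Coordinates and canonical indel calls

All coordinates are 0-based, half-open. The blunt SpCas9 cut falls between
`cut_pos - 1` and `cut_pos`; when the cut is derived from a protospacer the
cleavage point is taken 3 bp 5' of the PAM. An indel call is the pair
(kind, bases) anchored at a leftmost-aligned offset relative to the cut.
Left-alignment is computed from the longest common prefix/suffix of the
reference and observed central regions: for an insertion of length `d`,
every valid placement lies in `[len(ref) - lcs, lcp]`, and the smallest
one is chosen (symmetrically for deletions). This makes calls canonical —
the same biological event maps to the same string key (`I+0:GG`,
`D-1:CG`) in every sample — at the cost that a deletion inside a repeat
may be reported shifted 5' of the cut. Keys carry a deterministic total
order (kind, offset, bases) used for every tie-break in the pipeline.

## Read filtering model

A read is matched against three regions: exact 5' flank, flexible central
region spanning `del_window = 20` bp on both sides of the cut, exact 3'
flank. The central region may shrink by at most the window span (deletions
confined to cut ± 20 bp) and grow by at most `max_insertion = 10` bp.
Reads failing the pattern, containing non-ACGT characters, or shorter than
the flanks are *corrupted*; matched reads are *wild-type* (central region
identical), *substitution-only* (same length, ≥ 1 mismatch) or *indel*.
Central regions that cannot be explained by one contiguous indel (an indel
plus a separated mismatch) are rejected as corrupted and tallied
separately (`n_complex`); decomposing such complex events would require an
alignment model the single-flexible-region filter deliberately avoids.
Quality scores are ignored throughout — the filter is purely
sequence-based — and only single-end R1 reads are processed. A truncated
trailing FASTQ record is counted as one corrupted read rather than
aborting the sample.

Whether the ± 20 bp bound applies to a deletion's total span or to each
edge is ambiguous in principle; here the whole deletion window must lie
inside the flexible region (maximum deletion 40 bp).

## Diversity metrics

Entropy is the plug-in estimator $H = -\sum_i p_i \log_2 p_i$ in bits; no
bias correction is applied. To compare samples of unequal depth,
`resampled_entropy` draws `n_subsample` reads (default 100 000) without
replacement — a multivariate-hypergeometric draw over the key counts —
`n_reps` times (default 100) and reports mean and SD. When a profile is
shallower than `n_subsample` the draw is clamped to the full profile with
a warning instead of failing, so desk-scale fixtures remain usable; the
estimate then degenerates to the plug-in value with SD 0.

The expected contribution to diversity of a size class is its read
frequency times the number of distinct outcomes the class can realise:
$4^s$ for s-bp insertions, and $s$ for s-bp deletions (the number of
distinct s-long windows overlapping the cut junction — the factor is
pluggable, since "replacements" is only combinatorially forced for
insertions).

## Bray–Curtis analysis

BCD is computed on frequency-normalized profiles over the union key set;
after every filtering step (top-fraction cropping, singleton removal,
common-indel exclusion) profiles are renormalized so BCD stays in [0, 1].
`top_fraction` keeps the `ceil(f·m)` most frequent of `m` unique indels,
breaking count ties by key order. The heuristic discrimination pipeline
is: drop singleton reads per sample, intersect the reference sample's key
set with every other sample and remove that common set everywhere, then
compare top-25 % profiles pairwise. The passage-stability threshold is the
minimum inter-group BCD in a library; a time-course sample authenticates
while its (top-25 %) BCD to the registered profile stays below it.

BCD is a semimetric — the triangle inequality is not asserted anywhere.

## Authentication classifier

Profiles are vectorized into the union feature space of the training
library (frequencies over all of a profile's reads; query keys outside the
space are dropped *without* renormalization so training-support
frequencies stay comparable, with an opt-in to renormalize over seen keys
only). The classifier is one-vs-rest logistic regression with the
liblinear solver, one binary model per class, penalty L1 or L2, inverse
regularization strength `C = 1.0` by default; probabilities are the
normalized per-class sigmoids computed from the stored coefficients, which
makes a serialized model's predictions bit-identical to the fitted one.

By default the frequency features are square-root (Hellinger) transformed
inside the classifier. The identifying signal of a PUF lives in its many
rare tail indels, each with a frequency of ~10⁻³; on raw frequencies the
decision margins are tiny and accuracy depends delicately on `C`, whereas
the Hellinger transform — the standard preparation of compositional
frequency data for linear methods — equalizes row norms and up-weights the
tail, making accuracy flat across two orders of magnitude of `C`.
`hellinger=False` restores the raw-frequency behavior. One training
example per class is inherent to the design (the original sample trains,
the replicate tests), so no cross-validation is attempted; note that L1 at
`C = 1` can zero out entirely on very small training sets — use a larger
`C` with L1 there.

## Synthetic repair-outcome generator

The generator emulates two repair regimes at a random amplicon with a
chosen cut-flank dinucleotide:

| parameter | cas9_only | cas9_tdt | rationale |
|---|---|---|---|
| insertion fraction | 0.16 | 0.80 | deletion- vs insertion-dominant repair |
| insertion lengths | mostly +1 (0.7/0.2/0.1 for 1–3 bp) | 1–4 bp carry 0.87 of mass, ≤ 10 bp | TdT appends short tails |
| deletion lengths | enriched 1–2 bp (0.40/0.22), tail to 20 bp | same | NHEJ deletion spectrum |
| flank bias weight | 6 | 6 | inserted bases favor the two cut-flank nucleotides (weight 6 : 1), so ≥ 85 % of frequent insertions at a CG cut contain C or G |
| wt / substitution / corrupted | 0.30 / 0.02 / 0.03 | same | unedited cells and library noise |
| per-base error rate | 0.001 | same | post-filter Illumina scale |
| rank-frequency law | Zipf, exponent 1.2 | same | heavy-tailed outcome frequencies; top-20 outcomes capture > 30 % of reads |

Candidate events are drawn from this model, canonicalized, de-duplicated
until `n_unique` distinct keys exist (or the outcome space is exhausted —
the deletion-dominant model tops out near ~250 keys, which is precisely
why its profiles carry less entropy), ranked within each kind by their
generative probability (short, flank-matching insertions first), and given
Zipf weights over the global ranks, interleaving kinds greedily so the
cumulative insertion mass tracks the model's insertion fraction.

What the generator does *not* emulate: PCR duplicates and chimeras,
quality-score structure, paired-end reads, position-dependent error rates,
microhomology-driven deletion hotspots, and biological variance of outcome
*frequencies* between transfections (two outcome distributions generated
at the same locus differ only in their realized tails). A finite
founder-cell bottleneck — resampling the outcome distribution through a
few thousand draws before emitting reads — stands in for inter-transfection
individuality where libraries of distinct PUFs are needed.

## Simulated-PUF study

The master distribution pools outcome distributions of three loci (one per
cleavage context CG/AT/CT, 2000 keys each, support ≈ 5400 pooled),
mirroring how the empirical master concatenates all experiments. Simulated
PUFs are 1000-read multinomial samples from the master; each replicate
retains a 77 % hypergeometric subsample of the original's reads and fills
the rest with master draws restricted to keys outside the original's
support, which pins the measured mass overlap (Σ min of frequencies,
equal to 1 − BCD) to the 0.77 target by construction. Per library size
(25–300, step 25) the L2 classifier trains on the originals and classifies
the replicates.

Two regime limits are worth knowing. First, at 1000 reads over a ≥ 2000-key
master each PUF's sampled support is so individual that replicate
classification is essentially perfect at every size. Second, when the read
depth approaches the master support (≳ 20 000 reads here), independent
samples already overlap by more than 77 % and an overlap-controlled
replicate is no longer constructible — the scheme degenerates. All study
conditions sit well inside the first regime.

The insertion-size restriction study (master insertions limited to 3–7 bp,
deletions untouched) probes how the size of the outcome space limits PUF
capacity. At the default 1000-read depth the restriction is invisible —
profiles stay fully individuated and both runs saturate at accuracy 1.0 —
so the paired comparison is run at 10 000 reads per PUF (sizes 50/150/300),
where the restricted space is densely sampled: the restricted run loses
10–15 accuracy points while the unrestricted run stays at 1.0, consistently
across seeds.

## Problem sizes and tolerances

Test fixtures use 40–160 bp amplicons, hundreds to thousands of reads, and
masters of 150–5400 keys; the oracle-equivalence checks compare the
pipeline against brute-force enumeration (indel placements) and hand
formulas (BCD to 1e-12). Stochastic emulation targets carry the
tolerances stated with them (± 0.02 on mass fractions and overlap,
3σ multinomial bands on recovered frequencies); directional claims
(entropy contrast, exclusion gain, drift monotonicity, restriction
penalty) are asserted across 5–20 seeds. Probability vectors must sum to
1 within 1e-9.
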