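# Methods

## Model and update scheme

A gene-regulatory network is a set of annotated genes (pluripotency
transcription factor, differentiation, epigenetic, other) with at most one
signed, directed interaction per ordered gene pair; self-interactions
(auto-regulatory loops) are allowed and signs may be activation, inhibition
or undefined (a literature link whose mode is unknown).  The executable
model attaches one Boolean update rule to every regulated gene; genes
without regulators are inputs and hold their state.

Logic is synthesized from topology by the veto rule: activators OR-joined,
inhibitors OR-joined under a single NOT, the two clauses AND-joined, and
either clause omitted when empty.  A gene whose only regulators are
inhibitors is therefore constitutively on until an inhibitor fires — the
natural reading of "expressed unless repressed".  Dimer partners on a
configurable list (default POU5F1+SOX2) are AND-joined wherever both
co-activate a target, which encodes obligate heterodimer binding; the
partner symbols are folded into one clause term even when one of them is
the target itself.  Clause order is lexicographic so synthesis is
deterministic.

Updates are synchronous only: state S_t is a function of S_{t-1} for all
genes at once.  The deterministic trajectory from any start ends in a
cycle; cycles are stored in canonical rotation (lexicographically smallest
state first) so attractors compare by value.  Attractors are found either
by sampling (N seeded uniform random starts, each mapped to its attractor,
basin weight B_i = number of starts that reached attractor i) or
exhaustively for models of at most 20 genes.  The maximum-B_i attractor is
the stable phenotype; ties break to the smallest canonical state.

Knockdown clamps genes to 0 (overexpression to 1) for the whole
simulation, including the initial states, and the clamped and unclamped
runs draw identical random starts from the same seed so the comparison
isolates the clamp.  A cyclic attractor is collapsed per gene to its
majority state; genes with no majority (an exact tie along the cycle) are
flagged oscillating and excluded from the up/down classification, since a
0-to-1 rule has no meaning for a gene that never settles.  This collapse
rule is our choice: fixed points are the intended reading of a stable
phenotype, and the only oscillator the packaged model produces is the
MYC negative auto-loop (with TERT trailing it), which genuinely cannot
settle under synchronous update when its activators are on.

## Binarization

Expression is log-scale (a logCPM utility with pseudo-count `prior`,
default 0.5, is provided: log2((count + prior) / (libsize + 2 prior) x
1e6)).  Per gene, bimodality is scored on a histogram density with
ceil(sqrt(n)) bins, lightly smoothed with a 3-bin binomial kernel when
there are at least 5 bins and zero-padded so boundary point masses count
as peaks.  Peaks need prominence of at least 10% of the maximum height;
with fewer than two peaks the amplitude is 0, otherwise it is
(A_lo - A_anti) / A_lo for the smaller of the two highest peaks A_lo and
the minimum density A_anti between them, clipped to [0, 1].  The
smoothing and prominence defaults were fixed by a synthetic sweep:
unimodal Gaussian samples (n = 60 and n = 1000, 50 seeds each) must score
exactly 0 while two point masses and well-separated mixtures score 1 and
a 15/85-unbalanced mixture is still detected.  Both knobs are arguments.

Bimodal genes are split by 1-D k-means with k = 2 (10 restarts, seeded);
the high-mean cluster maps to state 1 and the threshold rho is the
midpoint between the largest low-cluster value and the smallest
high-cluster value, so states equal 1 exactly where expression exceeds
rho.  Unimodal genes carry no per-sample signal: they are pooled, 2-means
runs on their per-gene mean expression, and each gene receives one
gene-level state (higher group 1) replicated across samples.  A constant
gene falls into this fallback; a degenerate fallback pool (fewer than two
distinct summaries) assigns 0 with a warning.

The chi-square test builds the 2xK table of gene-level state against gene
category (default pair: pluripotency TF versus differentiation).
Gene-level states are the majority across samples for time-course genes
(exact ties resolve to 0) and the assigned state for fallback genes.
Pearson's statistic is used without continuity correction by default; the
Yates correction is a flag because 2x2 implementations differ on it.

## Rule validation, inference, selection

Fixed-point validation evaluates each rule on the gene-level state vector
and counts it validated when the output equals the target's own state;
transition validation feeds states at t-1 and requires the prediction to
match at t for at least `min_agreement` (default 1.0) of consecutive
pairs.  The validated fraction is over decided (non-skipped) rules; input
genes have no rule and never enter the denominator.  Because the
denominator convention matters, the analysis driver also prints the
fraction over all 45 genes.

Inference is lazy best-fit search.  One-step transitions are pooled from
one or many series (a list of short series is accepted because single
trajectories cannot cover a state space).  For each gene, every regulator
subset of size <= max_k (default 3; the subset pool can be restricted
globally or per gene) is scored: the truth table is filled by majority
vote per observed input pattern, exact ties — including patterns never
observed — enumerate both completions, and the error is the minority count
summed over patterns.  All candidates at the per-gene minimal error are
returned with uniform probabilities.  Tie completions are combinatorial on
sparse data, so candidate lists are capped (default 1000 per gene,
deterministic order, truncation recorded); with full one-step coverage no
pattern is unseen and the generating table is always among the zero-error
candidates.

Selection scores each candidate against the topology-derived rule by
Jaccard similarity of regulator sets plus 0.5 times the fraction of shared
regulators whose signs agree, signs being read off truth-table
monotonicity (non-monotone regulators count as sign-less; dummy regulators
are dropped).  Ties prefer fewer regulators, then the lexicographically
smallest rule string.  Genes with no candidates keep their topology rule;
topology inputs whose best candidate is a constant stay inputs, because a
constant carries no interaction structure.  Integration takes the union of
curated and inferred interactions, marks novel edges `inferred`, resolves
undefined curated signs from the inferred network, and on a sign conflict
keeps the curated sign and reports the pair.

## Synthetic data and the packaged fixture

The generators emulate the statistical structure the analysis assumes:
`generate_topology` draws a random signed DAG (regulators drawn from a
random topological order, Poisson in-degree, configurable inhibition
probability) plus a requested number of positive auto-regulatory loops;
`generate_timeseries` runs the synchronous model from a seeded random
start with optional independent bit-flip noise; `generate_expression`
emits Normal(mean_state, sd_state) per entry.  Mixture defaults (low mean
2, high mean 8, sd 0.8, log-scale-like) give near-clean but not degenerate
binarization.  What the generators do **not** emulate: scRNA-seq dropout,
library-size variation, doublets, or pseudotime uncertainty — passing
tests show the discrete machinery is correct, not that real single-cell
noise is handled.

The packaged 45-node pluripotency network is a synthetic reconstruction,
not a curated edge list: it has the canonical structure (45 nodes; 65
non-self edges plus 4 positive auto-regulatory loops on POU5F1, SOX2,
FGF2 and REST; 19/21/2/3 category split) and carries the system's
well-known literature-reported interactions (NANOG represses
KLF4; NANOG/POU5F1/SOX2 activate TBX3; FGF2 activates FGFR2; FGFR2
represses TCF3, NOG and BMP4; the MYC negative auto-loop — all carried by
the integrated variant, since KLF4, TBX3 and FGFR2 are unregulated inputs
in the curated topology).  The remaining edges are field-standard
pluripotency wiring chosen a priori so the model shows the documented
phenotypes: the core triad ignites from most random starts and latches;
GATA6 is expressed exactly when POU5F1 is off, so a POU5F1 knockdown
extinguishes NANOG through the GATA6 veto; and NANOG has no self-latching
descendants, so knocking down POU5F1+NANOG converges, start by start, to
the same attractors as POU5F1 alone.  Per-edge provenance
(literature-named versus constructed) ships in
`data/edge_provenance.synthetic.tsv`.  The synthetic single-cell snapshot
(`snapshot_expression`, default 10 cells x 12 time points) simulates the
integrated model from heterogeneous random starts and emits mixture
expression per state; because inputs such as FGF2 latch randomly per cell,
a few input/signalling genes have no designed cluster membership — only
the category-level pattern (pluripotency high, differentiation low) is a
designed property of the snapshot.

## Numerical and design choices

- All iteration orders, tie-breaks and serializations are lexicographic;
  outputs are byte-stable and seed-deterministic end to end.
- k-means restarts: 10; seeded.  1-D k-means yields interval clusters, so
  the midpoint threshold reproduces cluster membership exactly.
- Sampled basins use one RNG stream per run, seeded identically across
  clamp conditions.
- The exhaustive enumerator refuses models above 20 genes and is the
  oracle for the sampler in tests (10-gene models, 1024 starts).
- Simulation problem sizes in the analysis and acceptance script (10
  cells x 12 time points; 100 random starts; 10-gene inference oracles)
  are chosen to make every quantity stable across seeds while keeping a
  full run in seconds.
- Binarization accuracy has an information-theoretic ceiling: at a
  component separation of d standard deviations the per-sample Bayes error
  is Phi(-d/2), about 2.3% at d = 4 — the binarizer attains that bound,
  and recovery above 99% requires d greater than about 4.7.

## Known limitations

- Synchronous update only; asynchronous and probabilistic schemes are out
  of scope, and synchronous negative loops oscillate by construction.
- Best-fit inference is exhaustive over subsets up to max_k = 5 and is
  meant for small regulator neighbourhoods, not genome-scale search.
- The amplitude statistic is histogram-based; very small samples (< ~10)
  give coarse densities and the point-mass limit is only exact when the
  two masses fall in distinct bins.
- The packaged network is a stand-in: structure and named interactions are
  faithful, but edge-level conclusions about the real curated network
  should not be drawn from it.
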