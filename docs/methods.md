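# Methods

`proxiscaf` reassembles one-dimensional genome structures from chromosomal
contact data (Hi-C / 3C-seq).  This note documents the model, the sampler,
the synthetic-data generator, the evaluation metrics, and the numerical and
design choices a user should know about.

## The probabilistic model

A genome structure `G` is an ordered, oriented arrangement of bins (runs of
consecutive restriction fragments) into scaffolds, together with an unplaced
pool and per-bin copy numbers (duplications).  Given an observed contact
matrix `D`, the posterior over structures follows Bayes' rule with a flat
structural prior, so exploration is driven entirely by the likelihood
`p(D | G, ξ)`.

Contact intensities follow a power law with a plateau.  For a cis pair at
genomic distance `s` (midpoint to midpoint, in bp):

    Pc(s) = Pt · (s / s0)^b    for s ≤ s0,   b < 0
    Pc(s) = Pt                 for s ≥ s0

and all trans pairs contact with the uniform intensity `Pt` per bp².  The
form is continuous at `s0` by construction, which fixes the proportionality
constant.  Observed counts are independent Poisson draws:

    k_ij ~ Poisson(λ_ij),   λ_ij = exposure · L_i · L_j · intensity(i, j)

summed over all copy pairs of bins i and j.  The three nuisance parameters
`ξ = (b, s0, Pt)` are sampled jointly with the structure under a flat prior
inside box bounds.

### Sub-bin segments and orientability

Counts and λ are kept at sub-bin *segment* resolution: every orientable bin
(≥ 2 restriction fragments) is split at the fragment boundary nearest its
midpoint into two segments; single-fragment bins are one segment and carry
no orientation.  This is not an implementation detail but the reason
orientation is inferable at all: a bin's midpoint does not move when the bin
is flipped, so any purely bin-level distance model is exactly invariant
under orientation flips.  Flipping a bin *reverses its segments* inside the
bin's span, which changes the segment-level distances to its neighbours and
hence the likelihood.  This is also why a bin needs at least two restriction
fragments to be orientable.  Bin-level counts and expected counts are the
aggregates over the segment pairs.

### Floors, deletions, duplications

* **Small-distance floor.**  `s` is floored at `max(1 bp, half the smaller
  segment length)` before evaluating `Pc`, so coincident midpoints (self
  pairs, zero-distance copies) stay finite; segments self-contact at a
  finite rate as in real data.
* **Unplaced bins.**  A deleted bin enters the intensity product with a
  factor `1e-3` instead of its copy number, so pairs involving it keep a
  floor intensity `~1e-3·Pt`.  Without this, deleting bins would trivially
  raise the likelihood by removing terms; with it, the observed contacts of
  a deleted bin actively penalise the deletion.
* **Duplications.**  Reads cannot be assigned to copies, so observed counts
  stay on the single collapsed row while the model sums λ over all copy
  pairs.  A region present twice in the cell but once in the assembly is
  therefore expected to show roughly twice the contacts of an ordinary
  region — the diagnostic the sampler uses to restore collapsed duplicates.
* **Exposure.**  The depth-matching constant is deterministic, not sampled:
  it is fit so that `Σ λ` equals the observed total, and refit at each cycle
  start as the structure improves.  Exposure and `Pt` multiply the same
  term, so only their product (the trans contact rate in count units) is
  identifiable; sampling both would be unidentifiable.

## The sampler

Each *cycle* visits every bin exactly once in a random permutation.  For
the visited bin:

1. `m` partner bins (default 3) are drawn without replacement with
   probability proportional to their measured contacts with the bin plus a
   pseudocount of 0.01 (so zero-contact partners remain reachable);
   partners with several copies contribute one copy chosen uniformly.
2. The 14 moves against each partner give `14·m` candidate structures; the
   unchanged structure competes as a `14·m + 1`-th candidate.  One
   candidate is selected with probability `∝ exp(Δloglik / T)` (softmax
   stabilised by subtracting the maximum) and is *systematically accepted*.
   The default temperature `T = 1` uses the likelihoods as-is; `T → 0`
   recovers greedy argmax selection.  At realistic sequencing depth the
   likelihood differences are so large that `T = 1` is effectively greedy.
3. One component-wise Metropolis sweep updates `ξ`: a linear random walk on
   `b` and log-scale walks on `s0` and `Pt`, accepted with the usual
   `min(1, likelihood ratio)` inside the box bounds.  Default step sizes
   (0.02, 0.03, 0.008) give a 30–60% sweep acceptance rate at the depths
   used here.

Each new cycle restarts from the highest-likelihood structure seen during
the previous cycle; within a cycle the chain moves freely and can descend.
After a burn-in (default 2 cycles; the validation experiments discard more)
every `n_bins/10`-th structure is retained for posterior summaries: the
median and interquartile range of the scaffold count — `iqr(N_contigs)` is
the convergence/dispersion diagnostic, 0 when the likelihood peaks on one
structure — and, when a reference is available, the median reconstruction
error.

All randomness flows through one seeded generator in a fixed order (cycle
permutation → copy choice → partner draws → selection → ξ proposals), so
runs are bit-reproducible given the seed.

### The 14 moves

For selected bin A and partner B:

* **Transpositions (4).**  Remove A, reinsert before/after B, keeping or
  flipping its orientation.  Reinsertion next to A's own neighbour with a
  flip is an in-place inversion.
* **Translocations (4).**  Cut A's and B's scaffolds and rejoin the four
  arms in the four orientation-consistent ways: EXCHANGE (cuts before A and
  B, right arms swapped — the classic reciprocal translocation), HEAD_HEAD
  (the two cut starts joined), TAIL_HEAD (cut after A; A's end joined to
  B's start — one-move scaffold concatenation), TAIL_TAIL (the two ends
  joined).  When A and B share a scaffold these degenerate to a split, a
  double split, an excision of the spanned segment into its own scaffold,
  and an in-place inversion of the spanned segment.  The tail-side cuts
  matter in practice: without them, two correctly assembled fragments of a
  chromosome can only merge bin-by-bin through likelihood-neutral
  intermediate states, and dense-data runs stall in fragmented local optima.
* **Deletion (1).**  A moves to the unplaced pool (legal on the last copy).
  Unplaced bins are revisited by later cycles and can re-enter via
  transpose/duplicate/eject; their delete and translocation candidates are
  emitted as identity moves so the candidate count stays exactly `14·m`.
* **Duplications (4).**  Insert an extra copy of A before/after B, forward
  or flipped, the original staying in place; copy indices are assigned
  monotonically and never reused, so traces are replayable.
* **Ejection (1).**  A moves into a new single-bin scaffold.

Candidate scoring recomputes only the likelihood terms whose geometry can
change: the pairs within the bins of the scaffolds replaced by the move,
plus the moved bin's whole row when its copy number changes.  Agreement
with full recomputation is property-tested to 1e-6 relative tolerance;
the cached total is resynchronised by full recomputation at cycle starts.

### Initialisation of ξ

`b` and `s0` are fit by least squares on the log-binned cis
contact-vs-distance curve of the *initial* structure, `Pt` from the mean
trans rate.  On a scrambled or bin-per-scaffold start this curve is almost
flat and the fit falls back to mild defaults (`b = −1`, `s0` at 20 median
segment lengths); the Metropolis chain then steepens `b` as true cis
structure forms.  Bounds: `b ∈ [−4, −0.05]`, `s0 ∈ [1 kb, 100 Mb]`,
`Pt ∈ [1e-16, 1e-2]` per bp².

## Matrix construction

Pre-mapped pair records (`seq pos strand mapq` per mate) are filtered in
order: both mates strictly above mapping quality 30 (the classic rule);
fragment assignment against the restriction map (cut before every
occurrence of the site, e.g. GATC); same-fragment pairs discarded
(undigested/self-religated molecules); exact duplicates (same coordinates
and strands, unordered) counted once.  Retained pairs increment the count
between the two segments containing the mates.  Binning is greedy
left-to-right: close a bin once it has `min_rf` fragments (default 2, so
every regular bin is orientable) and, optionally, a target length; a
trailing under-sized group merges into its left neighbour; bins never span
sequences.

## The simulator

The generator draws pair-wise independent Poisson counts around the model
intensities of a known truth structure, scaled to a target total —
equivalent in distribution to read-by-read multinomial sampling at fixed
expected depth.  Defaults emulate the validation conditions of the method:

* a 16-chromosome genome with true S. cerevisiae chromosome-length ratios,
  160 bins of ~30 kb (the genome scales with the bin count so the decay
  regime is preserved at reduced size);
* a four-chromosome genome with hg19 chr7/17/19/22 length ratios, 200 bins;
* `b = −1.5`, `s0 = 100 kb`, nominal `Pt = 1e-9`/bp² (absorbed by the
  exposure fit), 1e7 contacts at full depth;
* scrambles: random permutation of all placements into a configurable
  number of scaffolds with i.i.d. random orientations;
* injected variants: reciprocal translocations, segment inversions,
  segmental duplications, and collapsed duplications (the truth carries two
  copies, the initial assembly one, producing the ~2× marginal signature).

What the simulator does *not* emulate: mapping noise and mappability
variation, restriction-site density bias and other coverage biases,
distance-dependent ligation artefacts, or structural heterogeneity between
cells.  Passing closed-loop tests therefore demonstrates correctness of the
inference machinery under the model's own assumptions, not robustness to
every artefact of real libraries.

## Evaluation metrics

* **Reconstruction error** — the fraction of the reference's oriented bin
  adjacencies not recovered by the assembly; an adjacency `(a,o_a)→(b,o_b)`
  matches directly or as its reverse complement, and duplicated bins are
  matched as adjacency multisets (an optimal copy pairing).  The error is 0
  iff the assembly equals the reference up to scaffold naming, order and
  whole-scaffold reversal; it accounts for both order and orientation.
* **Chromosome assignment** — each assembly scaffold maps to the reference
  chromosome contributing most of its length (majority rule); accuracy is
  the percentage of bins whose scaffold maps to their true chromosome.
* **Ordering** — a bin is accurately ordered when its set of immediate
  neighbours (unordered, orientation ignored) equals the reference's.
* **Rank error** — per bin, `|rank in assembly − rank in reference|`, with
  each scaffold read in the direction minimising its total (a reversed
  scaffold scores 0); bins whose scaffold maps to a different chromosome
  are excluded from rank statistics.

## Problem sizes and runtimes

The validation experiments shipped with the package run scaled-down twins
of the method's original validations: closed-loop reassembly at 96–160
bins / 1e7 contacts / ≥5,000 iterations (one run ≈ 1–2 min on one core),
tenfold and thousandfold downsampling of the same matrix, the
four-chromosome assignment twin at 120–200 bins, collapsed-duplication
recovery at 60 bins, and parameter recovery at 96 bins / 5e6 contacts.  At
full depth the chain reaches reconstruction error 0 with `iqr(N_contigs) =
0` and 16 scaffolds; at 0.1% depth it stays dispersed (`iqr > 0`) with
errors around 40–50%, which is the intended diagnostic behaviour: the
posterior honestly reports when the data no longer determine one structure.

## Known limitations

* Junctions between bins that were not neighbours in the input are resolved
  only to bin resolution; gap lengths between joined bins are not estimated
  (AGP output uses fixed 100-N scaffold gaps with proximity-ligation
  evidence).
* One global `ξ` is fit; per-chromosome decay exponents are not modelled.
* No matrix balancing/normalisation is applied; strong coverage biases in
  real data would enter the likelihood directly.
* Orientation of single-fragment bins is undefined by construction and
  pinned to forward.
* The sampler is a single chain without parallel tempering; very sparse
  data are explored, not optimised, and convergence is diagnosed via
  `iqr(N_contigs)` and the trace rather than any automatic criterion.
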