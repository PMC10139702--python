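# Methods

## Model

All computation assumes a reversible, homogeneous, site-independent
20-state amino-acid substitution process. A model is built from a
symmetric exchangeability matrix S and equilibrium frequencies π as
Q_ij = S_ij π_j (i ≠ j), diagonal set so rows sum to zero, then rescaled
so −Σ_i π_i Q_ii = 1; branch lengths are therefore expected substitutions
per site. Transition probabilities P(t) = exp(Qt) come from the
eigendecomposition of the π-symmetrized generator
B = diag(√π) Q diag(√π)⁻¹, which is real-symmetric for a reversible
process, so the exponential is numerically stable at any t. P(0) is
returned as the exact identity: a zero-length branch is a hard constraint,
and the distinction matters when data conflict across it. Rows are
renormalized only within 1e−8; larger deviations raise an error instead of
being masked.

The shipped empirical matrices (JTT, WAG, LG — the published
exchangeability/frequency tables) live in `src/convscan/data/*.dat` in the
classic PAML layout (19 lower-triangular rows, blank line, 20
frequencies), so they are inspectable and replaceable; any file in that
layout can be loaded. JTT is the default; `+F` substitutes observed
alignment frequencies, floored at 1e−6 and renormalized so a residue
absent from one ortholog is rare rather than impossible. Among-site rate
variation is **not** modeled: the simulator and the detector share one
homogeneous process, keeping the analysis internally consistent; see
Limitations.

## Likelihood and branch lengths

Site likelihoods use the pruning algorithm, vectorized over columns, with
per-node per-site log scaling to prevent underflow. Gaps (`-`) and
ambiguity (`X`) are missing data (all-ones tip partial), never a 21st
state; an entirely missing column contributes exactly zero
log-likelihood. A trifurcating root is accepted and treated as the root.

Branch lengths can be re-estimated per gene on the fixed species topology
(the default in the batch pipeline, mirroring common ancestral
reconstruction practice, since per-gene rates vary), or taken from the
input tree (`fixed`). Estimation is coordinate-wise: each branch is
optimized by bounded scalar minimization on [0, 10] substitutions/site
using the outside/inside decomposition of the likelihood at that branch
(so only one 20×20 matrix rebuild per trial value), sweeping until the
per-sweep log-likelihood gain is below 1e−6, at most 50 sweeps;
exhaustion returns the best-so-far tree with a warning flag. Under a
reversible model only the *sum* of the two root-adjacent branch lengths is
identifiable, so that pair is optimized jointly on its sum with the split
kept proportional to the input tree — this removes a spurious optimizer
degree of freedom rather than changing the fitted likelihood.

## Ancestral reconstruction

Marginal (empirical-Bayes) posteriors are exact for the given model, tree
and branch lengths: an outside (pre-order) pass complements the pruning
partials, and the posterior at node v is the normalized elementwise
product of the two. Marginal — not joint — reconstruction is used because
the null model consumes full per-node posteriors. The reported ancestral
state is the posterior mode; exact ties (top-two gap < 1e−9) break
alphabetically by one-letter code and are flagged. A MAP probability
below 0.8 is marked low-confidence in output but does not filter any
site: no posterior-confidence filter is applied anywhere by default, and
the observed and expected counts are always computed over the identical
set of usable sites (those where no focal-branch child tip is gap/`X`).

## Observed and expected convergence

A substitution is called on a focal branch where the parent MAP state
differs from the child state; on a terminal branch the child state is the
observed tip residue — extant sequences are data and are never replaced by
a reconstruction. A site yields an event when branches share the derived
residue: *parallel* if every contributing ancestral residue is identical,
*convergent* if at least two differ. The three-lineage analysis uses
all-branches mode (an event requires all three branches); pairwise sets
cover the two-lineage contrasts.

The expectation integrates over the ancestral posteriors at the focal
parents and the branch transition matrices (formulas in the README),
treating the focal parents as independent. That is legitimate only because
focal branches are required to be pairwise disjoint — no branch ancestral
to another; nested sets are a hard error. One asymmetry is deliberate and
standard: observed counts condition on the MAP ancestor, while
expectations integrate over the full posterior. Under null simulation from
the same model the two agree closely (the suite checks mean observed vs
mean expected within 10% over 500 genes), with a slight conservative
excess of the expectation.

Counts are tested as Poisson variables with mean equal to the expectation:
`p_upper = P(X ≥ obs)` (excess, the focal-branch question) and
`p_lower = P(X ≤ obs)` (deficit, the sister-branch control), exactly via
`scipy.stats.poisson`, with the degenerate mean-zero case handled
explicitly. Gene expectations add, so the genome-wide test is a single
Poisson tail on the summed counts; per-gene `p_upper` values also receive
Benjamini–Hochberg q-values across genes, for reporting only. For the
five-sister control both modes are computed; the headline contrast pairs
the focal all-branches excess with the sister *pairwise* deficit, because
a five-way shared derived state is so improbable that the all-branches
control expectation is numerically negligible and a deficit could never
register there.

## Synthetic data

The simulator emulates the study design: a 13-tip mammal tree with the
three focal myrmecophagous tips (anteater, echidna, pangolin) in disjoint
subtrees and their five non-myrmecophagous sisters (elephant, platypus,
dog, cat, giant panda), plus opossum, human, mouse, cow and horse. Branch
lengths (0.01–0.22 substitutions/site) are in the range typical of
conserved single-copy mammalian ortholog proteins. Default gene length is
300 sites (configurable, optionally drawn from a range to emulate
ortholog length variation). The root sequence is drawn from π and each
branch samples the child from the parent's transition row; every
ancestral sequence and per-branch substitution list is recorded.

Planted convergence overwrites the focal tip states at chosen sites with
a shared derived residue that differs from each focal parent's *true*
state (uniform over legal residues by default; a biased policy exists for
stress tests), recording the intended category from the true parents.
Overwriting tips — rather than re-simulating histories — gives exactly
controllable ground truth; its cost is that an injected site is slightly
adversarial for reconstruction, since the focal tip pulls its parent's
posterior toward the derived state. The simulator does not model indels,
alignment error, orthology error, rate heterogeneity or lineage-specific
composition, so passing tests demonstrate correctness of the machinery
under its own assumptions, not robustness of the biological conclusion to
violations of them.

## Validation experiments and problem sizes

The suite validates, at sizes chosen to keep the default run in minutes:

* **Exactness** — pruning likelihoods and marginal posteriors equal full
  enumeration over internal-state assignments on 3–4-tip trees (1e−10).
* **Closed forms** — equal-rates P(t), the two-sequence ML distance
  −(19/20)·ln(1 − (20/19)p), and the fixed-ancestor expected convergence
  18·p(t1)·p(t2) (1e−8).
* **Expectation oracle** — analytic expectations within 3 Monte-Carlo
  standard errors of a 200 000-replicate simulation of the same
  posteriors and branches, both modes.
* **Type-I calibration** — 50 replicates of 200 null genes × 300 sites:
  the genome-wide `p_upper < 0.05` rate stays ≤ 0.08 in both modes (the
  test is conservative in practice, since the expectation slightly
  exceeds the null mean of the MAP-based observed count).
* **Designed recovery** — with five sites planted per gene (12 genes per
  replicate, 50 replicates), the focal set is flagged and the sister
  control is not in ≥ 90% of replicates, and planted-site recall averages
  ≥ 4/5 per gene.
* **Determinism** — identical seeds give bit-identical TSVs, and a split
  batch reproduces the full batch's per-gene rows exactly.

Recall of individual branch substitutions depends on how well the focal
parents are constrained by their neighbors: with close sister taxa (the
dedicated recall test uses sisters at 0.02 substitutions/site) per-branch
recall exceeds 95%; on the deeper default tree (echidna's nearest
neighbor is platypus at 0.11 + a 0.22 stem) a terminal substitution
occasionally drags the parent's MAP state with it and recall is a few
points lower. Event-level recovery of planted sites on the default tree
averages ~85–95%.

## Known limitations

* Uniform rates across sites and time; no codon-level information.
* The null treats ancestral posteriors at distinct focal parents as
  independent; this is enforced structurally (disjoint branches) but the
  posteriors still share deep-tree data, a second-order dependence the
  Poisson null ignores.
* MAP-based observed counts undercount at poorly constrained parents,
  making the excess test mildly conservative rather than exact.
* No correction for alignment or orthology error, which in real ortholog
  sets are known to inflate apparent convergence.
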