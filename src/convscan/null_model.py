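"""Expected convergent/parallel counts and Poisson significance tests.

The null expectation integrates over the marginal ancestral posteriors at
the focal branches' parent nodes and over the branch transition
probabilities, treating disjoint focal branches as independent (enforced
structurally: a nested branch set is rejected upstream).

For one usable site and one branch pair with parent posteriors q1, q2 and
transition matrices P1, P2:

* parallel:   sum_x q1(x) q2(x) sum_{j != x} P1[x, j] P2[x, j]
* convergent: sum_{x1 != x2} q1(x1) q2(x2)
              sum_{j not in {x1, x2}} P1[x1, j] P2[x2, j]

In all-branches mode the inner sum runs over a single shared derived
residue j with j different from every branch's ancestral state, with the
product taken over all branches. Site contributions are summed over the
usable sites of the gene; Poisson additivity then justifies summing gene
expectations into the genome-wide null.

Observed counts are tested in both directions with exact Poisson tails:
``p_upper = P(X >= observed)`` flags an excess on focal branches,
``p_lower = P(X <= observed)`` a deficit on control (sister) branches.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .alignments import ProteinAlignment
from .ancestors import AncestralPosterior
from .convergence import FocalBranchSet, Mode, ObservedCounts, resolve_branches
from .models import SubstitutionModel
from .trees import PhyloTree

__all__ = [
    "ExpectedCounts",
    "ConvergenceResult",
    "site_expectations",
    "expected_counts",
    "poisson_tail",
    "make_result",
    "genome_wide_test",
    "contrast_branch_sets",
]


@dataclass(frozen=True)
class ExpectedCounts:
    convergent: float
    parallel: float

    @property
    def combined(self) -> float:
        return self.convergent + self.parallel


@dataclass
class ConvergenceResult:
    """Observed vs expected convergence for one gene (or the aggregate)."""

    gene: str
    branch_set: str
    mode: Mode
    obs_convergent: int
    obs_parallel: int
    exp_convergent: float
    exp_parallel: float
    p_upper: float
    p_lower: float
    n_usable_sites: int

    @property
    def obs_combined(self) -> int:
        return self.obs_convergent + self.obs_parallel

    @property
    def exp_combined(self) -> float:
        return self.exp_convergent + self.exp_parallel


def _pair_site_expectations(
    q1: np.ndarray, q2: np.ndarray, P1: np.ndarray, P2: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-site (convergent, parallel) expectations for one branch pair.

    Vectorized over sites: ``A_b[s, j] = sum_{x != j} q_b(x) P_b[x, j]`` is
    the probability that branch b substitutes INTO j; the pair sum over a
    shared j with x1 != j and x2 != j covers parallel + convergent, and the
    diagonal (x1 = x2) term isolates the parallel part.
    """
    A1 = q1 @ P1 - q1 * np.diag(P1)[None, :]
    A2 = q2 @ P2 - q2 * np.diag(P2)[None, :]
    combined = (A1 * A2).sum(axis=1)
    # parallel: same ancestral residue x on both branches, any shared j != x
    c = (P1 * P2).sum(axis=1) - np.diag(P1) * np.diag(P2)
    parallel = (q1 * q2) @ c
    # the subtraction may round to a tiny negative; rates are nonnegative
    return np.maximum(combined - parallel, 0.0), parallel


def _all_branch_site_expectations(
    qs: list[np.ndarray], Ps: list[np.ndarray]
) -> tuple[np.ndarray, np.ndarray]:
    """Per-site expectations when ALL k branches must share the derived j."""
    A = [q @ P - q * np.diag(P)[None, :] for q, P in zip(qs, Ps)]
    combined = np.prod(A, axis=0).sum(axis=1)
    # parallel: all k branches start from the same x and all move to j != x
    qprod = np.prod(qs, axis=0)  # (sites, 20)
    Pprod = np.prod(Ps, axis=0)  # (20, 20)
    c = Pprod.sum(axis=1) - np.diag(Pprod)
    parallel = qprod @ c
    return np.maximum(combined - parallel, 0.0), parallel


def site_expectations(
    qs: list[np.ndarray],
    Ps: list[np.ndarray],
    mode: Mode = "all-branches",
) -> tuple[np.ndarray, np.ndarray]:
    """Per-site (convergent, parallel) expectations from raw ingredients.

    ``qs`` are the (n_sites, 20) parent posteriors of each branch and
    ``Ps`` the matching (20, 20) transition matrices. This is the
    site-level core of :func:`expected_counts`, exposed for closed-form
    and Monte-Carlo cross-checks.
    """
    if len(qs) != len(Ps) or len(qs) < 2:
        raise ValueError("need one posterior and one transition matrix per branch")
    if mode == "all-branches":
        return _all_branch_site_expectations(qs, Ps)
    n_sites = qs[0].shape[0]
    conv = np.zeros(n_sites)
    par = np.zeros(n_sites)
    for i in range(len(qs)):
        for j in range(i + 1, len(qs)):
            c, p = _pair_site_expectations(qs[i], qs[j], Ps[i], Ps[j])
            conv += c
            par += p
    return conv, par


def expected_counts(
    tree: PhyloTree,
    alignment: ProteinAlignment,
    ancestors: AncestralPosterior,
    model: SubstitutionModel,
    branch_set: FocalBranchSet,
    usable: np.ndarray | None = None,
) -> ExpectedCounts:
    """Model-expected convergent/parallel counts over a gene's usable sites."""
    from .convergence import usable_site_mask

    nodes = resolve_branches(tree, branch_set)
    if usable is None:
        usable = usable_site_mask(tree, alignment, nodes)
    qs = [ancestors.node_probs(int(tree.parent[v]))[usable] for v in nodes]
    Ps = [model.transition_probs(float(tree.lengths[v])) for v in nodes]
    if not usable.any():
        return ExpectedCounts(0.0, 0.0)
    conv, par = site_expectations(qs, Ps, branch_set.mode)
    return ExpectedCounts(float(conv.sum()), float(par.sum()))


def poisson_tail(observed: int, lam: float) -> tuple[float, float]:
    """Exact two-directional Poisson tails.

    Returns ``(p_upper, p_lower)`` with ``p_upper = P(X >= observed)`` and
    ``p_lower = P(X <= observed)`` for X ~ Poisson(lam). The degenerate
    ``lam = 0`` gives p_upper 1 iff observed is 0 (else 0) and p_lower 1.
    """
    if observed < 0 or int(observed) != observed:
        raise ValueError(f"observed count must be a nonnegative integer: {observed}")
    if lam < 0:
        raise ValueError(f"Poisson mean must be nonnegative: {lam}")
    observed = int(observed)
    if lam == 0:
        return (1.0 if observed == 0 else 0.0, 1.0)
    p_upper = float(stats.poisson.sf(observed - 1, lam))
    p_lower = float(stats.poisson.cdf(observed, lam))
    return p_upper, p_lower


def make_result(
    observed: ObservedCounts, expected: ExpectedCounts, n_usable_sites: int
) -> ConvergenceResult:
    p_upper, p_lower = poisson_tail(observed.combined, expected.combined)
    return ConvergenceResult(
        gene=observed.gene,
        branch_set=observed.branch_set,
        mode=observed.mode,
        obs_convergent=observed.convergent,
        obs_parallel=observed.parallel,
        exp_convergent=expected.convergent,
        exp_parallel=expected.parallel,
        p_upper=p_upper,
        p_lower=p_lower,
        n_usable_sites=n_usable_sites,
    )


def genome_wide_test(
    results: list[ConvergenceResult],
) -> tuple[ConvergenceResult, np.ndarray]:
    """Aggregate Poisson test plus BH-adjusted per-gene q-values.

    Observed and expected counts are summed over genes (Poisson
    expectations add); per-gene ``p_upper`` values are Benjamini–Hochberg
    adjusted across genes for reporting only.
    """
    if not results:
        raise ValueError("no per-gene results to aggregate")
    sets = {(r.branch_set, r.mode) for r in results}
    if len(sets) > 1:
        raise ValueError(f"cannot aggregate across branch sets/modes: {sets}")
    obs_c = sum(r.obs_convergent for r in results)
    obs_p = sum(r.obs_parallel for r in results)
    exp_c = sum(r.exp_convergent for r in results)
    exp_p = sum(r.exp_parallel for r in results)
    p_upper, p_lower = poisson_tail(obs_c + obs_p, exp_c + exp_p)
    aggregate = ConvergenceResult(
        gene="GENOME_WIDE",
        branch_set=results[0].branch_set,
        mode=results[0].mode,
        obs_convergent=obs_c,
        obs_parallel=obs_p,
        exp_convergent=exp_c,
        exp_parallel=exp_p,
        p_upper=p_upper,
        p_lower=p_lower,
        n_usable_sites=sum(r.n_usable_sites for r in results),
    )
    q_values = multipletests([r.p_upper for r in results], method="fdr_bh")[1]
    return aggregate, q_values


@dataclass
class BranchSetContrast:
    """Side-by-side excess/deficit report for a focal vs control set."""

    focal: ConvergenceResult
    control: ConvergenceResult
    focal_ratio: float
    control_ratio: float
    focal_excess: bool
    control_deficit: bool


def contrast_branch_sets(
    focal: ConvergenceResult,
    control: ConvergenceResult,
    alpha: float = 0.05,
) -> BranchSetContrast:
    """Contrast an excess on focal branches with a deficit on controls."""

    def ratio(r: ConvergenceResult) -> float:
        return r.obs_combined / r.exp_combined if r.exp_combined > 0 else np.nan

    return BranchSetContrast(
        focal=focal,
        control=control,
        focal_ratio=ratio(focal),
        control_ratio=ratio(control),
        focal_excess=focal.p_upper < alpha,
        control_deficit=control.p_lower < alpha,
    )
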