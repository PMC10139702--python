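"""Slow, transparent reference computations for validation.

These deliberately avoid the pruning recursion: likelihoods and posteriors
are obtained by summing over every joint assignment of states to internal
nodes, and expected convergence counts by direct Monte-Carlo simulation of
ancestors and branch outcomes. They are exponential in the number of
internal nodes and exist only to cross-check the fast implementations on
small trees.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

from .alignments import ProteinAlignment
from .alphabet import MISSING, N_STATES

from .likelihood import branch_transition_matrices, tip_codes
from .models import SubstitutionModel
from .trees import PhyloTree

__all__ = [
    "enumeration_site_likelihood",
    "enumeration_gene_log_likelihood",
    "enumeration_posteriors",
    "monte_carlo_expected_counts",
]


def _joint_terms(
    tree: PhyloTree, codes: np.ndarray, P: np.ndarray, site: int
):
    """Yield (assignment, probability) over all internal-state assignments."""
    internal = [v for v in range(tree.n_nodes) if tree.children[v]]
    pi_index = {v: i for i, v in enumerate(internal)}
    root = tree.root
    for states in itertools.product(range(N_STATES), repeat=len(internal)):
        assign = dict(zip(internal, states))
        for t in range(tree.n_tips):
            assign[t] = int(codes[t, site])
        prob = 1.0
        for v in range(tree.n_nodes):
            if v == root:
                continue
            p_state = assign[int(tree.parent[v])]
            c_state = assign[v]
            if c_state == MISSING:  # missing tip: marginalized, factor 1
                continue
            prob *= P[v][p_state, c_state]
        yield assign, prob
    del pi_index


def enumeration_site_likelihood(
    tree: PhyloTree,
    alignment: ProteinAlignment,
    model: SubstitutionModel,
    site: int,
) -> float:
    """Site likelihood by explicit summation (not log scale)."""
    codes = tip_codes(tree, alignment)
    P = branch_transition_matrices(tree, model)
    root = tree.root
    total = 0.0
    for assign, prob in _joint_terms(tree, codes, P, site):
        total += model.frequencies[assign[root]] * prob
    return total


def enumeration_gene_log_likelihood(
    tree: PhyloTree, alignment: ProteinAlignment, model: SubstitutionModel
) -> float:
    return sum(
        math.log(enumeration_site_likelihood(tree, alignment, model, s))
        for s in range(alignment.length)
    )


def enumeration_posteriors(
    tree: PhyloTree, alignment: ProteinAlignment, model: SubstitutionModel
) -> dict[int, np.ndarray]:
    """Exact marginal posteriors per internal node by enumeration."""
    codes = tip_codes(tree, alignment)
    P = branch_transition_matrices(tree, model)
    internal = [v for v in range(tree.n_nodes) if tree.children[v]]
    root = tree.root
    out = {v: np.zeros((alignment.length, N_STATES)) for v in internal}
    for site in range(alignment.length):
        for assign, prob in _joint_terms(tree, codes, P, site):
            w = model.frequencies[assign[root]] * prob
            for v in internal:
                out[v][site, assign[v]] += w
    for v in internal:
        out[v] /= out[v].sum(axis=1, keepdims=True)
    return out


def monte_carlo_expected_counts(
    tree: PhyloTree,
    parent_posteriors: list[np.ndarray],
    branch_lengths: list[float],
    model: SubstitutionModel,
    mode: str = "all-branches",
    n_replicates: int = 200_000,
    seed: int = 0,
) -> tuple[dict[str, float], dict[str, float]]:
    """Monte-Carlo estimate of per-site expected convergence at ONE site.

    Samples each branch's ancestral state from its parent posterior
    (length-20 vector), evolves it by the branch transition matrix, and
    counts shared derived states. Returns (means, standard errors) for
    keys ``convergent``, ``parallel``, ``combined``.
    """
    rng = np.random.default_rng(seed)
    k = len(parent_posteriors)
    P = [model.transition_probs(t) for t in branch_lengths]
    anc = np.column_stack(
        [rng.choice(N_STATES, size=n_replicates, p=q) for q in parent_posteriors]
    )
    cum = [np.cumsum(p, axis=1) for p in P]
    der = np.column_stack(
        [
            (cum[b][anc[:, b]] > rng.random(n_replicates)[:, None]).argmax(axis=1)
            for b in range(k)
        ]
    )
    changed = der != anc

    def tallies(idx: list[int]) -> tuple[np.ndarray, np.ndarray]:
        a, d = anc[:, idx], der[:, idx]
        ch = changed[:, idx]
        event = ch.all(axis=1) & (d == d[:, [0]]).all(axis=1)
        par = event & (a == a[:, [0]]).all(axis=1)
        return event & ~par, par

    if mode == "all-branches":
        conv, par = tallies(list(range(k)))
        conv_n, par_n = conv.astype(float), par.astype(float)
    else:
        conv_n = np.zeros(n_replicates)
        par_n = np.zeros(n_replicates)
        for i in range(k):
            for j in range(i + 1, k):
                conv, par = tallies([i, j])
                conv_n += conv
                par_n += par
    comb_n = conv_n + par_n
    means = {
        "convergent": float(conv_n.mean()),
        "parallel": float(par_n.mean()),
        "combined": float(comb_n.mean()),
    }
    ses = {
        "convergent": float(conv_n.std(ddof=1) / math.sqrt(n_replicates)),
        "parallel": float(par_n.std(ddof=1) / math.sqrt(n_replicates)),
        "combined": float(comb_n.std(ddof=1) / math.sqrt(n_replicates)),
    }
    return means, ses
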