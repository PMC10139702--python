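"""Felsenstein pruning on a rooted tree, and per-gene branch-length ML.

All per-site quantities are vectorized over alignment columns: a partials
array has shape ``(n_sites, 20)`` per node, with a per-node, per-site log
scaling factor to prevent underflow on long paths.

Gap and 'X' columns are missing data: their tip partial is all ones, so a
column that is entirely missing contributes exactly zero log-likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .alignments import AlignmentError, ProteinAlignment
from .alphabet import MISSING, N_STATES
from .models import SubstitutionModel
from .trees import PhyloTree

__all__ = [
    "SitePartials",
    "compute_partials",
    "site_log_likelihoods",
    "prune_site_likelihood",
    "gene_log_likelihood",
    "estimate_branch_lengths",
    "branch_transition_matrices",
    "outside_partials",
    "tip_codes",
]

_TINY = np.finfo(float).tiny


@dataclass
class SitePartials:
    """Post-order conditional likelihoods.

    ``partials[v]`` is the (n_sites, 20) conditional likelihood of the data
    below node ``v`` given its state, up to ``exp(scale_log[v])`` per site.
    """

    partials: np.ndarray  # (n_nodes, n_sites, 20)
    scale_log: np.ndarray  # (n_nodes, n_sites)

    def __iter__(self):
        return iter((self.partials, self.scale_log))


def tip_codes(tree: PhyloTree, alignment: ProteinAlignment) -> np.ndarray:
    """Alignment rows in tree tip order; errors name the missing tip."""
    rows = []
    for name in tree.tip_names:
        if name not in alignment:
            raise AlignmentError(
                f"tree tip {name!r} has no sequence in the alignment"
            )
        rows.append(alignment.row(name))
    return np.vstack(rows)


def branch_transition_matrices(
    tree: PhyloTree, model: SubstitutionModel
) -> np.ndarray:
    """P(t) for every branch, indexed by child node (identity at the root)."""
    P = np.empty((tree.n_nodes, N_STATES, N_STATES))
    for v in range(tree.n_nodes):
        if tree.parent[v] == -1:
            P[v] = np.eye(N_STATES)
        else:
            P[v] = model.transition_probs(float(tree.lengths[v]))
    return P


def _tip_partial(codes_row: np.ndarray) -> np.ndarray:
    n_sites = codes_row.shape[0]
    L = np.zeros((n_sites, N_STATES))
    missing = codes_row == MISSING
    L[missing] = 1.0
    obs = ~missing
    L[np.where(obs)[0], codes_row[obs].astype(np.int64)] = 1.0
    return L


def compute_partials(
    tree: PhyloTree,
    codes: np.ndarray,
    P: np.ndarray,
) -> SitePartials:
    """Post-order pass over all sites.

    Parameters
    ----------
    codes : (n_tips, n_sites) int8
        Encoded tip data in tree tip order (see :func:`tip_codes`).
    P : (n_nodes, 20, 20)
        Per-branch transition matrices indexed by child node.
    """
    n_sites = codes.shape[1]
    partials = np.empty((tree.n_nodes, n_sites, N_STATES))
    scale_log = np.zeros((tree.n_nodes, n_sites))
    for v in tree.postorder():
        if not tree.children[v]:
            partials[v] = _tip_partial(codes[v])
            continue
        acc = np.ones((n_sites, N_STATES))
        sc = np.zeros(n_sites)
        for c in tree.children[v]:
            acc *= partials[c] @ P[c].T
            sc += scale_log[c]
        m = acc.max(axis=1)
        nz = m > 0
        acc[nz] /= m[nz, None]
        with np.errstate(divide="ignore"):
            sc += np.where(nz, np.log(np.maximum(m, _TINY)), -np.inf)
        partials[v] = acc
        scale_log[v] = sc
    return SitePartials(partials=partials, scale_log=scale_log)


def site_log_likelihoods(
    tree: PhyloTree,
    alignment: ProteinAlignment,
    model: SubstitutionModel,
) -> np.ndarray:
    """Per-column log-likelihoods (−inf where the data are impossible)."""
    codes = tip_codes(tree, alignment)
    P = branch_transition_matrices(tree, model)
    partials, scale_log = compute_partials(tree, codes, P)
    root = tree.root
    lik = partials[root] @ model.frequencies
    with np.errstate(divide="ignore"):
        return np.where(lik > 0, np.log(np.maximum(lik, _TINY)), -np.inf) + scale_log[root]


def prune_site_likelihood(
    tree: PhyloTree,
    alignment: ProteinAlignment,
    model: SubstitutionModel,
    site: int,
) -> float:
    """Log-likelihood of one alignment column."""
    if not 0 <= site < alignment.length:
        raise IndexError(f"site {site} out of range for length {alignment.length}")
    return float(site_log_likelihoods(tree, alignment, model)[site])


def gene_log_likelihood(
    tree: PhyloTree,
    alignment: ProteinAlignment,
    model: SubstitutionModel,
) -> float:
    """Total log-likelihood over all columns (sites independent)."""
    return float(site_log_likelihoods(tree, alignment, model).sum())


# ---------------------------------------------------------------------------
# branch-length estimation


def outside_partials(
    tree: PhyloTree,
    partials: np.ndarray,
    scale_log: np.ndarray,
    P: np.ndarray,
    pi: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Pre-order (outside) pass complementing :func:`compute_partials`.

    Returns ``(G, G_log, F, F_log)``. ``G[c][s, x]`` is (up to scaling) the
    likelihood of all data outside the subtree of ``c`` as a function of
    the state ``x`` at c's PARENT — i.e. excluding branch c's own
    transition matrix — with the equilibrium frequencies folded in at the
    root. ``F[v][s, x]`` is the same quantity as a function of the state at
    ``v`` itself (``F = G @ P``); the marginal posterior at ``v`` is
    proportional to ``F[v] * partials[v]`` per site.
    """
    n_sites = partials.shape[1]
    G = np.empty_like(partials)
    G_log = np.zeros_like(scale_log)
    # F[v]: outside likelihood as a function of the state AT v
    F = np.empty_like(partials)
    F_log = np.zeros_like(scale_log)
    root = tree.root
    F[root] = pi[None, :]
    F_log[root] = 0.0
    for v in tree.preorder():
        kids = tree.children[v]
        msgs = {c: partials[c] @ P[c].T for c in kids}
        for c in kids:
            acc = F[v].copy()
            sc = F_log[v].copy()
            for d in kids:
                if d != c:
                    acc = acc * msgs[d]
                    sc = sc + scale_log[d]
            m = acc.max(axis=1)
            nz = m > 0
            acc[nz] /= m[nz, None]
            with np.errstate(divide="ignore"):
                sc += np.where(nz, np.log(np.maximum(m, _TINY)), -np.inf)
            G[c] = acc
            G_log[c] = sc
            F[c] = acc @ P[c]
            F_log[c] = sc
    G[root] = np.nan  # no branch above the root
    G_log[root] = 0.0
    return G, G_log, F, F_log


def _branch_loglik(
    G_c: np.ndarray,
    G_log_c: np.ndarray,
    L_c: np.ndarray,
    L_log_c: np.ndarray,
    Pt: np.ndarray,
) -> float:
    lik = np.einsum("sx,xy,sy->s", G_c, Pt, L_c)
    with np.errstate(divide="ignore"):
        logs = np.where(lik > 0, np.log(np.maximum(lik, _TINY)), -np.inf)
    return float((logs + G_log_c + L_log_c).sum())


def estimate_branch_lengths(
    tree: PhyloTree,
    alignment: ProteinAlignment,
    model: SubstitutionModel,
    t_max: float = 10.0,
    tol: float = 1e-6,
    max_sweeps: int = 50,
) -> tuple[PhyloTree, float, bool]:
    """Coordinate-wise ML branch lengths on a fixed topology.

    Each branch is optimized by bounded scalar minimization on
    ``[0, t_max]``; sweeps repeat until the log-likelihood gain per sweep
    drops below ``tol``. For a bifurcating root only the SUM of the two
    root-adjacent branch lengths is identifiable under a reversible model,
    so that pair is optimized jointly on its sum with the split kept
    proportional to the input tree.

    Returns
    -------
    (tree, log_likelihood, converged)
        ``converged`` is False when ``max_sweeps`` was exhausted; the
        best-so-far tree is still returned.
    """
    work = tree.copy()
    codes = tip_codes(work, alignment)
    pi = model.frequencies
    root = work.root
    root_kids = work.children[root]
    joint_root_pair = len(root_kids) == 2

    free_branches = [
        v for v in range(work.n_nodes) if work.parent[v] != -1
    ]
    if joint_root_pair:
        free_branches = [v for v in free_branches if v not in root_kids]

    def full_loglik() -> float:
        P = branch_transition_matrices(work, model)
        partials, scale_log = compute_partials(work, codes, P)
        lik = partials[root] @ pi
        with np.errstate(divide="ignore"):
            logs = np.where(lik > 0, np.log(np.maximum(lik, _TINY)), -np.inf)
        return float((logs + scale_log[root]).sum())

    prev = full_loglik()
    converged = False
    for _ in range(max_sweeps):
        for v in free_branches:
            P = branch_transition_matrices(work, model)
            partials, scale_log = compute_partials(work, codes, P)
            G, G_log, _, _ = outside_partials(work, partials, scale_log, P, pi)

            def neg(t: float, v: int = v) -> float:
                return -_branch_loglik(
                    G[v], G_log[v], partials[v], scale_log[v], model.transition_probs(t)
                )

            res = minimize_scalar(neg, bounds=(0.0, t_max), method="bounded", options={"xatol": 1e-8})
            if -res.fun >= -neg(float(work.lengths[v])):
                work.lengths[v] = float(res.x)

        if joint_root_pair:
            c1, c2 = root_kids
            P = branch_transition_matrices(work, model)
            partials, scale_log = compute_partials(work, codes, P)
            s0 = float(work.lengths[c1] + work.lengths[c2])
            frac = 0.5 if s0 == 0 else float(work.lengths[c1]) / s0
            piL1 = partials[c1] * pi[None, :]

            def neg_pair(s: float) -> float:
                return -_branch_loglik(
                    piL1, scale_log[c1], partials[c2], scale_log[c2],
                    model.transition_probs(s),
                )

            res = minimize_scalar(neg_pair, bounds=(0.0, 2 * t_max), method="bounded", options={"xatol": 1e-8})
            if -res.fun >= -neg_pair(s0):
                work.lengths[c1] = frac * float(res.x)
                work.lengths[c2] = (1 - frac) * float(res.x)

        cur = full_loglik()
        if cur - prev < tol:
            converged = True
            prev = max(cur, prev)
            break
        prev = cur
    return work, prev, converged
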