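"""Marginal (empirical-Bayes) ancestral reconstruction.

For every internal node v and site s the exact marginal posterior
``P(state(v) = x | tips, tree, model)`` is obtained from the product of the
inside (post-order) and outside (pre-order) partials at v, normalized per
site. The maximum-a-posteriori (MAP) residue is the reported ancestral
state; exact ties are broken alphabetically by one-letter code and flagged.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .alignments import ProteinAlignment
from .alphabet import AA_ORDER, ALPHABETICAL_INDICES
from .likelihood import (
    branch_transition_matrices,
    compute_partials,
    outside_partials,
    tip_codes,
)
from .models import SubstitutionModel
from .trees import PhyloTree

__all__ = ["AncestralPosterior", "marginal_posteriors", "map_ancestral_sequences"]

#: Posterior-gap below which the top two states count as an exact tie.
TIE_DELTA = 1e-9

#: Reporting threshold for a low-confidence MAP ancestor (not a filter).
LOW_CONFIDENCE = 0.8


@dataclass
class AncestralPosterior:
    """Per-internal-node, per-site posterior distributions over residues.

    Attributes
    ----------
    node_ids : (n_internal,) int array
        Tree node indices, in the order of the remaining arrays.
    probs : (n_internal, n_sites, 20) array
        Posterior probability vectors (each sums to 1).
    map_state : (n_internal, n_sites) int8 array
        Posterior-mode residue index (alphabetical tie-break).
    map_prob : (n_internal, n_sites) array
        Posterior probability of the mode.
    ambiguous : (n_internal, n_sites) bool array
        True where the top two posteriors differ by less than TIE_DELTA.
    """

    node_ids: np.ndarray
    probs: np.ndarray
    map_state: np.ndarray
    map_prob: np.ndarray
    ambiguous: np.ndarray

    def __post_init__(self) -> None:
        self._row = {int(v): i for i, v in enumerate(self.node_ids)}

    def node_row(self, node: int) -> int:
        return self._row[int(node)]

    def node_probs(self, node: int) -> np.ndarray:
        """(n_sites, 20) posterior matrix for one internal node."""
        return self.probs[self.node_row(node)]

    def node_map(self, node: int) -> np.ndarray:
        return self.map_state[self.node_row(node)]

    def to_tsv(self, path: str | Path) -> None:
        """Audit dump: one row per (node, site) with all 20 probabilities."""
        with open(path, "w") as fh:
            cols = "\t".join(AA_ORDER)
            fh.write(f"node\tsite\tmap\tmap_prob\tambiguous\t{cols}\n")
            for i, v in enumerate(self.node_ids):
                for s in range(self.probs.shape[1]):
                    p = "\t".join(f"{x:.6g}" for x in self.probs[i, s])
                    fh.write(
                        f"{int(v)}\t{s}\t{AA_ORDER[self.map_state[i, s]]}\t"
                        f"{self.map_prob[i, s]:.6g}\t"
                        f"{int(self.ambiguous[i, s])}\t{p}\n"
                    )


def _map_with_alphabetical_ties(probs: np.ndarray) -> np.ndarray:
    """Argmax over the residue axis, exact ties to the earliest letter."""
    order = np.array(ALPHABETICAL_INDICES)
    # scanning in alphabetical order, argmax keeps the first maximum
    reordered = probs[..., order]
    return order[np.argmax(reordered, axis=-1)].astype(np.int8)


def marginal_posteriors(
    tree: PhyloTree,
    alignment: ProteinAlignment,
    model: SubstitutionModel,
) -> AncestralPosterior:
    """Exact marginal ancestral posteriors at every internal node."""
    codes = tip_codes(tree, alignment)
    P = branch_transition_matrices(tree, model)
    partials, scale_log = compute_partials(tree, codes, P)
    _, _, F, _ = outside_partials(tree, partials, scale_log, P, model.frequencies)

    internal = np.array(
        [v for v in range(tree.n_nodes) if tree.children[v]], dtype=int
    )
    w = F[internal] * partials[internal]
    total = w.sum(axis=-1, keepdims=True)
    if (total <= 0).any():
        raise ValueError(
            "zero site likelihood: the data are impossible under this tree/model"
        )
    probs = w / total
    map_state = _map_with_alphabetical_ties(probs)
    map_prob = np.take_along_axis(probs, map_state[..., None].astype(int), axis=-1)[
        ..., 0
    ]
    part = np.partition(probs, 18, axis=-1)
    ambiguous = (part[..., 19] - part[..., 18]) < TIE_DELTA
    return AncestralPosterior(
        node_ids=internal,
        probs=probs,
        map_state=map_state,
        map_prob=map_prob,
        ambiguous=ambiguous,
    )


def map_ancestral_sequences(posteriors: AncestralPosterior) -> dict[int, str]:
    """Posterior-mode residue string per internal node (keyed by node id)."""
    return {
        int(v): "".join(AA_ORDER[c] for c in posteriors.map_state[i])
        for i, v in enumerate(posteriors.node_ids)
    }
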