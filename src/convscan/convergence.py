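"""Detection of convergent and parallel substitutions on focal branches.

A *focal branch set* names two or more branches of the species tree —
here, typically the terminal branches of the three independently
myrmecophagous lineages (anteater, echidna, pangolin), or of their
non-myrmecophagous sister species. On each focal branch a substitution is
called where the MAP ancestral state at the branch's parent differs from
the state at its child; for a terminal branch the child state is the
observed tip residue (extant sequences are data, never reconstructed).

A site yields an event when branches acquired the same derived residue:
*parallel* if every contributing branch started from the same ancestral
residue, *convergent* if at least two ancestral residues differ. In
``all-branches`` mode every branch of the set must substitute to the shared
derived state; in ``pairwise`` mode each unordered pair of branches is
scored separately.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .alignments import ProteinAlignment
from .alphabet import AA_ORDER, MISSING
from .ancestors import AncestralPosterior
from .trees import PhyloTree, TreeError

__all__ = [
    "FocalBranchSet",
    "SubstitutionCall",
    "ConvergenceEvent",
    "ObservedCounts",
    "resolve_branches",
    "usable_site_mask",
    "infer_branch_substitutions",
    "classify_site",
    "count_observed",
]

Mode = Literal["all-branches", "pairwise"]


@dataclass(frozen=True)
class FocalBranchSet:
    """Named set of >= 2 disjoint branches, each given by its child node.

    A branch is specified either by a tip name (terminal branch) or by a
    sequence of tip names, meaning the branch above the MRCA of those tips.
    """

    name: str
    branches: tuple[str | tuple[str, ...], ...]
    mode: Mode = "all-branches"

    def __post_init__(self) -> None:
        if len(self.branches) < 2:
            raise ValueError(
                f"branch set {self.name!r} needs >= 2 branches, "
                f"got {len(self.branches)}"
            )
        if self.mode not in ("all-branches", "pairwise"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass(frozen=True)
class SubstitutionCall:
    """One inferred substitution on one focal branch at one site."""

    gene: str
    site: int
    branch: str
    from_state: str
    to_state: str
    from_prob: float
    to_prob: float

    def __post_init__(self) -> None:
        if self.from_state == self.to_state:
            raise ValueError("a substitution call requires from_state != to_state")


@dataclass(frozen=True)
class ConvergenceEvent:
    """Shared derived residue across branches of a set at one site."""

    gene: str
    site: int
    branch_set: str
    derived_state: str
    category: Literal["convergent", "parallel"]
    calls: tuple[SubstitutionCall, ...]


@dataclass
class ObservedCounts:
    """Per-gene observed event counts for one branch set and mode."""

    gene: str
    branch_set: str
    mode: Mode
    convergent: int
    parallel: int
    events: list[ConvergenceEvent] = field(repr=False, default_factory=list)

    @property
    def combined(self) -> int:
        return self.convergent + self.parallel


def resolve_branches(tree: PhyloTree, branch_set: FocalBranchSet) -> list[int]:
    """Child-node index of each branch; rejects nested (non-disjoint) sets."""
    nodes: list[int] = []
    labels: list[str] = []
    for spec in branch_set.branches:
        if isinstance(spec, str):
            nodes.append(tree.tip_index(spec))
            labels.append(spec)
        else:
            nodes.append(tree.mrca(list(spec)))
            labels.append("mrca(" + ",".join(spec) + ")")
    if len(set(nodes)) != len(nodes):
        raise TreeError(f"branch set {branch_set.name!r} lists a branch twice")
    for i, a in enumerate(nodes):
        for j, b in enumerate(nodes):
            if i != j and tree.is_ancestor(a, b):
                raise TreeError(
                    f"branch set {branch_set.name!r}: branch {labels[i]!r} is "
                    f"ancestral to {labels[j]!r}; focal branches must be disjoint"
                )
        if tree.parent[a] == -1:
            raise TreeError(
                f"branch set {branch_set.name!r}: the root has no branch above it"
            )
    return nodes


def usable_site_mask(
    tree: PhyloTree,
    alignment: ProteinAlignment,
    branch_nodes: Sequence[int],
) -> np.ndarray:
    """Sites where no focal-branch CHILD tip is gap/'X'.

    The same mask gates both observed counting and the null expectation, so
    the two are always computed over an identical site set.
    """
    mask = np.ones(alignment.length, dtype=bool)
    for v in branch_nodes:
        if not tree.children[v]:  # terminal branch: child state is tip data
            mask &= alignment.row(tree.tip_names[v]) != MISSING
    return mask


def _child_states(
    tree: PhyloTree,
    alignment: ProteinAlignment,
    ancestors: AncestralPosterior,
    v: int,
) -> tuple[np.ndarray, np.ndarray]:
    """(state codes, backing probabilities) along the branch child ``v``."""
    if tree.children[v]:
        row = ancestors.node_row(v)
        return ancestors.map_state[row].astype(np.int64), ancestors.map_prob[row]
    codes = alignment.row(tree.tip_names[v]).astype(np.int64)
    return codes, np.ones(alignment.length)


def infer_branch_substitutions(
    tree: PhyloTree,
    alignment: ProteinAlignment,
    ancestors: AncestralPosterior,
    branch_set: FocalBranchSet,
    gene: str = "gene",
) -> tuple[dict[int, list[SubstitutionCall]], np.ndarray]:
    """Substitution calls per site on every branch of the set.

    Returns ``(calls_by_site, usable)`` where ``usable`` is the boolean
    site mask shared with the null model.
    """
    nodes = resolve_branches(tree, branch_set)
    usable = usable_site_mask(tree, alignment, nodes)
    labels = [_branch_label(tree, v) for v in nodes]
    calls: dict[int, list[SubstitutionCall]] = {}
    for v, label in zip(nodes, labels):
        parent_row = ancestors.node_row(int(tree.parent[v]))
        pa_state = ancestors.map_state[parent_row].astype(np.int64)
        pa_prob = ancestors.map_prob[parent_row]
        ch_state, ch_prob = _child_states(tree, alignment, ancestors, v)
        changed = usable & (pa_state != ch_state) & (ch_state != MISSING)
        for s in np.where(changed)[0]:
            calls.setdefault(int(s), []).append(
                SubstitutionCall(
                    gene=gene,
                    site=int(s),
                    branch=label,
                    from_state=AA_ORDER[pa_state[s]],
                    to_state=AA_ORDER[ch_state[s]],
                    from_prob=float(pa_prob[s]),
                    to_prob=float(ch_prob[s]),
                )
            )
    return calls, usable


def _branch_label(tree: PhyloTree, v: int) -> str:
    if not tree.children[v]:
        return tree.tip_names[v]
    below = sorted(
        tree.tip_names[t] for t in range(tree.n_tips) if tree.is_ancestor(v, t)
    )
    return "mrca(" + ",".join(below) + ")"


def _event(
    calls: Sequence[SubstitutionCall], gene: str, branch_set: str
) -> ConvergenceEvent:
    derived = calls[0].to_state
    froms = {c.from_state for c in calls}
    category = "parallel" if len(froms) == 1 else "convergent"
    return ConvergenceEvent(
        gene=gene,
        site=calls[0].site,
        branch_set=branch_set,
        derived_state=derived,
        category=category,
        calls=tuple(sorted(calls, key=lambda c: c.branch)),
    )


def classify_site(
    calls: Sequence[SubstitutionCall],
    branch_set: FocalBranchSet,
    n_branches: int,
    gene: str = "gene",
) -> list[ConvergenceEvent]:
    """Events at one site, per the set's mode.

    all-branches: one event iff every branch substituted to the same
    derived residue. pairwise: one event per unordered branch pair sharing
    a derived residue.
    """
    if not calls:
        return []
    if branch_set.mode == "all-branches":
        if len(calls) < n_branches:
            return []
        derived = {c.to_state for c in calls}
        if len(derived) != 1:
            return []
        return [_event(calls, gene, branch_set.name)]
    events = []
    ordered = sorted(calls, key=lambda c: c.branch)
    for i in range(len(ordered)):
        for j in range(i + 1, len(ordered)):
            if ordered[i].to_state == ordered[j].to_state:
                events.append(
                    _event([ordered[i], ordered[j]], gene, branch_set.name)
                )
    return events


def count_observed(
    tree: PhyloTree,
    alignment: ProteinAlignment,
    ancestors: AncestralPosterior,
    branch_set: FocalBranchSet,
    gene: str = "gene",
) -> tuple[ObservedCounts, np.ndarray]:
    """Observed convergent/parallel counts for one gene and branch set."""
    calls_by_site, usable = infer_branch_substitutions(
        tree, alignment, ancestors, branch_set, gene=gene
    )
    n_branches = len(branch_set.branches)
    events: list[ConvergenceEvent] = []
    for site in sorted(calls_by_site):
        events.extend(
            classify_site(calls_by_site[site], branch_set, n_branches, gene=gene)
        )
    counts = ObservedCounts(
        gene=gene,
        branch_set=branch_set.name,
        mode=branch_set.mode,
        convergent=sum(e.category == "convergent" for e in events),
        parallel=sum(e.category == "parallel" for e in events),
        events=events,
    )
    return counts, usable
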