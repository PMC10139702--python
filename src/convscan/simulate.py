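"""Seeded simulation of ortholog alignments with known substitution history.

The default study design mirrors a 13-taxon mammal phylogeny with three
independently myrmecophagous tips — anteater (Xenarthra), echidna
(Monotremata) and pangolin (Pholidota) — in disjoint subtrees, plus their
five designated non-myrmecophagous sister species (elephant, platypus,
dog, cat, giant panda). Branch lengths are amino-acid substitutions per
site, in the range typical of single-copy mammalian ortholog proteins.

Sequences evolve site-independently under a reversible empirical model:
the root is drawn from the equilibrium frequencies and each branch samples
the child state from the parent's transition-probability row. The full
per-branch substitution history and every ancestral sequence are recorded,
so reconstruction and detection can be scored against the truth.

Convergent sites are injected by overwriting the focal-branch tip states
with a shared derived residue that differs from each focal parent's true
state; the registry records the intended site, branches, derived state and
category (parallel when the true parents agree, convergent otherwise).
Non-focal taxa are untouched, so injected datasets remain null data for
the sister branches.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .alignments import AlignmentError, ProteinAlignment
from .alphabet import AA_ORDER, N_STATES
from .models import SubstitutionModel, load_empirical_model
from .trees import PhyloTree

__all__ = [
    "FOCAL_TIPS",
    "SISTER_TIPS",
    "default_tree",
    "SimulationConfig",
    "SimTruth",
    "simulate_gene",
    "inject_convergence",
    "simulate_dataset",
    "write_dataset",
    "read_dataset",
]

#: The three independently myrmecophagous lineages.
FOCAL_TIPS = ("anteater", "echidna", "pangolin")

#: Their non-myrmecophagous sister species, as in the contrast analysis.
SISTER_TIPS = ("dog", "cat", "giant_panda", "elephant", "platypus")

# 13-taxon mammal topology: monotremes sister to therians; marsupial
# outgroup to placentals; anteater with elephant (Atlantogenata side),
# pangolin sister to the carnivores within Laurasiatheria. Lengths are
# amino-acid substitutions/site typical of conserved mammalian proteins.
_DEFAULT_NEWICK = (
    "((platypus:0.11,echidna:0.09):0.22,"
    "(opossum:0.16,"
    "((anteater:0.08,elephant:0.09):0.05,"
    "((human:0.06,mouse:0.12):0.04,"
    "(cow:0.09,(horse:0.07,"
    "((dog:0.05,(cat:0.05,giant_panda:0.05):0.02):0.03,"
    "pangolin:0.08):0.02):0.01):0.02):0.03):0.05):0.12);"
)


def default_tree() -> PhyloTree:
    """The default 13-tip study tree (three focal tips, five sisters)."""
    return PhyloTree.from_newick(_DEFAULT_NEWICK)


@dataclass(frozen=True)
class SimulationConfig:
    """Reproducible description of one synthetic ortholog dataset.

    ``sites_per_gene`` may be a single length or an inclusive (low, high)
    range sampled per gene, emulating ortholog length variation.
    ``n_convergent_sites`` focal-convergent sites are injected per gene.
    ``derived_policy`` is ``"uniform"`` (uniform over residues legal at the
    site) or ``"biased:<residue>"`` (always that residue where legal).
    """

    seed: int
    n_genes: int = 10
    sites_per_gene: int | tuple[int, int] = 300
    model_name: str = "JTT"
    n_convergent_sites: int = 0
    derived_policy: str = "uniform"
    focal_tips: tuple[str, ...] = FOCAL_TIPS
    tree: PhyloTree = field(default_factory=default_tree)

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        lo = self.sites_per_gene if isinstance(self.sites_per_gene, int) else self.sites_per_gene[0]
        if self.n_convergent_sites > lo:
            raise ValueError("n_convergent_sites exceeds sites_per_gene")
        if self.n_convergent_sites < 0:
            raise ValueError("n_convergent_sites must be >= 0")
        for tip in self.focal_tips:
            self.tree.tip_index(tip)  # raises TreeError on a bad name

    def model(self) -> SubstitutionModel:
        return load_empirical_model(self.model_name)


@dataclass
class InjectionRecord:
    site: int
    branches: tuple[str, ...]
    derived_state: str
    category: str  # parallel | convergent (by the TRUE parental states)


@dataclass
class SimTruth:
    """Complete generating history of one simulated gene."""

    gene: str
    node_sequences: dict[int, np.ndarray]  # node index -> (n_sites,) codes
    substitutions: dict[int, list[tuple[int, int, int]]]  # child -> (site, from, to)
    injections: list[InjectionRecord] = field(default_factory=list)

    def ancestral_codes(self, node: int) -> np.ndarray:
        return self.node_sequences[node]


def _gene_rng(seed: int, gene_index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, gene_index]))


def _sample_markov(
    parent_states: np.ndarray, P: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    cum = np.cumsum(P, axis=1)
    u = rng.random(parent_states.shape[0])
    return (cum[parent_states] > u[:, None]).argmax(axis=1)


def simulate_gene(
    config: SimulationConfig, gene_index: int
) -> tuple[ProteinAlignment, SimTruth]:
    """Evolve one gene down the tree; deterministic in (seed, gene_index)."""
    rng = _gene_rng(config.seed, gene_index)
    tree = config.tree
    model = config.model()
    if isinstance(config.sites_per_gene, int):
        n_sites = config.sites_per_gene
    else:
        lo, hi = config.sites_per_gene
        n_sites = int(rng.integers(lo, hi + 1))
    gene = f"gene{gene_index:04d}"

    seqs: dict[int, np.ndarray] = {}
    subs: dict[int, list[tuple[int, int, int]]] = {}
    root = tree.root
    seqs[root] = rng.choice(N_STATES, size=n_sites, p=model.frequencies)
    for v in tree.preorder():
        if v == root:
            continue
        P = model.transition_probs(float(tree.lengths[v]))
        child = _sample_markov(seqs[int(tree.parent[v])], P, rng)
        seqs[v] = child
        diff = np.where(child != seqs[int(tree.parent[v])])[0]
        subs[v] = [
            (int(s), int(seqs[int(tree.parent[v])][s]), int(child[s])) for s in diff
        ]
    alignment = ProteinAlignment(
        names=list(tree.tip_names),
        codes=np.vstack([seqs[t] for t in range(tree.n_tips)]).astype(np.int8),
    )
    truth = SimTruth(gene=gene, node_sequences=seqs, substitutions=subs)
    if config.n_convergent_sites > 0:
        alignment, truth = inject_convergence(alignment, truth, config, rng)
    return alignment, truth


def _legal_derived(
    parent_states: list[int], policy: str, rng: np.random.Generator
) -> int | None:
    legal = [j for j in range(N_STATES) if j not in parent_states]
    if not legal:
        return None
    if policy.startswith("biased:"):
        j = AA_ORDER.index(policy.split(":", 1)[1].upper())
        return j if j in legal else None
    return int(rng.choice(legal))


def inject_convergence(
    alignment: ProteinAlignment,
    truth: SimTruth,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[ProteinAlignment, SimTruth]:
    """Overwrite focal tips at chosen sites with a shared derived residue."""
    if rng is None:
        rng = _gene_rng(config.seed, hash(truth.gene) % (2**31))
    tree = config.tree
    k = config.n_convergent_sites
    if k == 0:
        return alignment, truth
    focal_nodes = [tree.tip_index(t) for t in config.focal_tips]
    parents = {v: int(tree.parent[v]) for v in focal_nodes}
    codes = alignment.codes.copy()
    order = rng.permutation(alignment.length)
    records: list[InjectionRecord] = []
    for site in order:
        if len(records) == k:
            break
        site = int(site)
        true_parents = [int(truth.node_sequences[parents[v]][site]) for v in focal_nodes]
        j = _legal_derived(true_parents, config.derived_policy, rng)
        if j is None:
            continue
        for v in focal_nodes:
            codes[alignment.names.index(tree.tip_names[v]), site] = j
            truth.node_sequences[v][site] = j
        category = "parallel" if len(set(true_parents)) == 1 else "convergent"
        records.append(
            InjectionRecord(
                site=site,
                branches=tuple(config.focal_tips),
                derived_state=AA_ORDER[j],
                category=category,
            )
        )
    if len(records) < k:
        raise ValueError(
            f"could only place {len(records)} of {k} convergent sites: "
            "no legal derived residue at the remaining sites"
        )
    new_alignment = ProteinAlignment(names=list(alignment.names), codes=codes)
    truth.injections = sorted(records, key=lambda r: r.site)
    # recorded per-branch histories must stay consistent with the new tips
    for v in focal_nodes:
        parent_seq = truth.node_sequences[parents[v]]
        child_seq = truth.node_sequences[v]
        diff = np.where(parent_seq != child_seq)[0]
        truth.substitutions[v] = [
            (int(s), int(parent_seq[s]), int(child_seq[s])) for s in diff
        ]
    return new_alignment, truth


def simulate_dataset(
    config: SimulationConfig,
) -> tuple[list[ProteinAlignment], list[SimTruth]]:
    """All genes of the configured dataset."""
    pairs = [simulate_gene(config, i) for i in range(config.n_genes)]
    return [p[0] for p in pairs], [p[1] for p in pairs]


# ---------------------------------------------------------------------------
# on-disk layout: gene0000.fasta ... , tree.nwk, truth.tsv, config.txt


def write_dataset(
    alignments: list[ProteinAlignment],
    truths: list[SimTruth],
    config: SimulationConfig,
    out_dir: str | Path,
) -> Path:
    """Write one FASTA per gene plus tree, injection registry and config echo."""
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        for aln, truth in zip(alignments, truths):
            aln.to_fasta(out / f"{truth.gene}.fasta")
        config.tree.write_newick(out / "tree.nwk")
        with open(out / "truth.tsv", "w") as fh:
            fh.write("gene\tsite\tbranches\tderived_state\tcategory\n")
            for truth in truths:
                for rec in truth.injections:
                    fh.write(
                        f"{truth.gene}\t{rec.site}\t{','.join(rec.branches)}\t"
                        f"{rec.derived_state}\t{rec.category}\n"
                    )
        with open(out / "config.txt", "w") as fh:
            fh.write(f"seed = {config.seed}\n")
            fh.write(f"n_genes = {config.n_genes}\n")
            fh.write(f"sites_per_gene = {config.sites_per_gene}\n")
            fh.write(f"model = {config.model_name}\n")
            fh.write(f"n_convergent_sites = {config.n_convergent_sites}\n")
            fh.write(f"derived_policy = {config.derived_policy}\n")
            fh.write(f"focal_tips = {','.join(config.focal_tips)}\n")
    except OSError as exc:
        raise OSError(f"cannot write dataset under {out}: {exc}") from exc
    return out


def read_dataset(directory: str | Path) -> tuple[list[ProteinAlignment], PhyloTree]:
    """Read back a written dataset (alignments in gene order, plus tree)."""
    directory = Path(directory)
    fastas = sorted(directory.glob("*.fasta"))
    if not fastas:
        raise AlignmentError(f"no .fasta files under {directory}")
    tree = PhyloTree.from_newick(directory / "tree.nwk")
    return [ProteinAlignment.from_fasta(f) for f in fastas], tree
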