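"""Batch orchestration: per-gene analysis, aggregation and TSV reports.

Each gene runs the full chain — (optional) branch-length re-estimation on
the fixed species topology, marginal ancestral reconstruction, observed
convergent/parallel counting, model-expected counts and Poisson tests —
for every configured focal branch set. A malformed gene is quarantined in
a failures manifest and never aborts the batch.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .alignments import ProteinAlignment
from .ancestors import marginal_posteriors
from .convergence import ConvergenceEvent, FocalBranchSet, count_observed
from .likelihood import estimate_branch_lengths
from .models import SubstitutionModel, load_empirical_model, observed_frequencies
from .null_model import (
    ConvergenceResult,
    expected_counts,
    genome_wide_test,
    make_result,
)
from .trees import PhyloTree

logger = logging.getLogger("convscan")

__all__ = ["RunConfig", "run_gene", "run_batch", "analyze_gene", "BatchResult"]


@dataclass
class RunConfig:
    """Configuration of a batch run over an ortholog directory."""

    alignment_dir: str | Path
    tree_path: str | Path
    branch_sets: list[FocalBranchSet]
    model_name: str = "JTT"
    plus_f: bool = False  # replace model frequencies with observed ones
    branch_length_policy: str = "estimate"  # estimate | fixed
    output_dir: str | Path = "convscan_out"
    name_map: dict[str, str] | None = None  # FASTA name -> tree tip name
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.branch_sets:
            raise ValueError("at least one focal branch set is required")
        if self.branch_length_policy not in ("estimate", "fixed"):
            raise ValueError(
                f"branch_length_policy must be estimate|fixed, "
                f"got {self.branch_length_policy!r}"
            )


def _apply_name_map(
    alignment: ProteinAlignment, name_map: dict[str, str] | None
) -> ProteinAlignment:
    if not name_map:
        return alignment
    names = [name_map.get(n, n) for n in alignment.names]
    return ProteinAlignment(names=names, codes=alignment.codes)


def analyze_gene(
    tree: PhyloTree,
    alignment: ProteinAlignment,
    model: SubstitutionModel,
    branch_sets: list[FocalBranchSet],
    gene: str = "gene",
    estimate_lengths: bool = False,
) -> tuple[list[ConvergenceResult], list[ConvergenceEvent]]:
    """Library entry point for one gene already in memory."""
    work = tree
    if estimate_lengths:
        work, _, converged = estimate_branch_lengths(tree, alignment, model)
        if not converged:
            logger.warning("%s: branch-length optimization hit max sweeps", gene)
    ancestors = marginal_posteriors(work, alignment, model)
    results: list[ConvergenceResult] = []
    events: list[ConvergenceEvent] = []
    for bset in branch_sets:
        observed, usable = count_observed(
            work, alignment, ancestors, bset, gene=gene
        )
        expected = expected_counts(
            work, alignment, ancestors, model, bset, usable=usable
        )
        results.append(make_result(observed, expected, int(usable.sum())))
        events.extend(observed.events)
    return results, events


def run_gene(
    fasta_path: str | Path, tree: PhyloTree, config: RunConfig
) -> tuple[list[ConvergenceResult], list[ConvergenceEvent]]:
    """Analyze one gene FASTA under the run configuration."""
    fasta_path = Path(fasta_path)
    alignment = _apply_name_map(
        ProteinAlignment.from_fasta(fasta_path), config.name_map
    )
    model = load_empirical_model(config.model_name)
    if config.plus_f:
        model = load_empirical_model(
            config.model_name,
            frequencies=observed_frequencies(alignment.residue_counts()),
        )
    return analyze_gene(
        tree,
        alignment,
        model,
        config.branch_sets,
        gene=fasta_path.stem,
        estimate_lengths=config.branch_length_policy == "estimate",
    )


@dataclass
class BatchResult:
    per_gene: pd.DataFrame
    aggregate: pd.DataFrame
    events: pd.DataFrame
    failures: list[dict] = field(default_factory=list)


def _results_frame(results: list[ConvergenceResult]) -> pd.DataFrame:
    rows = [
        {
            "gene": r.gene,
            "branch_set": r.branch_set,
            "mode": r.mode,
            "obs_convergent": r.obs_convergent,
            "obs_parallel": r.obs_parallel,
            "obs_combined": r.obs_combined,
            "exp_convergent": r.exp_convergent,
            "exp_parallel": r.exp_parallel,
            "exp_combined": r.exp_combined,
            "p_upper": r.p_upper,
            "p_lower": r.p_lower,
            "n_usable_sites": r.n_usable_sites,
        }
        for r in results
    ]
    return pd.DataFrame(rows)


def _events_frame(events: list[ConvergenceEvent]) -> pd.DataFrame:
    rows = []
    for e in events:
        detail = ";".join(
            f"{c.branch}:{c.from_state}>{c.to_state}"
            f"({c.from_prob:.3f},{c.to_prob:.3f})"
            for c in e.calls
        )
        rows.append(
            {
                "gene": e.gene,
                "site": e.site,
                "branch_set": e.branch_set,
                "category": e.category,
                "derived_state": e.derived_state,
                "calls": detail,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["gene", "site", "branch_set", "category", "derived_state", "calls"],
    )


def run_batch(config: RunConfig) -> BatchResult:
    """Analyze every ``*.fasta`` under the alignment directory."""
    alignment_dir = Path(config.alignment_dir)
    fastas = sorted(alignment_dir.glob("*.fasta")) + sorted(
        alignment_dir.glob("*.fa")
    )
    if not fastas:
        raise FileNotFoundError(f"no FASTA files under {alignment_dir}")
    tree = PhyloTree.from_newick(Path(config.tree_path))

    per_gene: list[ConvergenceResult] = []
    all_events: list[ConvergenceEvent] = []
    failures: list[dict] = []
    for fasta in fastas:
        try:
            results, events = run_gene(fasta, tree, config)
        except Exception as exc:  # quarantine, never abort the batch
            logger.error("gene %s failed: %s", fasta.stem, exc)
            failures.append({"gene": fasta.stem, "error": str(exc)})
            continue
        logger.info("gene %s: %d branch sets analyzed", fasta.stem, len(results))
        per_gene.extend(results)
        all_events.extend(events)

    if not per_gene:
        raise RuntimeError("every gene in the batch failed; see failures manifest")

    per_gene_df = _results_frame(per_gene)
    agg_rows = []
    q_frames = []
    for (bset, mode), sub in per_gene_df.groupby(["branch_set", "mode"], sort=True):
        sub_results = [
            r for r in per_gene if r.branch_set == bset and r.mode == mode
        ]
        aggregate, q = genome_wide_test(sub_results)
        genes_with_events = int((sub["obs_combined"] > 0).sum())
        row = _results_frame([aggregate]).iloc[0].to_dict()
        row["genes_with_events"] = genes_with_events
        agg_rows.append(row)
        q_frames.append(pd.Series(q, index=sub.index, name="q_upper"))
    per_gene_df = per_gene_df.join(pd.concat(q_frames))
    aggregate_df = pd.DataFrame(agg_rows)
    events_df = _events_frame(all_events)

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    fmt = dict(sep="\t", index=False, float_format="%.10g")
    per_gene_df.to_csv(out / "per_gene.tsv", **fmt)
    aggregate_df.to_csv(out / "genome_wide.tsv", **fmt)
    events_df.to_csv(out / "events.tsv", **fmt)
    with open(out / "failures.tsv", "w") as fh:
        fh.write("gene\terror\n")
        for f in failures:
            fh.write(f"{f['gene']}\t{f['error']}\n")
    manifest = {
        "convscan_version": __version__,
        "tree": str(config.tree_path),
        "alignment_dir": str(alignment_dir),
        "model": config.model_name + ("+F" if config.plus_f else ""),
        "branch_length_policy": config.branch_length_policy,
        "branch_sets": [
            {"name": b.name, "branches": [list(x) if not isinstance(x, str) else x for x in b.branches], "mode": b.mode}
            for b in config.branch_sets
        ],
        "n_genes_analyzed": int(per_gene_df["gene"].nunique()),
        "n_genes_failed": len(failures),
    }
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return BatchResult(
        per_gene=per_gene_df,
        aggregate=aggregate_df,
        events=events_df,
        failures=failures,
    )
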