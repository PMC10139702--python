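"""Observed convergent/parallel substitution detection."""

import numpy as np
import pytest

from convscan import PhyloTree, ProteinAlignment, count_observed, marginal_posteriors
from convscan.convergence import (
    FocalBranchSet,
    SubstitutionCall,
    classify_site,
    infer_branch_substitutions,
    resolve_branches,
    usable_site_mask,
)
from convscan.simulate import FOCAL_TIPS, SimulationConfig, default_tree, simulate_gene
from convscan.trees import TreeError


def _call(branch, frm, to, site=0):
    return SubstitutionCall(
        gene="g", site=site, branch=branch, from_state=frm, to_state=to,
        from_prob=0.99, to_prob=1.0,
    )


TWO_BRANCH = FocalBranchSet("pair", ("x", "y"), "all-branches")


class TestClassifySite:
    @pytest.mark.parametrize(
        "calls, expected_category",
        [
            ([_call("x", "S", "A"), _call("y", "T", "A")], "convergent"),
            ([_call("x", "S", "A"), _call("y", "S", "A")], "parallel"),
        ],
    )
    def test_shared_derived_state_classified_by_origins(
        self, calls, expected_category
    ):
        events = classify_site(calls, TWO_BRANCH, 2)
        assert len(events) == 1
        assert events[0].category == expected_category
        assert events[0].derived_state == "A"

    def test_different_derived_states_yield_nothing(self):
        assert classify_site([_call("x", "S", "A"), _call("y", "S", "V")], TWO_BRANCH, 2) == []

    def test_all_branches_mode_requires_every_branch(self):
        three = FocalBranchSet("trio", ("x", "y", "z"), "all-branches")
        calls = [_call("x", "S", "A"), _call("y", "T", "A")]
        assert classify_site(calls, three, 3) == []

    def test_pairwise_mode_scores_each_matching_pair(self):
        three = FocalBranchSet("trio", ("x", "y", "z"), "pairwise")
        calls = [_call("x", "S", "A"), _call("y", "T", "A"), _call("z", "S", "V")]
        events = classify_site(calls, three, 3)
        assert len(events) == 1 and events[0].category == "convergent"

    def test_call_requires_a_real_change(self):
        with pytest.raises(ValueError, match="from_state != to_state"):
            _call("x", "A", "A")


@pytest.fixture(scope="module")
def fixture_gene():
    """Hand-built 6-tip alignment with one parallel and one convergent site.

    Topology: ((f1,o1),(f2,o2)) plus two outgroups; focal tips f1, f2.
    Outgroup neighbors are nearly identical to the ancestral states, so
    the focal parents reconstruct confidently.
    """
    from convscan import load_empirical_model

    newick = "(((f1:0.15,o1:0.01):0.05,(f2:0.15,o2:0.01):0.05):0.03,(w:0.02,z:0.02):0.03);"
    tree = PhyloTree.from_newick(newick)
    # site0: parallel S>A on f1,f2 | site1: convergent S>A / T>A
    # site2: no event | site3: f1 gap (unusable)
    seqs = {
        "f1": "AAK-",
        "o1": "SSKK",
        "f2": "AAKK",
        "o2": "STKK",
        "w":  "SSKK",
        "z":  "STKK",
    }
    aln = ProteinAlignment.from_sequences(seqs)
    model = load_empirical_model("JTT")
    post = marginal_posteriors(tree, aln, model)
    return tree, aln, post


class TestCountObserved:
    def test_hand_built_parallel_and_convergent_sites(self, fixture_gene):
        tree, aln, post = fixture_gene
        bset = FocalBranchSet("focal", ("f1", "f2"), "all-branches")
        counts, usable = count_observed(tree, aln, post, bset)
        assert counts.parallel == 1
        assert counts.convergent == 1
        assert counts.combined == 2
        assert {e.site for e in counts.events} == {0, 1}
        assert usable.tolist() == [True, True, True, False]

    def test_event_sites_are_usable(self, fixture_gene):
        tree, aln, post = fixture_gene
        bset = FocalBranchSet("focal", ("f1", "f2"), "all-branches")
        counts, usable = count_observed(tree, aln, post, bset)
        assert all(usable[e.site] for e in counts.events)

    def test_pairwise_equals_all_branches_for_two_branches(self, fixture_gene):
        tree, aln, post = fixture_gene
        ab = FocalBranchSet("focal", ("f1", "f2"), "all-branches")
        pw = FocalBranchSet("focal", ("f1", "f2"), "pairwise")
        c_ab, _ = count_observed(tree, aln, post, ab)
        c_pw, _ = count_observed(tree, aln, post, pw)
        assert (c_ab.convergent, c_ab.parallel) == (c_pw.convergent, c_pw.parallel)

    def test_branch_order_is_irrelevant(self, fixture_gene):
        tree, aln, post = fixture_gene
        fwd = FocalBranchSet("focal", ("f1", "f2"), "all-branches")
        rev = FocalBranchSet("focal", ("f2", "f1"), "all-branches")
        c1, _ = count_observed(tree, aln, post, fwd)
        c2, _ = count_observed(tree, aln, post, rev)
        assert [(e.site, e.category, e.derived_state) for e in c1.events] == [
            (e.site, e.category, e.derived_state) for e in c2.events
        ]

    def test_no_change_means_no_call(self, fixture_gene):
        tree, aln, post = fixture_gene
        bset = FocalBranchSet("focal", ("f1", "f2"), "all-branches")
        calls, _ = infer_branch_substitutions(tree, aln, post, bset)
        assert 2 not in calls  # site 2 is identical everywhere

    def test_gene_with_no_focal_substitutions_counts_zero(self, jtt):
        tree = default_tree()
        names = tree.tip_names
        aln = ProteinAlignment.from_sequences({n: "MKV" for n in names})
        post = marginal_posteriors(tree, aln, jtt)
        bset = FocalBranchSet("myr", FOCAL_TIPS, "all-branches")
        counts, _ = count_observed(tree, aln, post, bset)
        assert (counts.convergent, counts.parallel, counts.combined) == (0, 0, 0)


class TestBranchSets:
    def test_nested_branches_rejected(self):
        tree = default_tree()
        nested = FocalBranchSet(
            "bad", (("dog", "cat"), "dog"), "all-branches"
        )
        with pytest.raises(TreeError, match="disjoint"):
            resolve_branches(tree, nested)

    def test_mrca_expression_resolves_internal_branch(self):
        tree = default_tree()
        bset = FocalBranchSet("mixed", (("dog", "cat"), "pangolin"), "all-branches")
        nodes = resolve_branches(tree, bset)
        assert tree.children[nodes[0]]  # internal node
        assert tree.tip_names[nodes[1]] == "pangolin"

    def test_fewer_than_two_branches_rejected(self):
        with pytest.raises(ValueError, match=">= 2"):
            FocalBranchSet("solo", ("anteater",), "all-branches")

    def test_gap_sites_masked_for_whole_set(self):
        tree = default_tree()
        seqs = {n: "MKVL" for n in tree.tip_names}
        seqs["anteater"] = "MKV-"
        seqs["pangolin"] = "XKVL"
        aln = ProteinAlignment.from_sequences(seqs)
        nodes = [tree.tip_index(t) for t in FOCAL_TIPS]
        mask = usable_site_mask(tree, aln, nodes)
        assert mask.tolist() == [False, True, True, False]


class TestSimulatedRecall:
    def test_true_focal_substitutions_recalled(self, jtt):
        """>= 95% of the generating substitution events on the focal
        terminal branches are called back on a 500-site gene."""
        newick = (
            "(((f1:0.10,s1:0.02):0.03,(f2:0.10,s2:0.02):0.03):0.03,"
            "(o1:0.04,o2:0.04):0.03);"
        )
        tree = PhyloTree.from_newick(newick)
        focal = ("f1", "f2")
        cfg = SimulationConfig(
            seed=77, n_genes=1, sites_per_gene=500, tree=tree, focal_tips=focal
        )
        aln, truth = simulate_gene(cfg, 0)
        post = marginal_posteriors(tree, aln, jtt)
        bset = FocalBranchSet("myr", focal, "all-branches")
        calls, usable = infer_branch_substitutions(tree, aln, post, bset)
        called = {
            (c.branch, c.site) for site_calls in calls.values() for c in site_calls
        }
        true_subs = {
            (tip, site)
            for tip in focal
            for site, _, _ in truth.substitutions[tree.tip_index(tip)]
            if usable[site]
        }
        assert true_subs, "simulation produced no focal substitutions"
        recall = len(true_subs & called) / len(true_subs)
        assert recall >= 0.95

    def test_injected_convergence_recovered(self, jtt):
        """A gene with 5 injected convergent sites yields >= 4 events."""
        cfg = SimulationConfig(
            seed=13, n_genes=1, sites_per_gene=300, n_convergent_sites=5
        )
        aln, truth = simulate_gene(cfg, 0)
        post = marginal_posteriors(cfg.tree, aln, jtt)
        bset = FocalBranchSet("myr", FOCAL_TIPS, "all-branches")
        counts, _ = count_observed(cfg.tree, aln, post, bset)
        recovered = {e.site for e in counts.events}
        injected = {r.site for r in truth.injections}
        assert len(injected) == 5
        assert len(injected & recovered) >= 4
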