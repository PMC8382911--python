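"""Marginal ancestral reconstruction, gap parsimony, and replacement counting."""

import itertools

import numpy as np
import pytest

from haloasr import (
    Alignment,
    Tree,
    compose_ancestors,
    count_replacements,
    infer_gap_states,
    marginal_profiles,
    poisson_model,
    well_identified_fraction,
)

from oracles import enumerate_fitch_score, enumerate_marginal_posterior


def _aln(tree, columns):
    names = tree.leaf_labels()
    return Alignment(names, [columns[n] for n in names])


class TestMarginalProfiles:
    def test_identical_tips_short_branches_are_certain(self, poisson4):
        tree = Tree.from_newick("(a:1e-9,b:1e-9);")
        prof = marginal_profiles(tree, _aln(tree, {"a": "A", "b": "A"}), poisson4)
        root = prof.node_labels[0]
        assert prof.probabilities[root][0, 0] > 1 - 1e-6
        assert prof.map_sequence(root) == "A"

    def test_symmetric_conflict_ties_to_first_state(self, poisson2):
        """Two states, equal branches, uniform frequencies: posterior is
        (1/2, 1/2) and the MAP tie resolves to the first state in order."""
        tree = Tree.from_newick("(a:0.3,b:0.3);")
        prof = marginal_profiles(tree, _aln(tree, {"a": "A", "b": "R"}), poisson2)
        root = prof.node_labels[0]
        assert np.allclose(prof.probabilities[root][0], [0.5, 0.5], atol=1e-12)
        assert prof.map_sequence(root) == "A"
        assert (root, 0) in prof.ties

    @pytest.mark.parametrize("model_name", ["poisson4_gamma", "random_model4"])
    def test_matches_enumeration_at_every_node(self, model_name, tree4, request):
        """Node marginals equal brute-force joint enumeration marginalized."""
        model = request.getfixturevalue(model_name)
        cols = {"a": "ARN", "b": "AAN", "c": "RRD", "d": "AND"}
        prof = marginal_profiles(tree4, _aln(tree4, cols), model)
        tagged = tree4.copy()
        tagged.label_internal()
        for node in tagged.internal_nodes():
            for j in range(3):
                leaf_states = {n: model.state_index(cols[n][j]) for n in cols}
                expect = enumerate_marginal_posterior(tagged, model, leaf_states, node)
                got = prof.probabilities[node.label][j]
                assert np.allclose(got, expect, atol=1e-10)

    def test_rows_sum_to_one(self, tree5, poisson4_gamma):
        rng = np.random.default_rng(0)
        cols = {n: "".join(rng.choice(list("ARND"), size=7)) for n in tree5.leaf_labels()}
        prof = marginal_profiles(tree5, _aln(tree5, cols), poisson4_gamma)
        for label in prof.node_labels:
            assert np.allclose(prof.probabilities[label].sum(axis=1), 1.0, atol=1e-9)

    def test_model_choice_changes_few_map_states(self):
        """Echo of the method-robustness check: Poisson vs empirical model on
        the same data disagree at only a small fraction of MAP sites."""
        from haloasr import lg_model, scale_branch_lengths, simulate_alignment
        from haloasr import simulate_gene_history, simulate_species_tree

        st = simulate_species_tree(8, 1.0, 0.3, seed=13)
        gtree, _ = simulate_gene_history(st, 0, 0, 0, seed=1)
        g = scale_branch_lengths(gtree, 0.25 / max(
            gtree.depths()[lf] for lf in gtree.leaves()
        ))
        aln, _ = simulate_alignment(g, lg_model(), 150, seed=2)
        p_lg = marginal_profiles(g, aln, lg_model())
        p_poi = marginal_profiles(g, aln, poisson_model())
        root = p_lg.node_labels[-1]
        diff = sum(
            x != y for x, y in zip(p_lg.map_sequence(root), p_poi.map_sequence(root))
        )
        assert diff <= 15  # a handful of sites out of 150


class TestGapStates:
    def test_all_present_column_gives_present_ancestors(self):
        tree = Tree.from_newick("((a:1,b:1):1,(c:1,d:1):1);")
        aln = _aln(tree, {"a": "A", "b": "R", "c": "N", "d": "D"})
        states, scores = infer_gap_states(aln, tree)
        assert all(v[0] == 1 for v in states.values())
        assert scores[0] == 0

    def test_single_present_leaf_gives_root_gap(self):
        tree = Tree.from_newick("((a:1,b:1):1,(c:1,d:1):1);")
        aln = _aln(tree, {"a": "A", "b": "-", "c": "-", "d": "-"})
        tagged = tree.copy()
        tagged.label_internal()
        states, scores = infer_gap_states(aln, tree)
        root_label = [n.label for n in tagged.internal_nodes()][-1]
        assert states[root_label][0] == 0
        assert scores[0] == 1

    @pytest.mark.parametrize("seed", range(6))
    def test_fitch_score_matches_enumeration(self, tree5, seed):
        rng = np.random.default_rng(seed)
        pattern = {}
        for lf in tree5.leaf_labels():
            pattern[lf] = "A" if rng.random() < 0.5 else "-"
        if all(v == "-" for v in pattern.values()):
            pattern["a"] = "A"
        aln = _aln(tree5, pattern)
        _, scores = infer_gap_states(aln, tree5)
        presence = {k: int(v != "-") for k, v in pattern.items()}
        assert scores[0] == enumerate_fitch_score(tree5, presence)

    def test_fitch_assignment_achieves_its_score(self, tree5):
        """The reported presence states imply exactly `score` changes."""
        rng = np.random.default_rng(42)
        cols = {
            lf: "".join(rng.choice(["A", "-"], size=12)) for lf in tree5.leaf_labels()
        }
        aln = _aln(tree5, cols)
        tagged = tree5.copy()
        tagged.label_internal()
        states, scores = infer_gap_states(aln, tree5)
        for j in range(12):
            changes = 0
            for node in tagged.postorder():
                if node.parent is None:
                    continue
                mine = (
                    int(aln[node.label][j] != "-")
                    if node.is_leaf
                    else states[node.label][j]
                )
                parent = states[node.parent.label][j]
                changes += int(mine != parent)
            assert changes == scores[j]

    def test_dollo_single_origin(self):
        tree = Tree.from_newick("(((a:1,b:1):1,c:2):1,d:3);")
        aln = _aln(tree, {"a": "A", "b": "-", "c": "A", "d": "-"})
        tagged = tree.copy()
        tagged.label_internal()
        states, scores = infer_gap_states(aln, tree, mode="dollo")
        labels = [n.label for n in tagged.internal_nodes()]
        # MRCA of {a, c} is the (a,b),c ancestor; root (above it) stays absent
        assert states[labels[-1]][0] == 0
        assert states[labels[-2]][0] == 1
        assert scores[0] == 1  # the single loss toward b


class TestComposition:
    def test_gap_overrides_profile(self, poisson4):
        tree = Tree.from_newick("(a:0.1,b:0.1);")
        prof = marginal_profiles(tree, _aln(tree, {"a": "AA", "b": "AA"}), poisson4)
        root = prof.node_labels[0]
        gaps = {root: np.array([1, 0])}
        anc = compose_ancestors(prof, gaps)
        assert anc[root] == "A-"

    def test_all_present_is_map_sequence(self, poisson4):
        tree = Tree.from_newick("(a:0.1,b:0.1);")
        prof = marginal_profiles(tree, _aln(tree, {"a": "ARN", "b": "ARN"}), poisson4)
        root = prof.node_labels[0]
        anc = compose_ancestors(prof, {root: np.ones(3, dtype=int)})
        assert anc[root] == prof.map_sequence(root)

    def test_dimension_mismatch_rejected(self, poisson4):
        tree = Tree.from_newick("(a:0.1,b:0.1);")
        prof = marginal_profiles(tree, _aln(tree, {"a": "AA", "b": "AA"}), poisson4)
        with pytest.raises(ValueError):
            compose_ancestors(prof, {prof.node_labels[0]: np.ones(5, dtype=int)})


class TestReplacementCount:
    @pytest.mark.parametrize(
        "a,b,expect",
        [
            ("ACDE", "ACDE", 0),
            ("ACD-", "ACE-", 1),
            ("A-DE", "AC-E", 0),
            ("ARND", "DNRA", 4),
        ],
    )
    def test_gap_excluding_counting(self, a, b, expect):
        assert count_replacements(a, b) == expect

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            count_replacements("AC", "ACD")


class TestWellIdentified:
    def _profile(self, pps):
        """Synthetic profile with prescribed MAP PPs on a 2-state alphabet."""
        from haloasr.asr import AncestralProfile

        P = np.array([[p, 1 - p] for p in pps])
        return AncestralProfile("AR", ["n0"], {"n0": P})

    def test_all_certain(self):
        prof = self._profile([1.0, 1.0, 1.0])
        assert well_identified_fraction(prof, "n0") == 1.0

    def test_exact_threshold_not_counted(self):
        prof = self._profile([0.9, 0.95])
        assert well_identified_fraction(prof, "n0") == 0.5

    def test_gap_columns_excluded(self):
        prof = self._profile([0.95, 0.5, 0.99])
        frac = well_identified_fraction(
            prof, "n0", presence=np.array([1, 0, 1], dtype=bool)
        )
        assert frac == 1.0
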