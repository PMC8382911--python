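"""Synthetic-data generators: determinism, distributional oracles, truth bookkeeping."""

import numpy as np
import pytest
from scipy.stats import chisquare

from haloasr import (
    build_rate_matrix,
    poisson_model,
    replay_events,
    scale_branch_lengths,
    simulate_alignment,
    simulate_gene_history,
    simulate_species_tree,
    simulate_stability_curve,
)
from haloasr.models import halophilic_frequencies, lg_model
from haloasr.simulate import SimulationError, logistic_folded_fraction


class TestSpeciesTree:
    def test_two_taxa_shape(self):
        st = simulate_species_tree(2, 1.0, 0.0, seed=0)
        assert len(st.tree.leaves()) == 2
        assert all(lf.age == 0 for lf in st.tree.leaves())
        assert st.root.age > 0

    def test_seed_determinism(self):
        a = simulate_species_tree(9, 1.0, 0.4, seed=5).to_newick()
        b = simulate_species_tree(9, 1.0, 0.4, seed=5).to_newick()
        assert a == b

    def test_distinct_internal_ages(self):
        st = simulate_species_tree(12, 1.0, 0.6, seed=2)
        ages = [n.age for n in st.tree.internal_nodes()]
        assert len(set(ages)) == len(ages)

    def test_yule_waiting_times(self):
        """Pure-birth process: the waiting time between the k-th and (k+1)-th
        speciation is Exp(k+1), and the time from the last speciation to the
        present is the censored Exp(n); check both against their means."""
        n_rep = 3000
        gap_2 = np.empty(n_rep)  # between 1st and 2nd speciation: 2 lineages
        tail = np.empty(n_rep)  # youngest internal age: Exp(5) by memorylessness
        for i in range(n_rep):
            st = simulate_species_tree(5, 1.0, 0.0, seed=10_000 + i)
            ages = sorted((n.age for n in st.tree.internal_nodes()), reverse=True)
            gap_2[i] = ages[0] - ages[1]
            tail[i] = ages[-1]
        for sample, mean in ((gap_2, 1 / 2), (tail, 1 / 5)):
            se = sample.std(ddof=1) / np.sqrt(n_rep)
            assert abs(sample.mean() - mean) < 3 * se

    def test_invalid_parameters(self):
        with pytest.raises(SimulationError):
            simulate_species_tree(1, 1.0, 0.0, seed=0)
        with pytest.raises(SimulationError):
            simulate_species_tree(4, 0.5, 0.5, seed=0)


@pytest.fixture(scope="module")
def stree():
    return simulate_species_tree(6, 1.0, 0.3, seed=42)


class TestGeneHistory:
    def test_zero_rates_congruent(self, stree):
        from haloasr import robinson_foulds

        gtree, events = simulate_gene_history(stree, 0, 0, 0, seed=1)
        assert sorted(gtree.leaf_labels()) == sorted(
            f"{s}|1" for s in stree.tree.leaf_labels()
        )
        relabeled = gtree.copy()
        for lf in relabeled.leaves():
            lf.label = lf.label.split("|")[0]
        assert robinson_foulds(relabeled, stree.tree) == 0
        assert all(e.kind == "speciation" for e in events)

    def test_loss_only_gives_leaf_subset(self, stree):
        gtree, events = simulate_gene_history(stree, 0, 0, 0.5, seed=3)
        kinds = {e.kind for e in events}
        assert kinds <= {"speciation", "loss"}
        if gtree is not None:
            species = set(stree.tree.leaf_labels())
            assert {l.split("|")[0] for l in gtree.leaf_labels()} <= species

    def test_all_lost_returns_none_with_events(self, stree):
        out = None
        for seed in range(200):
            gtree, events = simulate_gene_history(stree, 0, 0, 5.0, seed=seed)
            if gtree is None:
                out = events
                break
        assert out is not None and any(e.kind == "loss" for e in out)

    def test_event_list_replays_to_gene_tree(self, stree):
        for seed in range(25):
            gtree, events = simulate_gene_history(stree, 0.2, 0.3, 0.2, seed=seed)
            replayed = replay_events(stree, events)
            if gtree is None:
                assert replayed is None
            else:
                assert replayed.to_newick() == gtree.to_newick()

    def test_transfer_count_is_poisson_in_lineage_time(self, stree):
        """N_transfers - rate * total realized lineage time is a zero-mean
        martingale increment; its sample mean must vanish within 3 SE."""
        rate = 0.25
        diffs = []
        for seed in range(800):
            gtree, events = simulate_gene_history(stree, 0, rate, 0, seed=seed)
            n_t = sum(e.kind == "transfer" for e in events)
            total_time = sum(
                n.length for n in gtree.postorder() if n.length is not None
            )
            diffs.append(n_t - rate * total_time)
        diffs = np.array(diffs)
        se = diffs.std(ddof=1) / np.sqrt(len(diffs))
        assert abs(diffs.mean()) < 3 * se

    def test_replacement_transfer_kills_resident_copies(self, stree):
        saw_replacement_loss = False
        for seed in range(60):
            _, events = simulate_gene_history(
                stree, 0, 0.6, 0, seed=seed, replace=True
            )
            transfer_ages = {e.time for e in events if e.kind == "transfer"}
            if any(e.kind == "loss" and e.time in transfer_ages for e in events):
                saw_replacement_loss = True
                break
        assert saw_replacement_loss


class TestAlignmentSimulation:
    def test_zero_branch_lengths_copy_root(self, stree):
        gtree, _ = simulate_gene_history(stree, 0, 0, 0, seed=1)
        frozen = scale_branch_lengths(gtree, 0.0)
        aln, truth = simulate_alignment(frozen, poisson_model(alphabet="ARND", K=1), 50, seed=9)
        assert len(set(aln.rows)) == 1
        root_label = truth.gene_tree.root.label
        assert aln.rows[0] == truth.ancestors[root_label]

    def test_no_indels_gap_free_fixed_length(self, stree):
        gtree, _ = simulate_gene_history(stree, 0, 0, 0, seed=1)
        g = scale_branch_lengths(gtree, 0.3)
        aln, _ = simulate_alignment(g, lg_model(), 80, indel_rate=0.0, seed=4)
        assert len(aln) == 80
        assert all("-" not in row for row in aln.rows)

    def test_determinism(self, stree):
        gtree, _ = simulate_gene_history(stree, 0, 0, 0, seed=1)
        g = scale_branch_lengths(gtree, 0.3)
        a1, t1 = simulate_alignment(g, lg_model(), 60, indel_rate=0.05, seed=12)
        a2, t2 = simulate_alignment(g, lg_model(), 60, indel_rate=0.05, seed=12)
        assert a1.rows == a2.rows and t1.ancestors == t2.ancestors

    def test_single_branch_divergence_matches_matrix_exponential(self):
        """Fraction of differing sites on one branch of length t equals
        1 - sum_i pi_i p_ii(t) (+- 3 binomial SE)."""
        from haloasr import Tree

        t = 0.4
        model = lg_model(K=1)
        tree = Tree.from_newick(f"(a:{t},b:0.0);")
        L = 30000
        aln, _ = simulate_alignment(tree, model, L, seed=77)
        p_same_expect = float(
            (model.pi * np.diag(build_rate_matrix(model).transition_matrix(t))).sum()
        )
        frac_diff = np.mean([x != y for x, y in zip(aln["a"], aln["b"])])
        se = np.sqrt(p_same_expect * (1 - p_same_expect) / L)
        assert abs(frac_diff - (1 - p_same_expect)) < 3 * se

    def test_stationary_composition_chi_square(self):
        """A long root sequence drawn at stationarity matches pi (alpha=0.01)."""
        from haloasr import Tree

        model = lg_model(K=1)
        tree = Tree.from_newick("(a:0.0,b:0.0);")
        L = 100_000
        aln, _ = simulate_alignment(tree, model, L, seed=5)
        counts = np.array([aln["a"].count(aa) for aa in model.alphabet])
        stat, p = chisquare(counts, model.pi * L)
        assert p > 0.01

    def test_halophilic_bias_is_stationary(self):
        from haloasr import Tree

        bias = halophilic_frequencies()
        model = lg_model(K=1)
        tree = Tree.from_newick("(a:0.5,b:0.5);")
        aln, _ = simulate_alignment(tree, model, 50_000, halophilic_bias=bias, seed=6)
        # after evolution along t=0.5 the composition still matches the bias
        counts = np.array([aln["a"].count(aa) for aa in model.alphabet])
        stat, p = chisquare(counts, bias * 50_000)
        assert p > 0.01

    def test_indels_bookkeeping_truth_lengths_match(self, stree):
        gtree, _ = simulate_gene_history(stree, 0, 0, 0, seed=1)
        g = scale_branch_lengths(gtree, 0.3)
        aln, truth = simulate_alignment(g, lg_model(), 100, indel_rate=0.15, seed=21)
        for anc in truth.ancestors.values():
            assert len(anc) == len(aln)

    def test_invalid_bias_rejected(self, stree):
        gtree, _ = simulate_gene_history(stree, 0, 0, 0, seed=1)
        with pytest.raises(SimulationError):
            simulate_alignment(gtree, lg_model(), 10, halophilic_bias=np.ones(20), seed=0)


class TestStabilityCurve:
    def test_midpoint_is_half(self):
        c = simulate_stability_curve(0.5, 0.1, [0.1, 0.3, 0.5, 0.7], noise_sd=0)
        assert c.fractions[2] == pytest.approx(0.5)

    def test_noiseless_monotone(self):
        c = simulate_stability_curve(0.8, 0.07, np.linspace(0, 2, 21), noise_sd=0)
        assert np.all(np.diff(c.fractions) >= 0)

    def test_logistic_tail(self):
        assert logistic_folded_fraction(3.8, 0.3, 0.05) > 0.999

    def test_noise_clipped_and_deterministic(self):
        c1 = simulate_stability_curve(0.4, 0.05, np.linspace(0, 2, 9), 0.3, seed=8)
        c2 = simulate_stability_curve(0.4, 0.05, np.linspace(0, 2, 9), 0.3, seed=8)
        assert np.array_equal(c1.fractions, c2.fractions)
        assert c1.fractions.min() >= 0 and c1.fractions.max() <= 1

    def test_csv_roundtrip(self):
        c = simulate_stability_curve(0.4, 0.05, np.linspace(0, 2, 9), 0.0)
        from haloasr import StabilityCurve

        back = StabilityCurve.from_csv(c.to_csv())
        assert np.allclose(back.concentrations, c.concentrations)
        assert np.allclose(back.fractions, c.fractions, atol=1e-6)
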