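"""Gene-tree / species-tree reconciliation by minimum-cost duplication–transfer–loss
parsimony on a time-sliced dated species tree, plus conditional clade
probabilities (CCPs) from a gene-tree sample.

Transfers are only allowed between distinct species branches alive in the
same time slice (slices are bounded by consecutive internal-node ages of the
dated tree). The dynamic program runs over (gene node x species branch x
slice); one optimal scenario is backtracked with a deterministic tie-break
(event-kind order S < D < T, then species-branch index). A speciation-loss
costs one loss; a transfer-loss costs one transfer plus one loss.
"""

from __future__ import annotations

import json
import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Callable, Optional

from .trees import DatedSpeciesTree, Node, Tree

__all__ = [
    "TimeSlicedSpeciesTree",
    "DTLCosts",
    "ReconciliationScenario",
    "CCPTable",
    "time_slice",
    "reconcile_dtl",
    "compute_ccp",
    "event_counts",
    "default_leaf_map",
]

INF = math.inf


class ReconciliationError(ValueError):
    pass


@dataclass
class DTLCosts:
    """Event costs: duplication, transfer, loss (speciation is free)."""

    duplication: float = 2.0
    transfer: float = 3.0
    loss: float = 1.0

    def __post_init__(self):
        if min(self.duplication, self.transfer, self.loss) < 0:
            raise ReconciliationError("costs must be non-negative")


@dataclass
class TimeSlicedSpeciesTree:
    """Dated species tree with slices bounded by consecutive internal-node ages.

    ``boundaries[s] > boundaries[s+1]``; slice s spans
    (boundaries[s+1], boundaries[s]); ``slice_branches[s]`` lists the branches
    (identified by their child node) alive throughout slice s, ordered by
    branch index for deterministic tie-breaking.
    """

    stree: DatedSpeciesTree
    boundaries: list[float]
    slice_branches: list[list[Node]]
    branch_index: dict[Node, int]

    @property
    def n_slices(self) -> int:
        return len(self.slice_branches)


def time_slice(stree: DatedSpeciesTree) -> TimeSlicedSpeciesTree:
    """Discretize a dated species tree into transfer-compatible time slices."""
    internal_ages = sorted((n.age for n in stree.tree.internal_nodes()), reverse=True)
    if len(set(internal_ages)) != len(internal_ages):
        raise ReconciliationError("tied internal node ages; jitter the ages")
    boundaries = internal_ages + [0.0]
    branches = [n for n in stree.tree.postorder() if n.parent is not None]
    branch_index = {b: i for i, b in enumerate(branches)}
    slice_branches: list[list[Node]] = []
    for s in range(len(boundaries) - 1):
        top, bottom = boundaries[s], boundaries[s + 1]
        alive = [b for b in branches if b.parent.age >= top - 1e-12 and b.age <= bottom + 1e-12]
        slice_branches.append(sorted(alive, key=branch_index.__getitem__))
    return TimeSlicedSpeciesTree(stree, boundaries, slice_branches, branch_index)


@dataclass
class ReconciliationScenario:
    """One minimum-cost DTL scenario: the event at every gene node, the total
    cost, and the (D, T, L, S) event-count vector."""

    assignments: dict[str, tuple[str, int, str]]  # gene node label -> (species branch, slice, event)
    total_cost: float
    counts: tuple[int, int, int, int]  # (D, T, L, S)
    costs: DTLCosts
    events: list[tuple] = field(default_factory=list)  # (kind, branch, other-branch-or-None)

    def validate(self) -> None:
        D, T, L, S = self.counts
        expect = (
            self.costs.duplication * D + self.costs.transfer * T + self.costs.loss * L
        )
        if abs(expect - self.total_cost) > 1e-9:
            raise ReconciliationError("event counts inconsistent with total cost")

    def to_tsv(self) -> str:
        lines = ["gene_node\tspecies_branch\tslice\tevent"]
        for g in sorted(self.assignments):
            b, s, e = self.assignments[g]
            lines.append(f"{g}\t{b}\t{s}\t{e}")
        return "\n".join(lines) + "\n"

    def to_json(self) -> str:
        D, T, L, S = self.counts
        return json.dumps(
            {
                "total_cost": self.total_cost,
                "counts": {"duplication": D, "transfer": T, "loss": L, "speciation": S},
                "assignments": {g: list(v) for g, v in self.assignments.items()},
            },
            indent=1,
            sort_keys=True,
        )


def default_leaf_map(label: str) -> str:
    """Gene copies are named ``species|copy`` by the simulator; strip the copy."""
    return label.split("|")[0]


_EVENT_RANK = {"S": 0, "D": 1, "T": 2, "SL": 3, "TL": 4, "pass": 5, "leaf": 6}


def reconcile_dtl(
    sliced: TimeSlicedSpeciesTree,
    gtree: Tree,
    costs: DTLCosts = DTLCosts(),
    leaf_map: Callable[[str], str] = default_leaf_map,
) -> ReconciliationScenario:
    """Minimum-cost DTL reconciliation of ``gtree`` into the sliced species tree.

    The gene lineage originates in the root slice (where the simulator injects
    it). Returns one optimal scenario; ties are resolved deterministically.
    """
    gtree = gtree.copy()
    gtree.label_internal(prefix="g")
    species_leaf = {lf.label: lf for lf in sliced.stree.tree.leaves()}
    for lf in gtree.leaves():
        if leaf_map(lf.label) not in species_leaf:
            raise ReconciliationError(f"gene leaf {lf.label!r} maps to no species")

    S = sliced.n_slices
    bidx = sliced.branch_index
    # C[gene node] maps (branch, slice) -> (cost, priority, choice)
    C: dict[Node, dict[tuple[Node, int], tuple[float, tuple, tuple]]] = {}

    gene_postorder = list(gtree.postorder())
    for u in gene_postorder:
        table: dict[tuple[Node, int], tuple[float, tuple, tuple]] = {}
        for s in range(S - 1, -1, -1):
            bottom = sliced.boundaries[s + 1]
            in_slice = sliced.slice_branches[s]
            base: dict[Node, tuple[float, tuple, tuple]] = {}
            for e in in_slice:
                cands: list[tuple[float, tuple, tuple]] = []
                ends_here = abs(e.age - bottom) <= 1e-12 and not (e.is_leaf and s < S - 1)
                # -- bottom-boundary options -------------------------------
                if e.is_leaf and s == S - 1:
                    if u.is_leaf and species_leaf[leaf_map(u.label)] is e:
                        cands.append((0.0, (_EVENT_RANK["leaf"], bidx[e]), ("leaf",)))
                elif ends_here and not e.is_leaf:
                    f, g = e.children
                    if not u.is_leaf:
                        u1, u2 = u.children
                        for a, b in ((f, g), (g, f)):
                            c = C[u1][(a, s + 1)][0] + C[u2][(b, s + 1)][0]
                            cands.append((c, (_EVENT_RANK["S"], bidx[e], bidx[a]),
                                          ("S", (u1, a, s + 1), (u2, b, s + 1))))
                    for a in (f, g):
                        c = costs.loss + table[(a, s + 1)][0]
                        cands.append((c, (_EVENT_RANK["SL"], bidx[e], bidx[a]),
                                      ("SL", (u, a, s + 1))))
                else:
                    # branch continues into the next slice
                    if s < S - 1:
                        c = table[(e, s + 1)][0]
                        cands.append((c, (_EVENT_RANK["pass"], bidx[e]), ("pass", (u, e, s + 1))))
                # -- within-slice events -----------------------------------
                if not u.is_leaf:
                    u1, u2 = u.children
                    c = costs.duplication + C[u1][(e, s)][0] + C[u2][(e, s)][0]
                    cands.append((c, (_EVENT_RANK["D"], bidx[e]), ("D", (u1, e, s), (u2, e, s))))
                    for f in in_slice:
                        if f is e:
                            continue
                        for which, (stay, move) in enumerate(((u1, u2), (u2, u1))):
                            c = costs.transfer + C[stay][(e, s)][0] + C[move][(f, s)][0]
                            cands.append((c, (_EVENT_RANK["T"], bidx[e], bidx[f], which),
                                          ("T", (stay, e, s), (move, f, s))))
                base[e] = min(cands, default=(INF, (99,), ("none",)),
                              key=lambda t: (t[0], t[1]))
            # -- transfer-loss relaxation within the slice -----------------
            for e in in_slice:
                best_other = (INF, (99,), ("none",))
                for f in in_slice:
                    if f is e:
                        continue
                    c = costs.transfer + costs.loss + base[f][0]
                    cand = (c, (_EVENT_RANK["TL"], bidx[e], bidx[f]), ("TL", (u, f, s)))
                    if (cand[0], cand[1]) < (best_other[0], best_other[1]):
                        best_other = cand
                table[(e, s)] = min(base[e], best_other, key=lambda t: (t[0], t[1]))
        C[u] = table

    # Origination at the species root node: the entering lineage immediately
    # meets the root speciation, either surviving on both sides (S) or losing
    # one side (SL). This mirrors the simulator, which injects one gene
    # lineage at the species root.
    sroot = sliced.stree.root
    c1, c2 = sroot.children
    groot = gtree.root
    root_candidates: list[tuple[float, tuple, tuple]] = []
    if not groot.is_leaf:
        u1, u2 = groot.children
        for a, b in ((c1, c2), (c2, c1)):
            c = C[u1][(a, 0)][0] + C[u2][(b, 0)][0]
            root_candidates.append((c, (_EVENT_RANK["S"], bidx[a]),
                                    ("root_S", (u1, a, 0), (u2, b, 0))))
    for a in (c1, c2):
        c = costs.loss + C[groot][(a, 0)][0]
        root_candidates.append((c, (_EVENT_RANK["SL"], bidx[a]), ("root_SL", (groot, a, 0))))
    best = min(root_candidates, key=lambda t: (t[0], t[1]))
    if not math.isfinite(best[0]):
        raise ReconciliationError("no feasible reconciliation")

    # -- backtrack ---------------------------------------------------------
    assignments: dict[str, tuple[str, int, str]] = {}
    counts = Counter()
    ev_list: list[tuple] = []

    def walk(u: Node, e: Node, s: int) -> None:
        cost, _, choice = C[u][(e, s)]
        kind = choice[0]
        if kind == "leaf":
            assignments[u.label] = (e.label, s, "leaf")
            return
        if kind in ("S", "D"):
            counts[kind] += 1
            assignments[u.label] = (e.label, s, kind)
            ev_list.append((kind, e.label, None))
            for child_u, child_e, child_s in choice[1:]:
                walk(child_u, child_e, child_s)
            return
        if kind == "T":
            counts["T"] += 1
            assignments[u.label] = (e.label, s, "T")
            ev_list.append(("T", e.label, choice[2][1].label))
            for child_u, child_e, child_s in choice[1:]:
                walk(child_u, child_e, child_s)
            return
        if kind == "SL":
            counts["L"] += 1
            kept = choice[1][1]
            lost = next(c for c in e.children if c is not kept)
            ev_list.append(("L", lost.label, None))
            walk(*choice[1])
            return
        if kind == "TL":
            counts["T"] += 1
            counts["L"] += 1
            ev_list.append(("T", e.label, choice[1][1].label))
            ev_list.append(("L", e.label, None))
            walk(*choice[1])
            return
        if kind == "pass":
            walk(*choice[1])
            return
        raise ReconciliationError("backtrack hit an infeasible cell")  # pragma: no cover

    kind = best[2][0]
    if kind == "root_S":
        counts["S"] += 1
        assignments[groot.label] = (sroot.label, 0, "S")
        ev_list.append(("S", sroot.label, None))
        for child_u, child_e, child_s in best[2][1:]:
            walk(child_u, child_e, child_s)
    else:  # root_SL
        counts["L"] += 1
        kept = best[2][1][1]
        lost = next(c for c in sroot.children if c is not kept)
        ev_list.append(("L", lost.label, None))
        walk(*best[2][1])
    scenario = ReconciliationScenario(
        assignments=assignments,
        total_cost=best[0],
        counts=(counts["D"], counts["T"], counts["L"], counts["S"]),
        costs=costs,
        events=ev_list,
    )
    scenario.validate()
    return scenario


def event_counts(scenario: ReconciliationScenario) -> tuple[int, int, int, int]:
    """(duplications, transfers, losses, speciations) of a scenario."""
    return scenario.counts


# ---------------------------------------------------------------------------
# conditional clade probabilities


@dataclass
class CCPTable:
    """Clade marginal frequencies and conditional split probabilities from a
    sample of gene trees on a common leaf set."""

    clade_frequency: dict[frozenset, float]
    split_probability: dict[tuple[frozenset, frozenset], float] = field(default_factory=dict)
    n_trees: int = 0

    def frequency(self, leaves) -> float:
        return self.clade_frequency.get(frozenset(leaves), 0.0)

    def conditional(self, clade, left) -> float:
        clade, left = frozenset(clade), frozenset(left)
        right = clade - left
        key = (clade, min(left, right, key=sorted))
        return self.split_probability.get(key, 0.0)


def compute_ccp(sample: list[Tree]) -> CCPTable:
    """Clade frequency = fraction of trees containing the clade; split
    conditionals are normalized within each observed clade."""
    if not sample:
        raise ReconciliationError("empty tree sample")
    leaf_sets = {frozenset(t.leaf_labels()) for t in sample}
    if len(leaf_sets) != 1:
        raise ReconciliationError("sample trees are on different leaf sets")
    clade_counts: Counter = Counter()
    split_counts: Counter = Counter()
    for tree in sample:
        clades = tree.clades()
        for node, clade in clades.items():
            if len(clade) < 2:
                continue
            clade_counts[clade] += 1
            left = clades[node.children[0]]
            right = clade - left
            split_counts[(clade, min(left, right, key=sorted))] += 1
    n = len(sample)
    return CCPTable(
        clade_frequency={c: k / n for c, k in clade_counts.items()},
        split_probability={
            key: k / clade_counts[key[0]] for key, k in split_counts.items()
        },
        n_trees=n,
    )
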