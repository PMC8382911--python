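"""Independent brute-force oracles used by the test suite.

These deliberately avoid the production code paths: likelihoods and ancestral
posteriors come from explicit enumeration over all internal-state
assignments with scipy's matrix exponential; DTL costs come from exhaustive
scenario enumeration over shortest-path lineage movements; gamma category
rates come from numerical quadrature.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy.integrate import quad
from scipy.linalg import expm
from scipy.stats import gamma as gamma_dist


def raw_rate_matrix(model):
    """Q built independently (no eigendecomposition), normalized to rate 1."""
    pi = model.pi
    Q = model.S * pi[None, :]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q / (-(pi * np.diag(Q)).sum())


def enumerate_site_likelihood(tree, model, leaf_states: dict[str, int]) -> float:
    """P(column) by summing over every internal-node state assignment and
    averaging over gamma categories. ``leaf_states`` maps label -> state
    index, or -1 for a gap."""
    Q = raw_rate_matrix(model)
    rates = model.rates()
    nodes = list(tree.postorder())
    internal = [n for n in nodes if not n.is_leaf]
    k = model.n_states
    total = 0.0
    for r in rates:
        P = {n: expm(Q * r * n.length) for n in nodes if n.parent is not None}
        cat_sum = 0.0
        for assign in itertools.product(range(k), repeat=len(internal)):
            state = dict(zip(internal, assign))
            for leaf in tree.leaves():
                state[leaf] = leaf_states[leaf.label]
            p = model.pi[state[tree.root]]
            for n in nodes:
                if n.parent is None:
                    continue
                if state[n] == -1:
                    continue  # gap: marginalized below
                p *= P[n][state[n.parent], state[n]]
            # gap leaves: sum over their states = 1 (rows of P sum to 1)
            cat_sum += p
        total += cat_sum / len(rates)
    return total


def enumerate_marginal_posterior(tree, model, leaf_states: dict[str, int], node) -> np.ndarray:
    """Posterior distribution of ``node``'s state by brute-force enumeration."""
    Q = raw_rate_matrix(model)
    rates = model.rates()
    nodes = list(tree.postorder())
    internal = [n for n in nodes if not n.is_leaf]
    k = model.n_states
    joint = np.zeros(k)
    for r in rates:
        P = {n: expm(Q * r * n.length) for n in nodes if n.parent is not None}
        for assign in itertools.product(range(k), repeat=len(internal)):
            state = dict(zip(internal, assign))
            for leaf in tree.leaves():
                state[leaf] = leaf_states[leaf.label]
            p = model.pi[state[tree.root]]
            for n in nodes:
                if n.parent is None or state[n] == -1:
                    continue
                p *= P[n][state[n.parent], state[n]]
            joint[state[node]] += p / len(rates)
    return joint / joint.sum()


def enumerate_fitch_score(tree, presence: dict[str, int]) -> int:
    """Minimum number of presence/absence changes over all internal assignments."""
    internal = [n for n in tree.postorder() if not n.is_leaf]
    best = math.inf
    for assign in itertools.product((0, 1), repeat=len(internal)):
        state = dict(zip(internal, assign))
        for leaf in tree.leaves():
            state[leaf] = presence[leaf.label]
        changes = sum(
            1
            for n in tree.postorder()
            if n.parent is not None and state[n] != state[n.parent]
        )
        best = min(best, changes)
    return int(best)


def gamma_bin_mean_rates(alpha: float, K: int) -> np.ndarray:
    """Category rates by numerical quadrature of x * pdf over each quantile bin."""
    dist = gamma_dist(a=alpha, scale=1.0 / alpha)
    bounds = dist.ppf(np.arange(K + 1) / K)
    bounds[-1] = max(bounds[-1], 60.0 / alpha)  # finite upper limit for quad
    rates = []
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        mass, _ = quad(lambda x: x * dist.pdf(x), lo, hi, limit=200)
        rates.append(mass * K)
    return np.asarray(rates)


# ---------------------------------------------------------------------------
# exhaustive DTL reconciliation


def enumerate_dtl_cost(sliced, gtree, costs, leaf_map=lambda s: s.split("|")[0]) -> float:
    """Minimum DTL cost by exhaustive enumeration.

    Positions are (branch, slice) pairs. Single-lineage movement costs
    between positions come from Floyd–Warshall over pass (0), speciation-loss
    (loss cost) and transfer-loss (transfer+loss) edges. Every assignment of
    gene internal nodes to (position, event, recipient, child order) is
    enumerated; gene leaves are pinned to their species' terminal position.
    The origination convention matches the simulator: the lineage enters at
    the species root and immediately passes its speciation (surviving on both
    sides or losing one).
    """
    S = sliced.n_slices
    positions = [(e, s) for s in range(S) for e in sliced.slice_branches[s]]
    pidx = {p: i for i, p in enumerate(positions)}
    n = len(positions)
    M = np.full((n, n), math.inf)
    np.fill_diagonal(M, 0.0)
    for s in range(S):
        bottom = sliced.boundaries[s + 1]
        for e in sliced.slice_branches[s]:
            i = pidx[(e, s)]
            for f in sliced.slice_branches[s]:
                if f is not e:
                    M[i, pidx[(f, s)]] = min(
                        M[i, pidx[(f, s)]], costs.transfer + costs.loss
                    )
            if s + 1 < S:
                if abs(e.age - bottom) <= 1e-12 and not e.is_leaf:
                    for child in e.children:
                        M[i, pidx[(child, s + 1)]] = min(
                            M[i, pidx[(child, s + 1)]], costs.loss
                        )
                elif e.age < bottom - 1e-12 or e.is_leaf:
                    if (e, s + 1) in pidx:
                        M[i, pidx[(e, s + 1)]] = min(M[i, pidx[(e, s + 1)]], 0.0)
    for kk in range(n):
        M = np.minimum(M, M[:, kk : kk + 1] + M[kk : kk + 1, :])

    species_leaf = {lf.label: lf for lf in sliced.stree.tree.leaves()}
    terminal = {lf: pidx[(lf, S - 1)] for lf in species_leaf.values()}

    ginternal = [u for u in gtree.postorder() if not u.is_leaf]

    # options per internal gene node: (event cost, position index, child start positions)
    def node_options(u):
        out = []
        for (e, s) in positions:
            i = pidx[(e, s)]
            bottom = sliced.boundaries[s + 1]
            # speciation: branch must end at the slice bottom
            if abs(e.age - bottom) <= 1e-12 and not e.is_leaf and s + 1 < S:
                f, g = e.children
                for a, b in ((f, g), (g, f)):
                    out.append((0.0, i, (pidx[(a, s + 1)], pidx[(b, s + 1)])))
            out.append((costs.duplication, i, (i, i)))
            for f in sliced.slice_branches[s]:
                if f is not e:
                    j = pidx[(f, s)]
                    out.append((costs.transfer, i, (i, j)))
                    out.append((costs.transfer, i, (j, i)))
        return out

    options = {u: node_options(u) for u in ginternal}

    best = math.inf
    sroot = sliced.stree.root
    root_starts = []
    c1, c2 = sroot.children
    for a, b in ((c1, c2), (c2, c1)):
        root_starts.append(("S", pidx[(a, 0)], pidx[(b, 0)]))
    for a in (c1, c2):
        root_starts.append(("SL", pidx[(a, 0)], None))

    # bottom-up over gene nodes: minimal subtree cost as a function of the
    # lineage's start position; movement between positions always goes
    # through the shortest-path matrix M, so this construction shares no
    # recursion structure with the production slice-sweep DP.
    subtree_from: dict = {}
    for u in gtree.postorder():
        if u.is_leaf:
            subtree_from[u] = np.array(
                [M[p, terminal[species_leaf[leaf_map(u.label)]]] for p in range(n)]
            )
        else:
            best_at = np.full(n, math.inf)
            for ev_cost, pos, starts in options[u]:
                c = ev_cost + sum(
                    subtree_from[child][start]
                    for child, start in zip(u.children, starts)
                )
                best_at[pos] = min(best_at[pos], c)
            # arriving from any start position via movement
            subtree_from[u] = np.min(M + best_at[None, :], axis=1)

    groot = gtree.root
    for kind, p1, p2 in root_starts:
        if kind == "S":
            if groot.is_leaf:
                continue
            u1, u2 = groot.children
            best = min(best, subtree_from[u1][p1] + subtree_from[u2][p2])
        else:
            best = min(best, costs.loss + subtree_from[groot][p1])
    return float(best)
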