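"""Marginal (empirical-Bayes) ancestral sequence reconstruction with
indel-aware ancestral gap handling.

For every internal node and alignment column the posterior distribution of
the ancestral state given all tip data is computed by an inside–outside pass
of the pruning algorithm, marginalized over the discrete-gamma categories;
the maximum-posterior (MAP) state is reported with its PP. The ancestral gap
pattern is inferred separately on the binary presence/absence character of
each column (Fitch parsimony by default, Dollo optionally) and substituted
into the MAP sequences: a site inferred as a gap is masked regardless of its
amino-acid posterior.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alignment import Alignment, GAP
from .likelihood import compute_partials, encode_columns, LikelihoodError
from .models import SubstitutionModel, build_rate_matrix
from .trees import Node, Tree

__all__ = [
    "AncestralProfile",
    "marginal_profiles",
    "infer_gap_states",
    "compose_ancestors",
    "count_replacements",
    "well_identified_fraction",
]


@dataclass
class AncestralProfile:
    """Per internal node x column posterior state distributions and MAP calls."""

    alphabet: str
    node_labels: list[str]
    probabilities: dict[str, np.ndarray]  # label -> (n_cols, n_states), rows sum to 1
    map_state: dict[str, np.ndarray] = field(default_factory=dict)  # state indices
    map_pp: dict[str, np.ndarray] = field(default_factory=dict)
    ties: list[tuple[str, int]] = field(default_factory=list)  # (node, column) with tied MAP

    def __post_init__(self):
        for label in self.node_labels:
            P = self.probabilities[label]
            if label not in self.map_state:
                # argmax breaks ties by the fixed state order; log the ties
                self.map_state[label] = P.argmax(axis=1)
                self.map_pp[label] = P.max(axis=1)
                near = (np.abs(P - self.map_pp[label][:, None]) < 1e-12).sum(axis=1)
                for j in np.nonzero(near > 1)[0]:
                    self.ties.append((label, int(j)))

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.probabilities.values())))

    def map_sequence(self, label: str) -> str:
        return "".join(self.alphabet[i] for i in self.map_state[label])

    def to_tsv(self, label: str) -> str:
        header = "node\tcolumn\t" + "\t".join(self.alphabet) + "\tMAP\tPP"
        lines = [header]
        P = self.probabilities[label]
        for j in range(len(P)):
            probs = "\t".join(f"{p:.6g}" for p in P[j])
            lines.append(
                f"{label}\t{j}\t{probs}\t{self.alphabet[self.map_state[label][j]]}"
                f"\t{self.map_pp[label][j]:.6g}"
            )
        return "\n".join(lines) + "\n"


def marginal_profiles(
    tree: Tree, alignment: Alignment, model: SubstitutionModel
) -> AncestralProfile:
    """Posterior ancestral state distributions at every internal node.

    Inside–outside computation: the inside (pruning) pass conditions on the
    data below a node, the outside pass on everything else; gamma categories
    are mixed with their per-column posterior weights. The tree must be
    rooted; internal nodes without labels get deterministic ones.
    """
    tree = tree.copy()
    tree.label_internal()
    labels = set(tree.leaf_labels())
    missing = labels - set(alignment.names)
    if missing:
        raise LikelihoodError(f"leaves without sequences: {sorted(missing)}")
    rm = build_rate_matrix(model)
    enc = encode_columns(tree, alignment, model)
    rates = model.rates()
    n_cols = len(alignment)
    n_states = model.n_states

    cat_posteriors = []  # per category: dict node -> (n_states, n_cols) normalized joint
    cat_loglik = np.empty((model.K, n_cols))
    for k, r in enumerate(rates):
        partials, log_scale, messages = compute_partials(tree, enc, rm, r)
        site = rm.pi @ partials[tree.root]
        with np.errstate(divide="ignore"):
            cat_loglik[k] = np.where(
                site > 0, np.log(np.where(site > 0, site, 1.0)) + log_scale, -np.inf
            )
        # outside pass
        outside: dict[Node, np.ndarray] = {tree.root: np.tile(rm.pi[:, None], (1, n_cols))}
        posts: dict[str, np.ndarray] = {}
        for node in tree.preorder():
            if not node.is_leaf:
                # posterior(joint) ~ outside * inside, normalized per column
                J = outside[node] * partials[node]
                tot = J.sum(axis=0)
                tot[tot == 0] = 1.0
                posts[node.label] = (J / tot).T
            for child in node.children:
                if child.is_leaf:
                    continue
                sib_prod = outside[node].copy()
                for other in node.children:
                    if other is not child:
                        sib_prod *= messages[other]
                P = rm.transition_matrix((child.length or 0.0) * r)
                out = P.T @ sib_prod
                mx = out.max(axis=0)
                mx[mx == 0] = 1.0
                outside[child] = out / mx
            # free leaves' outside slots implicitly (never created)
        cat_posteriors.append(posts)

    # category weights per column (equal priors)
    mx = cat_loglik.max(axis=0)
    finite = np.isfinite(mx)
    w = np.exp(cat_loglik - np.where(finite, mx, 0.0)[None, :])
    w /= w.sum(axis=0, keepdims=True)

    internal = [n.label for n in tree.internal_nodes()]
    probabilities = {}
    for label in internal:
        P = np.zeros((n_cols, n_states))
        for k in range(model.K):
            P += w[k][:, None] * cat_posteriors[k][label]
        P /= P.sum(axis=1, keepdims=True)
        probabilities[label] = P
    return AncestralProfile(
        alphabet=model.alphabet, node_labels=internal, probabilities=probabilities
    )


# ---------------------------------------------------------------------------
# ancestral gaps


def infer_gap_states(
    alignment: Alignment, tree: Tree, mode: str = "fitch"
) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Ancestral presence (1) / gap (0) states per internal node and column.

    ``fitch``: two-pass Fitch parsimony on the binary presence character; where
    the minimum-change reconstruction leaves the state free (the root set is
    ambiguous, and descendants inherit downward), "present" is preferred.
    ``dollo``: a single origin at the MRCA of the present leaves, any number of
    losses below it.

    Returns (presence states keyed by internal node label, per-column
    parsimony score). Dollo scores count losses.
    """
    tree = tree.copy()
    tree.label_internal()
    leaves = tree.leaves()
    if set(alignment.names) != {lf.label for lf in leaves}:
        raise LikelihoodError("alignment names do not match the tree's leaf set")
    n_cols = len(alignment)
    present = {
        lf.label: np.frombuffer(alignment[lf.label].encode(), dtype=np.uint8)
        != ord(GAP)
        for lf in leaves
    }
    internal = tree.internal_nodes()
    states = {n.label: np.zeros(n_cols, dtype=np.uint8) for n in internal}
    scores = np.zeros(n_cols, dtype=np.int64)

    if mode == "fitch":
        # first pass: state sets as 2-bit masks (1 = gap, 2 = present, 3 = either)
        sets: dict[Node, np.ndarray] = {}
        for node in tree.postorder():
            if node.is_leaf:
                sets[node] = np.where(present[node.label], 2, 1).astype(np.uint8)
            else:
                a, b = (sets[c] for c in node.children)
                inter = a & b
                union = a | b
                empty = inter == 0
                sets[node] = np.where(empty, union, inter).astype(np.uint8)
                scores += empty
        # second pass
        assigned: dict[Node, np.ndarray] = {}
        for node in tree.preorder():
            if node.is_leaf:
                continue
            s = sets[node]
            if node is tree.root:
                choice = np.where(s == 1, 0, 1)  # ambiguous (3) -> present
            else:
                p = assigned[node.parent]
                pmask = np.where(p == 1, 2, 1).astype(np.uint8)
                inherit = (s & pmask) != 0
                choice = np.where(inherit, p, np.where(s == 2, 1, 0))
            assigned[node] = choice.astype(np.uint8)
            states[node.label] = assigned[node]
    elif mode == "dollo":
        # single origin at the MRCA of present leaves, losses below it: a node
        # is present iff it lies on the subtree spanning the present leaves
        count_below: dict[Node, np.ndarray] = {}
        for node in tree.postorder():
            if node.is_leaf:
                count_below[node] = present[node.label].astype(np.int64)
            else:
                count_below[node] = np.sum([count_below[c] for c in node.children], axis=0)
        total = count_below[tree.root]
        for node in internal:
            has_present = count_below[node] > 0
            # a node strictly above the MRCA funnels all present leaves
            # through a single child; the MRCA and everything below do not
            above_mrca = np.any(
                [(count_below[c] == total) & (total > 0) for c in node.children], axis=0
            )
            states[node.label] = (has_present & ~above_mrca).astype(np.uint8)
        # score = number of loss edges (present parent, absent child)
        scores = np.zeros(n_cols, dtype=np.int64)
        for node in tree.preorder():
            if node is tree.root:
                continue
            parent_state = states[node.parent.label].astype(bool)
            child_state = (
                present[node.label]
                if node.is_leaf
                else states[node.label].astype(bool)
            )
            scores += parent_state & ~child_state
    else:
        raise ValueError(f"unknown gap mode {mode!r}")
    return states, scores


def compose_ancestors(
    profile: AncestralProfile, gaps: dict[str, np.ndarray]
) -> dict[str, str]:
    """Substitute inferred ancestral gaps into the MAP sequences.

    A column whose presence state is 0 becomes the gap symbol regardless of
    the amino-acid posterior there.
    """
    out = {}
    for label in profile.node_labels:
        if label not in gaps:
            raise ValueError(f"no gap states for node {label!r}")
        presence = np.asarray(gaps[label])
        if len(presence) != profile.n_columns:
            raise ValueError("gap states and profile have different lengths")
        seq = profile.map_sequence(label)
        out[label] = "".join(
            c if p else GAP for c, p in zip(seq, presence)
        )
    return out


def count_replacements(a: str, b: str) -> int:
    """Replacements between two gapped sequences: columns where both are
    non-gap and the states differ. Gapped columns are excluded."""
    if len(a) != len(b):
        raise ValueError("sequences have unequal length")
    return sum(1 for x, y in zip(a, b) if x != GAP and y != GAP and x != y)


def well_identified_fraction(
    profile: AncestralProfile,
    node: str,
    threshold: float = 0.9,
    presence: np.ndarray | None = None,
) -> float:
    """Fraction of (non-gap) ancestral columns with MAP PP strictly above
    ``threshold`` — the reconstruction-confidence statistic."""
    pp = profile.map_pp[node]
    if presence is not None:
        pp = pp[np.asarray(presence, bool)]
    if len(pp) == 0:
        return 0.0
    return float(np.mean(pp > threshold))
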