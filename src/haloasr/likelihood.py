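"""Felsenstein pruning likelihood with discrete-gamma rate heterogeneity.

Gaps and unknown residues enter as missing data (all-ones partial vectors).
Per-node scaling keeps long alignments away from underflow; an impossible
column (zero likelihood) is reported as the explicit ``NEG_INF`` sentinel,
never as an exception.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .alignment import Alignment, GAP, UNKNOWN
from .models import RateMatrix, SubstitutionModel, build_rate_matrix
from .trees import Node, Tree

__all__ = ["NEG_INF", "SiteRates", "pruning_loglik", "site_posterior_rates"]

NEG_INF = float("-inf")


class LikelihoodError(ValueError):
    pass


def encode_columns(tree: Tree, alignment: Alignment, model: SubstitutionModel) -> dict[Node, np.ndarray]:
    """Map each leaf to an int vector of state indices; gap/unknown -> -1."""
    lut = np.full(128, -2, dtype=np.int64)
    for i, aa in enumerate(model.alphabet):
        lut[ord(aa)] = i
    lut[ord(GAP)] = -1
    lut[ord(UNKNOWN)] = -1
    enc: dict[Node, np.ndarray] = {}
    for leaf in tree.leaves():
        if leaf.label not in alignment:
            raise LikelihoodError(f"leaf {leaf.label!r} has no sequence")
        codes = lut[np.frombuffer(alignment[leaf.label].encode(), dtype=np.uint8)]
        if np.any(codes == -2):
            raise LikelihoodError(f"sequence of {leaf.label!r} has symbols outside the model alphabet")
        enc[leaf] = codes
    return enc


def compute_partials(
    tree: Tree,
    enc: dict[Node, np.ndarray],
    rm: RateMatrix,
    rate: float,
) -> tuple[dict[Node, np.ndarray], np.ndarray, dict[Node, np.ndarray]]:
    """Down-pass conditional likelihoods under one rate category.

    Returns (partials, log_scale, messages): ``partials[node]`` has shape
    (n_states, n_cols); ``log_scale`` (n_cols,) accumulates the per-column
    scaling; ``messages[node]`` is P(t_node) @ partials[node], the vector the
    node passes to its parent (kept for the ancestral up-pass).
    """
    n_states = rm.Q.shape[0]
    n_cols = len(next(iter(enc.values())))
    partials: dict[Node, np.ndarray] = {}
    messages: dict[Node, np.ndarray] = {}
    log_scale = np.zeros(n_cols)
    for node in tree.postorder():
        if node.is_leaf:
            codes = enc[node]
            F = np.zeros((n_states, n_cols))
            missing = codes < 0
            F[:, missing] = 1.0
            obs = ~missing
            F[codes[obs], np.nonzero(obs)[0]] = 1.0
        else:
            F = np.ones((n_states, n_cols))
            for child in node.children:
                F *= messages[child]
            mx = F.max(axis=0)
            pos = mx > 0
            F[:, pos] /= mx[pos]
            with np.errstate(divide="ignore"):
                log_scale += np.where(pos, np.log(np.where(pos, mx, 1.0)), NEG_INF)
        partials[node] = F
        if node.parent is not None:
            t = node.length
            if t is None:
                raise LikelihoodError(f"node {node.label!r} lacks a branch length")
            if t < 0:
                raise LikelihoodError("negative branch length")
            messages[node] = rm.transition_matrix(t * rate) @ F
    return partials, log_scale, messages


def per_category_site_loglik(
    tree: Tree, alignment: Alignment, model: SubstitutionModel
) -> np.ndarray:
    """Matrix (K, n_cols) of per-category per-column log-likelihoods."""
    labels = set(tree.leaf_labels())
    missing = labels - set(alignment.names)
    if missing:
        raise LikelihoodError(f"leaves without sequences: {sorted(missing)}")
    rm = build_rate_matrix(model)
    enc = encode_columns(tree, alignment, model)
    rates = model.rates()
    out = np.empty((model.K, len(alignment)))
    for k, r in enumerate(rates):
        partials, log_scale, _ = compute_partials(tree, enc, rm, r)
        site = rm.pi @ partials[tree.root]
        with np.errstate(divide="ignore"):
            out[k] = np.where(site > 0, np.log(np.where(site > 0, site, 1.0)) + log_scale, NEG_INF)
    return out


def pruning_loglik(tree: Tree, alignment: Alignment, model: SubstitutionModel) -> np.ndarray:
    """Per-column log-likelihoods, averaged over the K equal-weight gamma categories.

    The total alignment log-likelihood is ``pruning_loglik(...).sum()``.
    """
    cat = per_category_site_loglik(tree, alignment, model)
    return logsumexp(cat, axis=0) - np.log(model.K)


@dataclass
class SiteRates:
    """Per-column posterior mean rates and per-category posterior weights."""

    mean: np.ndarray  # (n_cols,)
    weights: np.ndarray  # (n_cols, K), rows sum to 1
    rates: np.ndarray  # (K,) category rates
    all_gap: np.ndarray  # (n_cols,) bool: posterior equals the prior there

    def __len__(self) -> int:
        return len(self.mean)

    def to_tsv(self) -> str:
        lines = ["column\tposterior_mean_rate\tall_gap\t" + "\t".join(
            f"w_cat{k}" for k in range(self.weights.shape[1])
        )]
        for j in range(len(self)):
            ws = "\t".join(f"{w:.6g}" for w in self.weights[j])
            lines.append(f"{j}\t{self.mean[j]:.6g}\t{int(self.all_gap[j])}\t{ws}")
        return "\n".join(lines) + "\n"


def site_posterior_rates(
    tree: Tree, alignment: Alignment, model: SubstitutionModel
) -> SiteRates:
    """Posterior mean evolutionary rate per column under the discrete gamma model.

    Category weights are proportional to the per-category column likelihoods
    (equal priors). All-gap columns carry no signal: their posterior equals
    the prior and they are flagged.
    """
    cat = per_category_site_loglik(tree, alignment, model)  # (K, n_cols)
    rates = model.rates()
    mx = cat.max(axis=0)
    informative = np.isfinite(mx)
    w = np.exp(cat - np.where(informative, mx, 0.0)[None, :])
    w /= w.sum(axis=0, keepdims=True)
    all_gap = np.array(
        [all(c < 0 for c in _leaf_codes_col(tree, alignment, model, j)) for j in range(len(alignment))]
    )
    w[:, all_gap] = 1.0 / model.K
    mean = rates @ w
    return SiteRates(mean=mean, weights=w.T, rates=rates, all_gap=all_gap)


def _leaf_codes_col(tree: Tree, alignment: Alignment, model: SubstitutionModel, j: int):
    sym = set(model.alphabet)
    for leaf in tree.leaves():
        c = alignment[leaf.label][j]
        yield model.alphabet.index(c) if c in sym else -1
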