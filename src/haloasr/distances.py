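"""Pairwise ML distances and neighbor joining — the distance stand-in for gene-tree inference.

The distance between two sequences maximizes the two-sequence likelihood
under the reversible model (gamma mixture included) over t in [1e-6, 10];
trees come from scikit-bio's neighbor joining with negative branch estimates
clamped to zero, returned rooted at the NJ trifurcation so the caller can
midpoint-root them.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from skbio import DistanceMatrix
from skbio.tree import nj as _skbio_nj

from .alignment import Alignment
from .models import SubstitutionModel, build_rate_matrix
from .trees import Tree

__all__ = ["ml_pairwise_distance", "distance_matrix", "nj_tree", "MIN_DISTANCE", "MAX_DISTANCE"]

MIN_DISTANCE = 1e-6
MAX_DISTANCE = 10.0


class DistanceError(ValueError):
    pass


def ml_pairwise_distance(a: str, b: str, model: SubstitutionModel) -> float:
    """Expected replacements per site maximizing the two-sequence likelihood.

    Columns where either sequence has a gap or unknown state are skipped.
    Symmetric in its arguments by time-reversibility.
    """
    if len(a) != len(b):
        raise DistanceError("sequences have unequal length")
    states = set(model.alphabet)
    counts = np.zeros((model.n_states, model.n_states))
    for x, y in zip(a, b):
        if x in states and y in states:
            counts[model.state_index(x), model.state_index(y)] += 1
    n = counts.sum()
    if n == 0:
        raise DistanceError("no comparable (gap-free) columns")
    rm = build_rate_matrix(model)
    rates = model.rates()
    pi = model.pi

    def neg_loglik(t: float) -> float:
        mix = np.zeros_like(counts)
        for r in rates:
            mix += rm.transition_matrix(t * r)
        mix *= pi[:, None] / len(rates)
        with np.errstate(divide="ignore"):
            logmix = np.log(mix)
        mask = counts > 0
        if np.any(np.isneginf(logmix[mask])):
            return np.inf
        return -(counts[mask] * logmix[mask]).sum()

    res = minimize_scalar(neg_loglik, bounds=(MIN_DISTANCE, MAX_DISTANCE), method="bounded",
                          options={"xatol": 1e-10})
    return float(np.clip(res.x, MIN_DISTANCE, MAX_DISTANCE))


def distance_matrix(alignment: Alignment, model: SubstitutionModel) -> pd.DataFrame:
    """Symmetric ML distance matrix over all sequence pairs of an alignment."""
    names = alignment.names
    n = len(names)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = ml_pairwise_distance(
                alignment[names[i]], alignment[names[j]], model
            )
    return pd.DataFrame(D, index=names, columns=names)


def nj_tree(distances: pd.DataFrame) -> Tree:
    """Neighbor joining; negative branch-length estimates are clamped to 0.

    The returned tree is the unrooted NJ tree represented as rooted at its
    final trifurcation; use :func:`haloasr.trees.midpoint_root` to root it.
    """
    D = distances.to_numpy(dtype=float)
    if D.shape[0] < 3:
        raise DistanceError("need at least 3 taxa for neighbor joining")
    if not np.allclose(D, D.T, atol=1e-9) or not np.allclose(np.diag(D), 0.0):
        raise DistanceError("distance matrix must be symmetric with zero diagonal")
    dm = DistanceMatrix(D, list(distances.index))
    sk = _skbio_nj(dm, neg_as_zero=True)
    tree = Tree.from_newick(str(sk))
    for node in tree.postorder():
        if node.length is not None and node.length < 0:
            node.length = 0.0
    tree.validate(allow_root_trifurcation=True)
    return tree
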