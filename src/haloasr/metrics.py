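"""Sequence-level halophily proxies: the acidic DE/KR ratio, the M^f½ salt-
stability midpoint extracted from folded-fraction transition curves, and the
metric-vs-replacement trajectory tables used to follow stability along
ancestral lineages.

Halophilic proteins carry a strongly acidic surface: a ratio of (D+E) over
(K+R) residue counts above 2 marks the halobacterial regime. M^f½ is the salt
concentration at which half of the protein is still folded and active after
incubation; halophilic MalDHs unfold when the salt concentration drops, so
transition curves rise with concentration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .alignment import GAP
from .asr import count_replacements
from .simulate import StabilityCurve, logistic_folded_fraction

__all__ = ["de_kr_ratio", "MfHalfFit", "fit_mf_half", "build_trajectory"]


def de_kr_ratio(sequence: str) -> float:
    """(D + E) / (K + R) residue-count ratio; gaps are ignored.

    Returns ``math.inf`` when acidic residues are present but no basic ones;
    raises if the sequence carries no charged residues at all.
    """
    s = sequence.replace(GAP, "")
    if not s:
        raise ValueError("empty sequence")
    de = s.count("D") + s.count("E")
    kr = s.count("K") + s.count("R")
    if kr == 0:
        if de == 0:
            raise ValueError("no charged residues: DE/KR undefined")
        return math.inf
    return de / kr


@dataclass
class MfHalfFit:
    """Two-parameter logistic fit of a stability transition curve."""

    mf_half: float  # M
    width: float  # M
    rss: float
    converged: bool
    method: str = "logistic"  # or "interpolation" fallback

    def __iter__(self):
        return iter((self.mf_half, self.width))


def fit_mf_half(
    curve: StabilityCurve, window: Optional[tuple[float, float]] = None
) -> MfHalfFit:
    """Least-squares fit of f(c) = 1 / (1 + exp(-(c - m)/w)) to a transition curve.

    Initialization: m at the concentration whose fraction is nearest 0.5,
    w = (c_max - c_min)/10. ``window`` restricts the fit to a concentration
    interval (used for bell-shaped MgCl2 curves, where only the
    low-concentration limb reflects the folding transition). If the optimizer
    fails, the 0.5-crossing is read off by linear interpolation instead.
    """
    c = np.asarray(curve.concentrations, float)
    f = np.asarray(curve.fractions, float)
    if window is not None:
        keep = (c >= window[0]) & (c <= window[1])
        c, f = c[keep], f[keep]
    if len(c) < 4:
        raise ValueError("need at least 4 points to fit a transition curve")
    m0 = float(c[np.argmin(np.abs(f - 0.5))])
    w0 = float((c.max() - c.min()) / 10.0)

    def residuals(theta):
        m, w = theta
        return logistic_folded_fraction(c, m, abs(w) + 1e-12) - f

    try:
        res = least_squares(residuals, x0=[m0, w0], method="lm", max_nfev=10000)
        ok = res.success and np.isfinite(res.x).all()
    except Exception:
        ok = False
    if ok:
        m, w = float(res.x[0]), float(abs(res.x[1]))
        return MfHalfFit(m, w, rss=float(2 * res.cost), converged=True)
    # fallback: linear interpolation of the first upward 0.5 crossing
    for i in range(len(c) - 1):
        lo, hi = f[i], f[i + 1]
        if (lo - 0.5) * (hi - 0.5) <= 0 and lo != hi:
            m = c[i] + (0.5 - lo) * (c[i + 1] - c[i]) / (hi - lo)
            return MfHalfFit(float(m), float("nan"), rss=float("nan"),
                             converged=False, method="interpolation")
    return MfHalfFit(float("nan"), float("nan"), rss=float("nan"),
                     converged=False, method="interpolation")


def build_trajectory(
    root_ancestor: str,
    chain: Sequence[tuple[str, str]],
    metrics: dict[str, dict[str, float]],
    salts: Optional[dict[tuple[str, str], str]] = None,
) -> pd.DataFrame:
    """Metric values along a lineage, against replacements since the root ancestor.

    ``chain`` is an ordered list of (enzyme id, gapped sequence) from oldest to
    youngest; ``metrics[enzyme][metric_name] = value``; ``salts`` optionally
    names the salt of a (enzyme, metric) pair. Replacement counts use
    gap-excluding pairwise counting against the root ancestor.
    """
    rows = []
    for enzyme, seq in chain:
        if len(seq) != len(root_ancestor):
            raise ValueError(f"sequence length mismatch for {enzyme!r}")
        n_repl = count_replacements(root_ancestor, seq)
        for metric, value in metrics.get(enzyme, {}).items():
            salt = (salts or {}).get((enzyme, metric))
            rows.append(
                {
                    "enzyme": enzyme,
                    "replacements_since_root": n_repl,
                    "metric": metric,
                    "value": value,
                    "salt": salt,
                }
            )
    df = pd.DataFrame(
        rows,
        columns=["enzyme", "replacements_since_root", "metric", "value", "salt"],
    )
    if df.duplicated(subset=["enzyme", "metric", "salt"]).any():
        raise ValueError("duplicate (enzyme, metric, salt) row")
    return df
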