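"""Weighted directed degree assortativity of per-participant flow networks.

The ten ROIs are nodes and each off-diagonal |tau| is a weighted directed
edge.  A node's weighted in-degree (out-degree) is the sum of |tau| over its
incoming (outgoing) connections.  The assortativity coefficient r_w is the
weight-weighted Pearson correlation, across edges, between the degree of the
edge's source and the degree of its target; it ranges from -1 (perfectly
disassortative) to 1 (perfectly assortative) and is undefined when either
endpoint degree has zero variance over edges.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .flow import FlowMatrix
from .group import cohens_d

VARIANTS = ("out-in", "in-out", "out-out", "in-in")


@dataclass
class NodeDegrees:
    in_degree: np.ndarray
    out_degree: np.ndarray
    roi_labels: tuple


def weighted_degrees(m: FlowMatrix) -> NodeDegrees:
    """Weighted in/out-degrees; masked cells contribute zero."""
    w = np.nan_to_num(m.abs_tau, nan=0.0)
    np.fill_diagonal(w, 0.0)
    return NodeDegrees(in_degree=w.sum(axis=0), out_degree=w.sum(axis=1),
                       roi_labels=m.roi_labels)


@dataclass
class AssortativityResult:
    r_w: float
    participant_id: str
    variant: str

    @property
    def defined(self) -> bool:
        return np.isfinite(self.r_w)


def _weighted_pearson(x, y, w) -> float:
    sw = w.sum()
    mx = np.sum(w * x) / sw
    my = np.sum(w * y) / sw
    cxy = np.sum(w * (x - mx) * (y - my)) / sw
    vx = np.sum(w * (x - mx) ** 2) / sw
    vy = np.sum(w * (y - my) ** 2) / sw
    # relative tolerance: regular graphs give variance ~ machine-eps * degree^2
    tol = 1e-12 * (np.abs(mx) + np.abs(my) + 1.0) ** 2
    if vx <= tol or vy <= tol:
        return np.nan
    return float(np.clip(cxy / np.sqrt(vx * vy), -1.0, 1.0))


def degree_assortativity(m: FlowMatrix, variant: str = "out-in") -> AssortativityResult:
    """Weight-weighted Pearson correlation of endpoint degrees over edges.

    ``variant`` picks which degree is read at each end: the default
    ``"out-in"`` correlates the source's out-degree with the target's
    in-degree.  Degenerate networks (fewer than 2 edges, or zero degree
    variance, e.g. a complete graph with equal weights) yield NaN with the
    ``defined`` flag false rather than an error.
    """
    if variant not in VARIANTS:
        raise ValueError(f"variant must be one of {VARIANTS}")
    deg = weighted_degrees(m)
    w_mat = np.nan_to_num(m.abs_tau, nan=0.0)
    np.fill_diagonal(w_mat, 0.0)
    src, tgt = np.nonzero(w_mat > 0)
    if src.size < 2:
        return AssortativityResult(np.nan, m.participant_id, variant)
    w = w_mat[src, tgt]
    src_deg = deg.out_degree if variant.startswith("out") else deg.in_degree
    tgt_deg = deg.in_degree if variant.endswith("in") else deg.out_degree
    r = _weighted_pearson(src_deg[src], tgt_deg[tgt], w)
    return AssortativityResult(r_w=r, participant_id=m.participant_id,
                               variant=variant)


@dataclass
class GroupAssortativityComparison:
    mean_a: float
    mean_b: float
    t_stat: float
    df: float
    p_value: float
    mean_diff: float
    se_diff: float
    ci_low: float
    ci_high: float
    cohens_d: float
    d_ci_low: float
    d_ci_high: float
    n_excluded: int = 0


def compare_assortativity(a, b, alpha: float = 0.05) -> GroupAssortativityComparison:
    """Welch (unequal-variance) t-test between two groups of r_w values.

    Undefined participants are excluded (count reported).  The confidence
    interval of the mean difference uses the Welch-Satterthwaite df; the
    Cohen's d interval uses the large-sample normal approximation of its
    standard error.
    """
    ra = np.array([x.r_w if isinstance(x, AssortativityResult) else x
                   for x in a], dtype=float)
    rb = np.array([x.r_w if isinstance(x, AssortativityResult) else x
                   for x in b], dtype=float)
    n_excluded = int(np.sum(~np.isfinite(ra)) + np.sum(~np.isfinite(rb)))
    ra = ra[np.isfinite(ra)]
    rb = rb[np.isfinite(rb)]
    if ra.size < 2 or rb.size < 2:
        raise ValueError("need >= 2 defined r_w values per group")

    na, nb = ra.size, rb.size
    va, vb = np.var(ra, ddof=1), np.var(rb, ddof=1)
    se = np.sqrt(va / na + vb / nb)
    diff = float(np.mean(ra) - np.mean(rb))
    if se == 0:
        t_stat, df, p = 0.0, float(na + nb - 2), 1.0
    else:
        t_stat = diff / se
        df = (va / na + vb / nb) ** 2 / (
            (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
        p = float(2 * sps.t.sf(abs(t_stat), df))
    tcrit = float(sps.t.ppf(1 - alpha / 2, df)) if se > 0 else 0.0

    d = cohens_d(ra, rb)
    se_d = np.sqrt((na + nb) / (na * nb) + d ** 2 / (2 * (na + nb - 2)))
    zcrit = float(sps.norm.ppf(1 - alpha / 2))
    return GroupAssortativityComparison(
        mean_a=float(np.mean(ra)), mean_b=float(np.mean(rb)),
        t_stat=float(t_stat), df=float(df), p_value=float(p),
        mean_diff=diff, se_diff=float(se),
        ci_low=diff - tcrit * se, ci_high=diff + tcrit * se,
        cohens_d=d, d_ci_low=d - zcrit * se_d, d_ci_high=d + zcrit * se_d,
        n_excluded=n_excluded)
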