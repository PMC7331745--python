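"""Signed coexpression edges between differentially expressed feature classes.

Pearson correlation is computed across all samples (both groups pooled, the
convention the small 3-vs-3 design forces), on log-scale values: counts must
be size-factor normalized and log2(x+1) transformed first. Edges are retained
only when they carry the ceRNA sign pattern — miRNA-circRNA and miRNA-mRNA
negative, circRNA-mRNA positive — since a sponge edge with the wrong sign is
meaningless downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io_formats import ExpressionMatrix

log = logging.getLogger(__name__)

SIGNS = ("positive", "negative")


@dataclass(frozen=True)
class CoexprEdge:
    """A retained signed correlation edge between two features."""

    a_id: str
    a_class: str
    b_id: str
    b_class: str
    r: float
    p_value: float
    required_sign: str


def pearson(x, y) -> tuple[float, float]:
    """Pearson r with the two-sided t-distribution p-value (n-2 df).

    Constant input makes r undefined; (0.0, 1.0) is returned with a warning
    so that degenerate features never produce edges.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-d vectors")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        log.warning("constant vector in correlation; returning r=0, p=1")
        return 0.0, 1.0
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def _corr_matrix(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs Pearson r and p between rows of a and rows of b."""
    n = a.shape[1]
    az = a - a.mean(axis=1, keepdims=True)
    bz = b - b.mean(axis=1, keepdims=True)
    asd = np.sqrt((az ** 2).sum(axis=1))
    bsd = np.sqrt((bz ** 2).sum(axis=1))
    const_a, const_b = asd == 0, bsd == 0
    asd[const_a] = 1.0
    bsd[const_b] = 1.0
    r = (az / asd[:, None]) @ (bz / bsd[:, None]).T
    r = np.clip(r, -1.0, 1.0)
    r[const_a, :] = 0.0
    r[:, const_b] = 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r ** 2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.isfinite(t), p, 0.0)  # |r| == 1 -> p = 0
    p[const_a, :] = 1.0
    p[:, const_b] = 1.0
    return r, p


def coexpression_edges(a: ExpressionMatrix, a_class: str,
                       b: ExpressionMatrix, b_class: str,
                       required_sign: str, r_min: float = 0.9,
                       alpha: float = 0.05) -> list[CoexprEdge]:
    """Test all cross-class feature pairs and keep sign-consistent edges.

    A pair is retained iff sign(r) matches ``required_sign``, |r| >= r_min
    and p < alpha. Both matrices must hold the same samples in the same
    order, on a log scale.
    """
    if required_sign not in SIGNS:
        raise ValueError(f"required_sign must be one of {SIGNS}")
    if a_class == b_class:
        raise ValueError("coexpression edges connect two different classes")
    if a.sample_ids != b.sample_ids:
        raise ValueError("sample sets/order differ between the two matrices")
    if a.layer == "counts" or b.layer == "counts":
        raise ValueError("coexpression requires log-scale values, got raw counts")

    r, p = _corr_matrix(a.values.to_numpy(dtype=float),
                        b.values.to_numpy(dtype=float))
    want_pos = required_sign == "positive"
    keep = (np.abs(r) >= r_min) & (p < alpha) & ((r > 0) == want_pos) & (r != 0)
    edges = [
        CoexprEdge(a.feature_ids[i], a_class, b.feature_ids[j], b_class,
                   float(r[i, j]), float(p[i, j]), required_sign)
        for i, j in np.argwhere(keep)
    ]
    edges.sort(key=lambda e: (e.a_id, e.b_id))
    log.info("coexpression %s-%s: %d/%d pairs retained (sign=%s, |r|>=%g, p<%g)",
             a_class, b_class, len(edges), r.size, required_sign, r_min, alpha)
    return edges


def edges_to_frame(edges: list[CoexprEdge]):
    import pandas as pd

    return pd.DataFrame(
        [
            {"a_id": e.a_id, "a_class": e.a_class, "b_id": e.b_id,
             "b_class": e.b_class, "r": e.r, "p": e.p_value,
             "required_sign": e.required_sign}
            for e in edges
        ],
        columns=["a_id", "a_class", "b_id", "b_class", "r", "p", "required_sign"],
    )
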