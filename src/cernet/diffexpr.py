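"""Differential expression for small-n case/control designs.

Counts (circRNA, mRNA) are normalized with median-of-ratios size factors and
tested feature-wise with a two-sided Student (pooled-variance) t-test on
log2(x+1); microarray log-intensities are tested the same way without
normalization. This is a deliberately simple, documented equivalent of the
DESeq workflow: the downstream ceRNA inference — not the count model — is
the point of the package. The pooled test is used rather than Welch because
with three samples per group the Welch-Satterthwaite approximation is
markedly conservative (attained type-I error near 0.033 at nominal 0.05
even on ideal Gaussian nulls) while the pooled test is near-exactly
calibrated; with a shared generative noise model per class, equal group
variances are also the natural assumption.

The study-wide filter is |fold change| >= 1.5 and p < 0.05, applied per
molecule class; Benjamini–Hochberg q-values are always computed and can be
used instead of raw p via a flag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import ExpressionMatrix

log = logging.getLogger(__name__)

MOLECULE_CLASSES = ("circRNA", "miRNA", "mRNA")

# tolerance for the >= fold-change boundary: log2(1.5) stored as a float
# must still count as a 1.5-fold change
_FC_EPS = 1e-9


@dataclass(frozen=True)
class DERecord:
    """Per-feature differential-expression result (case vs control)."""

    feature_id: str
    molecule_class: str
    log2fc: float
    p_value: float
    q_value: float
    direction: str  # up | down
    mean_case: float
    mean_control: float


def size_factors(counts: ExpressionMatrix) -> dict[str, float]:
    """Median-of-ratios size factors (the DESeq estimator).

    For each sample j, factor_j is the median over features of
    count_ij / geometric_mean_i, computed over features with no zero count;
    the factors are then rescaled to geometric mean 1, which makes the
    estimator idempotent (re-estimating on the normalized matrix returns
    unit factors).
    """
    if counts.layer != "counts":
        raise ValueError(f"size factors require a counts layer, got {counts.layer!r}")
    arr = counts.values.to_numpy(dtype=float)
    allpos = (arr > 0).all(axis=1)
    if not allpos.any():
        raise ValueError(
            "no feature has nonzero counts in every sample; size factors are "
            "undefined (consider adding a pseudocount upstream)")
    ref = arr[allpos]
    log_geomean = np.log(ref).mean(axis=1, keepdims=True)
    ratios = np.exp(np.log(ref) - log_geomean)
    factors = np.median(ratios, axis=0)
    factors = factors / np.exp(np.log(factors).mean())
    return dict(zip(counts.sample_ids, factors.astype(float)))


def normalize_log2(counts: ExpressionMatrix) -> ExpressionMatrix:
    """Divide by size factors and transform to log2(x+1)."""
    sf = size_factors(counts)
    norm = counts.values / pd.Series(sf)
    return ExpressionMatrix(np.log2(norm + 1.0), "log_norm", dict(counts.design))


def _ttest_table(y: pd.DataFrame, case: list[str], control: list[str]
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Feature-wise pooled-t p-values and case-minus-control mean differences."""
    a = y[case].to_numpy(dtype=float)
    b = y[control].to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ttest_ind(a, b, axis=1, equal_var=True)
    p = np.asarray(res.pvalue, dtype=float)
    degenerate = ~np.isfinite(p)
    if degenerate.any():
        # zero within-group variance in both groups; equal means -> no evidence
        log.info("%d feature(s) with degenerate variance; p set to 1", degenerate.sum())
        p = np.where(degenerate, 1.0, p)
    diff = a.mean(axis=1) - b.mean(axis=1)
    return p, diff


def _records(y: pd.DataFrame, design: dict[str, str], molecule_class: str
             ) -> list[DERecord]:
    case = [s for s in y.columns if design[s] == "case"]
    control = [s for s in y.columns if design[s] == "control"]
    if len(case) < 2 or len(control) < 2:
        raise ValueError("at least 2 samples per group are required")
    p, log2fc = _ttest_table(y, case, control)
    q = multipletests(p, method="fdr_bh")[1]
    lin = np.exp2(y) - 1.0
    mean_case = lin[case].mean(axis=1).to_numpy()
    mean_control = lin[control].mean(axis=1).to_numpy()
    return [
        DERecord(
            feature_id=str(fid),
            molecule_class=molecule_class,
            log2fc=float(fc),
            p_value=float(pv),
            q_value=float(qv),
            direction="up" if fc > 0 else "down",
            mean_case=float(mc),
            mean_control=float(mctl),
        )
        for fid, fc, pv, qv, mc, mctl
        in zip(y.index, log2fc, p, q, mean_case, mean_control)
    ]


def de_test_counts(counts: ExpressionMatrix, molecule_class: str = "mRNA"
                   ) -> list[DERecord]:
    """Differential expression on a counts matrix.

    Counts are size-factor normalized, transformed y = log2(x+1), and each
    feature is tested with a two-sided pooled t-test; log2fc is the difference
    of group means of y. BH q-values are computed over all features tested.
    """
    norm = normalize_log2(counts)
    return _records(norm.values, norm.design, molecule_class)


def de_test_intensity(intensity: ExpressionMatrix, molecule_class: str = "miRNA"
                      ) -> list[DERecord]:
    """Differential expression on an already-log-scale intensity matrix."""
    if intensity.layer == "counts":
        raise ValueError("de_test_intensity expects log-scale input, got counts")
    return _records(intensity.values, intensity.design, molecule_class)


def filter_de(records: list[DERecord], fc_threshold: float = 1.5,
              alpha: float = 0.05, use_q: bool = False
              ) -> tuple[list[DERecord], dict[str, int]]:
    """Keep records with 2^|log2fc| >= fc_threshold and p < alpha.

    With ``use_q`` the BH q-value replaces raw p in the significance clause.
    Returns the kept records and an up/down summary.
    """
    lfc_min = np.log2(fc_threshold)
    kept = [
        r for r in records
        if abs(r.log2fc) + _FC_EPS >= lfc_min
        and (r.q_value if use_q else r.p_value) < alpha
    ]
    summary = {
        "up": sum(1 for r in kept if r.direction == "up"),
        "down": sum(1 for r in kept if r.direction == "down"),
    }
    return kept, summary


def de_to_frame(records: list[DERecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "feature_id": r.feature_id,
                "class": r.molecule_class,
                "log2fc": r.log2fc,
                "p": r.p_value,
                "q": r.q_value,
                "direction": r.direction,
                "mean_case": r.mean_case,
                "mean_control": r.mean_control,
            }
            for r in records
        ],
        columns=["feature_id", "class", "log2fc", "p", "q", "direction",
                 "mean_case", "mean_control"],
    )


def frame_to_de(df: pd.DataFrame) -> list[DERecord]:
    return [
        DERecord(str(row.feature_id), str(row["class"]), float(row.log2fc),
                 float(row.p), float(row.q), str(row.direction),
                 float(row.mean_case), float(row.mean_control))
        for _, row in df.iterrows()
    ]
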