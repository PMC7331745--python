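"""Relative quantification of qPCR validation data by the 2^-ddCt method.

Each transcript is normalized against its reference gene (beta-actin for
circRNAs/mRNAs, U6 for miRNAs in the validation design): dCt = Ct_gene -
Ct_ref per sample, ddCt = mean dCt(case) - mean dCt(control), and the
reported fold change is 2^-ddCt. Per-sample relative quantities
2^-(dCt - mean dCt(control)) are also emitted for plotting and SEM.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

REQUIRED_COLUMNS = ("sample_id", "group", "gene_id", "reference_id",
                    "ct_gene", "ct_ref")


@dataclass(frozen=True)
class DdctResult:
    gene_id: str
    reference_id: str
    ddct: float
    fold_change: float
    delta_ct: dict[str, float]  # sample -> dCt
    rq: dict[str, float]  # sample -> 2^-(dCt - calibrator)


def read_ct_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    return validate_ct_table(df)


def validate_ct_table(df: pd.DataFrame) -> pd.DataFrame:
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"Ct table lacks column {col!r}")
    bad = df[~df["group"].isin(["case", "control"])]
    if len(bad):
        raise ValueError(f"unknown group value(s): {sorted(bad['group'].unique())}")
    ct = df[["ct_gene", "ct_ref"]].to_numpy(dtype=float)
    if not np.isfinite(ct).all() or (ct <= 0).any():
        i = np.argwhere(~np.isfinite(ct) | (ct <= 0))[0][0]
        raise ValueError(
            f"non-positive or missing Ct for sample {df.iloc[i]['sample_id']!r}")
    return df


def ddct(table: pd.DataFrame) -> list[DdctResult]:
    """Fold changes (case vs control) by the comparative-Ct method."""
    table = validate_ct_table(table)
    results = []
    for (gene, ref), sub in table.groupby(["gene_id", "reference_id"], sort=True):
        dct = sub["ct_gene"].astype(float) - sub["ct_ref"].astype(float)
        case = dct[sub["group"] == "case"]
        control = dct[sub["group"] == "control"]
        if case.empty or control.empty:
            raise ValueError(f"gene {gene!r}: need at least one sample per group")
        dd = float(case.mean() - control.mean())
        calib = float(control.mean())
        results.append(DdctResult(
            gene_id=str(gene),
            reference_id=str(ref),
            ddct=dd,
            fold_change=float(2.0 ** (-dd)),
            delta_ct=dict(zip(sub["sample_id"].astype(str), dct.astype(float))),
            rq={s: float(2.0 ** (-(d - calib)))
                for s, d in zip(sub["sample_id"].astype(str), dct.astype(float))},
        ))
    return results


def ddct_to_frame(results: list[DdctResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"gene_id": r.gene_id, "reference_id": r.reference_id,
          "ddct": r.ddct, "fold_change": r.fold_change}
         for r in results],
        columns=["gene_id", "reference_id", "ddct", "fold_change"],
    )
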