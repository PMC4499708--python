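"""Expression summaries: gene-wise matrix normalization and qPCR
relative quantification by the Livak 2^-ddCt method.

ddCt uses replicate-paired differencing (Ct_target - Ct_reference in
the same replicate), so any per-replicate additive shift in Ct cancels.
Regulation calls use a two-sided Welch t-test on the replicate dCt
values against the calibrator condition, starred at p < 0.05 and
p < 0.01.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "genewise_normalize",
    "ddct",
    "call_regulation",
    "DdctResult",
    "RegulationCall",
]


def genewise_normalize(
    m: pd.DataFrame, method: str = "zscore"
) -> tuple[pd.DataFrame, list[str]]:
    """Normalize each gene (row) across samples.

    ``zscore``: (x - row mean) / row sd (ddof 0); ``minmax``: scale the
    row to [0, 1].  Rows with zero spread become all zeros and are
    returned in the flag list.  Requires at least two samples.
    """
    if m.shape[1] < 2:
        raise ValueError("gene-wise normalization needs >= 2 samples")
    if m.isna().all(axis=1).any():
        raise ValueError("all-NaN expression rows are rejected")
    values = m.to_numpy(dtype=float)
    flagged: list[str] = []
    out = np.zeros_like(values)
    for i, gene in enumerate(m.index):
        row = values[i]
        if method == "zscore":
            sd = row.std()
            if sd == 0:
                flagged.append(str(gene))
                continue
            out[i] = (row - row.mean()) / sd
        elif method == "minmax":
            span = row.max() - row.min()
            if span == 0:
                flagged.append(str(gene))
                continue
            out[i] = (row - row.min()) / span
        else:
            raise ValueError(f"unknown method {method!r}")
    return pd.DataFrame(out, index=m.index, columns=m.columns), flagged


@dataclass(frozen=True)
class DdctResult:
    gene: str
    condition: str
    rq: float                  # 2^-ddCt
    ddct: float
    dct_values: tuple[float, ...]            # replicate dCt, this condition
    calibrator_dct_values: tuple[float, ...]
    sd_dct: float              # replicate SD of dCt in this condition


def ddct(
    table: pd.DataFrame,
    ref_gene: str,
    calibrator_condition: str = "CK",
) -> list[DdctResult]:
    """Relative expression 2^-ddCt per (gene, condition).

    ``table`` columns: gene, condition, replicate, Ct.  dCt is computed
    per replicate against the reference gene of the same condition and
    replicate; ddCt = mean dCt(condition) - mean dCt(calibrator).  The
    calibrator condition yields RQ = 1 by construction.
    """
    required = {"gene", "condition", "replicate", "Ct"}
    if not required.issubset(table.columns):
        raise ValueError(f"Ct table needs columns {sorted(required)}")
    ref = table[table["gene"] == ref_gene].set_index(
        ["condition", "replicate"]
    )["Ct"]
    results: list[DdctResult] = []
    for (gene, cond), grp in table[table["gene"] != ref_gene].groupby(
        ["gene", "condition"], sort=True
    ):
        dct = []
        for _, row in grp.iterrows():
            key = (cond, row["replicate"])
            if key not in ref.index:
                raise ValueError(
                    f"reference gene {ref_gene!r} missing replicate "
                    f"{row['replicate']!r} in condition {cond!r}"
                )
            dct.append(row["Ct"] - ref.loc[key])
        cal_grp = table[
            (table["gene"] == gene)
            & (table["condition"] == calibrator_condition)
        ]
        if cal_grp.empty:
            raise ValueError(
                f"{gene}: no calibrator condition {calibrator_condition!r}"
            )
        cal_dct = []
        for _, row in cal_grp.iterrows():
            key = (calibrator_condition, row["replicate"])
            if key not in ref.index:
                raise ValueError(
                    f"reference gene {ref_gene!r} missing calibrator "
                    f"replicate {row['replicate']!r}"
                )
            cal_dct.append(row["Ct"] - ref.loc[key])
        dd = float(np.mean(dct) - np.mean(cal_dct))
        results.append(
            DdctResult(
                gene=gene,
                condition=cond,
                rq=float(2.0 ** -dd),
                ddct=dd,
                dct_values=tuple(float(x) for x in dct),
                calibrator_dct_values=tuple(float(x) for x in cal_dct),
                sd_dct=float(np.std(dct, ddof=1)) if len(dct) > 1 else 0.0,
            )
        )
    return results


@dataclass(frozen=True)
class RegulationCall:
    direction: str  # up | down | ns
    p_value: float
    stars: str      # "", "*", "**"


def call_regulation(
    result: DdctResult,
    alpha_levels: tuple[float, float] = (0.05, 0.01),
) -> RegulationCall:
    """Up/down/ns call for one condition vs the calibrator.

    Welch two-sided t-test on replicate dCt values; *down* requires
    RQ < 1 with p below the first alpha, *up* RQ > 1 likewise.  With
    degenerate (zero) variance in both groups the call falls back to
    exact equality of means.
    """
    a = np.asarray(result.dct_values, dtype=float)
    b = np.asarray(result.calibrator_dct_values, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("significance needs >= 2 replicates per group")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        p = 1.0 if a.mean() == b.mean() else 0.0
    else:
        p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
    stars = ""
    if p < alpha_levels[1]:
        stars = "**"
    elif p < alpha_levels[0]:
        stars = "*"
    if p < alpha_levels[0] and result.rq < 1:
        direction = "down"
    elif p < alpha_levels[0] and result.rq > 1:
        direction = "up"
    else:
        direction = "ns"
    return RegulationCall(direction=direction, p_value=p, stars=stars)
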