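"""FPKM matrix handling, DEG calling and 2^-ddCt qPCR quantification.

A gene is *expressed* when its maximum FPKM over all samples exceeds a
floor (default 0.5).  Differential expression between two groups is
called by a Welch two-sample t-test on log2(FPKM + pseudocount) with
Benjamini-Hochberg correction across tested genes; a gene is "up" when
log2(mean_B/mean_A) >= fc_min and q < q_max (symmetric for "down").
The test statistic is a documented reconstruction: the thresholds
(|log2FC| >= 1.5, FDR < 0.05) are the scientific contract, the Welch t
on logs is the package's declared choice for a 3-vs-3 FPKM design.

qPCR relative expression uses the standard 2^-ddCt quantification
against a reference gene and a control group; the control group's
geometric-mean relative expression is 1 by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


def check_matrix(matrix: pd.DataFrame, groups: Mapping[str, str]) -> None:
    """Validate an FPKM matrix (genes x samples) and its sample->group map."""
    if (matrix.values < 0).any():
        raise ValueError("FPKM matrix must be nonnegative")
    missing = [s for s in matrix.columns if s not in groups]
    if missing:
        raise ValueError(f"samples without group assignment: {missing}")


def expressed_filter(matrix: pd.DataFrame, min_fpkm: float = 0.5) -> list[str]:
    """Genes whose maximum FPKM across all samples exceeds ``min_fpkm``."""
    mask = matrix.max(axis=1) > min_fpkm
    return list(matrix.index[mask])


def row_scale(matrix: pd.DataFrame) -> pd.DataFrame:
    """Z-score each row (sample sd, ddof=1); constant rows map to zeros."""
    if matrix.shape[1] < 2:
        raise ValueError("row scaling requires at least 2 samples")
    mean = matrix.mean(axis=1)
    sd = matrix.std(axis=1, ddof=1)
    zero = sd == 0
    if zero.any():
        logger.info("%d constant rows mapped to all zeros", int(zero.sum()))
    sd = sd.replace(0, np.nan)
    out = matrix.sub(mean, axis=0).div(sd, axis=0)
    return out.fillna(0.0)


@dataclass
class DegRecord:
    gene: str
    log2fc: float
    p_value: float
    fdr_q: float
    status: str  # up | down | ns


def call_degs(
    matrix: pd.DataFrame,
    groups: Mapping[str, str],
    group_a: str,
    group_b: str,
    fc_min: float = 1.5,
    q_max: float = 0.05,
    pseudocount: float = 1.0,
) -> list[DegRecord]:
    """Welch-t + BH differential expression of group_b vs group_a.

    log2fc is log2((mean_B + pc) / (mean_A + pc)) on raw FPKM group
    means; the test runs on log2(FPKM + pc) per replicate.  Genes with
    zero variance in both groups get p = 1 when the means are equal
    (p = 0 otherwise, the difference being then noiseless).
    """
    check_matrix(matrix, groups)
    cols_a = [s for s in matrix.columns if groups[s] == group_a]
    cols_b = [s for s in matrix.columns if groups[s] == group_b]
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError("need >= 2 replicates per group")
    raw_a, raw_b = matrix[cols_a].values, matrix[cols_b].values
    log2fc = np.log2((raw_b.mean(axis=1) + pseudocount) / (raw_a.mean(axis=1) + pseudocount))
    la, lb = np.log2(raw_a + pseudocount), np.log2(raw_b + pseudocount)
    import warnings

    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        # near-constant rows trip scipy's catastrophic-cancellation warning
        warnings.simplefilter("ignore", RuntimeWarning)
        _, p = stats.ttest_ind(lb, la, axis=1, equal_var=False)
    p = np.asarray(p, dtype=float)
    degenerate = np.isnan(p)
    if degenerate.any():
        equal_means = np.isclose(lb.mean(axis=1), la.mean(axis=1))
        p[degenerate & equal_means] = 1.0
        p[degenerate & ~equal_means] = 0.0
    _, q, _, _ = multipletests(p, method="fdr_bh")
    records = []
    for gene, fc, pv, qv in zip(matrix.index, log2fc, p, q):
        if fc >= fc_min and qv < q_max:
            status = "up"
        elif fc <= -fc_min and qv < q_max:
            status = "down"
        else:
            status = "ns"
        records.append(DegRecord(gene=gene, log2fc=float(fc), p_value=float(pv),
                                 fdr_q=float(qv), status=status))
    return records


def degs_to_frame(records: Sequence[DegRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene": [r.gene for r in records],
            "log2fc": [r.log2fc for r in records],
            "p_value": [r.p_value for r in records],
            "fdr_q": [r.fdr_q for r in records],
            "status": [r.status for r in records],
        }
    ).set_index("gene")


def relative_expression(
    ct_table: pd.DataFrame,
    control_group: str,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """2^-ddCt relative expression per sample, plus group summaries.

    ``ct_table`` needs columns gene, sample, group, ct_target, ct_ref.
    dCt = Ct_target - Ct_ref; ddCt = dCt - mean dCt of the control
    group (per gene); relative expression = 2^-ddCt, so the control
    group's geometric mean is 1 by construction.  Samples missing a
    reference Ct are dropped with a warning.  The summary reports group
    mean +/- sd and a Welch t-test of each group against control.
    """
    required = {"gene", "sample", "group", "ct_target", "ct_ref"}
    if not required <= set(ct_table.columns):
        raise ValueError(f"ct_table must have columns {sorted(required)}")
    table = ct_table.copy()
    missing = table["ct_ref"].isna() | table["ct_target"].isna()
    if missing.any():
        logger.warning("%d samples dropped for missing Ct values", int(missing.sum()))
        table = table[~missing]
    if (table[["ct_target", "ct_ref"]] <= 0).any().any():
        raise ValueError("Ct values must be positive")
    table["dct"] = table["ct_target"] - table["ct_ref"]
    rows = []
    for gene, sub in table.groupby("gene", sort=False):
        control = sub.loc[sub["group"] == control_group, "dct"]
        if control.empty:
            raise ValueError(f"gene {gene}: no control-group samples")
        base = control.mean()
        ddct = sub["dct"] - base
        rel = 2.0 ** (-ddct)
        for (_, r), value in zip(sub.iterrows(), rel):
            rows.append(
                {"gene": gene, "sample": r["sample"], "group": r["group"],
                 "rel_expr": float(value)}
            )
    per_sample = pd.DataFrame(rows)
    summaries = []
    for (gene, group), sub in per_sample.groupby(["gene", "group"], sort=False):
        control_vals = per_sample.query("gene == @gene and group == @control_group")["rel_expr"]
        if group == control_group or len(sub) < 2 or len(control_vals) < 2:
            pval = np.nan
        else:
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                pval = float(
                    stats.ttest_ind(sub["rel_expr"], control_vals, equal_var=False).pvalue
                )
        summaries.append(
            {"gene": gene, "group": group,
             "mean_rel_expr": float(sub["rel_expr"].mean()),
             "sd_rel_expr": float(sub["rel_expr"].std(ddof=1)) if len(sub) > 1 else np.nan,
             "p_vs_control": pval}
        )
    return per_sample, pd.DataFrame(summaries)
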