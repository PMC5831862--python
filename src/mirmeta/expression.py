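"""qPCR relative expression via the comparative Ct (2^-ddCt) method.

Ct tables are tidy frames with columns ``mirna, stage, replicate, ct``; the
reference gene (U6 by default) must appear for every stage/replicate.  Delta
Ct pairs target and reference replicate-wise; delta-delta Ct subtracts the
mean delta Ct of the reference stage.  Stage comparisons use Student's t on
delta-Ct values (log scale), unpaired by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

REFERENCE_GENE = "U6"


@dataclass(frozen=True)
class ExpressionParams:
    reference_gene: str = REFERENCE_GENE
    alpha: float = 0.01
    paired: bool = False
    bh_adjust: bool = False


def read_ct_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"mirna", "stage", "replicate", "ct"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    if (df["ct"] <= 0).any() or not np.isfinite(df["ct"]).all():
        raise ValueError("Ct values must be finite and positive")
    return df


def ddct(
    ct: pd.DataFrame,
    reference_stage,
    params: ExpressionParams | None = None,
) -> pd.DataFrame:
    """Per-replicate delta Ct, delta-delta Ct and relative expression.

    Returns a tidy frame (mirna, stage, replicate, dct, ddct, rel_expr).  The
    relative expression of the reference stage equals 1 on replicate means by
    construction.
    """
    params = params or ExpressionParams()
    ref_gene = params.reference_gene
    stages = list(dict.fromkeys(ct["stage"]))
    if reference_stage not in stages:
        raise ValueError(f"reference stage {reference_stage!r} not in table")
    u6 = ct[ct["mirna"] == ref_gene].set_index(["stage", "replicate"])["ct"]
    if u6.empty:
        raise ValueError(f"missing reference gene {ref_gene!r} rows")

    rows = []
    for (mirna, stage), grp in ct[ct["mirna"] != ref_gene].groupby(
        ["mirna", "stage"], sort=False
    ):
        for _, rec in grp.iterrows():
            key = (stage, rec["replicate"])
            if key not in u6.index:
                raise ValueError(
                    f"missing {ref_gene} Ct for stage={stage} replicate={rec['replicate']}"
                )
            rows.append(
                {
                    "mirna": mirna,
                    "stage": stage,
                    "replicate": rec["replicate"],
                    "dct": rec["ct"] - u6.loc[key],
                }
            )
    out = pd.DataFrame(rows)
    ref_means = (
        out[out["stage"] == reference_stage].groupby("mirna")["dct"].mean()
    )
    missing_ref = set(out["mirna"]) - set(ref_means.index)
    if missing_ref:
        raise ValueError(f"no reference-stage rows for: {sorted(missing_ref)}")
    out["ddct"] = out["dct"] - out["mirna"].map(ref_means)
    out["rel_expr"] = 2.0 ** (-out["ddct"])
    return out


def summarize(results: pd.DataFrame) -> pd.DataFrame:
    """Mean and SD of relative expression per (mirna, stage)."""
    g = results.groupby(["mirna", "stage"], sort=False)["rel_expr"]
    return g.agg(mean="mean", sd="std").reset_index()


def stage_test(
    results: pd.DataFrame,
    test_stage,
    baseline_stages: Sequence,
    params: ExpressionParams | None = None,
) -> pd.DataFrame:
    """Two-sided Student's t on delta-Ct replicates, test stage vs each
    baseline stage.

    A miRNA is flagged significant when the largest p across the baseline
    comparisons is below alpha; direction comes from the sign of the mean
    relative-expression change and must agree across baselines.
    """
    params = params or ExpressionParams()
    rows = []
    for mirna, grp in results.groupby("mirna", sort=False):
        test_dct = grp.loc[grp["stage"] == test_stage, "dct"].to_numpy()
        pvals, directions = [], []
        for base in baseline_stages:
            base_dct = grp.loc[grp["stage"] == base, "dct"].to_numpy()
            if len(test_dct) < 2 or len(base_dct) < 2:
                raise ValueError(f"{mirna}: need >=2 replicates per stage")
            if (
                np.allclose(test_dct.std(), 0)
                and np.allclose(base_dct.std(), 0)
                and np.isclose(test_dct.mean(), base_dct.mean())
            ):
                p = 1.0
            elif params.paired:
                p = stats.ttest_rel(test_dct, base_dct).pvalue
            else:
                p = stats.ttest_ind(test_dct, base_dct).pvalue
            pvals.append(float(p) if np.isfinite(p) else 1.0)
            # lower dCt = higher expression
            directions.append(np.sign(base_dct.mean() - test_dct.mean()))
        worst_p = max(pvals)
        consistent = len(set(directions)) == 1 and directions[0] != 0
        significant = worst_p < params.alpha and consistent
        rows.append(
            {
                "mirna": mirna,
                "p_value": worst_p,
                "significant": significant,
                "direction": (
                    {1.0: "up", -1.0: "down"}[directions[0]]
                    if significant
                    else "unchanged"
                ),
                **{
                    f"p_vs_{base}": p
                    for base, p in zip(baseline_stages, pvals)
                },
            }
        )
    table = pd.DataFrame(rows)
    if params.bh_adjust and len(table):
        table["q_value"] = bh_adjust(table["p_value"].to_numpy())
    return table


def bh_adjust(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvals, dtype=float)
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


def stage_profile_matrix(
    results: pd.DataFrame, stage_order: Sequence
) -> pd.DataFrame:
    """miRNA x stage matrix of mean relative expression, fixed stage order."""
    missing = set(stage_order) - set(results["stage"])
    if missing:
        raise ValueError(f"stages absent from results: {sorted(missing)}")
    summary = summarize(results)
    mat = summary.pivot(index="mirna", columns="stage", values="mean")
    return mat.reindex(columns=list(stage_order))


def stage_profile_vector(
    results: pd.DataFrame, mirna: str, stage_order: Sequence
) -> np.ndarray:
    """Ordered mean relative-expression vector across stages for one miRNA."""
    if len(stage_order) < 2:
        raise ValueError("need at least two stages for a profile")
    mat = stage_profile_matrix(results[results["mirna"] == mirna], stage_order)
    if mirna not in mat.index:
        raise ValueError(f"no results for miRNA {mirna!r}")
    vec = mat.loc[mirna].to_numpy(dtype=float)
    if np.isnan(vec).any():
        raise ValueError(f"{mirna}: missing stages in profile")
    return vec


def cluster_heatmap_matrix(
    results: pd.DataFrame, stage_order: Sequence
) -> tuple[pd.DataFrame, np.ndarray]:
    """Row-ordered log2 relative-expression matrix and its linkage.

    Rows are hierarchically clustered with correlation distance (1 - Pearson)
    and average linkage; output row order follows the dendrogram leaves so the
    result is deterministic for a given input.
    """
    mat = stage_profile_matrix(results, stage_order)
    if len(mat) < 2:
        raise ValueError("need at least two miRNAs to cluster")
    log = np.log2(mat.to_numpy(dtype=float))
    centered = log - log.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    safe = np.where(norms == 0, 1.0, norms)
    unit = centered / safe[:, None]
    corr = unit @ unit.T
    dist = np.clip(1.0 - corr, 0.0, 2.0)
    np.fill_diagonal(dist, 0.0)
    linkage = hierarchy.average(squareform(dist, checks=False))
    order = hierarchy.leaves_list(linkage)
    ordered = pd.DataFrame(
        log[order], index=mat.index[order], columns=mat.columns
    )
    return ordered, linkage
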