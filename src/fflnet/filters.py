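"""Evidence filters that turn raw tables into catalog edges and gene lists.

Three screens feed the motif search:

* a two-group differential-expression screen (fold change > 2 and
  Benjamini–Hochberg FDR < 0.01 by default) that yields the candidate genes
  of a stage transition;
* a z-score cutoff (default 2.33, one-sided normal p < 0.01) on scored
  transcription-factor binding-site predictions, yielding predicted TF→gene
  edges;
* the miRNA-target merge rule: experimentally verified miRNA targets pass
  unconditionally, while expression-supported targets must additionally be
  predicted by both sequence-based tools (TargetScan and miRanda by
  convention).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .catalog import ExpressionMatrix

DEFAULT_TOOLS = ("TargetScan", "miRanda")


@dataclass(frozen=True)
class DEResult:
    """Per-gene differential-expression screen outcome.

    ``log2_fold_change`` is mean(log2 group B) − mean(log2 group A) with
    groups in sorted label order; ``passes`` applies the strict criteria
    |FC| > fc_threshold and FDR < fdr_threshold.
    """

    gene: str
    log2_fold_change: float
    p_value: float
    fdr: float
    passes: bool


def welch_p_values(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise Welch two-sample t-test p-values on log2 intensities.

    Degenerate rows (zero variance in both groups) get p = 1 when the group
    means are equal and p = 0 otherwise.
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(a, b, axis=1, equal_var=False)
    p = np.asarray(res.pvalue, dtype=float)
    degenerate = np.isnan(p)
    if degenerate.any():
        equal_means = np.isclose(a.mean(axis=1), b.mean(axis=1))
        p[degenerate & equal_means] = 1.0
        p[degenerate & ~equal_means] = 0.0
    return p


def filter_de_genes(expr: ExpressionMatrix,
                    fc_threshold: float = 2.0,
                    fdr_threshold: float = 0.01) -> list[DEResult]:
    """Screen genes for differential expression between the two groups.

    Welch's t-test per gene on the log2 values, Benjamini–Hochberg correction
    across all genes, fold change as 2^(mean log2 difference). Results are
    returned in input gene order.
    """
    if fc_threshold <= 0 or fdr_threshold <= 0:
        raise ValueError("thresholds must be positive")
    group_a, group_b = expr.groups
    a = expr.group_columns(group_a).to_numpy(dtype=float)
    b = expr.group_columns(group_b).to_numpy(dtype=float)
    log2fc = b.mean(axis=1) - a.mean(axis=1)
    p = welch_p_values(a, b)
    fdr = multipletests(p, method="fdr_bh")[1]
    log2_cut = math.log2(fc_threshold)
    return [
        DEResult(
            gene=str(g),
            log2_fold_change=float(fc),
            p_value=float(pv),
            fdr=float(q),
            passes=bool(abs(fc) > log2_cut and q < fdr_threshold),
        )
        for g, fc, pv, q in zip(expr.values.index, log2fc, p, fdr)
    ]


def de_results_frame(results: Iterable[DEResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.gene, r.log2_fold_change, r.p_value, r.fdr, r.passes)
         for r in results],
        columns=["gene", "log2_fold_change", "p_value", "fdr", "passes"],
    )


def filter_tfbs(scored: pd.DataFrame, z_cut: float = 2.33,
                ) -> set[tuple[str, str]]:
    """Keep TF→gene binding-site predictions with z ≥ z_cut (inclusive).

    ``scored`` has columns (tf, gene, z). Non-finite z records are rejected
    with a warning. Returns the surviving (tf, gene) pairs, one per pair,
    to be catalogued with evidence ``predicted``.
    """
    z = pd.to_numeric(scored["z"], errors="coerce").to_numpy(dtype=float)
    bad = ~np.isfinite(z)
    if bad.any():
        warnings.warn(f"rejecting {int(bad.sum())} TFBS records with "
                      "non-finite z-scores")
    keep = np.zeros(len(z), dtype=bool)
    keep[~bad] = z[~bad] >= z_cut
    return {
        (str(tf), str(gene))
        for tf, gene in zip(scored.loc[keep, "tf"], scored.loc[keep, "gene"])
    }


def merge_mirna_targets(
    verified: Iterable[tuple[str, str]],
    expression_supported: Iterable[tuple[str, str]],
    predictions_by_tool: Mapping[str, Iterable[tuple[str, str]]],
    required_tools: tuple[str, str] = DEFAULT_TOOLS,
) -> dict[tuple[str, str], str]:
    """Merge verified and expression-supported miRNA targets.

    Verified (miRNA, target) edges pass unconditionally with evidence
    ``verified``. Expression-supported edges — target calls backed only by
    anti-correlated expression — are kept with evidence ``predicted`` only
    when both required prediction tools also call them.
    """
    verified = set(verified)
    expression_supported = set(expression_supported)
    if expression_supported:
        missing = [t for t in required_tools if t not in predictions_by_tool]
        if missing:
            raise ValueError(
                f"expression-supported targets present but prediction sets "
                f"missing for: {missing}"
            )
    merged: dict[tuple[str, str], str] = {}
    if expression_supported:
        tool_sets = [set(predictions_by_tool[t]) for t in required_tools]
        for edge in expression_supported:
            if all(edge in s for s in tool_sets):
                merged[edge] = "predicted"
    for edge in verified:
        merged[edge] = "verified"
    return merged
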