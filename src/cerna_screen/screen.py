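"""Expression anti-correlation screen and cohort replication.

Candidate sponge pairs are the consensus-predicted (lncRNA transcript,
miRNA) pairs; the screen correlates their expression across the
discovery cohort's samples, BH-adjusts the two-sided p-values over all
tested pairs, and keeps significantly negative correlations
(q < 0.05 by default).  Replication re-computes the correlations in an
independent cohort and flags pairs at raw p < 0.05 with a negative
coefficient — raw because the replication tests only the handful of
already-screened candidates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .targets import bh_adjust

logger = logging.getLogger(__name__)

__all__ = [
    "ScreenConfig",
    "pair_correlation",
    "screen_pairs",
    "flag_replicated",
    "replicate_pairs",
    "wilcoxon_rank_sum",
]


@dataclass(frozen=True)
class ScreenConfig:
    method: str = "pearson"  # or "spearman"
    q_threshold: float = 0.05
    replication_p_threshold: float = 0.05
    require_negative: bool = True

    def __post_init__(self):
        if self.method not in ("pearson", "spearman"):
            raise ValueError("method must be 'pearson' or 'spearman'")
        for v in (self.q_threshold, self.replication_p_threshold):
            if not 0 < v < 1:
                raise ValueError("thresholds must be in (0, 1)")


def _gene_of(transcript_id: str) -> str:
    """Transcript ids are '<gene>:<ordinal>'; bare ids are their own gene."""
    return transcript_id.rsplit(":", 1)[0]


def _corr(x: np.ndarray, y: np.ndarray, method: str) -> tuple[float, float]:
    if method == "pearson":
        res = stats.pearsonr(x, y)
    else:
        res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def pair_correlation(lnc_expr: pd.DataFrame, mirna_expr: pd.DataFrame,
                     pairs: pd.DataFrame,
                     cfg: ScreenConfig = ScreenConfig()) -> pd.DataFrame:
    """Per-pair correlation over the shared samples of two matrices.

    ``pairs`` needs columns ``mirna_id`` and ``transcript_id``; lncRNA
    expression is looked up at gene level (the part of the transcript id
    before the last ':'), falling back to the transcript id itself.
    Zero-variance features are flagged (status ``zero_variance``) and
    skipped; missing features get status ``missing``.
    """
    shared = [c for c in lnc_expr.columns if c in set(mirna_expr.columns)]
    if len(shared) < 3:
        raise ValueError(
            f"need at least 3 shared samples, found {len(shared)}")
    ln = lnc_expr[shared]
    mi = mirna_expr[shared]
    rows = []
    for row in pairs.itertuples():
        tid, mid = row.transcript_id, row.mirna_id
        gene = _gene_of(tid)
        key = gene if gene in ln.index else tid
        rec = {"mirna_id": mid, "transcript_id": tid, "lncrna_gene": gene,
               "corr_coeff": np.nan, "p_value": np.nan, "status": "ok"}
        if key not in ln.index or mid not in mi.index:
            rec["status"] = "missing"
            logger.warning("pair (%s, %s): feature missing from expression",
                           mid, tid)
        else:
            x = ln.loc[key].to_numpy(dtype=float)
            y = mi.loc[mid].to_numpy(dtype=float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                rec["status"] = "zero_variance"
            else:
                rec["corr_coeff"], rec["p_value"] = _corr(x, y, cfg.method)
        rows.append(rec)
    return pd.DataFrame(rows, columns=[
        "mirna_id", "transcript_id", "lncrna_gene", "corr_coeff", "p_value",
        "status"])


def screen_pairs(correlations: pd.DataFrame,
                 cfg: ScreenConfig = ScreenConfig()) -> pd.DataFrame:
    """BH-adjust the tested pairs and keep significant anti-correlations.

    Input rows need ``corr_coeff`` and ``p_value``; rows whose p is
    missing (skipped pairs) are excluded from the BH universe.  Retained
    rows satisfy ``q < q_threshold`` and, unless ``require_negative`` is
    off, ``corr_coeff < 0``; output is sorted by q then coefficient.
    """
    tested = correlations[correlations["p_value"].notna()].copy()
    if tested.empty:
        return tested.assign(q_value=pd.Series(dtype=float))
    tested["q_value"] = bh_adjust(tested["p_value"])
    keep = tested["q_value"] < cfg.q_threshold
    if cfg.require_negative:
        keep &= tested["corr_coeff"] < 0
    out = tested[keep].sort_values(["q_value", "corr_coeff"], kind="mergesort")
    return out.reset_index(drop=True)


def flag_replicated(table: pd.DataFrame,
                    cfg: ScreenConfig = ScreenConfig()) -> pd.DataFrame:
    """Apply the replication rule to a (corr_coeff, p_value) table:
    replicated iff coefficient < 0 and raw p below the threshold."""
    out = table.copy()
    ok = out["p_value"].notna()
    out["replicated"] = (
        ok & (out["corr_coeff"] < 0)
        & (out["p_value"] < cfg.replication_p_threshold))
    return out


def replicate_pairs(candidates: pd.DataFrame, lnc_expr2: pd.DataFrame,
                    mirna_expr2: pd.DataFrame,
                    cfg: ScreenConfig = ScreenConfig()) -> pd.DataFrame:
    """Re-correlate screened candidates in a second cohort.

    Candidates missing from the second cohort are reported with status
    ``missing`` rather than dropped; no multiplicity correction is
    applied to the replication p-values.
    """
    table = pair_correlation(lnc_expr2, mirna_expr2,
                             candidates[["mirna_id", "transcript_id"]], cfg)
    return flag_replicated(table, cfg)


def wilcoxon_rank_sum(values_g1: Sequence[float],
                      values_g2: Sequence[float]) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact p for groups of at most 10 without ties; otherwise the normal
    approximation with tie correction.  Returns (U statistic, p).
    Completely tied data yields p = 1.
    """
    x = np.asarray(values_g1, dtype=float)
    y = np.asarray(values_g2, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups need at least one value")
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        return float(len(x) * len(y) / 2.0), 1.0
    has_ties = len(np.unique(pooled)) < len(pooled)
    if len(x) <= 10 and len(y) <= 10 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=(method == "asymptotic"))
    return float(res.statistic), float(min(res.pvalue, 1.0))
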