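"""Selection of relevant lncRNAs and miRNAs.

Three filters reduce the detectable feature lists before target
prediction:

* SAM-style permutation differential expression between tumor and
  normal samples, thresholded at a 90th-percentile permutation FDR of
  zero (i.e. only features whose |d| is beyond the null in at least 90%
  of label permutations are called);
* a variational filter keeping the most variable features (top IQR
  quartile by default) regardless of group labels, to accommodate the
  heterogeneous genetic background of the disease;
* exclusion of lncRNAs on immunoglobulin-locus cytobands (14q32, 2p,
  22q by default), whose apparent expression reflects the polyclonal
  antibody repertoire rather than the lncRNA itself.

Differential and variable features are combined by union; the region
exclusion applies to lncRNAs only.

The SAM and variation filters are exposed both as scikit-learn
``SelectorMixin`` estimators operating on ``(n_samples, n_features)``
arrays (:class:`SamSelector`, :class:`VariationFilter`) and as
module-level functions operating on feature-by-sample data frames.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import iqr as _iqr, median_abs_deviation
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted, validate_data

logger = logging.getLogger(__name__)

__all__ = [
    "SelectionConfig",
    "SamSelector",
    "VariationFilter",
    "sam_statistic",
    "estimate_s0",
    "sam_select",
    "variation_filter",
    "exclude_regions",
    "select_relevant",
]

EXCLUDED_CYTOBANDS = ("14q32", "2p", "22q")


@dataclass(frozen=True)
class SelectionConfig:
    """Knobs of the selection funnel (defaults are the screen's)."""

    fdr_percentile: float = 90.0
    fdr_threshold: float = 0.0
    n_permutations: int = 1000
    variation_metric: str = "iqr"  # or "sd"
    variation_quantile: float = 0.75
    excluded_cytobands: tuple[str, ...] = EXCLUDED_CYTOBANDS
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.fdr_percentile <= 100:
            raise ValueError("fdr_percentile must be in (0, 100]")
        if not 0 <= self.fdr_threshold <= 1:
            raise ValueError("fdr_threshold must be in [0, 1]")
        if not 0 <= self.variation_quantile < 1:
            raise ValueError("variation_quantile must be in [0, 1)")
        if self.variation_metric not in ("iqr", "sd"):
            raise ValueError("variation_metric must be 'iqr' or 'sd'")


# ---------------------------------------------------------------------------
# SAM statistic
# ---------------------------------------------------------------------------

def _group_masks(labels: Sequence, ) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(labels)
    groups = pd.unique(labels)
    if len(groups) != 2:
        raise ValueError(f"expected exactly 2 groups, got {list(groups)}")
    return labels == groups[0], labels == groups[1]


def _sam_numerator_denominator(x: np.ndarray, mask1: np.ndarray,
                               mask2: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-feature mean difference (g2 - g1) and pooled standard error.

    ``x`` is (n_features, n_samples).  The pooled standard error is
    sqrt((1/n1 + 1/n2) * pooled variance), the denominator of the
    classical equal-variance two-sample t statistic.
    """
    n1, n2 = int(mask1.sum()), int(mask2.sum())
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 samples")
    x1, x2 = x[:, mask1], x[:, mask2]
    r = x2.mean(axis=1) - x1.mean(axis=1)
    ss = ((x1 - x1.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) \
        + ((x2 - x2.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    s = np.sqrt((1.0 / n1 + 1.0 / n2) * ss / (n1 + n2 - 2))
    return r, s


def sam_statistic(expr: pd.DataFrame, labels: Sequence, s0: float) -> pd.Series:
    """SAM d statistic per feature: d = (mean2 - mean1) / (s + s0).

    ``expr`` is features x samples; with ``s0 = 0`` this is the pooled
    two-sample t statistic.
    """
    mask1, mask2 = _group_masks(labels)
    r, s = _sam_numerator_denominator(expr.to_numpy(dtype=float), mask1, mask2)
    return pd.Series(r / (s + s0), index=expr.index, name="d")


def estimate_s0(r: np.ndarray, s: np.ndarray) -> float:
    """Exchangeability factor s0 chosen on a grid of percentiles of s.

    Tusher-style: for each candidate s0 (the 0th, 5th, ..., 100th
    percentile of s, plus 0 itself) compute d = r / (s + s0), bin
    features into s-quantile windows, and take the coefficient of
    variation of the windows' median absolute deviations of d; the
    candidate minimizing that CV wins.  All-equal s returns 0.
    """
    r = np.asarray(r, dtype=float)
    s = np.asarray(s, dtype=float)
    if len(r) < 10:
        raise ValueError("s0 estimation needs at least 10 features")
    if np.allclose(s, s[0]):
        return 0.0
    n_bins = min(100, max(2, len(s) // 5))
    edges = np.quantile(s, np.linspace(0, 1, n_bins + 1))
    bins = np.clip(np.searchsorted(edges, s, side="right") - 1, 0, n_bins - 1)
    candidates = [0.0] + [float(np.percentile(s, a)) for a in range(0, 101, 5)]
    best_s0, best_cv = 0.0, math.inf
    for s0 in candidates:
        d = r / (s + s0)
        mads = []
        for b in range(n_bins):
            sel = bins == b
            if sel.sum() >= 2:
                mads.append(median_abs_deviation(d[sel], scale="normal"))
        mads = np.asarray(mads)
        if len(mads) < 2 or np.mean(mads) == 0:
            continue
        cv = np.std(mads) / np.mean(mads)
        if cv < best_cv - 1e-12:
            best_cv, best_s0 = cv, s0
    return best_s0


def _enumerate_or_sample_masks(labels: np.ndarray, n_permutations: int,
                               rng: np.random.Generator) -> list[np.ndarray]:
    """Distinct two-group assignments: full enumeration when there are
    no more than ``n_permutations`` of them, else random label shuffles."""
    mask1, _ = _group_masks(labels)
    n, n1 = len(labels), int(mask1.sum())
    total = math.comb(n, n1)
    if total == 0:
        raise ValueError("no label permutations possible")
    if total <= n_permutations:
        return [np.isin(np.arange(n), idx)
                for idx in combinations(range(n), n1)]
    masks = []
    base = np.zeros(n, dtype=bool)
    base[:n1] = True
    for _ in range(n_permutations):
        masks.append(rng.permutation(base))
    return masks


def _exceedance_q(abs_d: np.ndarray, null_abs_d: list[np.ndarray],
                  percentile: float) -> tuple[np.ndarray, np.ndarray]:
    """Permutation FDR-like q per feature at cutoff |d_i|.

    For each feature, O = observed #{|d| >= |d_i|} and N_b = the same
    count in permutation b; q = percentile_b(N_b) / O capped at 1, then
    made monotone non-increasing in |d| (a feature's q is the minimal
    FDR over all cutoffs at or below its own |d|).  Returns the
    percentile-based q and the median-based q.
    """
    order = np.argsort(abs_d, kind="mergesort")
    sorted_d = abs_d[order]
    m = len(abs_d)
    obs = m - np.searchsorted(sorted_d, abs_d, side="left")
    counts = np.empty((len(null_abs_d), m))
    for b, nd in enumerate(null_abs_d):
        snd = np.sort(nd)
        counts[b] = len(snd) - np.searchsorted(snd, abs_d, side="left")
    q_pct = np.minimum(np.percentile(counts, percentile, axis=0) / obs, 1.0)
    q_med = np.minimum(np.median(counts, axis=0) / obs, 1.0)

    def monotone(q):
        qm = q.copy()
        # ascending |d|: running min makes q non-increasing in |d|
        run = math.inf
        out = np.empty_like(qm)
        for pos in order:
            run = min(run, qm[pos])
            out[pos] = run
        return out

    return monotone(q_pct), monotone(q_med)


def sam_select(expr: pd.DataFrame, labels: Sequence,
               cfg: SelectionConfig = SelectionConfig(),
               s0: float | None = None) -> tuple[list, pd.DataFrame]:
    """SAM permutation selection on a features x samples frame.

    Builds the null from all distinct label assignments when fewer than
    ``cfg.n_permutations`` exist, otherwise from that many random
    shuffles.  A feature is selected iff its q computed from the
    ``cfg.fdr_percentile``-th percentile of null exceedance counts is at
    or below ``cfg.fdr_threshold`` (default 0: the null must be entirely
    below the feature's |d| in at least 90% of permutations).

    Returns (selected feature ids, per-feature result table).
    """
    labels = np.asarray(labels)
    x = expr.to_numpy(dtype=float)
    mask1, mask2 = _group_masks(labels)
    r, s = _sam_numerator_denominator(x, mask1, mask2)
    if s0 is None:
        s0 = estimate_s0(r, s)
    d = r / (s + s0)
    rng = np.random.default_rng(cfg.seed)
    masks = _enumerate_or_sample_masks(labels, cfg.n_permutations, rng)
    null_abs = []
    for mk in masks:
        rb, sb = _sam_numerator_denominator(x, mk, ~mk)
        null_abs.append(np.abs(rb / (sb + s0)))
    q_pct, q_med = _exceedance_q(np.abs(d), null_abs, cfg.fdr_percentile)
    table = pd.DataFrame({
        "d": d, "r": r, "s": s, "s0": s0,
        "q": q_pct, "q_median": q_med,
        "selected": q_pct <= cfg.fdr_threshold,
    }, index=expr.index)
    selected = list(table.index[table["selected"]])
    return selected, table


# ---------------------------------------------------------------------------
# Variation filter and region exclusion
# ---------------------------------------------------------------------------

def _variation(x: np.ndarray, metric: str) -> np.ndarray:
    if metric == "iqr":
        return _iqr(x, axis=1)
    return x.std(axis=1, ddof=1)


def variation_filter(expr: pd.DataFrame,
                     cfg: SelectionConfig = SelectionConfig()) -> list:
    """Keep features whose spread metric reaches the across-feature
    ``variation_quantile`` (linear interpolation); default: IQR in the
    top quartile."""
    v = _variation(expr.to_numpy(dtype=float), cfg.variation_metric)
    thr = np.quantile(v, cfg.variation_quantile)
    return list(expr.index[v >= thr])


def exclude_regions(features: Iterable, cytobands: Mapping[str, str],
                    cfg: SelectionConfig = SelectionConfig()) -> list:
    """Drop features whose cytoband starts with an excluded prefix.

    Prefix matching lets band labels of mixed resolution match
    ("14q32.33" is excluded by "14q32").  Features without a cytoband
    pass through with a warning.
    """
    kept = []
    for f in features:
        band = cytobands.get(f)
        if band is None:
            logger.warning("feature %s has no cytoband; passed through", f)
            kept.append(f)
        elif not any(band.startswith(p) for p in cfg.excluded_cytobands):
            kept.append(f)
    return kept


def select_relevant(expr_lnc: pd.DataFrame, expr_mirna: pd.DataFrame,
                    labels: Sequence, cytobands: Mapping[str, str],
                    cfg: SelectionConfig = SelectionConfig(),
                    ) -> tuple[list, list, dict]:
    """Full funnel: (SAM ∪ variation filter), then Ig-region exclusion
    on the lncRNA side only.  ``labels`` must align with the shared
    sample columns.  Returns (lncRNA ids, miRNA ids, funnel report)."""
    if list(expr_lnc.columns) != list(expr_mirna.columns):
        shared = [c for c in expr_lnc.columns if c in set(expr_mirna.columns)]
        if not shared:
            raise ValueError("expression matrices share no samples")
        expr_lnc = expr_lnc[shared]
        expr_mirna = expr_mirna[shared]
    report: dict = {}
    out = {}
    for name, expr in (("lncrna", expr_lnc), ("mirna", expr_mirna)):
        de, table = sam_select(expr, labels, cfg)
        var = variation_filter(expr, cfg)
        union = [f for f in expr.index if f in set(de) | set(var)]
        report[name] = {
            "input": len(expr), "de": len(de), "variable": len(var),
            "union": len(union),
        }
        out[name] = union
    lnc_final = exclude_regions(out["lncrna"], cytobands, cfg)
    report["lncrna"]["after_region_exclusion"] = len(lnc_final)
    if not lnc_final or not out["mirna"]:
        logger.warning("selection funnel produced an empty feature list")
    return lnc_final, out["mirna"], report


# ---------------------------------------------------------------------------
# scikit-learn estimators
# ---------------------------------------------------------------------------

class SamSelector(SelectorMixin, BaseEstimator):
    """Permutation-FDR feature selector with the SAM d statistic.

    Parameters follow :class:`SelectionConfig`; ``X`` is
    ``(n_samples, n_features)`` and ``y`` the two-group labels.

    Attributes
    ----------
    d_ : ndarray of shape (n_features,)
        Moderated statistic per feature.
    s0_ : float
        Estimated (or supplied) exchangeability factor.
    q_ : ndarray of shape (n_features,)
        Permutation FDR at the configured null-count percentile.
    """

    def __init__(self, s0="auto", n_permutations=1000, fdr_percentile=90.0,
                 fdr_threshold=0.0, random_state=0):
        self.s0 = s0
        self.n_permutations = n_permutations
        self.fdr_percentile = fdr_percentile
        self.fdr_threshold = fdr_threshold
        self.random_state = random_state

    def fit(self, X, y):
        X = validate_data(self, X)
        y = np.asarray(y)
        if len(y) != X.shape[0]:
            raise ValueError("X and y disagree on the number of samples")
        cfg = SelectionConfig(
            fdr_percentile=self.fdr_percentile,
            fdr_threshold=self.fdr_threshold,
            n_permutations=self.n_permutations,
            seed=self.random_state,
        )
        frame = pd.DataFrame(X.T)
        s0 = None if self.s0 == "auto" else float(self.s0)
        _, table = sam_select(frame, y, cfg, s0=s0)
        self.d_ = table["d"].to_numpy()
        self.s0_ = float(table["s0"].iloc[0])
        self.q_ = table["q"].to_numpy()
        self.q_median_ = table["q_median"].to_numpy()
        self.support_ = table["selected"].to_numpy()
        return self

    def _get_support_mask(self):
        check_is_fitted(self)
        return self.support_


class VariationFilter(SelectorMixin, BaseEstimator):
    """Keep features whose IQR (or SD) reaches an across-feature quantile."""

    def __init__(self, metric="iqr", quantile=0.75):
        self.metric = metric
        self.quantile = quantile

    def fit(self, X, y=None):
        X = validate_data(self, X)
        v = _variation(X.T, self.metric)
        self.variation_ = v
        self.threshold_ = float(np.quantile(v, self.quantile))
        self.support_ = v >= self.threshold_
        return self

    def _get_support_mask(self):
        check_is_fitted(self)
        return self.support_
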