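"""Classification evaluation of the hurdle zero part and subgroup reporting.

The zero part's fitted probability of any follow-up LBP code is a binary
classifier score; this module computes its ROC curve, the AUC (equal to the
Mann--Whitney concordance probability, ties counted 1/2), a DeLong 95%
confidence interval, the conventional discrimination bands, and the
seek-of-care subgroup table that cross-classifies subjects by LBP evidence
before/at baseline versus during follow-up (labels 0|0, 0|1, 1|0, 1|1).

No probability threshold is fixed anywhere: full curves are reported, and a
confusion matrix is only produced for a user-supplied cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve as _sk_roc_curve

__all__ = ["RocCurve", "roc_auc", "discrimination_band", "seek_of_care_strata",
           "DEFAULT_NRS_BANDS"]


@dataclass
class RocCurve:
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    ci_95: tuple[float, float]
    n_pos: int
    n_neg: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"threshold": self.thresholds,
                             "sensitivity": self.sensitivity,
                             "specificity": self.specificity})


def _delong_variance(pos_scores: np.ndarray, neg_scores: np.ndarray) -> float:
    """DeLong variance of the AUC via placement values."""
    m, n = len(pos_scores), len(neg_scores)
    # V10_i = P(neg < pos_i) + .5 P(neg = pos_i); V01_j symmetric
    order_neg = np.sort(neg_scores)
    lt = np.searchsorted(order_neg, pos_scores, side="left")
    le = np.searchsorted(order_neg, pos_scores, side="right")
    v10 = (lt + 0.5 * (le - lt)) / n
    order_pos = np.sort(pos_scores)
    lt = np.searchsorted(order_pos, neg_scores, side="left")
    le = np.searchsorted(order_pos, neg_scores, side="right")
    v01 = 1.0 - (lt + 0.5 * (le - lt)) / m
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return s10 / m + s01 / n


def roc_auc(p_positive, labels) -> RocCurve:
    """ROC curve with concordance AUC and DeLong 95% CI.

    The AUC equals the Mann--Whitney probability that a random positive
    outscores a random negative, with ties counted one half.
    """
    p = np.asarray(p_positive, float)
    z = np.asarray(labels, int)
    if len(p) != len(z):
        raise ValueError("scores and labels differ in length")
    pos, neg = p[z == 1], p[z == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both outcome classes must be present")
    order = np.sort(neg)
    lt = np.searchsorted(order, pos, side="left")
    le = np.searchsorted(order, pos, side="right")
    auc = float((lt + 0.5 * (le - lt)).sum() / (len(pos) * len(neg)))
    se = np.sqrt(_delong_variance(pos, neg))
    ci = (float(np.clip(auc - 1.96 * se, 0, 1)), float(np.clip(auc + 1.96 * se, 0, 1)))
    fpr, tpr, thr = _sk_roc_curve(z, p)
    return RocCurve(thresholds=thr, sensitivity=tpr, specificity=1 - fpr,
                    auc=auc, ci_95=ci, n_pos=int(len(pos)), n_neg=int(len(neg)))


def discrimination_band(auc: float) -> str:
    """Conventional AUC discrimination labels (lower edges inclusive)."""
    if not 0 <= auc <= 1:
        raise ValueError("AUC must lie in [0, 1]")
    if auc < 0.7:
        return "non_acceptable"
    if auc < 0.8:
        return "acceptable"
    if auc < 0.9:
        return "excellent"
    return "outstanding"


DEFAULT_NRS_BANDS = ((0, 0), (1, 3), (4, 6), (7, 10))


def _nrs_band_label(v, bands=DEFAULT_NRS_BANDS):
    if pd.isna(v):
        return "missing"
    for lo, hi in bands:
        if lo <= v <= hi:
            return f"{lo}" if lo == hi else f"{lo}-{hi}"
    return "missing"


def seek_of_care_strata(candidate_rows: pd.DataFrame, outcome_rows: pd.DataFrame,
                        predictions, nrs: pd.Series | None = None,
                        nrs_bands=DEFAULT_NRS_BANDS) -> pd.DataFrame:
    """Subject-level seek-of-care strata with predicted-probability summaries.

    Stratum ``pre|post``: *pre* = 1 if there is any LBP evidence before or
    at baseline (history window or any baseline-period code), *post* = 1 if
    any follow-up code occurred.  The four strata partition the cohort.
    Returns one row per subject (stratum, prediction, optional NRS band)
    plus a ``summary`` attribute-style aggregation via
    :func:`summarise_strata`.
    """
    cand = candidate_rows.set_index("subject_id") if "subject_id" in candidate_rows \
        else candidate_rows
    outc = outcome_rows.set_index("subject_id") if "subject_id" in outcome_rows \
        else outcome_rows
    orphans = cand.index.symmetric_difference(outc.index)
    if len(orphans):
        raise ValueError(f"subject keys mismatch; orphans: {list(orphans[:5])}"
                         f"{'...' if len(orphans) > 5 else ''}")
    p = np.asarray(predictions, float)
    if len(p) != len(cand):
        raise ValueError("predictions length does not match subjects")

    pre = (cand["history_lbp"].astype(bool)
           | cand["any_baseline_lbp"].astype(bool)).to_numpy()
    post = (outc.loc[cand.index, "y"].to_numpy() > 0)
    label = np.char.add(np.char.add(pre.astype(int).astype(str), "|"),
                        post.astype(int).astype(str))
    out = pd.DataFrame({"subject_id": cand.index, "stratum": label,
                        "p_predicted": p})
    if nrs is not None:
        aligned = nrs.set_axis(cand.index) if len(nrs) == len(cand) else nrs
        out["nrs_band"] = [(_nrs_band_label(v, nrs_bands)) for v in aligned]
    return out


def summarise_strata(strata: pd.DataFrame, by=("stratum",)) -> pd.DataFrame:
    """Tidy per-stratum summary of predicted probabilities."""
    g = strata.groupby(list(by))["p_predicted"]
    return g.agg(n="size", mean_p="mean", median_p="median",
                 q25=lambda s: s.quantile(0.25),
                 q75=lambda s: s.quantile(0.75)).reset_index()
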