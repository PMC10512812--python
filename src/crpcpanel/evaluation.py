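"""Panel-performance evaluation: ROC/AUC, time correlation, median splits.

These are the numbers a prognostic panel is judged on: how well its
score separates clinical contrasts (normal vs tumor, recurrent vs
non-recurrent, hormone-treated recurrent vs non-recurrent), whether the
score correlates negatively with time to recurrence, and whether a
median split on either variable separates the other.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.stats
from sklearn.metrics import roc_auc_score, roc_curve

from .cohort import CohortStrata, stratify
from .datatypes import BulkCohort, GeneSet
from .signatures import compare_scores, panel_score_bulk

logger = logging.getLogger(__name__)


@dataclass
class ROCResult:
    auc: float
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray

    def points_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"fpr": self.fpr, "tpr": self.tpr})


def roc_auc(scores, labels) -> ROCResult:
    """Empirical ROC and AUC (higher score = positive class).

    The AUC equals the Mann–Whitney probability with midrank tie
    handling, i.e. the trapezoidal area under the empirical ROC curve.
    Both classes must be present.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if len(set(labels.tolist())) < 2:
        raise ValueError("both classes must be present for ROC analysis")
    fpr, tpr, thr = roc_curve(labels, scores)
    return ROCResult(float(roc_auc_score(labels, scores)), fpr, tpr, thr)


def score_time_correlation(scores, times) -> tuple[float, float]:
    """Pearson correlation between panel score and recurrence time.

    Two-sided p from the t transform with n-2 df. Pairs with a missing
    time are dropped; constant inputs yield (nan, nan) with a warning.
    """
    scores = np.asarray(scores, dtype=float)
    times = np.asarray(times, dtype=float)
    keep = ~(np.isnan(scores) | np.isnan(times))
    scores, times = scores[keep], times[keep]
    if len(scores) < 3:
        raise ValueError("need at least 3 complete (score, time) pairs")
    if scores.std() == 0 or times.std() == 0:
        logger.warning("constant input: correlation undefined, reported missing")
        return float("nan"), float("nan")
    r, p = scipy.stats.pearsonr(scores, times)
    return float(r), float(p)


@dataclass
class SplitComparison:
    """Welch comparison of one variable between median-split halves.

    ``split_variable`` "time": low = time <= median (short recurrence),
    high = time > median; the panel score is compared. "score": high =
    score >= median, low = score < median; recurrence time is compared.
    ``t`` is for mean(low) - mean(high).
    """

    split_variable: str
    threshold: float
    n_low: int
    n_high: int
    mean_low: float
    mean_high: float
    median_low: float
    median_high: float
    t: float
    p: float


def median_split_compare(split_values, compare_values, split_variable: str) -> SplitComparison:
    if split_variable not in ("time", "score"):
        raise ValueError("split_variable must be 'time' or 'score'")
    split_values = np.asarray(split_values, dtype=float)
    compare_values = np.asarray(compare_values, dtype=float)
    keep = ~(np.isnan(split_values) | np.isnan(compare_values))
    split_values, compare_values = split_values[keep], compare_values[keep]
    if len(split_values) < 4:
        raise ValueError("need at least 4 complete pairs for a median split")
    med = float(np.median(split_values))
    if split_variable == "time":
        low_mask = split_values <= med
    else:  # score split: the "high" group takes score >= median
        low_mask = split_values < med
    high_mask = ~low_mask
    if low_mask.sum() == 0 or high_mask.sum() == 0:
        raise ValueError("median split produced an empty group (heavy ties at the median)")
    low, high = compare_values[low_mask], compare_values[high_mask]
    if low.std(ddof=1) == 0 and high.std(ddof=1) == 0:
        t, p = 0.0, 1.0
    else:
        t, p = scipy.stats.ttest_ind(low, high, equal_var=False)
    return SplitComparison(
        split_variable, med, int(low_mask.sum()), int(high_mask.sum()),
        float(low.mean()), float(high.mean()),
        float(np.median(low)), float(np.median(high)),
        float(t), float(p),
    )


_CONTRASTS = (
    # (name, positive stratum, negative stratum) — positive class scores higher
    ("tumor_vs_normal", "tumor", "normal"),
    ("recurrent_vs_nonrecurrent", "recurrent", "non_recurrent"),
    ("HT_YES_vs_HT_NO", "HT_YES", "HT_NO"),
)


@dataclass
class PanelReport:
    """All panel-performance numbers from one evaluation run."""

    panel_name: str
    report: dict

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.report, indent=2, sort_keys=True) + "\n")

    def to_frame(self) -> pd.DataFrame:
        rows = []

        def _walk(prefix, obj):
            if isinstance(obj, dict):
                for k in sorted(obj):
                    _walk(f"{prefix}.{k}" if prefix else k, obj[k])
            else:
                rows.append({"metric": prefix, "value": obj})

        _walk("", self.report)
        return pd.DataFrame(rows)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def evaluate_panel(
    cohort: BulkCohort,
    panel: GeneSet,
    strata: CohortStrata | None = None,
) -> PanelReport:
    """Full panel evaluation against the cohort's clinical strata.

    Produces, in one deterministic report: Welch score comparisons and
    AUCs for the three clinical contrasts, the score–recurrence-time
    Pearson correlation and both median splits (split by time, split by
    score) within recurrent samples and within hormone-treated
    recurrent samples. Contrasts whose strata are empty (or too small)
    are reported as missing and the run continues.
    """
    if strata is None:
        strata = stratify(cohort)
    score = panel_score_bulk(cohort, panel)
    scores = score.scores
    report: dict = {
        "panel": panel.name,
        "n_genes_used": len(score.genes_used),
        "genes_missing": score.genes_missing,
        "strata_sizes": strata.sizes(),
        "contrasts": {},
        "time_analysis": {},
    }

    for name, pos, neg in _CONTRASTS:
        pos_ids, neg_ids = strata[pos], strata[neg]
        if len(pos_ids) < 2 or len(neg_ids) < 2:
            logger.warning("contrast %s missing (empty or too-small stratum)", name)
            report["contrasts"][name] = None
            continue
        cmp = compare_scores(scores, pos_ids, neg_ids)
        labels = [1] * len(pos_ids) + [0] * len(neg_ids)
        roc = roc_auc(scores.loc[pos_ids + neg_ids].to_numpy(), labels)
        report["contrasts"][name] = {
            "mean_positive": cmp.mean_a,
            "mean_negative": cmp.mean_b,
            "t": cmp.t,
            "p": cmp.p,
            "stars": cmp.stars,
            "auc": roc.auc,
        }

    times = cohort.phenotype["recurrence_time_days"]
    for block, ids in (("recurrent", strata["recurrent"]), ("HT_YES", strata["HT_YES"])):
        ids_t = [s for s in ids if pd.notna(times.loc[s])]
        if len(ids_t) < 4:
            logger.warning("time analysis for %s missing (n=%d with times)", block, len(ids_t))
            report["time_analysis"][block] = None
            continue
        s = scores.loc[ids_t].to_numpy()
        t = times.loc[ids_t].to_numpy(dtype=float)
        r, p = score_time_correlation(s, t)
        time_split = median_split_compare(t, s, "time")
        score_split = median_split_compare(s, t, "score")
        report["time_analysis"][block] = {
            "n": len(ids_t),
            "pearson_r": r,
            "pearson_p": p,
            "time_split": vars(time_split),
            "score_split": vars(score_split),
        }
    return PanelReport(panel.name, report)
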