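"""Evaluation statistics for HRD biomarkers.

The benchmark asks how well a scalar biomarker separates HR-deficient
(H1a*) from HR-proficient (H3) tumors.  This module provides the
evaluation protocol:

* ROC/AUC with an explicit score *direction* — f_deam is a negative
  predictor (``lower_predicts_positive``), HRDsum a positive one;
* DeLong's paired test for the difference of two correlated AUCs measured
  on the same samples;
* cutpoint optimization by exhaustive maximization of the balanced accuracy
  (= (sensitivity + specificity)/2) over midpoints of adjacent distinct
  scores, and confusion metrics at a fixed cutpoint;
* Spearman rank correlation (f_deam vs HRDsum, biomarkers vs TMB);
* per-channel differential analysis of the 96 normalized mutation-type
  frequencies between the two groups (two-sided Wilcoxon rank-sum,
  Benjamini-Hochberg FDR at 5%);
* Cohen's kappa for agreement between two binary HRD calls;
* the CG>TG content of mutational-signature probability vectors in the
  COSMIC 96-row layout (e.g. the clock-like signature SBS1 is dominated by
  CpG-site C>T mutations, which is why f_deam tracks its activity).

NA scores (f_deam of very-low-TMB tumors) are excluded pairwise from rank
statistics, with the exclusion count logged.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score
from statsmodels.stats.multitest import multipletests

from .catalog96 import (
    CHANNELS_96,
    CHANNEL_INDEX,
    CPG_CT_INDICES,
    MutationCatalog96,
    ValidationError,
)

logger = logging.getLogger("fdeam")

Direction = Literal["lower_predicts_positive", "higher_predicts_positive"]


def _as_binary_labels(labels: Sequence) -> np.ndarray:
    """Map labels to 0/1; accepts 'positive'/'negative', bools, or 0/1."""
    mapping = {"positive": 1, "negative": 0, True: 1, False: 0, 1: 1, 0: 0}
    try:
        y = np.array([mapping[l] for l in labels], dtype=int)
    except KeyError as exc:
        raise ValidationError(f"unrecognized label {exc.args[0]!r}") from exc
    return y


def _drop_na(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(scores, dtype=float)
    y = _as_binary_labels(labels)
    if s.shape != y.shape:
        raise ValidationError("scores and labels differ in length")
    keep = ~np.isnan(s)
    n_na = int((~keep).sum())
    if n_na:
        logger.info("excluding %d NA scores from rank statistics", n_na)
    return s[keep], y[keep]


def _check_both_classes(y: np.ndarray) -> None:
    if y.min() == y.max():
        raise ValidationError("both label classes are required")


def _orient(scores: np.ndarray, direction: Direction) -> np.ndarray:
    if direction == "lower_predicts_positive":
        return -scores
    if direction == "higher_predicts_positive":
        return scores
    raise ValidationError(f"unknown direction {direction!r}")


@dataclass
class RocResult:
    auc: float
    direction: Direction
    thresholds: pd.DataFrame = field(repr=False, default=None)

    """AUC after orientation, with the per-threshold (sensitivity,
    specificity) operating points of the ROC curve."""


def roc_auc(scores, labels, direction: Direction = "higher_predicts_positive") -> RocResult:
    """AUC = Mann-Whitney concordance probability (ties count 1/2).

    Scores are oriented by ``direction`` first, so a well-behaved negative
    predictor also yields AUC >= 0.5.  NA scores are dropped pairwise.
    """
    s, y = _drop_na(scores, labels)
    _check_both_classes(y)
    oriented = _orient(s, direction)
    auc = float(roc_auc_score(y, oriented))
    # operating points at every candidate cutpoint
    cand = candidate_thresholds(s)
    rows = [
        (t, *_confusion(s, y, t, direction)) for t in cand
    ]
    thresholds = pd.DataFrame(
        rows, columns=["threshold", "sensitivity", "specificity", "balanced_accuracy"]
    )
    return RocResult(auc=auc, direction=direction, thresholds=thresholds)


# -- DeLong ------------------------------------------------------------------


def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _delong_components(scores: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC and the DeLong structural components V10 (positives), V01 (negatives)."""
    pos = scores[y == 1]
    neg = scores[y == 0]
    m, n = len(pos), len(neg)
    all_ranks = _midrank(np.concatenate([pos, neg]))
    pos_ranks = _midrank(pos)
    neg_ranks = _midrank(neg)
    v10 = (all_ranks[:m] - pos_ranks) / n
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m
    auc = v10.mean()
    return float(auc), v10, v01


def delong_paired(
    scores_a,
    scores_b,
    labels,
    direction_a: Direction = "higher_predicts_positive",
    direction_b: Direction = "higher_predicts_positive",
) -> tuple[float, float, float]:
    """Paired DeLong test for the difference of two AUCs on the same samples.

    Returns ``(auc_a, auc_b, p_value)`` with a two-sided p from the normal
    approximation with DeLong's structural-components covariance.  Samples
    with an NA score in either biomarker are dropped pairwise.
    """
    sa = np.asarray(scores_a, dtype=float)
    sb = np.asarray(scores_b, dtype=float)
    y = _as_binary_labels(labels)
    if not (sa.shape == sb.shape == y.shape):
        raise ValidationError("paired DeLong needs both scores on identical samples")
    keep = ~(np.isnan(sa) | np.isnan(sb))
    n_na = int((~keep).sum())
    if n_na:
        logger.info("DeLong: excluding %d samples with NA scores", n_na)
    sa, sb, y = sa[keep], sb[keep], y[keep]
    _check_both_classes(y)

    auc_a, v10_a, v01_a = _delong_components(_orient(sa, direction_a), y)
    auc_b, v10_b, v01_b = _delong_components(_orient(sb, direction_b), y)
    m, n = len(v10_a), len(v01_a)

    s10 = np.cov(np.vstack([v10_a, v10_b]))
    s01 = np.cov(np.vstack([v01_a, v01_b]))
    cov = s10 / m + s01 / n  # 2x2 covariance of (auc_a, auc_b)
    var_diff = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    diff = auc_a - auc_b
    if var_diff <= 0 or math.isclose(var_diff, 0.0, abs_tol=1e-16):
        p = 1.0 if math.isclose(diff, 0.0, abs_tol=1e-12) else 0.0
    else:
        z = diff / math.sqrt(var_diff)
        p = float(2 * stats.norm.sf(abs(z)))
    return float(auc_a), float(auc_b), p


# -- cutpoints ---------------------------------------------------------------


@dataclass
class CutpointResult:
    threshold: float
    sensitivity: float
    specificity: float
    degenerate: bool = False

    @property
    def balanced_accuracy(self) -> float:
        return (self.sensitivity + self.specificity) / 2.0


def candidate_thresholds(scores: np.ndarray) -> list[float]:
    """Midpoints of adjacent distinct scores plus sentinels beyond the range."""
    u = np.unique(scores[~np.isnan(scores)])
    if len(u) == 0:
        return [0.0]
    mids = ((u[:-1] + u[1:]) / 2.0).tolist()
    lo = float(u[0] - 1.0)
    hi = float(u[-1] + 1.0)
    return [lo] + mids + [hi]


def _confusion(
    s: np.ndarray, y: np.ndarray, threshold: float, direction: Direction
) -> tuple[float, float, float]:
    if direction == "lower_predicts_positive":
        pred = s < threshold
    else:
        pred = s >= threshold
    sens = float(pred[y == 1].mean()) if (y == 1).any() else math.nan
    spec = float((~pred[y == 0]).mean()) if (y == 0).any() else math.nan
    return sens, spec, (sens + spec) / 2.0


def evaluate_at_cutpoint(
    scores, labels, threshold: float, direction: Direction
) -> CutpointResult:
    """Confusion metrics at a fixed cutpoint.

    Prediction rule: positive iff score < threshold for a negative
    predictor (``lower_predicts_positive``), score >= threshold otherwise.
    """
    if not math.isfinite(threshold):
        raise ValidationError("cutpoint threshold must be finite")
    s, y = _drop_na(scores, labels)
    _check_both_classes(y)
    sens, spec, _ = _confusion(s, y, threshold, direction)
    return CutpointResult(threshold=float(threshold), sensitivity=sens, specificity=spec)


def optimize_cutpoint(scores, labels, direction: Direction) -> CutpointResult:
    """Exhaustive balanced-accuracy maximization over candidate thresholds.

    Balanced-accuracy ties are broken toward the threshold with higher
    sensitivity.  When all scores are equal the cutpoint is degenerate and
    the balanced accuracy is 0.5.
    """
    s, y = _drop_na(scores, labels)
    _check_both_classes(y)
    if len(np.unique(s)) == 1:
        logger.info("optimize_cutpoint: all scores identical, degenerate cutpoint")
        sens, spec, _ = _confusion(s, y, float(s[0]), direction)
        return CutpointResult(float(s[0]), sens, spec, degenerate=True)
    best: CutpointResult | None = None
    for t in candidate_thresholds(s):
        sens, spec, ba = _confusion(s, y, t, direction)
        if (
            best is None
            or ba > best.balanced_accuracy + 1e-12
            or (
                math.isclose(ba, best.balanced_accuracy, abs_tol=1e-12)
                and sens > best.sensitivity + 1e-12
            )
        ):
            best = CutpointResult(float(t), sens, spec)
    return best


# -- correlation, agreement --------------------------------------------------


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with average ranks; two-sided p.

    Pairs with an NA in either coordinate are dropped; at least 3 complete
    pairs are required.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("spearman needs paired vectors")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise ValidationError("spearman needs at least 3 complete pairs")
    r, p = stats.spearmanr(x, y)
    return float(r), float(p)


def cohens_kappa(calls_a, calls_b) -> float:
    """Cohen's kappa for paired binary calls.

    kappa = (p_o - p_e) / (1 - p_e) with marginal-product expected agreement.
    When either call vector is constant, p_o equals p_e algebraically in
    expectation and kappa is defined as 0.
    """
    a = _as_binary_labels(calls_a)
    b = _as_binary_labels(calls_b)
    if a.shape != b.shape:
        raise ValidationError("call vectors differ in length")
    n = len(a)
    if n == 0:
        raise ValidationError("empty call vectors")
    p_o = float((a == b).mean())
    pa1, pb1 = a.mean(), b.mean()
    p_e = pa1 * pb1 + (1 - pa1) * (1 - pb1)
    if math.isclose(p_e, 1.0, abs_tol=1e-15):
        return 0.0
    return (p_o - p_e) / (1 - p_e)


# -- differential 96-channel analysis ----------------------------------------


def _wilcoxon_rank_sum(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p: exact when the combined sample is
    small (<= 50) and tie-free, normal approximation with continuity
    correction otherwise."""
    exact = len(x) + len(y) <= 50 and len(np.unique(np.concatenate([x, y]))) == len(x) + len(y)
    method = "exact" if exact else "asymptotic"
    return float(
        stats.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue
    )


def differential_channels(
    catalogs_pos: Sequence[MutationCatalog96],
    catalogs_neg: Sequence[MutationCatalog96],
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Compare the 96 normalized channel frequencies between two groups.

    Each catalog's counts are normalized by its TMB; per channel the groups
    are compared by the two-sided Wilcoxon rank-sum test, with
    Benjamini-Hochberg adjustment across the 96 tests.  ``delta`` is
    mean(positive) - mean(negative) of the normalized frequency.  Zero-TMB
    catalogs are excluded (logged).
    """
    def freqs(catalogs):
        mats = [c.counts / c.tmb for c in catalogs if c.tmb > 0]
        n_drop = len(catalogs) - len(mats)
        if n_drop:
            logger.info("differential_channels: dropping %d zero-TMB catalogs", n_drop)
        return np.array(mats)

    fp, fn = freqs(catalogs_pos), freqs(catalogs_neg)
    if len(fp) < 2 or len(fn) < 2:
        raise ValidationError("each group needs at least 2 non-empty catalogs")
    p_raw = np.array(
        [_wilcoxon_rank_sum(fp[:, j], fn[:, j]) for j in range(96)]
    )
    delta = fp.mean(axis=0) - fn.mean(axis=0)
    reject, p_adj, _, _ = multipletests(p_raw, alpha=fdr, method="fdr_bh")
    return pd.DataFrame(
        {
            "channel": list(CHANNELS_96),
            "delta": delta,
            "p_raw": p_raw,
            "p_adj": p_adj,
            "significant": p_adj < fdr,
        }
    )


# -- mutational-signature composition ----------------------------------------


def read_signature_matrix(path) -> pd.DataFrame:
    """Read a signature probability matrix in the COSMIC tab-separated
    layout: 96 context-labeled rows ("A[C>A]A", ...) x signature columns.
    Rows are reordered to the canonical channel order."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    labels = set(df.index)
    if labels != set(CHANNELS_96):
        raise ValidationError(
            f"signature matrix {path} does not have the 96 canonical row labels"
        )
    return df.loc[list(CHANNELS_96)]


def signature_cgtg_fraction(signature) -> float:
    """Percentage of a signature's probability mass on the four CpG-site
    C>T channels (the mutations defining f_deam).

    ``signature`` is a length-96 vector in canonical channel order, or a
    pandas Series indexed by channel labels.  Vectors that do not sum to 1
    within 1e-6 are renormalized with a warning.
    """
    if isinstance(signature, pd.Series):
        if set(signature.index) == set(CHANNELS_96):
            signature = signature.loc[list(CHANNELS_96)]
        signature = signature.to_numpy()
    v = np.asarray(signature, dtype=float)
    if v.shape != (96,):
        raise ValidationError(f"signature vector must have length 96, got {v.shape}")
    if (v < 0).any():
        raise ValidationError("signature probabilities must be non-negative")
    total = v.sum()
    if total <= 0:
        raise ValidationError("signature vector sums to zero")
    if abs(total - 1.0) > 1e-6:
        logger.warning("signature vector sums to %.6g; renormalizing", total)
    return 100.0 * float(v[list(CPG_CT_INDICES)].sum()) / float(total)
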