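"""Evaluation of gene prioritizations: ROC/AUC, Spearman, paired t-test.

Known gene–disease associations are the positive examples; every other
scored pair is treated as negative (no curated true-negative set exists).
The AUC is computed as the Mann–Whitney statistic — the probability that a
randomly chosen positive outranks a randomly chosen negative, with tied
pairs contributing 1/2 — which equals the trapezoidal area under the ROC
curve with tie-aware thresholds.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from collections.abc import Mapping, Sequence

import numpy as np
from scipy import stats
from sklearn.metrics import roc_curve as _sk_roc_curve

from .annotations import AssociationTable, OrthologyMap
from .errors import CampError, DegenerateLabelsError

logger = logging.getLogger(__name__)

POSITIVE = "positive"
NEGATIVE = "negative"


@dataclass
class LabeledScores:
    """Scored gene–disease pairs with positive/negative labels.

    ``records`` holds (gene_id, disease_id, score, label). Positives absent
    from the scored pairs are collected in ``unscored_positives`` as a
    coverage diagnostic; mouse genes dropped for lack of a human ortholog
    (morbidmap evaluation only) are counted in ``excluded_no_ortholog``.
    """

    records: tuple[tuple[str, str, float, str], ...]
    unscored_positives: tuple[tuple[str, str], ...] = ()
    excluded_no_ortholog: int = 0

    @property
    def n_positive(self) -> int:
        return sum(1 for r in self.records if r[3] == POSITIVE)

    @property
    def n_negative(self) -> int:
        return sum(1 for r in self.records if r[3] == NEGATIVE)

    def scores_labels(self) -> tuple[np.ndarray, np.ndarray]:
        scores = np.array([r[2] for r in self.records], dtype=float)
        labels = np.array([1 if r[3] == POSITIVE else 0 for r in self.records])
        return scores, labels


@dataclass
class ROCResult:
    """A ROC curve (fpr, tpr points from (0,0) to (1,1)) and its AUC."""

    curve: tuple[tuple[float, float], ...]
    auc: float
    n_positive: int
    n_negative: int

    def to_tsv(self, path: str) -> None:
        with open(path, "w", encoding="utf-8") as handle:
            handle.write("#fpr\ttpr\n")
            for fpr, tpr in self.curve:
                handle.write(f"{fpr:.6f}\t{tpr:.6f}\n")

    def summary_json(self, path: str, **extra: object) -> None:
        payload = {
            "auc": self.auc,
            "n_positive": self.n_positive,
            "n_negative": self.n_negative,
        }
        payload.update(extra)
        with open(path, "w", encoding="utf-8") as handle:
            json.dump(payload, handle, indent=2, sort_keys=True)
            handle.write("\n")


@dataclass
class TTestResult:
    """One-tailed paired t-test outcome.

    ``degenerate`` flags zero variance of the paired differences; in that
    limit the p-value is 0 when the first sample is uniformly better
    (smaller), 1 otherwise, with ``direction`` the sign of the constant
    difference.
    """

    statistic: float
    p_value: float
    degenerate: bool = False
    direction: int = 0


def label_pairs(
    scores: Mapping[tuple[str, str], float],
    assoc: AssociationTable,
    orthology: OrthologyMap | None = None,
) -> LabeledScores:
    """Label scored (gene, disease) pairs against a known-association table.

    ``scores`` is keyed by (mouse gene, disease id). For a morbidmap table
    the mouse genes are lifted to human symbols through ``orthology`` (a pair
    is positive if any human ortholog is associated with the disease); mouse
    genes without orthologs are excluded from that evaluation and counted.
    """
    if assoc.source == "morbidmap" and orthology is None:
        raise CampError("morbidmap evaluation requires an orthology map")
    records = []
    seen_positive_keys: set[tuple[str, str]] = set()
    excluded = 0
    for (gene, disease), score in sorted(scores.items()):
        if assoc.source == "morbidmap":
            humans = orthology.human_orthologs(gene)
            if not humans:
                excluded += 1
                continue
            keys = {(h, disease) for h in humans}
        else:
            keys = {(gene, disease)}
        hits = keys & assoc.pairs
        label = POSITIVE if hits else NEGATIVE
        seen_positive_keys.update(hits)
        records.append((gene, disease, float(score), label))
    unscored = tuple(sorted(assoc.pairs - seen_positive_keys))
    if excluded:
        logger.info("excluded %d mouse genes without human orthologs", excluded)
    if unscored:
        logger.info("%d known associations had no scored pair", len(unscored))
    return LabeledScores(
        records=tuple(records),
        unscored_positives=unscored,
        excluded_no_ortholog=excluded,
    )


def roc_auc(labeled: LabeledScores) -> ROCResult:
    """ROC curve and AUC for labeled scores.

    The AUC is the Mann–Whitney U divided by ``n_pos * n_neg`` (ties count
    1/2); the curve sweeps thresholds over the distinct scores. Raises
    :class:`DegenerateLabelsError` when either class is empty.
    """
    n_pos, n_neg = labeled.n_positive, labeled.n_negative
    if n_pos == 0 or n_neg == 0:
        raise DegenerateLabelsError(
            f"need both classes: {n_pos} positives, {n_neg} negatives"
        )
    scores, labels = labeled.scores_labels()
    ranks = stats.rankdata(scores)
    u_statistic = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2
    auc = float(u_statistic / (n_pos * n_neg))
    fpr, tpr, _ = _sk_roc_curve(labels, scores, drop_intermediate=False)
    curve = tuple((float(x), float(y)) for x, y in zip(fpr, tpr))
    return ROCResult(curve=curve, auc=auc, n_positive=n_pos, n_negative=n_neg)


def spearman_positive_ranks(
    ranks_a: Sequence[float], ranks_b: Sequence[float]
) -> float:
    """Spearman rank correlation between two paired rank lists.

    Used to compare where the same positive associations land under two
    prioritization variants. Requires equal lengths ≥ 3; fractional ranks
    handle ties. When either list is constant the coefficient is undefined
    and ``nan`` is returned.
    """
    if len(ranks_a) != len(ranks_b):
        raise CampError(
            f"paired rank lists differ in length: {len(ranks_a)} vs {len(ranks_b)}"
        )
    if len(ranks_a) < 3:
        raise CampError("need at least 3 paired ranks")
    if np.ptp(ranks_a) == 0 or np.ptp(ranks_b) == 0:
        return math.nan
    rho = stats.spearmanr(ranks_a, ranks_b).statistic
    return float(rho)


def paired_one_tailed_ttest(
    ranks_a: Sequence[float], ranks_b: Sequence[float]
) -> TTestResult:
    """Paired one-tailed t-test for ``ranks_a`` better (smaller) than ``ranks_b``.

    Tests H1: mean(ranks_a - ranks_b) < 0 on the paired differences. When the
    differences have zero variance the result is flagged degenerate and the
    p-value is taken at the sd→0 limit (0 if uniformly better, 1 otherwise;
    identical lists carry no significance).
    """
    if len(ranks_a) != len(ranks_b):
        raise CampError(
            f"paired rank lists differ in length: {len(ranks_a)} vs {len(ranks_b)}"
        )
    if len(ranks_a) < 3:
        raise CampError("need at least 3 paired ranks")
    diffs = np.asarray(ranks_a, dtype=float) - np.asarray(ranks_b, dtype=float)
    if np.ptp(diffs) == 0.0:
        d = diffs[0]
        direction = int(np.sign(d))
        if direction < 0:
            return TTestResult(statistic=-math.inf, p_value=0.0, degenerate=True, direction=-1)
        if direction > 0:
            return TTestResult(statistic=math.inf, p_value=1.0, degenerate=True, direction=1)
        return TTestResult(statistic=math.nan, p_value=1.0, degenerate=True, direction=0)
    result = stats.ttest_rel(ranks_a, ranks_b, alternative="less")
    return TTestResult(statistic=float(result.statistic), p_value=float(result.pvalue))
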