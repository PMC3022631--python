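"""Retrieval evaluation: leave-one-out cross-validation, ROC/AUC, precision at k.

Each labeled profile queries the rest of the library; a retrieved profile
is relevant when it shares the query's label.  AUC uses the
rank (Mann-Whitney) formulation with half credit for ties; curves are
averaged vertically over a common false-positive-rate grid.  Precision at
k is compared against a label-permutation null whose per-query mean, for
equally sized classes of m profiles among n, is (m - 1)/(n - 1).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from desearch.datamodel import DEProfile, ValidationError
from desearch.similarity import Method, WeightScheme, similarity_score

logger = logging.getLogger(__name__)


@dataclass
class RankedList:
    """One query's retrieval: targets sorted by similarity, with relevance."""

    query_id: str
    target_ids: list[str]
    scores: np.ndarray
    relevance: np.ndarray  # 1 = same label as query


def loocv_retrieval(
    profiles: list[DEProfile],
    labels: dict[str, str],
    scheme: WeightScheme | None = None,
    method: Method = "pearson",
    absolute: bool = False,
    min_overlap: int | None = None,
) -> list[RankedList]:
    """Leave-one-out retrieval over a labeled profile library.

    Signed similarity by default (a shared comparison direction, e.g.
    normal vs disease, makes sign informative); queries whose label has
    no other member are skipped with a warning.  Ranking ties break by
    target id, so output is deterministic.
    """
    label_counts: dict[str, int] = {}
    for p in profiles:
        label_counts[labels[p.profile_id]] = label_counts.get(labels[p.profile_id], 0) + 1
    if len(label_counts) < 2:
        raise ValidationError("need at least 2 distinct labels for retrieval evaluation")
    ranked_lists = []
    for q in profiles:
        if label_counts[labels[q.profile_id]] < 2:
            logger.warning(
                "skipping query %s: label %r has no other profile",
                q.profile_id,
                labels[q.profile_id],
            )
            continue
        rows = []
        for t in profiles:
            if t.profile_id == q.profile_id:
                continue
            s, _, _ = similarity_score(q, t, scheme, method, absolute, min_overlap)
            rows.append((s, t.profile_id, int(labels[t.profile_id] == labels[q.profile_id])))
        rows.sort(key=lambda r: (-r[0], r[1]))
        ranked_lists.append(
            RankedList(
                query_id=q.profile_id,
                target_ids=[r[1] for r in rows],
                scores=np.array([r[0] for r in rows]),
                relevance=np.array([r[2] for r in rows]),
            )
        )
    return ranked_lists


def _auc_mann_whitney(scores: np.ndarray, relevance: np.ndarray) -> float:
    pos = relevance == 1
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("AUC needs at least one positive and one negative")
    ranks = rankdata(scores, method="average")
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def _roc_curve_on_grid(scores: np.ndarray, relevance: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """True-positive rate at each grid false-positive rate (step interpolation)."""
    order = np.argsort(-scores, kind="stable")
    rel = relevance[order]
    tp = np.cumsum(rel)
    fp = np.cumsum(1 - rel)
    tpr = np.concatenate([[0.0], tp / tp[-1]])
    fpr = np.concatenate([[0.0], fp / fp[-1]])
    # highest TPR achievable at FPR <= g
    out = np.empty_like(grid)
    for k, g in enumerate(grid):
        out[k] = tpr[fpr <= g + 1e-12].max()
    return out


@dataclass
class ROCSummary:
    per_query_auc: dict[str, float]
    mean_auc: float
    se_auc: float
    fpr_grid: np.ndarray
    mean_tpr: np.ndarray


def roc_auc(ranked_lists: list[RankedList], n_grid: int = 101) -> ROCSummary:
    """Per-query AUC (rank formulation, ties half credit), mean and SE.

    The averaged curve interpolates each query's ROC on a common FPR grid
    and averages vertically; the SE is the standard error of the
    per-query AUCs.  Lists lacking positives or negatives are excluded
    and logged.
    """
    grid = np.linspace(0.0, 1.0, n_grid)
    aucs: dict[str, float] = {}
    curves = []
    for rl in ranked_lists:
        try:
            aucs[rl.query_id] = _auc_mann_whitney(rl.scores, rl.relevance)
        except ValidationError as exc:
            logger.warning("excluding %s from ROC: %s", rl.query_id, exc)
            continue
        curves.append(_roc_curve_on_grid(rl.scores, rl.relevance, grid))
    if not aucs:
        raise ValidationError("no evaluable ranked lists")
    vals = np.array(list(aucs.values()))
    se = float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else 0.0
    return ROCSummary(
        per_query_auc=aucs,
        mean_auc=float(vals.mean()),
        se_auc=se,
        fpr_grid=grid,
        mean_tpr=np.mean(curves, axis=0),
    )


def precision_at_k(ranked_list: RankedList, k: int = 4) -> float:
    """Fraction of the top k retrieved profiles sharing the query's label."""
    n = len(ranked_list.relevance)
    if n == 0:
        raise ValidationError("empty ranked list")
    if n < k:
        logger.warning("list of %d shorter than k=%d; using full list", n, k)
        k = n
    return float(np.mean(ranked_list.relevance[:k]))


@dataclass
class PermutationNull:
    per_query_mean: dict[str, float]
    per_query_interval: dict[str, tuple[float, float]]
    observed: dict[str, float]
    significant: dict[str, bool]  # observed above the 97.5th null percentile


def permutation_null_precision(
    ranked_lists: list[RankedList],
    labels: dict[str, str],
    k: int = 4,
    n_permutations: int = 10_000,
    seed: int = 0,
) -> PermutationNull:
    """Label-permutation null for precision at k.

    Rankings are fixed; labels are shuffled across all profiles each
    permutation and relevance recomputed.  Returns per-query null mean,
    central 95% interval, the observed precision, and whether it exceeds
    the 97.5th percentile.  With equally sized classes (m of n) the null
    mean is (m - 1)/(n - 1); with unequal classes it is the probability
    that two random profiles share a label.
    """
    rng = np.random.default_rng(seed)
    all_ids = sorted({rl.query_id for rl in ranked_lists} | {t for rl in ranked_lists for t in rl.target_ids})
    id_pos = {pid: i for i, pid in enumerate(all_ids)}
    label_arr = np.array([labels[pid] for pid in all_ids], dtype=object)
    perms = np.array([rng.permutation(len(all_ids)) for _ in range(n_permutations)])
    means, intervals, observed, significant = {}, {}, {}, {}
    for rl in ranked_lists:
        kk = min(k, len(rl.target_ids))
        top = np.array([id_pos[t] for t in rl.target_ids[:kk]])
        qpos = id_pos[rl.query_id]
        # permuted labels of the query and its fixed top-k targets
        q_lab = label_arr[perms[:, qpos]]
        t_lab = label_arr[perms[:, top]]  # n_permutations x kk
        prec = (t_lab == q_lab[:, None]).mean(axis=1)
        means[rl.query_id] = float(prec.mean())
        lo, hi = np.percentile(prec, [2.5, 97.5])
        intervals[rl.query_id] = (float(lo), float(hi))
        obs = precision_at_k(rl, k)
        observed[rl.query_id] = obs
        significant[rl.query_id] = bool(obs > hi)
    return PermutationNull(
        per_query_mean=means,
        per_query_interval=intervals,
        observed=observed,
        significant=significant,
    )


def evaluation_grid(
    profile_sets: dict[str, list[DEProfile]],
    labels: dict[str, str],
    schemes: dict[str, WeightScheme] | None = None,
    methods: tuple[Method, ...] = ("pearson", "spearman"),
    absolute: bool = False,
    min_overlap: int | None = None,
) -> pd.DataFrame:
    """Mean AUC +/- SE for every (reduction, measure) cell.

    ``profile_sets`` maps a reduction name (e.g. ``gene``, ``ica``,
    ``ica_modules``) to the library re-expressed in that space;
    ``schemes`` maps weighting names to schemes (default: unweighted and
    p-weighted; add inverse-variance by passing a scheme with compendium
    variances).  Cells whose requirements are unmet (e.g. p-weighting
    without p-values) are reported as NaN.
    """
    if schemes is None:
        schemes = {"unweighted": WeightScheme(kind="unweighted"), "p_value": WeightScheme(kind="p_value")}
    rows = []
    for reduction, profs in profile_sets.items():
        for method, (wname, scheme) in itertools.product(methods, schemes.items()):
            try:
                ranked = loocv_retrieval(profs, labels, scheme, method, absolute, min_overlap)
                summary = roc_auc(ranked)
                rows.append((reduction, method, wname, summary.mean_auc, summary.se_auc))
            except ValidationError as exc:
                logger.warning("grid cell (%s, %s, %s) failed: %s", reduction, method, wname, exc)
                rows.append((reduction, method, wname, np.nan, np.nan))
    return pd.DataFrame(rows, columns=["reduction", "method", "weighting", "mean_auc", "se_auc"])
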