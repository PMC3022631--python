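"""Build differential-expression profiles from two-group comparisons.

Three representations of differential expression are supported:

* ``logfc`` -- difference of group-mean log2 expression, after aggregating
  probes to genes with the inverse-variance (fixed-effect) meta-estimate;
* ``pvalue`` -- significance of differential expression from an
  empirical-Bayes moderated t-statistic, signed by the direction of change;
* ``rank`` -- median pairwise difference of group-averaged probe ranks.

The moderated t shrinks per-gene variances toward a common prior whose
degrees of freedom d0 and location s0^2 are estimated by matching moments
of log s_g^2 against the scaled-F sampling model (digamma/trigamma
matching).  With d0 = 0 it reduces exactly to the pooled-variance
two-sample t-test.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import polygamma, psi
from scipy.stats import t as t_dist
from statsmodels.stats.multitest import multipletests

from desearch.datamodel import DEProfile, ExpressionExperiment, HomologMap, ValidationError
from desearch.io import ensure_log_scale

logger = logging.getLogger(__name__)

#: Variance floor for zero-variance probes (keeps inverse weights finite).
VARIANCE_FLOOR = 1e-8

#: p-values of exactly 0 are floored here before storage (log-weights need p > 0).
P_FLOOR = 1e-300


class MappingError(ValidationError):
    """A profile failed to map into the requested feature space."""


# ---------------------------------------------------------------------------
# fixed-effect meta-estimate (shared by probe aggregation and module scores)
# ---------------------------------------------------------------------------

def fixed_effect_meta(
    values: pd.DataFrame, variances: pd.Series, grouping: pd.Series
) -> tuple[pd.DataFrame, pd.Series]:
    """Inverse-variance weighted aggregation of rows into groups.

    For group g with member rows p: per-column estimate
    ``sum(x_p / v_p) / sum(1 / v_p)`` and pooled variance
    ``1 / sum(1 / v_p)``.  Missing values are excluded per column with
    their weights.  Rows absent from ``grouping`` are dropped.

    Returns (aggregated values: groups x columns, group variances).
    """
    keep = values.index.intersection(grouping.index)
    if keep.empty:
        raise ValidationError("no rows of the matrix appear in the grouping")
    values = values.loc[keep]
    v = variances.loc[keep].clip(lower=VARIANCE_FLOOR)
    w = 1.0 / v
    genes = grouping.loc[keep]
    mask = values.notna()
    num = values.fillna(0.0).mul(w, axis=0).groupby(genes).sum()
    den = mask.mul(w, axis=0).groupby(genes).sum()
    agg = num / den.where(den > 0)
    gvar = 1.0 / w.groupby(genes).sum()
    return agg, gvar.reindex(agg.index)


def aggregate_probes_fixed_effects(
    experiment: ExpressionExperiment, probe_map: dict[str, str]
) -> ExpressionExperiment:
    """Aggregate probe-level values to gene level.

    Each probe is weighted by the inverse of its variance across all
    samples of the experiment; probes without a gene assignment are
    dropped.  The resulting experiment carries per-gene variances
    ``1 / sum(1 / v_p)`` for downstream meta-scores.
    """
    if experiment.is_log_scale is not True:
        raise ValidationError("aggregate_probes_fixed_effects requires log-scale data")
    probe_var = experiment.values.var(axis=1, ddof=1)
    grouping = pd.Series({p: g for p, g in probe_map.items() if p in experiment.values.index})
    if grouping.empty:
        raise ValidationError(
            f"no probes of {experiment.experiment_id!r} are present in the probe map"
        )
    dropped = len(experiment.values.index) - len(grouping)
    if dropped:
        logger.info("%s: dropping %d unmapped probes", experiment.experiment_id, dropped)
    agg, gvar = fixed_effect_meta(experiment.values, probe_var, grouping)
    return experiment.replace(values=agg, feature_variances=gvar)


# ---------------------------------------------------------------------------
# log fold-change
# ---------------------------------------------------------------------------

def logfc_profile(
    experiment: ExpressionExperiment, group_a: str, group_b: str
) -> DEProfile:
    """Log fold-change profile: mean(group_a) - mean(group_b) per feature."""
    cols_a = experiment.samples_in_group(group_a)
    cols_b = experiment.samples_in_group(group_b)
    scores = (
        experiment.values[cols_a].mean(axis=1) - experiment.values[cols_b].mean(axis=1)
    )
    variances = (
        experiment.feature_variances.to_numpy()
        if experiment.feature_variances is not None
        else None
    )
    return DEProfile(
        profile_id=f"{experiment.experiment_id}:{group_a}-vs-{group_b}",
        space="gene",
        feature_ids=np.asarray(experiment.values.index, dtype=object),
        scores=scores.to_numpy(),
        variances=variances,
        comparison=(group_a, group_b),
        source_experiment=experiment.experiment_id,
    )


# ---------------------------------------------------------------------------
# empirical-Bayes moderated t
# ---------------------------------------------------------------------------

@dataclass
class ModeratedTestResult:
    """Per-feature moderated two-sample test plus fitted prior."""

    feature_ids: np.ndarray
    mean_diff: np.ndarray  # log2 units, group_a - group_b
    s2: np.ndarray  # pooled within-group variance
    df_residual: np.ndarray
    prior_df: float  # d0 (may be inf)
    prior_var: float  # s0^2
    t: np.ndarray
    pvalues_raw: np.ndarray
    pvalues_adjusted: np.ndarray


def trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        raise ValidationError("trigamma_inverse requires y > 0")
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = polygamma(1, x)
        dif = tri * (1.0 - tri / y) / polygamma(2, x)
        x = x + dif
        if abs(dif) < 1e-8 * x:
            break
    return float(x)


def _fit_variance_prior(s2: np.ndarray, df: np.ndarray) -> tuple[float, float]:
    """Estimate (d0, s0^2) of the scaled inverse-chi-square variance prior.

    Moment-matches log s_g^2, whose sampling distribution given the prior
    is a shifted log-F: E and Var involve digamma/trigamma of df/2.
    A non-positive excess variance yields d0 = inf (all gene variances
    equal s0^2 up to sampling noise).
    """
    ok = (df > 0) & np.isfinite(s2)
    if ok.sum() < 2:
        raise ValidationError(
            "need at least 2 features with positive residual df to fit the variance prior"
        )
    s2 = np.maximum(s2[ok], VARIANCE_FLOOR)
    df = df[ok].astype(float)
    z = np.log(s2)
    e = z - psi(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) - np.mean(polygamma(1, df / 2.0))
    if evar > 0:
        d0 = 2.0 * trigamma_inverse(evar)
        s0_2 = float(np.exp(emean + psi(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s0_2 = float(np.exp(emean))
    return float(d0), s0_2


def moderated_t_pvalues(
    experiment: ExpressionExperiment,
    group_a: str,
    group_b: str,
    prior_df: float | None = None,
) -> ModeratedTestResult:
    """Empirical-Bayes moderated two-sample t-test per feature.

    Posterior variance ``s~_g^2 = (d0 s0^2 + d_g s_g^2) / (d0 + d_g)``;
    ``t~_g = diff_g / (s~_g sqrt(1/n_a + 1/n_b))`` referred to a t
    distribution on ``d0 + d_g`` degrees of freedom.  Features with
    ``d_g = 0`` (fewer than 3 informative samples) are excluded from the
    prior fit and assigned p = 1.  ``prior_df`` overrides the estimated
    d0 (0 gives the ordinary pooled-variance t-test).

    Adjusted p-values are Benjamini-Hochberg over all features.
    """
    cols_a = experiment.samples_in_group(group_a)
    cols_b = experiment.samples_in_group(group_b)
    xa = experiment.values[cols_a]
    xb = experiment.values[cols_b]
    na = xa.notna().sum(axis=1).to_numpy(dtype=float)
    nb = xb.notna().sum(axis=1).to_numpy(dtype=float)
    ma = xa.mean(axis=1).to_numpy()
    mb = xb.mean(axis=1).to_numpy()
    diff = ma - mb
    ssa = ((xa.sub(xa.mean(axis=1), axis=0)) ** 2).sum(axis=1).to_numpy()
    ssb = ((xb.sub(xb.mean(axis=1), axis=0)) ** 2).sum(axis=1).to_numpy()
    informative = (na >= 1) & (nb >= 1)
    df = np.where(informative, na + nb - 2, 0.0)
    df = np.maximum(df, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        s2 = np.where(df > 0, (ssa + ssb) / np.where(df > 0, df, 1.0), np.nan)

    if prior_df is None:
        d0, s0_2 = _fit_variance_prior(s2, df)
    elif prior_df == 0:
        # no shrinkage: ordinary pooled-variance t-test
        d0, s0_2 = 0.0, float(np.nanmean(s2))
    else:
        d0 = float(prior_df)
        if np.isfinite(d0):
            _, s0_2 = _fit_variance_prior(s2, df)
        else:
            s0_2 = float(np.nanmean(s2))

    with np.errstate(invalid="ignore", divide="ignore"):
        if np.isinf(d0):
            s2_post = np.full_like(s2, s0_2)
        elif d0 == 0:
            s2_post = s2
        else:
            s2_post = (d0 * s0_2 + df * s2) / (d0 + df)
        se = np.sqrt(s2_post * (1.0 / na + 1.0 / nb))
        tstat = diff / se
    df_total = d0 + df
    usable = (df > 0) & np.isfinite(tstat)
    praw = np.ones_like(diff)
    if np.isinf(d0):
        from scipy.stats import norm

        praw[usable] = 2.0 * norm.sf(np.abs(tstat[usable]))
    else:
        praw[usable] = 2.0 * t_dist.sf(np.abs(tstat[usable]), df_total[usable])
    praw = np.clip(praw, P_FLOOR, 1.0)
    padj = bh_adjust(praw)
    tstat = np.where(usable, tstat, 0.0)
    return ModeratedTestResult(
        feature_ids=np.asarray(experiment.values.index, dtype=object),
        mean_diff=diff,
        s2=s2,
        df_residual=df,
        prior_df=d0,
        prior_var=s0_2,
        t=tstat,
        pvalues_raw=praw,
        pvalues_adjusted=padj,
    )


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment, returned in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValidationError("bh_adjust expects a non-empty 1-d vector")
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in (0, 1]")
    _, padj, _, _ = multipletests(p, method="fdr_bh")
    return np.clip(padj, P_FLOOR, 1.0)


# ---------------------------------------------------------------------------
# rank representation
# ---------------------------------------------------------------------------

def rank_profile(
    experiment: ExpressionExperiment,
    group_a: str,
    group_b: str,
    probe_map: dict[str, str],
) -> DEProfile:
    """Nonparametric rank profile on the raw probe-level matrix.

    Probes are ranked ascending within each sample (average ranks for
    ties), ranks are averaged within each group, and each gene scores the
    median of ``rank_a(p) - rank_b(q)`` over all ordered probe pairs
    (p, q) drawn from its probe set.  Invariant to any strictly
    increasing per-sample transform of the raw values.
    """
    ranks = experiment.values.rank(axis=0, method="average", na_option="keep")
    cols_a = experiment.samples_in_group(group_a)
    cols_b = experiment.samples_in_group(group_b)
    mean_a = ranks[cols_a].mean(axis=1)
    mean_b = ranks[cols_b].mean(axis=1)
    grouping: dict[str, list[str]] = {}
    for probe in experiment.values.index:
        gene = probe_map.get(probe)
        if gene is not None:
            grouping.setdefault(gene, []).append(probe)
    if not grouping:
        raise ValidationError(
            f"no probes of {experiment.experiment_id!r} are present in the probe map"
        )
    genes = sorted(grouping)
    scores = np.empty(len(genes))
    for i, gene in enumerate(genes):
        probes = grouping[gene]
        a = mean_a.loc[probes].to_numpy()
        b = mean_b.loc[probes].to_numpy()
        scores[i] = np.nanmedian(a[:, None] - b[None, :])
    return DEProfile(
        profile_id=f"{experiment.experiment_id}:{group_a}-vs-{group_b}:rank",
        space="gene",
        feature_ids=np.asarray(genes, dtype=object),
        scores=scores,
        comparison=(group_a, group_b),
        source_experiment=experiment.experiment_id,
    )


# ---------------------------------------------------------------------------
# homolog mapping and comparison enumeration
# ---------------------------------------------------------------------------

def map_to_human(profile: DEProfile, homolog_map: HomologMap, species: str) -> DEProfile:
    """Rename features to human gene ids, keeping only one-to-one homologs.

    Human profiles pass through unchanged.  A profile in which no feature
    has a one-to-one human homolog raises :class:`MappingError` (such
    comparisons are excluded from indexing).
    """
    if profile.space != "gene":
        raise ValidationError("map_to_human applies to gene-space profiles")
    if species == "human":
        return profile
    keep_idx = []
    human_ids = []
    for i, gene in enumerate(profile.feature_ids):
        human = homolog_map.lookup_one_to_one(species, str(gene))
        if human is not None:
            keep_idx.append(i)
            human_ids.append(human)
    if not keep_idx:
        raise MappingError(
            f"profile {profile.profile_id!r} ({species}) failed to map: "
            "no one-to-one human homologs"
        )
    n_dropped = len(profile.feature_ids) - len(keep_idx)
    if n_dropped:
        logger.info("%s: dropped %d genes without one-to-one homologs", profile.profile_id, n_dropped)
    keep = np.asarray(keep_idx, dtype=int)
    return DEProfile(
        profile_id=profile.profile_id,
        space="gene",
        feature_ids=np.asarray(human_ids, dtype=object),
        scores=profile.scores[keep],
        pvalues=None if profile.pvalues is None else profile.pvalues[keep],
        variances=None if profile.variances is None else profile.variances[keep],
        comparison=profile.comparison,
        source_experiment=profile.source_experiment,
    )


def enumerate_comparisons(experiment: ExpressionExperiment) -> list[tuple[str, str]]:
    """All unordered group pairs of the experimental factor.

    Sorted lexicographically; within a pair the smaller label comes
    first.  For k groups this yields k(k-1)/2 comparisons (e.g. groups
    "1 hr", "2 hr", "4 hr" produce 1-vs-2, 1-vs-4, 2-vs-4).
    """
    labels = experiment.group_labels
    if len(labels) < 2:
        raise ValidationError(
            f"factor {experiment.factor!r} has {len(labels)} group(s); need at least 2"
        )
    return list(itertools.combinations(labels, 2))


# ---------------------------------------------------------------------------
# end-to-end profile construction
# ---------------------------------------------------------------------------

def build_profile(
    experiment: ExpressionExperiment,
    group_a: str,
    group_b: str,
    representation: str = "logfc",
    probe_map: dict[str, str] | None = None,
    homolog_map: HomologMap | None = None,
) -> DEProfile:
    """Full pipeline: log-scale, aggregate, score, test, map to human.

    ``logfc`` profiles score the fold change and carry moderated-t
    adjusted p-values and meta-estimate variances; ``pvalue`` profiles
    score ``sign(logFC) * -log10(p_adj)``; ``rank`` profiles use the
    rank representation (no p-values).
    """
    experiment = ensure_log_scale(experiment)
    if representation == "rank":
        if probe_map is None:
            probe_map = {f: f for f in experiment.feature_ids}
        profile = rank_profile(experiment, group_a, group_b, probe_map)
    else:
        if probe_map is not None:
            experiment = aggregate_probes_fixed_effects(experiment, probe_map)
        test = moderated_t_pvalues(experiment, group_a, group_b)
        base = logfc_profile(experiment, group_a, group_b)
        if representation == "logfc":
            scores = base.scores
        elif representation == "pvalue":
            scores = np.sign(base.scores) * -np.log10(test.pvalues_adjusted)
        else:
            raise ValidationError(f"unknown representation {representation!r}")
        profile = DEProfile(
            profile_id=base.profile_id,
            space="gene",
            feature_ids=base.feature_ids,
            scores=scores,
            pvalues=test.pvalues_adjusted,
            variances=base.variances,
            comparison=(group_a, group_b),
            source_experiment=experiment.experiment_id,
        )
    if homolog_map is not None:
        profile = map_to_human(profile, homolog_map, experiment.species)
    return profile
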