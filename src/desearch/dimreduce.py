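"""Dimension reduction of DE profiles.

Two routes out of gene space:

* projection onto a linear component basis S (components x genes) learned
  by independent component analysis: reduced profile A[c] = sum_g S[c,g] X[g]
  over the genes shared by the profile and the basis;
* discrete gene sets (curated collections, or "modules" of genes loading
  more than 3 SD above a component's mean), summarized by the
  inverse-variance fixed-effect meta-estimate.

A desk-scale component-derivation routine is included: repeated FastICA
runs on a (condition-balanced) compendium, pooled and aggregated by
partitioning-around-medoids clustering on correlation distance.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import skew
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

from desearch.datamodel import (
    ComponentMatrix,
    DEProfile,
    ExpressionExperiment,
    GeneSetCollection,
    ValidationError,
)
from desearch.profiles import fixed_effect_meta, moderated_t_pvalues

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# projection
# ---------------------------------------------------------------------------

def _common_genes(feature_ids, components: ComponentMatrix) -> tuple[np.ndarray, np.ndarray]:
    idx_p = pd.Index(feature_ids)
    idx_s = pd.Index(components.gene_ids)
    shared = idx_p.intersection(idx_s)
    if shared.empty:
        raise ValidationError("no genes shared between profile and component matrix")
    return idx_p.get_indexer(shared), idx_s.get_indexer(shared)


def project_ica(profile: DEProfile, components: ComponentMatrix) -> DEProfile:
    """Project a gene-space profile onto the component basis.

    Restricted to the genes common to profile and basis (genes present in
    only one contribute nothing); the reduced score for component c is
    the loadings-weighted sum of the profile scores.
    """
    if profile.space != "gene":
        raise ValidationError("project_ica expects a gene-space profile")
    pos_p, pos_s = _common_genes(profile.feature_ids, components)
    reduced = components.loadings[:, pos_s] @ profile.scores[pos_p]
    return DEProfile(
        profile_id=profile.profile_id,
        space="component",
        feature_ids=np.asarray(components.component_ids, dtype=object),
        scores=reduced,
        comparison=profile.comparison,
        source_experiment=profile.source_experiment,
    )


def project_experiment(
    experiment: ExpressionExperiment, components: ComponentMatrix
) -> ExpressionExperiment:
    """Project each sample's (gene-level) expression onto the basis.

    The resulting component x sample experiment supports the moderated
    t-test, giving per-component p-values of differential expression.
    """
    pos_g, pos_s = _common_genes(experiment.values.index, components)
    projected = components.loadings[:, pos_s] @ experiment.values.to_numpy()[pos_g, :]
    return experiment.replace(
        values=pd.DataFrame(
            projected, index=components.component_ids, columns=experiment.sample_ids
        ),
        feature_variances=None,
    )


def component_profile(
    experiment: ExpressionExperiment,
    profile: DEProfile,
    components: ComponentMatrix,
) -> DEProfile:
    """Reduced profile with per-component moderated-t p-values.

    Scores are the projection of the gene profile; p-values come from
    testing the two comparison groups on component-projected samples.
    """
    reduced = project_ica(profile, components)
    proj_exp = project_experiment(experiment, components)
    group_a, group_b = profile.comparison
    test = moderated_t_pvalues(proj_exp, group_a, group_b)
    reduced.pvalues = test.pvalues_adjusted
    return reduced


# ---------------------------------------------------------------------------
# component derivation (desk scale)
# ---------------------------------------------------------------------------

def _balance_samples(X: np.ndarray, threshold: float) -> np.ndarray:
    """Collapse near-duplicate samples to cluster medoids.

    Hierarchical (average-linkage) clustering on correlation distance,
    cut at ``threshold``; each cluster is represented by its medoid, so
    over-represented conditions contribute once.  Returns row indices.
    """
    n = X.shape[0]
    if n < 3:
        return np.arange(n)
    corr = np.corrcoef(X)
    dist = np.clip(1.0 - corr, 0.0, 2.0)
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2.0
    Z = linkage(squareform(dist, checks=False), method="average")
    labels = fcluster(Z, t=threshold, criterion="distance")
    reps = []
    for lab in np.unique(labels):
        members = np.nonzero(labels == lab)[0]
        if len(members) == 1:
            reps.append(members[0])
        else:
            sub = dist[np.ix_(members, members)]
            reps.append(members[int(np.argmin(sub.sum(axis=1)))])
    return np.array(sorted(reps))


def _orient_and_normalize(components: np.ndarray) -> np.ndarray:
    """Unit-normalize rows and flip signs so the heavier loading tail is positive."""
    norms = np.linalg.norm(components, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    out = components / norms
    flips = skew(out, axis=1) < 0
    out[flips] *= -1.0
    return out


def _pam(dist: np.ndarray, k: int, max_iter: int = 100) -> np.ndarray:
    """Partitioning around medoids on a precomputed distance matrix.

    Greedy build initialization followed by Voronoi-style medoid updates;
    ties break toward the lower index, so the result is deterministic.
    Returns the medoid indices.
    """
    n = dist.shape[0]
    if k > n:
        raise ValidationError(f"cannot pick {k} medoids from {n} points")
    medoids = [int(np.argmin(dist.sum(axis=1)))]
    while len(medoids) < k:
        current = np.min(dist[:, medoids], axis=1)
        gains = np.sum(np.maximum(current[None, :] - dist, 0.0), axis=1)
        gains[medoids] = -np.inf
        medoids.append(int(np.argmax(gains)))
    medoids = np.array(sorted(medoids))
    for _ in range(max_iter):
        assign = np.argmin(dist[:, medoids], axis=1)
        new = medoids.copy()
        for ci in range(k):
            members = np.nonzero(assign == ci)[0]
            if len(members):
                sub = dist[np.ix_(members, members)]
                new[ci] = members[int(np.argmin(sub.sum(axis=1)))]
        new = np.array(sorted(new))
        if np.array_equal(new, medoids):
            break
        medoids = new
    return medoids


def derive_components(
    compendium: pd.DataFrame,
    n_components: int,
    n_runs: int = 20,
    seed: int = 0,
    balance_threshold: float = 0.05,
) -> ComponentMatrix:
    """Learn a component basis from a samples x genes compendium.

    Steps: (1) balance over-represented conditions by collapsing
    near-duplicate samples (hierarchical clustering, medoid
    representatives); (2) run FastICA ``n_runs`` times with different
    seeds; (3) pool all estimated components, unit-normalized and
    sign-oriented (positive skew), and cluster them into ``n_components``
    groups by partitioning around medoids on the distance
    ``1 - |Pearson r|`` (sign-flipped duplicates cluster together);
    (4) return the medoid of each cluster.
    """
    X = compendium.to_numpy(dtype=float)
    reps = _balance_samples(X, balance_threshold)
    X = X[reps, :]
    if len(reps) < X.shape[0] and len(reps) < compendium.shape[0]:
        logger.info("balancing kept %d of %d samples", len(reps), compendium.shape[0])
    if n_components > min(X.shape):
        raise ValidationError(
            f"n_components={n_components} exceeds the available rank {min(X.shape)}"
        )
    pool = []
    for run in range(n_runs):
        ica = FastICA(
            n_components=n_components,
            random_state=int(seed) + run,
            whiten="unit-variance",
            max_iter=300,
            tol=1e-3,
        )
        # genes as observations: sources come out as gene-loading vectors
        with warnings.catch_warnings():
            # single runs need not converge: the medoid aggregation over
            # runs is the estimator, and unconverged runs just add pool
            # members that fail to form tight clusters
            warnings.simplefilter("ignore", ConvergenceWarning)
            sources = ica.fit_transform(X.T)  # genes x components
        pool.append(_orient_and_normalize(sources.T))
    pooled = np.vstack(pool)
    if n_runs == 1:
        medoid_rows = pooled
    else:
        corr = np.corrcoef(pooled)
        dist = np.clip(1.0 - np.abs(corr), 0.0, 1.0)
        np.fill_diagonal(dist, 0.0)
        medoids = _pam(dist, n_components)
        medoid_rows = pooled[medoids]
    ids = [f"IC{i + 1:03d}" for i in range(medoid_rows.shape[0])]
    return ComponentMatrix(
        component_ids=ids,
        gene_ids=[str(g) for g in compendium.columns],
        loadings=medoid_rows,
    )


# ---------------------------------------------------------------------------
# modules
# ---------------------------------------------------------------------------

def ica_modules(components: ComponentMatrix, n_sd: float = 3.0) -> GeneSetCollection:
    """Extract one gene set per component: genes loading > mean + n_sd * SD.

    Positive direction only (components are sign-oriented so the heavy
    tail is positive).  Components yielding an empty set are dropped with
    a warning.
    """
    genes = np.asarray(components.gene_ids, dtype=object)
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    for cid, row in zip(components.component_ids, components.loadings):
        sd = row.std()
        if sd == 0:
            logger.warning("component %s has constant loadings; module dropped", cid)
            continue
        members = genes[row > row.mean() + n_sd * sd]
        if len(members) == 0:
            logger.warning("component %s yields an empty module; dropped", cid)
            continue
        sets[f"module_{cid}"] = (
            f"genes loading > mean + {n_sd:g} SD on {cid}",
            frozenset(str(g) for g in members),
        )
    return GeneSetCollection(sets=sets)


def module_meta_scores(profile: DEProfile, gene_sets: GeneSetCollection) -> DEProfile:
    """Fixed-effect meta-score of a profile over each gene set.

    Per set: inverse-variance weighted mean of member-gene scores,
    ``sum(x_g / v_g) / sum(1 / v_g)``, with meta-variance
    ``1 / sum(1 / v_g)`` -- the same estimator used for probe
    aggregation.  Sets with no member present in the profile are dropped.
    """
    if profile.variances is None:
        raise ValidationError("module_meta_scores requires per-gene variances")
    score = pd.Series(profile.scores, index=pd.Index(profile.feature_ids))
    var = pd.Series(profile.variances, index=score.index)
    rows = []
    grouping = {}
    for set_id, (_, members) in gene_sets:
        for g in members:
            if g in score.index:
                key = f"{set_id}\t{g}"
                rows.append((key, g))
                grouping[key] = set_id
    if not rows:
        raise ValidationError("no gene set overlaps the profile")
    keys = [k for k, _ in rows]
    genes = [g for _, g in rows]
    expanded = pd.DataFrame({"score": score.loc[genes].to_numpy()}, index=keys)
    expanded_var = pd.Series(var.loc[genes].to_numpy(), index=keys)
    agg, meta_var = fixed_effect_meta(expanded, expanded_var, pd.Series(grouping))
    return DEProfile(
        profile_id=profile.profile_id,
        space="module",
        feature_ids=np.asarray(agg.index, dtype=object),
        scores=agg["score"].to_numpy(),
        variances=meta_var.to_numpy(),
        comparison=profile.comparison,
        source_experiment=profile.source_experiment,
    )


def module_experiment(
    experiment: ExpressionExperiment, gene_sets: GeneSetCollection
) -> ExpressionExperiment:
    """Sample-level module scores (fixed-effect meta-estimate per set).

    Requires per-gene variances on the experiment (from probe
    aggregation); supports the moderated t-test in module space.
    """
    if experiment.feature_variances is None:
        raise ValidationError("module_experiment requires per-gene variances")
    values = experiment.values
    rows = []
    grouping = {}
    for set_id, (_, members) in gene_sets:
        for g in members:
            if g in values.index:
                key = f"{set_id}\t{g}"
                rows.append((key, g))
                grouping[key] = set_id
    if not rows:
        raise ValidationError("no gene set overlaps the experiment")
    keys = [k for k, _ in rows]
    genes = [g for _, g in rows]
    expanded = pd.DataFrame(values.loc[genes].to_numpy(), index=keys, columns=values.columns)
    expanded_var = pd.Series(
        experiment.feature_variances.loc[genes].to_numpy(), index=keys
    )
    agg, meta_var = fixed_effect_meta(expanded, expanded_var, pd.Series(grouping))
    return experiment.replace(values=agg, feature_variances=meta_var)


def module_profile(
    experiment: ExpressionExperiment,
    profile: DEProfile,
    gene_sets: GeneSetCollection,
) -> DEProfile:
    """Module-space profile with meta-scores and moderated-t p-values."""
    reduced = module_meta_scores(profile, gene_sets)
    mod_exp = module_experiment(experiment, gene_sets)
    group_a, group_b = profile.comparison
    test = moderated_t_pvalues(mod_exp, group_a, group_b)
    order = pd.Index(test.feature_ids).get_indexer(reduced.feature_ids)
    reduced.pvalues = test.pvalues_adjusted[order]
    return reduced
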