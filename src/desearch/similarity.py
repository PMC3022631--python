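"""Similarity between differential-expression profiles.

Six measures: {Pearson, Spearman} x {unweighted, inverse-variance,
p-weighted}.  The p-weighted correlation upweights features that are
significantly differentially expressed in *both* profiles:

    w_i = [-log(p_i1 * p_i2)]^(1/C)

with FDR-adjusted p-values, natural log, and scaling factor C (default 2).
Correlations use weighted centering; the per-feature contribution
decomposition splits the (signed) correlation into additive terms so the
genes driving a match can be inspected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from desearch.datamodel import DEProfile, ValidationError

#: Minimum shared-feature overlap per space before a comparison is refused.
MIN_OVERLAP = {"gene": 100, "component": 10, "module": 10}

Method = Literal["pearson", "spearman"]


@dataclass
class WeightScheme:
    """Feature-weighting scheme for profile correlations.

    ``p_value`` weights need p-vectors on both profiles; ``inverse_variance``
    weights each feature by 1 / (its score variance across the compendium),
    supplied via ``compendium_variances``.
    """

    kind: Literal["unweighted", "inverse_variance", "p_value"] = "p_value"
    C: float = 2.0
    compendium_variances: dict[str, float] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValidationError("scaling factor C must be positive")
        if self.kind == "inverse_variance" and self.compendium_variances is None:
            raise ValidationError("inverse_variance weighting requires compendium_variances")


def p_weights(p1: np.ndarray, p2: np.ndarray, C: float = 2.0) -> np.ndarray:
    """Significance weights ``[-ln(p1 * p2)]^(1/C)`` per feature.

    Zero when both p-values are 1 (no evidence in either profile);
    monotone non-increasing in each p-value.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    if C <= 0:
        raise ValidationError("scaling factor C must be positive")
    for p in (p1, p2):
        if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
            raise ValidationError("p-values must lie in (0, 1]")
    return (-(np.log(p1) + np.log(p2))) ** (1.0 / C)


def _weighted_pearson(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> tuple[float, np.ndarray]:
    sw = w.sum()
    if sw <= 0:
        raise ValidationError("weights sum to zero; correlation undefined")
    xm = x - (w @ x) / sw
    ym = y - (w @ y) / sw
    sxx = w @ (xm * xm)
    syy = w @ (ym * ym)
    denom = np.sqrt(sxx * syy)
    if denom == 0 or not np.isfinite(denom):
        raise ValidationError("zero weighted variance; correlation undefined")
    contrib = w * xm * ym / denom
    return float(contrib.sum()), contrib


def weighted_correlation(
    x: np.ndarray, y: np.ndarray, w: np.ndarray, method: Method = "pearson"
) -> float:
    """Weighted Pearson or Spearman correlation in [-1, 1].

    Weighted means are used for centering; Spearman replaces values with
    average-tie ranks (computed unweighted) before the weighted Pearson
    formula is applied.  Uniform weights recover the classical
    coefficients.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.asarray(w, dtype=float)
    if not (len(x) == len(y) == len(w)):
        raise ValidationError("x, y, w must be aligned and equally long")
    if np.any(w < 0):
        raise ValidationError("weights must be nonnegative")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y, w = x[ok], y[ok], w[ok]
    if len(x) < 3:
        raise ValidationError(f"need at least 3 complete pairs, got {len(x)}")
    if method == "spearman":
        x = rankdata(x, method="average")
        y = rankdata(y, method="average")
    elif method != "pearson":
        raise ValidationError(f"unknown correlation method {method!r}")
    r, _ = _weighted_pearson(x, y, w)
    return r


def similarity_score(
    profile_a: DEProfile,
    profile_b: DEProfile,
    scheme: WeightScheme | None = None,
    method: Method = "pearson",
    absolute: bool = False,
    min_overlap: int | None = None,
) -> tuple[float, pd.Series, pd.Series]:
    """Similarity between two profiles on their shared features.

    Returns ``(score, weights, contributions)`` where the contributions
    are indexed by feature, remain signed even in absolute mode, and sum
    to the signed correlation.  ``absolute=True`` returns |r|, used when
    the direction of the underlying comparisons is arbitrary.
    """
    scheme = scheme or WeightScheme()
    if profile_a.space != profile_b.space:
        raise ValidationError(
            f"profiles live in different spaces: {profile_a.space} vs {profile_b.space}"
        )
    idx_a = pd.Index(profile_a.feature_ids)
    idx_b = pd.Index(profile_b.feature_ids)
    shared = idx_a.intersection(idx_b)
    floor = MIN_OVERLAP.get(profile_a.space, 10) if min_overlap is None else min_overlap
    if len(shared) < floor:
        raise ValidationError(
            f"only {len(shared)} shared features between {profile_a.profile_id!r} "
            f"and {profile_b.profile_id!r}; need at least {floor}"
        )
    pos_a = idx_a.get_indexer(shared)
    pos_b = idx_b.get_indexer(shared)
    x = profile_a.scores[pos_a]
    y = profile_b.scores[pos_b]

    if scheme.kind == "unweighted":
        w = np.ones(len(shared))
    elif scheme.kind == "p_value":
        if profile_a.pvalues is None or profile_b.pvalues is None:
            raise ValidationError("p_value weighting requires p-values on both profiles")
        w = p_weights(profile_a.pvalues[pos_a], profile_b.pvalues[pos_b], scheme.C)
    elif scheme.kind == "inverse_variance":
        v = np.array([scheme.compendium_variances.get(f, np.nan) for f in shared])
        if np.any(~np.isfinite(v) | (v <= 0)):
            bad = int(np.sum(~np.isfinite(v) | (v <= 0)))
            raise ValidationError(
                f"{bad} shared features lack a positive compendium variance"
            )
        w = 1.0 / v
    else:
        raise ValidationError(f"unknown weighting scheme {scheme.kind!r}")

    ok = np.isfinite(x) & np.isfinite(y)
    x, y, w = x[ok], y[ok], w[ok]
    kept = shared[ok]
    if len(x) < 3:
        raise ValidationError("fewer than 3 complete shared features")
    if method == "spearman":
        xr = rankdata(x, method="average")
        yr = rankdata(y, method="average")
    elif method == "pearson":
        xr, yr = x, y
    else:
        raise ValidationError(f"unknown correlation method {method!r}")
    r, contrib = _weighted_pearson(xr, yr, w)
    score = abs(r) if absolute else r
    return score, pd.Series(w, index=kept), pd.Series(contrib, index=kept)
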