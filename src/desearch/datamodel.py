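"""Core domain types shared across the pipeline.

All containers are thin dataclasses around pandas/numpy objects and
validate their structural invariants on construction.  Expression values
are stored features x samples; component loadings components x genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
import pandas as pd

Space = Literal["gene", "component", "module"]

CONTRIBUTION_TOL = 1e-8


class ValidationError(ValueError):
    """A domain-type invariant was violated."""


def _check_unique(ids, what: str) -> None:
    ids = pd.Index(ids)
    if ids.has_duplicates:
        dups = sorted(set(ids[ids.duplicated()]))
        raise ValidationError(f"duplicate {what}: {dups}")


@dataclass
class ExpressionExperiment:
    """One expression experiment: a value matrix plus sample grouping.

    Parameters
    ----------
    experiment_id
        Free-text identifier (e.g. a GEO accession).
    values
        Expression intensities, features (probes or genes) x samples.
    groups
        Mapping ``sample_id -> group label`` for the experimental factor.
    factor
        Name of the varying experimental variable (e.g. ``"disease state"``).
    species
        Source organism; ``"human"`` profiles skip homolog mapping.
    is_log_scale
        ``True`` once values are known to be log2 intensities; ``None``
        until :func:`desearch.io.ensure_log_scale` has decided.
    feature_variances
        Optional per-feature variance attached by probe aggregation.
    """

    experiment_id: str
    values: pd.DataFrame
    groups: dict[str, str]
    factor: str = "unspecified"
    species: str = "human"
    is_log_scale: bool | None = None
    feature_variances: pd.Series | None = None

    def __post_init__(self) -> None:
        _check_unique(self.values.index, "feature ids")
        _check_unique(self.values.columns, "sample ids")
        missing = [s for s in self.values.columns if s not in self.groups]
        if missing:
            raise ValidationError(
                f"samples without a group label in {self.experiment_id!r}: {missing}"
            )
        if self.feature_variances is not None and not self.feature_variances.index.equals(
            self.values.index
        ):
            raise ValidationError("feature_variances index must match values index")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def group_labels(self) -> list[str]:
        return sorted(set(self.groups[s] for s in self.values.columns))

    def samples_in_group(self, label: str) -> list[str]:
        cols = [s for s in self.values.columns if self.groups[s] == label]
        if not cols:
            raise ValidationError(
                f"unknown group {label!r} in {self.experiment_id!r}; "
                f"known groups: {self.group_labels}"
            )
        return cols

    def replace(self, **kwargs) -> "ExpressionExperiment":
        return replace(self, **kwargs)


@dataclass
class DEProfile:
    """A differential-expression profile: one score per feature.

    ``scores`` is the gene-space vector X (or its projection A in
    component space).  ``comparison`` records the ordered group labels:
    scores are first-group minus second-group, so swapping the pair
    negates the profile.
    """

    profile_id: str
    space: Space
    feature_ids: np.ndarray
    scores: np.ndarray
    pvalues: np.ndarray | None = None
    variances: np.ndarray | None = None
    comparison: tuple[str, str] = ("", "")
    source_experiment: str = ""

    def __post_init__(self) -> None:
        self.feature_ids = np.asarray(self.feature_ids, dtype=object)
        self.scores = np.asarray(self.scores, dtype=float)
        _check_unique(self.feature_ids, "profile feature ids")
        n = len(self.feature_ids)
        if self.scores.shape != (n,):
            raise ValidationError("scores length must match feature_ids")
        if self.pvalues is not None:
            self.pvalues = np.asarray(self.pvalues, dtype=float)
            if self.pvalues.shape != (n,):
                raise ValidationError("pvalues length must match feature_ids")
            if np.any((self.pvalues <= 0) | (self.pvalues > 1)):
                raise ValidationError("pvalues must lie in (0, 1]")
        if self.variances is not None:
            self.variances = np.asarray(self.variances, dtype=float)
            if self.variances.shape != (n,):
                raise ValidationError("variances length must match feature_ids")
            if np.any(self.variances < 0):
                raise ValidationError("variances must be nonnegative")

    def __len__(self) -> int:
        return len(self.feature_ids)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"score": self.scores}, index=pd.Index(self.feature_ids, name="feature_id"))
        if self.pvalues is not None:
            df["pvalue"] = self.pvalues
        if self.variances is not None:
            df["variance"] = self.variances
        return df

    def subset(self, feature_ids: np.ndarray, profile_id: str | None = None) -> "DEProfile":
        """Restrict to ``feature_ids`` (must be a subset), preserving the given order."""
        pos = pd.Index(self.feature_ids).get_indexer(feature_ids)
        if np.any(pos < 0):
            raise ValidationError("subset requested features absent from profile")
        return DEProfile(
            profile_id=profile_id or self.profile_id,
            space=self.space,
            feature_ids=self.feature_ids[pos],
            scores=self.scores[pos],
            pvalues=None if self.pvalues is None else self.pvalues[pos],
            variances=None if self.variances is None else self.variances[pos],
            comparison=self.comparison,
            source_experiment=self.source_experiment,
        )


@dataclass
class ComponentMatrix:
    """Linear gene-loading basis S (components x genes) for projection."""

    component_ids: list[str]
    gene_ids: list[str]
    loadings: np.ndarray

    def __post_init__(self) -> None:
        _check_unique(self.component_ids, "component ids")
        _check_unique(self.gene_ids, "gene ids")
        self.loadings = np.asarray(self.loadings, dtype=float)
        if self.loadings.shape != (len(self.component_ids), len(self.gene_ids)):
            raise ValidationError(
                f"loadings shape {self.loadings.shape} does not match "
                f"{len(self.component_ids)} components x {len(self.gene_ids)} genes"
            )
        zero = ~np.any(self.loadings != 0, axis=1)
        if np.any(zero):
            bad = [self.component_ids[i] for i in np.nonzero(zero)[0]]
            raise ValidationError(f"all-zero component rows: {bad}")

    @property
    def n_components(self) -> int:
        return len(self.component_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.loadings,
            index=pd.Index(self.component_ids, name="component_id"),
            columns=self.gene_ids,
        )


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT-style): set_id -> (description, member genes)."""

    sets: dict[str, tuple[str, frozenset[str]]]

    def __post_init__(self) -> None:
        for set_id, (_, members) in self.sets.items():
            if not members:
                raise ValidationError(f"gene set {set_id!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())

    def members(self, set_id: str) -> frozenset[str]:
        return self.sets[set_id][1]


@dataclass
class HomologMap:
    """Cross-species gene mapping, Homologene-style.

    ``entries`` maps ``(species, source_gene_id) -> human_gene_id``;
    ``one_to_one`` flags whether the pairing is bijective within its
    species.  Only one-to-one entries are used for profile mapping.
    """

    entries: dict[tuple[str, str], str]
    one_to_one: dict[tuple[str, str], bool]

    def __post_init__(self) -> None:
        for key in self.entries:
            if key not in self.one_to_one:
                raise ValidationError(f"entry {key} lacks a one_to_one flag")
        # one-to-one entries must form a bijection per species
        by_species: dict[str, dict[str, str]] = {}
        for (species, src), human in self.entries.items():
            if self.one_to_one[(species, src)]:
                by_species.setdefault(species, {})[src] = human
        for species, mapping in by_species.items():
            if len(set(mapping.values())) != len(mapping):
                raise ValidationError(
                    f"one-to-one entries for {species!r} are not a bijection"
                )

    def lookup_one_to_one(self, species: str, gene_id: str) -> str | None:
        key = (species, gene_id)
        if key in self.entries and self.one_to_one[key]:
            return self.entries[key]
        return None


@dataclass
class SearchResult:
    """One ranked hit: similarity of a library profile to the query."""

    query_id: str
    target_id: str
    score: float
    qvalue: float
    contributions: dict[str, float] | None = None
    signed_score: float | None = None

    def __post_init__(self) -> None:
        if self.contributions is not None:
            total = float(sum(self.contributions.values()))
            signed = self.score if self.signed_score is None else self.signed_score
            if abs(total - signed) > CONTRIBUTION_TOL:
                raise ValidationError(
                    f"contributions sum {total:.10g} != signed score {signed:.10g}"
                )


@dataclass
class NullDistribution:
    """Background similarity scores from random profile pairs."""

    scores: np.ndarray
    n_pairs: int
    seed: int
    mode: Literal["signed", "absolute"] = "absolute"
    pair_ids: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.scores) != self.n_pairs:
            raise ValidationError("length of scores must equal n_pairs")
        if self.mode == "absolute" and np.any(self.scores < 0):
            raise ValidationError("absolute-mode null contains negative scores")
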