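"""Index a library of DE profiles and search it with empirical significance.

The library is held in a common feature space (gene, or component when a
basis is supplied).  Significance of a similarity score is assessed
against a background of random profile pairs: the empirical q-value is
the (add-one smoothed) fraction of background scores at least as large.
Because random pairs can include genuinely related profiles (e.g. two
comparisons from the same dataset), these q-values are conservative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from desearch.datamodel import (
    ComponentMatrix,
    DEProfile,
    NullDistribution,
    SearchResult,
    ValidationError,
)
from desearch.dimreduce import project_ica
from desearch.profiles import MappingError
from desearch.similarity import Method, WeightScheme, similarity_score

logger = logging.getLogger(__name__)


@dataclass
class ProfileIndex:
    """Searchable library of DE profiles in a single feature space."""

    profiles: dict[str, DEProfile]
    space: str = "gene"
    exclusions: list[tuple[str, str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.profiles)

    @property
    def profile_ids(self) -> list[str]:
        return sorted(self.profiles)

    def compendium_variances(self) -> dict[str, float]:
        """Per-feature variance of scores across the indexed library.

        Used by the inverse-variance weighting scheme when no external
        variance table is supplied.
        """
        frames = {pid: p.to_frame()["score"] for pid, p in self.profiles.items()}
        mat = pd.DataFrame(frames)
        var = mat.var(axis=1, ddof=1)
        return {f: float(v) for f, v in var.items() if np.isfinite(v) and v > 0}


def build_index(
    profiles: list[DEProfile],
    components: ComponentMatrix | None = None,
    experiments: dict[str, "ExpressionExperiment"] | None = None,
    homolog_map=None,
    species: dict[str, str] | None = None,
) -> ProfileIndex:
    """Index a library of gene-space profiles, optionally reducing to components.

    Profiles that fail homolog mapping (when ``homolog_map`` and a
    ``profile_id -> species`` table are given) or projection are recorded
    in the exclusion report rather than aborting the build.  When
    ``experiments`` maps source-experiment ids to gene-level experiments,
    component-space p-values are computed by testing the comparison
    groups on component-projected samples; otherwise reduced profiles
    carry no p-values.
    """
    if not profiles:
        raise ValidationError("cannot index an empty profile library")
    indexed: dict[str, DEProfile] = {}
    exclusions: list[tuple[str, str]] = []
    for profile in profiles:
        try:
            if homolog_map is not None and species is not None:
                from desearch.profiles import map_to_human

                profile = map_to_human(
                    profile, homolog_map, species.get(profile.profile_id, "human")
                )
            if components is not None:
                if experiments and profile.source_experiment in experiments:
                    from desearch.dimreduce import component_profile

                    reduced = component_profile(
                        experiments[profile.source_experiment], profile, components
                    )
                else:
                    reduced = project_ica(profile, components)
                indexed[profile.profile_id] = reduced
            else:
                indexed[profile.profile_id] = profile
        except (MappingError, ValidationError) as exc:
            exclusions.append((profile.profile_id, str(exc)))
            logger.warning("excluding %s: %s", profile.profile_id, exc)
    if not indexed:
        raise ValidationError("every profile was excluded; empty index")
    space = "component" if components is not None else next(iter(indexed.values())).space
    return ProfileIndex(profiles=indexed, space=space, exclusions=exclusions)


def _sample_pairs(n: int, n_pairs: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform sample of distinct unordered index pairs, without replacement."""
    total = n * (n - 1) // 2
    if n_pairs >= total:
        return np.array([(i, j) for i in range(n) for j in range(i + 1, n)])
    chosen: set[tuple[int, int]] = set()
    while len(chosen) < n_pairs:
        need = n_pairs - len(chosen)
        i = rng.integers(0, n, size=2 * need + 8)
        j = rng.integers(0, n, size=2 * need + 8)
        for a, b in zip(i, j):
            if a == b:
                continue
            pair = (min(a, b), max(a, b))
            if pair not in chosen:
                chosen.add(pair)
                if len(chosen) == n_pairs:
                    break
    return np.array(sorted(chosen))


def sample_null(
    index: ProfileIndex,
    n_pairs: int = 10_000,
    seed: int = 0,
    scheme: WeightScheme | None = None,
    method: Method = "pearson",
    absolute: bool = True,
) -> NullDistribution:
    """Background similarity distribution from random profile pairs.

    Pairs are sampled uniformly without replacement from all distinct
    unordered pairs (self-pairs excluded; pairs from the same source
    experiment allowed, which only makes the q-values conservative).  If
    fewer than ``n_pairs`` distinct pairs exist, all of them are used and
    the shortfall is logged.
    """
    ids = index.profile_ids
    if len(ids) < 2:
        raise ValidationError("need at least 2 indexed profiles to sample a null")
    total = len(ids) * (len(ids) - 1) // 2
    if total < n_pairs:
        logger.warning(
            "only %d distinct pairs available (requested %d); using all", total, n_pairs
        )
    rng = np.random.default_rng(seed)
    pairs = _sample_pairs(len(ids), n_pairs, rng)
    scores = np.empty(len(pairs))
    pair_ids = []
    for k, (i, j) in enumerate(pairs):
        s, _, _ = similarity_score(
            index.profiles[ids[i]], index.profiles[ids[j]], scheme, method, absolute
        )
        scores[k] = s
        pair_ids.append((ids[i], ids[j]))
    return NullDistribution(
        scores=scores,
        n_pairs=len(pairs),
        seed=seed,
        mode="absolute" if absolute else "signed",
        pair_ids=pair_ids,
    )


def empirical_q(score: float, null: NullDistribution, absolute: bool | None = None) -> float:
    """Empirical q-value: smoothed fraction of background scores >= score.

    ``q = (#{null >= score} + 1) / (n_pairs + 1)``; the add-one keeps q
    strictly positive even above the background maximum.
    """
    if absolute is not None:
        mode = "absolute" if absolute else "signed"
        if mode != null.mode:
            raise ValidationError(
                f"score mode {mode!r} does not match null mode {null.mode!r}"
            )
    exceed = int(np.sum(null.scores >= score))
    return (exceed + 1) / (null.n_pairs + 1)


def query(
    index: ProfileIndex,
    query_profile: DEProfile,
    null: NullDistribution | None = None,
    top_k: int = 15,
    scheme: WeightScheme | None = None,
    method: Method = "pearson",
    absolute: bool = True,
) -> list[SearchResult]:
    """Rank the library against a query profile.

    All library profiles are scored; results are sorted by score
    descending with ties broken by target id.  The top ``top_k`` carry
    empirical q-values (when a null is given) and per-feature
    contributions.  Library profiles sharing too few features with the
    query are skipped with a warning.
    """
    if query_profile.space != index.space:
        raise ValidationError(
            f"query lives in {query_profile.space!r} space but the index is "
            f"{index.space!r}; project it first"
        )
    scored: list[tuple[float, str, float, pd.Series]] = []
    for target_id in index.profile_ids:
        try:
            s, _, contrib = similarity_score(
                index.profiles[target_id], query_profile, scheme, method, absolute
            )
        except ValidationError as exc:
            logger.warning("skipping %s: %s", target_id, exc)
            continue
        signed = float(contrib.sum())
        scored.append((s, target_id, signed, contrib))
    if not scored:
        raise ValidationError("query failed against every indexed profile")
    scored.sort(key=lambda t: (-t[0], t[1]))
    results = []
    for s, target_id, signed, contrib in scored[:top_k]:
        results.append(
            SearchResult(
                query_id=query_profile.profile_id,
                target_id=target_id,
                score=s,
                qvalue=empirical_q(s, null) if null is not None else float("nan"),
                contributions={str(f): float(c) for f, c in contrib.items()},
                signed_score=signed,
            )
        )
    return results


def build_network(
    index: ProfileIndex,
    null: NullDistribution,
    q_threshold: float = 0.001,
    scheme: WeightScheme | None = None,
    method: Method = "pearson",
    absolute: bool = True,
    metadata: dict[str, dict] | None = None,
) -> tuple[pd.DataFrame, nx.Graph]:
    """Similarity network: edges between profile pairs with q < threshold.

    Returns the edge table (profile_a, profile_b, score, q) and an
    undirected graph whose nodes carry any supplied metadata (source
    experiment, factor, condition) for downstream coloring.  All nodes
    appear in the graph even when no edge passes the threshold.
    """
    ids = index.profile_ids
    graph = nx.Graph()
    for pid in ids:
        attrs = dict(metadata.get(pid, {})) if metadata else {}
        attrs.setdefault("source_experiment", index.profiles[pid].source_experiment)
        graph.add_node(pid, **attrs)
    edges = []
    for a in range(len(ids)):
        for b in range(a + 1, len(ids)):
            try:
                s, _, _ = similarity_score(
                    index.profiles[ids[a]], index.profiles[ids[b]], scheme, method, absolute
                )
            except ValidationError:
                continue
            q = empirical_q(s, null)
            if q < q_threshold:
                edges.append((ids[a], ids[b], s, q))
                graph.add_edge(ids[a], ids[b], score=s, q=q)
    edge_df = pd.DataFrame(edges, columns=["profile_a", "profile_b", "score", "q"])
    return edge_df, graph
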