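"""Simulation studies exercising the full pipeline at desk scale.

Each function runs one self-contained study on generated data and
returns summary numbers: retrieval AUC in gene and component space,
null-compendium calibration, similarity-network purity, permutation-null
precision, and ICA source recovery.  The study designs (compendium
sizes, replicate counts) are fixed here so the test suite and the
reproduction script measure the same quantities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from desearch.datamodel import ComponentMatrix
from desearch.dimreduce import component_profile, derive_components
from desearch.evaluation import loocv_retrieval, roc_auc
from desearch.search import build_index, build_network, empirical_q, sample_null
from desearch.similarity import WeightScheme
from desearch.simulate import (
    SimulationConfig,
    compendium_profiles,
    gene_level_experiments,
    pooled_gene_matrix,
    simulate_compendium,
    simulate_component_compendium,
)

#: p-weighted Pearson is the reference search configuration
PW = WeightScheme(kind="p_value")


def heldout_component_basis(
    program_seed: int, seed: int, n_components: int = 50, n_runs: int = 20
) -> ComponentMatrix:
    """Derive a component basis from a held-out compendium.

    The held-out data shares the biology (``program_seed``) but none of
    the experiments with the compendia it will be applied to -- new
    platforms, samples and noise -- mirroring a basis learned once on a
    large reference collection and reused for new studies.  Platform
    dropout is disabled (single-platform reference) so the gene
    intersection across experiments stays complete.
    """
    held = simulate_compendium(
        SimulationConfig(
            experiments_per_condition=2,
            platform_dropout=0.0,
            species_mix=0.0,
            seed=seed,
            program_seed=program_seed,
        )
    )
    return derive_components(pooled_gene_matrix(held), n_components, n_runs=n_runs, seed=seed)


@dataclass
class RetrievalStudy:
    gene_aucs: list[float]
    component_aucs: list[float]
    n_seeds: int
    n_profiles: int


def retrieval_study(
    n_seeds: int = 20,
    effect_size: float = 1.0,
    program_seed: int = 4242,
    basis: ComponentMatrix | None = None,
    seed_offset: int = 0,
) -> RetrievalStudy:
    """LOOCV retrieval over replicate compendia (default study conditions).

    Per replicate seed: simulate the default compendium (3 conditions x 8
    experiments, 5000 genes, 200-gene programs, effect 1.0 log2 units,
    noise SD 1.0, batch SD 0.25, 20% platform dropout), build p-weighted
    profiles, and measure mean LOOCV AUC with signed p-weighted Pearson
    in gene space -- and, when a basis is supplied, in component space.
    """
    gene_aucs, comp_aucs = [], []
    n_profiles = 0
    for s in range(n_seeds):
        sim = simulate_compendium(
            SimulationConfig(
                effect_size=effect_size, seed=seed_offset + s, program_seed=program_seed
            )
        )
        profiles, labels = compendium_profiles(sim)
        n_profiles = len(profiles)
        ranked = loocv_retrieval(profiles, labels, PW, "pearson")
        gene_aucs.append(roc_auc(ranked).mean_auc)
        if basis is not None:
            gexps = gene_level_experiments(sim)
            cprofs = [component_profile(gexps[p.source_experiment], p, basis) for p in profiles]
            ranked_c = loocv_retrieval(cprofs, labels, PW, "pearson")
            comp_aucs.append(roc_auc(ranked_c).mean_auc)
    return RetrievalStudy(gene_aucs, comp_aucs, n_seeds, n_profiles)


def null_calibration_study(seed: int = 0, n_pairs: int = 10_000) -> tuple[float, int]:
    """Empirical-q calibration on a fully null 50-profile library.

    Fifty independent noise profiles (effect size 0); the background is
    sampled from the same library, so every pair is exchangeable with
    the null and the fraction at q < 0.05 should sit near 0.05.
    Returns (fraction of pairs with q < 0.05, background size used).
    """
    sim = simulate_compendium(
        SimulationConfig(
            n_conditions=10,
            experiments_per_condition=5,
            n_genes=2000,
            program_size=100,
            effect_size=0.0,
            seed=seed,
        )
    )
    profiles, _ = compendium_profiles(sim)
    index = build_index(profiles)
    null = sample_null(index, n_pairs=n_pairs, seed=seed, scheme=PW, absolute=True)
    qs = np.array([empirical_q(s, null) for s in null.scores])
    return float(np.mean(qs < 0.05)), null.n_pairs


def network_study(n_seeds: int = 20, program_seed: int = 9090, seed_offset: int = 0) -> float:
    """Within-cluster purity of the q < 0.001 similarity network.

    Per seed: a planted-cluster library (3 conditions x 20 experiments,
    2000 genes) plus a 50-profile noise library supplying the background
    of unrelated comparisons.  Edges join pairs whose absolute p-weighted
    correlation exceeds the q < 0.001 background quantile; returns the
    pooled fraction of edges connecting profiles of the same condition.
    """
    within = total = 0
    for s in range(n_seeds):
        sim = simulate_compendium(
            SimulationConfig(
                n_conditions=3,
                experiments_per_condition=20,
                n_genes=2000,
                program_size=100,
                seed=seed_offset + s,
                program_seed=program_seed,
            )
        )
        profiles, labels = compendium_profiles(sim)
        index = build_index(profiles)
        bg_sim = simulate_compendium(
            SimulationConfig(
                n_conditions=10,
                experiments_per_condition=5,
                n_genes=2000,
                program_size=100,
                effect_size=0.0,
                seed=10_000 + seed_offset + s,
            )
        )
        bg_profiles, _ = compendium_profiles(bg_sim)
        bg_index = build_index(bg_profiles)
        null = sample_null(bg_index, n_pairs=10_000, seed=s, scheme=PW, absolute=True)
        edges, _ = build_network(index, null, q_threshold=0.001, scheme=PW, absolute=True)
        for row in edges.itertuples(index=False):
            total += 1
            if labels[row.profile_a] == labels[row.profile_b]:
                within += 1
    return within / total if total else float("nan")


def precision_null_study(
    n_permutations: int = 10_000, seed: int = 0
) -> tuple[dict[str, float], float, float, float]:
    """Permutation-null precision-at-4 against the hypergeometric expectation.

    A 3 x 8 labeled compendium (1000 genes for speed) gives equally
    sized classes, so the null mean per query is (m-1)/(n-1) = 7/23.
    Returns (per-query null means, analytic expectation, Monte-Carlo SE,
    mean observed precision at 4).
    """
    from desearch.evaluation import permutation_null_precision

    sim = simulate_compendium(
        SimulationConfig(n_genes=1000, program_size=100, seed=seed)
    )
    profiles, labels = compendium_profiles(sim)
    ranked = loocv_retrieval(profiles, labels, PW, "pearson")
    null = permutation_null_precision(ranked, labels, k=4, n_permutations=n_permutations, seed=seed)
    n = len(profiles)
    m = n // 3
    expected = (m - 1) / (n - 1)
    mc_se = float(np.sqrt(expected * (1 - expected) / 4 / n_permutations))
    observed_mean = float(np.mean(list(null.observed.values())))
    return null.per_query_mean, expected, mc_se, observed_mean


def ica_recovery_study(n_seeds: int = 5, seed_offset: int = 0) -> list[float]:
    """Worst-case |r| between planted sparse sources and derived components.

    200 samples x 1000 genes mixed from 10 sparse sources at SNR 10;
    returns, per seed, the minimum over sources of the best absolute
    correlation achieved by any derived component.
    """
    mins = []
    for s in range(n_seeds):
        X, _, sources = simulate_component_compendium(
            200, 1000, 10, sparsity=0.05, snr=10.0, seed=seed_offset + s
        )
        basis = derive_components(X, 10, n_runs=5, seed=seed_offset + s)
        k = sources.shape[0]
        corr = np.abs(np.corrcoef(np.vstack([basis.loadings, sources]))[:k, k:])
        mins.append(float(corr.max(axis=0).min()))
    return mins
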