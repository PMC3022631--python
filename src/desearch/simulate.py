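"""Seeded simulation of multi-experiment expression compendia.

Emulates the structure of a curated disease compendium: several
conditions (diseases), each measured by multiple experiments on distinct
simulated platforms (different probe sets and probe-per-gene
multiplicities, a fraction of genes absent per platform), each with
case/control sample groups.  Each condition plants a fixed signed
differential program on a subset of genes; experiments add independent
per-sample noise and a per-experiment gene-wise batch shift.  A fraction
of experiments can be labeled as a non-human species with a generated
one-to-one homolog map, exercising the cross-species mapping path.

All values are generated directly on the log2 scale, with a baseline
around 7 log2 units -- typical of normalized microarray intensities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from desearch.datamodel import (
    DEProfile,
    ExpressionExperiment,
    HomologMap,
    ValidationError,
)
from desearch.profiles import aggregate_probes_fixed_effects, build_profile

#: probe-specific additive offset SD and probe-level measurement noise SD
PROBE_OFFSET_SD = 0.3
PROBE_NOISE_SD = 0.2

#: fraction of homolog-map entries flagged as not one-to-one
NON_ONE_TO_ONE_FRACTION = 0.05


@dataclass
class SimulationConfig:
    """Generator settings; defaults emulate a small disease compendium."""

    n_conditions: int = 3
    experiments_per_condition: int = 8
    n_genes: int = 5000
    probes_per_gene: tuple[int, int] = (1, 3)  # inclusive uniform range
    samples_per_group: int = 10
    program_size: int = 200
    effect_size: float = 1.0  # log2 units
    noise_sd: float = 1.0
    batch_sd: float = 0.25
    platform_dropout: float = 0.2
    species_mix: float = 0.25  # fraction of experiments labeled "mouse"
    seed: int = 0
    #: seed for the biology (baseline expression and condition programs);
    #: fix it across compendia to simulate new experiments measuring the
    #: same underlying transcriptional programs.  None: derived from seed.
    program_seed: int | None = None

    def __post_init__(self) -> None:
        if self.program_size > self.n_genes:
            raise ValidationError("program_size cannot exceed n_genes")
        for name in ("n_conditions", "experiments_per_condition", "n_genes", "samples_per_group"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be >= 1")
        if not (0 <= self.platform_dropout < 1):
            raise ValidationError("platform_dropout must lie in [0, 1)")
        if self.noise_sd <= 0 or self.batch_sd < 0:
            raise ValidationError("noise_sd must be positive and batch_sd nonnegative")


@dataclass
class CompendiumTruth:
    """Ground truth of a simulated compendium."""

    condition_of: dict[str, str]  # experiment_id -> condition label
    programs: dict[str, dict[str, int]]  # condition -> gene -> sign (+1/-1)
    config: SimulationConfig = field(repr=False, default=None)


@dataclass
class SimulatedCompendium:
    experiments: list[ExpressionExperiment]
    probe_maps: dict[str, dict[str, str]]
    homolog_map: HomologMap
    truth: CompendiumTruth


def simulate_compendium(config: SimulationConfig) -> SimulatedCompendium:
    """Generate a labeled multi-experiment compendium with planted programs.

    Per condition, ``program_size`` genes receive a fixed sign; case
    samples of every experiment of that condition shift by
    ``effect_size * sign`` on those genes.  Programs are disjoint across
    conditions when the gene pool allows, mirroring diseases with
    distinct transcriptional signatures.
    """
    cfg = config
    bio_seed = cfg.program_seed if cfg.program_seed is not None else cfg.seed
    # separate streams: the biology (baseline, programs, homologs) can be
    # held fixed while experiments, platforms and noise are redrawn
    rng_bio = np.random.default_rng(np.random.SeedSequence([int(bio_seed), 17]))
    rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), 29]))
    genes = np.array([f"G{i:05d}" for i in range(cfg.n_genes)], dtype=object)
    baseline = rng_bio.normal(7.0, 1.0, size=cfg.n_genes)

    conditions = [f"condition{c + 1}" for c in range(cfg.n_conditions)]
    programs: dict[str, dict[str, int]] = {}
    if cfg.program_size * cfg.n_conditions <= cfg.n_genes:
        perm = rng_bio.permutation(cfg.n_genes)
        blocks = [
            perm[c * cfg.program_size : (c + 1) * cfg.program_size]
            for c in range(cfg.n_conditions)
        ]
    else:
        blocks = [
            rng_bio.choice(cfg.n_genes, size=cfg.program_size, replace=False)
            for _ in range(cfg.n_conditions)
        ]
    for cond, block in zip(conditions, blocks):
        signs = rng_bio.choice([-1, 1], size=cfg.program_size)
        programs[cond] = {str(genes[g]): int(s) for g, s in zip(block, signs)}

    # mouse homologs: prefixed ids, a fixed random subset not one-to-one
    mouse_ids = np.array([f"Mm_{g}" for g in genes], dtype=object)
    non_oto = rng_bio.random(cfg.n_genes) < NON_ONE_TO_ONE_FRACTION
    entries = {("mouse", str(m)): str(g) for m, g in zip(mouse_ids, genes)}
    flags = {("mouse", str(m)): bool(not bad) for m, bad in zip(mouse_ids, non_oto)}
    homolog_map = HomologMap(entries=entries, one_to_one=flags)

    experiments = []
    probe_maps: dict[str, dict[str, str]] = {}
    condition_of: dict[str, str] = {}
    n_per_group = cfg.samples_per_group
    exp_counter = 0
    for cond in conditions:
        prog_idx = np.array(
            [np.nonzero(genes == g)[0][0] for g in programs[cond]], dtype=int
        )
        prog_signs = np.array([programs[cond][str(genes[i])] for i in prog_idx])
        for _ in range(cfg.experiments_per_condition):
            exp_counter += 1
            exp_id = f"exp{exp_counter:03d}"
            species = "mouse" if rng.random() < cfg.species_mix else "human"
            # platform: which genes are measured, and by how many probes
            present = rng.random(cfg.n_genes) >= cfg.platform_dropout
            present_idx = np.nonzero(present)[0]
            multiplicity = rng.integers(
                cfg.probes_per_gene[0], cfg.probes_per_gene[1] + 1, size=len(present_idx)
            )
            batch = rng.normal(0.0, cfg.batch_sd, size=cfg.n_genes)
            n_samples = 2 * n_per_group
            gene_vals = (
                baseline[present_idx, None]
                + batch[present_idx, None]
                + rng.normal(0.0, cfg.noise_sd, size=(len(present_idx), n_samples))
            )
            # case samples (second half) shift on the condition program
            effect = np.zeros(cfg.n_genes)
            effect[prog_idx] = cfg.effect_size * prog_signs
            gene_vals[:, n_per_group:] += effect[present_idx, None]

            probe_rows = np.repeat(np.arange(len(present_idx)), multiplicity)
            n_probes = len(probe_rows)
            probe_offsets = rng.normal(0.0, PROBE_OFFSET_SD, size=n_probes)
            probe_vals = (
                gene_vals[probe_rows, :]
                + probe_offsets[:, None]
                + rng.normal(0.0, PROBE_NOISE_SD, size=(n_probes, n_samples))
            )
            probe_ids = [f"{exp_id}_probe{i:05d}" for i in range(n_probes)]
            gene_names = genes if species == "human" else mouse_ids
            probe_map = {
                pid: str(gene_names[present_idx[row]])
                for pid, row in zip(probe_ids, probe_rows)
            }
            sample_ids = [f"{exp_id}_ctl{i}" for i in range(n_per_group)] + [
                f"{exp_id}_case{i}" for i in range(n_per_group)
            ]
            groups = {s: ("control" if i < n_per_group else "case") for i, s in enumerate(sample_ids)}
            experiments.append(
                ExpressionExperiment(
                    experiment_id=exp_id,
                    values=pd.DataFrame(probe_vals, index=probe_ids, columns=sample_ids),
                    groups=groups,
                    factor="disease state",
                    species=species,
                    is_log_scale=None,
                )
            )
            probe_maps[exp_id] = probe_map
            condition_of[exp_id] = cond
    truth = CompendiumTruth(condition_of=condition_of, programs=programs, config=cfg)
    return SimulatedCompendium(
        experiments=experiments, probe_maps=probe_maps, homolog_map=homolog_map, truth=truth
    )


def compendium_profiles(
    sim: SimulatedCompendium, representation: str = "logfc"
) -> tuple[list[DEProfile], dict[str, str]]:
    """Build case-vs-control gene-space profiles for every experiment.

    Returns the profiles (mapped to human gene ids) and a profile_id ->
    condition label map for retrieval evaluation.
    """
    profiles = []
    labels = {}
    for exp in sim.experiments:
        profile = build_profile(
            exp,
            "case",
            "control",
            representation=representation,
            probe_map=sim.probe_maps[exp.experiment_id],
            homolog_map=sim.homolog_map,
        )
        profiles.append(profile)
        labels[profile.profile_id] = sim.truth.condition_of[exp.experiment_id]
    return profiles, labels


def gene_level_experiments(sim: SimulatedCompendium) -> dict[str, ExpressionExperiment]:
    """Log-scale, probe-aggregated (human-gene) experiments keyed by id."""
    from desearch.io import ensure_log_scale

    out = {}
    for exp in sim.experiments:
        gene_exp = aggregate_probes_fixed_effects(
            ensure_log_scale(exp), sim.probe_maps[exp.experiment_id]
        )
        if exp.species != "human":
            # rename features via the one-to-one homolog entries
            renames = {}
            for g in gene_exp.values.index:
                human = sim.homolog_map.lookup_one_to_one(exp.species, str(g))
                if human is not None:
                    renames[g] = human
            vals = gene_exp.values.loc[list(renames)].rename(index=renames)
            fvar = gene_exp.feature_variances.loc[list(renames)].rename(index=renames)
            gene_exp = gene_exp.replace(values=vals, feature_variances=fvar)
        out[exp.experiment_id] = gene_exp
    return out


def pooled_gene_matrix(sim: SimulatedCompendium) -> pd.DataFrame:
    """Samples x genes matrix pooling all experiments (shared genes only).

    Intended as input for component derivation; use a compendium with no
    platform dropout so the shared-gene intersection stays large.
    """
    gene_exps = gene_level_experiments(sim)
    common = None
    for exp in gene_exps.values():
        idx = exp.values.index
        common = idx if common is None else common.intersection(idx)
    if common is None or len(common) == 0:
        raise ValidationError("no genes shared across the compendium")
    blocks = []
    for exp_id in sorted(gene_exps):
        exp = gene_exps[exp_id]
        block = exp.values.loc[common].T
        block.index = [f"{exp_id}:{s}" for s in block.index]
        blocks.append(block)
    return pd.concat(blocks, axis=0)


def simulate_component_compendium(
    n_samples: int,
    n_genes: int,
    n_sources: int,
    sparsity: float = 0.05,
    snr: float = 10.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Linear mixture of sparse gene-loading sources, for ICA recovery tests.

    Each source is nonzero on a ``sparsity`` fraction of genes (standard
    normal loadings); mixing coefficients are standard normal; isotropic
    Gaussian noise is scaled so the signal-to-noise variance ratio equals
    ``snr`` (``numpy.inf`` for noiseless data).  Returns the samples x
    genes matrix and the true mixing (samples x sources) and source
    (sources x genes) matrices.
    """
    if n_sources > min(n_samples, n_genes):
        raise ValidationError("n_sources cannot exceed min(n_samples, n_genes)")
    rng = np.random.default_rng(seed)
    sources = np.zeros((n_sources, n_genes))
    for k in range(n_sources):
        nnz = max(1, int(round(sparsity * n_genes)))
        idx = rng.choice(n_genes, size=nnz, replace=False)
        sources[k, idx] = rng.normal(0.0, 1.0, size=nnz)
    mixing = rng.normal(0.0, 1.0, size=(n_samples, n_sources))
    signal = mixing @ sources
    if np.isinf(snr):
        noise = 0.0
    else:
        noise_sd = np.sqrt(signal.var() / snr)
        noise = rng.normal(0.0, noise_sd, size=signal.shape)
    X = signal + noise
    df = pd.DataFrame(
        X,
        index=[f"s{i:04d}" for i in range(n_samples)],
        columns=[f"G{i:05d}" for i in range(n_genes)],
    )
    return df, mixing, sources
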