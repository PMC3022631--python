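"""Readers/writers for the pipeline's tab-separated formats, plus log-scale handling.

Formats
-------
* expression matrix: TSV, first column ``feature_id``, remaining columns samples
* annotation: TSV with columns ``sample_id``, ``group``, ``factor``
* homolog map: TSV with columns ``species``, ``source_gene_id``, ``human_gene_id``,
  ``one_to_one`` (0/1)
* gene sets: GMT (set name, description, tab-separated members)
* component matrix: TSV, rows components, columns genes
* DE profile: TSV with columns ``feature_id``, ``score`` [, ``pvalue``, ``variance``]
  plus a JSON sidecar ``<path>.meta.json`` holding profile metadata
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from desearch.datamodel import (
    ComponentMatrix,
    DEProfile,
    ExpressionExperiment,
    GeneSetCollection,
    HomologMap,
    ValidationError,
)

logger = logging.getLogger(__name__)

#: Linear-scale intensities exceed this; log2 intensities essentially never do.
LOG_DETECTION_MAX = 50.0

#: Values <= 0 are floored here before taking log2 (log2(1) = 0).
LOG_FLOOR = 1.0


def read_annotation(path: str | Path) -> tuple[dict[str, str], str]:
    """Read a sample annotation table; return (sample -> group, factor name)."""
    ann = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "group", "factor"}
    if not required.issubset(ann.columns):
        raise ValidationError(f"annotation must have columns {sorted(required)}")
    factors = ann["factor"].unique()
    if len(factors) != 1:
        raise ValidationError(f"annotation mixes factors: {sorted(factors)}")
    groups = dict(zip(ann["sample_id"], ann["group"]))
    return groups, str(factors[0])


def read_expression_matrix(
    path: str | Path,
    annotation_path: str | Path,
    experiment_id: str | None = None,
    species: str = "human",
) -> ExpressionExperiment:
    """Read a features x samples TSV matrix and its sample annotation.

    Samples present in the matrix but absent from the annotation are
    dropped with a warning; zero overlapping samples is an error.
    ``is_log_scale`` is left undecided (None) -- call
    :func:`ensure_log_scale` before any log-domain operation.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if df.index.has_duplicates:
        dups = sorted(set(df.index[df.index.duplicated()]))
        raise ValidationError(f"duplicate feature ids in {path}: {dups}")
    groups, factor = read_annotation(annotation_path)
    keep = [s for s in df.columns if s in groups]
    dropped = [s for s in df.columns if s not in groups]
    if not keep:
        raise ValidationError(f"no samples of {path} appear in the annotation")
    if dropped:
        logger.warning("dropping %d unannotated samples: %s", len(dropped), dropped)
    return ExpressionExperiment(
        experiment_id=experiment_id or path.stem,
        values=df[keep].astype(float),
        groups={s: groups[s] for s in keep},
        factor=factor,
        species=species,
        is_log_scale=None,
    )


def write_expression_matrix(
    experiment: ExpressionExperiment, path: str | Path, annotation_path: str | Path
) -> None:
    df = experiment.values.copy()
    df.index.name = "feature_id"
    df.to_csv(path, sep="\t")
    ann = pd.DataFrame(
        {
            "sample_id": experiment.sample_ids,
            "group": [experiment.groups[s] for s in experiment.sample_ids],
            "factor": experiment.factor,
        }
    )
    ann.to_csv(annotation_path, sep="\t", index=False)


def ensure_log_scale(experiment: ExpressionExperiment) -> ExpressionExperiment:
    """Return the experiment on the log2 scale, transforming only if needed.

    Decision rule: any negative value, or a maximum <= ``LOG_DETECTION_MAX``,
    means the data is already log-scale (linear microarray intensities are
    nonnegative and reach the thousands).  Otherwise values <= 0 are floored
    at ``LOG_FLOOR`` and log2 is applied.  Idempotent: log2 output always
    satisfies the already-log rule.
    """
    vals = experiment.values.to_numpy(dtype=float)
    finite = vals[np.isfinite(vals)]
    if finite.size == 0:
        raise ValidationError(f"{experiment.experiment_id!r} has no finite values")
    vmin, vmax = finite.min(), finite.max()
    if vmin < 0 or vmax <= LOG_DETECTION_MAX:
        logger.info(
            "%s: deemed log-scale (min %.3g, max %.3g)", experiment.experiment_id, vmin, vmax
        )
        return experiment.replace(is_log_scale=True)
    logger.info(
        "%s: linear scale detected (max %.3g > %.3g); applying log2",
        experiment.experiment_id,
        vmax,
        LOG_DETECTION_MAX,
    )
    logged = np.log2(np.maximum(experiment.values, LOG_FLOOR))
    return experiment.replace(values=logged, is_log_scale=True)


def read_homolog_map(path: str | Path) -> HomologMap:
    df = pd.read_csv(path, sep="\t", dtype={"species": str, "source_gene_id": str, "human_gene_id": str})
    required = {"species", "source_gene_id", "human_gene_id", "one_to_one"}
    if not required.issubset(df.columns):
        raise ValidationError(f"homolog map must have columns {sorted(required)}")
    entries = {}
    flags = {}
    for row in df.itertuples(index=False):
        key = (row.species, row.source_gene_id)
        entries[key] = row.human_gene_id
        flags[key] = bool(int(row.one_to_one))
    return HomologMap(entries=entries, one_to_one=flags)


def write_homolog_map(hmap: HomologMap, path: str | Path) -> None:
    rows = [
        {
            "species": species,
            "source_gene_id": src,
            "human_gene_id": human,
            "one_to_one": int(hmap.one_to_one[(species, src)]),
        }
        for (species, src), human in sorted(hmap.entries.items())
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_gmt(path: str | Path) -> GeneSetCollection:
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(f"GMT line with fewer than 3 fields: {line!r}")
            name, desc, members = fields[0], fields[1], fields[2:]
            if name in sets:
                raise ValidationError(f"duplicate gene-set id {name!r}")
            sets[name] = (desc, frozenset(m for m in members if m))
    return GeneSetCollection(sets=sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for set_id, (desc, members) in collection:
            fh.write("\t".join([set_id, desc, *sorted(members)]) + "\n")


def read_component_matrix(path: str | Path) -> ComponentMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    return ComponentMatrix(
        component_ids=[str(c) for c in df.index],
        gene_ids=[str(g) for g in df.columns],
        loadings=df.to_numpy(dtype=float),
    )


def write_component_matrix(components: ComponentMatrix, path: str | Path) -> None:
    components.to_frame().to_csv(path, sep="\t")


def read_probe_map(path: str | Path) -> dict[str, str]:
    """Read a probe -> gene table (TSV columns ``probe_id``, ``gene_id``)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"probe_id", "gene_id"}.issubset(df.columns):
        raise ValidationError("probe map must have columns probe_id, gene_id")
    return dict(zip(df["probe_id"], df["gene_id"]))


def write_probe_map(probe_map: dict[str, str], path: str | Path) -> None:
    pd.DataFrame(
        sorted(probe_map.items()), columns=["probe_id", "gene_id"]
    ).to_csv(path, sep="\t", index=False)


def write_profile(profile: DEProfile, path: str | Path) -> None:
    path = Path(path)
    profile.to_frame().to_csv(path, sep="\t")
    meta = {
        "profile_id": profile.profile_id,
        "space": profile.space,
        "comparison": list(profile.comparison),
        "source_experiment": profile.source_experiment,
    }
    Path(str(path) + ".meta.json").write_text(json.dumps(meta, indent=1))


def read_profile(path: str | Path) -> DEProfile:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    meta_path = Path(str(path) + ".meta.json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    return DEProfile(
        profile_id=meta.get("profile_id", path.stem),
        space=meta.get("space", "gene"),
        feature_ids=np.asarray(df.index.astype(str)),
        scores=df["score"].to_numpy(dtype=float),
        pvalues=df["pvalue"].to_numpy(dtype=float) if "pvalue" in df else None,
        variances=df["variance"].to_numpy(dtype=float) if "variance" in df else None,
        comparison=tuple(meta.get("comparison", ("", ""))),
        source_experiment=meta.get("source_experiment", ""),
    )
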