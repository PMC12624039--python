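"""Tabular interchange: the TSV bundle, provenance headers, and run config.

TSV is the canonical format (inspectable, diff-able); every file written by
the pipeline carries ``#``-prefixed provenance headers stating the stage,
seed, config hash and matrix orientation (taxa/features as rows, samples as
columns).  Networks are additionally exported as GraphML, statistics as
JSON.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .calibration import SpikeInDesign
from .core import AbundanceMatrix, check_metadata
from .metabolomics import MetaboliteMatrix

logger = logging.getLogger("qmpdecomp")


@dataclass
class RunConfig:
    """Flat pipeline configuration; unknown keys are rejected on load."""

    outdir: str = "results"
    seed: int = 0
    r_min: float = 0.6
    p_max: float = 0.001
    vip_min: float = 1.5
    vip_p_max: float = 0.05
    early_days: tuple[int, ...] = (1, 3, 7)
    late_days: tuple[int, ...] = (14, 21, 28, 35)
    top_n_genera: int = 100
    rarefaction_depth: int | None = None
    n_permutations: int = 999
    n_trees: int = 1000
    n_eval_runs: int = 100
    k_folds: int = 10
    cv_repeats: int = 5
    n_metabolite_features: int = 300
    read_depth: int = 50_000

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("early_days", "late_days"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def hash(self) -> str:
        fields = asdict(self)
        fields.pop("outdir")  # a location, not a parameter
        blob = json.dumps(fields, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def provenance_header(stage: str, config: RunConfig | None = None, seed: int | None = None, **extra) -> str:
    fields = {"stage": stage, "orientation": "rows=taxa_or_features, columns=samples"}
    if config is not None:
        fields["config_hash"] = config.hash()
    if seed is not None:
        fields["seed"] = seed
    fields.update(extra)
    return "".join(f"# {k}={v}\n" for k, v in fields.items())


def write_tsv(
    df: pd.DataFrame | pd.Series,
    path: str | Path,
    stage: str,
    config: RunConfig | None = None,
    seed: int | None = None,
    **extra,
) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(df, pd.Series):
        df = df.to_frame()
    with open(path, "w") as fh:
        fh.write(provenance_header(stage, config, seed, **extra))
        df.to_csv(fh, sep="\t")
    return path


def read_tsv(path: str | Path, numeric: bool = False) -> pd.DataFrame:
    """Read a provenance-headed TSV; with ``numeric=True`` every cell must
    parse as a number, and a malformed cell is reported by file, row and
    column."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique()
        raise ValueError(f"{path.name}: duplicate row IDs {list(dups)[:5]}")
    if numeric:
        for col in df.columns:
            converted = pd.to_numeric(df[col], errors="coerce")
            bad = converted.isna() & df[col].notna()
            if bad.any():
                row = df.index[bad][0]
                raise ValueError(f"{path.name}: malformed numeric cell at row {row!r}, column {col!r}")
            df[col] = converted
    return df


@dataclass
class Bundle:
    """The standard tabular bundle linking counts, spikes, metadata,
    taxonomy and (optionally) the metabolome on a consistent sample set."""

    metadata: pd.DataFrame
    counts: dict[str, AbundanceMatrix]
    spikes: dict[str, SpikeInDesign]
    taxonomy: pd.DataFrame
    metabolites: MetaboliteMatrix | None = None
    dropped_samples: dict[str, list[str]] = field(default_factory=dict)


def write_bundle(cohort, outdir: str | Path, config: RunConfig | None = None) -> Path:
    """Write a simulated cohort as the standard bundle (plus ground truth
    for tests)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = cohort.design.seed
    write_tsv(cohort.metadata, outdir / "metadata.tsv", "simulate", config, seed)
    write_tsv(cohort.taxonomy, outdir / "taxonomy.tsv", "simulate", config, seed)
    for domain, counts in cohort.counts.items():
        write_tsv(counts.data, outdir / f"counts_{domain}.tsv", "simulate", config, seed, mode=counts.mode)
        write_tsv(cohort.truth.loads[domain], outdir / f"ground_truth_{domain}.tsv", "simulate", config, seed,
                  mode="copies_per_gram")
    manifest = pd.concat(
        [
            sp.table.stack().rename("input_copies").reset_index().assign(domain=domain)
            for domain, sp in cohort.spikes.items()
        ]
    ).rename(columns={"level_1": "sample_id"}).set_index("spike_id")
    write_tsv(manifest, outdir / "spike_manifest.tsv", "simulate", config, seed)
    if cohort.metabolites is not None:
        write_tsv(cohort.metabolites.data, outdir / "metabolites.tsv", "simulate", config, seed)
        ann = cohort.metabolites.superclass.to_frame()
        if cohort.truth.metabolite_trend_sign is not None:
            ann["true_trend_sign"] = cohort.truth.metabolite_trend_sign
        write_tsv(ann, outdir / "metabolite_annotations.tsv", "simulate", config, seed)
    return outdir


def read_bundle(outdir: str | Path) -> Bundle:
    """Read the bundle back, enforcing cross-file sample consistency.

    Sample IDs present in a counts/metabolite table but absent from the
    metadata (or vice versa) are dropped with a log entry; samples with a
    missing mass are flagged and dropped.  Duplicate sample IDs raise.
    """
    outdir = Path(outdir)
    metadata = read_tsv(outdir / "metadata.tsv")
    metadata["day"] = pd.to_numeric(metadata["day"])
    metadata["mass_g"] = pd.to_numeric(metadata["mass_g"], errors="coerce")
    check_metadata(metadata)
    dropped: dict[str, list[str]] = {}
    no_mass = metadata.index[~(metadata["mass_g"] > 0)]
    if len(no_mass):
        logger.warning("samples flagged for missing/invalid mass: %s", list(no_mass))
        dropped["missing_mass"] = list(no_mass)
        metadata = metadata.drop(index=no_mass)

    manifest = pd.read_csv(outdir / "spike_manifest.tsv", sep="\t", comment="#")
    counts, spikes = {}, {}
    for path in sorted(outdir.glob("counts_*.tsv")):
        domain = path.stem.removeprefix("counts_")
        data = read_tsv(path, numeric=True)
        orphan = data.columns.difference(metadata.index)
        if len(orphan):
            logger.warning("%s: %d samples absent from metadata dropped: %s", path.name, len(orphan), list(orphan)[:5])
            dropped.setdefault(f"{domain}_orphans", []).extend(orphan)
        shared = [s for s in data.columns if s in metadata.index]
        counts[domain] = AbundanceMatrix(data[shared], mode="raw_reads", domain=domain)
        sub = manifest[manifest["domain"] == domain]
        table = sub.pivot_table(index="spike_id", columns="sample_id", values="input_copies")
        spikes[domain] = SpikeInDesign(table=table[ [s for s in shared if s in table.columns] ])
    taxonomy = read_tsv(outdir / "taxonomy.tsv")
    metabolites = None
    metab_path = outdir / "metabolites.tsv"
    if metab_path.exists():
        data = read_tsv(metab_path, numeric=True)
        shared = [s for s in data.columns if s in metadata.index]
        orphan = data.columns.difference(metadata.index)
        if len(orphan):
            logger.warning("metabolites.tsv: %d orphan samples dropped: %s", len(orphan), list(orphan)[:5])
            dropped.setdefault("metabolite_orphans", []).extend(orphan)
        ann = read_tsv(outdir / "metabolite_annotations.tsv")
        metabolites = MetaboliteMatrix(data[shared], superclass=ann["superclass"], state="raw")
    return Bundle(
        metadata=metadata, counts=counts, spikes=spikes, taxonomy=taxonomy,
        metabolites=metabolites, dropped_samples=dropped,
    )


def write_graphml(net, path: str | Path) -> Path:
    """Export a co-occurrence network for external viewers."""
    import networkx as nx

    g = net.graph()
    for node in g.nodes:
        row = net.nodes.loc[node]
        g.nodes[node]["module"] = int(row["module"])
        if pd.notna(row.get("domain")):
            g.nodes[node]["domain"] = str(row["domain"])
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nx.write_graphml(g, path)
    return path


def write_json(obj, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)

    def default(o):
        import numpy as np

        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, (set, frozenset, tuple)):
            return sorted(o) if isinstance(o, (set, frozenset)) else list(o)
        if isinstance(o, pd.Series):
            return o.to_dict()
        raise TypeError(f"cannot serialise {type(o)}")

    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=default))
    return path
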