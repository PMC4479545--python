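"""End-to-end orchestration: one identical procedure per dataset, then
cross-dataset congruence and delimitation.

Each dataset flows through encode -> correlation PCA -> axis retention
(plus a missingness screen for the molecular datasets) -> Gaussian
mixture model selection. Climate is the exception: it is clustered via
the replicated spatial-thinning consensus, because occurrence records
oversample accessible places and the climate signal would otherwise be
weighted by collecting effort. The intrinsic partitions then feed the
congruence report and the conservative species hypothesis.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .congruence import CongruenceReport, SpeciesHypothesis, congruence_report, delimit
from .encoding import (
    FeatureMatrix,
    climate_transform,
    extract_snps,
    impute_missing,
    missingness_vector,
    size_correct_morphometrics,
)
from .errors import ConfigError
from .introgression import test_battery
from .io_tables import PartitionTable
from .mixtures import FAMILIES, MixtureFit, Partition, classify, model_select
from .ordination import ScoreSet, pca_correlation, retain_axes, screen_missingness_axes
from .thinning import ConsensusResult, GridSpec, consensus_cluster

logger = logging.getLogger(__name__)

INTRINSIC_TAGS = ("mtdna", "snp", "phenotype")


@dataclass
class RunConfig:
    """Knobs for a full comparative run; every value lands in the manifest."""

    pca_threshold: float = 0.05
    missingness_r: float = 0.7
    K_max: int = 12
    families: tuple = FAMILIES
    restarts: int = 10
    cell_minutes: float = 0.5
    reps: int = 1000
    min_support: int = 2
    seed: int = 0
    dstat_blocks: int = 50

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha1(blob).hexdigest()[:12]


@dataclass
class DatasetResult:
    """Everything computed for one dataset on its way to a partition."""

    tag: str
    features: FeatureMatrix
    score_set: ScoreSet
    partition: Partition
    fit: MixtureFit | None = None
    bic_table: pd.DataFrame | None = None
    consensus: ConsensusResult | None = None
    dropped_axes: list = field(default_factory=list)

    def partition_table(self) -> PartitionTable:
        return PartitionTable(
            pd.DataFrame(
                {
                    "specimen_id": self.features.specimen_ids,
                    "dataset": self.tag if self.tag in ("mtdna", "snp", "phenotype", "climate") else "synthetic",
                    "cluster": self.partition.labels.astype(int),
                    "uncertainty": self.partition.uncertainty,
                }
            )
        )

    def label_map(self) -> dict[str, int]:
        return dict(zip(self.features.specimen_ids, self.partition.labels.tolist()))


def encode_dataset(tag: str, data) -> tuple[FeatureMatrix, np.ndarray | None]:
    """Encode one raw dataset; returns features and, for molecular data,
    the per-specimen missingness fraction used by the axis screen."""
    if tag == "mtdna":
        gm = extract_snps(data)
        return impute_missing(gm), missingness_vector(gm)
    if tag == "snp":
        return impute_missing(data), missingness_vector(data)
    if tag == "phenotype":
        return size_correct_morphometrics(data), None
    if tag == "climate":
        return climate_transform(data), None
    raise ConfigError(f"unknown dataset tag {tag!r}")


def cluster_dataset(
    tag: str,
    data,
    config: RunConfig | None = None,
    localities=None,
    screen_missingness: bool | None = None,
) -> DatasetResult:
    """Run encode -> PCA -> retention -> clustering for one dataset.

    Molecular datasets (mtdna, snp) get the missingness-axis screen by
    default. Climate requires ``localities`` and is clustered through
    the spatial-thinning consensus; the other datasets go through
    direct BIC model selection.
    """
    config = config or RunConfig()
    features, missing_frac = encode_dataset(tag, data)
    ss = pca_correlation(features)
    ss.retained = retain_axes(ss, threshold=config.pca_threshold)
    dropped: list = []
    if screen_missingness is None:
        screen_missingness = tag in ("mtdna", "snp")
    if screen_missingness and missing_frac is not None:
        dropped = screen_missingness_axes(ss, missing_frac, r_threshold=config.missingness_r)
        if dropped:
            logger.info("%s: dropped axes %s (missingness-correlated)", tag, dropped)
    X = ss.retained_scores()
    if tag == "climate":
        if localities is None:
            raise ConfigError("climate clustering requires localities")
        coords = localities.coords() if hasattr(localities, "coords") else np.asarray(localities)
        consensus = consensus_cluster(
            X,
            coords,
            grid=GridSpec(cell_size=config.cell_minutes / 60.0),
            reps=config.reps,
            seed=config.seed,
            K_max=config.K_max,
            families=config.families,
            restarts=config.restarts,
        )
        return DatasetResult(
            tag=tag, features=features, score_set=ss,
            partition=consensus.final_partition, consensus=consensus, dropped_axes=dropped,
        )
    fit, table = model_select(
        X, K_max=min(config.K_max, X.shape[0]), families=config.families,
        restarts=config.restarts, seed=config.seed,
    )
    part = classify(fit, X)
    return DatasetResult(
        tag=tag, features=features, score_set=ss, partition=part,
        fit=fit, bic_table=table, dropped_axes=dropped,
    )


@dataclass
class CompareSignalResult:
    """Bundle from a full comparative run."""

    datasets: dict[str, DatasetResult]
    congruence: CongruenceReport
    species: SpeciesHypothesis
    dstat_table: pd.DataFrame | None
    manifest: dict


def run_compare_signal(
    datasets: dict[str, object],
    localities,
    config: RunConfig | None = None,
    quartets=None,
) -> CompareSignalResult:
    """The full comparative analysis over >= 2 datasets.

    ``datasets`` maps tags (mtdna/snp/phenotype/climate) to raw inputs
    (SequenceAlignment, GenotypeMatrix, TraitTable, ClimateTable).
    Returns per-dataset partitions, the pairwise ARI report, the species
    hypothesis from the intrinsic partitions, an optional D-statistic
    battery, and a manifest recording every seed and threshold.
    """
    config = config or RunConfig()
    if len(datasets) < 2:
        raise ConfigError("compare-signal needs at least two datasets")
    results: dict[str, DatasetResult] = {}
    for tag, data in datasets.items():
        results[tag] = cluster_dataset(tag, data, config=config, localities=localities)
        logger.info(
            "%s: %d specimens, %d retained axes, K=%d",
            tag, len(results[tag].features.specimen_ids),
            len(results[tag].score_set.retained), results[tag].partition.K,
        )
    label_maps = {tag: r.label_map() for tag, r in results.items()}
    report = congruence_report(label_maps)
    loc_map = {
        sid: (lon, lat)
        for sid, lon, lat in zip(
            localities.specimen_ids, localities.coords()[:, 0], localities.coords()[:, 1]
        )
    }
    intrinsic = {t: m for t, m in label_maps.items() if t in INTRINSIC_TAGS}
    if len(intrinsic) >= 2:
        species = delimit(intrinsic, loc_map, min_support=config.min_support)
    else:
        species = delimit(label_maps, loc_map, min_support=config.min_support)
    dstat = None
    if quartets and "snp" in datasets:
        dstat = test_battery(datasets["snp"], quartets, n_blocks=config.dstat_blocks)
    manifest = {
        "version": __version__,
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "datasets": {t: len(r.features.specimen_ids) for t, r in results.items()},
        "retained_axes": {t: [k + 1 for k in r.score_set.retained] for t, r in results.items()},
        "dropped_axes": {t: [k + 1 for k in r.dropped_axes] for t, r in results.items()},
        "selected_K": {t: int(r.partition.K) for t, r in results.items()},
    }
    return CompareSignalResult(
        datasets=results, congruence=report, species=species,
        dstat_table=dstat, manifest=manifest,
    )


def output_header(config: RunConfig) -> str:
    """Header comment stamped on every output file."""
    return f"# delimix {__version__} seed={config.seed} config={config.config_hash()}\n"


def write_bundle(result: CompareSignalResult, outdir, config: RunConfig) -> None:
    """Write partitions, ARI report, species groups and manifest to a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    header = output_header(config)
    for tag, r in result.datasets.items():
        path = outdir / f"partition_{tag}.tsv"
        with open(path, "w") as fh:
            fh.write(header)
            r.partition_table().df.to_csv(fh, sep="\t", index=False)
        if r.bic_table is not None:
            with open(outdir / f"bic_{tag}.tsv", "w") as fh:
                fh.write(header)
                r.bic_table.to_csv(fh, sep="\t", index=False)
    with open(outdir / "ari_matrix.tsv", "w") as fh:
        fh.write(header)
        result.congruence.to_frame().to_csv(fh, sep="\t")
    with open(outdir / "species_groups.tsv", "w") as fh:
        fh.write(header)
        result.species.to_frame().to_csv(fh, sep="\t", index=False)
    if result.dstat_table is not None:
        with open(outdir / "dstat_battery.tsv", "w") as fh:
            fh.write(header)
            result.dstat_table.to_csv(fh, sep="\t", index=False)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=2, default=str)


def parse_flat_config(path) -> dict:
    """Parse the flat ``key: value`` run-configuration format."""
    out = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if ":" not in line:
            raise ConfigError(f"bad config line (expected key: value): {raw!r}")
        key, value = line.split(":", 1)
        out[key.strip()] = value.strip()
    return out
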