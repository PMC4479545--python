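"""Readers and writers for the five standard input tables and partition output.

All tables are plain text (FASTA, TSV/CSV with headers) and are validated
strictly on read: a file that violates a documented invariant raises one of
the exceptions in :mod:`delimix.errors` rather than propagating bad values
into the analysis. Specimen id is the join key across every table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import (
    AlignmentError,
    BoundsError,
    FormatError,
    IdError,
    SchemaError,
)

logger = logging.getLogger(__name__)

#: Tokens accepted as "missing" in genotype tables; all map to one internal code.
MISSING_TOKENS = {"NA", "", "-9", "?", "nan", "NaN"}

#: IUPAC nucleotide codes beyond the four unambiguous bases (kept on read,
#: treated as missing by downstream SNP extraction).
IUPAC_AMBIGUOUS = set("RYSWKMBDHVN")
VALID_BASES = set("ACGT") | IUPAC_AMBIGUOUS | {"-"}

TEMPERATURE_VARS = [f"bio{i:02d}" for i in range(1, 12)]
PRECIPITATION_VARS = [f"bio{i:02d}" for i in range(12, 20)]
CLIMATE_VARS = TEMPERATURE_VARS + PRECIPITATION_VARS

MERISTIC_COLS = [f"M{i:02d}" for i in range(1, 19)]
MORPHOMETRIC_COLS = [f"L{i:02d}" for i in range(1, 10)]

DATASET_TAGS = ("mtdna", "snp", "phenotype", "climate", "synthetic")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class SequenceAlignment:
    """Equal-length nucleotide sequences keyed by unique specimen ids."""

    ids: list[str]
    seqs: list[str]

    def __post_init__(self) -> None:
        if not self.ids:
            raise FormatError("alignment has no records")
        if len(self.ids) != len(set(self.ids)):
            dupes = sorted({i for i in self.ids if self.ids.count(i) > 1})
            raise IdError(f"duplicate sequence ids: {dupes}")
        lengths = {len(s) for s in self.seqs}
        if len(lengths) != 1:
            raise AlignmentError(f"ragged alignment: lengths {sorted(lengths)}")
        if min(lengths) < 1:
            raise AlignmentError("alignment length must be >= 1")
        self.seqs = [s.upper() for s in self.seqs]
        for sid, s in zip(self.ids, self.seqs):
            bad = set(s) - VALID_BASES
            if bad:
                raise FormatError(f"invalid characters {sorted(bad)} in sequence {sid!r}")

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def length(self) -> int:
        return len(self.seqs[0])


@dataclass
class GenotypeMatrix:
    """Samples x loci integer genotypes; missing cells are NaN.

    ``ploidy`` is 2 for diploid SNPs (codes 0/1/2 count the alternate
    allele) and 1 for haploid mtDNA-derived loci (codes 0/1).
    """

    sample_ids: list[str]
    locus_ids: list[str]
    genotypes: np.ndarray  # float array, NaN = missing
    ploidy: int = 2

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=float)
        if self.genotypes.shape != (len(self.sample_ids), len(self.locus_ids)):
            raise FormatError(
                f"genotype matrix shape {self.genotypes.shape} inconsistent with "
                f"{len(self.sample_ids)} samples x {len(self.locus_ids)} loci"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise IdError("duplicate sample ids")
        if self.ploidy not in (1, 2):
            raise BoundsError(f"ploidy must be 1 or 2, got {self.ploidy}")
        observed = self.genotypes[~np.isnan(self.genotypes)]
        if observed.size and (
            np.any(observed < 0)
            or np.any(observed > self.ploidy)
            or np.any(observed != np.round(observed))
        ):
            raise FormatError(f"genotype codes must be integers in 0..{self.ploidy}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_loci(self) -> int:
        return len(self.locus_ids)


@dataclass
class TraitTable:
    """Phenotypic characters: 18 meristic counts + 9 morphometric lengths (mm)."""

    df: pd.DataFrame  # columns: specimen_id, sex, ontogeny, body_length, M01..M18, L01..L09

    def __post_init__(self) -> None:
        required = ["specimen_id", "sex", "ontogeny", "body_length"] + MERISTIC_COLS + MORPHOMETRIC_COLS
        missing = [c for c in required if c not in self.df.columns]
        if missing:
            raise SchemaError(f"trait table missing columns: {missing}")
        if (self.df["body_length"] <= 0).any():
            raise BoundsError("body_length must be positive")
        morpho = self.df[MORPHOMETRIC_COLS].to_numpy(dtype=float)
        if np.any(morpho[~np.isnan(morpho)] <= 0):
            raise BoundsError("morphometric measurements must be positive")
        meristic = self.df[MERISTIC_COLS].to_numpy(dtype=float)
        if np.any(meristic[~np.isnan(meristic)] < 0):
            raise BoundsError("meristic counts must be non-negative")

    @property
    def specimen_ids(self) -> list[str]:
        return self.df["specimen_id"].astype(str).tolist()


@dataclass
class LocalityTable:
    """WGS84 decimal-degree coordinates, one row per specimen."""

    df: pd.DataFrame  # columns: specimen_id, lon, lat

    def __post_init__(self) -> None:
        missing = [c for c in ("specimen_id", "lon", "lat") if c not in self.df.columns]
        if missing:
            raise SchemaError(f"locality table missing columns: {missing}")
        if self.df["specimen_id"].duplicated().any():
            raise IdError("locality table must have one row per specimen")
        lon = self.df["lon"].to_numpy(dtype=float)
        lat = self.df["lat"].to_numpy(dtype=float)
        if np.any(np.abs(lon) > 180) or np.any(np.abs(lat) > 90):
            raise BoundsError("coordinates outside [-180,180] x [-90,90]")

    @property
    def specimen_ids(self) -> list[str]:
        return self.df["specimen_id"].astype(str).tolist()

    def coords(self) -> np.ndarray:
        return self.df[["lon", "lat"]].to_numpy(dtype=float)


@dataclass
class ClimateTable:
    """Nineteen bioclim-style variables per specimen.

    bio01..bio11 are temperature-type (real valued), bio12..bio19 are
    precipitation-type (non-negative).
    """

    df: pd.DataFrame  # columns: specimen_id, bio01..bio19

    def __post_init__(self) -> None:
        var_cols = [c for c in self.df.columns if c != "specimen_id"]
        if "specimen_id" not in self.df.columns:
            raise SchemaError("climate table missing specimen_id column")
        if sorted(var_cols) != sorted(CLIMATE_VARS):
            raise SchemaError(
                f"climate table must have exactly the 19 variables bio01..bio19, got {len(var_cols)} columns"
            )
        precip = self.df[PRECIPITATION_VARS].to_numpy(dtype=float)
        if np.any(precip < 0):
            raise BoundsError("precipitation-type variables must be >= 0")

    @property
    def specimen_ids(self) -> list[str]:
        return self.df["specimen_id"].astype(str).tolist()


@dataclass
class PartitionTable:
    """Cluster labels + classification uncertainty for one dataset."""

    df: pd.DataFrame  # columns: specimen_id, dataset, cluster, uncertainty
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = ["specimen_id", "dataset", "cluster", "uncertainty"]
        missing = [c for c in required if c not in self.df.columns]
        if missing:
            raise SchemaError(f"partition table missing columns: {missing}")
        bad_tags = set(self.df["dataset"]) - set(DATASET_TAGS)
        if bad_tags:
            raise SchemaError(f"unknown dataset tags: {sorted(bad_tags)}")
        labels = self.df["cluster"].to_numpy()
        if not np.issubdtype(labels.dtype, np.integer):
            raise FormatError("cluster labels must be integers")
        expect = np.arange(1, labels.max() + 1)
        if not np.array_equal(np.unique(labels), expect):
            raise FormatError("cluster labels must be contiguous from 1")
        unc = self.df["uncertainty"].to_numpy(dtype=float)
        if np.any(unc < 0) or np.any(unc > 1):
            raise BoundsError("uncertainty must lie in [0, 1]")

    @property
    def specimen_ids(self) -> list[str]:
        return self.df["specimen_id"].astype(str).tolist()

    def labels(self) -> np.ndarray:
        return self.df["cluster"].to_numpy()


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_fasta(path) -> SequenceAlignment:
    """Read an aligned FASTA file (single-line or wrapped records)."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    return SequenceAlignment(
        ids=[r.id for r in records], seqs=[str(r.seq) for r in records]
    )


def write_fasta(alignment: SequenceAlignment, path) -> None:
    records = [
        SeqRecord(Seq(s), id=i, description="")
        for i, s in zip(alignment.ids, alignment.seqs)
    ]
    SeqIO.write(records, str(path), "fasta")


def _parse_genotype_token(tok: str, ploidy: int) -> float:
    tok = tok.strip()
    if tok in MISSING_TOKENS:
        return np.nan
    try:
        value = int(tok)
    except ValueError as exc:
        raise FormatError(f"non-integer genotype token {tok!r}") from exc
    return float(value)


def read_genotype_table(path, dialect: str = "tsv012") -> GenotypeMatrix:
    """Read a genotype matrix from one of two tab-separated dialects.

    ``tsv012``: header ``sample_id`` + one column per locus; cells are
    0/1/2 counts of the alternate allele (or a missing token).

    ``two_row_alleles``: STRUCTURE-style, two rows per sample with one
    allele code per locus cell; per locus the genotype is recoded as the
    number of copies of the numerically larger allele; -9 marks a
    missing allele.
    """
    if dialect not in ("tsv012", "two_row_alleles"):
        raise ValueError(f"unknown dialect {dialect!r}")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise FormatError("genotype table needs sample_id plus at least one locus column")
    locus_ids = list(df.columns[1:])

    if dialect == "tsv012":
        sample_ids = df.iloc[:, 0].tolist()
        geno = np.empty((len(sample_ids), len(locus_ids)))
        for j, col in enumerate(locus_ids):
            geno[:, j] = [_parse_genotype_token(t, 2) for t in df[col]]
        gm = GenotypeMatrix(sample_ids, locus_ids, geno, ploidy=2)
        return gm

    # two_row_alleles: consecutive row pairs share a sample id
    raw = df.iloc[:, 0].tolist()
    if len(raw) % 2 != 0:
        raise FormatError("two_row_alleles file must have an even number of rows")
    sample_ids = []
    for k in range(0, len(raw), 2):
        if raw[k] != raw[k + 1]:
            raise FormatError(f"allele row pair mismatch: {raw[k]!r} vs {raw[k + 1]!r}")
        sample_ids.append(raw[k])
    alleles = np.empty((len(raw), len(locus_ids)))
    for j, col in enumerate(locus_ids):
        for i, tok in enumerate(df[col]):
            tok = tok.strip()
            if tok in MISSING_TOKENS:
                alleles[i, j] = np.nan
            else:
                try:
                    alleles[i, j] = int(tok)
                except ValueError as exc:
                    raise FormatError(f"non-integer allele token {tok!r}") from exc
    geno = np.full((len(sample_ids), len(locus_ids)), np.nan)
    for j in range(len(locus_ids)):
        col = alleles[:, j]
        observed = np.unique(col[~np.isnan(col)])
        if observed.size > 2:
            raise FormatError(
                f"locus {locus_ids[j]!r} has {observed.size} alleles; at most 2 allowed"
            )
        alt = observed.max() if observed.size else np.nan
        for s in range(len(sample_ids)):
            a, b = col[2 * s], col[2 * s + 1]
            if np.isnan(a) or np.isnan(b):
                continue
            geno[s, j] = float(a == alt) + float(b == alt) if observed.size == 2 else 0.0
    return GenotypeMatrix(sample_ids, locus_ids, geno, ploidy=2)


def write_genotype_table(gm: GenotypeMatrix, path) -> None:
    out = pd.DataFrame(gm.genotypes, columns=gm.locus_ids)
    out = out.map(lambda v: "NA" if np.isnan(v) else str(int(v)))
    out.insert(0, "sample_id", gm.sample_ids)
    out.to_csv(path, sep="\t", index=False)


def read_trait_table(path) -> TraitTable:
    return TraitTable(pd.read_csv(path))


def write_trait_table(tt: TraitTable, path) -> None:
    tt.df.to_csv(path, index=False)


def read_locality_table(path) -> LocalityTable:
    return LocalityTable(pd.read_csv(path))


def write_locality_table(lt: LocalityTable, path) -> None:
    lt.df.to_csv(path, index=False)


def read_climate_table(path) -> ClimateTable:
    return ClimateTable(pd.read_csv(path))


def write_climate_table(ct: ClimateTable, path) -> None:
    ct.df.to_csv(path, index=False)


def write_partition(pt: PartitionTable, path) -> None:
    """Write a partition as TSV (specimen_id, dataset, cluster, uncertainty)."""
    PartitionTable(pt.df)  # re-validate before writing
    pt.df.to_csv(path, sep="\t", index=False)


def read_partition(path) -> PartitionTable:
    df = pd.read_csv(path, sep="\t", comment="#")
    return PartitionTable(df)


def inner_join_ids(*id_lists: list[str]) -> list[str]:
    """Intersection of specimen id lists, in the order of the first list.

    Dropped ids are logged (count per table) so silent specimen loss is
    visible in pipeline logs.
    """
    common = set(id_lists[0])
    for ids in id_lists[1:]:
        common &= set(ids)
    for k, ids in enumerate(id_lists):
        dropped = len(ids) - len([i for i in ids if i in common])
        if dropped:
            logger.info("inner join drops %d of %d ids from table %d", dropped, len(ids), k)
    return [i for i in id_lists[0] if i in common]
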