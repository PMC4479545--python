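"""Convert raw inputs into the numeric matrices handed to PCA.

Four encoders, one per data source:

* mtDNA alignment -> haploid 0/1 matrix over biallelic sites
  (:func:`extract_snps`), then mean imputation (:func:`impute_missing`);
* SNP genotypes -> mean-imputed 0/1/2 matrix (same imputation path);
* traits -> 18 meristic counts passed through plus 9 log-log
  size-corrected morphometric residuals (:func:`size_correct_morphometrics`),
  body length excluded, 27 columns total;
* climate -> 19 variables with precipitation-type columns
  log10(x+1)-transformed for normality (:func:`climate_transform`).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DegenerateInputError, DomainError
from .io_tables import (
    MERISTIC_COLS,
    MORPHOMETRIC_COLS,
    PRECIPITATION_VARS,
    TEMPERATURE_VARS,
    ClimateTable,
    GenotypeMatrix,
    SequenceAlignment,
    TraitTable,
)

logger = logging.getLogger(__name__)


@dataclass
class FeatureMatrix:
    """Finite-valued specimens x features matrix ready for ordination."""

    specimen_ids: list[str]
    feature_ids: list[str]
    values: np.ndarray
    provenance: str  # mtdna | snp | phenotype | climate

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise DomainError("feature matrix must be finite")
        if self.values.shape != (len(self.specimen_ids), len(self.feature_ids)):
            raise DomainError("feature matrix shape inconsistent with ids")


def _drop_constant_columns(values: np.ndarray, feature_ids: list[str]):
    keep = ~np.all(values == values[0:1, :], axis=0)
    if not np.all(keep):
        dropped = [f for f, k in zip(feature_ids, keep) if not k]
        logger.info("dropping %d constant feature columns: %s", len(dropped), dropped[:10])
    return values[:, keep], [f for f, k in zip(feature_ids, keep) if k]


def extract_snps(alignment: SequenceAlignment) -> GenotypeMatrix:
    """Extract biallelic variable sites from an alignment as haploid 0/1 loci.

    Per site, only unambiguous bases (A/C/G/T) count as observations;
    gaps, N and IUPAC ambiguity codes become missing. Sites monomorphic
    or with more than two alleles among observed bases are excluded.
    The majority allele is coded 0 (ties broken alphabetically), the
    minor allele 1. Locus ids record 1-based site positions.
    """
    seq_array = np.array([list(s) for s in alignment.seqs])
    n, length = seq_array.shape
    codes = []
    locus_ids = []
    for j in range(length):
        col = seq_array[:, j]
        observed_mask = np.isin(col, list("ACGT"))
        bases, counts = np.unique(col[observed_mask], return_counts=True)
        if bases.size != 2:
            continue
        # majority allele -> 0; tie -> alphabetically first base is 0
        major = bases[np.argmax(counts)] if counts[0] != counts[1] else bases[0]
        site = np.full(n, np.nan)
        site[observed_mask] = (col[observed_mask] != major).astype(float)
        codes.append(site)
        locus_ids.append(f"site_{j + 1}")
    if not locus_ids:
        logger.warning("alignment has zero biallelic variable sites; empty matrix")
        return GenotypeMatrix(alignment.ids, [], np.empty((n, 0)), ploidy=1)
    return GenotypeMatrix(alignment.ids, locus_ids, np.column_stack(codes), ploidy=1)


def impute_missing(gm: GenotypeMatrix) -> FeatureMatrix:
    """Replace missing genotypes by the column mean of observed codes."""
    values = gm.genotypes.astype(float).copy()
    all_missing = np.all(np.isnan(values), axis=0)
    if np.any(all_missing):
        bad = [gm.locus_ids[j] for j in np.flatnonzero(all_missing)]
        raise DegenerateInputError(f"loci with no observed genotypes: {bad}")
    col_means = np.nanmean(values, axis=0)
    idx = np.where(np.isnan(values))
    values[idx] = col_means[idx[1]]
    provenance = "mtdna" if gm.ploidy == 1 else "snp"
    values, feature_ids = _drop_constant_columns(values, gm.locus_ids)
    return FeatureMatrix(list(gm.sample_ids), feature_ids, values, provenance)


def missingness_vector(gm: GenotypeMatrix) -> np.ndarray:
    """Fraction of missing loci per sample, in sample order."""
    if gm.n_loci == 0:
        return np.zeros(gm.n_samples)
    return np.isnan(gm.genotypes).mean(axis=1)


def bilateral_average(left, right):
    """Average a bilaterally counted character; half-integers are fine.

    Missing (NaN/None) on one side returns the observed side; both
    missing returns NaN. Accepts scalars or arrays.
    """
    left = np.asarray(left, dtype=float)
    right = np.asarray(right, dtype=float)
    if np.any(left[~np.isnan(left)] < 0) or np.any(right[~np.isnan(right)] < 0):
        raise DomainError("counts must be non-negative")
    stacked = np.stack(np.broadcast_arrays(left, right))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN pair -> NaN
        out = np.nanmean(stacked, axis=0)
    return out if out.shape else float(out)


def size_correct_morphometrics(traits: TraitTable) -> FeatureMatrix:
    """Size-correct the 9 morphometrics and assemble the 27-trait matrix.

    Each morphometric is log10-transformed and regressed by pooled OLS
    on log10 body length; the residuals enter the feature matrix and
    body length itself is excluded. Meristic counts pass through
    untransformed, for 18 + 9 = 27 quantitative phenotypic columns.
    """
    df = traits.df
    x = np.log10(df["body_length"].to_numpy(dtype=float))
    morpho = df[MORPHOMETRIC_COLS].to_numpy(dtype=float)
    if np.any(~np.isfinite(morpho)) or np.any(morpho <= 0):
        raise DomainError("morphometric measurements must be positive and present")
    residuals = np.empty_like(morpho)
    for j in range(morpho.shape[1]):
        y = np.log10(morpho[:, j])
        fit = stats.linregress(x, y)
        residuals[:, j] = y - (fit.intercept + fit.slope * x)
    meristic = df[MERISTIC_COLS].to_numpy(dtype=float)
    if np.any(~np.isfinite(meristic)):
        raise DomainError("meristic counts must be present (bilateral-average first)")
    values = np.column_stack([meristic, residuals])
    feature_ids = MERISTIC_COLS + [f"{c}_resid" for c in MORPHOMETRIC_COLS]
    values, feature_ids = _drop_constant_columns(values, feature_ids)
    return FeatureMatrix(traits.specimen_ids, feature_ids, values, "phenotype")


def climate_transform(climate: ClimateTable) -> FeatureMatrix:
    """log10(x+1)-transform precipitation-type variables; keep temperature as-is."""
    df = climate.df
    precip = df[PRECIPITATION_VARS].to_numpy(dtype=float)
    if np.any(precip < 0):
        raise DomainError("precipitation-type variables must be >= 0")
    values = np.column_stack(
        [df[TEMPERATURE_VARS].to_numpy(dtype=float), np.log10(precip + 1.0)]
    )
    feature_ids = list(TEMPERATURE_VARS) + [f"{c}_log" for c in PRECIPITATION_VARS]
    values, feature_ids = _drop_constant_columns(values, feature_ids)
    return FeatureMatrix(climate.specimen_ids, feature_ids, values, "climate")
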