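"""Synthetic five-table worlds with known lineage truth.

The generator encodes the contrast the whole package exists to test:
*intrinsic* data (SNPs, mtDNA, phenotype) carry lineage signal, while
*climate* is a property of where a specimen sits on the landscape, not
of what lineage it belongs to. Concretely:

* SNP allele frequencies drift down a rooted population tree under the
  Balding–Nichols model (child frequency ~ Beta(p(1-c)/c, (1-p)(1-c)/c)
  around parent frequency p, drift c per branch); optional admixture
  edges mix tip frequencies, which is what makes ABBA-BABA asymmetries
  appear; genotypes are Binomial(2, p) with random missingness.
* mtDNA evolves as a Jukes-Cantor Poisson substitution process down the
  same tree, haploid, with a short within-population star phase.
* Traits: Poisson meristic counts around per-lineage means, and
  log-linear allometric morphometrics log10(y) = a_g + b_g log10(SVL)
  plus Gaussian residual noise.
* Localities: uniform draws inside one ellipse per population.
* Climate: two latent landscape fields - a temperature-like step
  gradient T and a precipitation-like "monsoon bump plus gradient"
  field P - mixed linearly into 11 temperature-type and 8
  precipitation-type variables with noise. In the "crossing" scenario
  the climate boundary runs orthogonally to the lineage ranges, so
  climate clusters cannot coincide with lineages; in "aligned" it
  coincides with one lineage boundary.

Everything is deterministic given the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .io_tables import (
    MERISTIC_COLS,
    MORPHOMETRIC_COLS,
    ClimateTable,
    GenotypeMatrix,
    LocalityTable,
    SequenceAlignment,
    TraitTable,
)

BASES = np.array(list("ACGT"))

#: Default rooted topology for four populations: ((0,1),(2,3)).
DEFAULT_TOPOLOGY = ((0, 1), (2, 3))

#: Caterpillar topology for four-taxon introgression tests: (((P1,P2),P3),O).
QUARTET_TOPOLOGY = (((0, 1), 2), 3)

#: Drift profile for the introgression-test world, in depth-first branch
#: order for QUARTET_TOPOLOGY: deep internal branches and a long outgroup
#: branch (the tests target deeply diverged, well-supported splits) with
#: shallower drift on the sister tips P1/P2.
QUARTET_DRIFT = (0.5, 0.3, 0.2, 0.2, 0.5, 0.5)


@dataclass
class Ellipse:
    """Geographic range of one population (degrees)."""

    center: tuple[float, float]
    axes: tuple[float, float] = (0.7, 2.2)   # semi-axes (lon, lat)
    rotation: float = 0.0                     # radians

    def __post_init__(self) -> None:
        if min(self.axes) <= 0:
            raise ValueError("ellipse axes must be positive")

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        r = np.sqrt(rng.uniform(size=n))
        th = rng.uniform(0, 2 * np.pi, size=n)
        u = r * np.cos(th) * self.axes[0]
        v = r * np.sin(th) * self.axes[1]
        c, s = np.cos(self.rotation), np.sin(self.rotation)
        lon = self.center[0] + c * u - s * v
        lat = self.center[1] + s * u + c * v
        return np.column_stack([lon, lat])

    def contains(self, lon: float, lat: float) -> bool:
        c, s = np.cos(-self.rotation), np.sin(-self.rotation)
        u = c * (lon - self.center[0]) - s * (lat - self.center[1])
        v = s * (lon - self.center[0]) + c * (lat - self.center[1])
        return (u / self.axes[0]) ** 2 + (v / self.axes[1]) ** 2 <= 1.0 + 1e-12


def _default_ellipses(n_pops: int) -> list[Ellipse]:
    # ranges laid out west -> east; tall ellipses so a latitudinal climate
    # boundary cuts through every one of them ("crossing" scenario)
    centers = [(-116.5 + 2.0 * g, 30.0) for g in range(n_pops)]
    return [Ellipse(center=c) for c in centers]


@dataclass
class SimConfig:
    """Study conditions for one synthetic world.

    Defaults are the package's reference conditions: four lineages on a
    balanced tree, drift c = 0.25 per branch, 15 specimens per lineage,
    1000 SNP loci, a 590 bp mtDNA alignment, and the "crossing" climate
    scenario in which climate regions run orthogonal to lineage ranges.
    """

    topology: tuple = DEFAULT_TOPOLOGY
    n_pops: int = 4
    samples_per_pop: int = 15
    #: Balding-Nichols drift per branch: a scalar applied to every branch,
    #: or a sequence in depth-first branch order (parent before children).
    drift: float | tuple = 0.25
    n_snp_loci: int = 1000
    missing_rate: float = 0.05
    admixture: list = dc_field(default_factory=list)  # (donor_pop, recipient_pop, gamma)
    mtdna_length: int = 590
    mtdna_rate: float = 0.01                # substitutions / site / branch unit
    mtdna_tip_branch: float = 0.1
    meristic_base: np.ndarray = dc_field(
        default_factory=lambda: np.linspace(8.0, 30.0, len(MERISTIC_COLS))
    )
    meristic_shift: float = 4.0             # added per lineage index to every count mean
    allometric_alpha: tuple = (0.0, 0.04, 0.08, 0.12)
    allometric_beta: tuple = (1.0, 1.0, 1.0, 1.0)
    trait_sigma: float = 0.02               # residual sd on log10 morphometrics
    adult_fraction: float = 0.8
    ellipses: list = dc_field(default_factory=list)
    climate_scenario: str = "crossing"      # or "aligned"
    climate_noise_sd: float = 0.25
    climate_step_width: float = 0.3         # degrees; sharpness of the regime boundary
    precip_bump_amp: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        drifts = [self.drift] if np.isscalar(self.drift) else list(self.drift)
        if not all(0 < c < 1 for c in drifts):
            raise ValueError("drift must lie in (0, 1)")
        for _, _, gamma in self.admixture:
            if not (0 <= gamma < 1):
                raise ValueError("admixture gamma must lie in [0, 1)")
        if self.climate_scenario not in ("aligned", "crossing"):
            raise ValueError("climate_scenario must be 'aligned' or 'crossing'")
        if not self.ellipses:
            self.ellipses = _default_ellipses(self.n_pops)
        self.meristic_base = np.asarray(self.meristic_base, dtype=float)

    def specimen_ids(self) -> list[str]:
        return [
            f"P{g + 1}_{k + 1:02d}"
            for g in range(self.n_pops)
            for k in range(self.samples_per_pop)
        ]

    def lineage_of(self) -> np.ndarray:
        return np.repeat(np.arange(1, self.n_pops + 1), self.samples_per_pop)


@dataclass
class SimWorld:
    """All five tables plus the truth the generator knows."""

    config: SimConfig
    alignment: SequenceAlignment
    snps: GenotypeMatrix
    traits: TraitTable
    localities: LocalityTable
    climate: ClimateTable
    truth: dict        # specimen_id -> lineage label (1..G)
    truth_climate: dict  # specimen_id -> climate-region label (1/2)


def _tree_branches(topology) -> list[tuple]:
    """Flatten a nested-tuple topology into (parent_key, child_key) edges,
    root first; leaves are integers (population indices)."""
    edges = []

    def walk(node, key):
        if isinstance(node, tuple):
            for i, child in enumerate(node):
                child_key = key + (i,)
                edges.append((key, child_key, child))
                walk(child, child_key)

    walk(topology, ())
    return edges


def _leaf_keys(topology) -> dict[int, tuple]:
    keys = {}

    def walk(node, key):
        if isinstance(node, tuple):
            for i, child in enumerate(node):
                walk(child, key + (i,))
        else:
            keys[node] = key

    walk(topology, ())
    return keys


def sim_snps(config: SimConfig, rng: np.random.Generator | None = None) -> GenotypeMatrix:
    """Biallelic diploid SNP genotypes under Balding-Nichols drift."""
    rng = rng or np.random.default_rng(np.random.SeedSequence(config.seed).spawn(5)[0])
    L = config.n_snp_loci
    branches = _tree_branches(config.topology)
    if np.isscalar(config.drift):
        branch_c = [float(config.drift)] * len(branches)
    else:
        branch_c = [float(c) for c in config.drift]
        if len(branch_c) != len(branches):
            raise ValueError(
                f"per-branch drift needs {len(branches)} values, got {len(branch_c)}"
            )
    anc = rng.uniform(0.05, 0.95, size=L)
    node_freq = {(): anc}
    for (parent_key, child_key, _node), c in zip(branches, branch_c):
        p = np.clip(node_freq[parent_key], 1e-9, 1 - 1e-9)
        node_freq[child_key] = rng.beta(p * (1 - c) / c, (1 - p) * (1 - c) / c)
    leaf = _leaf_keys(config.topology)
    pop_freq = np.stack([node_freq[leaf[g]] for g in range(config.n_pops)])
    for donor, recipient, gamma in config.admixture:
        pop_freq[recipient] = (1 - gamma) * pop_freq[recipient] + gamma * pop_freq[donor]
    lineage = config.lineage_of() - 1
    geno = rng.binomial(2, pop_freq[lineage, :]).astype(float)
    if config.missing_rate > 0:
        mask = rng.uniform(size=geno.shape) < config.missing_rate
        geno[mask] = np.nan
    locus_ids = [f"snp_{j + 1}" for j in range(L)]
    return GenotypeMatrix(config.specimen_ids(), locus_ids, geno, ploidy=2)


def _mutate(seq: np.ndarray, n_sub: int, rng: np.random.Generator) -> np.ndarray:
    out = seq.copy()
    if n_sub == 0:
        return out
    sites = rng.integers(0, seq.size, size=n_sub)
    for s in sites:
        choices = BASES[BASES != out[s]]
        out[s] = choices[rng.integers(3)]
    return out


def sim_mtdna(config: SimConfig, rng: np.random.Generator | None = None) -> SequenceAlignment:
    """Haploid alignment under Jukes-Cantor Poisson substitution."""
    rng = rng or np.random.default_rng(np.random.SeedSequence(config.seed).spawn(5)[1])
    L = config.mtdna_length
    anc = BASES[rng.integers(4, size=L)]
    node_seq = {(): anc}
    for parent_key, child_key, _node in _tree_branches(config.topology):
        n_sub = rng.poisson(config.mtdna_rate * 1.0 * L)
        node_seq[child_key] = _mutate(node_seq[parent_key], n_sub, rng)
    leaf = _leaf_keys(config.topology)
    ids = config.specimen_ids()
    lineage = config.lineage_of() - 1
    seqs = []
    for g in lineage:
        n_sub = rng.poisson(config.mtdna_rate * config.mtdna_tip_branch * L)
        seqs.append("".join(_mutate(node_seq[leaf[g]], n_sub, rng)))
    return SequenceAlignment(ids=ids, seqs=seqs)


def sim_traits(
    config: SimConfig,
    rng: np.random.Generator | None = None,
    body_lengths: np.ndarray | None = None,
) -> TraitTable:
    """Meristic + allometric morphometric traits with lineage structure."""
    rng = rng or np.random.default_rng(np.random.SeedSequence(config.seed).spawn(5)[2])
    ids = config.specimen_ids()
    lineage = config.lineage_of() - 1
    n = len(ids)
    ontogeny = np.where(rng.uniform(size=n) < config.adult_fraction, "adult", "subadult")
    if body_lengths is None:
        svl_mean = np.where(ontogeny == "adult", 850.0, 450.0)
        body_lengths = svl_mean * np.exp(rng.normal(0, 0.08, size=n))
    meristic = rng.poisson(
        config.meristic_base[None, :] + config.meristic_shift * lineage[:, None]
    ).astype(float)
    alpha = np.asarray(config.allometric_alpha, dtype=float)[lineage]
    beta = np.asarray(config.allometric_beta, dtype=float)[lineage]
    log_svl = np.log10(body_lengths)
    base_offsets = np.linspace(-1.3, -0.3, len(MORPHOMETRIC_COLS))
    log_y = (
        alpha[:, None]
        + base_offsets[None, :]
        + beta[:, None] * log_svl[:, None]
        + rng.normal(0, config.trait_sigma, size=(n, len(MORPHOMETRIC_COLS)))
    )
    df = pd.DataFrame({"specimen_id": ids})
    df["sex"] = np.where(rng.uniform(size=n) < 0.5, "F", "M")
    df["ontogeny"] = ontogeny
    df["body_length"] = body_lengths
    for j, col in enumerate(MERISTIC_COLS):
        df[col] = meristic[:, j]
    for j, col in enumerate(MORPHOMETRIC_COLS):
        df[col] = 10.0 ** log_y[:, j]
    return TraitTable(df)


def sim_localities(config: SimConfig, rng: np.random.Generator | None = None) -> LocalityTable:
    """Uniform specimen localities inside each population's range ellipse."""
    rng = rng or np.random.default_rng(np.random.SeedSequence(config.seed).spawn(5)[3])
    coords = np.vstack(
        [config.ellipses[g].sample(config.samples_per_pop, rng) for g in range(config.n_pops)]
    )
    df = pd.DataFrame(
        {"specimen_id": config.specimen_ids(), "lon": coords[:, 0], "lat": coords[:, 1]}
    )
    return LocalityTable(df)


# fixed mixing weights: 11 temperature-type variables load mainly on the
# T field, 8 precipitation-type mainly on P (mirrors bioclim structure)
_TEMP_W_T = np.array([1.2, 1.1, 0.9, 1.0, 1.3, 0.8, 1.05, 0.95, 1.15, 0.85, 1.0])
_TEMP_W_P = np.array([0.1, -0.15, 0.05, 0.2, -0.1, 0.15, -0.05, 0.1, -0.2, 0.05, 0.12])
_PRECIP_W_P = np.array([1.1, 0.9, 1.2, 1.0, 0.85, 1.15, 0.95, 1.05])
_PRECIP_W_T = np.array([0.1, -0.12, 0.08, 0.15, -0.1, 0.05, 0.12, -0.08])


def climate_fields(config: SimConfig, lon: np.ndarray, lat: np.ndarray):
    """Latent temperature-like (T) and precipitation-like (P) fields.

    T is a sharp tanh step across the regime boundary — latitudinal in
    the "crossing" scenario, longitudinal (coinciding with the boundary
    between the second and third lineage ranges) in "aligned". P is a
    Gaussian monsoon bump plus a gentle gradient.
    """
    centers = np.array([e.center for e in config.ellipses])
    if config.climate_scenario == "crossing":
        boundary = float(np.mean(centers[:, 1]))
        T = np.tanh((lat - boundary) / config.climate_step_width)
    else:
        mid = (config.n_pops - 1) / 2.0
        boundary = float(np.interp(mid, np.arange(config.n_pops), np.sort(centers[:, 0])))
        T = np.tanh((lon - boundary) / config.climate_step_width)
    bump_center = (centers[:, 0].max() + 4.0, centers[:, 1].min() - 4.0)
    P = config.precip_bump_amp * np.exp(
        -(((lon - bump_center[0]) / 3.0) ** 2 + ((lat - bump_center[1]) / 3.0) ** 2) / 2.0
    ) + 0.03 * (lat - centers[:, 1].mean())
    return T, P


def sim_climate(
    config: SimConfig,
    localities: LocalityTable,
    rng: np.random.Generator | None = None,
) -> tuple[ClimateTable, np.ndarray]:
    """Nineteen bioclim-style variables plus the true climate-region labels."""
    rng = rng or np.random.default_rng(np.random.SeedSequence(config.seed).spawn(5)[4])
    coords = localities.coords()
    lon, lat = coords[:, 0], coords[:, 1]
    T, P = climate_fields(config, lon, lat)
    n = lon.size
    df = pd.DataFrame({"specimen_id": localities.specimen_ids})
    for i in range(11):
        latent = _TEMP_W_T[i] * T + _TEMP_W_P[i] * P
        df[f"bio{i + 1:02d}"] = 20.0 + 6.0 * (latent + rng.normal(0, config.climate_noise_sd, n))
    for i in range(8):
        latent = _PRECIP_W_P[i] * P + _PRECIP_W_T[i] * T
        x = 2.0 * (latent + rng.normal(0, config.climate_noise_sd, n))
        df[f"bio{i + 12:02d}"] = 40.0 * np.log1p(np.exp(x))   # softplus keeps precip >= 0
    truth_climate = np.where(T > 0, 2, 1)
    return ClimateTable(df), truth_climate


def quartet_world_config(gamma: float = 0.0, n_loci: int = 5000, seed: int = 0) -> SimConfig:
    """Config for a four-taxon introgression-test world.

    A caterpillar tree (((P1,P2),P3),O) with the deep-divergence drift
    profile; ``gamma`` > 0 adds a P3 -> P2 admixture pulse. Two samples
    per population so quartets draw single representatives.
    """
    return SimConfig(
        topology=QUARTET_TOPOLOGY,
        drift=QUARTET_DRIFT,
        samples_per_pop=2,
        n_snp_loci=n_loci,
        missing_rate=0.0,
        admixture=[(2, 1, gamma)] if gamma > 0 else [],
        seed=seed,
    )


def sim_world(config: SimConfig) -> SimWorld:
    """Compose the five generators from one seed tree; deterministic."""
    streams = np.random.SeedSequence(config.seed).spawn(5)
    rng_snp, rng_mt, rng_tr, rng_loc, rng_cl = (np.random.default_rng(s) for s in streams)
    snps = sim_snps(config, rng_snp)
    alignment = sim_mtdna(config, rng_mt)
    traits = sim_traits(config, rng_tr)
    localities = sim_localities(config, rng_loc)
    climate, truth_climate = sim_climate(config, localities, rng_cl)
    ids = config.specimen_ids()
    truth = dict(zip(ids, config.lineage_of().tolist()))
    return SimWorld(
        config=config,
        alignment=alignment,
        snps=snps,
        traits=traits,
        localities=localities,
        climate=climate,
        truth=truth,
        truth_climate=dict(zip(ids, truth_climate.tolist())),
    )
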