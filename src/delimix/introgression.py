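"""Four-taxon ABBA–BABA (Patterson's D) tests of introgression.

For a quartet (P1, P2, P3, O) of single representative individuals, the
statistic contrasts the two discordant site patterns expected under
incomplete lineage sorting alone:

    D = (sum ABBA - sum BABA) / (sum ABBA + sum BABA)

with per-site weights abba = (1-p1) p2 p3 (1-p4) and
baba = p1 (1-p2) p3 (1-p4) on derived-allele frequencies polarized by
the outgroup's major allele. Under ILS without gene flow E[D] = 0;
an excess of ABBA (D > 0) indicates P3<->P2 gene flow, an excess of
BABA (D < 0) P3<->P1. Significance comes from a delete-m_j block
jackknife over loci in order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import IdError
from .io_tables import GenotypeMatrix


@dataclass(frozen=True)
class QuartetSpec:
    """Single-individual representatives of ((P1,P2),P3),O."""

    P1: str
    P2: str
    P3: str
    O: str

    def ids(self) -> tuple[str, str, str, str]:
        return (self.P1, self.P2, self.P3, self.O)

    def __post_init__(self) -> None:
        if len(set(self.ids())) != 4:
            raise IdError("quartet must name four distinct samples")


@dataclass
class DResult:
    """ABBA/BABA sums and the D statistic for one quartet (SE/Z/p optional)."""

    quartet: QuartetSpec
    n_sites_used: int
    abba_sum: float
    baba_sum: float
    D: float                      # NaN when abba_sum + baba_sum == 0
    se: float = np.nan
    Z: float = np.nan
    p: float = np.nan

    @property
    def defined(self) -> bool:
        return np.isfinite(self.D)


def site_weights(p1, p2, p3, p4) -> tuple[np.ndarray, np.ndarray]:
    """ABBA and BABA weights from derived-allele frequencies in [0,1]."""
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    abba = (1 - p1) * p2 * p3 * (1 - p4)
    baba = p1 * (1 - p2) * p3 * (1 - p4)
    return abba, baba


def _derived_frequencies(gm: GenotypeMatrix, quartet: QuartetSpec) -> np.ndarray:
    """Per-site derived-allele frequencies (4 x usable sites).

    Sites are dropped when any quartet member is missing or when the
    outgroup is heterozygous (its major allele defines the ancestral
    state, so a het outgroup carries no polarity information).
    """
    index = {s: i for i, s in enumerate(gm.sample_ids)}
    try:
        rows = [index[s] for s in quartet.ids()]
    except KeyError as exc:
        raise IdError(f"quartet sample {exc.args[0]!r} absent from genotype matrix") from exc
    G = gm.genotypes[rows, :]
    freq = G / gm.ploidy
    usable = ~np.any(np.isnan(G), axis=0)
    if gm.ploidy == 2:
        usable &= G[3] != 1
    freq = freq[:, usable]
    # polarize: outgroup major allele is ancestral -> derived freq flips
    # at sites where the outgroup carries the alternate allele
    flip = freq[3] > 0.5
    freq[:, flip] = 1.0 - freq[:, flip]
    return freq


def patterson_d(gm: GenotypeMatrix, quartet: QuartetSpec) -> DResult:
    """Patterson's D for one quartet, without significance."""
    freq = _derived_frequencies(gm, quartet)
    abba, baba = site_weights(freq[0], freq[1], freq[2], freq[3])
    asum, bsum = float(abba.sum()), float(baba.sum())
    denom = asum + bsum
    D = (asum - bsum) / denom if denom > 0 else np.nan
    return DResult(
        quartet=quartet, n_sites_used=freq.shape[1],
        abba_sum=asum, baba_sum=bsum, D=D,
    )


def block_jackknife(
    abba: np.ndarray, baba: np.ndarray, n_blocks: int = 50
) -> tuple[float, float, float]:
    """Delete-m_j block jackknife SE, Z and two-sided normal p for D.

    Sites are cut into contiguous near-equal blocks in locus order;
    each block is deleted in turn and D recomputed; the weighted
    delete-m_j jackknife variance (Busing et al.) gives the SE. If
    there are fewer informative sites than blocks the block count is
    reduced to floor(sites/5). SE = 0 (identical blocks) is reported
    as Z = +/-inf, p = 0.
    """
    abba = np.asarray(abba, dtype=float)
    baba = np.asarray(baba, dtype=float)
    informative = (abba + baba) > 0
    n_info = int(informative.sum())
    if n_info == 0:
        return np.nan, np.nan, np.nan
    if n_info < n_blocks:
        n_blocks = max(2, n_info // 5)
    n_sites = abba.size
    bounds = np.linspace(0, n_sites, n_blocks + 1).astype(int)
    asum, bsum = abba.sum(), baba.sum()
    theta_hat = (asum - bsum) / (asum + bsum)
    theta_j = np.empty(n_blocks)
    m_j = np.empty(n_blocks)
    for j in range(n_blocks):
        lo, hi = bounds[j], bounds[j + 1]
        a = asum - abba[lo:hi].sum()
        b = bsum - baba[lo:hi].sum()
        theta_j[j] = (a - b) / (a + b) if (a + b) > 0 else theta_hat
        m_j[j] = informative[lo:hi].sum()
    m_j = np.maximum(m_j, 1e-12)
    n = m_j.sum()
    h_j = n / m_j
    theta_dot = n_blocks * theta_hat - np.sum((1 - m_j / n) * theta_j)
    var = np.sum((h_j * theta_hat - (h_j - 1) * theta_j - theta_dot) ** 2 / (h_j - 1)) / n_blocks
    se = float(np.sqrt(max(var, 0.0)))
    if se < 1e-12:  # identical blocks up to floating-point noise
        z = np.inf if theta_hat >= 0 else -np.inf
        return 0.0, float(z), 0.0
    z = theta_hat / se
    p = 2.0 * stats.norm.sf(abs(z))
    return se, float(z), float(p)


def patterson_d_test(gm: GenotypeMatrix, quartet: QuartetSpec, n_blocks: int = 50) -> DResult:
    """D with block-jackknife SE, Z and two-sided p for one quartet."""
    freq = _derived_frequencies(gm, quartet)
    abba, baba = site_weights(freq[0], freq[1], freq[2], freq[3])
    res = patterson_d(gm, quartet)
    if not res.defined:
        return res
    res.se, res.Z, res.p = block_jackknife(abba, baba, n_blocks=n_blocks)
    return res


#: Significance threshold applied in the battery output.
BATTERY_ALPHA = 0.001


def test_battery(
    gm: GenotypeMatrix, quartets: list[QuartetSpec], n_blocks: int = 50
) -> pd.DataFrame:
    """Run a battery of quartet tests; one row per quartet.

    Columns mirror the standard D-statistics report: P1, P2, P3, O,
    nsites, D, Z, p, and a significance flag at p <= 0.001.
    """
    rows = []
    for q in quartets:
        r = patterson_d_test(gm, q, n_blocks=n_blocks)
        rows.append(
            (q.P1, q.P2, q.P3, q.O, r.n_sites_used, r.D, r.Z, r.p,
             bool(np.isfinite(r.p) and r.p <= BATTERY_ALPHA))
        )
    return pd.DataFrame(
        rows, columns=["P1", "P2", "P3", "O", "nsites", "D", "Z", "p", "significant"]
    )


def read_quartets(path) -> list[QuartetSpec]:
    """Read a quartets CSV with columns P1,P2,P3,O."""
    df = pd.read_csv(path)
    missing = [c for c in ("P1", "P2", "P3", "O") if c not in df.columns]
    if missing:
        raise IdError(f"quartets file missing columns: {missing}")
    return [QuartetSpec(r.P1, r.P2, r.P3, r.O) for r in df.itertuples()]
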