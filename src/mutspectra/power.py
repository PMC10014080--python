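"""Power to detect generation-time-driven C>G/T>A differences.

Maternal age disproportionately drives C>G mutations, and a third of the
overall maternal age effect concentrates in "C>G enriched" hotspot regions
covering ~10% of the genome. If interpopulation differences in the C>G/T>A
polymorphism ratio were caused by maternal-age differences, the signal
should therefore be much stronger inside the hotspots than outside, despite
their smaller SNP counts — a testable prediction.

The simulation draws, for two populations with generation times G1 and G2,
binomial counts of C>G and T>A SNPs whose expected fractions among all
single-nucleotide DNM classes follow from the fitted parental-age effects at
(G, G), and evaluates a 2x2 chi-square (two types x two populations) per
replicate. Power is the fraction of replicates below the significance
threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .dnm import ParentalAgeEffect


@dataclass
class PowerConfig:
    G_values: tuple[float, ...] = (20.0, 25.0, 30.0, 35.0, 40.0)
    n_snps: int = 100_000
    n_reps: int = 10_000
    alpha: float = 0.001
    seed: int | None = None

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")


def expected_fractions(
    effects: dict[str, ParentalAgeEffect], G: float
) -> dict[str, float]:
    """Expected fraction of each class among all de novo single-nucleotide
    mutations when both parents reproduce at age G."""
    means = {c: max(e.total_mean(G, G), 0.0) for c, e in effects.items()}
    total = sum(means.values())
    if total <= 0:
        raise ValueError("non-positive total expected mutation count")
    return {c: m / total for c, m in means.items()}


def _chisq_2x2_p(a, b, c, d):
    """Vectorized Pearson chi-square p-values for 2x2 tables [[a,b],[c,d]]
    (no continuity correction)."""
    a, b, c, d = (np.asarray(x, dtype=float) for x in (a, b, c, d))
    n = a + b + c + d
    num = n * (a * d - b * c) ** 2
    den = (a + b) * (c + d) * (a + c) * (b + d)
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.where(den > 0, num / den, 0.0)
    return stats.chi2.sf(chi2, 1)


def simulate_power(
    effects: dict[str, ParentalAgeEffect],
    G1: float,
    G2: float,
    n_snps: int = 100_000,
    n_reps: int = 10_000,
    alpha: float = 0.001,
    seed: int | None = None,
    numerator_class: str = "C>G",
    denominator_class: str = "T>A",
) -> float:
    """Power of the 2x2 chi-square to detect the ratio difference between
    generation times G1 and G2 at the given per-population SNP count."""
    rng = np.random.default_rng(seed)
    counts = {}
    for pop, G in (("pop1", G1), ("pop2", G2)):
        fr = expected_fractions(effects, G)
        f_num, f_den = fr[numerator_class], fr[denominator_class]
        if not (0 < f_num < 1 and 0 < f_den < 1):
            raise ValueError("degenerate expected fractions")
        counts[pop] = (
            rng.binomial(n_snps, f_num, size=n_reps),
            rng.binomial(n_snps, f_den, size=n_reps),
        )
    p = _chisq_2x2_p(
        counts["pop1"][0], counts["pop2"][0], counts["pop1"][1], counts["pop2"][1]
    )
    return float(np.mean(p < alpha))


def hotspot_effects(
    effects: dict[str, ParentalAgeEffect],
    hotspot_genome_share: float = 0.10,
    maternal_effect_share: float | None = None,
    inside: bool = True,
    maternal_class: str = "C>G",
) -> dict[str, ParentalAgeEffect]:
    """Region-specific parental-age effects inside/outside maternal C>G
    hotspots.

    All parameters scale with the region's share of the genome, except the
    maternal C>G slope: hotspots carry ``maternal_effect_share`` of the
    genome-wide maternal C>G age effect (the complement falls outside). The
    default derives that share from the hotspots' defining property — they
    hold one-third of the overall maternal age effect summed over classes —
    so share = (total maternal slope / 3) / beta_m(C>G), capped at 1.
    """
    if not 0 < hotspot_genome_share < 1:
        raise ValueError("hotspot share must be in (0, 1)")
    if maternal_effect_share is None:
        total_maternal = sum(e.beta_m for e in effects.values())
        maternal_effect_share = min(
            1.0, total_maternal / 3.0 / effects[maternal_class].beta_m
        )
    share = hotspot_genome_share if inside else 1.0 - hotspot_genome_share
    m_share = maternal_effect_share if inside else 1.0 - maternal_effect_share
    out = {}
    for cls, e in effects.items():
        beta_m = e.beta_m * (m_share if cls == maternal_class else share)
        out[cls] = ParentalAgeEffect(
            cls, e.alpha_p * share, e.beta_p * share, e.alpha_m * share, beta_m
        )
    return out


def compare_hotspot_power(
    effects: dict[str, ParentalAgeEffect],
    G1: float,
    G2: float,
    config: PowerConfig | None = None,
    hotspot_snp_share: float = 0.15,
    hotspot_genome_share: float = 0.10,
    maternal_effect_share: float | None = None,
) -> tuple[float, float]:
    """(power inside hotspots, power outside) for a G1-vs-G2 contrast.

    Hotspot SNP counts default to 15% of the genome-wide count (hotspots
    hold <15% of SNPs); the maternal C>G slope enrichment follows from
    one-third of the maternal age effect concentrated in 10% of the genome.
    """
    config = config or PowerConfig()
    powers = []
    for inside in (True, False):
        region = hotspot_effects(
            effects, hotspot_genome_share, maternal_effect_share, inside
        )
        share = hotspot_snp_share if inside else 1.0 - hotspot_snp_share
        powers.append(
            simulate_power(
                region,
                G1,
                G2,
                n_snps=int(round(config.n_snps * share)),
                n_reps=config.n_reps,
                alpha=config.alpha,
                seed=config.seed,
            )
        )
    return powers[0], powers[1]
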