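"""Pairwise mutation ratios matched for GC-biased gene conversion.

Comparing raw class fractions across populations confounds the mutation
process with gBGC, which favors weak-to-strong (T>C, T>G) over
strong-to-weak (C>A, C>T) alleles with a strength that depends on effective
population size. Ratios of two classes on the same side of gBGC cancel that
effect to first order. The four canonical comparisons are:

1. non-CpG C>T / non-CpG C>A   (both S>W, same mutational opportunity)
2. CpG C>T / CpG C>A           (both S>W at CpG sites)
3. C>G / T>A                   (both gBGC-neutral)
4. T>C / T>G                   (both W>S, same opportunity)

Confidence intervals treat the two pseudo-counts as binomial conditional on
their total; interpopulation differences are tested per age bin with a
Pearson chi-square on the 2 x N_pop pseudo-count table, Bonferroni-corrected
for (number of bins) x (number of ratios) tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class PairwiseRatioDefinition:
    """Numerator and denominator mutation-class labels of one ratio.

    Labels may be lists to aggregate several refined classes (e.g. all C>G
    regardless of CpG status when tables are built at full resolution).
    """

    numerator: tuple[str, ...]
    denominator: tuple[str, ...]
    label: str

    def __post_init__(self):
        if set(self.numerator) & set(self.denominator):
            raise ValueError(f"{self.label}: numerator and denominator overlap")


def _ratio(label, num, den) -> PairwiseRatioDefinition:
    to_tuple = lambda x: (x,) if isinstance(x, str) else tuple(x)
    return PairwiseRatioDefinition(to_tuple(num), to_tuple(den), label)


#: the four gBGC-matched comparisons on eight-class tables
STANDARD_RATIOS = (
    _ratio("C>T_nonCpG/C>A_nonCpG", "C>T_nonCpG", "C>A"),
    _ratio("C>T_CpG/C>A_CpG", "C>T_CpG", "C>A"),
    _ratio("C>G/T>A", "C>G", "T>A"),
    _ratio("T>C/T>G", ("T>C_TpG", "T>C_nonTpG"), "T>G"),
)

#: same four ratios on full-resolution tables (C>A and C>G split by CpG),
#: with the CpG-matched denominators the comparisons call for and the
#: TpG-excluded variant of the T>C/T>G ratio
FULL_RESOLUTION_RATIOS = (
    _ratio("C>T_nonCpG/C>A_nonCpG", "C>T_nonCpG", "C>A_nonCpG"),
    _ratio("C>T_CpG/C>A_CpG", "C>T_CpG", "C>A_CpG"),
    _ratio("C>G/T>A", ("C>G_CpG", "C>G_nonCpG"), "T>A"),
    _ratio("T>C_nonTpG/T>G", "T>C_nonTpG", "T>G"),
)


@dataclass
class RatioEstimate:
    """A pseudo-count ratio with its normal-approximation CI.

    The fraction p̂ = n1/(n1+n2) gets the usual Wald interval
    p̂ ± z·sqrt(p̂(1−p̂)/(n1+n2)); the fraction CI maps to a ratio CI through
    p → p/(1−p), clipped to [0, ∞).
    """

    ratio: float
    ci_lower: float
    ci_upper: float
    n1: float
    n2: float
    p_hat: float
    z: float = 1.96
    degenerate: bool = False


def ratio_with_ci(n1: float, n2: float, z: float = 1.96) -> RatioEstimate:
    """Ratio n1/n2 of two pseudo-counts with a binomial-derived CI."""
    if n1 < 0 or n2 < 0 or n1 + n2 <= 0:
        raise ValueError("pseudo-counts must be non-negative with n1 + n2 > 0")
    if n2 == 0:
        return RatioEstimate(
            np.inf, np.nan, np.nan, n1, n2, 1.0, z, degenerate=True
        )
    total = n1 + n2
    p_hat = n1 / total
    half = z * np.sqrt(p_hat * (1.0 - p_hat) / total)
    p_lo = max(p_hat - half, 0.0)
    p_hi = min(p_hat + half, 1.0)
    degenerate = p_hat in (0.0, 1.0)
    lo = p_lo / (1.0 - p_lo)
    hi = p_hi / (1.0 - p_hi) if p_hi < 1.0 else np.inf
    return RatioEstimate(n1 / n2, lo, hi, n1, n2, p_hat, z, degenerate)


def interpopulation_chisq(table) -> tuple[float, float]:
    """Pearson chi-square on a 2 x N_pop pseudo-count table.

    Entries may be fractional (pseudo-counts are used directly, not
    rounded); degrees of freedom are N_pop − 1 and no continuity correction
    is applied.
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] != 2:
        raise ValueError("expected a 2 x N_pop table")
    if np.any(obs < 0):
        raise ValueError("negative pseudo-counts")
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    if np.any(row == 0) or np.any(col == 0):
        raise ValueError("zero row or column total")
    expected = row * col / obs.sum()
    statistic = float(((obs - expected) ** 2 / expected).sum())
    df = obs.shape[1] - 1
    return statistic, float(stats.chi2.sf(statistic, df))


def bonferroni_adjust(p: float, n_age_bins: int = 15, n_ratios: int = 4) -> float:
    """Bonferroni correction over (bins x ratios) tests, capped at 1."""
    if not 0 <= p <= 1:
        raise ValueError("p must lie in [0, 1]")
    return min(1.0, p * n_age_bins * n_ratios)


def significance_tier(p_adjusted: float) -> str:
    """Asterisk tiers after correction: * p<0.01, ** p<1e-4, *** p<1e-8."""
    if p_adjusted < 1e-8:
        return "***"
    if p_adjusted < 1e-4:
        return "**"
    if p_adjusted < 0.01:
        return "*"
    return ""


def ratio_trajectories(
    tables: dict[str, pd.DataFrame],
    definitions=STANDARD_RATIOS,
    z: float = 1.96,
    n_age_bins: int | None = None,
) -> pd.DataFrame:
    """Tidy per-(population, bin, ratio) estimates with interpopulation tests.

    ``tables`` maps population label to its pseudo-count table (classes x
    bins, identical layouts). Returns columns: population, age_bin, ratio
    label, ratio, ci_lower, ci_upper, n1, n2, p_raw, p_adjusted. The
    chi-square p-value per (bin, ratio) is shared across populations.
    """
    pops = list(tables)
    any_table = next(iter(tables.values()))
    n_bins = any_table.shape[1]
    if n_age_bins is None:
        n_age_bins = n_bins
    rows = []
    for rdef in definitions:
        for b in range(n_bins):
            n1s = {
                p: float(
                    tables[p].reindex(list(rdef.numerator)).fillna(0.0).iloc[:, b].sum()
                )
                for p in pops
            }
            n2s = {
                p: float(
                    tables[p].reindex(list(rdef.denominator)).fillna(0.0).iloc[:, b].sum()
                )
                for p in pops
            }
            contingency = np.array([[n1s[p] for p in pops], [n2s[p] for p in pops]])
            try:
                _, p_raw = interpopulation_chisq(contingency)
            except ValueError:
                p_raw = np.nan
            p_adj = (
                bonferroni_adjust(p_raw, n_age_bins, len(definitions))
                if np.isfinite(p_raw)
                else np.nan
            )
            for p in pops:
                if n1s[p] + n2s[p] <= 0:
                    continue
                est = ratio_with_ci(n1s[p], n2s[p], z)
                rows.append(
                    {
                        "population": p,
                        "age_bin": b,
                        "ratio_label": rdef.label,
                        "ratio": est.ratio,
                        "ci_lower": est.ci_lower,
                        "ci_upper": est.ci_upper,
                        "n1": est.n1,
                        "n2": est.n2,
                        "p_raw": p_raw,
                        "p_adjusted": p_adj,
                    }
                )
    return pd.DataFrame(rows)


def stratify_by_regions(
    variants: pd.DataFrame, regions: dict[str, np.ndarray]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition variants into (inside, outside) a merged interval set.

    ``regions`` maps chromosome to an (n, 2) array of 0-based half-open
    intervals (BED convention, already merged and sorted); variant positions
    are 1-based, so position p is inside iff p−1 falls in an interval.
    """
    inside = np.zeros(len(variants), dtype=bool)
    pos0 = variants["pos"].to_numpy(dtype=np.int64) - 1
    chroms = variants["chrom"].to_numpy()
    for chrom, intervals in regions.items():
        intervals = np.asarray(intervals)
        if intervals.size == 0:
            continue
        if intervals.ndim != 2 or np.any(intervals[:, 0] >= intervals[:, 1]):
            raise ValueError(f"malformed intervals for {chrom}")
        mask = chroms == chrom
        if not mask.any():
            continue
        p = pos0[mask]
        idx = np.searchsorted(intervals[:, 0], p, side="right") - 1
        ok = idx >= 0
        hit = np.zeros(p.size, dtype=bool)
        hit[ok] = p[ok] < intervals[idx[ok], 1]
        inside[mask] = hit
    return variants[inside].copy(), variants[~inside].copy()
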