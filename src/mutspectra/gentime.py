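"""Inverting polymorphism ratios to past generation times.

If shifts in average reproductive age were the sole driver of a change in a
pairwise mutation ratio, the observed ratio R of pseudo-counts in an age bin
would satisfy

    (beta_p1*Gp + alpha_p1 + beta_m1*Gm + alpha_m1)
    ----------------------------------------------- = R
    (beta_p2*Gp + alpha_p2 + beta_m2*Gm + alpha_m2)

with (alpha, beta) the intercepts and slopes fitted to trio DNM data. Fixing
the paternal/maternal age ratio gamma = Gp/Gm turns this into one linear
equation with the closed-form solution

    Gm = [R*(alpha_p2 + alpha_m2) − (alpha_p1 + alpha_m1)]
         / [(beta_p1*gamma + beta_m1) − R*(beta_p2*gamma + beta_m2)]

Solutions are flagged infeasible when the denominator vanishes, Gm is
non-positive, or the implied ages fall outside a plausible human
reproductive range (default 13–55 years, puberty to reproductive
cessation). With Gp and Gm free, the solutions form a line in the
(Gp, Gm) plane; its coefficients are reported for contour plots.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dnm import BootstrapSet, ParentalAgeEffect, predict_ratio

#: plausible human reproductive ages in years
PLAUSIBLE_RANGE = (13.0, 55.0)

#: paternal/maternal age ratios explored
GAMMA_GRID = (0.8, 1.0, 1.1, 1.2)


@dataclass
class GenerationTimeSolution:
    Gm: float
    Gp: float
    gamma: float
    feasible: bool
    ci_lower: float = np.nan
    ci_upper: float = np.nan
    infeasible_fraction: float = np.nan


def solve_generation_time(
    R: float,
    effect1: ParentalAgeEffect,
    effect2: ParentalAgeEffect,
    gamma: float = 1.0,
    plausible_range: tuple[float, float] = PLAUSIBLE_RANGE,
) -> GenerationTimeSolution:
    """Solve the ratio constraint for (Gp, Gm) at a fixed Gp/Gm = gamma."""
    if R <= 0 or gamma <= 0:
        raise ValueError("R and gamma must be positive")
    numerator = R * (effect2.alpha_p + effect2.alpha_m) - (
        effect1.alpha_p + effect1.alpha_m
    )
    denominator = (effect1.beta_p * gamma + effect1.beta_m) - R * (
        effect2.beta_p * gamma + effect2.beta_m
    )
    if abs(denominator) < 1e-12:
        return GenerationTimeSolution(np.nan, np.nan, gamma, False)
    Gm = numerator / denominator
    Gp = gamma * Gm
    lo, hi = plausible_range
    feasible = Gm > 0 and lo <= Gm <= hi and lo <= Gp <= hi
    return GenerationTimeSolution(float(Gm), float(Gp), gamma, feasible)


def bootstrap_generation_time(
    R,
    boot1: BootstrapSet,
    boot2: BootstrapSet,
    gamma: float = 1.0,
    level: float = 0.90,
    plausible_range: tuple[float, float] = PLAUSIBLE_RANGE,
) -> GenerationTimeSolution:
    """Percentile CI of the generation time over paired bootstrap replicates.

    Replicates of the two classes are paired by resample index (both classes
    refit on the same resampled trios), preserving their correlation. The CI
    is taken among feasible solutions; the infeasible fraction is reported.

    ``R`` may be a scalar or a sequence; passing the observed ratio together
    with its own CI endpoints folds the polymorphism sampling uncertainty
    into the interval alongside the pedigree uncertainty.
    """
    r1, r2 = boot1.replicates, boot2.replicates
    if len(r1) != len(r2):
        raise ValueError("bootstrap sets must be paired by resample index")
    R_values = np.atleast_1d(np.asarray(R, dtype=float))
    sols = []
    for i in range(len(r1)):
        a, b = r1.iloc[i], r2.iloc[i]
        if a.isna().any() or b.isna().any():
            sols.extend([np.nan] * R_values.size)
            continue
        e1 = ParentalAgeEffect(boot1.mutation_class, a.alpha_p, a.beta_p,
                               a.alpha_m, a.beta_m)
        e2 = ParentalAgeEffect(boot2.mutation_class, b.alpha_p, b.beta_p,
                               b.alpha_m, b.beta_m)
        for r in R_values:
            s = solve_generation_time(r, e1, e2, gamma, plausible_range)
            sols.append(s.Gm if s.feasible else np.nan)
    sols = np.asarray(sols, dtype=float)
    feasible = sols[np.isfinite(sols)]
    infeasible_fraction = 1.0 - feasible.size / sols.size
    if feasible.size == 0:
        raise ValueError("all bootstrap replicates infeasible")
    lo = (1.0 - level) / 2.0
    ci_lower, ci_upper = np.quantile(feasible, [lo, 1.0 - lo])
    point = np.nanmedian(feasible)
    return GenerationTimeSolution(
        float(point), float(gamma * point), gamma, True,
        float(ci_lower), float(ci_upper), float(infeasible_fraction),
    )


def constraint_line(
    R: float, effect1: ParentalAgeEffect, effect2: ParentalAgeEffect
) -> tuple[float, float, float]:
    """Coefficients (a, b, c) of the line a*Gp + b*Gm = c of all (Gp, Gm)
    reproducing the ratio R; degenerate (a=b=0, c!=0) raises."""
    if R <= 0:
        raise ValueError("R must be positive")
    a = effect1.beta_p - R * effect2.beta_p
    b = effect1.beta_m - R * effect2.beta_m
    c = R * (effect2.alpha_p + effect2.alpha_m) - (
        effect1.alpha_p + effect1.alpha_m
    )
    if a == 0 and b == 0 and c != 0:
        raise ValueError("inconsistent constraint: no (Gp, Gm) satisfies R")
    return float(a), float(b), float(c)


def generation_time_trajectory(
    ratios: "np.ndarray | list[float]",
    effect1: ParentalAgeEffect,
    effect2: ParentalAgeEffect,
    gamma: float = 1.0,
    boot1: BootstrapSet | None = None,
    boot2: BootstrapSet | None = None,
    plausible_range: tuple[float, float] = PLAUSIBLE_RANGE,
) -> list[GenerationTimeSolution]:
    """Per-bin generation-time solutions for one ratio trajectory, with
    bootstrap CIs when replicate sets are given."""
    out = []
    for R in ratios:
        sol = solve_generation_time(R, effect1, effect2, gamma, plausible_range)
        if boot1 is not None and boot2 is not None:
            try:
                ci = bootstrap_generation_time(
                    R, boot1, boot2, gamma, plausible_range=plausible_range
                )
                sol.ci_lower, sol.ci_upper = ci.ci_lower, ci.ci_upper
                sol.infeasible_fraction = ci.infeasible_fraction
            except ValueError:
                sol.infeasible_fraction = 1.0
        out.append(sol)
    return out


__all__ = [
    "GenerationTimeSolution",
    "solve_generation_time",
    "bootstrap_generation_time",
    "constraint_line",
    "generation_time_trajectory",
    "predict_ratio",
    "PLAUSIBLE_RANGE",
    "GAMMA_GRID",
]
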