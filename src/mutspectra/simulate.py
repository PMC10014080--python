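"""Synthetic variant and trio datasets with the structure the analysis assumes.

Two generators make the whole pipeline testable without external downloads:

* :func:`simulate_variant_dataset` draws polymorphisms under a configurable
  time-varying mutation spectrum. Time is divided into epochs, each with its
  own probability vector over mutation classes; a variant's true age is
  uniform within its epoch and its reported age interval is a uniform
  uncertainty window around the true age whose relative half-width is
  lognormal (median 0.5x the true age by default), mimicking the
  order-of-magnitude uncertainty of genealogy-based allele ages.

* :func:`simulate_trio_dataset` draws per-trio DNM counts whose means are
  linear in parental ages: paternal counts ~ Poisson(beta_p*Fa + alpha_p),
  maternal ~ Poisson(beta_m*Mo + alpha_m), with each mutation independently
  parent-of-origin phased with a fixed probability, the rest counted as
  unphased.

Neither generator models linkage, selection, gBGC or coalescent genealogy;
variants are independent draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classes import BASES, COMPLEMENT, MutationClass
from .dnm import ParentalAgeEffect

_FRACTION_TOL = 1e-9


@dataclass(frozen=True)
class Epoch:
    """One spectrum epoch: ages in [age_start, age_end) generations share the
    same class-fraction vector."""

    age_start: float
    age_end: float
    class_fractions: dict

    def __post_init__(self):
        if not self.class_fractions:
            raise ValueError("empty class fractions")
        if self.age_end <= self.age_start or self.age_start < 0:
            raise ValueError("invalid epoch ages")
        total = sum(self.class_fractions.values())
        if abs(total - 1.0) > _FRACTION_TOL:
            raise ValueError(f"class fractions sum to {total}, not 1")


@dataclass
class SpectrumScenario:
    epochs: list
    n_variants: int
    populations: dict = field(default_factory=lambda: {"POP": 1.0})
    interval_halfwidth_median: float = 0.5
    interval_halfwidth_sigma: float = 0.6
    seed: int | None = None

    def __post_init__(self):
        if not self.epochs:
            raise ValueError("scenario needs at least one epoch")
        self.epochs = sorted(self.epochs, key=lambda e: e.age_start)
        for a, b in zip(self.epochs, self.epochs[1:]):
            if b.age_start < a.age_end:
                raise ValueError("epochs overlap")
        if self.n_variants < 0:
            raise ValueError("n_variants must be non-negative")

    def presence_probability(self, population: str, epoch_index: int) -> float:
        spec = self.populations[population]
        if isinstance(spec, (int, float)):
            return float(spec)
        return float(spec[epoch_index])


def _compatible_context(label: str, rng: np.random.Generator) -> tuple[str, str]:
    """Draw (ctx5, ctx3) on the collapsed strand uniformly among triplets
    compatible with the class label."""
    cls = MutationClass.from_label(label)
    ctx5 = rng.choice(BASES)
    if cls.refinement in ("CpG", "TpG"):
        ctx3 = "G"
    elif cls.refinement in ("nonCpG", "nonTpG"):
        ctx3 = rng.choice(["A", "C", "T"])
    else:
        ctx3 = rng.choice(BASES)
    return ctx5, ctx3


def simulate_variant_dataset(scenario: SpectrumScenario) -> pd.DataFrame:
    """Variant table with columns chrom, pos, ancestral, derived, five_prime,
    three_prime, true_age, age_lower, age_upper, and one boolean presence
    column per population.

    The true age always lies within [age_lower, age_upper]. Variants are
    assigned to epochs with probability proportional to epoch duration;
    strand orientation is randomized so roughly half the rows carry the
    purine representation of their class. A variant absent from every
    population is assigned to one uniformly chosen population (unobserved
    variants never enter real call sets).
    """
    rng = np.random.default_rng(scenario.seed)
    n = scenario.n_variants
    epochs = scenario.epochs
    durations = np.array([e.age_end - e.age_start for e in epochs])
    epoch_idx = rng.choice(len(epochs), size=n, p=durations / durations.sum())

    true_age = np.empty(n)
    labels = np.empty(n, dtype=object)
    for i, e in enumerate(epochs):
        mask = epoch_idx == i
        k = int(mask.sum())
        true_age[mask] = rng.uniform(e.age_start, e.age_end, size=k)
        classes = list(e.class_fractions)
        probs = np.array([e.class_fractions[c] for c in classes])
        labels[mask] = rng.choice(classes, size=k, p=probs)

    halfwidth = true_age * rng.lognormal(
        np.log(scenario.interval_halfwidth_median),
        scenario.interval_halfwidth_sigma,
        size=n,
    )
    age_lower = np.maximum(true_age - halfwidth, 0.0)
    age_upper = true_age + halfwidth

    anc = np.empty(n, dtype="U1")
    der = np.empty(n, dtype="U1")
    five = np.empty(n, dtype="U1")
    three = np.empty(n, dtype="U1")
    bases = np.array(BASES)
    non_g = np.array(["A", "C", "T"])
    for label in pd.unique(labels):
        mask = labels == label
        k = int(mask.sum())
        cls = MutationClass.from_label(label)
        a, d = cls.base_class.split(">")
        anc[mask], der[mask] = a, d
        five[mask] = bases[rng.integers(0, 4, size=k)]
        if cls.refinement in ("CpG", "TpG"):
            three[mask] = "G"
        elif cls.refinement in ("nonCpG", "nonTpG"):
            three[mask] = non_g[rng.integers(0, 3, size=k)]
        else:
            three[mask] = bases[rng.integers(0, 4, size=k)]
    flip = rng.random(n) < 0.5
    comp = np.vectorize(COMPLEMENT.get)
    anc[flip] = comp(anc[flip])
    der[flip] = comp(der[flip])
    five_f, three_f = comp(three[flip]), comp(five[flip])
    five[flip], three[flip] = five_f, three_f

    df = pd.DataFrame(
        {
            "chrom": "chrS",
            "pos": np.arange(1, n + 1, dtype=np.int64) * 100,
            "ancestral": anc,
            "derived": der,
            "five_prime": five,
            "three_prime": three,
            "true_age": true_age,
            "age_lower": age_lower,
            "age_upper": age_upper,
            "true_class": labels,
        }
    )
    pops = list(scenario.populations)
    present = np.zeros((n, len(pops)), dtype=bool)
    for j, pop in enumerate(pops):
        probs = np.array(
            [scenario.presence_probability(pop, int(e)) for e in epoch_idx]
        )
        present[:, j] = rng.random(n) < probs
    orphan = ~present.any(axis=1)
    if orphan.any():
        present[np.flatnonzero(orphan), rng.integers(0, len(pops), orphan.sum())] = True
    for j, pop in enumerate(pops):
        df[pop] = present[:, j]
    return df


@dataclass
class TrioScenario:
    n_trios: int
    effects: dict  # class label -> ParentalAgeEffect
    father_age_mean: float = 30.0
    father_age_sd: float = 5.0
    mother_age_mean: float = 28.0
    mother_age_sd: float = 5.0
    phased_fraction: float = 0.4
    seed: int | None = None

    def __post_init__(self):
        if not 0.0 <= self.phased_fraction <= 1.0:
            raise ValueError("phased_fraction must lie in [0, 1]")
        if self.n_trios < 0 or not self.effects:
            raise ValueError("invalid trio scenario")


def _truncated_normal(rng, mean, sd, size, lo=10.0, hi=60.0):
    out = rng.normal(mean, sd, size=size)
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = (out < lo) | (out > hi)
    return out


def simulate_trio_dataset(scenario: TrioScenario) -> pd.DataFrame:
    """Long-format trio table: trio_id, father_age, mother_age,
    mutation_class, phased_paternal, phased_maternal, unphased.

    Raises if any class predicts a negative mean at a sampled age.
    """
    rng = np.random.default_rng(scenario.seed)
    n = scenario.n_trios
    fa = _truncated_normal(rng, scenario.father_age_mean, scenario.father_age_sd, n)
    mo = _truncated_normal(rng, scenario.mother_age_mean, scenario.mother_age_sd, n)
    phi = scenario.phased_fraction
    frames = []
    for cls, eff in scenario.effects.items():
        lp = eff.paternal_mean(fa)
        lm = eff.maternal_mean(mo)
        if np.any(lp < 0) or np.any(lm < 0):
            raise ValueError(f"negative predicted mean for class {cls}")
        n_pat = rng.poisson(lp)
        n_mat = rng.poisson(lm)
        phased_p = rng.binomial(n_pat, phi)
        phased_m = rng.binomial(n_mat, phi)
        frames.append(
            pd.DataFrame(
                {
                    "trio_id": np.arange(n),
                    "father_age": fa,
                    "mother_age": mo,
                    "mutation_class": cls,
                    "phased_paternal": phased_p,
                    "phased_maternal": phased_m,
                    "unphased": (n_pat - phased_p) + (n_mat - phased_m),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


#: parental-age effects at the scale of large Icelandic pedigree cohorts:
#: ~60 DNMs per trio at parental age 30, a paternal slope several-fold the
#: maternal one for most classes, a strongly maternal C>G slope, and
#: pairwise-ratio age dependencies of the observed magnitudes (C>G/T>A rises
#: ~12% and non-CpG C>T/C>A falls ~9% between parental ages 20 and 40);
#: realistic defaults for synthetic trio data
DECODE_SCALE_EFFECTS = {
    "C>A": ParentalAgeEffect("C>A", 0.8, 0.075, 0.3, 0.019),
    "C>G": ParentalAgeEffect("C>G", 0.35, 0.075, 0.25, 0.15),
    "C>T_nonCpG": ParentalAgeEffect("C>T_nonCpG", 4.5, 0.20, 1.2, 0.06),
    "C>T_CpG": ParentalAgeEffect("C>T_CpG", 2.8, 0.10, 0.8, 0.03),
    "T>A": ParentalAgeEffect("T>A", 0.9, 0.10, 0.35, 0.03),
    "T>C_nonTpG": ParentalAgeEffect("T>C_nonTpG", 2.2, 0.30, 0.7, 0.09),
    "T>C_TpG": ParentalAgeEffect("T>C_TpG", 0.5, 0.07, 0.15, 0.02),
    "T>G": ParentalAgeEffect("T>G", 0.55, 0.115, 0.2, 0.035),
}


def effects_to_fractions(effects: dict, Gp: float, Gm: float) -> dict:
    """Class fractions implied by parental-age effects at ages (Gp, Gm);
    usable directly as epoch class fractions."""
    means = {c: float(e.total_mean(Gp, Gm)) for c, e in effects.items()}
    total = sum(means.values())
    if total <= 0:
        raise ValueError("non-positive total expected count")
    fractions = {c: m / total for c, m in means.items()}
    # exact renormalization against float drift
    s = sum(fractions.values())
    return {c: f / s for c, f in fractions.items()}
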