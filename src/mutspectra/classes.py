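"""Strand-collapsed mutation classes and context-based refinements.

Every biallelic SNP, polarized into an ancestral and a derived allele, falls
into one of six disjoint substitution classes after collapsing reverse
complements so that the ancestral base is a pyrimidine-or-T: T>A, T>C, T>G,
C>A, C>G, C>T (e.g. A>G variants are counted as T>C). Two context
refinements matter for germline mutagenesis:

* CpG status — an ancestral C immediately followed (3') by G, the substrate
  of spontaneous deamination of methylated cytosine;
* TpG status — an ancestral T immediately followed by G, whose T>C mutations
  restore a CpG and are enriched for mis-polarized CpG transitions.

Both refinements reduce to the same predicate on the collapsed strand: the
3' neighbour of the ancestral base is G.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

BASES = ("A", "C", "G", "T")
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")

BASE_CLASSES = ("T>A", "T>C", "T>G", "C>A", "C>G", "C>T")

#: the six-class scheme plus CpG/non-CpG C>T and TpG/non-TpG T>C splits
EIGHT_CLASSES = (
    "T>A",
    "T>C_TpG",
    "T>C_nonTpG",
    "T>G",
    "C>A",
    "C>G",
    "C>T_CpG",
    "C>T_nonCpG",
)

SCHEMES = ("six", "eight", "full")


class AmbiguousContextError(ValueError):
    """Raised when a flanking base is missing or not one of A/C/G/T."""


@dataclass(frozen=True)
class MutationClass:
    """A strand-collapsed substitution class with optional context refinement."""

    base_class: str
    refinement: str = "none"

    def __post_init__(self) -> None:
        if self.base_class not in BASE_CLASSES:
            raise ValueError(f"unknown base class {self.base_class!r}")
        valid = {
            "none": BASE_CLASSES,
            "CpG": ("C>T", "C>A", "C>G"),
            "nonCpG": ("C>T", "C>A", "C>G"),
            "TpG": ("T>C",),
            "nonTpG": ("T>C",),
        }
        if self.refinement not in valid:
            raise ValueError(f"unknown refinement {self.refinement!r}")
        if self.base_class not in valid[self.refinement]:
            raise ValueError(
                f"refinement {self.refinement!r} cannot apply to {self.base_class!r}"
            )

    @property
    def label(self) -> str:
        if self.refinement == "none":
            return self.base_class
        return f"{self.base_class}_{self.refinement}"

    @classmethod
    def from_label(cls, label: str) -> "MutationClass":
        if "_" in label:
            base, refinement = label.split("_", 1)
            return cls(base, refinement)
        return cls(label)


@dataclass
class PolarizedVariant:
    """One biallelic SNP with ancestral/derived alleles, flanking context on the
    ancestral sequence, an allele-age interval in generations and the set of
    populations in which both alleles are observed."""

    chrom: str
    pos: int
    ancestral: str
    derived: str
    five_prime: str
    three_prime: str
    age_lower: float
    age_upper: float
    presence: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.ancestral not in BASES or self.derived not in BASES:
            raise ValueError(
                f"alleles must be A/C/G/T, got {self.ancestral}>{self.derived}"
            )
        if self.ancestral == self.derived:
            raise ValueError("ancestral and derived alleles are identical")
        if not 0 <= self.age_lower <= self.age_upper:
            raise ValueError(
                f"invalid age interval ({self.age_lower}, {self.age_upper})"
            )
        self.presence = frozenset(self.presence)


def collapse_strand(
    ancestral: str, derived: str, five_prime: str, three_prime: str
) -> tuple[str, str, str, str]:
    """Reverse-complement a variant (alleles and context) so the ancestral
    base is T or C. Flanks are swapped and complemented together with the
    alleles, keeping the 5'/3' orientation of the collapsed strand."""
    if ancestral in PURINES:
        return (
            COMPLEMENT[ancestral],
            COMPLEMENT[derived],
            COMPLEMENT[three_prime],
            COMPLEMENT[five_prime],
        )
    return ancestral, derived, five_prime, three_prime


def classify_variant(v: PolarizedVariant, scheme: str = "eight") -> MutationClass:
    """Classify one variant under the given refinement scheme.

    ``six``   — base classes only; ``eight`` — split C>T by CpG and T>C by
    TpG; ``full`` — additionally refine C>A and C>G by CpG (used for the
    CpG-matched ratio comparisons).

    Raises :class:`AmbiguousContextError` when a flanking base is missing or
    ambiguous; such variants are excluded upstream.
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}")
    if v.five_prime not in BASES or v.three_prime not in BASES:
        raise AmbiguousContextError(
            f"ambiguous context at {v.chrom}:{v.pos} "
            f"({v.five_prime!r}, {v.three_prime!r})"
        )
    anc, der, _, three = collapse_strand(
        v.ancestral, v.derived, v.five_prime, v.three_prime
    )
    base = f"{anc}>{der}"
    followed_by_g = three == "G"
    if scheme == "six":
        return MutationClass(base)
    if base == "C>T":
        return MutationClass(base, "CpG" if followed_by_g else "nonCpG")
    if base == "T>C":
        return MutationClass(base, "TpG" if followed_by_g else "nonTpG")
    if scheme == "full" and base in ("C>A", "C>G"):
        return MutationClass(base, "CpG" if followed_by_g else "nonCpG")
    return MutationClass(base)


def is_cosmic_proxy_context(
    base_class: str, five_prime: str, three_prime: str
) -> bool:
    """True for C>T mutations in YCN or NCY contexts (Y = pyrimidine), the
    trinucleotides dominating the UV (SBS7a/b) and alkylation (SBS11)
    signatures; expects the collapsed orientation (ancestral base C or T)."""
    if base_class != "C>T":
        return False
    return five_prime in PYRIMIDINES or three_prime in PYRIMIDINES


def classify_sharing(
    presence: frozenset | set, continental_groups: list[set]
) -> str:
    """``shared`` iff the variant segregates in at least one population of
    every continental group, else ``non_shared``."""
    if not continental_groups or any(len(g) == 0 for g in continental_groups):
        raise ValueError("continental groups must be non-empty")
    presence = set(presence)
    shared = all(presence & set(group) for group in continental_groups)
    return "shared" if shared else "non_shared"


# ---------------------------------------------------------------------------
# vectorized classification of variant tables


def classify_table(variants: pd.DataFrame, scheme: str = "eight") -> pd.DataFrame:
    """Classify a variant table (columns ``ancestral``, ``derived``,
    ``five_prime``, ``three_prime``).

    Returns a copy with added columns:

    ``base_class``
        collapsed substitution class (six labels);
    ``ctx5``, ``ctx3``
        flanking bases on the collapsed strand;
    ``followed_by_g``
        whether the collapsed ancestral base is 3'-followed by G (CpG status
        for C>*, TpG status for T>C);
    ``mutation_class``
        the label under ``scheme``;
    ``context96``
        COSMIC-style trinucleotide label, e.g. ``A[C>T]G``.

    Rows with missing/ambiguous context or invalid alleles are dropped; the
    number dropped is available via the ``attrs['n_excluded']`` entry.
    """
    df = variants.copy()
    for col in ("ancestral", "derived", "five_prime", "three_prime"):
        df[col] = df[col].astype(str).str.upper()

    valid = (
        df["ancestral"].isin(BASES)
        & df["derived"].isin(BASES)
        & (df["ancestral"] != df["derived"])
        & df["five_prime"].isin(BASES)
        & df["three_prime"].isin(BASES)
    )
    n_excluded = int((~valid).sum())
    df = df[valid].copy()

    comp = df["ancestral"].map(COMPLEMENT)
    flip = df["ancestral"].isin(list(PURINES))
    anc = df["ancestral"].where(~flip, comp)
    der = df["derived"].where(~flip, df["derived"].map(COMPLEMENT))
    ctx5 = df["five_prime"].where(~flip, df["three_prime"].map(COMPLEMENT))
    ctx3 = df["three_prime"].where(~flip, df["five_prime"].map(COMPLEMENT))

    df["base_class"] = anc.str.cat(der, sep=">")
    df["ctx5"] = ctx5
    df["ctx3"] = ctx3
    df["followed_by_g"] = ctx3 == "G"
    df["mutation_class"] = label_classes(df["base_class"], df["followed_by_g"], scheme)
    df["context96"] = ctx5 + "[" + df["base_class"] + "]" + ctx3
    df.attrs["n_excluded"] = n_excluded
    return df


def label_classes(
    base_class: pd.Series, followed_by_g: pd.Series, scheme: str = "eight"
) -> pd.Series:
    """Map (base class, 3'-G flag) pairs to class labels under a scheme."""
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}")
    labels = base_class.copy()
    if scheme == "six":
        return labels
    refine = {"eight": ("C>T", "T>C"), "full": ("C>T", "T>C", "C>A", "C>G")}[scheme]
    for base in refine:
        mask = base_class == base
        if base == "T>C":
            suffix = np.where(followed_by_g[mask], "_TpG", "_nonTpG")
        else:
            suffix = np.where(followed_by_g[mask], "_CpG", "_nonCpG")
        labels.loc[mask] = base + pd.Series(suffix, index=labels.index[mask])
    return labels


def cosmic_proxy_mask(classified: pd.DataFrame) -> pd.Series:
    """Boolean mask over a classified table marking C>T variants in YCN/NCY
    contexts (candidates driven by COSMIC SBS7a/b or SBS11)."""
    return (classified["base_class"] == "C>T") & (
        classified["ctx5"].isin(list(PYRIMIDINES))
        | classified["ctx3"].isin(list(PYRIMIDINES))
    )


def context96_labels() -> list[str]:
    """The 96 pyrimidine-centered trinucleotide mutation types in COSMIC
    order (class-major: C>A, C>G, C>T, T>A, T>C, T>G)."""
    out = []
    for base in ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G"):
        for five in BASES:
            for three in BASES:
                out.append(f"{five}[{base}]{three}")
    return out
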