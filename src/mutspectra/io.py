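"""Readers and writers for the pipeline's tabular formats.

TSV is the canonical interchange: a variant dialect mirroring per-SNP
genealogy output (position, alleles, flanking bases, allele-age bounds,
per-population presence flags), a long trio dialect (one row per trio x
mutation class), BED for genomic region strata, and COSMIC-style signature
loading tables. Variants use 1-based positions; BED intervals are 0-based
half-open, converted in exactly one place (:func:`mutspectra.ratios.stratify_by_regions`).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("mutspectra")

VARIANT_COLUMNS = (
    "chrom",
    "pos",
    "ancestral",
    "derived",
    "five_prime",
    "three_prime",
    "age_lower",
    "age_upper",
)

TRIO_TSV_COLUMNS = (
    "trio_id",
    "father_age",
    "mother_age",
    "mutation_class",
    "phased_paternal",
    "phased_maternal",
    "unphased",
)


def read_variant_table(path) -> pd.DataFrame:
    """Read and validate a variant TSV.

    Rows with non-ACGT alleles, ancestral == derived, unparseable or inverted
    age bounds are rejected; counts per rejection reason are logged and kept
    in ``attrs['rejections']``. Extra columns (e.g. population presence
    flags) pass through.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in VARIANT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    rejections = {}

    for col in ("age_lower", "age_upper"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    bad_age = df["age_lower"].isna() | df["age_upper"].isna()
    rejections["unparseable_age"] = int(bad_age.sum())
    df = df[~bad_age]

    inverted = (df["age_lower"] > df["age_upper"]) | (df["age_lower"] < 0)
    rejections["invalid_age_interval"] = int(inverted.sum())
    df = df[~inverted]

    bases = list("ACGT")
    anc = df["ancestral"].astype(str).str.upper()
    der = df["derived"].astype(str).str.upper()
    bad_allele = ~(anc.isin(bases) & der.isin(bases)) | (anc == der)
    rejections["invalid_alleles"] = int(bad_allele.sum())
    df = df[~bad_allele].copy()

    for reason, count in rejections.items():
        if count:
            logger.info("%s: rejected %d rows (%s)", path, count, reason)
    df = df.reset_index(drop=True)
    df.attrs["rejections"] = rejections
    return df


def write_variant_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_trio_table(path) -> pd.DataFrame:
    """Read a long-format trio DNM table."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in TRIO_TSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    for col in ("phased_paternal", "phased_maternal", "unphased"):
        if (df[col] < 0).any():
            raise ValueError(f"{path}: negative counts in {col}")
    return df


def write_trio_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_regions(path) -> dict[str, np.ndarray]:
    """Read a BED file into merged, sorted intervals per chromosome.

    0-based half-open convention; overlapping or book-ended intervals are
    merged. Returns {chrom: (n, 2) int array}.
    """
    try:
        df = pd.read_csv(
            path, sep="\t", header=None, usecols=[0, 1, 2],
            names=["chrom", "start", "end"], comment="#", dtype={"chrom": str},
        )
    except pd.errors.EmptyDataError:
        return {}
    if df.empty:
        return {}
    if (df["start"] >= df["end"]).any():
        raise ValueError(f"{path}: interval with start >= end")
    out = {}
    for chrom, grp in df.groupby("chrom", sort=True):
        ivals = grp[["start", "end"]].to_numpy(dtype=np.int64)
        ivals = ivals[np.argsort(ivals[:, 0], kind="stable")]
        merged = [ivals[0].copy()]
        for s, e in ivals[1:]:
            if s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append(np.array([s, e]))
        out[chrom] = np.asarray(merged)
    return out


def write_regions(regions: dict[str, np.ndarray], path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(regions):
            for s, e in regions[chrom]:
                fh.write(f"{chrom}\t{int(s)}\t{int(e)}\n")


def read_cosmic_loadings(path) -> pd.DataFrame:
    """Read a COSMIC-style SBS loading table (``Type`` column with
    ``A[C>A]A``-style labels, one column per signature).

    Signature columns are normalized to sum to 1; a table missing any of the
    96 contexts raises.
    """
    df = pd.read_csv(path, sep="\t")
    type_col = df.columns[0]
    df = df.set_index(type_col)
    from .classes import context96_labels

    expected = set(context96_labels())
    missing = expected - set(df.index)
    if missing:
        raise ValueError(f"{path}: missing contexts, e.g. {sorted(missing)[:3]}")
    df = df.astype(float)
    totals = df.sum(axis=0)
    if (totals <= 0).any():
        raise ValueError(f"{path}: signature with non-positive total loading")
    return df / totals


def context_subset_share(loadings: pd.Series, predicate) -> float:
    """Share of a signature's loading mass in contexts satisfying
    ``predicate(five_prime, base_class, three_prime)``."""
    share = 0.0
    for label, value in loadings.items():
        five, rest = label.split("[", 1)
        base, three = rest.split("]", 1)
        if predicate(five, base, three):
            share += float(value)
    return share


def ycn_share(loadings: pd.Series) -> float:
    """Share of C>T loading mass with a pyrimidine 5' flank."""
    return context_subset_share(
        loadings, lambda f, b, t: b == "C>T" and f in "CT"
    )


def ncy_share(loadings: pd.Series) -> float:
    """Share of C>T loading mass with a pyrimidine 3' flank."""
    return context_subset_share(
        loadings, lambda f, b, t: b == "C>T" and t in "CT"
    )


def read_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def write_manifest(path, **entries) -> None:
    """Write a JSON run manifest (inputs, seeds, parameters) sufficient to
    re-run a pipeline stage bit-identically."""
    import mutspectra

    manifest = {"mutspectra_version": mutspectra.__version__}
    manifest.update(entries)
    Path(path).write_text(json.dumps(manifest, indent=2, default=str) + "\n")
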