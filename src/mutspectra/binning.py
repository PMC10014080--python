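"""Allele-age binning with uniform-interval pseudo-counts.

Genealogy-based allele ages come with wide uncertainty: the inferred lower
and upper bounds often differ by an order of magnitude. Rather than commit
each SNP to a single age, each variant's unit mass is spread across age bins
in proportion to the overlap of its age interval with each bin, assuming the
true age is uniformly distributed between the bounds. Summing these weights
over variants yields fractional *pseudo-counts* per mutation class per bin.

Bin boundaries are set once, from a reference population, by Monte Carlo:
one point age is sampled uniformly inside each variant's interval and the
empirical quantiles of the sampled points become the boundaries, giving bins
of roughly equal occupancy in the reference sample. The same boundaries are
then applied to every population so that bins are comparable.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted, check_random_state

#: variants whose age upper bound exceeds this are too old to be compatible
#: with a reasonable human evolutionary history and are discarded
MAX_AGE_UPPER = 3_000_000.0


def filter_variants(
    variants: pd.DataFrame, max_age_upper: float = MAX_AGE_UPPER
) -> pd.DataFrame:
    """Drop variants with extremely old ages (age_upper > ``max_age_upper``
    generations)."""
    if variants.empty:
        return variants.copy()
    keep = variants["age_upper"] <= max_age_upper
    return variants[keep].copy()


class AgeBinner(BaseEstimator, TransformerMixin):
    """Monte-Carlo equal-occupancy age bins and uniform-interval bin weights.

    Parameters
    ----------
    n_bins : int, default=15
        Number of age bins.
    random_state : int, RandomState or None
        Seed for the Monte-Carlo point-age sampling in :meth:`fit`.

    Attributes
    ----------
    boundaries_ : ndarray of shape (n_bins + 1,)
        Ascending bin boundaries in generations; bins are half-open
        ``[b_i, b_{i+1})`` except the last, which is closed.
    """

    def __init__(self, n_bins: int = 15, random_state=None):
        self.n_bins = n_bins
        self.random_state = random_state

    def fit(self, X, y=None):
        """Determine bin boundaries from the reference population.

        ``X`` is a DataFrame with ``age_lower``/``age_upper`` columns or an
        array of shape (n, 2). One point age per variant is drawn uniformly
        within its interval; boundaries are the 0, 1/n_bins, ..., 1 empirical
        quantiles of the sampled points.
        """
        if self.n_bins < 1:
            raise ValueError("n_bins must be >= 1")
        lower, upper = _age_bounds(X)
        if lower.size < self.n_bins:
            raise ValueError(
                f"need at least n_bins={self.n_bins} variants, got {lower.size}"
            )
        rng = check_random_state(self.random_state)
        points = rng.uniform(lower, upper)
        qs = np.linspace(0.0, 1.0, self.n_bins + 1)
        boundaries = np.quantile(points, qs)
        # guard against ties producing zero-width bins
        if np.any(np.diff(boundaries) <= 0):
            boundaries = np.maximum.accumulate(boundaries)
            eps = 1e-9 * max(boundaries[-1], 1.0)
            for i in range(1, boundaries.size):
                if boundaries[i] <= boundaries[i - 1]:
                    boundaries[i] = boundaries[i - 1] + eps
        self.boundaries_ = boundaries
        return self

    def transform(self, X) -> np.ndarray:
        """Spread each variant's unit mass over the bins.

        Returns an array of shape (n_variants, n_bins); each row sums to 1,
        except rows for intervals entirely outside the binning range, which
        are all-zero (flagged, excluded from pseudo-counts). Mass falling
        outside the outermost boundaries is truncated and the row
        renormalized.
        """
        check_is_fitted(self, "boundaries_")
        lower, upper = _age_bounds(X)
        return assign_bin_weights(lower, upper, self.boundaries_)

    def to_frame(self) -> pd.DataFrame:
        check_is_fitted(self, "boundaries_")
        return pd.DataFrame({"boundary": self.boundaries_})


def _age_bounds(X) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(X, pd.DataFrame):
        lower = X["age_lower"].to_numpy(dtype=float)
        upper = X["age_upper"].to_numpy(dtype=float)
    else:
        arr = np.asarray(X, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise ValueError("expected a DataFrame or an (n, 2) array")
        lower, upper = arr[:, 0], arr[:, 1]
    if np.any(lower > upper):
        raise ValueError("age_lower > age_upper")
    return lower, upper


def assign_bin_weights(
    age_lower, age_upper, boundaries: np.ndarray
) -> np.ndarray:
    """Overlap weights of uniform age intervals with a set of bins.

    For an interval (l, u) with u > l the weight in bin [b_i, b_{i+1}) is
    ``overlap length / (u - l)``. Point estimates (u == l) place unit mass in
    the containing bin (the last bin is closed at the top). Rows whose
    interval is entirely outside [b_0, b_last] are zero.
    """
    boundaries = np.asarray(boundaries, dtype=float)
    lower = np.atleast_1d(np.asarray(age_lower, dtype=float))
    upper = np.atleast_1d(np.asarray(age_upper, dtype=float))
    n_bins = boundaries.size - 1

    starts = boundaries[:-1][None, :]
    ends = boundaries[1:][None, :]
    overlap = np.clip(
        np.minimum(upper[:, None], ends) - np.maximum(lower[:, None], starts),
        0.0,
        None,
    )

    weights = np.zeros((lower.size, n_bins))
    width = upper - lower
    pos = width > 0
    weights[pos] = overlap[pos] / width[pos, None]

    # point estimates: unit mass to the containing bin
    point = ~pos
    if np.any(point):
        ages = lower[point]
        inside = (ages >= boundaries[0]) & (ages <= boundaries[-1])
        idx = np.searchsorted(boundaries, ages, side="right") - 1
        idx = np.clip(idx, 0, n_bins - 1)  # top boundary belongs to last bin
        rows = np.flatnonzero(point)[inside]
        weights[rows, idx[inside]] = 1.0

    # truncate mass outside the range, renormalize surviving rows
    totals = weights.sum(axis=1)
    nonzero = totals > 0
    weights[nonzero] /= totals[nonzero, None]
    return weights


def build_pseudocount_table(
    classified: pd.DataFrame,
    binner: AgeBinner,
    class_column: str = "mutation_class",
    class_labels: list[str] | None = None,
) -> pd.DataFrame:
    """Pseudo-count table: rows = mutation classes, columns = age bins.

    Entry (c, b) is the summed bin-b weight of all variants of class c; the
    grand total equals the number of variants whose age interval overlaps the
    binning range.
    """
    weights = binner.transform(classified)
    labels = classified[class_column].to_numpy()
    if class_labels is None:
        class_labels = sorted(pd.unique(labels))
    table = np.zeros((len(class_labels), weights.shape[1]))
    index = {c: i for i, c in enumerate(class_labels)}
    rows = np.array([index[c] for c in labels])
    np.add.at(table, rows, weights)
    return pd.DataFrame(
        table, index=pd.Index(class_labels, name=class_column),
        columns=pd.RangeIndex(weights.shape[1], name="age_bin"),
    )


def pseudocounts_by_population(
    classified: pd.DataFrame,
    binner: AgeBinner,
    populations: list[str],
    class_column: str = "mutation_class",
    class_labels: list[str] | None = None,
) -> dict[str, pd.DataFrame]:
    """One pseudo-count table per population, using each population's
    presence flags (boolean columns named after the populations)."""
    if class_labels is None:
        class_labels = sorted(classified[class_column].unique())
    tables = {}
    for pop in populations:
        subset = classified[classified[pop].astype(bool)]
        tables[pop] = build_pseudocount_table(
            subset, binner, class_column, class_labels
        )
    return tables
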