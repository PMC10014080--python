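"""Sex-specific parental-age effects on de novo mutation counts.

The expected number of DNMs a child inherits from a parent is modeled as a
linear function of that parent's age at conception, separately per mutation
class: paternal mean ``beta_p * father_age + alpha_p`` and maternal mean
``beta_m * mother_age + alpha_m`` (intercepts at age zero). Observed counts
are Poisson. Parent-of-origin is known only for phased DNMs; unphased DNMs
still carry information through their total. With per-trio phased fraction
``phi`` (treated as known, estimated from the trio's own phased/unphased
totals pooled over classes), the likelihood per trio and class is

    phased_paternal ~ Poisson(phi * lambda_p)
    phased_maternal ~ Poisson(phi * lambda_m)
    unphased        ~ Poisson((1 - phi) * (lambda_p + lambda_m))

which reduces to the plain Poisson model when phi is 0 or 1. The
log-likelihood is concave in (alpha_p, beta_p, alpha_m, beta_m) wherever the
means are positive, so the constrained MLE is found reliably from
method-of-moments starts.

Uncertainty is assessed by bootstrap resampling of trios; ratio predictions
at given parental ages combine two fitted classes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted, check_random_state

TRIO_COLUMNS = (
    "father_age",
    "mother_age",
    "phased_paternal",
    "phased_maternal",
    "unphased",
)

#: default maternal-age cutoff; older mothers show a nonlinear extra effect
MAX_MOTHER_AGE = 40.0


@dataclass(frozen=True)
class ParentalAgeEffect:
    """Fitted linear age effects of one mutation class."""

    mutation_class: str
    alpha_p: float
    beta_p: float
    alpha_m: float
    beta_m: float

    def paternal_mean(self, age):
        return self.beta_p * np.asarray(age, dtype=float) + self.alpha_p

    def maternal_mean(self, age):
        return self.beta_m * np.asarray(age, dtype=float) + self.alpha_m

    def total_mean(self, father_age, mother_age):
        return self.paternal_mean(father_age) + self.maternal_mean(mother_age)


@dataclass
class BootstrapSet:
    """Bootstrap replicates of one class's parental-age effects."""

    mutation_class: str
    replicates: pd.DataFrame  # columns alpha_p, beta_p, alpha_m, beta_m
    seed: int | None = None

    def percentile_ci(self, level: float = 0.90) -> pd.DataFrame:
        lo = (1.0 - level) / 2.0
        qs = self.replicates[["alpha_p", "beta_p", "alpha_m", "beta_m"]].quantile(
            [lo, 1.0 - lo]
        )
        qs.index = ["ci_lower", "ci_upper"]
        return qs

    def standard_errors(self) -> pd.Series:
        return self.replicates[["alpha_p", "beta_p", "alpha_m", "beta_m"]].std(
            ddof=1
        )


def apply_trio_filters(
    trios: pd.DataFrame,
    outlier_ids: list | None = None,
    max_mother_age: float = MAX_MOTHER_AGE,
) -> pd.DataFrame:
    """Drop listed outlier trios and trios with maternal age above the cutoff
    (strictly greater; a mother aged exactly ``max_mother_age`` is kept)."""
    keep = trios["mother_age"] <= max_mother_age
    if outlier_ids:
        keep &= ~trios["trio_id"].isin(list(outlier_ids))
    return trios[keep].copy()


def trio_phased_fractions(trios: pd.DataFrame) -> pd.Series:
    """Per-trio phased fraction pooled over mutation classes.

    For wide tables (one row per trio) the fraction is computed from that
    row; for long tables (one row per trio x class) counts are pooled over
    classes per trio_id. Trios with no DNMs at all get the cohort-average
    fraction.
    """
    if "trio_id" in trios.columns and trios["trio_id"].duplicated().any():
        grouped = trios.groupby("trio_id")[
            ["phased_paternal", "phased_maternal", "unphased"]
        ].sum()
    else:
        key = trios["trio_id"] if "trio_id" in trios.columns else trios.index
        grouped = trios.set_axis(key)[
            ["phased_paternal", "phased_maternal", "unphased"]
        ]
    phased = grouped["phased_paternal"] + grouped["phased_maternal"]
    total = phased + grouped["unphased"]
    overall = phased.sum() / total.sum() if total.sum() > 0 else 0.5
    frac = phased / total.where(total > 0)
    return frac.fillna(overall)


class ParentalAgeModel(BaseEstimator):
    """Poisson maximum-likelihood fit of sex-specific parental-age effects.

    Parameters
    ----------
    tol : float, default=1e-8
        Convergence tolerance on the log-likelihood.
    n_starts : int, default=3
        Number of optimizer starts (method-of-moments plus perturbations).
    random_state : int, RandomState or None
        Seed for start-point perturbations.

    Attributes
    ----------
    alpha_p_, beta_p_, alpha_m_, beta_m_ : float
        MLE of the intercepts (expected DNMs at age 0) and slopes (DNMs per
        year of parental age).
    loglik_ : float
        Maximized log-likelihood (up to count-factorial constants).
    n_trios_ : int
    """

    def __init__(self, tol: float = 1e-8, n_starts: int = 3, random_state=None):
        self.tol = tol
        self.n_starts = n_starts
        self.random_state = random_state

    def fit(self, X: pd.DataFrame, y=None):
        """Fit to one class's trio counts.

        ``X`` needs columns father_age, mother_age, phased_paternal,
        phased_maternal, unphased, and optionally phased_fraction (otherwise
        computed from the counts themselves).
        """
        missing = [c for c in TRIO_COLUMNS if c not in X.columns]
        if missing:
            raise ValueError(f"missing trio columns: {missing}")
        fa = X["father_age"].to_numpy(dtype=float)
        mo = X["mother_age"].to_numpy(dtype=float)
        if np.unique(fa).size < 2 or np.unique(mo).size < 2:
            raise ValueError(
                "unidentifiable design: need >= 2 distinct ages per parent"
            )
        yp = X["phased_paternal"].to_numpy(dtype=float)
        ym = X["phased_maternal"].to_numpy(dtype=float)
        yu = X["unphased"].to_numpy(dtype=float)
        if np.any(yp < 0) or np.any(ym < 0) or np.any(yu < 0):
            raise ValueError("negative counts")
        if "phased_fraction" in X.columns:
            phi = X["phased_fraction"].to_numpy(dtype=float)
        else:
            tot = yp + ym + yu
            overall = (yp + ym).sum() / tot.sum() if tot.sum() > 0 else 0.5
            with np.errstate(invalid="ignore"):
                phi = np.where(tot > 0, (yp + ym) / np.maximum(tot, 1e-300), overall)
        phi = np.clip(phi, 0.0, 1.0)

        if (yp + ym + yu).sum() == 0:
            # boundary MLE: all means zero
            self.alpha_p_ = self.beta_p_ = self.alpha_m_ = self.beta_m_ = 0.0
            self.loglik_ = 0.0
            self.n_trios_ = len(X)
            self.converged_ = True
            return self

        theta, loglik = _maximize_likelihood(
            fa, mo, yp, ym, yu, phi,
            tol=self.tol,
            n_starts=self.n_starts,
            random_state=check_random_state(self.random_state),
        )
        self.alpha_p_, self.beta_p_, self.alpha_m_, self.beta_m_ = theta
        self.loglik_ = loglik
        self.n_trios_ = len(X)
        self.converged_ = True
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Expected total DNM count per trio at its parental ages."""
        check_is_fitted(self, "alpha_p_")
        return self.effect_().total_mean(
            X["father_age"].to_numpy(dtype=float),
            X["mother_age"].to_numpy(dtype=float),
        )

    def effect_(self, mutation_class: str = "") -> ParentalAgeEffect:
        check_is_fitted(self, "alpha_p_")
        return ParentalAgeEffect(
            mutation_class, self.alpha_p_, self.beta_p_, self.alpha_m_, self.beta_m_
        )

    def loglik(self, X: pd.DataFrame, effect: ParentalAgeEffect | None = None):
        """Log-likelihood of ``X`` under the fitted (or given) parameters."""
        if effect is None:
            effect = self.effect_()
        fa = X["father_age"].to_numpy(dtype=float)
        mo = X["mother_age"].to_numpy(dtype=float)
        yp = X["phased_paternal"].to_numpy(dtype=float)
        ym = X["phased_maternal"].to_numpy(dtype=float)
        yu = X["unphased"].to_numpy(dtype=float)
        tot = yp + ym + yu
        overall = (yp + ym).sum() / tot.sum() if tot.sum() > 0 else 0.5
        phi = np.where(tot > 0, (yp + ym) / np.maximum(tot, 1e-300), overall)
        theta = (effect.alpha_p, effect.beta_p, effect.alpha_m, effect.beta_m)
        return -_negloglik(np.asarray(theta), fa, mo, yp, ym, yu, phi)


def _negloglik(theta, fa, mo, yp, ym, yu, phi):
    ap, bp, am, bm = theta
    lp = bp * fa + ap
    lm = bm * mo + am
    if np.any(lp < 0) or np.any(lm < 0):
        return np.inf
    lsum = lp + lm
    ll = 0.0
    # y*log(mu) - mu with 0*log(0) = 0; mu = 0 with y > 0 is -inf
    for y, mu in ((yp, phi * lp), (ym, phi * lm), (yu, (1 - phi) * lsum)):
        pos = y > 0
        if np.any(mu[pos] <= 0):
            return np.inf
        ll += np.sum(y[pos] * np.log(mu[pos])) - np.sum(mu)
    return -ll


def _negloglik_grad(theta, fa, mo, yp, ym, yu, phi):
    ap, bp, am, bm = theta
    lp = np.maximum(bp * fa + ap, 1e-300)
    lm = np.maximum(bm * mo + am, 1e-300)
    lsum = lp + lm
    # d ll / d lambda_p = yp/lp + yu/lsum - 1 (and symmetrically for lm)
    dlp = yp / lp + yu / lsum - 1.0
    dlm = ym / lm + yu / lsum - 1.0
    return -np.array(
        [dlp.sum(), (dlp * fa).sum(), dlm.sum(), (dlm * mo).sum()]
    )


def _moment_start(fa, mo, yp, ym, yu, phi):
    """Method-of-moments start: least squares of inflated phased counts on
    age, falling back to flat means when phasing is absent."""
    with np.errstate(divide="ignore", invalid="ignore"):
        zp = np.where(phi > 0, yp / np.maximum(phi, 1e-6), np.nan)
        zm = np.where(phi > 0, ym / np.maximum(phi, 1e-6), np.nan)
    total = yp + ym + yu

    def ls(age, z, fallback_mean, share):
        ok = np.isfinite(z)
        if ok.sum() >= 2 and np.unique(age[ok]).size >= 2:
            A = np.vstack([np.ones(ok.sum()), age[ok]]).T
            coef, *_ = np.linalg.lstsq(A, z[ok], rcond=None)
            return float(coef[0]), float(coef[1])
        return fallback_mean * share, 0.0

    mean_total = total.mean()
    ap, bp = ls(fa, zp, mean_total, 0.8)
    am, bm = ls(mo, zm, mean_total, 0.2)
    return np.array([max(ap, 0.1), max(bp, 0.0), max(am, 0.1), max(bm, 0.0)])


def _maximize_likelihood(fa, mo, yp, ym, yu, phi, tol, n_starts, random_state):
    args = (fa, mo, yp, ym, yu, phi)
    ages_p = (fa.min(), fa.max())
    ages_m = (mo.min(), mo.max())
    constraints = [
        {  # paternal and maternal means non-negative at both age extremes
            "type": "ineq",
            "fun": lambda t, a=a, j=j: t[j] + t[j + 1] * a,
            "jac": lambda t, a=a, j=j: np.eye(4)[j] + a * np.eye(4)[j + 1],
        }
        for j, ages in ((0, ages_p), (2, ages_m))
        for a in ages
    ]
    start = _moment_start(*args)
    best, best_val = None, np.inf
    for k in range(max(1, n_starts)):
        x0 = start if k == 0 else start * random_state.uniform(0.5, 1.5, 4)
        res = optimize.minimize(
            _negloglik,
            x0,
            args=args,
            jac=_negloglik_grad,
            method="SLSQP",
            constraints=constraints,
            options={"maxiter": 500, "ftol": tol},
        )
        if res.fun < best_val and np.isfinite(res.fun):
            best, best_val = res.x, res.fun
    if best is None:
        raise RuntimeError("parental-age model failed to converge")
    best = np.asarray(best, dtype=float)
    return best, -best_val


def fit_parental_age_model(
    trios: pd.DataFrame, mutation_class: str | None = None, **kwargs
) -> ParentalAgeEffect:
    """Fit one class from a long-format trio table (or a wide single-class
    table when ``mutation_class`` is None)."""
    data = trios
    if mutation_class is not None and "mutation_class" in trios.columns:
        data = trios[trios["mutation_class"] == mutation_class]
        phi = trio_phased_fractions(trios)
        data = data.copy()
        data["phased_fraction"] = data["trio_id"].map(phi).to_numpy()
    model = ParentalAgeModel(**kwargs).fit(data)
    return model.effect_(mutation_class or "")


def predict_ratio(
    effect1: ParentalAgeEffect, effect2: ParentalAgeEffect, Gp: float, Gm: float
) -> float:
    """Expected class-1 / class-2 DNM ratio at paternal age Gp and maternal
    age Gm (years)."""
    num = effect1.paternal_mean(Gp) + effect1.maternal_mean(Gm)
    den = effect2.paternal_mean(Gp) + effect2.maternal_mean(Gm)
    if den <= 0:
        raise ValueError("non-positive expected denominator count")
    return float(num / den)


def bootstrap_effects(
    trios: pd.DataFrame,
    mutation_class: str | None = None,
    n_reps: int = 500,
    seed: int | None = None,
    **fit_kwargs,
) -> BootstrapSet:
    """Bootstrap the parental-age effects by resampling trios with
    replacement and refitting; failures are recorded as NaN rows."""
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    # the log-likelihood is concave, so one moment-based start suffices per
    # replicate; multiple starts are a safeguard reserved for point fits
    fit_kwargs.setdefault("n_starts", 1)
    rng = np.random.default_rng(seed)
    if mutation_class is not None and "mutation_class" in trios.columns:
        phi = trio_phased_fractions(trios)
        data = trios[trios["mutation_class"] == mutation_class].copy()
        data["phased_fraction"] = data["trio_id"].map(phi).to_numpy()
    else:
        data = trios.reset_index(drop=True)
    data = data.reset_index(drop=True)
    n = len(data)
    rows = []
    for _ in range(n_reps):
        idx = rng.integers(0, n, size=n)
        sample = data.iloc[idx]
        try:
            model = ParentalAgeModel(**fit_kwargs).fit(sample)
            rows.append(
                (model.alpha_p_, model.beta_p_, model.alpha_m_, model.beta_m_)
            )
        except (ValueError, RuntimeError):
            rows.append((np.nan,) * 4)
    reps = pd.DataFrame(rows, columns=["alpha_p", "beta_p", "alpha_m", "beta_m"])
    return BootstrapSet(mutation_class or "", reps, seed)


def quintile_cpg_ratio_test(
    trios: pd.DataFrame,
    numerator_class: str = "C>T_CpG",
    denominator_class: str = "C>A_CpG",
    quantile: float = 0.20,
) -> tuple[float, float, float]:
    """CpG C>T / CpG C>A ratio contrast between the youngest-parent and
    oldest-parent quintiles of trios.

    Trios are ranked by the sum of parental ages; total counts (phased plus
    unphased) of the two classes are pooled within the bottom and top
    ``quantile`` of trios and compared by a 2x2 chi-square. Returns
    (ratio_young, ratio_old, p_value).
    """
    wide = trios.copy()
    if "mutation_class" in wide.columns:
        wide["total"] = (
            wide["phased_paternal"] + wide["phased_maternal"] + wide["unphased"]
        )
        wide = wide.pivot_table(
            index=["trio_id", "father_age", "mother_age"],
            columns="mutation_class",
            values="total",
            fill_value=0,
        ).reset_index()
    for cls in (numerator_class, denominator_class):
        if cls not in wide.columns:
            raise ValueError(f"class {cls!r} absent from trio table")
    score = wide["father_age"] + wide["mother_age"]
    lo_cut, hi_cut = score.quantile([quantile, 1.0 - quantile])
    young = wide[score <= lo_cut]
    old = wide[score >= hi_cut]
    table = np.array(
        [
            [young[numerator_class].sum(), old[numerator_class].sum()],
            [young[denominator_class].sum(), old[denominator_class].sum()],
        ],
        dtype=float,
    )
    if np.any(table[1] == 0):
        raise ValueError("zero denominator counts in a quintile")
    ratio_young = table[0, 0] / table[1, 0]
    ratio_old = table[0, 1] / table[1, 1]
    _, p = stats.chi2_contingency(table, correction=False)[:2]
    return float(ratio_young), float(ratio_old), float(p)
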