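"""Maternal-age effects on crossover counts.

The central question is whether the number of crossovers transmitted to a
child changes with the parent's age at that child's birth.  Counts are
treated as Gaussian throughout.  The toolkit:

* family-adjusted simple regression (each transmission's count and age are
  centred on the mother's own mean, so between-mother differences cannot
  confound the within-family age trend);
* a linear mixed model with a random intercept per mother, optionally with
  the mother's number of children as a covariate;
* a penalized linear spline (truncated-line basis with a knot at every
  distinct age) fitted through its mixed-model representation, the
  smoothing parameter being the REML residual-to-spline variance ratio;
* permutation p-values under three exchangeability schemes, with the
  add-one convention p = (b + 1) / (n_perm + 1);
* rank correlation, the sign test, closed-form binomial calculations for
  chromosome-count significance, categorical age-group tests, and the
  among-parent variation ANOVA.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

SCHEMES = ("across_transmissions", "within_family", "child_reassignment")


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    pearson_r: float
    r_squared: float
    p_perm: float
    p_parametric: float
    n: int
    degenerate: bool = False


@dataclass
class MixedModelResult:
    slope_age: float
    intercept: float
    slope_n_children: float | None
    var_mother: float
    var_residual: float
    p_perm: float
    p_parametric: float
    n: int
    converged: bool


@dataclass
class SplineFit:
    knots: np.ndarray
    intercept: float
    slope: float
    spline_coefs: np.ndarray
    lam: float
    var_spline: float
    var_mother: float
    var_residual: float
    p_vs_linear: float
    n: int

    def predict(self, ages) -> np.ndarray:
        ages = np.asarray(ages, dtype=float)
        # basis spans all knots but the largest, whose term is always zero
        z = np.maximum(ages[:, None] - self.knots[None, :-1], 0.0)
        return self.intercept + self.slope * ages + z @ self.spline_coefs


# ---------------------------------------------------------------------------
# permutation machinery
# ---------------------------------------------------------------------------

def _permute(values: np.ndarray, groups: np.ndarray | None,
             rng: np.random.Generator) -> np.ndarray:
    if groups is None:
        return rng.permutation(values)
    out = values.copy()
    for g in np.unique(groups):
        sel = np.nonzero(groups == g)[0]
        out[sel] = values[sel[rng.permutation(len(sel))]]
    return out


def permutation_test(statistic_fn, df: pd.DataFrame, scheme: str,
                     n_perm: int = 10000, seed: int = 0,
                     value_col: str = "age_at_birth",
                     group_col: str = "parent_id",
                     alternative: str = "two-sided") -> tuple[float, float]:
    """Generic permutation p-value; returns (observed statistic, p).

    ``scheme`` fixes the exchangeability unit: ``across_transmissions``
    permutes ``value_col`` over all records, ``within_family`` permutes it
    only within ``group_col`` groups, and ``child_reassignment`` shuffles
    children among parents keeping family sizes (i.e. permutes the response
    globally while parent labels stay put).  ``alternative`` is
    ``two-sided`` (|stat| at least as extreme), ``less`` or ``greater``.
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown permutation scheme {scheme!r}")
    rng = np.random.default_rng(seed)
    obs = statistic_fn(df)
    groups = df[group_col].to_numpy() if scheme == "within_family" else None
    values = df[value_col].to_numpy()
    b = 0
    work = df.copy()
    for _ in range(n_perm):
        work[value_col] = _permute(values, groups, rng)
        stat = statistic_fn(work)
        if alternative == "two-sided":
            b += abs(stat) >= abs(obs) - 1e-12
        elif alternative == "less":
            b += stat <= obs + 1e-12
        elif alternative == "greater":
            b += stat >= obs - 1e-12
        else:
            raise ValueError(f"unknown alternative {alternative!r}")
    return obs, (b + 1) / (n_perm + 1)


# ---------------------------------------------------------------------------
# family-adjusted regression
# ---------------------------------------------------------------------------

def family_adjust(values, groups) -> np.ndarray:
    """Centre each value on its group (mother) mean; group means become 0."""
    s = pd.Series(np.asarray(values, dtype=float))
    return (s - s.groupby(np.asarray(groups)).transform("mean")).to_numpy()


def adjusted_regression(counts, ages, groups, n_perm: int = 10000,
                        seed: int = 0) -> RegressionResult:
    """OLS of family-adjusted counts on family-adjusted ages.

    The permutation p permutes ages within each mother's transmissions
    (family-adjusted analyses must respect the family as the
    exchangeability unit).  Requires at least one mother with >= 2
    transmissions; a zero-variance response is reported as slope 0 with the
    ``degenerate`` flag rather than NaN.
    """
    counts = np.asarray(counts, dtype=float)
    ages = np.asarray(ages, dtype=float)
    codes, _ = pd.factorize(np.asarray(groups))
    n = len(counts)
    sizes = np.bincount(codes)
    if (sizes < 2).all():
        raise ValueError("all families are singletons: nothing to adjust")

    def adjust(v: np.ndarray) -> np.ndarray:
        means = np.bincount(codes, weights=v) / sizes
        return v - means[codes]

    y = adjust(counts)
    x = adjust(ages)
    if np.allclose(x.var(), 0) or np.allclose(y.var(), 0):
        return RegressionResult(0.0, float(y.mean()), 0.0, 0.0, 1.0, 1.0,
                                n, degenerate=True)
    res = scipy.stats.linregress(x, y)

    # within-family permutation of ages, vectorized: sort rows by
    # (family, random key) and fill each family's slots in that order
    rng = np.random.default_rng(seed)
    order0 = np.argsort(codes, kind="stable")
    obs = float(res.slope)
    b = 0
    for _ in range(n_perm):
        order = np.lexsort((rng.random(n), codes))
        perm_ages = np.empty(n)
        perm_ages[order0] = ages[order]
        px = adjust(perm_ages)
        slope = float((px * y).sum() / (px * px).sum())
        b += abs(slope) >= abs(obs) - 1e-12
    p_perm = (b + 1) / (n_perm + 1)
    return RegressionResult(obs, float(res.intercept),
                            float(res.rvalue), float(res.rvalue ** 2),
                            p_perm, float(res.pvalue), n)


def mixed_model(counts, ages, mother_ids, n_children_covariate: bool = False,
                n_perm: int = 1000, seed: int = 0) -> MixedModelResult:
    """Random-intercept-per-mother linear mixed model for the age effect,
    fitted by REML.  The permutation p permutes ages across transmissions."""
    df = pd.DataFrame({"total_count": np.asarray(counts, dtype=float),
                       "age_at_birth": np.asarray(ages, dtype=float),
                       "parent_id": np.asarray(mother_ids)})
    if df["parent_id"].nunique() < 2:
        raise ValueError("mixed model requires at least two mothers")
    if n_children_covariate:
        df["n_children"] = df.groupby("parent_id")["parent_id"].transform("size")

    def fit(d: pd.DataFrame):
        cols = ["age_at_birth"] + (["n_children"] if n_children_covariate else [])
        exog = sm.add_constant(d[cols])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # boundary variance estimates
            return sm.MixedLM(d["total_count"], exog, groups=d["parent_id"]
                              ).fit(reml=True)

    res = fit(df)
    _, p_perm = permutation_test(lambda d: float(fit(d).params["age_at_birth"]),
                                 df, "across_transmissions", n_perm, seed)
    return MixedModelResult(
        slope_age=float(res.params["age_at_birth"]),
        intercept=float(res.params["const"]),
        slope_n_children=(float(res.params["n_children"])
                          if n_children_covariate else None),
        var_mother=float(res.cov_re.iloc[0, 0]),
        var_residual=float(res.scale),
        p_perm=p_perm,
        p_parametric=float(res.pvalues["age_at_birth"]),
        n=len(df), converged=bool(res.converged))


def spline_fit(counts, ages, mother_ids, n_perm: int = 1000,
               seed: int = 0) -> SplineFit:
    """Penalized linear spline via its mixed-model representation.

    Fixed part: intercept + linear age.  Random parts: one truncated-line
    coefficient per knot (a knot at every distinct age), iid with common
    variance, plus a random intercept per mother.  The smoothing parameter
    lambda is the REML estimate of var_residual / var_spline.

    ``p_vs_linear`` tests whether the spline improves on the straight line:
    the observed REML log-likelihood gain over the linear mixed model is
    compared with its distribution when linear-fit residuals are permuted
    (which preserves the linear trend but destroys any curvature).
    """
    counts = np.asarray(counts, dtype=float)
    ages = np.asarray(ages, dtype=float)
    mother_ids = np.asarray(mother_ids)
    knots = np.unique(ages)
    if len(knots) < 4:
        raise ValueError("need at least 4 distinct ages for a spline fit")

    def basis(a: np.ndarray) -> np.ndarray:
        # (age - knot)_+ for every knot except the largest, whose column
        # would be identically zero and break the REML solver
        return np.maximum(a[:, None] - knots[None, :-1], 0.0)

    def fit_spline(y: np.ndarray):
        z = basis(ages)
        zcols = [f"z{j}" for j in range(z.shape[1])]
        df = pd.concat([pd.DataFrame({"y": y, "age": ages,
                                      "mother": mother_ids, "g": 1}),
                        pd.DataFrame(z, columns=zcols)], axis=1)
        vcf = {"spline": "0 + " + " + ".join(zcols), "mother": "0 + C(mother)"}
        model = smf.mixedlm("y ~ age", df, groups="g", vc_formula=vcf)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # boundary variance estimates
            return model.fit(reml=True), model

    def fit_linear(y: np.ndarray):
        df = pd.DataFrame({"y": y, "age": ages, "mother": mother_ids})
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return smf.mixedlm("y ~ age", df, groups="mother").fit(reml=True)

    res, model = fit_spline(counts)
    lin = fit_linear(counts)
    gain_obs = max(0.0, 2.0 * (res.llf - lin.llf))

    # BLUPs of the vc coefficients for the fitted curve
    re = res.random_effects[1]
    u = np.array([re[f"spline[z{j}]"] for j in range(len(knots) - 1)])
    var_spline = float(res.vcomp[list(model.exog_vc.names).index("spline")])
    var_mother = float(res.vcomp[list(model.exog_vc.names).index("mother")])
    lam = float(res.scale / var_spline) if var_spline > 0 else np.inf

    # permutation of linear-fit residuals for the curvature test
    rng = np.random.default_rng(seed)
    lin_ols = np.polyval(np.polyfit(ages, counts, 1), ages)
    resid = counts - lin_ols
    b = 0
    for _ in range(n_perm):
        y_perm = lin_ols + rng.permutation(resid)
        try:
            gain = max(0.0, 2.0 * (fit_spline(y_perm)[0].llf
                                   - fit_linear(y_perm).llf))
        except Exception:
            continue
        b += gain >= gain_obs - 1e-12
    p_vs_linear = (b + 1) / (n_perm + 1)

    return SplineFit(knots=knots, intercept=float(res.params["Intercept"]),
                     slope=float(res.params["age"]), spline_coefs=u,
                     lam=lam, var_spline=var_spline, var_mother=var_mother,
                     var_residual=float(res.scale), p_vs_linear=p_vs_linear,
                     n=len(counts))


# ---------------------------------------------------------------------------
# rank / closed-form tests
# ---------------------------------------------------------------------------

def rank_correlation(x, y, n_perm: int = 10000, seed: int = 0
                     ) -> tuple[float, float]:
    """Spearman rho (average ranks for ties) with a permutation p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    df = pd.DataFrame({"x": x, "y": y})
    rho, p = permutation_test(
        lambda d: scipy.stats.spearmanr(d["x"], d["y"]).statistic,
        df, "across_transmissions", n_perm, seed, value_col="x",
        group_col="x")
    return float(rho), float(p)


def sign_test(n_negative: int, n_total: int) -> float:
    """One-sided binomial sign test: P(X >= n_negative), X ~ Bin(n, 1/2).

    Used to ask whether chromosomes shifting downward with age outnumber
    what coin flips would give."""
    if not 0 <= n_negative <= n_total:
        raise ValueError("need 0 <= n_negative <= n_total")
    if n_total == 0:
        return 1.0
    return float(scipy.stats.binomtest(n_negative, n_total, 0.5,
                                       alternative="greater").pvalue)


def p_chr_at_least_two(n_chrom: int = 22, per_chrom_p: float = 0.0355
                       ) -> tuple[float, float]:
    """Chance probability that >= 2 of ``n_chrom`` chromosomes reach
    per-chromosome significance, times 0.25 for the two shifts both being
    decreases.  Returns (intermediate tail probability, p_chr)."""
    p = per_chrom_p
    if not 0 < p < 1:
        raise ValueError("per_chrom_p must lie in (0, 1)")
    n = n_chrom
    tail = 1.0 - (1.0 - p) ** n - n * p * (1.0 - p) ** (n - 1)
    return float(tail), float(tail * 0.25)


def age_categories(ages) -> np.ndarray:
    """Four maternal-age classes: <25, 25-29, 30-34, >=35 (left-closed)."""
    return np.digitize(np.asarray(ages, dtype=float), [25.0, 30.0, 35.0])


def age_category_tests(counts, ages, n_perm: int = 10000, seed: int = 0
                       ) -> dict:
    """ANOVA and Kruskal-Wallis across the four age classes, with
    permutation p-values (ages permuted across transmissions) and per-class
    summaries."""
    counts = np.asarray(counts, dtype=float)
    df = pd.DataFrame({"total_count": counts,
                       "age_at_birth": np.asarray(ages, dtype=float)})

    def split(d):
        cat = age_categories(d["age_at_birth"])
        return [d["total_count"].to_numpy()[cat == k] for k in range(4)
                if (cat == k).sum() > 0]

    if len(split(df)) < 2:
        raise ValueError("fewer than two non-empty age categories")

    f_obs, p_f = permutation_test(
        lambda d: scipy.stats.f_oneway(*split(d)).statistic,
        df, "across_transmissions", n_perm, seed, alternative="greater")
    h_obs, p_h = permutation_test(
        lambda d: scipy.stats.kruskal(*split(d)).statistic,
        df, "across_transmissions", n_perm, seed, alternative="greater")

    cat = age_categories(df["age_at_birth"])
    labels = ["<25", "25-29", "30-34", ">=35"]
    per_bin = pd.DataFrame([
        {"category": labels[k], "n": int((cat == k).sum()),
         "mean": float(counts[cat == k].mean()) if (cat == k).any() else np.nan,
         "se": (float(counts[cat == k].std(ddof=1)
                      / np.sqrt((cat == k).sum()))
                if (cat == k).sum() > 1 else np.nan)}
        for k in range(4)])
    return {"anova_F": float(f_obs), "anova_p": float(p_f),
            "kruskal_chi2": float(h_obs), "kruskal_p": float(p_h),
            "per_category": per_bin}


def variation_among_parents(counts, parent_ids, n_perm: int = 10000,
                            seed: int = 0) -> tuple[float, float]:
    """One-way ANOVA of genome-wide counts among parents, significance by
    randomly reassigning children to parents (family sizes kept).

    Detects between-individual heterogeneity in recombination rate.
    """
    df = pd.DataFrame({"total_count": np.asarray(counts, dtype=float),
                       "parent_id": np.asarray(parent_ids)})
    sizes = df.groupby("parent_id").size()
    eligible = sizes[sizes >= 2].index
    if len(eligible) < 2:
        raise ValueError("need >= 2 parents with >= 2 transmissions each")
    df = df[df["parent_id"].isin(eligible)].reset_index(drop=True)

    def stat(d):
        groups = [g["total_count"].to_numpy() for _, g in d.groupby("parent_id")]
        return scipy.stats.f_oneway(*groups).statistic

    f_obs, p = permutation_test(stat, df, "child_reassignment", n_perm, seed,
                                value_col="total_count",
                                alternative="greater")
    return float(f_obs), float(p)
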