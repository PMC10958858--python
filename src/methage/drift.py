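"""Epigenetic drift: variably methylated positions and methylome entropy.

Two complementary views of drift.  Per site, the Breusch–Pagan
(Koenker studentized) test screens for methylation variance that
depends on age and sex — significant sites (after Holm–Bonferroni)
are variably methylated positions (VMPs); the beta regression of each
site's methylation fraction on age and sex is fitted alongside as the
mean-trend model.  Per sample, the normalized Shannon entropy of the
methylation fractions over a chosen site set summarises how noisy the
methylome is (0 = fully determined, 1 = maximally uncertain), and a
beta regression of entropy on age x sex tests whether the sexes lose
epigenetic stability at different rates.

Caveat emptor: with three replicates per sex per timepoint the
Lagrange-multiplier statistic (n·R² of the auxiliary regression) is
bounded by the sample count, so the per-site screen has modest power
and family-wise correction across many sites is extremely strict.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.diagnostic import het_breuschpagan
from statsmodels.stats.multitest import multipletests

from .betareg import BetaRegFit, BetaRegression, boundary_transform
from .errors import DataError, ValidationError
from .types import MethylationMatrix, SampleRecord, SiteKey

LN_HALF = float(np.log(0.5))


# ---------------------------------------------------------------------------
# Breusch–Pagan heteroscedasticity test
# ---------------------------------------------------------------------------

def breusch_pagan(y, X) -> tuple[float, int, float]:
    """Koenker studentized Breusch–Pagan test of y regressed on X.

    OLS of y on X (X must include the intercept column), then the
    auxiliary regression of squared residuals on X; LM = n·R²_aux is
    referred to chi-square with df = number of non-intercept columns.
    Returns ``(lm, df, p)``.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] != len(y):
        raise ValidationError("y and X have incompatible shapes")
    df = X.shape[1] - 1
    if df < 1:
        raise DataError("design must have at least one non-intercept column")
    if len(y) <= X.shape[1] + 1:
        raise DataError("need n > p + 1 observations")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise DataError("design matrix is rank deficient")
    resid = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
    if np.allclose(resid, 0.0):
        return 0.0, df, 1.0  # exact fit: no residual variance to model
    lm, p, _f, _fp = het_breuschpagan(resid, X, robust=True)
    return float(lm), df, float(p)


# ---------------------------------------------------------------------------
# VMP screen
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VMPResult:
    """Heteroscedasticity screen result for one CpG."""

    site: SiteKey
    bp_stat: float
    df: int
    p: float
    p_holm: float
    is_vmp: bool
    betareg_converged: bool


def _design(samples: list[SampleRecord]) -> np.ndarray:
    age = np.array([s.age_days for s in samples], dtype=float)
    male = np.array([1.0 if s.sex == "M" else 0.0 for s in samples])
    return np.column_stack([np.ones(len(samples)), age, male])


def detect_vmps(
    matrix: MethylationMatrix,
    alpha: float = 0.05,
    fit_mean_model: bool = True,
) -> list[VMPResult]:
    """Screen every site of ``matrix`` for age/sex heteroscedasticity.

    Per site the methylation fractions are boundary-transformed, the
    beta regression on (age, sex) is fitted as the mean-trend model
    (sites whose fit does not converge are excluded), and the
    Breusch–Pagan test is run on the same design.  Holm–Bonferroni is
    applied across all tested sites; ``is_vmp`` means p_holm < alpha.

    ``fit_mean_model=False`` skips the (relatively slow) beta
    regressions and only runs the variance screen.
    """
    samples = matrix.samples
    if len(samples) < 6:
        raise DataError(f"need >= 6 samples for the VMP screen, got {len(samples)}")
    X = _design(samples)
    fractions = matrix.fractions()
    results: list[tuple[SiteKey, float, int, float, bool]] = []
    for i, key in enumerate(matrix.sites):
        y = boundary_transform(fractions[i])
        converged = True
        if fit_mean_model:
            try:
                fit = BetaRegression(y, X, exog_names=["const", "age", "male"]).fit()
                converged = fit.converged
            except (DataError, np.linalg.LinAlgError):
                converged = False
            if not converged:
                continue  # excluded downstream, never a silent zero
        try:
            lm, df, p = breusch_pagan(y, X)
        except DataError:
            continue
        results.append((key, lm, df, p, converged))
    if not results:
        return []
    pvals = np.array([r[3] for r in results])
    _, p_holm, _, _ = multipletests(pvals, method="holm")
    return [
        VMPResult(site=key, bp_stat=lm, df=df, p=p, p_holm=float(ph),
                  is_vmp=bool(ph < alpha), betareg_converged=conv)
        for (key, lm, df, p, conv), ph in zip(results, p_holm)
    ]


def vmp_frame(results: list[VMPResult]) -> pd.DataFrame:
    return pd.DataFrame({
        "chrom": [r.site[0] for r in results],
        "pos": [r.site[1] for r in results],
        "bp_stat": [r.bp_stat for r in results],
        "df": [r.df for r in results],
        "p": [r.p for r in results],
        "p_holm": [r.p_holm for r in results],
        "is_vmp": [r.is_vmp for r in results],
    })


# ---------------------------------------------------------------------------
# Shannon entropy of the methylome
# ---------------------------------------------------------------------------

def shannon_entropy(mf, variant: str = "binary") -> float:
    """Normalized methylome entropy of a vector of methylation fractions.

    The ``binary`` variant is

        H = 1/(N·ln ½) · Σ_i [ MF_i·ln MF_i + (1−MF_i)·ln(1−MF_i) ],

    the average binary entropy of the per-CpG fractions, normalised to
    [0, 1] (0·ln 0 = 0 by convention; the 1/ln ½ prefactor makes the
    logarithm base irrelevant).  ``variant="as-printed"`` evaluates the
    alternative second term (1−MF_i)·(1−ln MF_i) for comparison; it is
    not normalised to [0, 1] and requires MF strictly positive.
    """
    mf = np.asarray(mf, dtype=float)
    if mf.size == 0:
        raise DataError("empty methylation-fraction vector")
    if (mf < 0).any() or (mf > 1).any():
        raise ValidationError("methylation fractions must lie in [0, 1]")
    if variant == "binary":
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(mf > 0, mf * np.log(mf), 0.0) + np.where(
                mf < 1, (1.0 - mf) * np.log(1.0 - mf), 0.0
            )
        return float(terms.sum() / (mf.size * LN_HALF))
    if variant == "as-printed":
        if (mf <= 0).any():
            raise ValidationError("the as-printed variant requires MF > 0")
        terms = mf * np.log(mf) + (1.0 - mf) * (1.0 - np.log(mf))
        return float(terms.sum() / (mf.size * LN_HALF))
    raise ValidationError(f"unknown entropy variant {variant!r}")


@dataclass(frozen=True)
class EntropyResult:
    """Per-sample methylome entropy over a fixed site set."""

    sample_id: str
    entropy: float
    n_sites: int


def entropy_per_sample(
    matrix: MethylationMatrix,
    site_set: list[SiteKey] | None = None,
) -> list[EntropyResult]:
    """Entropy of each sample's methylation fractions over ``site_set``.

    ``site_set`` defaults to all sites of the matrix; in the study
    pipeline it is the age-significant differentially methylated CpGs.
    Every site must be covered in every sample (united matrix).
    """
    sub = matrix if site_set is None else matrix.subset_sites(site_set)
    if sub.n_sites == 0:
        raise DataError("empty site set for entropy")
    if (sub.coverage == 0).any():
        raise DataError("entropy requires coverage > 0 at every cell")
    fractions = sub.fractions()
    return [
        EntropyResult(s.sample_id, shannon_entropy(fractions[:, j]), sub.n_sites)
        for j, s in enumerate(sub.samples)
    ]


# ---------------------------------------------------------------------------
# entropy ~ age x sex model
# ---------------------------------------------------------------------------

@dataclass
class EntropyAgeModel:
    """Beta regression of entropy on age, sex and their interaction."""

    full_fit: BetaRegFit
    reduced_fit: BetaRegFit
    interaction_chi2: float
    interaction_p: float
    #: sex -> (slope, se, z, p) from the stratified refit, or None if skipped
    per_sex: dict

    def summary(self) -> str:
        lines = [
            "entropy ~ age * sex (beta regression, logit link)",
            self.full_fit.summary(),
            "",
            f"age x sex interaction LRT: chi2 = {self.interaction_chi2:.4f}, "
            f"df = 1, p = {self.interaction_p:.4g}",
            "",
            "per-sex age slopes (stratified refits, Wald):",
        ]
        for sex in sorted(self.per_sex):
            res = self.per_sex[sex]
            if res is None:
                lines.append(f"  {sex}: skipped (fewer than 3 distinct ages)")
            else:
                slope, se, z, p = res
                lines.append(
                    f"  {sex}: slope = {slope:.6f} (se {se:.6f}), "
                    f"z = {z:.3f}, p = {p:.4g}"
                )
        return "\n".join(lines)


def entropy_age_model(
    entropies: list[EntropyResult],
    samples: list[SampleRecord],
) -> EntropyAgeModel:
    """Test how chronological age and sex shape methylome entropy.

    Fits entropy ~ age + sex + age:sex by beta regression, tests the
    interaction with a likelihood-ratio chi-square (1 df), then refits
    within each sex and Wald-tests the age coefficient (post hoc).
    """
    by_id = {s.sample_id: s for s in samples}
    recs = [by_id[e.sample_id] for e in entropies]
    for sex in ("F", "M"):
        if sum(r.sex == sex for r in recs) < 2:
            raise DataError(f"need >= 2 entropy values per sex (sex {sex})")
    y = boundary_transform(np.array([e.entropy for e in entropies]))
    age = np.array([r.age_days for r in recs], dtype=float)
    male = np.array([1.0 if r.sex == "M" else 0.0 for r in recs])
    ones = np.ones_like(age)

    X_full = np.column_stack([ones, age, male, age * male])
    X_red = np.column_stack([ones, age, male])
    full = BetaRegression(y, X_full,
                          exog_names=["const", "age", "male", "age:male"]).fit()
    red = BetaRegression(y, X_red, exog_names=["const", "age", "male"]).fit()
    chi2 = max(2.0 * (full.loglike - red.loglike), 0.0)
    p_int = float(stats.chi2.sf(chi2, df=1))

    per_sex: dict = {}
    for sex, flag in (("F", 0.0), ("M", 1.0)):
        mask = male == flag
        if len(np.unique(age[mask])) < 3:
            warnings.warn(f"sex {sex}: fewer than 3 distinct ages; slope test skipped")
            per_sex[sex] = None
            continue
        fit = BetaRegression(
            y[mask], np.column_stack([ones[mask], age[mask]]),
            exog_names=["const", "age"],
        ).fit()
        z, p = fit.wald_test(1)
        per_sex[sex] = (float(fit.params[1]), float(fit.bse[1]), z, p)

    return EntropyAgeModel(
        full_fit=full, reduced_fit=red,
        interaction_chi2=float(chi2), interaction_p=p_int, per_sex=per_sex,
    )
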