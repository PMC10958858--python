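"""Elastic-net epigenetic clock.

Chronological age (days) is regressed on per-CpG methylation fractions
("beta values") with the elastic-net penalty

    (1/2n)·Σ(age − β₀ − Xβ)² + λ·[α‖β‖₁ + (1−α)/2·‖β‖₂²],

λ chosen by seeded k-fold cross-validation (CV-MSE minimiser by
default, 1-SE rule optional) over a descending λ path.  Features are
standardized internally and coefficients returned on the original
scale; the clock's CpGs are the nonzero-coefficient support.  The
predicted age is the "epigenetic age"; its residual from the
regression of chronological on epigenetic age is the age acceleration.

In-sample accuracy of a clock trained on age-selected CpGs is
optimistic by construction; the cross-validated predictions stored on
the model are the honest counterpart.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import ElasticNet

from .errors import DataError, ValidationError
from .types import MethylationMatrix, SiteKey


# ---------------------------------------------------------------------------
# penalized fits
# ---------------------------------------------------------------------------

def elastic_net_coefficients(
    X: np.ndarray, y: np.ndarray, mixing: float, lam: float,
    tol: float = 1e-10, max_iter: int = 100000,
) -> tuple[float, np.ndarray]:
    """One elastic-net solution at fixed (mixing α, penalty λ).

    λ = 0 reduces exactly to ordinary least squares (computed by lstsq);
    otherwise coordinate descent.  X is used as given (no internal
    standardization here).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if lam < 0 or not (0.0 <= mixing <= 1.0):
        raise ValidationError("need lam >= 0 and mixing in [0, 1]")
    if lam == 0.0:
        A = np.column_stack([np.ones(len(y)), X])
        beta = np.linalg.lstsq(A, y, rcond=None)[0]
        return float(beta[0]), beta[1:]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        model = ElasticNet(alpha=lam, l1_ratio=mixing, fit_intercept=True,
                           max_iter=max_iter, tol=tol)
        model.fit(X, y)
    return float(model.intercept_), model.coef_.copy()


def _lambda_path(Xs, yc, mixing, n_lambdas=100, eps=1e-3) -> np.ndarray:
    """glmnet-style descending λ grid from the smallest all-zero λ."""
    n = len(yc)
    lam_max = np.abs(Xs.T @ yc).max() / (n * max(mixing, 1e-3))
    lam_max = max(lam_max, 1e-12)
    return np.geomspace(lam_max, lam_max * eps, n_lambdas)


def age_stratified_folds(ages, n_folds: int, seed: int) -> list[np.ndarray]:
    """Seeded fold assignment stratified by age.

    Samples are grouped by age, shuffled within groups, and dealt
    round-robin so every fold spans the age range — three folds on a
    small design otherwise risk age-degenerate folds.
    Returns a list of test-index arrays.
    """
    ages = np.asarray(ages)
    rng = np.random.default_rng(seed)
    order = []
    for a in np.unique(ages):
        idx = np.where(ages == a)[0]
        rng.shuffle(idx)
        order.extend(idx)
    folds: list[list[int]] = [[] for _ in range(n_folds)]
    for i, sample in enumerate(order):
        folds[i % n_folds].append(sample)
    return [np.sort(np.array(f, dtype=int)) for f in folds]


@dataclass
class ClockModel:
    """Fitted elastic-net clock: an affine map from fractions to days."""

    site_keys: list          # all candidate features, column order of X
    weights: np.ndarray      # per-feature coefficients on the original scale
    intercept: float
    mixing: float            # elastic-net α
    lam: float               # selected penalty λ
    cv_folds: int
    seed: int
    lambda_path: np.ndarray = field(repr=False, default=None)
    cv_mse: np.ndarray = field(repr=False, default=None)      # mean CV MSE per λ
    cv_predictions: np.ndarray = field(repr=False, default=None)

    @property
    def selected_sites(self) -> list:
        """CpGs with nonzero weight — the clock's marker set."""
        return [k for k, w in zip(self.site_keys, self.weights) if w != 0.0]

    @property
    def n_selected(self) -> int:
        return len(self.selected_sites)


def fit_elastic_net(
    X: np.ndarray,
    ages,
    site_keys: list | None = None,
    mixing: float = 0.5,
    cv_folds: int = 3,
    seed: int = 0,
    lambda_rule: str = "min",
) -> ClockModel:
    """Fit the clock on a samples x CpGs fraction matrix.

    λ is selected over a descending path as the CV-mean-squared-error
    minimiser (``lambda_rule="1se"`` picks the largest λ within one
    standard error of the minimum).  Identical inputs and seed
    reproduce identical weights.
    """
    X = np.asarray(X, dtype=float)
    ages = np.asarray(ages, dtype=float)
    if X.ndim != 2 or X.shape[0] != len(ages):
        raise ValidationError("X and ages have incompatible shapes")
    if np.isnan(X).any():
        raise DataError("missing methylation fractions in X")
    if np.ptp(ages) == 0:
        raise DataError("ages are constant; nothing to regress on")
    if cv_folds < 2 or cv_folds > len(ages):
        raise ValidationError(
            f"cv_folds must lie in [2, n]; got {cv_folds} with n = {len(ages)}"
        )
    if site_keys is None:
        site_keys = list(range(X.shape[1]))
    if len(site_keys) != X.shape[1]:
        raise ValidationError("site_keys length must match X columns")

    means = X.mean(axis=0)
    scales = X.std(axis=0)
    scales[scales == 0.0] = 1.0  # constant columns stay, weight 0 anyway
    Xs = (X - means) / scales
    yc = ages - ages.mean()

    lambdas = _lambda_path(Xs, yc, mixing)
    folds = age_stratified_folds(ages, cv_folds, seed)
    n = len(ages)

    mse = np.zeros((len(lambdas), cv_folds))
    cv_pred = np.zeros((len(lambdas), n))
    for f, test_idx in enumerate(folds):
        train = np.setdiff1d(np.arange(n), test_idx)
        for li, lam in enumerate(lambdas):
            # CV scoring tolerates a looser solve; the final refit is tight
            b0, b = elastic_net_coefficients(Xs[train], ages[train], mixing, lam,
                                             tol=1e-6, max_iter=20000)
            pred = b0 + Xs[test_idx] @ b
            cv_pred[li, test_idx] = pred
            mse[li, f] = float(np.mean((ages[test_idx] - pred) ** 2))
    mean_mse = mse.mean(axis=1)
    if lambda_rule == "min":
        best = int(np.argmin(mean_mse))
    elif lambda_rule == "1se":
        se = mse.std(axis=1, ddof=1) / np.sqrt(cv_folds)
        bound = mean_mse.min() + se[int(np.argmin(mean_mse))]
        best = int(np.min(np.where(mean_mse <= bound)[0]))  # path descends: largest λ first
    else:
        raise ValidationError(f"unknown lambda_rule {lambda_rule!r}")

    lam = float(lambdas[best])
    b0, b_std = elastic_net_coefficients(Xs, ages, mixing, lam)
    weights = b_std / scales
    intercept = b0 - float(np.sum(b_std * means / scales))
    return ClockModel(
        site_keys=list(site_keys), weights=weights, intercept=intercept,
        mixing=mixing, lam=lam, cv_folds=cv_folds, seed=seed,
        lambda_path=lambdas, cv_mse=mean_mse, cv_predictions=cv_pred[best],
    )


# ---------------------------------------------------------------------------
# prediction and evaluation
# ---------------------------------------------------------------------------

def clock_design_matrix(matrix: MethylationMatrix, site_keys: list) -> np.ndarray:
    """Samples x CpGs fraction matrix for the given site keys."""
    missing = [k for k in site_keys if k not in set(matrix.sites)]
    if missing:
        raise DataError(f"matrix lacks clock features {missing[:5]}...")
    sub = matrix.subset_sites(site_keys)
    order = [sub.site_index(k) for k in site_keys]
    return sub.fractions()[order].T


def predict_age(model: ClockModel, X) -> np.ndarray:
    """Epigenetic age per sample: β₀ + Xβ (days)."""
    if isinstance(X, MethylationMatrix):
        X = clock_design_matrix(X, model.site_keys)
    X = np.asarray(X, dtype=float)
    if X.shape[1] != len(model.site_keys):
        raise DataError(
            f"expected {len(model.site_keys)} features, got {X.shape[1]}"
        )
    return model.intercept + X @ model.weights


@dataclass
class ClockEvaluation:
    """Agreement between epigenetic and chronological age."""

    predicted: np.ndarray
    chronological: np.ndarray
    spearman_rho: float
    spearman_p: float
    rmse_days: float
    acceleration: np.ndarray | None = None

    def summary(self) -> str:
        lines = [
            f"n = {len(self.predicted)} samples",
            f"Spearman rho = {self.spearman_rho:.4f} (p = {self.spearman_p:.4g})",
            f"RMSE = {self.rmse_days:.4f} days",
        ]
        if self.acceleration is not None:
            lines.append(
                f"age acceleration: sd = {np.std(self.acceleration):.4f} days "
                f"(residuals sum to {self.acceleration.sum():.2e})"
            )
        return "\n".join(lines)


def evaluate_clock(predicted, chronological) -> ClockEvaluation:
    """Spearman correlation (average ranks, t approximation) and RMSE."""
    predicted = np.asarray(predicted, dtype=float)
    chronological = np.asarray(chronological, dtype=float)
    if len(predicted) != len(chronological):
        raise ValidationError("predicted and chronological lengths differ")
    if len(predicted) < 3:
        raise DataError("need >= 3 samples to evaluate")
    rho, p = stats.spearmanr(predicted, chronological)
    rmse = float(np.sqrt(np.mean((predicted - chronological) ** 2)))
    return ClockEvaluation(
        predicted=predicted, chronological=chronological,
        spearman_rho=float(rho), spearman_p=float(p), rmse_days=rmse,
    )


def age_acceleration(predicted, chronological) -> np.ndarray:
    """Residuals of chronological age regressed on epigenetic age.

    OLS with intercept, so the residuals sum to zero and any affine
    relation between the two ages is absorbed; positive residuals mean
    biologically "older" than the clock expects.
    """
    predicted = np.asarray(predicted, dtype=float)
    chronological = np.asarray(chronological, dtype=float)
    if len(predicted) != len(chronological) or len(predicted) < 3:
        raise ValidationError("need equal-length vectors with n >= 3")
    if np.ptp(predicted) == 0:
        raise DataError("constant predictions; acceleration undefined")
    A = np.column_stack([np.ones(len(predicted)), predicted])
    beta = np.linalg.lstsq(A, chronological, rcond=None)[0]
    return chronological - A @ beta


def rank_sum_test(group_a, group_b) -> tuple[float, float]:
    """Wilcoxon rank-sum (Mann–Whitney) comparison of two groups.

    Returns ``(W, p)`` with W the rank-sum statistic of group A minus
    n_A(n_A+1)/2.  The p-value is exact (full enumeration) when
    n_A + n_B <= 12 and there are no ties, and the tie-corrected normal
    approximation otherwise.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise DataError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (a.size + b.size <= 12 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)
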