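"""Beta regression with a logit mean link and constant precision.

Statsmodels-style usage: construct :class:`BetaRegression` with the
response and design matrix, call :meth:`~BetaRegression.fit`, get a
:class:`BetaRegFit` results object.  The density is parameterised by
mean mu = logistic(X beta) and precision phi (shape1 = mu*phi,
shape2 = (1-mu)*phi); maximisation is delegated to
``statsmodels.othermod.betareg.BetaModel`` (log link on phi
internally), with Wald standard errors from the observed information.

Responses must lie strictly inside (0, 1); exact 0/1 proportions are
mapped inside with :func:`boundary_transform`, the standard compression
y' = (y*(n-1) + 0.5)/n.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from statsmodels.othermod.betareg import BetaModel

from .errors import DataError, ValidationError


def boundary_transform(y: np.ndarray, n: int | None = None) -> np.ndarray:
    """Compress [0, 1] responses into (0, 1): y' = (y*(n-1) + 0.5)/n.

    ``n`` defaults to the number of observations.  The map is affine,
    hence strictly monotone and order-preserving.
    """
    y = np.asarray(y, dtype=float)
    if (y < 0).any() or (y > 1).any():
        raise ValidationError("responses must lie in [0, 1]")
    if n is None:
        n = y.size
    if n < 2:
        raise ValidationError("boundary transform needs n >= 2")
    return (y * (n - 1) + 0.5) / n


@dataclass
class BetaRegFit:
    """Results of one beta-regression fit."""

    params: np.ndarray          # mean-model coefficients (logit link)
    bse: np.ndarray             # Wald standard errors for params
    phi: float                  # precision estimate
    loglike: float
    converged: bool
    n: int
    exog_names: list = field(default_factory=list)

    def fitted_mean(self, X: np.ndarray) -> np.ndarray:
        eta = np.asarray(X, float) @ self.params
        return 1.0 / (1.0 + np.exp(-eta))

    def wald_test(self, index: int) -> tuple[float, float]:
        """Two-sided normal Wald z and p for one mean-model coefficient."""
        from scipy import stats

        z = self.params[index] / self.bse[index]
        return float(z), float(2.0 * stats.norm.sf(abs(z)))

    def summary(self) -> str:
        lines = [
            f"beta regression (logit link), n = {self.n}, "
            f"phi = {self.phi:.4g}, loglike = {self.loglike:.4f}, "
            f"converged = {self.converged}",
            f"{'term':>12} {'coef':>12} {'se':>10} {'z':>8}",
        ]
        names = self.exog_names or [f"x{i}" for i in range(len(self.params))]
        for name, b, se in zip(names, self.params, self.bse):
            z = b / se if se > 0 else np.nan
            lines.append(f"{name:>12} {b:>12.5f} {se:>10.5f} {z:>8.3f}")
        return "\n".join(lines)


class BetaRegression:
    """Model object: response in (0,1) against a full-rank design matrix."""

    def __init__(self, y, X, exog_names=None):
        y = np.asarray(y, dtype=float)
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or len(y) != X.shape[0]:
            raise ValidationError("y and X have incompatible shapes")
        if (y <= 0).any() or (y >= 1).any():
            raise DataError(
                "responses must lie strictly in (0, 1); apply boundary_transform"
            )
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise DataError("design matrix is rank deficient")
        if len(y) <= X.shape[1] + 1:
            raise DataError(
                f"need n > p + 1 observations (n={len(y)}, p={X.shape[1]})"
            )
        self.y = y
        self.X = X
        self.exog_names = list(exog_names) if exog_names else [
            f"x{i}" for i in range(X.shape[1])
        ]

    def fit(self, maxiter: int = 200) -> BetaRegFit:
        model = BetaModel(self.y, self.X)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(disp=0, maxiter=maxiter)
        converged = bool(getattr(res, "mle_retvals", {}).get("converged", True))
        k = self.X.shape[1]
        params = np.asarray(res.params[:k], dtype=float)
        bse = np.asarray(res.bse[:k], dtype=float)
        phi = float(np.exp(res.params[k]))  # precision uses a log link internally
        ll = float(res.llf)
        if not np.isfinite(ll):
            converged = False
        return BetaRegFit(
            params=params, bse=bse, phi=phi, loglike=ll,
            converged=converged, n=len(self.y), exog_names=self.exog_names,
        )


def fit_beta_regression(y, X, exog_names=None) -> BetaRegFit:
    """Functional façade over :class:`BetaRegression`."""
    return BetaRegression(y, X, exog_names=exog_names).fit()
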