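"""Ridge-penalized univariate logistic regression.

A small L2 penalty on the (standardized) slope keeps the fit finite under
complete separation, which is the common case when intra- and inter-patient
distance pools do not overlap.  The intercept is unpenalized.

Minimizes  mean cross-entropy + (ridge/2) * b1^2  over (b0, b1), with the
covariate standardized internally; coefficients are reported on both scales.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, xlogy
from scipy.stats import chi2


@dataclass(frozen=True)
class LogitFit:
    intercept: float          # raw-covariate scale
    slope: float              # raw-covariate scale
    intercept_std: float      # standardized-covariate scale
    slope_std: float
    x_mean: float
    x_sd: float
    loglike: float
    loglike_null: float
    lr_pvalue: float          # likelihood-ratio test of the slope
    n: int
    converged: bool

    def predict(self, x) -> np.ndarray:
        """P(y = 1 | x) on the raw covariate scale."""
        return expit(self.intercept + self.slope * np.asarray(x, dtype=float))


def fit_ridge_logit(x, y, ridge: float = 1e-4) -> LogitFit:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    sd = float(x.std(ddof=0))
    mu = float(x.mean())
    if sd == 0.0:
        sd = 1.0  # constant covariate: slope will fit to ~0
    z = (x - mu) / sd

    def objective(b):
        b0, b1 = b
        eta = b0 + b1 * z
        # numerically stable mean negative log-likelihood
        nll = np.mean(np.logaddexp(0.0, eta) - y * eta)
        return nll + 0.5 * ridge * b1 * b1

    def grad(b):
        b0, b1 = b
        r = expit(b0 + b1 * z) - y
        return np.array([r.mean(), (r * z).mean() + ridge * b1])

    res = minimize(objective, x0=np.zeros(2), jac=grad, method="BFGS",
                   options={"gtol": 1e-10, "maxiter": 500})
    b0, b1 = res.x
    eta = b0 + b1 * z
    ll = float(np.sum(xlogy(y, expit(eta)) + xlogy(1 - y, expit(-eta))))
    pbar = y.mean()
    ll_null = float(n * (xlogy(pbar, pbar) + xlogy(1 - pbar, 1 - pbar)))
    lr = max(0.0, 2.0 * (ll - ll_null))
    p = float(chi2.sf(lr, df=1))
    return LogitFit(
        intercept=float(b0 - b1 * mu / sd),
        slope=float(b1 / sd),
        intercept_std=float(b0),
        slope_std=float(b1),
        x_mean=mu,
        x_sd=sd,
        loglike=ll,
        loglike_null=ll_null,
        lr_pvalue=p,
        n=n,
        converged=bool(res.success),
    )
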