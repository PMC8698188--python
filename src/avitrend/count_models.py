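"""Maximum-likelihood fitting and AIC selection of the four count families.

For each species, four candidate models are fitted to the breeding-pair
counts on the same covariate design: Poisson (P), negative binomial NB2
(NB, variance mu + mu^2/k), zero-inflated Poisson (ZIP) and zero-inflated
negative binomial (ZINB).  The zero-inflated families mix a structural-zero
probability pi (logit link on the landscape-scale zero design) with the
count density.  The best family is the minimum-AIC converged fit; ties go
to the simpler family (P < NB < ZIP < ZINB).

Likelihood maximization is delegated to statsmodels' discrete models; this
module owns the design plumbing, start values, AIC bookkeeping, explained
deviance and the selection rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln
from statsmodels.discrete.count_model import (
    ZeroInflatedNegativeBinomialP,
    ZeroInflatedPoisson,
)
from statsmodels.discrete.discrete_model import NegativeBinomial, Poisson

from .design import ModelDesign

__all__ = [
    "FAMILIES",
    "FAMILY_LABELS",
    "FittedCountModel",
    "fit_count_model",
    "fit_all_families",
    "select_best_model",
    "explained_deviance",
]

#: simplicity order used for AIC tie-breaking
FAMILIES = ["P", "NB", "ZIP", "ZINB"]
FAMILY_LABELS = {"P": "C-P-GAM", "NB": "C-NB-GAM", "ZIP": "C-ZIP-GAM", "ZINB": "C-ZINB-GAM"}
_MAXITER = 500


@dataclass
class FittedCountModel:
    """One fitted candidate model for one species."""

    family: str
    params: pd.Series
    cov: pd.DataFrame
    llf: float
    aic: float
    n_params: int
    converged: bool
    deviance_explained_count: float | None
    deviance_explained_zero: float | None
    design: ModelDesign = field(repr=False)
    idx_count: np.ndarray = field(repr=False)
    idx_zero: np.ndarray | None = field(repr=False, default=None)
    alpha: float | None = None
    species_id: str | None = None

    @property
    def label(self) -> str:
        return FAMILY_LABELS[self.family]

    @property
    def is_zero_inflated(self) -> bool:
        return self.family in ("ZIP", "ZINB")

    def predict_mean(self, X: np.ndarray, Z: np.ndarray | None = None,
                     params: np.ndarray | None = None) -> np.ndarray:
        """Unconditional expected count: (1 - pi) * mu for ZI families."""
        theta = self.params.to_numpy() if params is None else np.asarray(params)
        mu = np.exp(X @ theta[self.idx_count])
        if self.is_zero_inflated:
            if Z is None:
                raise ValueError("zero-part design required for a ZI family")
            eta = Z @ theta[self.idx_zero]
            pi = 1.0 / (1.0 + np.exp(-eta))
            return (1.0 - pi) * mu
        return mu


def _ll_saturated(y: np.ndarray, family: str, alpha: float | None) -> float:
    """Per-observation maximized log-likelihood (mu = y; pi = 1 at zeros for ZI)."""
    y = np.asarray(y, float)
    pos = y[y > 0]
    if family in ("P", "ZIP"):
        ll_pos = np.sum(pos * np.log(pos) - pos - gammaln(pos + 1))
    else:
        a = max(alpha or 0.0, 1e-12)
        k = 1.0 / a
        # NB2 logpmf at mu = y
        ll_pos = np.sum(
            gammaln(pos + k) - gammaln(k) - gammaln(pos + 1)
            + k * np.log(k / (k + pos)) + pos * np.log(pos / (k + pos))
        )
    if family in ("P", "NB"):
        # zeros: Poisson/NB pmf at mu=0 is 1 -> contribution 0
        return float(ll_pos)
    return float(ll_pos)  # ZI zeros reach probability 1 via pi = 1


def _make_model(family: str, y: np.ndarray, X: np.ndarray, Z: np.ndarray | None):
    if family == "P":
        return Poisson(y, X)
    if family == "NB":
        return NegativeBinomial(y, X, loglike_method="nb2")
    if family == "ZIP":
        return ZeroInflatedPoisson(y, X, exog_infl=Z, inflation="logit")
    if family == "ZINB":
        return ZeroInflatedNegativeBinomialP(y, X, exog_infl=Z, inflation="logit", p=2)
    raise ValueError(f"unknown family {family!r}")


def _fit_raw(family: str, y: np.ndarray, X: np.ndarray, Z: np.ndarray | None,
             start: np.ndarray | None = None):
    """Fit with the default optimizer; on non-convergence, polish through a
    Nelder-Mead pass restarted from the best point so far."""
    model = _make_model(family, y, X, Z)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(disp=0, maxiter=_MAXITER, start_params=start)
        ok = res.mle_retvals.get("converged", True) and np.isfinite(res.llf)
        if not ok:
            # gradient methods can step into a region where the likelihood
            # is undefined (e.g. negative NB dispersion); restart a simplex
            # pass from the last finite point and polish from there
            restart = res.params if np.isfinite(res.llf) else start
            try:
                mid = model.fit(disp=0, maxiter=2000, method="nm",
                                start_params=restart)
                res2 = model.fit(disp=0, maxiter=_MAXITER, start_params=mid.params)
                if np.isfinite(res2.llf) and not (res2.llf < res.llf):
                    res = res2
            except Exception:
                pass
        return res


def _start_params(family: str, y, X, Z):
    """ZI fits start from the matching non-ZI fit plus an empirical zero-mass
    intercept; non-ZI fits use the statsmodels defaults."""
    if family not in ("ZIP", "ZINB"):
        return None
    base = _fit_raw("P" if family == "ZIP" else "NB", y, X, None)
    mu_hat = np.exp(np.clip(X @ base.params[: X.shape[1]], -30, 30))
    if family == "ZIP":
        p0_model = float(np.mean(np.exp(-mu_hat)))
        count_part = base.params
        alpha_part = []
    else:
        a = max(float(base.params[-1]), 1e-6)
        p0_model = float(np.mean((1 + a * mu_hat) ** (-1 / a)))
        count_part = base.params[:-1]
        alpha_part = [base.params[-1]]
    p0_obs = float(np.mean(y == 0))
    excess = np.clip((p0_obs - p0_model) / max(1 - p0_model, 1e-6), 1e-4, 1 - 1e-4)
    zi = np.zeros(Z.shape[1])
    zi[0] = np.log(excess / (1 - excess))
    return np.concatenate([zi, count_part, alpha_part])


def fit_count_model(
    design: ModelDesign,
    data: pd.DataFrame,
    y: np.ndarray | pd.Series,
    family: str,
    species_id: str | None = None,
    compute_deviance: bool = True,
) -> FittedCountModel:
    """Fit one family by maximum likelihood on the design's matrices.

    ``data`` is the covariate table aligned row-wise with ``y`` (pairs).
    Returns a :class:`FittedCountModel`; non-convergence is recorded in the
    ``converged`` flag rather than raised, so selection can skip the fit.
    """
    y = np.asarray(y)
    if np.any(y < 0) or not np.all(np.equal(np.mod(y, 1), 0)):
        raise ValueError("response must be non-negative integers")
    X = design.count_matrix(data)
    Z = design.zero_matrix(data) if family in ("ZIP", "ZINB") else None

    start = _start_params(family, y, X, Z)
    res = _fit_raw(family, y, X, Z, start=start)
    converged = bool(res.mle_retvals.get("converged", True))
    p = len(res.params)
    aic = -2.0 * res.llf + 2.0 * p

    names, idx_count, idx_zero, alpha = _param_layout(family, design, X, Z)
    params = pd.Series(np.asarray(res.params), index=names)
    cov = pd.DataFrame(_cov_params(res), index=names, columns=names)
    alpha_val = float(params.iloc[-1]) if family in ("NB", "ZINB") else None

    dev_c = dev_z = None
    if compute_deviance and converged:
        dev_c, dev_z = _explained_deviances(family, y, X, Z, res, alpha_val)

    return FittedCountModel(
        family=family, params=params, cov=cov, llf=float(res.llf), aic=float(aic),
        n_params=p, converged=converged, deviance_explained_count=dev_c,
        deviance_explained_zero=dev_z, design=design,
        idx_count=idx_count, idx_zero=idx_zero, alpha=alpha_val,
        species_id=species_id,
    )


def _cov_params(res) -> np.ndarray:
    """Inverse observed information; falls back to a numerical Hessian when
    the optimizer did not leave one behind."""
    try:
        return np.asarray(res.cov_params())
    except ValueError:
        H = res.model.hessian(res.params)
        return np.linalg.inv(-H)


def _param_layout(family, design, X, Z):
    count_names = list(design.count_names)[: X.shape[1]]
    if family in ("ZIP", "ZINB"):
        zero_names = list(design.zero_names)[: Z.shape[1]]
        names = zero_names + count_names
        idx_zero = np.arange(len(zero_names))
        idx_count = np.arange(len(zero_names), len(zero_names) + len(count_names))
    else:
        names = count_names
        idx_zero = None
        idx_count = np.arange(len(count_names))
    if family in ("NB", "ZINB"):
        names = names + ["alpha"]
    return names, idx_count, idx_zero, None


def _explained_deviances(family, y, X, Z, res, alpha):
    """Explained deviance per component: 1 - D_model / D_reduced.

    Deviances are measured against the saturated likelihood.  For plain
    families the reduced model is the intercept-only fit; for ZI families
    the count (zero) component is judged against a refit with that
    component reduced to its intercept while the other is kept in full.
    """
    ones = np.ones((len(y), 1))
    ll_sat = _ll_saturated(y, family, alpha)
    ll_full = float(res.llf)
    try:
        if family in ("P", "NB"):
            null = _fit_raw(family, y, ones, None)
            dev_c = _ed(ll_sat, ll_full, float(null.llf))
            return dev_c, None
        count_null = _fit_raw(family, y, ones, Z, start=None)
        zero_null = _fit_raw(family, y, X, ones,
                             start=_start_params(family, y, X, ones))
        dev_c = _ed(ll_sat, ll_full, float(count_null.llf))
        dev_z = _ed(ll_sat, ll_full, float(zero_null.llf))
        return dev_c, dev_z
    except Exception:  # pragma: no cover - degenerate refits
        return None, None


def _ed(ll_sat, ll_full, ll_reduced):
    d_full = 2.0 * (ll_sat - ll_full)
    d_red = 2.0 * (ll_sat - ll_reduced)
    if d_red <= 0:
        return None
    return float(np.clip(1.0 - d_full / d_red, 0.0, 1.0))


def explained_deviance(fit: FittedCountModel) -> tuple[float | None, float | None]:
    """(count-part, zero-part) explained-deviance fractions of a fit."""
    return fit.deviance_explained_count, fit.deviance_explained_zero


def fit_all_families(
    design: ModelDesign,
    data: pd.DataFrame,
    y,
    species_id: str | None = None,
    families: list[str] | None = None,
    compute_deviance: bool = True,
) -> dict[str, FittedCountModel]:
    """Fit every candidate family; fit failures are dropped with a warning."""
    out = {}
    for fam in families or FAMILIES:
        try:
            out[fam] = fit_count_model(
                design, data, y, fam, species_id=species_id,
                compute_deviance=compute_deviance,
            )
        except Exception as exc:
            warnings.warn(f"{fam} fit failed for {species_id!r}: {exc}")
    return out


def select_best_model(fits) -> FittedCountModel:
    """Minimum-AIC converged fit; exact ties go to the simpler family."""
    if isinstance(fits, dict):
        fits = list(fits.values())
    ok = [f for f in fits if f.converged and np.isfinite(f.aic)]
    if not ok:
        raise ValueError("no converged count-model fit to select from")
    return min(ok, key=lambda f: (f.aic, FAMILIES.index(f.family)))
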