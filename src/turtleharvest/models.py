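"""Trait regression: penalized random-intercept models with AICc selection.

For each life-history trait (clutch size, clutch frequency, age at sexual
maturity, annual adult survival) four candidate Gaussian models are fitted
on the transformed scale (natural log; arcsine-square-root for survival):
one focal term — continuous |latitude|, categorical latitudinal class,
bio10, or bio17 — plus ln carapace length as a size covariate and a
taxonomic-family random intercept in every model.

The random intercept is a ridge penalty on family indicator columns whose
penalty strength is chosen by REML: the variance ratio
``theta = sigma_family^2 / sigma_resid^2`` is profiled out with a bounded
1-D search on the log scale, and the fixed effects are the GLS solution at
the optimum.  This is exactly the "random effect as penalized regression
term" construction; no spline machinery is involved because every other
term is parametric.

Candidate models are ranked by AICc; Akaike weights give a 95% confidence
set, and zone-level predicted trait medians are weight-averaged over that
set.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "TRAIT_COLUMNS",
    "TraitTransform",
    "get_transform",
    "transform_trait",
    "RandomInterceptRegressor",
    "aicc",
    "akaike_weights",
    "confidence_set",
    "ModelSpec",
    "TraitModelFit",
    "fit_trait_models",
    "predict_traits",
    "FOCAL_TERMS",
]

#: trait key -> species-table column
TRAIT_COLUMNS = {
    "clutch_size": "clutch_size",
    "clutch_frequency": "clutch_frequency_per_yr",
    "age_maturity": "age_maturity_yr",
    "adult_survival": "adult_survival",
}

FOCAL_TERMS = ("latitude", "lat_class", "bio10", "bio17")

LAT_CLASS_ORDER = ("Temperate", "Temp-trop", "Trop-temp", "Tropical")


# ---------------------------------------------------------------------------
# Transforms
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TraitTransform:
    """Forward/inverse pair mapping a trait to its modelling scale."""

    name: str
    forward: callable
    inverse: callable


def _log_transform(name: str) -> TraitTransform:
    return TraitTransform(name, np.log, np.exp)


def _arcsine_sqrt() -> TraitTransform:
    return TraitTransform(
        "arcsine_sqrt",
        lambda x: np.arcsin(np.sqrt(x)),
        lambda y: np.sin(y) ** 2,
    )


def _arcsine_plain() -> TraitTransform:
    return TraitTransform("arcsine", np.arcsin, np.sin)


def get_transform(trait: str, survival_arcsine: str = "sqrt") -> TraitTransform:
    """Transform for a trait: ln everywhere, arcsine for survival.

    ``survival_arcsine`` selects ``arcsin(sqrt(x))`` (the standard
    variance-stabilizer for proportions, default) or plain ``arcsin(x)``.
    """
    if trait == "adult_survival":
        if survival_arcsine == "sqrt":
            return _arcsine_sqrt()
        if survival_arcsine == "plain":
            return _arcsine_plain()
        raise ValueError("survival_arcsine must be 'sqrt' or 'plain'")
    if trait in TRAIT_COLUMNS or trait == "carapace_length":
        return _log_transform("log")
    raise KeyError(f"unknown trait {trait!r}")


def transform_trait(
    values: np.ndarray, trait: str, survival_arcsine: str = "sqrt"
) -> np.ndarray:
    """Apply the trait's transform after validating its domain."""
    values = np.asarray(values, dtype=float)
    finite = values[np.isfinite(values)]
    if trait == "adult_survival":
        if ((finite <= 0) | (finite > 1)).any():
            raise ValueError("adult survival must lie in (0, 1]")
    else:
        if (finite <= 0).any():
            raise ValueError(f"{trait} values must be positive")
    return get_transform(trait, survival_arcsine).forward(values)


# ---------------------------------------------------------------------------
# REML random-intercept estimator
# ---------------------------------------------------------------------------


class RandomInterceptRegressor(BaseEstimator, RegressorMixin):
    """Gaussian regression with one random intercept, estimated by REML.

    The model is ``y = X beta + Z b + e`` with ``b ~ N(0, sigma_b^2 I)`` over
    the levels of a grouping factor and ``e ~ N(0, sigma_e^2 I)``.  The
    variance ratio ``theta = sigma_b^2 / sigma_e^2`` is found by a bounded
    1-D minimization of the REML criterion on the log-theta scale; fixed
    effects are the GLS solution at the optimum and group effects are BLUPs.
    Equivalently the group indicators enter as ridge-penalized columns with
    penalty ``1/theta``, whose effective degrees of freedom (trace of the
    shrinkage projector) are reported as ``edf_random_``.

    Parameters
    ----------
    fit_intercept : bool
        Prepend a constant column to the fixed design.
    theta : float or None
        If given, the variance ratio is fixed (0 reduces the fit to OLS)
        instead of REML-optimized.
    log_theta_bounds : tuple of float
        Search interval for ``ln theta``.

    Attributes (after ``fit``)
    --------------------------
    coef_, intercept_, coef_se_ : fixed effects and their standard errors
    group_effects_ : dict mapping group label -> BLUP intercept
    sigma2_resid_, sigma2_group_, theta_ : variance components
    edf_random_ : effective df of the random term, in [0, n_groups - 1]
    loglik_ : Gaussian ML log-likelihood at the fitted parameters
    reml_criterion_ : minimized REML criterion (up to an additive constant)
    """

    def __init__(
        self,
        fit_intercept: bool = True,
        theta: float | None = None,
        log_theta_bounds: tuple[float, float] = (-12.0, 12.0),
    ):
        self.fit_intercept = fit_intercept
        self.theta = theta
        self.log_theta_bounds = log_theta_bounds

    # -- internals ---------------------------------------------------------

    def _design(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if self.fit_intercept:
            X = np.column_stack([np.ones(len(X)), X])
        return X

    @staticmethod
    def _profile(y, X, Z, theta):
        """GLS fit at a fixed variance ratio; returns the pieces the REML
        criterion and the downstream statistics need."""
        n, p = X.shape
        V = np.eye(n) + theta * (Z @ Z.T)
        c, low = linalg.cho_factor(V, lower=True)
        logdet_V = 2.0 * np.log(np.diag(c)).sum()
        Vi_X = linalg.cho_solve((c, low), X)
        Vi_y = linalg.cho_solve((c, low), y)
        XtViX = X.T @ Vi_X
        sign, logdet_XtViX = np.linalg.slogdet(XtViX)
        if sign <= 0:
            raise np.linalg.LinAlgError("X'V^-1X not positive definite")
        beta = linalg.solve(XtViX, X.T @ Vi_y, assume_a="pos")
        resid = y - X @ beta
        Vi_r = linalg.cho_solve((c, low), resid)
        quad = float(resid @ Vi_r)
        crit = logdet_V + logdet_XtViX + (n - p) * math.log(quad)
        return crit, beta, XtViX, Vi_r, logdet_V, quad

    # -- API ---------------------------------------------------------------

    def fit(self, X, y, groups):
        y = np.asarray(y, dtype=float)
        X = self._design(X)
        n, p = X.shape
        if n <= p + 2:
            raise ValueError(f"need n > p + 2 (n={n}, p={p})")
        if np.linalg.matrix_rank(X) < p:
            raise np.linalg.LinAlgError("singular fixed-effect design")
        groups = np.asarray(groups)
        levels, gidx = np.unique(groups, return_inverse=True)
        if levels.size < 2:
            raise ValueError("need at least 2 groups for a random intercept")
        Z = np.zeros((n, levels.size))
        Z[np.arange(n), gidx] = 1.0

        if self.theta is not None:
            theta = float(self.theta)
            if theta < 0:
                raise ValueError("theta must be >= 0")
        else:
            lo, hi = self.log_theta_bounds
            res = optimize.minimize_scalar(
                lambda lt: self._profile(y, X, Z, math.exp(lt))[0],
                bounds=(lo, hi),
                method="bounded",
                options={"xatol": 1e-8},
            )
            if not res.success:
                raise RuntimeError(
                    f"REML search failed: {res.message!r} (bounds {lo}, {hi})"
                )
            theta = math.exp(res.x)
            # A ratio pinned at the lower bound is numerically zero variance.
            if res.x <= lo + 1e-6:
                theta = 0.0

        crit, beta, XtViX, Vi_r, _, quad = self._profile(
            y, X, Z, theta if theta > 0 else 0.0
        )
        sigma2_e = quad / (n - p)
        cov_beta = sigma2_e * np.linalg.inv(XtViX)

        if self.fit_intercept:
            self.intercept_ = float(beta[0])
            self.coef_ = beta[1:].copy()
            se = np.sqrt(np.diag(cov_beta))
            self.intercept_se_ = float(se[0])
            self.coef_se_ = se[1:].copy()
        else:
            self.intercept_ = 0.0
            self.intercept_se_ = float("nan")
            self.coef_ = beta.copy()
            self.coef_se_ = np.sqrt(np.diag(cov_beta))

        b = theta * (Z.T @ Vi_r)
        self.group_levels_ = levels
        self.group_effects_ = dict(zip(levels.tolist(), b.tolist()))
        self.theta_ = float(theta)
        self.sigma2_resid_ = float(sigma2_e)
        self.sigma2_group_ = float(theta * sigma2_e)
        self.reml_criterion_ = float(crit)
        self.n_obs_ = n
        self.n_fixed_ = p
        self.edf_random_ = self._edf_random(X, Z, theta)

        # Gaussian ML log-likelihood at (beta_hat, theta_hat), ML-profiled
        # residual variance — the quantity AICc consumes.
        V = np.eye(n) + theta * (Z @ Z.T)
        sign, logdet_V = np.linalg.slogdet(V)
        sigma2_ml = quad / n
        self.loglik_ = float(
            -0.5 * (n * math.log(2.0 * math.pi * sigma2_ml) + logdet_V + n)
        )

        self._beta_full_ = beta
        return self

    @staticmethod
    def _edf_random(X, Z, theta):
        """Trace of the random term's shrinkage projector.

        With the random intercept written as a ridge penalty ``1/theta`` on
        the indicator block, the joint hat matrix is
        ``H = C (C'C + P)^-1 C'`` for ``C = [X Z]`` and ``P`` penalizing only
        the Z block; the random term's effective df is ``tr(H) - p``.
        """
        if theta <= 0:
            return 0.0
        n, p = X.shape
        C = np.column_stack([X, Z])
        CtC = C.T @ C
        P = np.zeros_like(CtC)
        P[p:, p:] = np.eye(Z.shape[1]) / theta
        trH = float(np.trace(linalg.solve(CtC + P, CtC, assume_a="pos")))
        return max(trH - p, 0.0)

    def predict(self, X, groups=None):
        X = self._design(X)
        yhat = X @ self._beta_full_
        if groups is not None:
            effs = np.array(
                [self.group_effects_.get(g, 0.0) for g in np.asarray(groups)]
            )
            yhat = yhat + effs
        return yhat

    @property
    def edf_total_(self) -> float:
        """Fixed coefficients plus random-term edf (excludes the variance)."""
        return self.n_fixed_ + self.edf_random_


# ---------------------------------------------------------------------------
# Information-theoretic model comparison
# ---------------------------------------------------------------------------


def aicc(loglik: float, k: float, n: int) -> float:
    """Small-sample-corrected AIC: ``-2 loglik + 2k + 2k(k+1)/(n-k-1)``."""
    if n - k - 1 <= 0:
        raise ValueError(f"AICc undefined for n={n}, k={k} (need n > k + 1)")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1.0) / (n - k - 1.0)


def akaike_weights(aicc_values) -> np.ndarray:
    """Akaike weights ``w_i = exp(-d_i/2) / sum_j exp(-d_j/2)`` with
    ``d_i = AICc_i - min AICc``; invariant to a common additive shift."""
    a = np.asarray(aicc_values, dtype=float)
    if a.size == 0 or np.isnan(a).any():
        raise ValueError("AICc values must be non-empty and free of NaN")
    d = a - a.min()
    w = np.exp(-0.5 * d)
    return w / w.sum()


def confidence_set(weights, level: float = 0.95) -> np.ndarray:
    """Indices of the smallest prefix of weight-ranked models whose
    cumulative Akaike weight reaches *level*."""
    w = np.asarray(weights, dtype=float)
    order = np.argsort(-w, kind="stable")
    cum = np.cumsum(w[order])
    size = int(np.searchsorted(cum, level) + 1)
    size = min(size, w.size)
    return order[:size]


# ---------------------------------------------------------------------------
# Trait model set
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ModelSpec:
    """One candidate model: a trait, one focal term, the size covariate and
    the family random intercept (the last two are common to every model)."""

    trait: str
    focal: str

    def __post_init__(self):
        if self.focal not in FOCAL_TERMS:
            raise ValueError(f"focal must be one of {FOCAL_TERMS}")


@dataclass
class TraitModelFit:
    """A fitted candidate model plus everything needed to rank and predict."""

    spec: ModelSpec
    estimator: RandomInterceptRegressor
    term_names: list[str]
    coef: dict[str, float]
    se: dict[str, float]
    pvalue: dict[str, float]
    n: int
    k: float
    loglik: float
    aicc: float
    deviance_explained: float
    response_center: float
    response_scale: float
    covariate_center: dict[str, float]
    covariate_scale: dict[str, float]
    weight: float = float("nan")
    delta_aicc: float = float("nan")


def _focal_columns(df: pd.DataFrame, focal: str):
    """Design columns and their names for one focal term (unstandardized)."""
    if focal == "latitude":
        return {"latitude": df["abs_latitude"].to_numpy(float)}
    if focal == "bio10":
        return {"bio10": df["bio10_c"].to_numpy(float)}
    if focal == "bio17":
        return {"bio17": df["bio17_mm"].to_numpy(float)}
    if focal == "lat_class":
        cols = {}
        for cls in LAT_CLASS_ORDER[1:]:  # Temperate is the reference level
            ind = (df["lat_class"] == cls).to_numpy(float)
            if ind.any():  # drop contrasts for classes absent in this subset
                cols[f"lat_class[{cls}]"] = ind
        return cols
    raise ValueError(focal)


_CATEGORICAL_PREFIX = "lat_class["


def _build_design(df: pd.DataFrame, spec: ModelSpec):
    """Standardized design for one candidate model.

    Continuous covariates (focal term and ln carapace) are centered and
    scaled to unit SD; categorical class contrasts stay as 0/1 indicators
    with Temperate as the baseline.
    """
    cols = {"ln_carapace": np.log(df["carapace_length_mm"].to_numpy(float))}
    cols.update(_focal_columns(df, spec.focal))
    names, data, center, scale = [], [], {}, {}
    for name, x in cols.items():
        if name.startswith(_CATEGORICAL_PREFIX):
            center[name], scale[name] = 0.0, 1.0
        else:
            mu, sd = float(np.mean(x)), float(np.std(x, ddof=0))
            if sd == 0:
                raise ValueError(f"covariate {name} has zero variance")
            x = (x - mu) / sd
            center[name], scale[name] = mu, sd
        names.append(name)
        data.append(np.asarray(x, dtype=float))
    return names, np.column_stack(data), center, scale


def fit_trait_models(
    species: pd.DataFrame,
    trait: str,
    survival_arcsine: str = "sqrt",
) -> list[TraitModelFit]:
    """Fit the four candidate models for one trait and rank them by AICc.

    The response is the transformed trait, centered and scaled to unit SD,
    so coefficients are standardized.  ``k`` for AICc counts the fixed
    coefficients, the random term's effective df, and the residual variance.
    Returns fits sorted by increasing AICc with Akaike weights attached.
    """
    col = TRAIT_COLUMNS[trait]
    df = species.loc[species[col].notna()].copy()
    n = len(df)
    if n < 10:
        raise ValueError(f"too few species ({n}) with data for {trait}")
    y_t = transform_trait(df[col].to_numpy(float), trait, survival_arcsine)
    y_mu, y_sd = float(np.mean(y_t)), float(np.std(y_t, ddof=0))
    if y_sd == 0:
        raise ValueError(f"{trait} has zero variance after transform")
    y = (y_t - y_mu) / y_sd

    fits: list[TraitModelFit] = []
    for focal in FOCAL_TERMS:
        spec = ModelSpec(trait=trait, focal=focal)
        names, X, center, scale = _build_design(df, spec)
        est = RandomInterceptRegressor().fit(X, y, groups=df["family"])
        k = est.n_fixed_ + est.edf_random_ + 1.0
        term_names = ["intercept"] + names
        coefs = np.concatenate([[est.intercept_], est.coef_])
        ses = np.concatenate([[est.intercept_se_], est.coef_se_])
        dof = max(n - est.n_fixed_, 1)
        pvals = 2.0 * stats.t.sf(
            np.abs(coefs) / np.where(ses > 0, ses, np.inf), dof
        )
        yhat = est.predict(X, groups=df["family"])
        dev_expl = 1.0 - float(
            np.sum((y - yhat) ** 2) / np.sum((y - np.mean(y)) ** 2)
        )
        fits.append(
            TraitModelFit(
                spec=spec,
                estimator=est,
                term_names=term_names,
                coef=dict(zip(term_names, coefs.tolist())),
                se=dict(zip(term_names, ses.tolist())),
                pvalue=dict(zip(term_names, pvals.tolist())),
                n=n,
                k=k,
                loglik=est.loglik_,
                aicc=aicc(est.loglik_, k, n),
                deviance_explained=dev_expl,
                response_center=y_mu,
                response_scale=y_sd,
                covariate_center=center,
                covariate_scale=scale,
            )
        )
    aiccs = np.array([f.aicc for f in fits])
    weights = akaike_weights(aiccs)
    best = aiccs.min()
    for f, w in zip(fits, weights):
        f.weight = float(w)
        f.delta_aicc = float(f.aicc - best)
    fits.sort(key=lambda f: f.aicc)
    return fits


def _predict_one(fit: TraitModelFit, species: pd.DataFrame) -> np.ndarray:
    """Per-species prediction on the transformed (natural) scale."""
    names, _, _, _ = _build_design_for_predict(species, fit)
    X = np.column_stack(
        [
            _standardize_col(species, name, fit)
            for name in fit.term_names
            if name != "intercept"
        ]
    )
    families = species["family"].to_numpy()
    known = np.isin(families, fit.estimator.group_levels_)
    if not known.all():
        warnings.warn(
            "families unseen in training predicted with zero family effect: "
            + ", ".join(sorted(set(families[~known]))),
            stacklevel=2,
        )
    z = fit.estimator.predict(X, groups=families)
    return z * fit.response_scale + fit.response_center


def _standardize_col(species, name, fit):
    if name == "ln_carapace":
        x = np.log(species["carapace_length_mm"].to_numpy(float))
    elif name == "latitude":
        x = species["abs_latitude"].to_numpy(float)
    elif name == "bio10":
        x = species["bio10_c"].to_numpy(float)
    elif name == "bio17":
        x = species["bio17_mm"].to_numpy(float)
    elif name.startswith(_CATEGORICAL_PREFIX):
        cls = name[len(_CATEGORICAL_PREFIX):-1]
        x = (species["lat_class"] == cls).to_numpy(float)
    else:
        raise KeyError(name)
    return (x - fit.covariate_center[name]) / fit.covariate_scale[name]


def _build_design_for_predict(species, fit):
    # Prediction reuses the training centers/scales; this helper exists only
    # to validate required columns early with a clear message.
    required = {"carapace_length_mm", "family", "lat_class", "abs_latitude"}
    missing = required - set(species.columns)
    if missing:
        raise KeyError(f"species table lacks columns {sorted(missing)}")
    return fit.term_names, None, None, None


def predict_traits(
    species: pd.DataFrame,
    fits_by_trait: dict[str, list[TraitModelFit]],
    level: float = 0.95,
    survival_arcsine: str = "sqrt",
) -> pd.DataFrame:
    """Model-averaged per-species trait predictions, back-transformed.

    For each trait the confidence set is the smallest prefix of weight-ranked
    models reaching *level* cumulative weight; predictions are averaged over
    that set with renormalized weights on the transformed scale, then
    back-transformed.  Returns the species table with ``pred_<trait>``
    columns plus ``pred_fecundity`` (predicted clutch size x predicted
    clutch frequency).
    """
    out = species.copy()
    for trait, fits in fits_by_trait.items():
        weights = np.array([f.weight for f in fits])
        idx = confidence_set(weights, level)
        sel = [fits[i] for i in idx]
        w = weights[idx]
        w = w / w.sum()
        z = np.zeros(len(species))
        for f, wi in zip(sel, w):
            z += wi * _predict_one(f, species)
        inv = get_transform(trait, survival_arcsine).inverse
        out[f"pred_{trait}"] = inv(z)
    if {"pred_clutch_size", "pred_clutch_frequency"} <= set(out.columns):
        out["pred_fecundity"] = (
            out["pred_clutch_size"] * out["pred_clutch_frequency"]
        )
    return out


def model_summary_table(fits_by_trait: dict[str, list[TraitModelFit]]) -> pd.DataFrame:
    """Long-format comparison table (one row per trait x model)."""
    rows = []
    for trait, fits in fits_by_trait.items():
        for f in fits:
            rows.append(
                {
                    "trait": trait,
                    "model": f.spec.focal,
                    "n": f.n,
                    "dev_expl": f.deviance_explained,
                    "loglik": f.loglik,
                    "k": f.k,
                    "AICc": f.aicc,
                    "delta_AICc": f.delta_aicc,
                    "weight": f.weight,
                }
            )
    return pd.DataFrame(rows)
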