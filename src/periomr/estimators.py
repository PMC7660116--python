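"""Causal-effect estimators for two-sample Mendelian randomization.

Given J harmonized variants with exposure effects γ_j (se σ_xj) and outcome
effects Γ_j (se σ_Γj), each variant supplies a Wald ratio Γ_j/γ_j with
first-order delta-method standard error σ_Γj/|γ_j|.  Three estimators combine
them:

* **IVW** — inverse-variance weighted mean of the ratios, identical to a
  weighted regression of Γ on γ through the origin with weights 1/σ_Γj².
  The random-effects variant inflates standard errors by the multiplicative
  overdispersion scale φ̂ = max(1, RSS_w/(J−1)).
* **MR-Egger** — the same weighted regression with an unconstrained
  intercept.  The slope is the causal effect under the InSIDE assumption
  (instrument strength independent of direct effects); the intercept
  estimates average directional pleiotropy and has its own test.
* **Weighted median** — the 50% point of the ratio distribution under
  standardized cumulative inverse-variance weights; consistent when at least
  half the weight comes from valid instruments.  Its standard error comes
  from a parametric bootstrap that redraws γ̂_j and Γ̂_j from their sampling
  distributions.

The estimator classes follow the scikit-learn protocol (``fit``, fitted
attributes with trailing underscores, ``get_params``/``set_params``); the
module-level functions :func:`ivw`, :func:`egger` and :func:`weighted_median`
are thin wrappers that accept the harmonized-pairs table and return
:class:`MRResult` records.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin

from .exceptions import ValidationError

#: log-scale multiplier converting a per-unit-log-odds-of-exposure effect to a
#: per-doubling-of-exposure-odds effect (the conventional rounding of ln 2)
DOUBLING_FACTOR = 0.693

SCALE_PER_UNIT = "per-unit-log-odds-exposure"
SCALE_PER_DOUBLING = "per-doubling-exposure-odds"


@dataclass(frozen=True)
class MRResult:
    """One causal estimate: method, scale and inference summary."""

    method: str
    scale: str
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    p_value: float
    n_variants: int
    overdispersion_phi: float | None = None
    intercept: float | None = None
    intercept_se: float | None = None
    intercept_p: float | None = None
    exponentiated: bool = False

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def _ci_quantile(ci_dist: str, df: int, level: float = 0.95) -> float:
    if ci_dist == "normal":
        return float(stats.norm.ppf(0.5 + level / 2.0))
    if ci_dist == "t":
        return float(stats.t.ppf(0.5 + level / 2.0, df))
    raise ValidationError(f"unknown ci_dist {ci_dist!r}")


def _check_xy(X, y):
    x = np.asarray(X, dtype=float).reshape(-1)
    yy = np.asarray(y, dtype=float).reshape(-1)
    if x.shape != yy.shape:
        raise ValidationError("exposure and outcome effect vectors differ in length")
    if not np.all(np.isfinite(x)) or not np.all(np.isfinite(yy)):
        raise ValidationError("effects must be finite")
    return x, yy


def ratio_estimates(pairs: pd.DataFrame, second_order: bool = False) -> pd.DataFrame:
    """Per-variant Wald ratios, standard errors and inverse-variance weights.

    With ``second_order=True`` the ratio variance additionally carries the
    exposure-side sampling term Γ²σ_x²/γ⁴ (a sensitivity option; the default
    first-order form ignores exposure-side uncertainty).
    """
    g = pairs["beta_exposure"].to_numpy(dtype=float)
    G = pairs["beta_outcome"].to_numpy(dtype=float)
    sG = pairs["se_outcome"].to_numpy(dtype=float)
    if np.any(g == 0):
        raise ValidationError("beta_exposure = 0: Wald ratio undefined")
    var = sG**2 / g**2
    if second_order:
        sx = pairs["se_exposure"].to_numpy(dtype=float)
        var = var + G**2 * sx**2 / g**4
    se = np.sqrt(var)
    return pd.DataFrame(
        {
            "variant_id": pairs["variant_id"].to_numpy(),
            "ratio": G / g,
            "se": se,
            "weight": 1.0 / var,
        }
    )


class IVWEstimator(RegressorMixin, BaseEstimator):
    """Inverse-variance weighted MR: weighted regression through the origin.

    Parameters
    ----------
    model:
        ``"random"`` (default) applies multiplicative overdispersion
        φ̂ = max(1, RSS_w/(J−1)) to the standard error; ``"fixed"`` does not.
    ci_dist:
        ``"normal"`` (default) or ``"t"`` quantiles for the 95% interval.

    After ``fit``: ``estimate_``, ``se_``, ``ci_low_``, ``ci_high_``,
    ``p_value_``, ``overdispersion_``, ``n_variants_`` and sklearn's
    ``coef_`` (length-1 array).
    """

    def __init__(self, model: str = "random", ci_dist: str = "normal"):
        self.model = model
        self.ci_dist = ci_dist

    def fit(self, X, y, sample_weight=None):
        """Fit on exposure effects X, outcome effects y.

        ``sample_weight`` should be the inverse outcome-effect variances
        1/σ_Γj² (first-order IVW weights); uniform weights if omitted.
        """
        if self.model not in ("fixed", "random"):
            raise ValidationError(f"unknown IVW model {self.model!r}")
        x, yy = _check_xy(X, y)
        J = x.size
        if J == 0:
            raise ValidationError("IVW requires at least one variant")
        w = np.ones(J) if sample_weight is None else np.asarray(sample_weight, dtype=float).reshape(-1)
        if np.any(w <= 0) or not np.all(np.isfinite(w)):
            raise ValidationError("weights must be finite and > 0")

        model = self.model
        if model == "random" and J == 1:
            warnings.warn("single variant: random-effects IVW falls back to fixed-effects", stacklevel=2)
            model = "fixed"

        sxx = float(np.sum(w * x * x))
        theta = float(np.sum(w * x * yy) / sxx)
        se = float(np.sqrt(1.0 / sxx))
        rss = float(np.sum(w * (yy - theta * x) ** 2))
        phi = 1.0
        if model == "random":
            phi = max(1.0, rss / (J - 1))
            se *= np.sqrt(phi)

        q = _ci_quantile(self.ci_dist, df=J - 1 if J > 1 else 1)
        self.coef_ = np.array([theta])
        self.estimate_ = theta
        self.se_ = se
        self.ci_low_ = theta - q * se
        self.ci_high_ = theta + q * se
        self.p_value_ = float(2.0 * stats.norm.sf(abs(theta / se)))
        self.overdispersion_ = phi
        self.residual_ss_ = rss
        self.n_variants_ = J
        return self

    def predict(self, X):
        x = np.asarray(X, dtype=float).reshape(-1)
        return x * self.coef_[0]

    def result(self, scale: str = SCALE_PER_UNIT) -> MRResult:
        return MRResult(
            method="IVW",
            scale=scale,
            estimate=self.estimate_,
            se=self.se_,
            ci_low=self.ci_low_,
            ci_high=self.ci_high_,
            p_value=self.p_value_,
            n_variants=self.n_variants_,
            overdispersion_phi=self.overdispersion_,
        )


class EggerEstimator(RegressorMixin, BaseEstimator):
    """MR-Egger: weighted regression of Γ on γ with an unconstrained intercept.

    Requires J >= 3 and all exposure effects strictly positive (orient the
    exposure risk-increasing first — the intercept is only interpretable with
    a consistent effect-allele orientation).  Multiplicative overdispersion
    φ̂ = max(1, RSS_w/(J−2)) inflates both slope and intercept standard
    errors.
    """

    def __init__(self, model: str = "random", ci_dist: str = "normal"):
        self.model = model
        self.ci_dist = ci_dist

    def fit(self, X, y, sample_weight=None):
        x, yy = _check_xy(X, y)
        J = x.size
        if J < 3:
            raise ValidationError(f"MR-Egger needs at least 3 variants for a residual degree of freedom (got {J})")
        if np.any(x <= 0):
            raise ValidationError("MR-Egger requires all exposure effects > 0 (orientation precondition)")
        w = np.ones(J) if sample_weight is None else np.asarray(sample_weight, dtype=float).reshape(-1)
        if np.any(w <= 0) or not np.all(np.isfinite(w)):
            raise ValidationError("weights must be finite and > 0")

        sw = np.sqrt(w)
        design = np.column_stack([sw, sw * x])  # [intercept, slope] on the sqrt(w) transform
        target = sw * yy
        xtx = design.T @ design
        beta = np.linalg.solve(xtx, design.T @ target)
        resid = target - design @ beta
        rss = float(resid @ resid)
        cov = np.linalg.inv(xtx)
        phi = 1.0
        if self.model == "random":
            phi = max(1.0, rss / (J - 2))
        ses = np.sqrt(phi * np.diag(cov))

        q = _ci_quantile(self.ci_dist, df=J - 2)
        intercept, slope = float(beta[0]), float(beta[1])
        i_se, s_se = float(ses[0]), float(ses[1])
        self.coef_ = np.array([slope])
        self.intercept_ = intercept
        self.estimate_ = slope
        self.se_ = s_se
        self.ci_low_ = slope - q * s_se
        self.ci_high_ = slope + q * s_se
        self.p_value_ = float(2.0 * stats.norm.sf(abs(slope / s_se)))
        self.intercept_se_ = i_se
        self.intercept_p_ = float(2.0 * stats.norm.sf(abs(intercept / i_se)))
        self.overdispersion_ = phi
        self.residual_ss_ = rss
        self.n_variants_ = J
        return self

    def predict(self, X):
        x = np.asarray(X, dtype=float).reshape(-1)
        return self.intercept_ + x * self.coef_[0]

    def result(self, scale: str = SCALE_PER_UNIT) -> MRResult:
        return MRResult(
            method="MR-Egger",
            scale=scale,
            estimate=self.estimate_,
            se=self.se_,
            ci_low=self.ci_low_,
            ci_high=self.ci_high_,
            p_value=self.p_value_,
            n_variants=self.n_variants_,
            overdispersion_phi=self.overdispersion_,
            intercept=self.intercept_,
            intercept_se=self.intercept_se_,
            intercept_p=self.intercept_p_,
        )


def weighted_median_point(ratios, weights) -> float:
    """Weighted median by linear interpolation of standardized cumulative weights.

    Ratios are sorted ascending; with s_j = (Σ_{i<=j} w_i − w_j/2)/Σw, the
    estimate interpolates the sorted ratios at s = 0.5 (clamped to the
    extreme ratios when 0.5 falls outside [s_1, s_J]).
    """
    r = np.asarray(ratios, dtype=float)
    w = np.asarray(weights, dtype=float)
    order = np.argsort(r, kind="mergesort")
    r, w = r[order], w[order]
    s = (np.cumsum(w) - 0.5 * w) / np.sum(w)
    return float(np.interp(0.5, s, r))


class WeightedMedianEstimator(RegressorMixin, BaseEstimator):
    """Weighted-median MR with a parametric-bootstrap standard error.

    Each of ``n_boot`` replicates redraws every γ̂_j ~ N(γ̂_j, σ_xj²) and
    Γ̂_j ~ N(Γ̂_j, σ_Γj²), recomputes ratios and first-order weights, and
    takes the weighted median; the bootstrap standard deviation is the
    reported standard error.  ``seed`` is mandatory.
    """

    def __init__(self, n_boot: int = 10000, seed: int | None = None, ci_dist: str = "normal"):
        self.n_boot = n_boot
        self.seed = seed
        self.ci_dist = ci_dist

    def fit(self, X, y, outcome_se=None, exposure_se=None):
        if self.n_boot <= 0:
            raise ValidationError("n_boot must be positive")
        if self.seed is None:
            raise ValidationError("weighted median requires an explicit seed for its bootstrap")
        x, yy = _check_xy(X, y)
        J = x.size
        if J < 3:
            raise ValidationError(f"weighted median needs at least 3 variants (got {J})")
        if np.any(x == 0):
            raise ValidationError("beta_exposure = 0: Wald ratio undefined")
        if outcome_se is None:
            raise ValidationError("outcome_se is required (first-order weights and bootstrap)")
        sy = np.asarray(outcome_se, dtype=float).reshape(-1)
        sx = np.zeros(J) if exposure_se is None else np.asarray(exposure_se, dtype=float).reshape(-1)

        ratios = yy / x
        weights = x**2 / sy**2
        est = weighted_median_point(ratios, weights)

        rng = np.random.default_rng(self.seed)
        gs = rng.normal(x, sx, size=(self.n_boot, J))
        Gs = rng.normal(yy, sy, size=(self.n_boot, J))
        r_b = Gs / gs
        w_b = gs**2 / sy**2
        order = np.argsort(r_b, axis=1, kind="mergesort")
        r_b = np.take_along_axis(r_b, order, axis=1)
        w_b = np.take_along_axis(w_b, order, axis=1)
        s_b = (np.cumsum(w_b, axis=1) - 0.5 * w_b) / np.sum(w_b, axis=1, keepdims=True)
        boots = np.array([np.interp(0.5, s_b[i], r_b[i]) for i in range(self.n_boot)])
        se = float(np.std(boots, ddof=1))

        q = _ci_quantile(self.ci_dist, df=J - 1)
        self.coef_ = np.array([est])
        self.estimate_ = est
        self.se_ = se
        self.ci_low_ = est - q * se
        self.ci_high_ = est + q * se
        self.p_value_ = float(2.0 * stats.norm.sf(abs(est / se))) if se > 0 else 0.0
        self.n_variants_ = J
        self.bootstrap_estimates_ = boots
        return self

    def predict(self, X):
        x = np.asarray(X, dtype=float).reshape(-1)
        return x * self.coef_[0]

    def result(self, scale: str = SCALE_PER_UNIT) -> MRResult:
        return MRResult(
            method="weighted-median",
            scale=scale,
            estimate=self.estimate_,
            se=self.se_,
            ci_low=self.ci_low_,
            ci_high=self.ci_high_,
            p_value=self.p_value_,
            n_variants=self.n_variants_,
        )


# ---------------------------------------------------------------------------
# pairs-table wrappers


def _arrays(pairs: pd.DataFrame):
    g = pairs["beta_exposure"].to_numpy(dtype=float)
    G = pairs["beta_outcome"].to_numpy(dtype=float)
    sG = pairs["se_outcome"].to_numpy(dtype=float)
    sx = (
        pairs["se_exposure"].to_numpy(dtype=float)
        if "se_exposure" in pairs.columns
        else np.zeros_like(g)
    )
    return g, G, sG, sx


def ivw(pairs: pd.DataFrame, model: str = "random", ci_dist: str = "normal") -> MRResult:
    """IVW causal estimate from a harmonized-pairs table."""
    g, G, sG, _ = _arrays(pairs)
    est = IVWEstimator(model=model, ci_dist=ci_dist).fit(g, G, sample_weight=1.0 / sG**2)
    return est.result()


def egger(pairs: pd.DataFrame, model: str = "random", ci_dist: str = "normal") -> MRResult:
    """MR-Egger slope and directional-pleiotropy intercept."""
    g, G, sG, _ = _arrays(pairs)
    est = EggerEstimator(model=model, ci_dist=ci_dist).fit(g, G, sample_weight=1.0 / sG**2)
    return est.result()


def weighted_median(
    pairs: pd.DataFrame, n_boot: int = 10000, seed: int | None = None, ci_dist: str = "normal"
) -> MRResult:
    """Weighted-median causal estimate with parametric-bootstrap se."""
    g, G, sG, sx = _arrays(pairs)
    est = WeightedMedianEstimator(n_boot=n_boot, seed=seed, ci_dist=ci_dist).fit(
        g, G, outcome_se=sG, exposure_se=sx
    )
    return est.result()


def rescale_per_doubling(result: MRResult, binary: bool = True) -> MRResult:
    """Re-express a per-unit-log-odds-of-exposure estimate per doubling of exposure odds.

    The log-scale estimate and CI are multiplied by 0.693; for binary outcomes
    the estimate and CI are then exponentiated to an odds-ratio scale (the se
    stays on the multiplied log scale), for continuous outcomes they are not.
    Applying the rescale twice raises.
    """
    if result.scale != SCALE_PER_UNIT:
        raise ValidationError(f"result already on scale {result.scale!r}; per-doubling rescale applies once")
    k = DOUBLING_FACTOR
    if binary:
        return replace(
            result,
            scale=SCALE_PER_DOUBLING,
            estimate=float(np.exp(k * result.estimate)),
            ci_low=float(np.exp(k * result.ci_low)),
            ci_high=float(np.exp(k * result.ci_high)),
            se=k * result.se,
            exponentiated=True,
        )
    return replace(
        result,
        scale=SCALE_PER_DOUBLING,
        estimate=k * result.estimate,
        ci_low=k * result.ci_low,
        ci_high=k * result.ci_high,
        se=k * result.se,
        exponentiated=False,
    )
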