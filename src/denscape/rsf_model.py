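"""Used-available logistic RSF models: candidate set, fitting, AICc ranking,
prediction and effect curves.

The resource selection function w(x) = exp(b1 x1 + ... + bn xn) is estimated
by logistic regression contrasting used dens (1) against available points
(0).  Because availability is a sample rather than true absence, only the
slope coefficients are interpretable: the intercept absorbs the arbitrary
used:available ratio and is never used for prediction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg
from scipy.special import expit

from .raster import Grid
from .terrain_covariates import CovariateStack

Z95 = 1.959963984540054  # normal 97.5% quantile


@dataclass
class ModelSpec:
    """One candidate model: an ordered list of linear/quadratic terms.

    Terms are covariate names, with ``_sq`` marking the square of the
    standardized covariate; a quadratic term is only valid alongside its
    linear term.
    """

    id: int
    terms: list[str]
    description: str = ""

    def __post_init__(self) -> None:
        for t in self.terms:
            if t.endswith("_sq") and t[:-3] not in self.terms:
                raise ValueError(f"quadratic term {t} lacks its linear term")

    @property
    def k(self) -> int:
        """Parameter count including the intercept."""
        return len(self.terms) + 1


def candidate_set() -> list[ModelSpec]:
    """The 18 a-priori candidate den-selection models.

    Six hypothesis families (terrain; terrain+vegetation; terrain
    complexity; dry-snow climate; thermal-insulation climate; combined
    terrain-climate) each contribute variants that differ by the inclusion
    of quadratic terms or of optional factors.  Where the published factor
    lists are ambiguous about which optional quadratics a variant carries,
    the reconstruction matches each model's published term count, taking
    quadratics in the family's listed factor order.
    """
    m = [
        ModelSpec(1, ["dtm", "dtm_sq", "slope", "slope_sq", "tpi"],
                  "Terrain"),
        ModelSpec(2, ["dtm", "dtm_sq", "slope", "slope_sq", "tpi", "tpi_sq"],
                  "Terrain, tpi quadratic"),
        ModelSpec(3, ["dtm", "dtm_sq", "slope", "slope_sq", "vhi", "tpi"],
                  "Terrain and vegetation"),
        ModelSpec(4, ["dtm", "dtm_sq", "slope", "slope_sq", "vhi", "vhi_sq",
                      "tpi", "tpi_sq"],
                  "Terrain and vegetation, full quadratics"),
        ModelSpec(5, ["vrm", "tpi"], "Terrain complexity"),
        ModelSpec(6, ["vrm", "vrm_sq", "tpi", "tpi_sq"],
                  "Terrain complexity, quadratics"),
        ModelSpec(7, ["snow.load", "twi"], "Climate: dry snow"),
        ModelSpec(8, ["snow.load", "snow.load_sq", "twi", "twi_sq"],
                  "Climate: dry snow, quadratics"),
        ModelSpec(9, ["snow.load", "solrad"], "Climate: thermal insulation"),
        ModelSpec(10, ["snow.load", "snow.load_sq", "solrad", "solrad_sq"],
                  "Climate: thermal insulation, quadratics"),
        ModelSpec(11, ["slope", "slope_sq", "snow.load", "snow.load_sq",
                       "solrad", "tpi", "vhi"],
                  "Slope, vegetation and thermal climate"),
        ModelSpec(12, ["slope", "slope_sq", "snow.load", "snow.load_sq",
                       "solrad", "solrad_sq", "tpi", "tpi_sq", "vhi",
                       "vhi_sq"],
                  "Slope, vegetation and thermal climate, full quadratics"),
        ModelSpec(13, ["dtm", "dtm_sq", "slope", "slope_sq", "snow.load",
                       "solrad", "twi", "vhi", "vrm"],
                  "Terrain, vegetation and thermal/dry snow"),
        ModelSpec(14, ["dtm", "dtm_sq", "slope", "slope_sq", "snow.load",
                       "twi", "vhi", "vrm"],
                  "Terrain, vegetation and dry snow"),
        ModelSpec(15, ["dtm", "dtm_sq", "slope", "slope_sq", "snow.load",
                       "snow.load_sq", "solrad", "tpi", "twi", "vhi"],
                  "Complex terrain-climate without ruggedness"),
        ModelSpec(16, ["dtm", "dtm_sq", "slope", "slope_sq", "snow.load",
                       "snow.load_sq", "solrad", "solrad_sq", "tpi",
                       "tpi_sq", "twi", "twi_sq", "vhi", "vhi_sq"],
                  "Complex terrain-climate, full quadratics, no ruggedness"),
        ModelSpec(17, ["dtm", "dtm_sq", "slope", "slope_sq", "snow.load",
                       "solrad", "tpi", "twi", "vhi", "vrm"],
                  "Complex terrain-climate"),
        ModelSpec(18, ["dtm", "dtm_sq", "slope", "slope_sq", "snow.load",
                       "snow.load_sq", "solrad", "solrad_sq", "tpi",
                       "tpi_sq", "twi", "twi_sq", "vhi", "vhi_sq", "vrm",
                       "vrm_sq"],
                  "Global: all factors and quadratics"),
    ]
    return m


@dataclass
class FittedRSF:
    """A fitted used-available logistic model with AICc bookkeeping."""

    spec: ModelSpec
    beta: pd.Series          # per-term coefficients, standardized scale
    se: pd.Series
    ci95: pd.DataFrame       # columns lo, hi
    intercept: float         # estimated but not interpretable
    loglik: float
    k: int                   # parameters including intercept
    n: int                   # used + available rows
    aicc: float
    delta: float | None = None
    weight: float | None = None

    @property
    def informative(self) -> pd.Series:
        """True where the 95% CI excludes zero."""
        return (self.ci95["lo"] > 0) | (self.ci95["hi"] < 0)


def design_matrix(design: pd.DataFrame, terms: list[str]) -> np.ndarray:
    cols = [np.ones(len(design))]
    for t in terms:
        if t.endswith("_sq"):
            cols.append(design[t[:-3]].to_numpy(dtype=float) ** 2)
        else:
            cols.append(design[t].to_numpy(dtype=float))
    return np.column_stack(cols)


def _check_rank(X: np.ndarray, terms: list[str]) -> None:
    _, r, piv = linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps
    rank = int((diag > tol).sum())
    if rank < X.shape[1]:
        names = ["(intercept)"] + terms
        aliased = [names[j] for j in piv[rank:]]
        raise ValueError(f"singular design matrix; aliased terms: {aliased}")


def fit(design: pd.DataFrame, spec: ModelSpec, weights=None,
        max_iter: int = 500, tol: float = 1e-8) -> FittedRSF:
    """Maximum-likelihood logistic fit of one candidate model by IRLS.

    Used rows are coded 1, available rows 0; standard errors are Wald
    (inverse observed information) and the 95% CI is beta +/- 1.96 SE.
    Optional case ``weights`` replicate rows fractionally (a row with
    weight 2 is equivalent to two identical rows).  Raises on perfect
    separation (diverging coefficients) and on singular design matrices,
    naming the aliased terms.
    """
    y = (design["label"] == "used").to_numpy(dtype=float)
    if y.sum() < 1 or (1 - y).sum() < 1:
        raise ValueError("need at least one used and one available row")
    X = design_matrix(design, spec.terms)
    if not np.isfinite(X).all():
        raise ValueError("missing covariate values in design table")
    _check_rank(X, spec.terms)
    cw = np.ones(len(y)) if weights is None else np.asarray(weights, dtype=float)

    def _ll(b):
        pr = expit(X @ b)
        return float(np.sum(cw * (y * np.log(np.clip(pr, 1e-300, None))
                                  + (1 - y) * np.log(np.clip(1 - pr, 1e-300,
                                                             None)))))

    beta = np.zeros(X.shape[1])
    ll = _ll(beta)
    for _ in range(max_iter):
        eta = X @ beta
        p = expit(eta)
        w = cw * np.clip(p * (1 - p), 1e-12, None)
        # Newton/IRLS step: (X'WX) d = X'W0 (y - p), with step halving so
        # ill-conditioned quadratic terms cannot make the step overshoot
        XtW = X.T * w
        try:
            delta = np.linalg.solve(XtW @ X, X.T @ (cw * (y - p)))
        except np.linalg.LinAlgError as err:
            raise ValueError(f"IRLS failed: {err}") from err
        step = 1.0
        for _half in range(30):
            cand = beta + step * delta
            ll_new = _ll(cand)
            if ll_new >= ll - 1e-12:
                break
            step /= 2.0
        beta = beta + step * delta
        if np.max(np.abs(beta)) > 1e5:
            raise ValueError("perfect separation: coefficients diverging")
        # converge on a small step, or on a deviance plateau (the glm
        # convention, which also terminates monotone-likelihood directions)
        converged = (np.max(np.abs(step * delta)) < tol
                     or abs(ll_new - ll) < 1e-10 * (abs(ll_new) + 1.0))
        ll = ll_new
        if converged:
            break
    else:
        raise ValueError("IRLS did not converge in "
                         f"{max_iter} iterations (separation?)")
    if ll > -1e-6 * len(y):
        raise ValueError("perfect separation: model fits the labels exactly")
    eta = X @ beta
    p = expit(eta)
    loglik = float(np.sum(cw * (y * np.log(np.clip(p, 1e-300, None))
                                + (1 - y) * np.log(np.clip(1 - p, 1e-300, None)))))
    w = cw * np.clip(p * (1 - p), 1e-12, None)
    cov = np.linalg.inv((X.T * w) @ X)
    se = np.sqrt(np.diag(cov))
    names = spec.terms
    b = pd.Series(beta[1:], index=names, name="beta")
    s = pd.Series(se[1:], index=names, name="se")
    ci = pd.DataFrame({"lo": b - Z95 * s, "hi": b + Z95 * s})
    n = len(design)
    return FittedRSF(spec=spec, beta=b, se=s, ci95=ci,
                     intercept=float(beta[0]), loglik=loglik,
                     k=spec.k, n=n, aicc=aicc(loglik, spec.k, n))


def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample corrected Akaike information criterion.

    AICc = -2 loglik + 2k + 2k(k+1)/(n - k - 1); requires n > k + 1.
    """
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n} <= k+1={k + 1}")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def rank_models(fits: list[FittedRSF]) -> pd.DataFrame:
    """Rank fitted models by AICc with deltas and Akaike weights.

    Delta_i = AICc_i - min AICc; weight_i = exp(-Delta_i/2) normalized over
    the set.  All fits must be on the same data (same n).  Ties on AICc
    break toward fewer parameters, then lower model id.
    """
    if len(fits) < 2:
        raise ValueError("need at least two fits to rank")
    ns = {f.n for f in fits}
    if len(ns) != 1:
        raise ValueError("fits were made on differing data (n mismatch)")
    aiccs = np.array([f.aicc for f in fits])
    deltas = aiccs - aiccs.min()
    w = np.exp(-deltas / 2.0)
    w = w / w.sum()
    for f, d, wi in zip(fits, deltas, w):
        f.delta = float(d)
        f.weight = float(wi)
    table = pd.DataFrame({
        "model": [f.spec.id for f in fits],
        "description": [f.spec.description for f in fits],
        "K": [f.k - 1 for f in fits],   # published convention: terms only
        "aicc": aiccs,
        "delta": deltas,
        "weight": w,
    })
    return (table.sort_values(["aicc", "K", "model"])
                 .reset_index(drop=True))


def predict_surface(stack: CovariateStack, fit: FittedRSF) -> Grid:
    """Relative selection surface w = exp(sum beta x), intercept omitted.

    Requires the stack to be standardized with the same parameters used for
    the fit's design table; nodata cells propagate.
    """
    if not stack.standardized:
        raise ValueError("predict_surface requires a standardized stack")
    template = stack.template
    eta = np.zeros(template.shape)
    for term, b in fit.beta.items():
        eta = eta + b * stack.term_values(term)
    return template.like(np.exp(eta))


def effect_curve(fit: FittedRSF, covariate: str,
                 x: np.ndarray | None = None) -> pd.DataFrame:
    """Single-factor response curve with other covariates at their mean.

    On the standardized scale the mean of every other covariate is zero, so
    w(x) = exp(b1 x + b2 x^2) using only the covariate's own terms.  Returns
    columns x and w.
    """
    if covariate not in fit.beta.index:
        raise KeyError(f"{covariate!r} not in fitted model")
    if x is None:
        x = np.linspace(-3, 3, 121)
    x = np.asarray(x, dtype=float)
    b1 = float(fit.beta[covariate])
    b2 = float(fit.beta.get(covariate + "_sq", 0.0))
    w = np.exp(b1 * x + b2 * x ** 2)
    return pd.DataFrame({"x": x, "w": w})


def quadratic_optimum(beta_linear: float, beta_quadratic: float) -> float:
    """Stationary point of exp(b1 x + b2 x^2): x* = -b1 / (2 b2).

    A maximum when the quadratic coefficient is negative; in standardized
    units (SD above the availability mean).
    """
    if beta_quadratic == 0:
        raise ValueError("no quadratic term: curve is monotone")
    return -beta_linear / (2.0 * beta_quadratic)
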