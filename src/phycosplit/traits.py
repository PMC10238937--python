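"""Phenotype-level models: growth-curve interaction metrics and trait regression.

Covers the isolate-level side of the analysis: the area-under-the-curve (AUC)
ratio quantifying how a bacterial isolate changes algal growth in co-culture,
carrying-capacity comparisons against a plating detection limit,
spline-based growth features and carbon-utilization binarization, the
positive-slope screen for exudate compounds, and the LASSO regression that
predicts a taxon's enrichment rate from its binary carbon-utilization
profile, validated against response-shuffled null fits.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import interpolate, stats
from sklearn.linear_model import Lasso
from sklearn.model_selection import RepeatedKFold

__all__ = [
    "GrowthCurve",
    "UtilizationMatrix",
    "LassoFit",
    "auc",
    "auc_ratio",
    "growth_features",
    "capacity_compare",
    "positive_slope_screen",
    "lasso_lambda_max",
    "lasso_trait_regression",
    "OD_UTILIZATION_FLOOR",
    "PLATING_DETECTION_LIMIT",
]

#: maximum OD600 at or above which an isolate is scored as utilizing a carbon source.
OD_UTILIZATION_FLOOR = 0.05

#: lowest cell density resolvable by dilution plating (cells/mL).
PLATING_DETECTION_LIMIT = 1e6


@dataclass
class GrowthCurve:
    """A background-subtracted density time series for one culture.

    ``times`` are hours and must be strictly increasing; ``values`` are
    nonnegative densities (cells/mL or OD600).  ``label`` records the
    condition (e.g. ``"mono"`` or ``"co"``) and carbon source if relevant.
    """

    times: np.ndarray
    values: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.values.shape:
            raise ValueError("times and values must be 1-D arrays of equal length")
        if self.times.size < 2:
            raise ValueError("a growth curve needs at least two points")
        if not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.values < 0):
            raise ValueError("values must be nonnegative after background subtraction")


@dataclass
class UtilizationMatrix:
    """Binary isolates x carbon-sources utilization calls.

    ``g`` holds 0/1 entries; ``od_max``, when present, holds the maximum
    OD600 each call was derived from (1 iff od_max >= 0.05).
    """

    g: pd.DataFrame
    od_max: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        vals = self.g.to_numpy()
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("utilization entries must be 0 or 1")
        if self.od_max is not None:
            expected = (self.od_max.to_numpy() >= OD_UTILIZATION_FLOOR).astype(int)
            if not np.array_equal(vals, expected):
                raise ValueError("g inconsistent with od_max at the 0.05 OD floor")

    @classmethod
    def from_od(cls, od_max: pd.DataFrame) -> "UtilizationMatrix":
        g = (od_max >= OD_UTILIZATION_FLOOR).astype(int)
        return cls(g=g, od_max=od_max)

    @property
    def isolates(self) -> pd.Index:
        return self.g.index

    @property
    def carbon_sources(self) -> pd.Index:
        return self.g.columns


# ---------------------------------------------------------------------------
# growth-curve metrics
# ---------------------------------------------------------------------------

def auc(curve: GrowthCurve) -> float:
    """Trapezoidal area under the density-vs-time curve over the observed window."""
    return float(np.trapezoid(curve.values, curve.times))


def auc_ratio(
    mono_reps: list[GrowthCurve], co_reps: list[GrowthCurve]
) -> tuple[float, float]:
    """AUC(co-culture)/AUC(monoculture) with first-order error propagation.

    The ratio is taken between the replicate means; its standard deviation is
    propagated as ``ratio * sqrt((sd_co/mean_co)^2 + (sd_mono/mean_mono)^2)``.
    A ratio above 1 indicates facilitation of algal growth by the bacterium,
    below 1 inhibition.
    """
    if len(mono_reps) < 2 or len(co_reps) < 2:
        raise ValueError("need at least two replicates per condition")
    a_mono = np.array([auc(c) for c in mono_reps])
    a_co = np.array([auc(c) for c in co_reps])
    if a_mono.mean() == 0:
        raise ValueError("mean monoculture AUC is zero")
    ratio = a_co.mean() / a_mono.mean()
    rel = np.sqrt(
        (a_co.std(ddof=1) / a_co.mean()) ** 2
        + (a_mono.std(ddof=1) / a_mono.mean()) ** 2
    )
    return float(ratio), float(abs(ratio) * rel)


def growth_features(
    curve: GrowthCurve,
    od_floor: float = OD_UTILIZATION_FLOOR,
    offset: float = 1e-3,
    n_grid: int = 400,
) -> dict:
    """Spline-derived growth features from a single curve.

    The curve is shifted by a small positive ``offset`` and fit with a
    smoothing spline on the natural-log scale (smoothing chosen by
    generalized cross-validation).  ``max_od`` is the maximum of the fitted
    curve, ``max_growth_rate`` (per hour) the maximum of the first derivative
    of the log-scale fit, and ``grows`` flags whether ``max_od`` reaches
    ``od_floor``.
    """
    if curve.times.size < 4:
        raise ValueError("need at least four points to fit a cubic smoothing spline")
    log_vals = np.log(curve.values + offset)
    spline = interpolate.make_smoothing_spline(curve.times, log_vals)
    grid = np.linspace(curve.times[0], curve.times[-1], n_grid)
    fit_log = spline(grid)
    max_od = float(np.exp(fit_log.max()) - offset)
    rate = float(spline.derivative()(grid).max())
    return {
        "max_od": max_od,
        "max_growth_rate": rate,
        "grows": bool(max_od >= od_floor),
    }


def capacity_compare(
    with_algae: np.ndarray,
    without: np.ndarray,
    detection_limit: float = PLATING_DETECTION_LIMIT,
    alpha: float = 0.05,
) -> dict:
    """Compare endpoint CFU densities of an isolate grown with vs without algae.

    Densities below the plating detection limit are substituted at the limit
    and flagged (no imputation).  Replicate sets are compared with a
    two-sample Kolmogorov-Smirnov test; the effect direction comes from the
    censored means.  If every replicate in both conditions is censored the
    comparison is inconclusive.
    """
    from .divergence import ks_compare

    w = np.asarray(with_algae, dtype=float)
    wo = np.asarray(without, dtype=float)
    if w.size < 2 or wo.size < 2:
        raise ValueError("need at least two replicates per condition")
    n_cens_w = int((w < detection_limit).sum())
    n_cens_wo = int((wo < detection_limit).sum())
    w_c = np.maximum(w, detection_limit)
    wo_c = np.maximum(wo, detection_limit)
    if n_cens_w == w.size and n_cens_wo == wo.size:
        return {
            "inconclusive": True,
            "direction": "none",
            "statistic": np.nan,
            "p_value": np.nan,
            "n_censored": (n_cens_w, n_cens_wo),
        }
    statistic, p = ks_compare(w_c, wo_c)
    if w_c.mean() > wo_c.mean():
        direction = "higher_with_algae"
    elif w_c.mean() < wo_c.mean():
        direction = "lower_with_algae"
    else:
        direction = "none"
    return {
        "inconclusive": False,
        "direction": direction,
        "statistic": statistic,
        "p_value": p,
        "significant": bool(p < alpha),
        "n_censored": (n_cens_w, n_cens_wo),
    }


def positive_slope_screen(
    compound_table: pd.DataFrame,
    baseline: pd.Series,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Screen a compounds x timepoints abundance table for secreted compounds.

    Columns of ``compound_table`` are numeric time points; ``baseline`` gives
    the per-compound level in fresh media, subtracted before regression.  For
    each compound an ordinary least-squares line is fit against time; the
    compound is called secreted when the slope is positive and its p-value is
    below ``alpha``.  Returns a DataFrame with slope, p_value and secreted.
    """
    times = np.asarray(compound_table.columns, dtype=float)
    if times.size < 3:
        raise ValueError("need at least three timepoints for the slope screen")
    corrected = compound_table.sub(baseline, axis=0)
    rows = {}
    for compound, series in corrected.iterrows():
        res = stats.linregress(times, series.to_numpy(dtype=float))
        rows[compound] = {
            "slope": res.slope,
            "p_value": res.pvalue,
            "secreted": bool(res.slope > 0 and res.pvalue < alpha),
        }
    return pd.DataFrame.from_dict(rows, orient="index")


# ---------------------------------------------------------------------------
# LASSO trait regression
# ---------------------------------------------------------------------------

@dataclass
class LassoFit:
    """Result of the enrichment-on-utilization LASSO with shuffled-null validation."""

    lambda_grid: np.ndarray
    cv_mse: np.ndarray
    lambda_hat: float
    beta0: float
    beta: pd.Series
    r2_real: np.ndarray
    r2_real_pooled: np.ndarray
    r2_shuffled: np.ndarray
    boot_p: float
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {
            "lambda_grid": self.lambda_grid.tolist(),
            "cv_mse": self.cv_mse.tolist(),
            "lambda_hat": self.lambda_hat,
            "beta0": self.beta0,
            "beta": self.beta.to_dict(),
            "r2_real_median": float(np.median(self.r2_real)) if self.r2_real.size else None,
            "r2_shuffled_median": float(np.median(self.r2_shuffled)) if self.r2_shuffled.size else None,
            "boot_p": self.boot_p,
            "degenerate": self.degenerate,
        }


def _as_design(g: UtilizationMatrix | pd.DataFrame) -> pd.DataFrame:
    return g.g if isinstance(g, UtilizationMatrix) else g


def lasso_lambda_max(g: UtilizationMatrix | pd.DataFrame, r: pd.Series | np.ndarray) -> float:
    """Smallest penalty at which the LASSO solution is exactly zero.

    For the cost ``(1/N) ||r - b0 - G b||^2 + lam ||b||_1`` the all-zero
    solution is optimal iff ``lam >= (2/N) max_j |G_c[:,j]^T (r - mean r)|``
    with column-centered predictors (the intercept absorbs the means).
    """
    X = _as_design(g).to_numpy(dtype=float)
    y = np.asarray(r, dtype=float)
    n = y.size
    Xc = X - X.mean(axis=0, keepdims=True)
    return float(2.0 * np.abs(Xc.T @ (y - y.mean())).max() / n)


def _fit_lasso(X: np.ndarray, y: np.ndarray, lam: float) -> Lasso:
    # our cost (1/N)||.||^2 + lam||b||_1 equals sklearn's with alpha = lam/2
    model = Lasso(alpha=lam / 2.0, fit_intercept=True, max_iter=50_000, tol=1e-8)
    model.fit(X, y)
    return model


def _cv_select_lambda(
    X: np.ndarray,
    y: np.ndarray,
    lambda_grid: np.ndarray,
    k_folds: int,
    n_repeats: int,
    rng: np.random.Generator,
) -> tuple[float, np.ndarray, list[tuple[np.ndarray, np.ndarray]]]:
    """Repeated k-fold grid search; returns (lambda_hat, mean MSE per lambda, splits)."""
    cv = RepeatedKFold(
        n_splits=k_folds,
        n_repeats=n_repeats,
        random_state=int(rng.integers(2**31)),
    )
    splits = [(tr, te) for tr, te in cv.split(X)]
    mse = np.zeros((len(splits), lambda_grid.size))
    for i, (tr, te) in enumerate(splits):
        for j, lam in enumerate(lambda_grid):
            model = _fit_lasso(X[tr], y[tr], lam)
            mse[i, j] = np.mean((y[te] - model.predict(X[te])) ** 2)
    mean_mse = mse.mean(axis=0)
    lam_hat = float(lambda_grid[int(np.argmin(mean_mse))])
    return lam_hat, mean_mse, splits


def _heldout_r2(
    X: np.ndarray,
    y: np.ndarray,
    lam: float,
    splits: list[tuple[np.ndarray, np.ndarray]],
    k_folds: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Held-out R^2 per split, and pooled over the folds of each repeat.

    R^2 = 1 - SS_res/SS_tot with SS_tot taken about the training-fold mean,
    so a constant (intercept-only) predictor scores ~0 on average.
    """
    per_split = np.empty(len(splits))
    pooled_res: list[float] = []
    pooled_tot: list[float] = []
    for i, (tr, te) in enumerate(splits):
        model = _fit_lasso(X[tr], y[tr], lam)
        pred = model.predict(X[te])
        ss_res = float(np.sum((y[te] - pred) ** 2))
        ss_tot = float(np.sum((y[te] - y[tr].mean()) ** 2))
        per_split[i] = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
        pooled_res.append(ss_res)
        pooled_tot.append(ss_tot)
    n_rep = len(splits) // k_folds
    pooled = np.empty(n_rep)
    for rep in range(n_rep):
        sl = slice(rep * k_folds, (rep + 1) * k_folds)
        tot = sum(pooled_tot[sl])
        pooled[rep] = 1.0 - sum(pooled_res[sl]) / tot if tot > 0 else np.nan
    return per_split, pooled


def lasso_trait_regression(
    g: UtilizationMatrix | pd.DataFrame,
    r: pd.Series | np.ndarray,
    lambda_grid: np.ndarray | None = None,
    k_folds: int = 4,
    n_repeats: int = 100,
    n_shuffles: int = 10,
    shuffle_repeats: int = 10,
    n_boot: int = 10_000,
    seed: int | None = None,
) -> LassoFit:
    """Predict enrichment rates from binary carbon-utilization profiles.

    Fits ``r_s = b0 + sum_j b_j g_js + eps`` under the penalized cost
    ``(1/N)||r - rhat||^2 + lam ||b||_1``.  The penalty is selected by
    repeated k-fold cross-validation (``k_folds`` splits, ``n_repeats``
    reshuffles) as the grid point minimizing mean held-out squared error.
    Held-out R^2 values at the selected penalty form ``r2_real``; the entire
    procedure (including penalty selection) is re-run on ``n_shuffles``
    response-permuted copies to form ``r2_shuffled``.  ``boot_p`` is the
    bootstrap probability that the shuffled-median R^2 is at least the real
    median (small values mean genuine predictive power).

    Binary predictors are used unstandardized: all columns share the {0,1}
    scale and standardizing would distort the sparsity interpretation.
    """
    X = _as_design(g).to_numpy(dtype=float)
    sources = _as_design(g).columns
    y = np.asarray(r, dtype=float)
    if X.shape[0] != y.size:
        raise ValueError("rows of g must align with the enrichment vector")
    if y.size < 8:
        raise ValueError("need at least eight isolates")
    rng = np.random.default_rng(seed)

    if np.std(y) == 0:
        beta = pd.Series(np.zeros(X.shape[1]), index=sources)
        return LassoFit(
            lambda_grid=np.array([]), cv_mse=np.array([]), lambda_hat=np.nan,
            beta0=float(y.mean()), beta=beta,
            r2_real=np.array([]), r2_real_pooled=np.array([]),
            r2_shuffled=np.array([]), boot_p=np.nan, degenerate=True,
        )

    if lambda_grid is None:
        lam_max = lasso_lambda_max(_as_design(g), y)
        lambda_grid = np.geomspace(lam_max, lam_max * 1e-3, 30)
    lambda_grid = np.sort(np.asarray(lambda_grid, dtype=float))[::-1]

    lam_hat, cv_mse, splits = _cv_select_lambda(X, y, lambda_grid, k_folds, n_repeats, rng)
    r2_real, r2_real_pooled = _heldout_r2(X, y, lam_hat, splits, k_folds)

    r2_shuffled_parts = []
    for _ in range(n_shuffles):
        y_sh = rng.permutation(y)
        lam_sh, _, splits_sh = _cv_select_lambda(
            X, y_sh, lambda_grid, k_folds, shuffle_repeats, rng
        )
        r2_sh, _ = _heldout_r2(X, y_sh, lam_sh, splits_sh, k_folds)
        r2_shuffled_parts.append(r2_sh)
    r2_shuffled = np.concatenate(r2_shuffled_parts)

    real = r2_real[~np.isnan(r2_real)]
    shuf = r2_shuffled[~np.isnan(r2_shuffled)]
    d = np.empty(n_boot)
    for b in range(n_boot):
        d[b] = np.median(rng.choice(real, real.size)) - np.median(
            rng.choice(shuf, shuf.size)
        )
    boot_p = float(np.mean(d <= 0))

    final = _fit_lasso(X, y, lam_hat)
    beta = pd.Series(final.coef_, index=sources)
    return LassoFit(
        lambda_grid=lambda_grid,
        cv_mse=cv_mse,
        lambda_hat=lam_hat,
        beta0=float(final.intercept_),
        beta=beta,
        r2_real=r2_real,
        r2_real_pooled=r2_real_pooled,
        r2_shuffled=r2_shuffled,
        boot_p=boot_p,
    )
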