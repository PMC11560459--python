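"""Resampling harness, prediction metrics, and component selection.

The model-development protocol for one trait is:

1. repeat ``n_iterations`` times (default 1,000): split the samples at
   random into a calibration set (default 80%) and a validation holdout
   (remaining 20%);
2. inside the calibration set, run k-fold cross-validation (default
   fivefold): out-of-fold predictions for every component count
   ``A = 1..max_components`` give the *calibration* PRESS/RMSE/R2/RPD;
3. a model fit on the full calibration set and evaluated on the 20%
   holdout gives the *validation* metrics per A;
4. metrics are averaged over iterations into a :class:`ComponentCurve`,
   and per-sample validation squared residuals are retained per A for the
   randomization test.

Three rules then pick the component count from the mean validation PRESS
curve:

* **press_min** - the global minimum (ties toward fewer components);
* **press_adj** - backward penalty: starting from the press_min choice,
  components are removed one at a time while the PRESS increase of each
  removal stays within a threshold of 1.5% (default) of the maximum mean
  validation PRESS;
* **voet** - Van der Voet's randomization test: each smaller model is
  compared with the press_min reference through the mean difference of
  per-sample squared prediction errors, with a sign-flip permutation null;
  the smallest model not significantly worse (two-sided p >= alpha,
  default 0.01) is chosen.

Metric conventions: PRESS is the sum of squared out-of-sample residuals,
RMSE% expresses RMSE relative to the full-dataset trait mean, and RPD is
the observed-trait SD of the evaluated subset divided by RMSE, with
reliability classes: excellent (> 2.0), fair (1.40-2.00), non-reliable
(< 1.40).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError, DomainError, StateError
from .simpls import fit_simpls, predict_components

__all__ = [
    "CVConfig",
    "ComponentCurve",
    "SelectionResult",
    "run_cv",
    "press",
    "rmse",
    "rmse_percent",
    "r2",
    "rpd",
    "classify_rpd",
    "select_press_min",
    "select_backward_penalty",
    "select_voet",
    "sign_flip_pvalue",
    "report_table",
]


@dataclass
class CVConfig:
    """Settings of the repeated-split cross-validation harness."""

    n_iterations: int = 1000
    calibration_fraction: float = 0.8
    k_folds: int = 5
    max_components: int = 30
    seed: int = 0
    n_permutations: int = 1999
    voet_alpha: float = 0.01
    penalty_percent: float = 1.5

    def __post_init__(self) -> None:
        if not 0.0 < self.calibration_fraction < 1.0:
            raise ConfigError("calibration_fraction must be in (0, 1)")
        if self.k_folds < 2:
            raise ConfigError("k_folds must be >= 2")
        if self.max_components < 1:
            raise ConfigError("max_components must be >= 1")
        if self.n_iterations < 1:
            raise ConfigError("n_iterations must be >= 1")
        if self.n_permutations < 1:
            raise ConfigError("n_permutations must be >= 1")
        if not 0.0 < self.voet_alpha < 1.0:
            raise ConfigError("voet_alpha must be in (0, 1)")
        if self.penalty_percent <= 0.0:
            raise ConfigError("penalty_percent must be positive")


# ---------------------------------------------------------------- metrics


def press(residuals) -> float:
    """Predicted residual error sum of squares: sum of squared residuals."""
    residuals = np.asarray(residuals, dtype=float)
    return float(np.sum(residuals**2))


def rmse(press_value: float, n: int) -> float:
    """Root mean squared error from a PRESS value over ``n`` predictions."""
    if n < 1:
        raise DomainError("n must be >= 1")
    if press_value < 0:
        raise DomainError("PRESS must be non-negative")
    return float(np.sqrt(press_value / n))


def rmse_percent(press_value: float, n: int, trait_mean: float) -> float:
    """RMSE as a percentage of the full-dataset trait mean."""
    if trait_mean == 0:
        raise DomainError("trait mean is zero; RMSE% undefined")
    return rmse(press_value, n) / abs(trait_mean) * 100.0


def r2(obs, pred) -> float:
    """Coefficient of determination ``1 - SS_res / SS_tot``."""
    obs = np.asarray(obs, dtype=float)
    pred = np.asarray(pred, dtype=float)
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0.0:
        raise DomainError("observations have zero variance; R2 undefined")
    return 1.0 - float(np.sum((obs - pred) ** 2)) / ss_tot


def rpd(sd: float, rmse_value: float) -> float:
    """Ratio of performance to deviation: observed SD over RMSE."""
    if rmse_value <= 0:
        raise DomainError("RMSE must be positive for RPD")
    if sd <= 0:
        raise DomainError("observed SD must be positive for RPD")
    return float(sd / rmse_value)


def classify_rpd(rpd_value: float) -> str:
    """Reliability class of an RPD value.

    ``excellent`` above 2.0, ``fair`` within [1.40, 2.00], ``non-reliable``
    below 1.40.
    """
    if rpd_value <= 0:
        raise DomainError("RPD must be positive")
    if rpd_value > 2.0:
        return "excellent"
    if rpd_value >= 1.40:
        return "fair"
    return "non-reliable"


# ---------------------------------------------------------------- CV harness


@dataclass
class ComponentCurve:
    """Mean calibration/validation metrics per component count.

    All arrays have one entry per component count in ``components``.
    ``val_sq_residuals`` (n_components x total validation predictions,
    concatenated over iterations) feeds the randomization test.
    """

    components: np.ndarray
    cal_press: np.ndarray
    val_press: np.ndarray
    cal_rmse: np.ndarray
    val_rmse: np.ndarray
    cal_r2: np.ndarray
    val_r2: np.ndarray
    cal_rpd: np.ndarray
    val_rpd: np.ndarray
    y_mean: float
    n_cal: int
    n_val: int
    n_iterations: int
    val_sq_residuals: np.ndarray | None = None

    def normalized_press(self, which: str = "val") -> np.ndarray:
        """PRESS divided by the maximum PRESS within the same set, so the
        worst component count scores exactly 1."""
        arr = {"cal": self.cal_press, "val": self.val_press}[which]
        return arr / arr.max()

    def rmse_percent(self, which: str = "val") -> np.ndarray:
        arr = {"cal": self.cal_rmse, "val": self.val_rmse}[which]
        if self.y_mean == 0:
            raise DomainError("trait mean is zero; RMSE% undefined")
        return arr / abs(self.y_mean) * 100.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "n_components": self.components,
                "cal_press": self.cal_press,
                "val_press": self.val_press,
                "cal_press_norm": self.normalized_press("cal"),
                "val_press_norm": self.normalized_press("val"),
                "cal_rmse": self.cal_rmse,
                "val_rmse": self.val_rmse,
                "cal_rmse_percent": self.rmse_percent("cal"),
                "val_rmse_percent": self.rmse_percent("val"),
                "cal_r2": self.cal_r2,
                "val_r2": self.val_r2,
                "cal_rpd": self.cal_rpd,
                "val_rpd": self.val_rpd,
            }
        )


def _fold_slices(n: int, k: int) -> list[np.ndarray]:
    return np.array_split(np.arange(n), k)


def run_cv(X, y, config: CVConfig) -> ComponentCurve:
    """Run the repeated-split protocol for one trait.

    Fully reproducible: the master seed spawns one independent substream
    per iteration, so the iteration-mean curve does not depend on the order
    iterations are executed in.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if y.size != n:
        raise DataError(f"X has {n} rows but y has {y.size} values")
    n_cal = int(round(config.calibration_fraction * n))
    n_val = n - n_cal
    if n_val < 2:
        raise ConfigError("validation holdout needs at least 2 samples")
    if n_cal < config.k_folds:
        raise ConfigError(
            f"calibration set of {n_cal} cannot host {config.k_folds} folds"
        )
    min_fold_train = n_cal - int(np.ceil(n_cal / config.k_folds))
    a_cap = min(config.max_components, min_fold_train - 1, p)
    if a_cap < config.max_components:
        warnings.warn(
            f"max_components lowered from {config.max_components} to {a_cap} "
            "to respect the rank bound",
            stacklevel=2,
        )
    if a_cap < 1:
        raise ConfigError("no admissible component count under the rank bound")
    A = a_cap
    y_mean_full = float(y.mean())

    children = np.random.SeedSequence(config.seed).spawn(config.n_iterations)
    shape = (config.n_iterations, A)
    cal_press_it = np.empty(shape)
    val_press_it = np.empty(shape)
    cal_r2_it = np.empty(shape)
    val_r2_it = np.empty(shape)
    cal_rpd_it = np.empty(shape)
    val_rpd_it = np.empty(shape)
    val_sq_res = np.empty((A, config.n_iterations * n_val))

    for it, child in enumerate(children):
        rng = np.random.default_rng(child)
        perm = rng.permutation(n)
        cal_idx, val_idx = perm[:n_cal], perm[n_cal:]
        X_cal, y_cal = X[cal_idx], y[cal_idx]
        X_val, y_val = X[val_idx], y[val_idx]

        # inner k-fold CV on the calibration set -> out-of-fold predictions
        fold_perm = rng.permutation(n_cal)
        oof = np.empty((n_cal, A))
        for fold in _fold_slices(n_cal, config.k_folds):
            test = fold_perm[fold]
            train = np.setdiff1d(fold_perm, test, assume_unique=True)
            model = fit_simpls(X_cal[train], y_cal[train], A)
            preds = predict_components(model, X_cal[test])
            oof[test] = _pad_components(preds, A)

        model = fit_simpls(X_cal, y_cal, A)
        val_pred = _pad_components(predict_components(model, X_val), A)

        cal_res = y_cal[:, None] - oof
        val_res = y_val[:, None] - val_pred
        cal_press_a = (cal_res**2).sum(axis=0)
        val_press_a = (val_res**2).sum(axis=0)
        cal_press_it[it] = cal_press_a
        val_press_it[it] = val_press_a
        sst_cal = float(((y_cal - y_cal.mean()) ** 2).sum())
        sst_val = float(((y_val - y_val.mean()) ** 2).sum())
        cal_r2_it[it] = 1.0 - cal_press_a / sst_cal
        val_r2_it[it] = 1.0 - val_press_a / sst_val
        cal_rpd_it[it] = np.std(y_cal, ddof=1) / np.sqrt(cal_press_a / n_cal)
        val_rpd_it[it] = np.std(y_val, ddof=1) / np.sqrt(val_press_a / n_val)
        val_sq_res[:, it * n_val : (it + 1) * n_val] = (val_res**2).T

    return ComponentCurve(
        components=np.arange(1, A + 1),
        cal_press=cal_press_it.mean(axis=0),
        val_press=val_press_it.mean(axis=0),
        cal_rmse=np.sqrt(cal_press_it / n_cal).mean(axis=0),
        val_rmse=np.sqrt(val_press_it / n_val).mean(axis=0),
        cal_r2=cal_r2_it.mean(axis=0),
        val_r2=val_r2_it.mean(axis=0),
        cal_rpd=cal_rpd_it.mean(axis=0),
        val_rpd=val_rpd_it.mean(axis=0),
        y_mean=y_mean_full,
        n_cal=n_cal,
        n_val=n_val,
        n_iterations=config.n_iterations,
        val_sq_residuals=val_sq_res,
    )


def _pad_components(preds: np.ndarray, A: int) -> np.ndarray:
    """Pad a prediction matrix to A columns when a fit stopped early; the
    extra components add nothing, so the last achieved column is repeated."""
    if preds.shape[1] == A:
        return preds
    pad = np.repeat(preds[:, -1:], A - preds.shape[1], axis=1)
    return np.hstack([preds, pad])


# ---------------------------------------------------------------- selection


@dataclass
class SelectionResult:
    """Chosen component count and its metric block for one rule."""

    method: str
    n_components: int
    cal_r2: float
    val_r2: float
    cal_rpd: float
    val_rpd: float
    cal_press_norm: float
    val_press_norm: float
    cal_rmse_percent: float
    val_rmse_percent: float
    rpd_class: str = field(init=False)

    def __post_init__(self) -> None:
        self.rpd_class = classify_rpd(self.val_rpd)

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "n_components": self.n_components,
            "cal_r2": self.cal_r2,
            "val_r2": self.val_r2,
            "cal_rpd": self.cal_rpd,
            "val_rpd": self.val_rpd,
            "cal_press_norm": self.cal_press_norm,
            "val_press_norm": self.val_press_norm,
            "cal_rmse_percent": self.cal_rmse_percent,
            "val_rmse_percent": self.val_rmse_percent,
            "rpd_class": self.rpd_class,
        }


def _result(curve: ComponentCurve, method: str, chosen_a: int) -> SelectionResult:
    i = int(chosen_a - 1)
    return SelectionResult(
        method=method,
        n_components=int(chosen_a),
        cal_r2=float(curve.cal_r2[i]),
        val_r2=float(curve.val_r2[i]),
        cal_rpd=float(curve.cal_rpd[i]),
        val_rpd=float(curve.val_rpd[i]),
        cal_press_norm=float(curve.normalized_press("cal")[i]),
        val_press_norm=float(curve.normalized_press("val")[i]),
        cal_rmse_percent=float(curve.rmse_percent("cal")[i]),
        val_rmse_percent=float(curve.rmse_percent("val")[i]),
    )


def select_press_min(curve: ComponentCurve) -> SelectionResult:
    """Component count minimizing mean validation PRESS (ties -> fewer)."""
    if curve.components.size == 0:
        raise DataError("empty component curve")
    i = int(np.argmin(curve.val_press))  # argmin takes the first of ties
    if i == curve.components.size - 1 and curve.components.size > 1:
        warnings.warn(
            "PRESS minimum sits at max_components; the curve may still be "
            "decreasing (possible overfit region not explored)",
            stacklevel=2,
        )
    return _result(curve, "press_min", int(curve.components[i]))


def select_backward_penalty(
    curve: ComponentCurve, penalty_percent: float = 1.5
) -> SelectionResult:
    """Backward penalty: walk down from the PRESS-minimum component count.

    The threshold is ``penalty_percent / 100`` of the maximum mean
    validation PRESS. Starting at the press_min choice, the component count
    is reduced by one while the PRESS increase of that reduction stays
    within the threshold, stopping at the first reduction that would cost
    more (or at one component).
    """
    if penalty_percent <= 0:
        raise ConfigError("penalty_percent must be positive")
    start = select_press_min(curve).n_components
    tau = penalty_percent / 100.0 * float(curve.val_press.max())
    a = start
    while a > 1 and (curve.val_press[a - 2] - curve.val_press[a - 1]) <= tau:
        a -= 1
    return _result(curve, "press_adj", a)


def sign_flip_pvalue(d: np.ndarray, n_permutations: int, rng) -> float:
    """Two-sided sign-flip randomization p-value for mean(d) = 0.

    The null is built by flipping the sign of each paired difference
    independently; the p-value uses the add-one correction
    ``(1 + #{|perm| >= |obs|}) / (n_permutations + 1)``.
    """
    d = np.asarray(d, dtype=float)
    obs = abs(d.mean())
    if np.all(d == 0):
        return 1.0
    n = d.size
    count = 0
    chunk = max(1, int(5_000_000 // max(n, 1)))
    done = 0
    while done < n_permutations:
        m = min(chunk, n_permutations - done)
        signs = rng.integers(0, 2, size=(m, n)) * 2 - 1
        stats = np.abs(signs @ d) / n
        count += int(np.sum(stats >= obs - 1e-15))
        done += m
    return (1 + count) / (n_permutations + 1)


def select_voet(
    curve: ComponentCurve,
    alpha: float = 0.01,
    n_permutations: int = 1999,
    seed: int | None = None,
) -> SelectionResult:
    """Van der Voet randomization test against the PRESS-minimum model.

    For each candidate count below the reference, the per-sample squared
    validation residuals of the candidate and the reference are paired and
    their mean difference tested with a two-sided sign-flip randomization
    test. Scanning upward, the first candidate whose p-value is >= alpha
    (i.e. not significantly worse than the reference) is selected; if every
    smaller model is significantly worse, the reference stands.
    """
    if curve.val_sq_residuals is None:
        raise StateError(
            "per-sample validation residuals were not retained; rerun run_cv"
        )
    if not 0.0 < alpha < 1.0:
        raise DomainError("alpha must be in (0, 1)")
    a_ref = select_press_min(curve).n_components
    rng = np.random.default_rng(seed)
    ref_sq = curve.val_sq_residuals[a_ref - 1]
    for a in range(1, a_ref):
        d = curve.val_sq_residuals[a - 1] - ref_sq
        p = sign_flip_pvalue(d, n_permutations, rng)
        if p >= alpha:
            return _result(curve, "voet", a)
    return _result(curve, "voet", a_ref)


def report_table(results: dict[str, list[SelectionResult]]) -> pd.DataFrame:
    """Tabular summary: one row per trait x selection method."""
    rows = []
    for trait, res_list in results.items():
        for res in res_list:
            rows.append({"trait": trait, **res.to_dict()})
    return pd.DataFrame(rows)
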