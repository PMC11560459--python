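"""SIMPLS partial least squares regression for a single response.

Partial least squares regression projects a high-dimensional, collinear
predictor matrix (here: reflectance at ~2,000 1-nm wavebands) onto a small
number of latent components chosen to maximize covariance with the
response. The SIMPLS formulation (de Jong's algorithm) computes each weight
vector directly from the deflated cross-product vector ``s = X'y``:

    for a = 1..A:
        r_a  = s / ||X s||              (weight, normalized via the score)
        t_a  = X r_a                    (score, unit norm, mutually orthogonal)
        p_a  = X' t_a                   (X loading)
        q_a  = y' t_a                   (y loading)
        v_a  = orthonormalized p_a against previous v's
        s   <- s - v_a (v_a' s)         (deflate the cross-product)

with ``X`` and ``y`` mean-centered and *not* variance-scaled. The
regression vector is ``B = R q`` and predictions are
``yhat = (X_new - x_mean) B + y_mean``. Because scores are built
sequentially, one fit at ``A`` components yields the whole family of
sub-models ``1..A`` (see :func:`predict_components`), which the
cross-validation harness exploits.

Also provided: standardized coefficient profiles (mean 0, SD 1 over
wavebands), variable-importance-in-projection (VIP) scores with the
mean-square-one normalization, and extraction of the top VIP peak regions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import AlignmentError, ConfigError, DomainError

__all__ = [
    "PLSModel",
    "fit_simpls",
    "predict",
    "predict_components",
    "standardized_coefficients",
    "VIPProfile",
    "vip_scores",
    "top_peak_regions",
    "export_model_table",
]

_WEIGHT_TOL = 1e-12  # early-stop: component weight norm below tol x initial


@dataclass
class PLSModel:
    """A fitted SIMPLS factorization for one response.

    Attributes follow the usual PLS naming: ``x_weights`` R (p x A),
    ``x_scores`` T (n x A, orthonormal columns), ``x_loadings`` P (p x A),
    ``y_loadings`` q (A,), and ``regression_vector`` B = R q (p,).
    ``ss_components`` holds the response sum of squares explained per
    component, ``q_a^2 (t_a' t_a)``, used by the VIP formula.
    """

    n_components: int
    x_mean: np.ndarray
    y_mean: float
    x_weights: np.ndarray
    x_scores: np.ndarray
    x_loadings: np.ndarray
    y_loadings: np.ndarray
    regression_vector: np.ndarray
    ss_components: np.ndarray
    wavelengths: np.ndarray | None = None

    @property
    def intercept(self) -> float:
        return float(self.y_mean - self.x_mean @ self.regression_vector)


def fit_simpls(X, y, n_components: int, wavelengths=None) -> PLSModel:
    """Fit a SIMPLS model with ``n_components`` latent components.

    ``X`` (n x p) and ``y`` (n,) are mean-centered internally; no variance
    scaling is applied. If a component's cross-product norm collapses below
    ``1e-12`` times its initial value (response fully explained), fitting
    stops early and the achieved number of components is reported via a
    warning and ``model.n_components``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if y.size != n:
        raise AlignmentError(f"X has {n} rows but y has {y.size} values")
    if n_components < 1:
        raise ConfigError("n_components must be >= 1")
    if n_components > min(n - 1, p):
        raise ConfigError(
            f"n_components={n_components} exceeds the rank bound "
            f"min(n-1, p) = {min(n - 1, p)}"
        )
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise DomainError("X and y must be finite")

    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    X0 = X - x_mean
    y0 = y - y_mean
    if np.allclose(y0, 0.0):
        raise DomainError("response has zero variance")

    A = n_components
    R = np.zeros((p, A))
    T = np.zeros((n, A))
    P = np.zeros((p, A))
    q = np.zeros(A)
    V = np.zeros((p, A))

    s = X0.T @ y0
    s0_norm = np.linalg.norm(s)
    achieved = 0
    for a in range(A):
        if np.linalg.norm(s) <= _WEIGHT_TOL * s0_norm:
            break
        r = s.copy()
        t = X0 @ r
        t -= t.mean()  # guard against accumulated round-off in centering
        t_norm = np.linalg.norm(t)
        if t_norm <= _WEIGHT_TOL * max(s0_norm, 1.0):
            break
        t /= t_norm
        r /= t_norm
        pa = X0.T @ t
        qa = float(y0 @ t)
        # Modified Gram-Schmidt with one re-orthogonalization pass: keeps the
        # deflation basis orthonormal even at A ~ 30 on heavily collinear X.
        v = pa.copy()
        for _ in range(2):
            v -= V[:, :a] @ (V[:, :a].T @ v)
        v_norm = np.linalg.norm(v)
        if v_norm <= _WEIGHT_TOL * max(np.linalg.norm(pa), 1.0):
            break
        v /= v_norm
        s = s - v * (v @ s)

        R[:, a] = r
        T[:, a] = t
        P[:, a] = pa
        q[a] = qa
        V[:, a] = v
        achieved = a + 1

    if achieved == 0:
        raise DomainError("no usable PLS component (degenerate predictors)")
    if achieved < A:
        warnings.warn(
            f"SIMPLS stopped early at {achieved} of {A} components "
            "(response fully explained)",
            stacklevel=2,
        )
        R, T, P, q = R[:, :achieved], T[:, :achieved], P[:, :achieved], q[:achieved]

    B = R @ q
    ss = q**2  # t_a' t_a = 1 by construction
    return PLSModel(
        n_components=achieved,
        x_mean=x_mean,
        y_mean=y_mean,
        x_weights=R,
        x_scores=T,
        x_loadings=P,
        y_loadings=q,
        regression_vector=B,
        ss_components=ss,
        wavelengths=None if wavelengths is None else np.asarray(wavelengths, float),
    )


def _check_grid(model: PLSModel, X_new: np.ndarray) -> np.ndarray:
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if X_new.shape[1] != model.x_mean.size:
        raise AlignmentError(
            f"X_new has {X_new.shape[1]} wavebands; model expects {model.x_mean.size}"
        )
    return X_new


def predict(model: PLSModel, X_new) -> np.ndarray:
    """Predict the response: ``(X_new - x_mean) @ B + y_mean``."""
    X_new = _check_grid(model, X_new)
    return (X_new - model.x_mean) @ model.regression_vector + model.y_mean


def predict_components(model: PLSModel, X_new) -> np.ndarray:
    """Predictions of every sub-model ``a = 1..n_components`` at once.

    Returns an ``(n_new, n_components)`` matrix whose column ``a-1`` equals
    the prediction of the model truncated to its first ``a`` components.
    """
    X_new = _check_grid(model, X_new)
    T_new = (X_new - model.x_mean) @ model.x_weights
    return np.cumsum(T_new * model.y_loadings, axis=1) + model.y_mean


def standardized_coefficients(model: PLSModel) -> np.ndarray:
    """Regression vector rescaled over wavebands to mean 0 and SD 1.

    A display convention for comparing coefficient profiles across traits
    with very different units; the affine map has positive scale, so peak
    signs and locations are preserved.
    """
    b = model.regression_vector
    sd = float(np.std(b))
    if sd == 0.0:
        raise DomainError("regression vector is constant; cannot standardize")
    return (b - b.mean()) / sd


@dataclass
class VIPProfile:
    """Variable-importance-in-projection scores over the waveband grid.

    The mean of the squared scores is exactly 1, so wavebands with
    ``score > threshold`` (default 1) contribute more than an average
    waveband to the explained response variance.
    """

    wavelengths: np.ndarray
    scores: np.ndarray
    threshold: float = 1.0
    peak_regions: list[tuple[float, float]] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"wavelength": self.wavelengths, "vip": self.scores})


def vip_scores(model: PLSModel, threshold: float = 1.0) -> VIPProfile:
    """VIP score of each waveband for a fitted model.

    ``VIP_j = sqrt( p * sum_a SS_a (r_ja / ||r_a||)^2 / sum_a SS_a )`` where
    ``SS_a = q_a^2 (t_a' t_a)`` is the response sum of squares explained by
    component ``a`` and ``r_a`` the SIMPLS weight vectors.
    """
    R = model.x_weights
    ss = model.ss_components
    total = float(ss.sum())
    if total <= 0.0:
        raise DomainError("all components explain zero response variance")
    p = R.shape[0]
    wnorm2 = (R**2).sum(axis=0)
    wnorm2 = np.where(wnorm2 > 0, wnorm2, 1.0)
    contrib = (R**2 / wnorm2) @ ss
    scores = np.sqrt(p * contrib / total)
    wl = (
        model.wavelengths
        if model.wavelengths is not None
        else np.arange(p, dtype=float)
    )
    return VIPProfile(wavelengths=np.asarray(wl, float), scores=scores, threshold=threshold)


def top_peak_regions(
    profile: VIPProfile, k: int = 3, window: float = 25.0
) -> list[tuple[float, float]]:
    """The ``k`` highest VIP peaks as symmetric wavelength windows.

    Peaks are strict local maxima of the VIP curve above the profile
    threshold; peaks closer than ``window`` nm are merged keeping the
    higher. Each retained peak is reported as ``(center - window,
    center + window)`` clipped to the grid, ordered by decreasing score.
    Returns an empty list (with a warning) when no peak clears the
    threshold.
    """
    if k < 1:
        raise ConfigError("k must be >= 1")
    s = profile.scores
    wl = profile.wavelengths
    interior = np.arange(1, s.size - 1)
    is_peak = (s[interior] > s[interior - 1]) & (s[interior] > s[interior + 1])
    candidates = interior[is_peak & (s[interior] > profile.threshold)]
    if candidates.size == 0:
        warnings.warn("no VIP local maximum above threshold", stacklevel=2)
        profile.peak_regions = []
        return []
    order = candidates[np.argsort(s[candidates])[::-1]]
    kept: list[int] = []
    for idx in order:
        if all(abs(wl[idx] - wl[j]) > window for j in kept):
            kept.append(int(idx))
        if len(kept) == k:
            break
    regions = [
        (
            float(max(wl[0], wl[i] - window)),
            float(min(wl[-1], wl[i] + window)),
        )
        for i in kept
    ]
    profile.peak_regions = regions
    return regions


def export_model_table(model: PLSModel, path=None) -> pd.DataFrame:
    """Flat per-waveband dump: wavelength, B, standardized B, VIP score.

    The CSV mirrors what coefficient/VIP figures are drawn from.
    """
    vip = vip_scores(model)
    frame = pd.DataFrame(
        {
            "wavelength": vip.wavelengths,
            "coefficient": model.regression_vector,
            "standardized_coefficient": standardized_coefficients(model),
            "vip": vip.scores,
        }
    )
    if path is not None:
        frame.to_csv(path, index=False)
    return frame
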