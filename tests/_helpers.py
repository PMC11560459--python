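"""Shared test utilities: hand-constructed component curves."""

import numpy as np

from leafspec.selection import ComponentCurve


def make_curve(val_press, val_sq_residuals=None, n_val=20, y_mean=10.0):
    """ComponentCurve with a prescribed mean validation PRESS vector.

    Calibration arrays mirror the validation ones; R2/RPD entries are
    filled with consistent placeholder values so metric blocks can be
    assembled (R2 from a nominal SST, RPD positive).
    """
    val_press = np.asarray(val_press, dtype=float)
    a = val_press.size
    sst = max(val_press.max() * 2.0, 1.0)
    r2 = 1.0 - val_press / sst
    rpd = 1.0 / np.sqrt(np.maximum(1.0 - r2, 1e-12))
    return ComponentCurve(
        components=np.arange(1, a + 1),
        cal_press=val_press.copy(),
        val_press=val_press,
        cal_rmse=np.sqrt(val_press / n_val),
        val_rmse=np.sqrt(val_press / n_val),
        cal_r2=r2.copy(),
        val_r2=r2,
        cal_rpd=rpd.copy(),
        val_rpd=rpd,
        y_mean=y_mean,
        n_cal=4 * n_val,
        n_val=n_val,
        n_iterations=1,
        val_sq_residuals=val_sq_residuals,
    )


def random_curve_with_residuals(rng, n_components=None, n_val=40):
    """Random but internally consistent curve: PRESS equals the row sums of
    the retained per-sample squared residuals."""
    a = n_components or int(rng.integers(4, 21))
    sq = rng.exponential(scale=1.0, size=(a, n_val))
    curve = make_curve(sq.sum(axis=1), val_sq_residuals=sq, n_val=n_val)
    return curve
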