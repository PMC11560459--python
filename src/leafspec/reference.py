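"""Published reference statistics for winter-wheat foliar traits.

Descriptive statistics (min, max, mean, median, sample SD, CV%) of 360
fresh winter-wheat leaf samples collected over two growing seasons from
Ohio breeding trials: total nitrogen (N, %), thirteen mineral elements
(ug/g), and wet-basis moisture content (MC, %). They serve two purposes in
this package: as the worked example for the CV = SD/mean x 100 convention,
and as the realism yardstick the synthetic generator's trait spread
(CVs of roughly 5-60%) is tuned against.
"""

from __future__ import annotations

import pandas as pd

# trait -> (unit, min, max, mean, median, sd, cv_percent)
WHEAT_TRAIT_SUMMARY: dict[str, tuple[str, float, float, float, float, float, float]] = {
    "N": ("%", 1.77, 5.14, 3.47, 3.53, 0.59, 16.96),
    "P": ("ug/g", 1783.00, 5926.00, 3635.34, 3645.00, 660.74, 18.18),
    "K": ("ug/g", 9511.00, 31780.00, 19179.17, 19480.00, 3146.51, 16.41),
    "Ca": ("ug/g", 1839.00, 13260.00, 6210.99, 6405.50, 2287.14, 36.82),
    "Mg": ("ug/g", 918.10, 5123.00, 2409.48, 2435.50, 846.76, 35.14),
    "S": ("ug/g", 1681.00, 7286.00, 3379.64, 3459.50, 990.40, 29.30),
    "B": ("ug/g", 3.17, 18.23, 6.60, 6.10, 2.52, 38.13),
    "Cu": ("ug/g", 1.98, 11.04, 5.66, 5.56, 1.52, 26.79),
    "Fe": ("ug/g", 48.32, 173.10, 93.17, 90.62, 23.60, 25.33),
    "Mn": ("ug/g", 31.54, 247.30, 73.70, 66.97, 32.10, 43.56),
    "Zn": ("ug/g", 7.41, 26.61, 15.78, 16.23, 3.34, 21.15),
    "Mo": ("ug/g", 0.63, 33.37, 10.39, 10.10, 6.36, 61.19),
    "Al": ("ug/g", 5.96, 99.63, 26.86, 24.82, 13.92, 51.81),
    "Na": ("ug/g", 13.11, 152.60, 41.55, 37.62, 20.50, 49.34),
    "MC": ("%", 55.29, 77.83, 68.57, 68.11, 3.71, 5.41),
}

#: Traits whose listed mean/SD carry enough printed precision that the
#: recomputed CV agrees with the listed CV at two decimals; for the rest the
#: rounding of the printed mean/SD propagates to more than 0.005 in CV.
CV_EXACT_TRAITS: tuple[str, ...] = (
    "P", "K", "Ca", "Mg", "S", "Fe", "Na", "MC",
)


def reference_stats() -> pd.DataFrame:
    """The reference summary as a DataFrame indexed by trait."""
    frame = pd.DataFrame.from_dict(
        {
            name: dict(
                unit=unit, min=mn, max=mx, mean=mean, median=med,
                sd=sd, cv_percent=cv,
            )
            for name, (unit, mn, mx, mean, med, sd, cv) in WHEAT_TRAIT_SUMMARY.items()
        },
        orient="index",
    )
    frame.index.name = "trait"
    return frame


def recompute_cv(mean: float, sd: float) -> float:
    """CV% from a mean and SD: ``sd / mean * 100``."""
    return sd / mean * 100.0


def cv_rounding_bound(mean: float, sd: float, ulp: float = 0.01) -> float:
    """Worst-case CV% error induced by rounding of the listed mean and SD.

    The listed values are rounded to two decimals (``ulp = 0.01``); the two
    half-ulp perturbations are propagated through sd/mean x 100 and the
    larger one-sided deviation is returned.
    """
    dm = ds = ulp / 2.0
    hi = (sd + ds) / (mean - dm) * 100.0
    lo = (sd - ds) / (mean + dm) * 100.0
    mid = recompute_cv(mean, sd)
    return max(hi - mid, mid - lo)
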