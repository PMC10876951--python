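"""Design-based stratified area estimation and uncertainty propagation.

Class proportions are estimated from a reference sample with map-stratum
weights; standard errors follow the standard stratified variance formula.
The forest-mask and damage-classification uncertainties are combined under
an independence assumption (delta-method product rule), and per-region
estimates aggregate linearly by default — matching how the printed regional
totals add up — with quadrature available behind a flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "AreaEstimate",
    "stratified_area_estimate",
    "combine_uncertainty",
    "aggregate_regions",
]


@dataclass(frozen=True)
class AreaEstimate:
    """Area of one class with its standard error."""

    class_name: str
    area_ha: float
    se_ha: float
    proportion: float
    se_proportion: float
    region_area_ha: float

    def __post_init__(self):
        if self.se_ha < 0 or self.se_proportion < 0:
            raise ValueError("standard errors must be non-negative")
        if not (0.0 <= self.proportion <= 1.0 + 1e-12):
            raise ValueError("proportion must lie in [0, 1]")


def stratified_area_estimate(
    sample: pd.DataFrame,
    strata_weights: dict,
    region_area_ha: float,
    stratum_sizes: dict | None = None,
) -> dict[str, AreaEstimate]:
    """Estimate per-class area and SE from a stratified reference sample.

    Parameters
    ----------
    sample : DataFrame
        One row per reference location with columns ``stratum`` and
        ``reference_class``.
    strata_weights : dict
        Map-stratum areal weights ``W_i``; must sum to 1.
    region_area_ha : float
        Total region area converting proportions to hectares.
    stratum_sizes : dict, optional
        Stratum population pixel counts ``N_i``; when given, the finite
        population correction ``1 - n_i/N_i`` is applied, so a census sample
        yields SE = 0.

    Returns
    -------
    dict
        ``class -> AreaEstimate``; class proportions sum to 1.
    """
    w = float(sum(strata_weights.values()))
    if abs(w - 1.0) > 1e-9:
        raise ValueError(f"strata weights must sum to 1, got {w}")
    counts = sample.groupby("stratum").size()
    for stratum in strata_weights:
        n_i = int(counts.get(stratum, 0))
        if n_i == 0:
            raise ValueError(f"stratum {stratum!r} has no reference samples")
        if n_i < 2:
            raise ValueError(f"stratum {stratum!r} sampled < 2: SE undefined")
    classes = sorted(sample["reference_class"].unique())
    out: dict[str, AreaEstimate] = {}
    for cls in classes:
        p_hat = 0.0
        var = 0.0
        for stratum, w_i in strata_weights.items():
            sub = sample[sample["stratum"] == stratum]
            n_i = len(sub)
            p_ik = float((sub["reference_class"] == cls).mean())
            p_hat += w_i * p_ik
            fpc = 1.0
            if stratum_sizes is not None:
                n_pop = stratum_sizes[stratum]
                fpc = max(0.0, 1.0 - n_i / n_pop)
            var += w_i**2 * p_ik * (1.0 - p_ik) / (n_i - 1) * fpc
        se_p = math.sqrt(var)
        out[cls] = AreaEstimate(
            class_name=str(cls),
            area_ha=p_hat * region_area_ha,
            se_ha=se_p * region_area_ha,
            proportion=p_hat,
            se_proportion=se_p,
            region_area_ha=region_area_ha,
        )
    return out


def combine_uncertainty(
    forest_est: AreaEstimate, damage_est: AreaEstimate
) -> AreaEstimate:
    """Combine forest-mask and damage-classification uncertainty.

    The combined point estimate is the product of the two proportions scaled
    to the region area; assuming independent errors, the relative variance of
    the product is the sum of the relative variances. A zero point estimate
    falls back to additive-scale SE (the larger absolute SE in hectares).
    """
    for est in (forest_est, damage_est):
        if not math.isfinite(est.se_ha):
            raise ValueError("standard errors must be finite")
    region = forest_est.region_area_ha
    p = forest_est.proportion * damage_est.proportion
    area = p * region
    if forest_est.proportion > 0 and damage_est.proportion > 0:
        rel_var = 0.0
        rel_var += (forest_est.se_proportion / forest_est.proportion) ** 2
        rel_var += (damage_est.se_proportion / damage_est.proportion) ** 2
        se_p = p * math.sqrt(rel_var)
    else:
        se_p = max(forest_est.se_proportion, damage_est.se_proportion)
    return AreaEstimate(
        class_name=f"{damage_est.class_name}|{forest_est.class_name}",
        area_ha=area,
        se_ha=se_p * region,
        proportion=p,
        se_proportion=se_p,
        region_area_ha=region,
    )


def aggregate_regions(
    estimates: list[AreaEstimate], method: str = "linear"
) -> AreaEstimate:
    """Aggregate per-region area estimates into one total.

    The point estimate is always the plain sum. The default combines the
    uncertainty terms by linear summation (the rule behind the printed
    regional totals); ``method="quadrature"`` gives the root-sum-of-squares
    conventional for independent errors.
    """
    if not estimates:
        raise ValueError("need at least one estimate")
    if method not in ("linear", "quadrature"):
        raise ValueError(f"unknown aggregation method {method!r}")
    total_area = float(sum(e.area_ha for e in estimates))
    total_region = float(sum(e.region_area_ha for e in estimates))
    if method == "linear":
        total_se = float(sum(e.se_ha for e in estimates))
    else:
        total_se = float(np.sqrt(sum(e.se_ha**2 for e in estimates)))
    proportion = total_area / total_region if total_region > 0 else 0.0
    return AreaEstimate(
        class_name=estimates[0].class_name,
        area_ha=total_area,
        se_ha=total_se,
        proportion=proportion,
        se_proportion=total_se / total_region if total_region > 0 else 0.0,
        region_area_ha=total_region,
    )
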