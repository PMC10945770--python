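"""Root-to-tip regression: directional selection on continuous traits.

Under sustained directional selection, lineages that have accumulated more
molecular change since the clade's common ancestor should carry better
trait values. The test is an ordinary least-squares regression of a trait
on root-to-tip distance (substitutions per site):

    trait_i = a + b · rtt_i + ε_i

A positive, significant slope b indicates improvement with molecular
divergence; the intercept a estimates the trait value of the ancestor at
the root (rtt = 0), with its standard error as the uncertainty. Slopes are
converted into interpretable rates via the number of aligned sites and the
clade age: dividing the slope by the site count gives the change per single
substitution, and the clade age divided by the expected number of
substitutions per lineage gives the waiting time between substitutions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "RegressionResult",
    "ImprovementRates",
    "fit_ols",
    "ancestral_trait",
    "substitution_interval",
    "per_substitution_change",
    "relative_improvement",
    "improvement_per_my",
    "improvement_rates",
    "run_trait_regressions",
    "DERIVED_TRAITS",
]

DEFAULT_CLADE_AGE_MY = 160.0

#: trait → (numerator column, denominator column); computed on the fly when absent
DERIVED_TRAITS: dict[str, tuple[str, str]] = {
    "k_catC/K_C": ("k_catC", "K_C"),
    "K_C/K_O": ("K_C", "K_O"),
    "PNUE_mass": ("A_mass", "N_mass"),
    "PNUE_area": ("A_area", "N_area"),
}


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    se_slope: float
    se_intercept: float
    r_squared: float
    p_slope: float
    n: int


@dataclass(frozen=True)
class ImprovementRates:
    trait: str
    per_substitution_change: float
    relative_per_substitution: float  # percent
    relative_per_my: float  # percent per My
    my_per_substitution: float
    clade_age: float
    n_sites: int


def fit_ols(x: Sequence[float], y: Sequence[float]) -> RegressionResult:
    """Ordinary least squares of y on x with slope t-test (n − 2 df).

    Pairs with a missing value on either side are dropped. Requires at
    least three complete pairs and non-degenerate x. A constant y yields
    slope 0, r² = 0 and p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    n = len(x)
    if n < 3:
        raise ValueError(f"need at least 3 complete observations, got {n}")
    if np.ptp(x) == 0:
        raise ValueError("predictor has zero variance")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    intercept, slope = model.params
    se_intercept, se_slope = model.bse
    if np.ptp(y) == 0:  # SST = 0: statsmodels reports NaN r² and p
        return RegressionResult(0.0, float(y[0]), 0.0, 0.0, 0.0, 1.0, n)
    return RegressionResult(
        float(slope),
        float(intercept),
        float(se_slope),
        float(se_intercept),
        float(model.rsquared),
        float(model.pvalues[1]),
        n,
    )


def ancestral_trait(reg: RegressionResult) -> tuple[float, float]:
    """Ancestral trait estimate: the regression intercept and its SE.

    At the root, root-to-tip distance is zero, so the intercept estimates
    the trait value of the clade's last common ancestor.
    """
    return reg.intercept, reg.se_intercept


def substitution_interval(mean_rtt: float, n_sites: int, clade_age: float = DEFAULT_CLADE_AGE_MY) -> float:
    """Million years per substitution along an average root-to-tip lineage.

    ``mean_rtt`` is in substitutions per site, so mean_rtt × n_sites is the
    expected substitution count per lineage since the root, accumulated over
    ``clade_age`` million years.
    """
    if mean_rtt <= 0 or n_sites <= 0 or clade_age <= 0:
        raise ValueError("mean_rtt, n_sites and clade_age must all be positive")
    return clade_age / (mean_rtt * n_sites)


def per_substitution_change(slope: float, n_sites: int) -> float:
    """Trait change per single substitution: slope (per subs/site) ÷ site count."""
    if n_sites <= 0:
        raise ValueError("n_sites must be positive")
    return slope / n_sites


def relative_improvement(per_sub_change: float, ancestral_value: float) -> float:
    """Percent trait improvement per substitution, relative to the ancestor."""
    if ancestral_value == 0:
        raise ValueError("ancestral value must be nonzero")
    return 100.0 * per_sub_change / ancestral_value


def improvement_per_my(relative_per_substitution: float, my_per_substitution: float) -> float:
    """Percent improvement per million years from unrounded inputs."""
    if my_per_substitution <= 0:
        raise ValueError("my_per_substitution must be positive")
    return relative_per_substitution / my_per_substitution


def improvement_rates(
    trait: str,
    reg: RegressionResult,
    mean_rtt: float,
    n_sites: int,
    clade_age: float = DEFAULT_CLADE_AGE_MY,
) -> ImprovementRates:
    """Chain a fitted regression into per-substitution and per-My rates."""
    my_per_sub = substitution_interval(mean_rtt, n_sites, clade_age)
    per_sub = per_substitution_change(reg.slope, n_sites)
    ancestral, _ = ancestral_trait(reg)
    rel = relative_improvement(per_sub, ancestral)
    return ImprovementRates(
        trait, per_sub, rel, improvement_per_my(rel, my_per_sub), my_per_sub, clade_age, n_sites
    )


def _with_derived(traits: pd.DataFrame, names: Sequence[str]) -> pd.DataFrame:
    traits = traits.copy()
    for name in names:
        if name not in traits.columns and name in DERIVED_TRAITS:
            num, den = DERIVED_TRAITS[name]
            if num in traits.columns and den in traits.columns:
                traits[name] = traits[num] / traits[den]
    return traits


def run_trait_regressions(
    distances: Mapping[str, float] | pd.Series,
    traits: pd.DataFrame,
    trait_names: Sequence[str] | None = None,
) -> pd.DataFrame:
    """One root-to-tip regression per trait, pairwise-complete per trait.

    ``distances`` maps species to root-to-tip distance; ``traits`` is a
    species-indexed table. Ratio traits (carboxylation efficiency, CO2/O2
    Michaelis ratio, mass- and area-based nitrogen-use efficiency) are
    derived from their parent columns when absent. Returns one row per
    trait: slope, intercept, their SEs, r² (as a percent in
    ``r2_percent``), two-sided slope p-value and n.
    """
    dist = pd.Series(distances, dtype=float)
    if trait_names is None:
        trait_names = [c for c in traits.columns]
    traits = _with_derived(traits, trait_names)
    missing = [t for t in trait_names if t not in traits.columns]
    if missing:
        raise KeyError(
            f"traits {missing} not in table; available: {sorted(traits.columns)}"
        )
    common = dist.index.intersection(traits.index)
    rows = []
    for name in trait_names:
        joined = pd.DataFrame(
            {"x": dist.loc[common], "y": traits.loc[common, name]}
        ).dropna()
        if len(joined) < 3:
            raise ValueError(
                f"trait {name!r}: only {len(joined)} complete species after joining"
            )
        reg = fit_ols(joined["x"], joined["y"])
        rows.append(
            {
                "trait": name,
                "n": reg.n,
                "slope": reg.slope,
                "se_slope": reg.se_slope,
                "intercept": reg.intercept,
                "se_intercept": reg.se_intercept,
                "r2_percent": 100.0 * reg.r_squared,
                "p": reg.p_slope,
            }
        )
    return pd.DataFrame(rows).set_index("trait")
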