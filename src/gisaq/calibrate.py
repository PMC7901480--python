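"""qPCR standard curves, slope/intercept ANOVA, and calibration coefficients.

A qPCR standard curve relates cycle threshold to template amount,

    CT = a * x + b,        x = log10 concentration,

with a the slope (cycles per log10 unit, ~ -3.32 at 100% efficiency) and b
the intercept. Plasmid spike-ins and microbial genomes are not equivalent
templates: their curves share a slope but differ systematically in
intercept. The calibration step quantifies that difference with one-way
ANOVA across fitted curves and produces multiplicative coefficients

    CT = a*c * x + b*d,

where c corrects the slope (c = 1 when the slope ANOVA finds no significant
difference, the ratio of mean slopes otherwise) and d = mean microbial
intercept / mean spike-in intercept corrects the intercept. The same (c, d)
are later applied to the sequencing-based gradient curves.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import CalibrationError, FitError

AVOGADRO = 6.022e23        # copies per mole
MEAN_BP_WEIGHT = 660.0     # Da per mole per base pair
NG_PER_G = 1e9


@dataclass(frozen=True)
class StandardCurve:
    """One fitted qPCR curve: CT = slope * log10(conc) + intercept."""

    group: str
    slope: float
    intercept: float
    r_squared: float
    n: int
    kingdom: str = "internal"

    def __post_init__(self) -> None:
        if self.n < 3:
            raise FitError(f"{self.group}: need >= 3 points, got {self.n}")
        if not 0.0 <= self.r_squared <= 1.0 + 1e-12:
            raise FitError(f"{self.group}: r_squared outside [0, 1]")


@dataclass(frozen=True)
class AnovaResult:
    f_statistic: float
    p_value: float
    df_between: int
    df_within: int
    group_means: dict[str, float]


@dataclass(frozen=True)
class CalibrationCoefficients:
    """Multiplicative slope (c) and intercept (d) corrections for one kingdom."""

    kingdom: str
    c: float
    d: float
    alpha: float
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.c <= 0 or self.d <= 0:
            raise CalibrationError("calibration coefficients must be positive")


def fit_standard_curve(x: Sequence[float], ct: Sequence[float], group: str,
                       kingdom: str = "internal") -> StandardCurve:
    """Ordinary least squares of CT on log10 concentration."""
    x = np.asarray(x, dtype=float)
    ct = np.asarray(ct, dtype=float)
    if x.size != ct.size:
        raise FitError("x and ct differ in length")
    if np.unique(x).size < 3:
        raise FitError(f"{group}: need >= 3 distinct x values")
    res = stats.linregress(x, ct)
    return StandardCurve(group=group, slope=float(res.slope),
                         intercept=float(res.intercept),
                         r_squared=float(res.rvalue) ** 2, n=int(x.size),
                         kingdom=kingdom)


def fit_curves_from_table(measurements: pd.DataFrame) -> list[StandardCurve]:
    """Fit one curve per group from a long-format qPCR table.

    Expected columns: ``group``, ``kingdom``, ``log10_conc``, ``ct``.
    """
    curves = []
    for (group, kingdom), sub in measurements.groupby(["group", "kingdom"], sort=True):
        curves.append(fit_standard_curve(sub["log10_conc"], sub["ct"],
                                         group=str(group), kingdom=str(kingdom)))
    return curves


def anova_one_way(groups: Mapping[str, Sequence[float]]) -> AnovaResult:
    """One-way fixed-effects ANOVA: F = MS_between / MS_within.

    Degenerate cases are resolved explicitly: zero between-group variation
    gives F = 0, p = 1 (identical groups are maximally unsurprising); zero
    within-group variation with real between-group differences gives
    F = inf, p = 0.
    """
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    if any(a.size < 2 for a in arrays.values()):
        raise ValueError("every group needs >= 2 values")
    all_vals = np.concatenate(list(arrays.values()))
    grand = all_vals.mean()
    ss_between = sum(a.size * (a.mean() - grand) ** 2 for a in arrays.values())
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays.values())
    df_between = len(arrays) - 1
    df_within = all_vals.size - len(arrays)
    means = {k: float(a.mean()) for k, a in arrays.items()}
    scale = max(float((all_vals ** 2).sum()), 1.0)
    if ss_between <= 1e-12 * scale:
        f, p = 0.0, 1.0
    elif ss_within <= 1e-12 * scale:
        f, p = float("inf"), 0.0
    else:
        f = (ss_between / df_between) / (ss_within / df_within)
        p = float(stats.f.sf(f, df_between, df_within))
    return AnovaResult(f_statistic=float(f), p_value=float(p),
                       df_between=df_between, df_within=df_within,
                       group_means=means)


def compute_calibration(internal_curves: Sequence[StandardCurve],
                        microbe_curves: Sequence[StandardCurve],
                        kingdom: str, alpha: float = 0.05,
                        rounding: int = 3) -> CalibrationCoefficients:
    """Derive (c, d) from fitted spike-in and microbial qPCR curves.

    c = 1 when the one-way ANOVA of slopes (spike-ins vs microbes) finds no
    significant difference at ``alpha``, otherwise the ratio of mean slopes;
    d is the ratio of mean intercepts (unweighted per-curve means), rounded
    to ``rounding`` decimals. Unrounded values and the ANOVA are kept in
    ``provenance``.
    """
    if len(internal_curves) < 2 or len(microbe_curves) < 2:
        raise CalibrationError("need >= 2 curves on each side")
    slopes = {"internal": [cv.slope for cv in internal_curves],
              kingdom: [cv.slope for cv in microbe_curves]}
    intercepts = {"internal": [cv.intercept for cv in internal_curves],
                  kingdom: [cv.intercept for cv in microbe_curves]}
    slope_anova = anova_one_way(slopes)
    intercept_anova = anova_one_way(intercepts)
    mean_internal_slope = float(np.mean(slopes["internal"]))
    mean_microbe_slope = float(np.mean(slopes[kingdom]))
    mean_internal_b = float(np.mean(intercepts["internal"]))
    mean_microbe_b = float(np.mean(intercepts[kingdom]))
    if mean_internal_b <= 0:
        raise CalibrationError("mean internal intercept must be positive")
    if slope_anova.p_value > alpha:
        c_raw = 1.0
    else:
        if mean_internal_slope == 0:
            raise CalibrationError("mean internal slope is zero")
        c_raw = mean_microbe_slope / mean_internal_slope
    d_raw = mean_microbe_b / mean_internal_b
    return CalibrationCoefficients(
        kingdom=kingdom, c=round(c_raw, rounding), d=round(d_raw, rounding),
        alpha=alpha,
        provenance={
            "c_unrounded": c_raw, "d_unrounded": d_raw,
            "mean_internal_slope": mean_internal_slope,
            "mean_microbe_slope": mean_microbe_slope,
            "mean_internal_intercept": mean_internal_b,
            "mean_microbe_intercept": mean_microbe_b,
            "slope_anova_p": slope_anova.p_value,
            "intercept_anova_p": intercept_anova.p_value,
        },
    )


def copies_from_mass(mass_concentration: float, dna_length: int) -> float:
    """Convert a dsDNA mass concentration (ng/ml) to copies/ml.

    C = m * N_A / (L * 1e9 * 660), with L the construct length in bp and
    660 Da the mean weight of one base pair.
    """
    if dna_length <= 0:
        raise ValueError("dna_length must be positive")
    if mass_concentration < 0:
        raise ValueError("mass_concentration must be >= 0")
    return mass_concentration * AVOGADRO / (dna_length * NG_PER_G * MEAN_BP_WEIGHT)


def recovery_rate(added: Sequence[float], recovered: Sequence[float],
                  groups: Sequence[str]) -> tuple[pd.DataFrame, AnovaResult | None]:
    """Per-observation recovery percentages with an across-group ANOVA.

    Rates above 100% are possible (measurement noise) and flagged with a
    warning column rather than clipped.
    """
    added = np.asarray(added, dtype=float)
    recovered = np.asarray(recovered, dtype=float)
    if added.size != recovered.size or added.size != len(groups):
        raise ValueError("added, recovered and groups must align")
    if np.any(added <= 0):
        raise ValueError("added copies must be > 0")
    rate = 100.0 * recovered / added
    table = pd.DataFrame({"group": list(groups), "added": added,
                          "recovered": recovered, "recovery_pct": rate,
                          "over_unity": rate > 100.0})
    by_group = {g: sub["recovery_pct"].to_numpy()
                for g, sub in table.groupby("group")}
    anova = None
    if len(by_group) >= 2 and all(v.size >= 2 for v in by_group.values()):
        anova = anova_one_way(by_group)
    return table, anova
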