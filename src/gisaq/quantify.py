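"""Gradient quantitative equations and conversion of reads to copies per gram.

Five spike-ins added at a 10x concentration gradient (10^4..10^8 copies/g by
default) give, within each sample, a log-log standard curve

    log10 reads = a*c * log10 copies_per_g + b*d

fitted on the spike-ins (reads on concentration, the observational
direction) and inverted to convert community read counts into absolute
abundances. (c, d) come from the qPCR calibration step and default to
(1, 1). Each sample gets its own curve; cells outside the fitted gradient
range are extrapolated but flagged, zero-read cells are reported as 0 with a
below-detection flag, and the detection limit is the concentration whose
curve value equals a minimal read count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .calibrate import CalibrationCoefficients
from .errors import FitError, QuantificationError

FLAG_OK = "ok"
FLAG_BELOW_DETECTION = "below_detection"
FLAG_EXTRAPOLATED_LOW = "extrapolated_low"
FLAG_EXTRAPOLATED_HIGH = "extrapolated_high"


@dataclass(frozen=True)
class GradientDesign:
    """Nominal spike-in concentrations for one amplicon region."""

    concentrations: Mapping[str, float]  # standard id -> copies per gram
    region: str = "16S_V3V4"
    sample_mass_g: float = 1.0

    def __post_init__(self) -> None:
        if len(self.concentrations) < 3:
            raise ValueError("a gradient needs >= 3 standards")
        vals = list(self.concentrations.values())
        if any(v <= 0 for v in vals):
            raise ValueError("concentrations must be strictly positive")
        if len(set(vals)) != len(vals):
            raise ValueError("concentrations must be pairwise distinct")


@dataclass(frozen=True)
class QuantCurve:
    """Per-sample calibrated gradient curve in log10-log10 space."""

    sample: str
    region: str
    slope: float            # a: log10 reads per log10 copies/g
    intercept: float        # b: log10 reads
    c: float
    d: float
    r: float
    p: float
    n: int
    x_range: tuple[float, float]  # log10 copies/g span of usable standards
    excluded: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.n < 3:
            raise FitError(f"{self.sample}: need >= 3 usable points")

    def predict_log_reads(self, log10_copies: float) -> float:
        return self.slope * self.c * log10_copies + self.intercept * self.d

    def invert(self, reads: float) -> float:
        """Copies per gram for a positive read count."""
        ac = self.slope * self.c
        if ac == 0:
            raise QuantificationError(f"{self.sample}: a*c = 0, curve not invertible")
        return 10.0 ** ((np.log10(reads) - self.intercept * self.d) / ac)


def pearson_correlation(x, y) -> tuple[float, float]:
    """Sample Pearson r with a two-sided p value (t transform)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need aligned vectors of length >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise FitError("undefined correlation: zero variance")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def fit_gradient_curve(standard_counts: Mapping[str, float],
                       design: GradientDesign,
                       calibration: CalibrationCoefficients | None = None,
                       sample: str = "sample") -> QuantCurve:
    """Least squares of log10(reads) on log10(nominal copies/g).

    Standards with zero reads are excluded with a warning; at least three
    usable standards are required. A severely inverted gradient (r < 0)
    triggers a warning but still returns the fit.
    """
    xs, ys, excluded = [], [], []
    for sid, conc in design.concentrations.items():
        reads = float(standard_counts.get(sid, 0))
        if reads > 0:
            xs.append(np.log10(conc))
            ys.append(np.log10(reads))
        else:
            excluded.append(sid)
    if excluded:
        warnings.warn(
            f"{sample}: standards with zero reads excluded from fit: {excluded}",
            stacklevel=2,
        )
    if len(xs) < 3:
        raise FitError(f"{sample}: only {len(xs)} standards with reads > 0")
    res = stats.linregress(xs, ys)
    r, p = pearson_correlation(xs, ys)
    if r < 0:
        warnings.warn(f"{sample}: negative gradient correlation (r={r:.3f})",
                      stacklevel=2)
    c = calibration.c if calibration is not None else 1.0
    d = calibration.d if calibration is not None else 1.0
    return QuantCurve(sample=sample, region=design.region,
                      slope=float(res.slope), intercept=float(res.intercept),
                      c=float(c), d=float(d), r=r, p=p, n=len(xs),
                      x_range=(min(xs), max(xs)), excluded=tuple(excluded))


@dataclass
class AbsoluteAbundanceTable:
    """Taxon x sample copies per gram with per-cell provenance flags."""

    values: pd.DataFrame
    flags: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.flags.index) or not (
            self.values.columns.equals(self.flags.columns)
        ):
            raise ValueError("values and flags must share index/columns")


def absolute_abundance(community: pd.DataFrame,
                       curves: Mapping[str, QuantCurve]) -> AbsoluteAbundanceTable:
    """Invert each sample's calibrated gradient curve over a count table.

    ``community`` is features x samples. For reads y > 0 the estimate is
    10^((log10 y - b*d) / (a*c)); y = 0 maps to 0 with a below-detection
    flag; estimates outside the fitted gradient span are flagged
    extrapolated.
    """
    missing = [s for s in community.columns if s not in curves]
    if missing:
        raise QuantificationError(f"no gradient curve for samples: {missing}")
    values = pd.DataFrame(0.0, index=community.index, columns=community.columns)
    flags = pd.DataFrame(FLAG_OK, index=community.index, columns=community.columns)
    for s in community.columns:
        curve = curves[s]
        lo, hi = curve.x_range
        for taxon, reads in community[s].items():
            if reads <= 0:
                values.at[taxon, s] = 0.0
                flags.at[taxon, s] = FLAG_BELOW_DETECTION
                continue
            est = curve.invert(float(reads))
            values.at[taxon, s] = est
            log_est = np.log10(est)
            if log_est < lo:
                flags.at[taxon, s] = FLAG_EXTRAPOLATED_LOW
            elif log_est > hi:
                flags.at[taxon, s] = FLAG_EXTRAPOLATED_HIGH
    return AbsoluteAbundanceTable(values=values, flags=flags)


def single_standard_quantification(standard_counts: Mapping[str, float],
                                   standard_id: str, design: GradientDesign,
                                   community: pd.DataFrame,
                                   sample: str | None = None,
                                   ) -> AbsoluteAbundanceTable:
    """Ratio scaling through one spike-in, assuming a slope of exactly 1.

    copies/g = x_s * y / y_s, with x_s the standard's nominal concentration
    and y_s its read count. This is the single-spike-in shortcut the gradient
    design replaces; it is kept for gradient-vs-single perturbation
    comparisons.
    """
    y_s = float(standard_counts.get(standard_id, 0))
    if y_s <= 0:
        raise QuantificationError(f"standard {standard_id} has zero reads")
    if standard_id not in design.concentrations:
        raise KeyError(f"{standard_id} not in gradient design")
    x_s = design.concentrations[standard_id]
    cols = [sample] if sample is not None else list(community.columns)
    values = community[cols].astype(float) * (x_s / y_s)
    flags = pd.DataFrame(FLAG_OK, index=values.index, columns=values.columns)
    flags = flags.where(community[cols] > 0, FLAG_BELOW_DETECTION)
    return AbsoluteAbundanceTable(values=values, flags=flags)


def relative_abundance(community: pd.DataFrame) -> pd.DataFrame:
    """Per-sample proportions (columns sum to 1); empty samples become NaN."""
    totals = community.sum(axis=0)
    empty = totals[totals <= 0].index.tolist()
    if empty:
        warnings.warn(f"samples with zero total reads: {empty}", stacklevel=2)
    return community.div(totals.where(totals > 0), axis=1)


def detection_limit(curve: QuantCurve, min_reads: float = 1.0) -> float:
    """Concentration (copies/g) whose calibrated curve value is ``min_reads``."""
    if min_reads <= 0:
        raise ValueError("min_reads must be positive")
    return curve.invert(min_reads)
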