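"""Internal-standard calibration and absolute drug quantitation.

Quantitation uses the analyte / internal-standard (stable-isotope-labeled
drug, spiked at a single concentration) peak-area ratio, regressed against
nominal concentration in a matrix-matched extract.  A pooled-tissue curve
can replace per-organ curves; the module provides the paired comparison
between the two strategies, injection-count planning, QC statistics
(replicate RSD), steady-state assessment across exposure times, and the
organ-level ANOVA/Tukey comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

#: fixed tissue extraction rule: 40 µl of 2:2:1 MeOH:ACN:H2O per mg tissue
EXTRACTION_ML_PER_MG: float = 0.04
#: serum is extracted by 1:15 dilution instead of the per-mass rule
SERUM_DILUTION_FACTOR: float = 15.0


@dataclass(frozen=True)
class CalibrationPoint:
    """One calibrator injection: nominal level plus analyte and IS areas."""

    nominal_concentration: float    # µg/ml in extract
    analyte_area: float
    istd_area: float
    replicate: int = 0

    def __post_init__(self) -> None:
        if self.analyte_area < 0 or self.istd_area < 0:
            raise ValueError("peak areas must be non-negative")
        if self.istd_area <= 0:
            raise ValueError("internal-standard area must be positive")

    @property
    def ratio(self) -> float:
        return self.analyte_area / self.istd_area


@dataclass(frozen=True)
class CalibrationFit:
    """Fitted response-ratio calibration curve for one matrix."""

    matrix_id: str
    slope: float
    intercept: float
    r_squared: float
    pearson_r: float
    levels: tuple[float, ...]
    level_accuracy: Mapping[float, float]   # back-calculated, % of nominal
    level_rsd: Mapping[float, float]        # % RSD of back-calculated conc
    weighting: str = "ols"

    @property
    def lowest_level(self) -> float:
        return min(self.levels)

    @property
    def highest_level(self) -> float:
        return max(self.levels)


@dataclass(frozen=True)
class ExtractEstimate:
    """Extract concentration back-calculated from a response ratio."""

    concentration: float        # µg/ml in extract
    below_lowest: bool
    above_highest: bool

    @property
    def flags(self) -> tuple[str, ...]:
        out = []
        if self.below_lowest:
            out.append("below_lowest_calibrator")
        if self.above_highest:
            out.append("above_highest_calibrator")
        return tuple(out)


@dataclass(frozen=True)
class QuantResult:
    """Final concentration in the original matrix (tissue or serum)."""

    sample_id: str
    matrix_id: str
    extract_concentration: float    # µg/ml extract
    tissue_concentration: float     # µg/mg tissue, or µg/ml for serum
    units: str
    flags: tuple[str, ...] = ()


@dataclass(frozen=True)
class InjectionPlan:
    strategy: str           # "pooled" | "tissue_specific"
    n_matrices: int
    n_levels: int
    n_replicates: int

    @property
    def total_injections(self) -> int:
        return self.n_matrices * self.n_levels * self.n_replicates


def fit_calibration(points: Sequence[CalibrationPoint], matrix_id: str = "pooled",
                    weighting: str = "ols") -> CalibrationFit:
    """Least-squares fit of response ratio on nominal concentration.

    Parameters
    ----------
    weighting
        ``"ols"`` (default, matching reported curve statistics) or ``"1/x2"``
        — inverse-squared-concentration weights, which stop the top
        calibrator of a four-decade 1:10 series from dominating the fit.
    """
    if weighting not in ("ols", "1/x2"):
        raise ValueError(f"unknown weighting {weighting!r}")
    points = list(points)
    conc = np.array([p.nominal_concentration for p in points], dtype=float)
    ratio = np.array([p.ratio for p in points], dtype=float)
    levels = np.unique(conc)
    if levels.size < 2:
        raise ValueError("calibration needs at least 2 distinct levels")

    if weighting == "ols":
        w = np.ones_like(conc)
    else:
        w = 1.0 / conc ** 2
    wsum = w.sum()
    xbar = (w * conc).sum() / wsum
    ybar = (w * ratio).sum() / wsum
    sxx = (w * (conc - xbar) ** 2).sum()
    sxy = (w * (conc - xbar) * (ratio - ybar)).sum()
    slope = sxy / sxx
    intercept = ybar - slope * xbar

    predicted = slope * conc + intercept
    ss_res = ((ratio - predicted) ** 2).sum()
    ss_tot = ((ratio - ratio.mean()) ** 2).sum()
    r_squared = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    pearson_r = float(stats.pearsonr(conc, ratio).statistic)

    accuracy: dict[float, float] = {}
    rsd: dict[float, float] = {}
    for level in levels:
        back = (ratio[conc == level] - intercept) / slope
        accuracy[float(level)] = float(100.0 * back.mean() / level)
        if back.size >= 2 and back.mean() != 0:
            rsd[float(level)] = float(100.0 * back.std(ddof=1) / abs(back.mean()))
        else:
            rsd[float(level)] = float("nan")

    return CalibrationFit(matrix_id=matrix_id, slope=float(slope),
                          intercept=float(intercept), r_squared=float(r_squared),
                          pearson_r=pearson_r, levels=tuple(float(x) for x in levels),
                          level_accuracy=accuracy, level_rsd=rsd, weighting=weighting)


def quantify(ratio: float, fit: CalibrationFit) -> ExtractEstimate:
    """Back-calculate extract concentration from a response ratio.

    Out-of-range samples are flagged against the calibrator span, never
    suppressed.
    """
    if fit.slope <= 0:
        raise ValueError("calibration slope must be positive to quantify")
    conc = (ratio - fit.intercept) / fit.slope
    return ExtractEstimate(concentration=float(conc),
                           below_lowest=conc < fit.lowest_level,
                           above_highest=conc > fit.highest_level)


def to_tissue_concentration(extract_concentration: float, matrix_id: str,
                            sample_id: str = "", tissue_mass_mg: float | None = None,
                            flags: tuple[str, ...] = ()) -> QuantResult:
    """Convert extract concentration back to the original matrix.

    Tissues: µg/mg = µg/ml × 0.04 ml/mg (the fixed 40 µl/mg extraction
    volume makes the conversion mass-independent).  Serum: µg/ml = extract
    µg/ml × 15 (the 1:15 dilution at extraction).
    """
    if not matrix_id:
        raise ValueError("matrix_id must be a tissue name or 'serum'")
    if matrix_id == "serum":
        value = extract_concentration * SERUM_DILUTION_FACTOR
        units = "ug/ml serum"
    else:
        value = extract_concentration * EXTRACTION_ML_PER_MG
        units = "ug/mg tissue"
    return QuantResult(sample_id=sample_id, matrix_id=matrix_id,
                       extract_concentration=float(extract_concentration),
                       tissue_concentration=float(value), units=units, flags=flags)


def plan_injections(strategy: str, n_matrices: int = 1, n_levels: int = 5,
                    n_replicates: int = 3) -> InjectionPlan:
    """Injection count for a calibration strategy (pooled forces one matrix)."""
    if strategy not in ("pooled", "tissue_specific"):
        raise ValueError(f"unknown strategy {strategy!r}")
    if min(n_matrices, n_levels, n_replicates) <= 0:
        raise ValueError("counts must be positive")
    if strategy == "pooled":
        n_matrices = 1
    return InjectionPlan(strategy=strategy, n_matrices=n_matrices,
                         n_levels=n_levels, n_replicates=n_replicates)


def compare_calibration_strategies(samples: pd.DataFrame, pooled_fit: CalibrationFit,
                                   specific_fits: Mapping[str, CalibrationFit],
                                   ) -> pd.DataFrame:
    """Per-matrix comparison of pooled vs tissue-specific quantitation.

    ``samples`` needs columns ``matrix_id`` and ``ratio``.  For each matrix
    the same samples are quantified under both fits; the report carries the
    mean difference, a two-tailed unpaired t-test between the two estimate
    sets, and the Pearson correlation between strategies.  Identical fits
    are reported as no difference (p = 1).
    """
    rows = []
    for matrix_id, grp in samples.groupby("matrix_id"):
        if matrix_id not in specific_fits:
            raise KeyError(f"no tissue-specific fit for matrix {matrix_id!r}")
        if len(grp) < 2:
            raise ValueError(f"need >=2 samples per matrix, got {len(grp)} "
                             f"for {matrix_id!r}")
        ratios = grp["ratio"].to_numpy(float)
        pooled = np.array([quantify(r, pooled_fit).concentration for r in ratios])
        specific = np.array([quantify(r, specific_fits[matrix_id]).concentration
                             for r in ratios])
        diff = pooled - specific
        if np.allclose(diff, 0.0, atol=1e-12):
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_ind(pooled, specific)
        if np.all(pooled == pooled[0]) or np.all(specific == specific[0]):
            r = float("nan")
        else:
            r = float(stats.pearsonr(pooled, specific).statistic)
        rows.append({"matrix_id": matrix_id, "n": len(grp),
                     "mean_pooled": pooled.mean(), "mean_specific": specific.mean(),
                     "mean_difference": diff.mean(), "t_statistic": float(t),
                     "p_value": float(p), "pearson_r": r})
    return pd.DataFrame(rows)


def replicate_rsd(values: Iterable[float]) -> float:
    """Relative standard deviation in percent: 100 × sample sd / mean."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size < 2:
        raise ValueError("RSD needs at least 2 values")
    mean = arr.mean()
    if mean == 0:
        raise ValueError("RSD undefined for zero mean")
    return float(100.0 * arr.std(ddof=1) / abs(mean))


def assess_steady_state(timepoints: pd.DataFrame, reference_organ: str = "liver",
                        reference_time: float = 24.0, later_time: float = 48.0,
                        alpha: float = 0.05) -> pd.DataFrame:
    """Per-organ plateau verdict between the reference and later time points.

    ``timepoints`` needs columns ``organ``, ``time_h`` and ``value``.
    Concentrations are expressed relative to the reference organ's mean at
    the reference time, then each organ's reference vs later values are
    compared with a two-tailed unpaired t-test; an organ is at steady state
    when p > alpha.
    """
    required = {"organ", "time_h", "value"}
    if not required.issubset(timepoints.columns):
        raise ValueError(f"timepoints table needs columns {sorted(required)}")
    ref = timepoints.query("organ == @reference_organ and time_h == @reference_time")
    if ref.empty:
        raise ValueError(f"missing {reference_organ!r} data at {reference_time} h")
    ref_mean = ref["value"].mean()
    if ref_mean <= 0:
        raise ValueError("reference mean must be positive for normalization")

    rows = []
    for organ, grp in timepoints.groupby("organ"):
        at_ref = grp.loc[grp["time_h"] == reference_time, "value"].to_numpy(float)
        at_later = grp.loc[grp["time_h"] == later_time, "value"].to_numpy(float)
        if at_ref.size < 2 or at_later.size < 2:
            raise ValueError(f"organ {organ!r} needs >=2 fish at both "
                             f"{reference_time} h and {later_time} h")
        t, p = stats.ttest_ind(at_ref, at_later)
        if np.isnan(p):
            t, p = 0.0, 1.0
        rows.append({"organ": organ,
                     "relative_mean_ref": at_ref.mean() / ref_mean,
                     "relative_mean_later": at_later.mean() / ref_mean,
                     "t_statistic": float(t), "p_value": float(p),
                     "steady": bool(p > alpha)})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class OrganComparison:
    """One-way ANOVA across organs with Tukey HSD pairwise follow-up."""

    f_statistic: float
    p_value: float
    tukey: pd.DataFrame     # organ_a, organ_b, mean_difference, p_adjusted
    group_means: Mapping[str, float]


def compare_organ_concentrations(results: pd.DataFrame,
                                 value_column: str = "tissue_concentration",
                                 ) -> OrganComparison:
    """One-way ANOVA + Tukey HSD (95% family confidence) on per-organ values.

    ``results`` needs columns ``matrix_id`` (or ``organ``) and the value
    column; every organ must have at least 2 fish.
    """
    key = "organ" if "organ" in results.columns else "matrix_id"
    groups = {organ: grp[value_column].to_numpy(float)
              for organ, grp in results.groupby(key)}
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least 2 organs")
    for organ, vals in groups.items():
        if vals.size < 2:
            raise ValueError(f"organ {organ!r} has fewer than 2 fish")
    names = sorted(groups)
    arrays = [groups[n] for n in names]
    f, p = stats.f_oneway(*arrays)
    hsd = stats.tukey_hsd(*arrays)
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            rows.append({"organ_a": names[i], "organ_b": names[j],
                         "mean_difference": arrays[i].mean() - arrays[j].mean(),
                         "p_adjusted": float(hsd.pvalue[i, j])})
    return OrganComparison(f_statistic=float(f), p_value=float(p),
                           tukey=pd.DataFrame(rows),
                           group_means={n: float(groups[n].mean()) for n in names})
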