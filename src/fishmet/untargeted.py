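"""Untargeted feature filtering, annotation and differential analysis.

The fixed pipeline order is: blank filter → degeneracy collapse → annotate
→ differential statistics.  Blank filtering removes background ions present
in solvent blanks; degeneracy collapsing groups isotope/adduct satellites
of the same parent (matching mass shift, co-elution and intensity
correlation) so each physiological metabolite is counted once; annotation
assigns level-1 identities by accurate mass (≤10 ppm) and retention time;
differential analysis reports per-organ two-group t-tests with both raw and
Benjamini-Hochberg-adjusted p-values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

#: common degeneracy mass shifts relative to the parent ion (Da)
DEFAULT_SHIFT_TABLE: dict[str, float] = {
    "isotope_13C": 1.00336,
    "sodium_adduct": 21.98194,     # Na - H
    "potassium_adduct": 37.95588,  # K - H
    "ammonium_adduct": 17.02655,
}
DEFAULT_BLANK_RATIO: float = 3.0
DEFAULT_RT_WINDOW_MIN: float = 0.2
DEFAULT_CORR_THRESHOLD: float = 0.8
DEFAULT_PPM_TOLERANCE: float = 10.0
SHIFT_PPM_TOLERANCE: float = 5.0


@dataclass(frozen=True)
class AnnotationRecord:
    """Level-1 metabolite identity for a feature (mass + RT matched)."""

    feature_id: str
    metabolite: str
    reference_mz: float
    reference_rt: float
    mz_error_ppm: float
    rt_error_min: float
    confidence_level: int = 1


def blank_filter(features: pd.DataFrame, sample_columns: Sequence[str],
                 blank_columns: Sequence[str],
                 ratio_threshold: float = DEFAULT_BLANK_RATIO,
                 ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split features into retained and background by sample/blank ratio.

    A feature is retained iff mean(samples) / mean(blanks) >= threshold; a
    zero blank mean always retains.  Returns (retained, background) frames;
    the background frame carries a ``label`` column.
    """
    if len(blank_columns) == 0:
        raise ValueError("blank filtering needs at least one blank sample")
    sample_mean = features[list(sample_columns)].mean(axis=1)
    blank_mean = features[list(blank_columns)].mean(axis=1)
    keep = (blank_mean <= 0) | (sample_mean / blank_mean.replace(0, np.nan)
                                >= ratio_threshold).fillna(True)
    retained = features[keep].copy()
    background = features[~keep].copy()
    background["label"] = "background"
    return retained, background


def _match_shift(delta_mz: float, parent_mz: float,
                 shift_table: Mapping[str, float]) -> str | None:
    tol = parent_mz * SHIFT_PPM_TOLERANCE * 1e-6
    for name, shift in shift_table.items():
        if abs(delta_mz - shift) <= tol:
            return name
    return None


def collapse_degeneracies(features: pd.DataFrame, sample_columns: Sequence[str],
                          shift_table: Mapping[str, float] = DEFAULT_SHIFT_TABLE,
                          rt_window: float = DEFAULT_RT_WINDOW_MIN,
                          corr_threshold: float = DEFAULT_CORR_THRESHOLD,
                          ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Group adduct/isotope satellites with their parents; keep one representative.

    Two features are linked when their m/z difference matches a shift-table
    entry within 5 ppm, they co-elute within ``rt_window`` minutes, and
    their per-sample intensities correlate at ``corr_threshold`` or better.
    Links are merged transitively; the most intense member represents each
    group.

    Returns (representatives, groups) where ``groups`` maps every feature to
    its ``group_id``, ``representative`` flag and matched shift name.
    """
    if len(sample_columns) < 3:
        raise ValueError("intensity correlation needs at least 3 samples")
    df = features.reset_index(drop=True)
    n = len(df)
    parent = np.arange(n)

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        parent[find(i)] = find(j)

    mz = df["mz"].to_numpy(float)
    rt = df["rt"].to_numpy(float)
    intens = df[list(sample_columns)].to_numpy(float)
    order = np.argsort(mz)
    max_shift = max(shift_table.values()) + 1.0
    shift_names: dict[int, str] = {}
    for a_pos, i in enumerate(order):
        for j in order[a_pos + 1:]:
            delta = mz[j] - mz[i]
            if delta > max_shift:
                break
            if abs(rt[j] - rt[i]) > rt_window:
                continue
            name = _match_shift(delta, mz[i], shift_table)
            if name is None:
                continue
            xi, xj = intens[i], intens[j]
            if np.std(xi) == 0 or np.std(xj) == 0:
                continue
            r = np.corrcoef(xi, xj)[0, 1]
            if r >= corr_threshold:
                union(j, i)
                shift_names[j] = name

    group_id = np.array([find(i) for i in range(n)])
    mean_intensity = intens.mean(axis=1)
    groups = df[["id"]].copy() if "id" in df.columns else pd.DataFrame(
        {"id": df.index.astype(str)})
    groups["group_id"] = group_id
    groups["mean_intensity"] = mean_intensity
    groups["shift"] = [shift_names.get(i, "") for i in range(n)]
    rep_idx = groups.groupby("group_id")["mean_intensity"].idxmax()
    groups["representative"] = groups.index.isin(rep_idx)
    representatives = df.loc[sorted(rep_idx)].copy()
    return representatives, groups


def annotate_features(features: pd.DataFrame, library: pd.DataFrame,
                      ppm_tolerance: float = DEFAULT_PPM_TOLERANCE,
                      rt_window: float = DEFAULT_RT_WINDOW_MIN,
                      ) -> list[AnnotationRecord]:
    """Level-1 annotation: accurate mass within ppm tolerance and matching RT.

    The nearest-mass library candidate wins ties; unmatched features are
    simply absent from the result.
    """
    if library.empty:
        raise ValueError("annotation library is empty")
    records: list[AnnotationRecord] = []
    lib_mz = library["mz"].to_numpy(float)
    lib_rt = library["rt"].to_numpy(float)
    for _, feat in features.iterrows():
        ppm_err = np.abs(feat["mz"] - lib_mz) / lib_mz * 1e6
        rt_err = np.abs(feat["rt"] - lib_rt)
        ok = (ppm_err <= ppm_tolerance) & (rt_err <= rt_window)
        if not ok.any():
            continue
        best = int(np.where(ok, ppm_err, np.inf).argmin())
        records.append(AnnotationRecord(
            feature_id=str(feat["id"]), metabolite=str(library["name"].iloc[best]),
            reference_mz=float(lib_mz[best]), reference_rt=float(lib_rt[best]),
            mz_error_ppm=float(ppm_err[best]), rt_error_min=float(rt_err[best])))
    return records


def differential_analysis(features: pd.DataFrame, control_columns: Sequence[str],
                          treated_columns: Sequence[str], organ: str = "",
                          welch: bool = False, alpha: float = 0.05,
                          ) -> pd.DataFrame:
    """Per-feature two-group comparison: t-test, log2 fold change, BH adjustment.

    The default is the classic equal-variance Student's t-test (two-tailed,
    unpaired); Welch's correction is available by flag.  Both the raw
    p-value (used for the per-organ significant count) and the
    Benjamini-Hochberg-adjusted p-value are reported.
    """
    if len(control_columns) < 2 or len(treated_columns) < 2:
        raise ValueError("need at least 2 samples per group")
    ctrl = features[list(control_columns)].to_numpy(float)
    trt = features[list(treated_columns)].to_numpy(float)
    t, p = stats.ttest_ind(trt, ctrl, axis=1, equal_var=not welch)
    p = np.where(np.isnan(p), 1.0, p)         # zero-variance equal means
    t = np.where(np.isnan(t), 0.0, t)
    mean_c = ctrl.mean(axis=1)
    mean_t = trt.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        log2fc = np.log2(np.where(mean_c > 0, mean_t / mean_c, np.nan))
    p_adj = multipletests(p, method="fdr_bh")[1]
    out = pd.DataFrame({
        "organ": organ,
        "id": features["id"].to_numpy() if "id" in features.columns
        else features.index.astype(str),
        "mean_control": mean_c, "mean_treated": mean_t,
        "log2_fold_change": log2fc,
        "t_statistic": t, "p_value": p, "p_adjusted": p_adj,
    })
    out["direction"] = np.where(out["log2_fold_change"] > 0, "up",
                                np.where(out["log2_fold_change"] < 0, "down", "none"))
    out["significant_raw"] = out["p_value"] < alpha
    out["significant_bh"] = out["p_adjusted"] < alpha
    return out


def significant_counts(results_by_organ: Mapping[str, pd.DataFrame],
                       adjusted: bool = False) -> pd.DataFrame:
    """Per-organ count of significant features (the altered-metabolite histogram)."""
    col = "significant_bh" if adjusted else "significant_raw"
    rows = [{"organ": organ, "n_significant": int(df[col].sum()),
             "n_tested": len(df)} for organ, df in results_by_organ.items()]
    return pd.DataFrame(rows).sort_values("n_significant", ascending=False,
                                          ignore_index=True)


def fold_change_heatmap(results: pd.DataFrame, metabolites: Sequence[str] | None = None,
                        adjusted: bool = False) -> pd.DataFrame:
    """Organ × metabolite matrix of log2 fold changes, masked to significant cells.

    ``results`` is the concatenated differential table (one row per feature
    per organ, with a ``metabolite`` or ``id`` label).  Non-significant
    cells are NaN.
    """
    label = "metabolite" if "metabolite" in results.columns else "id"
    col = "significant_bh" if adjusted else "significant_raw"
    df = results if metabolites is None else results[results[label].isin(metabolites)]
    masked = df.assign(value=np.where(df[col], df["log2_fold_change"], np.nan))
    return masked.pivot_table(index="organ", columns=label, values="value",
                              dropna=False)


def grubbs_critical_value(n: int, alpha: float = 0.05) -> float:
    """Two-sided Grubbs critical value from Student-t quantiles."""
    t_crit = stats.t.ppf(1.0 - alpha / (2.0 * n), n - 2)
    return (n - 1) / np.sqrt(n) * np.sqrt(t_crit ** 2 / (n - 2 + t_crit ** 2))


def grubbs_outliers(values: Sequence[float], alpha: float = 0.05) -> list[int]:
    """Iterative two-sided Grubbs' test; returns indices of flagged outliers.

    The most extreme point is tested against the critical value at ``alpha``
    and, if flagged, removed; the test repeats on the remainder until no
    point is flagged or fewer than 3 remain.  Zero-variance input warns and
    flags nothing.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 3:
        raise ValueError("Grubbs' test needs at least 3 values")
    if np.ptp(arr) == 0:
        warnings.warn("zero variance: Grubbs' test cannot flag outliers",
                      stacklevel=2)
        return []
    active = list(range(arr.size))
    flagged: list[int] = []
    while len(active) >= 3:
        sub = arr[active]
        sd = sub.std(ddof=1)
        if sd == 0:
            break
        g = np.abs(sub - sub.mean()) / sd
        i_max = int(g.argmax())
        if g[i_max] > grubbs_critical_value(len(active), alpha):
            flagged.append(active.pop(i_max))
        else:
            break
    return sorted(flagged)
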