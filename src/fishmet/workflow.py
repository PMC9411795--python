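"""End-to-end study orchestration on synthetic (or user-supplied) data.

``run_study`` executes simulate → quantitation → tracing → imaging →
untargeted on one configuration and writes a reproducible bundle: tab
separated result tables, exported images, and a machine-readable
``summary.json`` that is byte-identical under a fixed seed.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import imaging, quantitation, synthetic, tracing, untargeted

ALL_STAGES: tuple[str, ...] = ("quant", "trace", "image", "untargeted")


@dataclass
class RunConfig:
    generator: synthetic.GeneratorConfig = field(
        default_factory=synthetic.GeneratorConfig)
    outdir: str = "fishmet_run"
    stages: tuple[str, ...] = ALL_STAGES

    def __post_init__(self) -> None:
        self.stages = tuple(self.stages)
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")


@dataclass
class StudyBundle:
    outdir: Path
    summary: dict

    @property
    def summary_path(self) -> Path:
        return self.outdir / "summary.json"


def _config_hash(config: synthetic.GeneratorConfig) -> str:
    blob = json.dumps(
        {k: (list(v) if isinstance(v, tuple) else v)
         for k, v in sorted(vars(config).items())},
        sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.8g")


def _stage_quant(config: synthetic.GeneratorConfig, outdir: Path, log: list) -> dict:
    pooled_table, _ = synthetic.generate_calibration_series(config, "pooled")
    serum_table, _ = synthetic.generate_calibration_series(config, "serum")

    def _fit(table: pd.DataFrame, matrix_id: str) -> quantitation.CalibrationFit:
        points = [quantitation.CalibrationPoint(r.nominal_concentration,
                                                r.analyte_area, r.istd_area,
                                                int(r.replicate))
                  for r in table.itertuples()]
        # 1/x^2 weighting: the 1:10 series spans four decades and an
        # unweighted fit would let the 100 µg/ml level set the intercept
        return quantitation.fit_calibration(points, matrix_id=matrix_id,
                                            weighting="1/x2")

    pooled_fit = _fit(pooled_table, "pooled")
    serum_fit = _fit(serum_table, "serum")
    specific_fits = {organ: _fit(synthetic.generate_calibration_series(config, organ)[0],
                                 organ)
                     for organ in config.tissue_organs}

    samples, truth = synthetic.generate_biodistribution_samples(config)
    log.append(f"quant: {len(samples)} biodistribution samples in, "
               f"{len(specific_fits) + 2} curves fitted")
    rows = []
    for rec in samples.itertuples():
        fit = serum_fit if rec.matrix_id == "serum" else pooled_fit
        est = quantitation.quantify(rec.analyte_area / rec.istd_area, fit)
        qr = quantitation.to_tissue_concentration(
            est.concentration, rec.matrix_id, sample_id=rec.sample_id,
            tissue_mass_mg=None if np.isnan(rec.tissue_mass_mg)
            else rec.tissue_mass_mg, flags=est.flags)
        rows.append({"sample_id": qr.sample_id, "organ": qr.matrix_id,
                     "extract_concentration": qr.extract_concentration,
                     "tissue_concentration": qr.tissue_concentration,
                     "units": qr.units, "flags": ";".join(qr.flags)})
    quant_df = pd.DataFrame(rows)
    _write_tsv(quant_df, outdir / "quant_results.tsv")

    tissue_df = quant_df[quant_df["organ"] != "serum"]
    comparison = quantitation.compare_organ_concentrations(tissue_df)
    _write_tsv(comparison.tukey, outdir / "organ_tukey.tsv")

    ratio_samples = samples[samples["matrix_id"] != "serum"].assign(
        ratio=lambda d: d["analyte_area"] / d["istd_area"])
    strategy = quantitation.compare_calibration_strategies(
        ratio_samples[["matrix_id", "ratio"]], pooled_fit, specific_fits)
    _write_tsv(strategy, outdir / "strategy_comparison.tsv")

    organ_means = {o: round(float(g["tissue_concentration"].mean()), 10)
                   for o, g in quant_df.groupby("organ")}
    return {
        "n_samples": int(len(samples)),
        "pooled_r_squared": round(pooled_fit.r_squared, 6),
        "serum_r_squared": round(serum_fit.r_squared, 6),
        "organ_mean_concentration": organ_means,
        "anova_p_value": float(comparison.p_value),
        "strategy_min_p": float(strategy["p_value"].min()),
        "injections": {
            "tissue_specific": quantitation.plan_injections(
                "tissue_specific", n_matrices=7).total_injections,
            "pooled": quantitation.plan_injections("pooled").total_injections,
        },
    }


def _stage_trace(config: synthetic.GeneratorConfig, outdir: Path, log: list) -> dict:
    raw, truth = synthetic.generate_tracing_dataset(config)
    log.append(f"trace: {len(raw)} isotopologue intensities in")
    labeling_frames = []
    corrected_by_group: dict[str, dict[str, list[np.ndarray]]] = {}
    for (group, fish), sub in raw.groupby(["group", "fish"]):
        mids: dict[str, tracing.MID] = {}
        for metabolite, m_sub in sub.groupby("metabolite"):
            m_sub = m_sub.sort_values("isotopologue")
            n = int(m_sub["n_carbons"].iloc[0])
            mid, _res = tracing.correct_mid(m_sub["intensity"].to_numpy(), n,
                                            config.natural_abundance,
                                            metabolite=metabolite)
            mids[metabolite] = mid
            corrected_by_group.setdefault(group, {}).setdefault(
                metabolite, []).append(mid.fractions)
        serum = mids["glucose_serum"]
        for name in ("naa_brain", "aspartate_brain"):
            labeling_frames.append(tracing.labeling_table(
                mids[name], serum, group=group, fish=fish))
    labeling = pd.concat(labeling_frames, ignore_index=True)
    _write_tsv(labeling, outdir / "labeling_results.tsv")

    route_rows = []
    inferred: dict[str, float] = {}
    for group, mets in sorted(corrected_by_group.items()):
        naa = tracing.MID("naa", np.mean(mets["naa_brain"], axis=0)
                          / np.mean(mets["naa_brain"], axis=0).sum())
        asp = tracing.MID("aspartate", np.mean(mets["aspartate_brain"], axis=0)
                          / np.mean(mets["aspartate_brain"], axis=0).sum())
        rf, diag = tracing.infer_route_fractions(naa, asp)
        inferred[group] = rf.asp_m3
        route_rows.append({"group": group, "acetyl_labeled": rf.acetyl_labeled,
                           "asp_m1": rf.asp_m1, "asp_m2": rf.asp_m2,
                           "asp_m3": rf.asp_m3, "residual": diag["residual"]})
    _write_tsv(pd.DataFrame(route_rows), outdir / "route_fractions.tsv")

    naa = labeling[labeling["metabolite"] == "naa_brain"]
    groups = sorted(config.n_fish_tracing)
    m3 = tracing.compare_isotopologues(
        naa[naa["group"] == groups[0]], naa[naa["group"] == groups[1]],
        isotopologue=3)
    return {
        "inferred_pc_route": {g: round(v, 6) for g, v in inferred.items()},
        "naa_m3_p_value": m3.p_value,
        "naa_m3_direction": m3.direction,
        "n_fish": dict(sorted(config.n_fish_tracing.items())),
    }


def _stage_image(config: synthetic.GeneratorConfig, outdir: Path, log: list) -> dict:
    grid, truth = synthetic.generate_desi_grid(config)
    log.append(f"image: grid {grid.shape[0]}x{grid.shape[1]}, "
               f"{grid.mzs.size} channels")
    normalized, zero_tic = imaging.tic_normalize(grid)
    drug_mz = truth.channel_mzs["hcq"]
    raw_img = imaging.extract_ion_image(grid, drug_mz)
    norm_img = imaging.extract_ion_image(normalized, drug_mz)
    masks = {o: m for o, m in truth.organ_masks.items() if o != "swim_bladder"}
    stats_raw = imaging.roi_statistics(raw_img, masks)
    stats_norm = imaging.roi_statistics(norm_img, masks)
    stats_raw["channel"] = "raw"
    stats_norm["channel"] = "tic_normalized"
    rankings = pd.concat([stats_raw, stats_norm], ignore_index=True)
    _write_tsv(rankings, outdir / "roi_rankings.tsv")
    imaging.write_grid_tsv(grid, outdir / "desi_grid.tsv")
    imaging.export_png(raw_img, outdir / "drug_channel.png")
    imaging.export_image_tsv(raw_img, outdir / "drug_channel.tsv")
    return {
        "zero_tic_pixels": int(zero_tic.sum()),
        "roi_rank_raw": stats_raw.sort_values("rank")["organ"].tolist(),
        "roi_rank_normalized": stats_norm.sort_values("rank")["organ"].tolist(),
    }


def _stage_untargeted(config: synthetic.GeneratorConfig, outdir: Path,
                      log: list) -> dict:
    tables, truth = synthetic.generate_feature_tables(config)
    ctrl_cols, trt_cols, blank_cols = synthetic.feature_sample_columns(config)
    results = {}
    funnel = []
    for organ, table in tables.items():
        retained, background = untargeted.blank_filter(
            table, ctrl_cols + trt_cols, blank_cols)
        reps, groups = untargeted.collapse_degeneracies(
            retained, ctrl_cols + trt_cols)
        results[organ] = untargeted.differential_analysis(
            reps, ctrl_cols, trt_cols, organ=organ)
        funnel.append(f"untargeted[{organ}]: {len(table)} in, "
                      f"{len(background)} background removed, "
                      f"{len(retained) - len(reps)} degeneracies collapsed, "
                      f"{len(reps)} unique features tested")
    log.extend(funnel)
    counts = untargeted.significant_counts(results)
    _write_tsv(counts, outdir / "significant_counts.tsv")
    all_results = pd.concat(results.values(), ignore_index=True)
    _write_tsv(all_results, outdir / "differential_results.tsv")

    sig = all_results[all_results["significant_raw"]]
    top = (sig.reindex(sig["log2_fold_change"].abs()
                       .sort_values(ascending=False).index)
           ["id"].drop_duplicates().head(15).tolist())
    heatmap = untargeted.fold_change_heatmap(all_results, top)
    heatmap.to_csv(outdir / "heatmap_matrix.tsv", sep="\t", float_format="%.6g")

    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    fig, ax = plt.subplots(figsize=(6, 3.5))
    ax.bar(counts["organ"], counts["n_significant"], color="#444444")
    ax.set_ylabel("significant features (raw p < 0.05)")
    ax.tick_params(axis="x", rotation=45)
    fig.tight_layout()
    fig.savefig(outdir / "significant_counts.png", dpi=120)
    plt.close(fig)

    return {"significant_counts": {r.organ: int(r.n_significant)
                                   for r in counts.itertuples()}}


def run_study(run_config: RunConfig) -> StudyBundle:
    """Execute the configured stages and write the report bundle.

    Any stage failure aborts with a stage-tagged error; outputs of a fixed
    seed and config are deterministic, including ``summary.json`` bytes.
    """
    config = run_config.generator
    outdir = Path(run_config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")

    log: list[str] = []
    summary: dict = {
        "software": {"name": "fishmet", "version": __version__},
        "seed": config.seed,
        "config_hash": _config_hash(config),
        "stages": {},
    }
    stage_fns = {"quant": _stage_quant, "trace": _stage_trace,
                 "image": _stage_image, "untargeted": _stage_untargeted}
    for stage in run_config.stages:
        try:
            summary["stages"][stage] = stage_fns[stage](config, outdir, log)
        except Exception as exc:   # noqa: BLE001 - re-tag with the stage name
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
    summary["log"] = log

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, sort_keys=True, indent=2)
        fh.write("\n")
    return StudyBundle(outdir=outdir, summary=summary)


def render_report(bundle: StudyBundle | str | os.PathLike) -> Path:
    """Render a human-readable markdown report from a bundle directory.

    The report is regenerated purely from ``summary.json`` and the files on
    disk, so it can be rebuilt from the bundle alone.
    """
    outdir = bundle.outdir if isinstance(bundle, StudyBundle) else Path(bundle)
    summary_path = outdir / "summary.json"
    if not summary_path.exists():
        raise FileNotFoundError(f"incomplete bundle: {summary_path} missing")
    summary = json.loads(summary_path.read_text())
    stages = summary.get("stages", {})

    lines = ["# fishmet study report", "",
             f"- software: fishmet {summary['software']['version']}",
             f"- seed: {summary['seed']}",
             f"- config hash: {summary['config_hash']}", ""]

    if "quant" in stages:
        q = stages["quant"]
        lines += ["## Absolute quantitation", "",
                  f"Calibration R² (pooled): {q['pooled_r_squared']}, "
                  f"(serum): {q['serum_r_squared']}.",
                  f"Injection counts: tissue-specific "
                  f"{q['injections']['tissue_specific']}, pooled "
                  f"{q['injections']['pooled']}.",
                  "", "| organ | mean concentration |", "| --- | --- |"]
        lines += [f"| {o} | {v:.4g} |"
                  for o, v in sorted(q["organ_mean_concentration"].items())]
        lines += ["", f"One-way ANOVA p = {q['anova_p_value']:.3g}; pooled vs "
                  f"tissue-specific minimum p = {q['strategy_min_p']:.3g}.", ""]
    if "trace" in stages:
        t = stages["trace"]
        lines += ["## Isotope tracing", "",
                  f"Inferred PC-route (aspartate M+3) fraction: "
                  + ", ".join(f"{g} = {v}" for g, v in
                              sorted(t["inferred_pc_route"].items())) + ".",
                  f"NAA M+3 fractional labeling comparison: p = "
                  f"{t['naa_m3_p_value']:.3g} ({t['naa_m3_direction']} in the "
                  "treated group).", ""]
    if "image" in stages:
        im = stages["image"]
        lines += ["## Whole-body imaging", "",
                  f"Zero-TIC (void) pixels: {im['zero_tic_pixels']}.",
                  "Drug-channel ROI ranking (TIC-normalized): "
                  + " > ".join(im["roi_rank_normalized"]) + ".", ""]
        for fig in ("drug_channel.png",):
            if (outdir / fig).exists():
                lines.append(f"![drug channel]({fig})")
        lines.append("")
    if "untargeted" in stages:
        u = stages["untargeted"]
        lines += ["## Untargeted differential analysis", "",
                  "| organ | significant features |", "| --- | --- |"]
        lines += [f"| {o} | {n} |"
                  for o, n in sorted(u["significant_counts"].items(),
                                     key=lambda kv: -kv[1])]
        if (outdir / "significant_counts.png").exists():
            lines += ["", "![significant counts](significant_counts.png)"]
        lines.append("")

    referenced = [ln.split("(")[-1].rstrip(")") for ln in lines
                  if ln.startswith("![")]
    for fig in referenced:
        if not (outdir / fig).exists():
            raise FileNotFoundError(f"report references missing figure {fig}")

    report_path = outdir / "report.md"
    report_path.write_text("\n".join(lines))
    return report_path
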