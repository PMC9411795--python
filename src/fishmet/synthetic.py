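"""Synthetic-data generator emulating an adult-zebrafish HCQ study.

Every input the pipeline consumes can be generated here with known ground
truth: internal-standard calibration series, organ biodistribution peak
areas, ¹³C₆-glucose tracing isotopologue intensities, whole-body DESI
pixel grids with organ masks, pooled-QC replicate panels, and untargeted
feature tables with blanks, contaminants and adduct/isotope degeneracies.

The defaults encode the study conditions: 8 organs + serum per fish, a
control and a 1 mM HCQ group, liver/intestine drug accumulation at 4× the
other organs, a five-level 1:10 calibration series from 0.01 to 100 µg/ml,
the 40 µl/mg extraction rule, and a three-route NAA labeling model whose
pyruvate-carboxylase route is raised in the treated group.  Noise is
multiplicative log-normal (mean 1) with a configurable CV: mass-spec peak
areas are positive with roughly proportional error.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .imaging import IonImageGrid
from .tracing import (MID, N_CARBON, P_C13, RouteFractions,
                      aspartate_mid_from_routes, convolve_natural_abundance,
                      simulate_naa_mid)

TISSUE_ORGANS: tuple[str, ...] = ("brain", "eye", "fin", "heart", "intestine",
                                  "kidney", "liver", "muscle")
DEFAULT_ORGANS: tuple[str, ...] = TISSUE_ORGANS + ("serum",)

#: five-level 1:10 calibration series, 10 ng/ml to 100 µg/ml in extract
CALIBRATION_LEVELS_UG_ML: tuple[float, ...] = (100.0, 10.0, 1.0, 0.1, 0.01)
ISTD_CONCENTRATION_UG_ML: float = 1.0
AREA_PER_UG_ML: float = 1.0e5        # detector response per (µg/ml) at unit suppression

#: m/z channels for the DESI grid: drug, two drug metabolites, one endogenous
DESI_CHANNELS: dict[str, float] = {
    "hcq": 334.1797,                  # hydroxychloroquine [M-H]-
    "desethylhydroxychloroquine": 306.1484,
    "desethylchloroquine": 290.1535,
    "endogenous": 124.0074,           # taurine [M-H]-, body-wide signal
}

_DEF_SUPPRESSION = {
    "brain": 0.95, "eye": 1.05, "fin": 0.85, "heart": 1.10, "intestine": 0.90,
    "kidney": 1.15, "liver": 0.80, "muscle": 1.20, "serum": 1.00,
}
# liver = intestine = 4× every other organ (µg/ml in extract)
_DEF_BIODISTRIBUTION = {
    "brain": 1.0, "eye": 1.0, "fin": 1.0, "heart": 1.0, "intestine": 4.0,
    "kidney": 1.0, "liver": 4.0, "muscle": 1.0, "serum": 1.0,
}
_DEF_ROUTES = {
    "control": RouteFractions(acetyl_labeled=0.15, asp_m1=0.05,
                              asp_m2=0.12, asp_m3=0.10),
    "hcq": RouteFractions(acetyl_labeled=0.15, asp_m1=0.05,
                          asp_m2=0.12, asp_m3=0.15),
}
# Fig.-3B-style qualitative ranking of per-organ metabolic alterations;
# free parameters of the generator (the study prints no counts per organ)
_DEF_PERTURBED = {
    "brain": 12, "eye": 10, "fin": 10, "heart": 15, "intestine": 40,
    "kidney": 20, "liver": 8, "muscle": 30,
}

# schematic whole-body layout: (row_center, col_center, row_radius,
# col_radius) as fractions of the grid; not anatomically fitted
ORGAN_LAYOUT: dict[str, tuple[float, float, float, float]] = {
    "eye": (0.38, 0.06, 0.07, 0.025),
    "brain": (0.32, 0.14, 0.09, 0.05),
    "heart": (0.58, 0.28, 0.08, 0.04),
    "liver": (0.62, 0.40, 0.11, 0.07),
    "kidney": (0.32, 0.50, 0.06, 0.12),
    "swim_bladder": (0.50, 0.52, 0.08, 0.07),
    "intestine": (0.72, 0.55, 0.09, 0.11),
    "muscle": (0.32, 0.75, 0.11, 0.09),
    "fin": (0.50, 0.93, 0.12, 0.04),
}
BODY_ELLIPSE: tuple[float, float, float, float] = (0.5, 0.5, 0.42, 0.47)


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic study; identical config ⇒ identical outputs."""

    seed: int = 0
    n_fish_per_group: int = 8
    organs: tuple[str, ...] = DEFAULT_ORGANS
    noise_cv: float = 0.05
    suppression_factors: dict[str, float] = field(
        default_factory=lambda: dict(_DEF_SUPPRESSION))
    biodistribution: dict[str, float] = field(
        default_factory=lambda: dict(_DEF_BIODISTRIBUTION))
    tracer_enrichment: float = 0.4       # serum glucose M+6 fraction
    route_fractions_by_group: dict[str, RouteFractions] = field(
        default_factory=lambda: dict(_DEF_ROUTES))
    n_fish_tracing: dict[str, int] = field(
        default_factory=lambda: {"control": 6, "hcq": 9})
    natural_abundance: float = P_C13
    pixel_pitch_um: float = 150.0
    grid_dims: tuple[int, int] = (40, 80)
    organ_layout: dict[str, tuple[float, float, float, float]] = field(
        default_factory=lambda: dict(ORGAN_LAYOUT))
    # untargeted feature generation
    n_endogenous_features: int = 120
    n_contaminant_features: int = 30
    perturbed_counts: dict[str, int] = field(
        default_factory=lambda: dict(_DEF_PERTURBED))
    perturbed_effect: float = 2.0
    feature_noise_cv: float = 0.2
    n_control_fish_features: int = 6
    n_treated_fish_features: int = 8
    satellite_probability: float = 0.3

    def __post_init__(self) -> None:
        self.organs = tuple(self.organs)
        self.grid_dims = tuple(self.grid_dims)
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if not 0.0 <= self.tracer_enrichment <= 1.0:
            raise ValueError("tracer_enrichment must be in [0, 1]")
        for organ in self.organs:
            if self.suppression_factors.get(organ, 0) <= 0:
                raise ValueError(f"suppression factor for {organ!r} must be > 0")
            if self.biodistribution.get(organ, -1) < 0:
                raise ValueError(f"biodistribution for {organ!r} must be >= 0")
        for group, rf in self.route_fractions_by_group.items():
            if not isinstance(rf, RouteFractions):
                self.route_fractions_by_group[group] = RouteFractions(**rf)
        if min(self.grid_dims) < 4:
            raise ValueError("grid must be at least 4x4 pixels")

    @property
    def tissue_organs(self) -> tuple[str, ...]:
        return tuple(o for o in self.organs if o != "serum")

    def pooled_suppression(self) -> float:
        """Pooled-tissue matrix: equal-parts mixture, mean of tissue factors."""
        return float(np.mean([self.suppression_factors[o]
                              for o in self.tissue_organs]))

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["route_fractions_by_group"] = {
            g: {"acetyl_labeled": rf.acetyl_labeled, "asp_m1": rf.asp_m1,
                "asp_m2": rf.asp_m2, "asp_m3": rf.asp_m3}
            for g, rf in self.route_fractions_by_group.items()}
        data["organs"] = list(self.organs)
        data["grid_dims"] = list(self.grid_dims)
        data["organ_layout"] = {k: list(v) for k, v in self.organ_layout.items()}
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if "organ_layout" in data:
            data["organ_layout"] = {k: tuple(v)
                                    for k, v in data["organ_layout"].items()}
        return cls(**data)


@dataclass
class GroundTruth:
    """Traceable truth behind one generated dataset."""

    true_concentrations: pd.DataFrame | None = None    # per sample
    route_fractions: dict[str, RouteFractions] | None = None
    true_mids: pd.DataFrame | None = None              # metabolite MIDs per group
    organ_masks: dict[str, np.ndarray] | None = None
    channel_mzs: dict[str, float] | None = None
    perturbed_features: dict[str, set[str]] | None = None
    contaminant_features: dict[str, set[str]] | None = None
    degeneracy_map: dict[str, str] | None = None       # satellite id -> parent id


def _rng(config: GeneratorConfig, stage: str) -> np.random.Generator:
    """Independent, reproducible stream per generator stage."""
    return np.random.default_rng([config.seed, zlib.crc32(stage.encode())])


def _lognormal_noise(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Multiplicative noise factors with mean 1 and the given CV."""
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv ** 2))
    return rng.lognormal(mean=-sigma ** 2 / 2.0, sigma=sigma, size=size)


# ---------------------------------------------------------------- calibration

def generate_calibration_series(config: GeneratorConfig, matrix_id: str,
                                ) -> tuple[pd.DataFrame, GroundTruth]:
    """Five-level 1:10 calibration series (triplicate) in one matrix.

    ``matrix_id`` is ``"pooled"``, ``"serum"`` or an organ name.  Analyte
    area = level × suppression × noise; internal-standard area = the 1 µg/ml
    response × suppression × noise, so the true response-ratio slope is 1
    per (µg/ml) in every matrix.
    """
    if matrix_id == "pooled":
        supp = config.pooled_suppression()
    elif matrix_id in config.organs:
        supp = config.suppression_factors[matrix_id]
    else:
        raise ValueError(f"unknown matrix {matrix_id!r}")
    rng = _rng(config, f"calibration:{matrix_id}")
    rows = []
    for level in CALIBRATION_LEVELS_UG_ML:
        for rep in range(3):
            noise_a, noise_i = _lognormal_noise(rng, config.noise_cv, 2)
            rows.append({
                "matrix_id": matrix_id, "nominal_concentration": level,
                "replicate": rep,
                "analyte_area": AREA_PER_UG_ML * level * supp * noise_a,
                "istd_area": AREA_PER_UG_ML * ISTD_CONCENTRATION_UG_ML
                * supp * noise_i,
            })
    table = pd.DataFrame(rows)
    truth = GroundTruth(true_concentrations=pd.DataFrame({
        "matrix_id": matrix_id,
        "nominal_concentration": list(CALIBRATION_LEVELS_UG_ML),
        "true_ratio_slope": 1.0 / ISTD_CONCENTRATION_UG_ML}))
    return table, truth


# ------------------------------------------------------------- biodistribution

def generate_biodistribution_samples(config: GeneratorConfig,
                                     ) -> tuple[pd.DataFrame, GroundTruth]:
    """Peak-area table for drug-treated fish: one analyte/IS pair per organ per fish.

    Tissue masses (uniform 2–20 mg) and the fixed 40 µl/mg extraction rule
    are emitted so unit conversion is exercised downstream; serum rows carry
    no mass (converted by its 1:15 dilution instead).
    """
    rng = _rng(config, "biodistribution")
    rows, truth_rows = [], []
    for fish in range(config.n_fish_per_group):
        for organ in config.organs:
            conc = config.biodistribution[organ]
            supp = config.suppression_factors[organ]
            noise_a, noise_i = _lognormal_noise(rng, config.noise_cv, 2)
            mass = float(rng.uniform(2.0, 20.0)) if organ != "serum" else np.nan
            sample_id = f"hcq_fish{fish + 1}_{organ}"
            rows.append({
                "sample_id": sample_id, "group": "hcq", "fish": fish + 1,
                "matrix_id": organ, "tissue_mass_mg": mass,
                "extraction_ml_per_mg": 0.04 if organ != "serum" else np.nan,
                "analyte_area": AREA_PER_UG_ML * conc * supp * noise_a,
                "istd_area": AREA_PER_UG_ML * ISTD_CONCENTRATION_UG_ML
                * supp * noise_i,
            })
            truth_rows.append({
                "sample_id": sample_id, "matrix_id": organ,
                "true_extract_concentration": conc,
                "true_tissue_concentration": conc * 15.0 if organ == "serum"
                else conc * 0.04,
            })
    return (pd.DataFrame(rows),
            GroundTruth(true_concentrations=pd.DataFrame(truth_rows)))


# -------------------------------------------------------------------- tracing

def _true_mids_for_group(config: GeneratorConfig, group: str) -> dict[str, MID]:
    rf = config.route_fractions_by_group[group]
    e = config.tracer_enrichment
    glucose = np.zeros(7)
    glucose[0], glucose[6] = 1.0 - e, e
    return {
        "glucose_serum": MID("glucose", glucose),
        "aspartate_brain": aspartate_mid_from_routes(rf),
        "naa_brain": simulate_naa_mid(rf),
    }


def generate_tracing_dataset(config: GeneratorConfig,
                             ) -> tuple[pd.DataFrame, GroundTruth]:
    """Raw isotopologue intensities for the ¹³C₆-glucose tracing experiment.

    For each fish the true MIDs (serum glucose with M+6 = tracer enrichment;
    brain aspartate and NAA from the group's route fractions) are convolved
    with ¹³C natural abundance and scaled with multiplicative noise, so the
    correction stage downstream is genuinely exercised.
    """
    rng = _rng(config, "tracing")
    rows = []
    truth_mids = []
    for group, n_fish in sorted(config.n_fish_tracing.items()):
        mids = _true_mids_for_group(config, group)
        for name, mid in mids.items():
            truth_mids.append(pd.DataFrame({
                "group": group, "metabolite": name,
                "isotopologue": np.arange(mid.n + 1),
                "true_fraction": mid.fractions}))
        for fish in range(n_fish):
            base = float(rng.uniform(5e5, 5e6))    # per-fish pool size scale
            for name, mid in mids.items():
                raw = convolve_natural_abundance(mid.fractions, mid.n,
                                                 config.natural_abundance)
                noise = _lognormal_noise(rng, config.noise_cv, raw.size)
                for k in range(raw.size):
                    rows.append({
                        "group": group, "fish": fish + 1, "metabolite": name,
                        "n_carbons": mid.n, "isotopologue": k,
                        "intensity": base * raw[k] * noise[k]})
    truth = GroundTruth(route_fractions=dict(config.route_fractions_by_group),
                        true_mids=pd.concat(truth_mids, ignore_index=True))
    return pd.DataFrame(rows), truth


# ----------------------------------------------------------------------- DESI

def _ellipse_mask(dims: tuple[int, int],
                  layout: tuple[float, float, float, float]) -> np.ndarray:
    rows, cols = dims
    rc, cc, rr, cr = layout
    if rc - rr < 0 or rc + rr > 1 or cc - cr < 0 or cc + cr > 1:
        raise ValueError(f"organ ellipse {layout} exceeds grid bounds")
    r = np.arange(rows)[:, None]
    c = np.arange(cols)[None, :]
    return (((r / rows - rc) / max(rr, 1e-9)) ** 2
            + ((c / cols - cc) / max(cr, 1e-9)) ** 2) <= 1.0


def generate_desi_grid(config: GeneratorConfig,
                       ) -> tuple[IonImageGrid, GroundTruth]:
    """Whole-body DESI pixel grid with organ masks and a swim-bladder void.

    Drug and drug-metabolite channels scale per organ with the
    biodistribution; the endogenous channel covers the whole body; the
    swim-bladder cavity carries zero intensity in every channel (TIC 0).
    Organ masks are part of the ground truth, not inferred.
    """
    rng = _rng(config, "desi")
    dims = config.grid_dims
    body = _ellipse_mask(dims, BODY_ELLIPSE)
    layout = config.organ_layout
    masks = {organ: _ellipse_mask(dims, ell) & body
             for organ, ell in layout.items()}
    void = masks.pop("swim_bladder", np.zeros(dims, dtype=bool))
    masks = {o: m & ~void for o, m in masks.items()}

    names = list(DESI_CHANNELS)
    mzs = np.array([DESI_CHANNELS[n] for n in names])
    inten = np.zeros(dims + (len(names),))
    baseline = {"hcq": 100.0, "desethylhydroxychloroquine": 50.0,
                "desethylchloroquine": 25.0, "endogenous": 800.0}
    for ch, name in enumerate(names):
        img = np.zeros(dims)
        if name == "endogenous":
            img[body] = baseline[name]
            for m in masks.values():
                img[m] = baseline[name] * 1.3
        else:
            img[body] = baseline[name]
            for organ, m in masks.items():
                img[m] = baseline[name] * 5.0 * config.biodistribution.get(organ, 1.0)
        img *= _lognormal_noise(rng, config.noise_cv, dims)
        img[~body] = 0.0
        img[void] = 0.0
        inten[..., ch] = img

    order = np.argsort(mzs)
    grid = IonImageGrid(mzs=mzs[order], intensities=inten[..., order],
                        pitch_um=config.pixel_pitch_um)
    all_masks = dict(masks)
    all_masks["swim_bladder"] = void
    truth = GroundTruth(organ_masks=all_masks, channel_mzs=dict(DESI_CHANNELS))
    return grid, truth


# ------------------------------------------------------------------------- QC

def generate_qc_replicates(config: GeneratorConfig, n_injections: int = 10,
                           n_metabolites: int = 20) -> pd.DataFrame:
    """Pooled-QC panel: IS-normalized peak-area ratios across replicate injections.

    Each metabolite has a fixed true ratio (log-uniform over two decades);
    every injection perturbs it with the configured multiplicative noise.
    """
    rng = _rng(config, "qc")
    true_ratio = 10.0 ** rng.uniform(-1, 1, n_metabolites)
    noise = _lognormal_noise(rng, config.noise_cv, (n_metabolites, n_injections))
    values = true_ratio[:, None] * noise
    return pd.DataFrame(values,
                        index=[f"metabolite_{i + 1:02d}" for i in range(n_metabolites)],
                        columns=[f"injection_{j + 1:02d}" for j in range(n_injections)])


# ------------------------------------------------------------------- features

SATELLITE_SHIFTS: dict[str, float] = {
    "isotope_13C": 1.00336,
    "sodium_adduct": 21.98194,
    "potassium_adduct": 37.95588,
}


def generate_feature_tables(config: GeneratorConfig,
                            ) -> tuple[dict[str, pd.DataFrame], GroundTruth]:
    """Per-organ untargeted feature tables with blanks and known degeneracies.

    Each organ table contains endogenous features (a configured subset with
    a group effect), contaminant features present equally in blanks, and
    satellite features at fixed mass shifts from their parents (shared RT,
    correlated intensity).  One blank per 10 samples.
    """
    tables: dict[str, pd.DataFrame] = {}
    perturbed: dict[str, set[str]] = {}
    contaminants: dict[str, set[str]] = {}
    degeneracy: dict[str, str] = {}
    n_ctrl = config.n_control_fish_features
    n_trt = config.n_treated_fish_features
    n_blank = max(1, int(np.ceil((n_ctrl + n_trt) / 10)))
    sample_cols = ([f"control_{i + 1}" for i in range(n_ctrl)]
                   + [f"hcq_{i + 1}" for i in range(n_trt)])
    blank_cols = [f"blank_{i + 1}" for i in range(n_blank)]

    for organ in config.tissue_organs:
        rng = _rng(config, f"features:{organ}")
        n_endo = config.n_endogenous_features
        n_pert = min(config.perturbed_counts.get(organ, 0), n_endo)
        rows = []
        perturbed[organ] = set()
        contaminants[organ] = set()

        base = 10.0 ** rng.uniform(4, 7, n_endo)
        mz = rng.uniform(80, 900, n_endo)
        rt = rng.uniform(0.5, 13.5, n_endo)
        pert_idx = rng.choice(n_endo, size=n_pert, replace=False)
        effect = np.ones(n_endo)
        up = rng.random(n_pert) < 0.5
        effect[pert_idx] = np.where(up, config.perturbed_effect,
                                    1.0 / config.perturbed_effect)

        for i in range(n_endo):
            fid = f"{organ}:feat{i:04d}"
            noise = _lognormal_noise(rng, config.feature_noise_cv,
                                     n_ctrl + n_trt + n_blank)
            vals = np.concatenate([
                base[i] * noise[:n_ctrl],
                base[i] * effect[i] * noise[n_ctrl:n_ctrl + n_trt],
                0.01 * base[i] * noise[n_ctrl + n_trt:],   # near-zero in blanks
            ])
            row = {"id": fid, "mz": mz[i], "rt": rt[i]}
            row.update(dict(zip(sample_cols + blank_cols, vals)))
            rows.append(row)
            if i in pert_idx:
                perturbed[organ].add(fid)

            if rng.random() < config.satellite_probability:
                shift_name = str(rng.choice(list(SATELLITE_SHIFTS)))
                sat_id = f"{fid}:{shift_name}"
                ratio = float(rng.uniform(0.05, 0.5))
                sat_noise = _lognormal_noise(rng, 0.05, vals.size)
                sat_row = {"id": sat_id,
                           "mz": mz[i] + SATELLITE_SHIFTS[shift_name],
                           "rt": rt[i] + float(rng.uniform(-0.02, 0.02))}
                sat_row.update(dict(zip(sample_cols + blank_cols,
                                        vals * ratio * sat_noise)))
                rows.append(sat_row)
                degeneracy[sat_id] = fid

        contam_base = 10.0 ** rng.uniform(4, 6, config.n_contaminant_features)
        contam_mz = rng.uniform(80, 900, config.n_contaminant_features)
        contam_rt = rng.uniform(0.5, 13.5, config.n_contaminant_features)
        for i in range(config.n_contaminant_features):
            fid = f"{organ}:contam{i:03d}"
            noise = _lognormal_noise(rng, config.feature_noise_cv,
                                     n_ctrl + n_trt + n_blank)
            row = {"id": fid, "mz": contam_mz[i], "rt": contam_rt[i]}
            row.update(dict(zip(sample_cols + blank_cols, contam_base[i] * noise)))
            rows.append(row)
            contaminants[organ].add(fid)

        tables[organ] = pd.DataFrame(rows)

    truth = GroundTruth(perturbed_features=perturbed,
                        contaminant_features=contaminants,
                        degeneracy_map=degeneracy)
    return tables, truth


def feature_sample_columns(config: GeneratorConfig,
                           ) -> tuple[list[str], list[str], list[str]]:
    """(control, treated, blank) column names of generated feature tables."""
    ctrl = [f"control_{i + 1}" for i in range(config.n_control_fish_features)]
    trt = [f"hcq_{i + 1}" for i in range(config.n_treated_fish_features)]
    n_blank = max(1, int(np.ceil((len(ctrl) + len(trt)) / 10)))
    blank = [f"blank_{i + 1}" for i in range(n_blank)]
    return ctrl, trt, blank
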