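"""Synthetic serum RT-qPCR cohort generator.

Emulates the data-generating process the downstream analysis assumes:
per-miRNA log2 abundance with group effects, per-sample RNA-isolation
efficiency recoverable from three spike-in controls, per-assay standard
curves with variable amplification efficiency, technical duplicates with
Gaussian Ct noise, and a hemolysed sample fraction that shifts
red-blood-cell miRNAs upward.

All randomness flows from a single master seed through deterministically
derived per-stage child streams, so identical configs produce bit-identical
plates and annotations.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

#: mL-serum <-> RT-reaction conversion: 200 uL serum -> 25 uL eluate,
#: 2 uL eluate per RT reaction => (25/2) / 0.2 mL = 62.5 reactions-worth per mL.
REACTIONS_PER_ML = 62.5

#: Ct value above which a well reads "undetermined".
CT_CEILING = 40.0

#: Spike-in control assays (added pre-isolation at known copies/reaction).
SPIKE_ASSAYS = ("spike-in-high", "spike-in-med", "spike-in-low")
SPIKE_NOMINAL_COPIES = {"spike-in-high": 1e6, "spike-in-med": 1e4, "spike-in-low": 3e2}

#: Hemolysis indicator pair (stable serum reference vs red-blood-cell miRNA).
HEMOLYSIS_REFERENCE = "hsa-miR-23a-3p"
HEMOLYSIS_RBC = "hsa-miR-451a"

#: Default informative miRNAs with log2 effect sizes (malignant - benign).
DEFAULT_INFORMATIVE = (
    ("hsa-miR-451a", 0.39),
    ("hsa-miR-195-5p", 0.41),
    ("hsa-miR-126-5p", 0.17),
    ("hsa-miR-423-3p", -0.09),
    ("hsa-miR-192-5p", -0.07),
    ("hsa-miR-17-5p", 0.10),
)

STANDARD_DILUTIONS = tuple(float(10**e) for e in range(7, 1, -1))  # 1e7 .. 1e2


class ConfigError(ValueError):
    """Invalid cohort configuration."""


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of the synthetic cohort.

    Counts give the number of *generated* samples per arm; hemolysed samples
    are generated among them and are meant to be excluded by downstream QC.
    """

    n_benign_discovery: int = 197
    n_malignant_discovery: int = 72
    n_benign_validation: int = 196
    n_malignant_validation: int = 73
    n_normal: int = 100
    n_mirnas: int = 324
    n_expressed: int = 179
    informative_mirnas: tuple[tuple[str, float], ...] = DEFAULT_INFORMATIVE
    baseline_log2_mean_range: tuple[float, float] = (11.5, 17.0)
    biological_sd: float = 0.25
    ct_noise_sd: float = 0.15
    isolation_efficiency_sd: float = 0.2
    median_recovery: float = 0.7
    hemolysis_fraction: float = 0.10
    hemolysis_shift: float = 12.0
    rbc_mirnas: tuple[str, ...] = (HEMOLYSIS_RBC,)
    efficiency_range: tuple[float, float] = (0.90, 1.05)
    intercept_range: tuple[float, float] = (38.0, 40.0)
    #: per-sample latent factor shared by these miRNAs (joint, label-free noise)
    shared_factor_mirnas: tuple[str, ...] = ()
    shared_factor_sd: float = 0.0
    #: if nonzero, malignant effects scale with stage: 1 + g*(stage - 1.5)
    stage_effect_gradient: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (
            self.n_benign_discovery,
            self.n_malignant_discovery,
            self.n_benign_validation,
            self.n_malignant_validation,
            self.n_normal,
            self.n_mirnas,
            self.n_expressed,
        )
        if any(c <= 0 for c in counts):
            raise ConfigError("all counts must be positive")
        if self.n_expressed > self.n_mirnas:
            raise ConfigError("n_expressed cannot exceed n_mirnas")
        if not 0.0 <= self.hemolysis_fraction <= 1.0:
            raise ConfigError("hemolysis_fraction must lie in [0, 1]")
        lo, hi = self.efficiency_range
        if not (0.0 < lo <= hi <= 1.2):
            raise ConfigError("efficiency_range must lie within (0, 1.2]")
        if HEMOLYSIS_RBC not in self.rbc_mirnas:
            raise ConfigError(f"rbc_mirnas must include {HEMOLYSIS_RBC}")
        if self.biological_sd < 0 or self.ct_noise_sd < 0:
            raise ConfigError("noise SDs must be non-negative")

    @property
    def n_samples(self) -> int:
        return (
            self.n_benign_discovery
            + self.n_malignant_discovery
            + self.n_benign_validation
            + self.n_malignant_validation
            + self.n_normal
        )

    def mirna_ids(self) -> list[str]:
        """Assay identifiers; named miRNAs first, simulated fillers after."""
        named: list[str] = [HEMOLYSIS_REFERENCE]
        for mid, _ in self.informative_mirnas:
            if mid not in named:
                named.append(mid)
        for mid in self.rbc_mirnas:
            if mid not in named:
                named.append(mid)
        for mid in self.shared_factor_mirnas:
            if mid not in named:
                named.append(mid)
        if len(named) > self.n_mirnas:
            raise ConfigError("more named miRNAs than n_mirnas")
        fillers = [f"hsa-miR-sim-{i:04d}" for i in range(self.n_mirnas - len(named))]
        return named + fillers

    def expressed_ids(self) -> list[str]:
        ids = self.mirna_ids()
        expressed = ids[: self.n_expressed]
        missing = [m for m, _ in self.informative_mirnas if m not in expressed]
        if missing:
            raise ConfigError(f"informative miRNAs not in expressed set: {missing}")
        return expressed

    def to_flat_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["informative_mirnas"] = ",".join(f"{m}:{e}" for m, e in self.informative_mirnas)
        for key in ("baseline_log2_mean_range", "efficiency_range", "intercept_range"):
            d[key] = ",".join(str(v) for v in d[key])
        for key in ("rbc_mirnas", "shared_factor_mirnas"):
            d[key] = ",".join(d[key])
        return d

    @classmethod
    def from_flat_dict(cls, d: dict) -> "CohortConfig":
        kwargs: dict = {}
        fields = {f.name: f for f in dataclasses.fields(cls)}
        for key, raw in d.items():
            if key not in fields:
                raise ConfigError(f"unknown config key: {key}")
            if key == "informative_mirnas":
                items = [s for s in str(raw).split(",") if s.strip()]
                kwargs[key] = tuple((m.strip(), float(e)) for m, e in (it.rsplit(":", 1) for it in items))
            elif key in ("baseline_log2_mean_range", "efficiency_range", "intercept_range"):
                lo, hi = str(raw).split(",")
                kwargs[key] = (float(lo), float(hi))
            elif key in ("rbc_mirnas", "shared_factor_mirnas"):
                kwargs[key] = tuple(s.strip() for s in str(raw).split(",") if s.strip())
            elif fields[key].type in ("int", int):
                kwargs[key] = int(raw)
            else:
                kwargs[key] = float(raw)
        return cls(**kwargs)


@dataclass
class SampleAnnotation:
    sample_id: str
    cohort: str  # discovery | validation | normal
    diagnosis: str  # malignant | benign | normal
    hemolysed_truth: bool
    age: float
    race: str  # Chinese | non-Chinese
    stage: int | None = None
    size_class: str | None = None  # <=10mm | 11-20mm | >20mm
    grade: int | None = None
    node_class: int | None = None  # 0 = negative, 1 = 1-3 nodes, 2 = >=4 nodes


@dataclass
class CohortTruth:
    """Latent generation record for test oracles."""

    config: CohortConfig
    curves: pd.DataFrame  # assay_id, slope, intercept, efficiency
    baselines: pd.Series  # per-miRNA baseline log2 copies/mL
    expressed: list[str]
    log2_copies_per_ml: pd.DataFrame  # samples x miRNAs latent truth
    recovery: pd.Series  # per-sample isolation recovery fraction
    hemolysed: pd.Series  # per-sample boolean


def _child_rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _assay_truth(config: CohortConfig) -> tuple[pd.DataFrame, pd.Series]:
    """True per-assay curves and per-miRNA baseline abundances.

    Derived from a dedicated child stream so the standalone standard-curve
    plate and the cohort plate share identical true calibration lines.
    """
    rng = _child_rngs(config.seed, 4)[0]
    mirnas = config.mirna_ids()
    assays = mirnas + list(SPIKE_ASSAYS)
    eff = rng.uniform(*config.efficiency_range, size=len(assays))
    slope = -1.0 / np.log10(1.0 + eff)
    intercept = rng.uniform(*config.intercept_range, size=len(assays))
    curves = pd.DataFrame(
        {"assay_id": assays, "slope": slope, "intercept": intercept, "efficiency": eff}
    ).set_index("assay_id", drop=False)

    lo, hi = config.baseline_log2_mean_range
    baselines = pd.Series(rng.uniform(lo, hi, size=len(mirnas)), index=mirnas)
    expressed = set(config.expressed_ids())
    not_expressed = [m for m in mirnas if m not in expressed]
    # below the 500 copies/mL filter (log2(500) ~ 8.97) for essentially all samples
    baselines[not_expressed] = rng.uniform(4.0, 7.5, size=len(not_expressed))
    # pin the hemolysis indicator pair to comparable abundance so the fixed
    # dCt rule has a stable operating point across random configs
    baselines[HEMOLYSIS_REFERENCE] = 14.0
    baselines[HEMOLYSIS_RBC] = 14.0
    return curves, baselines


def generate_standard_curve_plate(
    config: CohortConfig, dilutions: Sequence[float] = STANDARD_DILUTIONS
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the serial-dilution calibration plate for every assay.

    Returns (plate, truth): `plate` has columns assay_id, copies, replicate,
    ct; `truth` carries the true slope/intercept/efficiency per assay.
    """
    dilutions = np.asarray(list(dilutions), dtype=float)
    if len(dilutions) == 0 or np.any(dilutions <= 0):
        raise ValueError("dilution grid must be positive")
    curves, _ = _assay_truth(config)
    rng = _child_rngs(config.seed, 4)[1]
    n_assay, n_dil, n_rep = len(curves), len(dilutions), 2
    true_ct = curves["intercept"].to_numpy()[:, None] + curves["slope"].to_numpy()[:, None] * np.log10(dilutions)[None, :]
    ct = np.repeat(true_ct[:, :, None], n_rep, axis=2)
    ct = ct + rng.normal(0.0, config.ct_noise_sd, size=ct.shape)
    plate = pd.DataFrame(
        {
            "assay_id": np.repeat(curves["assay_id"].to_numpy(), n_dil * n_rep),
            "copies": np.tile(np.repeat(dilutions, n_rep), n_assay),
            "replicate": np.tile(np.arange(1, n_rep + 1), n_assay * n_dil),
            "ct": ct.ravel(),
        }
    )
    return plate, curves.reset_index(drop=True)


def _annotate(config: CohortConfig, rng: np.random.Generator) -> list[SampleAnnotation]:
    arms = (
        [("discovery", "benign")] * config.n_benign_discovery
        + [("discovery", "malignant")] * config.n_malignant_discovery
        + [("validation", "benign")] * config.n_benign_validation
        + [("validation", "malignant")] * config.n_malignant_validation
        + [("normal", "normal")] * config.n_normal
    )
    annotations: list[SampleAnnotation] = []
    # marginal clinicopathology frequencies of the emulated patient population
    stage_p = np.array([53, 52, 34, 6], dtype=float)
    stage_p /= stage_p.sum()
    size_p = np.array([40, 55, 52], dtype=float)
    size_p /= size_p.sum()
    grade_p = np.array([34, 61, 45], dtype=float)
    grade_p /= grade_p.sum()
    node_p = np.array([31, 63, 42], dtype=float)
    node_p /= node_p.sum()
    size_labels = ["<=10mm", "11-20mm", ">20mm"]
    for i, (cohort, diagnosis) in enumerate(arms):
        malignant = diagnosis == "malignant"
        hemolysed = bool(cohort != "normal" and rng.random() < config.hemolysis_fraction)
        age_mu = 55.0 if malignant else 50.0
        age = float(np.clip(rng.normal(age_mu, 8.0), 25.0, 82.0))
        race = "Chinese" if rng.random() < 0.82 else "non-Chinese"
        ann = SampleAnnotation(
            sample_id=f"S{i + 1:04d}",
            cohort=cohort,
            diagnosis=diagnosis,
            hemolysed_truth=hemolysed,
            age=round(age, 1),
            race=race,
        )
        if malignant:
            ann.stage = int(rng.choice(4, p=stage_p))
            ann.size_class = size_labels[int(rng.choice(3, p=size_p))]
            ann.grade = int(rng.choice(3, p=grade_p)) + 1
            ann.node_class = int(rng.choice(3, p=node_p))
        annotations.append(ann)
    return annotations


def annotations_to_frame(annotations: list[SampleAnnotation]) -> pd.DataFrame:
    df = pd.DataFrame([dataclasses.asdict(a) for a in annotations])
    return df.set_index("sample_id", drop=False)


def generate_cohort(
    config: CohortConfig,
) -> tuple[pd.DataFrame, list[SampleAnnotation], CohortTruth]:
    """Simulate the full cohort plate.

    Returns (ct_table, annotations, truth). `ct_table` is long-format with
    columns sample_id, assay_id, replicate, ct (NaN = undetermined well) and
    includes the three spike-in control assays for every sample.
    """
    _, _, rng_cohort, rng_ann = _child_rngs(config.seed, 4)
    curves, baselines = _assay_truth(config)
    annotations = _annotate(config, rng_ann)
    ann_df = annotations_to_frame(annotations)
    mirnas = config.mirna_ids()
    samples = ann_df["sample_id"].tolist()
    n_s, n_m = len(samples), len(mirnas)

    mean = np.tile(baselines.to_numpy()[None, :], (n_s, 1))
    malignant = (ann_df["diagnosis"] == "malignant").to_numpy()
    effect_mult = np.ones(n_s)
    if config.stage_effect_gradient != 0.0:
        stage = ann_df["stage"].to_numpy(dtype=float)
        mult = 1.0 + config.stage_effect_gradient * (stage - 1.5)
        effect_mult = np.where(malignant & ~np.isnan(stage), mult, 1.0)
    col = {m: j for j, m in enumerate(mirnas)}
    for mid, eff_size in config.informative_mirnas:
        mean[malignant, col[mid]] += eff_size * effect_mult[malignant]
    hemolysed = ann_df["hemolysed_truth"].to_numpy(dtype=bool)
    for mid in config.rbc_mirnas:
        mean[hemolysed, col[mid]] += config.hemolysis_shift

    log2_truth = mean + rng_cohort.normal(0.0, config.biological_sd, size=(n_s, n_m))
    if config.shared_factor_mirnas and config.shared_factor_sd > 0:
        factor = rng_cohort.normal(0.0, config.shared_factor_sd, size=n_s)
        for mid in config.shared_factor_mirnas:
            log2_truth[:, col[mid]] += factor

    log_recovery = rng_cohort.normal(np.log(config.median_recovery), config.isolation_efficiency_sd, size=n_s)
    recovery = np.exp(log_recovery)

    # copies per RT reaction: volumetric dilution then per-sample isolation loss
    copies_rxn = np.exp2(log2_truth) * recovery[:, None] / REACTIONS_PER_ML
    spike_rxn = np.array([SPIKE_NOMINAL_COPIES[a] for a in SPIKE_ASSAYS])[None, :] * recovery[:, None]
    all_rxn = np.concatenate([copies_rxn, spike_rxn], axis=1)

    assays = mirnas + list(SPIKE_ASSAYS)
    slope = curves.loc[assays, "slope"].to_numpy()
    intercept = curves.loc[assays, "intercept"].to_numpy()
    with np.errstate(divide="ignore"):
        true_ct = intercept[None, :] + slope[None, :] * np.log10(all_rxn)
    n_rep = 2
    ct = np.repeat(true_ct[:, :, None], n_rep, axis=2)
    ct = ct + rng_cohort.normal(0.0, config.ct_noise_sd, size=ct.shape)
    undetermined = (all_rxn[:, :, None] < 1.0) | (ct > CT_CEILING)
    ct = np.where(undetermined, np.nan, ct)

    table = pd.DataFrame(
        {
            "sample_id": np.repeat(samples, len(assays) * n_rep),
            "assay_id": np.tile(np.repeat(assays, n_rep), n_s),
            "replicate": np.tile(np.arange(1, n_rep + 1), n_s * len(assays)),
            "ct": ct.ravel(),
        }
    )
    truth = CohortTruth(
        config=config,
        curves=curves.reset_index(drop=True),
        baselines=baselines,
        expressed=config.expressed_ids(),
        log2_copies_per_ml=pd.DataFrame(log2_truth, index=samples, columns=mirnas),
        recovery=pd.Series(recovery, index=samples),
        hemolysed=pd.Series(hemolysed, index=samples),
    )
    return table, annotations, truth
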