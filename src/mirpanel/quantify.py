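"""Absolute quantification: standard curves, Ct -> copies/mL serum.

Each assay gets its own ordinary-least-squares calibration of Ct against
log10(input copies); sample Ct values are interpolated on that line and
converted to copies per mL serum using the volumetric constant and the
per-sample spike-in recovery (geometric mean of the three controls).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic import CT_CEILING, REACTIONS_PER_ML, SPIKE_ASSAYS, SPIKE_NOMINAL_COPIES

FLAG_MEASURED = "measured"
FLAG_FLOORED = "floored"
FLAG_DISCORDANT = "discordant"

#: |delta Ct| between technical duplicates above which the pair is flagged.
DUPLICATE_DISCORDANCE_CT = 1.0


class CalibrationError(ValueError):
    """Standard-curve fit failed or is unusable."""


@dataclass(frozen=True)
class StandardCurve:
    """Linear Ct-vs-log10(copies) calibration for one assay."""

    assay_id: str
    slope: float  # Ct per log10(copies), negative
    intercept: float  # Ct at 1 copy
    r2: float

    def __post_init__(self) -> None:
        if self.slope >= 0:
            raise CalibrationError(f"{self.assay_id}: non-negative slope {self.slope}")
        if not 0.0 <= self.r2 <= 1.0 + 1e-12:
            raise CalibrationError(f"{self.assay_id}: r2 out of range")

    @property
    def efficiency(self) -> float:
        """Per-cycle amplification efficiency E = 10^(-1/slope) - 1."""
        return 10.0 ** (-1.0 / self.slope) - 1.0

    @property
    def floor_copies(self) -> float:
        """Copies/reaction at the detection ceiling Ct."""
        return ct_to_copies(CT_CEILING, self)


@dataclass
class ExpressionMatrix:
    """Samples x miRNAs expression with per-cell provenance flags."""

    values: pd.DataFrame  # strictly positive
    flags: pd.DataFrame  # same shape; measured/floored/discordant

    def __post_init__(self) -> None:
        if self.values.shape != self.flags.shape:
            raise ValueError("values and flags must have identical shape")
        if self.values.index.has_duplicates or self.values.columns.has_duplicates:
            raise ValueError("sample and miRNA identifiers must be unique")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("expression values must be non-negative")

    @property
    def samples(self) -> list[str]:
        return list(self.values.index)

    @property
    def mirnas(self) -> list[str]:
        return list(self.values.columns)

    def subset_mirnas(self, mirnas: list[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values[mirnas].copy(), self.flags[mirnas].copy())

    def subset_samples(self, samples: list[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[samples].copy(), self.flags.loc[samples].copy())


def fit_standard_curve(dilution_cts: pd.DataFrame, assay_id: str | None = None) -> StandardCurve:
    """OLS fit of Ct on log10(copies) for one assay's dilution series.

    `dilution_cts` needs columns copies and ct (replicate rows allowed);
    requires at least 3 distinct dilution levels with finite Ct.
    """
    df = dilution_cts
    if assay_id is None:
        ids = df["assay_id"].unique()
        if len(ids) != 1:
            raise CalibrationError("pass a single assay's dilution series")
        assay_id = str(ids[0])
    ok = np.isfinite(df["ct"].to_numpy(dtype=float)) & (df["copies"].to_numpy(dtype=float) > 0)
    df = df.loc[ok]
    if df["copies"].nunique() < 3:
        raise CalibrationError(f"{assay_id}: need >=3 finite dilution levels")
    x = np.log10(df["copies"].to_numpy(dtype=float))
    y = df["ct"].to_numpy(dtype=float)
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (intercept + slope * x)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - float(np.sum(resid**2)) / ss_tot
    if slope >= 0:
        raise CalibrationError(f"{assay_id}: fitted slope {slope:.3f} is not negative")
    return StandardCurve(assay_id=assay_id, slope=float(slope), intercept=float(intercept), r2=float(min(max(r2, 0.0), 1.0)))


def fit_all_curves(standards: pd.DataFrame) -> dict[str, StandardCurve]:
    return {
        str(assay): fit_standard_curve(sub, assay_id=str(assay))
        for assay, sub in standards.groupby("assay_id", sort=False)
    }


def curves_to_frame(curves: dict[str, StandardCurve]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"assay_id": c.assay_id, "slope": c.slope, "intercept": c.intercept, "efficiency": c.efficiency, "r2": c.r2}
            for c in curves.values()
        ]
    )


def curves_from_frame(df: pd.DataFrame) -> dict[str, StandardCurve]:
    return {
        str(r.assay_id): StandardCurve(str(r.assay_id), float(r.slope), float(r.intercept), float(r.r2))
        for r in df.itertuples()
    }


def ct_to_copies(ct: float | np.ndarray, curve: StandardCurve) -> float | np.ndarray:
    """Interpolate Ct on the calibration line: copies = 10^((b - ct)/(-m)).

    Undetermined (NaN) Ct maps to the floor value at the detection ceiling,
    never zero, so downstream log transforms stay defined.
    """
    ct_arr = np.asarray(ct, dtype=float)
    filled = np.where(np.isnan(ct_arr), CT_CEILING, ct_arr)
    copies = 10.0 ** ((curve.intercept - filled) / (-curve.slope))
    if np.isscalar(ct) or ct_arr.ndim == 0:
        return float(copies)
    return copies


def copies_to_ct(copies: float | np.ndarray, curve: StandardCurve) -> float | np.ndarray:
    return curve.intercept + curve.slope * np.log10(copies)


def collapse_duplicates(ct_table: pd.DataFrame) -> pd.DataFrame:
    """Average technical duplicates to one row per sample x assay.

    Mean of finite replicates; flagged discordant when the replicates
    disagree by more than DUPLICATE_DISCORDANCE_CT or only one is finite.
    Both undetermined -> undetermined (NaN).
    """
    wide = ct_table.assign(_present=1.0).pivot(
        index=["sample_id", "assay_id"], columns="replicate", values=["ct", "_present"]
    )
    cts = wide["ct"]
    if cts.shape[1] > 2:
        raise ValueError("more than 2 replicates per well pair")
    n_total = wide["_present"].notna().sum(axis=1)
    n_finite = cts.notna().sum(axis=1)
    spread = cts.max(axis=1) - cts.min(axis=1)
    out = pd.DataFrame(
        {
            "ct": cts.mean(axis=1),
            "n_finite": n_finite,
            "discordant": (spread > DUPLICATE_DISCORDANCE_CT)
            | ((n_finite == 1) & (n_total == 2)),
        }
    )
    return out.reset_index()


def ct_table_to_copies(collapsed: pd.DataFrame, curves: dict[str, StandardCurve]) -> ExpressionMatrix:
    """Pivot a collapsed Ct table to a samples x assays copies/reaction matrix."""
    ct_wide = collapsed.pivot(index="sample_id", columns="assay_id", values="ct")
    disc = collapsed.pivot(index="sample_id", columns="assay_id", values="discordant")
    missing = [a for a in ct_wide.columns if a not in curves]
    if missing:
        raise CalibrationError(f"no standard curve for assays: {missing[:5]}")
    values = pd.DataFrame(index=ct_wide.index, columns=ct_wide.columns, dtype=float)
    for assay in ct_wide.columns:
        values[assay] = ct_to_copies(ct_wide[assay].to_numpy(dtype=float), curves[assay])
    flags = pd.DataFrame(FLAG_MEASURED, index=ct_wide.index, columns=ct_wide.columns)
    flags = flags.mask(disc.astype(bool), FLAG_DISCORDANT)
    flags = flags.mask(ct_wide.isna(), FLAG_FLOORED)
    values.index.name = flags.index.name = "sample_id"
    return ExpressionMatrix(values, flags)


def estimate_spike_recovery(
    copies_rxn: ExpressionMatrix,
    nominal: dict[str, float] = SPIKE_NOMINAL_COPIES,
) -> pd.Series:
    """Per-sample isolation recovery: geometric mean over the spike-ins of
    measured/nominal copies per reaction."""
    spikes = [a for a in nominal if a in copies_rxn.values.columns]
    if not spikes:
        raise ValueError("no spike-in assays present in the matrix")
    ratios = np.log(
        copies_rxn.values[spikes].to_numpy() / np.array([nominal[a] for a in spikes])[None, :]
    )
    return pd.Series(np.exp(ratios.mean(axis=1)), index=copies_rxn.values.index, name="recovery")


def spike_in_normalize(copies_rxn: ExpressionMatrix, recovery: pd.Series) -> ExpressionMatrix:
    """Convert copies/reaction to copies/mL serum: x * 62.5 / recovery."""
    rec = recovery.reindex(copies_rxn.values.index)
    if rec.isna().any() or (rec <= 0).any():
        raise ValueError("recovery must be positive for every sample")
    values = copies_rxn.values.mul(REACTIONS_PER_ML / rec, axis=0)
    return ExpressionMatrix(values, copies_rxn.flags.copy())


def quantify_cohort(
    ct_table: pd.DataFrame,
    standards: pd.DataFrame,
    spike_nominal: dict[str, float] = SPIKE_NOMINAL_COPIES,
) -> tuple[ExpressionMatrix, dict[str, StandardCurve], pd.Series, pd.DataFrame]:
    """Full quantification: fit curves, collapse duplicates, interpolate,
    spike-normalize.

    Returns (expression in copies/mL without spike columns, fitted curves,
    per-sample recovery, collapsed Ct table).
    """
    curves = fit_all_curves(standards)
    collapsed = collapse_duplicates(ct_table)
    copies_rxn = ct_table_to_copies(collapsed, curves)
    recovery = estimate_spike_recovery(copies_rxn, spike_nominal)
    per_ml = spike_in_normalize(copies_rxn, recovery)
    mirna_cols = [c for c in per_ml.values.columns if c not in SPIKE_ASSAYS and c not in spike_nominal]
    return per_ml.subset_mirnas(mirna_cols), curves, recovery, collapsed
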