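"""Sample and feature quality control.

Hemolysis calling uses the classic serum delta-Ct rule between a stable
reference miRNA and the red-blood-cell marker miR-451a; the expression
filter keeps only miRNAs detected at or above a copies/mL threshold in
every sample.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .quantify import ExpressionMatrix
from .synthetic import HEMOLYSIS_REFERENCE, HEMOLYSIS_RBC

#: dCt = Ct(reference) - Ct(miR-451a) above which a sample is called hemolysed.
HEMOLYSIS_DELTA_CT = 7.0

#: minimum copies/mL in all subjects for a miRNA to be considered expressed
MIN_COPIES_PER_ML = 500.0


def flag_hemolysis(
    collapsed_ct: pd.DataFrame,
    reference: str = HEMOLYSIS_REFERENCE,
    rbc: str = HEMOLYSIS_RBC,
    threshold: float = HEMOLYSIS_DELTA_CT,
) -> pd.DataFrame:
    """Score every sample for hemolysis from a collapsed Ct table.

    Score is dCt = Ct(reference) - Ct(rbc); large positive values mean the
    RBC marker is disproportionately abundant. Samples with a missing
    indicator Ct are marked un-assessable (not excluded).
    """
    ct_wide = collapsed_ct.pivot(index="sample_id", columns="assay_id", values="ct")
    for assay in (reference, rbc):
        if assay not in ct_wide.columns:
            raise KeyError(f"indicator assay {assay!r} absent from the Ct table")
    score = ct_wide[reference] - ct_wide[rbc]
    assessable = score.notna()
    report = pd.DataFrame(
        {
            "sample_id": ct_wide.index,
            "hemolysis_score": score.to_numpy(),
            "hemolysed_call": (score > threshold).fillna(False).to_numpy(),
            "reason": np.where(
                ~assessable,
                "indicator Ct undetermined: un-assessable",
                np.where(score > threshold, f"dCt > {threshold:g}", "pass"),
            ),
        }
    ).reset_index(drop=True)
    return report


def expression_filter(expression: ExpressionMatrix, min_copies: float = MIN_COPIES_PER_ML) -> list[str]:
    """miRNAs expressed at >= min_copies copies/mL in *all* samples."""
    values = expression.values
    if values.empty:
        raise ValueError("expression matrix is empty")
    keep = (values >= min_copies).all(axis=0)
    return [m for m in values.columns if keep[m]]
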