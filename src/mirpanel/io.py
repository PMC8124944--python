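"""Plain-text I/O helpers: flat config files, Ct tables, matrices, labels."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .quantify import ExpressionMatrix, FLAG_MEASURED
from .synthetic import CohortConfig


def read_config(path: str | Path) -> CohortConfig:
    """Parse a flat `key = value` config file (comments start with #)."""
    entries: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value'")
        key, value = line.split("=", 1)
        entries[key.strip()] = value.strip()
    return CohortConfig.from_flat_dict(entries)


def write_config(config: CohortConfig, path: str | Path) -> None:
    lines = [f"{key} = {value}" for key, value in config.to_flat_dict().items()]
    Path(path).write_text("\n".join(lines) + "\n")


def read_ct_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["ct"] = pd.to_numeric(df["ct"], errors="coerce")
    return df


def write_ct_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def read_expression(path: str | Path) -> ExpressionMatrix:
    values = pd.read_csv(path, index_col=0)
    flags = pd.DataFrame(FLAG_MEASURED, index=values.index, columns=values.columns)
    return ExpressionMatrix(values, flags)


def write_expression(expression: ExpressionMatrix, path: str | Path) -> None:
    expression.values.to_csv(path, index_label="sample_id")


def read_labels(path: str | Path) -> pd.Series:
    """Labels CSV: columns sample_id plus diagnosis (or label)."""
    df = pd.read_csv(path)
    col = "diagnosis" if "diagnosis" in df.columns else "label"
    return df.set_index("sample_id")[col]
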