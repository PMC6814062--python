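"""Packaged record of the 14 ex vivo hyperthermia procedures.

Columns: sample, experiment, medullar-cavity long axis (mm), mean
steady-state temperature elevation in the 13-pixel ROI (degC),
controller precision (degC), delivered energy (kJ).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_table1", "table1_summary", "PRESCRIBED_ELEVATION_C"]

PRESCRIBED_ELEVATION_C = 6.0


def load_table1() -> pd.DataFrame:
    with resources.files("osteotherm.data").joinpath("table1.csv").open() as fh:
        return pd.read_csv(fh)


def table1_summary(table: pd.DataFrame | None = None,
                   target_c: float = PRESCRIBED_ELEVATION_C) -> dict:
    """Aggregate the per-procedure steady-state elevations.

    Returns the grand mean, its std, and the relative error (percent)
    with respect to the prescribed elevation.
    """
    if table is None:
        table = load_table1()
    col = table["mean_elevation_c"]
    grand_mean = float(col.mean())
    return {
        "n": int(col.size),
        "grand_mean_c": grand_mean,
        "std_c": float(col.std(ddof=1)),
        "relative_error_pct": 100.0 * abs(grand_mean - target_c) / target_c,
        "mean_energy_kj": float(table["energy_kj"].mean()),
        "mean_precision_c": float(table["precision_c"].mean()),
    }
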