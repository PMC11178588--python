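"""CSV readers/writers for the pipeline's tabular interchange formats.

Formats:

* TAC CSV: ``patient, voi, window_keV, time_h, activity_bq``
* fit CSV: TAC columns plus ``A_t0_bq, T_eff_h, T_bio_h``
* counting CSV: ``sample_id, collection_time_h, t_h, counts`` (or
  ``activity_bq``) ``, window_keV, efficiency, bin_width_h``
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InvalidInputError
from .kinetics import TimeActivityPoint
from .urine import CountingSeries


def read_tac_csv(path) -> dict[tuple[str, str, int], list[TimeActivityPoint]]:
    """Group a TAC table into per-(patient, voi, window) point lists."""
    table = pd.read_csv(path)
    required = {"patient", "voi", "window_keV", "time_h", "activity_bq"}
    if not required.issubset(table.columns):
        raise InvalidInputError(f"TAC CSV needs columns {sorted(required)}")
    out = {}
    for (patient, voi, window), group in table.groupby(["patient", "voi", "window_keV"]):
        out[(str(patient), str(voi), int(window))] = [
            TimeActivityPoint(time=float(r.time_h), activity=float(r.activity_bq))
            for r in group.itertuples()
        ]
    return out


def write_tac_csv(path, rows: pd.DataFrame):
    rows.to_csv(path, index=False, float_format="%.10g")


def read_counting_csv(path) -> CountingSeries:
    """One urine counting series per file."""
    table = pd.read_csv(path)
    value_col = "counts" if "counts" in table.columns else "activity_bq"
    sample_id = str(table["sample_id"].iloc[0])
    efficiency = None
    if "efficiency" in table.columns and not np.isnan(table["efficiency"].iloc[0]):
        efficiency = float(table["efficiency"].iloc[0])
    bin_width = None
    if "bin_width_h" in table.columns and not np.isnan(table["bin_width_h"].iloc[0]):
        bin_width = float(table["bin_width_h"].iloc[0])
    return CountingSeries(
        sample_id=sample_id,
        collection_time=float(table["collection_time_h"].iloc[0]),
        times=table["t_h"].to_numpy(dtype=float),
        measured=table[value_col].to_numpy(dtype=float),
        kind="counts" if value_col == "counts" else "activity",
        bin_width_h=bin_width,
        efficiency=efficiency,
        window_kev=float(table["window_keV"].iloc[0]) if "window_keV" in table.columns else 440.0,
    )


def write_counting_csv(path: Path | str, series: CountingSeries):
    table = pd.DataFrame(
        {
            "sample_id": series.sample_id,
            "collection_time_h": series.collection_time,
            "t_h": series.times,
            ("counts" if series.kind == "counts" else "activity_bq"): series.measured,
            "window_keV": series.window_kev,
            "efficiency": series.efficiency if series.efficiency is not None else np.nan,
            "bin_width_h": series.bin_width_h if series.bin_width_h is not None else np.nan,
        }
    )
    table.to_csv(path, index=False, float_format="%.10g")
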