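"""Synthetic routine administrative data.

Produces the kind of table a patient administration system exports — one row
per ward stay with an ICD-10 primary diagnosis code, admission and discharge
timestamps and a discharge destination — with exactly the statistical
structure the estimation module assumes (exponential inter-arrivals,
parametric LOS, multinomial routing).  Timestamps are continuous day
fractions from an arbitrary origin; an ISO-8601 variant is available for
realism.  Bed-blocking contamination of recorded LOS (a known hazard of real
administrative data) is deliberately not emulated.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import PathwayConfig
from .sampling import DEST_LABELS, draw_pathway, substream

#: Small built-in ICD-10 code table mapping to the four patient groups.
#: This stands in for the hospital's coding practice; it is data, not logic.
DIAGNOSIS_CODES: dict[str, list[str]] = {
    "stroke": ["I61.0", "I61.9", "I63.0", "I63.3", "I63.9", "I64"],
    "tia": ["G45.3", "G45.8", "G45.9"],
    "complex_neuro": ["G35", "G40.9", "G61.0", "G93.4", "C71.9"],
    "other": ["J18.9", "N39.0", "A41.9", "L03.1", "R55"],
}

RECORD_COLUMNS = [
    "patient_id",
    "diagnosis_code",
    "ward",
    "admit_time",
    "discharge_time",
    "destination",
]


def generate_records(
    config: PathwayConfig, horizon: float, seed: int
) -> pd.DataFrame:
    """One row per ward stay over ``[0, horizon)`` days.

    Stays that begin before the horizon are recorded in full even if they end
    after it (discharge timestamps are always present).  Reproducible: the
    same seed yields a byte-identical table.
    """
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    draws = draw_pathway(config, horizon, seed, rep_id=0)

    pid_parts, admit_parts = [], []
    rows = []
    # Assign patient ids by admission order across all classes.
    offsets = {}
    start = 0
    for d in draws:
        offsets[d.name] = start
        admit_parts.append(d.arrivals)
        start += d.n
    all_admits = np.concatenate(admit_parts) if admit_parts else np.empty(0)
    rank = np.empty(all_admits.size, dtype=np.int64)
    rank[np.argsort(all_admits, kind="stable")] = np.arange(all_admits.size)

    for d in draws:
        rng_codes = substream(seed, 0, d.name, "codes")
        codes = rng_codes.choice(DIAGNOSIS_CODES[d.name], size=d.n)
        base = offsets[d.name]
        ids = [f"P{rank[base + i]:06d}" for i in range(d.n)]
        entry_end = d.arrivals + d.entry_los
        for i in range(d.n):
            rows.append(
                (
                    ids[i],
                    codes[i],
                    d.entry_ward,
                    float(d.arrivals[i]),
                    float(entry_end[i]),
                    DEST_LABELS[int(d.entry_dest[i])],
                )
            )
            if not np.isnan(d.rehab_start[i]):
                rows.append(
                    (
                        ids[i],
                        codes[i],
                        "rehab",
                        float(d.rehab_start[i]),
                        float(d.rehab_start[i] + d.rehab_los[i]),
                        DEST_LABELS[int(d.rehab_dest[i])],
                    )
                )
    df = pd.DataFrame(rows, columns=RECORD_COLUMNS)
    return df.sort_values(["admit_time", "patient_id"], kind="stable").reset_index(
        drop=True
    )


def write_records(df: pd.DataFrame, path, iso8601: bool = False,
                  origin: str = "2010-01-01") -> None:
    """Write the records table as CSV; optionally with ISO-8601 timestamps."""
    out = df.copy()
    if iso8601:
        base = pd.Timestamp(origin)
        for col in ("admit_time", "discharge_time"):
            out[col] = base + pd.to_timedelta(out[col], unit="D")
    out.to_csv(path, index=False)


def read_records(path) -> pd.DataFrame:
    """Read a records CSV, converting ISO-8601 timestamps back to day offsets."""
    df = pd.read_csv(path)
    for col in ("admit_time", "discharge_time"):
        if df[col].dtype == object:
            ts = pd.to_datetime(df[col])
            df[col] = (ts - ts.min()).dt.total_seconds() / 86400.0
    return df[RECORD_COLUMNS]
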