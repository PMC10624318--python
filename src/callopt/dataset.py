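"""Treatment-level dataset handling.

The packaged fixture is the 33-treatment factorial screen of four plant
growth regulators (BAP, KIN, NAA, IBA; mg/L) against callus formation rate
(CFR, percent of explants forming callus) and callus fresh weight (CFW,
grams).  Each treatment mean summarises seven replicate vessels of four
hypocotyl explants each.

Tables are plain :class:`pandas.DataFrame` objects with fixed column sets;
validation is done on read so downstream code can assume well-formed data.
"""

from __future__ import annotations

import importlib.resources
from pathlib import Path

import pandas as pd

HORMONES = ["bap", "kin", "naa", "iba"]
TREATMENT_COLUMNS = HORMONES + ["cfr_mean", "cfr_se", "cfw_mean", "cfw_se"]
REPLICATE_COLUMNS = ["treatment_id"] + HORMONES + ["cfr", "cfw"]

#: concentration range covered by the screen, mg/L
DOSE_RANGE = (0.0, 2.0)

#: per-replicate CFR values attainable with 4 explants per vessel
CFR_LATTICE = (0.0, 25.0, 50.0, 75.0, 100.0)


class DatasetError(ValueError):
    """Raised when a treatment or replicate table fails validation."""


def _fail(msg: str, row: int | None = None) -> None:
    loc = "" if row is None else f" (row {row})"
    raise DatasetError(msg + loc)


def validate_treatments(table: pd.DataFrame) -> pd.DataFrame:
    """Validate a treatment table in place and return it.

    Checks column presence, numeric dtypes, dose and response ranges, and
    the physical constraint that a hormone-free medium forms no callus.
    """
    missing = [c for c in TREATMENT_COLUMNS if c not in table.columns]
    if missing:
        _fail(f"missing column(s): {', '.join(missing)}")
    sub = table[TREATMENT_COLUMNS]
    non_numeric = sub.columns[
        ~sub.apply(lambda c: pd.to_numeric(c, errors="coerce").notna().all())
    ]
    if len(non_numeric):
        bad = sub[pd.to_numeric(sub[non_numeric[0]], errors="coerce").isna()]
        _fail(f"non-numeric value in column '{non_numeric[0]}'", int(bad.index[0]))
    for i, r in sub.iterrows():
        for h in HORMONES:
            if not DOSE_RANGE[0] <= r[h] <= DOSE_RANGE[1]:
                _fail(f"{h}={r[h]} outside tested range {DOSE_RANGE}", int(i))
        if not 0.0 <= r["cfr_mean"] <= 100.0:
            _fail(f"cfr_mean={r['cfr_mean']} outside [0, 100]", int(i))
        if r["cfw_mean"] < 0 or r["cfr_se"] < 0 or r["cfw_se"] < 0:
            _fail("negative weight or standard error", int(i))
        if all(r[h] == 0 for h in HORMONES) and (r["cfr_mean"] != 0 or r["cfw_mean"] != 0):
            _fail("hormone-free control must have zero CFR and CFW", int(i))
    dupes = sub.duplicated(subset=HORMONES)
    if dupes.any():
        _fail("duplicate hormone-dose combination", int(sub.index[dupes][0]))
    return table


def load_packaged_table() -> pd.DataFrame:
    """Load the packaged 33-treatment table, in printed order.

    Returns a DataFrame with columns ``bap, kin, naa, iba, cfr_mean,
    cfr_se, cfw_mean, cfw_se``.
    """
    ref = importlib.resources.files("callopt") / "data" / "treatments.csv"
    with importlib.resources.as_file(ref) as p:
        table = pd.read_csv(p)
    validate_treatments(table)
    if len(table) != 33:
        _fail(f"packaged fixture must have 33 rows, found {len(table)}")
    return table


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a treatment-level CSV (comma separator, ``.`` decimal)."""
    path = Path(path)
    try:
        table = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        _fail(f"empty treatment table: {path}")
    if table.empty:
        _fail(f"empty treatment table: {path}")
    return validate_treatments(table)


def write_table(table: pd.DataFrame, path: str | Path) -> None:
    validate_treatments(table)
    table[TREATMENT_COLUMNS].to_csv(path, index=False)


def validate_replicates(table: pd.DataFrame, granular: bool = True) -> pd.DataFrame:
    """Validate a replicate-level table.

    With ``granular=True`` (the default, matching four explants per
    vessel) CFR values must lie on the 0/25/50/75/100 lattice.
    """
    missing = [c for c in REPLICATE_COLUMNS if c not in table.columns]
    if missing:
        _fail(f"missing column(s): {', '.join(missing)}")
    for i, r in table.iterrows():
        for h in HORMONES:
            if not DOSE_RANGE[0] <= r[h] <= DOSE_RANGE[1]:
                _fail(f"{h}={r[h]} outside tested range {DOSE_RANGE}", int(i))
        if not 0.0 <= r["cfr"] <= 100.0:
            _fail(f"cfr={r['cfr']} outside [0, 100]", int(i))
        if granular and r["cfr"] not in CFR_LATTICE:
            _fail(f"cfr={r['cfr']} not on the 4-explant lattice {CFR_LATTICE}", int(i))
        if r["cfw"] < 0:
            _fail(f"negative cfw={r['cfw']}", int(i))
    return table


def read_replicates(path: str | Path, granular: bool = True) -> pd.DataFrame:
    """Read a replicate-level CSV (one row per vessel)."""
    path = Path(path)
    try:
        table = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        _fail(f"empty replicate table: {path}")
    if table.empty:
        _fail(f"empty replicate table: {path}")
    return validate_replicates(table, granular=granular)


def write_replicates(table: pd.DataFrame, path: str | Path, granular: bool = True) -> None:
    validate_replicates(table, granular=granular)
    table[REPLICATE_COLUMNS].to_csv(path, index=False)
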