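"""CSV/JSON readers and writers for the pipeline's table dialects.

Dialects (all plain CSV with C locale, strict headers):

* trace       — ``time_s,value,series``
* titration   — ``enzyme_uM,dna_uM,dilution_factor,value``
* quench      — ``time_s,length_nt,conc_uM`` (or series labels in
  ``series`` when bands are aggregated)
* trajectory  — ``time_s,species,conc_uM``
"""
from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .core import ConfigurationError

DIALECTS = {
    "trace": ["time_s", "value", "series"],
    "titration": ["enzyme_uM", "dna_uM", "dilution_factor", "value"],
    "quench": ["time_s", "series", "conc_uM"],
    "trajectory": ["time_s", "species", "conc_uM"],
}


class FormatError(ConfigurationError):
    """Malformed dataset file, naming the offending row/column."""


def write_dataset(df, path, dialect):
    cols = DIALECTS.get(dialect)
    if cols is None:
        raise FormatError(f"unknown dialect {dialect!r}")
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise FormatError(f"dataframe lacks columns {missing} for dialect {dialect!r}")
    df.loc[:, cols].to_csv(path, index=False)
    return Path(path)


def read_dataset(path, dialect):
    cols = DIALECTS.get(dialect)
    if cols is None:
        raise FormatError(f"unknown dialect {dialect!r}")
    df = pd.read_csv(path)
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    for c in ("series", "species"):
        if c in df.columns:
            df[c] = df[c].astype(str)
    numeric = [c for c in cols if c not in ("series", "species")]
    for c in numeric:
        try:
            df[c] = pd.to_numeric(df[c])
        except (ValueError, TypeError) as exc:
            raise FormatError(f"{path}: column {c!r} is not numeric: {exc}") from exc
        bad = df.index[df[c].isna()]
        if len(bad):
            raise FormatError(f"{path}: column {c!r} has missing values at row {bad[0]}")
    if "conc_uM" in df.columns and dialect == "quench":
        neg = df.index[df["conc_uM"] < 0]
        if len(neg):
            raise FormatError(
                f"{path}: negative concentration at row {neg[0]} (column conc_uM)"
            )
    if "time_s" in df.columns and (df["time_s"] < 0).any():
        raise FormatError(f"{path}: negative time values")
    return df[cols]


def write_trajectory(traj, path):
    return write_dataset(traj.to_frame(), path, "trajectory")


def _json_default(obj):
    if hasattr(obj, "item"):  # numpy scalar
        return obj.item()
    raise TypeError(f"cannot serialize {type(obj).__name__}")


def write_json(obj, path):
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True, default=_json_default)
    return Path(path)


def read_json(path):
    with open(path) as fh:
        return json.load(fh)


def fit_report_dict(result):
    """JSON-ready report of a global fit."""
    return {
        "chi2": result.chi2,
        "n_points": result.n_points,
        "n_free_params": result.n_free_params,
        "success": result.success,
        "message": result.message,
        "nfev": result.nfev,
        "unidentifiable": list(result.unidentifiable),
        "parameters": {
            sym: {
                "value": c.value,
                "units": c.units,
                "status": c.status,
                "fitted": sym in result.free_symbols,
                "ci": None,
            }
            for sym, c in result.rates.items()
        },
        "start": result.start,
    }
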