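"""Reading and writing the package's tabular artifacts and config files.

Event tables and killing-record tables travel as RFC-4180 CSV (UTF-8, '.'
decimal, header row required); missing dye intensities are empty fields.
Configuration files are TOML (preferred) or YAML.
"""

from __future__ import annotations

import dataclasses
import json
import tomllib
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .exceptions import ConfigError, SchemaError
from .simulate import EVENT_COLUMNS, SimConfig

MANDATORY_EVENT_COLUMNS = (
    "donor_id", "subset", "condition", "day", "dye_log_intensity", "dead",
)
RECORD_COLUMNS = (
    "donor_id", "effector", "target", "stratum", "day", "n_cells", "n_dead",
    "dead_fraction", "background_fraction", "specific_killing", "negative_flag",
)

_TRUE = {"true", "1", "t", "yes"}
_FALSE = {"false", "0", "f", "no"}


def _numeric_column(raw: pd.Series, name: str, optional_blank=False) -> pd.Series:
    s = raw.astype("string").str.strip()
    blank = s.isna() | (s == "")
    num = pd.to_numeric(s, errors="coerce")
    bad = num.isna() & ~blank
    if bad.any():
        rows = list(raw.index[bad][:10])
        raise SchemaError(
            f"column '{name}': unparseable value(s) at row(s) {rows}"
        )
    if blank.any() and not optional_blank:
        rows = list(raw.index[blank][:10])
        raise SchemaError(f"column '{name}': missing value(s) at row(s) {rows}")
    return num.astype(float)


def _bool_column(raw: pd.Series, name: str) -> pd.Series:
    s = raw.astype("string").str.strip().str.lower()
    out = pd.Series(pd.NA, index=raw.index, dtype="boolean")
    out[s.isin(_TRUE)] = True
    out[s.isin(_FALSE)] = False
    bad = out.isna()
    if bad.any():
        rows = list(raw.index[bad][:10])
        raise SchemaError(
            f"column '{name}': unparseable boolean(s) at row(s) {rows}"
        )
    return out.astype(bool)


def read_events(path) -> pd.DataFrame:
    """Read an event table CSV; unknown columns are preserved as-is.

    Raises :class:`SchemaError` naming the first missing mandatory column or
    the row numbers of unparseable values.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in MANDATORY_EVENT_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"missing mandatory column '{col}'")
    df["day"] = _numeric_column(df["day"], "day")
    df["dye_log_intensity"] = _numeric_column(
        df["dye_log_intensity"], "dye_log_intensity", optional_blank=True
    )
    df["dead"] = _bool_column(df["dead"], "dead")
    if "true_generation" in df.columns:
        df["true_generation"] = _numeric_column(
            df["true_generation"], "true_generation", optional_blank=True
        ).astype("Int64")
    return df


def write_events(events: pd.DataFrame, path) -> None:
    """Write an event table CSV (empty field for missing dye intensity)."""
    ordered = [c for c in EVENT_COLUMNS if c in events.columns]
    ordered += [c for c in events.columns if c not in ordered]
    events[ordered].to_csv(path, index=False, na_rep="")


def read_killing_records(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in RECORD_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"missing mandatory column '{col}'")
    return df


def write_killing_records(records: pd.DataFrame, path) -> None:
    records.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Config files
# ---------------------------------------------------------------------------

def _read_config_file(path) -> dict:
    path = Path(path)
    if path.suffix.lower() == ".toml":
        with open(path, "rb") as fh:
            return tomllib.load(fh)
    if path.suffix.lower() in (".yaml", ".yml"):
        with open(path, "r", encoding="utf-8") as fh:
            return yaml.safe_load(fh)
    raise ConfigError(f"unsupported config format: {path.suffix!r}")


def sim_config_from_dict(d: dict) -> SimConfig:
    """Build a :class:`SimConfig` from a (TOML/YAML-shaped) nested mapping.

    Nested tables use subset/effector names and day strings as keys, e.g.::

        [sim.background_death.Tconv."2.5"]
        high = 0.08
        low = 0.052
    """
    kw = {}
    simple = ("n_donors", "day_assignment", "cells_per_population", "dye_mu0",
              "dye_sigma", "g_max", "donor_sd_logit", "seed",
              "include_nk_rows")
    for key in simple:
        if key in d:
            kw[key] = d[key]
    if "generation_dist" in d:
        kw["generation_dist"] = {
            (subset, float(day)): np.asarray(vec, dtype=float)
            for subset, days in d["generation_dist"].items()
            for day, vec in days.items()
        }
    if "background_death" in d:
        kw["background_death"] = {
            (subset, float(day), stratum): float(p)
            for subset, days in d["background_death"].items()
            for day, strata in days.items()
            for stratum, p in strata.items()
        }
    if "kill_means" in d:
        kw["kill_means"] = {
            (effector, target, stratum): float(p)
            for effector, targets in d["kill_means"].items()
            for target, strata in targets.items()
            for stratum, p in strata.items()
        }
    return SimConfig(**kw)


def sim_config_to_dict(config: SimConfig) -> dict:
    """Inverse of :func:`sim_config_from_dict` (used for provenance)."""
    d = dataclasses.asdict(config)
    d["day_assignment"] = list(config.day_assignment)
    gd, bg, km = {}, {}, {}
    for (subset, day), vec in config.generation_dist.items():
        gd.setdefault(subset, {})[str(day)] = [float(v) for v in vec]
    for (subset, day, stratum), p in config.background_death.items():
        bg.setdefault(subset, {}).setdefault(str(day), {})[stratum] = float(p)
    for (effector, target, stratum), p in config.kill_means.items():
        km.setdefault(effector, {}).setdefault(target, {})[stratum] = float(p)
    d["generation_dist"], d["background_death"], d["kill_means"] = gd, bg, km
    return d


def load_sim_config(path) -> SimConfig:
    """Load a SimConfig from a TOML/YAML file (top-level or under ``[sim]``)."""
    d = _read_config_file(path)
    return sim_config_from_dict(d.get("sim", d)).validate()


def write_json(obj, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, default=_json_default)
        fh.write("\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
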