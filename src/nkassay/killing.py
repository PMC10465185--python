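"""Specific-killing statistics under the assay's gating rules.

The assay co-cultures dye-stained CD4+ T cells (conventional, ``Tconv``, or
regulatory, ``Treg``) with sorted NK effectors (``CD56br`` or ``CD56dim``) and
measures the dead-cell fraction with a viability dye.  Specific killing is the
dead fraction in co-culture minus the dead fraction of the same population
cultured alone (spontaneous-death background), computed either over all target
cells or stratified by proliferative state.  Two rules matter:

* all acquired cells are counted — dead cells are never gated out before the
  fraction is taken (no scatter pre-gating);
* target T cells are discriminated from NK cells by the presence of the
  proliferation dye (NK cells are not dye-stained).

A cell is "highly proliferative" when its division generation reaches a
day-specific threshold: >= 2 divisions at day 2.5, >= 3 at day 3.5 (the lower
day-2.5 cutoff accounts for the slower proliferation at that time point).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

T_SUBSETS = ("Tconv", "Treg")
EFFECTOR_FOR_CONDITION = {"cocult_br": "CD56br", "cocult_dim": "CD56dim"}
STRATA = ("all", "high", "low")

#: day -> minimum generation count of the "high" proliferative stratum
DEFAULT_THRESHOLDS = {2.5: 2, 3.5: 3}


@dataclass(frozen=True)
class StratifyRule:
    """Day-specific generation thresholds defining the 'high' stratum."""

    thresholds: dict = field(default_factory=lambda: dict(DEFAULT_THRESHOLDS))

    def __post_init__(self):
        for day, thr in self.thresholds.items():
            if not (isinstance(thr, (int, np.integer)) and thr > 0):
                raise ValueError(
                    f"stratify threshold for day {day} must be a positive "
                    f"integer, got {thr!r}"
                )

    def min_generations_high(self, day: float) -> int:
        try:
            return self.thresholds[float(day)]
        except KeyError:
            raise ValueError(
                f"unknown assay day {day!r}; known days: "
                f"{sorted(self.thresholds)}"
            ) from None

    def classify(self, generations, day) -> np.ndarray:
        """Vectorized stratum labels ('high'/'low') for generation counts."""
        g = np.asarray(generations)
        if np.any(g < 0):
            raise ValueError("generation counts must be non-negative")
        thr = self.min_generations_high(day)
        return np.where(g >= thr, "high", "low")


def stratify(generation: int, day: float, rule: StratifyRule | None = None) -> str:
    """Classify a single cell as 'high' or 'low' proliferative.

    Parameters
    ----------
    generation : int
        Number of divisions the cell has undergone (0 = undivided).
    day : float
        Assay day (2.5 or 3.5 under the default rule).
    """
    if generation < 0:
        raise ValueError("generation must be >= 0")
    rule = rule or StratifyRule()
    return "high" if generation >= rule.min_generations_high(day) else "low"


def gate_targets(events: pd.DataFrame) -> pd.DataFrame:
    """Return the target T-cell rows of an event table.

    Targets are the dye-stained rows (``dye_log_intensity`` present); NK
    effectors were not dye-stained and are excluded.  No viability-based
    exclusion is applied: dead cells stay in.
    """
    if "dye_log_intensity" in events.columns:
        mask = events["dye_log_intensity"].notna()
    elif "subset" in events.columns:
        mask = events["subset"].isin(T_SUBSETS)
    else:
        raise ValueError(
            "event table carries neither dye intensities nor subset labels"
        )
    gated = events.loc[mask]
    if len(gated) == 0:
        raise ValueError("no target T-cell rows in event table")
    return gated


def death_fraction(targets: pd.DataFrame) -> float:
    """Dead-cell fraction of a gated target population: (# dead) / (# cells)."""
    if len(targets) == 0:
        raise ValueError("empty target population")
    return float(np.asarray(targets["dead"], dtype=float).mean())


def specific_killing(dead_fraction: float, background_fraction: float) -> float:
    """Background-subtracted killing: co-culture dead fraction minus the
    spontaneous-death fraction of the matched no-NK control.

    Negative values are returned as-is (they are flagged, not censored, at
    the record level; see :func:`build_killing_table`).
    """
    for name, v in (("dead_fraction", dead_fraction),
                    ("background_fraction", background_fraction)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {v}")
    return dead_fraction - background_fraction


def build_killing_table(
    events: pd.DataFrame,
    generations,
    rule: StratifyRule | None = None,
) -> pd.DataFrame:
    """Per-donor specific-killing records, overall and by proliferative stratum.

    Parameters
    ----------
    events : pd.DataFrame
        Event table containing co-culture and matched ``alone`` (no-NK
        background) conditions.
    generations : array-like of int
        Division-generation assignment for each *gated target* row of
        ``events`` (same order as ``gate_targets(events)``), or a pandas
        Series indexed like ``events``.
    rule : StratifyRule, optional
        Day-specific thresholds for the high/low stratification.

    Returns
    -------
    pd.DataFrame
        One row per donor x effector x target x stratum with columns
        ``donor_id, effector, target, stratum, day, n_cells, n_dead,
        dead_fraction, background_fraction, specific_killing, negative_flag``.
        The background subtracted from a stratum is the matched control's
        dead fraction in the *same* stratum of the *same* donor and target.
    """
    rule = rule or StratifyRule()
    t = gate_targets(events).copy()
    if isinstance(generations, pd.Series):
        t["generation"] = generations.reindex(t.index)
        if t["generation"].isna().any():
            raise ValueError("generation series does not cover all target rows")
    else:
        gen = np.asarray(generations)
        if len(gen) != len(t):
            raise ValueError(
                f"got {len(gen)} generation assignments for {len(t)} "
                "gated target rows"
            )
        t["generation"] = gen

    records = []
    for (donor, target), grp in t.groupby(["donor_id", "subset"], sort=True):
        cocult = grp[grp["condition"].isin(EFFECTOR_FOR_CONDITION)]
        if len(cocult) == 0:
            continue
        alone = grp[grp["condition"] == "alone"]
        if len(alone) == 0:
            raise ValueError(
                f"missing 'alone' background control for donor {donor!r}, "
                f"target {target!r}"
            )
        for condition in ("cocult_br", "cocult_dim"):
            co = grp[grp["condition"] == condition]
            if len(co) == 0:
                continue
            effector = EFFECTOR_FOR_CONDITION[condition]
            day = float(co["day"].iloc[0])
            co_strat = rule.classify(co["generation"], day)
            bg_strat = rule.classify(alone["generation"], day)
            for stratum in STRATA:
                co_s = co if stratum == "all" else co[co_strat == stratum]
                bg_s = alone if stratum == "all" else alone[bg_strat == stratum]
                if len(co_s) == 0 or len(bg_s) == 0:
                    warnings.warn(
                        f"donor {donor} target {target} effector {effector}: "
                        f"stratum '{stratum}' empty in "
                        f"{'co-culture' if len(co_s) == 0 else 'control'}; "
                        "record skipped"
                    )
                    continue
                df = death_fraction(co_s)
                bf = death_fraction(bg_s)
                sk = specific_killing(df, bf)
                records.append(
                    dict(
                        donor_id=donor,
                        effector=effector,
                        target=target,
                        stratum=stratum,
                        day=day,
                        n_cells=len(co_s),
                        n_dead=int(np.asarray(co_s["dead"]).sum()),
                        dead_fraction=df,
                        background_fraction=bf,
                        specific_killing=sk,
                        negative_flag=sk < 0,
                    )
                )
    return pd.DataFrame.from_records(records)
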