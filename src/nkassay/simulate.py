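"""Synthetic event-level cytometry data with the structure the assay assumes.

The generator emulates a paired-donor NK-cell killing assay: each donor
contributes conventional (Tconv) and regulatory (Treg) CD4+ T-cell target
populations, each measured in three culture arms — co-culture with CD56-bright
NK cells, co-culture with CD56-dim NK cells, and alone (the spontaneous-death
background control).  T cells carry a proliferation dye whose log10
fluorescence drops by log10(2) per division; NK rows are not dye-stained.
Cell death is Bernoulli per cell with a probability that is additive on the
proportion scale (stratum background + stratum-specific killing in
co-culture), then shifted by a donor-level random offset on the logit scale.

Default calibration targets the study cohort: 14 donors split 10 (day 2.5) /
4 (day 3.5); generation distributions matching the printed division fractions
(94%/71% of Tconv/Treg divided by day 2.5; 97%/87% by day 3.5); spontaneous
death aggregating to 7.0%/16.2% (Tconv, day 2.5/3.5) and 8.6%/9.7% (Treg);
stratified killing means 25.6%/17.7% (CD56br on Tconv high/low) and
22.0%/15.0% (CD56br on Treg), with CD56dim near-flat across strata.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .exceptions import ConfigError
from .killing import EFFECTOR_FOR_CONDITION, StratifyRule, T_SUBSETS

LOG10_2 = float(np.log10(2.0))
CONDITIONS = ("cocult_br", "cocult_dim", "alone")
NK_SUBSET_FOR_CONDITION = {"cocult_br": "NK_br", "cocult_dim": "NK_dim"}
EVENT_COLUMNS = (
    "donor_id", "subset", "condition", "day",
    "dye_log_intensity", "dead", "true_generation",
)

G_MAX_DEFAULT = 6


def default_day_assignment(n_donors: int = 14) -> tuple:
    """10 donors at day 2.5 and 4 at day 3.5 for the default cohort size;
    otherwise the same ~10:4 proportion, rounded."""
    if n_donors == 14:
        n25 = 10
    else:
        n25 = int(round(n_donors * 10 / 14))
        n25 = min(max(n25, 0), n_donors)
    return (2.5,) * n25 + (3.5,) * (n_donors - n25)


def default_generation_dist() -> dict:
    """Probability over generations 0..6 per (subset, day).

    Chosen to match the study's printed division fractions: percent divided
    at day 2.5 = 94% (Tconv) / 71% (Treg), at day 3.5 = 97% / 87%; G5
    fraction at day 2.5 = 0.51% / 0.19%; >= G5 at day 3.5 = 16.52% / 25.81%.
    """
    return {
        ("Tconv", 2.5): np.array([0.06, 0.30, 0.34, 0.21, 0.0848, 0.0051, 0.0001]),
        ("Treg", 2.5): np.array([0.29, 0.33, 0.22, 0.11, 0.0480, 0.0019, 0.0001]),
        ("Tconv", 3.5): np.array([0.03, 0.10, 0.22, 0.27, 0.2148, 0.12, 0.0452]),
        ("Treg", 3.5): np.array([0.13, 0.08, 0.16, 0.19, 0.1819, 0.16, 0.0981]),
    }


def default_background_death() -> dict:
    """Spontaneous-death probability per (subset, day, stratum).

    Stratum values are set so that, weighted by the default generation
    distributions' stratum sizes, day-level means hit the printed medians
    (Tconv: 7.0% at day 2.5, 16.2% at day 3.5; Treg: 8.6%, 9.7%).
    """
    return {
        ("Tconv", 2.5, "high"): 0.080, ("Tconv", 2.5, "low"): 0.052,
        ("Tconv", 3.5, "high"): 0.180, ("Tconv", 3.5, "low"): 0.129,
        ("Treg", 2.5, "high"): 0.096, ("Treg", 2.5, "low"): 0.080,
        ("Treg", 3.5, "high"): 0.104, ("Treg", 3.5, "low"): 0.085,
    }


def default_kill_means() -> dict:
    """Specific-killing group mean per (effector, target, stratum),
    on the proportion scale (printed stratified medians for CD56br;
    CD56dim set near-flat so its stratum fold changes sit at ~0.96/0.94
    and its all-cells means at ~22.5%/20.7%)."""
    return {
        ("CD56br", "Tconv", "high"): 0.256, ("CD56br", "Tconv", "low"): 0.177,
        ("CD56br", "Treg", "high"): 0.220, ("CD56br", "Treg", "low"): 0.150,
        ("CD56dim", "Tconv", "high"): 0.221, ("CD56dim", "Tconv", "low"): 0.230,
        ("CD56dim", "Treg", "high"): 0.196, ("CD56dim", "Treg", "low"): 0.209,
    }


@dataclass
class SimConfig:
    """Full parameterization of a synthetic assay cohort.

    Attributes
    ----------
    n_donors : int
        Cohort size (default 14).
    day_assignment : tuple of float
        Assay day per donor; default 10 donors at 2.5 and 4 at 3.5.
    cells_per_population : int
        Acquired cells per donor x subset x condition population
        (default 20 000; real assays plate 50 000).
    dye_mu0, dye_sigma : float
        Undivided-peak position and within-generation SD, log10 scale.
    generation_dist : dict
        (subset, day) -> probability vector over generations 0..g_max.
    background_death : dict
        (subset, day, stratum) -> spontaneous-death probability.
    kill_means : dict
        (effector, target, stratum) -> specific-killing group mean.
    donor_sd_logit : float
        SD of the donor-level logit-scale offset, drawn once per
        donor x target subset and shared across that subset's culture arms.
    seed : int
        Seed of the panel-level RNG stream; per-donor substreams are
        derived deterministically.
    include_nk_rows : bool
        Whether to emit (dye-negative, never-counted) NK effector rows.
    """

    n_donors: int = 14
    day_assignment: tuple = None
    cells_per_population: int = 20_000
    dye_mu0: float = 4.5
    dye_sigma: float = 0.08
    g_max: int = G_MAX_DEFAULT
    generation_dist: dict = field(default_factory=default_generation_dist)
    background_death: dict = field(default_factory=default_background_death)
    kill_means: dict = field(default_factory=default_kill_means)
    donor_sd_logit: float = 0.15
    seed: int = 0
    include_nk_rows: bool = True

    def __post_init__(self):
        if self.day_assignment is None:
            self.day_assignment = default_day_assignment(self.n_donors)
        self.day_assignment = tuple(float(d) for d in self.day_assignment)
        self.generation_dist = {
            k: np.asarray(v, dtype=float) for k, v in self.generation_dist.items()
        }

    # -- validation -------------------------------------------------------
    def validate(self) -> "SimConfig":
        if self.n_donors < 1:
            raise ConfigError("n_donors: must be >= 1")
        if len(self.day_assignment) != self.n_donors:
            raise ConfigError(
                f"day_assignment: length {len(self.day_assignment)} != "
                f"n_donors {self.n_donors}"
            )
        if self.cells_per_population < 1:
            raise ConfigError("cells_per_population: must be >= 1")
        if not self.dye_sigma > 0:
            raise ConfigError("dye_sigma: must be > 0")
        if self.g_max < 1:
            raise ConfigError("g_max: must be >= 1")
        for key, w in self.generation_dist.items():
            if len(w) != self.g_max + 1:
                raise ConfigError(
                    f"generation_dist{key}: expected {self.g_max + 1} entries"
                )
            if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
                raise ConfigError(
                    f"generation_dist{key}: entries must be non-negative and "
                    f"sum to 1 (sum = {w.sum():.12f})"
                )
        for key, p in self.background_death.items():
            if not 0.0 <= p < 1.0:
                raise ConfigError(f"background_death{key}: {p} not in [0, 1)")
        for key, p in self.kill_means.items():
            if not 0.0 <= p < 1.0:
                raise ConfigError(f"kill_means{key}: {p} not in [0, 1)")
        if self.donor_sd_logit < 0:
            raise ConfigError("donor_sd_logit: must be >= 0")
        for day in self.day_assignment:
            for subset in T_SUBSETS:
                if (subset, day) not in self.generation_dist:
                    raise ConfigError(
                        f"generation_dist: missing entry for ({subset}, {day})"
                    )
        return self

    def replace(self, **kw) -> "SimConfig":
        return replace(self, **kw)


def simulate_dye(generations, mu0: float, sigma: float, seed=None) -> np.ndarray:
    """Log10 dye intensities for cells of known generation.

    Each division halves fluorescence, so intensity ~
    Normal(mu0 - g*log10(2), sigma).

    Parameters
    ----------
    generations : array-like of int, all >= 0
    mu0 : float
        Undivided-peak position (log10 scale).
    sigma : float
        Within-generation SD (> 0).
    seed : int, numpy Generator, or None
    """
    g = np.asarray(generations)
    if np.any(g < 0):
        raise ValueError("generations must be non-negative")
    if not sigma > 0:
        raise ValueError("sigma must be > 0")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    return rng.normal(loc=mu0 - g * LOG10_2, scale=sigma, size=len(g))


def _shift_logit(p: np.ndarray, delta: float) -> np.ndarray:
    """expit(logit(p) + delta) with the boundary cases 0 and 1 preserved."""
    p = np.asarray(p, dtype=float)
    out = np.empty_like(p)
    interior = (p > 0) & (p < 1)
    out[~interior] = p[~interior]
    out[interior] = expit(logit(p[interior]) + delta)
    return out


def simulate_panel(config: SimConfig, rule: StratifyRule | None = None) -> pd.DataFrame:
    """Generate an event table for the whole cohort.

    One row per acquired cell with columns ``donor_id, subset, condition,
    day, dye_log_intensity, dead, true_generation``.  For a fixed config
    (including seed) the output is byte-identical across calls.
    """
    config.validate()
    rule = rule or StratifyRule()
    n = config.cells_per_population
    donor_seeds = np.random.SeedSequence(config.seed).spawn(config.n_donors)

    frames = []
    for i, (day, ss) in enumerate(zip(config.day_assignment, donor_seeds)):
        rng = np.random.default_rng(ss)
        donor = f"D{i + 1:02d}"
        # one offset per target subset, shared across this subset's arms
        offsets = {s: rng.normal(0.0, config.donor_sd_logit) for s in T_SUBSETS}
        for subset in T_SUBSETS:
            w = config.generation_dist[(subset, day)]
            thr = rule.min_generations_high(day)
            for condition in CONDITIONS:
                g = rng.choice(config.g_max + 1, size=n, p=w)
                dye = simulate_dye(g, config.dye_mu0, config.dye_sigma, rng)
                strata = np.where(g >= thr, "high", "low")
                p = np.empty(n)
                for stratum in ("high", "low"):
                    mask = strata == stratum
                    base = config.background_death[(subset, day, stratum)]
                    if condition != "alone":
                        effector = EFFECTOR_FOR_CONDITION[condition]
                        base = base + config.kill_means.get(
                            (effector, subset, stratum), 0.0
                        )
                    p[mask] = min(max(base, 0.0), 1.0)
                p_cell = _shift_logit(p, offsets[subset])
                dead = rng.random(n) < p_cell
                frames.append(pd.DataFrame({
                    "donor_id": donor,
                    "subset": subset,
                    "condition": condition,
                    "day": day,
                    "dye_log_intensity": dye,
                    "dead": dead,
                    "true_generation": pd.array(g, dtype="Int64"),
                }))
        if config.include_nk_rows:
            for condition in ("cocult_br", "cocult_dim"):
                frames.append(pd.DataFrame({
                    "donor_id": donor,
                    "subset": NK_SUBSET_FOR_CONDITION[condition],
                    "condition": condition,
                    "day": day,
                    "dye_log_intensity": np.nan,
                    # NK death is out of scope; NK rows are never targets
                    "dead": False,
                    "true_generation": pd.array([pd.NA] * n, dtype="Int64"),
                }))
    out = pd.concat(frames, ignore_index=True)
    return out[list(EVENT_COLUMNS)]
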