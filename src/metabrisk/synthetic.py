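"""Seeded synthetic plasma-metabolomics cohorts for end-to-end testing.

Real case-control NMR cohorts of this kind are small (tens of samples per
group) and their metabolite concentrations are strictly positive and
right-skewed, so each concentration is drawn log-normally around a
group-specific mean. The generator plants three kinds of structure:

* a *panel* of metabolites whose means are shifted multiplicatively in every
  pancreatic-cancer (PC) stage group relative to both control groups (healthy
  controls, HC, and type-2 diabetics, DM2) — these are what univariate
  screening and OPLS-DA should recover;
* *trend* metabolites whose means follow a geometric progression across the
  three PC stage groups (early I+II -> III -> metastatic IV), up or down;
* a recent-onset-diabetes (RODM) group that is a labelled mixture of
  DM2-like and PC-like samples — the external cohort the risk ensemble
  classifies, with ground truth retained for recovery tests.

Two dummy contaminant metabolites ("Glycerol", "Propylene glycol") are always
generated so the preprocessing exclusion filter is exercised end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .profiles import DEFAULT_EXCLUSIONS, ProfileMatrix

__all__ = ["CohortConfig", "TruthLabels", "generate_cohort", "truth_summary"]

PC_STAGES = ("PC I+II", "PC III", "PC IV")
CONTROL_GROUPS = ("HC", "DM2")

DEFAULT_GROUP_SIZES = {
    "HC": 28,
    "DM2": 32,
    "PC I+II": 26,
    "PC III": 27,
    "PC IV": 35,
    "RODM": 59,
}

#: Metabolites carrying a group effect in every PC stage vs both controls.
DEFAULT_PANEL = (
    "3-hydroxyisovalerate",
    "creatine",
    "fumarate",
    "gluconate",
    "lysine",
    "mannose",
    "N-acetylcysteine",
    "proline",
    "propionate",
)

#: Metabolites whose means rise monotonically with PC stage.
DEFAULT_TREND_UP = ("hydroxyacetone", "2-hydroxyisovalerate", "3-methyl-2-oxovalerate")

#: Metabolites whose means fall monotonically with PC stage.
DEFAULT_TREND_DOWN = (
    "alanine",
    "creatinine",
    "dimethylamine",
    "N,N-dimethylglycine",
    "ethanol",
    "formate",
    "hypoxanthine",
    "valine",
)


class ConfigError(ValueError):
    """Raised when a CohortConfig field is invalid; the message names the field."""


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of one synthetic cohort.

    Parameters
    ----------
    group_sizes
        Samples per group; all sizes must be >= 2.
    n_metabolites
        Total metabolite count before contaminant exclusion (default 63,
        yielding 61 after the two contaminants are dropped).
    panel_metabolites, trend_up, trend_down
        Disjoint sets of metabolite names carrying planted effects.
    effect_size
        Multiplicative mean shift (> 0) of panel metabolites in PC groups vs
        controls; also sets the end-to-end span of the stage trends. 1 means
        no effect (exchangeable groups).
    noise_cv
        Coefficient of variation of the per-sample log-normal noise.
    rodm_pc_fraction
        Fraction of RODM samples drawn from a PC-like distribution (a stage is
        assigned round-robin); the rest are DM2-like. Count = nearest integer
        (ties rounded up).
    latent_correlation
        Optional strength of a single shared low-rank latent factor inducing
        metabolite-metabolite correlation; 0 (default) keeps metabolites
        independent so null calibration stays interpretable.
    seed
        Seed for all randomness; identical seeds give identical cohorts.
    """

    group_sizes: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    n_metabolites: int = 63
    panel_metabolites: tuple[str, ...] = DEFAULT_PANEL
    trend_up: tuple[str, ...] = DEFAULT_TREND_UP
    trend_down: tuple[str, ...] = DEFAULT_TREND_DOWN
    effect_size: float = 1.5
    noise_cv: float = 0.25
    rodm_pc_fraction: float = 0.2
    latent_correlation: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name, size in self.group_sizes.items():
            if not isinstance(size, (int, np.integer)) or size < 2:
                raise ConfigError(f"group_sizes[{name!r}] must be an integer >= 2, got {size!r}")
        if self.effect_size <= 0:
            raise ConfigError(f"effect_size must be > 0, got {self.effect_size}")
        if not 0 <= self.rodm_pc_fraction <= 1:
            raise ConfigError(
                f"rodm_pc_fraction must be in [0, 1], got {self.rodm_pc_fraction}"
            )
        if self.noise_cv <= 0:
            raise ConfigError(f"noise_cv must be > 0, got {self.noise_cv}")
        if not 0 <= self.latent_correlation < 1:
            raise ConfigError(
                f"latent_correlation must be in [0, 1), got {self.latent_correlation}"
            )
        names = self.metabolite_names()
        if self.n_metabolites != len(names):
            raise ConfigError(
                f"n_metabolites={self.n_metabolites} too small for "
                f"{len(set(self.panel_metabolites) | set(self.trend_up) | set(self.trend_down))}"
                " named effect metabolites plus the 2 contaminants"
            )
        panel, up, down = (
            set(self.panel_metabolites),
            set(self.trend_up),
            set(self.trend_down),
        )
        if panel & up or panel & down or up & down:
            raise ConfigError(
                "panel_metabolites, trend_up and trend_down must be disjoint"
            )

    def metabolite_names(self) -> list[str]:
        """Full ordered metabolite name list, contaminants last."""
        named = list(self.panel_metabolites) + list(self.trend_up) + list(self.trend_down)
        n_filler = self.n_metabolites - len(named) - len(DEFAULT_EXCLUSIONS)
        if n_filler < 0:
            raise ConfigError(
                f"n_metabolites={self.n_metabolites} is smaller than the named "
                "metabolites plus contaminants"
            )
        filler = [f"metab_{i:02d}" for i in range(1, n_filler + 1)]
        return named + filler + list(DEFAULT_EXCLUSIONS)


@dataclass
class TruthLabels:
    """Ground-truth generating labels: one row per sample.

    ``latent`` is the generating distribution ("DM2-like" or the PC stage
    name) and is informative only for RODM samples; for all other groups it
    equals the group itself.
    """

    table: pd.DataFrame  # columns: sample_id (index), group, latent

    @property
    def groups(self) -> pd.Series:
        return self.table["group"]

    @property
    def latent(self) -> pd.Series:
        return self.table["latent"]

    def pc_like_rodm(self) -> list[str]:
        t = self.table
        mask = (t["group"] == "RODM") & (t["latent"] != "DM2-like")
        return [str(i) for i in t.index[mask]]

    def dm2_like_rodm(self) -> list[str]:
        t = self.table
        mask = (t["group"] == "RODM") & (t["latent"] == "DM2-like")
        return [str(i) for i in t.index[mask]]

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path)


def _n_pc_like(fraction: float, n_rodm: int) -> int:
    # nearest integer, ties rounded up (0.2 * 59 = 11.8 -> 12)
    return int(np.floor(fraction * n_rodm + 0.5))


def generate_cohort(config: CohortConfig) -> tuple[ProfileMatrix, TruthLabels]:
    """Draw one synthetic cohort.

    Concentrations are strictly positive: sample i, metabolite j is
    ``mu_j * f(group_i, j) * exp(sigma * eps)`` with eps standard normal and
    ``sigma = sqrt(ln(1 + noise_cv^2))``, i.e. log-normal noise with the
    configured coefficient of variation. ``f`` encodes the planted effects:
    ``effect_size`` for panel metabolites in PC groups (and PC-like RODM
    samples), and a geometric progression ``effect_size**(k/3)`` for trend
    metabolites at stage k = 1..3 (inverted for downward trends). With
    ``effect_size = 1`` all groups are exchangeable.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    names = config.metabolite_names()
    m = len(names)
    name_idx = {n: j for j, n in enumerate(names)}

    # Baseline mean concentrations: log-uniform over ~2 decades, mimicking the
    # wide dynamic range of quantified plasma metabolites.
    baseline = 10.0 ** rng.uniform(-1.0, 1.0, size=m)

    sigma = float(np.sqrt(np.log1p(config.noise_cv**2)))

    def stage_factor(metab: str, group: str, latent_stage: "str | None" = None) -> float:
        g = latent_stage if latent_stage is not None else group
        if g in CONTROL_GROUPS or g == "DM2-like":
            return 1.0
        if g not in PC_STAGES:
            return 1.0
        if metab in config.panel_metabolites:
            return config.effect_size
        k = PC_STAGES.index(g) + 1
        if metab in config.trend_up:
            return float(config.effect_size ** (k / 3.0))
        if metab in config.trend_down:
            return float(config.effect_size ** (-k / 3.0))
        return 1.0

    rows = []
    sample_ids: list[str] = []
    groups: list[str] = []
    latents: list[str] = []

    for group, size in config.group_sizes.items():
        if group == "RODM":
            n_pc = _n_pc_like(config.rodm_pc_fraction, size)
            # PC-like samples get stages round-robin; order then shuffled so
            # sample id carries no information about the latent class.
            latent_pool = ["DM2-like"] * (size - n_pc) + [
                PC_STAGES[i % len(PC_STAGES)] for i in range(n_pc)
            ]
            rng.shuffle(latent_pool)
        else:
            latent_pool = [group] * size
        for i in range(size):
            latent = latent_pool[i]
            sid = f"{group.replace(' ', '')}_{i + 1:03d}"
            factors = np.array(
                [stage_factor(nm, group, latent if group == "RODM" else None) for nm in names]
            )
            eps = rng.standard_normal(m)
            if config.latent_correlation > 0:
                shared = rng.standard_normal()
                rho = config.latent_correlation
                eps = np.sqrt(1 - rho) * eps + np.sqrt(rho) * shared
            row = baseline * factors * np.exp(sigma * eps)
            rows.append(row)
            sample_ids.append(sid)
            groups.append(group)
            latents.append(latent)

    values = pd.DataFrame(np.array(rows), index=pd.Index(sample_ids, name="sample_id"), columns=names)
    matrix = ProfileMatrix(values, pd.Series(groups, index=values.index, name="group"))
    truth = TruthLabels(
        pd.DataFrame(
            {"group": groups, "latent": latents},
            index=pd.Index(sample_ids, name="sample_id"),
        )
    )
    return matrix, truth


def truth_summary(labels: TruthLabels) -> pd.DataFrame:
    """Counts per (group, latent class); counts sum to the total sample count."""
    if labels.table.empty:
        raise ValueError("labels are empty")
    out = (
        labels.table.groupby(["group", "latent"], sort=True)
        .size()
        .rename("count")
        .reset_index()
    )
    return out
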