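"""Synthetic cohort generators with planted ground truth.

Two generators emulate the data this package analyses:

* a cross-sectional "four-vessel" cohort — one plasma sample per maternal
  vessel (radial artery RA, antecubital vein AV, uterine vein UV) per
  participant, with a sparse set of proteins planted as released to or taken
  up from the maternal circulation by the uteroplacental unit, a per-sample
  multiplicative vein-vs-artery bias ("water shift") and optional
  missing-at-random vessels;

* a longitudinal cohort — up to three antecubital-vein samples per
  participant across gestation, with participant random intercepts, two
  trajectory-shape families, and a small set of "clock" proteins whose log2
  abundance rises linearly with gestational age.

Both return the simulated table together with a :class:`SyntheticTruth`
recording every plant, so downstream stages can be tested by parameter
recovery rather than against unavailable cohort data.

All abundances are generated directly on the log2 RFU scale (log-normal on
the raw scale).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError

VESSELS = ("RA", "AV", "UV")

__all__ = [
    "SimConfig",
    "SyntheticTruth",
    "simulate_four_vessel",
    "simulate_longitudinal",
    "four_vessel_config",
    "clock_cohort_config",
    "trajectory_panel_config",
]


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic cohorts.

    Effects and noise terms are on the log2 RFU scale. ``release_effect`` /
    ``uptake_effect`` are planted mean paired UV−RA differences in units of
    log2 RFU; with the default ``pair_noise_sd = 1.0`` they read directly as
    standardized paired effect sizes.
    """

    n_participants: int = 75
    n_proteins: int = 4564

    # --- four-vessel plants -------------------------------------------------
    frac_released: float = 0.05
    frac_uptake: float = 0.02
    frac_arm_exchange: float = 0.10
    release_effect: float = 0.5
    uptake_effect: float = -0.5
    arm_effect: float = 0.5
    pair_noise_sd: float = 1.0
    water_shift_sd: float = 0.1
    missing_vessel_rate: float = 0.0

    # --- abundance baseline -------------------------------------------------
    baseline_mean: float = 10.0
    baseline_sd: float = 2.0
    participant_sd: float = 0.3

    # --- longitudinal cohort ------------------------------------------------
    n_visits: int = 3
    ga_windows: tuple = ((12.0, 18.0), (21.0, 26.0), (29.0, 33.0))
    n_clock_proteins: int = 5
    clock_slope: float = 0.1
    random_intercept_sd: float = 0.3
    residual_sd: float = 0.05
    n_cluster1: int = 0
    n_cluster2: int = 0

    seed: int = 0

    def validate(self) -> None:
        for name in ("n_participants", "n_proteins", "n_visits"):
            if int(getattr(self, name)) < 1:
                raise ConfigurationError(f"{name} must be >= 1, got {getattr(self, name)}")
        for name in ("frac_released", "frac_uptake", "frac_arm_exchange",
                     "missing_vessel_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        if self.frac_released + self.frac_uptake + self.frac_arm_exchange > 1.0:
            raise ConfigurationError(
                "frac_released + frac_uptake + frac_arm_exchange must be <= 1"
            )
        for name in ("pair_noise_sd", "water_shift_sd", "baseline_sd",
                     "participant_sd", "random_intercept_sd", "residual_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0, got {getattr(self, name)}")
        prev_hi = -np.inf
        for lo, hi in self.ga_windows:
            if not (lo < hi and lo > prev_hi):
                raise ConfigurationError(
                    f"ga_windows must be increasing and non-overlapping, got {self.ga_windows}"
                )
            prev_hi = hi
        if self.n_visits > len(self.ga_windows):
            raise ConfigurationError(
                f"n_visits ({self.n_visits}) exceeds number of ga_windows ({len(self.ga_windows)})"
            )
        if (self.n_clock_proteins + self.n_cluster1 + self.n_cluster2) > self.n_proteins:
            raise ConfigurationError(
                "n_clock_proteins + n_cluster1 + n_cluster2 exceeds n_proteins"
            )


@dataclass
class SyntheticTruth:
    """Ground truth for one simulated cohort."""

    released_set: set = field(default_factory=set)
    uptake_set: set = field(default_factory=set)
    arm_exchange_set: set = field(default_factory=set)
    placenta_specific_set: set = field(default_factory=set)
    effect_sizes: dict = field(default_factory=dict)      # protein -> planted UV-RA mean
    arm_effect_sizes: dict = field(default_factory=dict)  # protein -> planted AV-RA mean
    water_shift: dict = field(default_factory=dict)       # participant -> {"UV": b, "AV": b}
    clock_set: dict = field(default_factory=dict)         # protein -> slope (log2 RFU / week)
    cluster_family: dict = field(default_factory=dict)    # protein -> 1 | 2 (others absent)

    def validate(self) -> None:
        assert self.placenta_specific_set <= self.released_set
        assert not (self.released_set & self.uptake_set)

    def to_json(self, path) -> None:
        payload = asdict(self)
        for k in ("released_set", "uptake_set", "arm_exchange_set", "placenta_specific_set"):
            payload[k] = sorted(payload[k])
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def _protein_ids(n: int) -> list[str]:
    return [f"seq_{i:05d}" for i in range(n)]


def _participant_ids(n: int) -> list[str]:
    return [f"P{i:04d}" for i in range(n)]


def simulate_four_vessel(config: SimConfig) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Simulate the cross-sectional three-maternal-vessel cohort.

    Returns a long-format table with columns ``participant_id``, ``vessel``
    and one numeric column per protein (log2 RFU); rows for vessels lost at
    ``missing_vessel_rate`` are absent. RA is the per-participant baseline;
    UV and AV add an independent per-sample water shift, planted exchange
    effects and within-pair noise.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, p = config.n_participants, config.n_proteins
    proteins = _protein_ids(p)
    participants = _participant_ids(n)

    protein_mean = rng.normal(config.baseline_mean, config.baseline_sd, size=p)
    participant_offset = rng.normal(0.0, config.participant_sd, size=n)

    # disjoint plants
    n_rel = round(config.frac_released * p)
    n_upt = round(config.frac_uptake * p)
    n_arm = round(config.frac_arm_exchange * p)
    perm = rng.permutation(p)
    rel_idx = perm[:n_rel]
    upt_idx = perm[n_rel:n_rel + n_upt]
    arm_idx = perm[n_rel + n_upt:n_rel + n_upt + n_arm]

    effect_uv = np.zeros(p)
    effect_uv[rel_idx] = config.release_effect
    effect_uv[upt_idx] = config.uptake_effect
    effect_av = np.zeros(p)
    effect_av[arm_idx] = config.arm_effect

    ws_uv = rng.normal(0.0, config.water_shift_sd, size=n)
    ws_av = rng.normal(0.0, config.water_shift_sd, size=n)

    ra = protein_mean[None, :] + participant_offset[:, None]
    uv = ra + ws_uv[:, None] + effect_uv[None, :] \
        + rng.normal(0.0, config.pair_noise_sd, size=(n, p))
    av = ra + ws_av[:, None] + effect_av[None, :] \
        + rng.normal(0.0, config.pair_noise_sd, size=(n, p))

    blocks = []
    for vessel, values in (("RA", ra), ("AV", av), ("UV", uv)):
        df = pd.DataFrame(values, columns=proteins)
        df.insert(0, "vessel", vessel)
        df.insert(0, "participant_id", participants)
        blocks.append(df)
    table = pd.concat(blocks, ignore_index=True)
    table = table.sort_values(["participant_id", "vessel"], kind="stable").reset_index(drop=True)

    if config.missing_vessel_rate > 0:
        keep = rng.random(len(table)) >= config.missing_vessel_rate
        table = table.loc[keep].reset_index(drop=True)

    rel = {proteins[i] for i in rel_idx}
    upt = {proteins[i] for i in upt_idx}
    arm = {proteins[i] for i in arm_idx}
    arm_positive = {proteins[i] for i in arm_idx if effect_av[i] > 0}
    truth = SyntheticTruth(
        released_set=rel,
        uptake_set=upt,
        arm_exchange_set=arm,
        placenta_specific_set=rel - arm_positive,
        effect_sizes={proteins[i]: float(effect_uv[i])
                      for i in np.concatenate([rel_idx, upt_idx])},
        arm_effect_sizes={proteins[i]: float(effect_av[i]) for i in arm_idx},
        water_shift={pid: {"UV": float(ws_uv[i]), "AV": float(ws_av[i])}
                     for i, pid in enumerate(participants)},
    )
    truth.validate()
    return table, truth


def _family1(ga: np.ndarray) -> np.ndarray:
    # monotone increase across gestation (scaled logistic)
    return 1.0 / (1.0 + np.exp(-(ga - 22.5) / 3.0))


def _family2(ga: np.ndarray) -> np.ndarray:
    # rise-then-fall with an interior maximum near week 23
    return 1.0 - ((ga - 23.0) / 9.0) ** 2


def simulate_longitudinal(config: SimConfig) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Simulate the longitudinal cohort (one sample per gestational window).

    Returns a table with columns ``participant_id``, ``visit``, ``ga_weeks``,
    ``age_years``, ``bmi``, ``nulliparity`` and one column per protein
    (log2 RFU). Clock proteins follow a linear gestational-age trend of
    ``clock_slope`` log2 RFU/week; family-1/2 proteins follow shared
    monotone-increasing and rise-then-fall mean shapes with per-protein
    amplitudes; everything else is flat. Every protein carries a participant
    random intercept (SD ``random_intercept_sd``) and residual noise.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, p = config.n_participants, config.n_proteins
    proteins = _protein_ids(p)
    participants = _participant_ids(n)

    perm = rng.permutation(p)
    clock_idx = perm[:config.n_clock_proteins]
    c1_idx = perm[config.n_clock_proteins:config.n_clock_proteins + config.n_cluster1]
    c2_idx = perm[config.n_clock_proteins + config.n_cluster1:
                  config.n_clock_proteins + config.n_cluster1 + config.n_cluster2]

    protein_mean = rng.normal(config.baseline_mean, config.baseline_sd, size=p)
    amp1 = rng.uniform(0.5, 1.5, size=len(c1_idx))
    amp2 = rng.uniform(0.5, 1.5, size=len(c2_idx))

    ga = np.column_stack([
        rng.uniform(lo, hi, size=n) for lo, hi in config.ga_windows[:config.n_visits]
    ])  # (n, n_visits)

    age = np.round(rng.normal(32.1, 3.6, size=n), 1)
    bmi = np.round(np.clip(rng.normal(24.1, 2.9, size=n), 17.0, None), 1)
    nullip = rng.random(n) < 0.5

    b = rng.normal(0.0, config.random_intercept_sd, size=(n, p))

    rows = []
    for v in range(config.n_visits):
        g = np.round(ga[:, v], 1)  # GA recorded (and used) to one decimal week
        values = protein_mean[None, :] + b
        if len(clock_idx):
            values[:, clock_idx] += config.clock_slope * (g[:, None] - 22.0)
        if len(c1_idx):
            values[:, c1_idx] += amp1[None, :] * _family1(g)[:, None]
        if len(c2_idx):
            values[:, c2_idx] += amp2[None, :] * _family2(g)[:, None]
        values = values + rng.normal(0.0, config.residual_sd, size=(n, p))
        df = pd.DataFrame(values, columns=proteins)
        df.insert(0, "nulliparity", nullip.astype(int))
        df.insert(0, "bmi", bmi)
        df.insert(0, "age_years", age)
        df.insert(0, "ga_weeks", g)
        df.insert(0, "visit", v + 1)
        df.insert(0, "participant_id", participants)
        rows.append(df)
    table = pd.concat(rows, ignore_index=True)
    table = table.sort_values(["participant_id", "visit"], kind="stable").reset_index(drop=True)

    truth = SyntheticTruth(
        clock_set={proteins[i]: float(config.clock_slope) for i in clock_idx},
        cluster_family={**{proteins[i]: 1 for i in c1_idx},
                        **{proteins[i]: 2 for i in c2_idx}},
    )
    return table, truth


# --- scenario factories -----------------------------------------------------

def four_vessel_config(seed: int = 0, **overrides) -> SimConfig:
    """Cross-sectional screening cohort: 75 participants, 4564 proteins, 5%
    released at standardized paired effect 0.5."""
    return SimConfig(**{**dict(seed=seed), **overrides})


def clock_cohort_config(seed: int = 0, **overrides) -> SimConfig:
    """Longitudinal clock cohort: 70 participants, 3 visits, 5 clock proteins
    (slope 0.1 log2 RFU/week) among 200, random-intercept SD 0.3, residual SD 0.05."""
    base = dict(
        n_participants=70, n_proteins=200, n_clock_proteins=5, clock_slope=0.1,
        random_intercept_sd=0.3, residual_sd=0.05, n_cluster1=0, n_cluster2=0,
        seed=seed,
    )
    return SimConfig(**{**base, **overrides})


def trajectory_panel_config(seed: int = 0, **overrides) -> SimConfig:
    """Longitudinal trajectory panel: 101 proteins in two shape families
    (85 monotone-increasing, 16 rise-then-fall)."""
    base = dict(
        n_participants=70, n_proteins=101, n_clock_proteins=0,
        n_cluster1=85, n_cluster2=16,
        random_intercept_sd=0.3, residual_sd=0.05, seed=seed,
    )
    return SimConfig(**{**base, **overrides})
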