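"""In-silico study generator.

Emulates the full design of a long-term dietary-intervention rat study
— four interventions (standard chow; high-fat high-sucrose diet; HFHSD
with metformin; HFHSD with liraglutide) crossed with both sexes, eight
animals per group — and produces every table the downstream pipeline
stages consume: weekly body mass and feeding records, GTT series at
weeks 0/5/12/18 (sampling 0/15/30/45/60/90/120/240 min) and ITT at week
18 (0/.../180 min), a fasting hormone panel, adipocyte surface areas,
and imaging-MS peak lists with group effects on designated m/z values.

Randomness is substreamed per animal (and per IMS sample) from a single
seed via spawn keys, so generation is bit-reproducible and adding
animals never perturbs the draws of existing ones.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .dynamics import DampedOscillationModel, ToleranceTestSeries, damped_oscillation
from .ims import PeakSpectrum
from .phenotype import DIETS

__all__ = [
    "IMSConfig",
    "CohortConfig",
    "Cohort",
    "load_default_dynamics",
    "generate_gtt_curve",
    "generate_cohort",
]

INTERVENTIONS = ("STD", "HFHSD", "HFHSD+M", "HFHSD+L")
SEXES = ("F", "M")

GTT_GRID_MIN = (0, 15, 30, 45, 60, 90, 120, 240)
ITT_GRID_MIN = (0, 15, 30, 45, 60, 90, 120, 180)
GTT_WEEKS = (0, 5, 12, 18)
ITT_WEEKS = (18,)

GLUCOSE_FLOOR_MGDL = 20.0  # physiological floor for simulated values


def load_default_dynamics() -> dict:
    """Load the versioned default group-true dynamics fixture."""
    ref = importlib.resources.files("glucodyn.data") / "default_dynamics.yaml"
    with importlib.resources.as_file(ref) as path:
        with open(path) as fh:
            return yaml.safe_load(fh)


@dataclass(frozen=True)
class IMSConfig:
    """Configuration of the imaging-MS peak-list generator.

    Peaks are laid on a fixed m/z grid inside ``mz_range``; per-peak
    base intensities are lognormal with peak-specific location drawn
    once per cohort, group effects multiply designated m/z values, each
    sample's m/z axis carries Gaussian ppm jitter, and the whole
    spectrum is scaled by a per-sample TIC factor (which TIC
    normalization must cancel).
    """

    n_peaks: int = 120
    mz_range: tuple[float, float] = (300.0, 1000.0)
    base_log_mu_sd: float = 1.2  # sd of per-peak lognormal location
    intensity_log_sd: float = 0.35  # biological lognormal spread per sample
    group_effects: dict = field(default_factory=lambda: {
        387.01: {"STD_M": 3.0},
        737.45: {"STD_M": 2.5, "HFHSD+L_M": 2.0},
        307.97: {"STD_F": 0.4, "STD_M": 0.4},
    })
    ppm_jitter_sd: float = 2.0
    tic_scale_range: tuple[float, float] = (0.5, 2.0)
    n_bio_replicates: int = 4
    n_tech_replicates: int = 2


@dataclass(frozen=True)
class CohortConfig:
    """Full synthetic-study description."""

    interventions: tuple[str, ...] = INTERVENTIONS
    sexes: tuple[str, ...] = SEXES
    n_per_group: int = 8
    gtt_grid_min: tuple[int, ...] = GTT_GRID_MIN
    itt_grid_min: tuple[int, ...] = ITT_GRID_MIN
    gtt_weeks: tuple[int, ...] = GTT_WEEKS
    itt_weeks: tuple[int, ...] = ITT_WEEKS
    weeks: tuple[int, ...] = tuple(range(0, 19))
    group_dynamics: dict | None = None  # defaults to the bundled fixture
    noise_sd_mgdl: float = 5.0
    animal_effect_cv: float = 0.08  # lognormal CV of per-animal A and G0 multipliers
    glucose_floor_mgdl: float = GLUCOSE_FLOOR_MGDL
    ims: IMSConfig = field(default_factory=IMSConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        for name in ("gtt_grid_min", "itt_grid_min"):
            grid = getattr(self, name)
            if len(grid) == 0 or grid[0] != 0:
                raise ValueError(f"{name} must start at 0")
            if any(b <= a for a, b in zip(grid, grid[1:])):
                raise ValueError(f"{name} must be strictly increasing")
        if self.noise_sd_mgdl < 0:
            raise ValueError("noise_sd_mgdl must be >= 0")
        if self.animal_effect_cv < 0:
            raise ValueError("animal_effect_cv must be >= 0")
        labels = [f"{i}_{s}" for i in self.interventions for s in self.sexes]
        if len(set(labels)) != len(labels):
            raise ValueError("group labels must be unique")

    @property
    def groups(self) -> list[tuple[str, str]]:
        return [(i, s) for i in self.interventions for s in self.sexes]

    def dynamics(self) -> dict:
        return self.group_dynamics if self.group_dynamics is not None \
            else load_default_dynamics()


@dataclass
class Cohort:
    config: CohortConfig
    animals: pd.DataFrame  # animal_id, intervention, sex, group
    body_mass: pd.DataFrame  # animal_id, week, mass_g
    feeding: pd.DataFrame  # group, week, food_g, group_mass_g
    tolerance_tests: list[ToleranceTestSeries]
    hormones: pd.DataFrame  # animal_id, fasting_glucose, insulin_ng_ml, leptin_ng_ml
    adipocytes: pd.DataFrame  # animal_id, area_um2
    spectra: list[PeakSpectrum]


def _model_from_params(p: dict, test_kind: str) -> DampedOscillationModel:
    return DampedOscillationModel(
        G0_setpoint=float(p["G0"]), A=float(p["A"]), alpha=float(p["alpha"]),
        T=float(p["T"]), phi=float(p["phi"]), r_squared=1.0, residual_sd=0.0,
        converged=True, test_kind=test_kind,
    )


def generate_gtt_curve(
    model: DampedOscillationModel,
    grid_min,
    noise_sd: float,
    rng: np.random.Generator,
    floor_mgdl: float = GLUCOSE_FLOOR_MGDL,
    subject_id: str = "sim",
    week: int = 0,
) -> ToleranceTestSeries:
    """Evaluate a group-true model on a minute grid and add Gaussian noise.

    Values are floored at ``floor_mgdl`` to stay physiological.
    """
    grid_min = np.asarray(grid_min, dtype=float)
    if grid_min.size == 0:
        raise ValueError("grid must be non-empty")
    t_h = grid_min / 60.0
    y = damped_oscillation(t_h, model.G0_setpoint, model.A, model.alpha, model.T, model.phi)
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=y.shape)
    y = np.maximum(y, floor_mgdl)
    return ToleranceTestSeries(subject_id, model.test_kind, week, t_h, y)


def _animal_rng(seed: int, group_idx: int, animal_idx: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(1, group_idx, animal_idx)))


def _stream(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=key))


# fasting hormone panel group means: (insulin ng/mL, leptin ng/mL).
# Liraglutide-treated females run hyperinsulinemic, diet groups exceed chow.
_HORMONE_MEANS = {
    ("STD", "F"): (1.2, 4.0), ("STD", "M"): (1.5, 5.0),
    ("HFHSD", "F"): (2.5, 8.0), ("HFHSD", "M"): (2.8, 9.0),
    ("HFHSD+M", "F"): (1.8, 7.0), ("HFHSD+M", "M"): (2.2, 8.0),
    ("HFHSD+L", "F"): (4.0, 10.0), ("HFHSD+L", "M"): (2.4, 7.5),
}

# adipocyte lognormal area parameters (mean of log um^2, sd of log):
# diet enlarges adipocytes, liraglutide shrinks them back.
_ADIPOCYTE_LOGMEAN = {
    ("STD", "F"): 8.10, ("STD", "M"): 8.20,
    ("HFHSD", "F"): 8.45, ("HFHSD", "M"): 8.50,
    ("HFHSD+M", "F"): 8.40, ("HFHSD+M", "M"): 8.60,
    ("HFHSD+L", "F"): 8.15, ("HFHSD+L", "M"): 8.25,
}
_ADIPOCYTE_LOGSD = 0.45
_N_ADIPOCYTES_PER_ANIMAL = 50

_BASE_MASS_G = {"F": 320.0, "M": 550.0}
_FOOD_G_PER_ANIMAL_WEEK = {"STD": 150.0, "HFHSD": 120.0,
                           "HFHSD+M": 105.0, "HFHSD+L": 110.0}


def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate the complete in-silico cohort for one configuration.

    Deterministic for a fixed seed; each animal's tolerance-test series
    is the group-true curve scaled by the animal's lognormal effect on
    amplitude and setpoint, plus independent Gaussian measurement noise.
    """
    dyn = config.dynamics()
    sigma = math.sqrt(math.log(1.0 + config.animal_effect_cv**2)) \
        if config.animal_effect_cv > 0 else 0.0

    animal_rows, mass_rows, tests = [], [], []
    hormone_rows, adipo_rows = [], []

    for gi, (interv, sex) in enumerate(config.groups):
        group = f"{interv}_{sex}"
        ins_mu, lep_mu = _HORMONE_MEANS.get((interv, sex), (1.5, 5.0))
        for ai in range(config.n_per_group):
            aid = f"{group}_{ai + 1:02d}"
            rng = _animal_rng(config.seed, gi, ai)
            # lognormal multiplicative animal effect on A and G0 only
            eff_A = float(np.exp(rng.normal(-sigma**2 / 2, sigma))) if sigma else 1.0
            eff_G0 = float(np.exp(rng.normal(-sigma**2 / 2, sigma))) if sigma else 1.0
            animal_rows.append({"animal_id": aid, "intervention": interv,
                                "sex": sex, "group": group,
                                "effect_A": eff_A, "effect_G0": eff_G0})

            base_mass = _BASE_MASS_G[sex] * float(np.exp(rng.normal(0, 0.05))) \
                if sigma else _BASE_MASS_G[sex]
            for wk in config.weeks:
                drift = 1.0 + 0.002 * wk
                jitter = float(np.exp(rng.normal(0, 0.01))) if sigma else 1.0
                mass_rows.append({"animal_id": aid, "week": wk,
                                  "mass_g": base_mass * drift * jitter})

            for test_kind, weeks, grid in (
                ("GTT", config.gtt_weeks, config.gtt_grid_min),
                ("ITT", config.itt_weeks, config.itt_grid_min),
            ):
                table = dyn["gtt" if test_kind == "GTT" else "itt"]
                for wk in weeks:
                    p = dict(table[interv][sex][wk])
                    p["A"] = p["A"] * eff_A
                    p["G0"] = p["G0"] * eff_G0
                    model = _model_from_params(p, test_kind)
                    tests.append(generate_gtt_curve(
                        model, grid, config.noise_sd_mgdl, rng,
                        config.glucose_floor_mgdl, subject_id=aid, week=wk))

            g0_18 = dyn["gtt"][interv][sex][max(config.gtt_weeks)]["G0"] * eff_G0
            fasting = g0_18 + (rng.normal(0, 4.0) if config.noise_sd_mgdl > 0 else 0.0)
            insulin = max(0.05, ins_mu * float(np.exp(rng.normal(0, 0.25))))
            leptin = max(0.1, lep_mu * float(np.exp(rng.normal(0, 0.25))))
            hormone_rows.append({"animal_id": aid, "group": group,
                                 "intervention": interv, "sex": sex,
                                 "fasting_glucose_mgdl": max(fasting, 40.0),
                                 "insulin_ng_ml": insulin,
                                 "leptin_ng_ml": leptin})

            areas = np.exp(rng.normal(_ADIPOCYTE_LOGMEAN[(interv, sex)],
                                      _ADIPOCYTE_LOGSD, _N_ADIPOCYTES_PER_ANIMAL))
            for a in areas:
                adipo_rows.append({"animal_id": aid, "group": group,
                                   "intervention": interv, "sex": sex,
                                   "area_um2": float(a)})

    animals = pd.DataFrame(animal_rows)
    body_mass = pd.DataFrame(mass_rows)

    feed_rng = _stream(config.seed, 2)
    feed_rows = []
    for interv, sex in config.groups:
        group = f"{interv}_{sex}"
        diet = DIETS["STD" if interv == "STD" else "HFHSD"]
        ids = animals.loc[animals["group"] == group, "animal_id"]
        for wk in config.weeks:
            gmass = body_mass[(body_mass["animal_id"].isin(ids))
                              & (body_mass["week"] == wk)]["mass_g"].sum()
            base = _FOOD_G_PER_ANIMAL_WEEK["STD" if (interv == "STD" or wk < 1) else interv]
            food = base * len(ids)
            # liraglutide-treated females turn hyperphagic late in the study
            if interv == "HFHSD+L" and sex == "F" and wk >= 13:
                food *= 1.9
            food *= float(np.exp(feed_rng.normal(0, 0.03)))
            feed_rows.append({"group": group, "intervention": interv, "sex": sex,
                              "week": wk, "food_g": food, "group_mass_g": gmass,
                              "diet": diet.name})
    feeding = pd.DataFrame(feed_rows)

    spectra = _generate_spectra(config)

    return Cohort(config=config, animals=animals, body_mass=body_mass,
                  feeding=feeding, tolerance_tests=tests,
                  hormones=pd.DataFrame(hormone_rows),
                  adipocytes=pd.DataFrame(adipo_rows), spectra=spectra)


def _generate_spectra(config: CohortConfig) -> list[PeakSpectrum]:
    ims = config.ims
    grid_rng = _stream(config.seed, 3)
    lo, hi = ims.mz_range
    mz_grid = np.sort(grid_rng.uniform(lo, hi, ims.n_peaks))
    base_log = grid_rng.normal(0.0, ims.base_log_mu_sd, ims.n_peaks)

    # map designated effect m/z values onto the nearest generated peak
    effect_mult = {}
    for target_mz, per_group in ims.group_effects.items():
        j = int(np.argmin(np.abs(mz_grid - target_mz)))
        mz_grid[j] = float(target_mz)
        for grp, mult in per_group.items():
            effect_mult.setdefault(grp, np.ones(ims.n_peaks))[j] = mult

    spectra = []
    si = 0
    for interv, sex in config.groups:
        group = f"{interv}_{sex}"
        mult = effect_mult.get(group, np.ones(ims.n_peaks))
        for b in range(ims.n_bio_replicates):
            for t in range(ims.n_tech_replicates):
                rng = _stream(config.seed, 4, si)
                si += 1
                inten = np.exp(base_log
                               + rng.normal(0.0, ims.intensity_log_sd, ims.n_peaks))
                inten = inten * mult
                scale = rng.uniform(*ims.tic_scale_range)
                mz = mz_grid * (1.0 + rng.normal(0, ims.ppm_jitter_sd * 1e-6,
                                                 ims.n_peaks))
                order = np.argsort(mz)
                spectra.append(PeakSpectrum(
                    sample_id=f"{group}_b{b + 1}_t{t + 1}", group=group,
                    mz=mz[order], intensity=(inten * scale)[order],
                    bio_replicate=f"b{b + 1}", tech_replicate=f"t{t + 1}"))
    return spectra
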