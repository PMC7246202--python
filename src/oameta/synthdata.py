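"""Synthetic study-record generator with known ground truth.

Emulates the statistical structure assumed by the random-effects model:
each (group, response, CO2 category) cell has a true log response ratio
theta_cell; individual studies draw their own true effect from
Normal(theta_cell, tau^2) (between-study heterogeneity) and observe both
arms with within-arm sampling noise controlled by a coefficient of
variation and a replicate count.  Configured fractions of records are
emitted in median/quartile form, or report pH (with alkalinity,
temperature and salinity) instead of pCO2 so the carbonate solver is
exercised end-to-end.

Randomness is split per cell: each cell's stream is seeded by
(seed, crc32(cell key)), so adding or removing cells never perturbs the
draws of existing cells.
"""

from __future__ import annotations

import json
import zlib
from pathlib import Path
from typing import Dict, List, Tuple

import numpy as np
from pydantic import BaseModel, model_validator
from scipy.stats import norm

from .carbonate import solve_ph_from_pco2
from .ingest import StudyRecord, TreatmentArm, write_study_table

__all__ = [
    "SyntheticConfig",
    "generate",
    "generate_frame",
    "make_fixture_suite",
    "default_true_effects",
    "CATEGORY_REPRESENTATIVE_UATM",
]

# Representative treatment level emitted for each CO2 category (μatm).
CATEGORY_REPRESENTATIVE_UATM = {
    "preindustrial": 180.0,
    "c500_800": 650.0,
    "c801_1000": 900.0,
    "c1001_1500": 1250.0,
    "c1501_2000": 1750.0,
    "gt2000": 2500.0,
}

# Seawater conditions used when a record is emitted in pH form: cold
# Antarctic surface water with a typical Southern Ocean alkalinity.
PH_FORM_TEMPERATURE_C = 1.0
PH_FORM_SALINITY_PSU = 34.0
PH_FORM_ALKALINITY = 2300.0


def default_true_effects() -> Dict[Tuple[str, str, str], float]:
    """A small benefit-then-harm effect surface across taxa.

    Bacteria benefit at any elevation; phytoplankton chlorophyll a is
    mildly positive at moderate CO2 and harmed above 1,000 μatm;
    invertebrate shell state is harmed above 1,500 μatm.
    """
    surface: Dict[Tuple[str, str, str], float] = {}
    for cat in ("c500_800", "c801_1000", "c1001_1500", "c1501_2000", "gt2000"):
        surface[("bacteria", "abundance", cat)] = 0.25
    for cat, theta in [
        ("c500_800", 0.15),
        ("c801_1000", 0.15),
        ("c1001_1500", -0.30),
        ("c1501_2000", -0.30),
        ("gt2000", -0.40),
    ]:
        surface[("phytoplankton", "chlorophyll_a", cat)] = theta
    for cat, theta in [
        ("c500_800", 0.0),
        ("c801_1000", 0.0),
        ("c1001_1500", 0.0),
        ("c1501_2000", -0.35),
        ("gt2000", -0.45),
    ]:
        surface[("invertebrate", "shell_state", cat)] = theta
    return surface


class SyntheticConfig(BaseModel):
    """Ground-truth surface plus reporting mix for one generated table.

    Defaults describe a realistic short-term perturbation-experiment
    corpus: modest between-study heterogeneity (tau2 = 0.02 on the LnRR
    scale), 6 replicates per arm, 10% within-arm CV, about one record in
    ten reported as boxplot summaries and one in four reported as pH.
    """

    true_effects: Dict[str, float] = {}  # "group|response|category" -> theta
    tau2: float = 0.02
    n_studies_per_cell: int = 20
    n_replicates: int = 6
    cv: float = 0.10
    frac_quartile_reported: float = 0.10
    frac_ph_reported: float = 0.25
    ambient_uatm: float = 400.0
    baseline_mean: float = 100.0
    duration_days: float = 21.0
    directions: Dict[str, str] = {}  # response_name -> direction label
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "SyntheticConfig":
        if self.tau2 < 0:
            raise ValueError("tau2 must be non-negative")
        for name in ("frac_quartile_reported", "frac_ph_reported"):
            val = getattr(self, name)
            if not (0.0 <= val <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.cv <= 0:
            raise ValueError("cv must be positive")
        if self.n_studies_per_cell < 1 or self.n_replicates < 1:
            raise ValueError("counts must be >= 1")
        return self

    @staticmethod
    def cell_key(group: str, response: str, category: str) -> str:
        return f"{group}|{response}|{category}"

    def effects_by_cell(self) -> Dict[Tuple[str, str, str], float]:
        out = {}
        for key, theta in self.true_effects.items():
            group, response, category = key.split("|")
            out[(group, response, category)] = theta
        return out


def _cell_rng(seed: int, key: str) -> np.random.Generator:
    return np.random.default_rng([seed, zlib.crc32(key.encode())])


_GROUP_SPECIES = {
    "bacteria": "Marinomonas sp.",
    "phytoplankton": "Phaeocystis antarctica",
    "macroalgae": "Desmarestia anceps",
    "invertebrate": "Sterechinus neumayeri",
    "fish": "Trematomus bernacchii",
}
_GROUP_TROPHIC = {
    "bacteria": "prokaryote",
    "phytoplankton": "autotroph",
    "macroalgae": "autotroph",
    "invertebrate": "heterotroph",
    "fish": "heterotroph",
}


def _observe_arm(
    rng: np.random.Generator,
    true_mean: float,
    cv: float,
    n: int,
    floor: float,
) -> Tuple[float, float, int]:
    """Sample n replicates ~ N(true_mean, (cv*true_mean)^2), floored at a
    small positive value; return (sample mean, sample SE, truncation count)."""
    draws = rng.normal(true_mean, cv * true_mean, size=n)
    truncated = int((draws < floor).sum())
    draws = np.maximum(draws, floor)
    mean = float(draws.mean())
    se = float(draws.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    return mean, se, truncated


def generate(config: SyntheticConfig) -> Tuple[List[StudyRecord], dict]:
    """Generate study records for every configured cell.

    Returns (records, truth) where ``truth`` carries the per-cell true
    effects, the config, and the count of noise-floor truncation events
    (asserted rare under default settings).
    """
    cells = config.effects_by_cell()
    if not cells:
        cells = default_true_effects()
    floor = 0.01 * config.baseline_mean
    records: List[StudyRecord] = []
    truncations = 0

    # Cache the pH back-solve per (category) — the target pCO2 per
    # category is fixed, so the pH is too.
    ph_cache: Dict[float, float] = {}

    def ph_for(pco2: float) -> float:
        if pco2 not in ph_cache:
            ph_cache[pco2] = solve_ph_from_pco2(
                pco2,
                PH_FORM_ALKALINITY,
                PH_FORM_TEMPERATURE_C,
                PH_FORM_SALINITY_PSU,
                ph_scale="total",
            )
        return ph_cache[pco2]

    for (group, response, category) in sorted(cells):
        theta_cell = cells[(group, response, category)]
        key = SyntheticConfig.cell_key(group, response, category)
        rng = _cell_rng(config.seed, key)
        direction = config.directions.get(response, "higher_is_better")
        treat_co2 = CATEGORY_REPRESENTATIVE_UATM[category]
        for i in range(config.n_studies_per_cell):
            theta_i = rng.normal(theta_cell, np.sqrt(config.tau2))
            raw = theta_i if direction == "higher_is_better" else -theta_i
            mu_c = config.baseline_mean
            mu_e = config.baseline_mean * float(np.exp(raw))
            as_quartile = rng.random() < config.frac_quartile_reported
            as_ph = rng.random() < config.frac_ph_reported
            arms = []
            for is_control, mu, co2 in (
                (True, mu_c, config.ambient_uatm),
                (False, mu_e, treat_co2),
            ):
                mean, se, trunc = _observe_arm(
                    rng, mu, config.cv, config.n_replicates, floor
                )
                truncations += trunc
                arm = {"n": config.n_replicates, "is_control": is_control}
                if as_quartile:
                    sd = se * np.sqrt(config.n_replicates)
                    arm.update(
                        q1=mean + norm.ppf(0.25) * sd,
                        median=mean,
                        q3=mean + norm.ppf(0.75) * sd,
                    )
                else:
                    arm.update(mean=mean, se=se)
                if as_ph:
                    arm.update(
                        ph=ph_for(co2),
                        ph_scale="total",
                        temperature_c=PH_FORM_TEMPERATURE_C,
                        salinity_psu=PH_FORM_SALINITY_PSU,
                        alkalinity_umol_kg=PH_FORM_ALKALINITY,
                    )
                else:
                    arm.update(co2_uatm=co2)
                arms.append(TreatmentArm(**arm))
            records.append(
                StudyRecord(
                    study_id=f"synth-{key}-{i:03d}",
                    experiment_id="e1",
                    species=_GROUP_SPECIES[group],
                    group=group,
                    trophic_level=_GROUP_TROPHIC[group],
                    response_name=response,
                    direction=direction,
                    community_flag="single_species",
                    duration_days=config.duration_days,
                    costressors_ambient=True,
                    arms=arms,
                )
            )
    truth = {
        "true_effects": {SyntheticConfig.cell_key(*k): v for k, v in cells.items()},
        "tau2": config.tau2,
        "config": config.model_dump(),
        "truncation_events": truncations,
        "n_records": len(records),
    }
    return records, truth


def generate_frame(config: SyntheticConfig):
    """Generate and flatten to the canonical one-row-per-arm DataFrame."""
    from .ingest import records_to_frame

    records, truth = generate(config)
    return records_to_frame(records), truth


def make_fixture_suite(out_dir) -> Dict[str, Path]:
    """Write small named fixture tables covering every screening branch,
    plus a "knee" dataset with a benefit-then-harm effect surface.

    Returns a mapping from fixture name to file path.  A sidecar
    ``knee_truth.json`` records the knee dataset's true threshold
    category.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: Dict[str, Path] = {}

    def _base_record(study_id: str, **overrides) -> StudyRecord:
        fields = dict(
            study_id=study_id,
            experiment_id="e1",
            species="Phaeocystis antarctica",
            group="phytoplankton",
            trophic_level="autotroph",
            response_name="chlorophyll_a",
            direction="higher_is_better",
            community_flag="single_species",
            duration_days=14.0,
            costressors_ambient=True,
            arms=[
                TreatmentArm(co2_uatm=400.0, mean=100.0, se=5.0, n=6, is_control=True),
                TreatmentArm(co2_uatm=900.0, mean=80.0, se=5.0, n=6),
            ],
        )
        fields.update(overrides)
        return StudyRecord(**fields)

    fixtures = {
        "long_duration": _base_record("fx-long", duration_days=147.0),
        "costressor": _base_record("fx-costressor", costressors_ambient=False),
        "high_ambient": _base_record(
            "fx-high-ambient",
            arms=[
                TreatmentArm(co2_uatm=700.0, mean=100.0, se=5.0, n=6, is_control=True),
                TreatmentArm(co2_uatm=1800.0, mean=70.0, se=5.0, n=6),
            ],
        ),
        "quartile_reported": _base_record(
            "fx-quartile",
            arms=[
                TreatmentArm(co2_uatm=400.0, q1=92.0, median=100.0, q3=110.0, n=6, is_control=True),
                TreatmentArm(co2_uatm=900.0, q1=70.0, median=78.0, q3=88.0, n=6),
            ],
        ),
        "ph_reported": _base_record(
            "fx-ph",
            arms=[
                TreatmentArm(
                    ph=8.05, ph_scale="total", temperature_c=1.0, salinity_psu=34.0,
                    alkalinity_umol_kg=2300.0, mean=100.0, se=5.0, n=6, is_control=True,
                ),
                TreatmentArm(
                    ph=7.70, ph_scale="total", temperature_c=1.0, salinity_psu=34.0,
                    alkalinity_umol_kg=2300.0, mean=75.0, se=5.0, n=6,
                ),
            ],
        ),
        "zero_variance": _base_record(
            "fx-zerovar",
            arms=[
                TreatmentArm(co2_uatm=400.0, mean=100.0, se=0.0, n=6, is_control=True),
                TreatmentArm(co2_uatm=900.0, mean=90.0, se=0.0, n=6),
            ],
        ),
    }
    for name, rec in fixtures.items():
        path = out / f"{name}.csv"
        write_study_table([rec], path)
        paths[name] = path

    # Knee dataset: benefit below 1,000 μatm, sustained harm above.
    knee_cfg = SyntheticConfig(
        true_effects={
            "phytoplankton|chlorophyll_a|c500_800": 0.2,
            "phytoplankton|chlorophyll_a|c801_1000": 0.2,
            "phytoplankton|chlorophyll_a|c1001_1500": -0.4,
            "phytoplankton|chlorophyll_a|c1501_2000": -0.4,
            "phytoplankton|chlorophyll_a|gt2000": -0.4,
        },
        tau2=0.01,
        n_studies_per_cell=20,
        frac_quartile_reported=0.0,
        frac_ph_reported=0.0,
        seed=20,
    )
    knee_records, knee_truth = generate(knee_cfg)
    knee_path = out / "knee.csv"
    write_study_table(knee_records, knee_path)
    paths["knee"] = knee_path
    truth_path = out / "knee_truth.json"
    knee_truth["knee_category"] = "c1001_1500"
    knee_truth["threshold_uatm"] = 1000.0
    truth_path.write_text(json.dumps(knee_truth, indent=2))
    paths["knee_truth"] = truth_path
    return paths
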