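"""Synthetic screening cohorts with a known latent tolerance factor.

The generator emulates the screening design — 57 accessions, the
22-trait registry, control vs. salt (150 mM at germination / 300 mM at
seedling stage), 3 replicates, 50 seeds per dish over 12 days — from a
single-latent-factor model:

* each accession i carries a latent tolerance ``tau_i ~ U(tau_range)``;
* each tolerance-linked trait j responds with a power sensitivity
  ``s_j ~ U(0.5, 1.5)``: its salt/control mean ratio is
  ``clip(tau_i ** s_j + eps, 0.01, 1.2)`` with ``eps ~ N(0, sigma_e)``;
* control means are ``baseline_j * (1 + g_i)``, ``g_i ~ N(0, 0.1)``,
  modelling intrinsic size differences between accessions;
* replicate values are normal around the cell mean with coefficient of
  variation ``cv_replicate``, truncated at zero;
* decoy traits (two by default) get salt/control ratios drawn
  independently of tau, mimicking traits like root-bud ratio or average
  root diameter that carry no tolerance signal — these are what the
  correlation screen should drop.

The upper clip at 1.2 permits occasional STC > 1 (hormesis-like
responses).  A single latent factor is the simplest structure consistent
with the observation that nearly all trait tolerance coefficients are
positively inter-correlated in real screens.

Germination time-courses are generated in parallel: daily counts are
multinomial over days 1..12 under a discrete logistic hazard whose
plateau and speed improve with tau under salt.  Physiology series and
qPCR Ct tables for the downstream statistics are generated by
:func:`generate_physio_series` and :func:`generate_ct_table`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from .germination import GerminationCourse
from .registry import (
    SEEDLING,
    TREATMENT_CONTROL,
    TREATMENT_SALT,
    Trait,
    TraitRegistry,
    default_registry,
)

#: Plausible control-condition baselines per registry trait (units as registered).
TRAIT_BASELINES: dict[str, float] = {
    "germination_vigor": 70.0,
    "germination_rate": 90.0,
    "radicle_length": 3.5,
    "embryo_length": 2.5,
    "root_bud_ratio": 1.4,
    "germination_index": 20.0,
    "vitality_index": 70.0,
    "plant_height": 30.0,
    "leaf_length": 12.0,
    "leaf_width": 0.6,
    "leaf_area": 5.0,
    "fresh_weight_above_ground": 1.2,
    "fresh_weight_underground": 0.8,
    "dry_weight_above_ground": 0.25,
    "dry_weight_underground": 0.15,
    "root_shoot_ratio": 0.6,
    "root_length": 25.0,
    "root_project_area": 3.0,
    "root_surface_area": 9.0,
    "average_root_diameter": 0.4,
    "root_volume": 0.5,
    "root_tips": 120.0,
}

DECOY_BASELINE = 1.5
#: Salt/control ratio range for decoy traits (independent of tau).
DECOY_RATIO_RANGE = (0.6, 1.1)


@dataclass
class GenerationScenario:
    """Design constants and noise levels for one synthetic cohort."""

    n_accessions: int = 57
    n_replicates: int = 3
    n_seeds_per_dish: int = 50
    n_days: int = 12
    tau_range: tuple[float, float] = (0.2, 0.95)
    cv_replicate: float = 0.05
    sigma_e: float = 0.08
    n_noise_traits: int = 2
    sensitivity_range: tuple[float, float] = (0.5, 1.5)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_accessions", "n_replicates", "n_seeds_per_dish", "n_days"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        lo, hi = self.tau_range
        if not (0.0 < lo <= hi <= 1.2):
            raise ValueError("tau_range must lie within (0, 1.2]")
        if self.n_noise_traits < 0:
            raise ValueError("n_noise_traits must be >= 0")
        if self.cv_replicate < 0 or self.sigma_e < 0:
            raise ValueError("noise levels must be non-negative")


@dataclass
class CohortGroundTruth:
    """Latent parameters behind one generated cohort."""

    tau: dict[str, float]
    sensitivity: dict[str, float]
    noise_sd: float
    baseline_effect: dict[str, float] = field(default_factory=dict)  # g_i per accession
    true_fold_change: dict[str, float] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")


def accession_ids(n: int) -> list[str]:
    width = len(str(n))
    return [f"Q{i:0{width}d}" for i in range(1, n + 1)]


def decoy_trait_names(n: int) -> list[str]:
    return [f"decoy_ratio_{i + 1}" for i in range(n)]


def cohort_registry(scenario: GenerationScenario) -> TraitRegistry:
    """The 22-trait registry extended with the scenario's decoy traits."""
    extra = [Trait(name, SEEDLING, "dimensionless") for name in decoy_trait_names(scenario.n_noise_traits)]
    return default_registry().extended(extra)


def generate_cohort(
    scenario: GenerationScenario,
) -> tuple[pd.DataFrame, list[GerminationCourse], CohortGroundTruth]:
    """Generate one synthetic cohort.

    Returns the tidy trait-observation table (accession x treatment x
    trait x replicate), the germination time-courses, and the ground
    truth (tau, sensitivities, accession size effects).
    """
    rng = np.random.default_rng(scenario.seed)
    ids = accession_ids(scenario.n_accessions)
    registry = default_registry()
    linked = registry.names  # all 22 registry traits are tolerance-linked
    decoys = decoy_trait_names(scenario.n_noise_traits)

    lo, hi = scenario.tau_range
    tau = rng.uniform(lo, hi, size=scenario.n_accessions)
    g = np.clip(rng.normal(0.0, 0.1, size=scenario.n_accessions), -0.8, None)
    s_lo, s_hi = scenario.sensitivity_range
    sens = rng.uniform(s_lo, s_hi, size=len(linked))

    n_acc, n_rep = scenario.n_accessions, scenario.n_replicates
    rows: dict[str, list] = {"accession": [], "treatment": [], "trait": [], "replicate": [], "value": []}

    def emit(trait: str, means: np.ndarray, treatment: str) -> None:
        # means: per-accession cell means; draw replicates around them
        sd = scenario.cv_replicate * means
        draws = rng.normal(means[:, None], sd[:, None], size=(n_acc, n_rep))
        draws = np.clip(draws, 0.0, None)
        if scenario.cv_replicate == 0:
            draws = np.repeat(means[:, None], n_rep, axis=1)
        for a in range(n_acc):
            for r in range(n_rep):
                rows["accession"].append(ids[a])
                rows["treatment"].append(treatment)
                rows["trait"].append(trait)
                rows["replicate"].append(r + 1)
                rows["value"].append(draws[a, r])

    for j, trait in enumerate(linked):
        baseline = TRAIT_BASELINES[trait]
        control_mean = baseline * (1.0 + g)
        eps = rng.normal(0.0, scenario.sigma_e, size=n_acc) if scenario.sigma_e > 0 else 0.0
        ratio = np.clip(tau ** sens[j] + eps, 0.01, 1.2)
        emit(trait, control_mean, TREATMENT_CONTROL)
        emit(trait, control_mean * ratio, TREATMENT_SALT)

    for trait in decoys:
        control_mean = DECOY_BASELINE * (1.0 + g)
        ratio = rng.uniform(*DECOY_RATIO_RANGE, size=n_acc)
        emit(trait, control_mean, TREATMENT_CONTROL)
        emit(trait, control_mean * ratio, TREATMENT_SALT)

    obs = pd.DataFrame(rows)
    courses = _generate_courses(scenario, ids, tau, g, rng)
    truth = CohortGroundTruth(
        tau=dict(zip(ids, tau.tolist())),
        sensitivity={**dict(zip(linked, sens.tolist())), **{t: 0.0 for t in decoys}},
        noise_sd=scenario.sigma_e,
        baseline_effect=dict(zip(ids, g.tolist())),
    )
    return obs, courses, truth


def _logistic_day_probs(n_days: int, t50: float, scale: float, plateau: float) -> np.ndarray:
    """Daily germination probabilities: plateau * increments of a logistic CDF."""
    days = np.arange(0, n_days + 1, dtype=float)
    cdf = expit((days - t50) / scale)
    cdf = (cdf - cdf[0]) / (1.0 - cdf[0])  # start at 0 on day 0
    return plateau * np.diff(cdf)


def _generate_courses(
    scenario: GenerationScenario,
    ids: list[str],
    tau: np.ndarray,
    g: np.ndarray,
    rng: np.random.Generator,
) -> list[GerminationCourse]:
    courses = []
    n_seeds = scenario.n_seeds_per_dish
    for a, acc in enumerate(ids):
        for treatment in (TREATMENT_CONTROL, TREATMENT_SALT):
            if treatment == TREATMENT_CONTROL:
                plateau, t50, scale = 0.92, 3.0, 0.9
                radicle_mean = TRAIT_BASELINES["radicle_length"] * (1.0 + g[a])
                embryo_mean = TRAIT_BASELINES["embryo_length"] * (1.0 + g[a])
            else:
                # tolerant accessions germinate more, earlier, and grow longer
                plateau = min(0.92 * tau[a], 1.0)
                t50 = 3.0 + 4.0 * (1.0 - tau[a])
                scale = 1.4
                radicle_mean = TRAIT_BASELINES["radicle_length"] * (1.0 + g[a]) * tau[a]
                embryo_mean = TRAIT_BASELINES["embryo_length"] * (1.0 + g[a]) * tau[a]
            day_p = _logistic_day_probs(scenario.n_days, t50, scale, plateau)
            probs = np.append(day_p, max(0.0, 1.0 - day_p.sum()))
            probs = probs / probs.sum()
            for rep in range(1, scenario.n_replicates + 1):
                counts = rng.multinomial(n_seeds, probs)
                new_germ = counts[:-1]
                not_germ = int(counts[-1])
                moldy = int(rng.binomial(not_germ, 0.05))
                cv = scenario.cv_replicate
                radicle = max(float(rng.normal(radicle_mean, cv * radicle_mean)), 0.05)
                embryo = max(float(rng.normal(embryo_mean, cv * embryo_mean)), 0.05)
                courses.append(
                    GerminationCourse(
                        accession_id=acc,
                        treatment=treatment,
                        replicate=rep,
                        new_germinations=new_germ,
                        n_seeds=n_seeds,
                        moldy=moldy,
                        radicle_length_cm=radicle,
                        embryo_length_cm=embryo,
                    )
                )
    return courses


# ---------------------------------------------------------------------------
# physiology series

PHYSIO_VARIABLES = ("MDA", "REL", "RWC", "SPAD", "proline", "soluble_protein", "soluble_sugar")
PHYSIO_DAYS = (1, 5, 9, 13)

#: (baseline under CK, per-day slope under salt for the tolerant genotype).
#: Damage markers (MDA, REL) rise under salt; water status and greenness
#: (RWC, SPAD) fall; osmolytes (proline, proteins, sugars) accumulate.
PHYSIO_TRENDS: dict[str, tuple[float, float]] = {
    "MDA": (8.0, 1.0),  # nmol/g FW
    "REL": (15.0, 2.5),  # %
    "RWC": (92.0, -1.5),  # %
    "SPAD": (42.0, -1.0),  # SPAD units
    "proline": (30.0, 8.0),  # ug/g FW
    "soluble_protein": (12.0, 0.8),  # mg/g FW
    "soluble_sugar": (20.0, 1.5),  # mg/g FW
}

#: Multiplier on the salt-stress slope for the sensitive genotype's damage
#: markers (and attenuation of its protective accumulation).
SENSITIVE_DAMAGE_FACTOR = 2.0
PROTECTIVE = {"proline", "soluble_protein", "soluble_sugar"}


def generate_physio_series(
    genotypes: tuple[str, str] = ("ST", "SS"),
    n_replicates: int = 3,
    noise_sd: float = 0.5,
    seed: int = 0,
    trends: dict[str, tuple[float, float]] | None = None,
) -> pd.DataFrame:
    """Physiology time-series for one tolerant and one sensitive genotype.

    Cell means follow linear trends in days of salt exposure: under CK
    all variables stay at baseline; under salt, damage markers rise
    faster (and protective osmolytes accumulate more slowly) in the
    sensitive genotype.  Replicates are normal around the cell mean.
    """
    if len(genotypes) != 2:
        raise ValueError("exactly two genotypes (tolerant, sensitive) required")
    trends = PHYSIO_TRENDS if trends is None else trends
    unknown = set(trends) - set(PHYSIO_VARIABLES)
    if unknown:
        raise ValueError(f"unknown physiology variable(s): {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    tolerant, sensitive = genotypes
    rows = []
    for variable in PHYSIO_VARIABLES:
        baseline, slope = trends.get(variable, PHYSIO_TRENDS[variable])
        for genotype in genotypes:
            for treatment in ("CK", "T"):
                for day in PHYSIO_DAYS:
                    if treatment == "CK":
                        mean = baseline
                    else:
                        eff = slope
                        if genotype == sensitive:
                            if variable in PROTECTIVE:
                                eff = slope / SENSITIVE_DAMAGE_FACTOR
                            else:
                                eff = slope * SENSITIVE_DAMAGE_FACTOR
                        mean = baseline + eff * (day - 1)
                    for rep in range(1, n_replicates + 1):
                        value = mean if noise_sd == 0 else float(rng.normal(mean, noise_sd))
                        rows.append(
                            {
                                "genotype": genotype,
                                "treatment": treatment,
                                "day": day,
                                "variable": variable,
                                "replicate": rep,
                                "value": value,
                            }
                        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# qPCR Ct tables

REFERENCE_GENE = "actin"


def generate_ct_table(
    true_fold_change: dict[str, float],
    n_replicates: int = 3,
    ct_sd: float = 0.15,
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic Ct table under the 2^-ddCt model.

    The reference gene's Ct is constant across conditions; each target's
    treatment Ct sits ``log2(fold change)`` cycles below its control Ct,
    plus normal technical noise of sd ``ct_sd``.
    """
    bad = {g: f for g, f in true_fold_change.items() if f <= 0}
    if bad:
        raise ValueError(f"fold changes must be positive: {bad}")
    if REFERENCE_GENE in true_fold_change:
        raise ValueError(f"{REFERENCE_GENE!r} is the reference gene, not a target")
    rng = np.random.default_rng(seed)
    rows = []
    ref_ct = 20.0
    control_ct = {gene: float(rng.uniform(22.0, 30.0)) for gene in sorted(true_fold_change)}
    for condition in ("control", "treatment"):
        for rep in range(1, n_replicates + 1):
            sample = f"{condition}_{rep}"
            rows.append(
                {"sample": sample, "condition": condition, "gene": REFERENCE_GENE,
                 "is_reference": True, "ct": ref_ct}
            )
            for gene in sorted(true_fold_change):
                ct = control_ct[gene]
                if condition == "treatment":
                    ct = ct - np.log2(true_fold_change[gene])
                    if ct_sd > 0:
                        ct = float(rng.normal(ct, ct_sd))
                rows.append(
                    {"sample": sample, "condition": condition, "gene": gene,
                     "is_reference": False, "ct": ct}
                )
    return pd.DataFrame(rows)
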