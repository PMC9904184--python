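"""Synthetic-data generators for the digestion pipeline.

The generators stand in for the animal experiment: they emit raw inputs
(pressure traces, bag records, feed compositions) with the statistical
structure the analysis stages assume, together with the ground truth
that produced them, so every stage can be tested by parameter recovery.

* :func:`simulate_incubation` inverts the gas-kinetics pipeline: it
  evaluates the monophasic model on a 10-minute grid over 48 h, converts
  mL -> moles -> kPa -> psi in the stated headspace, applies automatic
  venting above the gauge threshold (0.75 psi by default) and adds
  Gaussian sensor noise.
* :func:`simulate_bag_study` draws bag fates (caecal recovery 78%, total
  97% by default), discretized lognormal transit times (mean 4.7 h,
  sd 1.7 h), per-bag DM disappearance from a common-slope linear model
  in residence time, and residue compositions consistent with
  per-nutrient soluble fractions (washing loss) plus a time-linear
  degradation term.
* :func:`simulate_feeds` draws replicate field-block compositions around
  grass x harvest means with component sugars summing exactly to WSC.

All generators are pure functions of (scenario, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Tuple

import numpy as np
import pandas as pd

from .errors import ScenarioError
from .feed_composition import FeedSample, GRASSES, HARVESTS
from .gas_kinetics import IncubationConstants, PressureTrace, monophasic_G
from .mobile_bag import BagRecord, DesignPlan, enumerate_bags

__all__ = [
    "TABLE_KINETICS",
    "DEFAULT_FEED_COMPS",
    "DEFAULT_NUTRIENT_PROFILE",
    "GasScenario",
    "BagScenario",
    "simulate_incubation",
    "simulate_bag_study",
    "simulate_feeds",
    "default_feed_effects",
]

# Reference kinetic ground truth (A mL/g DM, B h, C) per grass x harvest,
# spanning the range observed for cool-season grasses fermented in equine
# caecal inoculum.
TABLE_KINETICS: Dict[str, Tuple[float, float, float]] = {
    "SB_early": (164.5, 9.7, 1.80),
    "MF_early": (185.5, 9.0, 1.72),
    "CF_early": (163.1, 8.4, 1.95),
    "PR_early": (181.8, 8.3, 1.62),
    "TF_early": (178.2, 10.5, 1.38),
    "TI_early": (173.0, 9.6, 1.79),
    "SB_late": (151.8, 10.2, 1.40),
    "MF_late": (140.2, 12.1, 1.44),
    "CF_late": (112.3, 12.0, 1.88),
    "PR_late": (133.5, 7.6, 1.45),
    "TF_late": (142.0, 10.5, 1.24),
    "TI_late": (136.9, 9.4, 1.35),
}

# Feed composition defaults for the bag study, g/kg DM. Invented but
# realistic cool-season grass values: PR rich in WSC, CP falling and
# fiber rising from early to late harvest; component sugars sum exactly
# to total WSC.
DEFAULT_FEED_COMPS: Dict[Tuple[str, str], Dict[str, float]] = {
    ("PR", "early"): {
        "CP": 150.0, "aNDFom": 480.0, "WSC": 200.0, "ash": 80.0,
        "glucose": 25.0, "fructose": 35.0, "sucrose": 40.0, "fructan": 100.0,
    },
    ("PR", "late"): {
        "CP": 90.0, "aNDFom": 560.0, "WSC": 190.0, "ash": 70.0,
        "glucose": 15.0, "fructose": 25.0, "sucrose": 30.0, "fructan": 120.0,
    },
    ("CF", "early"): {
        "CP": 170.0, "aNDFom": 540.0, "WSC": 110.0, "ash": 90.0,
        "glucose": 15.0, "fructose": 20.0, "sucrose": 25.0, "fructan": 50.0,
    },
    ("CF", "late"): {
        "CP": 80.0, "aNDFom": 640.0, "WSC": 80.0, "ash": 75.0,
        "glucose": 8.0, "fructose": 12.0, "sucrose": 15.0, "fructan": 45.0,
    },
}

# (instantly washed-out soluble %, further loss %/h of caecal residence).
# Sugar fractions are washing-loss dominated; structural fiber barely
# disappears precaecally; fructan combines a ~70% wash loss with fast
# precaecal degradation of the remainder.
DEFAULT_NUTRIENT_PROFILE: Dict[str, Tuple[float, float]] = {
    "CP": (55.0, 2.5),
    "aNDFom": (2.0, 0.7),
    "WSC": (93.0, 0.8),
    "glucose": (95.0, 0.55),
    "fructose": (95.0, 0.55),
    "sucrose": (92.0, 0.7),
    "fructan": (70.0, 3.5),
}

_DISAPPEARANCE_CAP = 99.9  # residues always retain a trace of each nutrient


@dataclass
class GasScenario:
    """Ground truth and protocol for a synthetic incubation run."""

    substrates: Mapping[str, Tuple[float, float, float]] = field(
        default_factory=lambda: dict(TABLE_KINETICS)
    )
    n_replicates: int = 3
    n_blanks: int = 3
    replicate_cv: Tuple[float, float, float] = (0.05, 0.05, 0.05)  # lognormal sigma A,B,C
    noise_sd_psi: float = 0.01
    record_interval: float = 1.0 / 6.0  # h
    duration: float = 48.0  # h
    substrate_mass: float = 1.1  # g as-weighed
    dm_fraction: float = 0.93
    blank_gas_ml: float = 8.0  # asymptotic inoculum-only gas, mL/bottle
    ddm_by_harvest: Mapping[str, float] = field(
        default_factory=lambda: {"early": 70.1, "late": 54.4}
    )
    constants: IncubationConstants = field(default_factory=IncubationConstants)
    seed: int = 0

    def validate(self) -> None:
        if self.duration < self.record_interval:
            raise ScenarioError("duration must cover at least one record interval")
        for name, (A, B, C) in self.substrates.items():
            if not (A > 0 and B > 0 and C > 0):
                raise ScenarioError(f"substrate {name!r}: A, B, C must be positive")
        if self.noise_sd_psi < 0 or any(s < 0 for s in self.replicate_cv):
            raise ScenarioError("noise and replicate variation must be non-negative")
        if not self.substrate_mass * self.dm_fraction > 0:
            raise ScenarioError("substrate DM must be positive")


@dataclass
class BagScenario:
    """Ground truth and protocol for a synthetic mobile-bag study."""

    plan: DesignPlan = field(default_factory=DesignPlan)
    slope: float = 0.608  # shared dDM slope, % per h
    intercepts: Mapping[Tuple[str, str], float] = field(
        default_factory=lambda: {
            ("PR", "early"): 38.01,
            ("PR", "late"): 32.51,
            ("CF", "early"): 35.29,
            ("CF", "late"): 21.37,
        }
    )
    ddm_noise_sd: float = 2.0  # percentage points
    transit_mean: float = 4.7  # h
    transit_sd: float = 1.7  # h
    p_caecal: float = 0.78  # probability a bag is captured in the caecum by 10 h
    p_total: float = 0.97  # probability a bag is ever found
    nutrient_profile: Mapping[str, Tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_NUTRIENT_PROFILE)
    )
    feed_comps: Mapping[Tuple[str, str], Mapping[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_FEED_COMPS.items()}
    )
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 <= self.p_caecal <= self.p_total <= 1.0):
            raise ScenarioError("need 0 <= p_caecal <= p_total <= 1")
        if self.ddm_noise_sd < 0 or self.transit_sd < 0:
            raise ScenarioError("standard deviations must be non-negative")
        if self.transit_mean <= 0:
            raise ScenarioError("transit_mean must be positive")
        for nut, (soluble, rate) in self.nutrient_profile.items():
            if not (0.0 <= soluble <= 100.0) or rate < 0:
                raise ScenarioError(f"{nut}: infeasible soluble fraction or rate")
        for (grass, harvest) in self.intercepts:
            if (grass, harvest) not in self.feed_comps:
                raise ScenarioError(f"no feed composition for {(grass, harvest)}")


# ---------------------------------------------------------------------------
# gas traces


def _ml_to_psi(ml: np.ndarray, c: IncubationConstants) -> np.ndarray:
    """Total gas volume (mL at standard conditions) -> headspace gauge psi."""
    moles = ml / c.molar_volume
    kpa = moles * c.gas_constant * c.temperature / c.headspace_volume
    return kpa / c.psi_to_kpa


def _vented_trace(
    bottle_id: str,
    times: np.ndarray,
    total_ml: np.ndarray,
    constants: IncubationConstants,
    noise_sd: float,
    rng: np.random.Generator,
    *,
    is_blank: bool,
    substrate_mass: float,
    dm_fraction: float,
    final_ph: Optional[float],
) -> PressureTrace:
    """Apply the read-then-vent protocol to a noiseless cumulative curve."""
    total_psi = _ml_to_psi(total_ml, constants)
    gauge = np.empty_like(total_psi)
    vent_times: List[float] = []
    vent_psi: List[float] = []
    vented = 0.0
    for k, p in enumerate(total_psi):
        g = p - vented
        gauge[k] = g
        if g > constants.vent_threshold:
            vent_times.append(times[k])
            vent_psi.append(g)
            vented += g
    if noise_sd > 0:
        noise = rng.normal(0.0, noise_sd, size=gauge.shape)
        noise[0] = 0.0  # the trace starts at an exact zero reading
        gauge = np.clip(gauge + noise, 0.0, None)
    return PressureTrace(
        bottle_id=bottle_id,
        substrate_mass=substrate_mass,
        dm_fraction=dm_fraction,
        times=times,
        gauge_psi=gauge,
        vent_times=np.array(vent_times),
        vent_psi=np.array(vent_psi),
        is_blank=is_blank,
        final_ph=final_ph,
    )


def simulate_incubation(
    scenario: GasScenario,
) -> Tuple[List[PressureTrace], pd.DataFrame]:
    """Generate vented pressure traces plus their ground-truth table.

    For each substrate x replicate, kinetic parameters are drawn around
    the scenario truth with independent lognormal replicate variation,
    the monophasic curve is evaluated on the recording grid and pushed
    through the headspace/venting physics, and Gaussian sensor noise is
    added to the gauge readings. Blank bottles carry a small
    inoculum-only gas curve. Reproducible under the scenario seed.
    """
    scenario.validate()
    rng = np.random.default_rng(scenario.seed)
    c = scenario.constants
    n_steps = int(round(scenario.duration / scenario.record_interval))
    times = np.arange(n_steps + 1) * scenario.record_interval
    g_dm = scenario.substrate_mass * scenario.dm_fraction

    traces: List[PressureTrace] = []
    truth_rows = []
    for name, (A, B, C) in scenario.substrates.items():
        harvest = "late" if name.endswith("late") else "early"
        ddm_mean = scenario.ddm_by_harvest.get(harvest, 60.0)
        for rep in range(1, scenario.n_replicates + 1):
            sa, sb, sc = scenario.replicate_cv
            a = A * math.exp(rng.normal(0.0, sa) - sa**2 / 2) if sa else A
            b = B * math.exp(rng.normal(0.0, sb) - sb**2 / 2) if sb else B
            cc = C * math.exp(rng.normal(0.0, sc) - sc**2 / 2) if sc else C
            total_ml = monophasic_G(times, a, b, cc) * g_dm
            bottle_id = f"{name}_r{rep}"
            ddm = float(np.clip(ddm_mean + rng.normal(0.0, 1.5), 0.0, 100.0))
            ph = float(6.57 + (0.06 if harvest == "late" else 0.0) + rng.normal(0.0, 0.02))
            traces.append(
                _vented_trace(
                    bottle_id,
                    times,
                    total_ml,
                    c,
                    scenario.noise_sd_psi,
                    rng,
                    is_blank=False,
                    substrate_mass=scenario.substrate_mass,
                    dm_fraction=scenario.dm_fraction,
                    final_ph=ph,
                )
            )
            truth_rows.append(
                {
                    "bottle_id": bottle_id,
                    "substrate": name,
                    "A": a,
                    "B": b,
                    "C": cc,
                    "g_dm": g_dm,
                    "ddm_true": ddm,
                    "residue_g_dm": g_dm * (1.0 - ddm / 100.0),
                    "final_ph": ph,
                }
            )
    for i in range(1, scenario.n_blanks + 1):
        blank_ml = monophasic_G(times, max(scenario.blank_gas_ml, 1e-9), 12.0, 1.3)
        traces.append(
            _vented_trace(
                f"blank_{i}",
                times,
                blank_ml,
                c,
                scenario.noise_sd_psi,
                rng,
                is_blank=True,
                substrate_mass=0.0,
                dm_fraction=0.0,
                final_ph=None,
            )
        )
    return traces, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# bag study


def _truncated_lognormal_hour(
    mean: float, sd: float, rng: np.random.Generator
) -> int:
    """Draw a transit time (h) from a lognormal, truncated to the 10 h window,
    and discretize to the hourly magnet check at which the bag is found."""
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    sigma = math.sqrt(sigma2)
    for _ in range(1000):
        t = rng.lognormal(mu, sigma) if sigma > 0 else mean
        hour = max(1, math.ceil(t))
        if hour <= 10:
            return hour
    raise ScenarioError("transit distribution puts essentially no mass below 10 h")


def simulate_bag_study(
    scenario: BagScenario,
) -> Tuple[List[BagRecord], Dict[str, object]]:
    """Generate a full mobile-bag study with known ground truth.

    Bags are laid out with :func:`~fermkin.mobile_bag.enumerate_bags`;
    each intubated bag is captured in the caecum with probability
    ``p_caecal`` (transit drawn from the truncated, hourly-discretized
    lognormal), otherwise passes to feces (found) or is lost. Per-bag DM
    disappearance follows the common-slope model in the check midpoint;
    per-nutrient residue compositions follow soluble-fraction plus
    time-linear degradation, capped below 100%. Wash controls lose only
    the soluble fractions. Returns the records and the ground truth.
    """
    scenario.validate()
    rng = np.random.default_rng(scenario.seed)
    records = enumerate_bags(scenario.plan, seed=scenario.seed)
    nutrient_noise_sd = 0.15 * scenario.ddm_noise_sd

    for record in records:
        comp = scenario.feed_comps[(record.grass, record.harvest)]
        if record.recovery_site == "wash_control":
            _apply_wash(record, comp, scenario)
            continue
        u = rng.random()
        if u < scenario.p_caecal:
            record.recovery_site = "caecum"
            record.recovery_hour = _truncated_lognormal_hour(
                scenario.transit_mean, scenario.transit_sd, rng
            )
            midpoint = record.recovery_hour - 0.5
        elif u < scenario.p_total:
            record.recovery_site = "feces"
            record.recovery_hour = int(round(24 + rng.exponential(10.0)))
            midpoint = 9.5  # disappearance saturates past the caecum window
        else:
            record.recovery_site = "lost"
            continue
        intercept = scenario.intercepts[(record.grass, record.harvest)]
        noise = rng.normal(0.0, scenario.ddm_noise_sd) if scenario.ddm_noise_sd else 0.0
        ddm = float(np.clip(intercept + scenario.slope * midpoint + noise, 0.0, 100.0))
        record.residue_mass = record.feed_in * (1.0 - ddm / 100.0)
        if record.recovery_site == "feces":
            record.residue_composition = None  # fecal residues are not assayed
            continue
        record.residue_composition = {}
        for nut, (soluble, rate) in scenario.nutrient_profile.items():
            jitter = rng.normal(0.0, nutrient_noise_sd) if nutrient_noise_sd else 0.0
            d = float(np.clip(soluble + rate * midpoint + jitter, 0.0, _DISAPPEARANCE_CAP))
            record.residue_composition[nut] = (
                comp[nut] * (1.0 - d / 100.0) * record.feed_in / record.residue_mass
            )
    truth: Dict[str, object] = {
        "slope": scenario.slope,
        "intercepts": dict(scenario.intercepts),
        "transit_mean": scenario.transit_mean,
        "transit_sd": scenario.transit_sd,
        "p_caecal": scenario.p_caecal,
        "p_total": scenario.p_total,
        "nutrient_profile": dict(scenario.nutrient_profile),
    }
    return records, truth


def _apply_wash(record: BagRecord, comp: Mapping[str, float], scenario: BagScenario) -> None:
    """Set a wash-control bag's residue from the soluble fractions alone."""
    profile = scenario.nutrient_profile
    # DM partition: CP, aNDFom, WSC, ash and the unassayed remainder.
    cp, ndf, wsc = comp["CP"], comp["aNDFom"], comp["WSC"]
    ash = comp.get("ash", 0.0)
    other = max(0.0, 1000.0 - cp - ndf - wsc - ash)
    sol = {
        "CP": profile["CP"][0],
        "aNDFom": profile["aNDFom"][0],
        "WSC": profile["WSC"][0],
        "ash": 50.0,
        "other": 30.0,
    }
    dm_loss = (
        cp * sol["CP"] + ndf * sol["aNDFom"] + wsc * sol["WSC"]
        + ash * sol["ash"] + other * sol["other"]
    ) / 1000.0 / 100.0
    record.residue_mass = record.feed_in * (1.0 - dm_loss)
    record.residue_composition = {
        nut: comp[nut] * (1.0 - profile[nut][0] / 100.0) * record.feed_in / record.residue_mass
        for nut in profile
        if nut in comp
    }


# ---------------------------------------------------------------------------
# feeds


def default_feed_effects() -> Dict[Tuple[str, str], Dict[str, float]]:
    """Grass x harvest composition means (g/kg DM) for the feed generator.

    Encodes the qualitative structure of cool-season grass maturation:
    CP falls and fiber rises with later harvest, PR carries the most
    WSC, fructan share rises late in SB, PR, TF and TI, and SB fiber
    falls late (lodged stands are cut higher).
    """
    wsc = {
        "MF": (90, 88, 85), "CF": (110, 95, 80), "PR": (200, 195, 190),
        "SB": (120, 140, 165), "TF": (130, 125, 128), "TI": (110, 120, 135),
    }
    cp_base = {"early": 175.0, "medium": 130.0, "late": 92.0}
    cp_offset = {"MF": 5, "CF": 10, "PR": 0, "SB": -5, "TF": 0, "TI": -10}
    ndf = {"early": 480.0, "medium": 550.0, "late": 610.0}
    ndf_special = {"SB": (560, 540, 520), "TI": (520, 525, 530)}
    ash = {"early": 85.0, "medium": 78.0, "late": 70.0}
    rising_fructan = {"SB", "PR", "TF", "TI"}

    effects: Dict[Tuple[str, str], Dict[str, float]] = {}
    for grass in GRASSES:
        for hi, harvest in enumerate(HARVESTS):
            total_wsc = float(wsc[grass][hi])
            fructan_share = (
                (0.45, 0.50, 0.60)[hi] if grass in rising_fructan else 0.45
            )
            glucose = 0.12 * total_wsc
            fructose = 0.18 * total_wsc
            fructan = fructan_share * total_wsc
            sucrose = total_wsc - glucose - fructose - fructan
            effects[(grass, harvest)] = {
                "CP": cp_base[harvest] + cp_offset[grass],
                "aNDFom": (
                    float(ndf_special[grass][hi]) if grass in ndf_special
                    else ndf[harvest]
                ),
                "WSC": total_wsc,
                "glucose": glucose,
                "fructose": fructose,
                "sucrose": sucrose,
                "fructan": fructan,
                "ash": ash[harvest],
            }
    return effects


def simulate_feeds(
    effects: Optional[Mapping[Tuple[str, str], Mapping[str, float]]] = None,
    block_sd: float = 8.0,
    n_blocks: int = 3,
    seed: int = 0,
    dm_fraction: float = 0.93,
) -> List[FeedSample]:
    """Draw replicate field-block feed samples around grass x harvest means.

    Gaussian block noise (sd ``block_sd`` g/kg DM) is applied to CP,
    aNDFom, ash and total WSC; component sugars are rescaled so they sum
    exactly to the drawn WSC, preserving the mean component shares. With
    ``block_sd=0`` the samples equal the means exactly.
    """
    if block_sd < 0:
        raise ScenarioError("block_sd must be non-negative")
    table = dict(effects) if effects is not None else default_feed_effects()
    for key, means in table.items():
        if any(v < 0 for v in means.values()):
            raise ScenarioError(f"negative mean in effects for {key}")
    rng = np.random.default_rng(seed)
    samples: List[FeedSample] = []
    for (grass, harvest), means in table.items():
        comp_sum = sum(means[c] for c in ("glucose", "fructose", "sucrose", "fructan"))
        for block in range(1, n_blocks + 1):
            draw = lambda m: float(max(0.0, m + rng.normal(0.0, block_sd)))  # noqa: E731
            total_wsc = draw(means["WSC"])
            scale = total_wsc / comp_sum if comp_sum > 0 else 0.0
            nutrients = {
                "CP": draw(means["CP"]),
                "aNDFom": draw(means["aNDFom"]),
                "ash": draw(means["ash"]),
                "WSC": total_wsc,
                "glucose": means["glucose"] * scale,
                "fructose": means["fructose"] * scale,
                "sucrose": means["sucrose"] * scale,
                "fructan": means["fructan"] * scale,
            }
            samples.append(
                FeedSample(
                    grass=grass,
                    harvest=harvest,
                    block=block,
                    dm_fraction=dm_fraction,
                    nutrients=nutrients,
                )
            )
    return samples
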