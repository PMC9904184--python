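"""Mobile nylon-bag precaecal digestion analysis.

Represents the factorial bag design (grass species x harvest time x bag
pore size, with intubated bags assigned to horse x period via a Latin
square plus never-intubated wash controls), and computes the summary
statistics of the technique:

* transit time from stomach to caecum as the recovery-fraction-weighted
  mean of hourly-check midpoints,
* caecal and total recovery rates,
* per-nutrient disappearance from feed-in and residue masses and
  compositions (DM basis),
* washing loss from wash-control bags,
* residue pooling by grass x harvest x pore x recovery interval
  (1-3, 4-6, 7-10 h),
* the common-slope ANCOVA of DM disappearance on residence time (one
  shared slope, one intercept per grass x harvest group, no interaction).
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import (
    DesignError,
    DomainError,
    MissingNutrientError,
    NoDataError,
    SingularDesignError,
)

__all__ = [
    "DesignPlan",
    "BagRecord",
    "PooledResidue",
    "CommonSlopeFit",
    "RecoveryRates",
    "INTERVALS",
    "NUTRIENTS",
    "enumerate_bags",
    "fsa",
    "transit_time",
    "recovery_rate",
    "assign_interval",
    "nutrient_disappearance",
    "washing_loss",
    "pool_residues",
    "disappearance_table",
    "common_slope_fit",
]

INTERVALS = ("1-3", "4-6", "7-10")
NUTRIENTS = ("DM", "CP", "aNDFom", "WSC", "glucose", "fructose", "sucrose", "fructan")


@dataclass(frozen=True)
class DesignPlan:
    """Factorial layout of a mobile-bag study.

    Defaults reproduce the reference design: 2 grasses x 2 harvests x
    2 pore sizes with 40 intubated and 4 wash-control replicates each,
    i.e. 352 bags, run as a 4x4 Latin square (4 horses x 4 periods over
    the 4 grass-harvest feeds). ``feed_mass`` of 0.5 g over a 24 cm2 bag
    face gives the target feed-to-surface-area of ~21 mg/cm2.
    """

    grasses: Tuple[str, ...] = ("CF", "PR")
    harvests: Tuple[str, ...] = ("early", "late")
    pore_sizes: Tuple[int, ...] = (15, 36)
    intubated_reps: int = 40
    wash_reps: int = 4
    horses: int = 4
    periods: int = 4
    feed_mass: float = 0.5  # g
    bag_face_area: float = 24.0  # cm2, one 2 x 12 cm face

    @property
    def total_bags(self) -> int:
        return (
            len(self.grasses)
            * len(self.harvests)
            * len(self.pore_sizes)
            * (self.intubated_reps + self.wash_reps)
        )


@dataclass
class BagRecord:
    """One mobile bag: design factors, masses and recovery outcome.

    ``recovery_site`` is one of caecum / feces / lost / wash_control, or
    None while the bag is still only a design skeleton. ``recovery_hour``
    is the hourly magnet check (1-10) for caecal bags and elapsed hours
    for fecal bags. Masses are grams of dry matter; ``residue_composition``
    maps nutrient -> g/kg residue DM.
    """

    bag_id: str
    grass: str
    harvest: str
    pore_size: int
    feed_in: float
    horse: Optional[int] = None
    period: Optional[int] = None
    recovery_site: Optional[str] = None
    recovery_hour: Optional[int] = None
    residue_mass: float = float("nan")
    residue_composition: Optional[Dict[str, float]] = None

    def validate(self) -> None:
        if self.recovery_site == "caecum":
            if self.recovery_hour is None or not 1 <= self.recovery_hour <= 10:
                raise DomainError(
                    f"{self.bag_id}: caecal recovery_hour must be in [1, 10]"
                )
        if self.recovery_site != "wash_control" and not self.feed_in > 0:
            raise DomainError(f"{self.bag_id}: feed_in must be positive")


@dataclass
class PooledResidue:
    """Residues of several bags pooled for chemical analysis."""

    grass: str
    harvest: str
    pore_size: int
    interval: str
    pooled_mass: float  # g DM, sum of member residues
    feed_in_total: float  # g DM of feed across member bags
    n_bags: int
    composition: Optional[Dict[str, float]] = None  # g/kg residue DM
    midpoints: Tuple[float, ...] = ()

    @property
    def empty(self) -> bool:
        return self.n_bags == 0


@dataclass
class CommonSlopeFit:
    """ANCOVA of disappearance on residence time: shared slope, group intercepts."""

    slope: float  # percent per hour
    intercepts: Dict[Tuple[str, str], float]  # (grass, harvest) -> percent
    r_squared: float
    n: int


class RecoveryRates(Tuple[float, float]):
    """(caecal %, total %) recovery, as a named 2-tuple."""

    __slots__ = ()

    def __new__(cls, caecal: float, total: float):
        return super().__new__(cls, (caecal, total))

    @property
    def caecal(self) -> float:
        return self[0]

    @property
    def total(self) -> float:
        return self[1]


# ---------------------------------------------------------------------------
# design


def _latin_square(n: int, rng: np.random.Generator) -> np.ndarray:
    """A random n x n Latin square: cyclic base with permuted rows/columns/symbols."""
    base = (np.arange(n)[:, None] + np.arange(n)[None, :]) % n
    rows, cols, syms = rng.permutation(n), rng.permutation(n), rng.permutation(n)
    return syms[base[np.ix_(rows, cols)]]


def enumerate_bags(plan: DesignPlan, seed: int = 0) -> List[BagRecord]:
    """Materialize one :class:`BagRecord` skeleton per bag of the plan.

    Intubated bags are assigned to horse x period cells through a seeded
    Latin square over the grass x harvest feeds (each horse receives each
    feed exactly once across periods); pore sizes split evenly within a
    cell. Wash controls stay unassigned. Raises :class:`DesignError` when
    a Latin square is requested but the feed count does not match the
    horse and period counts.
    """
    feeds = list(itertools.product(plan.grasses, plan.harvests))
    use_square = plan.horses > 0 and plan.periods > 0
    if use_square and not (len(feeds) == plan.horses == plan.periods):
        raise DesignError(
            f"Latin square needs |grasses x harvests| = horses = periods; "
            f"got {len(feeds)} feeds, {plan.horses} horses, {plan.periods} periods"
        )
    rng = np.random.default_rng(seed)
    cells_by_feed: Dict[Tuple[str, str], List[Tuple[int, int]]] = {f: [] for f in feeds}
    if use_square:
        square = _latin_square(len(feeds), rng)
        for h in range(plan.horses):
            for p in range(plan.periods):
                cells_by_feed[feeds[square[h, p]]].append((h + 1, p + 1))

    records: List[BagRecord] = []
    counter = itertools.count(1)
    for grass, harvest in feeds:
        cells = cells_by_feed[(grass, harvest)]
        for pore in plan.pore_sizes:
            for rep in range(plan.intubated_reps):
                horse = period = None
                if cells:
                    horse, period = cells[rep % len(cells)]
                records.append(
                    BagRecord(
                        bag_id=f"bag{next(counter):04d}",
                        grass=grass,
                        harvest=harvest,
                        pore_size=pore,
                        feed_in=plan.feed_mass,
                        horse=horse,
                        period=period,
                    )
                )
            for _ in range(plan.wash_reps):
                records.append(
                    BagRecord(
                        bag_id=f"bag{next(counter):04d}",
                        grass=grass,
                        harvest=harvest,
                        pore_size=pore,
                        feed_in=plan.feed_mass,
                        recovery_site="wash_control",
                    )
                )
    assert len(records) == plan.total_bags
    return records


def fsa(feed_mass: float, face_area: float) -> float:
    """Feed-to-surface-area ratio in mg/cm2 (1000 * g / cm2)."""
    if not face_area > 0:
        raise DomainError("face_area must be strictly positive")
    if feed_mass < 0:
        raise DomainError("feed_mass must be non-negative")
    return 1000.0 * feed_mass / face_area


# ---------------------------------------------------------------------------
# recovery statistics


def _caecal(records: Iterable[BagRecord]) -> List[BagRecord]:
    return [r for r in records if r.recovery_site == "caecum"]


def transit_time(records: Iterable[BagRecord]) -> float:
    """Mean stomach-to-caecum transit time, h.

    Sum over hourly checks i of t_i * M_i, where t_i = i - 0.5 h (the
    midpoint of the hour preceding check i) and M_i is the fraction of
    caecum-recovered bags found at check i. A convex combination of the
    midpoints, hence always inside their range.
    """
    caecal = _caecal(records)
    if not caecal:
        raise NoDataError("no caecum-recovered bags")
    counts = Counter(r.recovery_hour for r in caecal)
    total = sum(counts.values())
    return sum((hour - 0.5) * cnt / total for hour, cnt in counts.items())


def recovery_rate(records: Iterable[BagRecord]) -> RecoveryRates:
    """Caecal and total bag recovery, percent of intubated bags."""
    intubated = [r for r in records if r.recovery_site in ("caecum", "feces", "lost")]
    if not intubated:
        raise DomainError("no intubated bags")
    n = len(intubated)
    n_caecum = sum(r.recovery_site == "caecum" for r in intubated)
    n_feces = sum(r.recovery_site == "feces" for r in intubated)
    return RecoveryRates(100.0 * n_caecum / n, 100.0 * (n_caecum + n_feces) / n)


def assign_interval(recovery_hour: int) -> str:
    """Map an hourly check (1-10) to its pooling interval label."""
    if not 1 <= recovery_hour <= 10:
        raise DomainError(f"recovery_hour {recovery_hour} outside [1, 10]")
    if recovery_hour <= 3:
        return "1-3"
    if recovery_hour <= 6:
        return "4-6"
    return "7-10"


def interval_midpoint(interval: str) -> float:
    """Midpoint (h) of a pooling interval's check-midpoint range."""
    lo, hi = (float(x) for x in interval.split("-"))
    return ((lo - 0.5) + (hi - 0.5)) / 2.0


# ---------------------------------------------------------------------------
# disappearance


def nutrient_disappearance(
    feed_in: float,
    feed_comp: Mapping[str, float],
    residue_mass: float,
    residue_comp: Mapping[str, float],
    nutrient: str,
) -> float:
    """Percent of a nutrient lost between bag filling and recovery.

    Masses are g DM; compositions g/kg DM. For ``nutrient="DM"`` the
    compositions are ignored and the plain mass ratio is used.
    """
    if not feed_in > 0:
        raise DomainError("feed_in must be strictly positive")
    if residue_mass < 0:
        raise DomainError("residue_mass must be non-negative")
    if nutrient == "DM":
        return 100.0 * (feed_in - residue_mass) / feed_in
    if nutrient not in feed_comp:
        raise MissingNutrientError(f"{nutrient!r} absent from feed composition")
    if nutrient not in residue_comp:
        raise MissingNutrientError(f"{nutrient!r} absent from residue composition")
    feed_amount = feed_in * feed_comp[nutrient]
    if not feed_amount > 0:
        raise DomainError(f"feed carries no {nutrient}")
    residue_amount = residue_mass * residue_comp[nutrient]
    return 100.0 * (feed_amount - residue_amount) / feed_amount


def washing_loss(
    wash_controls: Sequence[BagRecord],
    feed_comps: Mapping[Tuple[str, str], Mapping[str, float]],
    nutrients: Sequence[str] = NUTRIENTS,
) -> pd.DataFrame:
    """Nutrient loss from never-intubated bags during the standard wash.

    Applies the disappearance formula to wash-control bags and averages
    replicates within each grass x harvest x pore combination. Reported
    alongside — never subtracted from — in vivo disappearance.
    Returns a tidy frame (grass, harvest, pore_size, nutrient, loss_pct, n).
    """
    controls = [r for r in wash_controls if r.recovery_site == "wash_control"]
    if not controls:
        raise NoDataError("no wash-control bags")
    rows = []
    for r in controls:
        comp = feed_comps[(r.grass, r.harvest)]
        for nut in nutrients:
            rows.append(
                {
                    "grass": r.grass,
                    "harvest": r.harvest,
                    "pore_size": r.pore_size,
                    "nutrient": nut,
                    "loss_pct": nutrient_disappearance(
                        r.feed_in, comp, r.residue_mass, r.residue_composition or {}, nut
                    ),
                }
            )
    frame = pd.DataFrame(rows)
    out = (
        frame.groupby(["grass", "harvest", "pore_size", "nutrient"], sort=True)["loss_pct"]
        .agg(loss_pct="mean", n="size")
        .reset_index()
    )
    return out


def pool_residues(
    records: Iterable[BagRecord],
    intervals: Sequence[str] = INTERVALS,
) -> List[PooledResidue]:
    """Pool caecum-recovered residues by grass x harvest x pore x interval.

    Fecal and wash-control bags are excluded. Pooled mass is the sum of
    member residue masses; the pooled composition is the residue-mass-
    weighted mean of member compositions when all members carry one.
    Combinations with no bags yield an empty pool (flagged, not fatal).
    """
    caecal = _caecal(records)
    groups: Dict[Tuple[str, str, int, str], List[BagRecord]] = {}
    factor_levels = (
        sorted({r.grass for r in caecal}),
        sorted({r.harvest for r in caecal}),
        sorted({r.pore_size for r in caecal}),
    )
    for r in caecal:
        key = (r.grass, r.harvest, r.pore_size, assign_interval(r.recovery_hour))
        groups.setdefault(key, []).append(r)

    pools: List[PooledResidue] = []
    for grass, harvest, pore in itertools.product(*factor_levels):
        for interval in intervals:
            members = groups.get((grass, harvest, pore, interval), [])
            if not members:
                pools.append(
                    PooledResidue(grass, harvest, pore, interval, 0.0, 0.0, 0)
                )
                continue
            masses = np.array([m.residue_mass for m in members])
            pooled_mass = float(masses.sum())
            comp = None
            if all(m.residue_composition for m in members) and pooled_mass > 0:
                nutrients = set.intersection(
                    *(set(m.residue_composition) for m in members)
                )
                comp = {
                    nut: float(
                        sum(
                            m.residue_mass * m.residue_composition[nut]
                            for m in members
                        )
                        / pooled_mass
                    )
                    for nut in sorted(nutrients)
                }
            pools.append(
                PooledResidue(
                    grass=grass,
                    harvest=harvest,
                    pore_size=pore,
                    interval=interval,
                    pooled_mass=pooled_mass,
                    feed_in_total=float(sum(m.feed_in for m in members)),
                    n_bags=len(members),
                    composition=comp,
                    midpoints=tuple(m.recovery_hour - 0.5 for m in members),
                )
            )
    return pools


def disappearance_table(
    pools: Sequence[PooledResidue],
    feed_comps: Mapping[Tuple[str, str], Mapping[str, float]],
    nutrients: Sequence[str] = NUTRIENTS,
) -> pd.DataFrame:
    """Per-cell nutrient disappearance (%) from pooled residues.

    One row per grass x harvest x pore x interval x nutrient. Empty
    pools are skipped.
    """
    rows = []
    for pool in pools:
        if pool.empty:
            continue
        comp = feed_comps[(pool.grass, pool.harvest)]
        for nut in nutrients:
            rows.append(
                {
                    "grass": pool.grass,
                    "harvest": pool.harvest,
                    "pore_size": pool.pore_size,
                    "interval": pool.interval,
                    "nutrient": nut,
                    "disappearance_pct": nutrient_disappearance(
                        pool.feed_in_total,
                        comp,
                        pool.pooled_mass,
                        pool.composition or {},
                        nut,
                    ),
                    "n_bags": pool.n_bags,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# common-slope regression


def common_slope_fit(
    points: Iterable[Tuple[Tuple[str, str], float, float]],
) -> CommonSlopeFit:
    """Least-squares fit of disappearance on time: one slope, per-group intercepts.

    ``points`` are (group, residence time h, disappearance %) triples,
    where a group is a (grass, harvest) pair. The design is the dummy-
    coded ANCOVA without interaction: each group gets its own intercept
    and all groups share the time slope. Raises
    :class:`SingularDesignError` when the design is rank deficient
    (e.g. a single common time point).
    """
    pts = list(points)
    if not pts:
        raise NoDataError("no points to fit")
    groups = sorted({g for g, _, _ in pts})
    g_index = {g: i for i, g in enumerate(groups)}
    n, k = len(pts), len(groups)
    X = np.zeros((n, k + 1))
    y = np.empty(n)
    for row, (g, t, d) in enumerate(pts):
        X[row, g_index[g]] = 1.0
        X[row, k] = t
        y[row] = d
    if np.linalg.matrix_rank(X) < k + 1:
        raise SingularDesignError(
            "design matrix is rank deficient (need >= 2 distinct times and "
            ">= 1 point per group)"
        )
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ coef
    rss = float(np.sum((y - fitted) ** 2))
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else 1.0
    return CommonSlopeFit(
        slope=float(coef[k]),
        intercepts={g: float(coef[g_index[g]]) for g in groups},
        r_squared=r2,
        n=n,
    )
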