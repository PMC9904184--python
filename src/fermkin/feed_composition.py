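"""Feed nutrient composition bookkeeping.

Holds per-sample grass composition (g/kg DM), the crude-protein
conversion (N x 6.25), a consistency check on the water-soluble
carbohydrate (WSC) fraction against its enzymatically assayed components
(glucose, fructose, sucrose, fructan), and the screening logic that
ranks grass pairs by how strongly they contrast in WSC content and in
vitro maximum gas production — the criterion used to pick feeds for an
in vivo bag study.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Tuple

import numpy as np

from .errors import DomainError

__all__ = [
    "GRASSES",
    "HARVESTS",
    "WSC_COMPONENTS",
    "FeedSample",
    "WscReport",
    "crude_protein",
    "wsc_consistency",
    "select_contrasting",
]

GRASSES = ("MF", "CF", "PR", "SB", "TF", "TI")
HARVESTS = ("early", "medium", "late")
WSC_COMPONENTS = ("glucose", "fructose", "sucrose", "fructan")


@dataclass
class FeedSample:
    """Nutrient composition of one grass x harvest x field-block sample.

    All nutrient values in g/kg DM. ``medium`` harvest is carried in the
    data model even though the kinetic and bag stages use only early and
    late material.
    """

    grass: str
    harvest: str
    block: int
    dm_fraction: float
    nutrients: Dict[str, float]  # CP, aNDFom, WSC, glucose, fructose, sucrose, fructan, ash

    def __post_init__(self) -> None:
        for name, value in self.nutrients.items():
            if value < 0:
                raise DomainError(f"{name} must be non-negative, got {value}")


@dataclass
class WscReport:
    """Outcome of checking component sugars against total WSC."""

    wsc: float
    component_sum: float
    relative_deviation: float
    passed: bool


def crude_protein(nitrogen: float) -> float:
    """Crude protein (g/kg DM) from Kjeldahl nitrogen: N x 6.25."""
    if nitrogen < 0:
        raise DomainError("nitrogen must be non-negative")
    return 6.25 * nitrogen


def wsc_consistency(sample: FeedSample, tol: float = 0.15) -> WscReport:
    """Check that glucose + fructose + sucrose + fructan ~= WSC.

    Enzymatic component assays need not sum exactly to the total WSC
    assay; the sample passes when the relative deviation is within
    ``tol`` (default 15%). Report only — never raises on mismatch.
    """
    missing = [c for c in WSC_COMPONENTS if c not in sample.nutrients]
    if missing or "WSC" not in sample.nutrients:
        raise DomainError(f"missing WSC components: {missing or ['WSC']}")
    wsc = sample.nutrients["WSC"]
    total = sum(sample.nutrients[c] for c in WSC_COMPONENTS)
    rel = abs(total - wsc) / wsc if wsc > 0 else (0.0 if total == 0 else float("inf"))
    return WscReport(wsc=wsc, component_sum=total, relative_deviation=rel, passed=rel <= tol)


def select_contrasting(
    samples: Iterable[FeedSample],
    fits: Mapping[Tuple[str, str], float],
) -> List[Tuple[Tuple[str, str], float]]:
    """Rank grass pairs by contrast in (WSC content, maximum gas production).

    ``fits`` maps (grass, harvest) to the fitted asymptote A (mL/g DM).
    Per grass, WSC and A are averaged over the harvests present in both
    inputs, standardized across grasses (z-scores), and pairs are ranked
    by descending Euclidean distance in the standardized plane. The
    ranking is deterministic and invariant to unit rescaling of either
    axis. Returns [(grass_a, grass_b), distance] pairs, most contrasting
    first.
    """
    wsc_by_key: Dict[Tuple[str, str], List[float]] = {}
    for s in samples:
        if "WSC" not in s.nutrients:
            raise DomainError(f"sample {s.grass}/{s.harvest} lacks WSC")
        wsc_by_key.setdefault((s.grass, s.harvest), []).append(s.nutrients["WSC"])

    grasses = sorted({g for g, _ in wsc_by_key})
    if len(grasses) < 2:
        raise DomainError("need at least two grasses to rank pairs")
    means = {}
    for grass in grasses:
        keys = [k for k in wsc_by_key if k[0] == grass and k in fits]
        if not keys:
            raise DomainError(f"no kinetic fit for grass {grass!r}")
        means[grass] = (
            float(np.mean([np.mean(wsc_by_key[k]) for k in keys])),
            float(np.mean([fits[k] for k in keys])),
        )
    wsc_vals = np.array([means[g][0] for g in grasses])
    a_vals = np.array([means[g][1] for g in grasses])

    def z(v: np.ndarray) -> np.ndarray:
        sd = v.std()
        return (v - v.mean()) / sd if sd > 0 else np.zeros_like(v)

    zw, za = z(wsc_vals), z(a_vals)
    coords = {g: (zw[i], za[i]) for i, g in enumerate(grasses)}
    ranked = [
        ((a, b), float(np.hypot(coords[a][0] - coords[b][0], coords[a][1] - coords[b][1])))
        for a, b in itertools.combinations(grasses, 2)
    ]
    ranked.sort(key=lambda item: (-item[1], item[0]))
    return ranked
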