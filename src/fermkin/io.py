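"""CSV schemas, readers/writers and input validation.

All files are UTF-8, comma-separated, header row required, "." decimal
separator. Schemas:

* ``pressure_traces.csv`` — bottle_id, time_h, psi, vented_psi (0 when
  no vent; a non-zero value records the gas released after that reading)
* ``bottles.csv`` — bottle_id, substrate, is_blank, substrate_mass_g,
  dm_fraction, final_ph
* ``gas_fits.csv`` — bottle_id, A, B, C, t_RM, rss, converged, dDM
* ``bags.csv`` — bag_id, horse, period, grass, harvest, pore_um,
  feed_in_g, recovery_site, recovery_hour, residue_g
* ``residue_composition.csv`` — grass, harvest, pore_um, interval,
  nutrient, g_per_kg (keyed by pooled sample)
* ``feeds.csv`` — grass, harvest, block, dm_fraction, cp, andfom, wsc,
  glucose, fructose, sucrose, fructan, ash
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import FermkinError, ValidationError
from .feed_composition import FeedSample
from .gas_kinetics import GasCurve, IncubationConstants, PressureTrace, cumulative_gas
from .mobile_bag import BagRecord

__all__ = [
    "FileReport",
    "ValidationReport",
    "read_pressure_traces",
    "write_pressure_traces",
    "read_bags",
    "write_bags",
    "read_feeds",
    "write_feeds",
    "feed_comps_from_samples",
    "read_residue_composition",
    "write_residue_composition",
    "validate_inputs",
]

_FEED_COLUMN_MAP = {
    "cp": "CP", "andfom": "aNDFom", "wsc": "WSC", "glucose": "glucose",
    "fructose": "fructose", "sucrose": "sucrose", "fructan": "fructan", "ash": "ash",
}

REQUIRED_COLUMNS: Dict[str, Sequence[str]] = {
    "pressure_traces": ("bottle_id", "time_h", "psi", "vented_psi"),
    "bottles": ("bottle_id", "substrate", "is_blank", "substrate_mass_g", "dm_fraction"),
    "bags": (
        "bag_id", "grass", "harvest", "pore_um", "feed_in_g",
        "recovery_site", "recovery_hour", "residue_g",
    ),
    "feeds": ("grass", "harvest", "block", "dm_fraction") + tuple(_FEED_COLUMN_MAP),
    "residue_composition": ("grass", "harvest", "pore_um", "interval", "nutrient", "g_per_kg"),
}


# ---------------------------------------------------------------------------
# pressure traces


def read_pressure_traces(
    traces_path: str | Path, bottles_path: str | Path
) -> List[PressureTrace]:
    """Load vented pressure traces joined with their bottle metadata."""
    traces = pd.read_csv(traces_path)
    bottles = pd.read_csv(bottles_path).set_index("bottle_id")
    _require(traces, "pressure_traces", traces_path)
    _require(bottles.reset_index(), "bottles", bottles_path)
    out: List[PressureTrace] = []
    for bottle_id, grp in traces.groupby("bottle_id", sort=False):
        if bottle_id not in bottles.index:
            raise ValidationError(f"bottle {bottle_id!r} missing from {bottles_path}")
        meta = bottles.loc[bottle_id]
        grp = grp.sort_values("time_h")
        vents = grp[grp["vented_psi"] > 0]
        ph = meta.get("final_ph", math.nan)
        out.append(
            PressureTrace(
                bottle_id=str(bottle_id),
                substrate_mass=float(meta["substrate_mass_g"]),
                dm_fraction=float(meta["dm_fraction"]),
                times=grp["time_h"].to_numpy(float),
                gauge_psi=grp["psi"].to_numpy(float),
                vent_times=vents["time_h"].to_numpy(float),
                vent_psi=vents["vented_psi"].to_numpy(float),
                is_blank=bool(meta["is_blank"]),
                final_ph=None if pd.isna(ph) else float(ph),
            )
        )
    return out


def write_pressure_traces(
    traces: Sequence[PressureTrace],
    traces_path: str | Path,
    bottles_path: str | Path,
    substrates: Optional[Mapping[str, str]] = None,
) -> None:
    """Write traces and bottle metadata in the standard two-file layout."""
    rows = []
    for tr in traces:
        vent_map = dict(zip(tr.vent_times.tolist(), tr.vent_psi.tolist()))
        for t, p in zip(tr.times, tr.gauge_psi):
            rows.append(
                {
                    "bottle_id": tr.bottle_id,
                    "time_h": t,
                    "psi": p,
                    "vented_psi": vent_map.get(t, 0.0),
                }
            )
    pd.DataFrame(rows).to_csv(traces_path, index=False)
    meta = pd.DataFrame(
        {
            "bottle_id": [t.bottle_id for t in traces],
            "substrate": [
                (substrates or {}).get(t.bottle_id, "" if t.is_blank else t.bottle_id)
                for t in traces
            ],
            "is_blank": [t.is_blank for t in traces],
            "substrate_mass_g": [t.substrate_mass for t in traces],
            "dm_fraction": [t.dm_fraction for t in traces],
            "final_ph": [t.final_ph if t.final_ph is not None else math.nan for t in traces],
        }
    )
    meta.to_csv(bottles_path, index=False)


# ---------------------------------------------------------------------------
# bags


def read_bags(path: str | Path) -> List[BagRecord]:
    frame = pd.read_csv(path)
    _require(frame, "bags", path)
    records = []
    for _, row in frame.iterrows():
        hour = row["recovery_hour"]
        site = row["recovery_site"]
        records.append(
            BagRecord(
                bag_id=str(row["bag_id"]),
                grass=str(row["grass"]),
                harvest=str(row["harvest"]),
                pore_size=int(row["pore_um"]),
                feed_in=float(row["feed_in_g"]),
                horse=None if pd.isna(row.get("horse", math.nan)) else int(row["horse"]),
                period=None if pd.isna(row.get("period", math.nan)) else int(row["period"]),
                recovery_site=None if pd.isna(site) else str(site),
                recovery_hour=None if pd.isna(hour) else int(hour),
                residue_mass=float(row["residue_g"]),
            )
        )
    return records


def write_bags(records: Sequence[BagRecord], path: str | Path) -> None:
    pd.DataFrame(
        {
            "bag_id": [r.bag_id for r in records],
            "horse": [r.horse for r in records],
            "period": [r.period for r in records],
            "grass": [r.grass for r in records],
            "harvest": [r.harvest for r in records],
            "pore_um": [r.pore_size for r in records],
            "feed_in_g": [r.feed_in for r in records],
            "recovery_site": [r.recovery_site for r in records],
            "recovery_hour": [r.recovery_hour for r in records],
            "residue_g": [r.residue_mass for r in records],
        }
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# feeds and residue compositions


def read_feeds(path: str | Path) -> List[FeedSample]:
    """Load feed samples; percent-of-DM inputs are not auto-detected here —
    values are taken as g/kg DM per the schema."""
    frame = pd.read_csv(path)
    _require(frame, "feeds", path)
    return [
        FeedSample(
            grass=str(row["grass"]),
            harvest=str(row["harvest"]),
            block=int(row["block"]),
            dm_fraction=float(row["dm_fraction"]),
            nutrients={out: float(row[col]) for col, out in _FEED_COLUMN_MAP.items()},
        )
        for _, row in frame.iterrows()
    ]


def write_feeds(samples: Sequence[FeedSample], path: str | Path) -> None:
    rows = []
    for s in samples:
        row = {"grass": s.grass, "harvest": s.harvest, "block": s.block,
               "dm_fraction": s.dm_fraction}
        row.update({col: s.nutrients.get(out, math.nan) for col, out in _FEED_COLUMN_MAP.items()})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def feed_comps_from_samples(
    samples: Sequence[FeedSample],
) -> Dict[Tuple[str, str], Dict[str, float]]:
    """Average block replicates into one composition per grass x harvest."""
    acc: Dict[Tuple[str, str], List[Dict[str, float]]] = {}
    for s in samples:
        acc.setdefault((s.grass, s.harvest), []).append(s.nutrients)
    return {
        key: {
            nut: float(np.mean([d[nut] for d in dicts]))
            for nut in dicts[0]
        }
        for key, dicts in acc.items()
    }


def read_residue_composition(
    path: str | Path,
) -> Dict[Tuple[str, str, int, str], Dict[str, float]]:
    """Load pooled residue compositions keyed by (grass, harvest, pore, interval)."""
    frame = pd.read_csv(path)
    _require(frame, "residue_composition", path)
    out: Dict[Tuple[str, str, int, str], Dict[str, float]] = {}
    for _, row in frame.iterrows():
        key = (str(row["grass"]), str(row["harvest"]), int(row["pore_um"]), str(row["interval"]))
        out.setdefault(key, {})[str(row["nutrient"])] = float(row["g_per_kg"])
    return out


def write_residue_composition(
    comps: Mapping[Tuple[str, str, int, str], Mapping[str, float]], path: str | Path
) -> None:
    rows = [
        {"grass": g, "harvest": h, "pore_um": p, "interval": iv,
         "nutrient": nut, "g_per_kg": val}
        for (g, h, p, iv), comp in comps.items()
        for nut, val in comp.items()
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# validation


@dataclass
class FileReport:
    path: str
    passed: bool
    messages: List[str] = field(default_factory=list)


@dataclass
class ValidationReport:
    files: List[FileReport] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return all(f.passed for f in self.files)

    def __str__(self) -> str:
        lines = []
        for f in self.files:
            lines.append(f"{'PASS' if f.passed else 'FAIL'}  {f.path}")
            lines.extend(f"      {m}" for m in f.messages)
        return "\n".join(lines)


def _require(frame: pd.DataFrame, schema: str, path) -> None:
    missing = [c for c in REQUIRED_COLUMNS[schema] if c not in frame.columns]
    if missing:
        raise ValidationError(f"{path}: missing required column(s) {missing}")


def validate_inputs(
    paths: Mapping[str, str | Path],
    constants: IncubationConstants = IncubationConstants(),
) -> ValidationReport:
    """Schema- and physics-check input files before a pipeline run.

    ``paths`` maps schema names (pressure_traces+bottles as a pair via
    keys 'pressure_traces' and 'bottles', plus 'bags', 'feeds',
    'residue_composition') to file paths; only the keys present are
    checked. Row-level problems (recovery hours outside 1-10, negative
    pressures, cumulative reconstructions that fall without a vent) are
    reported per file; the report never raises.
    """
    report = ValidationReport()

    def check(path, fn) -> None:
        fr = FileReport(str(path), passed=True)
        try:
            fn(fr)
        except FileNotFoundError:
            fr.passed = False
            fr.messages.append("file not found")
        except FermkinError as exc:
            fr.passed = False
            fr.messages.append(str(exc))
        if fr.messages:
            fr.passed = False
        report.files.append(fr)

    if "pressure_traces" in paths and "bottles" in paths:
        def check_traces(fr: FileReport) -> None:
            traces = read_pressure_traces(paths["pressure_traces"], paths["bottles"])
            for tr in traces:
                if np.any(tr.gauge_psi < 0):
                    fr.messages.append(f"{tr.bottle_id}: negative gauge pressure")
                try:
                    cumulative_gas(tr, constants)
                except FermkinError as exc:
                    fr.messages.append(str(exc))

        check(paths["pressure_traces"], check_traces)

    if "bags" in paths:
        def check_bags(fr: FileReport) -> None:
            for r in read_bags(paths["bags"]):
                if r.recovery_site == "caecum" and not (
                    r.recovery_hour is not None and 1 <= r.recovery_hour <= 10
                ):
                    fr.messages.append(
                        f"{r.bag_id}: caecal recovery_hour {r.recovery_hour} "
                        "outside the 1-10 h check window"
                    )
                if r.recovery_site != "wash_control" and not r.feed_in > 0:
                    fr.messages.append(f"{r.bag_id}: feed_in_g must be positive")

        check(paths["bags"], check_bags)

    if "feeds" in paths:
        def check_feeds(fr: FileReport) -> None:
            for s in read_feeds(paths["feeds"]):
                for nut, val in s.nutrients.items():
                    if val < 0:
                        fr.messages.append(
                            f"{s.grass}/{s.harvest}/block{s.block}: negative {nut}"
                        )

        check(paths["feeds"], check_feeds)

    if "residue_composition" in paths:
        def check_residues(fr: FileReport) -> None:
            for key, comp in read_residue_composition(paths["residue_composition"]).items():
                for nut, val in comp.items():
                    if val < 0:
                        fr.messages.append(f"{key}: negative {nut}")

        check(paths["residue_composition"], check_residues)

    return report
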