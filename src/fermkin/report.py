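"""Human-readable run summaries.

Renders the three result tables of a full pipeline run — kinetic fits
(A, B, C, t_RM, dDM per bottle), common-slope regression equations per
grass x harvest group, and the nutrient-disappearance table — plus run
metadata (seed, configuration hash) so any report can be traced back to
the exact run that produced it.
"""

from __future__ import annotations

import hashlib
import json
from typing import Dict, Iterable, Mapping, Optional, Tuple

import pandas as pd

from .gas_kinetics import IncubationResult
from .mobile_bag import CommonSlopeFit

__all__ = ["config_hash", "render_report"]


def config_hash(config: Mapping) -> str:
    """Short stable hash of a configuration mapping."""
    payload = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def _fits_table(results: Iterable[IncubationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "bottle_id": r.bottle_id,
                "A": r.fit.A,
                "B": r.fit.B,
                "C": r.fit.C,
                "t_RM": r.fit.t_rm,
                "rss": r.fit.rss,
                "converged": r.fit.converged,
                "dDM": r.ddm,
                "pH": r.final_ph,
            }
            for r in results
        ],
        columns=["bottle_id", "A", "B", "C", "t_RM", "rss", "converged", "dDM", "pH"],
    )


def render_report(
    *,
    seed: int,
    config: Mapping,
    gas_results: Iterable[IncubationResult] = (),
    regression: Optional[CommonSlopeFit] = None,
    disappearance: Optional[pd.DataFrame] = None,
    summary: Optional[Mapping[str, float]] = None,
) -> str:
    """Assemble the pipeline summary as plain text.

    Empty sections render as headed empty tables, so a partial run still
    produces a complete, parseable report.
    """
    lines = [
        "fermkin run report",
        f"seed: {seed}",
        f"config: {config_hash(config)}",
        "",
        "== Gas-production kinetics (per bottle) ==",
        _fits_table(gas_results).to_string(index=False, float_format=lambda v: f"{v:.3f}"),
        "",
        "== DM disappearance vs residence time (common slope) ==",
    ]
    if regression is None:
        lines.append("(no regression fitted)")
    else:
        for group in sorted(regression.intercepts):
            name = " ".join(group) if isinstance(group, tuple) else str(group)
            lines.append(
                f"{name}: dDM = {regression.slope:.3f} X + {regression.intercepts[group]:.2f}"
            )
        lines.append(f"r^2 = {regression.r_squared:.4f}, n = {regression.n}")
    lines += ["", "== Nutrient disappearance (%) by cell =="]
    if disappearance is None or disappearance.empty:
        lines.append("grass harvest pore_size interval nutrient disappearance_pct")
    else:
        lines.append(
            disappearance.to_string(index=False, float_format=lambda v: f"{v:.1f}")
        )
    if summary:
        lines += ["", "== Study summary =="]
        lines += [f"{key}: {value:.2f}" for key, value in summary.items()]
    return "\n".join(lines) + "\n"
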