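"""Muscle-force sensitivity analysis: +/-10% perturbation and the symmetric
percent-difference statistic.

Two modes:

* ``global`` — all muscle loads scaled together.  For a linear model this
  is an analytic oracle: MWAM scales exactly by the factor, so the percent
  differences are the load-independent constants 100*0.1/1.05 = 9.5238%
  (up) and 100*0.1/0.95 = 10.5263% (down).
* ``per_muscle`` (default) — each muscle group perturbed in its own run
  while the others stay at baseline; the perturbed MWAMs are averaged
  across groups before the percent difference is taken.

The statistic is the symmetric percent difference
|a - b| / ((a + b)/2) * 100.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

from .fe_solver import LoadCase, MaterialProperties, solve
from .stress_stats import mwam
from .synthetic_skull import LabeledModel

__all__ = ["SensitivityResult", "percent_difference", "perturb_loads",
           "run_sensitivity"]

PERTURBATION = 0.10


@dataclass
class SensitivityResult:
    label: str
    part: str
    baseline_mwam: float  # MPa
    mwam_up: float  # MPa, +10%
    mwam_down: float  # MPa, -10%
    pct_diff_up: float  # %
    pct_diff_down: float  # %
    mode: Literal["global", "per_muscle"]
    per_muscle: pd.DataFrame | None = None  # group, direction, mwam, pct_diff

    def as_row(self) -> dict:
        return {
            "label": self.label,
            "part": self.part,
            "baseline": self.baseline_mwam,
            "up": self.mwam_up,
            "down": self.mwam_down,
            "pct_up": self.pct_diff_up,
            "pct_down": self.pct_diff_down,
            "mode": self.mode,
        }


def percent_difference(a: float, b: float) -> float:
    """Symmetric percent difference |a-b| / mean(a,b) * 100.

    Symmetric in its arguments and zero iff a == b.
    """
    mean = (a + b) / 2.0
    if mean <= 0:
        raise ValueError(f"nonpositive mean of ({a}, {b})")
    return abs(a - b) / mean * 100.0


def perturb_loads(
    loadcase: LoadCase,
    factor: float,
    mode: Literal["global", "per_muscle"] = "global",
    target_group: str | None = None,
) -> LoadCase:
    """Scale muscle loads by ``factor``; bite loads and constraints untouched."""
    if factor <= 0:
        raise ValueError("perturbation factor must be positive")
    out = loadcase.copy()
    if mode == "global":
        groups = list(out.muscle_loads)
    else:
        if target_group not in out.muscle_loads:
            raise KeyError(
                f"unknown muscle group {target_group!r}; "
                f"have {sorted(out.muscle_loads)}"
            )
        groups = [target_group]
    for g in groups:
        for node in out.muscle_loads[g]:
            out.muscle_loads[g][node] = out.muscle_loads[g][node] * factor
    return out


def run_sensitivity(
    model: LabeledModel,
    material: MaterialProperties,
    loads: LoadCase,
    mode: Literal["global", "per_muscle"] = "per_muscle",
    perturbation: float = PERTURBATION,
) -> SensitivityResult:
    """Solve baseline and +/-perturbation cases; report percent differences.

    In per_muscle mode each group is perturbed in a separate run and the
    resulting MWAMs are averaged across groups per direction.
    """
    base_field = solve(model.mesh, material, loads)
    base = mwam(base_field.von_mises, base_field.element_volumes)

    def solved_mwam(lc: LoadCase) -> float:
        f = solve(model.mesh, material, lc)
        return mwam(f.von_mises, f.element_volumes)

    detail_rows = []
    per_dir: dict[str, float] = {}
    for direction, factor in (("up", 1 + perturbation), ("down", 1 - perturbation)):
        if mode == "global":
            m = solved_mwam(perturb_loads(loads, factor, "global"))
        else:
            groups = sorted(loads.muscle_loads)
            if not groups:
                m = base
            else:
                vals = []
                for g in groups:
                    mg = solved_mwam(perturb_loads(loads, factor, "per_muscle", g))
                    vals.append(mg)
                    detail_rows.append({
                        "group": g,
                        "direction": direction,
                        "mwam": mg,
                        "pct_diff": percent_difference(base, mg) if (base + mg) > 0 else 0.0,
                    })
                m = float(np.mean(vals))
        per_dir[direction] = m

    def pct(b: float, m: float) -> float:
        if b == 0.0 and m == 0.0:
            return 0.0
        return percent_difference(b, m)

    return SensitivityResult(
        label=model.label,
        part=model.part,
        baseline_mwam=base,
        mwam_up=per_dir["up"],
        mwam_down=per_dir["down"],
        pct_diff_up=pct(base, per_dir["up"]),
        pct_diff_down=pct(base, per_dir["down"]),
        mode=mode,
        per_muscle=pd.DataFrame(detail_rows) if detail_rows else None,
    )
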