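"""Comparative summary statistics over per-element solution fields.

The headline statistic is the mesh-weighted arithmetic mean (MWAM): the
element-volume-weighted mean of a per-element field, which corrects for
element-size differences in non-uniform meshes.  Strain means and the
reported quantiles are volume-weighted by the same argument; a plain
(unweighted) mean is reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fe_solver import SolutionField

__all__ = ["SummaryStats", "mwam", "weighted_quantile", "summarize",
           "comparison_table", "CSV_COLUMNS"]

CSV_COLUMNS = [
    "model", "part", "mode", "mwam_vm_mpa", "mean_maxps",
    "plain_mean_vm_mpa", "q50", "q95", "q99", "elements",
]


@dataclass
class SummaryStats:
    mwam_von_mises: float  # MPa
    mean_max_principal_strain: float
    plain_mean_von_mises: float  # MPa
    plain_mean_max_principal_strain: float
    quantiles: dict[int, float]  # {50, 95, 99} of von Mises, volume-weighted
    element_count: int


def mwam(values: np.ndarray, volumes: np.ndarray) -> float:
    """Mesh-weighted arithmetic mean: sum(v_i V_i) / sum(V_i)."""
    values = np.asarray(values, dtype=float).ravel()
    volumes = np.asarray(volumes, dtype=float).ravel()
    if values.shape != volumes.shape:
        raise ValueError(
            f"length mismatch: {values.size} values vs {volumes.size} volumes"
        )
    if values.size == 0:
        raise ValueError("empty field")
    if np.any(volumes <= 0):
        raise ValueError("element volumes must be positive")
    return float(np.dot(values, volumes) / volumes.sum())


def weighted_quantile(values: np.ndarray, volumes: np.ndarray, q: float) -> float:
    """Quantile of the volume-weighted empirical distribution (q in [0,1])."""
    order = np.argsort(values, kind="stable")
    v = np.asarray(values, float)[order]
    w = np.asarray(volumes, float)[order]
    cum = np.cumsum(w) / w.sum()
    return float(v[np.searchsorted(cum, q, side="left").clip(0, len(v) - 1)])


def summarize(field: SolutionField, strain_weighting: str = "volume") -> SummaryStats:
    """All comparative statistics of one solved model.

    ``strain_weighting``: "volume" (default, consistent with MWAM) or
    "plain"; both variants are always stored.
    """
    vm = np.asarray(field.von_mises, float)
    vols = np.asarray(field.element_volumes, float)
    mps = np.asarray(field.max_principal_strain, float)
    if vm.size == 0:
        raise ValueError("empty solution field")
    mw_strain = mwam(mps, vols)
    plain_strain = float(mps.mean())
    return SummaryStats(
        mwam_von_mises=mwam(vm, vols),
        mean_max_principal_strain=mw_strain if strain_weighting == "volume" else plain_strain,
        plain_mean_von_mises=float(vm.mean()),
        plain_mean_max_principal_strain=plain_strain,
        quantiles={p: weighted_quantile(vm, vols, p / 100) for p in (50, 95, 99)},
        element_count=int(vm.size),
    )


def comparison_table(
    models: list[tuple[str, str, SummaryStats]], mode: str
) -> pd.DataFrame:
    """CSV-ready comparison rows: one per (label, part), sorted by label.

    ``models`` holds (label, part, stats) triples; duplicate (label, part)
    pairs are rejected.
    """
    if not models:
        raise ValueError("no models to tabulate")
    keys = [(lbl, part) for lbl, part, _ in models]
    if len(set(keys)) != len(keys):
        raise ValueError(f"duplicate model labels: {keys}")
    rows = [
        {
            "model": lbl,
            "part": part,
            "mode": mode,
            "mwam_vm_mpa": s.mwam_von_mises,
            "mean_maxps": s.mean_max_principal_strain,
            "plain_mean_vm_mpa": s.plain_mean_von_mises,
            "q50": s.quantiles[50],
            "q95": s.quantiles[95],
            "q99": s.quantiles[99],
            "elements": s.element_count,
        }
        for lbl, part, s in models
    ]
    return (
        pd.DataFrame(rows, columns=CSV_COLUMNS)
        .sort_values(["part", "model"], kind="stable")
        .reset_index(drop=True)
    )
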