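"""Invasion-scenario scoring.

Two tools: a threshold-independent range-expansion metric (how much of the
landscape that a baseline model calls unsuitable becomes suitable under a
scenario model, averaged over every possible binarization threshold), and
'simple' extrapolation maps counting, per cell, how many predictors fall
outside the environmental range of the model's training region
(mobility-oriented parity, simple variant).

For the expansion metric, the number of converted cells at threshold z is
``C(z) = #{cells: base < z <= scenario}``; integrating C over z in [0, 1]
gives exactly ``sum_i max(0, scenario_i - base_i)`` — the closed form used
as the primary computation, with the z-curve retained for reporting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .enm import SuitabilityMap, fit_niche_model, sample_background
from .grids import EnvGrid
from .occurrences import OccurrenceSet

__all__ = ["ExpansionResult", "MopMap", "range_expansion", "mop_simple",
           "scenario_compare"]


@dataclass
class ExpansionResult:
    """Threshold-independent range-expansion summary.

    ``area`` is the mean number of converted cells over thresholds (the
    closed form); ``pct_of_landscape`` divides by the number of valid cells.
    """

    z_values: np.ndarray
    converted: np.ndarray  # C(z), non-negative integers
    area: float
    area_trapezoid: float
    pct_of_landscape: float
    n_valid_cells: int

    def curve(self) -> pd.DataFrame:
        return pd.DataFrame({"z": self.z_values, "converted": self.converted})


def range_expansion(base: SuitabilityMap, scenario: SuitabilityMap,
                    n_z: int = 1001) -> ExpansionResult:
    """Score how much unsuitable baseline habitat a scenario converts.

    Cells count as converted at threshold z when ``base < z <= scenario``
    (strict on base, inclusive on scenario), so each cell contributes
    exactly ``max(0, scenario - base)`` to the integrated area.
    """
    if not base.same_geometry(scenario):
        raise ValueError("suitability maps have different geometry or mask")
    b = base.valid_values()
    s = scenario.valid_values()
    n_valid = b.size
    area_exact = float(np.maximum(0.0, s - b).sum())
    z = np.linspace(0.0, 1.0, n_z)
    converted = ((b[None, :] < z[:, None]) & (z[:, None] <= s[None, :])
                 ).sum(axis=1)
    area_quad = float(np.trapezoid(converted, z))
    pct = 100.0 * area_exact / n_valid if n_valid else float("nan")
    return ExpansionResult(z, converted, area_exact, area_quad, pct, n_valid)


@dataclass
class MopMap:
    """Per-cell count of predictors outside the reference environmental range."""

    counts: np.ndarray
    mask: np.ndarray
    reference_ranges: dict  # layer -> (min, max) over the reference region
    layers: list


def mop_simple(reference: EnvGrid, projection: EnvGrid,
               layers: list | None = None,
               reference_mask: np.ndarray | None = None) -> MopMap:
    """'Simple' extrapolation map: count out-of-range predictors per cell.

    The reference environmental range of each layer is its (min, max) over
    the valid cells of ``reference`` (optionally restricted by
    ``reference_mask``, e.g. a buffer around occurrences); each valid
    projection cell counts the layers whose value falls strictly outside
    that interval.
    """
    if layers is None:
        layers = list(reference.layer_names)
    mask_ref = reference.mask if reference_mask is None else (
        reference.mask & np.asarray(reference_mask, dtype=bool))
    if not mask_ref.any():
        raise ValueError("reference region is empty")
    ranges = {}
    for name in layers:
        vals = reference.layer(name)[mask_ref]
        ranges[name] = (float(vals.min()), float(vals.max()))
    counts = np.zeros(projection.mask.shape, dtype=int)
    for name in layers:
        lo, hi = ranges[name]
        v = projection.layer(name)
        out = (v < lo) | (v > hi)
        counts[projection.mask & out] += 1
    counts[~projection.mask] = 0
    return MopMap(counts, projection.mask.copy(), ranges, list(layers))


def scenario_compare(base_records: OccurrenceSet,
                     scenario_records_by_source: dict,
                     grids: dict, target: EnvGrid,
                     betamultiplier: float = 1.0, n_background: int = 1000,
                     buffer_radius: float = 0.0,
                     seed: int | None = None) -> pd.DataFrame:
    """Rank invasion sources by the range expansion they would cause.

    Fits the baseline model on the target range's own records, then one
    model per (range, cluster) source on its range of origin with its own
    background sample; all models are projected to ``target`` and scored
    against the baseline with :func:`range_expansion`. Sources with fewer
    than 2 records are skipped with a warning. Returns a table sorted by
    descending percentage expansion (the threat ranking).
    """
    rng = np.random.default_rng(seed)

    def fit_project(records, grid):
        bg = sample_background(grid, records, n_background,
                               buffer_radius=buffer_radius,
                               seed=int(rng.integers(2**31 - 1)))
        model = fit_niche_model(records, bg, grid,
                                betamultiplier=betamultiplier)
        return model.predict_grid(target)

    base_proj = fit_project(base_records, target)
    rows = []
    for source, records in scenario_records_by_source.items():
        if len(records) < 2:
            warnings.warn(f"source {source!r} has {len(records)} record(s); "
                          "skipped (needs >= 2)")
            continue
        range_label, cluster = (source if isinstance(source, tuple)
                                else (source, None))
        proj = fit_project(records, grids[range_label])
        res = range_expansion(base_proj, proj)
        rows.append({"source_range": range_label, "cluster": cluster,
                     "pct_expansion": res.pct_of_landscape,
                     "area": res.area, "n_records": len(records)})
    table = pd.DataFrame(rows)
    if len(table):
        table = table.sort_values("pct_expansion", ascending=False,
                                  ignore_index=True)
    return table
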