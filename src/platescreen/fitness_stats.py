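"""Screen statistics: fitness, resolution, resolvable fraction, cost.

*Fitness* is the ratio of a mutant's quantitative phenotype (corrected
colony size, a proxy for growth) to the control strain's: a fitness of
0.9 means the mutant grows at 90% of the control rate.  From replicate
plates this module estimates per-strain fitness with its replicate
variability and a p-value against the control distribution, and derives
the screen-level quality metrics used to compare plate formats:

- **fitness resolution** — the minimal fitness difference detectable
  with statistical confidence given the replicate variability and count
  (a two-sample minimal detectable difference),
- **resolvable fraction** — percentage of strains significantly
  different from control at a given significance level,
- **dynamic range** — spread of observed fitness values
  (97.5th − 2.5th percentile),
- **fold growth** and **overgrown fraction** — growth-curve summaries,
- **screen cost** — consumables model at a 2:1 plate:pad cost ratio
  (dedicated pads use one pad per plate; 4-to-1 up-scaling needs four).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .colony_quant import SizeTable
from .grid import DENSITY_SHAPES

__all__ = [
    "FitnessRecord",
    "CostSpec",
    "compute_fitness",
    "fitness_frame",
    "fold_growth",
    "overgrown_fraction",
    "fitness_resolution",
    "resolvable_fraction",
    "dynamic_range",
    "screen_cost",
]


@dataclass(frozen=True)
class FitnessRecord:
    """Per-strain fitness estimate from replicate corrected sizes."""

    strain: str
    n: int
    mean_fitness: float
    sd_fitness: float
    p_value: float


@dataclass(frozen=True)
class CostSpec:
    """Consumables cost model: plates cost twice as much as pads, one
    pad per plate pinning for dedicated pads, four for up-scaling."""

    plate_cost: float = 2.0
    pad_cost: float = 1.0
    pads_per_plate: int = 1

    def __post_init__(self) -> None:
        if self.plate_cost <= 0 or self.pad_cost <= 0 or self.pads_per_plate <= 0:
            raise ValueError("costs must be positive")


def _strain_values(
    tables: list[SizeTable], layout: pd.DataFrame
) -> dict[str, np.ndarray]:
    """Pool corrected sizes per strain across positions and replicates."""
    out: dict[str, list] = {}
    rows = layout["row"].to_numpy(dtype=int)
    cols = layout["col"].to_numpy(dtype=int)
    strains = layout["strain"].to_numpy()
    for t in tables:
        vals = t.values[rows, cols]
        for s, v in zip(strains, vals):
            if np.isfinite(v):
                out.setdefault(str(s), []).append(float(v))
    return {s: np.asarray(v) for s, v in out.items()}


def compute_fitness(
    tables: list[SizeTable],
    layout: pd.DataFrame,
    control_strains: str | list[str] = "control",
) -> list[FitnessRecord]:
    """Per-strain fitness from replicate corrected size tables.

    Parameters
    ----------
    tables
        One corrected :class:`SizeTable` per replicate plate (same
        layout on each).
    layout
        Table with columns ``row, col, strain`` mapping grid positions
        to strain identifiers.
    control_strains
        Strain id(s) forming the control pool.

    Returns
    -------
    list of FitnessRecord
        Fitness = mean of the strain's pooled replicate values divided
        by the median of the control pool; sd on the same scale; p-value
        from Welch's two-sample t-test against the control pool (NaN
        when either side has < 2 values).
    """
    if not tables:
        raise ValueError("at least one replicate table required")
    if isinstance(control_strains, str):
        control_strains = [control_strains]
    pooled = _strain_values(tables, layout)
    ctrl = np.concatenate(
        [pooled[s] for s in control_strains if s in pooled]
        or [np.empty(0)]
    )
    if ctrl.size == 0:
        raise ValueError(f"no control positions found for {control_strains}")
    ctrl_med = float(np.median(ctrl))
    if ctrl_med <= 0:
        raise ValueError("control median must be positive")
    records = []
    for strain in sorted(pooled):
        if strain in control_strains:
            continue
        vals = pooled[strain]
        n = vals.size
        mean_f = float(vals.mean() / ctrl_med)
        sd_f = float(vals.std(ddof=1) / ctrl_med) if n >= 2 else float("nan")
        if n >= 2 and ctrl.size >= 2:
            p = float(stats.ttest_ind(vals, ctrl, equal_var=False).pvalue)
        else:
            p = float("nan")
        records.append(
            FitnessRecord(
                strain=strain, n=int(n), mean_fitness=mean_f, sd_fitness=sd_f, p_value=p
            )
        )
    return records


def fitness_frame(records: list[FitnessRecord]) -> pd.DataFrame:
    """Records as a table with columns strain, n, fitness, sd, p_value."""
    return pd.DataFrame(
        {
            "strain": [r.strain for r in records],
            "n": [r.n for r in records],
            "fitness": [r.mean_fitness for r in records],
            "sd": [r.sd_fitness for r in records],
            "p_value": [r.p_value for r in records],
        }
    )


def fold_growth(t_final: SizeTable, t0: SizeTable) -> float:
    """Median colony-area fold increase since pinning.

    ``median(final areas) / median(t0 areas)`` over positions with a
    non-zero t = 0 area.
    """
    if t_final.spec.density != t0.spec.density:
        raise ValueError("tables must share the same grid spec")
    a0 = t0.values
    af = t_final.values
    ok = np.isfinite(a0) & np.isfinite(af) & (a0 > 0)
    if not ok.any():
        raise ValueError("no positions with non-zero t0 area; fold growth undefined")
    return float(np.median(af[ok]) / np.median(a0[ok]))


def overgrown_fraction(measurements: pd.DataFrame) -> float:
    """Percentage of grid positions flagged overgrown."""
    flags = measurements["flags"].fillna("")
    return float(100.0 * flags.str.contains("overgrown").mean())


def fitness_resolution(sd: float, n: int, alpha: float = 0.05) -> float:
    """Minimal detectable fitness difference between two strains.

    Two-sample comparison with equal variance ``sd**2`` and ``n``
    replicates each: ``MDD = t(1 - alpha/2, 2n - 2) * sd * sqrt(2/n)``.
    """
    if n < 2:
        raise ValueError("at least 2 replicates required")
    if sd < 0:
        raise ValueError("sd must be non-negative")
    t_crit = stats.t.ppf(1.0 - alpha / 2.0, df=2 * n - 2)
    return float(t_crit * sd * math.sqrt(2.0 / n))


def resolvable_fraction(
    records: list[FitnessRecord] | pd.DataFrame,
    alpha: float = 0.05,
    fdr_correct: bool = False,
) -> float:
    """Percentage of strains significantly different from control.

    Raw ``p < alpha`` by default (no multiple-testing correction);
    ``fdr_correct=True`` applies Benjamini–Hochberg first.
    """
    if isinstance(records, pd.DataFrame):
        p = records["p_value"].to_numpy(dtype=float)
    else:
        p = np.array([r.p_value for r in records], dtype=float)
    p = p[np.isfinite(p)]
    if p.size == 0:
        raise ValueError("no finite p-values")
    if fdr_correct:
        p = stats.false_discovery_control(p)
    return float(100.0 * np.mean(p < alpha))


def dynamic_range(records: list[FitnessRecord] | pd.DataFrame) -> float:
    """Fitness spread: 97.5th minus 2.5th percentile of strain fitness."""
    if isinstance(records, pd.DataFrame):
        f = records["fitness"].to_numpy(dtype=float)
    else:
        f = np.array([r.mean_fitness for r in records], dtype=float)
    f = f[np.isfinite(f)]
    if f.size < 20:
        raise ValueError("at least 20 fitness records required")
    return float(np.percentile(f, 97.5) - np.percentile(f, 2.5))


def screen_cost(
    n_strains: int,
    density: int,
    n_replicates: int,
    cost: CostSpec | None = None,
) -> float:
    """Consumables cost of a screen, in pad-cost units.

    ``plates = ceil(n_strains * n_replicates / density)``;
    each plate costs ``plate_cost`` plus ``pads_per_plate * pad_cost``.
    """
    if density not in DENSITY_SHAPES:
        raise ValueError(f"unsupported density {density}")
    if n_strains < 0 or n_replicates < 0:
        raise ValueError("counts must be non-negative")
    cost = cost or CostSpec()
    plates = math.ceil(n_strains * n_replicates / density)
    return float(plates * (cost.plate_cost + cost.pads_per_plate * cost.pad_cost))
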