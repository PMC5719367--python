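"""Deterministic single-locus viability selection.

The derived allele Q has genotype fitnesses w_QQ = 1, w_Qq = 1 - h s and
w_qq = 1 - s, with selection coefficient s and dominance scalar h (0, 0.5
or 1 for dominant, additive or recessive action of Q).  Mean fitness is

    w_bar = p^2 w_QQ + 2 p (1-p) w_Qq + (1-p)^2 w_qq

and the allele frequency recursion (infinite population, constant
selection) is

    p_{t+1} = p_t [ p_t w_QQ + (1 - p_t) w_Qq ] / w_bar.

The grid search asks, for each starting frequency and time horizon, for the
smallest s on a grid that drives Q to at least 99% within the horizon;
sweeping the paper-scale scenario grid (p0 from 1% to 20%, horizons of 60
and 100 generations) brackets the selection intensity compatible with an
observed sweep.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FitnessParams",
    "Trajectory",
    "mean_fitness",
    "step_frequency",
    "simulate_trajectory",
    "generations_to_reach",
    "min_sufficient_s",
    "scenario_grid",
    "default_s_grid",
    "default_p0_grid",
]


@dataclasses.dataclass(frozen=True)
class FitnessParams:
    """Selection coefficient and dominance, with derived genotype fitnesses."""

    s: float
    h: float = 0.5

    def __post_init__(self) -> None:
        if not (0 <= self.s < 1):
            raise ValueError("selection coefficient must lie in [0, 1)")
        if not (0 <= self.h <= 1):
            raise ValueError("dominance scalar must lie in [0, 1]")

    @property
    def w_qq_hom(self) -> float:  # w_QQ
        return 1.0

    @property
    def w_het(self) -> float:  # w_Qq
        return 1.0 - self.h * self.s

    @property
    def w_anc_hom(self) -> float:  # w_qq
        return 1.0 - self.s


@dataclasses.dataclass(frozen=True)
class Trajectory:
    p0: float
    params: FitnessParams
    frequencies: np.ndarray  # p_t for t = 0..T

    @property
    def horizon(self) -> int:
        return self.frequencies.size - 1


def mean_fitness(p: float, params: FitnessParams) -> float:
    """Population mean fitness at derived-allele frequency ``p``."""
    if not (0 <= p <= 1):
        raise ValueError("frequency must lie in [0, 1]")
    q = 1.0 - p
    return (
        p * p * params.w_qq_hom
        + 2 * p * q * params.w_het
        + q * q * params.w_anc_hom
    )


def step_frequency(p: float, params: FitnessParams) -> float:
    """One generation of the selection recursion; 0 and 1 are fixed points."""
    w_bar = mean_fitness(p, params)
    if w_bar == 0:
        raise ZeroDivisionError("mean fitness is zero (s = 1 with p = 0)")
    return p * (p * params.w_qq_hom + (1.0 - p) * params.w_het) / w_bar


def simulate_trajectory(p0: float, params: FitnessParams, horizon: int) -> Trajectory:
    """Iterate the recursion for ``horizon`` generations from ``p0``."""
    if not (0 <= p0 <= 1):
        raise ValueError("initial frequency must lie in [0, 1]")
    freqs = np.empty(horizon + 1)
    freqs[0] = p = p0
    for t in range(horizon):
        p = step_frequency(p, params)
        freqs[t + 1] = p
    return Trajectory(p0=p0, params=params, frequencies=freqs)


def generations_to_reach(
    p0: float, params: FitnessParams, target: float = 0.99, cap: int = 100
) -> int | None:
    """Smallest t <= cap with p_t >= target, or None if never reached."""
    if not (0 < p0 <= 1):
        raise ValueError("initial frequency must lie in (0, 1]")
    if not (0 < target <= 1):
        raise ValueError("target frequency must lie in (0, 1]")
    if cap < 1:
        raise ValueError("cap must be >= 1")
    p = p0
    if p >= target:
        return 0
    for t in range(1, cap + 1):
        p = step_frequency(p, params)
        if p >= target:
            return t
    return None


def default_s_grid() -> np.ndarray:
    """s = 0.01, 0.02, ..., 0.50."""
    return np.round(np.arange(1, 51) / 100.0, 2)


def default_p0_grid() -> np.ndarray:
    """p0 = 0.01, 0.02, ..., 0.20."""
    return np.round(np.arange(1, 21) / 100.0, 2)


def min_sufficient_s(
    p0: float,
    horizon: int,
    target: float = 0.99,
    s_grid: Sequence[float] | None = None,
    h: float = 0.5,
) -> tuple[float, int] | None:
    """Smallest grid s reaching ``target`` within ``horizon`` generations.

    Returns ``(s, generations)`` for the first sufficient grid value, or
    ``None`` when even the largest s on the grid is insufficient.
    """
    grid = default_s_grid() if s_grid is None else np.asarray(s_grid, float)
    if grid.size == 0:
        raise ValueError("empty selection-coefficient grid")
    if np.any(np.diff(grid) <= 0):
        raise ValueError("s grid must be sorted strictly ascending")
    for s in grid:
        g = generations_to_reach(p0, FitnessParams(s=float(s), h=h), target, horizon)
        if g is not None:
            return float(s), g
    return None


def scenario_grid(
    p0_values: Sequence[float] | None = None,
    horizons: Sequence[int] = (60, 100),
    target: float = 0.99,
    s_grid: Sequence[float] | None = None,
    h: float = 0.5,
) -> pd.DataFrame:
    """Minimal sufficient s for every (p0, horizon) scenario.

    Returns a table with columns p0, horizon, min_s, generations (min_s and
    generations are NaN where no grid value suffices).  The overall min and
    max of min_s are available as ``df["min_s"].min()`` / ``.max()``.
    """
    p0s = default_p0_grid() if p0_values is None else np.asarray(p0_values, float)
    rows = []
    for p0 in p0s:
        for horizon in horizons:
            hit = min_sufficient_s(float(p0), int(horizon), target, s_grid, h)
            s, g = hit if hit is not None else (np.nan, np.nan)
            rows.append(
                {"p0": float(p0), "horizon": int(horizon), "min_s": s,
                 "generations": g}
            )
    return pd.DataFrame(rows)
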