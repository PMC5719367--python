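"""Synthetic data generators for every pipeline stage.

The panel generator is a discrete-generation forward Wright-Fisher
simulation of 2N haplotypes.  Neutral biallelic background markers start at
random frequencies; a single derived copy of the focal allele is introduced
``age`` generations before present and its carriers reproduce with the same
viability fitnesses (w_QQ = 1, w_Qq = 1 - h s, w_qq = 1 - s) used by the
deterministic selection recursion.  Gametes recombine with a Poisson number
of crossovers per meiosis placed uniformly on the physical map, converted
at the same constant bp-to-cM rate as the dating module.  Runs are
conditioned on non-loss of the focal allele (and optionally on a final
frequency window) by restarting with a logged restart count.

This is a stylised generator: it reproduces the features the pipeline
measures (a dated sweep with its haplotype-homozygosity footprint, an
additive tag-haplotype effect on weighted phenotypes, a two-period bone
size shift) but no demographic history, ascertainment or LD structure of
real cattle panels.
"""

from __future__ import annotations

import dataclasses
import json
from typing import Any

import numpy as np
import pandas as pd

from .assoc import WeightedPhenotypes, compute_weights
from .osteometry import bundled_reference
from .panel import MarkerMap, PhasedPanel
from .windows import HaplotypeWindow, score_genotypes

__all__ = [
    "SweepSimConfig",
    "TruthRecord",
    "ReliabilitySpec",
    "simulate_sweep_panel",
    "simulate_phenotypes",
    "simulate_bones",
]


@dataclasses.dataclass(frozen=True)
class SweepSimConfig:
    """Forward-simulation settings.

    Parameters
    ----------
    n_samples : int
        Diploid samples drawn (without replacement) at present.
    n_markers, spacing_bp : int
        Marker count and regular inter-marker spacing (bp); the default
        2,000 markers at 5 kbp mirror a dense SNP array segment.
    mbp_per_cm : float
        Physical-to-genetic conversion (1 cM per 1.23 Mbp by default),
        shared with the dating module.
    s, h : float
        Selection coefficient and dominance of the derived focal allele.
    age : int
        Generations between introduction of the single derived copy and
        the present-day sample.
    ne : int
        Diploid effective population size carrying the drift.
    freq_window : (float, float) or None
        Accept only runs whose final focal frequency lands in this window
        (None disables the check).
    condition_nonloss : bool
        Restart runs that lose the focal allele (disable to study pure
        drift, e.g. the neutral s = 0 martingale check).
    max_restarts : int
        Restart budget before giving up with diagnostics.
    seed : int
        RNG seed; recorded in the truth record.
    focal_index : int or None
        Focal marker column (default: middle of the map).
    """

    n_samples: int = 1000
    n_markers: int = 2000
    spacing_bp: int = 5000
    mbp_per_cm: float = 1.23
    s: float = 0.2
    h: float = 0.5
    age: int = 60
    ne: int = 1000
    freq_window: tuple[float, float] | None = (0.05, 1.0)
    condition_nonloss: bool = True
    max_restarts: int = 1000
    seed: int = 1
    focal_index: int | None = None

    def __post_init__(self) -> None:
        for name in ("n_samples", "n_markers", "spacing_bp", "age", "ne"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.n_samples > self.ne:
            raise ValueError("cannot sample more diploids than the population holds")
        focal = self.focal()
        if not (0 <= focal < self.n_markers):
            raise ValueError("focal marker index outside the panel")

    def focal(self) -> int:
        return self.n_markers // 2 if self.focal_index is None else self.focal_index

    @property
    def map_length_morgans(self) -> float:
        span_bp = (self.n_markers - 1) * self.spacing_bp
        return span_bp / (self.mbp_per_cm * 1e6) / 100.0


@dataclasses.dataclass(frozen=True)
class TruthRecord:
    """Ground truth shipped with every simulated dataset."""

    kind: str
    seed: int
    params: dict[str, Any]

    def to_json(self) -> str:
        return json.dumps(
            {"kind": self.kind, "seed": self.seed, **self.params}, indent=2
        )


def _recombine(
    pop: np.ndarray,
    parent: np.ndarray,
    start_hap: np.ndarray,
    n_cross: np.ndarray,
    pos: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Form one gamete per row of ``parent`` from the diploid parents."""
    m = pop.shape[1]
    gametes = pop[2 * parent + start_hap].copy()
    for i in np.flatnonzero(n_cross):
        bp = rng.uniform(pos[0], pos[-1], size=n_cross[i])
        cut = np.searchsorted(pos, bp, side="right")
        counts = np.bincount(cut, minlength=m + 1)[:m]
        phase = (np.cumsum(counts) % 2).astype(bool)
        other = pop[2 * parent[i] + 1 - start_hap[i]]
        gametes[i, phase] = other[phase]
    return gametes


def simulate_sweep_panel(config: SweepSimConfig) -> tuple[PhasedPanel, TruthRecord]:
    """Simulate a phased panel carrying one sweep of known age and strength.

    Returns the sampled panel plus a :class:`TruthRecord` holding the focal
    marker, derived-allele identity, true age and s, realised frequencies
    and the restart count.

    Raises
    ------
    RuntimeError
        If the restart budget is exhausted before a run keeps the focal
        allele (and hits the frequency window, when one is set).
    """
    rng = np.random.default_rng(config.seed)
    ne, m = config.ne, config.n_markers
    focal = config.focal()
    pos = 1 + config.spacing_bp * np.arange(m, dtype=np.int64)
    length_m = config.map_length_morgans
    w_by_count = np.array([1.0 - config.s, 1.0 - config.h * config.s, 1.0])

    restarts = 0
    while True:
        if restarts > config.max_restarts:
            raise RuntimeError(
                f"focal allele failed to satisfy the acceptance condition in "
                f"{config.max_restarts} restarts (s={config.s}, age={config.age}, "
                f"ne={config.ne}, window={config.freq_window})"
            )
        base_freq = rng.uniform(0.05, 0.95, size=m)
        pop = (rng.random((2 * ne, m)) < base_freq).astype(np.uint8)
        pop[:, focal] = 0
        pop[rng.integers(2 * ne), focal] = 1

        lost = False
        for _ in range(config.age):
            counts = pop[0::2, focal].astype(np.int64) + pop[1::2, focal]
            fitness = w_by_count[counts]
            probs = fitness / fitness.sum()
            parent = rng.choice(ne, size=2 * ne, p=probs)
            start_hap = rng.integers(0, 2, size=2 * ne)
            n_cross = rng.poisson(length_m, size=2 * ne)
            pop = _recombine(pop, parent, start_hap, n_cross, pos, rng)
            if not pop[:, focal].any():
                lost = True
                break
        if lost and config.condition_nonloss:
            restarts += 1
            continue
        p_final = pop[:, focal].mean()
        if config.freq_window is not None and not (
            config.freq_window[0] <= p_final <= config.freq_window[1]
        ):
            restarts += 1
            continue
        break

    chosen = np.sort(rng.choice(ne, size=config.n_samples, replace=False))
    rows = np.empty(2 * config.n_samples, dtype=np.int64)
    rows[0::2] = 2 * chosen
    rows[1::2] = 2 * chosen + 1
    hap = pop[rows]
    markers = MarkerMap(
        chrom="14",
        ids=tuple(f"snp{i + 1}" for i in range(m)),
        pos=pos,
    )
    samples = tuple(f"S{i + 1:05d}" for i in range(config.n_samples))
    panel = PhasedPanel(samples, hap, markers)
    truth = TruthRecord(
        kind="sweep_panel",
        seed=config.seed,
        params={
            "focal_index": focal,
            "focal_marker": markers.ids[focal],
            "derived_allele": 1,
            "age_generations": config.age,
            "s": config.s,
            "h": config.h,
            "ne": config.ne,
            "final_freq_population": float(p_final),
            "final_freq_sample": float(hap[:, focal].mean()),
            "n_restarts": restarts,
        },
    )
    return panel, truth


@dataclasses.dataclass(frozen=True)
class ReliabilitySpec:
    """Beta-distributed dEBV reliabilities truncated to a feasible range.

    The default Beta(38, 2) truncated to [0.58, 0.98] has mean ~0.95 and
    minimum 0.58, matching a progeny-tested bull panel in which most sires
    are densely recorded.
    """

    a: float = 38.0
    b: float = 2.0
    lo: float = 0.58
    hi: float = 0.98

    def draw(self, n: int, rng: np.random.Generator) -> np.ndarray:
        out = np.empty(n)
        filled = 0
        while filled < n:
            draw = rng.beta(self.a, self.b, size=2 * (n - filled))
            keep = draw[(draw >= self.lo) & (draw <= self.hi)][: n - filled]
            out[filled : filled + keep.size] = keep
            filled += keep.size
        return out


def simulate_phenotypes(
    panel: PhasedPanel,
    window: HaplotypeWindow,
    allele: str,
    alpha: float,
    h2: float = 0.37,
    qtl_share: float = 0.0809,
    reliability_spec: ReliabilitySpec | None = None,
    genetic_variance: float | None = None,
    seed: int = 1,
) -> tuple[WeightedPhenotypes, TruthRecord]:
    """Simulate dEBV phenotypes with an additive haplotype effect.

    The focal window contributes ``u_i = z_i alpha`` per sample; polygenic
    noise is scaled so the window explains ``qtl_share`` of the genetic
    variance, and each record's deregression noise has variance
    ``(1 - r2_i)/r2_i`` times the genetic variance, with reliabilities
    drawn from ``reliability_spec``.  GLS weights use ``c = 1 - qtl_share``.

    With ``alpha = 0`` the window variance vanishes and the genetic
    variance must be supplied explicitly via ``genetic_variance``.
    """
    if not (0 < h2 < 1):
        raise ValueError("h2 must lie in (0, 1)")
    if not (0 < qtl_share < 1):
        raise ValueError("qtl_share must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    spec = reliability_spec or ReliabilitySpec()
    geno = score_genotypes(panel, window)
    try:
        k = window.alleles.index(allele)
    except ValueError:
        raise KeyError(f"allele {allele!r} not in window") from None
    z = geno.z[:, k]
    u = z * alpha
    var_u = float(u.var())
    if var_u > 0:
        var_g = var_u / qtl_share
        var_poly = var_g - var_u
    elif genetic_variance is not None and genetic_variance > 0:
        var_g = float(genetic_variance)
        var_poly = var_g
    else:
        raise ValueError(
            "inconsistent variance shares: window effect has zero variance "
            "and no genetic_variance was supplied"
        )
    n = panel.n_samples
    g = u + rng.normal(0.0, np.sqrt(var_poly), size=n)
    r2 = spec.draw(n, rng)
    e = rng.normal(0.0, np.sqrt((1 - r2) / r2 * var_g))
    phenos = WeightedPhenotypes(
        samples=panel.samples,
        y=g + e,
        reliabilities=r2,
        weights=compute_weights(r2, h2, c=1 - qtl_share),
    )
    truth = TruthRecord(
        kind="phenotypes",
        seed=seed,
        params={
            "allele": allele,
            "alpha": alpha,
            "h2": h2,
            "qtl_share": qtl_share,
            "genetic_variance": var_g,
            "window": [window.start, window.end],
        },
    )
    return phenos, truth


# Skeletal-element and measurement-code sampling weights for synthetic bone
# assemblages, proportional to a typical North-Atlantic cattle-bone
# inventory (fragment counts by element; measurement counts by code).
_ELEMENT_WEIGHTS = {
    "humerus": 38,
    "tibia": 27,
    "metatarsal": 24,
    "metacarpal": 11,
    "calcaneus": 2,
    "femur": 15,
    "radius-ulna": 5,
}
_CODE_WEIGHTS = {
    "Bd": 14, "Bp": 13, "BT": 13, "DPA": 10, "GB": 15, "GL": 18, "SD": 16,
    "SDO": 12,
}


def simulate_bones(
    n_a: int,
    n_b: int,
    delta: float = 0.076,
    sigma: float = 0.0932,
    seed: int = 1,
    reference: pd.DataFrame | None = None,
    period_a: str = "14th-15th",
    period_b: str = "17th-18th",
) -> tuple[pd.DataFrame, TruthRecord]:
    """Simulate a two-period bone-measurement dataset.

    Log10 size indices are drawn N(0, sigma) for the earlier period and
    N(delta, sigma) for the later one, then back-transformed to mm against
    the reference skeleton, with element and measurement-code labels drawn
    from the inventory proportions above.  Defaults reflect assemblages of
    33 and 89 specimens and a 0.076 log10 shift (~1.2-fold).
    """
    if n_a < 2 or n_b < 2:
        raise ValueError("each period needs at least 2 specimens")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    rng = np.random.default_rng(seed)
    ref = bundled_reference() if reference is None else reference
    ref_lookup = ref.set_index(["element", "code"])["value_mm"]
    elements = list(_ELEMENT_WEIGHTS)
    e_w = np.array(list(_ELEMENT_WEIGHTS.values()), float)
    e_w /= e_w.sum()
    codes = list(_CODE_WEIGHTS)
    c_w = np.array(list(_CODE_WEIGHTS.values()), float)
    c_w /= c_w.sum()

    rows = []
    spec_counter = 0
    for period, n, mean in ((period_a, n_a, 0.0), (period_b, n_b, delta)):
        for _ in range(n):
            spec_counter += 1
            element = elements[rng.choice(len(elements), p=e_w)]
            code = codes[rng.choice(len(codes), p=c_w)]
            log_ratio = rng.normal(mean, sigma)
            rows.append(
                {
                    "specimen_id": f"B{spec_counter:04d}",
                    "period": period,
                    "element": element,
                    "code": code,
                    "value_mm": float(
                        ref_lookup.loc[(element, code)] * 10.0**log_ratio
                    ),
                }
            )
    truth = TruthRecord(
        kind="bones",
        seed=seed,
        params={
            "n_a": n_a, "n_b": n_b, "delta": delta, "sigma": sigma,
            "period_a": period_a, "period_b": period_b,
        },
    )
    return pd.DataFrame(rows), truth
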