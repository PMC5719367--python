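"""Extended haplotype homozygosity (EHH) and sweep-age estimation.

EHH at distance x from a core allele is the probability that two randomly
drawn chromosomes carrying the allele are identical over the whole segment
from the core to x:

    EHH = sum_h C(n_h, 2) / C(N, 2)

over the distinct extended haplotypes h among the N carriers.  Around a
young selected allele, homozygosity extends far before decaying; the decay
span converts to genetic length r (Morgans) and the expected number of
generations back to the carriers' common ancestor is

    E[g] = 1 - ln(p) / r

with p the identity-by-descent probability at which the decay is read off
(default 0.05).  Ages in years use a generation interval (default 5 years,
cattle); confidence intervals come from Monte-Carlo draws of a Poisson
number of generations with mean E[g], or from the closed-form Poisson
quantiles.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import stats

from .panel import PhasedPanel

__all__ = [
    "EHHProfile",
    "DatingResult",
    "ehh_profile",
    "decay_span",
    "expected_generations",
    "coalescence_interval",
    "date_sweep",
    "DEFAULT_MBP_PER_CM",
]

# Default physical-to-genetic conversion: 1 cM per 1.23 Mbp.
DEFAULT_MBP_PER_CM = 1.23


@dataclasses.dataclass(frozen=True)
class EHHProfile:
    """EHH decay to either side of a core (marker, allele) pair.

    ``marker_indices`` run left-to-right and include the core; ``ehh`` holds
    the corresponding EHH values (1.0 at the core).  The scan on each side
    stops at the first marker whose EHH falls strictly below ``threshold``
    (recorded in ``left_stop``/``right_stop``), or at the chromosome end,
    in which case the flank is censored.
    """

    core_index: int
    core_marker: str
    core_allele: int
    threshold: float
    n_carriers: int
    marker_indices: np.ndarray
    distances_bp: np.ndarray  # signed, position - core position
    ehh: np.ndarray
    left_stop: int | None  # marker index of first sub-threshold marker, or None
    right_stop: int | None

    @property
    def censored_left(self) -> bool:
        return self.left_stop is None

    @property
    def censored_right(self) -> bool:
        return self.right_stop is None


def _ehh_one_side(
    carriers: np.ndarray, order: np.ndarray, threshold: float
) -> tuple[list[float], int | None]:
    """Cumulative EHH over markers visited in ``order`` (outward from core)."""
    n = carriers.shape[0]
    pairs_total = n * (n - 1) / 2.0
    classes = np.zeros(n, dtype=np.int64)
    values: list[float] = []
    stop: int | None = None
    for j in order:
        classes = classes * 2 + carriers[:, j]
        _, classes, counts = np.unique(
            classes, return_inverse=True, return_counts=True
        )
        ehh = float((counts * (counts - 1) / 2.0).sum() / pairs_total)
        values.append(ehh)
        if ehh < threshold:
            stop = int(j)
            break
    return values, stop


def ehh_profile(
    panel: PhasedPanel,
    core_marker: str | int,
    core_allele: int,
    threshold: float = 0.05,
) -> EHHProfile:
    """EHH of ``core_allele`` at ``core_marker``, scanned out on both flanks.

    Only chromosomes carrying the core allele enter the computation; at
    least two carriers are required.  EHH is non-increasing outward because
    each added marker refines the haplotype partition.
    """
    if isinstance(core_marker, str):
        core = panel.markers.index_of(core_marker)
    else:
        core = int(core_marker)
        if not (0 <= core < panel.n_markers):
            raise ValueError(f"core marker index {core} out of range")
    carrier_rows = panel.haplotypes[:, core] == core_allele
    n = int(carrier_rows.sum())
    if n < 2:
        raise ValueError("EHH undefined for fewer than two carriers")
    carriers = panel.haplotypes[carrier_rows]

    m = panel.n_markers
    left_vals, left_stop = _ehh_one_side(
        carriers, np.arange(core - 1, -1, -1), threshold
    )
    right_vals, right_stop = _ehh_one_side(
        carriers, np.arange(core + 1, m), threshold
    )
    left_idx = np.arange(core - 1, core - 1 - len(left_vals), -1)
    right_idx = np.arange(core + 1, core + 1 + len(right_vals))
    idx = np.concatenate([left_idx[::-1], [core], right_idx])
    ehh = np.concatenate([np.asarray(left_vals)[::-1], [1.0], right_vals])
    pos = panel.markers.pos
    return EHHProfile(
        core_index=core,
        core_marker=panel.markers.ids[core],
        core_allele=int(core_allele),
        threshold=float(threshold),
        n_carriers=n,
        marker_indices=idx,
        distances_bp=pos[idx] - pos[core],
        ehh=ehh,
        left_stop=left_stop,
        right_stop=right_stop,
    )


def decay_span(
    profile: EHHProfile,
    panel: PhasedPanel | None = None,
    allow_censored: bool = False,
    boundary: str = "first-below",
) -> tuple[int, bool]:
    """Physical span (bp) of the EHH decay, stop marker to stop marker.

    ``boundary="first-below"`` measures between the first sub-threshold
    markers on each side ("entire length span"); ``"last-above"`` uses the
    outermost markers still at or above the threshold, differing by at most
    one marker spacing per side.  A flank that never decays raises unless
    ``allow_censored`` is set, in which case the chromosome end stands in
    and the returned flag marks the span as censored.

    Returns ``(span_bp, censored)``.
    """
    if boundary not in ("first-below", "last-above"):
        raise ValueError(f"unknown boundary rule {boundary!r}")
    censored = profile.censored_left or profile.censored_right
    if censored and not allow_censored:
        raise ValueError(
            "censored decay: EHH never fell below the threshold on "
            + ("both flanks" if profile.censored_left and profile.censored_right
               else "the left flank" if profile.censored_left else "the right flank")
        )
    idx = profile.marker_indices
    dist = profile.distances_bp
    pos_of = dict(zip(idx.tolist(), dist.tolist()))

    if profile.censored_left:
        left = float(dist[0])
    elif boundary == "first-below":
        left = pos_of[profile.left_stop]
    else:
        left = pos_of.get(profile.left_stop + 1, 0.0)
    if profile.censored_right:
        right = float(dist[-1])
    elif boundary == "first-below":
        right = pos_of[profile.right_stop]
    else:
        right = pos_of.get(profile.right_stop - 1, 0.0)
    span = int(round(right - left))
    if span <= 0:
        raise ValueError("non-positive decay span")
    return span, censored


def expected_generations(
    span_bp: float | None = None,
    threshold_p: float = 0.05,
    mbp_per_cm: float = DEFAULT_MBP_PER_CM,
    cm_span: float | None = None,
    classic: bool = False,
) -> tuple[float, float]:
    """Map length r (Morgans) of the decay span and E[generations].

    By default r converts the physical span at ``mbp_per_cm`` (1 cM per
    1.23 Mbp); supplying ``cm_span`` (genetic-map cM across the span)
    overrides the constant conversion.  ``E[g] = 1 - ln(p)/r``; with
    ``classic=True`` the unit offset is dropped, giving ``-ln(p)/r``.
    """
    if not (0 < threshold_p < 1):
        raise ValueError("threshold probability must lie in (0, 1)")
    if cm_span is not None:
        if cm_span <= 0:
            raise ValueError("cM span must be positive")
        r = cm_span / 100.0
    else:
        if span_bp is None or span_bp <= 0:
            raise ValueError("span must be positive")
        r = span_bp / (mbp_per_cm * 1e6) / 100.0
    e_g = -np.log(threshold_p) / r
    if not classic:
        e_g = 1.0 + e_g
    return float(r), float(e_g)


@dataclasses.dataclass(frozen=True)
class DatingResult:
    """Sweep age estimate with its confidence interval."""

    threshold: float
    span_bp: int | None
    r_morgans: float | None
    e_generations: float
    generation_years: float
    point_years: float
    ci_years: tuple[float, float]
    mode: str
    n_reps: int
    seed: int | None
    censored: bool = False

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "span_bp": self.span_bp,
            "r_morgans": self.r_morgans,
            "e_generations": self.e_generations,
            "generation_years": self.generation_years,
            "point_years": self.point_years,
            "ci_years": list(self.ci_years),
            "mode": self.mode,
            "reps": self.n_reps,
            "seed": self.seed,
            "censored": self.censored,
        }


def coalescence_interval(
    e_g: float,
    gen_interval_years: float = 5.0,
    n_reps: int = 1_000_000,
    seed: int | None = 1,
    mode: str = "monte-carlo",
    level: float = 0.95,
) -> DatingResult:
    """Confidence interval for the coalescence age in years.

    The number of generations back to coalescence is modelled as
    Poisson(lambda = E[g]); the interval is the (2.5%, 97.5%) quantiles of
    the draws times the generation interval.  Quantiles use the smallest
    value whose empirical CDF reaches the level.  ``mode="analytic"``
    replaces the draws by closed-form Poisson quantiles; ``mode="normal"``
    uses the N(0, lambda) error approximation (floored at 0 generations).
    """
    if e_g <= 0:
        raise ValueError("expected generations must be positive")
    lo_q, hi_q = (1 - level) / 2, 1 - (1 - level) / 2
    point = e_g * gen_interval_years
    if mode == "monte-carlo":
        rng = np.random.default_rng(seed)
        draws = rng.poisson(e_g, size=n_reps) * gen_interval_years
        lo, hi = np.quantile(draws, [lo_q, hi_q], method="inverted_cdf")
    elif mode == "analytic":
        lo = stats.poisson.ppf(lo_q, e_g) * gen_interval_years
        hi = stats.poisson.ppf(hi_q, e_g) * gen_interval_years
        n_reps = 0
    elif mode == "normal":
        half = stats.norm.ppf(hi_q) * np.sqrt(e_g)
        lo = max(0.0, e_g - half) * gen_interval_years
        hi = (e_g + half) * gen_interval_years
        n_reps = 0
    else:
        raise ValueError(f"unknown CI mode {mode!r}")
    return DatingResult(
        threshold=np.nan,
        span_bp=None,
        r_morgans=None,
        e_generations=float(e_g),
        generation_years=float(gen_interval_years),
        point_years=float(point),
        ci_years=(float(lo), float(hi)),
        mode=mode,
        n_reps=n_reps,
        seed=seed,
    )


def date_sweep(
    panel: PhasedPanel,
    core_marker: str | int,
    core_allele: int,
    threshold: float = 0.05,
    gen_interval_years: float = 5.0,
    mbp_per_cm: float = DEFAULT_MBP_PER_CM,
    use_genetic_map: bool = False,
    n_reps: int = 1_000_000,
    seed: int | None = 1,
    mode: str = "monte-carlo",
    allow_censored: bool = False,
    classic: bool = False,
) -> DatingResult:
    """Full pipeline: EHH profile -> decay span -> E[g] -> dated interval."""
    profile = ehh_profile(panel, core_marker, core_allele, threshold)
    span, censored = decay_span(profile, allow_censored=allow_censored)
    cm_span = None
    if use_genetic_map:
        cm = panel.markers.cm
        if cm is None:
            raise ValueError("panel has no genetic map (cM) column")
        left = profile.left_stop if profile.left_stop is not None else int(profile.marker_indices[0])
        right = profile.right_stop if profile.right_stop is not None else int(profile.marker_indices[-1])
        cm_span = float(cm[right] - cm[left])
    r, e_g = expected_generations(
        span_bp=span, threshold_p=threshold, mbp_per_cm=mbp_per_cm,
        cm_span=cm_span, classic=classic,
    )
    result = coalescence_interval(
        e_g, gen_interval_years, n_reps=n_reps, seed=seed, mode=mode
    )
    return dataclasses.replace(
        result, threshold=threshold, span_bp=span, r_morgans=r, censored=censored
    )
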