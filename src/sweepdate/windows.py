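"""Haplotype windows: allele calling, copy-number scoring and HWE diagnostics.

Short haplotype alleles are enumerated over sliding windows of consecutive
markers.  Within a window of ``L`` markers each chromosome spells an allele
string over {0, 1}; alleles are indexed ``1..K`` in ascending frequency
(allele 1 = rarest), with frequency ties broken lexicographically so output
is deterministic.  Per-sample copy numbers (0/1/2) yield the centered coding
``z_k = copies - 2 p_k`` used by the association scan: since ``p_k`` is the
sample allele frequency, every ``z_k`` column averages to zero.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Sequence

import numpy as np
from scipy import stats
from scipy.special import gammaln

from .panel import MarkerMap, PhasedPanel

__all__ = [
    "HaplotypeWindow",
    "HaplotypeGenotypes",
    "make_windows",
    "call_window_haplotypes",
    "score_genotypes",
    "hwe_and_frequency",
]

logger = logging.getLogger(__name__)


@dataclasses.dataclass(frozen=True)
class HaplotypeWindow:
    """Haplotype alleles of one marker interval, sorted by frequency.

    ``interval`` is half-open in 0-based marker indices: markers
    ``start .. end-1`` belong to the window.
    """

    index: int
    start: int
    end: int
    alleles: tuple[str, ...]
    freqs: np.ndarray  # ascending; freqs[k] is the frequency of alleles[k]

    def __post_init__(self) -> None:
        freqs = np.asarray(self.freqs, dtype=float)
        object.__setattr__(self, "freqs", freqs)
        if len(self.alleles) != freqs.size or freqs.size < 1:
            raise ValueError("alleles/freqs mismatch")
        if abs(freqs.sum() - 1.0) > 1e-12:
            raise ValueError("haplotype frequencies must sum to 1")
        if np.any(np.diff(freqs) < 0):
            raise ValueError("frequencies must be sorted ascending")
        width = self.end - self.start
        if any(len(a) != width for a in self.alleles):
            raise ValueError("allele string length != window width")

    @property
    def n_alleles(self) -> int:
        return len(self.alleles)


@dataclasses.dataclass(frozen=True)
class HaplotypeGenotypes:
    """Per-sample copy counts and centered codings for one window."""

    window: HaplotypeWindow
    samples: tuple[str, ...]
    copies: np.ndarray  # (n_samples, K) ints in {0,1,2}
    z: np.ndarray  # (n_samples, K) floats, copies - 2 p_k

    def __post_init__(self) -> None:
        if self.copies.shape != self.z.shape:
            raise ValueError("copies/z shape mismatch")
        if self.copies.shape[0] != len(self.samples):
            raise ValueError("row count != sample count")
        if np.any(self.copies.sum(axis=1) != 2):
            raise ValueError("copies must sum to 2 per sample")


def make_windows(
    markers: MarkerMap | int, size: int, step: int = 1
) -> list[tuple[int, int]]:
    """Half-open marker-index intervals ``[i, i+size)`` tiling one chromosome.

    Starts run ``0, step, 2*step, ...`` while the window fits, giving
    ``floor((M - size)/step) + 1`` windows for ``M >= size`` markers.  A
    too-short map yields an empty list with a logged warning.
    """
    if size < 1 or step < 1:
        raise ValueError("size and step must be >= 1")
    m = markers if isinstance(markers, int) else markers.n_markers
    if m < size:
        logger.warning("map has %d markers < window size %d: no windows", m, size)
        return []
    return [(i, i + size) for i in range(0, m - size + 1, step)]


def call_window_haplotypes(
    panel: PhasedPanel, interval: tuple[int, int], index: int = 0
) -> HaplotypeWindow:
    """Enumerate distinct haplotype alleles of ``panel`` over ``interval``.

    Frequencies are counts over the ``2N`` chromosomes; ties in frequency
    are broken lexicographically by allele string.
    """
    start, end = interval
    if not (0 <= start < end <= panel.n_markers):
        raise ValueError(f"interval {interval} outside marker range")
    sub = panel.haplotypes[:, start:end]
    uniq, counts = np.unique(sub, axis=0, return_counts=True)
    strings = ["".join(map(str, row)) for row in uniq]
    freqs = counts / counts.sum()
    order = sorted(range(len(strings)), key=lambda i: (freqs[i], strings[i]))
    return HaplotypeWindow(
        index=index,
        start=start,
        end=end,
        alleles=tuple(strings[i] for i in order),
        freqs=freqs[order],
    )


def score_genotypes(panel: PhasedPanel, window: HaplotypeWindow) -> HaplotypeGenotypes:
    """Score 0/1/2 copy numbers and centered codings for every window allele."""
    sub = panel.haplotypes[:, window.start : window.end]
    strings = np.array(["".join(map(str, row)) for row in sub])
    lookup = {a: k for k, a in enumerate(window.alleles)}
    try:
        codes = np.array([lookup[s] for s in strings])
    except KeyError as exc:
        raise ValueError(f"chromosome carries allele {exc} absent from window") from exc
    n = panel.n_samples
    k = window.n_alleles
    copies = np.zeros((n, k), dtype=np.int64)
    np.add.at(copies, (np.repeat(np.arange(n), 2), codes), 1)
    z = copies - 2.0 * window.freqs
    z -= z.mean(axis=0)  # remove last-bit rounding so columns sum to zero
    return HaplotypeGenotypes(
        window=window, samples=panel.samples, copies=copies, z=z
    )


def _hwe_exact_p(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Exact two-sided HWE test: sum of probabilities <= that observed.

    Enumerates all heterozygote counts compatible with the observed allele
    counts, computes each configuration's probability under random mating
    conditional on allele counts, and sums those no more probable than the
    observed configuration (with a small relative tolerance for float ties).
    """
    n = n_aa + n_ab + n_bb
    n_a = 2 * n_aa + n_ab
    parity = n_a % 2
    hets = np.arange(parity, min(n_a, 2 * n - n_a) + 1, 2)

    def logprob(h: np.ndarray) -> np.ndarray:
        aa = (n_a - h) // 2
        bb = n - aa - h
        return (
            gammaln(n + 1)
            - gammaln(aa + 1)
            - gammaln(h + 1)
            - gammaln(bb + 1)
            + h * np.log(2.0)
            + gammaln(n_a + 1)
            + gammaln(2 * n - n_a + 1)
            - gammaln(2 * n + 1)
        )

    lp = logprob(hets)
    probs = np.exp(lp - lp.max())
    probs /= probs.sum()
    observed = probs[np.searchsorted(hets, n_ab)]
    return float(min(1.0, probs[probs <= observed * (1 + 1e-12)].sum()))


def hwe_and_frequency(
    counts_hom_carrier: int,
    counts_het: int,
    counts_hom_noncarrier: int,
    method: str = "chi-square",
) -> tuple[float, float]:
    """Carrier-allele frequency and Hardy-Weinberg test p-value.

    Parameters
    ----------
    counts_hom_carrier, counts_het, counts_hom_noncarrier : int
        Genotype counts for carrier homozygotes, heterozygotes and
        non-carrier homozygotes.
    method : {"chi-square", "exact"}
        ``chi-square`` tests observed counts against HWE expectations with
        1 df; ``exact`` enumerates heterozygote counts conditional on the
        allele counts (two-sided sum of probabilities <= observed).

    Returns
    -------
    (frequency, p_value)
        Carrier-allele frequency as a fraction, and the HWE p-value.
    """
    counts = np.array(
        [counts_hom_carrier, counts_het, counts_hom_noncarrier], dtype=np.int64
    )
    if np.any(counts < 0):
        raise ValueError("genotype counts must be non-negative")
    n = counts.sum()
    if n == 0:
        raise ValueError("all genotype counts are zero")
    p = (2 * counts[0] + counts[1]) / (2 * n)
    if method == "chi-square":
        expected = np.array([n * p * p, 2 * n * p * (1 - p), n * (1 - p) ** 2])
        if p in (0.0, 1.0):
            return float(p), 1.0  # monomorphic: trivially at equilibrium
        chi2 = float(((counts - expected) ** 2 / expected).sum())
        pval = float(stats.chi2.sf(chi2, df=1))
    elif method == "exact":
        pval = _hwe_exact_p(*counts)
    else:
        raise ValueError(f"unknown HWE method {method!r}")
    return float(p), pval
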