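"""Reliability-weighted GLS haplotype-substitution regression.

Deregressed breeding values (dEBVs) have heterogeneous information content,
so each record enters the regression with a residual variance proportional
to ``w_i = lambda^-1 (d_i + c)`` where ``lambda = (1 - h2)/h2``,
``d_i = (1 - r2_i)/r2_i`` derives from the record's reliability ``r2_i``,
and ``c`` is the fraction of genetic variance the tested haplotype cannot
explain.  For each window and haplotype allele ``k`` the model

    y = 1 mu + z_k alpha_k + e,    e ~ N(0, W sigma2_e),  W = Diag(w)

is solved by generalized least squares; ``alpha_k`` is the substitution
effect per copy of allele ``k`` and the test is the two-tailed t on
``alpha_k / SE(alpha_k)``.  A binary mode (phenotypes coded -1/+1 with
identity weights, as used for horned/polled) reduces to ordinary least
squares on the coded trait.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .panel import PhasedPanel
from .windows import HaplotypeWindow, call_window_haplotypes, score_genotypes

__all__ = [
    "WeightedPhenotypes",
    "AssocConfig",
    "GLSResult",
    "ScanResult",
    "compute_weights",
    "gls_fit",
    "scan_windows",
    "partial_breeding_values",
    "load_phenotypes",
]


def compute_weights(
    reliabilities: np.ndarray, h2: float, c: float
) -> np.ndarray:
    """Per-record GLS weights ``w_i = ((1 - r2_i)/r2_i + c) * h2/(1 - h2)``.

    ``w_i`` multiplies the residual variance of record ``i``, so records
    with high reliability (small ``d_i``) are weighted up in the fit.
    """
    r2 = np.asarray(reliabilities, dtype=float)
    if not (0 < h2 < 1):
        raise ValueError("heritability must lie in (0, 1)")
    if c < 0:
        raise ValueError("c must be non-negative")
    if np.any(r2 <= 0) or np.any(r2 > 1):
        raise ValueError("reliabilities must lie in (0, 1]")
    d = (1 - r2) / r2
    w = (d + c) * h2 / (1 - h2)
    if np.any(w <= 0):
        raise ValueError("non-positive weight (reliability 1 with c = 0)")
    return w


@dataclasses.dataclass(frozen=True)
class WeightedPhenotypes:
    """dEBV records with reliabilities and derived GLS weights."""

    samples: tuple[str, ...]
    y: np.ndarray
    reliabilities: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        y = np.asarray(self.y, dtype=float)
        r2 = np.asarray(self.reliabilities, dtype=float)
        w = np.asarray(self.weights, dtype=float)
        for name, arr in (("y", y), ("reliabilities", r2), ("weights", w)):
            if arr.size != len(self.samples):
                raise ValueError(f"{name} length != sample count")
        if np.any(w <= 0):
            raise ValueError("weights must be strictly positive")
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "reliabilities", r2)
        object.__setattr__(self, "weights", w)

    @classmethod
    def from_reliabilities(
        cls,
        samples: Sequence[str],
        y: np.ndarray,
        reliabilities: np.ndarray,
        h2: float,
        c: float,
    ) -> "WeightedPhenotypes":
        return cls(
            tuple(samples),
            np.asarray(y, float),
            np.asarray(reliabilities, float),
            compute_weights(reliabilities, h2, c),
        )

    @classmethod
    def binary(cls, samples: Sequence[str], y: np.ndarray) -> "WeightedPhenotypes":
        """Unit-weight phenotypes coded -1/+1 (e.g. horned/polled)."""
        y = np.asarray(y, float)
        if not np.all(np.isin(y, (-1.0, 1.0))):
            raise ValueError("binary phenotypes must be coded -1/+1")
        n = len(samples)
        return cls(tuple(samples), y, np.ones(n), np.ones(n))


@dataclasses.dataclass(frozen=True)
class AssocConfig:
    """Scan settings.

    Parameters
    ----------
    h2 : float
        Trait heritability (0.37 for Nellore birth weight).
    c : float
        Fraction of genetic variance not attributable to the tested
        haplotype (default 0.9191, i.e. the window explains at most 8.09%).
    min_freq : float
        Haplotype alleles below this frequency are skipped, not merged.
    df_offset : int
        Degrees of freedom for the t-test are ``n - df_offset``
        (default 2: intercept + slope).
    bonferroni : bool
        If true, add a Bonferroni-adjusted p column to scan output.
    """

    h2: float = 0.37
    c: float = 0.9191
    min_freq: float = 0.01
    df_offset: int = 2
    bonferroni: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.h2 < 1):
            raise ValueError("h2 must lie in (0, 1)")
        if not (0 <= self.c < 1):
            raise ValueError("c must lie in [0, 1)")


@dataclasses.dataclass(frozen=True)
class GLSResult:
    mu: float
    alpha: float
    se: float
    t: float
    p: float
    df: int
    sigma2_e: float
    zero_residual: bool = False


def gls_fit(
    y: np.ndarray,
    z: np.ndarray,
    weights: np.ndarray | None = None,
    df_offset: int = 2,
) -> GLSResult:
    """Fit ``y = mu + alpha z + e`` with ``e ~ N(0, Diag(w) sigma2_e)``.

    Solves the normal equations ``b = (X' W^-1 X)^-1 X' W^-1 y`` with
    ``X = [1 z]``; the residual variance estimate is the weighted residual
    sum of squares over ``n - df_offset`` and the p-value the two-tailed t
    with the same degrees of freedom.  Scaling all weights by a constant
    leaves every reported statistic unchanged.
    """
    y = np.asarray(y, float)
    z = np.asarray(z, float)
    n = y.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    if z.size != n:
        raise ValueError("y and z length mismatch")
    if np.all(z == z[0]):
        raise ValueError("degenerate design: z is constant")
    w_inv = np.ones(n) if weights is None else 1.0 / np.asarray(weights, float)
    if np.any(~np.isfinite(w_inv)) or np.any(w_inv <= 0):
        raise ValueError("weights must be strictly positive")

    sw = w_inv.sum()
    sz = (w_inv * z).sum()
    szz = (w_inv * z * z).sum()
    sy = (w_inv * y).sum()
    szy = (w_inv * z * y).sum()
    det = sw * szz - sz * sz
    if det <= 0 or not np.isfinite(det):
        raise ValueError("degenerate design: singular normal equations")
    alpha = (sw * szy - sz * sy) / det
    mu = (sy - alpha * sz) / sw

    resid = y - mu - alpha * z
    df = n - df_offset
    sigma2 = float((w_inv * resid * resid).sum() / df)
    var_alpha = sigma2 * sw / det
    zero_resid = sigma2 <= 0 or var_alpha <= 0
    if zero_resid:
        warnings.warn("zero residual variance: p reported as 0", RuntimeWarning)
        se, t, p = 0.0, np.inf if alpha != 0 else 0.0, 0.0
    else:
        se = float(np.sqrt(var_alpha))
        t = float(alpha / se)
        p = float(2 * stats.t.sf(abs(t), df))
    return GLSResult(float(mu), float(alpha), se, t, p, df, sigma2, zero_resid)


@dataclasses.dataclass(frozen=True)
class ScanResult:
    """All per-(window, haplotype) regressions plus the tag selection."""

    table: pd.DataFrame
    tag: pd.Series  # the row flagged is_tag

    @property
    def tag_window(self) -> int:
        return int(self.tag["window_index"])

    @property
    def tag_haplotype(self) -> str:
        return str(self.tag["haplotype"])


def scan_windows(
    panel: PhasedPanel,
    windows: Iterable[tuple[int, int]],
    phenos: WeightedPhenotypes,
    config: AssocConfig | None = None,
) -> ScanResult:
    """Regress phenotypes on every testable haplotype of every window.

    Phenotyped samples must be a subset of panel samples; the panel is
    restricted (and haplotype frequencies recomputed) on that subset so the
    centered codings remain mean-zero.  The tag is the globally most
    significant haplotype; p ties are broken by larger ``|alpha|``, then by
    leftmost window.
    """
    config = config or AssocConfig()
    if set(phenos.samples) - set(panel.samples):
        raise ValueError("phenotype samples are not a subset of panel samples")
    if tuple(phenos.samples) != tuple(panel.samples):
        panel = panel.subset_samples(phenos.samples)

    rows: list[dict] = []
    pos = panel.markers.pos
    for idx, (start, end) in enumerate(windows):
        window = call_window_haplotypes(panel, (start, end), index=idx)
        geno = score_genotypes(panel, window)
        for k in range(window.n_alleles):
            if window.freqs[k] < config.min_freq or window.freqs[k] > 1 - config.min_freq:
                continue
            fit = gls_fit(phenos.y, geno.z[:, k], phenos.weights, config.df_offset)
            rows.append(
                {
                    "window_index": idx,
                    "start_bp": int(pos[start]),
                    "end_bp": int(pos[end - 1]),
                    "haplotype": window.alleles[k],
                    "freq": float(window.freqs[k]),
                    "mu": fit.mu,
                    "alpha": fit.alpha,
                    "se": fit.se,
                    "t": fit.t,
                    "p": fit.p,
                }
            )
    if not rows:
        raise ValueError("no haplotype passed the frequency floor in any window")
    table = pd.DataFrame(rows)
    if config.bonferroni:
        table["p_bonferroni"] = np.minimum(1.0, table["p"] * len(table))
    order = np.lexsort(
        (table["window_index"].to_numpy(), -np.abs(table["alpha"].to_numpy()),
         table["p"].to_numpy())
    )
    tag_pos = order[0]
    table["is_tag"] = False
    table.loc[table.index[tag_pos], "is_tag"] = True
    return ScanResult(table=table, tag=table.iloc[tag_pos])


def partial_breeding_values(z_k: np.ndarray, alpha_k: float) -> np.ndarray:
    """Partial breeding values ``u_k = z_k alpha_k`` (population mean zero)."""
    return np.asarray(z_k, float) * float(alpha_k)


def load_phenotypes(
    path,
    h2: float = 0.37,
    c: float = 0.9191,
    binary: bool = False,
    accuracy: bool = False,
) -> WeightedPhenotypes:
    """Read a phenotype TSV (sample_id, value, reliability).

    In binary mode the value column may hold ``horned``/``polled`` labels,
    mapped to -1/+1, and weights are identity.  With ``accuracy=True`` the
    third column is an accuracy (correlation) and is squared to a
    reliability before weighting.
    """
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if binary:
        vals = df.iloc[:, 1]
        mapping = {"horned": -1.0, "polled": 1.0}
        if vals.dtype == object:
            y = vals.str.lower().map(mapping)
            if y.isna().any():
                bad = vals[y.isna()].iloc[0]
                raise ValueError(f"unknown binary phenotype label {bad!r}")
            y = y.to_numpy()
        else:
            y = vals.to_numpy(dtype=float)
        return WeightedPhenotypes.binary(tuple(df.iloc[:, 0]), y)
    y = df.iloc[:, 1].to_numpy(dtype=float)
    r2 = df.iloc[:, 2].to_numpy(dtype=float)
    if accuracy:
        r2 = r2**2
    return WeightedPhenotypes.from_reliabilities(tuple(df.iloc[:, 0]), y, r2, h2, c)
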