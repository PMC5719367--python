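"""Log-size-index analysis of archaeological bone measurements.

Measurements from heterogeneous skeletal elements are made comparable by
the log-size index: log10 of the specimen measurement over the equivalent
measurement on a single reference skeleton.  Pooled log-ratios from two
occupation periods are compared with a t-test; the mean difference delta on
the log10 scale corresponds to a 10**delta-fold linear size change.
"""

from __future__ import annotations

import dataclasses
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ELEMENTS",
    "MEASUREMENT_CODES",
    "LogRatioDataset",
    "PeriodComparison",
    "load_measurements",
    "load_reference",
    "bundled_reference",
    "log_ratios",
    "compare_periods",
]

ELEMENTS = (
    "humerus",
    "tibia",
    "metatarsal",
    "metacarpal",
    "calcaneus",
    "femur",
    "radius-ulna",
)

# von-den-Driesch-style measurement codes: distal/proximal breadths, trochlea
# breadth, depth across the processus anconaeus, greatest breadth/length,
# smallest diaphysis breadth, smallest olecranon depth.
MEASUREMENT_CODES = ("Bd", "Bp", "BT", "DPA", "GB", "GL", "SD", "SDO")


@dataclasses.dataclass(frozen=True)
class LogRatioDataset:
    """Per-record log10 specimen/reference ratios with period labels."""

    records: pd.DataFrame  # columns: specimen_id, period, log_ratio
    policy: str

    def group(self, period: str) -> np.ndarray:
        return self.records.loc[
            self.records["period"] == period, "log_ratio"
        ].to_numpy()


@dataclasses.dataclass(frozen=True)
class PeriodComparison:
    n_a: int
    n_b: int
    delta: float  # mean(group_b) - mean(group_a), log10 scale
    se: float
    t: float
    df: float
    p: float
    fold: float  # 10 ** delta
    policy: str
    test_variant: str

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _check_table(df: pd.DataFrame, required: tuple[str, ...], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{what} is missing columns {missing}")


def load_measurements(path: str | Path) -> pd.DataFrame:
    """Read a bone-measurement CSV (specimen_id, period, element, code, value_mm)."""
    df = pd.read_csv(path, dtype={"specimen_id": str, "period": str})
    _check_table(df, ("specimen_id", "period", "element", "code", "value_mm"), "measurement table")
    bad_el = set(df["element"]) - set(ELEMENTS)
    if bad_el:
        raise ValueError(f"unknown skeletal element(s): {sorted(bad_el)}")
    bad_code = set(df["code"]) - set(MEASUREMENT_CODES)
    if bad_code:
        raise ValueError(f"unknown measurement code(s): {sorted(bad_code)}")
    if (df["value_mm"] <= 0).any():
        raise ValueError("measurement values must be positive (mm)")
    return df


def load_reference(path: str | Path) -> pd.DataFrame:
    """Read a reference-skeleton CSV (element, code, value_mm)."""
    df = pd.read_csv(path)
    _check_table(df, ("element", "code", "value_mm"), "reference table")
    if (df["value_mm"] <= 0).any():
        raise ValueError("reference values must be positive (mm)")
    if df.duplicated(["element", "code"]).any():
        raise ValueError("duplicate (element, code) entry in reference")
    return df


def bundled_reference() -> pd.DataFrame:
    """The synthetic reference-skeleton fixture shipped with the package.

    Placeholder measurements for a small 19th-century-type cow skeleton;
    values are plausible but synthetic, so only ratios computed against the
    same reference are meaningful.
    """
    with resources.files("sweepdate.data").joinpath(
        "reference_skeleton_synthetic.csv"
    ).open("r") as fh:
        return load_reference(fh)


def log_ratios(
    measurements: pd.DataFrame,
    reference: pd.DataFrame,
    grouping_policy: str = "per-measurement",
) -> LogRatioDataset:
    """log10(specimen / reference) for every measurement record.

    ``grouping_policy="per-measurement"`` keeps one log-ratio per record;
    ``"per-specimen-mean"`` averages a specimen's log-ratios (after the log
    transform) into a single value, so specimens with many measurable
    dimensions do not dominate the period means.
    """
    if grouping_policy not in ("per-measurement", "per-specimen-mean"):
        raise ValueError(f"unknown grouping policy {grouping_policy!r}")
    ref = reference.set_index(["element", "code"])["value_mm"]
    rows = []
    for rec in measurements.itertuples(index=False):
        key = (rec.element, rec.code)
        if key not in ref.index:
            raise KeyError(f"reference has no entry for (element={key[0]!r}, code={key[1]!r})")
        if rec.value_mm <= 0:
            raise ValueError(f"non-positive measurement for specimen {rec.specimen_id!r}")
        rows.append(
            {
                "specimen_id": rec.specimen_id,
                "period": rec.period,
                "log_ratio": np.log10(rec.value_mm / ref.loc[key]),
            }
        )
    out = pd.DataFrame(rows)
    if grouping_policy == "per-specimen-mean":
        out = (
            out.groupby(["specimen_id", "period"], as_index=False)["log_ratio"]
            .mean()
        )
    return LogRatioDataset(records=out, policy=grouping_policy)


def compare_periods(
    dataset: LogRatioDataset,
    group_a: str,
    group_b: str,
    test_variant: str = "welch",
) -> PeriodComparison:
    """Two-sample t-test of mean log-ratios, ``delta = mean(b) - mean(a)``.

    ``group_a`` is the earlier period and ``group_b`` the later one, so a
    positive delta means size increase; ``fold = 10**delta``.  Welch's
    unequal-variance test is the default; ``test_variant="student"`` pools
    variances.
    """
    if test_variant not in ("welch", "student"):
        raise ValueError(f"unknown test variant {test_variant!r}")
    a = dataset.group(group_a)
    b = dataset.group(group_b)
    for label, grp in ((group_a, a), (group_b, b)):
        if grp.size < 2:
            raise ValueError(f"period {label!r} has fewer than 2 records")
    res = stats.ttest_ind(b, a, equal_var=(test_variant == "student"))
    delta = float(b.mean() - a.mean())
    if test_variant == "welch":
        se = float(np.sqrt(a.var(ddof=1) / a.size + b.var(ddof=1) / b.size))
    else:
        sp2 = (
            (a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)
        ) / (a.size + b.size - 2)
        se = float(np.sqrt(sp2 * (1 / a.size + 1 / b.size)))
    return PeriodComparison(
        n_a=int(a.size),
        n_b=int(b.size),
        delta=delta,
        se=se,
        t=float(res.statistic),
        df=float(res.df),
        p=float(res.pvalue),
        fold=float(10.0**delta),
        policy=dataset.policy,
        test_variant=test_variant,
    )
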