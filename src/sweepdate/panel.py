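"""Phased haplotype panels and marker maps.

A :class:`PhasedPanel` stores the two phased chromosomes of every sample as
rows of a 0/1 allele matrix (biallelic markers only), together with a
:class:`MarkerMap` giving bp (and optionally cM) coordinates.  Panels are the
substrate for haplotype windowing, association scans and EHH profiles.

Two on-disk representations are supported:

* phased VCF (``GT`` separated by ``|``), read through :mod:`cyvcf2`;
* a plain tab-separated haplotype table (header row of marker ids; one row
  per chromosome with leading ``sample_id`` and ``hap`` in ``{A, B}``
  columns), optionally paired with a PLINK ``.bim``-style marker map.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MarkerMap",
    "PhasedPanel",
    "PanelFormatError",
    "load_phased_panel",
    "write_panel",
    "read_bim",
]


class PanelFormatError(ValueError):
    """Raised when a panel file violates the phased-biallelic contract."""


@dataclasses.dataclass(frozen=True)
class MarkerMap:
    """Coordinates of the markers of one chromosome.

    Parameters
    ----------
    chrom : str
        Chromosome label.
    ids : sequence of str
        Unique marker identifiers.
    pos : array of int
        1-based physical positions (bp), strictly increasing.
    cm : array of float, optional
        Genetic positions (cM), non-decreasing.  ``None`` when no genetic
        map is available; distances then fall back on a constant
        bp-to-cM conversion downstream.
    """

    chrom: str
    ids: tuple[str, ...]
    pos: np.ndarray
    cm: np.ndarray | None = None

    def __post_init__(self) -> None:
        ids = tuple(str(i) for i in self.ids)
        pos = np.asarray(self.pos, dtype=np.int64)
        object.__setattr__(self, "ids", ids)
        object.__setattr__(self, "pos", pos)
        if len(ids) != pos.size:
            raise ValueError("ids and pos must have equal length")
        if len(set(ids)) != len(ids):
            dup = pd.Series(ids)[pd.Series(ids).duplicated()].iloc[0]
            raise ValueError(f"duplicated marker id {dup!r}")
        if pos.size and np.any(np.diff(pos) <= 0):
            raise ValueError("positions must be strictly increasing")
        if self.cm is not None:
            cm = np.asarray(self.cm, dtype=float)
            object.__setattr__(self, "cm", cm)
            if cm.size != pos.size:
                raise ValueError("cM vector length mismatch")
            if cm.size and np.any(np.diff(cm) < 0):
                raise ValueError("cM positions must be non-decreasing")

    @property
    def n_markers(self) -> int:
        return self.pos.size

    def index_of(self, marker_id: str) -> int:
        try:
            return self.ids.index(marker_id)
        except ValueError:
            raise KeyError(f"marker {marker_id!r} not in map") from None


@dataclasses.dataclass(frozen=True)
class PhasedPanel:
    """Matrix of phased haplotypes: 2 rows per sample, 1 column per marker.

    Alleles are coded 0/1 (biallelic).  Row ``2*i`` holds haplotype A and
    row ``2*i + 1`` haplotype B of sample ``i``.
    """

    samples: tuple[str, ...]
    haplotypes: np.ndarray
    markers: MarkerMap

    def __post_init__(self) -> None:
        samples = tuple(str(s) for s in self.samples)
        hap = np.ascontiguousarray(np.asarray(self.haplotypes, dtype=np.uint8))
        object.__setattr__(self, "samples", samples)
        object.__setattr__(self, "haplotypes", hap)
        if hap.ndim != 2:
            raise ValueError("haplotype matrix must be 2-D")
        if hap.shape[0] != 2 * len(samples):
            raise ValueError(
                f"haplotype rows ({hap.shape[0]}) != 2 x samples ({len(samples)})"
            )
        if hap.shape[1] != self.markers.n_markers:
            raise ValueError("haplotype columns != marker count")
        if hap.size and hap.max(initial=0) > 1:
            raise ValueError("alleles must be coded 0/1")
        if len(set(samples)) != len(samples):
            raise ValueError("duplicated sample id")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_chromosomes(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_markers(self) -> int:
        return self.haplotypes.shape[1]

    def subset_samples(self, keep: Sequence[str]) -> "PhasedPanel":
        """Return a panel restricted to ``keep`` (in the given order)."""
        index = {s: i for i, s in enumerate(self.samples)}
        missing = [s for s in keep if s not in index]
        if missing:
            raise KeyError(f"samples not in panel: {missing[:5]}")
        rows = np.concatenate([[2 * index[s], 2 * index[s] + 1] for s in keep])
        return PhasedPanel(tuple(keep), self.haplotypes[rows], self.markers)


def read_bim(path: str | Path) -> MarkerMap:
    """Read a PLINK ``.bim``-style map (chrom, id, cM, bp, a1, a2).

    A cM column that is identically zero is treated as absent.
    """
    df = pd.read_csv(
        path,
        sep=r"\s+",
        header=None,
        names=["chrom", "id", "cm", "bp", "a1", "a2"],
        dtype={"chrom": str, "id": str},
    )
    chroms = df["chrom"].unique()
    if len(chroms) != 1:
        raise PanelFormatError(
            f"marker map spans {len(chroms)} chromosomes; exactly one expected"
        )
    cm = df["cm"].to_numpy(dtype=float)
    return MarkerMap(
        chrom=str(chroms[0]),
        ids=tuple(df["id"]),
        pos=df["bp"].to_numpy(dtype=np.int64),
        cm=None if np.all(cm == 0) else cm,
    )


def _load_vcf(path: str | Path) -> PhasedPanel:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = tuple(vcf.samples)
    if not samples:
        raise PanelFormatError("VCF has no samples")
    ids: list[str] = []
    pos: list[int] = []
    chrom: str | None = None
    columns: list[np.ndarray] = []
    n = len(samples)
    for v in vcf:
        if chrom is None:
            chrom = v.CHROM
        elif v.CHROM != chrom:
            raise PanelFormatError(
                f"panel spans chromosomes {chrom!r} and {v.CHROM!r}; one expected"
            )
        if len(v.ALT) != 1:
            raise PanelFormatError(
                f"non-biallelic record at {v.CHROM}:{v.POS} ({v.ID or '.'})"
            )
        col = np.empty(2 * n, dtype=np.int16)
        for i, (a, b, phased) in enumerate(v.genotypes):
            if not phased:
                raise PanelFormatError(
                    f"unphased genotype at {v.CHROM}:{v.POS} ({v.ID or '.'}) "
                    f"for sample {samples[i]!r}"
                )
            if a < 0 or b < 0:
                raise PanelFormatError(
                    f"missing genotype at {v.CHROM}:{v.POS} ({v.ID or '.'}) "
                    f"for sample {samples[i]!r}"
                )
            col[2 * i] = a
            col[2 * i + 1] = b
        ids.append(v.ID if v.ID not in (None, ".") else f"{v.CHROM}:{v.POS}")
        pos.append(v.POS)
        columns.append(col)
    if not columns:
        raise PanelFormatError("VCF contains no variant records")
    hap = np.stack(columns, axis=1)
    order = np.argsort(np.asarray(pos), kind="stable")
    hap = hap[:, order]
    markers = MarkerMap(
        chrom=str(chrom),
        ids=tuple(np.asarray(ids, dtype=object)[order]),
        pos=np.asarray(pos, dtype=np.int64)[order],
    )
    try:
        return PhasedPanel(samples, hap.astype(np.uint8), markers)
    except ValueError as exc:  # e.g. allele codes outside 0/1
        raise PanelFormatError(str(exc)) from exc


def _load_table(path: str | Path, marker_map: MarkerMap | str | Path | None) -> PhasedPanel:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 3 or list(df.columns[:2]) != ["sample_id", "hap"]:
        raise PanelFormatError(
            "haplotype table must start with columns 'sample_id', 'hap'"
        )
    marker_ids = list(df.columns[2:])
    if isinstance(marker_map, (str, Path)):
        marker_map = read_bim(marker_map)
    if marker_map is None:
        # No physical map supplied: synthesise unit-spaced positions so the
        # panel is still usable for windowing (not for bp-based dating).
        marker_map = MarkerMap(
            chrom="0", ids=tuple(marker_ids),
            pos=np.arange(1, len(marker_ids) + 1, dtype=np.int64),
        )
    if list(marker_map.ids) != marker_ids:
        raise PanelFormatError("table marker ids do not match marker map")
    samples: list[str] = []
    rows: list[np.ndarray] = []
    alleles = df.iloc[:, 2:].to_numpy()
    for i in range(0, len(df), 2):
        pair = df.iloc[i : i + 2]
        if len(pair) != 2 or pair.iloc[0, 0] != pair.iloc[1, 0]:
            raise PanelFormatError(
                f"sample {df.iloc[i, 0]!r} lacks a consecutive A/B haplotype pair"
            )
        if list(pair.iloc[:, 1]) != ["A", "B"]:
            raise PanelFormatError(
                f"sample {pair.iloc[0, 0]!r}: hap column must be 'A' then 'B'"
            )
        samples.append(pair.iloc[0, 0])
        for j in (i, i + 1):
            row = alleles[j]
            bad = ~np.isin(row, ["0", "1"])
            if bad.any():
                k = int(np.flatnonzero(bad)[0])
                raise PanelFormatError(
                    f"invalid allele {row[k]!r} at marker {marker_ids[k]!r} "
                    f"for sample {df.iloc[j, 0]!r}"
                )
            rows.append(row.astype(np.uint8))
    return PhasedPanel(tuple(samples), np.stack(rows), marker_map)


def load_phased_panel(
    path: str | Path,
    format: str = "vcf",
    marker_map: MarkerMap | str | Path | None = None,
    min_maf: float = 0.0,
) -> PhasedPanel:
    """Load a phased diploid panel from disk.

    Parameters
    ----------
    path : path
        Input file.
    format : {"vcf", "table"}
        ``"vcf"`` expects a phased VCF (``GT`` with ``|``); ``"table"`` the
        tab-separated haplotype table described in the module docstring.
    marker_map : MarkerMap or path, optional
        Marker coordinates for table input (PLINK ``.bim`` path accepted).
        Ignored for VCF input, whose records carry their own coordinates.
    min_maf : float
        Optional minor-allele-frequency floor; columns below it are dropped.
        Default 0 (keep everything).

    Raises
    ------
    PanelFormatError
        On unphased or missing genotypes, multi-allelic records, duplicate
        marker ids, or malformed tables; the message names the offending
        marker and sample where applicable.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "vcf":
        panel = _load_vcf(path)
    elif format == "table":
        panel = _load_table(path, marker_map)
    else:
        raise ValueError(f"unknown panel format {format!r}")
    if min_maf > 0:
        freq = panel.haplotypes.mean(axis=0)
        maf = np.minimum(freq, 1 - freq)
        keep = maf >= min_maf
        m = panel.markers
        panel = PhasedPanel(
            panel.samples,
            panel.haplotypes[:, keep],
            MarkerMap(
                m.chrom,
                tuple(np.asarray(m.ids, dtype=object)[keep]),
                m.pos[keep],
                None if m.cm is None else m.cm[keep],
            ),
        )
    return panel


def write_panel(panel: PhasedPanel, path: str | Path, format: str = "table") -> None:
    """Write a panel as a haplotype table or a minimal phased VCF."""
    path = Path(path)
    if format == "table":
        with open(path, "w") as fh:
            fh.write("sample_id\thap\t" + "\t".join(panel.markers.ids) + "\n")
            for i, s in enumerate(panel.samples):
                for j, hap in enumerate("AB"):
                    row = panel.haplotypes[2 * i + j]
                    fh.write(f"{s}\t{hap}\t" + "\t".join(map(str, row)) + "\n")
    elif format == "vcf":
        m = panel.markers
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write(f"##contig=<ID={m.chrom}>\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            fh.write(
                "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                + "\t".join(panel.samples)
                + "\n"
            )
            for k in range(m.n_markers):
                col = panel.haplotypes[:, k]
                gts = "\t".join(
                    f"{col[2 * i]}|{col[2 * i + 1]}" for i in range(panel.n_samples)
                )
                fh.write(
                    f"{m.chrom}\t{m.pos[k]}\t{m.ids[k]}\tA\tG\t.\tPASS\t.\tGT\t{gts}\n"
                )
    else:
        raise ValueError(f"unknown panel format {format!r}")


def write_bim(markers: MarkerMap, path: str | Path) -> None:
    """Write a marker map in PLINK ``.bim`` layout (cM written as 0 if absent)."""
    cm = markers.cm if markers.cm is not None else np.zeros(markers.n_markers)
    with open(path, "w") as fh:
        for i in range(markers.n_markers):
            fh.write(
                f"{markers.chrom}\t{markers.ids[i]}\t{cm[i]:g}\t{markers.pos[i]}\tA\tG\n"
            )
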