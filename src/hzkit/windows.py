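"""Genomic windows with barrier labels, in BED convention (0-based half-open).

Windows may overlap (the default tiling uses a 20% overlap); marker positions
are 1-based, so marker ``pos`` falls in window ``[start, end)`` iff
``start <= pos - 1 < end``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

REQUIRED_COLUMNS = ["chrom", "start", "end", "name", "barrier"]


@dataclass
class WindowSet:
    """Sorted, possibly overlapping genomic windows with a barrier flag.

    ``table`` has columns ``chrom, start, end, name, barrier`` plus optional
    metric columns.  Windows are sorted by (chromosome, start) in the order
    chromosomes first appear.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        missing = [c for c in REQUIRED_COLUMNS if c not in t.columns]
        if missing:
            raise ValueError(f"window table missing columns {missing}")
        t = t.copy()
        t["start"] = t["start"].astype(np.int64)
        t["end"] = t["end"].astype(np.int64)
        t["barrier"] = t["barrier"].astype(bool)
        if (t["start"] >= t["end"]).any():
            bad = t[t["start"] >= t["end"]].iloc[0]
            raise ValueError(f"window with start >= end: {bad['chrom']}:{bad['start']}")
        for _, grp in t.groupby("chrom", sort=False):
            if not grp["start"].is_monotonic_increasing:
                raise ValueError("windows not sorted by start within chromosome")
        self.table = t.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def chrom(self) -> np.ndarray:
        return self.table["chrom"].to_numpy()

    @property
    def start(self) -> np.ndarray:
        return self.table["start"].to_numpy()

    @property
    def end(self) -> np.ndarray:
        return self.table["end"].to_numpy()

    @property
    def span(self) -> np.ndarray:
        return self.end - self.start

    @property
    def barrier(self) -> np.ndarray:
        return self.table["barrier"].to_numpy()

    def with_metrics(self, metrics: pd.DataFrame) -> "WindowSet":
        """Attach per-window metric columns (aligned by position)."""
        if len(metrics) != len(self):
            raise ValueError("metrics not aligned to windows")
        t = self.table.drop(columns=metrics.columns, errors="ignore")
        return WindowSet(pd.concat([t, metrics.reset_index(drop=True)], axis=1))


def make_windows(
    chromosomes: list[tuple[str, int]],
    span: int,
    overlap: float = 0.2,
    barrier: np.ndarray | None = None,
) -> WindowSet:
    """Tile chromosomes with fixed-span windows at the given overlap fraction.

    Step is ``span * (1 - overlap)``; the last, partial window is kept only if
    it covers at least half a span.  A chromosome shorter than one span yields
    a single full-chromosome window.
    """
    if span <= 0:
        raise ValueError("span must be positive")
    if not 0 <= overlap < 1:
        raise ValueError("overlap must be in [0, 1)")
    step = max(1, int(round(span * (1.0 - overlap))))
    rows = []
    for chrom, length in chromosomes:
        if span >= length:
            rows.append((chrom, 0, length))
            continue
        start = 0
        while start < length:
            end = min(start + span, length)
            if end - start >= span / 2:
                rows.append((chrom, start, end))
            if end == length:
                break
            start += step
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    df["name"] = [f"{c}:{s}-{e}" for c, s, e in zip(df.chrom, df.start, df.end)]
    df["barrier"] = False if barrier is None else np.asarray(barrier, dtype=bool)
    return WindowSet(df)


def sites_in_window(
    chrom: np.ndarray, pos: np.ndarray, w_chrom: str, w_start: int, w_end: int
) -> np.ndarray:
    """Indices of markers (1-based positions) inside a 0-based half-open window."""
    return np.nonzero((chrom == w_chrom) & (pos - 1 >= w_start) & (pos - 1 < w_end))[0]


def read_windows(path) -> WindowSet:
    """Read a BED4+ window file: chrom, start, end, name, barrier, metrics..."""
    df = pd.read_csv(path, sep="\t", header=None)
    ncol = df.shape[1]
    names = REQUIRED_COLUMNS[: min(ncol, 5)]
    names += [f"metric_{i}" for i in range(ncol - len(names))]
    df.columns = names
    if "barrier" not in df.columns:
        df["barrier"] = False
    return WindowSet(df)


def write_windows(ws: WindowSet, path, metrics: list[str] | None = None) -> None:
    cols = REQUIRED_COLUMNS + [c for c in (metrics or []) if c in ws.table.columns]
    out = ws.table[cols].copy()
    out["barrier"] = out["barrier"].astype(int)
    out.to_csv(path, sep="\t", header=False, index=False)
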