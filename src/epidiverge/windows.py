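"""Shared fixed-width window grid.

The DMR-density, Fst, Tajima's D and diversity computations all join on the
same non-overlapping tiling of the genome, so the grid lives in one place.
"""
from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd


def tile_genome(genome_spec: Mapping[str, int], window_bp: int = 1_000_000,
                step_bp: int | None = None) -> pd.DataFrame:
    """Tile each chromosome into windows of ``window_bp``.

    The final partial window is kept.  ``step_bp`` defaults to the window
    width (non-overlapping tiles); a smaller step yields sliding windows.

    Returns a DataFrame with columns chrom, start, end (0-based half-open).
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    step = window_bp if step_bp is None else step_bp
    if step <= 0:
        raise ValueError("step_bp must be positive")
    rows = []
    for chrom, length in genome_spec.items():
        if length <= 0:
            raise ValueError(f"chromosome {chrom!r} has non-positive length")
        starts = np.arange(0, length, step)
        ends = np.minimum(starts + window_bp, length)
        for s, e in zip(starts, ends):
            rows.append((chrom, int(s), int(e)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def assign_to_windows(chrom: np.ndarray, pos: np.ndarray,
                      windows: pd.DataFrame) -> np.ndarray:
    """Index of the tiling window containing each position (by its start).

    Assumes ``windows`` came from :func:`tile_genome` with the default step
    (non-overlapping).  Returns -1 for positions on chromosomes absent from
    the grid or beyond the chromosome end.
    """
    out = np.full(len(pos), -1, dtype=np.int64)
    for c, sub in windows.groupby("chrom", sort=False):
        m = chrom == c
        if not m.any():
            continue
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        idx = np.searchsorted(starts, pos[m], side="right") - 1
        ok = (idx >= 0) & (pos[m] < ends[np.clip(idx, 0, len(ends) - 1)])
        res = np.where(ok, sub.index.to_numpy()[np.clip(idx, 0, len(ends) - 1)], -1)
        out[m] = res
    return out
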