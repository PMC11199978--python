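"""Internal vectorised interval-query helpers over fragment columns."""
from __future__ import annotations

import numpy as np
import pandas as pd

from .types import FragmentFrame


class ChromFragmentIndex:
    """Fragments grouped by chromosome and sorted by start, for range queries.

    ``query(chrom, win_start, win_end)`` returns indices (into the per-chrom
    sorted arrays) of fragments overlapping [win_start, win_end) by >= 1 bp.
    """

    def __init__(self, frame: FragmentFrame, cell_codes: np.ndarray):
        self.by_chrom: dict[str, dict[str, np.ndarray]] = {}
        chroms = pd.Series(frame.chrom)
        for chrom in chroms.unique():
            sel = (chroms == chrom).to_numpy()
            starts = frame.start[sel]
            ends = frame.end[sel]
            order = np.argsort(starts, kind="stable")
            self.by_chrom[str(chrom)] = {
                "start": starts[order],
                "end": ends[order],
                "code": cell_codes[sel][order],
                "count": frame.count[sel][order],
                "max_len": int((ends - starts).max()) if sel.any() else 0,
            }

    def query(self, chrom: str, win_start: int, win_end: int):
        """Return (start, end, code, count) arrays of overlapping fragments."""
        d = self.by_chrom.get(chrom)
        if d is None or len(d["start"]) == 0:
            z = np.empty(0, dtype=np.int64)
            return z, z, z, z
        lo = np.searchsorted(d["start"], win_start - d["max_len"], side="left")
        hi = np.searchsorted(d["start"], win_end, side="left")
        s = d["start"][lo:hi]
        e = d["end"][lo:hi]
        keep = e > win_start  # s < win_end guaranteed by hi
        return s[keep], e[keep], d["code"][lo:hi][keep], d["count"][lo:hi][keep]


def overlap_bp(starts, ends, win_start, win_end):
    """Per-fragment overlap in bp with [win_start, win_end), clipped at 0."""
    return np.maximum(0, np.minimum(ends, win_end) - np.maximum(starts, win_start))
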