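"""Localize word occurrences relative to CDS annotation.

An occurrence is "coding" only when the whole word lies inside a single CDS
interval — a reading frame is only well defined for fully contained words.
Occurrences inside overlapping genes are assigned once, to the first
containing CDS in annotation order, so totals are conserved. Frames are
numbered 1/2/3 from the offset (mod 3) of the word's 5' end relative to the
translation start, in coding orientation; frame 1 is in frame.
"""

from __future__ import annotations

import math
from bisect import bisect_right
from dataclasses import dataclass
from typing import NamedTuple

from scipy import stats

from .genome_io import CdsInterval


@dataclass
class CodingLocalization:
    oligomer: str
    chromosome_id: str
    n_total: int
    n_coding: int
    pct_coding: float
    frame_counts: tuple[int, int, int]


def frame_of(occurrence_start: int, cds: CdsInterval, word_length: int) -> int:
    """Reading frame (1-3) of a word fully contained in a CDS.

    On the '-' strand the word's 5' end in coding orientation is its last
    base, so the offset is measured from cds.end.
    """
    if not (cds.start <= occurrence_start and occurrence_start + word_length <= cds.end):
        raise ValueError("occurrence not contained in CDS")
    if cds.strand == "+":
        return (occurrence_start - cds.start) % 3 + 1
    return (cds.end - (occurrence_start + word_length)) % 3 + 1


class _CdsIndex:
    """First-containing-CDS lookup preserving annotation order."""

    def __init__(self, cds_list: list[CdsInterval]):
        self.cds_list = cds_list
        order = sorted(range(len(cds_list)), key=lambda i: cds_list[i].start)
        self._starts = [cds_list[i].start for i in order]
        self._order = order
        self._max_len = max((c.length for c in cds_list), default=0)

    def first_containing(self, start: int, length: int) -> CdsInterval | None:
        end = start + length
        hi = bisect_right(self._starts, start)
        best_idx = None
        i = hi - 1
        while i >= 0 and self._starts[i] > start - self._max_len:
            ann_idx = self._order[i]
            cds = self.cds_list[ann_idx]
            if cds.start <= start and end <= cds.end:
                if best_idx is None or ann_idx < best_idx:
                    best_idx = ann_idx
            i -= 1
        return None if best_idx is None else self.cds_list[best_idx]


def locate_in_coding(
    positions: list[int],
    word_length: int,
    cds_list: list[CdsInterval],
    oligomer: str = "",
    chromosome_id: str = "",
) -> CodingLocalization:
    """Classify occurrences as coding/non-coding and tally reading frames."""
    index = _CdsIndex(cds_list) if cds_list else None
    frames = [0, 0, 0]
    n_coding = 0
    for pos in positions:
        cds = index.first_containing(pos, word_length) if index else None
        if cds is not None:
            n_coding += 1
            frames[frame_of(pos, cds, word_length) - 1] += 1
    n_total = len(positions)
    pct = 100.0 * n_coding / n_total if n_total else 0.0
    return CodingLocalization(
        oligomer=oligomer,
        chromosome_id=chromosome_id,
        n_total=n_total,
        n_coding=n_coding,
        pct_coding=pct,
        frame_counts=(frames[0], frames[1], frames[2]),
    )


class FrameBiasResult(NamedTuple):
    statistic: float
    pvalue: float
    defined: bool


def frame_bias_test(frame_counts: tuple[int, int, int]) -> FrameBiasResult:
    """Pearson chi-squared of the frame counts against uniform (2 df).

    Undefined (NaN, flagged) when no coding occurrence exists.
    """
    n = sum(frame_counts)
    if n == 0:
        return FrameBiasResult(math.nan, math.nan, False)
    stat, pvalue = stats.chisquare(list(frame_counts))
    return FrameBiasResult(float(stat), float(pvalue), True)
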