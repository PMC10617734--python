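"""Record trimming and cohort inclusion criteria.

Animals that become inactive generate long trailing runs of zero counts;
records are trimmed to retain at most 12 h of trailing zeros.  Leading
all-zero bins (animals that had not yet started moving) are removed
entirely, advancing the record's circadian-time anchor.  Inclusion then
requires at least five tidal cycles of data, at least 400 beam
interruptions, and no more than five consecutive all-zero half-days.
"""
from __future__ import annotations

from typing import Tuple

import numpy as np

from .types import ActivityRecord, InclusionDecision, TrimReport

TOO_FEW_CYCLES = "too_few_cycles"
TOO_FEW_EVENTS = "too_few_events"
ZERO_RUN_TOO_LONG = "zero_run_too_long"


def trim_record(
    record: ActivityRecord, trailing_zero_keep_h: float = 12.0
) -> Tuple[ActivityRecord, TrimReport]:
    """Strip leading zeros and truncate long trailing zero runs.

    Trailing zeros are only truncated when the terminal run exceeds
    ``trailing_zero_keep_h``; exactly that much of the run is retained
    (24 bins at the standard 0.5-h width).  An all-zero record cannot be
    trimmed and is returned unchanged with ``untrimmable`` set.
    """
    counts = record.counts
    nz = np.flatnonzero(counts)
    if nz.size == 0:
        report = TrimReport(record.animal_id, 0, 0, record.n_bins, untrimmable=True)
        return record, report

    keep_bins = int(round(trailing_zero_keep_h / record.bin_width_h))
    first, last = int(nz[0]), int(nz[-1])
    trailing_run = record.n_bins - 1 - last
    end = record.n_bins if trailing_run <= keep_bins else last + 1 + keep_bins

    trimmed = record.replace_counts(
        counts[first:end], start_ct=record.start_ct + first * record.bin_width_h
    )
    report = TrimReport(
        animal_id=record.animal_id,
        leading_bins_removed=first,
        trailing_bins_removed=record.n_bins - end,
        final_length_bins=end - first,
    )
    return trimmed, report


def _halfday_segments(record: ActivityRecord, anchor_ct: float = 0.0):
    """Yield (start_idx, end_idx, segment_ct_start) for CT-aligned 12-h windows.

    Segments are anchored at ``anchor_ct + 12k``; partial edge segments are
    included (the zero-run rule looks at whatever part of a half-day the
    record covers).
    """
    ct0 = record.ct[0]
    ct_end = ct0 + record.duration_h
    # first segment boundary at or before ct0
    k0 = np.floor((ct0 - anchor_ct) / 12.0)
    seg_start = anchor_ct + 12.0 * k0
    out = []
    s = seg_start
    while s < ct_end - 1e-9:
        i0 = max(0, int(np.ceil((s - ct0) / record.bin_width_h - 1e-9)))
        i1 = min(record.n_bins, int(np.ceil((s + 12.0 - ct0) / record.bin_width_h - 1e-9)))
        if i1 > i0:
            out.append((i0, i1, s))
        s += 12.0
    return out


def longest_zero_halfday_run(record: ActivityRecord, anchor_ct: float = 0.0) -> int:
    """Longest run of consecutive all-zero 12-h half-day segments."""
    longest = run = 0
    for i0, i1, _ in _halfday_segments(record, anchor_ct):
        if record.counts[i0:i1].sum() == 0:
            run += 1
            longest = max(longest, run)
        else:
            run = 0
    return longest


def passes_inclusion(
    record: ActivityRecord,
    tidal_period_h: float = 12.4,
    min_cycles: int = 5,
    min_events: int = 400,
    max_zero_halfdays: int = 5,
    anchor_ct: float = 0.0,
) -> InclusionDecision:
    """Apply the cohort inclusion criteria to a trimmed record.

    Included iff duration ≥ ``min_cycles`` tidal cycles, total counts ≥
    ``min_events``, and no more than ``max_zero_halfdays`` consecutive
    all-zero half-days.  Always returns a decision listing every failed
    criterion.
    """
    reasons = []
    if record.duration_h < min_cycles * tidal_period_h:
        reasons.append(TOO_FEW_CYCLES)
    if int(record.counts.sum()) < min_events:
        reasons.append(TOO_FEW_EVENTS)
    if longest_zero_halfday_run(record, anchor_ct) > max_zero_halfdays:
        reasons.append(ZERO_RUN_TOO_LONG)
    return InclusionDecision(record.animal_id, included=not reasons, reasons=reasons)
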