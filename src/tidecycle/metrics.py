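"""Per-animal behavioural phenotypes.

The record is cut into consecutive 12-h subjective-day / subjective-night
segments on circadian-time boundaries (day = CT 0-12, night = CT 12-24,
from the pre-recording LD 12:12 entrainment).  The peak count of each
segment, on a log10 scale, is the circatidal amplitude for that half-day
(the trough is almost always zero, so the peak alone carries the
amplitude; an all-zero segment is substituted with 1 so its log10 is 0).
The modulation index MI is the mean over successive (night, following
day) pairs of the difference in peak log10 activity, and measures the
circadian modulation of circatidal swimming.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .types import ActivityRecord, RhythmCall

SUBJECTIVE_DAY = "subjective_day"
SUBJECTIVE_NIGHT = "subjective_night"


@dataclass
class Segment:
    index: int
    phase: str  # subjective_day | subjective_night
    peak_count: int
    min_count: int
    log10_peak: float
    log10_adjusted: float


@dataclass
class SegmentAmplitudes:
    animal_id: str
    segments: List[Segment] = field(default_factory=list)


def segment_amplitudes(
    record: ActivityRecord,
    day_night_anchor_ct: float = 0.0,
    max_segments: Optional[int] = 16,
) -> SegmentAmplitudes:
    """Peak/trough amplitudes of CT-aligned full 12-h segments.

    Only segments fully covered by the record are scored; partial edge
    half-days are dropped.  ``max_segments`` caps the output (16 = 8 days).
    """
    bins_per_seg = int(round(12.0 / record.bin_width_h))
    ct0 = record.ct[0]
    # first full segment boundary at or after the record start
    k0 = int(np.ceil((ct0 - day_night_anchor_ct) / 12.0 - 1e-9))
    segs: List[Segment] = []
    idx = 0
    while True:
        seg_ct = day_night_anchor_ct + 12.0 * (k0 + idx)
        i0 = int(round((seg_ct - ct0) / record.bin_width_h))
        i1 = i0 + bins_per_seg
        if i1 > record.n_bins:
            break
        window = record.counts[i0:i1]
        phase = SUBJECTIVE_DAY if (seg_ct - day_night_anchor_ct) % 24.0 < 12.0 else SUBJECTIVE_NIGHT
        peak = int(window.max())
        mn = int(window.min())
        segs.append(
            Segment(
                index=idx,
                phase=phase,
                peak_count=peak,
                min_count=mn,
                log10_peak=float(np.log10(max(peak, 1))),
                log10_adjusted=float(np.log10(max(peak - mn, 1))),
            )
        )
        idx += 1
        if max_segments is not None and len(segs) >= max_segments:
            break
    return SegmentAmplitudes(animal_id=record.animal_id, segments=segs)


def modulation_index(
    segs: SegmentAmplitudes, adjusted: bool = False
) -> Optional[float]:
    """Mean of (night peak log10 − following day peak log10) pairs.

    Returns None when no complete night→day pair exists (the row is
    flagged downstream).
    """
    attr = "log10_adjusted" if adjusted else "log10_peak"
    diffs = []
    s = segs.segments
    for a, b in zip(s[:-1], s[1:]):
        if a.phase == SUBJECTIVE_NIGHT and b.phase == SUBJECTIVE_DAY:
            diffs.append(getattr(a, attr) - getattr(b, attr))
    if not diffs:
        return None
    return float(np.mean(diffs))


def _phase_mean(segs: SegmentAmplitudes, phase: Optional[str], adjusted: bool) -> Optional[float]:
    attr = "log10_adjusted" if adjusted else "log10_peak"
    vals = [getattr(s, attr) for s in segs.segments if phase is None or s.phase == phase]
    return float(np.mean(vals)) if vals else None


def phenotype_row(
    record: ActivityRecord,
    call: Optional[RhythmCall] = None,
    day_night_anchor_ct: float = 0.0,
    adjusted: bool = False,
) -> dict:
    """Assemble one PhenotypeRow for the cohort statistics layer."""
    segs = segment_amplitudes(record, day_night_anchor_ct)
    return dict(
        animal_id=record.animal_id,
        knockdown=record.knockdown,
        collection=record.collection_id,
        MI=modulation_index(segs, adjusted=adjusted),
        amp_overall=_phase_mean(segs, None, adjusted),
        amp_night=_phase_mean(segs, SUBJECTIVE_NIGHT, adjusted),
        amp_day=_phase_mean(segs, SUBJECTIVE_DAY, adjusted),
        n_segments=len(segs.segments),
        period_h=call.period_h if call else None,
        power=call.power if call else None,
        rhythmic=call.rhythmic if call else None,
    )


def phenotype_table(
    records: Sequence[ActivityRecord],
    calls: Optional[Sequence[RhythmCall]] = None,
    day_night_anchor_ct: float = 0.0,
) -> pd.DataFrame:
    calls = calls if calls is not None else [None] * len(records)
    return pd.DataFrame(
        [phenotype_row(r, c, day_night_anchor_ct) for r, c in zip(records, calls)]
    )


def align_to_tide(
    records: Sequence[ActivityRecord],
    tide_tables: dict,
    tidal_period_h: float = 12.4,
) -> pd.DataFrame:
    """Pool records synchronised to local tidal time.

    Each record is shifted so that bin 0 falls at the first high tide at
    or after its recording start (``tide_tables`` maps collection id to
    high-tide times on the CT axis, as in
    :class:`tidecycle.io_monitor.CohortMetadata`).  Returns the
    across-animal mean count per 30-min bin with the number of animals
    contributing to each bin and the elapsed time since the reference
    tide.
    """
    if not records:
        raise ValueError("no records to pool")
    shifted = []
    for rec in records:
        if rec.collection_id not in tide_tables:
            raise KeyError(f"no tide table for collection {rec.collection_id!r}")
        tides = np.asarray(tide_tables[rec.collection_id], dtype=float)
        after = tides[tides >= rec.ct[0] - 1e-9]
        if after.size == 0:
            raise KeyError(
                f"tide table for {rec.collection_id!r} ends before recording start"
            )
        ref = after[0]
        k = int(round((ref - rec.ct[0]) / rec.bin_width_h))
        shifted.append(rec.counts[k:])
    n_max = max(s.size for s in shifted)
    acc = np.zeros(n_max)
    n = np.zeros(n_max, dtype=int)
    for s in shifted:
        acc[: s.size] += s
        n[: s.size] += 1
    bw = records[0].bin_width_h
    return pd.DataFrame(
        dict(
            bin=np.arange(n_max),
            time_since_tide_h=np.arange(n_max) * bw,
            mean_count=np.where(n > 0, acc / np.maximum(n, 1), np.nan),
            n_animals=n,
        )
    )
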