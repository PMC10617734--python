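"""Synthetic cohorts with the statistical structure the pipeline assumes.

Each simulated animal is an inhomogeneous Poisson counting process whose
per-bin rate combines a half-wave-rectified circatidal (~12.4 h)
oscillation, a weaker circalunidian (~24.8 h, locked to exactly twice
the tidal period) component, circadian night>day modulation (night rate
multiplied by 1+M on CT 12-24), a flat baseline, and an exponential
activity-cessation ("dropout") time after which the record is all
zeros — the feature that exercises the trailing-zero trimming rule.  A
configurable fraction of animals is arrhythmic: their oscillatory rate
is replaced by its time average (flat Poisson at matched mean).  Phases
are tied to a synthetic tide table so tidal-time pooling is testable
end to end.  Ground-truth labels (true period, amplitude, M, rhythmic
flag, dropout time) accompany every cohort.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .types import ActivityRecord


@dataclass(frozen=True)
class GroupEffect:
    """Multiplicative knockdown effects relative to the cohort baseline."""

    amplitude_mult: float = 1.0
    M_mult: float = 1.0
    arrhythmic_fraction_mult: float = 1.0
    period_shift_h: float = 0.0


@dataclass(frozen=True)
class SimConfig:
    """Cohort generator settings.

    Rates are expected events per 30-min bin.  Defaults emulate a
    summer control cohort: peak tidal rate ~60 events/bin (log10
    amplitude ~1.8-2.0), night component 2.5× the day component
    (M = 1.5), ~10% arrhythmic animals, 8-day recordings started at
    CT 96 with mean dropout at 150 h.
    """

    n_animals: int = 30
    tidal_period_h: float = 12.4
    tidal_amplitude: float = 60.0
    lunidian_weight: float = 0.2
    baseline_rate: float = 0.2
    modulation_M: float = 1.5
    waveform_sharpness: float = 2.0
    arrhythmic_fraction: float = 0.10
    dropout_mean_h: float = 150.0
    duration_days: float = 8.0
    bin_width_h: float = 0.5
    start_ct: float = 96.0
    phase_jitter_h: float = 1.0
    knockdown: str = "control"
    collection_id: str = "c0"
    lighting: str = "DD"
    first_high_tide_ct: float = 98.0
    rng_seed: int = 0
    group_effects: Dict[str, GroupEffect] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.duration_days <= 0 or self.bin_width_h <= 0:
            raise ValueError("duration and bin width must be positive")
        if min(self.tidal_amplitude, self.baseline_rate, self.modulation_M) < 0:
            raise ValueError("rates and modulation must be non-negative")
        if not 0 <= self.arrhythmic_fraction <= 1 or not 0 <= self.lunidian_weight <= 1:
            raise ValueError("fractions must lie in [0, 1]")
        if self.tidal_period_h <= 0:
            raise ValueError("periods must be positive")


def tide_table(config: SimConfig, margin_h: float = 26.0) -> Dict[str, np.ndarray]:
    """High-tide CT times for the simulated collection (12.4 h spacing)."""
    end = config.start_ct + config.duration_days * 24.0 + margin_h
    tides = np.arange(config.first_high_tide_ct, end, config.tidal_period_h)
    return {config.collection_id: tides}


def _rate(
    ct: np.ndarray,
    cfg: SimConfig,
    amplitude: float,
    M: float,
    tau_tide: float,
    phase_jitter_h: float,
) -> np.ndarray:
    """Per-bin expected counts λ(t) for one rhythmic animal."""
    tau_lun = 2.0 * tau_tide
    t0 = cfg.first_high_tide_ct + phase_jitter_h  # rate peaks at (jittered) high tide
    h = lambda tau: np.maximum(np.cos(2 * np.pi * (ct - t0) / tau), 0.0) ** cfg.waveform_sharpness
    osc = (1.0 - cfg.lunidian_weight) * h(tau_tide) + cfg.lunidian_weight * h(tau_lun)
    night = ((ct % 24.0) >= 12.0).astype(float)
    return cfg.baseline_rate + amplitude * osc * (1.0 + M * night)


def simulate_cohort(config: SimConfig) -> Tuple[List[ActivityRecord], pd.DataFrame]:
    """Generate one or more knockdown groups with ground-truth labels.

    When ``config.group_effects`` is empty a single group labelled
    ``config.knockdown`` is produced; otherwise one group of
    ``n_animals`` per entry, with each group's amplitude, modulation,
    arrhythmic fraction and tidal period scaled/shifted by its
    :class:`GroupEffect`.  Fully deterministic given ``rng_seed``.
    """
    rng = np.random.default_rng(config.rng_seed)
    groups = config.group_effects or {config.knockdown: GroupEffect()}
    n_bins = int(round(config.duration_days * 24.0 / config.bin_width_h))
    ct = config.start_ct + np.arange(n_bins) * config.bin_width_h

    records: List[ActivityRecord] = []
    truth_rows = []
    for gname, eff in groups.items():
        amplitude = config.tidal_amplitude * eff.amplitude_mult
        M = config.modulation_M * eff.M_mult
        arr_frac = min(1.0, config.arrhythmic_fraction * eff.arrhythmic_fraction_mult)
        tau = config.tidal_period_h + eff.period_shift_h
        for i in range(config.n_animals):
            aid = f"{config.collection_id}-{gname}-{i:03d}"
            jitter = rng.uniform(-config.phase_jitter_h, config.phase_jitter_h)
            is_arr = bool(rng.random() < arr_frac)
            lam = _rate(ct, config, amplitude, M, tau, jitter)
            if is_arr:
                lam = np.full(n_bins, lam.mean())
            dropout_h = float(rng.exponential(config.dropout_mean_h))
            elapsed = ct - config.start_ct
            lam = np.where(elapsed < dropout_h, lam, 0.0)
            counts = rng.poisson(lam)
            records.append(
                ActivityRecord(
                    animal_id=aid,
                    counts=counts,
                    start_ct=config.start_ct,
                    bin_width_h=config.bin_width_h,
                    knockdown=gname,
                    collection_id=config.collection_id,
                    lighting=config.lighting,
                )
            )
            truth_rows.append(
                dict(animal_id=aid, knockdown=gname, collection=config.collection_id,
                     rhythmic=not is_arr, period_h=tau if not is_arr else np.nan,
                     amplitude=amplitude, M=M, dropout_h=dropout_h,
                     phase_jitter_h=jitter)
            )
    return records, pd.DataFrame(truth_rows)


def write_monitor_fixture(
    records: Sequence[ActivityRecord],
    out_dir,
    tide_tables: Optional[Dict[str, np.ndarray]] = None,
    prefix: str = "Monitor",
    start_date: str = "2024-06-01 00:00:00",
) -> dict:
    """Emit Trikinetics-dialect monitor files plus the interchange CSVs.

    Records round-trip bit-exactly through
    :func:`tidecycle.io_monitor.read_monitor_file`.  At most 32 channels
    per file; larger cohorts are split.  Returns the written paths and a
    channel map per file.
    """
    if not records:
        raise ValueError("empty cohort")
    n_bins = {r.n_bins for r in records}
    if len(n_bins) != 1:
        raise ValueError("all records in a monitor file must share the time base")
    n_bins = n_bins.pop()
    bw = records[0].bin_width_h
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    stamps = pd.date_range(start=start_date, periods=n_bins, freq=f"{int(bw * 60)}min")
    monitor_paths = []
    channel_maps = []
    meta_rows = []
    for fi in range(0, len(records), 32):
        chunk = records[fi : fi + 32]
        path = out_dir / f"{prefix}{fi // 32 + 1}.txt"
        with path.open("w") as fh:
            for i, ts in enumerate(stamps):
                meta = [str(i + 1), ts.strftime("%d %b %y"), ts.strftime("%H:%M:%S"), "1",
                        "1", "0", "0", "0", "0", "0"]
                row = meta + [str(int(r.counts[i])) for r in chunk]
                fh.write("\t".join(row) + "\n")
        monitor_paths.append(path)
        cmap = {ch + 1: r.animal_id for ch, r in enumerate(chunk)}
        channel_maps.append(cmap)
        for ch, r in enumerate(chunk):
            meta_rows.append(dict(animal_id=r.animal_id, channel=ch + 1,
                                  knockdown=r.knockdown, collection=r.collection_id,
                                  lighting=r.lighting, start_ct=r.start_ct,
                                  monitor_file=path.name))
    meta_path = out_dir / "cohort_metadata.csv"
    pd.DataFrame(meta_rows).to_csv(meta_path, index=False)
    tide_path = None
    if tide_tables:
        tide_path = out_dir / "tide_table.csv"
        pd.DataFrame(
            [dict(collection=c, tide_ct_h=t) for c, ts in tide_tables.items() for t in ts]
        ).to_csv(tide_path, index=False)
    return dict(monitor_files=monitor_paths, channel_maps=channel_maps,
                metadata_csv=meta_path, tide_csv=tide_path)
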