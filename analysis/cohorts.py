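"""Shared definitions for the analysis drivers: two synthetic seasons.

Each season holds two collections of three knockdown groups.  The group
effects mirror the qualitative knockdown phenotypes the analysis is
designed to detect: the bmal1-like knockdown weakens circatidal
amplitude, halves the circadian modulation and triples arrhythmicity;
the cry2-like knockdown mainly suppresses the modulation index.
"""
from pathlib import Path

from tidecycle.simulate import GroupEffect, SimConfig

SCRATCH = Path(__file__).resolve().parent.parent / "scratch" / "analysis"
RESULTS = Path(__file__).resolve().parent.parent / "results"

CONTROL = "yfpi"

GROUP_EFFECTS = {
    "yfpi": GroupEffect(),
    "bmal1i": GroupEffect(amplitude_mult=0.6, M_mult=0.5,
                          arrhythmic_fraction_mult=3.0, period_shift_h=0.2),
    "cry2i": GroupEffect(M_mult=0.4, arrhythmic_fraction_mult=1.2,
                         period_shift_h=-0.1),
}


def season_configs(season: str, base_seed: int, n_per_group: int = 15):
    """Two collections per season, phase-offset tide tables."""
    out = []
    for i, coll in enumerate(("early", "mid")):
        out.append(SimConfig(
            n_animals=n_per_group,
            group_effects=GROUP_EFFECTS,
            collection_id=f"{season}_{coll}",
            first_high_tide_ct=98.0 + 4.0 * i,
            rng_seed=base_seed + i,
        ))
    return out
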