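"""Cohort statistics: ANOVAs, post-hocs, and rhythmicity contingency tests.

Two-way (Collection × Knockdown) ANOVAs with η² and Dunnett/Tukey
post-hocs on each simulated season's phenotypes, pooled one-way ANOVAs
with the Kruskal-Wallis companion where normality fails, contingency
tests on the simulated rhythmic/arrhythmic counts — and, as fixed
published inputs, the two seasons' printed cohort tables whose Pearson
χ² values the pipeline's statistics layer reproduces.
"""
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
import numpy as np
import pandas as pd

from cohorts import CONTROL, RESULTS
from tidecycle.stats import (
    one_way_pooled_anova,
    rhythmicity_contingency,
    two_way_anova,
)

PUBLISHED = {
    "season 2016": {"yfpi": (63, 7), "bmal1i": (66, 35), "cry2i": (59, 10)},
    "season 2022": {"yfpi": (82, 12), "bmal1i": (62, 26), "cry2i": (26, 4)},
}

RESPONSES = ("MI", "amp_overall", "amp_night", "amp_day", "period_h", "power")


def main() -> None:
    rows = []
    for pheno_path in sorted(RESULTS.glob("phenotypes_s*.csv")):
        season = pheno_path.stem.split("_")[-1]
        pheno = pd.read_csv(pheno_path)
        calls = pd.read_csv(RESULTS / f"calls_{season}.csv")
        print(f"== {season} ==")
        for resp in RESPONSES:
            if pheno[resp].notna().sum() < 10:
                continue
            aov = two_way_anova(pheno, resp, control_level=CONTROL)
            pooled = one_way_pooled_anova(pheno, resp, control_level=CONTROL)
            p_kd = aov.p("knockdown")
            dunnett = {d["comparison"]: d["p_adj"] for d in pooled.posthoc
                       if d["method"] == "dunnett"}
            rows.append(dict(season=season, response=resp,
                             p_knockdown_2way=p_kd,
                             eta_sq_knockdown=aov.eta_sq("knockdown"),
                             p_knockdown_pooled=pooled.p("knockdown"),
                             **{f"dunnett {k}": v for k, v in dunnett.items()}))
            print(f"  {resp:12s} two-way knockdown p={p_kd:.4g} "
                  f"(η²={aov.eta_sq('knockdown'):.3f}); pooled p={pooled.p('knockdown'):.4g}")
        counts = {k: (int(g.rhythmic.sum()), int((~g.rhythmic).sum()))
                  for k, g in calls.groupby("knockdown")}
        cont = rhythmicity_contingency(counts)
        print(f"  rhythmic/arrhythmic χ² = {cont.statistic:.2f}, df {cont.df}, "
              f"p = {cont.p:.3g} (G = {cont.all_stats['g_test']['statistic']:.2f}, "
              f"Fisher p = {cont.all_stats['fisher_exact']['p']:.3g})")
    pd.DataFrame(rows).to_csv(RESULTS / "anova_summary.csv", index=False)

    print("== published cohort tables ==")
    pub_rows = []
    for label, season in PUBLISHED.items():
        cont = rhythmicity_contingency(season)
        print(f"  {label}: Pearson χ² = {cont.statistic:.2f}, df {cont.df}, "
              f"p = {cont.p:.2g}; G = {cont.all_stats['g_test']['statistic']:.2f}; "
              f"Fisher p = {cont.all_stats['fisher_exact']['p']:.2g}")
        pub_rows.append(dict(season=label, chi2=cont.statistic, df=cont.df,
                             p=cont.p, g=cont.all_stats["g_test"]["statistic"],
                             fisher_p=cont.all_stats["fisher_exact"]["p"]))
    pd.DataFrame(pub_rows).to_csv(RESULTS / "published_contingency.csv", index=False)


if __name__ == "__main__":
    main()
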