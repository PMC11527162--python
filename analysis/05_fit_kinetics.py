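#!/usr/bin/env python
"""Kinetic analysis of the simulated uptake observations: cpm→rates,
background subtraction, V% normalization with group statistics and
compact letters, dose-response fit (IC50, Hill, Cheng-Prusoff Ki) and
the competition profile.

Writes rates, V% + letters, the fit JSON and the competition matrix.
"""

import argparse
import dataclasses
import json
from pathlib import Path

import pandas as pd

import mutscan as ms
from mutscan.kinetics import competition_matrix


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--indir", type=Path, default=Path("results"))
    args = ap.parse_args()

    obs = pd.read_csv(args.indir / "uptake_observations.tsv", sep="\t")
    rates = ms.correct_background(ms.rates_from_counts(obs), "ΔZAC")
    rates.to_csv(args.indir / "rates.tsv", sep="\t", index=False)

    # V% over the baseline panel, with significance letters
    panel = rates[(rates.assay == "panel") & (rates.competitor == "none")]
    v = ms.normalize_rates(panel).set_index("strain")
    stats = ms.compare_strains(
        panel[["strain", "rate_corrected"]].rename(
            columns={"rate_corrected": "rate"}
        )
    )
    v["letters"] = pd.Series(stats.group_letters)
    v = v.sort_values("v_percent", ascending=False)
    v.to_csv(args.indir / "v_percent.tsv", sep="\t")
    print(f"V%% panel ({stats.test_used}, normality p={stats.normality_p:.3f}):")
    print(v.round(1).to_string())

    # homologous competition fit for the wild type
    comp = rates[(rates.assay == "competition") & (rates.strain == "PhZwt")]
    series = comp[comp.competitor.isin(["none", "hypoxanthine"])]
    fit = ms.fit_dose_response(
        list(zip(series.competitor_conc_uM, series.rate_corrected)),
        labelled_conc_S=0.2, km=5.0,
    )
    (args.indir / "dose_response_fit.json").write_text(
        json.dumps(dataclasses.asdict(fit), indent=2, default=float)
    )
    print(f"\ndose-response: IC50 {fit.ic50:.2f} uM, Hill {fit.hill:.3f}, "
          f"Ki {fit.ki:.2f} uM (rmse {fit.rmse:.2e})")

    # competition matrix at 1 mM
    at_1mM = rates[
        (rates.assay == "competition")
        & (rates.strain == "PhZwt")
        & ((rates.competitor == "none") | (rates.competitor_conc_uM == 1000.0))
    ]
    profiles = ms.competition_profile(at_1mM)
    mat = competition_matrix(profiles)
    mat.to_csv(args.indir / "competition.tsv", sep="\t", index=False)
    for p in profiles:
        for comp_name, rem in sorted(p.percent_remaining.items()):
            print(f"competition {p.strain} + 1 mM {comp_name}: "
                  f"{100 - rem:.1f}% inhibition")


if __name__ == "__main__":
    main()
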