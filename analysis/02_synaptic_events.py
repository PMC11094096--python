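#!/usr/bin/env python
"""Spontaneous/miniature event detection and the multiplicity contrast.

For each synthetic cell, detects mEPSCs and sEPSCs by scaled-template
matching and summarizes frequency, amplitude and decay.  The control
cohort carries multivesicular release (k ~ 1 + Poisson(1) release sites
per spontaneous event); the deficient cohort is restricted to single
quanta, so its sEPSC amplitudes collapse onto the mEPSC level.

Writes results/event_summaries.csv and results/multiplicity.csv.
"""

import pandas as pd

from slicephys import synthgen as sg
from slicephys.stats import select_two_group_test
from slicephys.synaptic import detect_events_template, summarize_events

N_CELLS = 6
DUR_MS = 30_000.0


def main() -> None:
    rows = []
    for genotype, mult, seed0 in (("control", "one_plus_poisson", 1000),
                                  ("deficient", "single", 2000)):
        for c in range(N_CELLS):
            for mode in ("mEPSC", "sEPSC"):
                cfg = sg.SimConfig(seed=seed0 + 10 * c + (mode == "sEPSC"),
                                   duration=DUR_MS, event_rate=1.0, noise_sd=8.0,
                                   multiplicity=mult)
                sweep, _ = sg.simulate_event_trace(cfg, mode)
                table = detect_events_template(sweep, cfg.ampa_kernel, criterion=4.0)
                s = summarize_events(table)
                rows.append({"genotype": genotype, "cell": f"{genotype}_{c}",
                             "condition": mode, **s})
    df = pd.DataFrame(rows)
    df.to_csv("results/event_summaries.csv", index=False)
    print(f"wrote results/event_summaries.csv ({len(df)} recordings)")

    mult_rows = []
    for genotype in ("control", "deficient"):
        sub = df[df.genotype == genotype]
        s = sub[sub.condition == "sEPSC"]["mean_amp_pA"]
        m = sub[sub.condition == "mEPSC"]["mean_amp_pA"]
        rep = select_two_group_test(s, m)
        mult_rows.append({"genotype": genotype,
                          "mean_sepsc_pA": s.mean(), "mean_mepsc_pA": m.mean(),
                          "ratio": s.mean() / m.mean(),
                          "test": rep.test_name, "p": rep.p_value,
                          "multiplicity_present": bool(
                              s.mean() > m.mean() and rep.p_value < 0.05)})
        print(f"{genotype:>10}: sEPSC/mEPSC amplitude ratio "
              f"{s.mean() / m.mean():.2f}, {rep.test_name} p = {rep.p_value:.3g}")
    pd.DataFrame(mult_rows).to_csv("results/multiplicity.csv", index=False)
    print("wrote results/multiplicity.csv; expected pattern: ratio ~2 and "
          "significant only in the control cohort")


if __name__ == "__main__":
    main()
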