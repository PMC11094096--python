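#!/usr/bin/env python
"""Deterministic reference computations: power, junction potentials, DI.

Recomputes the study-design numbers that do not depend on simulated data:
the minimal sample size for the standard effect-size scenario, the
Henderson liquid junction potentials of both intracellular solutions
against ACSF, the discrimination-index arithmetic, the sequential
p-value correction on a worked example, and an ELISA normalization.

Writes results/stats_reference.json.
"""

import json

from slicephys.junction import acsf, henderson_ljp, k_gluconate_internal, kcl_internal
from slicephys.stats import (discrimination_index, holm_variant_correction,
                             normalize_to_protein, power_sample_size, t_test_power)


def main() -> None:
    out = {
        "power": {
            "scenario": "control 100 %, SD 25 %, effect 50 %, power 0.80, alpha 0.05",
            "n_per_group": power_sample_size(50.0, 25.0, power=0.80, alpha=0.05),
            "power_at_n5": round(t_test_power(2.0, 5), 4),
            "power_at_n6": round(t_test_power(2.0, 6), 4),
        },
        "junction_potentials_mV": {
            "k_gluconate_vs_acsf": round(henderson_ljp(k_gluconate_internal(), acsf()), 2),
            "kcl_vs_acsf": round(henderson_ljp(kcl_internal(), acsf()), 2),
        },
        "discrimination_index": {
            "novel_30s_familiar_10s": discrimination_index(30.0, 10.0),
            "equal_times": discrimination_index(10.0, 10.0),
        },
        "sequential_correction_example": {
            "input": [0.01, 0.04, 0.03],
            "corrected": holm_variant_correction([0.01, 0.04, 0.03]),
        },
        "elisa_normalization_pg_per_mg": normalize_to_protein(100.0, 2.0),
    }
    with open("results/stats_reference.json", "w") as fh:
        json.dump(out, fh, indent=1)
    print(json.dumps(out, indent=1))
    print("wrote results/stats_reference.json")


if __name__ == "__main__":
    main()
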