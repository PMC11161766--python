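"""Behavioral phase analysis on synthetic entrainment psychophysics data.

Generates a modulated and a null response table (18 participants, 12 SOAs
spanning two 6.25 Hz cycles, 40 trials per SOA), fits the demeaned
fixed-frequency sinusoid, and runs the SOA-permutation test and the
split-half comparison.

Finding: the permutation test detects a 0.15-probability modulation with
r^2 near 1 and p at the permutation floor, stays at chance-level p for the
null table, and the split-half statistic flags a modulation confined to
the first half of the experiment.

Writes results/behavioral_stats.json and the two tables.
"""

import json
from pathlib import Path

from phasecode.io import write_response_table
from phasecode.stats import (demean_responses, fit_fixed_frequency_sinusoid,
                             permutation_sinusoid_test, split_half_comparison)
from phasecode.synth import BehavioralSimSpec, generate_behavioral_dataset

FREQ = 6.25
SEED = 7


def analyze(table):
    conds, _, group = demean_responses(table)
    fit = fit_fixed_frequency_sinusoid(group, conds, FREQ)
    perm = permutation_sinusoid_test(table, FREQ, n_perm=2000, seed=SEED)
    return {"r_squared": round(fit.r_squared, 4),
            "amplitude": round(fit.amplitude, 4),
            "p": round(perm.p, 5)}


if __name__ == "__main__":
    out = Path("results")
    out.mkdir(exist_ok=True)
    report = {}
    for name, amp in (("modulated", 0.15), ("null", 0.0)):
        table = generate_behavioral_dataset(BehavioralSimSpec(
            modulation_amplitude=amp, seed=SEED))
        write_response_table(table, out / f"behavior_{name}.tsv")
        report[name] = analyze(table)
        print(name, report[name])
    half = generate_behavioral_dataset(BehavioralSimSpec(
        modulation_amplitude=0.2, amplitude_second_half=0.0, seed=SEED))
    res = split_half_comparison(half, FREQ, n_perm=2000, seed=SEED)
    report["split_half_first_minus_second"] = {
        "statistic": round(res.observed, 4), "p": round(res.p, 5)}
    print("split-half:", report["split_half_first_minus_second"])
    (out / "behavioral_stats.json").write_text(
        json.dumps(report, indent=2) + "\n")
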