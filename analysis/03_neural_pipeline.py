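"""Neural phase analysis on one synthetic MEG-like dataset.

Generates 20 participants x 150 trials of STG-like and MTG-like streams in
which the consonant percept is coupled to STG phase at (7.6 Hz, -0.2 s)
and the word percept to MTG phase at (6.4 Hz, -0.1 s), then runs the full
2x2 stream-by-labeling cluster analysis and the circular phase readout at
each participant's peak point.

Finding: significant clusters appear only in the two matching cells — the
regional double dissociation — and within them the two percepts sit at
roughly opposite phases (v-test toward pi).

Writes results/neural_clusters.json.
"""

import json
from pathlib import Path

import numpy as np

from phasecode.clusters import DEFAULT_FREQUENCIES, DEFAULT_TIMES
from phasecode.stats import combine_pvalues_product
from phasecode.synth import NeuralSimSpec, generate_neural_dataset
from phasecode.workflows import (analyze_stream_labeling,
                                 participant_phase_grids,
                                 phase_difference_readout)

SEED = 11

if __name__ == "__main__":
    data = generate_neural_dataset(NeuralSimSpec(seed=SEED))
    report = {}
    for stream in ("STG", "MTG"):
        grids = participant_phase_grids(data, stream, DEFAULT_FREQUENCIES,
                                        DEFAULT_TIMES)
        for labeling in ("consonant", "word"):
            res = analyze_stream_labeling(
                grids, data["responses"][labeling], seed=SEED)
            sig = res.significant(0.05)
            cell = {"significant_clusters": len(sig)}
            if sig:
                cell["cluster_statistic"] = round(sig[0].statistic, 1)
                cell["p"] = round(sig[0].p, 4)
                diffs, vres = phase_difference_readout(
                    grids, data["responses"][labeling], res)
                cell["mean_phase_difference_rad"] = round(
                    float(np.angle(np.exp(1j * diffs).mean())), 3)
                cell["v_test_toward_pi"] = {"v": round(vres.v, 2),
                                            "p": round(vres.p, 5)}
            report[f"{stream}/{labeling}"] = cell
            print(f"{stream}/{labeling}: {cell}")
    sig_ps = [c["p"] for c in report.values() if "p" in c]
    if sig_ps:
        report["combined_p_product"] = combine_pvalues_product(sig_ps)
    Path("results").mkdir(exist_ok=True)
    Path("results/neural_clusters.json").write_text(
        json.dumps(report, indent=2) + "\n")
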