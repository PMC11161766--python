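"""Quick calibration report for the statistics chain.

Runs the reduced synthetic-validation suites (type-I error and power of
the sinusoid permutation test, preferred-phase recovery of the phase
logistic regression, family-wise error of the cluster test on Gaussian
maps) and writes results/validation_report.json.  The full-size
calibrations (1000 null datasets, 500 FWER simulations, 50 detection
replicates) run in the test suite.
"""

import json

from phasecode.workflows import run_synthetic_validation

if __name__ == "__main__":
    report = run_synthetic_validation(n_datasets=200, n_perm=500, seed=17,
                                      out_path="results/validation_report.json")
    print(json.dumps(report, indent=2))
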