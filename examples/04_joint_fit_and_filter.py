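"""The full joint X-ray/neutron analysis at desk scale.

A 150-model toy ensemble is fitted against simulated duplicate X-ray and
neutron curves from a hidden truth structure (d1 = 9.5 nm).  The duplicate
comparison fixes the R-factor cutoffs, the joint filter intersects both
contrasts, and the survivors' distances are compared with the truth.
"""

import json
import tempfile
from pathlib import Path

from absasfit import RunConfig, run_pipeline

config = RunConfig(
    outdir=str(Path(tempfile.mkdtemp()) / "run"),
    seed=7,
    ensemble={"kind": "toy", "n_models": 150, "d1_range": [4.0, 12.0],
              "d23_range": [5.0, 10.0], "points_per_lobe": 250,
              "lobe_radii": [2.0, 2.0, 1.4]},
    filters={"ss_max": 0.75, "d1_threshold": 7.0, "asym_threshold": 1.5,
             "min_n": 40},
)
outdir = run_pipeline(config)
report = json.load(open(outdir / "report.json"))

print(f"ensemble size        : {report['n_models']}")
for key, cut in report["cutoffs"].items():
    shown = f"{cut:.2f}%" if cut is not None else "none found"
    print(f"{key:21s}: R-factor cutoff {shown}")
print(f"joint-filter survivors: {report['n_survivors']}")
print(f"survivor mean d1     : {report['survivor_mean_d1']:.2f} nm "
      f"(truth 9.5 nm)")
print(f"modal cluster        : {report['survivor_modal_cluster']}")
print()
print("The duplicate-curve correlation scan sets the cutoff where fit")
print("ranking stops being reproducible; the surviving models concentrate")
print("around the geometry that generated the data.")
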