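"""Generate a synthetic staining experiment and run the full pipeline.

Builds two replicate groups of noisy specimen photos whose true chromaticity
difference matches the published titanium magnitude (ΔC ≈ 0.0112), measures
each image, summarizes the groups, and reports the recovered ΔC.
"""

import tempfile
from pathlib import Path

from cvchroma import (
    SyntheticExperiment,
    SyntheticSpec,
    delta_c,
    generate_experiment,
    run_experiment,
)

ti_only = (0.3237, 0.3425)
ti_3day = (0.3171, 0.3335)

experiment = SyntheticExperiment(
    conditions=(
        ("Ti only", SyntheticSpec(target_xy=ti_only, noise_sd=5.0, size=(64, 64)), 10),
        ("Ti day 3", SyntheticSpec(target_xy=ti_3day, noise_sd=5.0, size=(64, 64)), 10),
    )
)

with tempfile.TemporaryDirectory() as tmp:
    sheet = generate_experiment(experiment, Path(tmp), master_seed=1)
    result = run_experiment(sheet)

    print("group summaries (mean ± sample SD of chromaticity):")
    for _, row in result.summaries.iterrows():
        print(
            f"  {row['condition']:<9} n={row['n']}  "
            f"x = {row['mean_x']:.5f} ± {row['sd_x']:.5f}  "
            f"y = {row['mean_y']:.5f} ± {row['sd_y']:.5f}"
        )

    est = result.differences["delta_c"].iloc[0]
    true = delta_c(ti_only, ti_3day)
    print(f"\nrecovered ΔC = {est:.5g}   (ground truth {true:.5g})")
    print("the pipeline resolves colour shifts of the size a 3-day biofilm produces.")
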