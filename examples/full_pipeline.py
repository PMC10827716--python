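"""End-to-end pipeline on a reduced synthetic cohort.

Generates a cohort (2 animals per arm at coarse resolution to keep this
example quick; defaults reproduce the full study conditions), quantifies
lesions, reactivity and behavior, and prints the group-comparison report.
"""

import warnings

from strokequant import CohortConfig, PipelineConfig, run_pipeline
from strokequant.synthesis import ARM_LABELS

config = PipelineConfig(cohort=CohortConfig(
    seed=0,
    arm_sizes={arm: 3 for arm in ARM_LABELS},
    image_shape=(300, 600),
    um_per_px=20.0,
))
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    result = run_pipeline(config)

print(f"cohort: {len(result.cohort.animals)} animals, "
      f"arms {sorted(set(a.arm for a in result.cohort.animals))}")
print("\nper-arm means:")
vol = result.volumetry.drop_duplicates("animal_id")
for arm in ARM_LABELS:
    v = vol[vol.arm == arm]["volume_mm3"].mean()
    r = result.reactivity_summary.query("arm == @arm")["pooled_mean"].mean()
    print(f"  {arm:>5} A/m^2: volume {v:5.1f} mm^3, "
          f"reactivity ratio diff {r:+.3f}")

cols = ["outcome", "gate", "test", "p", "significant"]
print("\ngroup-comparison report:")
print(result.report[cols].to_string(index=False,
                                    float_format=lambda x: f"{x:.4f}"))
print("\n-> volumes are dose-independent while reactivity separates the "
      "highest stimulation intensity, the qualitative safety pattern the "
      "pipeline is built to detect (group power is reduced at n=3/arm)")
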