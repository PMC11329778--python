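"""Cohort-level comparison of fiber disorder between two groups.

Generates a small 'treated' cohort of wavy, loosely aligned fiber images
and a 'vehicle' cohort of tightly aligned ones, writes them to disk, and
runs the batch pipeline: per-image entropy, then an unpaired two-tailed
Welch t-test between the groups with mean +/- SEM.
"""

import tempfile
from pathlib import Path

import pandas as pd

from detensio import FiberFieldSpec, RunConfig, render_fiber_image, run_batch
from detensio import io as dio

tmp = Path(tempfile.mkdtemp())
rows = []
for group, kappa, wav, base in [
    ("treated", 2.0, 4.0, 0),
    ("vehicle", 32.0, 0.0, 100),
]:
    for i in range(4):
        spec = FiberFieldSpec(
            image_size_px=(512, 512), n_fibers=75,
            kappa=kappa, waviness_amp_um=wav, seed=base + i,
        )
        stack, _ = render_fiber_image(spec)
        path = tmp / f"{group}_{i}.tif"
        dio.write_image_stack(path, stack)
        rows.append({"path": str(path), "group": group,
                     "animal_id": f"{group}{i % 2}"})

config = RunConfig(
    stage="entropy",
    params={"pixel_size_um": 0.5, "n_bins": 16, "circular_fov": True},
)
result = run_batch(config, pd.DataFrame(rows))

cmp = result.comparison
for grp in ("treated", "vehicle"):
    print(f"{grp}: H' = {cmp[grp]['mean']:.3f} +/- {cmp[grp]['sem']:.3f} nats "
          f"(n = {cmp[grp]['n']})")
print(f"Welch t-test: p = {cmp['p_value']:.2e}")
print("\nThe wavy, low-concentration cohort should have the higher mean "
      "entropy — the de-tensioned phenotype — at p well below 0.05.")
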