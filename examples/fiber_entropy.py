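"""Orientation entropy of a synthetic collagen fiber field.

Renders two fiber phantoms — one disordered ("de-tensioned") and one
well-aligned — and runs the full entropy pipeline on each: tubeness ridge
enhancement, fiber masking, local-gradient orientation histogram, Shannon
index H'.  Higher H' means a broader spread of fiber orientations.
"""

from detensio import (
    FiberAnalysisConfig,
    FiberFieldSpec,
    analyze_fiber_image,
    render_fiber_image,
)

config = FiberAnalysisConfig(
    pixel_size_um=0.5, n_bins=16, gradient_scale_um=0.5, circular_fov=True
)

for label, kappa in [("disordered (kappa=2)", 2.0), ("aligned (kappa=32)", 32.0)]:
    spec = FiberFieldSpec(kappa=kappa, seed=1)
    stack, truth = render_fiber_image(spec, truth_n_bins=config.n_bins)
    result = analyze_fiber_image(stack, config)
    print(f"{label}:")
    print(f"  estimated H' = {result.entropy.H_nats:.4f} nats "
          f"(ground truth {truth.entropy_nats:.4f}, "
          f"ceiling ln {config.n_bins} = {__import__('numpy').log(config.n_bins):.4f})")
    print(f"  coverage fraction = {result.coverage.fraction:.4f} "
          f"({result.coverage.n_particles} particles)")

print("\nThe disordered field should score a substantially higher H': "
      "orientation mass is spread over many bins instead of one.")
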