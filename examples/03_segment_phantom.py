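"""Full pipeline on one phantom study: lumen -> thrombus -> outer wall.

Generates a synthetic two-channel study, trains the shape model,
segments the study end to end, and scores both boundaries against the
ground truth with Dice and modified Hausdorff distance.
"""

from aaaseg.config import PipelineConfig
from aaaseg.evaluation import dice, evaluate_result
from aaaseg.phantom import PhantomSpec, generate_study, sample_training_shapes
from aaaseg.segmentation import segment_study
from aaaseg.shape_model import build_shape_model

spec = PhantomSpec()
model = build_shape_model(sample_training_shapes(75, spec, seed=123))
study = generate_study(spec, 42)

result = segment_study(study.pair, study.seed_point, model, PipelineConfig())

print(f"slices segmented   : {len(result.slice_indices)}")
print(
    f"iterations         : thrombus {result.iterations_thrombus}, "
    f"outer {result.iterations_outer} "
    f"(converged: {result.converged_thrombus}, {result.converged_outer})"
)
print(f"lumen Dice         : {dice(result.lumen_mask.data, study.lumen_mask.data):.3f}")
for row in evaluate_result(result, study):
    print(
        f"{row['structure']:9s} boundary : Dice {row['dice']:.3f}, "
        f"MHD {row['mhd_mm']:.2f} mm"
    )

# Dice near 1 means the delineated region overlaps the true structure
# almost completely; MHD below the 1 mm pixel size means the recovered
# boundary tracks the true interface to sub-pixel accuracy on average.
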