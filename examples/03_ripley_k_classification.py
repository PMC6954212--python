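"""Classify a gold-particle pattern against the four null geometries.

Simulates a ring-distributed protein (one ring of radius 300 nm, 65 nm
linkage jitter), fits all four candidate models to the pattern, builds a
95% pointwise simulation band of the 3D Ripley K function under each, and
reports how much of the data K curve each band contains.
"""

from immunogold3d import (
    ClassifySettings,
    MODEL_KINDS,
    NullModelSpec,
    classify_pattern,
    estimate_model_params,
    plot_k_with_envelopes,
    sample_null,
)

truth = NullModelSpec(
    kind="ring", radius=300.0, n_points=300,
    center=(0.0, 0.0, 0.0), normal=(0.0, 0.6, 0.8),
)
pattern = sample_null(truth, seed=42)

models = [estimate_model_params(pattern, kind) for kind in MODEL_KINDS]
report = classify_pattern(pattern, models, ClassifySettings(m_sims=199, seed=0))

for kind, frac in report.inside_fractions.items():
    print(f"  {kind:10s} inside fraction: {frac:.3f}")
print(f"best-supported model: {report.best_model}")
plot_k_with_envelopes(report.k_data, report.envelopes, "k_vs_bands.png")
print("plot written to k_vs_bands.png")
# The inside fraction is the share of the distance grid at which the data
# K lies within a model's band; a clustered ring pattern escapes the CSR
# and sphere bands at short range, so their fractions collapse while the
# matched ring band retains (almost) the whole curve.
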