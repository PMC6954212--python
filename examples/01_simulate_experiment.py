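"""Simulate a serial-section immunogold experiment and write its fixtures.

Builds the bundled single-cell preset — a small coccal cell followed over
13 consecutive 50 nm sections with a surface-associated (sphere-model)
epitope distribution — and writes the reconstruction files plus ground
truth to ./out_simulate/.
"""

from pathlib import Path

from immunogold3d import fig1f_preset, generate_experiment, write_reconstruct_xml

out = Path("out_simulate")
cfg = fig1f_preset()
series, truth = generate_experiment(cfg)

series_file = write_reconstruct_xml(series, out)
truth.to_csv(out / "ground_truth.csv")

n_marks = sum(len(s.marks) for s in series.sections)
print(f"series file:        {series_file}")
print(f"sections:           {len(series.sections)} x {cfg.section_thickness:.0f} nm")
print(f"epitopes simulated: {len(truth.epitope_xyz)}")
print(f"gold marks:         {n_marks}")
print(f"detected fraction:  {truth.detected.mean():.3f}")
# The detected fraction is labeling efficiency x the chance an epitope sits
# within the antibody-accessible capture depth of a section cut face; the
# rest of the epitopes are buried inside the resin and never labelled.
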