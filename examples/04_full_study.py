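"""Simulate, process and summarize a complete handle-design study.

Each participant records 18 trials (6 handle designs x 3 bilateral trunk
muscle pairs), each covering both sides — 36 feature records per
participant. The default effect table makes the hip-height horizontal
handle (HH) elicit the lowest mean activation and the most homogeneous
maps; the per-design summary table below recovers that ordering from the
processed features alone.
"""

from hdemg import StudyDesign, check_completeness, generate_study, process_study, summarize

design = StudyDesign(n_participants=2, duration=2.0, seed=11)
study = generate_study(design)
records = process_study(study)
print(check_completeness(design, records))

summary = summarize(records)
columns = ["design", "n", "mean_rms_pct_mean", "mean_rms_pct_sd",
           "entropy_bits_mean", "cov_pct_mean"]
print(summary.per_design[columns].to_string(index=False))
lowest = summary.per_design.set_index("design")["mean_rms_pct_mean"].idxmin()
print(f"\nlowest mean activation: {lowest} "
      "(ground truth: HH's activation multiplier is 0.5)")
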