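"""Compare the 12 reconstruction configurations on a simulated cohort.

Runs the full pipeline on an 8-subject phantom cohort: for each subject and
each of the 12 kernel/level cells, a scene with seven coronary
cross-sections and a fat region is generated, the 8 ROIs are measured, the
6 edge profiles are fitted, and per-cell summaries are reported. The
classic kernel trade-off appears: sharper levels raise both noise and
vessel sharpness while CNR falls; the vascular (Bv) family is sharpest.
"""

import tempfile

from vesseliq import RunConfig, run_simulate

run = run_simulate(RunConfig(out_dir=tempfile.mkdtemp(), seed=1,
                             n_subjects=8))

summary = run.metrics_summary.merge(
    run.sharp_summary[["family", "level", "s_mean"]], on=["family", "level"]
)
print(f"{'cell':7s} {'atten':>7s} {'noise':>7s} {'CNR':>6s} {'sharp':>6s}")
for _, r in summary.iterrows():
    print(f"{r['family']}{r['level']:<5} {r['attenuation_mean']:7.1f} "
          f"{r['noise_mean']:7.1f} {r['cnr_mean']:6.1f} {r['s_mean']:6.2f}")
print()
print("Trend checks across the grid:", run.trends)
print(f"Full artifacts (CSVs, report.txt, manifest) in {run.out_dir}")
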