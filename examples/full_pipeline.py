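"""End-to-end run: simulate two small cohorts, analyze, compare groups.

Writes synthetic sessions (EMG CSV + quaternion CSV with JSON sidecars)
for three control and three patient subjects, runs the complete
per-subject analysis on each, and produces the group-comparison report:
SPM clusters per muscle/pair/joint plus scalar tests on the temporal
parameters. Three subjects per group keeps this demonstration quick;
statistical power at n = 3 is of course minimal, so only the largest
injected differences (e.g. knee ROM) reach significance.

Equivalent shell commands: `gaitspm simulate`, `gaitspm analyze-subject`,
`gaitspm compare-groups`, `gaitspm report`.
"""

import tempfile
from pathlib import Path

from gaitspm import pipeline

with tempfile.TemporaryDirectory() as tmp:
    bundles = {"control": [], "patient": []}
    for group in bundles:
        for i in range(3):
            manifest = pipeline.simulate_session(
                Path(tmp) / group,
                seed=10 * (i + 1) + (0 if group == "control" else 5),
                group=group,
                subject_id=f"{group[:1].upper()}{i:02d}",
            )
            bundles[group].append(pipeline.run_subject(manifest))
            print(f"analyzed {manifest.subject_id} ({group})")

report = pipeline.run_group_comparison(bundles["control"], bundles["patient"])
print(f"\ngroups n = {report['n_a']} vs {report['n_b']}, alpha = {report['alpha']}")
for section in ("emg", "cci", "kinematics"):
    for name, block in report[section].items():
        for c in block["clusters"]:
            print(
                f"  {section:10s} {name:8s} cluster "
                f"{c['start_pct']:.0f}-{c['end_pct']:.0f} % "
                f"p = {c['p']:.3f}, mean |d| = {c['mean_d']:.2f}"
            )
for name in ("cycle_time_cv", "stance_pct", "rom_knee", "rom_ankle"):
    block = report["temporal"][name]
    print(f"  temporal   {name:14s} p = {block['p']:.3f}, d = {block['d']:.2f}")
print(
    "  slope ratio SOL/LG: control "
    f"{report['slope_ratio_sol_lg']['mean_a']:.2f} vs patient "
    f"{report['slope_ratio_sol_lg']['mean_b']:.2f}"
)
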