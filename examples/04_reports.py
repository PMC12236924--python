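"""Render diagnostic report pages and the cohort summary heatmap.

Writes one multi-panel PDF per sample plus the clustered pass/warn/fail
heatmap under scratch/example_reports/.
"""

from pathlib import Path

from bulkqc import FlagConfig, default_cohort_spec, flag_dataset, generate_cohort
from bulkqc.metrics import build_expression_histogram
from bulkqc.report import render_sample_report, render_summary_heatmap

out = Path("scratch/example_reports")
out.mkdir(parents=True, exist_ok=True)

cohort = generate_cohort(default_cohort_spec(n_samples=12, defect_fraction=0.15,
                                             seed=9, n_genes=1000))
flags, cutoffs = flag_dataset(cohort.qc, counts=cohort.counts, gbc=cohort.gbc,
                              config=FlagConfig(seed=9))
hist = build_expression_histogram(cohort.counts)

for sid in cohort.qc["sample_id"]:
    render_sample_report(sid, cohort.qc, flags, cutoffs, out / f"{sid}.pdf",
                         histogram=hist, gbc=cohort.gbc)
render_summary_heatmap(flags, out / "summary_heatmap.png")
print(f"wrote {len(cohort.qc)} sample reports and the summary heatmap to {out}/")
# each page shows up to eight panels; the teal marker is the current sample,
# the dashed purple line the batch mean, yellow/red lines the warn/fail cutoffs
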