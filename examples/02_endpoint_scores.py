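"""Endpoint quality scores (MSC, UGP, CTS) and stringency labels.

Computes the three per-sample quality scores on a synthetic cohort and
labels samples low/high quality at the 0.88 / 0.90 / 0.91 cutoffs by
the at-least-two-of-three rule.
"""

from bulkqc import (STRINGENCY_CUTOFFS, compute_endpoint_scores, default_cohort_spec,
                    generate_cohort)

cohort = generate_cohort(default_cohort_spec(n_samples=60, defect_fraction=0.10,
                                             seed=11, n_genes=2000))
scores = compute_endpoint_scores(cohort.counts, cohort.unique_positions,
                                 cohort.marker_genes, cohort.contaminant_genes,
                                 lim=2e6)

print("first rows (msc = centroid correlation, ugp = complexity, cts = purity):")
print(scores.head().round(3).to_string())

for name, cut in STRINGENCY_CUTOFFS.items():
    n_low = (scores[f"label_{name}"] == "low").sum()
    print(f"low-quality at {name} cutoff ({cut}): {n_low} of {len(scores)}")

defect = cohort.truth["is_defect"]
print("\nmean scores, clean vs defect samples:")
print(scores.loc[~defect, ["msc", "ugp", "cts"]].mean().round(3).to_string())
print(scores.loc[defect, ["msc", "ugp", "cts"]].mean().round(3).to_string())
# defects depress the score matching their failure mode: contamination lowers
# CTS and MSC, complexity/depth problems lower UGP and MSC
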