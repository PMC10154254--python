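#!/usr/bin/env python
"""Cohort-level statistics: median/IQR per cohort, the omnibus
Kruskal-Wallis test, and the seven planned comparisons against healthy
controls at p < 0.05/7.

Reads scratch/scores.tsv; writes results/cohort_summary.tsv and
results/planned_comparisons.tsv.
"""

import pandas as pd

from ssns_grs.cohort_analysis import summaries_to_frame
from ssns_grs.pipeline import analyse_study


def main() -> None:
    scores = pd.read_csv("scratch/scores.tsv", sep="\t").fillna({"subtype": ""})
    result = analyse_study(scores)

    summary = summaries_to_frame(result.summaries)
    summary.to_csv("results/cohort_summary.tsv", sep="\t", index=False)
    print(summary.round(3).to_string(index=False))
    print(f"\nomnibus Kruskal-Wallis: H={result.omnibus.h_statistic:.1f}, "
          f"df={result.omnibus.df}, p={result.omnibus.p_value:.3g}")

    rows = []
    for c in result.planned:
        rows.append({
            "cohort": c.groups[0],
            "H": c.h_statistic,
            "p": c.p_value,
            "alpha": c.alpha,
            "significant": c.significant,
        })
    comparisons = pd.DataFrame(rows)
    comparisons.to_csv("results/planned_comparisons.tsv", sep="\t", index=False)
    print("\nplanned comparisons vs healthy (threshold 0.05/7 = 0.007):")
    print(comparisons.round(4).to_string(index=False))


if __name__ == "__main__":
    main()
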