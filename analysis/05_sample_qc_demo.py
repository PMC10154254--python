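#!/usr/bin/env python
"""Sample-QC stage on a wide synthetic panel: marker pruning, kinship,
maximal unrelated set, and PCA ancestry assignment against a labelled
reference.

Self-contained (generates its own panel); writes results/sample_qc.json.
"""

import json

import numpy as np

from ssns_grs import (
    estimate_kinship,
    fit_reference_pca,
    maximal_unrelated_set,
    project_and_classify,
    select_pca_markers,
)
from ssns_grs.synthetic_data import PanelSpec, PedigreeBlock, simulate_panel


def main() -> None:
    spec = PanelSpec(
        n_markers=10_000,
        n_populations=5,
        divergence=0.05,
        n_per_population=120,
        pedigree_blocks=(PedigreeBlock(0, 2), PedigreeBlock(1, 3)),
        seed=515,
    )
    matrix, samples, pairs = simulate_panel(spec)
    print(f"panel: {matrix.n_samples} samples x {matrix.n_variants} markers, "
          f"{len(pairs)} related pairs planted")

    kept_markers = select_pca_markers(matrix, n_target=(1, 10_000))
    pruned = matrix.subset_variants(
        np.isin(np.arange(matrix.n_variants), kept_markers)
    )
    print(f"marker pruning kept {pruned.n_variants}")

    kin = estimate_kinship(pruned)
    unrelated = maximal_unrelated_set(kin, threshold=0.0442)
    print(f"unrelated set: {len(unrelated)}/{matrix.n_samples} retained")

    ref = pruned.subset_samples(unrelated)
    ref_labels = samples.set_index("sample_id").loc[unrelated, "population"].tolist()
    pca = fit_reference_pca(ref, k=10)
    assigns = project_and_classify(pca, pruned, ref_labels)
    truth = samples.set_index("sample_id")["population"]
    acc = float(np.mean([a.label == truth[a.sample_id] for a in assigns]))
    unassigned = int(sum(a.label == "unassigned" for a in assigns))
    print(f"ancestry: accuracy {acc:.4f}, unassigned {unassigned}")

    with open("results/sample_qc.json", "w") as fh:
        json.dump(
            {
                "n_samples": matrix.n_samples,
                "n_markers_after_pruning": int(pruned.n_variants),
                "n_unrelated": len(unrelated),
                "n_related_pairs_planted": int(len(pairs)),
                "ancestry_accuracy": acc,
                "n_unassigned": unassigned,
            },
            fh,
            indent=2,
        )
    print("wrote results/sample_qc.json")


if __name__ == "__main__":
    main()
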