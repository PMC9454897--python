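#!/usr/bin/env python
"""Simulate the two-condition tri-omics cohort the downstream analyses use.

Writes GTF, count matrices, narrowPeak, binding sites, footprint statistics,
target predictions and the planted ground truth under
results/analysis/inputs/.
"""

from triomics.synthetic_data import SimulationConfig, simulate_dataset, write_dataset

from common import INPUT_DIR

SEED = 2024


def main() -> None:
    config = SimulationConfig(seed=SEED)
    data = simulate_dataset(config)
    paths = write_dataset(data, INPUT_DIR)
    truth = data.truth
    print(f"cohort: {len(data.annotation)} genes ({len(data.annotation.tf_ids())} TFs), "
          f"{len(data.peaks)} peaks, {data.mirna_counts.shape[0]} miRNAs, "
          f"{data.gene_counts.shape[1]} samples ({'+'.join(map(str, config.reps_per_group))})")
    print(f"planted: seed TF {truth.seed_tf}, {len(truth.primary_targets)} primary and "
          f"{len(truth.secondary_targets)} secondary cascade targets, "
          f"{len(truth.tension_genes)} miRNA-repressed genes with opened promoters")
    print(f"wrote {len(paths)} files to {INPUT_DIR}")


if __name__ == "__main__":
    main()
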