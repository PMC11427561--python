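#!/usr/bin/env python
"""Generate the synthetic datasets every later analysis step consumes.

Three datasets with full ground truth:

1. the benchmark design — seven non-spiked 1-ng analyte replicates co-analyzed
   with three 10-ng matching-enhancer (ME) runs spiked with 10% foreign
   (entrapment) proteome, at the package's default false-transfer rate of 0.2%;
2. a spiked dilution series — analyte triplicates at 5/10/20% spike fractions
   plus matched 10x ME runs, for the quantification-accuracy analysis;
3. a single-cell matrix with two anti-correlated protein modules and a planted
   treatment-responder set.
"""

import sys
from pathlib import Path

from diame import report_io, simulate

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 2024
OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)

    cfg = simulate.SimulationConfig(seed=SEED, conditions=simulate.study_design())
    table, ann, truth = simulate.simulate_two_proteome(cfg)
    report_io.write_report(table, OUT / "benchmark_report.tsv")
    report_io.write_annotations(ann, OUT / "benchmark_annotations.tsv")
    truth.labels.to_csv(OUT / "benchmark_truth_labels.tsv", sep="\t", index=False)
    truth.loading_log2.to_frame().to_csv(OUT / "benchmark_truth_loading.tsv", sep="\t")
    rates = simulate.truth_rates(truth)
    rates.to_csv(OUT / "benchmark_truth_rates.tsv", sep="\t")
    print(f"benchmark: {len(table)} records, {len(table.runs)} runs")
    print(rates.to_string())

    cfg_dil = simulate.SimulationConfig(seed=SEED + 1, conditions=simulate.spiked_dilution_design())
    table_d, ann_d, truth_d = simulate.simulate_two_proteome(cfg_dil)
    report_io.write_report(table_d, OUT / "dilution_report.tsv")
    report_io.write_annotations(ann_d, OUT / "dilution_annotations.tsv")
    truth_d.loading_log2.to_frame().to_csv(OUT / "dilution_truth_loading.tsv", sep="\t")
    print(f"dilution series: {len(table_d)} records, {len(table_d.runs)} runs")

    sc_cfg = simulate.SingleCellConfig(
        seed=SEED + 2,
        n_proteins=600,
        n_control=40,
        n_treated=40,
        module_sizes=(30, 30),
        responder_count=40,
        noise_sd_log2=0.4,
        detection_midpoint_log2=10.0,
    )
    mat, sc_truth = simulate.simulate_single_cells(sc_cfg)
    report_io.write_matrix(mat, OUT / "singlecell_matrix.tsv")
    sc_truth.modules.to_frame().to_csv(OUT / "singlecell_truth_modules.tsv", sep="\t")
    sc_truth.treatment.to_frame().to_csv(OUT / "singlecell_truth_treatment.tsv", sep="\t")
    completeness = mat.notna().to_numpy().mean()
    print(f"single cells: {mat.shape[0]} proteins x {mat.shape[1]} cells, "
          f"{completeness:.0%} complete")


if __name__ == "__main__":
    main()
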