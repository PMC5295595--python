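#!/usr/bin/env python
"""Simulate the study data: an inbred wheat-like panel in a trial series.

Generates a scaled-down version of the multi-environment trial structure the
package targets — 80 inbred lines from a 3-generation crossing pedigree,
1500 markers above a 5% MAF floor, 6 environments with 2 replicates and
incomplete blocks, genetic signal split between genomic/pedigree main
effects and kernel-structured G×E — and writes the three input tables plus
the ground truth under results/study/.
"""

from pathlib import Path

from gxepred import SimulationConfig, simulate_study
from gxepred.simulate import write_study

OUT = Path(__file__).resolve().parent.parent / "results" / "study"

CONFIG = SimulationConfig(
    n_lines=80,
    n_markers=1500,
    maf_min=0.05,
    n_founders=20,
    n_generations=3,
    n_envs=6,
    n_reps=2,
    blocks_per_rep=4,
    mu=4.0,
    var_env=1.0,
    var_line=0.05,
    var_g=0.4,
    var_a=0.15,
    var_ge=0.4,
    var_ae=0.1,
    var_rep=0.05,
    var_block=0.05,
    var_e=1.0,
    missing_cell_rate=0.05,
    trait="GY_like",
    seed=2024,
)


def main() -> None:
    study = simulate_study(CONFIG)
    paths = write_study(study, OUT)
    n_plots = len(study.plot_records)
    n_cells = study.plot_records.frame.groupby(
        ["environment", "line"]
    ).ngroups
    print(f"simulated {CONFIG.n_lines} lines x {CONFIG.n_envs} environments")
    print(f"  {n_cells} observed line-environment cells, {n_plots} plots")
    print(f"  markers passing MAF >= {CONFIG.maf_min}: {study.genotypes.n_markers}")
    for k, v in paths.items():
        print(f"  wrote {k}: {v}")


if __name__ == "__main__":
    main()
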