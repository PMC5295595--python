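#!/usr/bin/env python
"""Build the relationship kernels: pedigree A and VanRaden G.

Applies the 5% MAF filter and marker-mean imputation, forms the genomic
relationship matrix, tabulates the pedigree numerator relationship matrix,
and writes both as labelled kernel files.
"""

from pathlib import Path

import numpy as np

from gxepred import (
    impute_mean,
    maf_filter,
    pedigree_a,
    read_genotypes,
    read_pedigree,
    vanraden_g,
    write_kernel,
)

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    geno = read_genotypes(ROOT / "study" / "genotypes.csv")
    ped = read_pedigree(ROOT / "study" / "pedigree.csv")

    filtered = maf_filter(geno, 0.05)
    g = vanraden_g(impute_mean(filtered))
    a = pedigree_a(ped)
    write_kernel(ROOT / "kernel_G.csv", g)
    write_kernel(ROOT / "kernel_A.csv", a)

    off_g = g.matrix[~np.eye(g.n, dtype=bool)]
    off_a = a.matrix[~np.eye(a.n, dtype=bool)]
    print(f"markers: {geno.n_markers} input, {filtered.n_markers} after MAF filter")
    print(f"G: {g.n}x{g.n}, mean diagonal {np.diag(g.matrix).mean():.3f}, "
          f"off-diagonal range [{off_g.min():.3f}, {off_g.max():.3f}]")
    print(f"A: {a.n}x{a.n}, mean diagonal {np.diag(a.matrix).mean():.3f}, "
          f"off-diagonal range [{off_a.min():.3f}, {off_a.max():.3f}]")
    corr = np.corrcoef(off_g, off_a)[0, 1]
    print(f"correlation of off-diagonal G vs A entries: {corr:.3f}")


if __name__ == "__main__":
    main()
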