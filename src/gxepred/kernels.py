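"""Relationship-kernel construction.

Builds every covariance structure the reaction-norm models need:

* marker QC (minor-allele-frequency filter, mean imputation),
* the VanRaden genomic relationship matrix G = X X' / (2 Σ p_l (1 - p_l))
  with marker columns centered at twice the allele frequency,
* the pedigree numerator relationship matrix A by the recursive tabular
  method with inbreeding (a_ii = 1 + F_i, F_i = a_{sire,dam} / 2),
* cell-level expansions Z K Z' over (line, environment) cells and the
  Hadamard interaction kernels (Z K Z') ∘ (Z_E Z_E') that are zero whenever
  two cells sit in different environments.

Cell ordering is environment-major, line-minor, both in input order; all
cell-level structures built from one :class:`IncidenceMap` therefore align.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DataError, KernelNotPSDError, NumericalError
from .io import GenotypeMatrix, PedigreeTable

PSD_TOL = 1e-8

__all__ = [
    "RelationshipKernel",
    "IncidenceMap",
    "maf_filter",
    "impute_mean",
    "vanraden_g",
    "pedigree_a",
    "main_expansion",
    "interaction_kernel",
]


@dataclass
class RelationshipKernel:
    """Symmetric PSD covariance matrix with ID labels.

    ``kind`` is one of ``A``, ``G``, ``main-expanded``, ``interaction`` (other
    strings are tolerated for ad-hoc kernels). ``ids`` label rows/columns:
    line names for line-level kernels, ``env||line`` strings for cell-level
    kernels.
    """

    ids: list[str]
    matrix: np.ndarray
    kind: str = "unknown"

    def __post_init__(self):
        self.ids = [str(x) for x in self.ids]
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.ids)
        if self.matrix.shape != (n, n):
            raise DataError(
                f"kernel matrix shape {self.matrix.shape} does not match "
                f"{n} ids"
            )
        if n and np.max(np.abs(self.matrix - self.matrix.T)) > 1e-10:
            raise DataError("kernel matrix is not symmetric (tol 1e-10)")
        if n and np.min(np.diag(self.matrix)) < -1e-12:
            raise DataError("kernel diagonal has negative entries")

    @property
    def n(self) -> int:
        return len(self.ids)

    def index_of(self, ids) -> np.ndarray:
        lookup = {x: i for i, x in enumerate(self.ids)}
        try:
            return np.array([lookup[str(x)] for x in ids], dtype=int)
        except KeyError as e:
            raise DataError(f"id {e.args[0]!r} not present in kernel") from None

    def validate_psd(self) -> "RelationshipKernel":
        """Clip eigenvalues in (-1e-8, 0) to zero; harder negatives are errors."""
        if not self.n:
            return self
        w = np.linalg.eigvalsh(self.matrix)
        lam_min = float(w[0])
        scale = max(1.0, float(w[-1]))
        if lam_min < -PSD_TOL * scale:
            raise KernelNotPSDError(lam_min)
        if lam_min < 0:
            w2, v = np.linalg.eigh(self.matrix)
            w2 = np.clip(w2, 0.0, None)
            self.matrix = (v * w2) @ v.T
            self.matrix = (self.matrix + self.matrix.T) / 2.0
        return self


@dataclass
class IncidenceMap:
    """Ordered (line, environment) cells with index maps into line/env lists.

    The canonical ordering is environment-major, line-minor, preserving the
    input order of both factors, so that every cell-level kernel built from
    the same map shares one alignment.
    """

    lines: list[str]
    envs: list[str]
    cells: list[tuple[str, str]]  # (line, environment)
    line_index: np.ndarray = field(init=False)
    env_index: np.ndarray = field(init=False)

    def __post_init__(self):
        self.lines = [str(x) for x in self.lines]
        self.envs = [str(x) for x in self.envs]
        self.cells = [(str(l), str(e)) for l, e in self.cells]
        if len(set(self.cells)) != len(self.cells):
            raise DataError("duplicate (line, environment) cell")
        li = {x: i for i, x in enumerate(self.lines)}
        ei = {x: i for i, x in enumerate(self.envs)}
        try:
            self.line_index = np.array([li[l] for l, _ in self.cells], dtype=int)
            self.env_index = np.array([ei[e] for _, e in self.cells], dtype=int)
        except KeyError as e:
            raise DataError(
                f"cell references unknown line/environment {e.args[0]!r}"
            ) from None

    @classmethod
    def from_cells(cls, cells, lines=None, envs=None) -> "IncidenceMap":
        """Build the canonical env-major map from an iterable of (line, env)."""
        cells = [(str(l), str(e)) for l, e in cells]
        if lines is None:
            lines = list(dict.fromkeys(l for l, _ in cells))
        if envs is None:
            envs = list(dict.fromkeys(e for _, e in cells))
        order_l = {str(x): i for i, x in enumerate(lines)}
        order_e = {str(x): i for i, x in enumerate(envs)}
        cells = sorted(cells, key=lambda c: (order_e[c[1]], order_l[c[0]]))
        return cls(lines=list(lines), envs=list(envs), cells=cells)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def cell_ids(self) -> list[str]:
        return [f"{e}||{l}" for l, e in self.cells]

    def subset(self, keep_mask) -> "IncidenceMap":
        keep = np.asarray(keep_mask, dtype=bool)
        return IncidenceMap(
            lines=self.lines,
            envs=self.envs,
            cells=[c for c, k in zip(self.cells, keep) if k],
        )


# ---------------------------------------------------------------------------
# marker QC
# ---------------------------------------------------------------------------


def maf_filter(genotypes: GenotypeMatrix, min_maf: float) -> GenotypeMatrix:
    """Drop markers whose minor-allele frequency is below ``min_maf``.

    Frequencies are computed on non-missing dosages of the analyzed line set;
    marker order is preserved. Raises if every marker is removed.
    """
    if not 0.0 <= min_maf <= 0.5:
        raise DataError(f"min_maf must be in [0, 0.5], got {min_maf}")
    p = genotypes.allele_frequencies()
    maf = np.minimum(p, 1.0 - p)
    keep = np.where(np.isfinite(maf) & (maf >= min_maf))[0]
    if keep.size == 0:
        raise DataError(
            f"MAF filter at {min_maf} removed all {genotypes.n_markers} markers"
        )
    return GenotypeMatrix(
        genotypes.line_ids,
        [genotypes.marker_ids[j] for j in keep],
        genotypes.dosages[:, keep],
    )


def impute_mean(genotypes: GenotypeMatrix) -> GenotypeMatrix:
    """Replace missing dosages by the marker mean (fractional values allowed)."""
    d = genotypes.dosages.copy()
    n_obs = np.sum(np.isfinite(d), axis=0)
    if (n_obs == 0).any():
        j = int(np.argmin(n_obs))
        raise DataError(
            f"marker {genotypes.marker_ids[j]!r} has no observed dosages"
        )
    with np.errstate(invalid="ignore"):
        means = np.nanmean(d, axis=0)
    idx = np.where(~np.isfinite(d))
    d[idx] = means[idx[1]]
    return GenotypeMatrix(genotypes.line_ids, genotypes.marker_ids, d)


# ---------------------------------------------------------------------------
# line-level kernels
# ---------------------------------------------------------------------------


def vanraden_g(genotypes: GenotypeMatrix) -> RelationshipKernel:
    """Genomic relationship matrix, method-1 convention.

    Columns are centered at 2 p_l and the cross-product is scaled by the
    single global divisor 2 Σ_l p_l (1 - p_l). Allele frequencies come from
    the analyzed lines themselves. An option for per-marker standardization
    is deliberately not the default; see :func:`vanraden_g_standardized`.
    """
    d = genotypes.dosages
    if not np.isfinite(d).all():
        raise DataError("vanraden_g requires no missing dosages (impute first)")
    p = d.mean(axis=0) / 2.0
    denom = 2.0 * float(np.sum(p * (1.0 - p)))
    if denom <= 0.0:
        raise DataError("all markers monomorphic: VanRaden denominator is zero")
    x = d - 2.0 * p
    g = (x @ x.T) / denom
    g = (g + g.T) / 2.0
    return RelationshipKernel(list(genotypes.line_ids), g, kind="G").validate_psd()


def vanraden_g_standardized(genotypes: GenotypeMatrix) -> RelationshipKernel:
    """Variant with per-marker standardization: G = W W' / p, w_l ~ unit variance.

    Agrees with the method-1 kernel in expectation under Hardy-Weinberg
    proportions; offered for sensitivity analyses.
    """
    d = genotypes.dosages
    if not np.isfinite(d).all():
        raise DataError("requires no missing dosages (impute first)")
    p = d.mean(axis=0) / 2.0
    sd = np.sqrt(2.0 * p * (1.0 - p))
    ok = sd > 0
    if not ok.any():
        raise DataError("all markers monomorphic")
    w = (d[:, ok] - 2.0 * p[ok]) / sd[ok]
    g = (w @ w.T) / int(ok.sum())
    g = (g + g.T) / 2.0
    return RelationshipKernel(list(genotypes.line_ids), g, kind="G").validate_psd()


def pedigree_a(pedigree: PedigreeTable) -> RelationshipKernel:
    """Numerator relationship matrix by the recursive tabular method.

    Individuals are processed in topological order (parents first); the
    result is relabelled back to the pedigree's input order. Diagonals are
    1 + F with F the inbreeding coefficient a_{sire,dam}/2.
    """
    order = pedigree.topological_order()
    pos = {ind: i for i, ind in enumerate(order)}
    parents = pedigree.parents_of()
    n = len(order)
    a = np.zeros((n, n))
    for i, ind in enumerate(order):
        s, d = parents[ind]
        si = pos[s] if s is not None else None
        di = pos[d] if d is not None else None
        f = a[si, di] / 2.0 if (si is not None and di is not None) else 0.0
        a[i, i] = 1.0 + f
        # relationship to all previously-tabulated individuals
        if si is not None or di is not None:
            row = np.zeros(i)
            if si is not None:
                row += a[si, :i]
            if di is not None:
                row += a[di, :i]
            row /= 2.0
            a[i, :i] = row
            a[:i, i] = row
    back = [pos[ind] for ind in pedigree.individuals]
    a = a[np.ix_(back, back)]
    return RelationshipKernel(list(pedigree.individuals), a, kind="A").validate_psd()


# ---------------------------------------------------------------------------
# cell-level kernels
# ---------------------------------------------------------------------------


def main_expansion(K: RelationshipKernel, cells: IncidenceMap) -> RelationshipKernel:
    """Expand a line-level kernel to cells: (Z K Z')_{cc'} = K(line(c), line(c'))."""
    rows = K.index_of([l for l, _ in cells.cells])
    m = K.matrix[np.ix_(rows, rows)]
    return RelationshipKernel(cells.cell_ids(), m, kind="main-expanded")


def interaction_kernel(
    K: RelationshipKernel, cells: IncidenceMap
) -> RelationshipKernel:
    """Hadamard interaction kernel (Z K Z') ∘ (Z_E Z_E').

    Entry (c, c') equals K(line(c), line(c')) when the two cells share an
    environment and is zero otherwise, giving the block-diagonal covariance
    of the kernel-structured G×E effect.
    """
    expanded = main_expansion(K, cells).matrix
    same_env = cells.env_index[:, None] == cells.env_index[None, :]
    m = np.where(same_env, expanded, 0.0)
    return RelationshipKernel(cells.cell_ids(), m, kind="interaction")


def psd_factor(matrix: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    """Return B with B B' = matrix for a PSD matrix (eigen square root).

    Eigenvalues below ``tol`` times the largest are dropped. Used for drawing
    correlated effects in the simulator.
    """
    w, v = np.linalg.eigh((matrix + matrix.T) / 2.0)
    scale = max(float(w[-1]), 1.0) if w.size else 1.0
    if w.size and float(w[0]) < -PSD_TOL * scale:
        raise KernelNotPSDError(float(w[0]))
    keep = w > tol * scale
    if not keep.any():
        raise NumericalError("matrix has no positive eigenvalues")
    return v[:, keep] * np.sqrt(w[keep])
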