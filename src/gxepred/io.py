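"""Typed containers and delimited-text I/O for every table the pipeline touches.

Canonical dialect is comma-separated with a header row; tab-separated input is
accepted (the delimiter is sniffed from the header line). Missing genotype
dosages are written as ``NA`` and read from ``{"NA", ""}``. Unknown pedigree
parents use the sentinel ``"0"``.

All joins between tables are by line/marker identifier, never by position.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError, PedigreeCycleError

UNKNOWN_PARENT = "0"
MISSING_TOKENS = {"NA", ""}

__all__ = [
    "GenotypeMatrix",
    "PedigreeTable",
    "PlotRecordTable",
    "LineEnvTable",
    "read_genotypes",
    "write_genotypes",
    "read_pedigree",
    "write_pedigree",
    "read_plot_records",
    "write_plot_records",
    "read_line_env",
    "write_line_env",
    "read_kernel",
    "write_kernel",
]


def _sniff_sep(path: Path) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if header.count("\t") > header.count(",") else ","


def _check_unique(values, what: str) -> None:
    seen = pd.Index(values)
    if seen.has_duplicates:
        dup = seen[seen.duplicated()][0]
        raise DataError(f"duplicate {what}: {dup!r}")


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class GenotypeMatrix:
    """Lines × markers dosage matrix with values in {0, 1, 2, NaN}.

    ``dosages`` is a float array so that NaN can encode missing calls; after
    mean imputation fractional dosages are also allowed (``validate`` is only
    enforced on raw matrices).
    """

    line_ids: list[str]
    marker_ids: list[str]
    dosages: np.ndarray  # (n_lines, n_markers) float

    def __post_init__(self):
        self.line_ids = [str(x) for x in self.line_ids]
        self.marker_ids = [str(x) for x in self.marker_ids]
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.line_ids), len(self.marker_ids)):
            raise DataError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.line_ids)} lines x {len(self.marker_ids)} markers"
            )
        _check_unique(self.line_ids, "line ID")
        _check_unique(self.marker_ids, "marker ID")

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    def validate_raw(self) -> "GenotypeMatrix":
        """Check that all non-missing dosages are in {0, 1, 2}."""
        d = self.dosages
        bad = np.isfinite(d) & ~np.isin(d, (0.0, 1.0, 2.0))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise DataError(
                f"invalid dosage {d[i, j]!r} for line {self.line_ids[i]!r}, "
                f"marker {self.marker_ids[j]!r}: allowed values are 0/1/2/NA"
            )
        return self

    def allele_frequencies(self) -> np.ndarray:
        """Per-marker frequency of the counted allele from non-missing calls."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0


@dataclass
class PedigreeTable:
    """Rows of (individual, sire, dam); unknown parents coded ``"0"``.

    Construction validates that every named parent is itself listed (or
    unknown) and that the pedigree is acyclic; a topological order is cached.
    """

    individuals: list[str]
    sires: list[str]
    dams: list[str]
    _topo_order: list[int] = field(init=False, repr=False)

    def __post_init__(self):
        self.individuals = [str(x) for x in self.individuals]
        self.sires = [str(x) for x in self.sires]
        self.dams = [str(x) for x in self.dams]
        if not (len(self.individuals) == len(self.sires) == len(self.dams)):
            raise DataError("pedigree columns have unequal lengths")
        _check_unique(self.individuals, "pedigree individual")
        known = set(self.individuals)
        for p in self.sires + self.dams:
            if p != UNKNOWN_PARENT and p not in known:
                raise DataError(
                    f"parent {p!r} is not listed as an individual and is not "
                    f"the unknown sentinel {UNKNOWN_PARENT!r}"
                )
        self._topo_order = self._toposort()

    def __len__(self) -> int:
        return len(self.individuals)

    def _toposort(self) -> list[int]:
        index = {ind: i for i, ind in enumerate(self.individuals)}
        parents = [
            [index[p] for p in (s, d) if p != UNKNOWN_PARENT]
            for s, d in zip(self.sires, self.dams)
        ]
        state = [0] * len(self)  # 0 new, 1 on stack, 2 done
        order: list[int] = []

        for start in range(len(self)):
            if state[start] == 2:
                continue
            stack = [(start, iter(parents[start]))]
            state[start] = 1
            path = [start]
            while stack:
                node, it = stack[-1]
                advanced = False
                for par in it:
                    if state[par] == 1:
                        cut = path.index(par)
                        raise PedigreeCycleError(
                            [self.individuals[i] for i in path[cut:]] +
                            [self.individuals[par]]
                        )
                    if state[par] == 0:
                        state[par] = 1
                        path.append(par)
                        stack.append((par, iter(parents[par])))
                        advanced = True
                        break
                if not advanced:
                    state[node] = 2
                    order.append(node)
                    stack.pop()
                    path.pop()
        return order

    def topological_order(self) -> list[str]:
        """Individuals ordered so every parent precedes its offspring."""
        return [self.individuals[i] for i in self._topo_order]

    def parents_of(self) -> dict[str, tuple[str | None, str | None]]:
        none = lambda p: None if p == UNKNOWN_PARENT else p  # noqa: E731
        return {
            ind: (none(s), none(d))
            for ind, s, d in zip(self.individuals, self.sires, self.dams)
        }


_PLOT_KEY = ["trait", "environment", "replicate", "block", "line"]


@dataclass
class PlotRecordTable:
    """Plot-level phenotype records: one row per (trait, env, rep, block, line)."""

    frame: pd.DataFrame  # columns: trait, environment, replicate, block, line, value

    def __post_init__(self):
        df = self.frame
        missing = [c for c in _PLOT_KEY + ["value"] if c not in df.columns]
        if missing:
            raise DataError(f"plot record table missing columns: {missing}")
        df = df.copy()
        for c in _PLOT_KEY:
            df[c] = df[c].astype(str)
        df["value"] = pd.to_numeric(df["value"], errors="raise")
        if not np.isfinite(df["value"].dropna()).all():
            raise DataError("plot record values must be finite where present")
        if df.duplicated(_PLOT_KEY).any():
            row = df[df.duplicated(_PLOT_KEY)].iloc[0]
            raise DataError(
                "duplicate plot record key: "
                + ", ".join(f"{k}={row[k]!r}" for k in _PLOT_KEY)
            )
        self.frame = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)


@dataclass
class LineEnvTable:
    """Adjusted per-line, per-environment phenotypes (one value per cell)."""

    frame: pd.DataFrame  # columns: trait, environment, line, value

    def __post_init__(self):
        df = self.frame
        key = ["trait", "environment", "line"]
        missing = [c for c in key + ["value"] if c not in df.columns]
        if missing:
            raise DataError(f"line-env table missing columns: {missing}")
        df = df.copy()
        for c in key:
            df[c] = df[c].astype(str)
        df["value"] = pd.to_numeric(df["value"], errors="raise")
        if df.duplicated(key).any():
            row = df[df.duplicated(key)].iloc[0]
            raise DataError(
                "duplicate line-env key: "
                + ", ".join(f"{k}={row[k]!r}" for k in key)
            )
        self.frame = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def read_genotypes(path, dialect: str = "csv-wide") -> GenotypeMatrix:
    """Read a lines × markers dosage table.

    ``csv-wide``: delimited header of marker IDs (first column holds the line
    ID), one row per line. ``plink-raw``: same layout but whitespace-separated.
    Tokens ``NA`` and the empty string are read as missing.
    """
    path = Path(path)
    if dialect not in ("csv-wide", "plink-raw"):
        raise DataError(f"unknown genotype dialect {dialect!r}")
    sep = _sniff_sep(path) if dialect == "csv-wide" else r"\s+"
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False, engine="python")
    if df.shape[1] < 2:
        raise DataError(f"{path}: expected line ID column plus >=1 marker column")
    line_ids = df.iloc[:, 0].tolist()
    marker_ids = list(df.columns[1:])
    raw = df.iloc[:, 1:].to_numpy()
    dosages = np.empty(raw.shape, dtype=float)
    for j in range(raw.shape[1]):
        col = raw[:, j]
        for i, tok in enumerate(col):
            tok = tok.strip()
            if tok in MISSING_TOKENS:
                dosages[i, j] = np.nan
            else:
                try:
                    dosages[i, j] = float(tok)
                except ValueError:
                    raise DataError(
                        f"{path}: unparseable dosage {tok!r} at line "
                        f"{line_ids[i]!r}, marker {marker_ids[j]!r}"
                    ) from None
    return GenotypeMatrix(line_ids, marker_ids, dosages).validate_raw()


def write_genotypes(path, genotypes: GenotypeMatrix, sep: str = ",") -> None:
    df = pd.DataFrame(
        genotypes.dosages, index=genotypes.line_ids, columns=genotypes.marker_ids
    )
    # integral raw dosages are written without a decimal point
    def fmt(v):
        if np.isnan(v):
            return "NA"
        return str(int(v)) if float(v).is_integer() else repr(float(v))

    out = df.map(fmt)
    out.index.name = "line"
    out.to_csv(path, sep=sep)


def read_pedigree(path) -> PedigreeTable:
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path), dtype=str, keep_default_na=False)
    cols = {c.lower(): c for c in df.columns}
    for want in ("individual", "sire", "dam"):
        if want not in cols:
            raise DataError(f"{path}: pedigree needs columns individual,sire,dam")
    return PedigreeTable(
        df[cols["individual"]].tolist(),
        df[cols["sire"]].tolist(),
        df[cols["dam"]].tolist(),
    )


def write_pedigree(path, pedigree: PedigreeTable, sep: str = ",") -> None:
    pd.DataFrame(
        {
            "individual": pedigree.individuals,
            "sire": pedigree.sires,
            "dam": pedigree.dams,
        }
    ).to_csv(path, sep=sep, index=False)


def read_plot_records(path) -> PlotRecordTable:
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path))
    return PlotRecordTable(df)


def write_plot_records(path, records: PlotRecordTable, sep: str = ",") -> None:
    records.frame.to_csv(path, sep=sep, index=False)


def read_line_env(path) -> LineEnvTable:
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path))
    return LineEnvTable(df)


def write_line_env(path, table: LineEnvTable, sep: str = ",") -> None:
    table.frame.to_csv(path, sep=sep, index=False)


def write_kernel(path, kernel) -> None:
    """Write a labelled relationship kernel.

    ``.npz`` paths get a binary container (exact); anything else gets CSV with
    17-significant-digit floats, which round-trips IEEE doubles losslessly.
    """
    path = Path(path)
    if path.suffix == ".npz":
        np.savez_compressed(
            path,
            ids=np.asarray(kernel.ids, dtype=object),
            matrix=kernel.matrix,
            kind=np.asarray(kernel.kind),
        )
        return
    df = pd.DataFrame(kernel.matrix, index=kernel.ids, columns=kernel.ids)
    df.index.name = f"kind:{kernel.kind}"
    df.to_csv(path, float_format="%.17g")


def read_kernel(path):
    from .kernels import RelationshipKernel

    path = Path(path)
    if path.suffix == ".npz":
        with np.load(path, allow_pickle=True) as z:
            ids = [str(x) for x in z["ids"]]
            matrix = z["matrix"]
            kind = str(z["kind"])
    else:
        df = pd.read_csv(path, index_col=0)
        kind = "unknown"
        if df.index.name and df.index.name.startswith("kind:"):
            kind = df.index.name[len("kind:"):]
        ids = [str(x) for x in df.columns]
        matrix = df.to_numpy(dtype=float)
    asym = float(np.max(np.abs(matrix - matrix.T))) if matrix.size else 0.0
    if asym > 1e-8:
        raise DataError(
            f"{path}: kernel asymmetric (max |K - K'| = {asym:.3e} > 1e-8)"
        )
    matrix = (matrix + matrix.T) / 2.0
    return RelationshipKernel(ids=ids, matrix=matrix, kind=kind)


def write_json(path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
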