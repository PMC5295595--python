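"""Synthetic multi-environment trial generator.

Emulates the structure of an elite inbred wheat panel evaluated in a series
of international yield trials: a few hundred inbred lines descended from a
shallow biparental crossing pedigree, biallelic markers above a minor-allele
frequency floor, and plot-level phenotypes generated from the reaction-norm
decomposition

    y = mu + E + L + g + a + Eg + Ea + rep + block + e

with a genomic main effect g ~ N(0, G σg²), a pedigree main effect
a ~ N(0, A σa²), and kernel-structured interactions Eg, Ea whose covariance
is the Hadamard product of the expanded line kernel with the same-environment
indicator (block-diagonal by environment). G and A are rescaled to unit mean
diagonal inside the generator so each configured variance is the realized
per-line variance of its effect.

Ground truth (all variance components plus the cell-level genetic value of
every line in every environment) is recorded so parameter-recovery and
prediction experiments can score against it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError
from .io import (
    GenotypeMatrix,
    LineEnvTable,
    PedigreeTable,
    PlotRecordTable,
    write_genotypes,
    write_json,
    write_pedigree,
    write_plot_records,
)
from .kernels import pedigree_a, psd_factor, vanraden_g

__all__ = [
    "SimulationConfig",
    "SimulatedStudy",
    "simulate_population",
    "simulate_phenotypes",
    "simulate_study",
    "wami_like_preset",
    "gene_drop_relationship",
]

_VARIANCE_FIELDS = (
    "var_env",
    "var_line",
    "var_g",
    "var_a",
    "var_ge",
    "var_ae",
    "var_rep",
    "var_block",
    "var_e",
)


@dataclass
class SimulationConfig:
    """Generative parameters for one synthetic study.

    Variances are on the trait scale: ``var_env`` (σE²) environment main
    effects, ``var_line`` (σL²) non-genetic line effects, ``var_g``/``var_a``
    genomic and pedigree main effects, ``var_ge``/``var_ae`` the matching
    kernel-structured interactions, ``var_rep``/``var_block`` trial design
    effects, ``var_e`` plot residual.
    """

    n_lines: int = 200
    n_markers: int = 1000
    maf_min: float = 0.05
    n_founders: int = 40
    n_generations: int = 2
    n_envs: int = 8
    n_reps: int = 2
    blocks_per_rep: int = 5
    mu: float = 4.0
    var_env: float = 1.0
    var_line: float = 0.05
    var_g: float = 0.3
    var_a: float = 0.1
    var_ge: float = 0.3
    var_ae: float = 0.1
    var_rep: float = 0.05
    var_block: float = 0.05
    var_e: float = 1.0
    missing_cell_rate: float = 0.05
    trait: str = "sim_trait"
    seed: int = 1

    def validate(self) -> "SimulationConfig":
        if self.n_lines < self.n_founders:
            raise ConfigError(
                f"n_lines ({self.n_lines}) < n_founders ({self.n_founders})"
            )
        if self.n_lines > self.n_founders and self.n_generations < 1:
            raise ConfigError(
                "descendants requested (n_lines > n_founders) but "
                "n_generations < 1"
            )
        if self.n_founders < 1 or self.n_markers < 1:
            raise ConfigError("n_founders and n_markers must be >= 1")
        if self.n_envs < 2:
            raise ConfigError("n_envs must be >= 2")
        if self.n_reps < 1 or self.blocks_per_rep < 1:
            raise ConfigError("n_reps and blocks_per_rep must be >= 1")
        if not 0.0 <= self.maf_min <= 0.5:
            raise ConfigError("maf_min must be in [0, 0.5]")
        if not 0.0 <= self.missing_cell_rate < 1.0:
            raise ConfigError("missing_cell_rate must be in [0, 1)")
        for name in _VARIANCE_FIELDS:
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        return self

    def variance_components(self) -> dict[str, float]:
        return {name: float(getattr(self, name)) for name in _VARIANCE_FIELDS}


@dataclass
class SimulatedStudy:
    """A complete synthetic study plus its generative ground truth.

    ``truth`` holds the configured variance components, the per-line main
    effects, and the per-cell (line × environment) total genetic value
    g + a + Eg + Ea used to score predictions.
    """

    genotypes: GenotypeMatrix
    pedigree: PedigreeTable
    plot_records: PlotRecordTable
    truth: dict
    config: SimulationConfig = field(repr=False, default=None)

    def genetic_values(self) -> LineEnvTable:
        df = self.truth["genetic_values"].copy()
        df.insert(0, "trait", self.config.trait if self.config else "sim_trait")
        return LineEnvTable(df)


def wami_like_preset() -> SimulationConfig:
    """Configuration shaped like an elite spring-wheat association panel.

    287 lines in 18 environments with 2 replicates and a 5% MAF floor, with
    variance components chosen so across-environment broad-sense heritability
    on an entry-mean basis is about 0.4: line-variance total 0.055 against a
    G×E total of 1.0 and plot residual 1.0 gives
    0.055 / (0.055 + 1.0/18 + 1.0/36) ≈ 0.40.
    """
    return SimulationConfig(
        n_lines=287,
        n_markers=15000,
        maf_min=0.05,
        n_founders=60,
        n_generations=3,
        n_envs=18,
        n_reps=2,
        blocks_per_rep=10,
        mu=4.0,
        var_env=2.0,
        var_line=0.01,
        var_g=0.03,
        var_a=0.015,
        var_ge=0.6,
        var_ae=0.4,
        var_rep=0.05,
        var_block=0.05,
        var_e=1.0,
        missing_cell_rate=0.05,
        trait="GY_like",
        seed=2010,
    )


# ---------------------------------------------------------------------------
# population
# ---------------------------------------------------------------------------


def _build_pedigree_structure(config: SimulationConfig, rng: np.random.Generator):
    """Names and parent indices: founders first, then crosses by generation."""
    names = [f"L{i + 1:04d}" for i in range(config.n_lines)]
    parent_idx: list[tuple[int | None, int | None]] = [
        (None, None)
    ] * config.n_founders
    n_desc = config.n_lines - config.n_founders
    if n_desc:
        per_gen = [n_desc // config.n_generations] * config.n_generations
        for i in range(n_desc % config.n_generations):
            per_gen[i] += 1
        gen_members = [list(range(config.n_founders))]
        nxt = config.n_founders
        for size in per_gen:
            pool = gen_members[-1] if len(gen_members[-1]) >= 2 else list(
                range(nxt)
            )
            members = []
            for _ in range(size):
                s, d = rng.choice(pool, size=2, replace=False)
                parent_idx.append((int(s), int(d)))
                members.append(nxt)
                nxt += 1
            gen_members.append(members)
    return names, parent_idx


def _drop_markers(
    parent_idx, founder_freqs: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Propagate dosages through the pedigree, one column per marker.

    Founders are fully inbred draws (dosage = 2·Bernoulli(p)). Each
    descendant samples one gamete from each parent and then doubles one of
    the two at every marker — the single-seed-descent shortcut that keeps
    lines inbred without simulating selfing generations.
    """
    n_ind = len(parent_idx)
    m = founder_freqs.size
    dos = np.empty((n_ind, m), dtype=np.int8)
    for i, (s, d) in enumerate(parent_idx):
        if s is None:
            dos[i] = 2 * (rng.random(m) < founder_freqs)
        else:
            gam_s = _gamete(dos[s], rng)
            gam_d = _gamete(dos[d], rng)
            keep_s = rng.random(m) < 0.5
            dos[i] = 2 * np.where(keep_s, gam_s, gam_d)
    return dos


def _gamete(dosage: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    gam = (dosage // 2).astype(np.int8)  # 0 -> 0, 2 -> 1
    het = dosage == 1
    if het.any():
        gam[het] = rng.integers(0, 2, size=int(het.sum()), dtype=np.int8)
    return gam


def simulate_population(
    config: SimulationConfig,
) -> tuple[GenotypeMatrix, PedigreeTable]:
    """Simulate marker dosages and a crossing pedigree for inbred lines.

    Founder allele frequencies are uniform on [maf_min, 1 - maf_min];
    markers whose realized minor-allele frequency falls below ``maf_min``
    after pedigree descent are regenerated until ``n_markers`` survive, so
    the returned panel is already past the MAF floor.
    """
    config.validate()
    ss = np.random.SeedSequence([int(config.seed), 101])
    rng_ped, rng_geno = (np.random.default_rng(s) for s in ss.spawn(2))

    names, parent_idx = _build_pedigree_structure(config, rng_ped)

    kept: list[np.ndarray] = []
    n_kept = 0
    for attempt in range(60):
        batch = config.n_markers if attempt == 0 else max(
            config.n_markers // 2, 50
        )
        freqs = rng_geno.uniform(config.maf_min, 1.0 - config.maf_min, size=batch)
        dos = _drop_markers(parent_idx, freqs, rng_geno)
        p = dos.mean(axis=0) / 2.0
        maf = np.minimum(p, 1.0 - p)
        ok = dos[:, maf >= config.maf_min]
        if ok.shape[1]:
            kept.append(ok)
            n_kept += ok.shape[1]
        if n_kept >= config.n_markers:
            break
    else:
        raise ConfigError(
            f"could not generate {config.n_markers} markers with realized "
            f"MAF >= {config.maf_min} (population too small?)"
        )
    dosages = np.concatenate(kept, axis=1)[:, : config.n_markers].astype(float)
    marker_ids = [f"M{j + 1:05d}" for j in range(config.n_markers)]
    genotypes = GenotypeMatrix(names, marker_ids, dosages)

    sentinel = "0"
    sires = [sentinel if s is None else names[s] for s, _ in parent_idx]
    dams = [sentinel if d is None else names[d] for _, d in parent_idx]
    pedigree = PedigreeTable(names, sires, dams)
    return genotypes, pedigree


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------


def _unit_diag(matrix: np.ndarray) -> np.ndarray:
    scale = float(np.mean(np.diag(matrix)))
    return matrix / scale if scale > 0 else matrix


def simulate_phenotypes(
    genotypes: GenotypeMatrix,
    pedigree: PedigreeTable,
    config: SimulationConfig,
) -> SimulatedStudy:
    """Draw effects and assemble plot-level records for every environment.

    A fraction ``missing_cell_rate`` of line × environment cells is removed
    completely at random (every line keeps at least one environment), which
    reproduces the unbalanced structure of real trial series.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 202]))
    lines = list(genotypes.line_ids)
    n_l = len(lines)
    envs = [f"E{i + 1:02d}" for i in range(config.n_envs)]
    n_e = config.n_envs

    # correlated line effects; kernels rescaled to unit mean diagonal so the
    # configured variances are realized per-line variances
    g_fac = a_fac = None
    if config.var_g > 0 or config.var_ge > 0:
        g_fac = psd_factor(_unit_diag(vanraden_g(genotypes).matrix))
    if config.var_a > 0 or config.var_ae > 0:
        a_fac = psd_factor(_unit_diag(pedigree_a(pedigree).matrix))

    env_eff = rng.normal(0.0, np.sqrt(config.var_env), size=n_e)
    line_eff = rng.normal(0.0, np.sqrt(config.var_line), size=n_l)
    g_eff = (
        g_fac @ rng.normal(0.0, np.sqrt(config.var_g), size=g_fac.shape[1])
        if (g_fac is not None and config.var_g > 0)
        else np.zeros(n_l)
    )
    a_eff = (
        a_fac @ rng.normal(0.0, np.sqrt(config.var_a), size=a_fac.shape[1])
        if (a_fac is not None and config.var_a > 0)
        else np.zeros(n_l)
    )
    # interaction covariance is block-diagonal by environment: independent
    # kernel-correlated draws per environment
    ge_eff = np.zeros((n_e, n_l))
    if g_fac is not None and config.var_ge > 0:
        for i in range(n_e):
            ge_eff[i] = g_fac @ rng.normal(
                0.0, np.sqrt(config.var_ge), size=g_fac.shape[1]
            )
    ae_eff = np.zeros((n_e, n_l))
    if a_fac is not None and config.var_ae > 0:
        for i in range(n_e):
            ae_eff[i] = a_fac @ rng.normal(
                0.0, np.sqrt(config.var_ae), size=a_fac.shape[1]
            )

    # MCAR cell masking; every line keeps at least one environment
    observed = rng.random((n_e, n_l)) >= config.missing_cell_rate
    for j in np.where(~observed.any(axis=0))[0]:
        observed[rng.integers(n_e), j] = True

    genetic = (
        g_eff[None, :] + a_eff[None, :] + ge_eff + ae_eff
    )  # (env, line) cell-level genetic value

    rows = []
    for i, env in enumerate(envs):
        present = np.where(observed[i])[0]
        n_reps = config.n_reps
        n_blocks = min(config.blocks_per_rep, max(1, present.size))
        rep_eff = rng.normal(0.0, np.sqrt(config.var_rep), size=n_reps)
        for k in range(n_reps):
            block_eff = rng.normal(0.0, np.sqrt(config.var_block), size=n_blocks)
            perm = rng.permutation(present)
            block_of = np.arange(perm.size) * n_blocks // perm.size
            resid = rng.normal(0.0, np.sqrt(config.var_e), size=perm.size)
            for pos, j in enumerate(perm):
                b = block_of[pos]
                value = (
                    config.mu
                    + env_eff[i]
                    + line_eff[j]
                    + genetic[i, j]
                    + rep_eff[k]
                    + block_eff[b]
                    + resid[pos]
                )
                rows.append(
                    (
                        config.trait,
                        env,
                        f"R{k + 1}",
                        f"B{b + 1}",
                        lines[j],
                        value,
                    )
                )
    frame = pd.DataFrame(
        rows,
        columns=["trait", "environment", "replicate", "block", "line", "value"],
    )
    records = PlotRecordTable(frame)

    gv = pd.DataFrame(
        [
            (envs[i], lines[j], genetic[i, j])
            for i in range(n_e)
            for j in range(n_l)
        ],
        columns=["environment", "line", "value"],
    )
    truth = {
        "variance_components": config.variance_components(),
        "mu": float(config.mu),
        "seed": int(config.seed),
        "environments": envs,
        "lines": lines,
        "env_effects": env_eff,
        "line_effects": line_eff,
        "g_effects": g_eff,
        "a_effects": a_eff,
        "ge_effects": ge_eff,
        "ae_effects": ae_eff,
        "observed_cells": observed,
        "genetic_values": gv,
    }
    return SimulatedStudy(genotypes, pedigree, records, truth, config)


def simulate_study(config: SimulationConfig) -> SimulatedStudy:
    """Convenience: population + phenotypes in one call."""
    genotypes, pedigree = simulate_population(config)
    return simulate_phenotypes(genotypes, pedigree, config)


def write_study(study: SimulatedStudy, outdir) -> dict[str, str]:
    """Write genotype/pedigree/plot tables plus a JSON truth file."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genotypes": str(outdir / "genotypes.csv"),
        "pedigree": str(outdir / "pedigree.csv"),
        "plot_records": str(outdir / "plot_records.csv"),
        "truth": str(outdir / "truth.json"),
    }
    write_genotypes(paths["genotypes"], study.genotypes)
    write_pedigree(paths["pedigree"], study.pedigree)
    write_plot_records(paths["plot_records"], study.plot_records)
    truth_json = {
        "variance_components": study.truth["variance_components"],
        "mu": study.truth["mu"],
        "seed": study.truth["seed"],
        "genetic_values": study.truth["genetic_values"].to_dict("records"),
    }
    write_json(paths["truth"], truth_json)
    return paths


# ---------------------------------------------------------------------------
# gene-dropping oracle
# ---------------------------------------------------------------------------


def gene_drop_relationship(
    pedigree: PedigreeTable, n_replicates: int = 100_000, seed: int = 0
) -> np.ndarray:
    """Monte-Carlo estimate of the additive relationship matrix.

    Drops unique founder alleles through the pedigree ``n_replicates`` times
    and estimates a_ij as twice the coefficient of kinship (the probability
    that alleles drawn at random from i and j are identical by descent).
    Individuals with an unknown parent receive fresh unrelated alleles on
    that side. This is an algorithmically independent check of the tabular
    A-matrix construction.
    """
    order = pedigree.topological_order()
    pos = {ind: i for i, ind in enumerate(order)}
    parents = pedigree.parents_of()
    n = len(order)
    rng = np.random.default_rng(seed)
    alleles = np.empty((n, 2, n_replicates), dtype=np.int32)
    next_label = 0
    for i, ind in enumerate(order):
        s, d = parents[ind]
        for slot, par in enumerate((s, d)):
            if par is None:
                alleles[i, slot] = next_label
                next_label += 1
            else:
                pick = rng.integers(0, 2, size=n_replicates)
                pi = pos[par]
                alleles[i, slot] = np.where(
                    pick == 0, alleles[pi, 0], alleles[pi, 1]
                )
    a = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            matches = sum(
                np.mean(alleles[i, u] == alleles[j, v])
                for u in (0, 1)
                for v in (0, 1)
            )
            a[i, j] = a[j, i] = matches / 2.0
    back = [pos[ind] for ind in pedigree.individuals]
    return a[np.ix_(back, back)]
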