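"""Hierarchical zero-inflated negative binomial (ZINB) data generator.

Counts are generated at three levels, mimicking how multi-individual
scRNA-seq data actually vary:

1. **Population level.** Each gene i carries mean parameters
   (mu_i, phi_i, pi_i, sigma_i) on transformed scales — log mean, log
   dispersion, logit zero-probability, and the log of the between-cell SD of
   log-means — plus a 4×4 covariance Sigma describing how individuals
   scatter around the gene's population values.
2. **Individual level.** For individual j, (mu_ij, phi_ij, pi_ij,
   log sigma_ij) ~ MVN((mu_i, phi_i, pi_i, sigma_i), Sigma); a continuous
   covariate z_j shifts the log-mean by cov_beta · z_j.
3. **Cell level.** Each cell draws a log-mean from N(mu_ij, sigma_ij²);
   dispersion and zero-probability are inherited from the individual.  The
   count is ZINB: zero with probability pi, otherwise negative binomial with
   mean m = exp(log-mean) and size phi, so that Var = m + m²/phi.

Differential signals are injected for a random half of the individuals (the
"cases"): mean-type genes shift mu_ij by ±log f, variance-type genes scale
sigma_ij by f^±1, and "both"-type genes get both shifts with one shared
sign.  f = 1 is the global null and injects nothing.

Randomness is split into independent child streams per stage (population,
individuals, design, DE selection, baseline counts, DE-block counts), and
baseline counts are always drawn under null parameters with affected
gene × case blocks regenerated from their own stream.  Consequence: two
datasets generated with the same seed but different fold changes differ
*only* in the DE genes' case-individual cells.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .data_model import CountMatrix, DesignSpec, write_counts
from .exceptions import ValidationError

__all__ = [
    "PopulationParams",
    "IndividualParams",
    "SimTruth",
    "SimulatedDataset",
    "default_population_params",
    "load_population_params",
    "sample_individual_params",
    "inject_de",
    "zinb_draw",
    "generate_counts",
    "generate_dataset",
    "write_dataset",
]

DE_TYPES = ("mean", "variance", "both")

# transformed-scale clipping bounds applied before exponentiation, to keep
# exp() finite and counts representable
LOG_MEAN_BOUNDS = (-12.0, 6.0)
LOG_DISP_BOUNDS = (-8.0, 8.0)


@dataclass
class PopulationParams:
    """Per-gene population parameters on transformed scales.

    ``mu``: log-scale mean of individual log-means; ``phi``: log dispersion;
    ``pi``: logit zero-inflation probability; ``sigma``: log of the
    between-cell SD of log-means.  ``cov``: shared 4×4 covariance of the
    individual-level draw in (mu, phi, pi, log sigma) order.  ``cov_beta``:
    regression coefficient of the continuous covariate on the log-mean.
    """

    mu: np.ndarray
    phi: np.ndarray
    pi: np.ndarray
    sigma: np.ndarray
    cov: np.ndarray
    cov_beta: float = 0.1

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float)
        self.phi = np.asarray(self.phi, dtype=float)
        self.pi = np.asarray(self.pi, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        self.cov = np.asarray(self.cov, dtype=float)
        m = self.mu.size
        if not (self.phi.size == self.pi.size == self.sigma.size == m):
            raise ValidationError("population parameter arrays differ in length")
        if self.cov.shape != (4, 4):
            raise ValidationError("cov must be 4×4")
        if not np.allclose(self.cov, self.cov.T):
            raise ValidationError("cov must be symmetric")
        eig = np.linalg.eigvalsh(self.cov)
        if eig.min() < -1e-10:
            raise ValidationError("cov must be positive semi-definite")

    @property
    def n_genes(self) -> int:
        return self.mu.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"mu": self.mu, "phi": self.phi, "pi": self.pi, "sigma": self.sigma}
        )


@dataclass
class IndividualParams:
    """Individual-level parameters, each array genes × individuals."""

    mu: np.ndarray
    phi: np.ndarray
    pi: np.ndarray
    log_sigma: np.ndarray

    def copy(self) -> "IndividualParams":
        return IndividualParams(
            self.mu.copy(), self.phi.copy(), self.pi.copy(), self.log_sigma.copy()
        )


@dataclass
class SimTruth:
    """Ground-truth DE labels and the simulated design."""

    table: pd.DataFrame  # gene_id, de_type, direction, fold
    case_mask: np.ndarray  # length N, True for cases
    covariate: np.ndarray  # length N, continuous z_j
    individual_ids: np.ndarray

    def de_genes(self, de_type: str | None = None) -> np.ndarray:
        t = self.table
        sel = t["de_type"] != "none" if de_type is None else t["de_type"] == de_type
        return t.loc[sel, "gene_id"].to_numpy()


@dataclass
class SimulatedDataset:
    counts: CountMatrix
    design: DesignSpec
    truth: SimTruth
    seed: int


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------

# Default sampling distributions for the per-gene population parameters.
# Chosen so the implied marginal gene sparsity falls mostly inside the
# 80%-sparsity filter used upstream; see docs/methods.md for the rationale.
_DEFAULTS = {
    "mu": (0.3, 1.0),        # log mean of cell log-means
    "phi": (0.0, 0.4),       # log dispersion
    "pi": (-2.0, 0.8),       # logit zero-inflation (≈ 0.12 median)
    "sigma": (np.log(0.35), 0.25),  # log between-cell SD of log-means
}
_DEFAULT_COV_DIAG = (0.15**2, 0.10**2, 0.30**2, 0.10**2)
_DEFAULT_COV_BETA = 0.1


def default_population_params(
    n_genes: int,
    seed: int | np.random.Generator = 0,
    cov_diag: tuple = _DEFAULT_COV_DIAG,
    cov_beta: float = _DEFAULT_COV_BETA,
) -> PopulationParams:
    """Sample per-gene population parameters from the documented defaults.

    Reproducible given ``seed``; every default can be bypassed by loading a
    parameter table with :func:`load_population_params`.
    """
    if n_genes < 1:
        raise ValidationError("need at least one gene")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    draws = {k: rng.normal(loc, sd, size=n_genes) for k, (loc, sd) in _DEFAULTS.items()}
    return PopulationParams(
        draws["mu"], draws["phi"], draws["pi"], draws["sigma"],
        np.diag(cov_diag), cov_beta,
    )


def load_population_params(
    path, cov_diag: tuple = _DEFAULT_COV_DIAG, cov_beta: float = _DEFAULT_COV_BETA
) -> PopulationParams:
    """Load per-gene (mu, phi, pi, sigma) from a TSV, bypassing the defaults."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ("mu", "phi", "pi", "sigma") if c not in df.columns]
    if missing:
        raise ValidationError(f"parameter TSV lacks columns {missing}")
    return PopulationParams(
        df["mu"].to_numpy(), df["phi"].to_numpy(), df["pi"].to_numpy(),
        df["sigma"].to_numpy(), np.diag(cov_diag), cov_beta,
    )


def sample_individual_params(
    pp: PopulationParams,
    n_individuals: int,
    covariate_z: np.ndarray,
    seed: int | np.random.Generator = 0,
) -> IndividualParams:
    """Draw (mu, phi, pi, log sigma) per gene × individual from the MVN."""
    if n_individuals < 4:
        raise ValidationError("need at least 4 individuals")
    if n_individuals % 2:
        raise ValidationError("need an even number of individuals for a 50/50 split")
    z = np.asarray(covariate_z, dtype=float)
    if z.size != n_individuals:
        raise ValidationError("covariate length must equal the number of individuals")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    m = pp.n_genes
    # PSD factor via eigendecomposition: exact for singular covariances
    w, v = np.linalg.eigh(pp.cov)
    if w.min() < -1e-10:
        raise ValidationError("covariance matrix is not PSD")
    chol = v @ np.diag(np.sqrt(np.clip(w, 0.0, None)))
    eps = rng.standard_normal((m, n_individuals, 4)) @ chol.T
    mu = pp.mu[:, None] + eps[:, :, 0] + pp.cov_beta * z[None, :]
    phi = pp.phi[:, None] + eps[:, :, 1]
    pi = pp.pi[:, None] + eps[:, :, 2]
    log_sigma = pp.sigma[:, None] + eps[:, :, 3]
    return IndividualParams(mu, phi, pi, log_sigma)


# ---------------------------------------------------------------------------
# Signal injection
# ---------------------------------------------------------------------------

def inject_de(
    params: IndividualParams,
    case_mask: np.ndarray,
    gene_ids: np.ndarray,
    fold: float = 1.5,
    density: float = 0.05,
    seed: int | np.random.Generator = 0,
) -> tuple[IndividualParams, SimTruth]:
    """Inject mean / variance / both differential signals into case columns.

    Three disjoint random gene sets of size ``density · M`` each are chosen;
    every DE gene is up- or down-regulated with equal probability (one shared
    sign per gene).  Mean-type genes shift the case log-mean by ±log(fold);
    variance-type genes scale the case between-cell SD by fold^±1; "both"
    applies the two with the same sign.  ``fold=1`` injects nothing and
    labels every gene "none" — the global null.
    """
    if fold < 1:
        raise ValidationError("fold must be ≥ 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    m = params.mu.shape[0]
    case_mask = np.asarray(case_mask, dtype=bool)
    table = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "de_type": "none",
            "direction": "",
            "fold": 1.0,
        }
    )
    out = params.copy()
    if fold == 1.0:
        return out, _finish_truth(table, case_mask)
    n_per_type = int(round(density * m))
    if 3 * n_per_type > m:
        raise ValidationError("3 · density · M exceeds the number of genes")
    if n_per_type == 0:
        import warnings

        warnings.warn("density · M < 1: no DE genes injected", stacklevel=2)
        return out, _finish_truth(table, case_mask)
    chosen = rng.choice(m, size=3 * n_per_type, replace=False)
    signs = rng.choice([1.0, -1.0], size=3 * n_per_type)
    log_f = np.log(fold)
    for t_idx, de_type in enumerate(DE_TYPES):
        idx = chosen[t_idx * n_per_type : (t_idx + 1) * n_per_type]
        s = signs[t_idx * n_per_type : (t_idx + 1) * n_per_type]
        if de_type in ("mean", "both"):
            out.mu[np.ix_(idx, np.flatnonzero(case_mask))] += (s * log_f)[:, None]
        if de_type in ("variance", "both"):
            out.log_sigma[np.ix_(idx, np.flatnonzero(case_mask))] += (s * log_f)[:, None]
        table.loc[idx, "de_type"] = de_type
        table.loc[idx, "direction"] = np.where(s > 0, "up", "down")
        table.loc[idx, "fold"] = fold
    return out, _finish_truth(table, case_mask)


def _finish_truth(table: pd.DataFrame, case_mask: np.ndarray) -> SimTruth:
    return SimTruth(table, case_mask, np.array([]), np.array([]))


# ---------------------------------------------------------------------------
# Count emission
# ---------------------------------------------------------------------------

def zinb_draw(
    rng: np.random.Generator,
    mean: np.ndarray,
    size: np.ndarray,
    pi_zero: np.ndarray,
) -> np.ndarray:
    """ZINB sampler: zero w.p. ``pi_zero``, else NB(mean, size).

    NB parameterization: mean m, size (dispersion) phi, variance m + m²/phi.
    The NB draw uses its gamma–Poisson mixture representation,
    NB(m, phi) = Poisson(m · G / phi) with G ~ Gamma(phi, 1), which is
    exactly equivalent and several times faster than the direct sampler.
    """
    shape = np.broadcast_shapes(np.shape(mean), np.shape(size), np.shape(pi_zero))
    g = rng.gamma(size, size=shape)
    nb = rng.poisson(g * (mean / size))
    zero = rng.random(shape) < pi_zero
    return np.where(zero, 0, nb)


def _emit_block(
    rng: np.random.Generator,
    params: IndividualParams,
    n_cell: int,
    size_factors: np.ndarray | None,
) -> np.ndarray:
    """Counts for a (genes × individuals) parameter block, n_cell cells each.

    Draw order is fixed (log-mean normals, NB, zero mask) so identical
    streams yield identical counts.
    """
    mu = params.mu[:, :, None]
    sigma = np.exp(params.log_sigma)[:, :, None]
    m_genes, n_ind = params.mu.shape
    log_mean = mu + sigma * rng.standard_normal((m_genes, n_ind, n_cell))
    if size_factors is not None:
        log_mean = log_mean + size_factors[None, :, :]
    log_mean = np.clip(log_mean, *LOG_MEAN_BOUNDS)
    phi = np.exp(np.clip(params.phi, *LOG_DISP_BOUNDS))[:, :, None]
    pi_zero = 1.0 / (1.0 + np.exp(-params.pi))[:, :, None]
    counts = zinb_draw(rng, np.exp(log_mean), phi, pi_zero)
    return counts.reshape(m_genes, n_ind * n_cell)


def generate_counts(
    params: IndividualParams,
    n_cell: int,
    size_factor_sd: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Emit a dense genes × (individuals · n_cell) count matrix.

    Cells of one individual occupy contiguous columns.  ``size_factor_sd``
    adds a per-cell log-normal depth factor to the log-mean (0 disables).
    """
    if n_cell < 1:
        raise ValidationError("need at least one cell per individual")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_ind = params.mu.shape[1]
    sf = None
    if size_factor_sd > 0:
        sf = rng.normal(0.0, size_factor_sd, size=(n_ind, n_cell))
    return _emit_block(rng, params, n_cell, sf)


def _individual_ids(n: int) -> np.ndarray:
    width = max(2, len(str(n)))
    return np.array([f"S{j + 1:0{width}d}" for j in range(n)], dtype=object)


def generate_dataset(
    n_genes: int = 1000,
    n_individuals: int = 24,
    n_cell: int = 375,
    fold: float = 1.0,
    density: float = 0.05,
    seed: int = 0,
    size_factor_sd: float = 0.0,
    pop_params: PopulationParams | None = None,
) -> SimulatedDataset:
    """End-to-end generation of one simulated multi-individual dataset.

    Returns counts (with individuals attached, canonical order), the design
    (Y = case/control indicator, Z = continuous covariate z) and the ground
    truth.  Bit-identical for a fixed seed.
    """
    root = np.random.SeedSequence(seed)
    ss = root.spawn(6)
    rng_pop, rng_ind, rng_design, rng_de, rng_base, rng_deblk = (
        np.random.default_rng(s) for s in ss
    )

    if pop_params is None:
        pop_params = default_population_params(n_genes, rng_pop)
    elif pop_params.n_genes != n_genes:
        raise ValidationError("pop_params gene count does not match n_genes")

    gene_ids = np.array([f"g{i + 1:05d}" for i in range(n_genes)], dtype=object)
    ind_ids = _individual_ids(n_individuals)

    z = rng_design.normal(0.0, 1.0, size=n_individuals)
    case_mask = np.zeros(n_individuals, dtype=bool)
    case_mask[rng_design.choice(n_individuals, n_individuals // 2, replace=False)] = True

    null_params = sample_individual_params(pop_params, n_individuals, z, rng_ind)
    de_params, truth = inject_de(
        null_params, case_mask, gene_ids, fold=fold, density=density, seed=rng_de
    )
    truth.case_mask = case_mask
    truth.covariate = z
    truth.individual_ids = ind_ids

    sf = None
    if size_factor_sd > 0:
        sf = rng_design.normal(0.0, size_factor_sd, size=(n_individuals, n_cell))

    counts = _emit_block(rng_base, null_params, n_cell, sf)

    de_idx = np.flatnonzero((truth.table["de_type"] != "none").to_numpy())
    case_idx = np.flatnonzero(case_mask)
    if de_idx.size and case_idx.size:
        sub = IndividualParams(
            de_params.mu[np.ix_(de_idx, case_idx)],
            de_params.phi[np.ix_(de_idx, case_idx)],
            de_params.pi[np.ix_(de_idx, case_idx)],
            de_params.log_sigma[np.ix_(de_idx, case_idx)],
        )
        sub_sf = sf[case_idx] if sf is not None else None
        block = _emit_block(rng_deblk, sub, n_cell, sub_sf)
        for a, j in enumerate(case_idx):
            counts[de_idx, j * n_cell : (j + 1) * n_cell] = block[
                :, a * n_cell : (a + 1) * n_cell
            ]

    cell_ids = np.array(
        [f"{ind}_c{c + 1:04d}" for ind in ind_ids for c in range(n_cell)],
        dtype=object,
    )
    labels = np.repeat(ind_ids, n_cell)
    cm = CountMatrix(
        sp.csr_matrix(counts.astype(np.int64)), gene_ids, cell_ids, labels
    )
    design = DesignSpec(
        Y=case_mask.astype(float)[:, None],
        Z=z[:, None],
        individual_ids=ind_ids,
        y_names=["group"],
        z_names=["z"],
    )
    return SimulatedDataset(cm, design, truth, seed)


def write_dataset(ds: SimulatedDataset, outdir) -> None:
    """Write a dataset in the formats the I/O layer reads back.

    Emits matrix.mtx, genes.txt, cells.txt, cell_meta.tsv,
    individual_meta.tsv and truth.tsv under ``outdir``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_counts(
        ds.counts, outdir / "matrix.mtx", outdir / "genes.txt", outdir / "cells.txt"
    )
    pd.DataFrame(
        {"cell_id": ds.counts.cell_ids, "individual": ds.counts.individual_of_cell}
    ).to_csv(outdir / "cell_meta.tsv", sep="\t", index=False)
    pd.DataFrame(
        {
            "individual": ds.design.individual_ids,
            "group": ds.design.Y[:, 0],
            "z": ds.design.Z[:, 0],
        }
    ).to_csv(outdir / "individual_meta.tsv", sep="\t", index=False, float_format="%.10g")
    ds.truth.table.to_csv(outdir / "truth.tsv", sep="\t", index=False)
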