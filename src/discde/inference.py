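"""Covariate-adjusted F statistics, omnibus max-F, and permutation inference.

For each gene i and feature k the transformed feature vector U_{i,k} (length
N, one value per individual) is regressed on the variables of interest Y and
covariates Z.  Association strength is the classical F statistic written with
projection (hat) matrices,

    F_{k,i} = [U' (H_{YZ} - H_Z) U / p] / [U' (I - H_{YZ}) U / df_res],

where H_{YZ} and H_Z project onto the column spans of (1, Z, Y) and (1, Z);
an intercept is always included and df_res = N - rank(1, Z, Y).

The omnibus statistic is F_O = max_k F_{k}.  Because the maximum of F
statistics has no convenient null distribution, significance comes from
permutation: one shared plan of B permutations of the individuals is applied
to the variable of interest (plain scheme), or to its residuals after
projecting out the covariates (Smith's procedure), and F_O is recomputed for
every gene under each permutation.  Sharing the plan across genes and
features is what allows the N×N projections to be built once per permutation
rather than once per gene, and is required by the pooled FDR estimate, which
compares each observed F_O against the combined permutation statistics of
all genes.
"""

from __future__ import annotations

import logging
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .data_model import CountMatrix, DesignSpec, normalize_tss
from .exceptions import ValidationError
from .features import extract_features, transform_features

logger = logging.getLogger(__name__)

__all__ = [
    "PermutationPlan",
    "DiscResult",
    "hat_matrix",
    "f_statistic",
    "omnibus_f",
    "make_permutation_plan",
    "permuted_response",
    "permutation_pvalues",
    "permutation_fdr",
    "run_disc",
]

_QF_RTOL = 1e-12  # quadratic forms below _QF_RTOL * ||u||^2 count as zero


# ---------------------------------------------------------------------------
# Linear-model building blocks
# ---------------------------------------------------------------------------

def hat_matrix(design: np.ndarray) -> np.ndarray:
    """Orthogonal projection onto the column space of ``design``.

    Rank-deficient designs are handled by projecting onto the actual column
    space (SVD-based orthonormal basis), so duplicated columns change
    nothing.  An empty design yields the zero matrix.
    """
    design = np.atleast_2d(np.asarray(design, dtype=float))
    n = design.shape[0]
    if design.size == 0 or design.shape[1] == 0:
        return np.zeros((n, n))
    u, s, _ = np.linalg.svd(design, full_matrices=False)
    tol = s.max(initial=0.0) * max(design.shape) * np.finfo(float).eps
    q = u[:, s > tol]
    return q @ q.T


def _design_with_intercept(Z: np.ndarray | None, n: int, include_intercept: bool) -> np.ndarray:
    cols = []
    if include_intercept:
        cols.append(np.ones((n, 1)))
    if Z is not None and np.asarray(Z).size:
        cols.append(np.atleast_2d(np.asarray(Z, dtype=float)).reshape(n, -1))
    if not cols:
        return np.empty((n, 0))
    return np.column_stack(cols)


def _f_from_quadratic_forms(
    num_qf: np.ndarray, den_qf: np.ndarray, ss: np.ndarray, p: int, df_res: int
) -> np.ndarray:
    """Assemble F values with the degenerate-case conventions.

    A constant feature vector (both quadratic forms ≈ 0) gives F = 0 — no
    evidence rather than NaN, keeping the omnibus max well defined.  A
    perfect fit (residual form ≈ 0 with signal in the numerator) gives +inf,
    which sorts above every finite statistic downstream.
    """
    tol = _QF_RTOL * (ss + 1.0)
    num = np.clip(num_qf, 0.0, None) / p
    den = np.clip(den_qf, 0.0, None) / max(df_res, 1)
    out = np.empty_like(num)
    degenerate = (num_qf < tol) & (den_qf < tol)
    perfect = (den_qf < tol) & ~degenerate
    ok = ~degenerate & ~perfect
    with np.errstate(divide="ignore", invalid="ignore"):
        out[ok] = num[ok] / den[ok]
    out[degenerate] = 0.0
    out[perfect] = np.inf
    return out


def f_statistic(
    u: np.ndarray,
    Y: np.ndarray,
    Z: np.ndarray | None = None,
    include_intercept: bool = True,
) -> float:
    """F statistic for the association of feature vector ``u`` with Y given Z.

    Equivalent to the classical nested-OLS F comparing the model with and
    without Y, computed via hat matrices.  Scale- and shift-invariant in
    ``u`` when an intercept is included.
    """
    u = np.asarray(u, dtype=float).ravel()
    n = u.size
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if Y.shape[0] != n:
        Y = Y.T
    p = Y.shape[1]
    base = _design_with_intercept(Z, n, include_intercept)
    full = np.column_stack([base, Y])
    r_base = np.linalg.matrix_rank(base) if base.size else 0
    r_full = np.linalg.matrix_rank(full)
    if r_full == r_base:
        bad = [
            k
            for k in range(p)
            if np.linalg.matrix_rank(np.column_stack([base, Y[:, k]])) == r_base
        ]
        raise ValidationError(
            f"variable(s) of interest collinear with intercept/covariates: "
            f"columns {bad}"
        )
    df_res = n - r_full
    if df_res < 1:
        raise ValidationError(f"no residual degrees of freedom (N={n}, rank={r_full})")
    h_base = hat_matrix(base)
    h_full = hat_matrix(full)
    num_qf = float(u @ (h_full - h_base) @ u)
    den_qf = float(u @ u - u @ h_full @ u)
    val = _f_from_quadratic_forms(
        np.array([num_qf]), np.array([den_qf]), np.array([float(u @ u)]), p, df_res
    )
    return float(val[0])


def omnibus_f(f_per_feature: np.ndarray) -> float:
    """Maximum of per-feature F statistics (+inf sentinels propagate)."""
    f = np.asarray(f_per_feature, dtype=float)
    if f.size == 0:
        raise ValidationError("omnibus over an empty feature set")
    return float(np.max(f))


# ---------------------------------------------------------------------------
# Permutation machinery
# ---------------------------------------------------------------------------

@dataclass
class PermutationPlan:
    """A shared set of B permutations of the N individuals.

    Rows are drawn uniformly from the permutation group with replacement
    (duplicates and the identity are allowed).  The same plan is applied to
    every gene and every feature — required by the pooled FDR estimate and
    the reason hat matrices are reused across genes.
    """

    perm_indices: np.ndarray  # B × N
    scheme: str
    seed: int

    @property
    def B(self) -> int:
        return self.perm_indices.shape[0]

    @property
    def N(self) -> int:
        return self.perm_indices.shape[1]


def make_permutation_plan(
    n_individuals: int, B: int = 999, scheme: str = "plain", seed: int = 0
) -> PermutationPlan:
    if B < 1:
        raise ValidationError("need at least one permutation")
    if n_individuals < 3:
        raise ValidationError("need at least 3 individuals to permute")
    if scheme not in ("plain", "smith"):
        raise ValidationError(f"unknown permutation scheme {scheme!r}")
    rng = np.random.default_rng(seed)
    perms = np.empty((B, n_individuals), dtype=np.intp)
    for b in range(B):
        perms[b] = rng.permutation(n_individuals)
    return PermutationPlan(perms, scheme, seed)


def _residualize(Y: np.ndarray, base: np.ndarray) -> np.ndarray:
    """Column-wise OLS residuals of Y on ``base``."""
    if base.shape[1] == 0:
        return Y.copy()
    coef, *_ = np.linalg.lstsq(base, Y, rcond=None)
    return Y - base @ coef


def permuted_response(
    Y: np.ndarray,
    Z: np.ndarray | None,
    plan_row: np.ndarray,
    scheme: str = "plain",
    include_intercept: bool = True,
) -> np.ndarray:
    """The permuted variable of interest for one plan row.

    ``plain`` reorders the rows of Y.  ``smith`` (Smith's procedure, a
    residual-permutation scheme for nuisance covariates) residualizes Y on
    (1, Z) column-wise, permutes the residual rows, and returns the permuted
    residuals as the variable of interest; Z stays in both projections when
    the F statistic is computed.  With an empty Z, smith degrades to
    permuting the centered Y.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    n = len(plan_row)
    if Y.shape[0] != n:
        Y = Y.T
    if scheme == "plain":
        return Y[plan_row]
    if scheme != "smith":
        raise ValidationError(f"unknown permutation scheme {scheme!r}")
    base = _design_with_intercept(Z, n, include_intercept)
    if Z is None or np.asarray(Z).size == 0:
        logger.info("smith scheme without covariates: permuting centered Y")
    resid = _residualize(Y, base)
    return resid[plan_row]


def permutation_pvalues(
    f_obs: np.ndarray, f_perm: np.ndarray, add_one: bool = False
) -> np.ndarray:
    """Per-gene permutation p-values: p_i = Σ_b I(F_b ≥ F_obs) / (B + 1).

    The numerator has no +1 by default, so p = 0 is attainable; set
    ``add_one`` for the conservative (1 + Σ)/(B + 1) convention.
    """
    f_obs = np.asarray(f_obs, dtype=float)
    f_perm = np.atleast_2d(np.asarray(f_perm, dtype=float))
    if f_perm.shape[0] != f_obs.size:
        raise ValidationError("observed and permuted statistics do not align")
    B = f_perm.shape[1]
    counts = (f_perm >= _tie_threshold(f_obs)[:, None]).sum(axis=1)
    return (counts + (1 if add_one else 0)) / (B + 1)


def _tie_threshold(f_obs: np.ndarray) -> np.ndarray:
    """Observed statistics lowered by a relative epsilon.

    Permuted designs can reproduce the observed one exactly (e.g. a binary
    group relabelling that recreates the same partition); the two F values
    are then mathematically equal but may differ in the last bits.  The ``≥``
    comparisons treat such numerical ties as ties.
    """
    with np.errstate(invalid="ignore"):
        out = f_obs - 1e-9 * (1.0 + np.abs(f_obs))
    return np.where(np.isinf(f_obs), f_obs, out)


def permutation_fdr(
    f_obs: np.ndarray,
    f_perm: np.ndarray,
    cap: bool = True,
) -> np.ndarray:
    """Pooled-permutation q-values, in the input gene order.

    With genes sorted by decreasing observed omnibus statistic F_(1) ≥ F_(2)
    ≥ …, the expected number of null genes reaching F_(i) is estimated from
    the permutation statistics of *all* genes pooled:

        q̃_(i) = max(#{(l, b): F^b_{O,l} ≥ F_(i)}, 0.5) / (i · B)

    (0.5 is a pseudo-count for when no pooled value reaches the threshold),
    followed by the monotonicity step q_(i) = min_{j ≥ i} q̃_(j).  Ties in
    the observed statistics are broken by stable gene order.  Reported
    q-values are capped at 1; pass ``cap=False`` for the raw estimate.
    """
    f_obs = np.asarray(f_obs, dtype=float)
    f_perm = np.atleast_2d(np.asarray(f_perm, dtype=float))
    m = f_obs.size
    if f_perm.shape[0] != m:
        raise ValidationError("observed and permuted statistics do not align")
    B = f_perm.shape[1]
    order = np.lexsort((np.arange(m), -f_obs))  # descending F, stable
    sorted_obs = f_obs[order]
    pooled = np.sort(f_perm.ravel())
    n_ge = pooled.size - np.searchsorted(
        pooled, _tie_threshold(sorted_obs), side="left"
    )
    ranks = np.arange(1, m + 1)
    q_tilde = np.maximum(n_ge, 0.5) / (ranks * B)
    q_sorted = np.minimum.accumulate(q_tilde[::-1])[::-1]
    q = np.empty(m)
    q[order] = q_sorted
    return np.minimum(q, 1.0) if cap else q


# ---------------------------------------------------------------------------
# End-to-end driver
# ---------------------------------------------------------------------------

@dataclass
class DiscResult:
    """Per-gene test results plus the configuration that produced them."""

    gene_ids: np.ndarray
    feature_names: list[str]
    F: np.ndarray  # genes × K, observed per-feature statistics
    F_omnibus: np.ndarray  # genes
    p: np.ndarray
    q: np.ndarray  # capped at 1
    q_raw: np.ndarray  # uncapped pooled estimate
    B: int
    scheme: str
    seed: int
    rho: float
    cap: float

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"gene_id": self.gene_ids})
        for k, name in enumerate(self.feature_names):
            df[f"F_{name}"] = self.F[:, k]
        df["F_omnibus"] = self.F_omnibus
        df["p_value"] = self.p
        df["q_value"] = self.q
        return df

    def write_tsv(self, path) -> None:
        header = (
            f"# B={self.B}\n# seed={self.seed}\n# scheme={self.scheme}\n"
            f"# rho={self.rho}\n# cap={self.cap}\n"
        )
        body = self.to_frame().to_csv(sep="\t", index=False, float_format="%.10g")
        Path(path).write_text(header + body)


def _f_matrix(
    u2: np.ndarray,
    ss: np.ndarray,
    h_base: np.ndarray,
    Yeff: np.ndarray,
    base: np.ndarray,
    p: int,
) -> np.ndarray:
    """Per-(gene, feature) F statistics for one effective Y, vectorized.

    ``u2`` is (M·K) × N; one pair of N×N projections serves every row.
    """
    full = np.column_stack([base, Yeff])
    h_full = hat_matrix(full)
    df_res = u2.shape[1] - np.linalg.matrix_rank(full)
    a = h_full - h_base
    num_qf = np.einsum("ij,ij->i", u2 @ a, u2)
    den_qf = ss - np.einsum("ij,ij->i", u2 @ h_full, u2)
    return _f_from_quadratic_forms(num_qf, den_qf, ss, p, df_res)


def run_disc(
    cm: CountMatrix,
    design: DesignSpec,
    B: int = 999,
    seed: int = 0,
    rho: float = 0.5,
    cap: float = 7.0,
    scheme: str | None = None,
    pvalue_add_one: bool = False,
    n_threads: int = 1,
) -> DiscResult:
    """Run the full individual-level DE test on a count matrix.

    Pipeline: TSS normalization → distributional feature extraction →
    transforms → per-feature F on the observed design and on each of B
    shared permutations → omnibus max-F → permutation p-values → pooled
    permutation q-values.  Deterministic given ``seed``; ``n_threads`` only
    splits the permutation loop and never changes results.

    ``scheme`` defaults to Smith's residual permutation when covariates are
    present and plain permutation otherwise.
    """
    nm = normalize_tss(cm)
    individuals = nm.individuals
    aligned = design.subset(individuals)
    if scheme is None:
        scheme = "smith" if aligned.q > 0 else "plain"

    fa = transform_features(extract_features(nm), rho=rho, cap=cap)
    m, n, k = fa.U.shape
    u2 = np.ascontiguousarray(fa.U.transpose(0, 2, 1).reshape(m * k, n))
    ss = np.einsum("ij,ij->i", u2, u2)

    Y, Z, p = aligned.Y, aligned.Z, aligned.p
    base = _design_with_intercept(Z, n, True)
    h_base = hat_matrix(base)

    f_obs = _f_matrix(u2, ss, h_base, Y, base, p).reshape(m, k)
    f_o_obs = f_obs.max(axis=1)

    plan = make_permutation_plan(n, B, scheme, seed)

    def _one_perm(b: int) -> np.ndarray:
        yb = permuted_response(Y, Z, plan.perm_indices[b], scheme)
        return _f_matrix(u2, ss, h_base, yb, base, p).reshape(m, k).max(axis=1)

    f_o_perm = np.empty((m, B))
    if n_threads > 1:
        with ThreadPoolExecutor(max_workers=n_threads) as pool:
            for b, col in zip(range(B), pool.map(_one_perm, range(B))):
                f_o_perm[:, b] = col
    else:
        for b in range(B):
            f_o_perm[:, b] = _one_perm(b)

    pvals = permutation_pvalues(f_o_obs, f_o_perm, add_one=pvalue_add_one)
    q_raw = permutation_fdr(f_o_obs, f_o_perm, cap=False)
    return DiscResult(
        gene_ids=nm.gene_ids,
        feature_names=list(fa.feature_names),
        F=f_obs,
        F_omnibus=f_o_obs,
        p=pvals,
        q=np.minimum(q_raw, 1.0),
        q_raw=q_raw,
        B=B,
        scheme=scheme,
        seed=seed,
        rho=rho,
        cap=cap,
    )
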