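"""Built-in preprocessing methods exposed through a common subset contract.

Every method here maps ``(probe-level data, subset of arrays)`` to an
:class:`~jedkit.containers.ExpressionMatrix`, so the leave-one-out jackknife
can drive any of them:

``summarize_per_array``
    A strictly per-array baseline (per-gene mean of log2 PM on each array).
    It shares no information across arrays at any step, so it provably has
    the independence property that MAS5 exhibits; it is a stand-in, not a
    MAS5 reimplementation.
``summarize_rma_like``
    Quantile normalization across the chosen arrays followed by per-gene
    median polish — the two information-sharing steps that make RMA-style
    summaries on one array depend on intensities on the others.
``summarize_mindep``
    The MINDEP ("minimum dependency") reference model: a per-gene two-way
    ANOVA fit, LSMEAN per array, minus a weight ``lam`` times the minimum
    LSMEAN as a pseudo-background-correction.  Its summaries are linear in
    the least-squares estimates, so their between-array covariance has a
    closed form (see :func:`mindep_covariance`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .containers import ExpressionMatrix, ProbeLevelMatrix, reset_negative_summaries

__all__ = [
    "summarize_per_array",
    "quantile_normalize",
    "median_polish",
    "summarize_rma_like",
    "MINDEPFit",
    "mindep_fit",
    "mindep_summarize",
    "mindep_covariance",
    "summarize_mindep",
    "get_method",
    "PreprocessingMethod",
]

PreprocessingMethod = Callable[[ProbeLevelMatrix, Sequence[str]], ExpressionMatrix]


def _check_subset(data: ProbeLevelMatrix, arrays: Sequence[str], min_size: int) -> list[str]:
    arrays = list(arrays)
    if len(arrays) < min_size:
        raise ValueError(f"need at least {min_size} array(s), got {len(arrays)}")
    unknown = [a for a in arrays if a not in data.intensities.columns]
    if unknown:
        raise KeyError(f"arrays not present in the data: {unknown}")
    return arrays


def summarize_per_array(data: ProbeLevelMatrix, arrays: Sequence[str]) -> ExpressionMatrix:
    """Per-gene, per-array mean of log2 PM intensities.

    Each summary depends only on its own array's column, so removing any
    other array from the subset leaves the remaining summaries bit-identical.
    """
    arrays = _check_subset(data, arrays, 1)
    sub = data.intensities[arrays]
    raw = sub.groupby(data.probeset_map, sort=False).mean()
    raw = raw.loc[data.gene_ids]
    return reset_negative_summaries(raw, method_tag="perarray", included_arrays=arrays)


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Force all columns to share the across-column mean distribution.

    Each column's k-th order statistic is replaced by the mean of the k-th
    order statistics across columns; ties within a column receive the
    average of the reference values at their tied ranks.  After the
    operation every column's sorted value vector is identical.
    """
    values = matrix.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise ValueError("quantile normalization requires finite values")
    if values.shape[1] < 2:
        warnings.warn("quantile normalization with a single column is a no-op")
        return matrix.copy()
    order_stat_mean = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    for k in range(values.shape[1]):
        ranks = rankdata(values[:, k], method="average")  # 1-based, ties averaged
        lo = np.floor(ranks).astype(int) - 1
        hi = np.ceil(ranks).astype(int) - 1
        out[:, k] = 0.5 * (order_stat_mean[lo] + order_stat_mean[hi])
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def median_polish(
    gene_matrix: pd.DataFrame,
    max_iter: int = 10,
    rel_tol: float = 0.01,
) -> tuple[pd.Series, pd.Series, float, pd.DataFrame]:
    """Tukey median polish of a probe-by-array matrix.

    Alternating row-first/column median sweeps decompose the input into
    ``overall + probe_effect + array_effect + residual`` (an exact
    reconstruction).  Iteration stops when the sum of absolute changes in
    the residual matrix falls below ``rel_tol`` times the mean absolute
    deviation of the input, or after ``max_iter`` sweeps.

    Returns
    -------
    (array_effects, probe_effects, overall, residuals)
    """
    z = gene_matrix.to_numpy(dtype=float).copy()
    if not np.isfinite(z).all():
        raise ValueError("median polish requires finite values")
    n_probe, n_array = z.shape
    overall = 0.0
    row_eff = np.zeros(n_probe)
    col_eff = np.zeros(n_array)
    scale = np.abs(z - np.median(z)).mean()
    tol = rel_tol * scale if scale > 0 else 0.0
    for _ in range(max_iter):
        before = z.copy()
        # rows first
        row_med = np.median(z, axis=1)
        z -= row_med[:, None]
        row_eff += row_med
        col_med_of_row = np.median(col_eff)
        col_eff -= col_med_of_row
        overall += col_med_of_row
        # then columns
        col_med = np.median(z, axis=0)
        z -= col_med[None, :]
        col_eff += col_med
        row_med_of_col = np.median(row_eff)
        row_eff -= row_med_of_col
        overall += row_med_of_col
        if np.abs(z - before).sum() <= tol:
            break
    array_effects = pd.Series(col_eff, index=gene_matrix.columns)
    probe_effects = pd.Series(row_eff, index=gene_matrix.index)
    residuals = pd.DataFrame(z, index=gene_matrix.index, columns=gene_matrix.columns)
    return array_effects, probe_effects, float(overall), residuals


def summarize_rma_like(data: ProbeLevelMatrix, arrays: Sequence[str]) -> ExpressionMatrix:
    """Quantile normalization over the chosen subset, then per-gene median polish.

    The summary for (gene, array) is ``overall + array_effect`` from the
    gene's median polish.  Because both steps pool information across the
    subset, summaries on one array generally change when the subset does.
    """
    arrays = _check_subset(data, arrays, 2)
    norm = quantile_normalize(data.intensities[arrays])
    genes = data.gene_ids
    raw = pd.DataFrame(index=pd.Index(genes, name="gene"), columns=arrays, dtype=float)
    for gene in genes:
        probes = data.probeset_map.index[data.probeset_map == gene]
        arr_eff, _, overall, _ = median_polish(norm.loc[probes])
        raw.loc[gene] = overall + arr_eff
    return reset_negative_summaries(raw, method_tag="rmalike", included_arrays=arrays)


# ---------------------------------------------------------------------------
# MINDEP
# ---------------------------------------------------------------------------


@dataclass
class MINDEPFit:
    """Per-gene two-way ANOVA fit underlying the MINDEP summaries.

    The model for the gene's log2 PM intensity of probe ``p`` on array ``i``
    is ``x_pi = mu_i + beta_p + error``, fit by ordinary least squares on a
    balanced layout.  ``lsmean_coefs`` maps the parameter vector ``theta``
    to the per-array LSMEANs (array effect plus mean probe effect); the
    LSMEANs are invariant to the identifiability constraint used.
    """

    gene: str
    arrays: list[str]
    probes: list[str]
    theta: np.ndarray
    cov_theta: np.ndarray
    xtx_inv: np.ndarray
    sigma2: float
    df_resid: int
    lsmean_coefs: np.ndarray  # (A, n_params)
    constraint: str

    @property
    def n_probes(self) -> int:
        return len(self.probes)

    @property
    def lsmeans(self) -> pd.Series:
        return pd.Series(self.lsmean_coefs @ self.theta, index=self.arrays)

    @property
    def argmin_array(self) -> str:
        return str(self.lsmeans.idxmin())


def _two_way_design(A: int, P: int, constraint: str) -> tuple[np.ndarray, np.ndarray]:
    """Design matrix for the balanced two-way layout and LSMEAN coefficient rows.

    Observations are ordered probe-major: (probe 1, array 1..A), (probe 2, ...).
    ``constraint='sum'`` uses sum-to-zero probe effects with one mean per
    array; ``constraint='reference'`` uses an intercept with first-level
    reference coding for both factors.
    """
    n = A * P
    array_idx = np.tile(np.arange(A), P)
    probe_idx = np.repeat(np.arange(P), A)
    if constraint == "sum":
        # params: mu_1..mu_A, b_1..b_{P-1} (b_P = -sum of the rest)
        X = np.zeros((n, A + P - 1))
        X[np.arange(n), array_idx] = 1.0
        for p in range(P - 1):
            X[probe_idx == p, A + p] = 1.0
            X[probe_idx == P - 1, A + p] = -1.0
        L = np.zeros((A, A + P - 1))
        L[:, :A] = np.eye(A)  # mean probe effect is 0 under sum-to-zero
    elif constraint == "reference":
        # params: intercept, a_2..a_A, b_2..b_P
        X = np.zeros((n, 1 + (A - 1) + (P - 1)))
        X[:, 0] = 1.0
        for i in range(1, A):
            X[array_idx == i, i] = 1.0
        for p in range(1, P):
            X[probe_idx == p, A + p - 1] = 1.0
        L = np.zeros((A, X.shape[1]))
        L[:, 0] = 1.0
        for i in range(1, A):
            L[i, i] = 1.0
        L[:, A:] = 1.0 / P  # average over probe effects (b_1 = 0 implicit)
    else:
        raise ValueError(f"unknown constraint {constraint!r}")
    return X, L


def mindep_fit(
    data: ProbeLevelMatrix,
    gene: str,
    arrays: Sequence[str],
    constraint: str = "sum",
) -> MINDEPFit:
    """Ordinary least squares fit of the per-gene array + probe model.

    Requires the balanced layout (every probe of the gene observed on every
    included array).  In that case the LSMEAN for an array equals the column
    mean of the gene's probe matrix; the parameter covariance is
    ``MSE * (X'X)^{-1}`` with ``df = N - (A + P - 1)``.
    """
    arrays = _check_subset(data, arrays, 1)
    gm = data.gene_matrix(gene, arrays)
    P, A = gm.shape
    if P < 2 or A < 2:
        warnings.warn(
            f"gene {gene!r}: fewer than 2 probes or 2 arrays; covariance is degenerate"
        )
    X, L = _two_way_design(A, P, constraint)
    y = gm.to_numpy(dtype=float).reshape(-1)  # probe-major, matching the design
    XtX = X.T @ X
    theta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ theta
    df = A * P - (A + P - 1)
    ssr = float(resid @ resid)
    if ssr <= 1e-24 * max(float(y @ y), 1.0):  # exact fit up to float noise
        ssr = 0.0
    sigma2 = ssr / df if df > 0 else 0.0
    XtX_inv = np.linalg.inv(XtX)
    return MINDEPFit(
        gene=gene,
        arrays=list(arrays),
        probes=list(gm.index),
        theta=theta,
        cov_theta=sigma2 * XtX_inv,
        xtx_inv=XtX_inv,
        sigma2=sigma2,
        df_resid=max(df, 0),
        lsmean_coefs=L,
        constraint=constraint,
    )


def _c_vectors(fit: MINDEPFit, lam: float) -> tuple[np.ndarray, int]:
    """Coefficient vectors c_i with summary_i = c_i' theta, and the argmin index."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError("the MINDEP weight must lie in [0, 1]")
    lsmeans = fit.lsmean_coefs @ fit.theta
    m = int(np.argmin(lsmeans))
    C = fit.lsmean_coefs - lam * fit.lsmean_coefs[m]
    return C, m


def mindep_summarize(fit: MINDEPFit, lam: float) -> pd.Series:
    """Raw MINDEP summaries ``y_i = LSMEAN_i - lam * min_k LSMEAN_k``.

    The subtraction of the minimum array LSMEAN acts as a
    pseudo-background-correction; ``lam`` ranges from 0 (summaries depend
    only on their own array) to 1 (maximal induced dependence).  Each
    summary is exactly ``c_i' theta`` for the coefficient vectors used by
    :func:`mindep_covariance`.
    """
    C, _ = _c_vectors(fit, lam)
    return pd.Series(C @ fit.theta, index=fit.arrays, name=fit.gene)


def mindep_covariance(
    fit: MINDEPFit,
    lam: float,
    sigma2: float | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Closed-form between-array covariance and correlation of MINDEP summaries.

    ``Cov(y_i, y_j) = c_i' Cov(theta) c_j``, treating the array attaining
    the minimum LSMEAN as fixed at its observed value (the closed form does
    not account for argmin switching).  ``sigma2`` overrides the fit's
    residual-MSE estimate, e.g. to evaluate the form at a known error
    variance.  Pairs with zero variance get correlation 0 by convention.
    """
    C, _ = _c_vectors(fit, lam)
    if sigma2 is None:
        sigma2 = fit.sigma2
    if sigma2 == 0:
        warnings.warn(f"gene {fit.gene!r}: zero residual variance; covariance is zero")
    cov_theta = sigma2 * fit.xtx_inv
    cov = C @ cov_theta @ C.T
    cov = 0.5 * (cov + cov.T)
    sd = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = cov / np.outer(sd, sd)
    corr[~np.isfinite(corr)] = 0.0
    idx = pd.Index(fit.arrays)
    return (
        pd.DataFrame(cov, index=idx, columns=idx),
        pd.DataFrame(corr, index=idx, columns=idx),
    )


def summarize_mindep(
    data: ProbeLevelMatrix,
    arrays: Sequence[str],
    lam: float,
    constraint: str = "sum",
) -> ExpressionMatrix:
    """MINDEP preprocessing of every gene on an array subset (subset contract)."""
    arrays = _check_subset(data, arrays, 1)
    rows = []
    for gene in data.gene_ids:
        fit = mindep_fit(data, gene, arrays, constraint=constraint)
        rows.append(mindep_summarize(fit, lam))
    raw = pd.DataFrame(rows)
    raw.index.name = "gene"
    return reset_negative_summaries(
        raw, method_tag=f"mindep(weight={lam:g})", included_arrays=arrays
    )


def get_method(name: str, lam: float | None = None) -> PreprocessingMethod:
    """Look up a built-in preprocessing method by name.

    ``name`` is one of ``perarray``, ``rmalike`` or ``mindep``; the MINDEP
    weight ``lam`` is required for (and only for) ``mindep``.
    """
    if name == "perarray":
        if lam is not None:
            raise ValueError("the per-array method takes no weight parameter")
        return summarize_per_array
    if name == "rmalike":
        if lam is not None:
            raise ValueError("the rma-like method takes no weight parameter")
        return summarize_rma_like
    if name == "mindep":
        if lam is None:
            raise ValueError("the MINDEP method requires a weight in [0, 1]")
        weight = float(lam)
        return lambda data, arrays: summarize_mindep(data, arrays, weight)
    raise ValueError(f"unknown preprocessing method {name!r}")
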