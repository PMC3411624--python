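"""The Jackknife Expression Difference (JED) and its leave-one-out machinery.

For a gene and a pair of arrays (i, j), let y_i be the gene's post-reset
summary on array i from the full data and y_{i(-j)} its summary when array j
is removed from every step of preprocessing.  Then

    JED_ij = 1/2 * ( |y_i - y_{i(-j)}| / y_i  +  |y_j - y_{j(-i)}| / y_j )

the average relative change in the pair's summaries under mutual
leave-one-out.  JED is 0 exactly when both jackknife summaries equal the
full-data summaries (numerical independence), and the convention
y_{i(-i)} = 0 (an excluded array carries no information) makes the diagonal
exactly 1.  JED is a diagnostic of preprocessing methods, not of arrays,
samples or genes, and it carries no basis for inference.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, JackknifeSet, ProbeLevelMatrix
from .preprocess import PreprocessingMethod

__all__ = [
    "run_jackknife",
    "compute_jed",
    "count_sign_changes",
    "summarize_jed",
]

JED_COLUMNS = ["gene", "array_i", "array_j", "jed", "sign_changes", "distance"]


def run_jackknife(data: ProbeLevelMatrix, method: PreprocessingMethod) -> JackknifeSet:
    """Run a preprocessing method on the full data and on every leave-one-out subset.

    Exactly A+1 preprocessing runs are performed for A arrays: the full set,
    then each subset with one array removed from every step.  Each run
    applies the non-positive reset with its own array floors.  The A runs
    are cached in the returned set, so every pair (i, j) reuses the (-i) and
    (-j) runs.
    """
    arrays = data.array_ids
    if len(arrays) < 2:
        raise ValueError("the jackknife needs at least 2 arrays")

    def run(subset: list[str], label: str) -> ExpressionMatrix:
        try:
            return method(data, subset)
        except Exception as exc:  # re-raise with the subset identity
            raise RuntimeError(f"preprocessing failed on subset {label}: {exc}") from exc

    full = run(arrays, "full")
    loo = {
        j: run([a for a in arrays if a != j], f"leave-out-{j}")
        for j in arrays
    }
    return JackknifeSet(full=full, loo=loo)


def _pair_terms(jk: JackknifeSet, i: str, j: str) -> tuple[pd.Series, pd.Series]:
    """Per-gene relative-change and sign-flip indicators for array i when j is dropped."""
    y_full = jk.full.summaries[i]
    y_loo = jk.loo[j].summaries[i]
    rel = (y_full - y_loo).abs() / y_full
    flip = (jk.full.raw_summaries[i] > 0) != (jk.loo[j].raw_summaries[i] > 0)
    return rel, flip


def compute_jed(jk: JackknifeSet, include_diagonal: bool = True) -> pd.DataFrame:
    """JED, sign-change count and distance for every gene and array pair.

    Returns a long-format table with columns ``gene, array_i, array_j, jed,
    sign_changes, distance``: one row per unordered pair (i < j in array
    order) and, when ``include_diagonal`` is set, one diagonal row per
    array with jed 1 and distance 0.  ``sign_changes`` counts how many of
    the pair's two raw jackknife summaries changed strict sign (positive vs
    non-positive) relative to the full-data raw summaries; the distance is
    the JED itself off the diagonal and 0 on it.
    """
    arrays = jk.array_ids
    genes = pd.Index(jk.gene_ids, name="gene")
    blocks = []
    for a, i in enumerate(arrays):
        for j in arrays[a + 1 :]:
            rel_i, flip_i = _pair_terms(jk, i, j)
            rel_j, flip_j = _pair_terms(jk, j, i)
            jed = 0.5 * (rel_i + rel_j)
            blocks.append(
                pd.DataFrame(
                    {
                        "gene": genes,
                        "array_i": i,
                        "array_j": j,
                        "jed": jed.to_numpy(),
                        "sign_changes": flip_i.to_numpy().astype(int)
                        + flip_j.to_numpy().astype(int),
                        "distance": jed.to_numpy(),
                    }
                )
            )
    if include_diagonal:
        for i in arrays:
            blocks.append(
                pd.DataFrame(
                    {
                        "gene": genes,
                        "array_i": i,
                        "array_j": i,
                        "jed": 1.0,
                        "sign_changes": 0,
                        "distance": 0.0,
                    }
                )
            )
    table = pd.concat(blocks, ignore_index=True)
    order = {a: k for k, a in enumerate(arrays)}
    table = table.sort_values(
        by=["gene", "array_i", "array_j"],
        key=lambda s: s.map(order) if s.name in ("array_i", "array_j") else s,
        kind="stable",
    ).reset_index(drop=True)
    return table[JED_COLUMNS]


def count_sign_changes(jk: JackknifeSet) -> pd.DataFrame:
    """Number of jackknife-induced sign changes (0, 1 or 2) per gene and array pair.

    A sign change means the raw (pre-reset) summary crossed between
    positive and non-positive when the partner array was excluded.
    """
    table = compute_jed(jk, include_diagonal=False)
    return table[["gene", "array_i", "array_j", "sign_changes"]]


def summarize_jed(
    table: pd.DataFrame,
    suppress_diagonal: bool = True,
    thresholds: tuple[float, ...] = (),
    by_sign_changes: bool = False,
) -> pd.DataFrame:
    """Distribution summaries of a JED table.

    With ``suppress_diagonal`` (the default, mirroring how JED results are
    usually displayed) the diagonal rows — identically 1 by convention —
    are dropped before summarizing.  ``thresholds`` adds a
    fraction-exceeding column per value; ``by_sign_changes`` stratifies the
    summary by the number of jackknife sign changes.
    """
    t = table
    if suppress_diagonal:
        t = t[t["array_i"] != t["array_j"]]
    if t.empty:
        raise ValueError("no JED values left to summarize")

    def one(group: pd.DataFrame) -> pd.Series:
        vals = group["jed"]
        out = {
            "n": float(len(vals)),
            "mean": vals.mean(),
            "q50": vals.quantile(0.5),
            "q90": vals.quantile(0.9),
            "q99": vals.quantile(0.99),
            "max": vals.max(),
        }
        for thr in thresholds:
            out[f"frac_gt_{thr:g}"] = float((vals > thr).mean())
        return pd.Series(out)

    if by_sign_changes:
        return t.groupby("sign_changes").apply(one, include_groups=False)
    return one(t).to_frame(name="all").T
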