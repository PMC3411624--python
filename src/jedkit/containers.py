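"""In-memory containers for probe-level data, expression summaries and jackknife runs.

All matrices are :class:`pandas.DataFrame` objects with gene (or probe)
identifiers on the index and array labels on the columns.  Intensities and
summaries live on the log2 scale throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ProbeLevelMatrix",
    "ExpressionMatrix",
    "JackknifeSet",
    "reset_negative_summaries",
]


@dataclass
class ProbeLevelMatrix:
    """Log2-scale perfect-match probe intensities with a probe-to-gene map.

    Parameters
    ----------
    intensities
        Probe-by-array matrix of log2 PM intensities.  The index holds
        unique probe identifiers, the columns unique array labels.
    probeset_map
        Series mapping every probe identifier to the gene (probeset) it
        belongs to.
    """

    intensities: pd.DataFrame
    probeset_map: pd.Series

    def __post_init__(self) -> None:
        if not np.isfinite(self.intensities.to_numpy(dtype=float)).all():
            raise ValueError("probe intensities must all be finite")
        if self.intensities.shape[1] < 2:
            raise ValueError("a probe-level matrix needs at least 2 arrays")
        if self.intensities.columns.duplicated().any():
            raise ValueError("array labels must be unique")
        if self.intensities.index.duplicated().any():
            dup = self.intensities.index[self.intensities.index.duplicated()][0]
            raise ValueError(f"duplicate probe identifier: {dup!r}")
        missing = self.intensities.index.difference(self.probeset_map.index)
        if len(missing):
            raise ValueError(f"probes missing from probeset map: {list(missing[:5])}")
        # align map to the matrix rows; drops stale entries
        self.probeset_map = self.probeset_map.reindex(self.intensities.index)
        self.intensities = self.intensities.astype(float)

    @property
    def array_ids(self) -> list[str]:
        return list(self.intensities.columns)

    @property
    def gene_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self.probeset_map:
            seen.setdefault(g, None)
        return list(seen)

    def gene_matrix(self, gene: str, arrays: Sequence[str] | None = None) -> pd.DataFrame:
        """Probe-by-array submatrix for a single gene (optionally an array subset)."""
        probes = self.probeset_map.index[self.probeset_map == gene]
        if len(probes) == 0:
            raise KeyError(f"gene {gene!r} has no probes")
        cols = self.array_ids if arrays is None else list(arrays)
        return self.intensities.loc[probes, cols]


@dataclass
class ExpressionMatrix:
    """Gene-by-array expression summaries from one preprocessing run.

    Stores both the raw summaries as the method produced them (possibly
    negative) and the post-reset strictly positive summaries, together with
    the per-array floors used by the reset rule.
    """

    summaries: pd.DataFrame
    raw_summaries: pd.DataFrame
    array_floors: pd.Series
    method_tag: str
    included_arrays: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.included_arrays:
            self.included_arrays = list(self.summaries.columns)
        if (self.summaries.to_numpy() <= 0).any():
            raise ValueError("post-reset summaries must be strictly positive")
        if (self.array_floors.to_numpy() <= 0).any():
            raise ValueError("array floors must be strictly positive")
        raw = self.raw_summaries.to_numpy()
        pos = raw > 0
        if not np.array_equal(self.summaries.to_numpy()[pos], raw[pos]):
            raise ValueError("positive raw summaries must pass through the reset unchanged")

    @property
    def array_ids(self) -> list[str]:
        return list(self.summaries.columns)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.summaries.index)


def reset_negative_summaries(
    raw: pd.DataFrame,
    method_tag: str = "external",
    included_arrays: Sequence[str] | None = None,
) -> ExpressionMatrix:
    """Apply the non-positive-summary reset rule and wrap into an ExpressionMatrix.

    Every summary that is zero or negative on an array is replaced by the
    smallest positive raw summary observed for any gene on that same array
    (the array's "floor").  Methods such as PLIER and PUMA can legitimately
    emit negative log-scale summaries; this rule treats them as carrying very
    little evidence of expression.

    Raises
    ------
    ValueError
        If some array has no positive raw summary at all, naming the array.
    """
    raw = raw.astype(float)
    pos = raw.where(raw > 0)
    floors = pos.min(axis=0)
    dead = floors.index[floors.isna()]
    if len(dead):
        raise ValueError(
            f"array {dead[0]!r} has no positive expression summary; cannot apply the reset rule"
        )
    summaries = raw.where(raw > 0, floors, axis=1)
    return ExpressionMatrix(
        summaries=summaries,
        raw_summaries=raw,
        array_floors=floors.astype(float),
        method_tag=method_tag,
        included_arrays=list(included_arrays) if included_arrays is not None else list(raw.columns),
    )


@dataclass
class JackknifeSet:
    """A full-data preprocessing run plus one leave-one-out run per array.

    ``loo[j]`` holds the summaries recomputed with array ``j`` removed from
    every step of preprocessing; it therefore covers every array except
    ``j``.  The convention that an excluded array carries no information
    (its own leave-one-out summary is 0) is applied downstream, when the
    JED is computed.
    """

    full: ExpressionMatrix
    loo: Mapping[str, ExpressionMatrix]
    method_tag: str = ""

    def __post_init__(self) -> None:
        if not self.method_tag:
            self.method_tag = self.full.method_tag
        arrays = set(self.full.array_ids)
        if set(self.loo) != arrays:
            raise ValueError("leave-one-out runs must cover exactly the full set of arrays")
        genes = list(self.full.gene_ids)
        for j, em in self.loo.items():
            if j in em.array_ids:
                raise ValueError(f"leave-one-out run for array {j!r} still contains it")
            if set(em.array_ids) != arrays - {j}:
                raise ValueError(f"leave-one-out run for array {j!r} has the wrong array set")
            if list(em.gene_ids) != genes:
                raise ValueError("all runs in a jackknife set must share the gene index")

    @property
    def array_ids(self) -> list[str]:
        return list(self.full.array_ids)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.full.gene_ids)
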