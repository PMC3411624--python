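"""Seeded generators for probe-level data and jackknife fixtures.

``gen_probe_data`` simulates balanced probe-level intensity matrices from the
additive two-way structure the MINDEP model assumes (gene baseline + array
effect + probe effect + optional group effect + gaussian noise, all in log2
units), so every preprocessing method and the jackknife can be exercised
without any real arrays.  ``gen_sign_change_fixture`` and
``gen_jackknife_fixture`` build summary-level jackknife sets directly, for
worked examples and for realizing controlled sign-change patterns.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import JackknifeSet, ProbeLevelMatrix, reset_negative_summaries

__all__ = [
    "GeneratorConfig",
    "gen_probe_data",
    "gen_sign_change_fixture",
    "gen_jackknife_fixture",
]


@dataclass
class GeneratorConfig:
    """Settings for the probe-level generator (all intensities in log2 units).

    Defaults emulate a modest Affymetrix-like layout: 200 probesets of 11
    probes on 6 arrays, baselines uniform on (6, 10) log2 units, array
    effects with sd 0.5, probe effects with sd 1.0, measurement noise with
    sd 0.25, and a group effect of ``de_effect`` log2 units added on the
    second half of the arrays for a fraction ``de_fraction`` of genes.
    """

    genes: int = 200
    probes_per_gene: int = 11
    arrays: int = 6
    baseline_range: tuple[float, float] = (6.0, 10.0)
    array_effect_sd: float = 0.5
    probe_effect_sd: float = 1.0
    noise_sd: float = 0.25
    de_fraction: float = 0.1
    de_effect: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.genes < 1 or self.probes_per_gene < 1:
            raise ValueError("need at least 1 gene and 1 probe per gene")
        if self.arrays < 2:
            raise ValueError("need at least 2 arrays")
        if self.noise_sd < 0 or self.array_effect_sd < 0 or self.probe_effect_sd < 0:
            raise ValueError("spreads must be non-negative")
        if not 0.0 <= self.de_fraction <= 1.0:
            raise ValueError("de_fraction must lie in [0, 1]")


def gen_probe_data(cfg: GeneratorConfig) -> ProbeLevelMatrix:
    """Simulate a balanced probe-level matrix from the additive two-way model.

    For gene g, probe p, array i:
    ``x = baseline_g + array_i + probe_pg + de_g * treated_i + noise`` with
    iid gaussian noise.  Treated arrays are the second half.  Output is
    bit-reproducible for a fixed seed and exactly balanced (every probe on
    every array), satisfying the MINDEP fit's precondition.
    """
    rng = np.random.default_rng(cfg.seed)
    G, P, A = cfg.genes, cfg.probes_per_gene, cfg.arrays
    genes = [f"g{k + 1:04d}" for k in range(G)]
    arrays = [f"A{k + 1}" for k in range(A)]
    baselines = rng.uniform(*cfg.baseline_range, size=G)
    array_effects = rng.normal(0.0, cfg.array_effect_sd, size=A)
    probe_effects = rng.normal(0.0, cfg.probe_effect_sd, size=(G, P))
    de_genes = rng.random(G) < cfg.de_fraction
    treated = np.arange(A) >= A - A // 2
    x = (
        baselines[:, None, None]
        + array_effects[None, None, :]
        + probe_effects[:, :, None]
        + np.where(de_genes[:, None, None] & treated[None, None, :], cfg.de_effect, 0.0)
        + rng.normal(0.0, cfg.noise_sd, size=(G, P, A))
    )
    probe_ids = [f"{g}_p{p + 1:02d}" for g in genes for p in range(P)]
    intensities = pd.DataFrame(
        x.reshape(G * P, A), index=pd.Index(probe_ids, name="probe_id"), columns=arrays
    )
    probeset_map = pd.Series(
        np.repeat(genes, P), index=intensities.index, name="probeset_id"
    )
    return ProbeLevelMatrix(intensities=intensities, probeset_map=probeset_map)


def gen_jackknife_fixture(
    full_raw: pd.DataFrame,
    loo_raw: Mapping[str, pd.DataFrame],
    method_tag: str = "external",
) -> JackknifeSet:
    """Wrap given raw summary matrices as a JackknifeSet (no preprocessing run).

    ``full_raw`` is gene x array; ``loo_raw[j]`` holds the summaries of the
    run that excluded array j (all arrays except j).  The non-positive
    reset is applied to each matrix with its own floors.
    """
    full = reset_negative_summaries(full_raw, method_tag=method_tag)
    loo = {
        j: reset_negative_summaries(m, method_tag=method_tag) for j, m in loo_raw.items()
    }
    return JackknifeSet(full=full, loo=loo, method_tag=method_tag)


def gen_sign_change_fixture(
    floor: float = 1e-6,
    pattern: int | Sequence[int] = 1,
    value: float = 8.0,
) -> JackknifeSet:
    """Two-array jackknife set realizing controlled jackknife sign changes.

    One target gene per entry of ``pattern`` (each 0, 1 or 2) has full-data
    raw summaries ``value`` on both arrays; with pattern 1 its leave-one-out
    raw summary on array 1 is flipped negative (so the reset maps it to the
    floor), with pattern 2 both leave-one-out summaries are flipped, and
    with pattern 0 nothing changes.  A positive "floor-carrier" gene pins
    every run's array floor at ``floor``, so as the floor vanishes a single
    sign change drives the pair's JED toward 1/2 and two sign changes drive
    it toward 1.
    """
    if floor <= 0:
        raise ValueError("floor must be positive")
    patterns = [pattern] if isinstance(pattern, int) else list(pattern)
    if any(p not in (0, 1, 2) for p in patterns):
        raise ValueError("each pattern entry must be 0, 1 or 2")
    arrays = ["A1", "A2"]
    genes = [f"target{k + 1}" for k in range(len(patterns))] + ["floor_carrier"]
    full = pd.DataFrame(value, index=pd.Index(genes, name="gene"), columns=arrays)
    full.loc["floor_carrier"] = floor
    loo = {}
    for excluded, kept in (("A2", "A1"), ("A1", "A2")):
        m = full[[kept]].copy()
        for k, p in enumerate(patterns):
            flip = (excluded == "A2" and p >= 1) or (excluded == "A1" and p == 2)
            if flip:
                m.loc[f"target{k + 1}", kept] = -value
        loo[excluded] = m
    return gen_jackknife_fixture(full, loo, method_tag="sign-change-fixture")
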