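"""Functional-profile comparison: COG fractions, Poisson dissimilarity, ANOSIM.

Gene-content profiles are genome x COG-category count tables.  Pairwise
genome distances use the Poisson log-likelihood-ratio dissimilarity: for
genomes i, j with counts X_ig, X_jg and pairwise size factors s_i, s_j
(each pair normalised to its own mean total), the shared rate estimate is
N_g = (X_ig + X_jg) / (s_i + s_j) and

    d(i,j) = sum_g [ s_i N_g - X_ig + X_ig log(X_ig / (s_i N_g))
                   + s_j N_g - X_jg + X_jg log(X_jg / (s_j N_g)) ]

with 0 log 0 = 0.  Group separation on the resulting distance matrix is
tested with ANOSIM: R = (mean between-group rank - mean within-group
rank) / (M/2) over the M off-diagonal distances (average ranks on ties),
with a permutation p-value using the add-one convention (p is never 0;
the smallest attainable p at 99,999 permutations is 1/100,000).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .genome_compare import DistanceMatrix
from .io import logger


def cog_fractions(table: pd.DataFrame) -> pd.DataFrame:
    """Row-normalized percentages of genes per COG category."""
    sums = table.sum(axis=1)
    zero = sums == 0
    if zero.any():
        logger.warning("cog_fractions: excluding zero-sum rows %s", list(table.index[zero]))
        table = table.loc[~zero]
        sums = sums[~zero]
    return table.div(sums, axis=0) * 100.0


def _pair_dissimilarity(xi: np.ndarray, xj: np.ndarray) -> float:
    ti, tj = xi.sum(), xj.sum()
    mean_total = (ti + tj) / 2.0
    si, sj = ti / mean_total, tj / mean_total
    n_hat = (xi + xj) / (si + sj)
    with np.errstate(divide="ignore", invalid="ignore"):
        li = np.where(xi > 0, xi * np.log(xi / (si * n_hat)), 0.0)
        lj = np.where(xj > 0, xj * np.log(xj / (sj * n_hat)), 0.0)
    return float(np.sum(si * n_hat - xi + li + sj * n_hat - xj + lj))


def poisson_dissimilarity(table: pd.DataFrame) -> DistanceMatrix:
    """Pairwise Poisson dissimilarities between genome count profiles."""
    values = table.to_numpy()
    if values.shape[0] < 2:
        raise ValueError("need >= 2 genomes for pairwise dissimilarities")
    if not np.issubdtype(values.dtype, np.integer):
        if not np.allclose(values, np.round(values)):
            raise ValueError("counts must be nonnegative integers")
        values = np.round(values).astype(int)
    if (values < 0).any():
        raise ValueError("counts must be nonnegative integers")
    sums = values.sum(axis=1)
    if (sums == 0).any():
        bad = list(table.index[sums == 0])
        logger.warning("poisson_dissimilarity: excluding zero-sum rows %s", bad)
        keep = sums > 0
        values = values[keep]
        table = table.loc[keep]
    n = values.shape[0]
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = _pair_dissimilarity(values[i].astype(float), values[j].astype(float))
            out[i, j] = out[j, i] = max(d, 0.0)
    return DistanceMatrix(list(table.index), out)


@dataclass(frozen=True)
class AnosimResult:
    R: float
    p: float
    n_permutations: int
    seed: int


def anosim(
    distances: DistanceMatrix,
    groups: Mapping[str, str],
    n_permutations: int = 99_999,
    seed: int = 0,
) -> AnosimResult:
    """Rank-based permutation test of group separation on a distance matrix.

    ``groups`` maps each genome label to its group.  Every group needs at
    least two members and at least two groups are required.  Labels are
    permuted uniformly with the stated seed; the p-value uses the add-one
    convention and is therefore never 0.
    """
    labels = distances.labels
    missing = [g for g in labels if g not in groups]
    if missing:
        raise ValueError(f"labels without a group: {missing}")
    group_names = sorted({groups[g] for g in labels})
    sizes = {name: sum(1 for g in labels if groups[g] == name) for name in group_names}
    for name, size in sizes.items():
        if size < 2:
            raise ValueError(f"group {name!r} has fewer than 2 members")
    if len(group_names) < 2:
        raise ValueError("ANOSIM needs at least two groups")
    n = len(labels)
    iu = np.triu_indices(n, 1)
    condensed = distances.values[iu]
    ranks = rankdata(condensed)  # average ranks on ties
    m = len(condensed)
    codes = np.array([group_names.index(groups[g]) for g in labels])

    def _r(code_rows: np.ndarray) -> np.ndarray:
        within = code_rows[:, iu[0]] == code_rows[:, iu[1]]
        sum_within = within @ ranks
        n_within = within.sum(axis=1)
        mean_within = sum_within / n_within
        mean_between = (ranks.sum() - sum_within) / (m - n_within)
        return (mean_between - mean_within) / (m / 2.0)

    r_obs = float(_r(codes[None, :])[0])
    rng = np.random.default_rng(seed)
    count = 0
    chunk = 10_000
    done = 0
    while done < n_permutations:
        size = min(chunk, n_permutations - done)
        perms = rng.permuted(np.tile(np.arange(n), (size, 1)), axis=1)
        r_perm = _r(codes[perms])
        count += int((r_perm >= r_obs - 1e-12).sum())
        done += size
    p = (1 + count) / (1 + n_permutations)
    logger.info("anosim: R=%.4f p=%.5g (%d permutations)", r_obs, p, n_permutations)
    return AnosimResult(R=r_obs, p=p, n_permutations=n_permutations, seed=seed)
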