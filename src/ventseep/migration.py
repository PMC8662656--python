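"""Directional relative migration between genetic groups (migrant-pool G_ST).

For every ordered pair of groups a hypothetical *migrant pool* is formed
whose allele frequencies are the unweighted mean of the pair's
frequencies.  Nei's multi-locus G_ST is then computed between each
member and the pool; a population receiving many migrants sits close to
the pool, so its differentiation from the pool is low and the
island-model conversion ``Nm = (1/G_ST - 1) / 4`` is high.  The
directional entry ``m[i -> j]`` is the Nm derived from the
differentiation of the *recipient* ``j`` from the pool, and the whole
matrix is divided by its maximum so the strongest flow equals 1
(Sundqvist et al. 2016 convention).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .demography import GenotypeMatrix
from .popstats import _alt_freqs

_G_EPS = 1e-12


@dataclass
class MigrationMatrix:
    """Square relative-migration matrix; rows = source, columns = target."""

    values: pd.DataFrame
    statistic: str = "G_ST"

    def thresholded(self, threshold: float) -> pd.DataFrame:
        """Display helper: entries below ``threshold`` masked (limited flow)."""
        return self.values.where(self.values >= threshold)


def _gst_vs_pool(p_member: np.ndarray, p_pool: np.ndarray, usable: np.ndarray) -> float:
    """Nei multi-locus G_ST between one population and the migrant pool.

    H_S and H_T are averaged over loci before the ratio (multi-locus form).
    """
    hs = 0.5 * (2 * p_member * (1 - p_member) + 2 * p_pool * (1 - p_pool))
    pbar = 0.5 * (p_member + p_pool)
    ht = 2 * pbar * (1 - pbar)
    ht_mean = ht[usable].mean()
    if ht_mean <= 0:
        return float("nan")
    return float((ht_mean - hs[usable].mean()) / ht_mean)


def relative_migration(
    gm: GenotypeMatrix, groups: list[str] | None = None
) -> MigrationMatrix:
    """Directional relative migration for all group pairs.

    Pairs sharing no polymorphic locus get NaN entries (flagged as
    undefined).  After filling, all finite entries are divided by the
    maximum, so the largest relative migration is exactly 1.
    """
    groups = list(groups) if groups is not None else list(gm.group_names())
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    freqs = {}
    for g in groups:
        idx = gm.group_index(g)
        if idx.size < 2:
            raise ValueError(f"group {g} has fewer than 2 individuals")
        freqs[g] = _alt_freqs(gm.genotypes[idx])

    nm = pd.DataFrame(np.nan, index=groups, columns=groups, dtype=float)
    for ga, gb in combinations(groups, 2):
        pa, na = freqs[ga]
        pb, nb = freqs[gb]
        usable = (na >= 1) & (nb >= 1)
        pool = 0.5 * (pa + pb)
        poly = usable & (pool > 0) & (pool < 1)
        if not poly.any():
            continue  # undefined pair, stays NaN
        g_a = _gst_vs_pool(pa, pool, usable)
        g_b = _gst_vs_pool(pb, pool, usable)
        # Nm into a population comes from its own differentiation from the pool
        nm_into_a = (1.0 / max(g_a, _G_EPS) - 1.0) / 4.0
        nm_into_b = (1.0 / max(g_b, _G_EPS) - 1.0) / 4.0
        nm.loc[gb, ga] = nm_into_a
        nm.loc[ga, gb] = nm_into_b

    finite = nm.values[np.isfinite(nm.values)]
    if finite.size and finite.max() > 0:
        nm = nm / finite.max()
    return MigrationMatrix(values=nm)
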