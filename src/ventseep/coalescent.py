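"""Coalescent simulation of independent biallelic SNP loci.

The engine simulates, backward in time, genealogies under a
piecewise-constant multi-population model with divergence (merge) events
and instantaneous size changes.  Each locus retains a genealogy accepted
with probability proportional to its total branch length — the
ascertainment effect of observing only loci on which a mutation occurred
— and carries exactly one mutation placed uniformly at random on the
branches below the most recent common ancestor.  Every simulated locus
is therefore segregating in the pooled sample, and a neutral
single-population sample reproduces the classic 1/i site-frequency
spectrum exactly.

Rates follow the standard diploid continuous-time approximation: with
``k`` lineages in a deme of diploid size ``N`` the pair-coalescence rate
is ``k(k-1)/(4N)`` per generation.

The inner loop is compiled with numba so that reference tables with
millions of locus genealogies are affordable on one CPU.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .demography import (
    GROUPS,
    GenotypeMatrix,
    SampleConfig,
    ScenarioParams,
    scenario_event_table,
)

_MAX_SEED = 2**31 - 1


_PILOT_TREES = 128
_CAP_MULTIPLIER = 1.0
_MAX_REJECT = 100_000


@njit(cache=True)
def _one_tree(
    sample_deme, sizes0, ev_time, ev_src, ev_dst, ev_szdeme, ev_szval,
    start, end, first, last, nxt, members, msize, sizes,
):  # pragma: no cover - exercised through the wrappers
    """Simulate one genealogy; returns (root node id, total length below root).

    Deme membership is maintained incrementally (per-deme member lists),
    so each coalescent event costs O(#demes) plus O(1) bookkeeping.
    """
    n = sample_deme.shape[0]
    n_demes = sizes0.shape[0]
    n_ev = ev_time.shape[0]

    msize[:] = 0
    for i in range(n):
        d = sample_deme[i]
        members[d, msize[d]] = i
        msize[d] += 1
        start[i] = 0.0
        first[i] = i
        last[i] = i
        nxt[i] = -1
    sizes[:] = sizes0
    k = n
    t = 0.0
    p = 0
    nxt_node = n

    while k > 1:
        rate = 0.0
        for d in range(n_demes):
            c = msize[d]
            if c >= 2:
                rate += c * (c - 1) / (4.0 * sizes[d])

        if rate <= 0.0:
            if p >= n_ev:
                raise ValueError("demography leaves lineages in disconnected demes")
            t = ev_time[p]
        else:
            dt = np.random.exponential(1.0 / rate)
            if p < n_ev and t + dt >= ev_time[p]:
                t = ev_time[p]
            else:
                t += dt
                # choose the deme proportionally to its coalescence rate
                u = np.random.random() * rate
                acc = 0.0
                chosen = -1
                for d in range(n_demes):
                    c = msize[d]
                    if c >= 2:
                        acc += c * (c - 1) / (4.0 * sizes[d])
                        if u < acc:
                            chosen = d
                            break
                if chosen < 0:
                    for d in range(n_demes - 1, -1, -1):
                        if msize[d] >= 2:
                            chosen = d
                            break
                c = msize[chosen]
                a1 = np.random.randint(c)
                a2 = np.random.randint(c - 1)
                if a2 >= a1:
                    a2 += 1
                c1 = members[chosen, a1]
                c2 = members[chosen, a2]
                new = nxt_node
                nxt_node += 1
                end[c1] = t
                end[c2] = t
                start[new] = t
                first[new] = first[c1]
                nxt[last[c1]] = first[c2]
                last[new] = last[c2]
                members[chosen, a1] = new
                members[chosen, a2] = members[chosen, c - 1]
                msize[chosen] = c - 1
                k -= 1
                continue

        # apply the demographic event at time t
        if ev_src[p] >= 0:
            src = ev_src[p]
            dst = ev_dst[p]
            for i in range(msize[src]):
                members[dst, msize[dst]] = members[src, i]
                msize[dst] += 1
            msize[src] = 0
        if ev_szdeme[p] >= 0:
            sizes[ev_szdeme[p]] = ev_szval[p]
        p += 1

    root = nxt_node - 1
    total = 0.0
    for v in range(root):
        total += end[v] - start[v]
    return root, total


@njit(cache=True)
def _simulate_loci(
    n_loci,
    sample_deme,
    sizes0,
    ev_time,
    ev_src,
    ev_dst,
    ev_szdeme,
    ev_szval,
    seed,
    out,
):  # pragma: no cover - exercised through the wrappers
    """Fill ``out[loc, lineage]`` with derived-allele indicators.

    Genealogies are accepted with probability proportional to their total
    branch length (SNP ascertainment: a locus is observed because a
    mutation occurred on it, and mutations land on long genealogies
    proportionally more often).  The acceptance cap is estimated from a
    pilot batch; genealogies above the cap are accepted outright (tail
    probability ~1e-3, a negligible clip).  One mutation is then placed
    uniformly on the accepted genealogy's branches below the root.
    """
    np.random.seed(seed)
    n = sample_deme.shape[0]
    n_demes = sizes0.shape[0]
    n_nodes = 2 * n - 1

    start = np.empty(n_nodes)
    end = np.empty(n_nodes)
    first = np.empty(n_nodes, np.int64)
    last = np.empty(n_nodes, np.int64)
    nxt = np.empty(n, np.int64)
    members = np.empty((n_demes, n), np.int64)
    msize = np.empty(n_demes, np.int64)
    sizes = np.empty(n_demes)

    # pilot pass: estimate the length-bias acceptance cap
    cap = 0.0
    for _ in range(_PILOT_TREES):
        _, total = _one_tree(
            sample_deme, sizes0, ev_time, ev_src, ev_dst, ev_szdeme, ev_szval,
            start, end, first, last, nxt, members, msize, sizes,
        )
        if total > cap:
            cap = total
    cap *= _CAP_MULTIPLIER

    for loc in range(n_loci):
        root = -1
        total = 0.0
        for _ in range(_MAX_REJECT):
            root, total = _one_tree(
                sample_deme, sizes0, ev_time, ev_src, ev_dst, ev_szdeme,
                ev_szval, start, end, first, last, nxt, members, msize, sizes,
            )
            if total >= cap or np.random.random() * cap < total:
                break

        u = np.random.random() * total
        node = root - 1
        acc = 0.0
        for v in range(root):
            acc += end[v] - start[v]
            if u < acc:
                node = v
                break

        for i in range(n):
            out[loc, i] = 0
        j = first[node]
        stop = last[node]
        while True:
            out[loc, j] = 1
            if j == stop:
                break
            j = nxt[j]


def _normalize_seed(rng_seed: int) -> int:
    return int(rng_seed) % _MAX_SEED


def simulate_haplotypes(
    params: ScenarioParams,
    lineage_counts,
    n_loci: int,
    rng_seed: int,
) -> np.ndarray:
    """Simulate ``n_loci`` independent loci; returns int8 (n_loci, n_lineages).

    ``lineage_counts`` maps group name -> haploid lineage count; lineages are
    laid out group by group in :data:`~ventseep.demography.GROUPS` order.
    """
    params.validate(check_founder=False)
    if isinstance(lineage_counts, dict):
        counts = [(g, lineage_counts[g]) for g in GROUPS if g in lineage_counts]
    else:
        counts = list(lineage_counts)
    for g, c in counts:
        if c < 1:
            raise ValueError(f"group {g} needs >= 1 lineage")
    sample_deme = np.concatenate(
        [np.full(c, GROUPS.index(g), dtype=np.int64) for g, c in counts]
    )
    sizes0, ev_t, ev_s, ev_d, ev_zd, ev_zv = scenario_event_table(params)
    out = np.empty((n_loci, sample_deme.size), dtype=np.int8)
    _simulate_loci(
        n_loci, sample_deme, sizes0, ev_t, ev_s, ev_d, ev_zd, ev_zv,
        _normalize_seed(rng_seed), out,
    )
    return out


def simulate_locus(params: ScenarioParams, lineage_counts, rng_seed: int) -> np.ndarray:
    """Derived-allele indicator (0/1) per lineage for a single locus."""
    return simulate_haplotypes(params, lineage_counts, 1, rng_seed)[0]


def simulate_panmictic_haplotypes(
    n_lineages: int, ne: float, n_loci: int, rng_seed: int
) -> np.ndarray:
    """Single-population loci: int8 (n_loci, n_lineages), one SNP each."""
    if n_lineages < 2:
        raise ValueError("need >= 2 lineages")
    sample_deme = np.zeros(n_lineages, dtype=np.int64)
    sizes0 = np.array([float(ne)])
    empty_f = np.empty(0)
    empty_i = np.empty(0, np.int64)
    out = np.empty((n_loci, n_lineages), dtype=np.int8)
    _simulate_loci(
        n_loci, sample_deme, sizes0, empty_f, empty_i, empty_i, empty_i,
        empty_f, _normalize_seed(rng_seed), out,
    )
    return out


def _haplotypes_to_matrix(
    hap: np.ndarray, sample_config: SampleConfig, rng_seed: int
) -> GenotypeMatrix:
    import pandas as pd

    n_loci = hap.shape[0]
    genotypes = (hap[:, 0::2] + hap[:, 1::2]).T.astype(np.int8)
    individuals: list[str] = []
    groups: list[str] = []
    for g in sample_config.groups:
        for i in range(sample_config.sizes[g]):
            individuals.append(f"{g}_{i + 1:03d}")
            groups.append(g)
    pos_rng = np.random.default_rng(rng_seed)
    loci = pd.DataFrame(
        {
            "scaffold": [f"locus_{i + 1:06d}" for i in range(n_loci)],
            "pos": pos_rng.integers(100, 10_000, size=n_loci),
        }
    )
    return GenotypeMatrix(genotypes, individuals, np.array(groups), loci)


def simulate_dataset(
    params: ScenarioParams,
    sample_config: SampleConfig,
    n_loci: int,
    rng_seed: int,
    maf_min: float = 0.0,
) -> GenotypeMatrix:
    """Simulate a complete multi-group SNP dataset.

    Each locus is an independent genealogy of ``2 x`` the diploid sample
    sizes; diploid genotypes pair consecutive lineages within each group
    (random-mating demes).  Every locus lives on its own scaffold, matching
    the one-SNP-per-GBS-locus layout the downstream analyses assume.
    ``maf_min > 0`` optionally re-draws loci until the pooled minor-allele
    frequency reaches the threshold (ascertainment conditioning, off by
    default).
    """
    if n_loci < 1:
        raise ValueError("n_loci must be >= 1")
    lineage_counts = {g: 2 * sample_config.sizes[g] for g in sample_config.groups}
    hap = simulate_haplotypes(params, lineage_counts, n_loci, rng_seed)
    if maf_min > 0.0:
        seed = _normalize_seed(rng_seed)
        for _ in range(1000):
            freq = hap.mean(axis=1)
            bad = np.flatnonzero(np.minimum(freq, 1 - freq) < maf_min)
            if bad.size == 0:
                break
            seed = (seed * 6364136223846793005 + 1442695040888963407) % _MAX_SEED
            hap[bad] = simulate_haplotypes(params, lineage_counts, bad.size, seed)
    return _haplotypes_to_matrix(hap, sample_config, rng_seed)
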