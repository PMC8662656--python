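"""Population-genetic statistics on diploid SNP genotype matrices.

Implements the per-group diversity summary (expected/observed
heterozygosity, nucleotide diversity, inbreeding coefficient, counts of
polymorphic and private sites), the Weir & Cockerham (1984) F_ST
estimator with a permutation test, Nei's (1972) standard genetic
distance, and a genotype PCA with the usual allele-frequency
standardization.

All statistics use complete-case allele frequencies per site: missing
genotypes are simply not counted, and sites with fewer than two called
diploids in a group are skipped for that group.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .demography import MISSING, GenotypeMatrix


def _group_site_arrays(geno: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-site (n_called, alt_allele_sum, het_count) for a genotype block."""
    called = geno != MISSING
    g = np.where(called, geno, 0)
    return called.sum(axis=0), g.sum(axis=0), (geno == 1).sum(axis=0)


def group_summary(gm: GenotypeMatrix) -> pd.DataFrame:
    """Per-group diversity table.

    For each group, over its *variant sites* (sites with >= 2 called
    diploids in that group):

    * ``H_exp``  mean of ``2p(1-p)`` with ``p`` the within-group alt
      frequency;
    * ``H_obs``  mean heterozygote fraction;
    * ``pi``     mean of ``2p(1-p) * 2n/(2n-1)`` (unbiased pairwise
      difference, so ``pi`` slightly exceeds ``H_exp``);
    * ``F_IS``   mean of ``1 - H_obs/H_exp`` over sites, taking 0 where
      ``H_exp = 0``;
    * ``poly``   sites polymorphic within the group; ``private`` sites
      polymorphic in this group and in no other.
    """
    groups = gm.group_names()
    n_groups = len(groups)
    poly_by_group = np.zeros((n_groups, gm.n_loci), dtype=bool)
    per_group: dict[str, dict] = {}

    for gi, g in enumerate(groups):
        idx = gm.group_index(g)
        if idx.size < 2:
            raise ValueError(f"group {g} has fewer than 2 individuals")
        n_c, alt, het = _group_site_arrays(gm.genotypes[idx])
        variant = n_c >= 2
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(variant, alt / np.maximum(2 * n_c, 1), np.nan)
        hexp = 2 * p * (1 - p)
        hobs = np.where(variant, het / np.maximum(n_c, 1), np.nan)
        pi = hexp * (2 * n_c) / np.maximum(2 * n_c - 1, 1)
        with np.errstate(divide="ignore", invalid="ignore"):
            fis = np.where(hexp > 0, 1 - hobs / hexp, 0.0)
        poly = variant & (p > 0) & (p < 1)
        poly_by_group[gi] = poly
        per_group[g] = dict(
            n=idx.size,
            variant=int(variant.sum()),
            poly=int(poly.sum()),
            H_exp=float(np.nanmean(np.where(variant, hexp, np.nan))),
            H_obs=float(np.nanmean(np.where(variant, hobs, np.nan))),
            pi=float(np.nanmean(np.where(variant, pi, np.nan))),
            F_IS=float(np.nanmean(np.where(variant, fis, np.nan))),
        )

    n_poly_groups = poly_by_group.sum(axis=0)
    rows = []
    for gi, g in enumerate(groups):
        private = int((poly_by_group[gi] & (n_poly_groups == 1)).sum())
        d = per_group[g]
        rows.append(
            dict(
                group=g,
                n=d["n"],
                variant=d["variant"],
                poly=d["poly"],
                poly_pct=100 * d["poly"] / d["variant"] if d["variant"] else np.nan,
                private=private,
                private_pct=100 * private / d["variant"] if d["variant"] else np.nan,
                H_exp=d["H_exp"],
                H_obs=d["H_obs"],
                pi=d["pi"],
                F_IS=d["F_IS"],
            )
        )
    return pd.DataFrame(rows).set_index("group")


# --- Weir & Cockerham (1984) ------------------------------------------------

def wc84_components(
    geno_a: np.ndarray, geno_b: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-locus WC84 variance components (a, b, c) for two populations.

    Returns ``(a, b, c, usable)`` where ``usable`` marks loci with at
    least one called genotype in each population and mean sample size
    above one (the estimator's denominators exist there).
    """
    na, sa, ha = _group_site_arrays(geno_a)
    nb, sb, hb = _group_site_arrays(geno_b)
    usable = (na >= 1) & (nb >= 1) & (na + nb >= 3)
    na_f = na.astype(float)
    nb_f = nb.astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        nbar = (na_f + nb_f) / 2.0
        ntot = na_f + nb_f
        nc = ntot - (na_f**2 + nb_f**2) / ntot
        pa = sa / (2.0 * na_f)
        pb = sb / (2.0 * nb_f)
        pbar = (sa + sb) / (2.0 * ntot)
        s2 = (na_f * (pa - pbar) ** 2 + nb_f * (pb - pbar) ** 2) / nbar
        hbar = (ha + hb) / ntot
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - s2 / 2.0 - hbar / 4.0) / (nbar - 1.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1 - pbar) - s2 / 2.0 - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar
        )
        c = hbar / 2.0
    a = np.where(usable, a, 0.0)
    b = np.where(usable, b, 0.0)
    c = np.where(usable, c, 0.0)
    return a, b, c, usable


def wc84_theta(geno_a: np.ndarray, geno_b: np.ndarray) -> float:
    """Multi-locus ratio-of-averages estimate ``sum(a) / sum(a+b+c)``."""
    a, b, c, usable = wc84_components(geno_a, geno_b)
    denom = (a + b + c)[usable].sum()
    if denom == 0 or not usable.any():
        return float("nan")
    return float(a[usable].sum() / denom)


def wc84_theta_per_locus(geno_a: np.ndarray, geno_b: np.ndarray) -> np.ndarray:
    """Per-locus theta; NaN where the locus is unusable or monomorphic."""
    a, b, c, usable = wc84_components(geno_a, geno_b)
    denom = a + b + c
    with np.errstate(divide="ignore", invalid="ignore"):
        theta = np.where(usable & (denom != 0), a / denom, np.nan)
    return theta


@dataclass
class FstResult:
    estimate: float
    p_value: float | None
    n_permutations: int
    n_loci_used: int

    @property
    def defined(self) -> bool:
        return np.isfinite(self.estimate)


def pairwise_fst(
    gm: GenotypeMatrix,
    group_a: str,
    group_b: str,
    n_perm: int = 10_000,
    rng_seed: int | None = 0,
) -> FstResult:
    """Multi-locus WC84 F_ST between two groups with a permutation test.

    The permutation null shuffles individuals between the two groups
    (group sizes fixed); ``p = (1 + #{theta_perm >= theta_obs}) / (1 + B)``.
    With no usable segregating site the estimate is NaN (undefined), not 0.
    """
    ia = gm.group_index(group_a)
    ib = gm.group_index(group_b)
    if ia.size < 2 or ib.size < 2:
        raise ValueError("both groups need >= 2 individuals")
    geno = gm.genotypes[np.concatenate([ia, ib])]
    n_a = ia.size
    a, b, c, usable = wc84_components(geno[:n_a], geno[n_a:])
    n_used = int(usable.sum())
    denom = (a + b + c)[usable].sum()
    if n_used == 0 or denom == 0:
        return FstResult(float("nan"), None, 0, n_used)
    theta_obs = float(a[usable].sum() / denom)
    if n_perm <= 0:
        return FstResult(theta_obs, None, 0, n_used)

    rng = np.random.default_rng(rng_seed)
    n_tot = geno.shape[0]
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n_tot)
        pa, pb, pc, pu = wc84_components(geno[perm[:n_a]], geno[perm[n_a:]])
        pd_ = (pa + pb + pc)[pu].sum()
        if pd_ == 0:
            continue
        if pa[pu].sum() / pd_ >= theta_obs:
            count += 1
    p_value = (1 + count) / (1 + n_perm)
    return FstResult(theta_obs, p_value, n_perm, n_used)


def fst_matrix(gm: GenotypeMatrix, n_perm: int = 0, rng_seed: int = 0) -> pd.DataFrame:
    """Symmetric matrix of pairwise multi-locus WC84 estimates."""
    groups = gm.group_names()
    out = pd.DataFrame(np.nan, index=groups, columns=groups, dtype=float)
    for i, ga in enumerate(groups):
        for gb in groups[i + 1:]:
            r = pairwise_fst(gm, ga, gb, n_perm=n_perm, rng_seed=rng_seed)
            out.loc[ga, gb] = out.loc[gb, ga] = r.estimate
    return out


# --- Nei (1972) standard genetic distance -----------------------------------

@dataclass
class NeiDistanceResult:
    per_locus: np.ndarray     # D per locus; +inf where J_xy = 0
    mean: float               # mean over finite, usable loci
    n_loci_used: int
    n_infinite: int


def _alt_freqs(geno: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n_c, alt, _ = _group_site_arrays(geno)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = alt / (2.0 * n_c)
    return p, n_c


def nei_distance(gm: GenotypeMatrix, group_a: str, group_b: str) -> NeiDistanceResult:
    """Per-locus Nei (1972) distance ``D = -ln(J_xy / sqrt(J_x J_y))``.

    ``J`` terms use the biallelic frequencies; loci with identical fixed
    alleles give D = 0; opposite fixation gives ``J_xy = 0`` and a +inf
    sentinel which is excluded from the mean (with a count reported).
    """
    pa, na = _alt_freqs(gm.genotypes[gm.group_index(group_a)])
    pb, nb = _alt_freqs(gm.genotypes[gm.group_index(group_b)])
    usable = (na >= 1) & (nb >= 1)
    jx = pa**2 + (1 - pa) ** 2
    jy = pb**2 + (1 - pb) ** 2
    jxy = pa * pb + (1 - pa) * (1 - pb)
    with np.errstate(divide="ignore", invalid="ignore"):
        d = -np.log(jxy / np.sqrt(jx * jy))
    d = np.where(usable, d, np.nan)
    d = np.where(usable & (jxy == 0), np.inf, d)
    finite = usable & np.isfinite(d)
    return NeiDistanceResult(
        per_locus=d,
        mean=float(d[finite].mean()) if finite.any() else float("nan"),
        n_loci_used=int(usable.sum()),
        n_infinite=int((usable & np.isinf(d)).sum()),
    )


# --- PCA --------------------------------------------------------------------

@dataclass
class PcaResult:
    eigenvalues: np.ndarray
    coords: pd.DataFrame      # individuals x components
    n_loci_used: int


def genotype_pca(gm: GenotypeMatrix, n_components: int = 10) -> PcaResult:
    """PCA of individuals from standardized genotypes.

    Missing entries are imputed to the per-site mean; each site is
    centered by ``2p`` and scaled by ``sqrt(2p(1-p))`` (the standard
    allele-frequency standardization); monomorphic sites are excluded.
    Coordinates are the eigenvectors of the individual x individual
    covariance, reproducible up to sign.
    """
    geno = gm.genotypes.astype(float)
    called = gm.genotypes != MISSING
    n_c = called.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        mean_g = np.where(called, geno, 0).sum(axis=0) / n_c
    p = mean_g / 2.0
    keep = (n_c >= 2) & (p > 0) & (p < 1)
    if keep.sum() == 0:
        raise ValueError("no polymorphic sites for PCA")
    x = np.where(called, geno, mean_g)[:, keep]
    p = p[keep]
    x = (x - 2 * p) / np.sqrt(2 * p * (1 - p))
    cov = x @ x.T / x.shape[1]
    vals, vecs = np.linalg.eigh(cov)
    order = np.argsort(vals)[::-1]
    k = min(n_components, len(vals))
    vals = vals[order][:k]
    vecs = vecs[:, order][:, :k]
    coords = pd.DataFrame(
        vecs,
        index=gm.individuals,
        columns=[f"PC{i + 1}" for i in range(k)],
    )
    return PcaResult(eigenvalues=vals, coords=coords, n_loci_used=int(keep.sum()))
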