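"""Seven-criterion SNP filtering cascade for GBS-style variant data.

The cascade mirrors the common VCFtools workflow for
genotyping-by-sequencing SNPs, applied in a fixed order:

1. keep biallelic sites only;
2. set genotypes with read depth outside ``[min_dp, max_dp]`` to missing;
3. set genotypes with genotype quality below ``min_gq`` to missing;
4. keep sites called in at least ``1 - max_missing_fraction`` of samples;
5. keep sites with minor allele frequency >= ``min_maf`` over called
   genotypes;
6. keep sites with observed heterozygosity strictly below ``max_hobs``
   (removes likely paralog collapses);
7. group surviving SNPs by scaffold ("genomic locus") and discard all
   SNPs on scaffolds carrying more than ``max_snps_per_locus`` survivors
   (likely repetitive or error-prone regions).

Genotype-level masking (2, 3) precedes the site-level tests (4-6),
matching VCFtools ``--minDP/--minGQ`` semantics; the MAF threshold is
inclusive (``--maf``) while the heterozygosity cut is strict.

The module also provides a GBS read-noise generator that decorates clean
simulated genotypes with per-genotype depth (DP), quality (GQ) and
missingness so the cascade can be exercised end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .demography import MISSING, GenotypeMatrix


@dataclass
class VariantRecord:
    """One VCF site: genotypes as alt-allele counts plus DP/GQ."""

    scaffold: str
    pos: int                  # 1-based
    ref: str
    alt: list[str]
    gt: np.ndarray            # int8 in {0,1,2,MISSING}
    dp: np.ndarray | None = None
    gq: np.ndarray | None = None

    def copy(self) -> "VariantRecord":
        return VariantRecord(
            self.scaffold, self.pos, self.ref, list(self.alt),
            self.gt.copy(),
            None if self.dp is None else self.dp.copy(),
            None if self.gq is None else self.gq.copy(),
        )


@dataclass
class FilterConfig:
    min_alleles: int = 2
    max_alleles: int = 2
    min_dp: int = 5
    max_dp: int = 200
    min_gq: int = 20
    max_missing_fraction: float = 0.2   # presence >= 80%
    min_maf: float = 0.02
    max_hobs: float = 0.5               # strict <
    max_snps_per_locus: int = 9         # strict: discard loci with more

    def __post_init__(self) -> None:
        if not (0 <= self.max_missing_fraction <= 1):
            raise ValueError("max_missing_fraction must be in [0, 1]")
        if not (0 <= self.min_maf <= 1):
            raise ValueError("min_maf must be in [0, 1]")


@dataclass
class FilterReport:
    """Per-criterion site counts; counts never increase along the cascade."""

    stages: list[tuple[str, int, int]] = field(default_factory=list)
    final_snps: int = 0
    final_scaffolds: int = 0

    def add(self, name: str, n_in: int, n_out: int) -> None:
        if n_out > n_in:
            raise AssertionError("filter stage increased the site count")
        self.stages.append((name, n_in, n_out))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.stages, columns=["criterion", "sites_in", "sites_out"])
        return df

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


DEFAULT_GQ_MODEL = {"hom_scale": 4.0, "het_scale": 3.0, "sigma": 0.3}


def add_gbs_noise(
    gm: GenotypeMatrix,
    depth_mean: float = 30.0,
    gq_model: dict | None = None,
    missing_rate: float = 0.1,
    rng_seed: int = 0,
    dispersion: float = 5.0,
) -> list[VariantRecord]:
    """Decorate clean genotypes with GBS-like DP, GQ and missingness.

    * DP is negative-binomial around ``depth_mean`` (overdispersion
      ``dispersion``, the usual model for restriction-site read counts);
    * GQ grows with DP and is lower for heterozygotes, whose two alleles
      must both be sampled in the reads:
      ``GQ = min(99, round(scale * DP * exp(sigma * Z)))`` with
      ``scale = hom_scale`` or ``het_scale``;
    * each genotype is independently dropped to missing with probability
      ``missing_rate``; DP = 0 also forces a missing call.
    """
    if depth_mean <= 0:
        raise ValueError("depth_mean must be > 0")
    if not (0 <= missing_rate < 1):
        raise ValueError("missing_rate must be in [0, 1)")
    model = dict(DEFAULT_GQ_MODEL, **(gq_model or {}))
    rng = np.random.default_rng(rng_seed)
    n, L = gm.genotypes.shape
    p_nb = dispersion / (dispersion + depth_mean)
    dp = rng.negative_binomial(dispersion, p_nb, size=(n, L)).astype(np.int32)
    scale = np.where(gm.genotypes == 1, model["het_scale"], model["hom_scale"])
    jitter = np.exp(model["sigma"] * rng.standard_normal((n, L)))
    gq = np.minimum(99, np.round(scale * dp * jitter)).astype(np.int32)
    drop = rng.random((n, L)) < missing_rate
    gt = gm.genotypes.copy()
    gt[drop | (dp == 0)] = MISSING

    records = []
    for j in range(L):
        records.append(
            VariantRecord(
                scaffold=str(gm.loci["scaffold"].iloc[j]),
                pos=int(gm.loci["pos"].iloc[j]),
                ref=str(gm.loci["ref"].iloc[j]) if "ref" in gm.loci else "A",
                alt=[str(gm.loci["alt"].iloc[j])] if "alt" in gm.loci else ["G"],
                gt=gt[:, j].copy(),
                dp=dp[:, j].copy(),
                gq=gq[:, j].copy(),
            )
        )
    return records


def _site_stats(gt: np.ndarray) -> tuple[int, float, float]:
    called = gt != MISSING
    n_c = int(called.sum())
    if n_c == 0:
        return 0, 0.0, 0.0
    p = gt[called].sum() / (2.0 * n_c)
    maf = min(p, 1 - p)
    hobs = float((gt[called] == 1).mean())
    return n_c, maf, hobs


def apply_filters(
    records: Iterable[VariantRecord], config: FilterConfig | None = None
) -> tuple[list[VariantRecord], FilterReport]:
    """Run the seven-criterion cascade; returns survivors and a report."""
    config = config or FilterConfig()
    recs = [r.copy() for r in records]
    report = FilterReport()

    # 1 biallelic
    n_in = len(recs)
    recs = [
        r for r in recs
        if config.min_alleles - 1 <= len(r.alt) <= config.max_alleles - 1
    ]
    report.add("biallelic", n_in, len(recs))

    # 2 depth mask (genotype-level); 3 quality mask
    for r in recs:
        if r.dp is None or r.gq is None:
            raise ValueError(
                f"record {r.scaffold}:{r.pos} lacks DP/GQ; the cascade needs both"
            )
    for r in recs:
        bad = (r.dp < config.min_dp) | (r.dp > config.max_dp)
        r.gt[bad] = MISSING
    report.add("depth_mask", len(recs), len(recs))
    for r in recs:
        r.gt[r.gq < config.min_gq] = MISSING
    report.add("quality_mask", len(recs), len(recs))

    # 4 presence
    n_in = len(recs)
    min_presence = 1.0 - config.max_missing_fraction
    recs = [
        r for r in recs
        if (r.gt != MISSING).sum() / r.gt.size >= min_presence
    ]
    report.add("presence", n_in, len(recs))

    # 5 minor allele frequency (inclusive, over called genotypes)
    n_in = len(recs)
    recs = [r for r in recs if _site_stats(r.gt)[1] >= config.min_maf]
    report.add("maf", n_in, len(recs))

    # 6 observed heterozygosity (strict <)
    n_in = len(recs)
    recs = [r for r in recs if _site_stats(r.gt)[2] < config.max_hobs]
    report.add("hobs", n_in, len(recs))

    # 7 SNPs per genomic locus (= scaffold)
    n_in = len(recs)
    counts: dict[str, int] = {}
    for r in recs:
        counts[r.scaffold] = counts.get(r.scaffold, 0) + 1
    recs = [r for r in recs if counts[r.scaffold] <= config.max_snps_per_locus]
    report.add("snps_per_locus", n_in, len(recs))

    report.final_snps = len(recs)
    report.final_scaffolds = len({r.scaffold for r in recs})
    return recs, report


def select_one_snp_per_locus(
    records: Sequence[VariantRecord],
    rng_seed: int | None = None,
    mode: str = "first",
) -> list[VariantRecord]:
    """Keep exactly one SNP per scaffold.

    ``mode='first'`` keeps the lowest position (default); ``mode='random'``
    picks uniformly under ``rng_seed``.
    """
    if mode not in ("first", "random"):
        raise ValueError("mode must be 'first' or 'random'")
    by_scaffold: dict[str, list[VariantRecord]] = {}
    order: list[str] = []
    for r in records:
        if r.scaffold not in by_scaffold:
            order.append(r.scaffold)
        by_scaffold.setdefault(r.scaffold, []).append(r)
    rng = np.random.default_rng(rng_seed)
    out = []
    for s in order:
        group = sorted(by_scaffold[s], key=lambda r: r.pos)
        if mode == "first":
            out.append(group[0])
        else:
            out.append(group[int(rng.integers(len(group)))])
    return out


def records_to_matrix(
    records: Sequence[VariantRecord],
    samples: list[str],
    popmap: pd.DataFrame,
) -> GenotypeMatrix:
    """Assemble filtered records back into a genotype matrix."""
    pop = dict(zip(popmap["sample_id"], popmap["group"]))
    missing = [s for s in samples if s not in pop]
    if missing:
        raise ValueError(f"samples absent from popmap: {missing[:5]}")
    gt = np.stack([r.gt for r in records], axis=1) if records else np.empty(
        (len(samples), 0), dtype=np.int8
    )
    loci = pd.DataFrame(
        {
            "scaffold": [r.scaffold for r in records],
            "pos": [r.pos for r in records],
            "ref": [r.ref for r in records],
            "alt": [r.alt[0] if r.alt else "." for r in records],
        }
    )
    groups = np.array([pop[s] for s in samples])
    return GenotypeMatrix(gt.astype(np.int8), list(samples), groups, loci)
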