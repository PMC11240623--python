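"""Synthetic sheep-population generator.

Emulates the statistical structure a GWAS-prior genomic-selection analysis
relies on: many biallelic SNPs on 26 autosomes with distance-decaying
linkage disequilibrium, a quantitative trait (weaning weight, kg) driven by
a few sizeable QTL on top of a polygenic background at a target narrow-sense
heritability, and herd / birth-type fixed effects.

Haplotypes come from a first-order Markov process: a standard-normal latent
chain with AR(1) correlation ``exp(-distance / ld_rho)`` between adjacent
markers (``ld_rho`` is the LD correlation length in bp; 0 means free
recombination), thresholded at each marker's allele-frequency quantile.
Adjacent markers therefore show LD that decays smoothly with physical
distance; there is no pedigree, selection or mutation model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .plinkio import GenotypeMatrix, PhenotypeTable


class SimConfigError(ValueError):
    pass


@dataclass
class SimConfig:
    """Study-design parameters for the synthetic population.

    Defaults follow the design this package targets: ~1000 ewes genotyped at
    ~42K autosomal SNPs, weaning weight averaging 28.27 kg (sd 3.19 kg) with
    herd and birth-type effects, heritability 0.30.
    """

    n_samples: int = 1007
    n_markers: int = 41956
    n_chromosomes: int = 26
    chrom_length_bp: int = 100_000_000
    #: LD correlation length in bp: adjacent-marker latent correlation is
    #: exp(-distance / ld_rho); 0 disables LD (free recombination)
    ld_rho: float = 500_000.0
    maf_min: float = 0.05
    n_qtl: int = 10
    #: share of the genetic variance carried by the explicit QTL (the rest is
    #: a polygenic background over all remaining markers)
    qtl_variance_fraction: float = 0.5
    h2_target: float = 0.30
    trait_mean: float = 28.27
    trait_sd: float = 3.19
    herd_effects: Mapping[str, float] = field(
        default_factory=lambda: {"H1": 0.0, "H2": 0.9, "H3": -0.9, "H4": 1.8}
    )
    birth_type_effects: Mapping[str, float] = field(
        default_factory=lambda: {"1": 0.0, "2": -1.5}
    )
    #: if True, QTL effects are scaled by [2p(1-p)]^(-1/2) so rare alleles
    #: get larger effects
    af_scaled_effects: bool = False
    seed: int | None = None

    @classmethod
    def scaled_down(cls, n_samples: int, n_markers: int, **kwargs) -> "SimConfig":
        """A smaller population that keeps the default marker density.

        Shrinks the chromosome length in proportion to the marker count so
        inter-marker spacing — and hence the LD structure and the effective
        number of independent genome segments per marker — matches the
        full-scale defaults.  Use this for desk-scale fixtures; a small
        marker count spread over full-length chromosomes would have
        essentially LD-free markers and a much harder variance-component
        estimation problem than the design being emulated.
        """
        base = cls()
        scale = n_markers / base.n_markers
        length = max(int(base.chrom_length_bp * scale), 10_000)
        kwargs.setdefault("chrom_length_bp", length)
        return cls(n_samples=n_samples, n_markers=n_markers, **kwargs)

    def __post_init__(self) -> None:
        if not 0 < self.h2_target < 1:
            raise SimConfigError("h2_target must be in (0, 1)")
        if not 0 < self.maf_min < 0.5:
            raise SimConfigError("maf_min must be in (0, 0.5)")
        if self.ld_rho < 0:
            raise SimConfigError("ld_rho (LD correlation length, bp) must be >= 0")
        if self.n_qtl > self.n_markers:
            raise SimConfigError("n_qtl cannot exceed n_markers")
        if not 0 <= self.qtl_variance_fraction <= 1:
            raise SimConfigError("qtl_variance_fraction must be in [0, 1]")
        if self.n_samples < 2 or self.n_markers < 1 or self.n_chromosomes < 1:
            raise SimConfigError("population dimensions must be positive")


@dataclass
class SimTruth:
    """Ground truth of one simulated population, for parameter-recovery tests."""

    qtl_ids: list[str]
    qtl_effects: np.ndarray
    tbv: np.ndarray  # true breeding value per sample, kg deviation
    realized_h2: float
    herd: pd.Series
    birth_type: pd.Series


def _rng(cfg_seed: int | None, rng: np.random.Generator | None) -> np.random.Generator:
    if rng is not None:
        return rng
    return np.random.default_rng(cfg_seed)


def simulate_genotypes(
    cfg: SimConfig, rng: np.random.Generator | None = None
) -> GenotypeMatrix:
    """Draw a genotype matrix with Markov-chain LD along each chromosome."""
    rng = _rng(cfg.seed, rng)
    n, m = cfg.n_samples, cfg.n_markers

    # markers spread over chromosomes, positions uniform then sorted
    per_chrom = np.full(cfg.n_chromosomes, m // cfg.n_chromosomes)
    per_chrom[: m % cfg.n_chromosomes] += 1
    chroms, positions = [], []
    for c, k in enumerate(per_chrom, start=1):
        pos = np.sort(rng.integers(1, cfg.chrom_length_bp, size=k))
        # de-duplicate positions to keep the (chrom, pos) key strictly usable
        pos = pos + np.arange(k)
        chroms.append(np.full(k, c))
        positions.append(pos)
    chrom = np.concatenate(chroms)
    pos = np.concatenate(positions)

    freqs = rng.uniform(cfg.maf_min, 1 - cfg.maf_min, size=m)
    thresholds = norm.ppf(freqs)

    # latent AR(1) chain per haplotype; 2n haplotypes
    H = np.empty((2 * n, m), dtype=np.int8)
    z = rng.standard_normal(2 * n)
    start = 0
    for c, k in enumerate(per_chrom):
        cpos = pos[start : start + k]
        for j in range(k):
            if j == 0:
                z = rng.standard_normal(2 * n)
            else:
                r = (
                    np.exp(-(cpos[j] - cpos[j - 1]) / cfg.ld_rho)
                    if cfg.ld_rho > 0
                    else 0.0
                )
                z = r * z + np.sqrt(1 - r * r) * rng.standard_normal(2 * n)
            H[:, start + j] = z < thresholds[start + j]
        start += k

    dosages = (H[0::2] + H[1::2]).astype(np.int8)

    # keep every realized allele frequency away from fixation: top up columns
    # that drifted below the configured floor
    counts = dosages.sum(axis=0)
    lo = int(np.ceil(2 * n * cfg.maf_min))
    hi = 2 * n - lo
    for j in np.where((counts < lo) | (counts > hi))[0]:
        col = dosages[:, j].astype(np.int64)
        while col.sum() < lo:
            i = rng.choice(np.where(col < 2)[0])
            col[i] += 1
        while col.sum() > hi:
            i = rng.choice(np.where(col > 0)[0])
            col[i] -= 1
        dosages[:, j] = col.astype(np.int8)

    markers = pd.DataFrame(
        {
            "chrom": chrom,
            "id": [f"snp_{c}_{p}" for c, p in zip(chrom, pos)],
            "cm": 0.0,
            "pos": pos,
            "a1": "A",
            "a2": "G",
        }
    )
    samples = [f"ind{i + 1:04d}" for i in range(n)]
    return GenotypeMatrix(dosages, markers, samples)


def simulate_phenotypes(
    geno: GenotypeMatrix,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[PhenotypeTable, SimTruth]:
    """Lay a quantitative trait over a genotype matrix.

    Phenotype = mean + herd effect + birth-type effect + TBV + residual,
    where the true breeding value combines the configured QTL with a
    polygenic background over every other marker and is rescaled so that
    var(TBV) equals ``h2_target * trait_sd**2`` exactly in-sample.
    """
    if geno.has_missing:
        raise ValueError("genotypes must be imputed before phenotype simulation")
    rng = _rng(cfg.seed, rng)
    n, m = geno.n_samples, geno.n_markers
    var_g_target = cfg.h2_target * cfg.trait_sd**2

    W = geno.dosages.astype(float)
    W = W - W.mean(axis=0)

    qtl_idx = np.sort(rng.choice(m, size=cfg.n_qtl, replace=False)) if cfg.n_qtl else \
        np.array([], dtype=int)
    qtl_eff = rng.standard_normal(cfg.n_qtl)
    if cfg.af_scaled_effects and cfg.n_qtl:
        p = geno.dosages[:, qtl_idx].mean(axis=0) / 2.0
        qtl_eff = qtl_eff / np.sqrt(2 * p * (1 - p))

    g_qtl = W[:, qtl_idx] @ qtl_eff if cfg.n_qtl else np.zeros(n)
    bg_idx = np.setdiff1d(np.arange(m), qtl_idx)
    g_bg = W[:, bg_idx] @ rng.standard_normal(bg_idx.size) if bg_idx.size else \
        np.zeros(n)

    def _scaled(x: np.ndarray, target_var: float) -> np.ndarray:
        v = x.var()
        if v <= 0 or target_var <= 0:
            return np.zeros_like(x)
        return x * np.sqrt(target_var / v)

    f = cfg.qtl_variance_fraction if cfg.n_qtl else 0.0
    if bg_idx.size == 0:
        f = 1.0
    tbv = _scaled(g_qtl, f * var_g_target) + _scaled(g_bg, (1 - f) * var_g_target)
    qtl_eff_scaled = qtl_eff * (
        np.sqrt(f * var_g_target / g_qtl.var()) if cfg.n_qtl and g_qtl.var() > 0 else 0.0
    )

    residual = rng.standard_normal(n) * np.sqrt((1 - cfg.h2_target)) * cfg.trait_sd

    herd_levels = list(cfg.herd_effects)
    bt_levels = list(cfg.birth_type_effects)
    herd = pd.Series(rng.choice(herd_levels, size=n), index=geno.samples)
    birth = pd.Series(rng.choice(bt_levels, size=n), index=geno.samples)
    fixed = herd.map(cfg.herd_effects).to_numpy() + birth.map(
        cfg.birth_type_effects
    ).to_numpy()

    y = cfg.trait_mean + fixed + tbv + residual
    y = np.maximum(y, 0.01)  # weights are physically positive
    y = np.round(y, 2)  # recorded to two decimals, kg

    pheno = PhenotypeTable(
        pd.DataFrame(
            {
                "sample_id": geno.samples,
                "trait": y,
                "herd": herd.to_numpy(),
                "birth_type": birth.to_numpy(),
            }
        )
    )
    denom = tbv.var() + residual.var()
    truth = SimTruth(
        qtl_ids=[geno.markers["id"].iloc[i] for i in qtl_idx],
        qtl_effects=qtl_eff_scaled,
        tbv=tbv,
        realized_h2=float(tbv.var() / denom) if denom > 0 else 0.0,
        herd=herd,
        birth_type=birth,
    )
    return pheno, truth


def simulate_population(
    cfg: SimConfig, rng: np.random.Generator | None = None
) -> tuple[GenotypeMatrix, PhenotypeTable, SimTruth]:
    """Convenience wrapper: genotypes plus a trait in one call."""
    rng = _rng(cfg.seed, rng)
    geno = simulate_genotypes(cfg, rng=rng)
    pheno, truth = simulate_phenotypes(geno, cfg, rng=rng)
    return geno, pheno, truth


def split_population(
    samples: Sequence[str], seed: int | None = None
) -> tuple[list[str], list[str]]:
    """Randomly split sample ids into two near-equal disjoint groups.

    Sizes differ by at most one (the larger group second, e.g. 503 / 504).
    """
    samples = list(samples)
    if len(samples) < 2:
        raise ValueError("need at least two samples to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(samples))
    half = len(samples) // 2
    g1 = [samples[i] for i in sorted(perm[:half])]
    g2 = [samples[i] for i in sorted(perm[half:])]
    return g1, g2


__all__ = [
    "SimConfig",
    "SimTruth",
    "SimConfigError",
    "simulate_genotypes",
    "simulate_phenotypes",
    "simulate_population",
    "split_population",
]
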