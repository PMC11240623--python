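"""Genomic relationship matrices: VanRaden construction, marker-set
partitioning, variance-weighted blending, PSD conditioning and the usual
population diagnostics (PCA, LD decay).

The estimator is VanRaden's first method: dosages are column-centered by
twice the observed frequency of the counted allele and the cross-product is
normalized by ``2 * sum_i p_i (1 - p_i)``.  Two matrices built on a
partition of the marker set recombine exactly into the all-marker matrix
when weighted by their normalization denominators — a useful identity for
testing.  A prior-marker matrix ``G1`` and its complement ``G2`` are blended
as ``G3 = gamma * G1 + (1 - gamma) * G2`` with ``gamma`` equal to G1's share
of the two models' genetic variances.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .plinkio import GenotypeMatrix

log = logging.getLogger(__name__)


class GRMError(ValueError):
    pass


@dataclass
class GRM:
    """Symmetric sample-by-sample genomic relationship matrix."""

    values: np.ndarray
    samples: list[str]
    marker_count: int
    gamma: float | None = None
    conditioning_applied: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.samples = list(self.samples)
        n = len(self.samples)
        if self.values.shape != (n, n):
            raise GRMError(
                f"GRM shape {self.values.shape} does not match {n} sample ids"
            )
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise GRMError("GRM is not symmetric to 1e-10")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def subset(self, sample_ids: Sequence[str]) -> "GRM":
        pos = {s: i for i, s in enumerate(self.samples)}
        missing = [s for s in sample_ids if s not in pos]
        if missing:
            raise GRMError(f"samples absent from GRM: {missing[:5]}")
        idx = np.array([pos[s] for s in sample_ids])
        return replace(
            self, values=self.values[np.ix_(idx, idx)], samples=list(sample_ids)
        )

    # -- text round-trip ----------------------------------------------------

    def write_matrix(self, prefix: str | Path) -> None:
        """Plain whitespace matrix (``.grm.txt``) plus an ``.ids`` sidecar."""
        prefix = Path(prefix)
        np.savetxt(str(prefix) + ".grm.txt", self.values, fmt="%.10g")
        Path(str(prefix) + ".grm.ids").write_text("\n".join(self.samples) + "\n")

    def write_lower_triangle(self, prefix: str | Path) -> None:
        """GCTA-style uncompressed lower-triangle text: i j m_count value."""
        prefix = Path(prefix)
        with open(str(prefix) + ".grm", "w") as fh:
            for i in range(self.n_samples):
                for j in range(i + 1):
                    fh.write(
                        f"{i + 1}\t{j + 1}\t{self.marker_count}\t"
                        f"{self.values[i, j]:.10g}\n"
                    )
        Path(str(prefix) + ".grm.ids").write_text("\n".join(self.samples) + "\n")


def read_grm_matrix(prefix: str | Path) -> GRM:
    prefix = str(prefix)
    values = np.loadtxt(prefix + ".grm.txt")
    samples = Path(prefix + ".grm.ids").read_text().split()
    return GRM(values, samples, marker_count=0)


def read_grm_lower_triangle(prefix: str | Path) -> GRM:
    prefix = str(prefix)
    rec = pd.read_csv(prefix + ".grm", sep="\t", header=None,
                      names=["i", "j", "m", "v"])
    samples = Path(prefix + ".grm.ids").read_text().split()
    n = len(samples)
    values = np.zeros((n, n))
    values[rec["i"] - 1, rec["j"] - 1] = rec["v"]
    values = values + np.tril(values, -1).T
    return GRM(values, samples, marker_count=int(rec["m"].iloc[0]))


# ---------------------------------------------------------------------------
# construction
# ---------------------------------------------------------------------------


def vanraden_grm(geno: GenotypeMatrix) -> GRM:
    """VanRaden genomic relationship matrix from dosages.

    ``G = Z Z' / (2 * sum_i p_i (1 - p_i))`` with ``Z`` the dosage matrix
    column-centered by ``2 p_i``; ``p_i`` is the observed frequency of the
    counted allele in the samples at hand.  Monomorphic markers carry no
    information and are excluded from the denominator (with a warning).
    """
    if geno.has_missing:
        raise GRMError("impute missing dosages before building a GRM")
    M = geno.dosages.astype(float)
    p = M.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    if not poly.any():
        raise GRMError("all markers are monomorphic; GRM undefined")
    if not poly.all():
        warnings.warn(
            f"{int((~poly).sum())} monomorphic markers excluded from the "
            "GRM denominator",
            stacklevel=2,
        )
    Z = M[:, poly] - 2 * p[poly]
    denom = 2.0 * np.sum(p[poly] * (1 - p[poly]))
    values = (Z @ Z.T) / denom
    values = 0.5 * (values + values.T)
    return GRM(values, geno.samples, marker_count=int(poly.sum()))


def vanraden_denominator(geno: GenotypeMatrix) -> float:
    """The scaling constant ``2 * sum p(1-p)`` over polymorphic markers."""
    p = geno.dosages.astype(float).mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    return float(2.0 * np.sum(p[poly] * (1 - p[poly])))


def partition_markers(
    all_marker_ids: Sequence[str], prior
) -> tuple[list[str], list[str]]:
    """Split the marker list into (prior, remaining), preserving genome order.

    ``prior`` is a :class:`~priorblup.gwas.MarkerSet` or any sequence of ids.
    """
    prior_ids = list(getattr(prior, "ids", prior))
    all_ids = list(all_marker_ids)
    known = set(all_ids)
    unknown = [m for m in prior_ids if m not in known]
    if unknown:
        raise GRMError(f"prior markers absent from the map: {unknown[:5]}")
    prior_set = set(prior_ids)
    if not prior_set:
        raise GRMError("empty prior marker set: G1 undefined")
    if len(prior_set) == len(all_ids):
        raise GRMError("prior set covers every marker: G2 undefined")
    in_prior = [m for m in all_ids if m in prior_set]
    rest = [m for m in all_ids if m not in prior_set]
    return in_prior, rest


def blend_grm(g1: GRM, g2: GRM, var_g1: float, var_g2: float) -> GRM:
    """Blend prior and remainder kinships by their genetic-variance shares.

    ``gamma = var_g1 / (var_g1 + var_g2)``;
    ``G3 = gamma * G1 + (1 - gamma) * G2``.
    """
    if var_g1 < 0 or var_g2 < 0:
        raise GRMError("genetic variances must be non-negative")
    if var_g1 + var_g2 == 0:
        raise GRMError("both genetic variances are zero; blend undefined")
    if g1.samples != g2.samples:
        raise GRMError("G1 and G2 must share the same samples in the same order")
    gamma = var_g1 / (var_g1 + var_g2)
    values = gamma * g1.values + (1.0 - gamma) * g2.values
    return GRM(
        values,
        g1.samples,
        marker_count=g1.marker_count + g2.marker_count,
        gamma=float(gamma),
    )


def condition_psd(g: GRM, epsilon: float = 1e-6, min_eig: float = 1e-8) -> GRM:
    """Make a GRM safely invertible by inflating the diagonal if needed.

    If the minimum eigenvalue falls below ``min_eig``, add ``epsilon`` to the
    diagonal (repeatedly, doubling) until it does not; sets the
    ``conditioning_applied`` flag.  Already well-conditioned matrices are
    returned unchanged.
    """
    w = np.linalg.eigvalsh(g.values)
    lo = float(w[0])
    if lo >= min_eig:
        return g
    values = g.values.copy()
    bump = epsilon
    while lo < min_eig:
        shift = max(bump, min_eig - lo)
        values = values + shift * np.eye(values.shape[0])
        lo = float(np.linalg.eigvalsh(values)[0])
        bump *= 2
    log.info("condition_psd: diagonal inflated (min eigenvalue was %.3g)", w[0])
    return replace(g, values=values, conditioning_applied=True)


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------


def grm_pca(g: GRM, k: int) -> pd.DataFrame:
    """Principal coordinates of the double-centered relationship matrix.

    Returns a sample-by-PC table of eigenvector coordinates scaled by the
    square root of each eigenvalue; eigenvalues attach as ``.attrs``.
    """
    n = g.n_samples
    if k > n:
        raise GRMError(f"k={k} exceeds the number of samples ({n})")
    J = np.eye(n) - np.ones((n, n)) / n
    C = J @ g.values @ J
    w, v = np.linalg.eigh(0.5 * (C + C.T))
    order = np.argsort(w)[::-1][:k]
    eigvals = w[order]
    coords = v[:, order] * np.sqrt(np.maximum(eigvals, 0.0))
    out = pd.DataFrame(
        coords, index=pd.Index(g.samples, name="sample_id"),
        columns=[f"PC{i + 1}" for i in range(k)],
    )
    out.attrs["eigenvalues"] = eigvals
    return out


def ld_decay(
    geno: GenotypeMatrix, max_dist_bp: int = 1_000_000, bin_bp: int = 50_000
) -> pd.DataFrame:
    """Mean squared dosage correlation in physical-distance bins.

    Considers intra-chromosomal marker pairs up to ``max_dist_bp`` apart;
    returns one row per distance bin with the pair count and mean r².
    """
    if geno.has_missing:
        raise GRMError("impute missing dosages before LD analysis")
    D = geno.dosages.astype(float)
    sd = D.std(axis=0)
    chrom = geno.markers["chrom"].to_numpy()
    pos = geno.markers["pos"].to_numpy()

    n_bins = int(np.ceil(max_dist_bp / bin_bp))
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=int)
    Zs = (D - D.mean(axis=0)) / np.where(sd > 0, sd, np.inf)
    n = geno.n_samples
    for j in range(geno.n_markers - 1):
        upto = j + 1
        while (
            upto < geno.n_markers
            and chrom[upto] == chrom[j]
            and pos[upto] - pos[j] <= max_dist_bp
        ):
            upto += 1
        if upto == j + 1 or sd[j] == 0:
            continue
        r = Zs[:, j] @ Zs[:, j + 1 : upto] / n
        dist = pos[j + 1 : upto] - pos[j]
        b = np.minimum((dist - 1) // bin_bp, n_bins - 1)
        np.add.at(sums, b, r**2)
        np.add.at(counts, b, 1)

    if counts.sum() == 0:
        warnings.warn("no eligible marker pairs for LD decay", stacklevel=2)
    with np.errstate(invalid="ignore"):
        mean_r2 = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return pd.DataFrame(
        {
            "bin_start_bp": np.arange(n_bins) * bin_bp + 1,
            "bin_end_bp": (np.arange(n_bins) + 1) * bin_bp,
            "n_pairs": counts,
            "mean_r2": mean_r2,
        }
    )


__all__ = [
    "GRM",
    "GRMError",
    "vanraden_grm",
    "vanraden_denominator",
    "partition_markers",
    "blend_grm",
    "condition_psd",
    "grm_pca",
    "ld_decay",
    "read_grm_matrix",
    "read_grm_lower_triangle",
]
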