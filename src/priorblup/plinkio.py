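"""PLINK binary genotype I/O, quality control and mean imputation.

Genotypes are held as an ``n_samples x n_markers`` dosage matrix counting
copies of the A1 allele (column 5 of the ``.bim`` file); missing calls carry
the sentinel :data:`MISSING`.  Quality control runs the conventional
four-stage filter cascade (per-marker missingness, per-sample missingness,
minor-allele frequency, Hardy-Weinberg exact test), each stage operating on
the matrix that survived the previous one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: Sentinel for a missing genotype call.  Distinct from the valid dosages
#: {0, 1, 2}; downstream numeric code requires :func:`mean_impute` first.
MISSING: int = -9

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])

MARKER_COLUMNS = ["chrom", "id", "cm", "pos", "a1", "a2"]


class PlinkFormatError(ValueError):
    """Raised on malformed PLINK binary files."""


class QCError(ValueError):
    """Raised when quality control empties the dataset."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class GenotypeMatrix:
    """Sample-by-marker dosage matrix with its marker map and sample ids.

    Parameters
    ----------
    dosages
        ``(n_samples, n_markers)`` array of A1-allele counts in
        ``{0, 1, 2, MISSING}`` (integer) or real-valued after imputation.
    markers
        Marker map with columns ``chrom, id, cm, pos, a1, a2``, sorted by
        ``(chrom, pos)``.
    samples
        Ordered sample identifiers.
    """

    dosages: np.ndarray
    markers: pd.DataFrame
    samples: list[str]

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (samples x markers)")
        self.markers = self.markers.reset_index(drop=True)
        self.samples = list(self.samples)
        self.validate()

    # -- basic introspection ------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosages.shape[1]

    @property
    def has_missing(self) -> bool:
        return bool(np.any(self.dosages == MISSING))

    def validate(self) -> None:
        n, m = self.dosages.shape
        if len(self.samples) != n:
            raise ValueError(f"{len(self.samples)} sample ids for {n} rows")
        if len(self.markers) != m:
            raise ValueError(f"{len(self.markers)} marker records for {m} columns")
        if self.markers["id"].duplicated().any():
            dups = self.markers.loc[self.markers["id"].duplicated(), "id"].tolist()
            raise ValueError(f"duplicate marker ids: {dups[:5]}")
        key = self.markers[["chrom", "pos"]].to_numpy()
        if m > 1:
            ordered = np.all(
                (np.diff(key[:, 0]) > 0)
                | ((np.diff(key[:, 0]) == 0) & (np.diff(key[:, 1]) >= 0))
            )
            if not ordered:
                raise ValueError("markers must be sorted by (chrom, pos)")
        if np.issubdtype(self.dosages.dtype, np.integer):
            vals = np.unique(self.dosages)
            bad = set(vals.tolist()) - {0, 1, 2, MISSING}
            if bad:
                raise ValueError(f"invalid dosage codes: {sorted(bad)}")

    # -- views --------------------------------------------------------------

    def take_markers(self, index: np.ndarray | Sequence[int]) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            self.dosages[:, index], self.markers.iloc[index], self.samples
        )

    def take_samples(self, index: np.ndarray | Sequence[int]) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            self.dosages[index, :],
            self.markers,
            [self.samples[i] for i in index],
        )

    def subset_samples(self, sample_ids: Sequence[str]) -> "GenotypeMatrix":
        pos = {s: i for i, s in enumerate(self.samples)}
        missing = [s for s in sample_ids if s not in pos]
        if missing:
            raise KeyError(f"unknown sample ids: {missing[:5]}")
        return self.take_samples([pos[s] for s in sample_ids])

    def subset_markers(self, marker_ids: Sequence[str]) -> "GenotypeMatrix":
        pos = {mid: i for i, mid in enumerate(self.markers["id"])}
        missing = [mid for mid in marker_ids if mid not in pos]
        if missing:
            raise KeyError(f"unknown marker ids: {missing[:5]}")
        idx = sorted(pos[mid] for mid in marker_ids)
        return self.take_markers(idx)

    def allele_freqs(self) -> np.ndarray:
        """Observed frequency of the counted (A1) allele per marker."""
        d = np.ma.masked_equal(self.dosages, MISSING)
        return np.asarray(d.mean(axis=0) / 2.0)


@dataclass
class PhenotypeTable:
    """Per-sample trait records (kg) plus herd and birth-type levels."""

    data: pd.DataFrame  # columns: sample_id, trait, herd, birth_type
    n_dropped: int = 0

    def __post_init__(self) -> None:
        required = {"sample_id", "trait", "herd", "birth_type"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"phenotype table missing columns: {sorted(missing)}")
        df = self.data.reset_index(drop=True).copy()
        df["sample_id"] = df["sample_id"].astype(str)
        df["herd"] = df["herd"].astype(str)
        df["birth_type"] = df["birth_type"].astype(str)
        df["trait"] = pd.to_numeric(df["trait"])
        if df["sample_id"].duplicated().any():
            dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
            raise ValueError(f"duplicate sample ids: {dups[:5]}")
        if not np.all(np.isfinite(df["trait"])) or not np.all(df["trait"] > 0):
            raise ValueError("trait values must be finite and positive")
        if (df["herd"].str.len() == 0).any() or (df["birth_type"].str.len() == 0).any():
            raise ValueError("fixed-effect levels must be non-empty")
        self.data = df

    @property
    def sample_ids(self) -> list[str]:
        return self.data["sample_id"].tolist()

    def subset(self, sample_ids: Sequence[str]) -> "PhenotypeTable":
        df = self.data.set_index("sample_id").loc[list(sample_ids)].reset_index()
        return PhenotypeTable(df)

    def trait_vector(self, sample_order: Sequence[str]) -> np.ndarray:
        s = self.data.set_index("sample_id")["trait"]
        return s.loc[list(sample_order)].to_numpy(float)


@dataclass
class QCReport:
    """Per-stage removal tallies of the QC cascade."""

    n_markers_in: int
    n_samples_in: int
    markers_removed_missingness: int = 0
    samples_removed_missingness: int = 0
    markers_removed_maf: int = 0
    markers_removed_hwe: int = 0
    n_markers_out: int = 0
    n_samples_out: int = 0

    def __post_init__(self) -> None:
        counts = [
            self.n_markers_in,
            self.n_samples_in,
            self.markers_removed_missingness,
            self.samples_removed_missingness,
            self.markers_removed_maf,
            self.markers_removed_hwe,
            self.n_markers_out,
            self.n_samples_out,
        ]
        if any(c < 0 for c in counts):
            raise ValueError("QC counts must be non-negative")
        if self.n_markers_out and (
            self.n_markers_in
            != self.n_markers_out
            + self.markers_removed_missingness
            + self.markers_removed_maf
            + self.markers_removed_hwe
        ):
            raise ValueError("marker counts not additive")
        if self.n_samples_out and (
            self.n_samples_in != self.n_samples_out + self.samples_removed_missingness
        ):
            raise ValueError("sample counts not additive")

    def to_dict(self) -> dict:
        return dict(self.__dict__)


# ---------------------------------------------------------------------------
# PLINK binary read / write
# ---------------------------------------------------------------------------

# 2-bit .bed codes, SNP-major: 00 = hom A1 (dosage 2), 01 = missing,
# 10 = het (1), 11 = hom A2 (0).  Sample 0 sits in the lowest-order bits.
_CODE_TO_DOSAGE = np.array([2, MISSING, 1, 0], dtype=np.int8)
_DOSAGE_TO_CODE = {2: 0b00, MISSING: 0b01, 1: 0b10, 0: 0b11}

_BYTE_LUT = np.empty((256, 4), dtype=np.int8)
for _b in range(256):
    for _s in range(4):
        _BYTE_LUT[_b, _s] = _CODE_TO_DOSAGE[(_b >> (2 * _s)) & 0b11]


def read_plink(
    bed_path: str | Path,
    bim_path: str | Path | None = None,
    fam_path: str | Path | None = None,
) -> GenotypeMatrix:
    """Read a PLINK 1 binary fileset into a :class:`GenotypeMatrix`.

    ``bed_path`` may be a prefix (``data`` for ``data.bed/.bim/.fam``) or the
    ``.bed`` file itself; the sidecars default to the matching names.
    Dosages count the A1 allele (``.bim`` column 5).
    """
    bed = Path(bed_path)
    if bed.suffix != ".bed":
        bed = bed.with_suffix(".bed")
    bim = Path(bim_path) if bim_path else bed.with_suffix(".bim")
    fam = Path(fam_path) if fam_path else bed.with_suffix(".fam")
    for p in (bed, bim, fam):
        if not p.exists():
            raise FileNotFoundError(p)

    markers = pd.read_csv(
        bim, sep=r"\s+", header=None, names=MARKER_COLUMNS,
        dtype={"chrom": int, "id": str, "cm": float, "pos": int, "a1": str, "a2": str},
    )
    fam_df = pd.read_csv(fam, sep=r"\s+", header=None)
    samples = fam_df[1].astype(str).tolist()

    raw = np.fromfile(bed, dtype=np.uint8)
    if raw[:3].tobytes() != _BED_MAGIC:
        raise PlinkFormatError(f"{bed}: bad magic bytes (not SNP-major PLINK v1)")
    n, m = len(samples), len(markers)
    bpm = (n + 3) // 4  # bytes per marker block
    body = raw[3:]
    if body.size != m * bpm:
        raise PlinkFormatError(
            f"{bed}: {body.size} data bytes, expected {m * bpm} "
            f"for {n} samples x {m} markers"
        )
    blocks = body.reshape(m, bpm)
    dosages = _BYTE_LUT[blocks].reshape(m, bpm * 4)[:, :n].T.copy()
    return GenotypeMatrix(dosages, markers, samples)


def write_plink(geno: GenotypeMatrix, prefix: str | Path) -> None:
    """Write a :class:`GenotypeMatrix` as PLINK 1 ``.bed/.bim/.fam``."""
    if not np.issubdtype(geno.dosages.dtype, np.integer):
        raise ValueError("cannot write imputed (real-valued) dosages to .bed")
    prefix = Path(prefix)
    mk = geno.markers
    with open(prefix.with_suffix(".bim"), "w") as fh:
        for row in mk.itertuples(index=False):
            fh.write(
                f"{row.chrom}\t{row.id}\t{row.cm:g}\t{row.pos}\t{row.a1}\t{row.a2}\n"
            )
    with open(prefix.with_suffix(".fam"), "w") as fh:
        for s in geno.samples:
            fh.write(f"{s}\t{s}\t0\t0\t0\t-9\n")

    n, m = geno.n_samples, geno.n_markers
    bpm = (n + 3) // 4
    codes = np.empty((m, bpm * 4), dtype=np.uint8)
    padded = np.full((m, bpm * 4), 0, dtype=np.int8)
    padded[:, :n] = geno.dosages.T
    for dose, code in _DOSAGE_TO_CODE.items():
        codes[padded == dose] = code
    codes[:, n:] = 0b00  # pad bits; by convention hom-A1 padding is ignored
    shifted = codes.reshape(m, bpm, 4) << np.array([0, 2, 4, 6], dtype=np.uint8)
    body = shifted.sum(axis=2, dtype=np.uint8)
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(body.tobytes())


# ---------------------------------------------------------------------------
# quality control
# ---------------------------------------------------------------------------


def hwe_exact_p(n_hom1: int, n_het: int, n_hom2: int) -> float:
    """Two-sided Hardy-Weinberg exact-test p-value on genotype counts.

    Enumerates every heterozygote count compatible with the observed allele
    counts and sums the probabilities of outcomes no more likely than the
    observed one (the standard SNP-HWE exact test, no mid-p correction).
    """
    if min(n_hom1, n_het, n_hom2) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_hom1 + n_het + n_hom2
    if n == 0:
        return 1.0
    n_rare = 2 * min(n_hom1, n_hom2) + n_het
    # heterozygote counts share the parity of the rare-allele count
    het_values = np.arange(n_rare % 2, min(n_rare, 2 * n - n_rare) + 1, 2)
    if het_values.size == 0:
        return 1.0
    from scipy.special import gammaln

    def log_prob(h: np.ndarray) -> np.ndarray:
        hom_r = (n_rare - h) // 2
        hom_c = n - hom_r - h
        return (
            h * np.log(2.0)
            + gammaln(n + 1)
            - gammaln(h + 1)
            - gammaln(hom_r + 1)
            - gammaln(hom_c + 1)
            + gammaln(n_rare + 1)
            + gammaln(2 * n - n_rare + 1)
            - gammaln(2 * n + 1)
        )

    lp = log_prob(het_values)
    lp -= np.logaddexp.reduce(lp)  # normalize for numerical safety
    obs = np.where(het_values == n_het)[0]
    if obs.size == 0:  # impossible het count for these allele counts
        raise ValueError("heterozygote count incompatible with allele counts")
    p_obs = lp[obs[0]]
    keep = lp <= p_obs + 1e-12
    return float(min(1.0, np.exp(np.logaddexp.reduce(lp[keep]))))


def hwe_chi2_p(n_hom1: int, n_het: int, n_hom2: int) -> float:
    """One-degree-of-freedom chi-square HWE test (alternative to the exact test)."""
    from scipy.stats import chi2

    n = n_hom1 + n_het + n_hom2
    if n == 0:
        return 1.0
    p = (2 * n_hom1 + n_het) / (2 * n)
    q = 1 - p
    exp = np.array([n * p * p, 2 * n * p * q, n * q * q])
    obs = np.array([n_hom1, n_het, n_hom2], dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.nansum(np.where(exp > 0, (obs - exp) ** 2 / exp, 0.0))
    return float(chi2.sf(stat, df=1))


def _marker_missing_rate(d: np.ndarray) -> np.ndarray:
    return (d == MISSING).mean(axis=0)


def _marker_maf(d: np.ndarray) -> np.ndarray:
    masked = np.ma.masked_equal(d, MISSING)
    p = np.asarray(masked.mean(axis=0) / 2.0)
    p = np.where(np.isfinite(p), p, 0.0)
    return np.minimum(p, 1 - p)


def apply_qc(
    geno: GenotypeMatrix,
    geno_thresh: float = 0.1,
    mind_thresh: float = 0.1,
    maf_thresh: float = 0.01,
    hwe_alpha: float = 1e-6,
    hwe_method: str = "exact",
) -> tuple[GenotypeMatrix, QCReport]:
    """Four-stage SNP/sample quality control.

    Stages, each applied to the survivors of the previous one:

    1. drop markers with missing-call rate > ``geno_thresh``;
    2. drop samples with missing-call rate > ``mind_thresh``;
    3. drop markers with minor-allele frequency < ``maf_thresh``;
    4. drop markers whose HWE test p-value < ``hwe_alpha``.
    """
    for name, v in [("geno", geno_thresh), ("mind", mind_thresh), ("maf", maf_thresh)]:
        if not 0 <= v <= 1:
            raise ValueError(f"{name} threshold must be in [0, 1]")
    if not 0 < hwe_alpha < 1:
        raise ValueError("hwe_alpha must be in (0, 1)")
    hwe_fn = {"exact": hwe_exact_p, "chi2": hwe_chi2_p}[hwe_method]

    report = QCReport(n_markers_in=geno.n_markers, n_samples_in=geno.n_samples)
    g = geno

    keep = _marker_missing_rate(g.dosages) <= geno_thresh
    report.markers_removed_missingness = int((~keep).sum())
    if not keep.any():
        raise QCError("all markers removed at the per-marker missingness stage")
    g = g.take_markers(np.where(keep)[0])

    keep_s = (g.dosages == MISSING).mean(axis=1) <= mind_thresh
    report.samples_removed_missingness = int((~keep_s).sum())
    if not keep_s.any():
        raise QCError("all samples removed at the per-sample missingness stage")
    g = g.take_samples(np.where(keep_s)[0])

    keep = _marker_maf(g.dosages) >= maf_thresh
    report.markers_removed_maf = int((~keep).sum())
    if not keep.any():
        raise QCError("all markers removed at the MAF stage")
    g = g.take_markers(np.where(keep)[0])

    pvals = np.empty(g.n_markers)
    for j in range(g.n_markers):
        col = g.dosages[:, j]
        obs = col[col != MISSING]
        pvals[j] = hwe_fn(int((obs == 2).sum()), int((obs == 1).sum()),
                          int((obs == 0).sum()))
    keep = pvals >= hwe_alpha
    report.markers_removed_hwe = int((~keep).sum())
    if not keep.any():
        raise QCError("all markers removed at the HWE stage")
    g = g.take_markers(np.where(keep)[0])

    report.n_markers_out = g.n_markers
    report.n_samples_out = g.n_samples
    log.info(
        "QC: %d/%d markers, %d/%d samples retained "
        "(missingness %d markers, %d samples; MAF %d; HWE %d)",
        report.n_markers_out, report.n_markers_in,
        report.n_samples_out, report.n_samples_in,
        report.markers_removed_missingness, report.samples_removed_missingness,
        report.markers_removed_maf, report.markers_removed_hwe,
    )
    return g, report


def mean_impute(geno: GenotypeMatrix) -> GenotypeMatrix:
    """Replace missing dosages by the marker's mean observed dosage.

    Returns a real-valued matrix; non-missing entries are unchanged.
    """
    d = geno.dosages
    if np.issubdtype(d.dtype, np.floating) and not np.any(d == MISSING):
        return geno
    mask = d == MISSING
    if mask.all(axis=0).any():
        raise QCError(
            "fully-missing marker present; run apply_qc before mean_impute"
        )
    out = d.astype(np.float64)
    obs = np.where(mask, 0.0, out)
    counts = (~mask).sum(axis=0)
    means = obs.sum(axis=0) / counts
    out[mask] = np.broadcast_to(means, out.shape)[mask]
    return GenotypeMatrix(out, geno.markers, geno.samples)


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------


def read_phenotypes(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    delimiter: str | None = None,
) -> PhenotypeTable:
    """Read a delimited phenotype/covariate table.

    ``column_map`` maps the canonical names ``sample_id / trait / herd /
    birth_type`` to the file's column headers (identity by default).  Rows
    with a missing trait value are dropped and counted.
    """
    cmap = {k: k for k in ("sample_id", "trait", "herd", "birth_type")}
    if column_map:
        cmap.update(column_map)
    df = pd.read_csv(path, sep=delimiter, engine="python" if delimiter is None else "c")
    missing_cols = [v for v in cmap.values() if v not in df.columns]
    if missing_cols:
        raise ValueError(f"columns not found in {path}: {missing_cols}")
    df = df[[cmap[k] for k in cmap]].copy()
    df.columns = list(cmap.keys())
    n0 = len(df)
    df = df.dropna(subset=["trait"])
    dropped = n0 - len(df)
    if dropped:
        log.info("read_phenotypes: dropped %d rows with missing trait", dropped)
    return PhenotypeTable(df.reset_index(drop=True), n_dropped=dropped)


__all__ = [
    "MISSING",
    "GenotypeMatrix",
    "PhenotypeTable",
    "QCReport",
    "PlinkFormatError",
    "QCError",
    "read_plink",
    "write_plink",
    "apply_qc",
    "mean_impute",
    "read_phenotypes",
    "hwe_exact_p",
    "hwe_chi2_p",
]
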