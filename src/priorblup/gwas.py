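"""Marker-trait association: fixed-effect scans and a FarmCPU-style
iterative model, plus top-percentile prior-marker selection.

The scan regresses the phenotype on each marker in turn alongside the fixed
covariates and any current pseudo-QTNs (large-effect markers promoted to
covariates), reporting the marker coefficient's two-sided t-test p-value.
FarmCPU alternates that fixed-effect scan with a random-effect step that
re-selects the pseudo-QTN set: candidate sets of spacing-filtered top
markers are scored by the REML likelihood of a kinship model built from the
candidate markers themselves, and the best-scoring set becomes the next
iteration's covariates.  Iteration stops when the set repeats.

The top-k% smallest-p markers form the "prior marker information" consumed
by the blended-kinship genomic-selection pipeline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .plinkio import GenotypeMatrix, PhenotypeTable

log = logging.getLogger(__name__)


class GwasError(ValueError):
    pass


@dataclass
class MarkerSet:
    """An ordered set of selected marker ids with its provenance."""

    ids: list[str]
    fraction: float | None = None
    source: str = ""

    def __post_init__(self) -> None:
        if len(set(self.ids)) != len(self.ids):
            raise GwasError("marker set contains duplicate ids")

    def __len__(self) -> int:
        return len(self.ids)


@dataclass
class GwasResult:
    """Per-marker scan statistics plus the final pseudo-QTN set."""

    table: pd.DataFrame  # chrom, pos, id, effect, se, p, is_pseudo_qtn
    pseudo_qtn_ids: list[str]
    n_iterations: int
    converged: bool
    covariate_names: list[str] = field(default_factory=list)
    iteration_logliks: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        p = self.table["p"].to_numpy()
        if np.any((p < 0) | (p > 1)):
            raise GwasError("p-values outside [0, 1]")
        known = set(self.table["id"])
        stray = [q for q in self.pseudo_qtn_ids if q not in known]
        if stray:
            raise GwasError(f"pseudo-QTNs not among tested markers: {stray[:5]}")

    def select_top(self, fraction: float) -> MarkerSet:
        return select_top(self, fraction)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# fixed-effect scan
# ---------------------------------------------------------------------------


def _scan_group(
    D: np.ndarray,
    cols: np.ndarray,
    base: np.ndarray,
    y: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized per-marker OLS t-tests given a shared covariate block.

    Residualizes the response and each marker against ``base`` (the
    Frisch-Waugh projection), then runs the marker-coefficient t-test with
    ``n - rank(base) - 1`` degrees of freedom.
    """
    n = len(y)
    Q, _ = np.linalg.qr(base)
    k = Q.shape[1]
    ry = y - Q @ (Q.T @ y)
    W = D[:, cols]
    RW = W - Q @ (Q.T @ W)
    denom = np.einsum("ij,ij->j", RW, RW)
    colnorm = np.einsum("ij,ij->j", W, W)
    ok = denom > 1e-10 * np.maximum(colnorm, 1.0)
    df = n - k - 1
    beta = np.zeros(len(cols))
    se = np.full(len(cols), np.nan)
    p = np.ones(len(cols))
    if df > 0 and ok.any():
        beta[ok] = (RW[:, ok].T @ ry) / denom[ok]
        sse = np.maximum(ry @ ry - beta[ok] ** 2 * denom[ok], 0.0)
        sigma2 = sse / df
        with np.errstate(divide="ignore", invalid="ignore"):
            se_ok = np.sqrt(sigma2 / denom[ok])
            t = np.where(se_ok > 0, beta[ok] / se_ok, np.inf * np.sign(beta[ok]))
        se[ok] = se_ok
        p[ok] = 2.0 * stats.t.sf(np.abs(t), df)
    if (~ok).any():
        log.info("scan: %d collinear markers flagged with p=1", int((~ok).sum()))
    return beta, se, p, ok


def glm_scan(
    geno: GenotypeMatrix,
    y: np.ndarray,
    covariates: np.ndarray,
    qtn_covariate_ids: Sequence[str] = (),
    spacing_bp: int = 1_000_000,
) -> GwasResult:
    """One pass of the fixed-effect marker scan.

    Each marker is tested in ``y ~ covariates + pseudo-QTN dosages +
    marker``.  Markers inside a pseudo-QTN's spacing window (the pseudo-QTN
    itself included) are tested with that pseudo-QTN dropped from the
    covariates, so a locus is never adjusted for itself or a near-duplicate.
    Collinear markers are flagged (p = 1).
    """
    if geno.has_missing:
        raise GwasError("impute missing dosages before the scan")
    D = geno.dosages.astype(float)
    y = np.asarray(y, float)
    X0 = np.asarray(covariates, float)
    if X0.ndim != 2 or X0.shape[0] != len(y) or len(y) != geno.n_samples:
        raise GwasError("covariates must be (n_samples, c) aligned with y")

    mk = geno.markers
    id_pos = {mid: i for i, mid in enumerate(mk["id"])}
    qtn_ids = list(qtn_covariate_ids)
    missing_q = [q for q in qtn_ids if q not in id_pos]
    if missing_q:
        raise GwasError(f"unknown pseudo-QTN ids: {missing_q[:5]}")
    qtn_idx = np.array([id_pos[q] for q in qtn_ids], dtype=int)

    chrom = mk["chrom"].to_numpy()
    pos = mk["pos"].to_numpy()
    m = geno.n_markers

    # bitmask per marker of which pseudo-QTNs must be dropped from its design
    group_key = np.zeros(m, dtype=np.int64)
    for qi, q in enumerate(qtn_idx):
        window = (chrom == chrom[q]) & (np.abs(pos - pos[q]) <= spacing_bp)
        group_key[window] |= 1 << qi

    beta = np.zeros(m)
    se = np.full(m, np.nan)
    pvals = np.ones(m)
    flagged = np.zeros(m, dtype=bool)
    for key in np.unique(group_key):
        cols = np.where(group_key == key)[0]
        keep_q = [i for i in range(len(qtn_idx)) if not (key >> i) & 1]
        base = (
            np.column_stack([X0, D[:, qtn_idx[keep_q]]]) if len(keep_q) else X0.copy()
        )
        b, s, p, ok = _scan_group(D, cols, base, y)
        beta[cols], se[cols], pvals[cols] = b, s, p
        flagged[cols] = ~ok

    table = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": pos,
            "id": mk["id"].to_numpy(),
            "effect": beta,
            "se": se,
            "p": pvals,
            "is_pseudo_qtn": np.isin(np.arange(m), qtn_idx),
        }
    )
    return GwasResult(
        table,
        pseudo_qtn_ids=qtn_ids,
        n_iterations=1,
        converged=True,
        covariate_names=[f"cov{i}" for i in range(X0.shape[1])],
    )


# ---------------------------------------------------------------------------
# FarmCPU
# ---------------------------------------------------------------------------


@dataclass
class FarmCPUParams:
    """Iteration controls for the fixed/random alternating model."""

    max_iter: int = 10
    spacing_bp: int = 1_000_000
    candidate_sizes: tuple[int, ...] = (2, 4, 8, 16)
    prefilter_p: float = 0.01
    #: stop after the first scan when no marker reaches this p-value;
    #: None means 0.01 / n_markers (guards against promoting chance hits
    #: to covariates under a null trait)
    seed_p: float | None = None


class FarmCPU:
    """FarmCPU-style iterative association model.

    Parameters
    ----------
    geno
        Imputed genotypes for the discovery population.
    pheno
        Phenotype table covering the genotyped samples (herd and birth type
        become fixed covariates).
    params
        Iteration controls; see :class:`FarmCPUParams`.
    """

    def __init__(
        self,
        geno: GenotypeMatrix,
        pheno: PhenotypeTable,
        params: FarmCPUParams | None = None,
    ) -> None:
        from .gblup import build_design

        self.geno = geno.subset_samples(pheno.sample_ids)
        self.params = params or FarmCPUParams()
        self.design = build_design(pheno, self.geno.samples)
        # align records to genotype row order
        order = np.argsort(self.design.record_sample_index)
        self.y = self.design.y[order]
        self.X0 = self.design.X[order]

    # -- random-effect step -------------------------------------------------

    def _candidate_loglik(self, marker_ids: Sequence[str]) -> float:
        from .gblup import GBLUP, MixedModelDesign
        from .grm import condition_psd, vanraden_grm

        sub = self.geno.subset_markers(list(marker_ids))
        try:
            g = condition_psd(vanraden_grm(sub))
        except Exception:
            return -np.inf
        design = MixedModelDesign(
            self.y,
            self.X0,
            [f"cov{i}" for i in range(self.X0.shape[1])],
            np.arange(len(self.y)),
            self.geno.samples,
        )
        try:
            res = GBLUP(design, g).fit(max_iter=50)
        except Exception:
            return -np.inf
        return res.vc.loglik

    def _spaced_candidates(self, table: pd.DataFrame, limit: int) -> list[str]:
        sig = table[table["p"] < self.params.prefilter_p]
        sig = sig.sort_values(["p", "chrom", "pos"], kind="stable")
        chosen: list[tuple[int, int, str]] = []
        for row in sig.itertuples(index=False):
            if any(
                c == row.chrom and abs(p - row.pos) <= self.params.spacing_bp
                for c, p, _ in chosen
            ):
                continue
            chosen.append((row.chrom, row.pos, row.id))
            if len(chosen) >= limit:
                break
        return [mid for _, _, mid in chosen]

    def fit(self) -> GwasResult:
        """Alternate the marker scan and the pseudo-QTN selection step."""
        p = self.params
        qtns: list[str] = []
        history = [frozenset()]
        iter_logliks: list[float] = []
        converged = False
        scan = None
        scan_qtns: list[str] | None = None
        it = 0
        seed_p = p.seed_p if p.seed_p is not None else 0.01 / self.geno.n_markers
        for it in range(1, p.max_iter + 1):
            scan = glm_scan(self.geno, self.y, self.X0, qtns, p.spacing_bp)
            scan_qtns = list(qtns)

            if it == 1 and float(scan.table["p"].min()) >= seed_p:
                converged = True  # nothing near significance: plain scan stands
                break

            cand = self._spaced_candidates(scan.table, max(p.candidate_sizes))
            if not cand:
                new: list[str] = []
            else:
                sizes = sorted({min(s, len(cand)) for s in p.candidate_sizes})
                options: list[list[str]] = [cand[:s] for s in sizes]
                if qtns and qtns not in options:
                    options.append(list(qtns))  # keeps the step monotone
                lls = [self._candidate_loglik(o) for o in options]
                best = int(np.argmax(lls))
                iter_logliks.append(float(lls[best]))
                new = options[best]

            key = frozenset(new)
            if key in history:
                qtns = new
                converged = True
                break
            history.append(key)
            qtns = new

        if scan is None or scan_qtns != qtns:
            scan = glm_scan(self.geno, self.y, self.X0, qtns, p.spacing_bp)
        if not converged:
            log.warning("FarmCPU did not converge in %d iterations", p.max_iter)
        return GwasResult(
            scan.table,
            pseudo_qtn_ids=list(qtns),
            n_iterations=it,
            converged=converged,
            covariate_names=self.design.fixed_names,
            iteration_logliks=iter_logliks,
        )


def farmcpu(
    geno: GenotypeMatrix,
    pheno: PhenotypeTable,
    params: FarmCPUParams | None = None,
) -> GwasResult:
    """Functional wrapper: ``FarmCPU(geno, pheno, params).fit()``."""
    return FarmCPU(geno, pheno, params).fit()


# ---------------------------------------------------------------------------
# prior-marker selection
# ---------------------------------------------------------------------------


def select_top(result: GwasResult, fraction: float) -> MarkerSet:
    """The round(fraction * m) markers with the smallest p-values.

    Rounding is round-half-even; ties at the cut break by (p, chrom, pos).
    """
    if not 0 < fraction <= 1:
        raise GwasError("fraction must be in (0, 1]")
    m = len(result.table)
    n_sel = round(fraction * m)
    if n_sel < 1:
        raise GwasError(f"fraction {fraction} selects no markers out of {m}")
    ranked = result.table.sort_values(["p", "chrom", "pos"], kind="stable")
    ids = ranked["id"].head(n_sel).tolist()
    return MarkerSet(ids, fraction=fraction, source=f"top {fraction:.0%} by scan p")


def bonferroni_threshold(m: int, alpha: float = 0.05) -> float:
    """Genome-wide significance threshold ``alpha / m``."""
    if m < 1:
        raise GwasError("m must be >= 1")
    if not 0 < alpha <= 1:
        raise GwasError("alpha must be in (0, 1]")
    return alpha / m


__all__ = [
    "MarkerSet",
    "GwasResult",
    "GwasError",
    "FarmCPU",
    "FarmCPUParams",
    "farmcpu",
    "glm_scan",
    "select_top",
    "bonferroni_threshold",
]
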