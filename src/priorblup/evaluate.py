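"""Cross-validated prediction accuracy and the two-group study driver.

Accuracy follows the genomic-prediction convention: the population is split
into k folds; for each fold the mixed model is re-fitted on the remaining
folds and breeding values of the held-out individuals are predicted through
the relationship matrix; the Pearson correlation between held-out GEBVs and
(fixed-effect-adjusted) phenotypes, averaged over folds and divided by the
square root of the heritability, is the reported accuracy.  "Promotion" is
the percent change of a blended-kinship accuracy over the plain-G baseline.

:func:`run_two_group_design` reproduces the full experimental layout: split
the population in two, run the GWAS on one half, build prior/remainder
kinships on the other, blend them by their REML genetic-variance shares and
compare cross-validated accuracies against the all-marker baseline — in
both directions.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .gblup import GBLUP, build_design, gblup_predict
from .grm import GRM, blend_grm, condition_psd, partition_markers, vanraden_grm
from .gwas import FarmCPU, FarmCPUParams, select_top
from .plinkio import GenotypeMatrix, PhenotypeTable
from .simulate import split_population

log = logging.getLogger(__name__)


class EvaluationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# folds
# ---------------------------------------------------------------------------


def kfold_split(
    sample_ids: Sequence[str], k: int, seed: int | None = None
) -> pd.Series:
    """Random k-fold partition; fold sizes differ by at most one.

    Returns a Series of fold indices (1..k) indexed by sample id,
    deterministic for a fixed seed.
    """
    ids = list(sample_ids)
    n = len(ids)
    if k < 2:
        raise EvaluationError("k must be >= 2")
    if k > n:
        raise EvaluationError(f"k={k} exceeds the number of samples ({n})")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    folds = np.empty(n, dtype=int)
    sizes = np.full(k, n // k)
    sizes[: n % k] += 1
    start = 0
    for f, size in enumerate(sizes, start=1):
        folds[perm[start : start + size]] = f
        start += size
    return pd.Series(folds, index=pd.Index(ids, name="sample_id"), name="fold")


@dataclass
class CVResult:
    """k-fold cross-validation outcome for one relationship matrix."""

    fold_assignments: pd.Series
    fold_r: list[float]
    mean_r: float
    accuracy: float
    h2_used: float
    seed: int | None
    denominator: str = "sqrt_h2"


def _fixed_values(
    pheno: PhenotypeTable, fixed_names: list[str], beta: np.ndarray
) -> np.ndarray:
    """Fixed-effect fitted values for arbitrary rows under a trained coding."""
    coef = dict(zip(fixed_names, beta))
    out = np.full(len(pheno.data), coef.get("intercept", 0.0))
    for factor in ("herd", "birth_type"):
        levels = pheno.data[factor].to_numpy()
        out += np.array([coef.get(f"{factor}[{lev}]", 0.0) for lev in levels])
    return out


def cv_accuracy(
    pheno: PhenotypeTable,
    grm: GRM,
    k: int = 5,
    seed: int | None = None,
    denominator: str = "sqrt_h2",
    adjust_phenotype: bool = True,
    h2: float | None = None,
    folds: pd.Series | None = None,
) -> CVResult:
    """Cross-validated prediction accuracy of GBLUP under one GRM.

    Per fold: REML + GBLUP on the other k-1 folds, GEBVs for the held-out
    fold through the (single, shared) relationship matrix, Pearson r between
    held-out GEBVs and fixed-effect-adjusted phenotypes.  Accuracy is
    ``mean r / sqrt(h2)`` with h2 from the full-group REML fit (the ``h2``
    denominator convention is available via ``denominator="h2"``).
    """
    if denominator not in ("sqrt_h2", "h2"):
        raise EvaluationError("denominator must be 'sqrt_h2' or 'h2'")
    samples = pheno.sample_ids
    grm = grm.subset(samples)
    if h2 is None:
        h2 = GBLUP.from_tables(pheno, grm).fit().vc.h2
    if folds is None:
        folds = kfold_split(samples, k, seed)
    else:
        if sorted(folds.index) != sorted(samples):
            raise EvaluationError("supplied folds must cover exactly the samples")
        k = folds.nunique()

    fold_r: list[float] = []
    for f in sorted(folds.unique()):
        val_ids = folds.index[folds == f].tolist()
        train_pheno = pheno.subset([s for s in samples if s not in set(val_ids)])
        design = build_design(train_pheno, samples)
        res = GBLUP(design, grm).fit()
        gebv = gblup_predict(design, grm, res.vc, val_ids).data.set_index("sample_id")
        gv = gebv.loc[val_ids, "gebv"].to_numpy()

        val_pheno = pheno.subset(val_ids)
        yv = val_pheno.data["trait"].to_numpy(float)
        if adjust_phenotype:
            yv = yv - _fixed_values(val_pheno, design.fixed_names, res.beta)
        if np.std(gv) == 0 or np.std(yv) == 0:
            warnings.warn(f"fold {f}: zero-variance GEBVs, r recorded as 0",
                          stacklevel=2)
            fold_r.append(0.0)
        else:
            fold_r.append(float(np.corrcoef(gv, yv)[0, 1]))

    mean_r = float(np.mean(fold_r))
    if h2 <= 0:
        raise EvaluationError("non-positive heritability; accuracy undefined")
    denom = np.sqrt(h2) if denominator == "sqrt_h2" else h2
    return CVResult(
        fold_assignments=folds,
        fold_r=fold_r,
        mean_r=mean_r,
        accuracy=float(mean_r / denom),
        h2_used=float(h2),
        seed=seed,
        denominator=denominator,
    )


# ---------------------------------------------------------------------------
# summary arithmetic
# ---------------------------------------------------------------------------


def promotion(accuracy_base: float, accuracy_new: float) -> float:
    """Percent change in accuracy relative to the baseline, to 2 dp."""
    if accuracy_base == 0:
        raise EvaluationError("baseline accuracy is zero; promotion undefined")
    return round(100.0 * (accuracy_new - accuracy_base) / accuracy_base, 2)


def descriptive_stats(pheno: PhenotypeTable | Sequence[float]) -> pd.Series:
    """Trait summary row: n, mean, sd, median, trimmed mean, MAD, min, max, se.

    sd uses the n-1 denominator; the trimmed mean drops 10% in each tail;
    the dispersion column is the median absolute deviation scaled by 1.4826.
    """
    x = (
        pheno.data["trait"].to_numpy(float)
        if isinstance(pheno, PhenotypeTable)
        else np.asarray(pheno, float)
    )
    n = len(x)
    if n < 2:
        raise EvaluationError("need at least two records for summary statistics")
    sd = float(np.std(x, ddof=1))
    return pd.Series(
        {
            "n": n,
            "mean": float(np.mean(x)),
            "sd": sd,
            "median": float(np.median(x)),
            "trimmed": float(stats.trim_mean(x, 0.1)),
            "mad": float(stats.median_abs_deviation(x, scale="normal")),
            "min": float(np.min(x)),
            "max": float(np.max(x)),
            "se": sd / np.sqrt(n),
        }
    )


# ---------------------------------------------------------------------------
# the two-group cross design
# ---------------------------------------------------------------------------


@dataclass
class DesignReport:
    """Scenario table of the two-group study (one row per matrix fitted)."""

    table: pd.DataFrame
    config: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        g3 = self.table[self.table["matrix"] == "G3"]
        if g3["accuracy"].isna().any():
            raise EvaluationError("G3 rows must carry an accuracy")

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for key, val in self.config.items():
                fh.write(f"# {key}: {val}\n")
            self.table.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def _scenario_rows(
    direction: str,
    val_geno: GenotypeMatrix,
    val_pheno: PhenotypeTable,
    gwas_result,
    fractions: Sequence[float],
    k: int,
    seed: int | None,
    denominator: str,
) -> list[dict]:
    design = build_design(val_pheno, val_pheno.sample_ids)
    rows: list[dict] = []

    G = condition_psd(vanraden_grm(val_geno))
    vc_g = GBLUP(design, G).fit().vc
    cv_g = cv_accuracy(val_pheno, G, k=k, seed=seed, denominator=denominator,
                       h2=vc_g.h2)
    rows.append(
        dict(direction=direction, prior_fraction=np.nan, matrix="G",
             genetic_variance=vc_g.sigma_a2, environmental_variance=vc_g.sigma_e2,
             heritability=vc_g.h2, weight=np.nan, accuracy=cv_g.accuracy,
             promotion_pct=np.nan)
    )
    base_acc = cv_g.accuracy

    all_ids = val_geno.markers["id"].tolist()
    for frac in fractions:
        prior = select_top(gwas_result, frac)
        p_ids, r_ids = partition_markers(all_ids, prior)
        G1 = condition_psd(vanraden_grm(val_geno.subset_markers(p_ids)))
        G2 = condition_psd(vanraden_grm(val_geno.subset_markers(r_ids)))
        vc1 = GBLUP(design, G1).fit().vc
        vc2 = GBLUP(design, G2).fit().vc
        G3 = condition_psd(blend_grm(G1, G2, vc1.sigma_a2, vc2.sigma_a2))
        vc3 = GBLUP(design, G3).fit().vc
        cv3 = cv_accuracy(val_pheno, G3, k=k, seed=seed, denominator=denominator,
                          h2=vc3.h2)
        gamma = G3.gamma
        rows.extend(
            [
                dict(direction=direction, prior_fraction=frac, matrix="G1",
                     genetic_variance=vc1.sigma_a2,
                     environmental_variance=vc1.sigma_e2,
                     heritability=vc1.h2, weight=gamma, accuracy=np.nan,
                     promotion_pct=np.nan),
                dict(direction=direction, prior_fraction=frac, matrix="G2",
                     genetic_variance=vc2.sigma_a2,
                     environmental_variance=vc2.sigma_e2,
                     heritability=vc2.h2, weight=1.0 - gamma, accuracy=np.nan,
                     promotion_pct=np.nan),
                dict(direction=direction, prior_fraction=frac, matrix="G3",
                     genetic_variance=vc3.sigma_a2,
                     environmental_variance=vc3.sigma_e2,
                     heritability=vc3.h2, weight=np.nan, accuracy=cv3.accuracy,
                     promotion_pct=promotion(base_acc, cv3.accuracy)),
            ]
        )
    return rows


def run_two_group_design(
    geno: GenotypeMatrix,
    pheno: PhenotypeTable,
    fractions: Sequence[float] = (0.05, 0.10, 0.15, 0.20),
    seed: int | None = 0,
    k: int = 5,
    directions: Sequence[str] = ("1to2", "2to1"),
    farmcpu_params: FarmCPUParams | None = None,
    denominator: str = "sqrt_h2",
) -> DesignReport:
    """End-to-end two-group cross design.

    Splits the population in half; for each requested direction the
    discovery half is scanned with FarmCPU, the top-k% markers define the
    prior kinship G1 and their complement G2 on the validation half, the two
    REML genetic variances set the blend weight of G3, and five-fold
    cross-validated accuracies of G3 and the all-marker baseline G are
    compared (the "promotion" percentage).
    """
    bad = [f for f in fractions if not 0 < f < 1]
    if bad:
        raise EvaluationError(f"fractions must lie in (0, 1): {bad}")
    ids = [s for s in geno.samples if s in set(pheno.sample_ids)]
    g1_ids, g2_ids = split_population(ids, seed)

    rows: list[dict] = []
    for direction in directions:
        disc_ids, val_ids = (g1_ids, g2_ids) if direction == "1to2" else (
            g2_ids, g1_ids)
        try:
            scan = FarmCPU(
                geno.subset_samples(disc_ids), pheno.subset(disc_ids),
                farmcpu_params,
            ).fit()
            rows.extend(
                _scenario_rows(
                    direction,
                    geno.subset_samples(val_ids),
                    pheno.subset(val_ids),
                    scan,
                    fractions,
                    k,
                    seed,
                    denominator,
                )
            )
        except Exception as exc:
            raise EvaluationError(f"direction {direction} failed: {exc}") from exc

    table = pd.DataFrame(rows)
    config = dict(
        fractions=list(fractions), seed=seed, k=k,
        directions=list(directions), denominator=denominator,
        n_samples=len(ids), n_markers=geno.n_markers,
        group_sizes=(len(g1_ids), len(g2_ids)),
    )
    return DesignReport(table, config)


__all__ = [
    "CVResult",
    "DesignReport",
    "EvaluationError",
    "kfold_split",
    "cv_accuracy",
    "promotion",
    "descriptive_stats",
    "run_two_group_design",
]
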