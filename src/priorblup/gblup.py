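"""GBLUP: the genomic mixed model ``y = Xb + Zu + e`` fitted by REML.

The random genetic effect ``u ~ N(0, G * sigma_a2)`` has the genomic
relationship matrix as its covariance structure and ``e ~ N(0, I *
sigma_e2)``.  Variance components are estimated by average-information REML
with expectation-maximization fallback steps; breeding values solve
Henderson's mixed-model equations, with validation individuals predicted
through the relationship matrix that links them to the training records.

The model is exposed statsmodels-style: build a :class:`GBLUP` from a
phenotype table and a :class:`~priorblup.grm.GRM`, call :meth:`GBLUP.fit`,
and read estimates, GEBVs and the summary off the returned
:class:`GBLUPResults`.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, qr

from .grm import GRM
from .plinkio import PhenotypeTable

log = logging.getLogger(__name__)


class ModelError(ValueError):
    pass


# ---------------------------------------------------------------------------
# design
# ---------------------------------------------------------------------------


@dataclass
class MixedModelDesign:
    """Aligned response, fixed-effect design and record-to-sample incidence.

    ``record_sample_index[i]`` gives the position in ``sample_order`` of the
    genotyped sample that record ``i`` belongs to (the incidence matrix Z in
    index form; one record per sample here).
    """

    y: np.ndarray
    X: np.ndarray
    fixed_names: list[str]
    record_sample_index: np.ndarray
    sample_order: list[str]

    def __post_init__(self) -> None:
        n = len(self.y)
        if self.X.shape[0] != n or len(self.record_sample_index) != n:
            raise ModelError("y, X and the incidence index must align row-wise")

    @property
    def n_records(self) -> int:
        return len(self.y)

    @property
    def record_ids(self) -> list[str]:
        return [self.sample_order[i] for i in self.record_sample_index]


def build_design(
    pheno: PhenotypeTable, sample_order: Sequence[str]
) -> MixedModelDesign:
    """Treatment-coded fixed-effect design (intercept + herd + birth type).

    The first level of each factor is the reference; aliased (collinear)
    columns are dropped with a log message so X has full column rank.
    Factors with a single level contribute no columns.
    """
    sample_order = list(sample_order)
    pos = {s: i for i, s in enumerate(sample_order)}
    missing = [s for s in pheno.sample_ids if s not in pos]
    if missing:
        raise ModelError(f"phenotyped samples missing from sample_order: {missing[:5]}")
    df = pheno.data
    y = df["trait"].to_numpy(float)

    cols = [np.ones(len(df))]
    names = ["intercept"]
    for factor in ("herd", "birth_type"):
        levels = sorted(df[factor].unique())
        for lev in levels[1:]:
            cols.append((df[factor] == lev).to_numpy(float))
            names.append(f"{factor}[{lev}]")
        if len(levels) == 1:
            log.info("build_design: factor %r has a single level, no columns", factor)

    X = np.column_stack(cols)
    # rank repair: pivoted QR, drop aliased columns
    _, R, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag[0] * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    if rank < X.shape[1]:
        dropped = sorted(piv[rank:])
        log.warning(
            "build_design: dropped aliased columns %s",
            [names[i] for i in dropped],
        )
        keep = sorted(piv[:rank])
        X = X[:, keep]
        names = [names[i] for i in keep]

    for factor in ("herd", "birth_type"):
        singletons = df[factor].value_counts()
        ones = singletons[singletons == 1]
        if len(ones):
            log.warning(
                "build_design: %s level(s) %s have a single observation",
                factor, list(ones.index),
            )

    rec_idx = np.array([pos[s] for s in df["sample_id"]])
    return MixedModelDesign(y, X, names, rec_idx, sample_order)


# ---------------------------------------------------------------------------
# variance components
# ---------------------------------------------------------------------------


@dataclass
class VarianceComponents:
    """REML estimates of the additive and residual variances (kg²)."""

    sigma_a2: float
    sigma_e2: float
    loglik: float
    n_iter: int
    converged: bool
    h2: float = field(init=False)

    def __post_init__(self) -> None:
        if self.sigma_a2 < 0 or self.sigma_e2 <= 0:
            raise ModelError("sigma_a2 must be >= 0 and sigma_e2 > 0")
        self.h2 = self.sigma_a2 / (self.sigma_a2 + self.sigma_e2)


def heritability(sigma_a2: float, sigma_e2: float) -> float:
    """Narrow-sense heritability ``sigma_a2 / (sigma_a2 + sigma_e2)``."""
    if sigma_a2 < 0 or sigma_e2 < 0:
        raise ValueError("variance components must be non-negative")
    total = sigma_a2 + sigma_e2
    if total == 0:
        raise ValueError("both variance components are zero")
    return sigma_a2 / total


@dataclass
class GEBVTable:
    """Predicted breeding values (kg deviation) with training-set flags."""

    data: pd.DataFrame  # columns: sample_id, gebv, in_training

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.data["gebv"])):
            raise ModelError("non-finite GEBV")

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# the model object
# ---------------------------------------------------------------------------


class GBLUP:
    """Genomic BLUP mixed model for one trait.

    Parameters
    ----------
    design
        Aligned response/design/incidence, from :func:`build_design`.
    grm
        Relationship matrix covering (at least) every sample in
        ``design.sample_order``; it is re-ordered internally.
    """

    def __init__(self, design: MixedModelDesign, grm: GRM) -> None:
        self.design = design
        self.grm = grm.subset(design.sample_order)
        n = design.n_records
        if n < design.X.shape[1] + 2:
            raise ModelError("too few records for the fixed-effect design")
        # records covariance block: with one record per sample, Z G Z' is a
        # row/column selection of G
        idx = design.record_sample_index
        self._G_rr = self.grm.values[np.ix_(idx, idx)]
        self._eig_d, self._eig_U = np.linalg.eigh(self._G_rr)
        self._yt = self._eig_U.T @ design.y
        self._Xt = self._eig_U.T @ design.X

    @classmethod
    def from_tables(
        cls, pheno: PhenotypeTable, grm: GRM, sample_order: Sequence[str] | None = None
    ) -> "GBLUP":
        """Build the model from a phenotype table and a GRM.

        ``sample_order`` defaults to the GRM's samples, so non-phenotyped
        genotyped individuals remain predictable.
        """
        order = list(sample_order) if sample_order is not None else list(grm.samples)
        return cls(build_design(pheno, order), grm)

    # -- restricted likelihood machinery -----------------------------------

    def _with_weights(self, a: float, e: float):
        w = 1.0 / (a * self._eig_d + e)
        if np.any(w <= 0) or not np.all(np.isfinite(w)):
            return None
        WX = self._Xt * w[:, None]
        XtWX = self._Xt.T @ WX
        try:
            cf = cho_factor(XtWX)
        except np.linalg.LinAlgError:
            return None
        XtWy = WX.T @ self._yt
        beta = cho_solve(cf, XtWy)
        Py = w * self._yt - WX @ beta
        return w, WX, XtWX, cf, beta, Py

    def reml_loglik(self, sigma_a2: float, sigma_e2: float) -> float:
        """Restricted log-likelihood (up to an additive constant)."""
        parts = self._with_weights(sigma_a2, sigma_e2)
        if parts is None:
            return -np.inf
        w, _WX, XtWX, cf, _beta, Py = parts
        logdetV = -np.sum(np.log(w))
        sign, logdetXtWX = np.linalg.slogdet(XtWX)
        if sign <= 0:
            return -np.inf
        return float(-0.5 * (logdetV + logdetXtWX + self._yt @ Py))

    def _score_ai(self, a: float, e: float):
        parts = self._with_weights(a, e)
        if parts is None:
            return None
        w, WX, XtWX, cf, _beta, Py = parts
        d = self._eig_d

        def P(v: np.ndarray) -> np.ndarray:
            return w * v - WX @ cho_solve(cf, WX.T @ v)

        trPD = float(np.sum(w * d) - np.trace(cho_solve(cf, WX.T @ (d[:, None] * WX))))
        trPI = float(np.sum(w) - np.trace(cho_solve(cf, WX.T @ WX)))
        DPy = d * Py
        score = np.array(
            [
                -0.5 * (trPD - Py @ DPy),
                -0.5 * (trPI - Py @ Py),
            ]
        )
        PDPy = P(DPy)
        PPy = P(Py)
        ai = 0.5 * np.array(
            [[DPy @ PDPy, DPy @ PPy], [DPy @ PPy, Py @ PPy]]
        )
        em_grad = np.array([Py @ DPy - trPD, Py @ Py - trPI])
        return score, ai, em_grad

    def fit(
        self,
        start: tuple[float, float] | None = None,
        max_iter: int = 100,
        tol: float = 1e-8,
    ) -> "GBLUPResults":
        """AI-REML with EM fallback; returns a :class:`GBLUPResults`."""
        y = self.design.y
        vary = float(np.var(y, ddof=1))
        if vary <= 0:
            raise ModelError("response has zero variance")
        floor = 1e-8 * vary
        n = self.design.n_records
        theta = np.array(start if start is not None else (vary / 2, vary / 2), float)
        theta = np.maximum(theta, floor)

        ll = self.reml_loglik(*theta)
        path = [ll]
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            sa = self._score_ai(*theta)
            if sa is None:
                break
            score, ai, em_grad = sa
            delta = None
            try:
                delta = np.linalg.solve(ai, score)
                if not np.all(np.isfinite(delta)):
                    delta = None
            except np.linalg.LinAlgError:
                delta = None

            accepted = False
            if delta is not None:
                step = 1.0
                for _ in range(12):
                    cand = np.maximum(theta + step * delta, floor)
                    ll_new = self.reml_loglik(*cand)
                    if ll_new >= ll - 1e-12:
                        theta, ll_cand = cand, ll_new
                        accepted = True
                        break
                    step *= 0.5
            if not accepted:
                # EM-style scaled-gradient step; always an ascent direction
                cand = np.maximum(theta + (theta**2 / n) * em_grad, floor)
                ll_new = self.reml_loglik(*cand)
                if ll_new < ll - 1e-10:
                    log.debug("REML: EM step rejected at iter %d", it)
                    break
                theta, ll_cand = cand, ll_new
                log.debug("REML: EM fallback step at iter %d", it)

            path.append(ll_cand)
            if abs(ll_cand - ll) < tol:
                ll = ll_cand
                converged = True
                break
            ll = ll_cand

        if not converged:
            log.warning("REML did not converge in %d iterations", max_iter)
        vc = VarianceComponents(
            sigma_a2=float(theta[0] if theta[0] > floor else 0.0),
            sigma_e2=float(theta[1]),
            loglik=float(ll),
            n_iter=it,
            converged=converged,
        )
        parts = self._with_weights(max(theta[0], floor), theta[1])
        _w, _WX, XtWX, cf, beta, _Py = parts
        beta_cov = cho_solve(cf, np.eye(XtWX.shape[0]))
        return GBLUPResults(self, vc, np.asarray(beta), beta_cov, path)


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------


class GBLUPResults:
    """Estimates, uncertainties and predictions from a fitted GBLUP model."""

    def __init__(
        self,
        model: GBLUP,
        vc: VarianceComponents,
        beta: np.ndarray,
        beta_cov: np.ndarray,
        loglik_path: list[float],
    ) -> None:
        self.model = model
        self.vc = vc
        self.beta = beta
        self.beta_cov = beta_cov
        self.loglik_path = loglik_path

    @property
    def fixed_effects(self) -> pd.DataFrame:
        se = np.sqrt(np.maximum(np.diag(self.beta_cov), 0.0))
        return pd.DataFrame(
            {"coef": self.beta, "se": se},
            index=self.model.design.fixed_names,
        )

    def predict(self, predict_ids: Sequence[str] | None = None) -> GEBVTable:
        """GEBVs for every sample in the GRM.

        Records of samples in ``predict_ids`` are withheld from training;
        their breeding values come through the relationship matrix.
        """
        return gblup_predict(
            self.model.design, self.model.grm, self.vc, predict_ids or []
        )

    def summary(self) -> str:
        d = self.model.design
        lines = [
            "GBLUP mixed model (REML)",
            "=" * 44,
            f"records: {d.n_records}    genotyped samples: {len(d.sample_order)}",
            f"fixed-effect columns: {d.X.shape[1]}",
            "-" * 44,
            f"sigma_a2 (genetic, kg^2):   {self.vc.sigma_a2:10.4f}",
            f"sigma_e2 (residual, kg^2):  {self.vc.sigma_e2:10.4f}",
            f"h2 (narrow-sense):          {self.vc.h2:10.4f}",
            f"REML log-likelihood:        {self.vc.loglik:10.4f}",
            f"iterations: {self.vc.n_iter}    converged: {self.vc.converged}",
            "-" * 44,
            "fixed effects:",
        ]
        fe = self.fixed_effects
        for name, row in fe.iterrows():
            lines.append(f"  {name:<22s} {row['coef']:10.4f}  (se {row['se']:.4f})")
        lines.append("=" * 44)
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# functional surface
# ---------------------------------------------------------------------------


def reml_fit(
    design: MixedModelDesign,
    g: GRM,
    start: tuple[float, float] | None = None,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> VarianceComponents:
    """Fit variance components; thin wrapper over :meth:`GBLUP.fit`."""
    return GBLUP(design, g).fit(start=start, max_iter=max_iter, tol=tol).vc


def gblup_predict(
    design: MixedModelDesign,
    g: GRM,
    vc: VarianceComponents,
    predict_ids: Sequence[str],
) -> GEBVTable:
    """Solve the mixed-model equations on training records and predict GEBVs.

    Training records are those whose sample is not in ``predict_ids``.  All
    individuals share one relationship matrix; validation phenotypes are
    simply withheld, so validation GEBVs flow through the genomic
    relationships to the training set.  (Computed in the equivalent
    variance-matrix form of Henderson's equations:
    ``u = sigma_a2 * G[:, train] V^-1 (y - X beta)`` with
    ``V = sigma_a2 * G_tt + sigma_e2 * I``.)
    """
    g = g.subset(design.sample_order)
    predict_set = set(predict_ids)
    unknown = predict_set - set(design.sample_order)
    if unknown:
        raise ModelError(f"predict ids absent from the GRM: {sorted(unknown)[:5]}")
    rec_ids = design.record_ids
    train_mask = np.array([s not in predict_set for s in rec_ids])
    if train_mask.sum() < design.X.shape[1] + 1:
        raise ModelError("too few training records after withholding predict_ids")

    n_all = len(design.sample_order)
    if vc.sigma_a2 <= 0:
        warnings.warn("sigma_a2 is zero: all GEBVs are zero", stacklevel=2)
        u = np.zeros(n_all)
    else:
        t_rec = np.where(train_mask)[0]
        t_smp = design.record_sample_index[t_rec]
        yt = design.y[t_rec]
        Xt = design.X[t_rec]
        Vt = vc.sigma_a2 * g.values[np.ix_(t_smp, t_smp)] + vc.sigma_e2 * np.eye(
            len(t_rec)
        )
        cf = cho_factor(Vt)
        ViX = cho_solve(cf, Xt)
        beta = np.linalg.solve(Xt.T @ ViX, ViX.T @ yt)
        resid = yt - Xt @ beta
        Vir = cho_solve(cf, resid)
        u = vc.sigma_a2 * (g.values[:, t_smp] @ Vir)

    trained_samples = {rec_ids[i] for i in np.where(train_mask)[0]}
    table = pd.DataFrame(
        {
            "sample_id": design.sample_order,
            "gebv": u,
            "in_training": [s in trained_samples for s in design.sample_order],
        }
    )
    return GEBVTable(table)


__all__ = [
    "MixedModelDesign",
    "VarianceComponents",
    "GEBVTable",
    "GBLUP",
    "GBLUPResults",
    "ModelError",
    "build_design",
    "reml_fit",
    "heritability",
    "gblup_predict",
]
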