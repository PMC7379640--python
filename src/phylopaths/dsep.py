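"""The d-separation path-analysis engine.

For each candidate causal DAG, every basis-set independence claim is
tested by a phylogenetic regression (PGLS for continuous responses,
phylogenetic logistic for the binary outcome); the claim p-values combine
into Fisher's C = −2 Σ ln p, referred to a χ² distribution with 2k d.f.
Models are ranked by CICc = C + 2q·n/(n − 1 − q), and path coefficients of
the supported models (ΔCICc below threshold, d-sep p above α) are combined
by conditional model averaging with CICc weights.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .graphs import CausalDAG, IndependenceClaim, ModelSet, basis_set
from .regression import RegressionFit, fit_pgls, fit_phylo_logistic
from .traits import StandardizedDesign
from .tree import PhyloCovariance

log = logging.getLogger(__name__)

__all__ = [
    "DsepFit",
    "SelectionTable",
    "AveragedModel",
    "fishers_c",
    "cicc",
    "run_dsep",
    "select_models",
    "average_paths",
    "PhylogeneticPathAnalysis",
]

_P_FLOOR = 1e-300


def fishers_c(claim_pvalues) -> tuple[float, int, float]:
    """Fisher's C statistic of a set of independence-claim p-values.

    Returns ``(C, df, p)`` with C = −2 Σ ln p_i, df = 2k and p the upper
    χ²(df) tail at C.  An empty claim list is the saturated model:
    (0, 0, 1).  Zero p-values are clipped to 1e-300 with a warning.
    """
    p = np.asarray(list(claim_pvalues), dtype=float)
    if p.size == 0:
        return 0.0, 0, 1.0
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("claim p-values must lie in [0, 1]")
    if np.any(p == 0):
        warnings.warn(
            "claim p-value of 0 clipped to 1e-300 before taking logs",
            stacklevel=2,
        )
        p = np.clip(p, _P_FLOOR, 1.0)
    c = float(-2.0 * np.sum(np.log(p)))
    df = 2 * p.size
    return c, df, float(stats.chi2.sf(c, df))


def cicc(C: float, q: int, n: int) -> float:
    """C-statistic information criterion with small-sample correction:

        CICc = C + 2q · n / (n − 1 − q)

    where q is the number of free path coefficients and n the number of
    species.  Undefined (raises) when n ≤ q + 1.
    """
    if n <= q + 1:
        raise ValueError(f"CICc undefined for n={n} <= q+1={q + 1}")
    return float(C) + 2.0 * q * n / (n - 1.0 - q)


@dataclass
class ClaimResult:
    claim: IndependenceClaim
    p_value: float | None
    engine: str
    fit: RegressionFit | None = None
    failed: bool = False
    reason: str | None = None

    def to_dict(self) -> dict:
        return {
            "x": self.claim.x,
            "y": self.claim.y,
            "conditioning": sorted(self.claim.conditioning_set),
            "response": self.claim.response,
            "engine": self.engine,
            "p_value": self.p_value,
            "failed": self.failed,
            "reason": self.reason,
        }


@dataclass
class DsepFit:
    """One candidate DAG's d-separation test results."""

    model_id: str
    model: CausalDAG
    claims: list[ClaimResult]
    n: int
    evaluable: bool = True

    @property
    def claim_pvalues(self) -> list[float]:
        return [c.p_value for c in self.claims if not c.failed]

    @property
    def k(self) -> int:
        return len(self.claims)

    @property
    def q(self) -> int:
        return self.model.q

    @property
    def C(self) -> float:
        return fishers_c(self.claim_pvalues)[0]

    @property
    def df(self) -> int:
        return fishers_c(self.claim_pvalues)[1]

    @property
    def p(self) -> float:
        return fishers_c(self.claim_pvalues)[2]

    @property
    def CICc(self) -> float:
        return cicc(self.C, self.q, self.n)


class _ClaimCache:
    """Memoizes claim regressions across models of one dataset.

    Claims are keyed by (response, predictor, conditioning set): distinct
    candidate DAGs share most of their basis sets, so caching removes the
    bulk of the regression work in a 2^k model scan.
    """

    def __init__(self, design: StandardizedDesign, cov: PhyloCovariance,
                 lambda_mode: str = "ml"):
        order = list(design.species)
        if list(cov.species_order) != order:
            cov = cov.subset(order)
        self.design = design
        self.cov = cov
        self.lambda_mode = lambda_mode
        self._cache: dict[tuple, ClaimResult] = {}

    def test(self, claim: IndependenceClaim) -> ClaimResult:
        key = (claim.response, claim.predictor, claim.conditioning_set)
        if key in self._cache:
            return self._cache[key]
        result = self._run(claim)
        self._cache[key] = result
        return result

    def structural_fit(self, child: str, parents: tuple) -> RegressionFit:
        key = ("__structural__", child, frozenset(parents))
        if key not in self._cache:
            self._cache[key] = self._fit(child, list(parents))
        return self._cache[key]

    def _fit(self, response: str, predictors: list[str]) -> RegressionFit:
        X = self.design.data[predictors]
        y = self.design.column(response)
        if response == self.design.binary_var:
            return fit_phylo_logistic(y, X, self.cov, response=response)
        return fit_pgls(y, X, self.cov, lambda_mode=self.lambda_mode,
                        response=response)

    def _run(self, claim: IndependenceClaim) -> ClaimResult:
        predictors = [claim.predictor] + sorted(claim.conditioning_set)
        engine = ("phylo_logistic" if claim.response == self.design.binary_var
                  else "pgls")
        try:
            fit = self._fit(claim.response, predictors)
        except Exception as exc:
            log.warning("claim %s failed: %s", claim, exc)
            return ClaimResult(claim=claim, p_value=None, engine=engine,
                               failed=True, reason=str(exc))
        if not fit.converged:
            log.warning("claim %s: engine did not converge", claim)
            return ClaimResult(claim=claim, p_value=None, engine=engine,
                               fit=fit, failed=True, reason="non-convergence")
        return ClaimResult(claim=claim, p_value=fit.p_value_of(claim.predictor),
                           engine=engine, fit=fit)


def run_dsep(model: CausalDAG, design: StandardizedDesign,
             cov: PhyloCovariance, lambda_mode: str = "ml",
             cache: _ClaimCache | None = None) -> DsepFit:
    """Test every basis-set claim of ``model`` against the data.

    Each claim is tested as response ~ predictor + conditioning set with
    the engine chosen by response type; the claim p-value is the tested
    predictor's coefficient p-value.  A model with any failed claim is
    marked unevaluable.
    """
    missing = [v for v in model.vertices if v not in design.data.columns]
    if missing:
        raise KeyError(f"model vertices absent from design: {missing}")
    if cache is None:
        cache = _ClaimCache(design, cov, lambda_mode=lambda_mode)
    claims = [cache.test(cl) for cl in basis_set(model)]
    evaluable = not any(c.failed for c in claims)
    if not evaluable:
        log.warning("model %s has failed claims; marked unevaluable",
                    model.name)
    return DsepFit(model_id=model.name or "model", model=model, claims=claims,
                   n=design.n, evaluable=evaluable)


@dataclass
class SelectionTable:
    """Ranked candidate models with ΔCICc, weights and support flags."""

    fits: list[DsepFit]
    delta: np.ndarray
    omega: np.ndarray
    supported: np.ndarray
    delta_threshold: float
    alpha: float

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for fit, d, w, s in zip(self.fits, self.delta, self.omega,
                                self.supported):
            rows.append({
                "model": fit.model_id,
                "q": fit.q,
                "k": fit.k,
                "C": fit.C,
                "df": fit.df,
                "p": fit.p,
                "CICc": fit.CICc,
                "dCICc": d,
                "omega": w,
                "supported": bool(s),
            })
        return pd.DataFrame(rows)

    @property
    def supported_fits(self) -> list["DsepFit"]:
        return [f for f, s in zip(self.fits, self.supported) if s]

    def omega_renormalized(self) -> np.ndarray:
        """Weights renormalised over the supported models only."""
        w = np.where(self.supported, self.omega, 0.0)
        total = w.sum()
        return w / total if total > 0 else w


def select_models(fits: list[DsepFit], delta_threshold: float = 2.0,
                  alpha: float = 0.05) -> SelectionTable:
    """Rank evaluable models by CICc and flag the supported set.

    ω is computed over *all* evaluable models; a model is supported when
    its ΔCICc is below ``delta_threshold`` AND its d-sep p-value is at
    least ``alpha`` (its conditional independencies are met).
    """
    fits = [f for f in fits if f.evaluable]
    if not fits:
        raise ValueError("no evaluable model fits to select among")
    fits = sorted(fits, key=lambda f: f.CICc)
    cic = np.array([f.CICc for f in fits])
    delta = cic - cic.min()
    rel = np.exp(-delta / 2.0)
    omega = rel / rel.sum()
    pvals = np.array([f.p for f in fits])
    supported = (delta < delta_threshold) & (pvals >= alpha)
    return SelectionTable(fits=fits, delta=delta, omega=omega,
                          supported=supported,
                          delta_threshold=delta_threshold, alpha=alpha)


@dataclass
class AveragedModel:
    """Conditional model-averaged path coefficients."""

    edges: list[tuple]
    beta_avg: dict
    se_avg: dict
    contributing_models: dict

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "parent": [e[0] for e in self.edges],
            "child": [e[1] for e in self.edges],
            "beta": [self.beta_avg[e] for e in self.edges],
            "se": [self.se_avg[e] for e in self.edges],
            "n_models": [len(self.contributing_models[e]) for e in self.edges],
        })


def average_paths(table: SelectionTable, path_fits: dict) -> AveragedModel:
    """Conditional model averaging of path coefficients.

    ``path_fits`` maps model_id -> {edge: (beta, se)} for every supported
    model.  For each edge appearing in any supported model, the averaged
    coefficient is the ω-weighted mean over the supported models that
    contain the edge, with ω renormalised over those models; the SE uses
    the unconditional-variance estimator, which adds the between-model
    spread to the within-model variance.
    """
    supported = table.supported_fits
    if not supported:
        raise ValueError("no supported models to average over")
    omega = {f.model_id: w for f, w, s in
             zip(table.fits, table.omega, table.supported) if s}
    edges: list[tuple] = []
    for f in supported:
        for e in f.model.edges:
            if e not in edges:
                edges.append(e)
    beta_avg, se_avg, contrib = {}, {}, {}
    for e in edges:
        models = [f.model_id for f in supported if e in f.model.edges]
        w = np.array([omega[m] for m in models])
        w = w / w.sum()
        b = np.array([path_fits[m][e][0] for m in models])
        s = np.array([path_fits[m][e][1] for m in models])
        bbar = float(w @ b)
        beta_avg[e] = bbar
        se_avg[e] = float(w @ np.sqrt(s ** 2 + (b - bbar) ** 2))
        contrib[e] = models
    return AveragedModel(edges=edges, beta_avg=beta_avg, se_avg=se_avg,
                         contributing_models=contrib)


class PhylogeneticPathAnalysis(BaseEstimator):
    """End-to-end phylogenetic path analysis over a candidate model set.

    Fit enumerates nothing itself: pass a :class:`ModelSet` (or list of
    DAGs); every model's basis set is tested, models are ranked by CICc,
    and path coefficients of the supported models are averaged.

    Parameters
    ----------
    delta_threshold : float, default 2.0
        ΔCICc bound for a model to count as supported.
    alpha : float, default 0.05
        d-sep significance level: models with Fisher's-C p below it are
        rejected (their independencies fail).
    lambda_mode : {"ml", "fixed"}
        Pagel's-λ handling for the PGLS claims.

    Attributes
    ----------
    fits_ : list of :class:`DsepFit`, one per evaluable model
    selection_ : :class:`SelectionTable`
    averaged_ : :class:`AveragedModel` or None when nothing is supported
    """

    def __init__(self, delta_threshold: float = 2.0, alpha: float = 0.05,
                 lambda_mode: str = "ml"):
        self.delta_threshold = delta_threshold
        self.alpha = alpha
        self.lambda_mode = lambda_mode

    def fit(self, design: StandardizedDesign, cov: PhyloCovariance,
            models: ModelSet | list):
        dags = models.models if isinstance(models, ModelSet) else list(models)
        cache = _ClaimCache(design, cov, lambda_mode=self.lambda_mode)
        fits = []
        skipped = []
        for dag in dags:
            f = run_dsep(dag, design, cov, cache=cache)
            if f.evaluable:
                fits.append(f)
            else:
                skipped.append(f)
        self.fits_ = fits
        self.unevaluable_ = skipped
        self.selection_ = select_models(fits,
                                        delta_threshold=self.delta_threshold,
                                        alpha=self.alpha)
        path_fits = {}
        for f in self.selection_.supported_fits:
            coefs = {}
            ok = True
            for child in f.model.vertices:
                parents = tuple(sorted(f.model.parents(child)))
                if not parents:
                    continue
                try:
                    rf = cache.structural_fit(child, parents)
                except Exception as exc:
                    log.warning("structural fit for %s failed: %s", child, exc)
                    ok = False
                    break
                for p in parents:
                    coefs[(p, child)] = (rf.coef_of(p), rf.se_of(p))
            if ok:
                path_fits[f.model_id] = coefs
        usable = [f for f in self.selection_.supported_fits
                  if f.model_id in path_fits]
        if usable:
            # restrict averaging to supported models whose structural fits
            # all succeeded
            mask = np.array([f.model_id in path_fits
                             for f in self.selection_.fits])
            table = SelectionTable(
                fits=self.selection_.fits, delta=self.selection_.delta,
                omega=self.selection_.omega,
                supported=self.selection_.supported & mask,
                delta_threshold=self.delta_threshold, alpha=self.alpha,
            )
            self.averaged_ = average_paths(table, path_fits)
        else:
            self.averaged_ = None
        return self
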