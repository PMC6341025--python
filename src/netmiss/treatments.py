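"""The four tie non-response treatments.

Each treatment maps a partially observed report matrix to one (or, for
multiple imputation, ``m``) completed networks.  Observed report cells are
never modified by any treatment.

* **complete-case** (listwise deletion): drop every non-respondent and all
  their incoming and outgoing ties; analyse the reduced network.
* **unconditional mean imputation** (UMI): fill each missing tie with the
  mean of observed ties, thresholded at 0.5 for binary ties — which imputes
  zeros in sparse networks and ones in dense ones.  Variants condition the
  mean on nothing (global density), the receiver's observed incoming ties,
  or the sender's observed outgoing ties.
* **reconstruction**: fill a non-respondent's missing outgoing tie with the
  opposite actor's observed incoming report, ``x_ij <- x_ji``.  Dyads with
  both reports missing cannot be reconstructed and fall to a secondary rule
  (zero-fill by default).
* **multiple imputation** (MI): fit a logistic model of observed tie values
  on cell-level predictors, then draw each missing cell ``m`` times with
  parameter uncertainty propagated by sampling coefficients from their
  asymptotic normal distribution; per-imputation analyses are pooled with
  Rubin's rules.

Undirected data: the two ordered reports per pair are collapsed first
(surviving report wins; a pair is unresolved only when both reports are
missing), and each treatment's own rule fills the unresolved pairs, so the
completed network is symmetric by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np

from .missingness import MISSING, ConfigurationError, ObservedReports, nonrespondents, pair_reports
from .net_core import TrueNetwork

__all__ = [
    "MIConfig",
    "NotApplicableError",
    "PooledEstimate",
    "TreatmentResult",
    "complete_case",
    "multiple_impute",
    "reconstruct",
    "rubin_combine",
    "unconditional_mean_impute",
]

UMI_VARIANTS = ("density", "actor_in", "actor_out")
SECONDARY_RULES = ("zero", "umi_density")
MI_PREDICTORS = ("sender_alcohol", "sender_outdeg_obs", "receiver_indeg_obs", "reciprocal_tie")


class NotApplicableError(Exception):
    """The treatment cannot produce a usable network for these reports.

    Raised e.g. when listwise deletion leaves too few actors; the simulation
    driver records the failure instead of propagating it.
    """


@dataclass(frozen=True)
class TreatmentResult:
    completed: Union[TrueNetwork, list[TrueNetwork]]
    retained_actors: tuple[str, ...]
    n_imputed: int
    variant: str

    @property
    def networks(self) -> list[TrueNetwork]:
        c = self.completed
        return list(c) if isinstance(c, list) else [c]


@dataclass(frozen=True)
class MIConfig:
    """Multiple-imputation settings.

    Defaults: ``m = 5`` imputations with predictors sender alcohol score and
    the observed reciprocal tie — the simplest logistic model that still
    reacts to attribute-driven (MAR-style) missingness.
    """

    m: int = 5
    predictors: tuple[str, ...] = ("sender_alcohol", "reciprocal_tie")
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.m < 2:
            raise ConfigurationError("multiple imputation needs m >= 2")
        bad = set(self.predictors) - set(MI_PREDICTORS)
        if bad:
            raise ConfigurationError(f"unknown predictors {sorted(bad)}")


@dataclass(frozen=True)
class PooledEstimate:
    """Rubin's-rules pooling of m per-imputation estimates.

    point = mean of estimates; between = sample variance of estimates;
    total = within + (1 + 1/m) * between.
    """

    point: float
    within: float
    between: float
    total: float
    m: int


def _work_matrix(reports: ObservedReports) -> np.ndarray:
    """Report matrix a treatment operates on (pair-collapsed if undirected)."""
    if reports.directed_data:
        return reports.entries.copy()
    return pair_reports(reports)


def _as_network(filled: np.ndarray, reports: ObservedReports) -> TrueNetwork:
    return TrueNetwork(filled, directed=reports.directed_data, labels=reports.labels)


def complete_case(reports: ObservedReports, min_retained: int = 3) -> TreatmentResult:
    """Listwise deletion of non-respondents.

    Keeps only actors with fully observed outgoing reports and restricts the
    network to them.  Signals not-applicable when fewer than ``min_retained``
    actors (default 3, the smallest network with a defined centralization)
    survive.
    """
    bad = nonrespondents(reports)
    retained = tuple(a for a in reports.labels if a not in bad)
    if len(retained) < min_retained:
        raise NotApplicableError(
            f"complete-case retains {len(retained)} actors (< {min_retained})"
        )
    idx = [reports.labels.index(a) for a in retained]
    sub = reports.entries[np.ix_(idx, idx)]
    # a retained actor has no missing outgoing cells, so the sub-matrix is complete
    net = TrueNetwork(sub, directed=reports.directed_data, labels=retained)
    return TreatmentResult(net, retained, n_imputed=0, variant="cc")


def _umi_fill(work: np.ndarray, variant: str, threshold: float) -> np.ndarray:
    """Per-cell imputed values (0/1) for the missing cells of ``work``."""
    n = work.shape[0]
    off = ~np.eye(n, dtype=bool)
    obs = (work != MISSING) & off
    if not obs.any():
        raise NotApplicableError("no observed report cells to average")
    gmean = work[obs].mean()
    fill = np.empty((n, n), dtype=np.int8)
    if variant == "density":
        fill[:] = 1 if gmean >= threshold else 0
    elif variant in ("actor_in", "actor_out"):
        w = work if variant == "actor_out" else work.T
        o = obs if variant == "actor_out" else obs.T
        sums = np.where(o, w, 0).sum(axis=1)
        cnts = o.sum(axis=1)
        means = np.where(cnts > 0, sums / np.maximum(cnts, 1), gmean)  # empty set -> global
        vals = (means >= threshold).astype(np.int8)
        fill[:] = vals[None, :] if variant == "actor_in" else vals[:, None]
    else:
        raise ConfigurationError(f"variant must be one of {UMI_VARIANTS}")
    return fill


def unconditional_mean_impute(
    reports: ObservedReports,
    variant: str = "density",
    threshold: float = 0.5,
) -> TreatmentResult:
    """Unconditional mean imputation with a 0.5 threshold on binary ties.

    A missing cell becomes 1 when the relevant observed mean is >= threshold
    (ties at exactly 0.5 impute 1), else 0.  ``density`` uses the global
    observed mean; ``actor_in`` the receiver's observed incoming mean;
    ``actor_out`` the sender's observed outgoing mean; actor variants fall
    back to the global mean when the conditioning set is empty.  Undirected
    completions are max-symmetrized (actor variants may propose conflicting
    values for a pair).
    """
    work = _work_matrix(reports)
    miss = work == MISSING
    fill = _umi_fill(work, variant, threshold)
    work[miss] = fill[miss]
    if not reports.directed_data:
        work = np.maximum(work, work.T)
    return TreatmentResult(
        _as_network(work, reports),
        reports.labels,
        n_imputed=int(miss.sum()),
        variant=f"umi:{variant}",
    )


def reconstruct(reports: ObservedReports, secondary: str = "zero") -> TreatmentResult:
    """Reconstruction from the opposite report, ``x_ij <- x_ji``.

    Directed data: each missing cell takes the opposite observed incoming
    report.  Undirected data: the surviving endpoint report already decides
    the pair.  Dyads with both reports missing cannot be reconstructed; the
    ``secondary`` rule resolves them (``zero`` fills 0 — the value the mean
    rule would give on a sparse network — or ``umi_density`` applies the
    thresholded global observed mean).
    """
    if secondary not in SECONDARY_RULES:
        raise ConfigurationError(f"secondary must be one of {SECONDARY_RULES}")
    work = _work_matrix(reports)
    miss = work == MISSING
    if reports.directed_data:
        opp = work.T
        take = miss & (opp != MISSING)
        work[take] = opp[take]
        miss = work == MISSING
    # undirected: pair collapse above *is* the reconstruction step
    if miss.any():
        if secondary == "zero":
            work[miss] = 0
        else:
            fill = _umi_fill(work, "density", 0.5)
            work[miss] = fill[miss]
    if not reports.directed_data:
        work = np.maximum(work, work.T)
    n_imp = int((reports.entries == MISSING).sum()) if reports.directed_data else int(
        (pair_reports(reports) == MISSING).sum()
    )
    return TreatmentResult(
        _as_network(work, reports),
        reports.labels,
        n_imputed=n_imp,
        variant=f"re:{secondary}",
    )


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _mi_design(
    work: np.ndarray,
    reports: ObservedReports,
    predictors: Sequence[str],
    attrs: Optional[np.ndarray],
) -> np.ndarray:
    """Cell-level design matrix (with intercept) over all off-diagonal cells.

    Predictors are computed from observed data only.  For undirected data the
    sender/receiver distinction vanishes: alcohol becomes the pair mean and
    the reciprocal-tie predictor is dropped (it would be the cell itself).
    """
    n = work.shape[0]
    off = ~np.eye(n, dtype=bool)
    obs = (work != MISSING) & off
    cols = [np.ones((n, n))]
    directed = reports.directed_data
    for name in predictors:
        if name == "sender_alcohol":
            if attrs is None:
                continue
            a = np.asarray(attrs, dtype=float)
            feat = np.broadcast_to(a[:, None], (n, n)) if directed else (a[:, None] + a[None, :]) / 2
        elif name == "reciprocal_tie":
            if not directed:
                continue
            feat = ((work.T == 1) & obs.T).astype(float)
        elif name in ("sender_outdeg_obs", "receiver_indeg_obs"):
            axis_obs = obs if name == "sender_outdeg_obs" else obs.T
            axis_val = work if name == "sender_outdeg_obs" else work.T
            cnt = axis_obs.sum(axis=1)
            mean = np.where(cnt > 0, np.where(axis_obs, axis_val, 0).sum(axis=1) / np.maximum(cnt, 1), 0.0)
            feat = mean[:, None] if name == "sender_outdeg_obs" else mean[None, :]
            feat = np.broadcast_to(feat, (n, n))
        else:
            raise ConfigurationError(f"unknown predictor {name!r}")
        cols.append(np.asarray(feat, dtype=float))
    return np.stack([c.reshape(-1) for c in cols], axis=1).reshape(n, n, -1)


def _fit_logistic(X: np.ndarray, y: np.ndarray):
    """Logit fit returning (params, cov) or None on a degenerate fit."""
    if y.min() == y.max() or X.shape[1] == 1:
        return None
    import statsmodels.api as sm

    import warnings as _warnings

    try:
        with np.errstate(all="ignore"), _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            res = sm.Logit(y, X).fit(disp=0, maxiter=100)
        if not res.mle_retvals.get("converged", False):
            return None
        params = np.asarray(res.params, dtype=float)
        cov = np.asarray(res.cov_params(), dtype=float)
    except Exception:
        return None
    if not (np.isfinite(params).all() and np.isfinite(cov).all()):
        return None
    # wildly inflated variances signal (quasi-)separation
    if np.diagonal(cov).max() > 1e4:
        return None
    return params, cov


def multiple_impute(
    reports: ObservedReports,
    cfg: MIConfig = MIConfig(),
    attrs: Optional[np.ndarray] = None,
    rng: Optional[np.random.Generator] = None,
) -> TreatmentResult:
    """Logistic-model multiple imputation of missing ties.

    Fits one logistic regression of observed tie values on the configured
    cell-level predictors, then produces ``m`` completed networks: for each,
    coefficients are drawn from their asymptotic normal distribution and
    every missing cell is drawn as a Bernoulli at its predicted probability.
    Degenerate fits (all ties equal, separation, no usable predictors) fall
    back to an intercept-only model at the observed density.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    work = _work_matrix(reports)
    n = work.shape[0]
    off = ~np.eye(n, dtype=bool)
    obs = (work != MISSING) & off
    if not obs.any():
        raise NotApplicableError("no observed cells to fit the imputation model")
    miss = (work == MISSING) & off
    if not miss.any():
        net = _as_network(work, reports)
        return TreatmentResult([net] * cfg.m, reports.labels, 0, variant=f"mi:m={cfg.m}")

    if not reports.directed_data:
        # unordered pairs are the units; use the upper triangle once
        tri = np.triu(np.ones((n, n), dtype=bool), k=1)
        obs_fit, miss_fill = obs & tri, miss & tri
    else:
        obs_fit, miss_fill = obs, miss

    X = _mi_design(work, reports, cfg.predictors, attrs)
    y = work[obs_fit].astype(float)
    fit = _fit_logistic(X[obs_fit], y)
    density_hat = y.mean()

    nets: list[TrueNetwork] = []
    Xm = X[miss_fill]
    for _ in range(cfg.m):
        if fit is None:
            p = np.full(Xm.shape[0], density_hat)
        else:
            params, cov = fit
            beta = rng.multivariate_normal(params, cov, method="svd")
            p = _sigmoid(Xm @ beta)
        draw = (rng.random(p.shape) < p).astype(np.int8)
        filled = work.copy()
        filled[miss_fill] = draw
        if not reports.directed_data:
            filled = np.where(tri, filled, filled.T)  # mirror completed upper triangle
        nets.append(_as_network(filled, reports))
    return TreatmentResult(
        nets, reports.labels, n_imputed=int(miss_fill.sum()), variant=f"mi:m={cfg.m}"
    )


def rubin_combine(
    estimates: Sequence[float],
    within_vars: Optional[Sequence[float]] = None,
) -> PooledEstimate:
    """Pool m per-imputation estimates with Rubin's rules.

    point = mean; between B = sample variance of the estimates; within W =
    mean of the per-imputation variances (0 when absent — descriptive network
    statistics carry no analytic within-imputation variance here);
    total T = W + (1 + 1/m) B.
    """
    est = np.asarray(estimates, dtype=float)
    m = est.size
    if m < 2:
        raise ConfigurationError("Rubin's rules need at least 2 imputations")
    point = float(est.mean())
    between = float(est.var(ddof=1))
    if within_vars is None:
        within = 0.0
    else:
        wv = np.asarray(within_vars, dtype=float)
        if wv.size != m:
            raise ConfigurationError("within_vars must match the number of estimates")
        within = float(wv.mean())
    total = within + (1.0 + 1.0 / m) * between
    return PooledEstimate(point, within, between, total, m)
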