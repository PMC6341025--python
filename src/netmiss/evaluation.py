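"""Monte-Carlo evaluation of tie non-response treatments.

The full factorial design crosses 2 network types x 3 sample sizes x 3
missing proportions (18 cells) for each of the three missingness mechanisms,
and evaluates all four treatments in every cell.  Per replicate the driver

1. generates a complete network and actor attributes,
2. measures the true values theta (density, mean normalized degree,
   centralization),
3. deletes ties under the cell's mechanism and proportion,
4. applies each treatment and re-measures theta_hat on the completed
   network (multiple imputation is pooled with Rubin's rules; the
   complete-case estimate is measured on the reduced network with its own
   n, against the full network's theta),

and accumulates ``bias = sum_i (theta_hat_i - theta_i) / r``.  Treatments
share the replicate's truth and corrupted reports, so comparisons between
treatments are paired.  Every number is reproducible from the master seed:
replicate k of a cell uses fixed named substreams derived from
(seed, cell index, k).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import net_core
from .missingness import MissingnessSpec, delete_ties
from .net_core import TrueNetwork
from .synthetic import GenerationSpec, generate_attributes, generate_network
from .treatments import MIConfig, NotApplicableError, complete_case, multiple_impute, reconstruct, rubin_combine, unconditional_mean_impute

__all__ = [
    "BiasResult",
    "Condition",
    "DEFAULT_DESIGN",
    "MEASURES",
    "TREATMENTS",
    "bias",
    "run_condition",
    "run_factorial",
    "standardized_bias",
]

MEASURES = ("density", "mean_normalized_degree", "centralization")
TREATMENTS = ("cc", "umi", "re", "mi")

DEFAULT_DESIGN = {
    "mechanisms": ("MCAR", "MAR", "MNAR"),
    "network_types": ("directed", "undirected"),
    "sizes": (50, 150, 250),
    "proportions": (0.05, 0.1, 0.25),
    "r": 500,
}


def bias(estimates: Sequence[float], theta: float) -> float:
    """Monte-Carlo bias: mean over replications of (estimate - truth)."""
    est = np.asarray(estimates, dtype=float)
    if est.size == 0:
        raise ValueError("bias needs at least one estimate")
    return float((est - theta).mean())


def standardized_bias(
    estimates: Sequence[float], theta: float, scaling: str = "by_sd"
) -> float:
    """Bias scaled by the replicate SD (``by_sd``) or by theta (``by_theta``).

    Returns NaN when the chosen scale is zero (e.g. all estimates identical).
    """
    est = np.asarray(estimates, dtype=float)
    b = bias(est, theta)
    if scaling == "by_sd":
        if est.size < 2:
            raise ValueError("by_sd scaling needs at least 2 estimates")
        sd = float(est.std(ddof=1))
        return b / sd if sd > 0 else float("nan")
    if scaling == "by_theta":
        return b / theta if theta != 0 else float("nan")
    raise ValueError("scaling must be 'by_sd' or 'by_theta'")


@dataclass(frozen=True)
class Condition:
    """One cell of the design, for one treatment."""

    mechanism: str = "MCAR"
    network_type: str = "directed"
    n: int = 50
    proportion: float = 0.1
    treatment: str = "umi"
    r: int = 500
    seed: int = 0
    granularity: str = "cell"
    degree_mode: str = "in"
    umi_variant: str = "density"
    re_secondary: str = "zero"
    mi_config: MIConfig = MIConfig()

    def __post_init__(self) -> None:
        if self.network_type not in ("directed", "undirected"):
            raise ValueError("network_type must be 'directed' or 'undirected'")
        if self.treatment not in TREATMENTS:
            raise ValueError(f"treatment must be one of {TREATMENTS}")
        if self.r < 1:
            raise ValueError("r must be >= 1")


@dataclass(frozen=True)
class BiasResult:
    """Bias summary for one (condition, measure)."""

    condition: Condition
    measure: str
    theta: float
    theta_hat_mean: float
    bias: float
    sd: float
    std_bias_sd: float
    std_bias_theta: float
    n_failed: int
    r: int


def _measure_vector(net: TrueNetwork, mode: str) -> np.ndarray:
    m = net_core.network_measures(net, mode)
    return np.array([m.density, m.mean_normalized_degree, m.centralization])


def _apply_treatment(cond: Condition, reports, attrs, rng) -> Optional[np.ndarray]:
    """theta_hat for each measure, or None when the treatment is not applicable."""
    t = cond.treatment
    try:
        if t == "cc":
            res = complete_case(reports)
            return _measure_vector(res.completed, cond.degree_mode)
        if t == "umi":
            res = unconditional_mean_impute(reports, variant=cond.umi_variant)
            return _measure_vector(res.completed, cond.degree_mode)
        if t == "re":
            res = reconstruct(reports, secondary=cond.re_secondary)
            return _measure_vector(res.completed, cond.degree_mode)
        res = multiple_impute(reports, cfg=cond.mi_config, attrs=attrs, rng=rng)
        per_imp = np.stack([_measure_vector(net, cond.degree_mode) for net in res.networks])
        return np.array([rubin_combine(per_imp[:, j]).point for j in range(per_imp.shape[1])])
    except NotApplicableError:
        return None


def _replicate_streams(seed: int, cell_key: tuple, rep: int) -> dict[str, np.random.Generator]:
    root = np.random.SeedSequence(seed, spawn_key=(*cell_key, rep))
    names = ("network", "attributes", "missingness", "imputation")
    return dict(zip(names, map(np.random.default_rng, root.spawn(4))))


def _run_cell(
    cond: Condition,
    treatments: Sequence[str],
    cell_key: tuple = (),
) -> list[BiasResult]:
    """Run one design cell for one or more treatments on shared replicates."""
    directed = cond.network_type == "directed"
    gen = GenerationSpec(n=cond.n, directed=directed)
    diffs: dict[str, list[np.ndarray]] = {t: [] for t in treatments}
    hats: dict[str, list[np.ndarray]] = {t: [] for t in treatments}
    failed = {t: 0 for t in treatments}
    mspec = MissingnessSpec(
        mechanism=cond.mechanism, proportion=cond.proportion, granularity=cond.granularity
    )
    theta_sum = np.zeros(3)
    for rep in range(cond.r):
        rngs = _replicate_streams(cond.seed, cell_key, rep)
        truth = generate_network(gen, rng=rngs["network"])
        attrs = generate_attributes(cond.n, rng=rngs["attributes"])
        theta = _measure_vector(truth, cond.degree_mode)
        theta_sum += theta
        reports = delete_ties(truth, mspec, attrs=attrs, rng=rngs["missingness"])
        for t in treatments:
            hat = _apply_treatment(replace(cond, treatment=t), reports, attrs, rngs["imputation"])
            if hat is None:
                failed[t] += 1
            else:
                diffs[t].append(hat - theta)
                hats[t].append(hat)
    theta_mean = theta_sum / cond.r
    out = []
    for t in treatments:
        tc = replace(cond, treatment=t)
        ok = len(hats[t])
        for j, measure in enumerate(MEASURES):
            if ok == 0:
                out.append(
                    BiasResult(tc, measure, float(theta_mean[j]), np.nan, np.nan, np.nan,
                               np.nan, np.nan, failed[t], cond.r)
                )
                continue
            hj = np.array([h[j] for h in hats[t]])
            dj = np.array([d[j] for d in diffs[t]])
            b = float(dj.mean())
            sd = float(hj.std(ddof=1)) if ok > 1 else 0.0
            th = float(theta_mean[j])
            out.append(
                BiasResult(
                    tc, measure, th, float(hj.mean()), b, sd,
                    b / sd if sd > 0 else float("nan"),
                    b / th if th != 0 else float("nan"),
                    failed[t], cond.r,
                )
            )
    return out


def run_condition(cond: Condition) -> list[BiasResult]:
    """Bias of one treatment in one design cell, one result per measure."""
    return _run_cell(cond, (cond.treatment,))


def _results_frame(results: list[BiasResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        c = r.condition
        rows.append(
            {
                "mechanism": c.mechanism, "type": c.network_type, "n": c.n,
                "proportion": c.proportion, "treatment": c.treatment,
                "measure": r.measure, "theta": r.theta,
                "theta_hat_mean": r.theta_hat_mean, "bias": r.bias, "sd": r.sd,
                "std_bias_sd": r.std_bias_sd, "std_bias_theta": r.std_bias_theta,
                "n_failed": r.n_failed, "r": r.r, "seed": c.seed,
            }
        )
    return pd.DataFrame(rows)


def run_factorial(
    mechanisms: Sequence[str] = DEFAULT_DESIGN["mechanisms"],
    network_types: Sequence[str] = DEFAULT_DESIGN["network_types"],
    sizes: Sequence[int] = DEFAULT_DESIGN["sizes"],
    proportions: Sequence[float] = DEFAULT_DESIGN["proportions"],
    treatments: Sequence[str] = TREATMENTS,
    r: int = DEFAULT_DESIGN["r"],
    seed: int = 0,
    granularity: str = "cell",
    degree_mode: str = "in",
    mi_config: MIConfig = MIConfig(),
) -> pd.DataFrame:
    """Tidy results table for the full factorial design.

    One row per (mechanism, network type, n, proportion, treatment, measure);
    the default design yields 3 x 18 x 4 x 3 = 648 rows.  Treatments within a
    cell share replicates, so between-treatment contrasts are paired.
    Bit-reproducible for a fixed seed.
    """
    results: list[BiasResult] = []
    for im, mech in enumerate(mechanisms):
        for it, ntype in enumerate(network_types):
            for isz, n in enumerate(sizes):
                for ip, p in enumerate(proportions):
                    cond = Condition(
                        mechanism=mech, network_type=ntype, n=n, proportion=p,
                        treatment=treatments[0], r=r, seed=seed,
                        granularity=granularity, degree_mode=degree_mode,
                        mi_config=mi_config,
                    )
                    results.extend(_run_cell(cond, treatments, cell_key=(im, it, isz, ip)))
    return _results_frame(results)


def run_manifest(seed: int, r: int, **design) -> dict:
    """Serializable record of a simulation run's configuration."""
    import netmiss

    return {"package": "netmiss", "version": getattr(netmiss, "__version__", "0"),
            "seed": seed, "r": r, **design}
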