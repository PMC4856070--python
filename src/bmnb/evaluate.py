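"""Posterior prediction and cross-validated predictive checks.

Predicted counts average the posterior-draw means on the response scale,

    ŷ_ijkt = (1/M) Σ_s exp(x_ikᵀ β*⁽ˢ⁾ + log r⁽ˢ⁾ + g_j⁽ˢ⁾ + gE_ij⁽ˢ⁾),

and predictive accuracy on held-out records is summarized by the Spearman
rank correlation (higher is better; counts tie often, so average ranks are
used) and the mean squared error of prediction (lower is better).  K-fold
cross-validation partitions the records into mutually exclusive subsets,
refits on each training complement, and scores the validation subset per
environment.  The scenario comparison refits the model under the four
linear-predictor variants used for real trials — main effects with
independent lines (S1) or marker-derived covariance (S2), plus the
interaction term with independent lines (S3) or markers (S4) — and ranks
them by the two checks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .design import CountPanel, CovarianceSet, MarkerMatrix, build_design, compute_grm
from .model import PosteriorChains, PriorSpec, nb_log_pmf, run_gibbs

logger = logging.getLogger(__name__)

__all__ = [
    "predict_counts",
    "spearman_cor",
    "msep",
    "posterior_loglik",
    "cross_validate",
    "scenario_table",
    "CVResult",
]


def _design_rows(chains: PosteriorChains, records: pd.DataFrame):
    """Map (env, block, line) labels of target records to design indices."""
    meta = chains.meta
    env_levels = meta["env_levels"]
    line_levels = meta["line_levels"]
    block_levels = meta["block_levels"]
    I, J, K = meta["I"], meta["J"], len(block_levels)
    try:
        env_idx = records["env"].map({v: i for i, v in enumerate(env_levels)}).to_numpy()
        line_idx = records["line"].map({v: i for i, v in enumerate(line_levels)}).to_numpy()
    except KeyError as exc:  # pragma: no cover
        raise ValueError("records need env and line columns") from exc
    if np.any(pd.isna(env_idx)):
        raise ValueError("unknown environment label in prediction records")
    if np.any(pd.isna(line_idx)):
        raise ValueError("unknown line label in prediction records")
    env_idx = env_idx.astype(np.int64)
    line_idx = line_idx.astype(np.int64)
    n = len(records)
    p_full = I + (I * K if meta["include_blocks"] else 0)
    X = np.zeros((n, p_full))
    X[np.arange(n), env_idx] = 1.0
    if meta["include_blocks"]:
        block_idx = (
            records["block"].map({v: i for i, v in enumerate(block_levels)}).to_numpy()
        )
        if np.any(pd.isna(block_idx)):
            raise ValueError("unknown block label in prediction records")
        X[np.arange(n), I + env_idx * K + block_idx.astype(np.int64)] = 1.0
    X = X[:, meta["kept_cols"]]
    return X, line_idx, env_idx * J + line_idx


def predict_counts(chains: PosteriorChains, records: pd.DataFrame) -> np.ndarray:
    """Posterior-mean predicted counts for the given records (env/block/line)."""
    X, line_idx, cell_idx = _design_rows(chains, records)
    fixed_r = chains.meta.get("fixed_r")
    log_r = np.log(chains.r if fixed_r is None else np.full_like(chains.r, fixed_r))
    # (M, n): eta* + log r per draw and record
    eta = chains.beta_star @ X.T + chains.b1[:, line_idx]
    if chains.meta.get("include_gxe", True):
        eta = eta + chains.b2[:, cell_idx]
    yhat = np.exp(eta + log_r[:, None]).mean(axis=0)
    return yhat


def spearman_cor(observed, predicted) -> float:
    """Spearman rank correlation with average ranks for ties.

    Returns NaN (with a warning) when either vector is constant, where rank
    correlation is undefined.
    """
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if observed.shape != predicted.shape:
        raise ValueError("observed and predicted must have the same length")
    if np.ptp(observed) == 0 or np.ptp(predicted) == 0:
        logger.warning("Spearman correlation undefined for a constant vector")
        return float("nan")
    return float(spearmanr(observed, predicted).statistic)


def msep(observed, predicted) -> float:
    """Mean squared error of prediction."""
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if observed.shape != predicted.shape:
        raise ValueError("observed and predicted must have the same length")
    return float(np.mean((observed - predicted) ** 2))


def posterior_loglik(chains: PosteriorChains, panel: Optional[CountPanel] = None) -> float:
    """Posterior mean of the full-data log-likelihood over retained draws.

    Uses the per-draw log-likelihood stored in the chains; pass ``panel`` to
    recompute from scratch instead (e.g. for records not used in fitting).
    """
    if panel is None:
        return float(chains.loglik.mean())
    records = panel.frame
    X, line_idx, cell_idx = _design_rows(chains, records)
    fixed_r = chains.meta.get("fixed_r")
    r = chains.r if fixed_r is None else np.full_like(chains.r, fixed_r)
    eta = chains.beta_star @ X.T + chains.b1[:, line_idx]
    if chains.meta.get("include_gxe", True):
        eta = eta + chains.b2[:, cell_idx]
    ll = nb_log_pmf(panel.y[None, :], eta, r[:, None]).sum(axis=1)
    return float(ll.mean())


def make_folds(
    panel: CountPanel,
    k: int,
    rng: np.random.Generator,
    stratify_env: bool = False,
    max_retries: int = 20,
) -> np.ndarray:
    """Seeded random partition of records into k folds of near-equal size.

    Every training complement must contain every environment; the partition
    is re-randomized a bounded number of times if that fails (only possible
    for extremely small environments), then raises.
    """
    n = panel.n_T
    if not (2 <= k <= n):
        raise ValueError("need 2 <= k <= number of records")
    for _ in range(max_retries):
        folds = np.empty(n, dtype=np.int64)
        if stratify_env:
            for i in range(panel.I):
                idx = np.flatnonzero(panel.env_idx == i)
                perm = rng.permutation(idx)
                folds[perm] = np.arange(perm.size) % k
        else:
            folds[rng.permutation(n)] = np.arange(n) % k
        ok = all(
            np.unique(panel.env_idx[folds != f]).size == panel.I for f in range(k)
        )
        if ok:
            return folds
    raise RuntimeError(
        "could not build folds whose training sets cover every environment"
    )


@dataclass
class CVResult:
    """Cross-validation predictive checks.

    ``per_fold`` has one row per (fold, environment) with Cor and MSEP on
    the validation records; ``summary`` aggregates mean and SD across folds
    per environment.
    """

    per_fold: pd.DataFrame
    summary: pd.DataFrame
    folds: np.ndarray
    scenario: Optional[str] = None


def cross_validate(
    panel: CountPanel,
    covset: CovarianceSet,
    prior: Optional[PriorSpec] = None,
    k: int = 10,
    seed: int = 0,
    iterations: int = 2000,
    burn_in: int = 1000,
    include_blocks: bool = True,
    include_gxe: bool = True,
    fixed_r: Optional[float] = None,
    stratify_env: bool = False,
    scenario: Optional[str] = None,
) -> CVResult:
    """K-fold cross-validation of the BMNB model with per-environment checks."""
    rng = np.random.Generator(np.random.PCG64(seed))
    folds = make_folds(panel, k, rng, stratify_env=stratify_env)
    rows = []
    for f in range(k):
        train = panel.subset(folds != f)
        test_frame = panel.frame.loc[folds == f]
        design = build_design(train, include_blocks=include_blocks)
        pr = prior if prior is not None else PriorSpec.default(design.X.shape[1])
        chains = run_gibbs(
            train,
            design,
            covset,
            pr,
            iterations,
            burn_in,
            rng,
            fixed_r=fixed_r,
            include_gxe=include_gxe,
        )
        yhat = predict_counts(chains, test_frame)
        yobs = test_frame["count"].to_numpy(dtype=float)
        env = test_frame["env"].to_numpy()
        for e in panel.env_levels:
            m = env == e
            if not m.any():
                continue
            rows.append(
                {
                    "fold": f,
                    "env": e,
                    "n": int(m.sum()),
                    "cor": spearman_cor(yobs[m], yhat[m]),
                    "msep": msep(yobs[m], yhat[m]),
                }
            )
    per_fold = pd.DataFrame(rows)
    summary = (
        per_fold.groupby("env")
        .agg(
            cor_mean=("cor", "mean"),
            cor_sd=("cor", "std"),
            msep_mean=("msep", "mean"),
            msep_sd=("msep", "std"),
        )
        .reset_index()
    )
    return CVResult(per_fold=per_fold, summary=summary, folds=folds, scenario=scenario)


_SCENARIOS = {
    # (uses markers for G1, includes the interaction term)
    "S1": (False, False),
    "S2": (True, False),
    "S3": (False, True),
    "S4": (True, True),
}


def scenario_table(
    panel: CountPanel,
    markers: Optional[MarkerMatrix] = None,
    scenarios=("S1", "S2", "S3", "S4"),
    k: int = 10,
    seed: int = 0,
    iterations: int = 2000,
    burn_in: int = 1000,
    include_blocks: bool = True,
    fixed_r: Optional[float] = None,
    grm_ridge: float = 1e-6,
):
    """Compare linear-predictor scenarios by CV checks and goodness of fit.

    S1/S3 treat lines as i.i.d. effects (G1 = identity); S2/S4 use the
    marker-derived GRM; S3/S4 add the line-within-environment interaction.
    Returns ``(metrics, ranks)``: per-scenario, per-environment Cor/MSEP
    (mean and SD over folds) plus full-data posterior log-likelihood, and
    the rank-average table (mean of the Cor rank and MSEP rank, lower is
    better).
    """
    unknown = set(scenarios) - set(_SCENARIOS)
    if unknown:
        raise ValueError(f"unknown scenarios: {sorted(unknown)}")
    if any(_SCENARIOS[s][0] for s in scenarios) and markers is None:
        need = [s for s in scenarios if _SCENARIOS[s][0]]
        raise ValueError(f"scenarios {need} require a marker matrix")

    metric_rows = []
    for s in scenarios:
        use_markers, gxe = _SCENARIOS[s]
        G1 = (
            compute_grm(markers, ridge=grm_ridge)
            if use_markers
            else np.eye(panel.J)
        )
        covset = CovarianceSet.from_g1(G1, panel.I)
        cv = cross_validate(
            panel,
            covset,
            k=k,
            seed=seed,
            iterations=iterations,
            burn_in=burn_in,
            include_blocks=include_blocks,
            include_gxe=gxe,
            fixed_r=fixed_r,
            scenario=s,
        )
        design = build_design(panel, include_blocks=include_blocks)
        pr = PriorSpec.default(design.X.shape[1])
        rng = np.random.Generator(np.random.PCG64(seed + 1))
        chains = run_gibbs(
            panel, design, covset, pr, iterations, burn_in, rng,
            fixed_r=fixed_r, include_gxe=gxe,
        )
        ll = posterior_loglik(chains)
        for _, row in cv.summary.iterrows():
            metric_rows.append(
                {
                    "scenario": s,
                    "env": row["env"],
                    "cor_mean": row["cor_mean"],
                    "cor_sd": row["cor_sd"],
                    "msep_mean": row["msep_mean"],
                    "msep_sd": row["msep_sd"],
                    "loglik": ll,
                }
            )
    metrics = pd.DataFrame(metric_rows)

    # Rank scenarios within each environment (1 = best; ties get average
    # rank): Cor descending, MSEP ascending; report the mean of both ranks.
    ranks = []
    for e, grp in metrics.groupby("env"):
        cor_rank = grp["cor_mean"].rank(ascending=False)
        msep_rank = grp["msep_mean"].rank(ascending=True)
        for (idx, row), cr, mr in zip(grp.iterrows(), cor_rank, msep_rank):
            ranks.append(
                {"scenario": row["scenario"], "env": e, "rank_avg": (cr + mr) / 2.0}
            )
    ranks = pd.DataFrame(ranks).sort_values(["env", "scenario"]).reset_index(drop=True)
    return metrics, ranks
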