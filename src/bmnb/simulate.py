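"""Synthetic multi-environment count-trial generator and recovery studies.

The generator draws from exactly the model the sampler fits:

    g ~ N(0, G1·σ₁²),  gE_i ~ N(0, G1·σ₂²) independently per environment,
    η_ij(k) = E_i (+ R(E)_ik) + g_j + gE_ij,
    y_ijkt ~ NB(μ = e^η, r)  i.i.d. over replicates t  (Poisson when r = ∞).

Two named configurations reproduce the simulation-study conditions: three
environments, J = 20 genotypes, environment effects (1.5, −1, 1), both
variance components 0.5, dispersion r = 5, with G1 either the identity
(independent lines) or the compound-symmetry matrix 0.7·I20 + 0.3·J20 that
mimics the correlation between lines seen in genomic-selection data.
Replicate counts per genotype × environment cell of n = 5, 10, 20, 40 are
the study's sample sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
import pandas as pd

from .design import CountPanel, CovarianceSet, build_design
from .model import PosteriorChains, PriorSpec, run_gibbs

__all__ = [
    "ScenarioConfig",
    "scenario1",
    "scenario2",
    "simulate_panel",
    "run_recovery_study",
]


@dataclass
class ScenarioConfig:
    """Design sizes, true parameters, and effect covariance for a simulation.

    ``K = 0`` means no block structure (the simulation-study predictor
    η_ij = E_i + g_j + gE_ij); ``r_true = inf`` simulates Poisson counts.
    ``g1`` is "identity", ("cs", rho) for (1−ρ)·I + ρ·J compound symmetry,
    or an explicit J × J matrix.
    """

    I: int  # noqa: E741
    J: int
    n: int
    beta_true: np.ndarray
    K: int = 0
    block_true: Optional[np.ndarray] = None
    g1: Union[str, tuple, np.ndarray] = "identity"
    sigma_b12: float = 0.5
    sigma_b22: float = 0.5
    r_true: float = 5.0
    replications: int = 50
    seed: Optional[int] = None

    def __post_init__(self):
        self.beta_true = np.asarray(self.beta_true, dtype=float)
        if self.beta_true.size != self.I:
            raise ValueError("beta_true must have one entry per environment")
        if self.sigma_b12 < 0 or self.sigma_b22 < 0:
            raise ValueError("variance components must be >= 0")
        if not self.r_true > 0:
            raise ValueError("r_true must be > 0 (inf for Poisson)")
        if self.K > 0:
            if self.block_true is None:
                self.block_true = np.zeros(self.I * self.K)
            self.block_true = np.asarray(self.block_true, dtype=float)
            if self.block_true.size != self.I * self.K:
                raise ValueError("block_true must have I*K entries")

    def g1_matrix(self) -> np.ndarray:
        if isinstance(self.g1, str):
            if self.g1 != "identity":
                raise ValueError(f"unknown G1 spec {self.g1!r}")
            return np.eye(self.J)
        if isinstance(self.g1, tuple):
            kind, rho = self.g1
            if kind != "cs":
                raise ValueError(f"unknown G1 spec {kind!r}")
            return (1.0 - rho) * np.eye(self.J) + rho * np.ones((self.J, self.J))
        G1 = np.asarray(self.g1, dtype=float)
        if G1.shape != (self.J, self.J):
            raise ValueError("explicit G1 must be J x J")
        return G1


def scenario1(n: int = 10, **overrides) -> ScenarioConfig:
    """Independent lines: I=3, J=20, G1=I, σ₁²=σ₂²=0.5, β=(1.5,−1,1), r=5."""
    base = dict(
        I=3, J=20, n=n, beta_true=np.array([1.5, -1.0, 1.0]),
        g1="identity", sigma_b12=0.5, sigma_b22=0.5, r_true=5.0,
    )
    base.update(overrides)
    return ScenarioConfig(**base)


def scenario2(n: int = 10, **overrides) -> ScenarioConfig:
    """Correlated lines: as scenario 1 with G1 = 0.7·I20 + 0.3·J20."""
    return scenario1(n, g1=("cs", 0.3), **overrides)


def simulate_panel(config: ScenarioConfig, rng: np.random.Generator):
    """Simulate one panel; returns ``(CountPanel, truth)``.

    ``truth`` holds the latent draws (g, gE, optional block effects) and the
    derived η and μ per (environment, line) cell, for recovery checks.
    """
    I, J, K, n = config.I, config.J, config.K, config.n
    G1 = config.g1_matrix()
    try:
        chol = np.linalg.cholesky(G1)
    except np.linalg.LinAlgError as exc:
        raise ValueError("G1 specification is not positive definite") from exc

    g = chol @ rng.standard_normal(J) * np.sqrt(config.sigma_b12)
    gE = np.concatenate(
        [chol @ rng.standard_normal(J) * np.sqrt(config.sigma_b22) for _ in range(I)]
    )
    eta_cell = config.beta_true[:, None] + g[None, :] + gE.reshape(I, J)  # (I, J)

    env_lab = [f"E{i + 1}" for i in range(I)]
    line_lab = [f"L{j + 1:03d}" for j in range(J)]
    blocks = max(K, 1)
    block_lab = [f"B{k + 1}" for k in range(blocks)]

    recs = {"env": [], "block": [], "line": [], "rep": [], "count": []}
    mu_rows = np.empty((I, blocks, J))
    for i in range(I):
        for k in range(blocks):
            eta = eta_cell[i]
            if K > 0:
                eta = eta + config.block_true[i * K + k]
            mu = np.exp(eta)
            mu_rows[i, k] = mu
            for j in range(J):
                if np.isinf(config.r_true):
                    ys = rng.poisson(mu[j], size=n)
                else:
                    p = config.r_true / (config.r_true + mu[j])
                    ys = rng.negative_binomial(config.r_true, p, size=n)
                recs["env"].extend([env_lab[i]] * n)
                recs["block"].extend([block_lab[k]] * n)
                recs["line"].extend([line_lab[j]] * n)
                recs["rep"].extend(range(1, n + 1))
                recs["count"].extend(ys.tolist())

    panel = CountPanel.from_frame(pd.DataFrame(recs), line_levels=line_lab)
    truth = {
        "g": g,
        "gE": gE,
        "block": config.block_true if K > 0 else None,
        "eta_cell": eta_cell,
        "mu": mu_rows,
        "G1": G1,
        "beta": config.beta_true.copy(),
        "sigma_b12": config.sigma_b12,
        "sigma_b22": config.sigma_b22,
        "r": config.r_true,
    }
    return panel, truth


@dataclass
class RecoveryResult:
    """Replication-averaged posterior means with cross-replication SDs."""

    table: pd.DataFrame  # parameter, true, mean, sd
    per_replication: pd.DataFrame  # one row per replication
    failed: list = field(default_factory=list)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.table.to_string(index=False, float_format=lambda v: f"{v:8.3f}")


def run_recovery_study(
    config: ScenarioConfig,
    replications: Optional[int] = None,
    iterations: int = 20_000,
    burn_in: int = 10_000,
    seed: Optional[int] = None,
    prior: Optional[PriorSpec] = None,
) -> RecoveryResult:
    """Repeat simulate → fit and tabulate posterior means across replications.

    Each replication simulates a fresh panel from ``config``, fits the BMNB
    sampler with the simulation-study priors (unless ``prior`` overrides
    them), and records the posterior means of the environment coefficients
    (back-transformed to the β scale), r, and both variance components.  The
    returned table reports, per parameter, the average of those posterior
    means and their SD across replications.
    """
    reps = replications if replications is not None else config.replications
    if reps < 2:
        raise ValueError("need at least 2 replications")
    seed = seed if seed is not None else config.seed
    children = np.random.SeedSequence(seed).spawn(reps)

    rows = []
    failed = []
    for rep, ss in enumerate(children):
        rng = np.random.Generator(np.random.PCG64(ss))
        panel, truth = simulate_panel(config, rng)
        design = build_design(panel, include_blocks=config.K > 0)
        covset = CovarianceSet.from_g1(truth["G1"], config.I)
        pr = prior if prior is not None else PriorSpec.simulation(design.X.shape[1])
        fixed_r = None if np.isfinite(config.r_true) else 1000.0
        try:
            chains = run_gibbs(
                panel, design, covset, pr, iterations, burn_in, rng, fixed_r=fixed_r
            )
        except FloatingPointError as exc:
            failed.append((rep, str(exc)))
            rows.append({"replication": rep, "ok": False})
            continue
        row = {"replication": rep, "ok": True}
        for i in range(config.I):
            row[f"beta{i}"] = chains.beta[:, i].mean()
        row["r"] = chains.r.mean()
        row["sigma2_1"] = chains.sigma_b12.mean()
        row["sigma2_2"] = chains.sigma_b22.mean()
        rows.append(row)
    per_rep = pd.DataFrame(rows)

    true_vals = {f"beta{i}": config.beta_true[i] for i in range(config.I)}
    true_vals.update(
        r=config.r_true, sigma2_1=config.sigma_b12, sigma2_2=config.sigma_b22
    )
    ok = per_rep[per_rep["ok"]] if "ok" in per_rep else per_rep
    table_rows = []
    for name, tv in true_vals.items():
        vals = ok[name].to_numpy(dtype=float) if name in ok else np.array([])
        table_rows.append(
            {
                "parameter": name,
                "true": tv,
                "mean": vals.mean() if vals.size else np.nan,
                "sd": vals.std(ddof=1) if vals.size > 1 else np.nan,
            }
        )
    return RecoveryResult(
        table=pd.DataFrame(table_rows), per_replication=per_rep, failed=failed
    )
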