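"""Bayesian mixed negative-binomial (BMNB) regression for count phenotypes.

The model for count y_ijkt (replicate t, block k, line j, environment i) is

    y_ijkt | g_j, gE_ij  ~  NB(mean μ_ijk, dispersion r),
    log μ_ijk = η_ijk = x_ikᵀβ + g_j + gE_ij,
    g = (g_1..g_J)ᵀ ~ N(0, G1 σ₁²),     gE ~ N(0, (I_I ⊗ G1) σ₂²),

with G1 the (genomic) relationship matrix of the lines, so the genetic and
G×E effects are GBLUP-style random effects.  Writing the NB pmf in logistic
form with shifted environment coefficients β*_i = β_i − log r makes every
conditional conjugate once two sets of latent variables are introduced:
Pólya-Gamma weights ω_ijkt ~ PG(y + r, η*) for the Gaussian blocks, and
Chinese-restaurant-table counts L_ijkt ~ CRT(y, r) for the gamma update of
the dispersion.  The resulting Gibbs loop cycles

    ω → L → r → β* → b1 (= g) → b2 (= gE) → σ₁², σ₂² → σβ²

and is exact (no Metropolis steps).  The Poisson model is the same sampler
with r fixed at a large value (r → ∞ recovers Poisson), skipping the L and
r steps.

Variance priors are scaled inverse chi-square χ⁻²(ν, S); the dispersion
prior is Gamma(a0, scale 1/b0).  Conditional of r (CRT augmentation):
r | L, π ~ Gamma(a0 + ΣL, rate b0 − Σ log(1 − π)) with π = logistic(η*).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, cholesky, solve_triangular
from scipy.special import gammaln

from .augmentation import crt_segments, sample_crt_indexed, sample_pg
from .design import CountPanel, CovarianceSet, DesignSet

__all__ = [
    "PriorSpec",
    "GibbsState",
    "PosteriorChains",
    "BMNBSampler",
    "nb_log_pmf",
    "run_gibbs",
]


def nb_log_pmf(y, eta_star, r):
    """Log-pmf of NB(μ = r·e^{η*}, r) in logistic form, vectorized.

    log Γ(y+r) − log y! − log Γ(r) + y·η* − (y+r)·log(1 + e^{η*});
    equivalent to the standard NB log-pmf with success probability
    π = e^{η*}/(1+e^{η*}) = μ/(r+μ).
    """
    y = np.asarray(y, dtype=float)
    if np.any(y < 0) or np.any(y != np.floor(y)):
        raise ValueError("y must be non-negative integers")
    if np.any(np.asarray(r, dtype=float) <= 0):
        raise ValueError("dispersion r must be > 0")
    eta_star = np.asarray(eta_star, dtype=float)
    return (
        gammaln(y + r)
        - gammaln(y + 1.0)
        - gammaln(r)
        + y * eta_star
        - (y + r) * np.logaddexp(0.0, eta_star)
    )


@dataclass
class PriorSpec:
    """Hyper-parameters of the conditionally conjugate priors.

    β*|σβ² ~ N_p(beta0, Sigma0·σβ²); σβ² ~ χ⁻²(nu_beta, S_beta) or fixed at 1
    when nu_beta is None; σ_bh² ~ χ⁻²(nu_bh, S_bh); r ~ Gamma(a0, 1/b0).
    ``flat_beta`` drops the Σ0 terms from the β* conditional (improper flat
    prior); with block indicators this requires dropping one redundant block
    column per environment, which the sampler does automatically.
    """

    beta0: np.ndarray
    Sigma0: np.ndarray
    nu_b1: float = 3.0
    S_b1: float = 0.001
    nu_b2: float = 3.0
    S_b2: float = 0.001
    a0: float = 0.01
    b0: float = 0.01
    nu_beta: Optional[float] = None
    S_beta: Optional[float] = None
    flat_beta: bool = False

    def __post_init__(self):
        self.beta0 = np.asarray(self.beta0, dtype=float)
        self.Sigma0 = np.asarray(self.Sigma0, dtype=float)
        if self.Sigma0.shape != (self.beta0.size, self.beta0.size):
            raise ValueError("Sigma0 must be p x p matching beta0")
        for name in ("nu_b1", "S_b1", "nu_b2", "S_b2", "a0", "b0"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if (self.nu_beta is None) != (self.S_beta is None):
            raise ValueError("supply both nu_beta and S_beta, or neither")

    @classmethod
    def default(cls, p: int) -> "PriorSpec":
        """Weakly informative real-data defaults: N(0, 10⁴·I), χ⁻²(3, 0.001),
        Gamma(0.01, 1/0.01)."""
        return cls(beta0=np.zeros(p), Sigma0=1e4 * np.eye(p))

    @classmethod
    def simulation(cls, p: int) -> "PriorSpec":
        """Approximately flat priors used for the simulation study:
        N(0, 10⁴·I) for β*, χ⁻²(0.50002, 4.0002) for both variance
        components, Gamma(0.001, 1/0.001) for r."""
        return cls(
            beta0=np.zeros(p),
            Sigma0=1e4 * np.eye(p),
            nu_b1=0.50002,
            S_b1=4.0002,
            nu_b2=0.50002,
            S_b2=4.0002,
            a0=0.001,
            b0=0.001,
        )


@dataclass
class GibbsState:
    """Current values of all sampled quantities."""

    beta_star: np.ndarray
    sigma_beta2: float
    b1: np.ndarray
    sigma_b12: float
    b2: np.ndarray
    sigma_b22: float
    r: float
    omega: np.ndarray
    L: np.ndarray

    def copy(self) -> "GibbsState":
        return replace(
            self,
            beta_star=self.beta_star.copy(),
            b1=self.b1.copy(),
            b2=self.b2.copy(),
            omega=self.omega.copy(),
            L=self.L.copy(),
        )


@dataclass
class PosteriorChains:
    """Retained post-burn-in draws and derived quantities.

    ``beta`` holds the back-transformed coefficients: the first I entries are
    β_i = β*_i + log r (per draw); block coefficients are unshifted.
    """

    beta_star: np.ndarray  # (M, p)
    beta: np.ndarray  # (M, p)
    b1: np.ndarray  # (M, J)
    b2: np.ndarray  # (M, I*J)
    sigma_b12: np.ndarray
    sigma_b22: np.ndarray
    sigma_beta2: np.ndarray
    r: np.ndarray
    loglik: np.ndarray
    iterations: int
    burn_in: int
    meta: dict = field(default_factory=dict)

    @property
    def n_draws(self) -> int:
        return self.r.size

    def summary(self) -> pd.DataFrame:
        """Posterior mean and SD of every scalar parameter."""
        rows = []
        I = self.meta.get("I", 0)
        for i in range(self.beta.shape[1]):
            name = f"beta{i}" if i < I else f"block{i - I}"
            rows.append((name, self.beta[:, i].mean(), self.beta[:, i].std(ddof=1)))
        for name, chain in (
            ("r", self.r),
            ("sigma2_1", self.sigma_b12),
            ("sigma2_2", self.sigma_b22),
        ):
            rows.append((name, chain.mean(), chain.std(ddof=1)))
        return pd.DataFrame(rows, columns=["parameter", "mean", "sd"])

    def to_frame(self) -> pd.DataFrame:
        """One row per retained draw, scalar/vector chains as labelled columns."""
        cols = {}
        for i in range(self.beta_star.shape[1]):
            cols[f"beta_star_{i}"] = self.beta_star[:, i]
            cols[f"beta_{i}"] = self.beta[:, i]
        for j in range(self.b1.shape[1]):
            cols[f"b1_{j}"] = self.b1[:, j]
        for c in range(self.b2.shape[1]):
            cols[f"b2_{c}"] = self.b2[:, c]
        cols["sigma_b12"] = self.sigma_b12
        cols["sigma_b22"] = self.sigma_b22
        cols["sigma_beta2"] = self.sigma_beta2
        cols["r"] = self.r
        cols["loglik"] = self.loglik
        return pd.DataFrame(cols)


def _draw_mvn_prec(A: np.ndarray, rhs: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Draw from N(A⁻¹ rhs, A⁻¹) via the Cholesky factor of the precision A."""
    try:
        c, low = cho_factor(A, lower=False)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - diagnostic path
        raise np.linalg.LinAlgError(
            "singular precision matrix in a Gaussian conditional; "
            "check for collinear design columns or add a GRM ridge"
        ) from exc
    mean = cho_solve((c, low), rhs)
    z = rng.standard_normal(rhs.size)
    return mean + solve_triangular(c, z, lower=False)


def _draw_scaled_inv_chi2(nu: float, scale: float, rng: np.random.Generator) -> float:
    """Draw from χ⁻²(ν, S): ν·S / χ²_ν."""
    return nu * scale / rng.chisquare(nu)


class BMNBSampler:
    """Precomputed workspace plus the individual full-conditional updates.

    Parameters
    ----------
    panel, design, covset
        Data, design matrices, and known effect covariances (G1, G2).
    prior
        :class:`PriorSpec`.
    fixed_r
        Fix the dispersion (Poisson model); skips the CRT/gamma steps.
    include_gxe
        When False the interaction term b2 is dropped from the predictor
        (main-effects model, e.g. scenarios without E×G).
    fixed_sigma_b1, fixed_sigma_b2
        Freeze a variance component (used by oracle tests).
    ridge
        Added to G1's diagonal only if its Cholesky fails.
    """

    def __init__(
        self,
        panel: CountPanel,
        design: DesignSet,
        covset: CovarianceSet,
        prior: PriorSpec,
        fixed_r: Optional[float] = None,
        include_gxe: bool = True,
        fixed_sigma_b1: Optional[float] = None,
        fixed_sigma_b2: Optional[float] = None,
        ridge: float = 1e-6,
        pg_trunc: int = 32,
    ):
        if covset.G1.shape[0] != panel.J:
            raise ValueError("G1 dimension does not match the number of lines")
        if design.X.shape[0] != panel.n_T:
            raise ValueError("design rows do not match the panel")
        self.panel = panel
        self.design = design
        self.covset = covset
        self.prior = prior
        self.fixed_r = fixed_r
        self.include_gxe = include_gxe
        self.fixed_sigma_b1 = fixed_sigma_b1
        self.fixed_sigma_b2 = fixed_sigma_b2
        self.pg_trunc = pg_trunc

        self.y = panel.y.astype(np.int64)
        self.yf = self.y.astype(float)
        self.line_idx = panel.line_idx
        self.cell_idx = panel.cell_idx
        self.I, self.J = design.I, design.J
        self.n_T = panel.n_T

        # Flat improper prior on beta*: drop one redundant block column per
        # environment (cell-means env coding + full block indicators is
        # rank-deficient); the proper prior regularizes it instead.
        X = design.X
        self._kept_cols = np.arange(X.shape[1])
        if prior.flat_beta and design.include_blocks and design.K > 0:
            drop = [design.I + i * design.K + (design.K - 1) for i in range(design.I)]
            self._kept_cols = np.array(
                [c for c in range(X.shape[1]) if c not in set(drop)], dtype=np.int64
            )
            X = X[:, self._kept_cols]
        self.X = np.ascontiguousarray(X)
        self.p = self.X.shape[1]
        if prior.beta0.size != self.p:
            raise ValueError(
                f"prior dimension {prior.beta0.size} does not match p = {self.p}"
            )

        G1 = np.asarray(covset.G1, dtype=float)
        try:
            cholesky(G1, lower=True)
        except np.linalg.LinAlgError:
            G1 = G1 + ridge * np.eye(self.J)
        self._G1_chol = cho_factor(G1, lower=True)
        self.G1_inv = cho_solve(self._G1_chol, np.eye(self.J))

        if not prior.flat_beta:
            self.Sigma0_inv = np.linalg.inv(prior.Sigma0)
        else:
            self.Sigma0_inv = np.zeros((self.p, self.p))

        self._crt_seg, self._crt_table = crt_segments(self.y)

    # ----- linear predictor -------------------------------------------------

    def eta_star(self, state: GibbsState) -> np.ndarray:
        eta = self.X @ state.beta_star + state.b1[self.line_idx]
        if self.include_gxe:
            eta = eta + state.b2[self.cell_idx]
        return eta

    def loglik(self, state: GibbsState) -> float:
        return float(np.sum(nb_log_pmf(self.y, self.eta_star(state), state.r)))

    # ----- initial state ----------------------------------------------------

    def init_state(self, rng: np.random.Generator) -> GibbsState:
        r0 = self.fixed_r if self.fixed_r is not None else 1.0
        return GibbsState(
            beta_star=np.zeros(self.p),
            sigma_beta2=1.0,
            b1=np.zeros(self.J),
            sigma_b12=self.fixed_sigma_b1 or 1.0,
            b2=np.zeros(self.I * self.J),
            sigma_b22=self.fixed_sigma_b2 or 1.0,
            r=float(r0),
            omega=np.full(self.n_T, 0.25),
            L=np.zeros(self.n_T, dtype=np.int64),
        )

    # ----- full-conditional updates ----------------------------------------

    def update_omega(self, state: GibbsState, rng: np.random.Generator) -> None:
        """ω_ijkt ~ PG(y_ijkt + r, η*_ijk)."""
        state.omega = sample_pg(
            self.yf + state.r, self.eta_star(state), rng, trunc=self.pg_trunc
        )

    def update_r(self, state: GibbsState, rng: np.random.Generator) -> None:
        """L ~ CRT(y, r), then r ~ Gamma(a0 + ΣL, rate b0 − Σ log(1−π)).

        π = logistic(η*) does not involve r, so the gamma parameters depend
        on r only through the freshly drawn table counts.
        """
        state.L = sample_crt_indexed(
            self._crt_seg, self._crt_table, self.n_T, state.r, rng
        )
        # −log(1−π) = log(1 + e^{η*}), computed without overflow
        neg_log1mpi = np.logaddexp(0.0, self.eta_star(state))
        shape = self.prior.a0 + float(state.L.sum())
        rate = self.prior.b0 + float(neg_log1mpi.sum())
        state.r = float(rng.gamma(shape) / rate)

    def _kappa(self, state: GibbsState) -> np.ndarray:
        return 0.5 * (self.yf - state.r)

    def update_beta(self, state: GibbsState, rng: np.random.Generator) -> None:
        """β* ~ N(β̃0, Σ̃0), Σ̃0 = (Σ0⁻¹/σβ² + XᵀDωX)⁻¹."""
        om = state.omega
        prec0 = self.Sigma0_inv / state.sigma_beta2
        A = prec0 + self.X.T @ (om[:, None] * self.X)
        zb = state.b1[self.line_idx]
        if self.include_gxe:
            zb = zb + state.b2[self.cell_idx]
        rhs = prec0 @ self.prior.beta0 + self.X.T @ (self._kappa(state) - om * zb)
        state.beta_star = _draw_mvn_prec(A, rhs, rng)

    def update_b1(self, state: GibbsState, rng: np.random.Generator) -> None:
        """b1 ~ N(b̃1, F1), F1 = (G1⁻¹/σ₁² + Z1ᵀDωZ1)⁻¹."""
        om = state.omega
        eta1 = self.X @ state.beta_star
        if self.include_gxe:
            eta1 = eta1 + state.b2[self.cell_idx]
        s = np.bincount(self.line_idx, weights=om, minlength=self.J)
        rhs = np.bincount(
            self.line_idx, weights=self._kappa(state) - om * eta1, minlength=self.J
        )
        A = self.G1_inv / state.sigma_b12 + np.diag(s)
        state.b1 = _draw_mvn_prec(A, rhs, rng)

    def update_b2(self, state: GibbsState, rng: np.random.Generator) -> None:
        """b2 ~ N(b̃2, F2) solved per environment (G2 and Z2ᵀDωZ2 are block
        diagonal, so the IJ-dimensional draw factorizes into I solves)."""
        if not self.include_gxe:
            return
        om = state.omega
        eta2 = self.X @ state.beta_star + state.b1[self.line_idx]
        s = np.bincount(self.cell_idx, weights=om, minlength=self.I * self.J)
        rhs = np.bincount(
            self.cell_idx,
            weights=self._kappa(state) - om * eta2,
            minlength=self.I * self.J,
        )
        out = np.empty(self.I * self.J)
        for i in range(self.I):
            sl = slice(i * self.J, (i + 1) * self.J)
            A = self.G1_inv / state.sigma_b22 + np.diag(s[sl])
            out[sl] = _draw_mvn_prec(A, rhs[sl], rng)
        state.b2 = out

    def update_sigma_b(self, state: GibbsState, which: int, rng: np.random.Generator) -> None:
        """σ_bh² ~ χ⁻²(ν + n_bh, (bhᵀGh⁻¹bh + νS)/(ν + n_bh))."""
        if which == 1:
            if self.fixed_sigma_b1 is not None:
                return
            quad = float(state.b1 @ self.G1_inv @ state.b1)
            nu, S, n_b = self.prior.nu_b1, self.prior.S_b1, self.J
            state.sigma_b12 = _draw_scaled_inv_chi2(nu + n_b, (quad + nu * S) / (nu + n_b), rng)
        elif which == 2:
            if not self.include_gxe or self.fixed_sigma_b2 is not None:
                return
            b2m = state.b2.reshape(self.I, self.J)
            quad = float(np.sum(b2m * (b2m @ self.G1_inv)))
            nu, S, n_b = self.prior.nu_b2, self.prior.S_b2, self.I * self.J
            state.sigma_b22 = _draw_scaled_inv_chi2(nu + n_b, (quad + nu * S) / (nu + n_b), rng)
        else:
            raise ValueError("which must be 1 or 2")

    def update_sigma_beta(self, state: GibbsState, rng: np.random.Generator) -> None:
        """σβ² ~ χ⁻²(νβ + p, ...); no-op when the prior fixes σβ² or is flat."""
        if self.prior.nu_beta is None or self.prior.flat_beta:
            return
        d = state.beta_star - self.prior.beta0
        quad = float(d @ self.Sigma0_inv @ d)
        nu, S = self.prior.nu_beta, self.prior.S_beta
        df = nu + self.p
        state.sigma_beta2 = _draw_scaled_inv_chi2(df, (quad + nu * S) / df, rng)

    # ----- main loop --------------------------------------------------------

    def step(self, state: GibbsState, rng: np.random.Generator) -> None:
        """One full scan: L, r, ω, β*, b1, b2, σ₁², σ₂², σβ².

        The CRT/gamma update of r is derived with the Pólya-Gamma latents
        integrated out, so ω must be refreshed immediately after r changes
        and before any Gaussian block uses it (κ = (y − r)/2 and ω must
        reflect the same r); this ordering makes the scan a valid partially
        collapsed Gibbs sampler.  With r fixed (Poisson model) the first two
        steps are skipped.
        """
        if self.fixed_r is None:
            self.update_r(state, rng)
        self.update_omega(state, rng)
        self.update_beta(state, rng)
        self.update_b1(state, rng)
        self.update_b2(state, rng)
        self.update_sigma_b(state, 1, rng)
        self.update_sigma_b(state, 2, rng)
        self.update_sigma_beta(state, rng)

    def run(
        self,
        iterations: int,
        burn_in: int,
        rng: np.random.Generator,
        thin: int = 1,
    ) -> PosteriorChains:
        if not (iterations > burn_in >= 0):
            raise ValueError("need iterations > burn_in >= 0")
        if thin < 1:
            raise ValueError("thin must be >= 1")
        state = self.init_state(rng)
        kept = [i for i in range(iterations) if i >= burn_in and (i - burn_in) % thin == 0]
        M = len(kept)
        ch = PosteriorChains(
            beta_star=np.empty((M, self.p)),
            beta=np.empty((M, self.p)),
            b1=np.empty((M, self.J)),
            b2=np.empty((M, self.I * self.J)),
            sigma_b12=np.empty(M),
            sigma_b22=np.empty(M),
            sigma_beta2=np.empty(M),
            r=np.empty(M),
            loglik=np.empty(M),
            iterations=iterations,
            burn_in=burn_in,
            meta={
                "I": self.I,
                "J": self.J,
                "p": self.p,
                "include_blocks": self.design.include_blocks,
                "include_gxe": self.include_gxe,
                "fixed_r": self.fixed_r,
                "env_levels": list(self.panel.env_levels),
                "line_levels": list(self.panel.line_levels),
                "block_levels": list(self.panel.block_levels),
                "kept_cols": self._kept_cols.tolist(),
                "thin": thin,
            },
        )
        m = 0
        for it in range(iterations):
            self.step(state, rng)
            if not np.isfinite(state.beta_star).all() or not np.isfinite(state.r):
                raise FloatingPointError(
                    f"non-finite sampler state at iteration {it}; "
                    f"r={state.r}, max|beta*|={np.abs(state.beta_star).max()}"
                )
            if it >= burn_in and (it - burn_in) % thin == 0:
                ch.beta_star[m] = state.beta_star
                beta = state.beta_star.copy()
                beta[: self.I] += np.log(state.r)
                ch.beta[m] = beta
                ch.b1[m] = state.b1
                ch.b2[m] = state.b2
                ch.sigma_b12[m] = state.sigma_b12
                ch.sigma_b22[m] = state.sigma_b22
                ch.sigma_beta2[m] = state.sigma_beta2
                ch.r[m] = state.r
                ch.loglik[m] = self.loglik(state)
                m += 1
        return ch


def run_gibbs(
    panel: CountPanel,
    design: DesignSet,
    covset: CovarianceSet,
    prior: PriorSpec,
    iterations: int,
    burn_in: int,
    rng: np.random.Generator,
    fixed_r: Optional[float] = None,
    include_gxe: bool = True,
    thin: int = 1,
    **kwargs,
) -> PosteriorChains:
    """Fit the BMNB (or fixed-r Poisson) model and return retained chains."""
    sampler = BMNBSampler(
        panel, design, covset, prior, fixed_r=fixed_r, include_gxe=include_gxe, **kwargs
    )
    return sampler.run(iterations, burn_in, rng, thin=thin)
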