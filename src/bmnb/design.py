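"""Containers and design/covariance construction for multi-environment count trials.

The experimental layout is the classic multi-environment trial: J lines
(genotypes) grown in I environments, each arranged in a randomized complete
block design with K blocks, and n_ijk replicate counts per line × block ×
environment cell.  Records are kept in a canonical environment-major order
(environment, line, block, replicate) so that the stacking of the response,
the fixed-effect design X, and the incidence matrices Z1 (lines) and Z2
(line-within-environment) all agree with the block ordering of the
Kronecker-structured covariance I_I ⊗ G1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "CountPanel",
    "MarkerMatrix",
    "CovarianceSet",
    "DesignSet",
    "compute_grm",
    "build_g2",
    "build_design",
    "maf_filter",
]


@dataclass
class CountPanel:
    """Long-format table of count observations y_ijkt with trial structure.

    Attributes
    ----------
    frame
        Canonically sorted DataFrame with columns env, block, line, rep, count.
    env_levels, line_levels, block_levels
        Label vocabularies; internal indices are 0-based positions in these.
    env_idx, line_idx, block_idx, y
        Per-record integer index arrays and the count vector.
    """

    frame: pd.DataFrame
    env_levels: list
    line_levels: list
    block_levels: list
    env_idx: np.ndarray = field(repr=False)
    line_idx: np.ndarray = field(repr=False)
    block_idx: np.ndarray = field(repr=False)
    y: np.ndarray = field(repr=False)

    @property
    def I(self) -> int:  # noqa: E743 - field-standard symbol
        return len(self.env_levels)

    @property
    def J(self) -> int:
        return len(self.line_levels)

    @property
    def K(self) -> int:
        return len(self.block_levels)

    @property
    def n_T(self) -> int:
        return self.y.size

    @property
    def cell_idx(self) -> np.ndarray:
        """Environment-major (env, line) cell index in 0..I·J−1."""
        return self.env_idx * self.J + self.line_idx

    @classmethod
    def from_frame(cls, df: pd.DataFrame, line_levels=None) -> "CountPanel":
        """Build a panel from a long-format frame (env, block, line, rep, count).

        ``line_levels`` fixes the line vocabulary/order (e.g. to match the rows
        of a marker matrix, or to keep held-out lines addressable in
        cross-validation); by default sorted unique labels are used.
        """
        required = ["env", "block", "line", "rep", "count"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"phenotype table is missing columns: {missing}")
        if len(df) == 0:
            raise ValueError("phenotype table is empty")
        counts = df["count"].to_numpy()
        if not np.all(np.isfinite(np.asarray(counts, dtype=float))):
            bad = int(np.flatnonzero(~np.isfinite(np.asarray(counts, dtype=float)))[0])
            raise ValueError(f"non-finite count at row {bad}")
        if np.any(np.asarray(counts, dtype=float) != np.floor(counts)) or np.any(counts < 0):
            bad = int(
                np.flatnonzero(
                    (np.asarray(counts, dtype=float) != np.floor(counts)) | (counts < 0)
                )[0]
            )
            raise ValueError(f"count must be a non-negative integer (row {bad})")
        dup = df.duplicated(subset=["env", "block", "line", "rep"])
        if dup.any():
            raise ValueError(
                f"duplicate (env, block, line, rep) key at row {int(np.flatnonzero(dup)[0])}"
            )

        frame = df[required].copy()
        frame = frame.sort_values(["env", "line", "block", "rep"], kind="mergesort")
        frame = frame.reset_index(drop=True)

        env_levels = sorted(frame["env"].unique().tolist())
        block_levels = sorted(frame["block"].unique().tolist())
        if line_levels is None:
            line_levels = sorted(frame["line"].unique().tolist())
        else:
            line_levels = list(line_levels)
            unknown = set(frame["line"]) - set(line_levels)
            if unknown:
                raise ValueError(f"lines not in supplied vocabulary: {sorted(unknown)[:5]}")

        env_pos = {v: i for i, v in enumerate(env_levels)}
        line_pos = {v: i for i, v in enumerate(line_levels)}
        block_pos = {v: i for i, v in enumerate(block_levels)}
        return cls(
            frame=frame,
            env_levels=env_levels,
            line_levels=line_levels,
            block_levels=block_levels,
            env_idx=frame["env"].map(env_pos).to_numpy(dtype=np.int64),
            line_idx=frame["line"].map(line_pos).to_numpy(dtype=np.int64),
            block_idx=frame["block"].map(block_pos).to_numpy(dtype=np.int64),
            y=np.asarray(frame["count"].to_numpy(), dtype=np.int64),
        )

    def subset(self, mask: np.ndarray) -> "CountPanel":
        """Record subset keeping the full label vocabularies (for CV folds)."""
        sub = self.frame.loc[np.asarray(mask)].copy()
        out = CountPanel.from_frame(sub, line_levels=self.line_levels)
        # preserve env/block vocabularies even if a level drops out of the subset
        if out.env_levels != self.env_levels or out.block_levels != self.block_levels:
            env_pos = {v: i for i, v in enumerate(self.env_levels)}
            block_pos = {v: i for i, v in enumerate(self.block_levels)}
            out = CountPanel(
                frame=out.frame,
                env_levels=self.env_levels,
                line_levels=self.line_levels,
                block_levels=self.block_levels,
                env_idx=out.frame["env"].map(env_pos).to_numpy(dtype=np.int64),
                line_idx=out.line_idx,
                block_idx=out.frame["block"].map(block_pos).to_numpy(dtype=np.int64),
                y=out.y,
            )
        return out


@dataclass
class MarkerMatrix:
    """Line × marker matrix of 0/1 allele-dosage codes."""

    W: np.ndarray
    lines: list
    markers: list

    def __post_init__(self):
        self.W = np.asarray(self.W)
        if self.W.ndim != 2 or self.W.shape[1] < 1:
            raise ValueError("marker matrix must be 2-D with at least one marker")
        if not np.isin(self.W, (0, 1)).all():
            raise ValueError("marker codes must be 0/1 (impute or filter first)")

    @property
    def q(self) -> int:
        return self.W.shape[1]


def compute_grm(W, ridge: float = 0.0) -> np.ndarray:
    """Genomic relationship matrix G1 = W Wᵀ / q (+ ridge·I).

    W is the J × q matrix of 0/1 marker codes (a :class:`MarkerMatrix` or a
    plain array).  No allele-frequency centering or scaling is applied; pass
    a centered matrix explicitly if a centered GRM is wanted.  The ridge is
    only needed when the GRM must be inverted and is numerically singular.
    """
    if isinstance(W, MarkerMatrix):
        W = W.W
    W = np.asarray(W, dtype=float)
    if W.ndim != 2 or W.shape[1] < 1:
        raise ValueError("marker matrix must be 2-D with at least one marker")
    if not np.isin(W, (0.0, 1.0)).all():
        raise ValueError("marker codes must be 0/1")
    if ridge < 0:
        raise ValueError("ridge must be non-negative")
    q = W.shape[1]
    G = W @ W.T / q
    if ridge > 0:
        G = G + ridge * np.eye(W.shape[0])
    return G


def build_g2(G1: np.ndarray, I: int) -> np.ndarray:
    """Block-diagonal covariance I_I ⊗ G1 for line-within-environment effects.

    The identity factor encodes independence of the interaction effects
    across environments; block (i, i) equals G1 exactly.
    """
    G1 = np.asarray(G1, dtype=float)
    if int(I) < 1:
        raise ValueError("environment count I must be >= 1")
    return np.kron(np.eye(int(I)), G1)


@dataclass
class CovarianceSet:
    """Known covariances of the genetic (G1, J × J) and G×E (G2, IJ × IJ) effects."""

    G1: np.ndarray
    G2: np.ndarray

    @classmethod
    def from_g1(cls, G1: np.ndarray, I: int) -> "CovarianceSet":
        G1 = np.asarray(G1, dtype=float)
        if not np.allclose(G1, G1.T, atol=1e-10):
            raise ValueError("G1 must be symmetric")
        return cls(G1=G1, G2=build_g2(G1, I))

    @classmethod
    def from_markers(cls, markers: MarkerMatrix, I: int, ridge: float = 0.0) -> "CovarianceSet":
        return cls.from_g1(compute_grm(markers, ridge=ridge), I)

    @property
    def J(self) -> int:
        return self.G1.shape[0]

    @property
    def I(self) -> int:  # noqa: E743
        return self.G2.shape[0] // self.G1.shape[0]


@dataclass
class DesignSet:
    """Fixed-effect design and incidence matrices, rows in panel order.

    X has the I environment indicator columns first, then (optionally) the
    I·K block-within-environment indicators, environment-major; Z1 maps each
    record to its line; Z2 = Z1 *~ X_env (row-wise/face-splitting Kronecker
    product with the environment columns only), giving the n_T × IJ incidence
    of the interaction effects in the same environment-major order as G2.
    """

    X: np.ndarray
    Z1: np.ndarray
    Z2: np.ndarray
    include_blocks: bool
    I: int  # noqa: E741
    J: int
    K: int

    @property
    def p(self) -> int:
        return self.X.shape[1]


def build_design(panel: CountPanel, include_blocks: bool = True) -> DesignSet:
    """Construct X, Z1, Z2 for a panel.

    With blocks, p = I + I·K; without, X holds only the I environment
    indicators (the simulation-study predictor η_ij = E_i + g_j + gE_ij).
    """
    I, J, K, n = panel.I, panel.J, panel.K, panel.n_T
    X_env = np.zeros((n, I))
    X_env[np.arange(n), panel.env_idx] = 1.0
    if include_blocks:
        Xb = np.zeros((n, I * K))
        Xb[np.arange(n), panel.env_idx * K + panel.block_idx] = 1.0
        X = np.hstack([X_env, Xb])
    else:
        X = X_env
    Z1 = np.zeros((n, J))
    Z1[np.arange(n), panel.line_idx] = 1.0
    Z2 = np.zeros((n, I * J))
    Z2[np.arange(n), panel.cell_idx] = 1.0
    return DesignSet(X=X, Z1=Z1, Z2=Z2, include_blocks=include_blocks, I=I, J=J, K=K)


def maf_filter(
    W_raw,
    maf_threshold: float = 0.05,
    max_missing: float = 0.10,
    lines=None,
    markers=None,
) -> MarkerMatrix:
    """Filter a raw 0/1/missing marker matrix and impute what remains.

    Markers with minor-allele frequency below ``maf_threshold`` (computed on
    non-missing calls) or with more than ``max_missing`` missing fraction are
    dropped; surviving missing calls are imputed to the marker's modal code.
    """
    if not (0.0 <= maf_threshold <= 0.5):
        raise ValueError("maf_threshold must be in [0, 0.5]")
    if not (0.0 <= max_missing <= 1.0):
        raise ValueError("max_missing must be in [0, 1]")
    W = np.asarray(W_raw, dtype=float)
    if W.ndim != 2 or W.shape[1] < 1:
        raise ValueError("marker matrix must be 2-D with at least one marker")
    obs = np.isfinite(W)
    vals = np.where(obs, W, 0.0)
    if not np.isin(vals, (0.0, 1.0)).all():
        raise ValueError("marker codes must be 0, 1 or missing (NaN)")
    n_obs = obs.sum(axis=0)
    miss_frac = 1.0 - n_obs / W.shape[0]
    with np.errstate(invalid="ignore"):
        freq = np.where(n_obs > 0, vals.sum(axis=0) / np.maximum(n_obs, 1), 0.0)
    maf = np.minimum(freq, 1.0 - freq)
    keep = (maf >= maf_threshold) & (miss_frac <= max_missing)
    if markers is None:
        markers = list(range(W.shape[1]))
    if lines is None:
        lines = list(range(W.shape[0]))
    kept_idx = np.flatnonzero(keep)
    Wk = W[:, kept_idx]
    n_imputed = int(np.sum(~np.isfinite(Wk)))
    if n_imputed:
        modal = (freq[kept_idx] > 0.5).astype(float)  # ties -> 0
        Wk = np.where(np.isfinite(Wk), Wk, modal[None, :])
        logger.info("imputed %d missing marker calls to modal codes", n_imputed)
    logger.info(
        "MAF filter kept %d of %d markers (maf >= %.3g, missing <= %.3g)",
        kept_idx.size,
        W.shape[1],
        maf_threshold,
        max_missing,
    )
    return MarkerMatrix(
        W=Wk.astype(np.int64), lines=list(lines), markers=[markers[i] for i in kept_idx]
    )
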