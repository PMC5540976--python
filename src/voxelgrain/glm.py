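"""Block-design GLM: boxcar predictors, gamma HRF, OLS t-patterns.

The experiment is a two-condition block design.  Each run splits into four
subruns; each subrun contains six 14-s stimulus blocks (three per
condition, conditions alternating across blocks, with the leading
condition alternating across subruns).  The GLM uses one predictor per
(condition, subrun) pair, so a run yields one t-value per condition per
subrun per voxel — the "t-pattern" currency of the whole pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import (
    DegenerateDataError,
    InvalidDesignError,
    InvalidParameterError,
    SingularDesignError,
)


@dataclass(frozen=True)
class HrfParams:
    """Gamma-shaped hemodynamic response: h(t) ~ ((t-d)/tau)^(n-1) exp(-(t-d)/tau).

    Defaults n=3, tau=1.25 s, onset_delay=0, no undershoot; the kernel is
    rescaled to unit sum so convolution preserves block amplitude.
    """

    n: int = 3
    tau: float = 1.25
    onset_delay: float = 0.0

    def __post_init__(self):
        if self.n < 1 or self.tau <= 0 or self.onset_delay < 0:
            raise InvalidParameterError(f"invalid HRF parameters {self}")


@dataclass(frozen=True)
class BlockDesign:
    """Timing of one scanner run.

    ``rest_length`` seconds of fixation follow every block, so a subrun
    lasts ``blocks_per_subrun * (block_length + rest_length)`` seconds.
    Stimuli appear at ``presentation_rate_hz`` within blocks (28 exemplar
    presentations per 14-s block at 2 Hz).
    """

    tr: float = 2.0
    n_runs: int = 2
    subruns_per_run: int = 4
    blocks_per_subrun: int = 6
    block_length: float = 14.0
    rest_length: float = 6.0
    conditions: int = 2
    presentation_rate_hz: float = 2.0

    def __post_init__(self):
        if min(self.tr, self.block_length) <= 0 or self.rest_length < 0:
            raise InvalidDesignError("non-positive timing parameters")
        if self.conditions < 1 or self.blocks_per_subrun % self.conditions:
            raise InvalidDesignError("blocks_per_subrun must be a multiple of conditions")
        cycle = self.block_length + self.rest_length
        for value, name in ((cycle, "block+rest"), (self.block_length, "block_length")):
            if abs(value / self.tr - round(value / self.tr)) > 1e-9:
                raise InvalidDesignError(f"TR must divide {name}")

    @property
    def presentations_per_block(self) -> int:
        return int(round(self.block_length * self.presentation_rate_hz))

    @property
    def volumes_per_subrun(self) -> int:
        return int(round(self.blocks_per_subrun * (self.block_length + self.rest_length) / self.tr))

    @property
    def volumes_per_run(self) -> int:
        return self.volumes_per_subrun * self.subruns_per_run

    def block_onsets(self) -> list[tuple[float, int, int]]:
        """(onset_seconds, subrun, condition) for every block of one run.

        Conditions alternate across blocks and the leading condition
        alternates across subruns.
        """
        out = []
        cycle = self.block_length + self.rest_length
        for sub in range(self.subruns_per_run):
            base = sub * self.blocks_per_subrun * cycle
            for blk in range(self.blocks_per_subrun):
                cond = (blk + sub) % self.conditions
                out.append((base + blk * cycle, sub, cond))
        return out


def boynton_hrf(params: HrfParams, dt: float, duration: float = 30.0) -> np.ndarray:
    """Sampled gamma HRF kernel, non-negative, rescaled to unit sum."""
    if dt <= 0:
        raise InvalidParameterError("dt must be positive")
    t = np.arange(0.0, duration, dt)
    if t.size == 0:
        raise InvalidParameterError("duration must cover at least one sample")
    ts = t - params.onset_delay
    h = np.where(ts >= 0, np.power(np.clip(ts, 0, None) / params.tau, params.n - 1)
                 * np.exp(-np.clip(ts, 0, None) / params.tau), 0.0)
    # (t/tau)^(n-1) at t=0, n=1 gives 1: boxcar-onset convention
    total = h.sum()
    if total <= 0:
        raise InvalidParameterError("duration too short: kernel support not covered")
    return h / total


def _boxcar(design: BlockDesign, subrun: int, condition: int) -> np.ndarray:
    """Unconvolved indicator over volumes for one (condition, subrun) predictor."""
    n = design.volumes_per_run
    box = np.zeros(n)
    for onset, sub, cond in design.block_onsets():
        if sub == subrun and cond == condition:
            v0 = int(round(onset / design.tr))
            v1 = v0 + int(round(design.block_length / design.tr))
            if np.any(box[v0:v1]):
                raise InvalidDesignError("overlapping blocks")
            box[v0:v1] = 1.0
    return box


def build_design_matrix(
    design: BlockDesign,
    hrf: HrfParams = HrfParams(),
    confounds: int = 0,
) -> tuple[np.ndarray, list[str]]:
    """Design matrix for one run and its column labels.

    One HRF-convolved boxcar column per (condition, subrun) pair —
    ``conditions * subruns_per_run`` task columns — followed by
    ``confounds`` Legendre polynomial drift columns and an intercept.
    """
    if confounds < 0:
        raise InvalidParameterError("confounds must be >= 0")
    n = design.volumes_per_run
    kernel = boynton_hrf(hrf, dt=design.tr)
    cols, labels = [], []
    for cond in range(design.conditions):
        for sub in range(design.subruns_per_run):
            box = _boxcar(design, sub, cond)
            cols.append(np.convolve(box, kernel)[:n])
            labels.append(f"cond{cond}_subrun{sub}")
    x = np.linspace(-1, 1, n)
    for order in range(1, confounds + 1):
        cols.append(np.polynomial.legendre.Legendre.basis(order)(x))
        labels.append(f"drift{order}")
    cols.append(np.ones(n))
    labels.append("intercept")
    return np.column_stack(cols), labels


@dataclass
class GlmFit:
    """OLS fit of one run: betas always available, t on demand.

    ``t`` raises :class:`DegenerateDataError` if any voxel has (near-)zero
    residual variance, which in simulation signals a noise-free series.
    """

    beta: np.ndarray  # (predictors, voxels)
    _se: np.ndarray
    dof: int
    labels: list[str]

    @property
    def t(self) -> np.ndarray:
        if not np.all(np.isfinite(self._se)) or np.any(self._se <= 0):
            raise DegenerateDataError(
                "zero residual variance: t-values undefined for some voxels"
            )
        return self.beta / self._se


def fit_glm(series: np.ndarray, X: np.ndarray, labels: list[str] | None = None) -> GlmFit:
    """Ordinary least squares of ``series`` (volumes x voxels) on ``X``.

    t = beta / SE(beta) with residual dof = volumes - rank(X); requires X
    full column rank.
    """
    series = np.atleast_2d(np.asarray(series, dtype=float))
    if series.shape[0] == 1 and X.shape[0] != 1:
        series = series.T
    n, p = X.shape
    if series.shape[0] != n:
        raise InvalidParameterError("series length does not match design matrix")
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        raise SingularDesignError(f"design matrix rank {rank} < {p} columns")
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ (X.T @ series)
    resid = series - X @ beta
    dof = n - rank
    if dof <= 0:
        raise SingularDesignError("no residual degrees of freedom")
    sigma2 = np.einsum("ij,ij->j", resid, resid) / dof
    # (near-)zero residual variance, relative to the data scale, means the
    # model fits exactly and t is undefined
    scale = np.einsum("ij,ij->j", series, series) / n
    degenerate = sigma2 <= 1e-20 * np.maximum(scale, 1e-300)
    se = np.sqrt(np.outer(np.diag(xtx_inv), sigma2))
    with np.errstate(invalid="ignore"):
        se = np.where((se > 0) & ~degenerate[None, :], se, np.nan)
    return GlmFit(beta=beta, _se=se, dof=dof, labels=labels or [f"b{i}" for i in range(p)])


def fit_tpatterns(
    series: np.ndarray,
    X: np.ndarray,
    labels: list[str] | None = None,
    n_task: int | None = None,
) -> np.ndarray:
    """Per-predictor t-values per voxel; returns only the first ``n_task`` rows.

    With the default design this is the (2 conditions x 4 subruns) = 8
    task t-patterns of one run.
    """
    fit = fit_glm(series, X, labels)
    t = fit.t
    return t[: n_task if n_task is not None else t.shape[0]]


def design_matrix_to_frame(X: np.ndarray, labels: list[str]):
    """Labeled DataFrame view of a design matrix, for TSV audit export."""
    import pandas as pd

    return pd.DataFrame(X, columns=labels)
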