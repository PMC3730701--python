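"""Self-organized perception: do internal dynamics predict external motion?

If the internal states of a blanketed system parametrize posterior beliefs
about hidden states, internal activity should carry a statistical
dependency on external events.  The test mirrors classical brain mapping:

1. lag-embed the internal electrochemical timeseries (±16 s by default),
2. summarize it by its first 32 eigenvariates (SVD),
3. regress the 2-D position of each external subsystem on the eigenvariates
   with canonical variates analysis, scoring each with Wilks' lambda and
   Bartlett's chi-square transformation,
4. repeat against time-reversed external series — a surrogate null that
   destroys cross-coupling while preserving within-set autocorrelation,
5. count true statistics exceeding the largest null statistic; the
   probability of that count under a per-test exchange rate of 1/n_tests is
   the exceedance p-value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, stats

from .blanket import BlanketPartition
from .soup import Trajectory

logger = logging.getLogger(__name__)


@dataclass
class EmbeddedSeries:
    """Valid-region lag embedding of a multichannel series."""

    matrix: np.ndarray                      # (T - 2L, c * (2L + 1))
    lag_range: float                        # seconds (±)
    channel_index: list[tuple[int, int]]    # (channel, lag in samples) per column


@dataclass
class CvaResult:
    """Canonical variates analysis of X against Y."""

    wilks_lambda: float
    chi2: float
    dof: int
    canonical_correlations: np.ndarray
    predicted: np.ndarray   # first canonical variate of X (the predictor side)
    actual: np.ndarray      # first canonical variate of Y


@dataclass
class PredictabilityMap:
    """Per-external-subsystem dependency statistics with the time-flip null."""

    external_indices: np.ndarray
    chi2_true: np.ndarray
    chi2_null: np.ndarray
    threshold: float
    n_exceed: int
    p_value: float
    dof: int
    best_external: int
    best_cva: CvaResult | None = None
    decisions: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "external_indices": self.external_indices.tolist(),
            "chi2_true": self.chi2_true.tolist(),
            "chi2_null": self.chi2_null.tolist(),
            "threshold": self.threshold,
            "n_exceed": self.n_exceed,
            "p_value": self.p_value,
            "dof": self.dof,
            "best_external": self.best_external,
            "decisions": self.decisions,
        }


def temporal_embed(
    series: np.ndarray, lag_seconds: float, sample_interval: float = 1.0
) -> EmbeddedSeries:
    """Embed a (T, c) series with integer lags spanning ±lag_seconds.

    Column (channel, lag) at valid row t holds series[t + lag, channel];
    rows are restricted to the valid region where every lag is in range, so
    the output has T - 2L rows and c * (2L + 1) columns with
    L = lag_seconds / sample_interval.
    """
    series = np.atleast_2d(np.asarray(series, dtype=float))
    if series.ndim != 2:
        raise ValueError("series must be 2-D (time x channels)")
    T, c = series.shape
    L = round(lag_seconds / sample_interval)
    if T <= 2 * L:
        raise ValueError(
            f"series too short to embed: need more than {2 * L} samples, got {T}"
        )
    lags = range(-L, L + 1)
    cols = []
    index = []
    for ch in range(c):
        for lag in lags:
            cols.append(series[L + lag : T - L + lag, ch])
            index.append((ch, lag))
    return EmbeddedSeries(
        matrix=np.column_stack(cols), lag_range=float(lag_seconds), channel_index=index
    )


def eigenvariates(embedded: EmbeddedSeries | np.ndarray, n_components: int) -> np.ndarray:
    """Principal temporal patterns of an embedded series.

    Left singular vectors of the column-centred matrix scaled by their
    singular values; each component's sign is fixed so that its
    largest-magnitude loading is positive.
    """
    M = embedded.matrix if isinstance(embedded, EmbeddedSeries) else np.asarray(embedded)
    if n_components > min(M.shape):
        raise ValueError(
            f"n_components ({n_components}) exceeds the smaller matrix dimension {min(M.shape)}"
        )
    Mc = M - M.mean(axis=0)
    U, s, Vt = np.linalg.svd(Mc, full_matrices=False)
    U, s, Vt = U[:, :n_components], s[:n_components], Vt[:n_components]
    signs = np.sign(Vt[np.arange(n_components), np.abs(Vt).argmax(axis=1)])
    signs[signs == 0] = 1.0
    return U * (s * signs)


def cva(X: np.ndarray, Y: np.ndarray, ridge: float = 1e-8) -> CvaResult:
    """Canonical variates analysis with Bartlett's chi-square approximation.

    Canonical correlations r_i come from the whitened cross-covariance;
    Wilks' lambda = prod(1 - r_i**2) is mapped to
    chi2 = -(T - 1 - (p + q + 1)/2) * ln(lambda) on p*q degrees of freedom.
    Covariance blocks receive a ridge of ``ridge * trace/dim`` so strongly
    collinear embeddings remain well posed (logged at debug level).
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if Y.ndim == 1:
        Y = Y[:, None]
    T, p = X.shape
    Ty, q = Y.shape
    if T != Ty:
        raise ValueError("X and Y must have the same number of rows")
    if T <= p + q + 1:
        raise ValueError(f"need T > p + q + 1 rows (T={T}, p={p}, q={q})")
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    Sxx = Xc.T @ Xc / (T - 1)
    Syy = Yc.T @ Yc / (T - 1)
    Sxy = Xc.T @ Yc / (T - 1)
    ex = ridge * np.trace(Sxx) / p
    ey = ridge * np.trace(Syy) / q
    if ex > 0 or ey > 0:
        logger.debug("cva ridge epsilons: %.3e (X), %.3e (Y)", ex, ey)
    Sxx = Sxx + ex * np.eye(p)
    Syy = Syy + ey * np.eye(q)
    Lx = linalg.cholesky(Sxx, lower=True)
    Ly = linalg.cholesky(Syy, lower=True)
    M = linalg.solve_triangular(Lx, Sxy, lower=True)
    M = linalg.solve_triangular(Ly, M.T, lower=True).T
    U, r, Vt = np.linalg.svd(M)
    r = np.clip(r[: min(p, q)], 0.0, 1.0 - 1e-12)
    wilks = float(np.prod(1.0 - r**2))
    chi2 = float(-(T - 1 - (p + q + 1) / 2.0) * np.log(wilks))
    dof = p * q
    a = linalg.solve_triangular(Lx.T, U[:, 0], lower=False)
    b = linalg.solve_triangular(Ly.T, Vt[0], lower=False)
    return CvaResult(
        wilks_lambda=wilks,
        chi2=chi2,
        dof=dof,
        canonical_correlations=r,
        predicted=Xc @ a,
        actual=Yc @ b,
    )


def time_flip_null(Y: np.ndarray) -> np.ndarray:
    """Reverse a series in time: the surrogate null for cross-dependency.

    Reversal preserves each channel's marginal distribution and the
    magnitude of its autocorrelation structure while destroying any
    temporal alignment with another set of series.
    """
    return np.asarray(Y)[::-1].copy()


def exceedance_pvalue(count: int, n_tests: int) -> float:
    """Probability of strictly more than ``count`` exceedances by chance.

    Each of n_tests statistics exceeds the maximum of n_tests exchangeable
    null statistics with probability 1/n_tests, so the chance count is
    Binomial(n_tests, 1/n_tests); the returned value is its strict upper
    tail P(K > count).
    """
    if not 0 <= count <= n_tests:
        raise ValueError(f"count must lie in [0, n_tests], got {count}")
    return float(stats.binom.sf(count, n_tests, 1.0 / n_tests))


def predictability_map(
    traj: Trajectory,
    partition: BlanketPartition,
    analysis_window: float = 512.0,
    lag_seconds: float = 16.0,
    n_components: int = 32,
) -> PredictabilityMap:
    """Score how well internal dynamics predict each external subsystem's motion.

    The predictors are the first ``n_components`` eigenvariates of the
    lag-embedded internal electrochemical series over the trailing
    ``analysis_window`` seconds; each external subsystem's 2-D position over
    the matching valid region is the response.  True and time-flipped
    analyses give the exceedance count and p-value.
    """
    if analysis_window > traj.duration + 1e-9:
        raise ValueError(
            f"analysis_window ({analysis_window} s) exceeds trajectory duration ({traj.duration} s)"
        )
    external = partition.external
    if external.size < 1:
        raise ValueError("partition has no external subsystems to predict")
    internal = partition.internal
    dt = traj.config.save_interval
    sel = np.flatnonzero(traj.times >= traj.times[-1] - analysis_window - 1e-9)
    chem = traj.chem[sel][:, internal, :]
    T = chem.shape[0]
    series = chem.reshape(T, -1)
    emb = temporal_embed(series, lag_seconds, dt)
    X = eigenvariates(emb, n_components)
    L = round(lag_seconds / dt)
    valid = slice(L, T - L)

    chi2_true = np.empty(external.size)
    chi2_null = np.empty(external.size)
    dof = 0
    results = {}
    for j, e in enumerate(external):
        Y = traj.positions[sel][:, e, :][valid]
        res = cva(X, Y)
        res_null = cva(X, time_flip_null(Y))
        chi2_true[j] = res.chi2
        chi2_null[j] = res_null.chi2
        dof = res.dof
        results[int(e)] = res
    threshold = float(chi2_null.max())
    n_exceed = int((chi2_true > threshold).sum())
    p_value = exceedance_pvalue(n_exceed, external.size)
    best = int(external[int(np.argmax(chi2_true))])
    return PredictabilityMap(
        external_indices=external.copy(),
        chi2_true=chi2_true,
        chi2_null=chi2_null,
        threshold=threshold,
        n_exceed=n_exceed,
        p_value=p_value,
        dof=dof,
        best_external=best,
        best_cva=results[best],
        decisions={
            "embedding": f"±{lag_seconds} s at {dt} s sampling ({2 * L + 1} lags)",
            "n_components": n_components,
            "chi2_transform": "Bartlett: -(T-1-(p+q+1)/2) ln(Wilks lambda), dof = p*q",
            "response": "external position series, no detrending",
            "null": "time reversal of the external series",
        },
    )
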