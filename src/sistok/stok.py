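"""Self-tuning optimized Kalman (STOK) filtering for tv-MVAR estimation.

The filter tracks a time-varying multivariate autoregressive model

    Y_t = sum_{k=1..p} A_{k,t} Y_{t-k} + eps_t

by treating the stacked coefficients as a latent random-walk state and
updating them recursively with a damped least-squares measurement estimate:

    x+_t = (x-_t + c_t * pinv(H~_t) z_t) / (1 + c_t)

where ``H~+`` is a Moore-Penrose pseudoinverse in which small singular
values are truncated so that a prespecified fraction of the design variance
is retained, and ``c_t`` is an adaptation constant that controls the speed
of the filter (large c -> trust the instantaneous measurement, small c ->
trust the accumulated state).

The self-tuning rule for ``c`` implemented here scales a base constant by
the ratio of the current one-step innovation energy to its exponential
moving average, clipped to a configurable range: the filter speeds up when
residuals grow (the model is falling behind a dynamic change) and slows
down in stationary stretches.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np

from .datamodel import TimeSeriesData, TVMVARModel

__all__ = ["DampedSVD", "damped_pinv", "stok_fit", "innovations"]


@dataclass
class DampedSVD:
    """Damped singular value decomposition of a design matrix.

    ``U @ diag(s_damped) @ Vt`` reconstructs the damped design ``H~``;
    ``pinv`` is its Moore-Penrose pseudoinverse. ``rank`` counts the
    singular values kept by the variance-retention rule.
    """

    U: np.ndarray
    s: np.ndarray          # original singular values
    s_damped: np.ndarray   # truncated singular values (zeros beyond rank)
    Vt: np.ndarray
    rank: int

    @property
    def pinv(self) -> np.ndarray:
        inv = np.zeros_like(self.s_damped)
        nz = self.s_damped > 0
        inv[nz] = 1.0 / self.s_damped[nz]
        return (self.Vt.T * inv) @ self.U.T

    def gram(self) -> np.ndarray:
        """The damped normal matrix ``H~' H~ = V diag(s~^2) V'``."""
        return (self.Vt.T * self.s_damped**2) @ self.Vt

    def ht_z(self, z: np.ndarray) -> np.ndarray:
        """``H~' z`` for a vector or matrix of right-hand sides."""
        uz = self.U.T @ z
        scale = self.s_damped if uz.ndim == 1 else self.s_damped[:, None]
        return self.Vt.T @ (scale * uz)


def damped_pinv(H: np.ndarray, f: float) -> DampedSVD:
    """SVD of ``H`` with small singular values truncated.

    The smallest leading set of singular values whose cumulative squared sum
    reaches a fraction ``f`` of the total squared sum is retained; the rest
    are set to zero. With ``f = 1`` the result is the exact Moore-Penrose
    pseudoinverse.
    """
    if not 0 < f <= 1:
        raise ValueError(f"variance fraction f must be in (0, 1]; got {f}")
    H = np.asarray(H, dtype=float)
    if not np.all(np.isfinite(H)):
        raise ValueError("design matrix contains non-finite values")
    U, s, Vt = np.linalg.svd(H, full_matrices=False)
    total = float(np.sum(s**2))
    if total == 0:
        warnings.warn("all-zero design matrix: pseudoinverse is the zero operator")
        return DampedSVD(U=U, s=s, s_damped=s.copy(), Vt=Vt, rank=0)
    cum = np.cumsum(s**2) / total
    rank = int(np.searchsorted(cum, f - 1e-12) + 1)
    # singular values tied with the last retained one are kept as well, so
    # isotropic designs (e.g. the identity) are never truncated
    while rank < s.size and s[rank] >= s[rank - 1] * (1 - 1e-12):
        rank += 1
    s_damped = s.copy()
    s_damped[rank:] = 0.0
    return DampedSVD(U=U, s=s, s_damped=s_damped, Vt=Vt, rank=rank)


def _check_channels(data: TimeSeriesData) -> None:
    var = data.values.var(axis=(0, 2))
    flat = np.flatnonzero(var == 0)
    if flat.size:
        labels = data.channel_labels
        names = [labels[i] if labels else str(i) for i in flat]
        raise ValueError(f"constant (zero-variance) channels cannot be modeled: {names}")


def _lag_stack(values: np.ndarray, p: int) -> np.ndarray:
    """Precompute lag-major designs for all t: shape (N, trials, d*p).

    Entries for t < p are unused by the filter loop.
    """
    trials, d, N = values.shape
    out = np.zeros((N, trials, d * p))
    for k in range(1, p + 1):
        out[p:, :, (k - 1) * d : k * d] = values[:, :, p - k : N - k].transpose(2, 0, 1)
    return out


def _recursive_fit(
    data: TimeSeriesData,
    p: int,
    f: float,
    measurement: Callable[[DampedSVD, np.ndarray], np.ndarray],
    c_mode: str,
    c_fixed: float | None,
    c_base: float,
    c_min: float,
    c_max: float,
    ema_halflife: float,
    metadata: dict,
) -> TVMVARModel:
    """Shared recursion: per-time damped design, measurement estimate, update.

    ``measurement(dsvd, z)`` maps the damped design factors and present
    samples (trials x d) to a stacked coefficient estimate (d*p x d); the
    plain filter uses the damped pseudoinverse, the structurally informed
    variant a per-receiver Tikhonov solve.
    """
    if p < 1:
        raise ValueError("model order p must be >= 1")
    trials, d, N = data.values.shape
    if p >= N:
        raise ValueError(f"model order p={p} must be smaller than the series length N={N}")
    _check_channels(data)
    if c_mode not in ("adaptive", "fixed"):
        raise ValueError(f"unknown c_mode {c_mode!r}")
    if c_mode == "fixed" and c_fixed is None:
        raise ValueError("c_mode='fixed' requires a c value")

    designs = _lag_stack(data.values, p)
    A = np.full((d, d, p, N), np.nan)
    c_trace = np.full(N, np.nan)
    eps = np.full((trials, d, N), np.nan)

    x = np.zeros((d * p, d))  # stacked state, column i = receiver i
    decay = 0.5 ** (1.0 / ema_halflife)
    e_bar: float | None = None

    for t in range(p, N):
        H = designs[t]
        z = data.values[:, :, t]
        dsvd = damped_pinv(H, f)
        b = measurement(dsvd, z)

        prior_resid = z - H @ x
        e_t = float(np.mean(prior_resid**2))
        if c_mode == "fixed":
            c = float(c_fixed)  # type: ignore[arg-type]
        else:
            e_bar = e_t if e_bar is None else decay * e_bar + (1 - decay) * e_t
            c = float(np.clip(c_base * e_t / max(e_bar, 1e-300), c_min, c_max))

        if np.isinf(c):
            x = b
        else:
            x = (x + c * b) / (1.0 + c)

        c_trace[t] = c
        eps[:, :, t] = z - H @ x
        # state rows are (lag k, sender j) -> A[i, j, k, t]
        A[:, :, :, t] = x.reshape(p, d, d).transpose(2, 1, 0)

    model = TVMVARModel(
        A=A,
        order=p,
        variance_fraction=f,
        c_trace=c_trace,
        innovations=eps,
        valid_from=p,
        channel_labels=data.channel_labels,
        metadata=dict(metadata),
    )
    model.innovation_covariance = _innovation_cov(eps, p)
    return model


def _innovation_cov(eps: np.ndarray, valid_from: int, window: tuple[int, int] | None = None) -> np.ndarray:
    lo, hi = window if window is not None else (valid_from, eps.shape[2])
    lo = max(lo, valid_from)
    if hi <= lo:
        raise ValueError("empty window for innovation covariance")
    # (trials, d, T) -> (trials*T, d)
    seg = eps[:, :, lo:hi].transpose(0, 2, 1).reshape(-1, eps.shape[1])
    return np.cov(seg, rowvar=False)


def stok_fit(
    data: TimeSeriesData,
    p: int,
    f: float = 0.99,
    c_mode: str = "adaptive",
    c_fixed: float | None = None,
    c_base: float = 0.05,
    c_min: float = 1e-3,
    c_max: float = 1.0,
    ema_halflife: float = 10.0,
) -> TVMVARModel:
    """Fit a tv-MVAR model with the STOK filter.

    Parameters
    ----------
    data
        Multi-trial time series; all trials enter each per-time regression
        as rows of the design matrix.
    p
        Model order (number of lags).
    f
        Fraction of design variance retained by the damped pseudoinverse.
        0.99 suits low-dimensional recordings; ~0.9 is appropriate for
        high-dimensional source-space data with strong collinearity.
    c_mode, c_fixed
        ``"adaptive"`` uses the self-tuning rule; ``"fixed"`` uses the
        constant ``c_fixed`` (``0`` freezes the state, ``inf`` yields the
        pure per-time least-squares estimate).
    c_base, c_min, c_max, ema_halflife
        Parameters of the self-tuning rule
        ``c_t = clip(c_base * e_t / ema(e_t), c_min, c_max)`` with ``e_t``
        the mean squared one-step innovation.
    """
    return _recursive_fit(
        data, p, f,
        measurement=lambda dsvd, z: dsvd.pinv @ z,
        c_mode=c_mode, c_fixed=c_fixed,
        c_base=c_base, c_min=c_min, c_max=c_max, ema_halflife=ema_halflife,
        metadata={"filter": "stok", "f": f, "c_mode": c_mode},
    )


def innovations(
    model: TVMVARModel,
    data: TimeSeriesData,
    window: tuple[int, int] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Recompute one-step residuals of ``model`` on ``data``.

    Returns the residual array (trials x d x N, NaN before ``valid_from``)
    and the innovation covariance estimated over ``window`` (0-based,
    half-open; defaults to the full valid range).
    """
    trials, d, N = data.values.shape
    if model.n_channels != d or model.n_samples != N:
        raise ValueError(
            f"model shape (d={model.n_channels}, N={model.n_samples}) does not match "
            f"data shape (d={d}, N={N})"
        )
    p = model.order
    designs = _lag_stack(data.values, p)
    eps = np.full((trials, d, N), np.nan)
    for t in range(model.valid_from, N):
        # x columns = receivers; rebuild stacked state from A
        x = model.A[:, :, :, t].transpose(2, 1, 0).reshape(d * p, d)
        eps[:, :, t] = data.values[:, :, t] - designs[t] @ x
    cov = _innovation_cov(eps, model.valid_from, window)
    return eps, cov
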