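"""Core domain types for multi-trial time-series modeling.

The central object is :class:`TimeSeriesData`, a multi-trial, multichannel,
uniformly sampled signal array (e.g., epoched EEG/LFP source activity).
Time-varying MVAR estimators regress present samples ``z`` on a lag-stacked
design matrix ``H`` built from the past of the series; :func:`build_lag_design`
constructs that regression at a single time point.

Conventions used throughout the package
---------------------------------------
* Coefficient orientation is receiver <- sender: ``A[i, j, ...]`` and
  ``W[i, j]`` quantify the influence of node ``j`` on node ``i``.
* Lag stacking is lag-major: the columns of ``H`` are ordered
  (ch1 lag1, ch2 lag1, ..., chd lag1, ch1 lag2, ...), i.e. column
  ``k*d + j`` holds channel ``j`` at lag ``k+1``.
* Storage uses 0-based sample indices; the first time index with a defined
  coefficient estimate is ``valid_from = p`` (the sample predicted from the
  ``p`` preceding samples). In 1-based notation this is sample ``p + 1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TimeSeriesData",
    "LagDesign",
    "TVMVARModel",
    "StructuralPrior",
    "RegularizerSet",
    "build_lag_design",
    "zscore_global",
    "normalize_sc",
]


@dataclass
class TimeSeriesData:
    """Multi-trial, multichannel, uniformly sampled signals.

    Parameters
    ----------
    values
        Real array of shape ``(trials, channels, samples)``.
    sampling_rate
        Sampling frequency in Hz.
    channel_labels
        Optional channel names; length must equal the number of channels.
    time_axis
        Optional time stamps in seconds, one per sample.
    """

    values: np.ndarray
    sampling_rate: float
    channel_labels: list[str] | None = None
    time_axis: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError(
                f"values must be (trials, channels, samples); got shape {self.values.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values contain non-finite entries")
        trials, channels, samples = self.values.shape
        if trials < 1:
            raise ValueError("at least one trial is required")
        if channels < 1:
            raise ValueError("at least one channel is required")
        if samples < 2:
            raise ValueError("at least two samples are required")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.channel_labels is not None:
            self.channel_labels = [str(c) for c in self.channel_labels]
            if len(self.channel_labels) != channels:
                raise ValueError(
                    f"channel_labels has {len(self.channel_labels)} entries "
                    f"for {channels} channels"
                )
        if self.time_axis is not None:
            self.time_axis = np.asarray(self.time_axis, dtype=float)
            if self.time_axis.shape != (samples,):
                raise ValueError("time_axis length must equal the number of samples")

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]

    @property
    def n_samples(self) -> int:
        return self.values.shape[2]

    def copy(self) -> "TimeSeriesData":
        return TimeSeriesData(
            self.values.copy(),
            self.sampling_rate,
            None if self.channel_labels is None else list(self.channel_labels),
            None if self.time_axis is None else self.time_axis.copy(),
        )


@dataclass
class LagDesign:
    """Lagged regression design at one sample index.

    ``H`` stacks, for each trial (row), the ``p`` preceding samples of all
    channels in lag-major order; ``z`` holds the present samples. Regressing
    ``z`` on ``H`` yields the MVAR coefficients at ``t_index``.
    """

    H: np.ndarray  # (trials, d*p)
    z: np.ndarray  # (trials, d)
    t_index: int

    def __post_init__(self) -> None:
        if self.H.shape[0] != self.z.shape[0]:
            raise ValueError("H and z must have the same number of rows (trials)")


@dataclass
class TVMVARModel:
    """A fitted time-varying MVAR model.

    Attributes
    ----------
    A
        Coefficient tensor of shape ``(d, d, p, N)``; entry ``(i, j, k, t)``
        is the influence of sender ``j`` on receiver ``i`` at lag ``k + 1``
        and time ``t``. Entries before ``valid_from`` are NaN (no estimate),
        finite from ``valid_from`` onward.
    order
        Model order ``p``.
    variance_fraction
        Fraction of design-matrix variance retained by the damped
        pseudoinverse, in ``(0, 1]``.
    c_trace
        Adaptation constant used at each update (NaN before ``valid_from``).
    innovations
        One-step residuals, shape ``(trials, d, N)``; NaN before
        ``valid_from``.
    valid_from
        First 0-based sample index with a defined estimate (``= p``).
    metadata
        Provenance: filter flavor, prior description, tuning parameters.

    The state-transition model is a random walk (transition matrix fixed at
    the identity), so it is never materialized.
    """

    A: np.ndarray
    order: int
    variance_fraction: float
    c_trace: np.ndarray
    innovations: np.ndarray
    valid_from: int
    channel_labels: list[str] | None = None
    innovation_covariance: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    @property
    def n_channels(self) -> int:
        return self.A.shape[0]

    @property
    def n_samples(self) -> int:
        return self.A.shape[3]


@dataclass
class StructuralPrior:
    """Nonnegative structural-connectivity weights, receiver <- sender.

    ``W[i, j]`` is the anatomical connection strength from node ``j`` to
    node ``i``. A normalized prior has maximum 1; the diagonal
    (self-connections) is uniform at ``diagonal_value``.
    """

    W: np.ndarray
    normalized: bool = False
    diagonal_value: float | None = None
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        if self.W.ndim != 2 or self.W.shape[0] != self.W.shape[1]:
            raise ValueError(f"W must be square; got shape {self.W.shape}")
        if np.any(self.W < 0):
            raise ValueError("structural weights must be nonnegative")
        if not np.all(np.isfinite(self.W)):
            raise ValueError("structural weights must be finite")
        if self.normalized and not np.isclose(self.W.max(), 1.0):
            raise ValueError("a normalized prior must have maximum 1")
        if self.labels is not None:
            self.labels = [str(c) for c in self.labels]
            if len(self.labels) != self.W.shape[0]:
                raise ValueError("labels length must match matrix dimension")

    @property
    def n_nodes(self) -> int:
        return self.W.shape[0]


@dataclass
class RegularizerSet:
    """Per-receiver diagonal Tikhonov precisions derived from a prior.

    ``qinv[i]`` holds the ``d*p`` diagonal entries ``1 / sc_scaled[i, j]``
    for receiver ``i``, each sender's value replicated over the ``p`` lags in
    the package's lag-major stacking order. ``x0`` is the prior expectation
    of the coefficients and is identically zero by default (no functional
    connection expected a priori).
    """

    qinv: np.ndarray  # (d, d*p)
    scaling_range: tuple[float, float]
    x0: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.qinv = np.asarray(self.qinv, dtype=float)
        if np.any(self.qinv <= 0) or not np.all(np.isfinite(self.qinv)):
            raise ValueError("precision entries must be strictly positive and finite")


def build_lag_design(data: TimeSeriesData, t: int, p: int) -> LagDesign:
    """Build the lagged design ``(H, z)`` at 0-based sample index ``t``.

    Row ``r`` of ``H`` concatenates, for lags ``1..p``, the ``d`` channel
    values of trial ``r`` at ``t-1, ..., t-p`` (lag-major order); row ``r``
    of ``z`` holds the channel values at ``t``.

    Raises
    ------
    ValueError
        If ``t`` precedes the first sample with ``p`` available lags
        (``valid_from = p``), or ``p`` is not a positive order smaller than
        the series length.
    """
    if p < 1:
        raise ValueError("model order p must be >= 1")
    N = data.n_samples
    if p >= N:
        raise ValueError(f"model order p={p} must be smaller than the series length N={N}")
    if t < p or t >= N:
        raise ValueError(
            f"t={t} out of range: estimates are defined for t in [valid_from={p}, {N - 1}]"
        )
    # (trials, d, p) slices at t-1..t-p, transposed to lag-major (trials, p, d)
    lags = data.values[:, :, t - 1 - np.arange(p)]
    H = np.ascontiguousarray(lags.transpose(0, 2, 1)).reshape(data.n_trials, -1)
    z = data.values[:, :, t].copy()
    return LagDesign(H=H, z=z, t_index=t)


def zscore_global(data: TimeSeriesData) -> TimeSeriesData:
    """Standardize with a single global mean and standard deviation.

    One mean and one standard deviation are computed over all trials,
    channels, and samples jointly, so relative amplitude differences between
    channels are preserved. The output has global mean 0 and global sd 1.
    """
    mu = data.values.mean()
    sd = data.values.std()
    if sd == 0:
        raise ValueError("cannot z-score data with zero global variance")
    out = data.copy()
    out.values = (data.values - mu) / sd
    return out


def normalize_sc(
    raw: np.ndarray,
    diagonal_value: float,
    labels: list[str] | None = None,
) -> StructuralPrior:
    """Normalize a raw structural-connectivity matrix to maximum 1.

    The diagonal (self-connections) is overwritten with ``diagonal_value``
    *before* dividing by the global maximum, mirroring the convention of
    assigning self-connections the strongest rank in ranked tracer
    connectomes.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.ndim != 2 or raw.shape[0] != raw.shape[1]:
        raise ValueError(f"SC matrix must be square; got shape {raw.shape}")
    if np.any(raw < 0):
        raise ValueError("SC matrix must be nonnegative")
    W = raw.copy()
    np.fill_diagonal(W, diagonal_value)
    m = W.max()
    if m <= 0:
        raise ValueError("SC matrix has no positive entries after setting the diagonal")
    W /= m
    return StructuralPrior(
        W=W,
        normalized=True,
        diagonal_value=float(diagonal_value) / m,
        labels=labels,
    )
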