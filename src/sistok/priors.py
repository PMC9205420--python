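"""Structural-connectivity priors as Tikhonov regularizers (si-STOK).

Anatomical connection strengths are converted into the prior variance of a
zero-mean Gaussian belief on each functional-connectivity coefficient:
strong structural connectivity -> large prior variance -> the coefficient
may deviate from zero when the data support it; weak or absent structural
connectivity -> small prior variance -> the coefficient is shrunk toward
zero. For each receiver node ``i`` the per-coefficient precisions form a
diagonal matrix ``Qinv_i`` and the measurement estimate of the recursive
filter becomes the generalized-Tikhonov solution

    b*_i = (H~' H~ + Qinv_i)^-1 H~' z_i

computed from the same damped design factorization the plain filter uses.
Because the prior enters as a variance rather than a mask, a true
functional connection missing from the structural matrix is attenuated but
not forced to zero (protection against structural false negatives), and a
structural connection with no functional support is not inflated
(robustness against structural false positives).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .datamodel import RegularizerSet, StructuralPrior, TimeSeriesData, TVMVARModel
from .stok import DampedSVD, _recursive_fit, stok_fit

__all__ = [
    "scale_sc",
    "threshold_sc",
    "build_precision",
    "build_regularizers",
    "tikhonov_solve",
    "si_stok_fit",
    "sweep_scaling_max",
]


def scale_sc(
    prior: StructuralPrior,
    lo: float = 1e-4,
    hi: float = 0.1,
    log_spaced: bool = False,
) -> np.ndarray:
    """Map normalized structural weights to prior variances in ``[lo, hi]``.

    The default linear map sends absent connections (weight 0) to ``lo`` —
    a small but strictly positive variance, so the precision stays finite —
    and the strongest connection (weight 1) to ``hi``. A log-spaced map is
    available for priors spanning several orders of magnitude.
    """
    if lo <= 0:
        raise ValueError("lo must be strictly positive (zero variance -> infinite precision)")
    if hi <= lo:
        raise ValueError(f"scaling range requires lo < hi; got ({lo}, {hi})")
    W = prior.W
    if W.min() < 0 or W.max() > 1 + 1e-12:
        raise ValueError("prior must be normalized to [0, 1] before scaling")
    if log_spaced:
        return np.exp(np.log(lo) + W * (np.log(hi) - np.log(lo)))
    return lo + W * (hi - lo)


def threshold_sc(prior: StructuralPrior, keep: float = 0.25) -> StructuralPrior:
    """Proportional thresholding of a structural prior.

    Among off-diagonal entries, the top ``ceil(keep * count)`` by weight are
    retained and the rest set to zero; values tied with the cutoff are all
    retained. The diagonal (self-connections) is set to 1.
    """
    if not 0 < keep <= 1:
        raise ValueError(f"keep must be in (0, 1]; got {keep}")
    W = prior.W.copy()
    d = W.shape[0]
    off = ~np.eye(d, dtype=bool)
    vals = W[off]
    m = int(np.ceil(keep * vals.size))
    cutoff = np.sort(vals)[::-1][m - 1]
    W[off & (prior.W < cutoff)] = 0.0
    np.fill_diagonal(W, 1.0)
    return StructuralPrior(W=W, normalized=True, diagonal_value=1.0, labels=prior.labels)


def build_precision(scaled: np.ndarray, receiver: int, p: int) -> np.ndarray:
    """Diagonal Tikhonov precision for one receiver node.

    Returns the ``d*p`` diagonal entries ``1 / scaled[receiver, j]``, each
    sender ``j``'s value replicated across its ``p`` lag positions in the
    lag-major stacking order of the design matrix.
    """
    scaled = np.asarray(scaled, dtype=float)
    if np.any(scaled <= 0) or not np.all(np.isfinite(scaled)):
        raise ValueError("prior variances must be strictly positive and finite")
    return np.tile(1.0 / scaled[receiver], p)


def build_regularizers(
    prior: StructuralPrior,
    p: int,
    lo: float = 1e-4,
    hi: float = 0.1,
    log_spaced: bool = False,
) -> RegularizerSet:
    """Precision diagonals for all receivers, from a normalized prior."""
    scaled = scale_sc(prior, lo=lo, hi=hi, log_spaced=log_spaced)
    d = prior.n_nodes
    qinv = np.stack([build_precision(scaled, i, p) for i in range(d)])
    return RegularizerSet(qinv=qinv, scaling_range=(lo, hi))


def tikhonov_solve(
    dsvd: DampedSVD,
    z_i: np.ndarray,
    qinv_diag: np.ndarray,
    x0: np.ndarray | None = None,
) -> np.ndarray:
    """Generalized-Tikhonov coefficients for one receiver.

    Solves ``(H~' H~ + Qinv) b = H~' (z_i - H~ x0)`` from the damped design
    factors and returns ``x0 + b`` (``x0`` defaults to zero, the package's
    prior expectation of no functional connectivity). The system matrix is
    symmetric positive definite because every precision entry is positive.
    """
    qinv_diag = np.asarray(qinv_diag, dtype=float)
    M = dsvd.gram()
    M[np.diag_indices_from(M)] += qinv_diag
    if x0 is not None:
        # residualize the measurement against the prior mean
        resid = z_i - dsvd.U @ (dsvd.s_damped * (dsvd.Vt @ x0))
    else:
        resid = z_i
    rhs = dsvd.ht_z(resid)
    try:
        cf = linalg.cho_factor(M, lower=True, check_finite=False)
        b = linalg.cho_solve(cf, rhs, check_finite=False)
    except linalg.LinAlgError as err:  # pragma: no cover - defensive
        raise np.linalg.LinAlgError(
            f"Tikhonov solve failed (cond(H~'H~ + Qinv) ~ {np.linalg.cond(M):.3e}): {err}"
        ) from err
    if not np.all(np.isfinite(b)):
        raise np.linalg.LinAlgError(
            f"non-finite Tikhonov solution; cond(H~'H~ + Qinv) ~ {np.linalg.cond(M):.3e}"
        )
    return b if x0 is None else x0 + b


def _tikhonov_measurement(reg: RegularizerSet):
    """Measurement operator solving the per-receiver Tikhonov systems."""

    def measure(dsvd: DampedSVD, z: np.ndarray) -> np.ndarray:
        G = dsvd.gram()
        HtZ = dsvd.ht_z(z)
        d = z.shape[1]
        b = np.empty_like(HtZ)
        for i in range(d):
            M = G.copy()
            M[np.diag_indices_from(M)] += reg.qinv[i]
            cf = linalg.cho_factor(M, lower=True, check_finite=False)
            b[:, i] = linalg.cho_solve(cf, HtZ[:, i], check_finite=False)
        if not np.all(np.isfinite(b)):
            raise np.linalg.LinAlgError("non-finite Tikhonov solution in recursive update")
        return b

    return measure


def si_stok_fit(
    data: TimeSeriesData,
    p: int,
    f: float = 0.99,
    prior: StructuralPrior | None = None,
    scaling: tuple[float, float] = (1e-4, 0.1),
    log_spaced: bool = False,
    c_mode: str = "adaptive",
    c_fixed: float | None = None,
    c_base: float = 0.05,
    c_min: float = 1e-3,
    c_max: float = 1.0,
    ema_halflife: float = 10.0,
) -> TVMVARModel:
    """Fit a tv-MVAR model with the structurally informed STOK filter.

    Identical to :func:`sistok.stok.stok_fit` except that the per-time
    measurement estimate is the generalized-Tikhonov solution with
    per-receiver precisions derived from ``prior`` (scaled to the prior
    variance range ``scaling``). The fitted model records the prior and
    scaling used in its metadata.
    """
    if prior is None:
        raise ValueError("si_stok_fit requires a structural prior; use stok_fit otherwise")
    if prior.n_nodes != data.n_channels:
        raise ValueError(
            f"prior has {prior.n_nodes} nodes but data has {data.n_channels} channels"
        )
    if prior.labels is not None and data.channel_labels is not None:
        if prior.labels != data.channel_labels:
            raise ValueError(
                "prior labels do not match data channel labels: "
                f"{prior.labels} vs {data.channel_labels}"
            )
    lo, hi = scaling
    reg = build_regularizers(prior, p, lo=lo, hi=hi, log_spaced=log_spaced)
    return _recursive_fit(
        data, p, f,
        measurement=_tikhonov_measurement(reg),
        c_mode=c_mode, c_fixed=c_fixed,
        c_base=c_base, c_min=c_min, c_max=c_max, ema_halflife=ema_halflife,
        metadata={
            "filter": "si_stok",
            "f": f,
            "c_mode": c_mode,
            "sc_scaling": (float(lo), float(hi)),
            "sc_log_spaced": bool(log_spaced),
            "sc_diagonal_value": prior.diagonal_value,
        },
    )


def sweep_scaling_max(
    data: TimeSeriesData,
    prior: StructuralPrior,
    candidates: list[float],
    p: int,
    f: float = 0.99,
    lo: float = 1e-4,
    window: tuple[int, int] | None = None,
    **fit_kwargs,
) -> pd.DataFrame:
    """Diagnostics for choosing the upper end of the SC variance scaling.

    For each candidate maximum ``hi`` the function fits the structurally
    informed filter and reports, per row:

    * ``spearman_sc_fc`` — rank correlation between off-diagonal structural
      weights and time-averaged directed-influence magnitudes (how strongly
      the prior imprints on the estimate); Spearman because ranked tracer
      connectomes are ordinal.
    * ``pearson_stok_sistok`` — correlation between the uninformed and
      informed estimates (how much the prior distorts the data-driven
      solution).

    Reasonable scaling maxima increase the first without collapsing the
    second; the choice is left to the user, no selection is made here.
    """
    from .metrics import mdi  # local import to avoid a cycle

    if len(candidates) < 2:
        raise ValueError("provide at least two candidate scaling maxima")
    base = stok_fit(data, p, f, **fit_kwargs)
    lo_t, hi_t = window if window is not None else (base.valid_from, base.n_samples)
    d = data.n_channels
    off = ~np.eye(d, dtype=bool)
    base_mdi = np.nanmean(mdi(base).values[:, :, lo_t:hi_t], axis=2)

    rows = []
    for hi in candidates:
        fit = si_stok_fit(data, p, f, prior=prior, scaling=(lo, hi), **fit_kwargs)
        m = np.nanmean(mdi(fit).values[:, :, lo_t:hi_t], axis=2)
        rho = stats.spearmanr(prior.W[off], m[off]).statistic
        r = stats.pearsonr(base_mdi[off], m[off]).statistic
        rows.append({"hi": hi, "spearman_sc_fc": rho, "pearson_stok_sistok": r})
    return pd.DataFrame(rows)
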