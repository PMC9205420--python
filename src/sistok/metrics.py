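"""Directed-influence metrics, network summaries, and group statistics.

From a fitted tv-MVAR model, the magnitude of directed influence (MDI)
summarizes the coefficients of each sender->receiver connection across
lags into a single nonnegative time course:

    MDI_{i<-j,t} = sqrt( sum_{k=1..p} a_{i<-j,k,t}^2 )

Downstream summaries — per-node outflow, driver scores, proportionally
thresholded adjacencies, consistency under perturbation — and a sign-flip
permutation test for group-level condition differences operate on these
tensors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import TVMVARModel

__all__ = [
    "MDITensor",
    "PermutationResult",
    "mdi",
    "summed_outflow",
    "rank_outflows",
    "proportional_adjacency",
    "consistency",
    "driver_score",
    "sign_permutation_test",
]


@dataclass
class MDITensor:
    """Directed-influence values, shape ``(d, d, N)``.

    Entry ``(i, j, t)`` is the influence of sender ``j`` on receiver ``i``
    at time ``t``; NaN before ``valid_from``, nonnegative elsewhere, and
    zero exactly when all lag coefficients of the connection are zero.
    """

    values: np.ndarray
    valid_from: int
    mode: str = "rss"
    labels: list[str] | None = None

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]


@dataclass
class PermutationResult:
    """Outcome of a group-level sign-flip permutation test."""

    observed: np.ndarray       # group-mean differences per edge/time
    p_values: np.ndarray       # two-sided, in (0, 1]
    n_permutations: int
    alpha: float
    method: str = "montecarlo"

    @property
    def significant(self) -> np.ndarray:
        return self.p_values < self.alpha


def mdi(model: TVMVARModel, mode: str = "rss") -> MDITensor:
    """Magnitude of directed influence per connection and time point.

    ``mode="rss"`` (default) takes the root-sum-square of the ``p`` lag
    coefficients — a Euclidean norm, in the lineage of direct-causality
    measures; ``mode="ss"`` reports the plain sum of squares.
    """
    if mode not in ("rss", "ss"):
        raise ValueError(f"mode must be 'rss' or 'ss'; got {mode!r}")
    ss = np.sum(model.A**2, axis=2)
    values = np.sqrt(ss) if mode == "rss" else ss
    return MDITensor(
        values=values,
        valid_from=model.valid_from,
        mode=mode,
        labels=model.channel_labels,
    )


def summed_outflow(
    tensor: MDITensor,
    window: tuple[int, int],
    include_self: bool = False,
) -> np.ndarray:
    """Per-node outgoing influence, averaged over a time window.

    Node ``j``'s outflow is the sum over receivers ``i != j`` of
    ``MDI[i, j, t]`` (self-connections excluded unless requested), averaged
    over the half-open window ``[lo, hi)``.
    """
    lo, hi = window
    lo = max(lo, tensor.valid_from)
    if hi <= lo or hi > tensor.values.shape[2]:
        raise ValueError(f"empty or out-of-range window ({window})")
    vals = tensor.values[:, :, lo:hi]
    if not include_self:
        vals = vals.copy()
        d = tensor.n_nodes
        vals[np.arange(d), np.arange(d), :] = 0.0
    return vals.sum(axis=0).mean(axis=1)


def rank_outflows(delta: np.ndarray, labels: list[str] | None = None) -> pd.DataFrame:
    """Stable descending sort of per-node outflow values.

    Ties are broken by node label order (lexicographic; positional order
    when labels are absent). Returns a DataFrame with columns
    ``node``, ``outflow``, ``rank``.
    """
    delta = np.asarray(delta, dtype=float)
    labels = [str(i) for i in range(delta.size)] if labels is None else [str(x) for x in labels]
    df = pd.DataFrame({"node": labels, "outflow": delta})
    df = df.sort_values(["outflow", "node"], ascending=[False, True], kind="stable")
    df["rank"] = np.arange(1, len(df) + 1)
    return df.reset_index(drop=True)


def proportional_adjacency(mdi_slice: np.ndarray, keep: float = 0.5) -> np.ndarray:
    """Binary directed adjacency keeping the strongest off-diagonal entries.

    The top ``ceil(keep * count)`` off-diagonal values are set to 1 and the
    rest to 0; values tied with the cutoff are all retained. The diagonal
    is always 0.
    """
    if not 0 < keep <= 1:
        raise ValueError(f"keep must be in (0, 1]; got {keep}")
    mdi_slice = np.asarray(mdi_slice, dtype=float)
    d = mdi_slice.shape[0]
    off = ~np.eye(d, dtype=bool)
    vals = mdi_slice[off]
    m = int(np.ceil(keep * vals.size))
    cutoff = np.sort(vals)[::-1][m - 1]
    adj = np.zeros((d, d), dtype=int)
    adj[off & (mdi_slice >= cutoff)] = 1
    return adj


def consistency(adj: np.ndarray, adj_ref: np.ndarray, mode: str = "intersection") -> float:
    """Fraction of reference edges preserved in a perturbed adjacency.

    ``mode="intersection"`` (default) is |E(adj) ∩ E(ref)| / |E(ref)| —
    the proportion of the reference's retained connections that survive the
    perturbation; ``mode="jaccard"`` uses the union in the denominator.
    Both adjacencies must come from the same keep proportion (equal edge
    counts) for the intersection ratio to be comparable.
    """
    adj = np.asarray(adj, dtype=bool)
    adj_ref = np.asarray(adj_ref, dtype=bool)
    if adj.shape != adj_ref.shape:
        raise ValueError("adjacency shapes differ")
    if mode == "intersection":
        if adj.sum() != adj_ref.sum():
            raise ValueError(
                "adjacencies retain different edge counts "
                f"({int(adj.sum())} vs {int(adj_ref.sum())}); "
                "use the same keep proportion, or mode='jaccard'"
            )
        return float((adj & adj_ref).sum() / adj_ref.sum())
    if mode == "jaccard":
        union = (adj | adj_ref).sum()
        return float((adj & adj_ref).sum() / union) if union else 1.0
    raise ValueError(f"unknown mode {mode!r}")


def driver_score(mdi_slice: np.ndarray, node: int) -> float:
    """Excess outflow of one node over the network-average outflow.

    Outflow is the column sum of the directed-influence slice with the
    diagonal excluded. Positive scores mark nodes that drive the network
    more than average; scores sum to zero across nodes.
    """
    mdi_slice = np.asarray(mdi_slice, dtype=float)
    d = mdi_slice.shape[0]
    off = mdi_slice.copy()
    off[np.arange(d), np.arange(d)] = 0.0
    outflow = off.sum(axis=0)
    return float(outflow[node] - outflow.mean())


def _exact_sign_patterns(n_subjects: int) -> np.ndarray:
    bits = np.arange(2**n_subjects)[:, None] >> np.arange(n_subjects)
    return np.where(bits & 1, 1.0, -1.0)


def sign_permutation_test(
    per_subject_diffs: np.ndarray,
    n_perm: int = 100_000,
    alpha: float = 0.01,
    seed: int | None = None,
    exact: bool = False,
    chunk: int = 2000,
) -> PermutationResult:
    """Group-level sign-flip permutation test on per-subject differences.

    For each edge/time entry, the null distribution of the group mean is
    built by randomly flipping the sign of every subject's difference and
    re-averaging. One-sided exceedance proportions ``p_hi`` and ``p_lo``
    use the add-one correction ``(1 + count) / (1 + n_perm)`` so p-values
    are never zero; the two-sided p-value is ``min(1, 2 * min(p_hi, p_lo))``.
    No multiple-comparison correction is applied.

    With ``exact=True`` all ``2^S`` sign patterns are enumerated (feasible
    for small groups; the identity pattern makes the correction
    unnecessary, so raw proportions are reported).
    """
    diffs = np.asarray(per_subject_diffs, dtype=float)
    S = diffs.shape[0]
    if S < 2:
        raise ValueError("at least two subjects are required")
    flat = diffs.reshape(S, -1)
    observed = flat.mean(axis=0)

    if exact:
        if S > 20:
            raise ValueError("exact enumeration is limited to 20 subjects (2^S patterns)")
        signs = _exact_sign_patterns(S)
        null = signs @ flat / S
        n_total = signs.shape[0]
        count_hi = (null >= observed - 1e-15).sum(axis=0)
        count_lo = (null <= observed + 1e-15).sum(axis=0)
        p_hi = count_hi / n_total
        p_lo = count_lo / n_total
        method = "exact"
        n_used = n_total
    else:
        if seed is None:
            raise ValueError("a seed is required for Monte-Carlo permutations")
        if n_perm < 100:
            warnings.warn(f"n_perm={n_perm} is very small; p-values will be coarse")
        rng = np.random.default_rng(seed)
        count_hi = np.zeros(flat.shape[1], dtype=np.int64)
        count_lo = np.zeros(flat.shape[1], dtype=np.int64)
        done = 0
        while done < n_perm:
            m = min(chunk, n_perm - done)
            signs = rng.choice([-1.0, 1.0], size=(m, S))
            null = signs @ flat / S
            count_hi += (null >= observed - 1e-15).sum(axis=0)
            count_lo += (null <= observed + 1e-15).sum(axis=0)
            done += m
        p_hi = (1 + count_hi) / (1 + n_perm)
        p_lo = (1 + count_lo) / (1 + n_perm)
        method = "montecarlo"
        n_used = n_perm

    p = np.minimum(1.0, 2.0 * np.minimum(p_hi, p_lo))
    shape = diffs.shape[1:]
    return PermutationResult(
        observed=observed.reshape(shape),
        p_values=p.reshape(shape),
        n_permutations=n_used,
        alpha=alpha,
        method=method,
    )
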