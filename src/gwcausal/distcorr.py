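"""Distance covariance / correlation and the causal contrast T_C.

Sample distance correlation is a [0, 1] dependence measure between random
vectors of arbitrary dimension that is zero (in population) exactly under
independence. It is built from double-centered pairwise Euclidean distance
matrices A and B:

    V_n^2(X, Y) = (1/n^2) sum_kl A_kl B_kl,
    R_n^2 = V_n^2(X, Y) / sqrt(V_n^2(X) V_n^2(Y))   (0 when a variance is 0).

For causal inference the dependence is measured between *distributions*
rather than observations: the cause distribution P(X) should carry no
information about the mechanism P(Y|X). Each observed x-level i becomes one
sample point pairing the scalar P(X = x_i) with the vector P(Y | X = x_i);
the normalized distance covariance of those m points gives Delta_{X->Y}, the
reverse construction Delta_{Y->X}, and the causal contrast is
T_C = |Delta_{X->Y} - Delta_{Y->X}| with a permutation null.

Note the contrast needs the cause to take more than a couple of states to be
informative; on 3-state genotypes the scan reports it as advisory.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np

from .discrete_core import (
    DiscreteSample,
    TestResult,
    estimate_conditional,
    joint_counts,
    randomized_tail_pvalue,
    sample_null_tables,
)


@dataclass
class CenteredDistances:
    """Double-centered pairwise-distance matrices and grand means."""

    A: np.ndarray
    B: np.ndarray
    a_bar_dotdot: float
    b_bar_dotdot: float


@dataclass
class DCovResult:
    V2_xy: float
    V2_x: float
    V2_y: float
    R2: float


@dataclass
class DistributionEmbedding:
    """Per-group points (P(X^(i)), P(Y|X^(i))) for the Delta measures."""

    px: np.ndarray
    rows: np.ndarray
    dropped: int = 0


@dataclass
class CausalContrast:
    delta_xy: float
    delta_yx: float
    T_C: float
    p_value: Optional[float] = None
    verdict: Literal["X_causes_Y", "Y_causes_X", "no_decision"] = "no_decision"
    extra: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# sampling distance covariance / correlation
# ---------------------------------------------------------------------------

def _as_points(xs) -> np.ndarray:
    a = np.asarray(xs, dtype=float)
    if a.ndim == 1:
        a = a[:, None]
    return a


def _pairwise(points: np.ndarray) -> np.ndarray:
    diff = points[:, None, :] - points[None, :, :]
    return np.sqrt((diff ** 2).sum(axis=-1))


def _double_center(d: np.ndarray) -> np.ndarray:
    return (d - d.mean(axis=1, keepdims=True) - d.mean(axis=0, keepdims=True)
            + d.mean())


def centered_distances(xs, ys) -> CenteredDistances:
    """Euclidean distance matrices of two point sets, double-centered."""
    X, Y = _as_points(xs), _as_points(ys)
    if len(X) != len(Y):
        raise ValueError("xs and ys must have equal counts")
    if len(X) < 2:
        raise ValueError("need n >= 2 points")
    a, b = _pairwise(X), _pairwise(Y)
    return CenteredDistances(_double_center(a), _double_center(b),
                             float(a.mean()), float(b.mean()))


def distance_correlation(xs, ys) -> DCovResult:
    """Sampling distance covariance and squared distance correlation."""
    cd = centered_distances(xs, ys)
    n = cd.A.shape[0]
    v_xy = float((cd.A * cd.B).sum()) / n ** 2
    v_x = float((cd.A ** 2).sum()) / n ** 2
    v_y = float((cd.B ** 2).sum()) / n ** 2
    denom = v_x * v_y
    r2 = v_xy / np.sqrt(denom) if denom > 0 else 0.0
    return DCovResult(v_xy, v_x, v_y, float(min(max(r2, 0.0), 1.0)))


def weighted_distance_correlation(xvals, yvals, w) -> float:
    """Squared distance correlation of weighted point masses.

    Equivalent to :func:`distance_correlation` on data where point i occurs
    with relative frequency w_i; used to evaluate distance-correlation
    dependence measures directly from a contingency table.
    """
    X, Y = _as_points(xvals), _as_points(yvals)
    w = np.asarray(w, dtype=float)
    a, b = _pairwise(X), _pairwise(Y)

    def center(d):
        row = d @ w
        grand = float(w @ row)
        return d - row[:, None] - row[None, :] + grand

    A, B = center(a), center(b)
    ww = np.outer(w, w)
    v_xy = float((ww * A * B).sum())
    v_x = float((ww * A * A).sum())
    v_y = float((ww * B * B).sum())
    denom = v_x * v_y
    if denom <= 0:
        return 0.0
    return float(min(max(v_xy / np.sqrt(denom), 0.0), 1.0))


def t_ind_test(xs, ys, B: int = 999, seed: int = 0) -> TestResult:
    """Permutation test of independence via T_IND = n V_n^2 / (a_bar b_bar)."""
    if B < 1:
        raise ValueError("B must be >= 1")
    X, Y = _as_points(xs), _as_points(ys)
    cd = centered_distances(X, Y)
    if cd.a_bar_dotdot * cd.b_bar_dotdot <= 0:
        raise ValueError("degenerate input: all xs or all ys identical "
                         "(zero normalizer)")
    n = len(X)

    def t_ind(a_cent, b_cent, a_bar, b_bar):
        return n * float((a_cent * b_cent).sum()) / n ** 2 / (a_bar * b_bar)

    obs = t_ind(cd.A, cd.B, cd.a_bar_dotdot, cd.b_bar_dotdot)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    hits = 0
    for _ in range(B):
        perm = rng.permutation(n)
        cdp = centered_distances(X, Y[perm])
        stat = t_ind(cdp.A, cdp.B, cdp.a_bar_dotdot, cdp.b_bar_dotdot)
        if stat >= obs - 1e-15:
            hits += 1
    p = (1 + hits) / (B + 1)
    return TestResult(obs, p, "t_ind_permutation", n_permutations=B,
                      seed=seed)


# ---------------------------------------------------------------------------
# distribution-level Delta measures and the T_C causal test
# ---------------------------------------------------------------------------

def embed_distributions(sample: DiscreteSample) -> DistributionEmbedding:
    """Per-level embedding: point i = (P(X = x_i), P(Y | X = x_i)).

    Every observed discrete level forms its own group; levels with no
    observations are dropped with a warning.
    """
    cond = estimate_conditional(sample)
    keep = ~cond.undefined
    dropped = int(cond.undefined.sum())
    if dropped:
        warnings.warn(f"{dropped} empty group(s) dropped from the embedding",
                      stacklevel=2)
    return DistributionEmbedding(px=cond.marginal[keep],
                                 rows=cond.rows[keep], dropped=dropped)


def _delta(px: np.ndarray, rows: np.ndarray) -> float:
    """Normalized distance covariance between P(X) and P(Y|X) points."""
    m = len(px)
    if m < 2:
        return 0.0
    a = np.abs(px[:, None] - px[None, :])
    b = _pairwise(rows)
    s = float(a.mean()) * float(b.mean())
    if s <= 0:
        return 0.0
    v2 = float((_double_center(a) * _double_center(b)).sum()) / m ** 2
    return max(m * v2 / s, 0.0)


def delta_measures(emb_xy: DistributionEmbedding,
                   emb_yx: DistributionEmbedding) -> CausalContrast:
    """Delta_{X->Y}, Delta_{Y->X} and the contrast T_C (no p-value)."""
    dxy = _delta(emb_xy.px, emb_xy.rows)
    dyx = _delta(emb_yx.px, emb_yx.rows)
    return CausalContrast(dxy, dyx, abs(dxy - dyx))


def _batch_delta(px: np.ndarray, rows: np.ndarray) -> np.ndarray:
    """Vectorized :func:`_delta` over a (B, m) / (B, m, k) stack."""
    B, m = px.shape
    if m < 2:
        return np.zeros(B)
    a = np.abs(px[:, :, None] - px[:, None, :])
    diff = rows[:, :, None, :] - rows[:, None, :, :]
    b = np.sqrt((diff ** 2).sum(axis=-1))

    def center(d):
        return (d - d.mean(axis=2, keepdims=True)
                - d.mean(axis=1, keepdims=True)
                + d.mean(axis=(1, 2), keepdims=True))

    v2 = (center(a) * center(b)).mean(axis=(1, 2))
    s = a.mean(axis=(1, 2)) * b.mean(axis=(1, 2))
    out = np.zeros(B)
    ok = s > 0
    out[ok] = np.maximum(m * v2[ok] / s[ok], 0.0)
    return out


def batch_tc(tables: np.ndarray) -> np.ndarray:
    """T_C per joint count table in a (B, r, c) stack.

    Empty x-levels / y-levels are dropped uniformly (margins are constant
    across a permutation-null stack).
    """
    t = np.asarray(tables, dtype=float)
    rowm = t[0].sum(axis=1) > 0
    colm = t[0].sum(axis=0) > 0
    t = t[:, rowm][:, :, colm]
    n = t.sum(axis=(1, 2), keepdims=True)
    px = t.sum(axis=2) / n[:, :, 0]
    rows_f = t / t.sum(axis=2, keepdims=True)
    tt = np.swapaxes(t, 1, 2)
    py = tt.sum(axis=2) / n[:, :, 0]
    rows_b = tt / tt.sum(axis=2, keepdims=True)
    return np.abs(_batch_delta(px, rows_f) - _batch_delta(py, rows_b))


def tc_causal_test(sample: DiscreteSample, B: int = 1000, seed: int = 0,
                   alpha: float = 0.05) -> CausalContrast:
    """Permutation test of 'no causation' via T_C with a direction verdict.

    The null permutes y against x (fixed-margin null tables). A direction is
    declared only when the permutation p-value is at or below ``alpha``; the
    larger Delta names the cause. The direction convention (larger
    Delta_{X->Y} means X causes Y) is recorded in the output metadata since
    the two candidate readings differ only by a label swap of the verdict.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    emb_xy = embed_distributions(sample)
    emb_yx = embed_distributions(sample.swapped())
    contrast = delta_measures(emb_xy, emb_yx)
    joint = joint_counts(sample)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    obs = float(batch_tc(joint[None])[0])
    null = batch_tc(sample_null_tables(joint, B, rng))
    p = randomized_tail_pvalue(obs, null, rng)
    contrast.p_value = p
    if p <= alpha and contrast.delta_xy > contrast.delta_yx:
        contrast.verdict = "X_causes_Y"
    elif p <= alpha and contrast.delta_yx > contrast.delta_xy:
        contrast.verdict = "Y_causes_X"
    else:
        contrast.verdict = "no_decision"
    contrast.extra["direction_convention"] = (
        "larger Delta names the cause (Delta_{X->Y} > Delta_{Y->X} => X->Y)")
    contrast.extra["advisory_small_support"] = bool(sample.x_domain.m <= 3)
    contrast.extra["n_permutations"] = B
    contrast.extra["seed"] = seed
    return contrast
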