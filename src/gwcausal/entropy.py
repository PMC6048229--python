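"""Causal direction inference via minimal-entropy exogenous construction.

The model Y = f(X, E) with X independent of E always exists for discrete
variables; what distinguishes the causal direction is how simple an exogenous
variable E suffices. Under the true direction E can be chosen with small
Shannon entropy H1(E), whereas the reverse construction needs a richer
Etilde, so comparing H1(E) with H1(Etilde) points at the cause.

E's distribution is built greedily from the conditional matrix M whose row i
is P(Y | X = x_i): repeatedly peel the mass block alpha = min over rows of
the current row maximum, record it as one state of E, subtract it from every
row's maximum and re-sort, until no mass remains. The construction works for
any r x c stochastic matrix (squareness is not needed); an allele-level 2x2
reduction for genotype data is available in the CLI.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np

from .discrete_core import (
    DiscreteSample,
    TestResult,
    estimate_conditional,
    joint_counts,
    randomized_twosided_pvalue,
    sample_null_tables,
    shannon_entropy,
)

#: mass below this counts as exhausted in the greedy loop (guards float drift)
GREEDY_TOL = 1e-12
#: |H1 difference| below this is called a tie
TIE_TOL = 1e-9


@dataclass
class ConditionalMatrix:
    """Row-stochastic matrix: row i estimates P(Y | X = x_i)."""

    M: np.ndarray
    row_labels: Optional[list] = None

    def __post_init__(self) -> None:
        M = np.asarray(self.M, dtype=float)
        object.__setattr__(self, "M", M)
        if M.ndim != 2:
            raise ValueError("M must be a 2-d matrix")
        if np.any(M < -1e-12):
            raise ValueError("conditional probabilities must be non-negative")
        if np.any(np.abs(M.sum(axis=1) - 1.0) > 1e-9):
            raise ValueError("every row of M must sum to 1")


@dataclass
class ExogenousDistribution:
    """Greedy output: the mass vector e and the block-to-label assignment.

    ``f_assignment[b, i]`` is the output label y that block b of E produces
    when X is in state i; distributing e's blocks accordingly reconstructs
    every row of M (the defining correctness property).
    """

    e: np.ndarray
    f_assignment: np.ndarray

    def reconstruct(self, n_labels: int) -> np.ndarray:
        """Rows of M implied by (e, f_assignment)."""
        nblocks, r = self.f_assignment.shape
        out = np.zeros((r, n_labels))
        for b in range(nblocks):
            for i in range(r):
                out[i, self.f_assignment[b, i]] += self.e[b]
        return out

    @property
    def h1(self) -> float:
        return shannon_entropy(self.e)


@dataclass
class EntropyDecision:
    H1_forward: float
    H1_backward: float
    verdict: Literal["X_causes_Y", "Y_causes_X", "tie"]


# ---------------------------------------------------------------------------
# greedy construction
# ---------------------------------------------------------------------------

def greedy_exogenous(M, tol: float = GREEDY_TOL) -> ExogenousDistribution:
    """Build the minimal-entropy exogenous distribution from P(Y|X).

    Iteratively peels alpha = min over rows of the current row maximum,
    appends it to e, subtracts it from each row's maximum, and stops once the
    remaining mass per row is below ``tol``. Ties in each row's argmax go to
    the smallest column index (and the min over rows is index-free), which
    makes the output deterministic and invariant to row order.
    """
    if isinstance(M, ConditionalMatrix):
        W = M.M.copy()
    else:
        W = ConditionalMatrix(np.asarray(M, dtype=float)).M.copy()
    r, c = W.shape
    rows = np.arange(r)
    e: list[float] = []
    assign: list[np.ndarray] = []
    max_blocks = r * c + c
    for _ in range(max_blocks + 1):
        idx = W.argmax(axis=1)
        alpha = float(W[rows, idx].min())
        if alpha <= tol:
            break
        e.append(alpha)
        assign.append(idx.copy())
        W[rows, idx] -= alpha
    else:
        raise RuntimeError("greedy exogenous construction failed to "
                           f"terminate within {max_blocks} blocks")
    leftover = float(np.abs(W).sum())
    if leftover > max(r * c * tol * 10, 1e-6):
        raise ValueError("rows of M are not stochastic enough to exhaust "
                         f"(leftover mass {leftover:g})")
    ev = np.asarray(e, dtype=float)
    ev = ev / ev.sum()
    return ExogenousDistribution(ev, np.asarray(assign, dtype=np.int64))


def entropy_from_conditional(M, tol: float = GREEDY_TOL) -> float:
    """H1 (bits) of the greedy exogenous distribution for conditional M."""
    return greedy_exogenous(M, tol=tol).h1


# ---------------------------------------------------------------------------
# direction decision
# ---------------------------------------------------------------------------

def entropy_direction(sample: DiscreteSample,
                      tie_tol: float = TIE_TOL) -> EntropyDecision:
    """Compare H1 of the exogenous constructions in the two directions.

    H1_forward comes from the greedy construction on P(Y|X), H1_backward
    from P(X|Y); the smaller entropy wins, with a tie inside ``tie_tol``.
    """
    cond_fwd = estimate_conditional(sample)
    cond_bwd = estimate_conditional(sample.swapped())
    for name, cond in (("x", cond_fwd), ("y", cond_bwd)):
        if cond.undefined.any():
            missing = np.nonzero(cond.undefined)[0].tolist()
            raise ValueError(
                f"conditioning state(s) {missing} of {name} were never "
                "observed; pool states or collect more data")
    h_f = entropy_from_conditional(cond_fwd.rows)
    h_b = entropy_from_conditional(cond_bwd.rows)
    if abs(h_f - h_b) < tie_tol:
        verdict = "tie"
    elif h_f < h_b:
        verdict = "X_causes_Y"
    else:
        verdict = "Y_causes_X"
    return EntropyDecision(h_f, h_b, verdict)


# ---------------------------------------------------------------------------
# batch machinery and the permutation test
# ---------------------------------------------------------------------------

def _batch_greedy_h1(M: np.ndarray, tol: float = GREEDY_TOL) -> np.ndarray:
    """Greedy-exogenous H1 for a (B, r, c) stack of row-stochastic matrices.

    Runs the same peeling loop as :func:`greedy_exogenous` on all matrices at
    once (the block count is bounded by r(c-1)+1, so the loop is short).
    """
    W = np.array(M, dtype=float)
    B, r, c = W.shape
    H = np.zeros(B)
    for _ in range(r * c + c):
        idx = W.argmax(axis=2)
        p1 = np.take_along_axis(W, idx[:, :, None], axis=2)[:, :, 0]
        alpha = p1.min(axis=1)
        active = alpha > tol
        if not active.any():
            break
        a = np.where(active, alpha, 1.0)
        H -= np.where(active, a * np.log2(a), 0.0)
        step = np.where(active, alpha, 0.0)
        np.put_along_axis(W, idx[:, :, None],
                          (p1 - step[:, None])[:, :, None], axis=2)
    return H


def batch_entropy_contrast(tables: np.ndarray) -> np.ndarray:
    """H1(backward) - H1(forward) per (B, r, c) joint count table.

    Rows (x states) with zero margin are dropped before conditioning; margins
    are identical across a permutation-null stack, so the drop is uniform.
    """
    t = np.asarray(tables, dtype=float)
    rowm = t[0].sum(axis=1) > 0
    colm = t[0].sum(axis=0) > 0
    t = t[:, rowm][:, :, colm]
    fwd = t / t.sum(axis=2, keepdims=True)
    bwd_t = np.swapaxes(t, 1, 2)
    bwd = bwd_t / bwd_t.sum(axis=2, keepdims=True)
    return _batch_greedy_h1(bwd) - _batch_greedy_h1(fwd)


def entropy_permutation_test(sample: DiscreteSample, B: int = 1000,
                             seed: int = 0) -> TestResult:
    """Permutation test of 'no causation' via the entropy contrast.

    The statistic is H1(Etilde) - H1(E) (backward minus forward greedy
    entropies); the null permutes y against x, realized exactly by
    fixed-margin null tables. The test is two-sided (equal tail): under the
    independence null the contrast sits at the baseline H1(X) - H1(Y), and
    genuine structure — causal or confounded — can push it off the baseline
    in either direction, so neither tail is privileged a priori.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    joint = joint_counts(sample)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    obs = float(batch_entropy_contrast(joint[None])[0])
    null = batch_entropy_contrast(sample_null_tables(joint, B, rng))
    p = randomized_twosided_pvalue(obs, null, rng)
    return TestResult(obs, p, "entropy_permutation", n_permutations=B,
                      seed=seed)


def allele_matrix(sample: DiscreteSample) -> np.ndarray:
    """Collapse a genotype (0/1/2) sample to the allele-level 2x2 conditional.

    Each genotype contributes two allele observations (minor-allele count);
    the returned matrix has rows P(Y | allele = a) for a in {0, 1}, matching
    the square-matrix setting of the original construction.
    """
    joint = joint_counts(sample)
    if joint.shape[0] != 3:
        raise ValueError("allele reduction expects a 3-state genotype x")
    # allele 1 observations: one per het, two per hom-alt
    allele = np.empty((2, joint.shape[1]), dtype=float)
    allele[1] = joint[1] + 2 * joint[2]
    allele[0] = 2 * joint[0] + joint[1]
    return allele / allele.sum(axis=1, keepdims=True)
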