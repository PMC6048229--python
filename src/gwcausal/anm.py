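"""Discrete / cyclic additive-noise-model (ANM) regression and causal tests.

An ANM from X to Y states Y = f(X) + N with the noise N independent of the
cause X (addition modulo k for a k-cyclic response, ordinary addition for
integer responses). Fitting minimizes a dependence measure (DM) between the
regressor and the residuals N = Y - f(X) over candidate function tables f;
the causal direction is then read off from which direction leaves residuals
independent of the regressor. For genotype-trait data the genotype is
3-cyclic and a binary trait 2-cyclic.

Dependence measures (smaller = closer to independence):

``chi2_p``
    1 minus the Pearson chi-square p-value of the regressor x residual table
    (the default for genetics; cheap and matches the contingency-table test).
``distance_correlation``
    squared sample distance correlation between regressor and residual
    values, computed from the joint table with probability weights.
``shannon_entropy``
    mutual information I(X; N) in bits (zero iff empirically independent).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np

from .discrete_core import (
    SMALL_EXPECTED,
    ContingencyTable,
    DiscreteSample,
    DomainSpec,
    MultiSample,
    PMF,
    TestResult,
    batch_chi2_pvalues,
    batch_chi2_stats,
    chi_square_test,
    fisher_exact,
    joint_counts,
    permutation_pvalue,
    randomized_tail_pvalue,
    sample_null_tables,
    shannon_entropy,
)

#: largest function-table family enumerated exhaustively (|Y| ** |X|)
EXHAUSTIVE_LIMIT = 100_000
#: largest family for the vectorized all-functions permutation path
_BATCH_FUNC_LIMIT = 1024


@dataclass
class ANMConfig:
    """Tuning knobs for ANM fitting and the direction decision.

    ``eps`` is the residual-independence significance threshold used by the
    direction decision; ``max_iter`` caps coordinate-descent sweeps in
    iterative search; ``search`` picks exhaustive enumeration, iterative
    coordinate descent, or an automatic choice by family size.
    """

    dm_kind: Literal["chi2_p", "distance_correlation", "shannon_entropy"] = "chi2_p"
    eps: float = 0.05
    max_iter: int = 20
    search: Literal["auto", "exhaustive", "iterative"] = "auto"
    df_convention: Literal["paper", "classical"] = "paper"

    def __post_init__(self) -> None:
        if not (0.0 < self.eps < 1.0):
            raise ValueError("eps must lie in (0, 1)")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


@dataclass
class ANMFit:
    """A fitted additive-noise regression in one direction."""

    direction: Literal["forward", "backward"]
    f: np.ndarray
    residuals: np.ndarray
    noise_values: np.ndarray
    noise_pmf: PMF
    dm_value: float
    dm_kind: str
    domain: DomainSpec
    converged: bool
    iterations: int
    mode_at_zero: bool


@dataclass
class CausalDecision:
    """Bidirectional ANM verdict with the per-direction evidence."""

    verdict: Literal["X_causes_Y", "Y_causes_X", "reversible", "no_decision"]
    forward: ANMFit
    backward: ANMFit
    p_forward: float
    p_backward: float
    p_causal: Optional[float] = None


# ---------------------------------------------------------------------------
# residual tables and dependence measures
# ---------------------------------------------------------------------------

def _residual_table(joint: np.ndarray, f: np.ndarray,
                    ry: DomainSpec) -> tuple[np.ndarray, np.ndarray]:
    """Regressor x residual count table and the residual value labels.

    ``joint`` is the |X| x |Y| joint count table; row i is shifted so that
    column j lands at residual value j - f(i) (mod k when cyclic).
    """
    r, c = joint.shape
    f = np.asarray(f, dtype=np.int64)
    if ry.mode == "cyclic":
        out = np.empty_like(joint)
        for i in range(r):
            out[i] = np.roll(joint[i], -int(f[i]) % c)
        return out, np.arange(c)
    lo = 0 - int(f.max())
    hi = (c - 1) - int(f.min())
    width = hi - lo + 1
    out = np.zeros((r, width), dtype=joint.dtype)
    for i in range(r):
        start = -int(f[i]) - lo
        out[i, start:start + c] += joint[i]
    return out, np.arange(lo, hi + 1)


def _mutual_information_bits(table: np.ndarray) -> float:
    t = np.asarray(table, dtype=float)
    n = t.sum()
    if n <= 0:
        return 0.0
    p = t / n
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        terms = p * np.log2(p / (px * py))
    return float(np.nansum(terms))


def _dm_from_residual_table(table: np.ndarray, residual_values: np.ndarray,
                            dm_kind: str) -> float:
    """Dependence measure between regressor groups and residual values."""
    if dm_kind == "chi2_p":
        p = float(batch_chi2_pvalues(table[None])[0])
        return 1.0 - p
    if dm_kind == "chi2_stat":  # internal: chi2_p fit on the statistic scale
        from .discrete_core import batch_chi2_stats
        return float(batch_chi2_stats(table[None])[0])
    if dm_kind == "shannon_entropy":
        return _mutual_information_bits(table)
    if dm_kind == "distance_correlation":
        from .distcorr import weighted_distance_correlation
        r = table.shape[0]
        xs = np.repeat(np.arange(r, dtype=float), table.shape[1])
        ys = np.tile(residual_values.astype(float), r)
        w = table.astype(float).ravel()
        total = w.sum()
        if total <= 0:
            return 0.0
        return weighted_distance_correlation(xs, ys, w / total)
    raise ValueError(f"unknown dm_kind {dm_kind!r}")


# ---------------------------------------------------------------------------
# function search
# ---------------------------------------------------------------------------

def _search_exhaustive(joint: np.ndarray, ry: DomainSpec, dm_kind: str):
    r, c = joint.shape
    best_dm, best_f = np.inf, None
    for f in itertools.product(range(c), repeat=r):
        table, vals = _residual_table(joint, np.array(f), ry)
        dm = _dm_from_residual_table(table, vals, dm_kind)
        if dm < best_dm:  # strict: first (lexicographically smallest) f wins ties
            best_dm, best_f = dm, np.array(f, dtype=np.int64)
    return best_f, best_dm, True, 1


def _descend(joint: np.ndarray, ry: DomainSpec, dm_kind: str,
             f: np.ndarray, max_iter: int):
    """Coordinate descent on one function table until no move improves."""
    r, c = joint.shape
    table, vals = _residual_table(joint, f, ry)
    dm = _dm_from_residual_table(table, vals, dm_kind)
    converged = False
    sweeps = 0
    for sweeps in range(1, max_iter + 1):
        changed = False
        for i in range(r):
            for cand in range(c):
                if cand == f[i]:
                    continue
                trial = f.copy()
                trial[i] = cand
                t, v = _residual_table(joint, trial, ry)
                d = _dm_from_residual_table(t, v, dm_kind)
                # accept strict improvements; on exact ties prefer the smaller
                # function value so the result matches exhaustive tie-breaking
                if d < dm or (d == dm and cand < f[i]):
                    f, dm = trial, d
                    changed = True
        if not changed:
            converged = True
            break
    return f, dm, converged, sweeps


def _search_iterative(joint: np.ndarray, ry: DomainSpec, dm_kind: str,
                      max_iter: int):
    """Multi-start coordinate descent.

    Starts from the conditional-mode table and, on small supports, also from
    its constant shifts and each constant function; the extra deterministic
    starts escape the single-coordinate local optima the plain
    conditional-mode start occasionally lands in, at negligible cost where
    the family is small (large supports keep the single start).
    """
    r, c = joint.shape
    mode = joint.argmax(axis=1).astype(np.int64)
    inits = [mode]
    if r * c <= 32:
        if ry.mode == "cyclic":
            inits += [(mode + k) % c for k in range(1, c)]
        inits += [np.full(r, k, dtype=np.int64) for k in range(c)]
    best = None
    tot_sweeps = 0
    any_converged = True
    for f0 in inits:
        f, dm, conv, sweeps = _descend(joint, ry, dm_kind, f0.copy(),
                                       max_iter)
        tot_sweeps += sweeps
        any_converged &= conv
        key = (dm, tuple(f))
        if best is None or key < best:
            best = key
    f = np.asarray(best[1], dtype=np.int64)
    return f, best[0], any_converged, tot_sweeps


def fit_anm(sample: DiscreteSample,
            direction: Literal["forward", "backward"] = "forward",
            config: Optional[ANMConfig] = None) -> ANMFit:
    """Fit Y = f(X) + N by minimizing the dependence measure over f.

    ``direction='backward'`` fits X = g(Y) + N_x instead. Exhaustive search
    enumerates all |Y| ** |X| function tables (8 for the genotype-trait case);
    iterative search starts from the conditional mode and updates one f(x) at
    a time. Regressor states never observed get f set to the overall majority
    response, with a warning.
    """
    config = config or ANMConfig()
    s = sample if direction == "forward" else sample.swapped()
    joint = joint_counts(s)
    r, c = joint.shape
    ry = s.y_domain
    search = config.search
    if search == "auto":
        search = "exhaustive" if c ** r <= EXHAUSTIVE_LIMIT else "iterative"
    if search == "exhaustive" and c ** r > EXHAUSTIVE_LIMIT:
        raise ValueError(
            f"exhaustive search infeasible: |Y|**|X| = {c}**{r} exceeds "
            f"{EXHAUSTIVE_LIMIT}; use search='iterative'")
    if search == "exhaustive":
        f, dm, converged, iters = _search_exhaustive(joint, ry, config.dm_kind)
    else:
        f, dm, converged, iters = _search_iterative(joint, ry, config.dm_kind,
                                                    config.max_iter)
    empty = joint.sum(axis=1) == 0
    if empty.any():
        warnings.warn("regressor states never observed; their f values are "
                      "set to the majority response", stacklevel=2)
        f[empty] = int(np.argmax(joint.sum(axis=0)))
    residuals = ry.subtract(s.y, f[s.x])
    vals, counts = np.unique(residuals, return_counts=True)
    if ry.mode == "cyclic":
        full = np.zeros(ry.m, dtype=np.int64)
        full[vals] = counts
        vals = np.arange(ry.m)
        counts = full
    pmf = PMF.from_counts(counts)
    at_zero = pmf.probs[np.nonzero(vals == 0)[0][0]] if (vals == 0).any() else 0.0
    return ANMFit(direction=direction, f=f, residuals=residuals,
                  noise_values=vals, noise_pmf=pmf, dm_value=float(dm),
                  dm_kind=config.dm_kind, domain=ry, converged=converged,
                  iterations=iters,
                  mode_at_zero=bool(at_zero >= pmf.probs.max() - 1e-12))


# ---------------------------------------------------------------------------
# residual-independence testing and direction decision
# ---------------------------------------------------------------------------

def residual_independence(fit: ANMFit, sample: DiscreteSample,
                          method: str = "auto", B: int = 999,
                          seed: int = 0,
                          config: Optional[ANMConfig] = None) -> TestResult:
    """Test independence of the regressor and the fitted residuals.

    ``auto`` applies the chi-square test and falls back to Fisher's exact
    test when any retained expected count is below 5 (small cells). For a
    binary residual the table is laid out response-by-genotype so the paper's
    3**q - 1 degrees of freedom apply; wider residual supports use the
    classical (r-1)(c-1).
    """
    config = config or ANMConfig()
    s = sample if fit.direction == "forward" else sample.swapped()
    joint = joint_counts(s)
    table, vals = _residual_table(joint, fit.f, fit.domain)
    if method == "permutation":
        return permutation_pvalue(lambda sm: _dm_from_residual_table(
            *_residual_table(joint_counts(sm), fit.f, fit.domain),
            config.dm_kind), s, B, seed)
    if table.shape[1] == 2 and fit.domain.mode == "cyclic":
        q = int(round(np.log(table.shape[0]) / np.log(3))) \
            if 3 ** int(round(np.log(table.shape[0]) / np.log(3))) == table.shape[0] else 1
        ct = ContingencyTable(table.T, list(range(table.shape[0])), q=q)
        if method == "fisher":
            return fisher_exact(ct, seed=seed)
        try:
            res = chi_square_test(ct, df_convention=config.df_convention)
        except ValueError:
            if method == "chi2":
                raise
            return fisher_exact(ct, seed=seed)
        if method == "auto":
            from .discrete_core import expected_counts
            exp = expected_counts(ct)
            keep = ct.counts.sum(axis=0) > 0
            if np.any(exp[:, keep] < SMALL_EXPECTED):
                return fisher_exact(ct, seed=seed)
        return res
    # general residual support: classical Pearson chi-square
    p = float(batch_chi2_pvalues(table[None])[0])
    rowt = table.sum(axis=1, keepdims=True)
    colt = table.sum(axis=0, keepdims=True)
    exp = rowt * colt / max(table.sum(), 1)
    statistic = float(np.where(exp > 0, (table - exp) ** 2 /
                               np.where(exp > 0, exp, 1.0), 0.0).sum())
    df = (table.shape[0] - 1) * (table.shape[1] - 1)
    return TestResult(statistic, p, "chi_square", df=df)


def decide_direction(sample: DiscreteSample,
                     config: Optional[ANMConfig] = None,
                     seed: int = 0) -> CausalDecision:
    """Fit both directions and apply the accept/reject direction rule.

    A direction is accepted when its residual-independence p-value exceeds
    the threshold ``eps``: only forward accepted -> X causes Y; only backward
    -> Y causes X; both -> reversible (no direction identifiable); neither
    -> no decision.
    """
    config = config or ANMConfig()
    fwd = fit_anm(sample, "forward", config)
    bwd = fit_anm(sample, "backward", config)
    p_f = residual_independence(fwd, sample, seed=seed, config=config).p_value
    p_b = residual_independence(bwd, sample, seed=seed, config=config).p_value
    ok_f, ok_b = p_f > config.eps, p_b > config.eps
    if ok_f and not ok_b:
        verdict = "X_causes_Y"
    elif ok_b and not ok_f:
        verdict = "Y_causes_X"
    elif ok_f and ok_b:
        verdict = "reversible"
    else:
        verdict = "no_decision"
    return CausalDecision(verdict, fwd, bwd, p_f, p_b)


# ---------------------------------------------------------------------------
# permutation causal test
# ---------------------------------------------------------------------------

def _best_dm_from_joint(joint: np.ndarray, ry: DomainSpec,
                        config: ANMConfig) -> float:
    # the permutation contrast uses the statistic scale for chi2_p fits
    dm_kind = "chi2_stat" if config.dm_kind == "chi2_p" else config.dm_kind
    r, c = joint.shape
    if c ** r <= EXHAUSTIVE_LIMIT:
        _, dm, _, _ = _search_exhaustive(joint, ry, dm_kind)
    else:
        _, dm, _, _ = _search_iterative(joint, ry, dm_kind, config.max_iter)
    return dm


def _batch_best_chi2_stat(tables: np.ndarray) -> np.ndarray:
    """Smallest regressor-residual chi-square statistic over all functions.

    ``tables`` has shape (B, r, c) with cyclic response arithmetic; for a
    fixed table width the function minimizing the chi-square statistic also
    maximizes its p-value, so this is the chi2_p fit on the statistic scale.
    """
    B, r, c = tables.shape
    best = np.full(B, np.inf)
    cols = np.arange(c)
    for f in itertools.product(range(c), repeat=r):
        rt = np.empty_like(tables)
        for i in range(r):
            rt[:, i, :] = tables[:, i, (cols + f[i]) % c]
        np.minimum(best, batch_chi2_stats(rt), out=best)
    return best


def batch_dm_contrast(tables: np.ndarray) -> np.ndarray:
    """Directional DM contrast (backward best - forward best) per table.

    Vectorized over a (B, r, c) stack of joint count tables with cyclic
    domains on both sides. The dependence measure is the best-fit
    regressor-residual chi-square statistic: the statistic scale (unlike
    1 - p) keeps discriminating when both directions are strongly dependent,
    which is where the causal signal lives. Larger contrast = the forward
    (X -> Y) ANM fits better relative to the backward one.
    """
    fwd = _batch_best_chi2_stat(tables)
    bwd = _batch_best_chi2_stat(np.swapaxes(tables, 1, 2))
    return bwd - fwd


def anm_permutation_test(sample: DiscreteSample,
                         config: Optional[ANMConfig] = None,
                         B: int = 1000, seed: int = 0) -> TestResult:
    """Permutation test of 'no causation X -> Y' via the directional DM contrast.

    The statistic is the backward-best minus forward-best dependence measure
    (larger = more forward-causal); its null distribution comes from permuting
    y against x, which for a purely tabular statistic is realized exactly by
    drawing fixed-margin null tables. The contrast has an atom at zero under
    independence (the identity relabeling is optimal in both directions), so
    exact ties are split by a seeded randomized rank, which keeps the test
    exact instead of severely conservative.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    config = config or ANMConfig()
    joint = joint_counts(sample)
    r, c = joint.shape
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    fast = (config.dm_kind == "chi2_p"
            and sample.x_domain.mode == "cyclic"
            and sample.y_domain.mode == "cyclic"
            and c ** r <= _BATCH_FUNC_LIMIT and r ** c <= _BATCH_FUNC_LIMIT)
    if fast:
        obs = float(batch_dm_contrast(joint[None])[0])
        null = batch_dm_contrast(sample_null_tables(joint, B, rng))
    else:
        obs = (_best_dm_from_joint(joint.T, sample.x_domain, config)
               - _best_dm_from_joint(joint, sample.y_domain, config))
        tables = sample_null_tables(joint, B, rng)
        null = np.array([
            _best_dm_from_joint(t.T, sample.x_domain, config)
            - _best_dm_from_joint(t, sample.y_domain, config)
            for t in tables])
    p = randomized_tail_pvalue(obs, null, rng)
    return TestResult(obs, p, "anm_permutation", n_permutations=B, seed=seed)


# ---------------------------------------------------------------------------
# multivariate (multi-SNP) ANM
# ---------------------------------------------------------------------------

def fit_multivariate(ms: MultiSample,
                     config: Optional[ANMConfig] = None) -> ANMFit:
    """ANM with a q-SNP genotype tuple as a single 3**q-state regressor.

    Identical to :func:`fit_anm` after encoding each genotype row as one
    base-3 integer; the residual-independence test then carries the paper's
    3**q - 1 degrees of freedom.
    """
    if ms.q > 8:
        raise ValueError("q > 8: the 3**q cells are not enumerable; "
                         "run a per-SNP scan instead")
    sample = DiscreteSample(ms.encoded(), ms.y,
                            DomainSpec("integer", 3 ** ms.q),
                            DomainSpec("cyclic", 2))
    return fit_anm(sample, "forward", config)


def multivariate_sample(ms: MultiSample) -> DiscreteSample:
    """The encoded 3**q-state DiscreteSample used by :func:`fit_multivariate`."""
    return DiscreteSample(ms.encoded(), ms.y,
                          DomainSpec("integer", 3 ** ms.q),
                          DomainSpec("cyclic", 2))
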