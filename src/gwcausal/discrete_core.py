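"""Discrete-data primitives shared by the three causal-inference methods.

This module houses the vocabulary every other module builds on: paired
discrete samples with declared (cyclic or plain integer) domains, probability
mass functions, genotype-by-response contingency tables, Pearson chi-square
and Fisher exact independence tests, Shannon/Renyi entropies, conditional
distribution estimation, and the permutation p-value engine.

Conventions
-----------
* Entropies are in bits (log base 2) throughout.
* Permutation p-values use the add-one convention
  ``p = (1 + #{b : stat_b >= stat_obs}) / (B + 1)`` so p is never zero.
* Every stochastic routine takes an explicit integer seed; child streams are
  derived deterministically with :class:`numpy.random.SeedSequence`.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Callable, Literal, Optional, Sequence

import numpy as np
from scipy import stats

# ---------------------------------------------------------------------------
# module-wide numerical configuration
# ---------------------------------------------------------------------------

#: tolerance for a probability vector summing to one
PMF_SUM_TOL = 1e-9
#: probabilities below this count as zero when counting support states (H0)
H0_STATE_TOL = 1e-12
#: expected-count threshold below which the chi-square test defers to Fisher
SMALL_EXPECTED = 5.0
#: Monte-Carlo draws for the generalized (wider than 2x2) Fisher exact test
FISHER_MC_DRAWS = 100_000


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DomainSpec:
    """Support description for one discrete variable.

    ``cyclic`` domains are the ring Z/mZ (arithmetic modulo ``m``); ``integer``
    domains hold ``m`` ordered states {0..m-1} with ordinary subtraction.
    Genetics defaults: a genotype is 3-cyclic, a binary trait 2-cyclic.
    """

    mode: Literal["cyclic", "integer"]
    m: int

    def __post_init__(self) -> None:
        if self.mode not in ("cyclic", "integer"):
            raise ValueError(f"unknown domain mode {self.mode!r}")
        if self.m < 1:
            raise ValueError("domain size m must be a positive integer")

    def subtract(self, a: np.ndarray, b: np.ndarray) -> np.ndarray:
        """Residual arithmetic: (a - b) mod m when cyclic, plain a - b else."""
        d = np.asarray(a, dtype=np.int64) - np.asarray(b, dtype=np.int64)
        if self.mode == "cyclic":
            d %= self.m
        return d


GENOTYPE_DOMAIN = DomainSpec("cyclic", 3)
TRAIT_DOMAIN = DomainSpec("cyclic", 2)


@dataclass(frozen=True)
class PMF:
    """Probability mass function over a finite support {0..K-1}."""

    probs: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        object.__setattr__(self, "probs", p)
        if p.ndim != 1 or p.size == 0:
            raise ValueError("PMF must be a nonempty 1-d vector")
        if np.any(p < -PMF_SUM_TOL):
            raise ValueError("PMF entries must be non-negative")
        if abs(p.sum() - 1.0) > PMF_SUM_TOL:
            raise ValueError(f"PMF must sum to 1 (got {p.sum()!r})")

    @classmethod
    def from_counts(cls, counts: np.ndarray) -> "PMF":
        c = np.asarray(counts, dtype=float)
        total = c.sum()
        if total <= 0:
            raise ValueError("cannot normalize an all-zero count vector")
        return cls(c / total)

    def __len__(self) -> int:
        return self.probs.size


@dataclass
class DiscreteSample:
    """Paired discrete series (x, y) with declared supports."""

    x: np.ndarray
    y: np.ndarray
    x_domain: DomainSpec
    y_domain: DomainSpec

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=np.int64)
        self.y = np.asarray(self.y, dtype=np.int64)
        if self.x.ndim != 1 or self.y.ndim != 1:
            raise ValueError("x and y must be 1-d series")
        if len(self.x) != len(self.y) or len(self.x) < 1:
            raise ValueError("x and y must be equal-length, nonempty series")
        for name, v, dom in (("x", self.x, self.x_domain),
                             ("y", self.y, self.y_domain)):
            if v.min() < 0 or v.max() >= dom.m:
                raise ValueError(
                    f"{name} values must lie in the declared support "
                    f"{{0..{dom.m - 1}}}")

    @property
    def n(self) -> int:
        return len(self.x)

    def swapped(self) -> "DiscreteSample":
        """The same sample with the roles of x and y exchanged."""
        return DiscreteSample(self.y.copy(), self.x.copy(),
                              self.y_domain, self.x_domain)

    @classmethod
    def from_arrays(cls, x, y,
                    x_mode: str = "cyclic", y_mode: str = "cyclic",
                    x_states: Optional[int] = None,
                    y_states: Optional[int] = None) -> "DiscreteSample":
        x = np.asarray(x, dtype=np.int64)
        y = np.asarray(y, dtype=np.int64)
        xd = DomainSpec(x_mode, x_states if x_states else int(x.max()) + 1)
        yd = DomainSpec(y_mode, y_states if y_states else int(y.max()) + 1)
        return cls(x, y, xd, yd)


@dataclass
class MultiSample:
    """Genotype matrix (n x q, values 0/1/2) with a binary response."""

    W: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=np.int64)
        self.y = np.asarray(self.y, dtype=np.int64)
        if self.W.ndim != 2 or self.W.shape[0] != len(self.y):
            raise ValueError("W must be n x q with n matching len(y)")
        if self.q < 1:
            raise ValueError("q must be >= 1")

    @property
    def q(self) -> int:
        return self.W.shape[1]

    @property
    def n(self) -> int:
        return self.W.shape[0]

    def encoded(self) -> np.ndarray:
        """Encode each q-tuple of genotypes as a single base-3 integer."""
        powers = 3 ** np.arange(self.q - 1, -1, -1)
        return (self.W * powers).sum(axis=1)


@dataclass
class ContingencyTable:
    """Genotype-by-response count table (2 rows: response 0 and 1).

    Row 0 holds the cell counts for response 0, row 1 for response 1; columns
    run over all 3**q genotype combinations (empty combinations kept as
    zeros). For a single variable, cells are its states in order.
    """

    counts: np.ndarray
    cell_labels: list
    q: int = 1

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2 or self.counts.shape[0] != 2:
            raise ValueError("counts must be a 2 x C matrix")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if len(self.cell_labels) != self.counts.shape[1]:
            raise ValueError("cell_labels length must match column count")

    @property
    def n0(self) -> int:
        return int(self.counts[0].sum())

    @property
    def n1(self) -> int:
        return int(self.counts[1].sum())

    @property
    def n(self) -> int:
        return self.n0 + self.n1

    @property
    def C(self) -> int:
        return self.counts.shape[1]

    def to_tsv(self, path) -> None:
        import pandas as pd
        labels = ["/".join(map(str, c)) if isinstance(c, tuple) else str(c)
                  for c in self.cell_labels]
        pd.DataFrame(self.counts, index=["response0", "response1"],
                     columns=labels).to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "ContingencyTable":
        import pandas as pd
        df = pd.read_csv(path, sep="\t", index_col=0)
        labels = []
        for c in df.columns:
            parts = str(c).split("/")
            labels.append(tuple(int(p) for p in parts) if len(parts) > 1
                          else int(parts[0]))
        q = len(labels[0]) if labels and isinstance(labels[0], tuple) else 1
        return cls(df.to_numpy(), labels, q=q)


@dataclass
class ConditionalDistribution:
    """Estimated P(X) and P(Y|X) from grouped counts.

    ``marginal[i] = m_i / n`` and ``rows[i, j] = k_ij / m_i``; groups that were
    never observed (m_i = 0) have NaN rows and are flagged in ``undefined``.
    """

    marginal: np.ndarray
    rows: np.ndarray
    group_counts: np.ndarray
    joint_counts: np.ndarray
    undefined: np.ndarray


@dataclass
class TestResult:
    """Outcome of an independence / causal test."""

    statistic: float
    p_value: float
    method: str
    df: Optional[int] = None
    n_permutations: Optional[int] = None
    seed: Optional[int] = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")

    def to_tsv_row(self) -> str:
        fields = [f"{self.statistic:.10g}",
                  "" if self.df is None else str(self.df),
                  f"{self.p_value:.10g}", self.method,
                  "" if self.n_permutations is None else str(self.n_permutations),
                  "" if self.seed is None else str(self.seed)]
        return "\t".join(fields)


# ---------------------------------------------------------------------------
# counting
# ---------------------------------------------------------------------------

def joint_counts(sample: DiscreteSample) -> np.ndarray:
    """|X| x |Y| matrix of joint occurrence counts over declared supports."""
    r, c = sample.x_domain.m, sample.y_domain.m
    flat = np.bincount(sample.x * c + sample.y, minlength=r * c)
    return flat.reshape(r, c)


def tabulate(sample, response: Optional[np.ndarray] = None) -> ContingencyTable:
    """Build the genotype-by-response contingency table.

    Accepts either a :class:`DiscreteSample` (its y is the response) or a
    :class:`MultiSample` plus its binary response. Columns enumerate all
    3**q genotype combinations; empty cells are kept as zeros.
    """
    if isinstance(sample, MultiSample):
        if response is None:
            response = sample.y
        W = sample.W
        q = sample.q
        bad = (W < 0) | (W > 2)
        if bad.any():
            row = int(np.argwhere(bad.any(axis=1))[0][0])
            raise ValueError(f"genotype value outside {{0,1,2}} at row {row}")
        codes = sample.encoded()
        C = 3 ** q
        labels = list(itertools.product(range(3), repeat=q))
    else:
        if response is None:
            response = sample.y
        x = sample.x
        bad = (x < 0) | (x > 2)
        if bad.any():
            row = int(np.argwhere(bad)[0][0])
            raise ValueError(f"genotype value outside {{0,1,2}} at row {row}")
        codes = x
        q = 1
        C = 3
        labels = [0, 1, 2]
    response = np.asarray(response, dtype=np.int64)
    if not np.isin(response, (0, 1)).all():
        raise ValueError("response must be binary {0, 1}")
    counts = np.zeros((2, C), dtype=np.int64)
    np.add.at(counts, (response, codes), 1)
    return ContingencyTable(counts, labels, q=q)


def expected_counts(table: ContingencyTable) -> np.ndarray:
    """Expected cell counts under independence given the observed margins."""
    if table.n == 0:
        raise ValueError("empty table: n = 0")
    col = table.counts.sum(axis=0).astype(float)
    return np.vstack([table.n0 / table.n * col, table.n1 / table.n * col])


# ---------------------------------------------------------------------------
# independence tests
# ---------------------------------------------------------------------------

def chi_square_test(table: ContingencyTable,
                    df_convention: Literal["paper", "classical"] = "paper",
                    ) -> TestResult:
    """Pearson chi-square test of independence on a 2 x C genotype table.

    Cells whose column total is zero contribute nothing to the statistic and
    are excluded from the expected-count positivity check; the degrees of
    freedom stay at the full-table value (``paper``: 3**q - 1; ``classical``:
    (2-1)(C-1), identical for a 2-row table with all 3**q columns).
    """
    exp = expected_counts(table)
    keep = table.counts.sum(axis=0) > 0
    if not keep.any():
        raise ValueError("empty table")
    e = exp[:, keep]
    if np.any(e <= 0):
        raise ValueError(
            "a retained expected cell is zero (a response margin is empty); "
            "use fisher_exact instead")
    o = table.counts[:, keep].astype(float)
    statistic = float(((o - e) ** 2 / e).sum())
    if df_convention == "paper":
        df = 3 ** table.q - 1
    elif df_convention == "classical":
        df = table.C - 1
    else:
        raise ValueError(f"unknown df_convention {df_convention!r}")
    p = float(stats.chi2.sf(statistic, df))
    return TestResult(statistic, p, "chi_square", df=df)


def _fisher_mc(table: ContingencyTable, draws: int, seed: int) -> TestResult:
    """Monte-Carlo Fisher exact test for 2 x C tables (C > 2).

    Samples tables from the fixed-margin null (row 0 counts are multivariate
    hypergeometric given the column totals) and compares conditional table
    probabilities; p is add-one over the draws.
    """
    col = table.counts.sum(axis=0)
    keep = col > 0
    col = col[keep]
    obs0 = table.counts[0, keep]
    n0 = table.n0

    def log_prob(a0: np.ndarray) -> np.ndarray:
        # conditional probability of the row-0 vector given all margins
        from scipy.special import gammaln
        a0 = np.atleast_2d(a0)
        lp = (gammaln(col + 1).sum()
              - gammaln(a0 + 1).sum(axis=1)
              - gammaln(col - a0 + 1).sum(axis=1))
        return lp

    rng = np.random.default_rng(seed)
    sim0 = rng.multivariate_hypergeometric(col, n0, size=draws)
    lp_obs = log_prob(obs0)[0]
    lp_sim = log_prob(sim0)
    hits = int((lp_sim <= lp_obs + 1e-12).sum())
    p = (1 + hits) / (draws + 1)
    return TestResult(float(np.exp(lp_obs)), p, "fisher_mc",
                      n_permutations=draws, seed=seed)


def fisher_exact(table: ContingencyTable, seed: int = 0) -> TestResult:
    """Fisher's exact test of independence.

    2 x 2 tables use the exact hypergeometric enumeration; wider tables fall
    back to a seeded Monte-Carlo exact test conditioning on both margins.
    """
    col = table.counts.sum(axis=0)
    keep = col > 0
    kept = table.counts[:, keep]
    if kept.shape[1] <= 1 or table.n0 == 0 or table.n1 == 0:
        # no possible variation given the margins
        return TestResult(0.0, 1.0, "fisher_exact")
    if kept.shape[1] == 2:
        _, p = stats.fisher_exact(kept)
        return TestResult(0.0, float(p), "fisher_exact")
    return _fisher_mc(table, FISHER_MC_DRAWS, seed)


# ---------------------------------------------------------------------------
# entropies
# ---------------------------------------------------------------------------

def shannon_entropy(p) -> float:
    """Shannon entropy H1 = -sum p log2 p in bits (0 log 0 := 0)."""
    probs = p.probs if isinstance(p, PMF) else PMF(np.asarray(p, float)).probs
    pos = probs[probs > 0]
    return float(-(pos * np.log2(pos)).sum())


def renyi_entropy0(p, tol: float = H0_STATE_TOL) -> float:
    """Renyi entropy of order zero: log2 of the number of occupied states."""
    probs = p.probs if isinstance(p, PMF) else PMF(np.asarray(p, float)).probs
    k = int((probs > tol).sum())
    return float(np.log2(max(k, 1)))


# ---------------------------------------------------------------------------
# conditional estimation
# ---------------------------------------------------------------------------

def estimate_conditional(sample: DiscreteSample) -> ConditionalDistribution:
    """Estimate P(X) and the rows P(Y | X = x_i) by empirical frequencies."""
    k = joint_counts(sample)
    m = k.sum(axis=1)
    n = m.sum()
    undefined = m == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        rows = k / m[:, None]
    rows[undefined] = np.nan
    return ConditionalDistribution(marginal=m / n, rows=rows,
                                   group_counts=m, joint_counts=k,
                                   undefined=undefined)


# ---------------------------------------------------------------------------
# permutation engine
# ---------------------------------------------------------------------------

def permutation_pvalue(stat_fn: Callable[[DiscreteSample], float],
                       sample: DiscreteSample, B: int,
                       seed: int) -> TestResult:
    """Permutation p-value of ``stat_fn`` by shuffling y against x.

    Large observed statistics are evidence against the null; the returned
    p uses the add-one convention and is reproducible for a fixed seed.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    obs = float(stat_fn(sample))
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    hits = 0
    y = sample.y
    for _ in range(B):
        perm = DiscreteSample(sample.x, rng.permutation(y),
                              sample.x_domain, sample.y_domain)
        if float(stat_fn(perm)) >= obs:
            hits += 1
    p = (1 + hits) / (B + 1)
    return TestResult(obs, p, "permutation", n_permutations=B, seed=seed)


def randomized_tail_pvalue(obs: float, null: np.ndarray,
                           rng: np.random.Generator) -> float:
    """Exact upper-tail permutation p-value with randomized tie-splitting.

    Ranks the observed statistic among the permutation draws, breaking exact
    ties by iid uniform jitter (the classical randomized-test device). For a
    statistic whose null distribution has atoms — e.g. a best-fit contrast
    that is exactly zero for most permutations — the conventional ``>=`` rule
    is severely conservative, while the randomized rank is exactly uniform
    under exchangeability. Reproducible through ``rng``.
    """
    null = np.asarray(null, dtype=float)
    B = null.size
    u = rng.random(B + 1)
    beats = (null > obs) | ((null == obs) & (u[1:] > u[0]))
    return (1 + int(beats.sum())) / (B + 1)


def randomized_twosided_pvalue(obs: float, null: np.ndarray,
                               rng: np.random.Generator) -> float:
    """Equal-tail two-sided permutation p-value with randomized tie-splitting.

    Doubles the smaller of the two randomized tail probabilities (capped at
    1), for statistics whose interesting departures from the permutation
    null can go in either direction.
    """
    null = np.asarray(null, dtype=float)
    B = null.size
    u = rng.random(B + 1)
    above = (null > obs) | ((null == obs) & (u[1:] > u[0]))
    hi = (1 + int(above.sum())) / (B + 1)
    lo = (1 + B - int(above.sum())) / (B + 1)
    return min(1.0, 2.0 * min(hi, lo))


def sample_null_tables(counts: np.ndarray, B: int,
                       rng: np.random.Generator) -> np.ndarray:
    """Draw B joint count tables from the permutation (fixed-margin) null.

    Permuting y against x leaves both margins of the |X| x |Y| joint table
    fixed and makes every assignment of labels equally likely, so the null
    tables follow the multivariate hypergeometric law. For two y-states this
    is a single vectorized draw; more states are filled column by column.

    Returns an array of shape (B, |X|, |Y|).
    """
    counts = np.asarray(counts, dtype=np.int64)
    r, c = counts.shape
    row = counts.sum(axis=1)
    colsums = counts.sum(axis=0)
    out = np.empty((B, r, c), dtype=np.int64)
    if c == 2:
        ones = rng.multivariate_hypergeometric(row, int(colsums[1]), size=B)
        out[:, :, 1] = ones
        out[:, :, 0] = row[None, :] - ones
        return out
    remaining = np.broadcast_to(row, (B, r)).copy()
    for j in range(c - 1):
        nj = int(colsums[j])
        for b in range(B):
            draw = rng.multivariate_hypergeometric(remaining[b], nj)
            out[b, :, j] = draw
            remaining[b] -= draw
    out[:, :, c - 1] = remaining
    return out


def batch_chi2_stats(tables: np.ndarray) -> np.ndarray:
    """Vectorized Pearson chi-square statistics for a (B, r, c) table stack.

    Matches :func:`chi_square_test`'s conventions: cells whose expected count
    is zero (empty rows or columns) contribute nothing to the sum.
    """
    t = np.asarray(tables, dtype=float)
    rowt = t.sum(axis=2, keepdims=True)
    colt = t.sum(axis=1, keepdims=True)
    n = rowt.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        exp = rowt * colt / n
        contrib = (t - exp) ** 2 / exp
    contrib = np.where(exp > 0, contrib, 0.0)
    return contrib.sum(axis=(1, 2))


def batch_chi2_pvalues(tables: np.ndarray,
                       df: Optional[int] = None) -> np.ndarray:
    """Vectorized Pearson chi-square p-values for a (B, r, c) stack of tables.

    Zero-expected cells are dropped from the sum while the degrees of
    freedom stay at the full-table value; df defaults to the classical
    (r-1)(c-1).
    """
    B, r, c = np.asarray(tables).shape
    if df is None:
        df = (r - 1) * (c - 1)
    return stats.chi2.sf(batch_chi2_stats(tables), df)
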