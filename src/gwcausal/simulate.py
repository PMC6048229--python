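"""Scenario generators and the benchmark harness.

Three generator families cover the study designs the causal tests are
evaluated on:

``anm_pair``
    cyclic additive-noise pairs: random non-constant f, random cause pmf,
    random noise pmf with bounded support |N| and its mode at 0; ground
    truth X -> Y.
``random_joint``
    random discrete joints P(X) . P(Y|X) with P(X) and every conditional row
    drawn from a flat Dirichlet over the configured state sizes; ground
    truth X -> Y.
``geno_null`` / ``geno_assoc_only`` / ``geno_assoc_causal``
    genotype-trait data: a biallelic SNP under Hardy-Weinberg equilibrium
    and a binary trait that is independent of it, associated with it only
    through a latent binary confounder, or caused by it through a penetrance
    vector (a cyclic ANM with a 3-cyclic cause and 2-cyclic effect).

The benchmark harness scores direction accuracy (forced choice, as
cause-effect-pair benchmarks are scored) or rejection rates of the three
permutation causal tests, with Monte-Carlo standard errors.
"""

from __future__ import annotations

import dataclasses
import time
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd

from .anm import ANMConfig, _best_dm_from_joint, batch_dm_contrast, fit_anm
from .discrete_core import (
    DiscreteSample,
    DomainSpec,
    GENOTYPE_DOMAIN,
    TRAIT_DOMAIN,
    joint_counts,
    randomized_tail_pvalue,
    randomized_twosided_pvalue,
    sample_null_tables,
)
from .distcorr import batch_tc, _batch_delta
from .entropy import batch_entropy_contrast

#: cyclic support size shared by both variables in the anm_pair scenarios;
#: large enough to hold every studied noise support |N| in {2, 3, 5, 7}
ANM_PAIR_STATES = 7

ScenarioKind = Literal["anm_pair", "random_joint", "geno_null",
                       "geno_assoc_only", "geno_assoc_causal"]


@dataclass
class ScenarioConfig:
    """Parameters of one simulation scenario.

    ``maf=None`` draws the minor-allele frequency afresh from Uniform(0.1,
    0.5) per sample, which is how the benchmark emulates SNPs spread across
    the genome. ``penetrance`` is P(disease | genotype) for genotypes 0/1/2.
    ``confounder_strength`` shifts both the MAF and the trait risk by +-s
    depending on a latent binary confounder (s = 0.135 gives a marginal
    allele-disease odds ratio of about 1.5 with the default MAF/prevalence).
    """

    kind: ScenarioKind
    n: int
    noise_support: int = 2
    state_sizes: tuple[int, int] = (12, 12)
    maf: Optional[float] = 0.3
    penetrance: tuple[float, float, float] = (0.1, 0.3, 0.6)
    confounder_strength: float = 0.135
    prevalence: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 10:
            raise ValueError("n must be >= 10")
        if self.maf is not None and not (0.0 < self.maf <= 0.5):
            raise ValueError("maf must lie in (0, 0.5]")
        if not (0.0 <= self.prevalence <= 1.0):
            raise ValueError("prevalence must lie in [0, 1]")
        if any(not (0.0 <= p <= 1.0) for p in self.penetrance):
            raise ValueError("penetrance entries must lie in [0, 1]")
        if self.noise_support < 2:
            raise ValueError("noise support must be >= 2")


@dataclass
class BenchmarkResult:
    """Per-scenario, per-method rates with Monte-Carlo standard errors."""

    rows: list[dict]
    reps: int
    B: int
    seed: int
    elapsed_s: float = 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)

    def rate(self, method: str, *, kind: Optional[str] = None,
             n: Optional[int] = None, alpha: Optional[float] = None) -> float:
        df = self.to_frame()
        m = df["method"] == method
        if kind is not None:
            m &= df["kind"] == kind
        if n is not None:
            m &= df["n"] == n
        if alpha is not None:
            m &= df["alpha"] == alpha
        sub = df[m]
        if len(sub) != 1:
            raise KeyError("query does not identify a unique benchmark row")
        return float(sub["rate"].iloc[0])


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def _hwe_probs(maf: float) -> np.ndarray:
    q = maf
    return np.array([(1 - q) ** 2, 2 * q * (1 - q), q ** 2])


def gen_anm_pair(cfg: ScenarioConfig,
                 rng: Optional[np.random.Generator] = None
                 ) -> DiscreteSample:
    """Draw one cyclic ANM sample; ground-truth direction is X -> Y."""
    if cfg.kind != "anm_pair":
        raise ValueError("config kind must be 'anm_pair'")
    m = k = ANM_PAIR_STATES
    if cfg.noise_support > k:
        raise ValueError(f"noise support must be <= {k}")
    rng = rng or np.random.default_rng(np.random.SeedSequence(cfg.seed))
    px = rng.dirichlet(np.ones(m))
    while True:
        f = rng.integers(0, k, size=m)
        if np.unique(f).size > 1:  # reject trivially symmetric constant f
            break
    noise_pmf = rng.dirichlet(np.ones(cfg.noise_support))
    top = int(noise_pmf.argmax())  # enforce the mode-at-zero noise convention
    noise_pmf[0], noise_pmf[top] = noise_pmf[top], noise_pmf[0]
    x = rng.choice(m, size=cfg.n, p=px)
    noise = rng.choice(cfg.noise_support, size=cfg.n, p=noise_pmf)
    y = (f[x] + noise) % k
    return DiscreteSample(x, y, DomainSpec("cyclic", m), DomainSpec("cyclic", k))


def gen_random_joint(cfg: ScenarioConfig,
                     rng: Optional[np.random.Generator] = None
                     ) -> DiscreteSample:
    """Draw one sample from a random joint P(X) . P(Y|X); truth is X -> Y."""
    if cfg.kind != "random_joint":
        raise ValueError("config kind must be 'random_joint'")
    mx, my = cfg.state_sizes
    rng = rng or np.random.default_rng(np.random.SeedSequence(cfg.seed))
    px = rng.dirichlet(np.ones(mx))
    rows = rng.dirichlet(np.ones(my), size=mx)
    x = rng.choice(mx, size=cfg.n, p=px)
    cum = rows.cumsum(axis=1)
    y = (rng.random(cfg.n)[:, None] > cum[x]).sum(axis=1)
    return DiscreteSample(x, y, DomainSpec("cyclic", mx),
                          DomainSpec("cyclic", my))


def gen_genotype_trait(cfg: ScenarioConfig,
                       rng: Optional[np.random.Generator] = None
                       ) -> DiscreteSample:
    """Draw one genotype-trait sample under the configured scenario."""
    if cfg.kind not in ("geno_null", "geno_assoc_only", "geno_assoc_causal"):
        raise ValueError("config kind must be a geno_* scenario")
    rng = rng or np.random.default_rng(np.random.SeedSequence(cfg.seed))
    maf = cfg.maf if cfg.maf is not None else rng.uniform(0.1, 0.5)
    n = cfg.n
    if cfg.kind == "geno_null":
        g = rng.choice(3, size=n, p=_hwe_probs(maf))
        y = rng.binomial(1, cfg.prevalence, size=n)
    elif cfg.kind == "geno_assoc_only":
        s = cfg.confounder_strength
        u = rng.integers(0, 2, size=n)
        maf_u = np.clip(maf + s * (2 * u - 1), 0.01, 0.99)
        alleles = rng.random((n, 2)) < maf_u[:, None]
        g = alleles.sum(axis=1)
        risk_u = np.clip(cfg.prevalence + s * (2 * u - 1), 0.0, 1.0)
        y = rng.binomial(1, risk_u)
    else:  # geno_assoc_causal: a cyclic ANM through the penetrance vector
        g = rng.choice(3, size=n, p=_hwe_probs(maf))
        pen = np.asarray(cfg.penetrance, dtype=float)
        y = rng.binomial(1, pen[g])
    return DiscreteSample(g, y, GENOTYPE_DOMAIN, TRAIT_DOMAIN)


def generate(cfg: ScenarioConfig,
             rng: Optional[np.random.Generator] = None) -> DiscreteSample:
    """Dispatch to the generator matching ``cfg.kind``."""
    if cfg.kind == "anm_pair":
        return gen_anm_pair(cfg, rng)
    if cfg.kind == "random_joint":
        return gen_random_joint(cfg, rng)
    return gen_genotype_trait(cfg, rng)


# ---------------------------------------------------------------------------
# forced-choice direction calls (accuracy mode)
# ---------------------------------------------------------------------------

def _anm_forced_choice(sample: DiscreteSample, config: ANMConfig) -> bool:
    """True when the forward ANM attains the smaller dependence measure.

    Uses the chi-square-statistic scale, which keeps discriminating when the
    dependence in both directions is strong enough for p-values to underflow.
    """
    joint = joint_counts(sample)
    fwd = _best_dm_from_joint(joint, sample.y_domain, config)
    bwd = _best_dm_from_joint(joint.T.copy(), sample.x_domain, config)
    return fwd < bwd


def _entropy_forced_choice(sample: DiscreteSample) -> bool:
    contrast = float(batch_entropy_contrast(joint_counts(sample)[None])[0])
    return contrast > 0  # H1 backward exceeds H1 forward


def _dc_forced_choice(sample: DiscreteSample) -> bool:
    t = joint_counts(sample)[None].astype(float)
    rowm = t[0].sum(axis=1) > 0
    colm = t[0].sum(axis=0) > 0
    t = t[:, rowm][:, :, colm]
    n = t.sum()
    dxy = _batch_delta(t.sum(axis=2) / n, t / t.sum(axis=2, keepdims=True))[0]
    tt = np.swapaxes(t, 1, 2)
    dyx = _batch_delta(tt.sum(axis=2) / n,
                       tt / tt.sum(axis=2, keepdims=True))[0]
    return dxy > dyx


#: batch statistic and tail convention per method tag (the entropy contrast
#: is tested two-sided; the ANM contrast and T_C are upper-tail)
_NULL_STATS = {
    "anm_perm": (batch_dm_contrast, "upper"),
    "anm_entropy": (batch_entropy_contrast, "two_sided"),
    "dc": (batch_tc, "upper"),
}


# ---------------------------------------------------------------------------
# benchmark harness
# ---------------------------------------------------------------------------

def run_benchmark(cfgs: Sequence[ScenarioConfig],
                  methods: Sequence[str] = ("anm_perm", "anm_entropy", "dc"),
                  reps: int = 1000,
                  alpha_levels: Sequence[float] = (0.05, 0.01),
                  B: int = 999,
                  seed: int = 0,
                  anm_config: Optional[ANMConfig] = None) -> BenchmarkResult:
    """Monte-Carlo benchmark over scenarios.

    For ``anm_pair`` / ``random_joint`` scenarios the score is forced-choice
    direction accuracy; for ``geno_*`` scenarios it is the rejection rate of
    each permutation causal test at every requested alpha (the three tests
    share one stack of null tables per replicate, which is exact because the
    permutation null conditions only on the table margins).
    """
    if reps < 10:
        raise ValueError("reps must be >= 10")
    unknown = set(methods) - set(_NULL_STATS)
    if unknown:
        raise ValueError(f"unknown method tag(s): {sorted(unknown)}")
    anm_config = anm_config or ANMConfig()
    t0 = time.perf_counter()
    rows: list[dict] = []
    master = np.random.SeedSequence(seed)
    # common random numbers: the same replicate streams are reused for every
    # scenario, so curves across sample sizes share MAF/effect draws and
    # monotone trends are not washed out by independent Monte-Carlo noise
    rep_seeds = master.spawn(reps)
    for cfg in cfgs:
        accuracy_mode = cfg.kind in ("anm_pair", "random_joint")
        rep_rngs = [np.random.default_rng(s) for s in rep_seeds]
        if accuracy_mode:
            correct = {m: 0 for m in methods}
            for rng in rep_rngs:
                sample = generate(cfg, rng)
                if "anm_perm" in methods and _anm_forced_choice(sample, anm_config):
                    correct["anm_perm"] += 1
                if "anm_entropy" in methods and _entropy_forced_choice(sample):
                    correct["anm_entropy"] += 1
                if "dc" in methods and _dc_forced_choice(sample):
                    correct["dc"] += 1
            for m in methods:
                rate = correct[m] / reps
                rows.append(dict(kind=cfg.kind, n=cfg.n, method=m, alpha=None,
                                 mode="accuracy", rate=rate,
                                 se=float(np.sqrt(rate * (1 - rate) / reps)),
                                 reps=reps, B=None))
        else:
            rejects = {(m, a): 0 for m in methods for a in alpha_levels}
            for rng in rep_rngs:
                sample = generate(cfg, rng)
                joint = joint_counts(sample)
                tables = sample_null_tables(joint, B, rng)
                for m in methods:
                    stat, tail = _NULL_STATS[m]
                    obs = float(stat(joint[None])[0])
                    null = stat(tables)
                    if tail == "two_sided":
                        p = randomized_twosided_pvalue(obs, null, rng)
                    else:
                        p = randomized_tail_pvalue(obs, null, rng)
                    for a in alpha_levels:
                        if p <= a:
                            rejects[(m, a)] += 1
            for m in methods:
                for a in alpha_levels:
                    rate = rejects[(m, a)] / reps
                    rows.append(dict(kind=cfg.kind, n=cfg.n, method=m,
                                     alpha=a, mode="rejection", rate=rate,
                                     se=float(np.sqrt(rate * (1 - rate) / reps)),
                                     reps=reps, B=B))
    return BenchmarkResult(rows, reps=reps, B=B, seed=seed,
                           elapsed_s=time.perf_counter() - t0)
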