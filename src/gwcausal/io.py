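"""Genotype/phenotype file I/O and the per-SNP causal scan.

The scan mirrors how a genome-wide causal study runs in practice: for every
biallelic variant, test genotype-trait association (Pearson chi-square on
the 2 x 3 contingency table), then apply the three causal tests — ANM
permutation, entropy contrast, distance-correlation T_C — each with its own
permutation null, and report per-variant p-values with a multiple-testing
threshold across variants. Distance-correlation results on 3-state
genotypes are marked advisory (the contrast needs a cause with more states
to be informative).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np
import pandas as pd

from . import __version__
from .anm import ANMConfig, anm_permutation_test, decide_direction
from .discrete_core import (
    DiscreteSample,
    GENOTYPE_DOMAIN,
    TRAIT_DOMAIN,
    chi_square_test,
    tabulate,
)
from .distcorr import tc_causal_test
from .entropy import entropy_permutation_test

logger = logging.getLogger("gwcausal")

SCAN_COLUMNS = ["chrom", "pos", "id", "n_used", "p_association", "p_anm",
                "p_anm_entropy", "p_dc", "dc_advisory", "verdict",
                "causal_significant", "B", "seed"]


@dataclass
class GenotypeDataset:
    """Biallelic genotype matrix with variant and sample metadata.

    ``G`` is n_samples x n_variants with minor/alt-allele dosages 0/1/2 and
    NaN for missing calls.
    """

    sample_ids: list[str]
    variants: pd.DataFrame  # columns: chrom, pos, id, ref, alt
    G: np.ndarray
    n_skipped_multiallelic: int = 0

    @property
    def n_samples(self) -> int:
        return self.G.shape[0]

    @property
    def n_variants(self) -> int:
        return self.G.shape[1]


@dataclass
class ScanConfig:
    """Settings for the per-variant causal scan."""

    B: int = 10_000
    seed: int = 0
    alpha: float = 0.05
    multiple_testing: Literal["bonferroni", "fdr"] = "bonferroni"
    max_missing: float = 0.05
    anm: ANMConfig = field(default_factory=ANMConfig)

    def digest(self) -> str:
        payload = json.dumps({
            "B": self.B, "seed": self.seed, "alpha": self.alpha,
            "multiple_testing": self.multiple_testing,
            "max_missing": self.max_missing,
            "anm": vars(self.anm)}, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class ScanResult:
    """Per-variant scan rows plus the global testing configuration."""

    table: pd.DataFrame
    alpha: float
    threshold: float
    multiple_testing: str
    config_digest: str
    seed: int

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# gwcausal {__version__}\n")
            fh.write(f"# config {self.config_digest} seed {self.seed}\n")
            fh.write(f"# multiple_testing {self.multiple_testing} "
                     f"alpha {self.alpha} threshold {self.threshold:.6g}\n")
            self.table.to_csv(fh, sep="\t", index=False)


def read_scan_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_genotypes(path, format: Literal["auto", "vcf", "tsv"] = "auto"
                   ) -> GenotypeDataset:
    """Read a genotype matrix from VCF or TSV.

    VCF: biallelic SNPs only (multiallelic records are skipped and counted);
    GT is converted to alt-allele dosage, missing calls to NaN. TSV: header
    of variant ids, first column sample ids, cells 0/1/2 or blank.
    """
    path = str(path)
    if format == "auto":
        format = "vcf" if path.endswith((".vcf", ".vcf.gz", ".bcf")) else "tsv"
    if format == "vcf":
        return _read_vcf(path)
    return _read_tsv(path)


def _read_vcf(path: str) -> GenotypeDataset:
    from cyvcf2 import VCF
    vcf = VCF(path)
    samples = list(vcf.samples)
    cols, meta = [], []
    skipped = 0
    for v in vcf:
        if len(v.ALT) != 1:
            skipped += 1
            continue
        dos = np.empty(len(samples))
        for i, g in enumerate(v.genotypes):
            a = g[:-1]
            dos[i] = np.nan if any(x < 0 for x in a) else float(sum(
                1 for x in a if x > 0))
        cols.append(dos)
        meta.append((v.CHROM, v.POS, v.ID or f"{v.CHROM}:{v.POS}",
                     v.REF, v.ALT[0]))
    if skipped:
        logger.info("skipped %d multiallelic record(s)", skipped)
    G = np.column_stack(cols) if cols else np.empty((len(samples), 0))
    variants = pd.DataFrame(meta, columns=["chrom", "pos", "id", "ref", "alt"])
    return GenotypeDataset(samples, variants, G,
                           n_skipped_multiallelic=skipped)


def _read_tsv(path: str) -> GenotypeDataset:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    G = np.full(df.shape, np.nan)
    for j, col in enumerate(df.columns):
        for i, val in enumerate(df[col]):
            if pd.isna(val) or str(val).strip() == "":
                continue
            try:
                d = int(val)
            except ValueError:
                raise ValueError(
                    f"malformed genotype {val!r} at line {i + 2} "
                    f"column {col!r}") from None
            if d not in (0, 1, 2):
                raise ValueError(f"genotype {d} outside {{0,1,2}} at "
                                 f"line {i + 2} column {col!r}")
            G[i, j] = d
    variants = pd.DataFrame({
        "chrom": ".", "pos": 0, "id": list(df.columns),
        "ref": ".", "alt": "."})
    return GenotypeDataset([str(s) for s in df.index], variants, G)


def write_genotypes_tsv(ds: GenotypeDataset, path) -> None:
    df = pd.DataFrame(ds.G, index=ds.sample_ids,
                      columns=ds.variants["id"].tolist())
    df = df.map(lambda v: "" if np.isnan(v) else str(int(v)))
    df.index.name = "sample"
    df.to_csv(path, sep="\t")


def read_phenotype(path) -> pd.Series:
    """Read a two-column TSV of (sample id, binary status)."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise ValueError("phenotype file must have two columns: id, status")
    # tolerate a header line
    if str(df.iloc[0, 1]).strip() not in ("0", "1"):
        df = df.iloc[1:]
    ids = df.iloc[:, 0].astype(str).tolist()
    raw = df.iloc[:, 1].astype(str).str.strip()
    if not raw.isin(["0", "1"]).all():
        bad = raw[~raw.isin(["0", "1"])].iloc[0]
        raise ValueError(f"non-binary phenotype status {bad!r}")
    return pd.Series(raw.astype(int).to_numpy(), index=ids, name="status")


def align_phenotype(ds: GenotypeDataset, pheno: pd.Series
                    ) -> tuple[GenotypeDataset, np.ndarray]:
    """Intersect genotype and phenotype sample ids; log mismatches."""
    common = [s for s in ds.sample_ids if s in pheno.index]
    dropped = len(set(pheno.index)) - len(common)
    if dropped > 0:
        logger.warning("%d phenotype id(s) absent from genotype data",
                       dropped)
    if len(common) < len(ds.sample_ids):
        logger.warning("%d genotyped sample(s) lack phenotype",
                       len(ds.sample_ids) - len(common))
    if not common:
        raise ValueError("no overlapping sample ids between genotypes "
                         "and phenotypes")
    idx = [ds.sample_ids.index(s) for s in common]
    sub = GenotypeDataset(common, ds.variants, ds.G[idx],
                          ds.n_skipped_multiallelic)
    return sub, pheno.loc[common].to_numpy()


# ---------------------------------------------------------------------------
# the scan
# ---------------------------------------------------------------------------

def scan_variant(g: np.ndarray, y: np.ndarray, B: int, seed: int,
                 anm_config: Optional[ANMConfig] = None) -> dict:
    """All four tests for one variant (complete genotype/trait pairs)."""
    anm_config = anm_config or ANMConfig()
    sample = DiscreteSample(g.astype(np.int64), y.astype(np.int64),
                            GENOTYPE_DOMAIN, TRAIT_DOMAIN)
    assoc = chi_square_test(tabulate(sample),
                            df_convention=anm_config.df_convention)
    ss = np.random.SeedSequence(seed).spawn(3)
    child = [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss]
    p_anm = anm_permutation_test(sample, anm_config, B=B, seed=child[0])
    p_ent = entropy_permutation_test(sample, B=B, seed=child[1])
    tc = tc_causal_test(sample, B=B, seed=child[2])
    verdict = decide_direction(sample, anm_config).verdict
    return dict(n_used=sample.n, p_association=assoc.p_value,
                p_anm=p_anm.p_value, p_anm_entropy=p_ent.p_value,
                p_dc=tc.p_value, dc_advisory=True, verdict=verdict,
                B=B, seed=seed)


def scan(ds: GenotypeDataset, pheno: pd.Series,
         config: Optional[ScanConfig] = None,
         out: Optional[str] = None) -> ScanResult:
    """Per-variant association + causal tests across a genotype dataset.

    Variants with more than ``max_missing`` missing calls are excluded and
    reported with verdict ``excluded_qc`` (never silently dropped);
    remaining missing calls are dropped pairwise per variant. The causal
    significance column applies the configured multiple-testing correction
    across tested variants. Rows are streamed to ``out`` as they complete
    when a path is given.
    """
    config = config or ScanConfig()
    ds, y = align_phenotype(ds, pheno)
    V = ds.n_variants
    if V < 1:
        raise ValueError("no variants to scan")
    threshold = config.alpha / V if config.multiple_testing == "bonferroni" \
        else config.alpha
    seeds = np.random.SeedSequence(config.seed).spawn(V)
    rows = []
    stream = open(out, "w") if out else None
    try:
        if stream:
            stream.write(f"# gwcausal {__version__} config {config.digest()} "
                         f"seed {config.seed}\n")
            stream.write("\t".join(SCAN_COLUMNS) + "\n")
        for j in range(V):
            meta = ds.variants.iloc[j]
            g = ds.G[:, j]
            ok = ~np.isnan(g)
            row = dict(chrom=meta["chrom"], pos=meta["pos"], id=meta["id"])
            if 1 - ok.mean() > config.max_missing:
                row.update(n_used=int(ok.sum()), p_association=np.nan,
                           p_anm=np.nan, p_anm_entropy=np.nan, p_dc=np.nan,
                           dc_advisory=True, verdict="excluded_qc",
                           causal_significant=False, B=config.B,
                           seed=config.seed)
            else:
                vseed = int(seeds[j].generate_state(1)[0] % (2 ** 31))
                row.update(scan_variant(g[ok], y[ok], config.B, vseed,
                                        config.anm))
                row["causal_significant"] = bool(row["p_anm"] <= threshold)
            rows.append(row)
            if stream:
                stream.write("\t".join(str(row[c]) for c in SCAN_COLUMNS)
                             + "\n")
                stream.flush()
    finally:
        if stream:
            stream.close()
    table = pd.DataFrame(rows, columns=SCAN_COLUMNS)
    if config.multiple_testing == "fdr":
        from scipy.stats import false_discovery_control
        tested = table["p_anm"].notna()
        q = np.full(len(table), np.nan)
        if tested.any():
            q[tested.to_numpy()] = false_discovery_control(
                table.loc[tested, "p_anm"].to_numpy())
        table["q_anm"] = q
        table["causal_significant"] = pd.Series(q) <= config.alpha
    return ScanResult(table, config.alpha, threshold,
                      config.multiple_testing, config.digest(), config.seed)
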