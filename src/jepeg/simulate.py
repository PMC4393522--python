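"""Synthetic panels, GWAS summary statistics and toy annotation databases.

The generators reproduce the statistical structure the method assumes, at
desk scale:

* ``simulate_panel`` draws haplotypes from a latent Gaussian AR(1) process
  thresholded at MAF-derived quantiles, giving controllable exponentially
  decaying LD; two haplotypes are summed to an ALT dosage.  Locus-level
  properties (positions, alleles, MAFs) are controlled by ``locus_seed`` so
  that a GWAS cohort source and a differently seeded analysis panel represent
  different samples from the same population -- the same-population LD
  mismatch a summary-statistics method faces when its reference panel is not
  the study cohort.
* ``simulate_null_gwas`` / ``simulate_alt_gwas`` resample a cohort with
  replacement from a super-panel, attach a phenotype (standard-normal
  continuous, or balanced case/control), and compute per-SNP Wald Z-scores
  from simple linear or logistic regression on dosage.
* ``make_toy_db`` fabricates valid annotation databases with signed weights.
* ``type_one_error_experiment`` runs the full pipeline on null replicates
  (with a fraction of functional SNPs hidden to exercise imputation) and
  tabulates empirical gene-level type-I error.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit, logit

from .annotation import CATEGORIES, AnnotationDB, FunctionalAnnotation
from .data_io import GenotypePanel, SummaryDataset, SummaryRecord, harmonize
from .genetest import run_jepeg

log = logging.getLogger(__name__)

# non-strand-ambiguous allele pairs, cycled deterministically along the locus
_ALLELE_CYCLE = [
    ("A", "G"),
    ("C", "T"),
    ("G", "A"),
    ("T", "C"),
    ("A", "C"),
    ("G", "T"),
    ("C", "A"),
    ("T", "G"),
]

__all__ = [
    "SimConfig",
    "simulate_panel",
    "simulate_null_gwas",
    "simulate_alt_gwas",
    "make_toy_db",
    "make_structured_db",
    "type_one_error_experiment",
    "power_experiment",
    "write_fixture_set",
]


@dataclass(frozen=True)
class SimConfig:
    """Desk-scale study conditions for the simulation experiments.

    ``seed`` controls which individuals are sampled; ``locus_seed`` (defaults
    to ``seed``) controls population-level locus properties and must be
    shared between panels meant to represent the same population.
    """

    n_panel: int = 500
    n_gwas: int = 2000
    n_snps: int = 500
    ld_decay: float = 0.95
    maf_range: tuple[float, float] = (0.05, 0.5)
    phenotype: str = "continuous"
    case_fraction: float = 0.5
    seed: int = 0
    locus_seed: int | None = None
    chrom: str = "1"
    spacing_bp: int = 2000

    def __post_init__(self):
        if self.phenotype not in ("continuous", "binary"):
            raise ValueError("phenotype must be continuous or binary")
        if not (0 < self.ld_decay < 1 or self.ld_decay == 0):
            raise ValueError("ld_decay must lie in [0, 1)")
        if self.maf_range[0] < 0.01 or self.maf_range[1] > 0.5:
            raise ValueError("maf_range must lie within [0.01, 0.5]")
        if min(self.n_panel, self.n_gwas, self.n_snps) < 1:
            raise ValueError("sizes must be positive")


def _locus(cfg: SimConfig):
    """Population-level locus definition shared across panels."""
    lseed = cfg.seed if cfg.locus_seed is None else cfg.locus_seed
    rng = np.random.default_rng(lseed)
    mafs = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], cfg.n_snps)
    pos = cfg.spacing_bp * (1 + np.arange(cfg.n_snps))
    alleles = [_ALLELE_CYCLE[i % len(_ALLELE_CYCLE)] for i in range(cfg.n_snps)]
    ids = [f"snp{cfg.chrom}_{p}" for p in pos]
    return ids, pos, alleles, mafs


def _haplotypes(n_hap: int, mafs: np.ndarray, rho: float, rng) -> np.ndarray:
    """Threshold a latent AR(1) Gaussian at Phi^{-1}(maf) per SNP."""
    m = len(mafs)
    thresh = stats.norm.ppf(mafs)
    hap = np.empty((n_hap, m), dtype=np.int8)
    x = rng.standard_normal(n_hap)
    hap[:, 0] = x < thresh[0]
    innov_sd = np.sqrt(1.0 - rho * rho)
    for j in range(1, m):
        x = rho * x + innov_sd * rng.standard_normal(n_hap)
        hap[:, j] = x < thresh[j]
    return hap


def simulate_panel(cfg: SimConfig, seed: int | None = None, n_samples: int | None = None) -> GenotypePanel:
    """Draw a genotype panel of ``n_samples`` (default ``cfg.n_panel``)."""
    ids, pos, alleles, mafs = _locus(cfg)
    n = cfg.n_panel if n_samples is None else n_samples
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    dos = (
        _haplotypes(n, mafs, cfg.ld_decay, rng).astype(float)
        + _haplotypes(n, mafs, cfg.ld_decay, rng)
    )
    # guard against (vanishingly rare) monomorphic draws so LD stays defined
    var0 = dos.var(axis=0) <= 0
    if var0.any():
        for j in np.nonzero(var0)[0]:
            dos[0, j] = 1.0 if dos[1, j] != 1.0 else 2.0
    return GenotypePanel(
        snp_ids=list(ids),
        chrom=np.array([cfg.chrom] * cfg.n_snps, dtype=object),
        pos=np.asarray(pos),
        ref=[a[0] for a in alleles],
        alt=[a[1] for a in alleles],
        dosages=dos,
    )


# ---------------------------------------------------------------------------
# per-SNP association scans


def _ols_wald_z(G: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Wald Z (t statistic) of the slope in y ~ 1 + g, vectorized over SNPs."""
    n = len(y)
    gc = G - G.mean(axis=0)
    yc = y - y.mean()
    sg = np.sqrt((gc**2).sum(axis=0))
    sy = np.sqrt((yc**2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (gc * yc[:, None]).sum(axis=0) / (sg * sy)
        z = r * np.sqrt((n - 2) / (1.0 - r**2))
    z[sg == 0] = np.nan
    return z


def _logistic_wald_z(
    G: np.ndarray, y: np.ndarray, max_iter: int = 30, tol: float = 1e-8, chunk: int = 512
) -> np.ndarray:
    """Wald Z of the slope in logit P(y=1) = b0 + b1 g, per SNP.

    Newton-Raphson on the two-parameter model, vectorized across SNPs in
    chunks; non-converged fits return NaN.
    """
    y = np.asarray(y, dtype=float)
    out = np.empty(G.shape[1])
    for lo in range(0, G.shape[1], chunk):
        g = G[:, lo : lo + chunk]
        mcols = g.shape[1]
        b0 = np.full(mcols, logit(np.clip(y.mean(), 1e-9, 1 - 1e-9)))
        b1 = np.zeros(mcols)
        ok = np.ones(mcols, dtype=bool)
        converged = np.zeros(mcols, dtype=bool)
        for _ in range(max_iter):
            p = expit(b0 + b1 * g)
            w = p * (1.0 - p)
            resid = y[:, None] - p
            s0 = resid.sum(axis=0)
            s1 = (g * resid).sum(axis=0)
            i00 = w.sum(axis=0)
            i01 = (w * g).sum(axis=0)
            i11 = (w * g * g).sum(axis=0)
            det = i00 * i11 - i01 * i01
            ok &= det > 1e-12
            with np.errstate(divide="ignore", invalid="ignore"):
                d0 = np.where(ok, (i11 * s0 - i01 * s1) / det, 0.0)
                d1 = np.where(ok, (-i01 * s0 + i00 * s1) / det, 0.0)
            b0 += d0
            b1 += d1
            converged = ok & (np.maximum(np.abs(d0), np.abs(d1)) < tol)
            if converged.all():
                break
        p = expit(b0 + b1 * g)
        w = p * (1.0 - p)
        i00 = w.sum(axis=0)
        i01 = (w * g).sum(axis=0)
        i11 = (w * g * g).sum(axis=0)
        det = i00 * i11 - i01 * i01
        good = converged & (det > 1e-12)
        with np.errstate(divide="ignore", invalid="ignore"):
            se1 = np.sqrt(np.where(good, i00 / det, np.nan))
            out[lo : lo + chunk] = np.where(good, b1 / se1, np.nan)
    return out


def _scan_to_dataset(panel: GenotypePanel, z: np.ndarray, n: int) -> SummaryDataset:
    records = []
    n_drop = 0
    for j, zj in enumerate(z):
        if not np.isfinite(zj):
            n_drop += 1
            continue
        records.append(
            SummaryRecord(
                snp_id=panel.snp_ids[j],
                chrom=str(panel.chrom[j]),
                pos=int(panel.pos[j]),
                allele_effect=panel.alt[j],
                allele_other=panel.ref[j],
                zscore=float(zj),
            )
        )
    if n_drop:
        log.warning("association scan: dropped %d SNPs (degenerate/non-converged)", n_drop)
    return SummaryDataset(records, gwas_n=n)


def _draw_cohort(source: GenotypePanel, cfg: SimConfig, rng) -> np.ndarray:
    idx = rng.integers(0, source.n_samples, cfg.n_gwas)
    return source.dosages[idx]


def _phenotype(cfg: SimConfig, rng, linpred: np.ndarray | None = None) -> np.ndarray:
    n = cfg.n_gwas
    if cfg.phenotype == "continuous":
        y = rng.standard_normal(n)
        return y if linpred is None else y + linpred
    if linpred is None:
        y = np.zeros(n)
        y[rng.permutation(n)[: int(round(cfg.case_fraction * n))]] = 1.0
        return y
    b0 = logit(np.clip(cfg.case_fraction, 1e-9, 1 - 1e-9)) - linpred.mean()
    return (rng.random(n) < expit(b0 + linpred)).astype(float)


def simulate_null_gwas(source: GenotypePanel, cfg: SimConfig, seed: int | None = None) -> SummaryDataset:
    """Null GWAS: phenotype independent of genotype, per-SNP regression Z."""
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    G = _draw_cohort(source, cfg, rng)
    y = _phenotype(cfg, rng)
    z = _ols_wald_z(G, y) if cfg.phenotype == "continuous" else _logistic_wald_z(G, y)
    return _scan_to_dataset(source, z, cfg.n_gwas)


def simulate_alt_gwas(
    source: GenotypePanel,
    cfg: SimConfig,
    effects: Sequence[tuple[str, float]],
    seed: int | None = None,
) -> SummaryDataset:
    """GWAS with planted additive effects: linear predictor sum(beta * dosage)."""
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    G = _draw_cohort(source, cfg, rng)
    linpred = np.zeros(cfg.n_gwas)
    for sid, beta in effects:
        linpred += beta * G[:, source.index_of(sid)]
    y = _phenotype(cfg, rng, linpred)
    z = _ols_wald_z(G, y) if cfg.phenotype == "continuous" else _logistic_wald_z(G, y)
    return _scan_to_dataset(source, z, cfg.n_gwas)


# ---------------------------------------------------------------------------
# toy annotation databases


def _entry(panel: GenotypePanel, j: int, gene: str, category: str, weight: float):
    return FunctionalAnnotation(
        snp_id=panel.snp_ids[j],
        chrom=str(panel.chrom[j]),
        pos=int(panel.pos[j]),
        allele_ref=panel.ref[j],
        allele_alt=panel.alt[j],
        gene=gene,
        category=category,
        weight=weight,
    )


def _signed_weight(rng) -> float:
    return float(rng.choice([-1.0, 1.0]) * rng.uniform(0.2, 1.0))


def make_toy_db(
    panel: GenotypePanel,
    genes: int,
    snps_per_gene: tuple[int, int] = (3, 6),
    categories_per_gene: tuple[int, int] = (1, 3),
    seed: int = 0,
) -> AnnotationDB:
    """Random assignment of contiguous panel SNP blocks to genes/categories.

    Gene blocks may overlap, so a SNP can appear under several genes; weights
    are signed Uniform(0.2, 1).  Deterministic under ``seed``.
    """
    rng = np.random.default_rng(seed)
    entries = []
    for g in range(genes):
        spg = int(rng.integers(snps_per_gene[0], snps_per_gene[1] + 1))
        spg = min(spg, panel.n_snps)
        start = int(rng.integers(0, panel.n_snps - spg + 1))
        ncat = int(rng.integers(categories_per_gene[0], categories_per_gene[1] + 1))
        cats = rng.choice(CATEGORIES, size=min(ncat, spg), replace=False)
        gene = f"G{g:04d}"
        for i in range(spg):
            cat = str(cats[i % len(cats)])
            entries.append(_entry(panel, start + i, gene, cat, _signed_weight(rng)))
    return AnnotationDB(entries)


def make_structured_db(
    panel: GenotypePanel,
    n_genes: int,
    snps_per_gene: int = 5,
    gap_snps: int = 15,
    categories_per_gene: tuple[int, int] = (1, 3),
    seed: int = 0,
) -> AnnotationDB:
    """Non-overlapping gene blocks separated by unannotated backbone SNPs.

    Gene i owns ``snps_per_gene`` consecutive SNPs starting at
    i * (snps_per_gene + gap_snps); the backbone SNPs in the gaps stay
    measured-only, supplying imputation conditioning and decorrelating
    neighboring genes.
    """
    stride = snps_per_gene + gap_snps
    if n_genes * stride > panel.n_snps:
        raise ValueError("panel too small for requested gene layout")
    rng = np.random.default_rng(seed)
    entries = []
    for g in range(n_genes):
        start = g * stride
        ncat = int(rng.integers(categories_per_gene[0], categories_per_gene[1] + 1))
        cats = rng.choice(CATEGORIES, size=min(ncat, snps_per_gene), replace=False)
        gene = f"G{g:04d}"
        for i in range(snps_per_gene):
            cat = str(cats[i % len(cats)])
            entries.append(_entry(panel, start + i, gene, cat, _signed_weight(rng)))
    return AnnotationDB(entries)


# ---------------------------------------------------------------------------
# experiments


def _mask_functional(
    sumstats: SummaryDataset, db: AnnotationDB, fraction: float, rng
) -> SummaryDataset:
    """Hide a random fraction of annotated SNPs from the summary data."""
    func_pos = sorted(db.positions())
    k = int(round(fraction * len(func_pos)))
    hidden = {func_pos[i] for i in rng.permutation(len(func_pos))[:k]}
    return SummaryDataset(
        [r for r in sumstats if r.key not in hidden], gwas_n=sumstats.gwas_n
    )


def type_one_error_experiment(
    cfg: SimConfig,
    reps: int = 50,
    nominal: Sequence[float] = (0.05, 0.01),
    n_genes: int = 100,
    snps_per_gene: int = 5,
    gap_snps: int = 15,
    mask_fraction: float = 0.3,
) -> pd.DataFrame:
    """Empirical gene-level type-I error of the full pipeline under the null.

    Each replicate draws a fresh cohort (with replacement) from a super-panel,
    computes null regression Z-scores, and analyses against an independently
    drawn reference panel of the same population (different individuals) --
    twice: once with all annotated SNPs measured and once with
    ``mask_fraction`` of them hidden to exercise imputation.  Returns a table
    of (masked, nominal, empirical, mc_se); the Monte-Carlo SE is taken
    across replicate-level rates, which is robust to LD dependence between
    neighboring genes.
    """
    stride = snps_per_gene + gap_snps
    cfg = replace(cfg, n_snps=max(cfg.n_snps, n_genes * stride))
    lseed = cfg.seed if cfg.locus_seed is None else cfg.locus_seed
    cfg = replace(cfg, locus_seed=lseed)

    n_super = max(cfg.n_gwas // 2, 2)
    source = simulate_panel(cfg, seed=cfg.seed, n_samples=n_super)
    ref_panel = simulate_panel(cfg, seed=cfg.seed + 104_729)
    db = make_structured_db(
        ref_panel, n_genes, snps_per_gene=snps_per_gene, gap_snps=gap_snps, seed=lseed
    )

    nominal = list(nominal)
    arms = [False, True] if mask_fraction > 0 else [False]
    per_rep = {m: np.empty((reps, len(nominal))) for m in arms}
    for r in range(reps):
        rep_seed = cfg.seed + 1000 + r
        ss_full = harmonize(simulate_null_gwas(source, cfg, seed=rep_seed), ref_panel)
        for masked in arms:
            ss = ss_full
            if masked:
                rng = np.random.default_rng(rep_seed + 500_000)
                ss = _mask_functional(ss_full, db, mask_fraction, rng)
            results = run_jepeg(ss, db, ref_panel, enrichment=False)
            p = np.array([g.p_raw for g in results])
            per_rep[masked][r] = [(p <= a).mean() for a in nominal]
    rows = []
    for masked in arms:
        rates = per_rep[masked]
        rows.append(
            pd.DataFrame(
                {
                    "masked": masked,
                    "nominal": nominal,
                    "empirical": rates.mean(axis=0),
                    "mc_se": rates.std(axis=0, ddof=1) / np.sqrt(reps)
                    if reps > 1
                    else np.nan,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def power_experiment(
    cfg: SimConfig | None = None,
    reps: int = 200,
    n_causal: int = 3,
    beta: float = 0.10,
    weight: float = 0.8,
    causal_stride: int = 10,
) -> float:
    """Fraction of replicates where the joint gene p beats the best
    univariate SNP p for a gene with several coordinated planted eQTLs.

    The planted gene has ``n_causal`` equally spaced SNPs (``causal_stride``
    SNPs apart, so pairwise LD is weak) with equal positive effects and
    annotation weights of matching sign in one category: the regime the joint
    test targets, where the signal is distributed across several individually
    suggestive eQTLs.  The default effect size puts each marginal Z near 3
    (p ~ 0.003, two orders of magnitude short of genome-wide significance) at
    the default cohort size, from the
    closed-form noncentrality beta * sqrt(n * 2 maf (1 - maf)).
    """
    if cfg is None:
        cfg = SimConfig(n_snps=40, phenotype="continuous", seed=7)
    cfg = replace(cfg, locus_seed=cfg.seed if cfg.locus_seed is None else cfg.locus_seed)
    n_super = max(cfg.n_gwas // 2, 2)
    source = simulate_panel(cfg, seed=cfg.seed, n_samples=n_super)
    ref_panel = simulate_panel(cfg, seed=cfg.seed + 104_729)
    first = (cfg.n_snps - (n_causal - 1) * causal_stride) // 2
    idx = [first + i * causal_stride for i in range(n_causal)]
    if min(idx) < 0 or max(idx) >= cfg.n_snps:
        raise ValueError("panel too small for causal layout")
    causal = [ref_panel.snp_ids[j] for j in idx]
    entries = [_entry(ref_panel, j, "GPLANT", "CIS", weight) for j in idx]
    db = AnnotationDB(entries)
    effects = [(sid, beta) for sid in causal]

    wins = 0
    for r in range(reps):
        ss = simulate_alt_gwas(source, cfg, effects, seed=cfg.seed + 2000 + r)
        ss = harmonize(ss, ref_panel)
        results = run_jepeg(ss, db, ref_panel, impute=False, enrichment=False)
        g = results[0]
        if g.p_raw < g.top_snp[1]:
            wins += 1
    return wins / reps


# ---------------------------------------------------------------------------
# fixtures


def write_fixture_set(
    out_dir,
    cfg: SimConfig | None = None,
    n_genes: int = 10,
    snps_per_gene: int = 5,
    gap_snps: int = 15,
    mask_fraction: float = 0.3,
    effects: Sequence[tuple[str, float]] = (),
) -> dict:
    """Write a complete synthetic input set (VCF + sumstats TSV + annotation
    TSV + truth JSON) for end-to-end runs; returns the path map."""
    import json
    from pathlib import Path

    from .annotation import write_db
    from .data_io import write_panel_vcf, write_sumstats

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if cfg is None:
        cfg = SimConfig(n_snps=n_genes * (snps_per_gene + gap_snps))
    else:
        cfg = replace(cfg, n_snps=max(cfg.n_snps, n_genes * (snps_per_gene + gap_snps)))
    cfg = replace(cfg, locus_seed=cfg.seed if cfg.locus_seed is None else cfg.locus_seed)
    n_super = max(cfg.n_gwas // 2, 2)
    source = simulate_panel(cfg, seed=cfg.seed, n_samples=n_super)
    ref_panel = simulate_panel(cfg, seed=cfg.seed + 104_729)
    db = make_structured_db(
        ref_panel, n_genes, snps_per_gene=snps_per_gene, gap_snps=gap_snps, seed=cfg.locus_seed
    )
    if effects:
        ss = simulate_alt_gwas(source, cfg, effects, seed=cfg.seed + 1)
    else:
        ss = simulate_null_gwas(source, cfg, seed=cfg.seed + 1)
    rng = np.random.default_rng(cfg.seed + 2)
    ss = _mask_functional(ss, db, mask_fraction, rng)

    paths = {
        "panel": str(out / "panel.vcf"),
        "sumstats": str(out / "sumstats.tsv"),
        "annotation": str(out / "annotation.tsv"),
        "truth": str(out / "truth.json"),
    }
    write_panel_vcf(ref_panel, paths["panel"])
    write_sumstats(ss, paths["sumstats"])
    write_db(db, paths["annotation"])
    with open(paths["truth"], "w") as fh:
        json.dump(
            {
                "effects": [[sid, b] for sid, b in effects],
                "seed": cfg.seed,
                "n_gwas": cfg.n_gwas,
                "mask_fraction": mask_fraction,
            },
            fh,
            indent=1,
        )
    return paths
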