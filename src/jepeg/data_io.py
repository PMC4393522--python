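"""Summary-statistic and reference-panel I/O, allele harmonization, LD estimation.

Coordinates are 1-based inclusive throughout (VCF convention).  All Z-scores
handled downstream are oriented to the reference panel's ALT allele; the
:func:`harmonize` step establishes that orientation and is the only place
where allele bookkeeping happens.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF
from scipy import stats

log = logging.getLogger(__name__)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

__all__ = [
    "SummaryRecord",
    "SummaryDataset",
    "GenotypePanel",
    "CorrelationMatrix",
    "read_sumstats",
    "write_sumstats",
    "read_panel",
    "write_panel_vcf",
    "harmonize",
    "estimate_correlation",
    "ridge_adjust",
    "default_ridge",
]


def _chrom_key(chrom: str) -> tuple:
    c = chrom[3:] if chrom.lower().startswith("chr") else chrom
    return (0, int(c), "") if c.isdigit() else (1, 0, c)


@dataclass(frozen=True)
class SummaryRecord:
    """One SNP's association summary.

    ``zscore`` is the two-tailed association Z-score for ``allele_effect``
    (after harmonization: the panel ALT allele).  ``info`` is the imputation
    information in [0, 1]; measured SNPs carry info exactly 1.
    """

    snp_id: str
    chrom: str
    pos: int
    allele_effect: str
    allele_other: str
    zscore: float
    info: float = 1.0
    origin: str = "measured"

    def __post_init__(self):
        if self.origin not in ("measured", "imputed"):
            raise ValueError(f"origin must be measured/imputed, got {self.origin!r}")
        if self.origin == "measured" and self.info != 1.0:
            raise ValueError("measured records must have info exactly 1.0")
        if not (0.0 <= self.info <= 1.0 + 1e-9):
            raise ValueError(f"info out of range: {self.info}")
        if not math.isfinite(self.zscore):
            raise ValueError(f"non-finite zscore for {self.snp_id}")
        if not self.allele_effect or not self.allele_other:
            raise ValueError("alleles must be nonempty")
        if self.allele_effect == self.allele_other:
            raise ValueError(f"identical alleles for {self.snp_id}")

    @property
    def key(self) -> tuple[str, int]:
        return (self.chrom, self.pos)


class SummaryDataset:
    """Ordered collection of :class:`SummaryRecord`, sorted by (chrom, pos)."""

    def __init__(self, records: Iterable[SummaryRecord], gwas_n: int | None = None):
        recs = sorted(records, key=lambda r: (_chrom_key(r.chrom), r.pos))
        seen: set[tuple] = set()
        for r in recs:
            k = (r.chrom, r.pos, frozenset((r.allele_effect, r.allele_other)))
            if k in seen:
                raise ValueError(f"duplicate record at {r.chrom}:{r.pos}")
            seen.add(k)
        self.records: list[SummaryRecord] = recs
        self.gwas_n = gwas_n
        self._by_pos: dict[tuple[str, int], SummaryRecord] = {r.key: r for r in recs}

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def get(self, chrom: str, pos: int) -> SummaryRecord | None:
        return self._by_pos.get((chrom, pos))

    def positions(self) -> set[tuple[str, int]]:
        return set(self._by_pos)

    def with_records(self, extra: Iterable[SummaryRecord]) -> "SummaryDataset":
        return SummaryDataset(list(self.records) + list(extra), gwas_n=self.gwas_n)


@dataclass
class GenotypePanel:
    """Reference genotypes as ALT-allele dosages (n_samples x m_snps).

    Monomorphic columns are excluded at construction; every retained column
    has positive variance so Pearson LD is defined.
    """

    snp_ids: list[str]
    chrom: np.ndarray  # object array of str, length m
    pos: np.ndarray  # int array, length m
    ref: list[str]
    alt: list[str]
    dosages: np.ndarray  # float (n_samples, m)

    def __post_init__(self):
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2 or self.dosages.shape[1] != len(self.snp_ids):
            raise ValueError("dosage matrix does not conform to SNP metadata")
        if self.n_samples < 2:
            raise ValueError("panel needs at least 2 samples")
        var = self.dosages.var(axis=0)
        if np.any(var <= 0):
            bad = [self.snp_ids[i] for i in np.nonzero(var <= 0)[0]]
            raise ValueError(f"monomorphic SNPs in panel: {bad[:5]}")
        self._idx: dict[str, int] = {s: i for i, s in enumerate(self.snp_ids)}
        self._by_pos: dict[tuple[str, int], int] = {
            (c, int(p)): i for i, (c, p) in enumerate(zip(self.chrom, self.pos))
        }

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def index_of(self, snp_id: str) -> int:
        try:
            return self._idx[snp_id]
        except KeyError:
            raise KeyError(f"SNP {snp_id!r} not in panel") from None

    def lookup(self, chrom: str, pos: int) -> int | None:
        return self._by_pos.get((chrom, pos))

    def columns(self, ids: Sequence[str]) -> np.ndarray:
        return self.dosages[:, [self.index_of(s) for s in ids]]


@dataclass
class CorrelationMatrix:
    """Symmetric SNP-SNP Pearson correlation matrix, optionally ridge-adjusted.

    ``ridge`` is the amount already added to the diagonal (0 for a raw
    estimate), so the diagonal equals ``1 + ridge``.
    """

    snp_ids: list[str]
    values: np.ndarray
    ridge: float = 0.0

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.snp_ids), len(self.snp_ids)):
            raise ValueError("matrix shape does not match snp_ids")
        if v.size and np.max(np.abs(v - v.T)) > 1e-12:
            raise ValueError("correlation matrix not symmetric")
        off = v - np.diag(np.diag(v))
        if off.size and np.max(np.abs(off)) > 1.0 + 1e-9:
            raise ValueError("off-diagonal correlation outside [-1, 1]")
        if v.size and np.max(np.abs(np.diag(v) - (1.0 + self.ridge))) > 1e-9:
            raise ValueError("diagonal must equal 1 + ridge")
        self.values = v

    @property
    def m(self) -> int:
        return len(self.snp_ids)


# ---------------------------------------------------------------------------
# summary statistics I/O


def read_sumstats(
    path: str | Path,
    dialect: Mapping[str, str],
    sep: str = "\t",
    gwas_n: int | None = None,
) -> SummaryDataset:
    """Read a delimited summary-statistics table into a :class:`SummaryDataset`.

    ``dialect`` maps roles to column names and must provide ``id, chrom, pos,
    a1, a2`` plus one of ``{z}``, ``{beta, se}`` or ``{p, direction}``; ``a1``
    is the effect allele.  The Z-score is taken directly, derived as beta/se,
    or as sign(direction) * Phi^{-1}(1 - p/2).  Rows with missing or
    non-finite values (including p = 0 or p > 1) are dropped and counted.
    """
    need = {"id", "chrom", "pos", "a1", "a2"}
    missing = need - set(dialect)
    if missing:
        raise ValueError(f"dialect missing mandatory roles: {sorted(missing)}")
    if "z" in dialect:
        mode = "z"
    elif {"beta", "se"} <= set(dialect):
        mode = "beta_se"
    elif {"p", "direction"} <= set(dialect):
        mode = "p_dir"
    else:
        raise ValueError("dialect must map one of {z}, {beta,se}, {p,direction}")

    df = pd.read_csv(path, sep=sep)
    for role, col in dialect.items():
        if col not in df.columns:
            raise ValueError(f"column {col!r} (role {role!r}) not in {path}")

    records = []
    dropped = 0
    for _, row in df.iterrows():
        try:
            if mode == "z":
                z = float(row[dialect["z"]])
            elif mode == "beta_se":
                se = float(row[dialect["se"]])
                z = float(row[dialect["beta"]]) / se
            else:
                p = float(row[dialect["p"]])
                if not (0.0 < p <= 1.0):
                    raise ValueError("p out of (0, 1]")
                d = row[dialect["direction"]]
                sgn = {"+": 1.0, "-": -1.0}.get(str(d).strip(), None)
                if sgn is None:
                    sgn = math.copysign(1.0, float(d))
                z = sgn * float(stats.norm.isf(p / 2.0))
            rec = SummaryRecord(
                snp_id=str(row[dialect["id"]]),
                chrom=str(row[dialect["chrom"]]),
                pos=int(row[dialect["pos"]]),
                allele_effect=str(row[dialect["a1"]]).upper(),
                allele_other=str(row[dialect["a2"]]).upper(),
                zscore=z,
            )
        except (ValueError, ZeroDivisionError, TypeError):
            dropped += 1
            continue
        records.append(rec)
    if dropped:
        log.warning("read_sumstats: dropped %d unusable rows from %s", dropped, path)
    return SummaryDataset(records, gwas_n=gwas_n)


def write_sumstats(ds: SummaryDataset, path: str | Path) -> None:
    """Write a dataset as TSV with the package's native dialect."""
    df = pd.DataFrame(
        {
            "id": [r.snp_id for r in ds],
            "chrom": [r.chrom for r in ds],
            "pos": [r.pos for r in ds],
            "a1": [r.allele_effect for r in ds],
            "a2": [r.allele_other for r in ds],
            "z": [r.zscore for r in ds],
            "info": [r.info for r in ds],
            "origin": [r.origin for r in ds],
        }
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# reference panel


def read_panel(path: str | Path, region: str | None = None) -> GenotypePanel:
    """Load a VCF reference panel as ALT dosages.

    Only biallelic records are kept; multi-allelic and monomorphic records
    and records with missing/malformed genotypes are skipped.  ``region`` is
    ``chrom`` or ``chrom:start-end`` with 1-based inclusive coordinates.
    """
    vcf = VCF(str(path))
    if len(vcf.samples) == 0:
        raise ValueError(f"VCF {path} has no samples")
    want_chrom, lo, hi = None, None, None
    if region:
        if ":" in region:
            want_chrom, rng = region.split(":", 1)
            s, e = rng.split("-", 1)
            lo, hi = int(s), int(e)
        else:
            want_chrom = region

    ids, chroms, poss, refs, alts, cols = [], [], [], [], [], []
    skipped_multi = skipped_gt = skipped_mono = 0
    for v in vcf:
        if want_chrom is not None and v.CHROM != want_chrom:
            continue
        if lo is not None and not (lo <= v.POS <= hi):
            continue
        if len(v.ALT) != 1:
            skipped_multi += 1
            continue
        gts = np.array([g[:2] for g in v.genotypes], dtype=float)
        if gts.size == 0 or np.any(gts < 0):
            skipped_gt += 1
            continue
        dose = gts.sum(axis=1)
        if dose.var() <= 0:
            skipped_mono += 1
            continue
        ids.append(v.ID if v.ID else f"{v.CHROM}:{v.POS}")
        chroms.append(v.CHROM)
        poss.append(v.POS)
        refs.append(v.REF)
        alts.append(v.ALT[0])
        cols.append(dose)
    if skipped_multi or skipped_gt or skipped_mono:
        log.warning(
            "read_panel: skipped %d multi-allelic, %d malformed-GT, %d monomorphic records",
            skipped_multi,
            skipped_gt,
            skipped_mono,
        )
    if not ids:
        raise ValueError(f"no usable biallelic records in {path} (region={region})")
    return GenotypePanel(
        snp_ids=ids,
        chrom=np.array(chroms, dtype=object),
        pos=np.array(poss),
        ref=refs,
        alt=alts,
        dosages=np.column_stack(cols),
    )


def write_panel_vcf(panel: GenotypePanel, path: str | Path) -> None:
    """Write a panel as a minimal VCFv4.2 text file (unphased GTs).

    Dosages are rounded to {0, 1, 2} -> 0/0, 0/1, 1/1; intended for
    synthetic-fixture round-trips, not for dosage-valued data.
    """
    n = panel.n_samples
    samples = [f"S{i}" for i in range(n)]
    gt_of = {0: "0/0", 1: "0/1", 2: "1/1"}
    order = sorted(
        range(panel.n_snps), key=lambda j: (_chrom_key(panel.chrom[j]), panel.pos[j])
    )
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in dict.fromkeys(panel.chrom[order]):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(samples) + "\n")
        for j in order:
            gts = "\t".join(gt_of[int(round(d))] for d in panel.dosages[:, j])
            fh.write(
                f"{panel.chrom[j]}\t{panel.pos[j]}\t{panel.snp_ids[j]}\t"
                f"{panel.ref[j]}\t{panel.alt[j]}\t.\t.\t.\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# harmonization


def _is_ambiguous(a1: str, a2: str) -> bool:
    return _COMPLEMENT.get(a1) == a2


def harmonize(
    sumstats: SummaryDataset,
    panel: GenotypePanel,
    keep_ambiguous: bool = False,
) -> SummaryDataset:
    """Orient summary Z-scores to the panel ALT allele.

    Records are matched to the panel by (chrom, pos).  If the effect/other
    pair equals (ALT, REF) the Z-score is kept; if it equals (REF, ALT) the
    sign is flipped; otherwise the strand complement is tried.  Strand-
    ambiguous SNPs (A/T, C/G) are dropped by default because their strand
    cannot be resolved from alleles alone; ``keep_ambiguous`` matches them on
    the as-given strand instead.  Unmatched records are dropped.  Idempotent.
    """
    out: list[SummaryRecord] = []
    n_flip = n_drop = 0
    for rec in sumstats:
        j = panel.lookup(rec.chrom, rec.pos)
        if j is None:
            n_drop += 1
            continue
        ref, alt = panel.ref[j], panel.alt[j]
        e, o = rec.allele_effect, rec.allele_other
        ambiguous = _is_ambiguous(e, o)
        if ambiguous and not keep_ambiguous:
            n_drop += 1
            continue
        sign = None
        if (e, o) == (alt, ref):
            sign = +1.0
        elif (e, o) == (ref, alt):
            sign = -1.0
        elif not ambiguous and e in _COMPLEMENT and o in _COMPLEMENT:
            ce, co = _COMPLEMENT[e], _COMPLEMENT[o]
            if (ce, co) == (alt, ref):
                sign = +1.0
            elif (ce, co) == (ref, alt):
                sign = -1.0
        if sign is None:
            n_drop += 1
            continue
        if sign < 0:
            n_flip += 1
        out.append(
            replace(
                rec,
                allele_effect=alt,
                allele_other=ref,
                zscore=sign * rec.zscore,
            )
        )
    log.info("harmonize: %d kept (%d flipped), %d dropped", len(out), n_flip, n_drop)
    return SummaryDataset(out, gwas_n=sumstats.gwas_n)


# ---------------------------------------------------------------------------
# LD estimation


def estimate_correlation(panel: GenotypePanel, ids: Sequence[str]) -> CorrelationMatrix:
    """Pearson dosage correlation among ``ids``, block-diagonal by chromosome.

    Cross-chromosome entries are fixed at exactly 0: at reference-panel
    sample sizes the empirical cross-chromosome correlation is pure noise,
    and trans-eQTL SNP sets legitimately span chromosomes.
    """
    idx = [panel.index_of(s) for s in ids]
    m = len(idx)
    vals = np.eye(m)
    chroms = np.array([panel.chrom[i] for i in idx], dtype=object)
    for c in dict.fromkeys(chroms):
        sel = np.nonzero(chroms == c)[0]
        if len(sel) > 1:
            sub = np.corrcoef(panel.dosages[:, [idx[i] for i in sel]], rowvar=False)
            vals[np.ix_(sel, sel)] = sub
    np.fill_diagonal(vals, 1.0)
    vals = np.clip((vals + vals.T) / 2.0, -1.0, 1.0)
    return CorrelationMatrix(snp_ids=list(ids), values=vals, ridge=0.0)


def default_ridge(n_samples: int) -> float:
    """Heuristic ridge 2/n, n = number of reference-panel samples."""
    if n_samples <= 0:
        raise ValueError("panel sample size must be positive")
    return 2.0 / n_samples


def ridge_adjust(m: CorrelationMatrix, lam: float) -> CorrelationMatrix:
    """Add ``lam`` to the diagonal of a raw correlation matrix."""
    if lam < 0:
        raise ValueError("ridge must be nonnegative")
    if m.ridge != 0:
        raise ValueError("matrix already ridge-adjusted")
    if lam == 0:
        return m
    return CorrelationMatrix(
        snp_ids=list(m.snp_ids),
        values=m.values + lam * np.eye(m.m),
        ridge=lam,
    )
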