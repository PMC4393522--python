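"""Functional-SNP annotation database and per-gene weight matrices.

Each annotation assigns one SNP to one gene under one of six functional
categories: protein function/structure (PFS), transcription-factor binding
site (TFBS), miRNA structure (STR), miRNA target (TAR), and empirically
derived cis- (CIS) and trans- (TRN) eQTLs.  The signed weight is a proxy for
the predicted change in the gene's expression brought on by the annotation's
stated reference allele (negative = predicted decrease); at assembly time it
is re-signed to the harmonized panel-ALT orientation so that the weighted
category score is orientation-invariant.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .data_io import _chrom_key, _COMPLEMENT

log = logging.getLogger(__name__)

CATEGORIES = ("PFS", "TFBS", "STR", "TAR", "CIS", "TRN")

__all__ = [
    "CATEGORIES",
    "FunctionalAnnotation",
    "AnnotationDB",
    "WeightMatrix",
    "load_db",
    "write_db",
    "gene_annotations",
    "build_weights",
]


@dataclass(frozen=True)
class FunctionalAnnotation:
    snp_id: str
    chrom: str
    pos: int
    allele_ref: str
    allele_alt: str
    gene: str
    category: str
    weight: float

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if not math.isfinite(self.weight) or self.weight == 0.0:
            raise ValueError(f"weight must be finite and nonzero ({self.snp_id})")

    @property
    def key(self) -> tuple[str, int]:
        return (self.chrom, self.pos)


class AnnotationDB:
    """Validated, indexed collection of functional annotations.

    A SNP may appear under several genes and categories; the exact
    (snp, gene, category) triple must be unique.
    """

    def __init__(self, entries: Iterable[FunctionalAnnotation]):
        self.entries: list[FunctionalAnnotation] = list(entries)
        seen: set[tuple] = set()
        self._by_gene: dict[str, list[FunctionalAnnotation]] = {}
        self._by_pos: dict[tuple[str, int], list[FunctionalAnnotation]] = {}
        for a in self.entries:
            k = (a.snp_id, a.gene, a.category)
            if k in seen:
                raise ValueError(f"duplicate annotation {k}")
            seen.add(k)
            self._by_gene.setdefault(a.gene, []).append(a)
            self._by_pos.setdefault(a.key, []).append(a)

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def genes(self) -> list[str]:
        return sorted(self._by_gene)

    def for_gene(self, gene: str) -> list[FunctionalAnnotation]:
        return list(self._by_gene.get(gene, []))

    def at(self, chrom: str, pos: int) -> list[FunctionalAnnotation]:
        return list(self._by_pos.get((chrom, pos), []))

    def positions(self) -> set[tuple[str, int]]:
        return set(self._by_pos)

    def category_counts(self) -> dict[str, int]:
        out = {c: 0 for c in CATEGORIES}
        for a in self.entries:
            out[a.category] += 1
        return out


@dataclass
class WeightMatrix:
    """k x m signed weight matrix S for one gene.

    Row j holds the weights of category ``categories[j]``; entries are zero
    except at SNPs annotated to that category.  All-zero rows are excluded
    at construction (k shrinks accordingly).
    """

    categories: tuple[str, ...]
    snp_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.categories), len(self.snp_ids)):
            raise ValueError("weight matrix shape mismatch")
        if v.size and np.any(~v.any(axis=1)):
            raise ValueError("weight matrix has an all-zero category row")
        self.values = v

    @property
    def k(self) -> int:
        return len(self.categories)

    @property
    def m(self) -> int:
        return len(self.snp_ids)


def load_db(path: str | Path) -> AnnotationDB:
    """Read a TSV annotation database.

    Columns: ``id chrom pos ref alt gene category weight``.  Unknown category
    labels abort with the offending line; zero-weight rows are rejected
    (dropped with a warning) since they carry no information.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    need = ["id", "chrom", "pos", "ref", "alt", "gene", "category", "weight"]
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise ValueError(f"annotation DB {path} missing columns {missing}")
    entries = []
    n_zero = 0
    for i, row in df.iterrows():
        cat = str(row["category"])
        if cat not in CATEGORIES:
            raise ValueError(f"unknown category {cat!r} at line {i + 2} of {path}")
        w = float(row["weight"])
        if w == 0.0 or not math.isfinite(w):
            n_zero += 1
            continue
        entries.append(
            FunctionalAnnotation(
                snp_id=str(row["id"]),
                chrom=str(row["chrom"]),
                pos=int(row["pos"]),
                allele_ref=str(row["ref"]).upper(),
                allele_alt=str(row["alt"]).upper(),
                gene=str(row["gene"]),
                category=cat,
                weight=w,
            )
        )
    if n_zero:
        log.warning("load_db: rejected %d zero/non-finite-weight rows", n_zero)
    db = AnnotationDB(entries)
    log.info("load_db: %d entries, per-category %s", len(db), db.category_counts())
    return db


def write_db(db: AnnotationDB, path: str | Path) -> None:
    pd.DataFrame(
        {
            "id": [a.snp_id for a in db.entries],
            "chrom": [a.chrom for a in db.entries],
            "pos": [a.pos for a in db.entries],
            "ref": [a.allele_ref for a in db.entries],
            "alt": [a.allele_alt for a in db.entries],
            "gene": [a.gene for a in db.entries],
            "category": [a.category for a in db.entries],
            "weight": [a.weight for a in db.entries],
        }
    ).to_csv(path, sep="\t", index=False)


def gene_annotations(db: AnnotationDB, gene: str) -> list[FunctionalAnnotation]:
    """All annotations for ``gene``, ordered by (chrom, pos); [] if absent."""
    return sorted(db.for_gene(gene), key=lambda a: (_chrom_key(a.chrom), a.pos))


def _orientation_sign(anno: FunctionalAnnotation, effect: str, other: str) -> float | None:
    """Sign aligning the annotation's allele orientation with the harmonized one.

    +1 when the harmonized effect allele is the annotation's ALT, -1 when it
    is the annotation's REF; the strand complement is tried for unambiguous
    SNPs.  None when the allele pairs cannot be reconciled.
    """
    r, a = anno.allele_ref, anno.allele_alt
    if (effect, other) == (a, r):
        return +1.0
    if (effect, other) == (r, a):
        return -1.0
    if all(x in _COMPLEMENT for x in (effect, other)) and _COMPLEMENT[effect] != other:
        ce, co = _COMPLEMENT[effect], _COMPLEMENT[other]
        if (ce, co) == (a, r):
            return +1.0
        if (ce, co) == (r, a):
            return -1.0
    return None


def build_weights(
    annos: Sequence[FunctionalAnnotation],
    snp_order: Sequence[str],
    alleles: Mapping[str, tuple[str, str]],
) -> WeightMatrix:
    """Assemble the k x m weight matrix S for one gene.

    ``snp_order`` fixes column order; ``alleles`` maps snp_id to the
    harmonized (effect, other) pair used to re-sign each weight.  Annotations
    whose alleles cannot be reconciled with the harmonized pair are dropped
    with a warning; categories left without any weight are dropped (k
    shrinks).
    """
    col = {s: i for i, s in enumerate(snp_order)}
    full = np.zeros((len(CATEGORIES), len(snp_order)))
    n_drop = 0
    for a in annos:
        if a.snp_id not in col:
            raise KeyError(f"annotation SNP {a.snp_id!r} not in snp_order")
        effect, other = alleles[a.snp_id]
        sign = _orientation_sign(a, effect, other)
        if sign is None:
            n_drop += 1
            continue
        full[CATEGORIES.index(a.category), col[a.snp_id]] = sign * a.weight
    if n_drop:
        log.warning("build_weights: dropped %d allele-incompatible annotations", n_drop)
    keep = [j for j in range(len(CATEGORIES)) if full[j].any()]
    return WeightMatrix(
        categories=tuple(CATEGORIES[j] for j in keep),
        snp_ids=tuple(snp_order),
        values=full[keep],
    )
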