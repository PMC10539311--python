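"""Priority classification of unannotated transcribed loci (UTLs).

Each UTL gets four tags — dominant transposable-element (TE) family with a
TE-score, proximity of its 5' end to an active cis-regulatory element (CRE),
a readthrough flag (5' end at a same-strand gene's 3' end) and an antisense
flag — combined by a first-match-wins priority rule into one of seven
classes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .genome import GeneModel

logger = logging.getLogger(__name__)

__all__ = [
    "UTLInterval",
    "CRERecord",
    "SMALL_RNA_FAMILIES",
    "dominant_te",
    "tag_cre",
    "tag_readthrough",
    "tag_antisense",
    "classify_utl",
    "classify_utls",
]

SMALL_RNA_FAMILIES = frozenset(
    {"snRNA", "snoRNA", "scaRNA", "srpRNA", "scRNA", "rRNA"})


@dataclass(frozen=True)
class UTLInterval:
    utl_id: str
    chrom: str
    strand: str
    start: int
    end: int
    fpm: float = 0.0

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval for {self.utl_id}")
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be '+' or '-'")

    @property
    def five_prime(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class CRERecord:
    chrom: str
    start: int
    end: int
    cre_class: str            # 7-group ENCODE-style class, e.g. enhancer-like
    active_es: bool = False   # overlaps an ATAC peak in that state
    active_de: bool = False


def dominant_te(read_labels: Sequence[str | None]) -> tuple[str | None, float]:
    """Dominant TE family among a UTL's reads and its TE-score.

    The score is the dominant family's read count over *all* reads of the UTL
    (unlabeled reads included in the denominator).  Ties break
    lexicographically (logged).
    """
    labels = [l for l in read_labels if l]
    if not read_labels:
        raise ValueError("UTL has no reads")
    if not labels:
        return None, 0.0
    counts = pd.Series(labels).value_counts()
    top = counts[counts == counts.max()]
    if len(top) > 1:
        logger.info("TE-family tie %s; choosing lexicographically smallest",
                    sorted(top.index))
    family = sorted(top.index)[0]
    return family, counts[family] / len(read_labels)


def tag_cre(utl: UTLInterval, cres: Sequence[CRERecord],
            window: int = 300) -> str | None:
    """Class of the nearest active CRE within ±window bp of the UTL 5' end.

    The subtype comes from the ES annotation when the CRE is active in ES,
    otherwise from the DE annotation.
    """
    five = utl.five_prime
    best = None
    best_dist = None
    for cre in cres:
        if cre.chrom != utl.chrom or not (cre.active_es or cre.active_de):
            continue
        if cre.end <= five:
            dist = five - (cre.end - 1)
        elif cre.start > five:
            dist = cre.start - five
        else:
            dist = 0
        if dist <= window and (best_dist is None or dist < best_dist):
            best, best_dist = cre, dist
    return best.cre_class if best is not None else None


def tag_readthrough(utl: UTLInterval, gene_models: Sequence[GeneModel],
                    upstream: int = 200, downstream: int = 100,
                    same_strand: bool = True) -> bool:
    """True iff the UTL 5' end sits in the oriented window
    [3'end - upstream, 3'end + downstream] of a gene, '+' meaning downstream
    in the gene's direction of transcription (same strand required by
    default)."""
    five = utl.five_prime
    for g in gene_models:
        if g.chrom != utl.chrom:
            continue
        if same_strand and g.strand != utl.strand:
            continue
        end3 = g.gene_3prime
        if g.strand == "+":
            lo, hi = end3 - upstream, end3 + downstream
        else:
            lo, hi = end3 - downstream, end3 + upstream
        if lo <= five <= hi:
            return True
    return False


def tag_antisense(utl: UTLInterval, gene_models: Sequence[GeneModel],
                  min_overlap: float = 0.10) -> bool:
    """True iff overlap with any opposite-strand gene body is at least
    ``min_overlap`` of the UTL length."""
    for g in gene_models:
        if g.chrom != utl.chrom or g.strand == utl.strand:
            continue
        overlap = min(g.end, utl.end) - max(g.start, utl.start)
        if overlap >= min_overlap * utl.length:
            return True
    return False


def classify_utl(te_family: str | None, te_score: float,
                 readthrough: bool, cre_class: str | None,
                 antisense: bool) -> str:
    """Seven-class priority rule, first match wins:

    1. tRNA family, score > 0.10         -> tRNA-derived
    2. small-RNA family, score > 0.10    -> snRNA-derived
    3. readthrough flag                  -> readthrough
    4. CRE tag                           -> CRE-derived(<subtype>)
    5. score > 0.50                      -> repeat-derived(<family>)
    6. antisense flag                    -> antisense
    7.                                   -> intergenic
    """
    if te_family == "tRNA" and te_score > 0.10:
        return "tRNA-derived"
    if te_family in SMALL_RNA_FAMILIES and te_score > 0.10:
        return "snRNA-derived"
    if readthrough:
        return "readthrough"
    if cre_class is not None:
        return f"CRE-derived({cre_class})"
    if te_family is not None and te_score > 0.50:
        return f"repeat-derived({te_family})"
    if antisense:
        return "antisense"
    return "intergenic"


def classify_utls(utls: Sequence[UTLInterval],
                  read_te_labels: dict[str, Sequence[str | None]],
                  cres: Sequence[CRERecord],
                  gene_models: Sequence[GeneModel],
                  cre_window: int = 300, min_antisense_overlap: float = 0.10,
                  readthrough_same_strand: bool = True) -> pd.DataFrame:
    """Tag and classify a UTL roster; one row per UTL, one class each."""
    rows = []
    for utl in utls:
        labels = read_te_labels.get(utl.utl_id, [])
        family, score = dominant_te(labels) if labels else (None, 0.0)
        cre = tag_cre(utl, cres, window=cre_window)
        rt = tag_readthrough(utl, gene_models,
                             same_strand=readthrough_same_strand)
        anti = tag_antisense(utl, gene_models,
                             min_overlap=min_antisense_overlap)
        rows.append({
            "utl_id": utl.utl_id, "te_family": family, "te_score": score,
            "readthrough": rt, "cre_class": cre, "antisense": anti,
            "final_class": classify_utl(family, score, rt, cre, anti),
        })
    return pd.DataFrame(rows)
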