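"""caRNA-gene interactome, edge-sign classification and bootstrap enrichment.

Contacts are aggregated over each protein-coding gene's proximal regulatory
region (PRR), the 100 kb window from 10 kb upstream of the TSS to 90 kb into
the gene.  Differential contacts become edges whose sign compares the
contact dynamics with the target gene's expression dynamics; positive-edge
enrichment is measured against a gene-label permutation null with bootstrap
confidence intervals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .contacts import BinScheme, ContactRecord, bin_contacts, records_to_frame
from .genome import GeneModel, GenomeLayout

logger = logging.getLogger(__name__)

__all__ = [
    "PRRWindow",
    "EnrichmentResult",
    "build_prr",
    "build_gene_interactome",
    "classify_edges",
    "edge_sign_enrichment",
    "metagene_profile",
]

_CLASS_TO_STATE = {"upES": "ES", "upDE": "DE"}


@dataclass(frozen=True)
class PRRWindow:
    """Strand-oriented proximal regulatory region around a gene's TSS."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    clipped: bool = False


@dataclass(frozen=True)
class EnrichmentResult:
    observed_fraction: float
    null_fraction: float
    fold: float
    ci_low: float
    ci_high: float
    boot_pvalue: float
    n_edges: int
    n_boot: int
    seed: int

    @property
    def significant(self) -> bool:
        """CI excluding fold = 1."""
        return not (self.ci_low <= 1.0 <= self.ci_high)


def build_prr(gene_models: Sequence[GeneModel], genome: GenomeLayout,
              upstream: int = 10_000, downstream: int = 90_000
              ) -> list[PRRWindow]:
    """PRR windows [TSS - upstream, TSS + downstream) in transcription
    direction, reflected for '-' strand genes and clipped at chromosome
    bounds (flagged)."""
    out = []
    for g in gene_models:
        t = g.tss
        if g.strand == "+":
            start, end = t - upstream, t + downstream
        else:
            start, end = t - downstream + 1, t + upstream + 1
        L = genome.length_of(g.chrom)
        cstart, cend = max(start, 0), min(end, L)
        clipped = (cstart, cend) != (start, end)
        if clipped:
            width = end - start
            if cstart == 0:
                cend = min(width, L)
            elif cend == L:
                cstart = max(L - width, 0)
        out.append(PRRWindow(g.gene_id, g.chrom, cstart, cend, g.strand, clipped))
    return out


def build_gene_interactome(records: Sequence[ContactRecord] | pd.DataFrame,
                           prr_windows: Sequence[PRRWindow],
                           genome: GenomeLayout) -> pd.DataFrame:
    """caRNA x gene contact count matrix over PRR windows.

    A contact inside several overlapping PRRs counts once per gene.
    """
    scheme = BinScheme(genome, windows=tuple(
        (w.chrom, w.start, w.end, w.gene_id) for w in prr_windows))
    matrix = bin_contacts(records, scheme)
    df = pd.DataFrame(matrix.counts.toarray(), index=matrix.gene_ids,
                      columns=scheme.bin_labels)
    df.index.name = "carna_id"
    df.columns.name = "target_gene"
    return df


def classify_edges(contact_dynamics: pd.DataFrame,
                   carna_de: pd.Series, gene_de: pd.Series) -> pd.DataFrame:
    """Edge list with signs from the contact/gene dynamics truth table.

    ``contact_dynamics`` needs columns carna_id, target_gene and
    contact_class in {upES, upDE, stable}; stable contacts yield no edge.
    Sign: positive when the contact is up in the state where the gene is up;
    negative when states are crossed; neutral when the gene is stable.
    """
    valid = {"upES", "upDE", "stable"}
    bad = set(contact_dynamics["contact_class"].unique()) - valid
    if bad:
        raise ValueError(f"unknown contact classes: {sorted(bad)}")
    bad = (set(carna_de.unique()) | set(gene_de.unique())) - {"ES", "DE", "stable"}
    if bad:
        raise ValueError(f"unknown DE labels: {sorted(bad)}")
    sub = contact_dynamics[contact_dynamics["contact_class"] != "stable"].copy()
    missing = set(sub["target_gene"]) - set(gene_de.index)
    if missing:
        raise ValueError(f"genes without DE labels: {sorted(missing)[:5]}...")
    sub["carna_de"] = sub["carna_id"].map(carna_de)
    sub["gene_de"] = sub["target_gene"].map(gene_de)
    up_state = sub["contact_class"].map(_CLASS_TO_STATE)
    sub["sign"] = np.select(
        [sub["gene_de"] == "stable", up_state == sub["gene_de"]],
        ["neutral", "positive"], default="negative")
    return sub.reset_index(drop=True)


def _permutation_null(classes: np.ndarray, gene_idx: np.ndarray,
                      gene_labels: np.ndarray, n_perm: int,
                      rng: np.random.Generator) -> float:
    """Mean positive fraction over gene-label permutations."""
    target_state = np.array([_CLASS_TO_STATE[c] for c in classes], dtype=object)
    total = 0.0
    for _ in range(n_perm):
        perm = rng.permutation(gene_labels)
        total += float(np.mean(perm[gene_idx] == target_state))
    return total / n_perm


def edge_sign_enrichment(edges: pd.DataFrame, n_boot: int = 10_000,
                         seed: int = 0, n_perm: int = 1_000,
                         min_edges: int = 10) -> EnrichmentResult:
    """Fold enrichment of positive edges over the shuffled-gene-label null.

    The null permutes gene DE labels across target genes (label counts
    preserved), averaging the positive fraction over ``n_perm`` permutations.
    The 95% CI comes from ``n_boot`` edge resamples; each resample recomputes
    both the positive fraction and the permutation-expected null fraction on
    the resampled edge set, so the CI reflects label-marginal noise as well.
    """
    if len(edges) < min_edges:
        raise ValueError(f"need >= {min_edges} edges, got {len(edges)}")
    rng = np.random.default_rng(seed)
    classes = edges["contact_class"].to_numpy(dtype=object)
    labels = edges["gene_de"].to_numpy(dtype=object)
    genes, gene_idx = np.unique(edges["target_gene"].to_numpy(), return_inverse=True)
    gene_labels = np.empty(len(genes), dtype=object)
    gene_labels[gene_idx] = labels
    target_state = np.array([_CLASS_TO_STATE[c] for c in classes], dtype=object)
    p_obs = float(np.mean(labels == target_state))
    p_null = _permutation_null(classes, gene_idx, gene_labels, n_perm, rng)
    fold = p_obs / p_null if p_null > 0 else np.inf
    # bootstrap over joint (contact class, gene label) category counts
    cats = pd.crosstab(pd.Series(classes, name="class"),
                       pd.Series(labels, name="label"))
    class_levels = list(cats.index)
    label_levels = list(cats.columns)
    counts = cats.to_numpy().ravel()
    probs = counts / counts.sum()
    draws = rng.multinomial(len(edges), probs, size=n_boot).reshape(
        n_boot, len(class_levels), len(label_levels))
    n = float(len(edges))
    pos_mask = np.array([[_CLASS_TO_STATE[c] == l for l in label_levels]
                         for c in class_levels])
    p_obs_b = draws[:, pos_mask].sum(axis=1) / n
    class_marg = draws.sum(axis=2)   # n_boot x classes
    label_marg = draws.sum(axis=1)   # n_boot x labels
    p_null_b = np.zeros(n_boot)
    for ci, c in enumerate(class_levels):
        state = _CLASS_TO_STATE[c]
        if state in label_levels:
            li = label_levels.index(state)
            p_null_b += class_marg[:, ci] * label_marg[:, li]
    p_null_b /= n * n
    with np.errstate(divide="ignore", invalid="ignore"):
        fold_b = np.where(p_null_b > 0, p_obs_b / p_null_b, np.inf)
    ci_low, ci_high = np.percentile(fold_b, [2.5, 97.5])
    p_le = float(np.mean(fold_b <= 1.0))
    p_ge = float(np.mean(fold_b >= 1.0))
    boot_p = min(1.0, 2.0 * min(p_le, p_ge))
    return EnrichmentResult(p_obs, p_null, fold, float(ci_low), float(ci_high),
                            boot_p, len(edges), n_boot, seed)


def metagene_profile(records: Sequence[ContactRecord] | pd.DataFrame,
                     rna_id: str, feature_centers: Sequence[tuple[str, int]],
                     half_window: int, bin_size: int,
                     genome: GenomeLayout) -> pd.DataFrame:
    """Background-normalized mean contact profile around feature centers.

    Windows [center - half_window, center + half_window) are binned at
    ``bin_size``; the profile is the mean count per bin across features
    divided by the RNA's genome-wide mean per-bin count, so background = 1.
    """
    if not feature_centers:
        raise ValueError("need at least one feature center")
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    sub = df[df["rna_gene_id"] == rna_id]
    n_bins = int(np.ceil(2 * half_window / bin_size))
    offsets = -half_window + np.arange(n_bins) * bin_size
    if len(sub) == 0:
        logger.warning("RNA %s has no contacts; flat zero profile", rna_id)
        return pd.DataFrame({"offset": offsets, "profile": np.zeros(n_bins)})
    total_bins = sum(int(np.ceil(L / bin_size)) for L in genome.chrom_lengths)
    background = len(sub) / total_bins
    acc = np.zeros(n_bins)
    pos = sub["dna_pos"].to_numpy()
    chroms = sub["dna_chrom"].to_numpy(dtype=object)
    for chrom, center in feature_centers:
        lo = center - half_window
        mask = (chroms == chrom) & (pos >= lo) & (pos < center + half_window)
        idx = ((pos[mask] - lo) // bin_size).astype(int)
        acc += np.bincount(idx, minlength=n_bins)[:n_bins]
    profile = acc / len(feature_centers) / background
    return pd.DataFrame({"offset": offsets, "profile": profile})
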