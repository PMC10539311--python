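"""Contact records, pairs-file I/O, binning schemes and sparse contact matrices.

One contact is a single RNA-DNA proximity-ligation event.  On disk, contacts
live in a pairs-style tab-separated text format with the RNA side first::

    #columns: readID chrom1 pos1 strand1 chrom2 pos2 strand2 gene_id annot sample

Positions are 1-based on disk and 0-based in memory.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .genome import GenomeLayout

logger = logging.getLogger(__name__)

__all__ = [
    "ContactRecord",
    "BinScheme",
    "ContactMatrix",
    "read_pairs",
    "write_pairs",
    "records_to_frame",
    "frame_to_records",
    "bin_contacts",
    "travel_distance",
    "rna_coverage_track",
    "write_bedgraph",
]

PAIRS_COLUMNS = (
    "readID chrom1 pos1 strand1 chrom2 pos2 strand2 gene_id annot sample"
)
ANNOTATION_CLASSES = frozenset({"exon", "intron", "intergenic"})


class ContactRecord(NamedTuple):
    """One RNA-DNA ligation event (positions 0-based)."""

    read_id: str
    rna_gene_id: str
    rna_chrom: str
    rna_pos: int
    rna_strand: str
    dna_chrom: str
    dna_pos: int
    dna_strand: str
    annotation_class: str
    sample_id: str


def travel_distance(record: ContactRecord) -> Optional[int]:
    """Signed RNA-to-DNA travel distance (DNA minus RNA position).

    Defined for cis contacts only; trans contacts return ``None``.
    """
    if record.rna_chrom != record.dna_chrom:
        return None
    return record.dna_pos - record.rna_pos


def records_to_frame(records: Sequence[ContactRecord]) -> pd.DataFrame:
    """Columnar view of a record sequence (order preserved)."""
    return pd.DataFrame(records, columns=ContactRecord._fields)


def frame_to_records(df: pd.DataFrame) -> list[ContactRecord]:
    return [ContactRecord(*row) for row in df[list(ContactRecord._fields)].itertuples(index=False)]


def read_pairs(path, genome: GenomeLayout) -> list[ContactRecord]:
    """Read a pairs file, validating positions against ``genome``.

    On-disk positions are 1-based and converted to the internal 0-based
    convention.  Malformed lines, unknown chromosomes and out-of-bounds
    positions raise errors naming the offending line.
    """
    records: list[ContactRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 10:
                raise ValueError(
                    f"{path}:{lineno}: expected 10 tab-separated fields, got {len(parts)}"
                )
            (read_id, rna_chrom, rna_pos_s, rna_strand,
             dna_chrom, dna_pos_s, dna_strand, gene_id, annot, sample) = parts
            try:
                rna_pos = int(rna_pos_s) - 1
                dna_pos = int(dna_pos_s) - 1
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-integer position") from None
            for chrom, pos, side in ((rna_chrom, rna_pos, "RNA"), (dna_chrom, dna_pos, "DNA")):
                if chrom not in genome:
                    raise ValueError(
                        f"{path}:{lineno}: {side} chromosome {chrom!r} not in genome layout"
                    )
                if not (0 <= pos < genome.length_of(chrom)):
                    raise ValueError(
                        f"{path}:{lineno}: {side} position {pos + 1} out of bounds for {chrom}"
                    )
            if annot not in ANNOTATION_CLASSES:
                raise ValueError(
                    f"{path}:{lineno}: annotation class {annot!r} not in {sorted(ANNOTATION_CLASSES)}"
                )
            records.append(
                ContactRecord(read_id, gene_id, rna_chrom, rna_pos, rna_strand,
                              dna_chrom, dna_pos, dna_strand, annot, sample)
            )
    return records


def write_pairs(records: Sequence[ContactRecord], path, *, genome: GenomeLayout | None = None,
                sort: bool = False) -> None:
    """Write records as a pairs file (1-based on disk).

    With ``sort=True`` output is ordered by (rna_gene_id, dna_chrom, dna_pos).
    """
    if sort:
        records = sorted(records, key=lambda r: (r.rna_gene_id, r.dna_chrom, r.dna_pos))
    with open(path, "w") as fh:
        fh.write("## pairs format v1.0\n")
        if genome is not None:
            for name, length in zip(genome.chrom_names, genome.chrom_lengths):
                fh.write(f"#chromsize: {name} {length}\n")
        fh.write(f"#columns: {PAIRS_COLUMNS}\n")
        for r in records:
            fh.write(
                "\t".join(
                    (r.read_id, r.rna_chrom, str(r.rna_pos + 1), r.rna_strand,
                     r.dna_chrom, str(r.dna_pos + 1), r.dna_strand,
                     r.rna_gene_id, r.annotation_class, r.sample_id)
                )
                + "\n"
            )


@dataclass(frozen=True)
class BinScheme:
    """Genomic binning: uniform tiling or an explicit list of named windows.

    Uniform bins are disjoint and cover each chromosome.  Explicit windows may
    overlap; overlap is flagged on :attr:`has_overlaps` and a contact falling
    in several windows is assigned to each of them.
    """

    genome: GenomeLayout
    bin_size: int | None = None
    windows: tuple[tuple[str, int, int, str], ...] | None = None  # (chrom, start, end, label)

    def __post_init__(self) -> None:
        if (self.bin_size is None) == (self.windows is None):
            raise ValueError("specify exactly one of bin_size or windows")
        if self.bin_size is not None and self.bin_size <= 0:
            raise ValueError("bin_size must be positive")

    # ---- uniform-mode geometry -------------------------------------------------
    @property
    def uniform(self) -> bool:
        return self.bin_size is not None

    @property
    def _chrom_nbins(self) -> np.ndarray:
        lengths = np.asarray(self.genome.chrom_lengths)
        return np.ceil(lengths / self.bin_size).astype(int)

    @property
    def _chrom_offsets(self) -> dict[str, int]:
        offsets = np.concatenate([[0], np.cumsum(self._chrom_nbins)[:-1]])
        return dict(zip(self.genome.chrom_names, offsets.tolist()))

    @property
    def n_bins(self) -> int:
        if self.uniform:
            return int(self._chrom_nbins.sum())
        return len(self.windows)

    @property
    def bin_chroms(self) -> np.ndarray:
        """Chromosome of each bin, aligned with bin indices."""
        if self.uniform:
            return np.repeat(np.asarray(self.genome.chrom_names, dtype=object),
                             self._chrom_nbins)
        return np.asarray([w[0] for w in self.windows], dtype=object)

    @property
    def bin_starts(self) -> np.ndarray:
        if self.uniform:
            return np.concatenate(
                [np.arange(n) * self.bin_size for n in self._chrom_nbins]
            )
        return np.asarray([w[1] for w in self.windows])

    @property
    def bin_ends(self) -> np.ndarray:
        if self.uniform:
            ends = self.bin_starts + self.bin_size
            lengths = dict(zip(self.genome.chrom_names, self.genome.chrom_lengths))
            limit = np.asarray([lengths[c] for c in self.bin_chroms])
            return np.minimum(ends, limit)
        return np.asarray([w[2] for w in self.windows])

    @property
    def bin_labels(self) -> np.ndarray:
        if self.uniform:
            return np.asarray(
                [f"{c}:{s}-{e}" for c, s, e in
                 zip(self.bin_chroms, self.bin_starts, self.bin_ends)], dtype=object)
        return np.asarray([w[3] for w in self.windows], dtype=object)

    @property
    def bin_midpoints(self) -> np.ndarray:
        return (self.bin_starts + self.bin_ends) / 2.0

    @property
    def bin_widths(self) -> np.ndarray:
        return self.bin_ends - self.bin_starts

    @property
    def has_overlaps(self) -> bool:
        if self.uniform:
            return False
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end, _ in self.windows:
            by_chrom.setdefault(chrom, []).append((start, end))
        for intervals in by_chrom.values():
            intervals.sort()
            for (s1, e1), (s2, _) in zip(intervals, intervals[1:]):
                if s2 < e1:
                    return True
        return False

    def chrom_bin_indices(self, chrom: str) -> np.ndarray:
        """Bin indices belonging to one chromosome."""
        if self.uniform:
            off = self._chrom_offsets[chrom]
            n = dict(zip(self.genome.chrom_names, self._chrom_nbins.tolist()))[chrom]
            return np.arange(off, off + n)
        return np.flatnonzero(self.bin_chroms == chrom)

    def assign(self, chroms: np.ndarray, positions: np.ndarray
               ) -> tuple[np.ndarray, np.ndarray]:
        """Map (chrom, pos) pairs to bin indices.

        Returns ``(record_idx, bin_idx)`` pairs; a record absent from the
        scheme yields no pair (uniform mode) and a record inside several
        explicit windows yields one pair per window.
        """
        chroms = np.asarray(chroms, dtype=object)
        positions = np.asarray(positions)
        if self.uniform:
            rec_idx, bin_idx = [], []
            for chrom in np.unique(chroms):
                mask = chroms == chrom
                if chrom not in self.genome:
                    continue
                idx = self._chrom_offsets[chrom] + positions[mask] // self.bin_size
                rec_idx.append(np.flatnonzero(mask))
                bin_idx.append(idx)
            if not rec_idx:
                return np.array([], dtype=int), np.array([], dtype=int)
            return np.concatenate(rec_idx), np.concatenate(bin_idx).astype(int)
        rec_idx, bin_idx = [], []
        starts, ends, wchroms = self.bin_starts, self.bin_ends, self.bin_chroms
        for j in range(self.n_bins):
            mask = (chroms == wchroms[j]) & (positions >= starts[j]) & (positions < ends[j])
            hits = np.flatnonzero(mask)
            rec_idx.append(hits)
            bin_idx.append(np.full(hits.size, j))
        return np.concatenate(rec_idx), np.concatenate(bin_idx).astype(int)


@dataclass
class ContactMatrix:
    """Sparse RNA x genomic-bin contact count matrix for one sample."""

    counts: sp.csr_matrix
    gene_ids: pd.Index
    scheme: BinScheme
    sample_id: str | None = None
    n_unassigned: int = 0

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        if self.counts.shape != (len(self.gene_ids), self.scheme.n_bins):
            raise ValueError("counts shape does not match gene/bin indexes")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("contact counts must be non-negative")

    @property
    def totals(self) -> pd.Series:
        """Per-RNA total contact counts N_i."""
        return pd.Series(np.asarray(self.counts.sum(axis=1)).ravel(),
                         index=self.gene_ids, name="N")

    def per_chromosome_totals(self) -> pd.DataFrame:
        """Per-RNA per-chromosome contact totals (genes x chromosomes)."""
        chroms = self.scheme.bin_chroms
        out = {}
        for chrom in self.scheme.genome.chrom_names:
            cols = np.flatnonzero(chroms == chrom)
            out[chrom] = np.asarray(self.counts[:, cols].sum(axis=1)).ravel()
        return pd.DataFrame(out, index=self.gene_ids)

    def row(self, gene_id: str) -> np.ndarray:
        i = self.gene_ids.get_loc(gene_id)
        return np.asarray(self.counts[i].todense()).ravel()


def bin_contacts(records: Sequence[ContactRecord], scheme: BinScheme,
                 gene_ids: Iterable[str] | None = None,
                 sample_id: str | None = None) -> ContactMatrix:
    """Tally DNA-side positions of each record into a sparse contact matrix.

    Records on chromosomes absent from the scheme are counted as unassigned
    (warning logged), so assigned + unassigned = input.
    """
    df = records_to_frame(records) if not isinstance(records, pd.DataFrame) else records
    if gene_ids is None:
        gene_index = pd.Index(pd.unique(df["rna_gene_id"])) if len(df) else pd.Index([])
    else:
        gene_index = pd.Index(gene_ids)
    if sample_id is None and len(df):
        uniq = df["sample_id"].unique()
        sample_id = uniq[0] if len(uniq) == 1 else None
    n = len(df)
    if n == 0:
        mat = sp.csr_matrix((len(gene_index), scheme.n_bins), dtype=np.int64)
        return ContactMatrix(mat, gene_index, scheme, sample_id, 0)
    rec_idx, bin_idx = scheme.assign(df["dna_chrom"].to_numpy(),
                                     df["dna_pos"].to_numpy())
    gene_codes = gene_index.get_indexer(df["rna_gene_id"].to_numpy()[rec_idx])
    keep = gene_codes >= 0
    n_unassigned = n - len(np.unique(rec_idx)) if scheme.uniform else 0
    if n_unassigned:
        logger.warning("%d contacts on chromosomes absent from the bin scheme", n_unassigned)
    mat = sp.coo_matrix(
        (np.ones(keep.sum(), dtype=np.int64), (gene_codes[keep], bin_idx[keep])),
        shape=(len(gene_index), scheme.n_bins),
    ).tocsr()
    return ContactMatrix(mat, gene_index, scheme, sample_id, n_unassigned)


def rna_coverage_track(records: Sequence[ContactRecord], rna_gene_id: str,
                       bin_size: int, genome: GenomeLayout) -> pd.DataFrame:
    """Per-bin DNA contact counts of one RNA as a bedGraph-style frame.

    Columns chrom/start/end/count; only non-zero bins are reported, so the
    count column sums to the number of that RNA's records.
    """
    df = records_to_frame(records) if not isinstance(records, pd.DataFrame) else records
    sub = df[df["rna_gene_id"] == rna_gene_id]
    if len(sub) == 0:
        logger.warning("gene %s absent from records; empty track", rna_gene_id)
        return pd.DataFrame(columns=["chrom", "start", "end", "count"])
    scheme = BinScheme(genome, bin_size=bin_size)
    rec_idx, bin_idx = scheme.assign(sub["dna_chrom"].to_numpy(), sub["dna_pos"].to_numpy())
    counts = np.bincount(bin_idx, minlength=scheme.n_bins)
    nz = np.flatnonzero(counts)
    return pd.DataFrame(
        {
            "chrom": scheme.bin_chroms[nz],
            "start": scheme.bin_starts[nz],
            "end": scheme.bin_ends[nz],
            "count": counts[nz],
        }
    )


def write_bedgraph(track: pd.DataFrame, path) -> None:
    track.to_csv(path, sep="\t", header=False, index=False)
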