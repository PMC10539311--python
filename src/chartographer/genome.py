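"""Genome layout and gene-model containers.

Coordinates are 0-based, half-open throughout the package (BED convention).
Strand-aware anchors (TSS, 3' end) are derived properties of :class:`GeneModel`.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
import pyranges as pr

__all__ = [
    "GenomeLayout",
    "GeneModel",
    "read_chrom_sizes",
    "write_chrom_sizes",
    "read_gene_models",
    "write_gene_models",
    "gene_models_to_frame",
]


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosome names and lengths (bp)."""

    chrom_names: tuple[str, ...]
    chrom_lengths: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.chrom_names) != len(set(self.chrom_names)):
            raise ValueError("chromosome names must be unique")
        if len(self.chrom_names) != len(self.chrom_lengths):
            raise ValueError("names and lengths differ in length")
        if any(length <= 0 for length in self.chrom_lengths):
            raise ValueError("all chromosome lengths must be > 0")

    @property
    def sizes(self) -> dict[str, int]:
        return dict(zip(self.chrom_names, self.chrom_lengths))

    @property
    def total_length(self) -> int:
        return int(sum(self.chrom_lengths))

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sizes

    def length_of(self, chrom: str) -> int:
        try:
            return self.sizes[chrom]
        except KeyError:
            raise KeyError(f"chromosome {chrom!r} not in genome layout") from None


@dataclass(frozen=True)
class GeneModel:
    """A gene interval with its RNA class.

    ``rna_class`` is one of ``mRNA``, ``lncRNA``, ``ncRNA:<subtype>`` or ``UTL``.
    """

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    rna_class: str = "mRNA"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) for {self.gene_id}"
            )

    @property
    def tss(self) -> int:
        """Strand-aware 5' end (transcription start site)."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def gene_3prime(self) -> int:
        """Strand-aware 3' end."""
        return self.end - 1 if self.strand == "+" else self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    @property
    def length(self) -> int:
        return self.end - self.start


def read_chrom_sizes(path) -> GenomeLayout:
    """Read a two-column ``chrom.sizes`` file into a :class:`GenomeLayout`."""
    names, lengths = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected two tab-separated columns")
            names.append(parts[0])
            lengths.append(int(parts[1]))
    return GenomeLayout(tuple(names), tuple(lengths))


def write_chrom_sizes(layout: GenomeLayout, path) -> None:
    with open(path, "w") as fh:
        for name, length in zip(layout.chrom_names, layout.chrom_lengths):
            fh.write(f"{name}\t{length}\n")


def gene_models_to_frame(genes: list[GeneModel]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "chrom": [g.chrom for g in genes],
            "strand": [g.strand for g in genes],
            "start": [g.start for g in genes],
            "end": [g.end for g in genes],
            "rna_class": [g.rna_class for g in genes],
        }
    )


def write_gene_models(genes: list[GeneModel], path) -> None:
    """Write gene models as GTF (1-based, closed intervals on disk)."""
    df = pd.DataFrame(
        {
            "Chromosome": [g.chrom for g in genes],
            "Source": "chartographer",
            "Feature": "gene",
            "Start": [g.start for g in genes],
            "End": [g.end for g in genes],
            "Score": ".",
            "Strand": [g.strand for g in genes],
            "Frame": ".",
            "gene_id": [g.gene_id for g in genes],
            "gene_type": [g.rna_class for g in genes],
        }
    )
    pr.PyRanges(df).to_gtf(str(path))


def read_gene_models(path) -> list[GeneModel]:
    """Read gene models from GTF (``gene`` features; attributes gene_id, gene_type)."""
    gr = pr.read_gtf(str(path))
    df = gr.df
    df = df[df["Feature"] == "gene"]
    genes = []
    for row in df.itertuples(index=False):
        genes.append(
            GeneModel(
                gene_id=str(row.gene_id),
                chrom=str(row.Chromosome),
                strand=str(row.Strand),
                start=int(row.Start),
                end=int(row.End),
                rna_class=str(getattr(row, "gene_type", "mRNA")),
            )
        )
    return genes
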