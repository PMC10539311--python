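"""Generative null model of RNA-DNA contact maps.

The probability for an RNA transcribed at positions {r_k} to contact genomic
bin j is, in cis,

    p_j  propto  b_j * sum_k rho(d_j - r_k)

with rho the distance-decay contact density (per bp) and b_j an
RNA-independent DNA-locus bias; on trans chromosomes p_j is proportional to
b_j alone.  Conditional on the observed per-RNA per-chromosome contact
totals, each chromosome's contacts follow a multinomial with these
probabilities, so simulated maps preserve every per-RNA per-chromosome total
exactly.  Both rho and b_j are estimated from mRNA contacts, the assumption
being that mRNAs have no defined chromatin targets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .contacts import BinScheme, ContactMatrix, ContactRecord, records_to_frame
from .genome import GeneModel

__all__ = [
    "DistanceKernel",
    "DNABias",
    "PredictedMap",
    "estimate_kernel",
    "estimate_bias",
    "cis_probabilities",
    "predict_expected_map",
    "simulate_model_map",
    "ContactGenerativeModel",
    "ContactGenerativeModelResults",
]


@dataclass(frozen=True)
class DistanceKernel:
    """Piecewise-constant per-bp contact density over log-spaced |delta| bins.

    ``edges`` has length len(density)+1 and starts at 0; distances beyond the
    last edge take the uniform ``floor`` density.  The density integrates to
    one over [0, edges[-1]].
    """

    edges: np.ndarray
    density: np.ndarray
    floor: float
    training_class: str = "mRNA"
    n_contacts: int = 0

    def __post_init__(self) -> None:
        edges = np.asarray(self.edges, dtype=float)
        dens = np.asarray(self.density, dtype=float)
        if len(edges) != len(dens) + 1:
            raise ValueError("edges must have len(density) + 1 entries")
        if np.any(dens < 0):
            raise ValueError("density must be non-negative")
        total = float(np.sum(dens * np.diff(edges)))
        if not np.isclose(total, 1.0, atol=1e-9):
            raise ValueError(f"density must integrate to 1, got {total}")
        object.__setattr__(self, "edges", edges)
        object.__setattr__(self, "density", dens)

    def evaluate(self, dist) -> np.ndarray:
        """Per-bp density rho(|delta|); beyond the modeled range: the floor."""
        d = np.abs(np.asarray(dist, dtype=float))
        idx = np.searchsorted(self.edges, d, side="right") - 1
        out = np.full(d.shape, self.floor)
        inside = (idx >= 0) & (idx < len(self.density))
        out[inside] = self.density[idx[inside]]
        return out


@dataclass(frozen=True)
class DNABias:
    """Per-bin DNA-locus bias b_j over a bin scheme; sums to one genome-wide."""

    values: np.ndarray
    scheme: BinScheme
    pseudocount: float = 0.5

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if len(vals) != self.scheme.n_bins:
            raise ValueError("bias length does not match scheme")
        if np.any(vals <= 0):
            raise ValueError("bias must be strictly positive")
        if abs(vals.sum() - 1.0) > 1e-12:
            raise ValueError("bias must sum to 1 within 1e-12")
        object.__setattr__(self, "values", vals)


@dataclass
class PredictedMap:
    """Expected counts per RNA x bin, conditioned on per-chromosome totals."""

    expected: np.ndarray
    gene_ids: pd.Index
    scheme: BinScheme


def estimate_kernel(records: Sequence[ContactRecord] | pd.DataFrame,
                    gene_models: Sequence[GeneModel],
                    training_class: str = "mRNA",
                    bins_per_decade: int = 25,
                    min_distance: float = 100.0,
                    min_contacts: int = 1000,
                    floor_weight: float = 1e-3) -> DistanceKernel:
    """Estimate the distance-decay density from cis training-class contacts.

    Histogram of |delta| over log-spaced bins (``bins_per_decade`` from
    ``min_distance`` up to the longest chromosome), converted to per-bp
    density, mixed with a uniform floor of weight ``floor_weight`` (so empty
    bins and bins beyond the last observed distance stay positive), and
    normalized.
    """
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    genes = {g.gene_id: g for g in gene_models}
    cls = df["rna_gene_id"].map(lambda g: genes[g].rna_class if g in genes else None)
    src = df["rna_gene_id"].map(lambda g: genes[g].chrom if g in genes else None)
    mask = (cls == training_class) & (df["dna_chrom"].to_numpy() == src.to_numpy())
    sub = df[mask]
    if len(sub) < min_contacts:
        raise ValueError(f"need >= {min_contacts} cis training contacts, got {len(sub)}")
    delta = np.abs(sub["dna_pos"].to_numpy() - sub["rna_pos"].to_numpy())
    max_len = float(max(g.end for g in gene_models))
    # modeled range extends to the longest chromosome if the scheme is known
    max_range = max(max_len, float(delta.max()) + 1.0)
    n_decades = np.log10(max_range / min_distance)
    n_bins = max(int(np.ceil(n_decades * bins_per_decade)), 1)
    edges = np.concatenate([[0.0],
                            np.logspace(np.log10(min_distance),
                                        np.log10(max_range), n_bins + 1)])
    hist, _ = np.histogram(delta, bins=edges)
    widths = np.diff(edges)
    emp = hist / hist.sum() / widths
    uniform = 1.0 / edges[-1]
    density = (1.0 - floor_weight) * emp + floor_weight * uniform
    density = density / np.sum(density * widths)
    return DistanceKernel(edges, density, floor=floor_weight * uniform,
                          training_class=training_class, n_contacts=len(sub))


def estimate_bias(matrix: ContactMatrix, gene_models: Sequence[GeneModel],
                  training_class: str = "mRNA",
                  pseudocount: float = 0.5) -> DNABias:
    """Estimate per-bin bias from trans coverage of training-class RNAs.

    For each bin, counts from training RNAs whose source chromosome differs
    from the bin's chromosome are summed, a pseudocount added, and the vector
    normalized to sum one.
    """
    genes = {g.gene_id: g for g in gene_models}
    bin_chroms = matrix.scheme.bin_chroms
    coverage = np.zeros(matrix.scheme.n_bins)
    n_trans = 0
    for i, gid in enumerate(matrix.gene_ids):
        g = genes.get(gid)
        if g is None or g.rna_class != training_class:
            continue
        row = np.asarray(matrix.counts[i].todense()).ravel()
        trans_mask = bin_chroms != g.chrom
        coverage[trans_mask] += row[trans_mask]
        n_trans += int(row[trans_mask].sum())
    if n_trans == 0:
        raise ValueError("no trans contacts from the training class; cannot estimate bias")
    vals = coverage + pseudocount
    return DNABias(vals / vals.sum(), matrix.scheme, pseudocount)


def cis_probabilities(source_positions, kernel: DistanceKernel,
                      bias_values: np.ndarray, bin_midpoints: np.ndarray,
                      ) -> np.ndarray:
    """Multinomial cis probabilities p_j propto b_j * sum_k rho(d_j - r_k)."""
    r = np.atleast_1d(np.asarray(source_positions, dtype=float))
    if r.size == 0:
        raise ValueError("need at least one source position")
    mids = np.asarray(bin_midpoints, dtype=float)
    rho = kernel.evaluate(mids[None, :] - r[:, None]).sum(axis=0)
    weights = np.asarray(bias_values, dtype=float) * rho
    total = weights.sum()
    if total <= 0:
        raise ValueError("degenerate cis probabilities (all-zero weights)")
    return weights / total


def _per_rna_probabilities(matrix: ContactMatrix, kernel: DistanceKernel,
                           bias: DNABias, gene_models: Sequence[GeneModel],
                           source_positions: dict[str, np.ndarray] | None = None):
    """Yield (row index, chromosome, bin indices, probabilities, N_i_c)."""
    if bias.scheme is not matrix.scheme and bias.scheme.n_bins != matrix.scheme.n_bins:
        raise ValueError("bias estimated on an incompatible bin scheme")
    genes = {g.gene_id: g for g in gene_models}
    scheme = matrix.scheme
    per_chrom = matrix.per_chromosome_totals()
    chrom_bins = {c: scheme.chrom_bin_indices(c) for c in scheme.genome.chrom_names}
    mids = scheme.bin_midpoints
    for i, gid in enumerate(matrix.gene_ids):
        g = genes.get(gid)
        if g is None:
            raise KeyError(f"gene {gid!r} absent from gene models")
        for chrom in scheme.genome.chrom_names:
            n_ic = int(per_chrom.iloc[i][chrom])
            bins = chrom_bins[chrom]
            b = bias.values[bins]
            if chrom == g.chrom:
                src = (source_positions.get(gid, np.array([g.midpoint]))
                       if source_positions else np.array([g.midpoint]))
                p = cis_probabilities(src, kernel, b, mids[bins])
            else:
                p = b / b.sum()
            yield i, chrom, bins, p, n_ic


def predict_expected_map(matrix: ContactMatrix, kernel: DistanceKernel,
                         bias: DNABias, gene_models: Sequence[GeneModel],
                         source_positions: dict[str, np.ndarray] | None = None,
                         ) -> PredictedMap:
    """Expected counts N_{i,c} * p_j; per-chromosome marginals match exactly."""
    expected = np.zeros((len(matrix.gene_ids), matrix.scheme.n_bins))
    for i, _, bins, p, n_ic in _per_rna_probabilities(
            matrix, kernel, bias, gene_models, source_positions):
        expected[i, bins] = n_ic * p
    return PredictedMap(expected, matrix.gene_ids, matrix.scheme)


def simulate_model_map(matrix: ContactMatrix, kernel: DistanceKernel,
                       bias: DNABias, gene_models: Sequence[GeneModel],
                       seed: int = 0,
                       source_positions: dict[str, np.ndarray] | None = None,
                       ) -> ContactMatrix:
    """One realization of the model, conditioned on per-chromosome totals."""
    rng = np.random.default_rng(seed)
    out = np.zeros((len(matrix.gene_ids), matrix.scheme.n_bins), dtype=np.int64)
    for i, _, bins, p, n_ic in _per_rna_probabilities(
            matrix, kernel, bias, gene_models, source_positions):
        if n_ic > 0:
            out[i, bins] = rng.multinomial(n_ic, p)
    return ContactMatrix(sp.csr_matrix(out), matrix.gene_ids, matrix.scheme,
                         sample_id=(f"{matrix.sample_id}:model"
                                    if matrix.sample_id else "model"))


class ContactGenerativeModel:
    """Model object bundling kernel and bias estimation from training contacts."""

    def __init__(self, records, gene_models: Sequence[GeneModel],
                 scheme: BinScheme, training_class: str = "mRNA"):
        self.records = (records if isinstance(records, pd.DataFrame)
                        else records_to_frame(records))
        self.gene_models = list(gene_models)
        self.scheme = scheme
        self.training_class = training_class

    def fit(self, matrix: ContactMatrix | None = None,
            **kernel_kwargs) -> "ContactGenerativeModelResults":
        from .contacts import bin_contacts

        if matrix is None:
            matrix = bin_contacts(self.records, self.scheme)
        kernel = estimate_kernel(self.records, self.gene_models,
                                 training_class=self.training_class,
                                 **kernel_kwargs)
        bias = estimate_bias(matrix, self.gene_models,
                             training_class=self.training_class)
        return ContactGenerativeModelResults(self, kernel, bias)


class ContactGenerativeModelResults:
    """Fitted kernel + bias with prediction and simulation methods."""

    def __init__(self, model: ContactGenerativeModel, kernel: DistanceKernel,
                 bias: DNABias):
        self.model = model
        self.kernel = kernel
        self.bias = bias

    def predict(self, matrix: ContactMatrix,
                source_positions: dict[str, np.ndarray] | None = None) -> PredictedMap:
        return predict_expected_map(matrix, self.kernel, self.bias,
                                    self.model.gene_models, source_positions)

    def simulate(self, matrix: ContactMatrix, seed: int = 0,
                 source_positions: dict[str, np.ndarray] | None = None) -> ContactMatrix:
        return simulate_model_map(matrix, self.kernel, self.bias,
                                  self.model.gene_models, seed=seed,
                                  source_positions=source_positions)

    def summary(self) -> str:
        k = self.kernel
        return (
            "Generative contact model\n"
            f"  kernel: {len(k.density)} log bins to {k.edges[-1]:.3g} bp, "
            f"trained on {k.n_contacts} {k.training_class} cis contacts\n"
            f"  bias: {self.bias.scheme.n_bins} bins, pseudocount "
            f"{self.bias.pseudocount}"
        )
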