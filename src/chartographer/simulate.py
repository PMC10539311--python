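"""Ground-truth-annotated synthetic RNA-DNA contact datasets.

The generator draws data from the same statistical structure the analysis
assumes: per-RNA contact totals from expression weights, a beta-binomial
cis/trans split with a logit-linear mean (into which planted delocalization
offsets are added), cis placement from a truncated power-law distance kernel
mixed with a uniform floor and modulated by a per-bin DNA bias, trans
placement proportional to the bias alone, planted type III peak mass,
an XIST-like RNA (cis-delocalized and trans-excluded), two cell states with
per-RNA expression fold changes, and a paired total-RNA-seq count table tied
to per-gene chromatin-enrichment factors.

Defaults describe a desk-scale study: 3 chromosomes x 30 Mb, 500 RNAs,
2e5 contacts per sample, 2 states x 2 replicates.  The kernel default
(alpha = 2, delta0 = 10 kb) gives a ~100-fold density drop 100 kb from the
transcription locus, matching the scale of decay seen in real contact data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .betabin import BetaBinomialGLMResults
from .contacts import write_pairs
from .genome import GeneModel, GenomeLayout, write_gene_models, write_chrom_sizes

__all__ = [
    "KernelParams",
    "SimulationConfig",
    "PlantedTruth",
    "SimulatedDataset",
    "simulate_dataset",
    "simulate_null_glm_counts",
    "sample_travel_distances",
    "truth_report",
]


@dataclass(frozen=True)
class KernelParams:
    """Truncated power-law distance kernel with a uniform floor.

    rho(delta) propto (|delta| + delta0)^(-alpha) with probability
    1 - floor_weight, else uniform over the chromosome.
    """

    alpha: float = 2.0
    delta0: float = 10_000.0
    floor_weight: float = 0.02

    def powerlaw_cdf(self, delta, delta_max: float) -> np.ndarray:
        """CDF of the power-law component truncated to [0, delta_max]."""
        d = np.clip(np.asarray(delta, dtype=float), 0.0, delta_max)
        a, d0 = self.alpha, self.delta0
        if abs(a - 1.0) < 1e-12:
            return np.log1p(d / d0) / np.log1p(delta_max / d0)
        A = d0 ** (1.0 - a)
        B = (delta_max + d0) ** (1.0 - a)
        return (A - (d + d0) ** (1.0 - a)) / (A - B)

    def powerlaw_sample(self, rng: np.random.Generator, n: int,
                        delta_max: float) -> np.ndarray:
        """Inverse-CDF draw from the truncated power-law component."""
        a, d0 = self.alpha, self.delta0
        u = rng.random(n)
        if abs(a - 1.0) < 1e-12:
            return d0 * ((1.0 + delta_max / d0) ** u - 1.0)
        A = d0 ** (1.0 - a)
        B = (delta_max + d0) ** (1.0 - a)
        return (A - u * (A - B)) ** (1.0 / (1.0 - a)) - d0


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic dataset."""

    # genome
    n_chroms: int = 3
    chrom_length: int = 30_000_000
    # RNA roster (counts per class) and expression distribution (log-normal)
    n_rnas: dict = field(default_factory=lambda:
                         {"mRNA": 300, "lncRNA": 100, "ncRNA": 50, "UTL": 50})
    expr_mu: float = 0.0
    expr_sigma: float = 1.0
    gene_length_mu: float = np.log(10_000.0)
    gene_length_sigma: float = 0.5
    # distance kernel and DNA bias
    kernel: KernelParams = field(default_factory=KernelParams)
    bias_sigma: float = 0.0            # log-normal per-bin bias; 0 = uniform
    bias_bin_size: int = 100_000
    # trans-contact GLM truth
    eta_chr: tuple = (-1.6, -1.8, -1.7)
    eta_expr: float = 0.0
    gamma: float = 0.02
    # planted effects
    n_trans_delocalized: int = 20
    n_trans_ultralocalized: int = 20
    trans_offset: float = 2.5          # logit units
    n_cis_delocalized: int = 10
    cis_offset: float = 2.5
    n_xist_like: int = 1
    xist_trans_factor: float = 1e-3    # multiplies trans odds
    n_peak_rnas: int = 5
    peak_frac: float = 0.05            # fraction of cis contacts routed to the peak
    peak_width: int = 100_000
    peak_expr_boost: float = 10.0      # expression multiplier for peak-bearing RNAs
    n_reloc_rnas: int = 2              # RNAs moving mass from locus A (ES) to B (DE)
    reloc_frac: float = 0.10
    cis_threshold: int = 1_000_000     # D used to calibrate planted cis offsets
    # two-state dynamics
    frac_dynamic: float = 0.3
    lfc_magnitude: tuple = (1.5, 3.0)  # |log2 FC| range for dynamic RNAs
    de_lfc_threshold: float = 1.0
    # paired RNA-seq
    chromatin_enrich_sigma: float = 0.5    # log2-scale spread of enrichment factors
    n_enriched_genes: int = 10
    enriched_factor: float = 8.0
    rnaseq_depth: int = 200_000
    rnaseq_replicates: int = 2
    # sampling
    depth: int = 200_000
    replicates_per_state: int = 2
    states: tuple = ("ES", "DE")

    def __post_init__(self) -> None:
        if len(self.eta_chr) != self.n_chroms:
            raise ValueError("eta_chr must have one entry per chromosome")
        if self.depth <= 0 or self.rnaseq_depth <= 0:
            raise ValueError("depths must be > 0")
        if not (0 <= self.gamma < 1):
            raise ValueError("gamma must be in [0, 1)")

    @property
    def genome(self) -> GenomeLayout:
        return GenomeLayout(tuple(f"chr{i + 1}" for i in range(self.n_chroms)),
                            (self.chrom_length,) * self.n_chroms)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "kernel" in raw and isinstance(raw["kernel"], dict):
            raw["kernel"] = KernelParams(**raw["kernel"])
        for key in ("eta_chr", "lfc_magnitude", "states"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        import yaml

        def plain(v):
            if isinstance(v, dict):
                return {k: plain(x) for k, x in v.items()}
            if isinstance(v, (tuple, list)):
                return [plain(x) for x in v]
            if isinstance(v, np.generic):
                return v.item()
            return v

        with open(path, "w") as fh:
            yaml.safe_dump(plain(asdict(self)), fh, sort_keys=False)


@dataclass
class PlantedTruth:
    """Ground truth: per-RNA effects, peaks, kernel, bias, enrichment."""

    rnas: pd.DataFrame          # gene_id, rna_class, offsets, flags, lfc, de_label
    peaks: pd.DataFrame         # gene_id, chrom, start, end, frac
    relocs: pd.DataFrame        # gene_id, chrom, A/B windows, frac
    kernel: KernelParams
    bias: pd.DataFrame          # chrom, start, end, bias
    config: SimulationConfig


@dataclass
class SimulatedDataset:
    samples: dict                      # sample_id -> DataFrame of contact records
    sample_states: dict                # sample_id -> state
    gene_models: list
    genome: GenomeLayout
    rnaseq_counts: pd.DataFrame        # genes x RNA-seq samples
    charseq_gene_counts: pd.DataFrame  # genes x ChAR samples (RNA-side totals)
    truth: PlantedTruth

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for sample_id, df in self.samples.items():
            from .contacts import frame_to_records
            write_pairs(frame_to_records(df), outdir / f"{sample_id}.pairs",
                        genome=self.genome)
        write_gene_models(self.gene_models, outdir / "genes.gtf")
        write_chrom_sizes(self.genome, outdir / "genome.chrom.sizes")
        self.rnaseq_counts.to_csv(outdir / "rnaseq_counts.tsv", sep="\t")
        self.charseq_gene_counts.to_csv(outdir / "charseq_gene_counts.tsv", sep="\t")
        self.truth.rnas.to_csv(outdir / "truth_rnas.tsv", sep="\t", index=False)
        self.truth.peaks.to_csv(outdir / "truth_peaks.tsv", sep="\t", index=False)


def sample_travel_distances(kernel: KernelParams, rng: np.random.Generator,
                            source_pos: np.ndarray, chrom_length: int,
                            max_retries: int = 200) -> np.ndarray:
    """Draw DNA positions around source positions from the kernel mixture.

    Power-law draws landing off the chromosome are redrawn (sign included);
    the uniform-floor component draws positions uniformly over the chromosome.
    Returns DNA positions (same length as ``source_pos``).
    """
    n = len(source_pos)
    out = np.empty(n)
    is_floor = rng.random(n) < kernel.floor_weight
    out[is_floor] = rng.uniform(0, chrom_length, is_floor.sum())
    idx = np.flatnonzero(~is_floor)
    pending = idx
    for _ in range(max_retries):
        if pending.size == 0:
            break
        delta = kernel.powerlaw_sample(rng, pending.size, float(chrom_length))
        sign = rng.choice([-1.0, 1.0], size=pending.size)
        d = source_pos[pending] + sign * delta
        ok = (d >= 0) & (d < chrom_length)
        out[pending[ok]] = d[ok]
        pending = pending[~ok]
    if pending.size:
        out[pending] = rng.uniform(0, chrom_length, pending.size)
    return out


def cis_far_fraction(kernel: KernelParams, source: float,
                     chrom_length: float, D: float) -> float:
    """P(|delta| > D) for a contact placed by the kernel mixture around
    ``source``, accounting for chromosome-end truncation."""
    L = float(chrom_length)
    near_lo, near_hi = max(source - D, 0.0), min(source + D, L)
    q = 1.0 - (near_hi - near_lo) / L          # far mass of the uniform floor
    cdf = kernel.powerlaw_cdf
    hi, lo = L - source, source                # reach on each side
    far_mass = 0.0
    if hi > D:
        far_mass += 0.5 * (cdf(hi, L) - cdf(D, L))
    if lo > D:
        far_mass += 0.5 * (cdf(lo, L) - cdf(D, L))
    denom = 0.5 * cdf(hi, L) + 0.5 * cdf(lo, L)
    p_kernel = far_mass / max(denom, 1e-12)
    return float((1 - kernel.floor_weight) * p_kernel + kernel.floor_weight * q)


def _powerlaw_sample_range(kernel: KernelParams, rng: np.random.Generator,
                           lo, hi, delta_max: float) -> np.ndarray:
    """Inverse-CDF draw from the power-law component restricted to [lo, hi]."""
    lo = np.asarray(lo, dtype=float)
    hi = np.asarray(hi, dtype=float)
    flo = kernel.powerlaw_cdf(lo, delta_max)
    fhi = kernel.powerlaw_cdf(hi, delta_max)
    u = flo + rng.random(np.broadcast(lo, hi).shape) * (fhi - flo)
    a, d0 = kernel.alpha, kernel.delta0
    if abs(a - 1.0) < 1e-12:
        return d0 * ((1.0 + delta_max / d0) ** u - 1.0)
    A = d0 ** (1.0 - a)
    B = (delta_max + d0) ** (1.0 - a)
    return (A - u * (A - B)) ** (1.0 / (1.0 - a)) - d0


def _sample_cis_class(kernel: KernelParams, rng: np.random.Generator,
                      source: np.ndarray, chrom_length: int, D: float,
                      far: bool) -> np.ndarray:
    """Exact draw of DNA positions from the kernel mixture conditioned on the
    travel-distance class (|delta| > D for far, <= D for near).

    Matches the conditional law of :func:`sample_travel_distances` given the
    class, so recombining classes at their unconditional rates reproduces the
    unconditional kernel placement.
    """
    L = float(chrom_length)
    r = np.asarray(source, dtype=float)
    n = len(r)
    out = np.empty(n)
    reach_hi = L - r
    reach_lo = r
    cdf = kernel.powerlaw_cdf
    # component masses within the class
    if far:
        seg_lo = np.maximum(r - D, 0.0)
        seg_hi = np.minimum(r + D, L)
        floor_mass = kernel.floor_weight * (L - (seg_hi - seg_lo)) / L
        pl_hi = np.where(reach_hi > D, cdf(reach_hi, L) - cdf(D, L), 0.0)
        pl_lo = np.where(reach_lo > D, cdf(reach_lo, L) - cdf(D, L), 0.0)
    else:
        seg_lo = np.maximum(r - D, 0.0)
        seg_hi = np.minimum(r + D, L)
        floor_mass = kernel.floor_weight * (seg_hi - seg_lo) / L
        pl_hi = cdf(np.minimum(reach_hi, D), L)
        pl_lo = cdf(np.minimum(reach_lo, D), L)
    denom = 0.5 * cdf(reach_hi, L) + 0.5 * cdf(reach_lo, L)
    w_pl_hi = (1 - kernel.floor_weight) * 0.5 * pl_hi / denom
    w_pl_lo = (1 - kernel.floor_weight) * 0.5 * pl_lo / denom
    total = floor_mass + w_pl_hi + w_pl_lo
    total = np.maximum(total, 1e-300)
    u = rng.random(n) * total
    take_floor = u < floor_mass
    take_hi = (~take_floor) & (u < floor_mass + w_pl_hi)
    take_lo = ~(take_floor | take_hi)
    # uniform floor within the class region
    if take_floor.any():
        idx = np.flatnonzero(take_floor)
        if far:
            left_len = seg_lo[idx]
            right_len = L - seg_hi[idx]
            pick_left = rng.random(idx.size) * (left_len + right_len) < left_len
            pos = np.where(pick_left,
                           rng.random(idx.size) * left_len,
                           seg_hi[idx] + rng.random(idx.size) * right_len)
        else:
            pos = seg_lo[idx] + rng.random(idx.size) * (seg_hi[idx] - seg_lo[idx])
        out[idx] = pos
    # power-law tails per sign
    for mask, sign in ((take_hi, +1.0), (take_lo, -1.0)):
        if not mask.any():
            continue
        idx = np.flatnonzero(mask)
        reach = reach_hi[idx] if sign > 0 else reach_lo[idx]
        if far:
            lo_b, hi_b = np.full(idx.size, float(D)), reach
        else:
            lo_b, hi_b = np.zeros(idx.size), np.minimum(reach, float(D))
        delta = _powerlaw_sample_range(kernel, rng, lo_b, hi_b, L)
        out[idx] = r[idx] + sign * delta
    return np.clip(out, 0, L - 1)


def _make_genes(cfg: SimulationConfig, rng: np.random.Generator) -> list[GeneModel]:
    genes = []
    counter = 0
    for rna_class, count in cfg.n_rnas.items():
        for _ in range(count):
            chrom_i = rng.integers(cfg.n_chroms)
            length = int(np.clip(rng.lognormal(cfg.gene_length_mu,
                                               cfg.gene_length_sigma), 200,
                                 cfg.chrom_length / 10))
            start = int(rng.integers(0, cfg.chrom_length - length))
            prefix = {"mRNA": "GENE", "lncRNA": "LNC", "ncRNA": "NCR", "UTL": "UTL"}[rna_class]
            genes.append(GeneModel(f"{prefix}{counter:04d}", f"chr{chrom_i + 1}",
                                   "+" if rng.random() < 0.5 else "-",
                                   start, start + length, rna_class))
            counter += 1
    return genes


def _plant_effects(cfg: SimulationConfig, genes: list[GeneModel],
                   rng: np.random.Generator) -> tuple[pd.DataFrame, pd.DataFrame]:
    df = pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "rna_class": [g.rna_class for g in genes],
            "chrom": [g.chrom for g in genes],
            "trans_offset": 0.0,
            "cis_offset": 0.0,
            "xist_like": False,
            "peak": False,
        }
    )
    # planted effects go on non-training RNAs so the mRNA null stays clean
    pool = df.index[df["rna_class"] != "mRNA"].to_numpy()
    rng.shuffle(pool)
    cursor = 0

    def take(k):
        nonlocal cursor
        sel = pool[cursor:cursor + k]
        cursor += k
        return sel

    df.loc[take(cfg.n_trans_delocalized), "trans_offset"] = cfg.trans_offset
    df.loc[take(cfg.n_trans_ultralocalized), "trans_offset"] = -cfg.trans_offset
    df.loc[take(cfg.n_cis_delocalized), "cis_offset"] = cfg.cis_offset
    xist_rows = take(cfg.n_xist_like)
    df.loc[xist_rows, "xist_like"] = True
    df.loc[xist_rows, "cis_offset"] = cfg.cis_offset
    peak_rows = take(cfg.n_peak_rnas)
    df.loc[peak_rows, "peak"] = True
    df["reloc"] = False
    reloc_rows = take(cfg.n_reloc_rnas)
    df.loc[reloc_rows, "reloc"] = True
    # expression dynamics (relocalizing RNAs stay at constant abundance)
    n = len(df)
    dyn = (rng.random(n) < cfg.frac_dynamic) & ~df["reloc"].to_numpy()
    mag = rng.uniform(*cfg.lfc_magnitude, size=n)
    sign = rng.choice([-1.0, 1.0], size=n)
    df["expr_lfc"] = np.where(dyn, sign * mag, 0.0)  # log2(DE/ES)
    df["de_label"] = np.select(
        [df["expr_lfc"] > cfg.de_lfc_threshold, df["expr_lfc"] < -cfg.de_lfc_threshold],
        ["DE", "ES"], default="stable")
    # chromatin-enrichment factors (linear scale)
    enrich = 2.0 ** rng.normal(0.0, cfg.chromatin_enrich_sigma, size=n)
    enriched_rows = rng.choice(n, size=min(cfg.n_enriched_genes, n), replace=False)
    enrich[enriched_rows] = cfg.enriched_factor
    df["chromatin_enrich"] = enrich
    # peak / relocalization windows 1-3 Mb from the source gene, same chromosome
    gene_by_row = {i: genes[i] for i in range(n)}
    L = cfg.chrom_length

    def _window(g, width):
        for _ in range(100):
            offset = rng.uniform(1e6, 3e6) * rng.choice([-1, 1])
            start = int(g.midpoint + offset)
            if 0 <= start and start + width <= L:
                return start
        return max(0, min(int(g.midpoint + 1_500_000), L - width))

    peaks = []
    for i in peak_rows:
        g = gene_by_row[i]
        start = _window(g, cfg.peak_width)
        peaks.append({"gene_id": g.gene_id, "chrom": g.chrom, "start": start,
                      "end": start + cfg.peak_width, "frac": cfg.peak_frac})
    relocs = []
    for i in reloc_rows:
        g = gene_by_row[i]
        start_a = _window(g, cfg.peak_width)
        for _ in range(100):
            start_b = _window(g, cfg.peak_width)
            if abs(start_b - start_a) >= cfg.peak_width:
                break
        relocs.append({"gene_id": g.gene_id, "chrom": g.chrom,
                       "start_a": start_a, "end_a": start_a + cfg.peak_width,
                       "start_b": start_b, "end_b": start_b + cfg.peak_width,
                       "frac": cfg.reloc_frac})
    return (df,
            pd.DataFrame(peaks, columns=["gene_id", "chrom", "start", "end", "frac"]),
            pd.DataFrame(relocs, columns=["gene_id", "chrom", "start_a", "end_a",
                                          "start_b", "end_b", "frac"]))


def _bias_track(cfg: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for chrom in cfg.genome.chrom_names:
        starts = np.arange(0, cfg.chrom_length, cfg.bias_bin_size)
        vals = (np.exp(rng.normal(0.0, cfg.bias_sigma, size=len(starts)))
                if cfg.bias_sigma > 0 else np.ones(len(starts)))
        for s, v in zip(starts, vals):
            rows.append({"chrom": chrom, "start": int(s),
                         "end": int(min(s + cfg.bias_bin_size, cfg.chrom_length)),
                         "bias": float(v)})
    return pd.DataFrame(rows)


def _betabin_draw(rng, n, pi, gamma):
    n = np.asarray(n)
    pi = np.clip(np.asarray(pi, dtype=float), 1e-12, 1 - 1e-12)
    if gamma < 1e-12:
        return rng.binomial(n, pi)
    s = 1.0 / gamma - 1.0
    shape = np.broadcast(n, pi).shape
    p = rng.beta(np.broadcast_to(pi * s, shape),
                 np.broadcast_to((1 - pi) * s, shape))
    return rng.binomial(n, p)


def simulate_dataset(config: SimulationConfig, seed: int,
                     outdir=None) -> SimulatedDataset:
    """Draw the full synthetic dataset (deterministic given config and seed)."""
    root = np.random.default_rng(seed)
    rng_genes = np.random.default_rng(root.integers(2 ** 31))
    genes = _make_genes(config, rng_genes)
    truth_rnas, peaks, relocs = _plant_effects(config, genes, rng_genes)
    bias = _bias_track(config, rng_genes)
    base_expr = rng_genes.lognormal(config.expr_mu, config.expr_sigma,
                                    size=len(genes))
    boost = (truth_rnas["peak"] | truth_rnas["reloc"]).to_numpy()
    base_expr[boost] *= config.peak_expr_boost
    genome = config.genome
    gene_by_id = {g.gene_id: g for g in genes}
    chrom_index = {c: i for i, c in enumerate(genome.chrom_names)}
    eta_chr = np.asarray(config.eta_chr)

    bias_by_chrom = {c: grp for c, grp in bias.groupby("chrom")}
    bias_max = {c: grp["bias"].max() for c, grp in bias_by_chrom.items()}
    all_bias_vals = bias["bias"].to_numpy()
    bias_chroms = bias["chrom"].to_numpy()
    bias_starts = bias["start"].to_numpy()
    bias_widths = (bias["end"] - bias["start"]).to_numpy()
    annot_of = {"mRNA": "exon", "lncRNA": "exon", "ncRNA": "exon",
                "UTL": "intergenic"}

    # per-RNA baseline far fraction at the cis threshold, with planted offsets
    from scipy.special import expit, logit as slogit

    p_cis_far = np.empty(len(genes))
    for i, g in enumerate(genes):
        p0 = np.clip(cis_far_fraction(config.kernel, g.midpoint,
                                      config.chrom_length,
                                      config.cis_threshold), 1e-6, 1 - 1e-6)
        p_cis_far[i] = expit(slogit(p0) + truth_rnas.loc[i, "cis_offset"])

    peak_by_gene = {r.gene_id: r for r in peaks.itertuples(index=False)}
    reloc_by_gene = {r.gene_id: r for r in relocs.itertuples(index=False)}

    samples: dict[str, pd.DataFrame] = {}
    sample_states: dict[str, str] = {}
    char_counts = {}
    read_counter = 0
    for state in config.states:
        state_mult = np.where(
            np.repeat(True, len(genes)),
            2.0 ** (truth_rnas["expr_lfc"].to_numpy() if state == "DE" else 0.0),
            1.0,
        )
        weights = base_expr * state_mult
        weights = weights / weights.sum()
        for rep in range(1, config.replicates_per_state + 1):
            sample_id = f"{state}_rep{rep}"
            rng = np.random.default_rng(root.integers(2 ** 31))
            n_i = rng.multinomial(config.depth, weights)
            rows = {k: [] for k in ("read_id", "rna_gene_id", "rna_chrom", "rna_pos",
                                    "rna_strand", "dna_chrom", "dna_pos",
                                    "dna_strand", "annotation_class", "sample_id")}
            for i, g in enumerate(genes):
                n = int(n_i[i])
                if n == 0:
                    continue
                lnN = np.log(n)
                logit_pi = (eta_chr[chrom_index[g.chrom]]
                            + config.eta_expr * lnN
                            + truth_rnas.loc[i, "trans_offset"])
                if truth_rnas.loc[i, "xist_like"]:
                    logit_pi += np.log(config.xist_trans_factor)
                from scipy.special import expit
                pi = float(expit(logit_pi))
                n_trans = int(_betabin_draw(rng, n, pi, config.gamma))
                n_cis = n - n_trans
                # --- cis contacts: beta-binomial near/far split at the cis
                # threshold (RNA-level overdispersion), then class-conditioned
                # kernel placement so the unconditional law is the kernel
                n_far_cis = int(_betabin_draw(rng, n_cis, p_cis_far[i],
                                              config.gamma))
                r_pos = rng.integers(g.start, g.end, size=n_cis).astype(float)
                d_pos = np.empty(n_cis)
                is_far = np.zeros(n_cis, dtype=bool)
                is_far[rng.choice(n_cis, size=n_far_cis, replace=False)] = True
                for far_cls in (True, False):
                    m = is_far == far_cls
                    if m.any():
                        d_pos[m] = _sample_cis_class(
                            config.kernel, rng, r_pos[m], config.chrom_length,
                            config.cis_threshold, far=far_cls)
                # planted peak mass reroutes a fraction of cis contacts
                if truth_rnas.loc[i, "peak"] and g.gene_id in peak_by_gene:
                    pk = peak_by_gene[g.gene_id]
                    reroute = rng.random(n_cis) < pk.frac
                    d_pos[reroute] = rng.uniform(pk.start, pk.end, reroute.sum())
                # planted relocalization: window A in the first state, B in the second
                if truth_rnas.loc[i, "reloc"] and g.gene_id in reloc_by_gene:
                    rl = reloc_by_gene[g.gene_id]
                    lo, hi = ((rl.start_a, rl.end_a) if state == config.states[0]
                              else (rl.start_b, rl.end_b))
                    reroute = rng.random(n_cis) < rl.frac
                    d_pos[reroute] = rng.uniform(lo, hi, reroute.sum())
                # DNA-locus bias via rejection on the containing bias bin
                if config.bias_sigma > 0:
                    bmax = bias_max[g.chrom]
                    grp = bias_by_chrom[g.chrom]
                    bvals = grp["bias"].to_numpy()
                    pending = np.arange(n_cis)
                    for _ in range(200):
                        if pending.size == 0:
                            break
                        bins = (d_pos[pending] // config.bias_bin_size).astype(int)
                        accept = rng.random(pending.size) < bvals[bins] / bmax
                        redraw = pending[~accept]
                        for far_cls in (True, False):
                            sel = redraw[is_far[redraw] == far_cls]
                            if sel.size:
                                d_pos[sel] = _sample_cis_class(
                                    config.kernel, rng, r_pos[sel],
                                    config.chrom_length, config.cis_threshold,
                                    far=far_cls)
                        pending = redraw
                cis_d = np.clip(d_pos, 0, config.chrom_length - 1).astype(int)
                # --- trans contacts: bin chosen propto bias over trans bins
                trans_mask = bias_chroms != g.chrom
                tvals = all_bias_vals[trans_mask] * bias_widths[trans_mask]
                tprobs = tvals / tvals.sum()
                tbins = rng.choice(np.flatnonzero(trans_mask), size=n_trans, p=tprobs)
                t_chroms = bias_chroms[tbins]
                t_pos = (bias_starts[tbins]
                         + rng.integers(0, bias_widths[tbins])).astype(int)
                t_rpos = rng.integers(g.start, g.end, size=n_trans)
                # --- emit records
                total = n_cis + n_trans
                ids = [f"r{read_counter + k}" for k in range(total)]
                read_counter += total
                rows["read_id"].extend(ids)
                rows["rna_gene_id"].extend([g.gene_id] * total)
                rows["rna_chrom"].extend([g.chrom] * total)
                rows["rna_pos"].extend(np.concatenate([r_pos.astype(int), t_rpos]).tolist())
                rows["rna_strand"].extend([g.strand] * total)
                rows["dna_chrom"].extend([g.chrom] * n_cis + list(t_chroms))
                rows["dna_pos"].extend(np.concatenate([cis_d, t_pos]).tolist())
                rows["dna_strand"].extend(rng.choice(["+", "-"], size=total).tolist())
                rows["annotation_class"].extend([annot_of[g.rna_class]] * total)
                rows["sample_id"].extend([sample_id] * total)
            df = pd.DataFrame(rows)
            samples[sample_id] = df
            sample_states[sample_id] = state
            char_counts[sample_id] = pd.Series(n_i, index=[g.gene_id for g in genes])

    # --- paired total RNA-seq counts
    rnaseq = {}
    enrich = truth_rnas["chromatin_enrich"].to_numpy()
    for state in config.states:
        state_mult = 2.0 ** (truth_rnas["expr_lfc"].to_numpy()
                             if state == "DE" else 0.0)
        w = base_expr * state_mult / enrich
        w = w / w.sum()
        for rep in range(1, config.rnaseq_replicates + 1):
            rng = np.random.default_rng(root.integers(2 ** 31))
            rnaseq[f"rnaseq_{state}_rep{rep}"] = rng.multinomial(
                config.rnaseq_depth, w)
    rnaseq_df = pd.DataFrame(rnaseq, index=[g.gene_id for g in genes])
    char_df = pd.DataFrame(char_counts)

    ds = SimulatedDataset(samples, sample_states, genes, genome, rnaseq_df,
                          char_df, PlantedTruth(truth_rnas, peaks, relocs,
                                                config.kernel, bias, config))
    if outdir is not None:
        ds.write(outdir)
    return ds


def simulate_null_glm_counts(fit: BetaBinomialGLMResults, chrom, seed: int,
                             N=None, n: int | None = None,
                             N_range: tuple[float, float] = (500.0, 50_000.0),
                             ) -> pd.DataFrame:
    """Draw per-RNA (N, N_far) from a fitted beta-binomial null.

    ``N`` may be supplied; otherwise ``n`` totals are drawn log-uniform over
    ``N_range``.  With gamma <= 0 the draw falls back to binomial (warned).
    """
    import logging

    rng = np.random.default_rng(seed)
    chrom = np.asarray(chrom, dtype=object)
    if N is None:
        if n is None:
            n = len(chrom)
        N = np.exp(rng.uniform(np.log(N_range[0]), np.log(N_range[1]), size=n))
        N = np.round(N).astype(int)
    else:
        N = np.asarray(N, dtype=int)
    if len(chrom) != len(N):
        chrom = rng.choice(chrom, size=len(N))
    lnN = np.log(N.astype(float))
    pi = fit.predict(chrom, lnN)
    gamma = fit.gamma
    if gamma <= 0:
        logging.getLogger(__name__).warning(
            "gamma <= 0: simulating binomial counts")
        gamma = 0.0
    far = _betabin_draw(rng, N, pi, gamma)
    return pd.DataFrame({"gene_id": [f"sim{i}" for i in range(len(N))],
                         "chrom": chrom, "rna_class": "mRNA",
                         "N": N, "N_far": far, "lnN": lnN,
                         "N_near": N - far, "mode": "trans"})


def truth_report(truth_labels: pd.Series, predicted_labels: pd.Series) -> pd.DataFrame:
    """Recall / precision / FDR per planted class from two label series.

    Both series are indexed by gene id and hold class labels (the negative
    class may be any label, e.g. ``"neither"``).  Indices must coincide.
    """
    if set(truth_labels.index) != set(predicted_labels.index):
        raise ValueError("truth and prediction cover different RNA rosters")
    predicted_labels = predicted_labels.reindex(truth_labels.index)
    classes = sorted(set(truth_labels.unique()) | set(predicted_labels.unique()))
    rows = []
    for cls in classes:
        t = truth_labels == cls
        p = predicted_labels == cls
        tp = int((t & p).sum())
        fp = int((~t & p).sum())
        fn = int((t & ~p).sum())
        rows.append({
            "class": cls, "n_true": int(t.sum()), "n_pred": int(p.sum()),
            "tp": tp, "fp": fp, "fn": fn,
            "recall": tp / max(tp + fn, 1) if (tp + fn) else np.nan,
            "precision": tp / max(tp + fp, 1) if (tp + fp) else np.nan,
            "fdr": fp / max(tp + fp, 1) if (tp + fp) else np.nan,
        })
    return pd.DataFrame(rows).set_index("class")
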