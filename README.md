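# chartographer

Statistical analysis of RNA-chromatin contact maps from proximity-ligation
assays (ChAR-seq and kin: GRID-seq, RADICL-seq). These assays sequence
chimeric reads joining an RNA to a nearby genomic DNA fragment, yielding,
for every chromatin-associated RNA (caRNA), a genome-wide profile of its DNA
contacts. `chartographer` is for computational genomicists who have such
contact data (pairs-style files) and want to answer, quantitatively:

- **Which RNAs spread beyond their transcription locus?** Most caRNAs stay
  near their gene; a few (XIST, MALAT1, 7SK, ...) coat a chromosome or the
  genome. The *trans-* and *cis-delocalization* screens calibrate each RNA's
  far-contact rate against a beta-binomial GLM null trained on mRNAs:

      E[K_i | N_i]   = pi_i N_i
      var[K_i | N_i] = pi_i (1 - pi_i) N_i (1 + (N_i - 1) gamma)
      logit(pi_i)    = eta_chr(i) + eta_expr ln N_i

  The fitted null serves as an empirical-Bayes prior
  (alpha + beta = 1/gamma - 1); each RNA's calibrated score is the log2 odds
  ratio Delta = [logit(pi_post) - logit(pi_model)] / ln 2, and its
  posterior-vs-prior tail probability, Fisher-combined over replicates and
  BH-corrected, classifies it as delocalized, ultralocalized, or neither.

- **Are any contacts more than diffusion from the locus?** A generative
  model predicts every RNA's map from three ingredients only — its abundance,
  a distance-decay kernel rho(delta), and an RNA-independent DNA-locus bias
  b_j — as per-chromosome multinomials, `p_j propto b_j sum_k rho(d_j - r_k)`
  in cis and `p_j propto b_j` in trans, conditioned on observed
  per-chromosome totals. Observed maps are tested against single model
  realizations with a moderated negative-binomial engine; interactions
  exceeding the model (LFC > log2 1.3, FDR 0.05) are candidate affinity-driven
  contacts.

- **Is interactome dynamics just transcription dynamics?** Differential
  testing of (RNA, locus) interactions between cell states, against
  *expression-only* maps (row-constant N_i) to isolate genuine
  relocalization, and gene-level ChAR-seq vs RNA-seq chromatin-association
  scores.

- **What are the unannotated transcripts?** A seven-class priority rule
  (tRNA-derived > snRNA-derived > readthrough > CRE-derived > repeat-derived
  > antisense > intergenic) from TE k-mer read labels, CRE proximity, and
  gene-end geometry.

- **Do caRNA contacts track target-gene regulation?** A caRNA-gene
  interactome over 100 kb promoter-proximal windows, signed edges
  (positive / negative / neutral) against gene expression dynamics, and
  positive-edge fold enrichment over a shuffled-label null with 10,000-sample
  bootstrap CIs.

A fully ground-truthed synthetic data generator
(`chartographer.simulate`) emulates the assumed statistical structure —
multinomial contact placement with distance decay and locus bias,
beta-binomial overdispersion, planted delocalized / XIST-like / peak-bearing
/ relocalizing RNAs, two states x two replicates, paired RNA-seq — so every
stage is testable end to end without downloads.

## Worked example

Simulate a default dataset (3 chromosomes x 30 Mb, 500 RNAs, 2e5 contacts
per sample, ES/DE x 2 replicates) and run the trans-delocalization screen:

```python
from chartographer import SimulationConfig, simulate_dataset
from chartographer.delocalization import delocalization_pipeline

ds = simulate_dataset(SimulationConfig(), seed=1)
res, per_rep, fits = delocalization_pipeline(
    ds.samples, ds.sample_states, ds.gene_models, ds.genome, mode="trans")
print(fits["ES_rep1"].summary())
```

```
Beta-binomial GLM (logit mean link, shared overdispersion)
  n obs: 277   llf: -1105.285   converged: True
  gamma: 0.01822 (SE 0.00196)
  coefficients:
    eta_chr[chr1]      -1.40437  (SE 0.16137)
    eta_chr[chr2]      -1.58182  (SE 0.16481)
    eta_chr[chr3]      -1.46029  (SE 0.16592)
    eta_expr           -0.04099  (SE 0.02820)
```

The null was fitted on the 277 mRNAs with at least 50 contacts in that
sample; the fitted overdispersion (gamma = 0.018) matches the generator's
0.02, and the chromosome intercepts sit near the planted trans-contact
logits. The top delocalized calls in ES:

```python
top = (res[(res.state == "ES") & (res.category == "delocalized")]
       .sort_values("delta", ascending=False)
       [["gene_id", "rna_class", "delta", "p_deloc", "p_adj_deloc"]])
print(top.head(5).to_string(index=False))
```

```
gene_id rna_class    delta       p_deloc   p_adj_deloc
LNC0392    lncRNA 3.881674 1.353745e-310 3.160994e-308
LNC0376    lncRNA 3.768844  2.768380e-23  2.154722e-21
LNC0343    lncRNA 3.717521 9.320683e-310 1.450920e-307
NCR0418     ncRNA 3.653268  1.917040e-23  1.790516e-21
UTL0463       UTL 3.535623  1.581925e-23  1.790516e-21
```

Delta ~ 3.5-3.9 means these RNAs' trans-contact odds are ~12-15 times the
mRNA-null prediction at their expression and chromosome. All 18 RNAs flagged
in ES carry a planted delocalization offset (`ds.truth.rnas`), so recall and
false-discovery behavior can be read off directly against the ground truth.

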