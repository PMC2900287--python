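# allelescan

Detection of allelic-imbalance (AI) regions from high-density allelic
expression measurements.

## The problem

When both alleles of a gene can be distinguished — e.g. on a genotyping
array hybridized with cDNA — each heterozygous SNP yields two
observables per individual:

* **E**, the total expression, `E = log2((cdnaA + cdnaB) / (gdnaA + gdnaB))`,
  the DNA-normalized combined abundance of both alleles, and
* **R**, the allelic log-ratio,
  `R = log2((cdnaA / cdnaB) / (gdnaA / gdnaB))`, the DNA-normalized
  fold imbalance between the alleles (defined only at het sites).

Single-site values of R are far too noisy to call imbalance — the noise
grows sharply as expression falls — but genuine allelic imbalance
(imprinting, cis-regulatory variation, allele-specific silencing)
covers transcripts containing many SNPs. `allelescan` implements four
detectors that exploit this spatial structure, a structured-permutation
false-discovery-rate framework to compare and threshold them, region
calling and classification against gene annotation, and a calibrated
simulator so everything can be tested with known ground truth.

## The detectors

1. **Simple smoothing** — each het site's score is the mean of its own
   R and that of its k het neighbours on each side (default k=2).
2. **Z-score** — R is standardized against the mean/sd of R in its
   total-expression bin (100 equal-width bins over E), giving site
   scores z_i ~ N(0,1) under the null; a run of k consecutive het
   sites scores `Z = sum(z_i) / sqrt(k)`. Every window of 1..w_max het
   sites is scored, and windows are greedily selected by |Z| without
   overlap until every het site is assigned the score of the best
   window containing it.
3. **Ergodic HMM** — 2m+2 hidden states (m=3 by default: N
   non-expressed, B balanced, P1..P3 / M1..M3 positive/negative
   imbalance). Expressed states share a fixed non-parametric E
   distribution obtained by deconvolving genic/intergenic E histograms
   (assuming 50% of genic and 10% of intergenic sites are expressed);
   each state has a trained normal over R. Baum-Welch trains the R
   means/sds, transitions and initial distribution on all individuals
   pooled. Decoding corrects transitions for inter-SNP distance: the
   unit (per-bp) kernel is `T1 = T^(1/D)` (D = mean inter-SNP gap),
   computed by eigendecomposition, and a gap of d bp uses `T1^d`. The
   per-site score is the posterior expected log-ratio
   `S_i = sum_s P(state s | data) mu_s`.
4. **Left-to-right HMM** — one copy of the state set per site,
   transitions only between neighbouring sites. Emissions come from
   the ergodic fit (stage 1); stage 2 learns a transition matrix per
   inter-SNP gap jointly from all individuals, with the
   distance-corrected ergodic transitions as a pseudocount prior of
   weight w: `A_i(s,t) = (sum_j xi_j,i(s,t) + w P_i(s,t)) /
   (sum_j gamma_j,i(s) + w)`. Shared imbalance boundaries sharpen the
   per-gap transitions, so each individual is then decoded in the
   context of the whole population.

**FDR.** Sites are stratified into ≤25 bins (5 heterozygosity-frequency
levels × 5 mean-expression levels) and shuffled within bins with all
individuals' columns moving together; `FDR(t) = N_perm(t) / N_real(t)`
compares calls on permuted versus real data at score threshold t.

## Worked example

```python
import allelescan as al

cfg = al.SimConfig(chrom_length=8_000_000, n_individuals=8)
sites, matrix, truth = al.simulate_dataset(cfg, seed=11)
print(len(sites), matrix.n_individuals)   # 2009 8

from allelescan.ergodic import fit_ergodic
model = fit_ergodic(sites, matrix, max_iter=60)
print([round(float(m), 2) for m in model.mu])
# [0.0, -2.9, -0.06, -0.03, -0.02, 0.02, 0.42, 3.01]

track = al.score_ergodic(sites, matrix, model)
regions = al.call_regions(track, sites, threshold=1.0, min_snps=3)
print(len(regions))                        # 7
```

The eight state means are the trained imbalance levels in log2 units:
the outer states (±2.9, +3.0) have locked onto the near-monoallelic
regions this small dataset happens to contain, while the inner states
sit near balance because little moderate imbalance is present — with
more data (or more AI regions) the levels spread out across the
imbalance range. The 7 region calls are runs of ≥3 consecutive sites whose
posterior expected log-ratio exceeds 1 (a 2-fold allelic imbalance) for
some individual; compare them against `truth.ai_regions` or estimate
their FDR with `assign_permutation_bins` / `permute_within_bins` /
`fdr_curve`.

A command-line interface mirrors the library
(`allelescan simulate|preprocess|train|score|permute|fdr|regions|classify|enrich`);
every subcommand reads and writes plain text (TSV, BED, bedGraph,
JSON).

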