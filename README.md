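# mregle

Multimodal representation learning for genetic discovery on physiological
waveforms.

Biobanks increasingly hold several waveform modalities per individual —
12-lead ECG median complexes, PPG median beats, spirograms — that describe
one physiological system from complementary angles. `mregle` is for
statistical geneticists who want to use such high-dimensional, unlabeled
records as GWAS phenotypes. It jointly learns a low-dimensional embedding of
the fused modalities ("M-style", early fusion) with a variational
autoencoder, orthogonalizes the embedding by PCA, runs a covariate-adjusted
GWAS on each coordinate, and combines the scans with a summed chi-squared
statistic:

> for m sample-uncorrelated coordinates P₁…P_m, the combined statistic for
> variant i is Σⱼ χ²_{Pⱼ,i} ~ χ²(m), which is asymptotically equivalent to a
> MANOVA of the m-variate embedding on the variant.

Hits are clump leads (p < 5×10⁻⁸, independent at r² < 0.1 in a reference
panel); loci are the hits' LD spans (r² ≥ 0.1) merged below 250 kb; hit
dosages feed an elastic-net genetic risk score (l1_ratio over
[0.1, 0.5, 0.7, 0.9, 0.95, 0.99, 1.0], 5-fold CV) compared across models by
paired bootstrap. The unimodal alternative ("U-style": one autoencoder per
modality, embeddings concatenated at a matched total budget) is built in as
the baseline for every stage, and a synthetic-data module generates
multimodal waveforms with shared/specific latent factors, Hardy-Weinberg
genotypes, covariates and phenotypes so the whole pipeline runs without
restricted biobank data.

## Worked example

Why does joint learning help genetics even when it barely helps prediction?
The built-in toy study draws two modalities M1 ~ MVN([F, 0.1·s], I),
M2 ~ MVN([F, 0.2·s], I) from two dominant non-genetic factors F and a weak
genetic factor s, with phenotype Y = 0.05·s + ΣF + 0.8·e:

```python
from mregle import experiments
rep = experiments.run_mu_toy_study(n=50_000, replicates=50, seed=0)
print(rep.table.to_string(index=False))
```

```
                 metric       value       se
 prediction_correlation    0.999920 0.000007
m_style_max_chi2_median 2449.821771      NaN
u_style_max_chi2_median    1.524508      NaN
     m_beats_u_fraction    1.000000 0.000000
```

Both embedding styles predict Y essentially identically (correlation
0.9999), but the M-style embedding keeps a coordinate for s — its median
association chi-squared with the genetic factor is ~2450 versus ~1.5
(chance level) for the U-style embedding, in 100% of replicates. Shared
structure is stored once, leaving capacity for the weak genetic signal.

The full pipeline on a synthetic cohort (2000 individuals, 500 variants,
two modalities, genotype-driven shared factors):

```bash
mregle run --synthetic --small --seed 1 --out demo/
# M-style: 6 hits / 5 loci; U-style: 6 hits / 5 loci
head -3 demo/m_hits.tsv
# id    chrom  pos      p                      sum_chi2            n_members
# rs62  1      1610000  7.840577042938832e-57  298.9396116967537   1
# rs158 1      2570000  3.0758409527955767e-48 257.898678038663    1
```

The six hits are exactly the six causal variants planted by the generator
(two genetic shared factors × three causal variants each); `demo/` also
contains the combined summary statistics, loci as BED, and a JSON run
summary with the genomic-inflation factors (λ_GC ≈ 1.0 on the null
coordinates).

Other entry points: `mregle simulate` (waveforms/genotypes/factors/toy),
`mregle preprocess` (FIR filter, percentile QC, hash splits, 90th-percentile
scaling), `mregle gwas` / `mregle clump` on files, and
`mregle study power|toy|cca` for the methodological studies.

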