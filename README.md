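# coexmap

Topologically guided gene prioritization for imaging transcriptomics:
predict dense brain-wide gene-expression maps from sparse well samples by
ordinary kriging, screen the predicted maps against a molecular-imaging
target map, and prioritize and annotate the resulting gene set.

## The problem

Receptor-density maps from PET (e.g. the nondisplaceable binding potential
BP_ND of the serotonin-1A receptor measured with a selective radioligand)
are dense: one value per voxel in a standard volumetric space, or per
vertex on a reconstructed cortical surface.  Postmortem gene-expression
atlases are the opposite: thousands of genes, but measured only at a few
hundred sparse tissue wells.  To ask *which genes' spatial expression
patterns track a receptor's distribution*, the sparse expression data must
first be turned into dense maps, and the comparison must be guarded
against genes whose maps cannot be predicted reliably.

## The method

For each gene with wells (s_i, z_i):

1. **Variogram estimation.**  The empirical semivariogram
   γ̂(h) = Σ_{pairs in bin} (z_i − z_j)² / (2 N_bin) is fitted with a
   parametric model (exponential by default) with nugget c₀, partial sill
   c and range a, by pair-count-weighted least squares.  The **relative
   structured variability** RSV = 100·c/(c₀+c) summarizes how much of a
   gene's sampling variance is spatially structured.
2. **Ordinary kriging.**  Each analysis site x₀ gets the best linear
   unbiased prediction ẑ(x₀) = wᵀz with weights from
   [Γ 1; 1ᵀ 0]·[w; μ] = [γ₀; 1], where Γ holds well–well semivariances
   and γ₀ the well–site semivariances; Σw = 1 by construction, and the
   kriging variance is wᵀγ₀ + μ.
3. **Prediction validity (LOOCV).**  Each well is predicted from the
   remaining wells (with the variogram refitted per fold); genes are kept
   only if the Pearson correlation of observed and held-out predictions
   exceeds r > 0.3 — a signal-to-noise filter.
4. **Coexpression screen.**  Spearman's ρ between each predicted map and
   the target map, site-wise over the analysis mask; genes with ρ ≥ 0.7
   are considered highly coexpressed.
5. **SD-closeness prioritization.**  Among screened genes, those whose
   map standard deviation is closest to the target map's SD (top decile
   of closeness, the "90th percentile" rule) are kept.
6. **Overrepresentation.**  The prioritized list is tested per annotation
   term with a one-sided Fisher's exact test against a reference gene
   population, with Benjamini–Hochberg FDR; terms with q < 0.05 are
   reported.

A synthetic-data module generates Gaussian-random-field gene maps with
known nugget/partial-sill/range, well-style sparse sampling, and a target
map built from designated *driver* genes — so the whole chain is testable
against planted ground truth without any external data.

## Worked example

```python
from coexmap.synthetic import SyntheticConfig
from coexmap.pipeline import run_synthetic_pipeline

cfg = SyntheticConfig(n_sites=1000, n_genes=50, n_drivers=2,
                      noise_sd=0.3, seed=11)
res = run_synthetic_pipeline(cfg)
print(f"target map SD: {res.target_sd:.3f}")
for g in res.screened:
    print(f"{g.gene_id}  rho={g.rho_target:.2f}  r={g.loocv_r:.2f}  "
          f"SD={g.sd:.2f}  RSV={g.rsv:.1f}%")
```

prints

```
target map SD: 1.350
g001  rho=0.82  r=0.77  SD=0.58  RSV=91.0%
g000  rho=0.80  r=0.77  SD=0.55  RSV=88.5%
```

The two screened genes are exactly the two planted drivers: their kriged
maps rank-correlate with the noisy target at ρ ≈ 0.8 and survive the
LOOCV validity filter at r ≈ 0.77, while all 48 non-driver genes fall
below the ρ ≥ 0.7 threshold.  The fitted RSV values (≈ 90%) recover the
generator's ground truth (structured variance 1.0 against nugget 0.02,
i.e. 98%, estimated from 180 wells).

The same pipeline runs from the shell on files (NIfTI/GIFTI maps, CSV
well tables, TSV annotations):

```bash
coexmap simulate --n-sites 1000 --n-genes 50 --n-drivers 2 --out sim/
coexmap predict  --wells sim/wells.csv --geometry sim/target.nii.gz --out maps/
coexmap screen   --target sim/target.nii.gz --maps maps/ \
                 --qc maps/prediction_qc.csv --out screened.csv
coexmap prioritize --screened screened.csv --target-sd 1.35 --out prioritized.csv
coexmap enrich   --genes prioritized.csv --annotations go.tsv --out enrichment.csv
```

Cortical-surface and subcortical-volume analyses are separate runs on
their own geometries; `coexmap report` lists the genes passing both.

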