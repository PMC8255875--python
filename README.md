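# popchip

Conservation-genetics analysis of SNP-chip genotypes for labelled breeds
(populations), built around PLINK text PED/MAP files:

- **genotype_io** — PED/MAP reading/writing, per-SNP QC (call rate ≥ 0.95,
  pooled MAF ≥ 0.05 by default), map spacing summaries.
- **diversity** — per-breed MAF, informative-SNP counts (MAF > 0.05),
  observed/expected heterozygosity, within-breed IBS genetic distance
  (D = 1 − mean allele sharing).
- **roh** — runs of homozygosity (defaults: ≥ 40 homozygous SNPs, ≥ 1000 kb,
  ≥ 1 SNP / 1000 kb, gaps ≤ 1 Mb, ≤ 1 heterozygote, ≤ 5 missing) and the
  genomic inbreeding coefficient F_ROH = ΣL_ROH / L_AUTO.
- **ld_ne** — genotypic r² for SNP pairs up to 5 Mb, distance binning
  (0.01-Mb steps to 0.05 Mb, 0.05-Mb steps to 1 Mb, 1-Mb bins to 5 Mb),
  LD-decay summaries, and effective population size via
  Ne = (1/4c)(1/r² − 1) with past-Ne trajectories at T = 1/(2c).
- **differentiation** — Weir–Cockerham variance-component F_ST (weighted
  ratio-of-sums headline, per-SNP mean alongside), Tajima–Nei (equal-input)
  distances between breed consensus sequences with pairwise deletion, and a
  from-scratch neighbour-joining tree with Newick output.
- **pca** — genotype-matrix PCA on standardized dosages (mean imputation,
  2f centring, sqrt(2f(1−f)) scaling), deterministic sign convention.
- **simulate** — forward-time Wright–Fisher multi-breed simulator (diploid,
  Poisson recombination, breed-split trees, optional admixture and full-sib
  inbreeding programs) emitting PED/MAP plus generator truth values; all
  tests run on simulated data only.
- **pipeline / cli** — end-to-end orchestration producing the report bundle
  (diversity, ROH, F_ST/distance tables, LD profiles, Ne trajectories, PCA
  scores, Newick tree, reproducibility manifest).

## Command line

```sh
popchip simulate --breeds 3 --size 50 --split-generations 30 \
    --out-ped demo.ped --out-map demo.map
popchip all --ped demo.ped --map demo.map --out-dir out/
popchip roh --ped demo.ped --map demo.map            # defaults match the
                                                     # stated ROH criteria
popchip ne --ped demo.ped --map demo.map --breed breed1 --cm-per-mb 1.0
```

Subcommands: `qc`, `diversity`, `roh`, `ld`, `ne`, `fst`, `tree`, `pca`,
`simulate`, `all`. Each maps 1:1 onto a library operation; `--help` lists
the flags. `cm-per-mb` (genome-average recombination rate for Mb → Morgan
conversion) is a required analysis constant with a documented default of
1.0 cM/Mb.

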