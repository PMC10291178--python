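# otufilter

Replicate-based assessment of low-abundance OTU filtering for 16S rRNA
amplicon count tables.

## The problem

Amplicon sequencing detects hundreds of operational taxonomic units
(OTUs) per stool sample, but a large share of the low-copy ones are
PCR/sequencing artifacts ("spurious OTUs") that appear in one technical
replicate of a specimen and not another, inflating richness estimates.
When a specimen is sequenced in triplicate, the *reliability* of an OTU
— the percentage of OTUs, among those detected in at least one
replicate, that are detected in all three — quantifies how much of a
table is reproducible signal, and the coefficient of variation (CV =
sd/mean of an OTU's copy counts across the triplicate) quantifies how
precisely it is measured. `otufilter` implements the filtering methods
commonly used to remove low-abundance OTUs, the replicate-agreement and
CV statistics used to judge them, and the downstream alpha/beta
diversity comparison that shows what each filter costs. A
synthetic-community generator with known ground truth (spurious OTUs
marked as such) exercises every stage.

Seven filtering methods are covered, differing in the scope at which
the abundance criterion is applied:

| scope | method | criterion |
|---|---|---|
| — | `none` | keep everything (baseline) |
| dataset | `dataset_relative` | remove OTU everywhere if its pooled share < 0.1% of all reads |
| dataset | `dataset_max_copies` | remove OTU everywhere unless >10 copies in some sample |
| sample | `sample_singleton` | zero cells equal to 1 |
| sample | `sample_min_copies` | zero cells with <10 copies |
| triplicate | `triplicate_max_copies` | zero OTU in a specimen's three replicates unless ≥10 copies in one of them |
| triplicate | `triplicate_intersection` | zero OTU in a specimen unless detected in all three replicates |

Downstream summaries: observed OTUs, bias-corrected Chao1
(S_obs + f₁(f₁−1)/(2(f₂+1))), Shannon (−Σ pᵢ ln pᵢ), inverse Simpson
(1/Σ pᵢ²), Bray–Curtis dissimilarity (Σ|xᵢ−yᵢ| / Σ(xᵢ+yᵢ)), classical
PCoA, and one-way PERMANOVA (R² = SS_between/SS_total with a
permutation p-value), plus phylum-level relative abundances and
t-test / Mann–Whitney comparisons of alpha metrics against the
unfiltered baseline.

## Worked example

```python
from otufilter import SimulationConfig, generate, run_grid, report

ds = generate(SimulationConfig(), seed=1)      # 12 specimens x 3 replicates
grid = run_grid(ds.table, ds.design, ds.taxonomy, seed=1)
for m, s in grid.methods.items():
    print(f"{m:25s} {s.reliability.mean[0]:6.1f} ({s.reliability.se[0]:.1f})"
          f"   reads removed {s.pct_reads_removed_mean:.2f}%")
report(grid, "grid_out")                       # TSV tables + JSON
```

prints (three-replicate reliability, mean over the 12 specimens, with
its standard error, and the read cost of each filter):

```
none                        51.3 (0.9)   reads removed 0.00%
dataset_relative            98.0 (0.5)   reads removed 5.10%
dataset_max_copies          87.8 (1.1)   reads removed 0.17%
sample_singleton            69.7 (0.9)   reads removed 0.09%
sample_min_copies           89.4 (0.9)   reads removed 0.49%
triplicate_max_copies       98.3 (0.3)   reads removed 0.41%
triplicate_intersection    100.0 (0.0)   reads removed 0.20%
```

Unfiltered, only half of the OTUs detected in a specimen appear in all
three of its replicates; every filter raises that, the dataset-level
0.1% relative-abundance cutoff at the largest read cost (~5% of reads),
the per-sample <10-copy filter cheaply (~0.5%), and the triplicate
intersection to exactly 100% by construction. On the same run,
Chao1 drops from 241 to 115 under the <10-copy filter and becomes equal
to observed richness (no singletons survive, so the rare-species
correction vanishes — flagged `**`, p<0.001), while Shannon (3.0 → 2.9)
and inverse Simpson (6.3 → 6.2) barely move, phylum shares are
unchanged (Firmicutes 72.8%, Bacteroidetes 18.2%), and the PERMANOVA R²
for the individual stays at 0.97 (p=0.001) under every method: filtering
discards unreliable rare detections without touching composition-level
signal.

The same pipeline runs from the shell:

```sh
otufilter simulate --seed 1 --out data/
otufilter compare --table data/synthetic.shared --design data/design.tsv \
    --taxonomy data/taxonomy.tsv --seed 1 --out grid_out/
```

Real mothur `.shared` tables, generic TSV count matrices, and
greengenes-style taxonomy files load through `read_shared`,
`read_tsv_table` and `read_taxonomy`.

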