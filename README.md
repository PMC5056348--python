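# medipdmr

Differential-methylation analysis for MeDIP-seq (methylated-DNA
immunoprecipitation sequencing), built around the comparison of backfat
methylomes from lean (Landrace, LBF) and obese (Rongchang, RBF) pig breeds
— two groups of three biological replicates.  In MeDIP-seq, read depth at a
CpG site is the proxy for its methylation level, so the pipeline runs from
reads to regions:

1. **QC** — discard reads with more than 5 `N` bases or with more than 50%
   of bases below Phred 5.
2. **Duplicate collapse** — a read mapping to multiple genomic locations
   counts as one read.
3. **CpG depth** — fragments overlapping each CpG dinucleotide `[pos, pos+2)`
   are counted per sample; sites covered by less than a 10 read depth are
   discarded; depths are normalized to the overall average library size of
   each group.
4. **DMR calling** — per CpG, Bartlett's test (α = 0.05) routes the
   two-group comparison to a pooled-variance *t*-test or an exact
   Mann–Whitney test.  CpGs with *P* < 0.01 seed regions that extend 3′ over
   adjacent significant CpGs within 200 bp; a non-significant CpG (up to
   2 kb away) terminates the region.  Regions with ≥ 5 significant CpGs are
   scored by Σ −log₁₀ *P*, ranked against a 1,000-permutation group-label
   null, and reported at Benjamini–Hochberg FDR < 0.01 with a
   hyper-/hypomethylation direction.
5. **Annotation** — each DMR is assigned to one of the five canonical gene
   features (promoter 2 kb > exon > intron > downstream 2 kb > intergenic)
   and tabulated by direction.
6. **Profiles** — 1 Mb window tracks, chromosome-level correlations of
   methylation with length/GC/CpG_o/e, strand-aware gene-body metaprofiles
   (2 kb flanks, scaled body), hierarchical clustering of samples on DMR
   depths (1 − Pearson r, average linkage).
7. **Validation computations** — bisulfite-clone (BSP) lollipop summaries,
   2^−ΔΔCt relative expression, SFA/MUFA/PUFA fatty-acid class sums with
   the PUFA:SFA ratio, and count-weighted mean adipocyte volume
   V = Σ fᵢ·(π/6)·Dᵢ³ / Σ fᵢ.

A synthetic-data generator (`medipdmr.simulate`) produces every input the
pipeline consumes — a small multi-chromosome genome whose CpG density
tracks window GC, negative-binomial depth tracks with planted DMRs and a
ground-truth BED, aligned fragments and FASTQ, clone matrices and Ct
tables — so the whole analysis is testable at desk scale.

## Worked example

```python
from medipdmr import (SimConfig, DMRParams, make_genome, make_truth,
                      simulate_depths, call_dmrs)
from medipdmr.preprocess import filter_low_coverage, normalize

cfg = SimConfig(seed=42, chromosomes=(("chr1", 600_000),), n_dmrs=3,
                dmr_direction="hyper")
genome = make_genome(cfg)
truth = make_truth(genome, cfg)
matrix = normalize(filter_low_coverage(simulate_depths(genome, truth, cfg)))
dmrs, meta = call_dmrs(matrix, DMRParams(seed=42))
print(f"{matrix.n_sites} CpGs retained; {meta['n_candidates']} candidates")
print(dmrs[["chrom", "start", "end", "n_sig", "mean_LBF", "mean_RBF",
            "direction", "region_p", "q"]].round(4).to_string(index=False))
```

prints

```
7317 CpGs retained; 3 candidates
chrom  start    end  n_sig  mean_LBF  mean_RBF direction  region_p     q
 chr1  44941  45298     10   92.9844   30.6021     hyper     0.001 0.001
 chr1  82936  83178      5   93.6051   29.9347     hyper     0.001 0.001
 chr1 517480 517920     10   90.7984   29.8631     hyper     0.001 0.001
```

All three planted regions (group-1 depth boosted 3× over a baseline of 30)
are recovered with the correct hypermethylation direction; `region_p` =
1/1001 is the smallest empirical P attainable with 1,000 permutations, and
`q` is its BH adjustment.  The same steps are available from the shell:

```sh
medipdmr simulate --out sim --seed 42 --emit-reads
medipdmr preprocess --aln LBF_1:LBF:sim/alignments/LBF_1.bed ... \
    --cpg sim/genome/cpg_sites.bed --out matrix.tsv
medipdmr call-dmr --matrix matrix.tsv --seed 42 --out dmrs
medipdmr annotate --dmrs dmrs.tsv --genes sim/genes.gtf \
    --chrom-sizes sim/genome/chrom.sizes --out annotated.tsv
medipdmr profile --matrix matrix.tsv --genome-dir sim/genome \
    --genes sim/genes.gtf --dmrs dmrs.tsv --out profiles
```

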