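# atacsim

Correlation and association metrics behave badly on chromatin
accessibility data: genome-binned ATAC-seq signal is non-normal,
tie-heavy, and contains *co-zero* bins — regions with zero coverage in
both of the samples being compared — that silently inflate the very
statistics used to certify that replicates agree. `atacsim` is a toolkit
for quantifying that behaviour. It generates synthetic replicate pairs
whose true level of agreement is designed in, measures seven
correlation/association statistics with and without co-zero masking, and
summarizes how faithfully each statistic tracks the designed truth. It is
aimed at epigenomics analysts choosing QC metrics for ATAC-seq (or
ChIP-seq) experiments and at methodologists studying reproducibility
statistics.

## What it does

1. **Synthetic replicates with known agreement.** A parent sample (real
   fragments from a BAM/BED plus its reproducible peaks, or a fully
   synthetic parent) is duplicated into two "sister" replicates. A
   designed fraction p of peaks is left shared; each remaining peak is
   depleted in one randomly chosen replicate by removing 85% (or 50/95%)
   of its fragments. Sweeping p from 0.99 to 0.05 gives replicate pairs
   whose disagreement is known exactly, with nested peak selections and
   shared removal draws along the sweep so the axis stays autocorrelated.
2. **WFpkm binning.** Fragments are counted in 10 kb genomic bins,
   standardized to fragments per kilobase per million (FPKM) and rounded
   *up* to whole integers (WFpkm), so a bin is zero iff it has no
   fragments.
3. **Seven statistics, two policies.** Pearson's R, Spearman's rho,
   Kendall's tau-b, Top-Down correlation on Savage scores
   (r_T = (Σ S(x_i)S(y_i) − n)/(n − S₁), which up-weights the largest
   observations), R², Kendall's coefficient of concordance W, and
   normalized mutual information — each computed with co-zero bins
   retained and removed.
4. **Evaluation.** Statistic-vs-shared-fraction curves are reduced to
   normalized AUCs (a constant curve at c scores c; the identity curve
   scores 0.52), with bootstrap confidence intervals and permutation
   tests on differences of mean AUC.
5. **Cohort tools and a replicate classifier.** Pairwise statistic tables
   across sample cohorts with Wilcoxon/Bonferroni tests of the co-zero
   effect, and a 100-tree random forest predicting the relationship of a
   sample pair (different cell line / same cell line / true replicate)
   from its (R², NMI) features, with per-fold feature-importance
   comparison.

## Worked example

```python
import atacsim as a

config = a.ParentConfig(seed=11)
fragments, peaks, layout = a.generate_parent_sample(config)
print(f"parent: {fragments.library_size:,} fragments, "
      f"{len(peaks):,} peaks, FrIP = {a.realized_frip(fragments, peaks):.3f}")

design = a.SweepDesign(depletion_rate=0.85, seed=1)
plan = a.plan_varied_peaks(peaks, design, repeat_index=0)
pair = a.generate_replicate_pair(fragments, peaks, plan, fraction=0.50, rate=0.85)

grid = a.make_bins(layout, bin_size=10_000)
track1 = a.wfpkm_track(pair.rep1, grid)
track2 = a.wfpkm_track(pair.rep2, grid)

print(f"co-zero bins: {a.make_bivariate(track1, track2).cozero_fraction:.1%}")
print(f"{'statistic':<14}{'retained':>10}{'removed':>10}")
results = {(r.name, r.cozero_policy): r.value
           for r in a.compute_statistic_suite(track1, track2)}
for name in a.STATISTIC_NAMES:
    print(f"{name:<14}{results[name,'retained']:>10.3f}{results[name,'removed']:>10.3f}")
```

prints

```
parent: 2,500,000 fragments, 100,000 peaks, FrIP = 0.504
co-zero bins: 5.0%
statistic       retained   removed
pearson_r          0.754     0.729
spearman_rho       0.856     0.709
kendall_tau        0.848     0.702
topdown            0.440     0.410
r_squared          0.569     0.531
kendall_w          0.928     0.855
nmi                0.692     0.495
```

These two tracks share exactly 50% of their peaks, yet with co-zeros
retained every rank statistic reports agreement of 0.85–0.93 — the
constant background block and the shared zero-coverage bins prop the
values up. After removing the 5% co-zero bins, normalized mutual
information lands at 0.495, essentially the designed sharing of 0.5,
while Spearman/tau/W remain inflated. That gap — and NMI's near one-to-one
tracking of the designed truth after co-zero removal — is the package's
central measurement; run across the full fraction sweep it becomes the
mean-AUC table produced by `summarize_simulation_set` or the `sweep-eval`
command.

## Command line

The `atacsim` entry point chains the same steps from a shell:

```
atacsim synth --out-prefix sim/parent --seed 7
atacsim simulate --parent sim/parent.bed --peaks sim/parent.narrowPeak \
        --chrom-sizes sim/parent.chrom.sizes --rate 0.85 --repeats 15 \
        --seed 7 --out sweep.tsv
atacsim sweep-eval --in sweep.tsv --boot 1000 --perms 1000 --seed 7 \
        --out auc_table.tsv
```

plus `bin`, `stats`, `cohort`, `classify`, and `run` (the full pipeline
with a YAML config and a checksummed manifest). Real data enter as
coordinate-sorted SAM/BAM (filtered at ingestion with mapq ≥ 30,
excluding unmapped/secondary/QC-fail/duplicate/supplementary records and
mitochondrial contigs), fragment BED3, and ENCODE narrowPeak.

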