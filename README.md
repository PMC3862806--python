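# samflow

Moderated d-statistic expression profiling with permutation FDR — a tested,
reusable reimplementation of the classic two-group microarray analysis stack:
SAM-style differential expression, empirical low-intensity filtering,
correlation-distance ordination QC, cross-dataset d-statistic concordance,
gene-set distribution-shift tests, and Bonferroni-corrected
over-representation. A synthetic-cohort generator with planted ground truth
drives calibration, power and recovery testing of every step.

## The scientific problem

Bulk expression studies of the aging hippocampus (and many designs like them)
compare small groups of arrays — e.g. aged rats with preserved vs impaired
spatial memory, each split across two behavioral-induction conditions, with
7–8 arrays per cell. At these sample sizes per-gene variance estimates are
unstable, so naive t-tests over ~31,000 probesets reward low-variance noise.
The standard remedy is the moderated d-statistic: for gene *i* with group
mean difference *r&#7522;* and pooled gene scatter *s&#7522;*,

```
d_i = r_i / (s_i + s0),

s_i = sqrt[ (1/n1 + 1/n2) · (Σ₁(x−x̄₁)² + Σ₂(x−x̄₂)²) / (n1+n2−2) ]
```

where the "fudge factor" *s₀* is chosen (by minimizing the coefficient of
variation of windowed MADs of *d* across the range of *s*) so that |d| is
decoupled from gene-wise variance. Significance comes from a permutation
null: group labels are reassigned (full enumeration when feasible), the
sorted permuted d's give expected order statistics d̄₍ᵢ₎, and a symmetric
offset Δ from the identity line induces asymmetric up/down cutoffs. The
estimated FDR at each Δ is the median permuted call count beyond those
cutoffs divided by the observed call count.

Around that core the package provides the rest of the published workflow:
quantile normalization; an empirically detected low-intensity cutoff (the
density dip of the bimodal log2 intensity distribution, defaulting to
log2 = 4); outlier-array flagging from median inter-array correlations;
classical (Torgerson) MDS on 1 − Pearson-r distances; Pearson concordance of
d-statistics across independently run datasets paired by probeset ID;
rank-sum / KS / permutation tests for whether a named gene set's d
distribution is shifted against the all-genes background; and upper-tail
hypergeometric over-representation with Bonferroni correction.

## Worked example

```python
import samflow as sf

cfg = sf.SimConfig(n_genes=5000, seed=1)          # 2 phenotypes x 2 conditions,
matrix, truth = sf.generate_cohort(cfg)           # 8/8/8/7 arrays, 300 DE genes

matrix = sf.quantile_normalize(matrix)
cutoff = sf.detect_low_cutoff(matrix)             # density dip, fallback 4.0
filtered = sf.filter_low_expression(matrix, cutoff)
print(f"cutoff log2={cutoff:.2f}, retained {filtered.n_genes}/{matrix.n_genes} probesets")

design = sf.Design.from_annotations(filtered, "AU", "AI", labels=("AU-act", "AI-act"))
result = sf.sam_analysis(filtered, design, target_fdrs=(0.05,), B=500, seed=1)
s = result.summary()
print(f"s0={s['s0']:.4f}; {s['n_called_fdr_0.05']} probesets at FDR 0.05 "
      f"({s['n_increased_fdr_0.05']} increased in AU-act)")

up = sf.GeneSet("planted_up", truth.loc[truth.true_effect > 0, "probeset_id"])
shift = sf.geneset_shift_test(result, up)
print(f"planted-up set: N={shift.n}, {shift.direction} in AU-act, p={shift.p_str}")
```

prints

```
cutoff log2=4.96, retained 2951/5000 probesets
s0=0.0348; 314 probesets at FDR 0.05 (145 increased in AU-act)
planted-up set: N=138, increased in AU-act, p=1.13734e-87
```

The detected cutoff sits in the density dip between the unexpressed
(log2 ≈ 2) and expressed (log2 ≈ 8) modes; 314 calls against 300 planted
effects at FDR 0.05 corresponds to 99% sensitivity at an empirical FDR of
0.054 for this seed; and the planted up-set's d distribution is shifted
decisively toward "increased" in the AU phenotype.

The same workflow is scripted as a narrative analysis under `analysis/`
(run `python analysis/01_simulate_cohort.py` … `06_enrichment.py` from the
repository root; tables land in `results/analysis/`) and is available from
the shell via the `samflow` CLI (`samflow simulate`, `qc`, `filter`, `sam`,
`mds`, `pca`, `concordance`, `shift`, `enrich`, `pipeline`).

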