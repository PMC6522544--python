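# tssmeth

TSS-centric integration of DNA methylation and gene expression for
tumor/normal cohorts.

In many solid tumors, where promoter DNA methylation couples to
transcription is as informative as how much: in normal tissue the
methylation most associated with a gene's expression tends to sit ~1 kb
upstream of the transcription start site (TSS), while in tumors the most
strongly expression-associated methylation can shift directly onto the TSS.
`tssmeth` implements the full analysis stack for detecting and
characterizing that spatial shift from processed methylation peak calls
(MBD-seq/MACS style) or array beta values, plus a synthetic-cohort
generator so every stage is testable without any data download.

## The model

- **Binary segment methylation.** Each 100-bp genomic segment is scored
  `1` in a sample iff a methylation peak overlaps it by ≥ 1 bp. The
  methylation level of a non-overlapping 500-bp window is the sum of its
  five segment binaries (0–5). Windows tile TSS ± 5 kb on the strand-aware
  TSS-relative grid (−5000, −4500, …, +4500).
- **Correlation map.** For each (gene, window), Spearman's ρ between the
  window score and the gene's normalized expression across the samples of
  one arm, with p from the t approximation and Benjamini–Hochberg FDR taken
  jointly over all testable records of the arm. Windows with q < 0.05
  define significant methylation–expression coordinates.
- **Density shift statistic.** Significant window midpoints enter a
  Gaussian KDE over [−5 kb, +5 kb], truncated and renormalized to unit
  area. The headline statistic is the tumor/normal ratio of density mass
  within TSS ± 500 bp,

  AUC ratio = ∫₋₅₀₀⁺⁵⁰⁰ f_tumor / ∫₋₅₀₀⁺⁵⁰⁰ f_normal ,

  tested against a permutation null (default 1000 iterations) that
  shuffles the expression-to-methylation sample pairing within each arm;
  the one-sided empirical p uses the add-one estimator.
- **Subtyping and association.** Genes with strongly significant (q <
  0.001) negative correlation are selected at their best window; tumor
  samples are Ward-clustered (Euclidean) on those window scores, labels
  ordered so cluster 1 is the hypermethylation phenotype; mutation status
  is related to cluster membership by a two-sided Fisher exact test, with a
  protein-change parser for domain-effect classification (e.g. the CREBBP
  HAT domain, residues 1342–1649).
- **Meta-profiles.** Expression-quartile (Q1 low … Q4 high) methylation
  ratio profiles in 100-bp bins, split by CpG-island overlap, and 10-bp
  ChIP coverage meta-profiles with a randomized-gene-list background band.

## Worked example

```bash
tssmeth simulate --out cohort/ --seed 11            # synthetic planted cohort
tssmeth run-full --cohort cohort/ --out-dir results/ --n-perm 200 --seed 11 --q-select 0.05
```

or in Python:

```python
from tssmeth import CohortConfig, generate_cohort, permutation_test, window_scores

cohort = generate_cohort(CohortConfig(seed=1))      # 300 genes, 40 tumor + 40 normal
wsm = window_scores(cohort.segments, cohort.annotation)
res = permutation_test(wsm, cohort.expression, n_perm=200, seed=1)
print(round(res.ratio, 2), res.p_value, res.tumor_profile.mode())
```

prints `6.13 0.004975124378109453 -40.0`: the tumor arm concentrates 6.1×
more significant-coordinate density at TSS ± 500 bp than the normal arm
(p = 1/201, the permutation floor), and the tumor density peaks 40 bp from
the TSS — recovering the planted geometry (normal coupling at −1000 bp,
tumor coupling at the TSS, Spearman ρ ≈ 0.5). On the same cohort, gene
selection at q < 0.05 recovers 107 genes of which 88.8% show increased
tumor methylation (90% planted), and Ward clustering returns 3 subtypes.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

regenerates the default planted cohort from the seed, reruns window
scoring, both arms' correlation maps, the AUC-ratio permutation test, gene
selection, and clustering from scratch, prints a run summary to stderr and
writes the results JSON to `--out`.

## Layout

| module | contents |
| --- | --- |
| `tssmeth.genome` | intervals, gene/TSS model, promoters, CGI classification, BED readers |
| `tssmeth.scoring` | segment binarization, window scores, methylation ratio, array-mode probe weighting |
| `tssmeth.correlation` | Spearman maps, BH-FDR, significant coordinates, density profiles |
| `tssmeth.shift_test` | AUC-in-region, AUC ratio, permutation test |
| `tssmeth.profiles` | expression quartiles, methylation/ChIP meta-profiles, background bands |
| `tssmeth.subtypes` | gene selection, Ward clustering, protein changes, Fisher association |
| `tssmeth.simulate` | synthetic cohort, subtype, and ChIP coverage generators |
| `tssmeth.cli` | `tssmeth` command-line entry point |

See `docs/methods.md` for the statistical model, generator assumptions,
and known limitations.
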