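# Methods

## Coordinate model

All coordinates are 0-based half-open (BED). Each gene is reduced to one
canonical TSS: the BED start on `+`, `end − 1` on `−`. TSS-relative
positions are signed along the gene's strand (negative = upstream), so a
minus-strand gene whose signal is the base-level reflection of a
plus-strand twin produces bit-identical TSS-relative outputs at every
stage (window scores, correlation maps, meta-profiles); this mirror
invariance is asserted end-to-end in the test suite. The promoter is
[TSS − 1500, TSS + 500) along the strand (2000 bp unless clipped at
position 0), and a gene is a *CGI gene* iff any CpG-island interval
overlaps its promoter by ≥ 1 bp. The ≥ 1 bp rule is the least-surprising
reading of "contains a CpG island"; no overlap fraction is imposed.

## Segment and window scoring

The 100-bp segment grid is genome-anchored (starts divisible by 100); a
segment is methylated in a sample iff any peak call overlaps it by ≥ 1 bp.
The twenty 500-bp windows per gene are anchored on the **TSS-relative**
grid −5000 … +4500, not on absolute genomic multiples of 500: profiles are
only comparable across genes in the TSS frame, and this is the one
deliberate interpretation of "non-overlapping 500-bp windows" the package
commits to. A segment is assigned to the window containing its
TSS-relative midpoint; since midpoints are spaced 100 bp, every window
receives exactly five segments and the sum of the twenty window scores
equals the count of methylated segments in TSS ± 5 kb (a tested
conservation law).

Array mode replaces the segment path with a probe-density-corrected gene
summary: each probe's beta is weighted by its Voronoi cell width within
the ± 5 kb domain (half-distance to flanking probes, clipped at the domain
edges; duplicated positions share their cell). Weights are nonnegative and
sum to 10,000 bp, so a dense TSS probe cluster cannot dominate sparse
upstream coverage. An alternative inverse-bin-count weighting
(`scheme="bin_inverse"`, 500-bp bins) is available.

## Correlation maps and FDR

Spearman's ρ uses average ranks; p-values come from the large-sample t
approximation on n − 2 degrees of freedom (exact zero at |ρ| = 1).
Zero-variance methylation windows and constant-expression genes are
excluded **before** the BH step-up adjustment, so m counts only testable
hypotheses; including them would deflate q-values with undefined
statistics. The FDR is taken over all retained gene × window records
jointly, separately within each cohort arm (tumor, normal), because the
two arms yield separate density curves. The analysis universe is
"expressed genes": nonzero expression in ≥ 20% of the arm's samples
(configurable; no published rule exists for this filter).

Significant coordinates are the **window midpoints** (start + 250) of
records with q below threshold, optionally filtered by ρ sign and gene
class (CGI/noCGI); duplicates across genes are retained as a multiset.

## Density profiles and the AUC-ratio test

The KDE is Gaussian with Silverman's rule bandwidth by default (a fixed
bandwidth in bp may be supplied), evaluated on a 10-bp grid over
[−5000, 5000], then truncated to the domain and renormalized so the
trapezoidal integral is exactly 1 (± 1e−6 asserted); this makes "the area
under the curve adds up to 1" hold as a hard invariant rather than an
asymptotic property. Fewer than two distinct coordinates is an error —
there is no density to estimate.

The shift statistic is AUC_tumor/AUC_normal over TSS ± 500 bp. The default
permutation scheme (`pair`) permutes expression columns against fixed
methylation columns independently within each arm: this preserves each
arm's marginal structure while destroying exactly the methylation–
expression coupling under test. An alternative (`label`) reshuffles the
tumor/normal arm assignment. Permutation i draws its RNG from (seed, i),
so results are reproducible and order-independent. A permutation yielding
fewer than two distinct significant coordinates in an arm contributes the
neutral ratio 1 and is tallied rather than dropped, keeping the null size
fixed. The one-sided p-value uses the add-one estimator,
p = (1 + #{null ≥ observed}) / (1 + n_perm) ∈ [1/(n_perm+1), 1].

**Conservatism at small scale.** When the observed data themselves yield
fewer than two significant coordinates in an arm, the observed ratio is
set to the neutral 1 (flagged `observed_degenerate`) and p is effectively
1. On null cohorts of desk scale (e.g. 200 genes × 20 windows, 20+20
samples) BH at q < 0.05 almost never yields two discoveries — under the
global null the probability of *any* BH discovery is bounded by α — so the
test's empirical size is ≈ 0 rather than the nominal 0.05. The test is
valid (never anti-conservative) but a calibration band assuming a
continuous null statistic, such as [0.01, 0.11] around 0.05, is not
reachable in that regime; the corresponding acceptance test records this
honestly. At the scale of a real transcriptome (≈ 20,000 genes, hundreds
of thousands of tests, thousands of significant windows) the statistic is
effectively continuous and the issue vanishes.

## Quartile meta-profiles and backgrounds

Quartiles come from mean (optionally median) expression across one arm's
samples, ranked ascending with lexicographic gene-id tie-breaks;
remainders go to the lowest quartiles first (10 genes → 3,3,2,2), so Q4 is
always the highest-expression quartile and the assignment is
deterministic. Methylation meta-profiles average the across-sample
methylation ratio per 100-bp TSS-relative bin over a quartile's genes,
restricted to segments within or outside CpG islands (boundary-straddling
segments count as within, consistent with the global ≥ 1 bp rule); bins
with no eligible segment are missing for that gene, not zero. ChIP
profiles average strand-aware 10-bp binned bedGraph coverage; coverage is
consumed as already depth-normalized. The randomized background band is
the per-bin min–max envelope of the meta-profiles of `n_lists` random
same-size gene lists (central-95% envelope available); min–max is the
default because a "signal of randomized gene lists" band carries no stated
quantile.

## Subtyping and mutation association

Gene selection takes, per gene, the minimum-q window passing the q and
ρ-sign filters (ties → smaller |start|, then upstream). The clustering
matrix is the **raw 0–5 best-window scores** (samples × genes); per-gene
z-scoring is available but off by default since the heatmap being emulated
shows raw methylation levels. Ward linkage with Euclidean distance is cut
to k clusters (default 3) and labels are reordered by descending
cluster-mean methylation, giving stable high/intermediate/low semantics.
Whether to cluster on best-window scores or a per-gene ± 5 kb summary is
genuinely open; best-window was chosen because the selection statistic
already identifies that window as the gene's informative locus.

The direction call per selected gene is the sign of (tumor mean − normal
mean) at its best window; exact ties are called "decreased" with a logged
warning so the hypermethylated fraction is never inflated.

Protein changes accept compact notation (`R1446C`, `Q771X`,
`Q2202_Q2203del`, `K123fs`) and simple HGVS `p.` forms (three-letter codes
and `Ter`). A change affects a residue-interval domain iff an altered
residue lies inside it, **or** the change truncates the protein (nonsense
or frameshift) at or upstream of the domain end — a truncation upstream of
a domain removes it even though the altered residue is outside. Under this
rule, of the five CREBBP changes E1566X, Q771X, R1446C, E1550K and
Q2202_Q2203del, exactly four affect the HAT domain (residues 1342–1649):
the in-frame deletion at 2202–2203 lies downstream and spares it. The
Fisher test is two-sided on the 2×2 table (target cluster vs rest ×
mutant vs wildtype), p from the hypergeometric distribution
(`scipy.stats.fisher_exact`, cross-checked against exhaustive enumeration
in the tests); the odds ratio applies the Haldane 0.5 correction when a
cell is zero. The dichotomization (which cluster is "target") is a
required explicit argument — no default is imposed.

## Synthetic cohorts

`CohortConfig` defaults are the stated world: 300 genes, 40 tumor + 40
normal samples, 70% CGI genes, half the genes coupled at realized Spearman
ρ ≈ 0.5, normal-arm coupling centred 1 kb upstream, tumor-arm coupling at
the TSS (bump SD 400 bp), 90% of coupled genes hypermethylated in tumor,
baseline segment methylation probability 0.2, expression noise SD 0.5 on
the log2 scale.

Generation is latent-variable-first (O(n), no rejection sampling): per
coupled gene and sample, a methylation propensity z ~ N(0,1) and an
expression latent z_e = ρ_lat·z + √(1−ρ_lat²)·η drive, respectively,
segment Bernoulli probabilities sigmoid(b0 + 2.5·k(x)·z) under the spatial
kernel k, and log2 expression μ_g − z_e + noise. Binarization and window
summation attenuate the correlation, so ρ_lat is inflated by the measured
calibration constant `ALPHA_BINARIZATION = 0.80` (best-window Spearman ρ
against the latent at ρ_lat = 1 on the default geometry measures ≈ 0.82);
realized best-window |ρ| lands within ± 0.1 of the target at n = 40, the
documented sampling tolerance. Tumor-vs-normal methylation change is a
± 2.5 logit shift under the tumor kernel (sign per hyper/hypo status);
± 1.2 or smaller is too weak to survive the convexity of the sigmoid under
the latent term. Subtype structure adds offsets linspace(−1, 1, k) ×
`subtype_effect` (latent-SD units) to z for coupled genes in tumor
samples, so `subtype_effect = 3` means adjacent subtypes are 3 SD apart.

One generator field goes beyond within-gene coupling:
`quartile_meth_effect` (default 1.5 logit) tilts the baseline methylation
of TSS-proximal segments (Gaussian bump, SD 700 bp) down the gene's
expression rank, planting the across-gene phenomenon that low-expression
genes carry more TSS methylation. Within-gene sample coupling cannot
produce that quartile contrast — quartile membership is a property of gene
means — so the gradient is a separate, explicitly configurable mechanism.
It adds no sample-wise methylation–expression dependence and therefore
does not perturb null calibration of the correlation machinery.

ChIP coverage emulates two mark geometries: an active mark with biphasic
bumps flanking a nucleosome-depleted TSS (dominant bump ~800 bp
downstream, amplitude scaled by expression rank) and a repressive mark
with a broad plateau inversely scaled by expression, whose TSS dip
`tumor_mode` removes. Poisson noise per 10-bp bin; `noise=False` emits the
exact intensity.

**What a green test does not establish.** The generator plants clean,
gene-wise-independent structure on one contig: no chromosomal
autocorrelation of methylation, no copy-number or purity effects, no
batch structure, no isoform or alternative-TSS ambiguity, no probe-level
measurement error model in array mode, and expression values that are
log-normal rather than count-distributed. Recovery on these cohorts
validates the statistical machinery and its conventions, not robustness to
those real-data complications.

## Numerical and degenerate-input choices

- Spearman p at |ρ| = 1 is exactly 0 (the t statistic diverges).
- BH is the vectorized textbook step-up; q-values are capped at 1 and
  validated against brute-force enumeration and statsmodels.
- `ward_cluster` drops genes with missing windows (logged) rather than
  imputing; k = 1 is allowed and trivially labels every sample 1.
- Empty sample groups, sub-minimum arms (< 5 samples), universes smaller
  than a background list, degenerate Fisher margins, unparseable protein
  changes, and < 2 distinct KDE coordinates all raise errors rather than
  guessing.
- Peaks on unknown chromosomes and genes whose ± 5 kb territory leaves the
  chromosome are skipped with logged counts.

## Known limitations

- One TSS per gene: the annotation must pre-resolve multi-isoform genes.
- Whether the original 100-bp grid was genome- or TSS-anchored is not
  recoverable; this package anchors the grid to the genome and the windows
  to the TSS (see above), and flags this as the main interpretive choice.
- The `pair` permutation scheme is the default null; shuffling arm labels
  (`label`) answers a subtly different question and is slower because the
  rank matrices must be rebuilt per permutation.
- Array mode supplies one weighted methylation summary per gene rather
  than per-window scores; the windowed correlation map requires
  segment-mode input.
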