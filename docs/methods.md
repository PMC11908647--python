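# Methods

This note records the model choices behind `trajalign`, the defaults and the
reasoning where the design was genuinely open. Notation: one condition has a
g x c normalized expression matrix `X` (log1p scale) and per-cell pseudotime
`p`; its `u` interpolated points have pseudotimes `q`, per-point cell counts
`qTotal`, adjusted bandwidths `qWindowSize`, and smoothed expression columns.

## Interpolation

Points are placed evenly on `[min(p), max(p)]`, endpoints included. The base
kernel window is `windowSize = max(p) / (0.9 u)`, so neighboring windows
overlap slightly at any `u`. `qTotal_h` counts cells with
`|p_l - q_h| <= windowSize` (inclusive bounds), and

```
qWindowSize_h = windowSize * (1 - (qTotal_h - mean(qTotal)) / max(qTotal))
```

shrinks the window where cells are dense and widens it where they are
sparse; a point at exactly mean density keeps the base window. Smoothed
expression is a normalized Gaussian-kernel average with weight
`exp(-(p_l - q_h)^2 / qWindowSize_h^2)`. The kernel constant is a convention
(some smoothing implementations put a factor 2 in the denominator); the form
without the factor is used here, and all invariants (shift equivariance,
convexity, refinement convergence) hold either way since weights are
normalized per point. Recommended `u` is 10–20 points per cluster of the
larger dataset, the same `u` on both sides; this is logged advice, not a
constraint. Runs of pseudotime longer than `2 * windowSize` containing no
cells are reported as gap warnings: no kernel window covers them, so
smoothed expression there is extrapolation and the alignment across the gap
is unreliable.

## Dissimilarity

The default cost between two point profiles is the Spearman distance
`1 - rho` with average ranks under ties, which lies in [0, 2] (0 = identical
ordering, 1 = unrelated, 2 = reversed). For tie-free profiles this equals
the classical rank-difference form `6 * sum(d_v^2) / (g (g^2 - 1))`, which
the test suite verifies to 1e-12. Pearson cost is `1 - r` (same range, by
analogy); Euclidean is the plain L2 distance. Zero-variance profiles make
correlation undefined and raise an error naming the offending point.

## Endpoint search, path selection, pruning

The provisional start is the argmin of `D` over the first row and first
column; the end, over the last row and last column. Ties are broken toward
the nearer corner to maximize the aligned span (the choice is arbitrary but
must be fixed; corner-ward maximizes information retained). The cut-off that
limits alternative endpoints is the mean absolute successive difference of
the border line holding the endpoint — an empirical scale of cost
fluctuation per border step; a length-1 border gives 0. Candidate starts are
the border positions between the provisional start and the (1,1) corner
(inclusive) whose cost lies within the cut-off of the start's cost;
candidate ends extend toward (n,m) likewise.

DTW runs for every admissible pair with the symmetric unweighted step set
{(1,0), (0,1), (1,1)}; backtrace ties prefer diagonal, then horizontal.
Because candidate paths have different lengths, raw total costs are not
comparable; each path is scored by bootstrap: resample `bootstrapLen` (= the
shortest candidate's length) match costs with replacement, average, repeat
`n_boot` times (default 1000), and average the resample means. Candidates
scoring below `min(scores) + mean(S)` survive, where `S` is the full matrix
of pairwise absolute score differences — the diagonal zeros are included in
the mean (excluding them would only scale the slack; either convention is
defensible, this one is fixed and documented). Among survivors the path
whose endpoints sit closest to the corners (Manhattan distance on matrix
indices) wins; ties fall to the lower score, then enumeration order. When
every candidate ties at the minimum (e.g. a single candidate) the strict
threshold would exclude all, so tied minima survive. On severely unrelated
data the border minima can be mutually non-monotone (every admissible start
after every admissible end); the alignment then falls back to the classical
corner-to-corner path with a logged warning, so a (poor, flagged) path
always exists.

Pruning computes `matchThreshold` (mean cost on the chosen path) and
`nonmatchThreshold` (mean of `D` off the path) once, from the un-pruned
path, and drops a match iff its cost is strictly closer to the non-match
mean. This is deliberately non-iterative: re-estimating thresholds after
each cut would let the pruned set feed back into its own criterion. Note the
match nearest the on-path mean is always kept, so pruning can never empty a
path; the "everything pruned" error is purely defensive. Kept matches form
contiguous segments; the gaps between segments are the unshared sections.
Alignment quality is summarized by the median path cost, with a warning
above 0.8 (under the Spearman cost, 1.0 is the expected cost of unrelated
profiles; 0.8 flags paths within noise reach of that level). The threshold
is configurable.

## Warping

Matches are processed in path order. For each block (a 1:1 match, or a
multi-match run where one side's index repeats along consecutive steps) the
first pair is aligned by shifting the trajectory whose matched point has the
larger pseudotime: that point and everything after it moves by the
difference, so shifts accumulate through the path. Remaining multi-match
members, and the interior points of pruned gaps, are then evenly re-spaced
between the bounding aligned values: spacing = (next - first)/(k+1) for k
interior points, i.e. the boundary values count as interval ends. The
even-spacing denominator could be read as k instead of k+1; k+1 (true even
spacing including both boundaries) is implemented. Points before the first
matched point follow its shift; points after the last keep their shifted
spacing. This scheme keeps both warped axes non-decreasing (anchor values
are non-decreasing because each is the running minimum of two non-decreasing
sequences) and makes every 1:1 matched pair coincide exactly.

Cell-level warping maps each cell to the kernel-weighted mean of the aligned
point pseudotimes, with weights computed from the cell's *original*
pseudotime against the points' original positions — the same kernel and
bandwidths used for smoothing. The map is affine-equivariant (a uniform
shift of all points shifts every cell identically) and preserves cell order
within a trajectory; a cell beyond every kernel's reach keeps its offset
from the nearest point (with a warning).

## Windowed differential expression

With `matches` kept matches, `nWindow` windows and `overlap` shared matches
per junction, the total number of window slots is
`totalMatches = matches + overlap * nWindow - overlap`. Per-window counts
come from repeatedly taking `round(remaining / windows_left)`; rounding is
half-away-from-zero, fixed here because banker's rounding (the default in
some numeric environments) differs on exact .5 and would change window sizes
silently. Each window starts `overlap` matches before the previous one ends,
so consecutive windows share exactly `overlap` matches and counts sum to
`totalMatches`.

Cells are assigned to the interpolated points of their own trajectory by one
round of k-means on the aligned axis (nearest point in squared distance, no
centroid update; ties to the lower index). Cells at pruned points are
excluded — only matched segments are comparable between conditions. Windows
with fewer than 3 cells in either condition are skipped with a warning.

Per window and gene, a two-sided Mann-Whitney U test compares conditions:
exact (scipy's U null distribution) for tie-free groups of at most 20,
exact by full permutation enumeration on midranks when ties are present and
the pooled sample has at most 16 observations, normal approximation with tie
correction otherwise. The fold change follows the Seurat V5 convention,
`log2(mean(expm1 x_A) + 1) - log2(mean(expm1 x_B) + 1)`, which assumes
log1p-normalized input — this is an input requirement, not something the
package checks or converts. P-values are Bonferroni-adjusted with the genes
of one window as the family (results are reported per window, so the
per-window family matches how they are read). Significance requires
adjusted p < alpha (0.05), |log2FC| > 0.5, and more than 10% expressing
cells in at least one condition. Because the fold-change and expression
filters gate the calls, the realized false-positive rate on null data sits
well below alpha.

## Synthetic data

The generator produces ground-truthed geometry, not a full transcriptomic
simulation. Latent process time is uniform on [0, 1] per cell; each gene
follows a smooth compactly supported pulse
`base + amp * exp(1 - 1/(1 - z^2))`, `z = (t - center)/halfwidth`, with
centers ordered along the axis (sequential activation). The compact support
(rather than a Gaussian) makes "programs identical outside the divergence
interval" an exact statement. Counts are negative binomial around the
program mean (size 15), then log1p-transformed. Observed pseudotime is the
latent time through a mild random power distortion (exponent 0.9–1.1) plus
uniform jitter (±0.02), min-max rescaled to [0, 1] — so trajectory inference
itself stays out of the test loop, while the observed axis is still a noisy,
nonlinearly stretched version of the truth.

Defaults: 300 cells/side, 50 genes, pulse half-width 0.18, amplitude 6,
baselines uniform on [0.05, 0.3]. They were chosen once so that matched
shared segments score Spearman costs well below 0.3 and unrelated points
well above 0.6, the regimes the method is designed to separate.

Geometries:

- **truncated** — condition B's latent time spans [0, tau] of A's axis
  (default tau 0.6), same programs. Emulates a knockout arrested
  mid-process. Both observed axes are rescaled to [0, 1], so the truncation
  is invisible from the pseudotime scale alone and must be recovered by the
  alignment.
- **diverge_converge** — shared programs outside [d1, d2] (default
  [0.4, 0.7]); inside, each condition activates its own disjoint set of
  pulse genes whose half-width `min(h, (d2-d1)/2.5)` fits the interval
  exactly; shared pulse centers keep out of the interval so any support leak
  (at most h/2) is identical on both sides.
- **negative_control** — two distinct regulatory networks: each condition's
  network drives its own half of the gene panel (a mix of transient pulses
  and switch-on sigmoids with independent order, widths and amplitudes)
  while the other half sits at a common basal level. This mirrors how two
  unrelated processes share a measurement panel but not a regulatory
  program. An earlier design that shared per-gene baselines across the pair
  was discarded: identical baseline rankings gave unrelated trajectories a
  spurious correlation floor and masked the expected warning.

A separate null generator draws both conditions from the identical
full-length model (for type-I-error studies). `score_alignment_against_truth`
converts interpolated-point indices to axis fractions as a stand-in for
latent time, which the jittered pseudotime tracks closely.

What the generator does **not** emulate: branching lineages, doublets,
ambient RNA, batch effects, dropout beyond NB sampling, library-size
variation, or realistic gene-gene correlation structure. Passing the
synthetic benchmarks therefore shows the algorithm recovers geometry from
smooth noisy programs, not that it is robust to every artifact of real
scRNA-seq; on real data the pseudotime quality of the upstream TI method is
the dominant unmodeled factor.

## Problem sizes and reproducibility

The benchmark statistics reported by `scripts/acceptance.py` use 10
simulation seeds per geometry at 300 cells/side, 50 genes and u = 15, and 50
null replicates at 20 genes with 4 comparison windows — sizes at which the
recovery statistics are stable across seeds while a full run stays in the
low minutes on one core. All randomness (simulation, bootstrap) derives
from explicit integer seeds; two runs with the same configuration and seed
produce byte-identical output files.

## Known limitations

- Exactly two trajectories; no multi-way alignment.
- Pseudotime is trusted as given (no uncertainty propagation); gaps in the
  axis are only warned about, not bridged.
- No banded DTW constraints: pathological cost matrices can produce highly
  skewed paths, mitigated but not prevented by endpoint selection and the
  quality warning.
- The warp is monotone by construction and cannot express locally reversed
  biology.
- DE windows inherit the alignment: a wrong alignment silently shifts which
  cells are compared. The median-cost warning is the main guard.
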