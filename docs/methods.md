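# Methods

## The procedure

For each protein the package reduces an (L, H, n, n) attention tensor to an
L × n heatmap: heads are mean-pooled per layer, columns of the pooled
matrix are summed (attention *received* per residue; summing rows would
measure attention *given*, which is not an importance notion), and each
layer's vector is divided by its maximum. Max-normalization, rather than a
sum- or z-normalization, keeps the top residue at exactly 1 in every layer
so layers and proteins of different lengths are comparable; ties at the
maximum are left as multiple 1s.

The convergence layer is found from the *sorted* profile of each layer.
Sorting is stable, with ties keeping ascending residue order, so the
rank→residue map is deterministic. Two ordinary least-squares lines are fit
independently on either side of every admissible breakpoint k ∈ [2, n−2]
(each side needs two points); the k with minimal total SSE wins, ties going
to the smallest k. Fitting is closed-form over prefix sums, so the full
breakpoint scan is O(n) per layer; tests check it against a brute-force
polyfit enumeration. Minimizing total SSE and total MSE give the same
argmin; SSE is what is stored.

Two choices here are deliberate:

- **Independent segments, no continuity constraint.** The cutoff between
  high and low attention is then defined by the *intersection* of the two
  lines rather than by the breakpoint rank, which makes the "left of the
  intersection" rule well defined even when the optimal breakpoint sits a
  point or two into the tail.
- **Rank axis rescaled to [0, 1]** before slopes and angles are computed.
  In raw rank units a near-vertical drop over 3 of 400 residues has slope
  ≈ −0.3 and the angle criterion would never approach 90°; rescaling makes
  θ = |atan(m_left) − atan(m_right)| (folded into [0, 90]) comparable
  across protein lengths.

The layer with θ closest to 90° is the convergence layer (ties → lowest
layer: the method looks for the *earliest* consistent layer). HA sites are
the sorted ranks r < k with x_r left of the fit-line intersection, mapped
back to residue positions (1-based in all outputs). If the lines are
parallel or intersect at or beyond x_k, the whole left segment qualifies;
an intersection at or left of x_0 yields no HA sites — a legal outcome
that downstream analyses treat as exclusion, not failure.

The HA-trajectory distance averages cosine distances over all cross pairs
of two proteins' trajectory sets. No bipartite matching is attempted; a
consequence worth knowing is that the self-distance of a protein with
several distinct trajectories is positive (it measures the spread of its
own trajectory set), so "distance zero on identical sets" holds exactly
for single-trajectory sets or sets of mutually identical trajectories.
The measure is symmetric and order-invariant but not a metric (no triangle
inequality is claimed).

## Statistics

Family separability uses the two-sample Kolmogorov–Smirnov statistic with
the asymptotic p-value; the out-family sample is seeded and sized to the
in-family pair count for a balanced comparison, with the per-family seed
recorded in the report. Significance counting defaults to p < 0.05; no
multiple-testing correction is applied (raw KS values are the quantity of
interest). The across-family interval reported in summaries is the
2.5–97.5 percentile range of the KS statistic, labeled as such. Silhouette
scores use the precomputed-distance formula (b − a)/max(a, b) with
singleton-family proteins scored 0 and flagged; the implementation is
cross-checked against scikit-learn.

Proximity analysis uses CA atoms only, Euclidean distances in Å, and a
Mann–Whitney U test (exact when the combined sample is ≤ 20 without ties,
tie-corrected normal approximation otherwise) against a seeded uniform
sample of non-active residues. The attention/contact comparison pools
pairs (i, j) over HA rows i and all j ≠ i (the diagonal is degenerate by
construction) and reports Spearman's ρ per layer; constant layers are
reported missing rather than zero.

Alignment consensus counts the modal non-gap residue over *all* rows, so
gap-heavy columns score low — gaps dilute but can never be the consensus.
The "alignment mean" is the unweighted mean over columns (averaging over
residues instead would up-weight gapless columns; the choice is labeled in
the report).

## The synthetic generator

The generator emulates the three-phase attention dynamics the method
targets, with exactly row-stochastic heads throughout:

- **Early layers** (below the convergence layer): uniform rows.
- **Convergence window** (three layers starting at the convergence layer):
  each row sends a `concentration` fraction (default 0.6) of its mass to
  the planted sites and spreads the rest uniformly.
- **Late layers:** a circular band of half-width `band_width` (default 3)
  around the diagonal — wrap-around, so every column receives identical
  banded mass and no spurious edge step appears in the sorted profile —
  plus a residual planted-site share decaying linearly to zero at the last
  layer. If a contact map is supplied, the last layer's rows are the
  contact rows themselves (with a 1e-9 floor against zero rows), which is
  what makes the attention/contact correlation peak at the last layer.

Within the convergence window the planted sites receive *geometrically
decreasing* shares (ratio 0.75 at the convergence layer, relaxing by 0.1
per subsequent window layer). This reflects how real sorted profiles look —
a steep decay over the top residues, not a flat plateau — and it is what
gives the left fit segment its near-vertical slope. Had all planted sites
received equal shares, the sorted profile would be a flat step: the angle
would be driven entirely by noise, statistically identical across the three
window layers, and the "recovered layer within ±1" guarantee would reduce
to a coin flip. With the heterogeneity ramp the convergence layer is the
unique angle optimum, deterministically, even at zero noise. With the
defaults (n = 120, 3 sites, concentration 0.6) the weakest planted site
sits at ≈ 0.56 normalized attention against a ≈ 0.01 background.

Noise is elementwise multiplicative log-normal (default σ = 0.05) applied
before each row is renormalized — the one hard invariant, row-stochasticity,
is preserved at any noise level. Defaults L = 33, H = 4, n = 120 match the
layer count of the 650M-parameter ESM-2 model while keeping a full study
(50 recovery replicates + 20 family seeds + 20 structure seeds) around a
minute on one CPU; head count is deliberately small since mean-pooling
makes the analysis head-count-insensitive.

Synthetic families share planted sites and convergence layer and differ by
noise; member embeddings are a large shared offset plus shared per-position
background vectors, a small family direction (scale 0.15) and per-member
noise (scale 0.5). Pooled vectors are therefore dominated by family-blind
components while HA trajectories stay family-specific — emulating the
tendency of whole-protein pooling to wash out residue-level family signal.
Synthetic structures are persistent random walks with exact 3.8 Å CA
spacing; planted active sites are drawn among residues within a chosen
radius of each planted HA site, and soft contact maps come from a logistic
falloff of CA distance (midpoint 8 Å, steepness 2 Å).

## What passing tests do and do not show

The synthetic studies demonstrate that the *procedure* does what it claims
under its stated assumptions: when attention concentrates on a residue set
at some layer, that set and that layer are recovered; when families share
attention programs, the trajectory distance separates them better than
pooled embeddings; when active sites are spatially near high-attention
residues, the proximity test detects it. They do not show that real ESM-2
attention has these properties — the generator reproduces the qualitative
three-phase pattern, not the statistics of real attention (no head
specialization, no sequence-dependent structure, no length variation
within a family). Claims about real proteins require the extraction
adapter and real annotations.

## Degenerate inputs and tie-breaks (summary)

- All-zero attention layer → error naming the layer (impossible for
  softmax output; signals a malformed archive).
- Profiles shorter than 4 residues cannot be fit → error.
- Collinear sorted profiles: SSE ties broken toward smallest k (within
  1e-12), parallel fit lines fall back to the whole left segment.
- Proteins without HA sites are excluded from distance analyses and
  reported; empty trajectory sets raise a dedicated error type.
- Archive row sums are checked to 1e-4 unless the archive records
  renormalization; violations are warnings on read, never silent.
- Stored arrays are float32 (size); all computation is float64.

## Known limitations

- The HA-trajectory distance is not a metric and its self-distance
  semantics (above) make it unsuitable for algorithms that assume d(x,x)=0
  on multi-site proteins.
- Chain-to-sequence alignment for structures is exact-match only;
  structures whose numbering disagrees with the canonical sequence abort
  rather than realign.
- The consensus module consumes alignments; it never computes them.
- The extraction adapter loads one protein at a time; no batching.
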