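# Methods

This document describes the models, statistics, and numerical choices
behind each `frogsynt` module. Coordinates are 0-based, half-open
throughout; all randomness flows through `numpy.random.default_rng`.

## Genome layout (`frogsynt.layout`)

`GenomeLayout` holds chromosome lengths and centromere positions.
Derived regions:

- **arms** — p is the shorter side of the centromere;
- **subtelomeres** — a fixed window (default 30 Mb, clipped to the
  chromosome) at each end;
- **pericentromeres** — a fixed window (default 5 Mb each side) around
  the centromere;
- **acrocentric** — arm ratio q/p above a threshold (default 3).

`region_classes` labels positions with precedence
pericentromere > subtelomere > arm, so the two windows never
double-count a position.

## Karyotype simulation (`frogsynt.simulate.karyotype`)

Chromosomes are sequences of oriented segments of 13 ancestral elements
(A–M, ~2.6 Gb genome). Five event types:

- **Robertsonian fusion** — joins two chromosomes at their centromeres;
  one centromere survives (monocentric products only).
- **Robertsonian fission** — splits a chromosome at (or within a small
  margin of) its centromere into two telocentric/acrocentric daughters.
- **End-to-end fusion** — joins two chromosomes at telomeres; the
  centromere of one product is inactivated.
- **Reciprocal translocation** — exchanges terminal segments between
  two (or, rarely, four) chromosomes; dicentric or acentric products
  are rejected and resampled.
- **Inversion** — reverses an internal interval; a centromere inside
  the interval is reflected.

Events are Poisson on branch lengths with per-type rates (events/My);
the per-type defaults (fusion 0.003, fission 0.001, end-to-end 0.002,
reciprocal 0.002, inversion 0.01) make interchromosomal changes
rare enough that 80–200 My branches carry a handful of events, matching
the regime the rate statistics are designed for. The history logs every
event per branch, and `replay()` re-derives all leaf karyotypes from the
ancestor — the event log is the exact generative record, not a summary.

Ortholog tables place genes uniformly along elements (density
proportional to element length) and report each gene's chromosome and
position in every leaf genome, plus the planted element label.

## Syntenic-element inference (`frogsynt.synteny`)

Genes are grouped by their **joint chromosome signature** (the tuple of
carrying chromosomes across species); signatures carried by fewer than
`min_cluster` genes are set aside as stray. For each pair of clusters,
per-species leaf states ("together" on one chromosome vs "apart") feed
a **branch-length-weighted (Sankoff) parsimony**: a state change on a
branch of length *b* costs 1/*b*, so changes are preferentially placed
on long branches — the parsimony analogue of a constant-rate model's
likelihood tie-break. Clusters are merged when the root state
"together" is strictly cheaper; ties resolve to "apart" (a conservative
choice: spurious merges are harder to detect downstream than spurious
splits). Unweighted Fitch parsimony is recoverable by passing a tree
without branch lengths.

`conservation_fraction` reports how many assigned genes travel with
their element in every species; `element_proportions` summarizes
per-species spans with across-species coefficients of variation.

## Rearrangement rates (`frogsynt.karyorate`)

`classify_junction` re-derives the event type from geometry alone
(which chromosome ends meet, where the breakpoints sit relative to
centromeres/telomeres within `eps` windows of 5 Mb), so classification
can be validated against the simulator's event log.

`count_translocations` counts inter-chromosomal changes; a four-way
reciprocal exchange counts as 3 (it is a composite of pairwise
rearrangements), inversions are excluded. `karyotype_change_rate`
converts a count and total branch length into My/change.

`branch_poisson_test` is the exact Poisson test of a branch's count
against a genome-wide constant rate, reporting both tails, the smaller
tail, and the doubled-tail two-sided value. `random_break_test` excises
terminal and pericentromeric windows, computes the interior genome
fraction *q*, and returns the exact binomial lower tail for the number
of interior breakpoints. Multiple comparisons use Hochberg's step-up
correction.

## Contact matrices (`frogsynt.contacts`)

`ContactMatrix` stores a dense symmetric count matrix over fixed-size
bins. Balancing methods:

- **KR** — Knight–Ruiz equilibration implemented directly (inner
  Newton step solved by conjugate gradients). The fixed point satisfies
  `x * (A x) = 1`; an independent check is the symmetric Sinkhorn
  iteration `x <- sqrt(x / (A x))`, which converges to the same point.
- **ICE** — iterative row/column scaling to unit mean coverage.

Zero-coverage bins are masked (NaN weights) before balancing.
`expected_by_distance` averages balanced contacts per diagonal within
chromosomes to form observed/expected (O/E) matrices.

## Hi-C simulation (`frogsynt.simulate.hic`)

Expected intra-chromosomal contacts:
`decay(s) * (1 + w_ab * a_i * a_j)` with power-law decay
`(1 + s/bin)^(-alpha)` (alpha = 1), compartment signs `a` drawn as
alternating blocks, plus an opposite-arm **Rabl wing** term that decays
with the difference of centromere distances. Expected
inter-chromosomal contacts multiply a background by territory
(same-chromosome factor does not apply across chromosomes; background
itself is the territory baseline), centromere-clustering,
telomere-clustering, polar (similar relative arm position), and
same-arm-orientation factors. Counts are Poisson draws scaled to
`total_reads`. Gene density is generated correlated with the planted
compartment signs so compartment calls can be oriented and validated.

Defaults (`HicSimParams`) are the study conditions: bin 1 Mb,
`w_rabl = 2`, `w_pol = 1.5`, `w_cen = 2`, `w_tel = 1`, `w_arm = 0.06`,
`w_ab = 0.3`, territory factor 6. They were chosen so each planted
signal is detectable but not dominant at ~1e7–2e7 reads.

## Architecture statistics (`frogsynt.architecture`)

- **Centromere inference** — on each chromosome's intra O/E matrix, a
  candidate boundary maximizes the opposite-side (wing) contrast; the
  call is refined by a local search over neighboring bins. Chromosomes
  with too few bins are flagged rather than called.
- **Compartments** — per-chromosome (or per-arm when centromere bins
  are supplied) O/E correlation matrices are eigendecomposed; among the
  top 3 eigenvectors the one most correlated with gene density is the
  compartment axis, oriented so A is gene-dense. Per-arm decomposition
  exists because the Rabl wing contaminates whole-chromosome leading
  eigenvectors; restricted to one arm, the wing term (which only
  couples opposite arms) vanishes.
- **Rabl SSD** — the spread of centromere positions in a
  contact-profile principal-component embedding; smaller = stronger
  centromere alignment.
- **Rabl CTP** — centromere-to-telomere polarity: mean polar contact
  enrichment between same-relative-position bins across chromosomes.
- **Permutation test** — the null rotates bin order circularly and
  independently within each chromosome, preserving marginals and
  distance decay while destroying cross-chromosome alignment;
  p = (1 + #extreme) / (n + 1).
- **Enrichments** — same-arm-orientation (p–p/q–q vs p–q) contacts and
  chromosome-territory contacts are tested with chi-squared statistics:
  df = 1 for the inter-arm 2-way margin, df = (K−1)² for the K×K
  territory table; pairwise territory follow-ups are
  Hochberg-corrected.

## Recombination (`frogsynt.recomb`, `frogsynt.simulate.marey` / `pedigree` / `variants`)

- **Marey smoothing** — a not-a-knot cubic spline interpolates cM
  against bp per chromosome (≥4 markers required); its derivative is
  the local rate in cM/Mb. Negative derivatives (spline overshoot on
  plateaus) are clamped to 0 and counted in `n_clamped`.
- **Landscape statistics** — medians by region class with pairwise
  Kolmogorov–Smirnov tests (Hochberg-corrected); concentration curves
  (fraction of genome holding given map quantiles); Spearman
  correlation of rate against feature tracks.
- **Variant filtering** — sites pass if bi-allelic, depth within
  mode ± 1.78 SD (mode and SD estimated from the bi-allelic depths
  actually observed), heterozygote allele balance within [0.3, 0.7],
  and (when parental columns exist) parents are fixed for different
  alleles with depth ≥ 10. The simulator plants outliers and computes
  `expected_pass` by replaying these same documented rules on the
  generated observables, so the filter is validated against the rules,
  not against planted intent.
- **Heterozygosity windows** — sliding-window het density, merged into
  blocks, with the genetic-map fraction of the blocks reported.
- **Inbreeding** — full-sib residual heterozygosity follows the
  recurrence H_t = H_{t−1}/2 + H_{t−2}/4; asymptotically
  H_t ≈ 1.17 × 0.809^t with 0.809 = (1+√5)/4. The forward simulator
  tracks founder-labelled haplotype mosaics on the genetic map, one
  brother–sister pair per generation, crossovers Poisson with no
  interference, and reports the non-IBD map fraction per replicate.

## Repeats (`frogsynt.repeats`, `frogsynt.simulate.repeats`)

- **Monomer clustering** — greedy single-linkage-to-representative
  clustering: each query aligns (via `edlib`) against the doubled
  sequence of each existing representative (the *dimer trick*, making
  identity rotation-invariant for circularly permuted tandem
  monomers); it joins the first cluster with identity ≥ 75% over ≥ 45%
  coverage, else founds a new one. Monomers must exceed 10 bp.
- **Regional enrichment** — per-family footprint densities inside vs
  outside regions of interest, with a pseudocount guarding empty
  complements.
- **Divergence** — Jukes–Cantor distance −¾ ln(1 − 4p/3), defined for
  p < 0.75.
- **Tetramer enrichment** — overlapping counts of TGGG/AGGG/ACAG (by
  default on both strands) per kb in tandem vs background sequence.
- **Density landscapes** — windowed interval coverage or GC fraction;
  PCA on standardized density tracks, with correlations of component
  scores against a compartment track.

## Problem sizes and budgets

Default analysis scale is a 10-chromosome, ~1.5 Gb genome at 1 Mb Hi-C
bins (~1500 bins): dense-matrix balancing, O/E, eigendecomposition, and
all enrichment statistics run in seconds on one CPU. The full
end-to-end pipeline (history simulation, element inference, Hi-C
simulation, balancing, centromere/compartment calls, Rabl/territory
statistics with a 200-draw permutation test, Marey landscape) completes
in well under 10 minutes on one CPU; the test suite asserts this. The
pedigree simulator runs ~600 replicates of a 17-generation, 1070 cM
genome in ~8 s.

## Reproducibility

Every stochastic function takes a `seed` (int or `Generator`); equal
seeds give bit-identical outputs. Property-based tests are
derandomized. Nothing reads global random state.
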