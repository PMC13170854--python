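# Methods

## Problem setting

A drug panel is measured pairwise and every pair is classed as synergy,
additive, or antagonism (either directly or by thresholding a numeric
interaction score `s`: synergy if `s ≤ low`, antagonism if `s ≥ high`,
additive between — the cut-offs are user configuration, since published
screens use score scales that are not interchangeable). The analysis looks
for a partition of the drugs under which class labels are as homogeneous as
possible within each cluster-pair block ("monochromatic"), relates that
partition to independent drug annotations, and uses the block structure to
predict unmeasured interactions.

## Similarity measures

Only the structural measure has a single canonical form (Tanimoto over
MACCS keys). The other three are deliberate, parameter-free choices matched
to each modality, each replaceable behind the same matrix interface:

| measure | formula | default | notes |
|---|---|---|---|
| structural | Tanimoto over 166 MACCS keys | — | RDKit pads a never-set bit 0 in its 167-bit vector; we drop it. Two all-empty fingerprints score 0 with a warning. |
| pharmacological | Jaccard over MoA term sets | — | single-label annotations reduce to 1/0 |
| phenotypic | `(Pearson r + 1)/2` over growth curves | cosine variant available | zero-variance curves score the uninformative 0.5 with a warning |
| therapeutic | ATC level score `L/5`, level cuts after characters 1, 3, 4, 5, 7 | — | code lists combined by best-match averaging in both directions |

All matrices are validated at construction: symmetric within 1e-9, unit
diagonal, entries in [0, 1].

## Clustering

Spectral clustering is the Ng–Jordan–Weiss variant: take the `k`
eigenvectors of `I − D^(−1/2) S D^(−1/2)` with smallest eigenvalues,
normalize rows, k-means with 20 restarts at a fixed seed. This form was
chosen for determinism and ubiquity. A drug with zero similarity to every
other drug makes the embedding degenerate, so it is rejected with advice to
prune it. k-means cannot return empty clusters here, but a repair path
(split the largest cluster at its farthest member, logged) guards the
invariant that labels are a contiguous 1..k.

Cluster-count selection reports mean silhouette (on distance `1 − s`) per
candidate `k` as the headline criterion — it is defined for every `k` —
with the Laplacian eigengap as secondary evidence; ties go to the smallest
`k`.

## Edge purity

For the classes of interest (default synergy + antagonism; additive edges
are treated as "no directional evidence" and excluded), count edges per
cluster-pair block `(g, h)`, `g ≤ h`, including diagonal blocks. Purity is
the micro-average `Σ_blocks max_class_count / Σ_blocks total` — the
fraction of counted edges that agree with their block's majority. A
macro-average (equal block weights) is available via a flag. Ties inside a
block still contribute the maximal count to the numerator but the block's
majority is reported as "tied" (and prediction abstains on it).

On a planted network where a fraction `epsilon` of non-additive edges is
class-flipped, the truth partition's expected purity is `≈ 1 − epsilon`
(slightly above, because a small block's majority can absorb flips); the
acceptance suite checks the mean over 100 studies is within 0.03 of
`1 − epsilon` for `epsilon ≤ 0.2`.

## Integration

Evidence accumulation: the co-association matrix `C(i,j)` = fraction of
input partitions co-clustering `i` and `j`, re-clustered by average-linkage
on `1 − C` (the classic choice; spectral re-clustering is an option). `k`
is user-fixed rather than chosen by a lifetime criterion, mirroring the
fixed-k study design. Fusion: element-wise mean is the default for
transparency; weighted averaging and an SNF-style cross-diffusion (row-
normalized global kernel diffused through a K-nearest-neighbor local
kernel, symmetrized each iteration, min–max rescaled at the end) are
provided. Per-source min–max normalization is off by default since all
sources already live in [0, 1].

## Network-based similarity

Each drug's signed profile holds +1/−1 for synergy/antagonism partners and
a configurable weight for additive partners (default 0). For a pair
`(u, v)` both profiles are truncated by deleting coordinates `u` and `v`,
so similarity measures shared context only, not the direct edge; the score
is `(1 + cosine)/2`, with 0 (and a warning) when a truncated profile is
all-zero. The unsigned variant is the Jaccard index of neighbor sets. These
are the simplest measures that separate sign agreement from mere adjacency.

Matrix association uses the strict upper triangles (Spearman default) with
a Mantel permutation test: rows/columns of the second matrix are permuted
jointly, `p = (1 + #{|r_perm| ≥ |r_obs|}) / (1 + n_perm)`, default
`n_perm = 999` (`n_perm = 0` skips the test). The add-one estimator makes
the test exact under exchangeability; the acceptance suite verifies the
type-I rate at `α = 0.05` sits in the exact binomial 99% band.

## DDI prediction

A new drug joins the cluster maximizing *mean* similarity to members
(mean, not max, for robustness to one spurious similarity; ties go to the
smallest label with a warning). A pair's class is the majority of its
cluster-pair block in the training network; empty or tied blocks abstain
rather than guess, and accuracy is reported only over non-abstained pairs,
with coverage and per-class counts alongside.

## Synthetic studies

The generator emulates a small antibiotic combination screen: default 6
clusters × 3 drugs (18-drug panel), complete network (`density = 1`),
within-cluster blocks biased to synergy (probability 0.8), remaining blocks
balanced half synergy / half antagonism, class-flip noise
`epsilon = 0.05` by default. Features per cluster: a random 166-bit
prototype fingerprint (density 0.3) copied with per-bit flips; a 3-term MoA
set (two cluster-specific terms plus a broad term shared by all drugs, as
real annotation vocabularies share generic terms); a logistic growth curve
with cluster-specific midpoint U(0.15, 0.85) and rate U(5, 20) over 12
timepoints plus Gaussian noise; and ATC codes within the antibacterial
`J01` stem — clusters own distinct 5-character prefixes, members differ in
the final digits, and a scrambled code is a random `J01` code. Keeping all
codes inside `J01` mirrors a real antibiotic panel and guarantees no drug
is therapeutically isolated.

What the generator does *not* emulate: chemically valid molecules (bit
vectors stand in for fingerprints; no synthetic SMILES is fabricated),
dose–response surfaces behind the class labels, correlated measurement
error across pairs sharing a drug, and partially observed networks' 
structured missingness. Passing recovery tests therefore shows the pipeline
is correct and calibrated under the planted model, not that real screens
have this much signal.

## Problem sizes and numerical choices

Experiments in the test suite use 100 generated studies per condition
(50 in `scripts/acceptance.py`, 500 draws for the type-I check), an 18-drug
panel, and Mantel tests with 999 permutations (99 in the type-I
simulation). Seeds are threaded explicitly everywhere: study generation
derives independent child streams for network and features, k-means uses
the caller's seed, and CLI manifests record config + seed + output hashes
so reruns are byte-identical. Ties are broken deterministically (smallest
cluster label, lexicographic pair normalization, sorted JSON keys).
Tolerances: matrix symmetry/range 1e-9 on read, round-trip equality 1e-12.

## Known limitations

- Edge purity is trivially 1 when every counted edge is one class;
  interpret it jointly with the class balance and `counted_edges`.
- Signed-cosine similarity is uninformative for sparsely connected drugs
  (zero-norm truncated profiles score 0); dense screens are the intended
  input.
- The SNF-style diffusion is a light-weight variant (fixed iteration
  count, K-NN locality) rather than a tuned reimplementation; mean fusion
  is the default precisely because it has no knobs.
- Block-majority prediction cannot beat `1 − epsilon` accuracy under
  class-flip noise and abstains on blocks never observed in training.
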