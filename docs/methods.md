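# Methods

## The intron-size mixture model

Intron sizes within a genome vary roughly exponentially, so all analysis is
done on log2-transformed sizes. The synthetic generator models a species'
intron sizes as a two-component normal mixture in log2-bp space:

    f(x) = w N(x; m1, s1) + (1 − w) N(x; m2, s2)

The two defaults encode the two distribution shapes under study:

| mixture | m1 | s1 | m2 | s2 | antimode target | solved w |
|---|---|---|---|---|---|---|
| teleost (TD) | 6.5 | 0.35 | 10.0 | 1.2 | 8.00 | ≈ 0.988 |
| vertebrate (non-TD) | 6.5 | 0.3 | 9.75 | 1.25 | 7.25 | ≈ 0.124 |

Only the antimode positions (2^7.25 and 2^8 bp) and the qualitative shape
(a dominant short-intron peak in the TD) are empirically anchored; the
mixture family itself is a modelling convenience, constrained by those
positions. The free weight is solved exactly: stationarity of f at the
target t is linear in w, giving w = g2′(t)/(g2′(t) − g1′(t)); a dense-grid
check confirms the stationary point is the interior minimum and rejects
infeasible targets. Note the solved TD weight is extreme (≈ 99% of mass in
the short component) — a consequence of pushing the antimode 4.3 sds away
from the short peak — so the TD's long-intron tail is sparse.

Sizes are realised as round(2^x) with a minimum intron size (default
60 bp, a typical vertebrate lower bound) enforced by rejection resampling;
clipping would pile rejected mass into a spurious spike at the floor.

## Antimode detection

The histogram uses half-open 0.25-log2 bins anchored at integer log2
values, normalised so Σ density·width = 1 (location is therefore invariant
to sample size). Detection: smooth with a 3-bin moving average, find local
maxima over the full support, take the two highest as the modes, and
return the argmin strictly between them (restricted to the search window,
default 6.5–10.5 log2 bp), refined by the vertex of the parabola through
the three bins around the minimum (clipped to ±half a bin). Maxima are
deliberately sought over the full support rather than the window because
the TD's short-intron mode sits exactly on the default window edge.

Quantisation bias: for the strongly asymmetric TD valley (steep left wall,
flat right basin) the refined estimate lands ~0.2 log2 units right of the
analytic antimode (≈ 8.2 vs 8.0 at n = 2·10^5); the vertebrate-type valley
shows a smaller shift (≈ 7.37 vs 7.25). Both sit within the 0.25-log2
quantisation tolerance used throughout, and the estimate is stable to
within one bin across seeds at n ≥ 10^5.

## The TD call

Two interval densities summarise a distribution: d8, the mean density over
(2^8, 2^8.5) — which covers the TD antimode valley and is therefore low in
a TD — and d11 over (2^11, 2^11.5), a long-intron reference interval. A
species is TD iff d8 < intercept + slope·d11 (equality → non-TD; the rule
is monotone in d8). The line is configuration, not a constant: it was
calibrated once against the *analytic* interval densities of the two
default mixtures — TD: (d11, d8) ≈ (0.002, 0.001); non-TD: (0.136, 0.136),
the two intervals happening to be symmetric about the non-TD long-peak
mean — and frozen at intercept 0.08, slope 0.25. Any slope below ≈ 0.41
separates the defaults; 0.25 leaves the non-TD margin at ≈ 9 sampling
standard deviations for 5·10^4 introns. Species yielding fewer than 1000
introns (configurable) are called ambiguous rather than forced.

Isoform handling is exposed as a flag: by default introns identical in
(seqid, start, end, strand) are counted once across isoforms; `dedupe=False`
counts per transcript. Both conventions are defensible and the summary can
be produced either way.

## Domain scanning

Profiles are position-specific log-odds matrices built from an alignment:
weight(col, r) = log2(((count + pc·bg_r)/(n + pc))/bg_r) with pseudocount
1.0 and uniform background by default; columns with > 50% gaps are dropped.
This reproduces the windowed score-plus-threshold contract of an HMM domain
search without HMM transition structure; an alignment-quality filter
(consensus score — the per-row sum over columns of how many rows share the
row's residue — with rows below 250 removed, consensus recomputed, no
re-alignment) precedes profile construction. Scanning slides the profile
over every window, selecting non-overlapping hits greedily by score; the
best window is always reported even when sub-threshold so that calls can be
calibrated on best-score distributions.

Presence thresholds are configuration with the conventional defaults:
aKRAB against six-frame genome translations, present at ≥ 30; against
proteins, absent ≤ 20 / present ≥ 50 / uncertain between (the empirical
score gap); ePR-SET present at ≥ 180. On synthetic families the planted
and background best-score distributions are separated by hundreds of bits
(null best ≈ −120, planted ≈ +190 for a 60-column profile at 5%
substitution), so recovery of planted presence is exact; real HMM scans
face paralogues and partial domains that this synthetic null does not
emulate, so passing tests validate the decision logic, not hmmer-scale
sensitivity.

Six-frame translation splits each frame at stop codons and carries genomic
offsets so every residue maps back to its codon start (for reverse frames,
the codon's higher coordinate, being its first base as read on that
strand). C2H2 fingers use the simplified motif C-x(2,4)-C-x(11,13)-H-x(3,5)-H
taken non-overlapping left-to-right; fingers separated by ≤ 15 residues
form one array. Canonical transcripts maximise distinct domain count, then
summed hit length, then take the lexicographically smallest id.

## Distances, trees, classes

The residue distance is D(x,y) = −B(x,y) + (B(x,x)+B(y,y))/2 with B =
BLOSUM62 (via Biopython); D is symmetric, zero-diagonal and non-negative
for BLOSUM62. Pair distance is the mean of D over columns where *both*
rows carry one of the 20 canonical residues — gaps and ambiguity codes are
excluded, and a pair with no overlapping columns is recorded as missing.

Neighbour joining is the classic Saitou–Nei algorithm (Q-criterion,
standard branch lengths, three-point closure), chosen over BioNJ's
variance weighting because the downstream use is topology plus coarse
class structure and classic NJ is deterministic and exact on additive
inputs; ties in Q are broken by the lexicographically smallest label pair
and negative branch lengths are clamped to zero (logged). Rooting places
the root at the midpoint of the outgroup's pendant branch (the reference
is the mouse-like sequence in the intended use).

Class assignment codifies what is visually apparent in a distance heat
map: average-linkage hierarchical clustering cut at k (default 4),
renumbered by increasing mean distance to a designated reference row, so
class I is the most reference-similar (PRDM9-α-like) and II–IV are the
β-like classes. The number of classes is a parameter, not an inference.

## Loss/origin inference

On a rooted tree with leaf labels in {present, absent, unknown}, a
post-order pass finds the maximal clades whose labelled leaves uniformly
carry the target state; each clade maps to its MRCA and the clade count is
the number of independent events. The count is a lower bound — events on
sister branches merge — and this is documented behaviour, not corrected
(no probabilistic ancestral-state reconstruction is attempted). Unknown
leaves are transparent: they cannot break a clade's uniformity (so
low-quality assemblies do not inflate event counts) but are reported per
clade. The same operation counts aKRAB losses (target = absent) and TD
origins (target = present).

The packaged order-level teleost tree has one representative leaf per
taxon, topology assembled from the named clade memberships of the teleost
literature, and arbitrary unit branch lengths (only topology enters the
inference). Gymnotiformes is included as aKRAB-present inside Otophysi;
without a present-state lineage between them, the Cypriniformes and
Characiformes+Siluriformes losses would merge into a single clade. With
its aKRAB labels the tree yields 8 independent losses; with its TD labels,
4 independent origins.

## Problem sizes and determinism

Antimode checks sample 2·10^5 introns per distribution; classifier
agreement uses 100 synthetic species at 5·10^4 introns; loss-recovery
properties run 100 planted scenarios; scanner nulls use 200 background
sequences. All generators take explicit integer seeds (numpy Generator)
and are bit-reproducible; the pipeline manifest records per-stage seeds
and output digests, and `scripts/acceptance.py` derives every random
stream from its single `--seed`.

## Known limitations

* The synthetic mixtures have exactly two log-normal components; real
  intron-size distributions are heavier-tailed and can be multi-modal, so
  the dividing-line defaults are calibrated to the synthetic conditions,
  not to any genome.
* PSSM scanning has no insert/delete states; domains interrupted by long
  insertions score lower than an HMM would score them.
* The event count inherits the monophyly rule's lower-bound character and
  depends on the input topology being correct.
* `filter_alignment` recomputes the consensus on survivors but does not
  re-align them; columns remain those of the original alignment.
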