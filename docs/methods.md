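# Methods

## Problem

Circular prokaryotic chromosomes accumulate dimers through odd numbers of
homologous-recombination crossovers; site-specific tyrosine recombinases
(Xer family) resolve them at a dedicated chromosomal site (*dif*) located
near the replication terminus. A *dif* site is a quasi-palindrome: two
~11-bp recombinase-binding arms around a short spacer. Its position is not
annotated in genome records and the terminus itself is often poorly
defined, so prediction rests on three signals that `difskew` implements as
separate, composable stages:

1. the *geometry* of the site (imperfect inverted repeat in intergenic
   DNA),
2. its *conservation* across related genomes, and
3. its *location* at the inversion point of replication-strand-polarized
   short words (KOPS in Bacteria, 4-8-nt analogues elsewhere), found via
   cumulative skew analysis.

## Inverted-repeat enumeration (`ir_search`)

Every window `arm1 + spacer + arm2` with `arm` in [11, 15] bp and `spacer`
in [4, 10] bp is scored by the Hamming distance between `arm1` and the
reverse complement of `arm2`; windows with at most `max_arm_mismatches`
(default 3, i.e. >= 73% arm identity at arm length 11) are reported.
Windows containing N are skipped. Enumeration is exhaustive and
auditable: overlapping candidates are all emitted, and per-locus reduction
is a separate explicit step (`best_site`).

`best_site` minimizes the mismatch *fraction* `mismatches / arm_len`, with
ties broken by larger arm, then larger spacer, then smaller start. The
larger-spacer tie-break matters: a shifted sub-window of a quasi-palindrome
frequently preserves the mismatch count (on the 43-nt worked example the
28-bp site and a contained 26-bp window both have 2 mismatches), and
preferring the maximal extent keeps the full site rather than a fragment.

The implementation is vectorized: for fixed geometry the mismatch count of
every start position is a sum of shifted base-comparison arrays, and the
count for arm length a+1 is the count for arm length a (shifted by one)
plus a single outer-pair comparison, so a genome is processed in
O(spacer_range * (arm_min + arm_range) * L) byte operations. A brute-force
triple-loop oracle in the test suite checks exact equivalence.

Candidates are canonicalized as `min(site, revcomp(site))` so the two
orientations of a quasi-palindrome count once in cross-genome matching.

## Conservation filtering (`conservation`)

Similarity between two equal-length sites is ungapped positional identity,
maximized over the two orientations of one partner. No gaps are allowed
and only candidates with identical (arm, spacer) geometry are compared:
the site class of interest is defined by its geometry, and ungapped
identity over a fixed 28-bp frame is what an alignment of such sites
amounts to.

A conserved group is one candidate per genome with **all** pairwise
similarities >= the threshold (default 0.80). Groups are formed greedily
by descending minimum pairwise similarity under a one-to-one constraint,
which makes the output deterministic and permutation-invariant. Matching
is exact, not heuristic: within each geometry class all cross-genome pairs
are evaluated (one-hot matrix products give pairwise identities in a
single BLAS call per genome pair), and genome-by-genome joins keep only
tuples whose every pair clears the threshold.

The consensus of a group is the minimal IUPAC symbol per column plus the
per-column information content `2 - H` bits (uniform background, no
small-sample correction) -- the quantity drawn as letter height in a
sequence logo. Flank conservation is reported descriptively as the AT
fraction of +-25 bp flanks; it is not a filter.

## Profile extension (`profile_scan`)

To search for the site family in genomes outside the training set, the
aligned group members become a position weight matrix: column
probabilities `(count + pseudocount * background) / (n + pseudocount)`
(default pseudocount 1), scores log2(p / background). This is a
deliberate simplification of a profile HMM: the training alignment is
ungapped and fixed-width, so match-state emissions carry all the
information and insert/delete states would be untrainable from a handful
of 28-bp sites.

Significance is defined operationally: the threshold is the (1 - alpha)
quantile (default alpha 0.05) of per-shuffle maximum scores over at least
100 dinucleotide-preserving shuffles of the *target* genome
(Altschul-Erickson Euler-path shuffling; the walk is numba-jitted). The
dinucleotide null preserves the AT-richness and nearest-neighbour
structure that dominate archaeal intergenic DNA, which a mononucleotide
null would misrepresent. Both strands are scanned over the full circle
(wraparound windows once).

## Polarized words and terminus inference (`skew`)

Because strand polarity is defined relative to replication direction, the
genome is transformed to a *leading-strand view* for a candidate terminus
`ter`: segment oriC->ter as given, segment ter->oriC reverse complemented.
As the true terminus is unknown, candidate termini are placed on an
angular grid, by default every 5 degrees from 120 to 200 degrees from
oriC, and statistics are aggregated across rotations by medians; a word
whose skew sign flips across plausible termini is discarded as unstable.

Over-representation of a k-mer (k = 4..8, overlap counting) on a view
uses the maximal-order Markov model (order k-2): expected count
`E = N(w[:-1]) * N(w[1:]) / N(w[1:-1])`, variance
`E (1 - N(w[:-1])/N(w[1:-1])) (1 - N(w[1:])/N(w[1:-1]))`, z = (obs - E)/sd.
The variance formula is empirically accurate (the suite verifies predicted
vs replicate sd), and on sequences generated from an order-(k-2) source
the z-scores are approximately standard normal *as a population over
words*. Two caveats are deliberate: no compound-Poisson correction for
self-overlapping words (such words are flagged per record), and individual
words whose prefix/suffix counts co-vary through a repeated central
context (e.g. GTTC via "TT") carry a small O(1) ratio-estimator bias
(about +0.15 sd for 4-mers at 200 kb) that does not shrink with sequence
length. Calibration checks therefore average over random words.

Ranking combines over-representation and polarization as
`median_z * median_skew_z`, both medians over grid rotations, where
`skew_z = (fwd - rev) / sqrt(fwd + rev)` is the standardized strand skew;
only words with rotation-consistent skew sign are ranked, each
reverse-complement pair is reported once (positive-skew orientation), and
palindromes are excluded (skew identically 0). The standardized skew --
rather than the raw fraction `(fwd-rev)/(fwd+rev)` -- is the package's
answer to an otherwise open comparability question: raw fractions make a
word seen 15 times with 80% skew outrank one seen 5000 times with 20%
skew, although the latter is overwhelming evidence of polarization and
the former is noise; standardizing also puts 4-mers and 8-mers on one
scale. The scoring function is pluggable for users who want the raw
ordering.

The cumulative skew curve of a word walks the circle once from oriC,
adding +1 per forward occurrence and -1 per reverse-complement occurrence
(1-kb bins by default); its final value equals total forward minus reverse
counts. The *summit* (global maximum; midpoint of the first maximal
plateau on ties) estimates the polarity inversion point, reported in bp
and in degrees from oriC. With a linear drift of +-1.5 occurrences/kb
(the default planted rates) the argmax wanders by only a few kb around
the true switch point, well under one degree per Mb-scale genome.

## Angular coordinates (`geometry`)

Positions map to signed angles `360 d / L` in (-180, 180], positive in
the direction of increasing coordinate from oriC; quarters are
1: [0, 90), 2: [90, 180], 3: (-180, -90], 4: (-90, 0). Deposited-strand
orientation flips the sign convention globally, so comparisons against
published positions should use |angle|. oriC is treated as a point input
(users should take the midpoint of an origin interval); the package does
not infer origins.

## Synthetic data (`synthetic_data`)

The generator produces the three structures the pipeline assumes, each
with exact truth records:

* **Architecture**: i.i.d. sequence at configurable GC (default 0.5),
  non-overlapping gene masks at 80% density (mean length 950 bp,
  gamma-distributed) -- genes are annotation masks only, since only the
  intergenic mask matters to the site search. On a 1-Mb genome this
  yields roughly 2,000 decoy inverted-repeat candidates at default search
  parameters.
* **Conserved site quartet**: independent random backgrounds per genome
  (real target genomes are extensively rearranged, so decoy candidates
  across genomes are unrelated sequence), each carrying a variant of the
  28-bp master site at 122-142 degrees from oriC. Genome 0 carries the
  master; each other genome gets one compensatory substitution at a
  distinct matched arm pair (both bases of the pair change together, so
  arm complementarity and the master's 2-mismatch imperfection are
  preserved exactly). Pairwise site identities are then 24/28-26/28
  (0.857-0.929), and the site survives the inverted-repeat search in
  every genome by construction.
* **Polarized word**: Poisson placements of the word (default GTTG) on
  the forward strand at 2/kb between oriC and the terminus and 0.5/kb
  beyond it, mirrored for the reverse complement, polarity inverting at
  the configured terminus (default 150 degrees). Overwritten or
  overlapping placements are pruned from the truth record.
* **Divergence** (`diverge_set`): per-copy i.i.d. uniform base exchange
  (Jukes-Cantor-like, no indels -- the pipeline is ungapped and would not
  see them). Inside protected planted-site intervals, arm positions
  mutate as complementary pairs and spacer positions freely, at a lower
  protected rate: palindrome-compensatory drift, the way a
  recombinase-bound site actually evolves. A plain i.i.d. model at the
  rates that produce 0.85-0.95 site identity would destroy the
  inverted-repeat structure itself in a large fraction of copies, leaving
  nothing for any site finder to detect. Note that even with
  compensatory drift, protection at 0.05/site leaves a non-negligible
  chance that some genome pair of a quadruplet drifts below 0.80
  all-pairwise identity on 28 bp (each arm event moves two positions);
  recovery below 100% at such rates is a property of the evolutionary
  model, not of the detector.

What the generator does **not** emulate: codon structure, repeat
families, CRISPR arrays, horizontally transferred islands, or
rearrangement/inversion histories. Passing recovery tests on this
generator therefore demonstrates the statistical machinery (detection,
matching, ranking, localization) under the stated noise models, not
robustness to every genomic confounder; on real genomes, conserved
repeats such as CRISPR spacers can and do enter the conserved-group list
and must be triaged by the user (the pipeline reports all groups).

## Numerical and degenerate-input choices

* Coordinates 0-based half-open; circular intervals normalized mod L with
  `end > L` for wraparound; features and regions carry lengths invariant
  under normalization.
* N is permitted in input sequence; any scanner window containing N is
  skipped; shuffles keep N positions fixed; words may not contain N.
* Ties: `best_site` as above; skew summit takes the midpoint of the first
  maximal plateau; ranked words sort by (score desc, k, word) for
  determinism.
* `word_zscore` errors on absent middle words (zero denominator) rather
  than guessing; `rank_asps` maps such words to z = 0.
* All randomness flows through `numpy.random.default_rng(seed)`;
  generators are pure functions of (config, seed).

## Problem sizes used in the shipped analyses and tests

The analysis drivers under `analysis/` use 500-kb genomes (seed 1); the
test suite exercises the full pipeline at 1 Mb across 100 seeds for
conserved-site recovery, 20 seeds for terminus recovery, and 100
replicates of 200-kb sequences for null calibration. These sizes are the
package's chosen study conditions; all scale linearly in L if users want
larger runs.

## Known limitations

* Single circular replicon only; no plasmids, no multi-origin handling
  (multi-origin chromosomes violate the single-terminus polarity model
  underlying the leading-strand view).
* Gapped (indel-containing) palindromes are invisible to the enumerator.
* The empirical PWM threshold is genome-specific and must be recalibrated
  per target genome.
* R'MES-style compound-Poisson statistics for self-overlapping words are
  not implemented; such words are flagged and their z-scores are mildly
  anticonservative.
* oriC must be supplied; the package deliberately does not predict
  origins from GC skew.
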