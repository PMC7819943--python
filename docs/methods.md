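# Methods

## The measurement and its model

A promoter-tiling PBM measures, for every 40-nt probe core tiled across a
gene's upstream region, the fluorescence of a tagged transcription factor
bound to that double-stranded probe. Two regimes dominate the rank-ordered
intensity curve: a steep head of probes carrying sequence-specific binding
sites and a long, almost flat tail of background binding. We model the curve
with two independent ordinary-least-squares lines in (rank, intensity)
coordinates,

    y = a1·x + b1   (steep head,  ranks 1..m)
    y = a2·x + b2   (tail,        ranks m+1..n)

and use the extrapolated tail intercept `b2` as the strong-binding cutoff:
a probe is a strong binder when its intensity strictly exceeds the value the
background trend would have at rank 0.

The motif signal is extracted from strong probes by *pseudo-intensity*
k-mer analysis: each probe core is decomposed into its `40 − k + 1`
overlapping k-mers, every occurrence inherits the probe's intensity, and a
k-mer's pseudo-intensity is the mean over all of its occurrences. K-mers
tied to a real binding site recur across many strong probes and accumulate a
stable, high average; background k-mers are rare in the strong set and
average toward the strong-set mean.

## Breakpoint selection

The split between head and tail is not observable directly, so it is chosen
by exhaustive search: every admissible breakpoint `m` (each segment at least
50 points, `m` within 0.1–50 % of the ranks) is scored by the summed squared
error of the two independent line fits, and the minimiser wins (ties to the
smaller `m`). For more than 10,000 candidates a uniform stride is scanned
first and the neighbourhood of the best stride point is then searched
exhaustively; below that the search is literally brute force. Candidate
scoring uses prefix-sum OLS identities (O(1) per candidate); the final
coefficients are refit on the chosen split with centred least squares for
numerical accuracy. Consequences worth knowing:

* the fit is equivariant under affine intensity transforms (shifting all
  intensities by `c` shifts both intercepts and the cutoff by `c`; scaling
  by `m > 0` scales slopes, intercepts and cutoff by `m`);
* on data generated exactly from two lines the parameters are recovered to
  floating-point accuracy;
* constant intensity tables are rejected as degenerate, and fewer than 100
  above-background probes refuse to fit.

Background subtraction is never silent: a background level (scalar or
per-probe) must be supplied by the caller or the simulator, and probes must
exceed it strictly.

## K-mer statistics and ranking

Counting is forward-strand only by default; the two orientations of a
double-stranded site show genuinely different intensity distributions on the
array, so they are kept as separate k-mers (a `collapse_rc` option merges
them by lexicographic canonical representative). A probe containing a k-mer
at `m` offsets contributes `m` occurrences at the probe's intensity; a
per-probe-unique variant is available. K-mers containing N are skipped and
counted in a diagnostics field.

K-mers with a homopolymer run of ≥ 4 G or ≥ 4 C are discarded before
ranking: such G/C-rich oligomers bind nonspecifically across unrelated
proteins. This is the most literal operationalisation of "4–5 consecutive"
G/C enrichment; composition-based filters are out of scope.

Two rankings are provided: by pseudo-intensity and by pseudo-intensity ×
occurrence. **The product ranking is the package default.** Pure
pseudo-intensity ranking is fragile at low occurrence: a k-mer seen a
handful of times inherits the noise of a handful of probes, and the maximum
over many such k-mers can exceed the average of a genuinely bound k-mer seen
hundreds of times. The product score suppresses exactly that failure mode,
and an occurrence floor (`min_occurrence`, either an integer or `"auto4x"` =
⌈4 × mean occurrence⌉) removes near-singletons before ranking; the
pipeline's default floor is `auto4x`. Intensity ranking remains available
and is appropriate when a single dominant site saturates the strong set.

## Clustering and the consensus

The top-ranked k-mer seeds a cluster; any k-mer joins it when some ungapped
sliding alignment against the seed (offsets up to ±(k − 5)) contains an
exact run of ≥ 5 consecutive matching bases and at most 2 mismatches within
the aligned overlap. Overhanging bases are neither matches nor mismatches.
The best offset has the fewest mismatches, then the smallest magnitude,
negative before positive. Passing `max_mismatch=None` reproduces the looser
"5-nt core match only" rule. Clustering is greedy and non-overlapping:
members are removed and the next unassigned k-mer seeds the next cluster, so
cluster membership partitions the ranked list.

Members stack at their alignment offsets into a 4 × width count matrix, one
vote per member (an intensity-weighted option exists); columns normalise to
the PWM. Two consensus readings are derived:

* **consensus** — per-column majority base, with end columns supported by
  fewer than 25 % of members trimmed (a 9-mer seed cluster typically yields
  an 8–14 column consensus);
* **core consensus** — a base is emitted only where its column probability
  strictly exceeds 0.5, N otherwise, N-trimmed at the ends. This is the same
  occupancy rule the package applies to database letter-probability
  matrices, and it is what the pipeline scans with: the majority consensus
  keeps weakly biased flank columns that make a literal substring scan
  needlessly specific, while the occupancy core reduces a 9-mer seed cluster
  of an 8-base site to exactly those 8 bases.

## Refinement

*Mutation scan.* For each motif position the pseudo-intensities of the three
single-base mutants are averaged (a sum-based variant is exposed) and
subtracted from the wild type. Mutants absent from the k-mer table are
excluded from the mean rather than imputed as zero — absence from the
strong-binder set does not mean zero affinity — and a position with no
observed mutant has an undefined delta. The position of maximal drop marks
the bases the protein requires.

*Greedy extension.* A same-length window slides one base 5′ or 3′; of the
four candidate windows the one with the highest pseudo-intensity is kept
(ties to the alphabetically first base, making the trace deterministic).
Directions alternate 5′/3′ by default, up to 2 steps each side; a side with
no candidate window in the table is marked truncated. The final motif is the
chosen 5′ bases + start motif + chosen 3′ bases.

*Flank preference.* Base counts at ±window positions around forward-strand
motif occurrences in a promoter set (reverse-complement occurrences can be
added, tallied in the motif's orientation); edge-truncated occurrences
contribute only the positions that exist.

## Significance testing

Motif significance is a two-sided Wilcoxon–Mann–Whitney test on intensity
ranks, motif-bearing vs motif-free probes (scipy's implementation): the
exact null when the smaller group has ≤ 8 observations and there are no
ties, the tie-corrected normal approximation otherwise. P-values below the
double-precision floor 2.22e-16 are reported as the floor, never as zero.
The enrichment summary cross-tabulates forward / reverse-complement /
motif-free probes against the steep/tail partition; probes containing both
orientations go to the forward group (flagged), palindromic motifs collapse
the two orientations, and fold changes are ratios of arithmetic group means
over the motif-free mean.

## The simulator, and what passing tests do and do not show

`synthetic_pbm.simulate` draws i.i.d. uniform-ACGT promoters, overwrites
motif instances at uniform positions, tiles them with the standard design
and assigns probe intensities

    intensity = baseline + scale · exp(sigma·Z) · Π(boost per planted
                occurrence fully inside the probe core),  Z ~ N(0,1)

Defaults, chosen once as a realistic mid-sized experiment: 2,000 genes of
1,000 nt (98,000 probes), one 8-mer (`ATTGATTG`) planted in 10 % of genes at
an 8× boost, `baseline` 100 AU (scanner floor), `scale` 1,000 AU (background
median), `sigma` 0.5, background threshold 250 AU (which ≈ 99.99 % of probes
exceed, as on real arrays where nearly all features clear background). The
multiplicative boost reproduces the steep-head/heavy-tail rank shape, and a
single explicitly seeded RNG stream makes runs byte-identical.

The simulator emulates the *shape* of PBM data, not its chemistry: no
spatial artifacts, dye effects, probe secondary structure, scanner
saturation, sequence-composition bias in the background, or partial-site
binding (a probe is boosted only when the full motif lies inside its core).
Passing the planted-motif tests therefore shows the inference machinery is
correct and well-calibrated under the stated noise model; it does not show
that any particular biological array meets that model.

## Numerical and interface conventions

* Coordinates 0-based half-open in memory, 1-based inclusive in exported
  TSV; promoters stored 5′→3′ ending at the anchor base.
* Sorting by intensity breaks ties by probe id; all writers are
  deterministic with fixed float formats (2 decimals for intensity averages
  in TSV, full precision in JSON).
* Promoters shorter than 1 kb tile into fewer probes
  (⌊(L − 40)/20⌋ + 1) rather than being rejected; N-containing cores are
  retained but flagged, and k-mers containing N are skipped downstream.
* Gene ids are parsed from probe ids at the last underscore
  (`Os08g0536300_14` → `Os08g0536300`).
* Reverse-complement k-mer space: 4^k/2 classes for odd k,
  (4^k + 4^(k/2))/2 for even k; verified against brute-force enumeration.
* The k-mer length is restricted to 5–11, the range in which pseudo-intensity
  averaging is informative on 40-nt cores.

## Known limitations

* The two-segment model assumes a monotone rank curve with exactly one
  regime change; arrays with several binding regimes (multi-affinity TFs)
  still get a single cutoff.
* Sequence extraction from a genome annotation is upstream of this package:
  callers supply promoter FASTA, and the 5′-UTR anchoring rule is recorded
  as metadata only.
* Substring scanning is literal (plus N in consensus strings); degenerate
  IUPAC patterns are not scanned.
* Problem sizes in the test suite (2,000-gene simulations, 100 seeded
  replicates, ≤ 500k-rank fits) were chosen as the package's own
  demonstration scale; all operations are linear or near-linear in the
  number of probes and run comfortably at genome scale (10⁶ probes).
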