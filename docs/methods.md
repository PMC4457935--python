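# Methods

`evoselect` re-implements the computational skeleton of a directed-evolution
experiment in which a doped-oligonucleotide library over a 59-codon window of
a recombinase gene is carried through iterative conjugational selection, the
per-cycle populations are read out by paired-end amplicon deep sequencing,
and selected variants are characterised by a handful of defined assay
formulas.  This note records the models, the defaults and why they were
chosen, the numerical decisions, and what the synthetic-data tests do and do
not demonstrate.

## Doped-library model (`library_model`)

Degenerate synthesis spikes each coupling step with a small fraction of each
incorrect base, so every window position mutates independently.  A
`DopingScheme` is an ordered list of `(length_nt, per-position substitution
probability)` segments; with 0.5% of each wrong base per step the
per-position probability is 0.015, with 0.33% it is 0.010.  Because synthesis
of doped oligonucleotides is limited to ~100 nt, the default scheme covers
the 177-nt window as two tandem oligos: 100 nt at p = 0.015 followed by 77 nt
at p = 0.010.  The exact per-oligo lengths and which oligo received which
doping ratio are not public; the split is an assumption and fully
configurable.  The alternative base is uniform over the three non-reference
bases (equal spiking implies equality).

The substitution-count distribution per molecule is the convolution of one
Binomial(L_i, p_i) per segment, computed exactly with `scipy.stats.binom` and
`numpy.convolve`; class fractions bucket k = 0, 1, 2, 3, >=4.  Under the
nominal doping the wild-type fraction is ~10%, while realised doped libraries
commonly carry far fewer substitutions (~70% wild type is typical of this
design); `DopingScheme.efficiency` is a scalar multiplying every p_i, and
`fit_efficiency` solves prod (1 - s p_i)^{L_i} = observed WT fraction for s
(Brent's method).  The cause of under-incorporation is chemical and not
modelled; the scalar simply lets users match a realised spectrum.

Coordinates are 1-based and inclusive on the CDS coding strand; codon 1 is
the initiator Met, so a window of codons 79-137 spans CDS nucleotides
235-411 (177 nt) and carries 3 x 177 = 531 possible single substitutions.

## Coverage confidence (`coverage_confidence`)

"How many clones guarantee the whole set of 531 single substitutions?" is
the coupon-collector problem with m = 531 equally likely types.  Two routes:

* **Monte Carlo.**  Each trial draws types until all are seen and records
  the number of draws.  The implementation samples each trial as the sum of
  m independent geometric waiting times with success probabilities m/m,
  (m-1)/m, ..., 1/m — *exactly* the distribution of the literal draw loop
  (waiting times between successive new types are independent geometrics) —
  which vectorises to ~10 s for 10^6 trials.  A literal draw-loop oracle in
  the tests confirms the distributional identity (two-sample KS at small m).
  The empirical threshold at level q is the smallest n such that at least
  q x n_trials trials completed within n draws, matching an "at least
  900,000 of 1,000,000 trials" reading for q = 0.9.  The generator is
  seeded; the seed is part of every simulation interface.
* **Exact.**  P(complete in n draws) = sum_k (-1)^k C(m,k) (1-k/m)^n,
  computed with log-gamma terms and compensated summation, clamped to
  [0, 1].  The alternating sum loses all significance when the result is
  many orders below the largest term (n close to m, vanishing probability);
  results under `max|term| x 1e-11` are therefore recomputed with the
  numerically stable all-nonnegative distinct-types Markov-chain recursion
  (O(n m)).  Exact thresholds are found by bisection.

For m = 531 the exact thresholds are 4,524 (90%) and 4,905 (95%); a
1,000,000-trial simulation reproduces them to within a couple of draws
(the quantile's Monte Carlo standard error is ~2 draws), consistent with the
published 4,521 / 4,904 from an unseeded single run.  The Gumbel asymptotic
m(ln m - ln(-ln q)) agrees within 0.5%.  A library with ~4,565 single-mutant
colonies has completion probability 0.907, i.e. >90% confidence of
containing all 531 substitutions.

## Amplicon pipeline (`amplicon_enrichment`)

The read-processing chain mirrors the published analysis: merge paired reads
on their overlap; quality-trim and concatenate (forward + reverse-complement
of reverse) the pairs that do not merge; align each processed read to the
CDS with the classic Smith-Waterman algorithm; call substitutions inside the
window, adjusting for gaps and missing data; translate; tabulate; threshold;
rank.

* **Merging** slides the reverse-complemented mate along the forward read;
  the ungapped overlap (>= 6 nt, mismatch fraction <= 0.08 — dialect
  defaults emulating the common joiners, not published values) with the
  lowest mismatch fraction wins, ties to the longer overlap.  Disagreements
  resolve to the higher-quality base (forward on ties), agreements keep the
  higher quality.
* **Quality trimming** truncates a read at its 5'-most base below Phred 20.
  This is the fixed point of repeatedly clipping the read at its 3'-most
  low-quality base and guarantees the surviving prefix is clean; it is
  stricter than trimmers that only peel bases off the 3' end.
* **Alignment** is an affine-gap Smith-Waterman (numba kernel; match +2,
  mismatch -3, gap open -5 for the first gap base, extend -2 — configurable
  defaults, none were published).  Tie-breaking is deterministic: the
  rightmost maximal cell (largest reference column, then largest query row)
  and a diagonal > up > left traceback preference with gaps closed as early
  as possible.  A naive pure-Python full-matrix implementation serves as the
  oracle on hundreds of random instances.
* **Calling** reports substitutions only at aligned, non-gap, non-N window
  positions; gapped/absent/N positions are "uncovered" — neither reference
  nor variant — so indel-containing reads still contribute their substituted
  positions but no indel alleles are emitted (the selection concerns
  substitutions).  A read must cover >= 90% of the window to receive a
  whole-read genotype; partial reads still feed per-position counts.
* **Translation** uses the standard codon table; reads with no change or
  only synonymous changes are wild type at the protein level, others are
  single/double/triple/four-plus missense by the number of changed residues.
  Labels are one-letter style (V79L); two hits in one codon yield one
  amino-acid change.
* **Tabulation** reports fractions per amino-acid change — a read with k
  changes counts toward k labels, with each label's support split by the
  single/double/triple context it occurred in — and per whole genotype.
  The detection threshold is strict ("more than 0.5%"): entries with
  fraction > 0.005 appear in reports, everything is retained internally.
  Whether such a threshold should apply per amino-acid change or per
  genotype is ambiguous in this kind of experiment; both tables are
  computed and reporting defaults to per amino-acid change, which matches
  how prominent variants are usually labelled.
* **Trajectories** follow every label reported in any cycle across strictly
  ordered cycles (absent = 0), flag strict monotone increase, and give the
  first-to-last fold change (infinite from zero).

## Selection simulator (`selection_sim`)

One selection cycle is a single multinomial draw of `bottleneck` colonies
with probabilities proportional to frequency x fitness, where fitness is the
relative transconjugant yield of the protein variant (wild type = 1).  This
is the simplest model consistent with the experiment's cycle narrative:
fitness acts once per cycle at the conjugation/selection step and there are
no within-cycle growth dynamics.  The default enhanced-variant fitness is
2.8, the ratio of a prominent variant's yield to wild type's
(~352.8 / 125.3 colonies per 10^6 donors).  The default bottlenecks are
(2000, 10000, 800, 75, 75, 40): the first three are reported colony counts;
for the last three cycles only transconjugant frequencies per 10^6 donors
were reported and those numbers are repurposed as counts — an assumption,
configurable via `SelectionConfig`.  A deterministic (infinite-population)
mode iterates the exact frequency update f' = f w / sum(f w) and is used to
pin closed-form expectations (e.g. f0 = 0.01 at w = 2.8 reaches 0.8296 after
six cycles).

Sequencing emulates a short-amplicon paired-end run: the amplicon is the
window plus 25-nt flanks (227 nt), and the default 250-nt read length is
truncated at the amplicon end so the two mates fully overlap — the standard
design for amplicons shorter than twice the read length, and what makes
merge-based error correction effective.  Per-base substitution errors are
i.i.d. with mean rate `error_rate` (default 0.003); the "decline" quality
model lets Phred fall linearly 35 -> 20 along the read, with per-base error
probabilities proportional to 10^(-Q/10) and rescaled so their mean equals
the configured rate, and the written qualities always match the realised
per-base probabilities.  Errors are substitution-only and uniform over the
three alternatives; no indel errors by default.  Selection and sequencing
use two independent seeded RNG streams so either stage can be varied alone;
identical seeds give byte-identical FASTQ.

What the simulator does *not* emulate: mechanistic conjugation (crossover
number enters only through the fitness scale), mating kinetics, plasmid
copy-number effects, PCR amplification bias, chimeras, quality-correlated
indels, and adapter read-through.  Passing recovery tests therefore shows
the pipeline is correct under an idealised error model, not that it is
robust to every artefact of real amplicon data.

## Assay arithmetic (`assay_calc`)

* NADH-coupled ATPase: rate (uM/min) = |dA380/min| / (1.21 mM^-1 cm^-1 x
  1.0 cm) x 1000.
* Apparent k_cat = rate / available binding sites, sites = min(protein,
  ssDNA/3) in uM (one protomer site per 3 nt, or protein-limited);
  `rate_from_kcat` is its exact inverse.
* Percent-of-maximum, percent decline, transconjugant frequency per 10^6
  donors, fold change, UV survival percent, and specific fluorescence
  (F/OD600, error on nonpositive OD mirroring the suppression of early
  low-density points) are the obvious ratios.
* Competition plates are countable at 40-300 total colonies and excluded if
  either competitor has < 20; fractions use included plates only, a cycle
  with none reports NaN.  The rule depends only on each plate's own counts,
  hence order-independent and idempotent.
* Report rounding is one decimal, round-half-even; raw values are never
  rounded.  Optional +/- values propagate first-order and are labelled
  derived.  Note one published decline ("27.6% to 11.4") cannot be
  reproduced from its own rounded inputs (15.7 -> 11.4 is 27.4%) and was
  presumably computed from unrounded rates; it is documented, not
  reconciled.

## Synthetic reference

No reference sequence or reads are deposited for the emulated study, so the
package ships a synthetic 150-codon CDS (see `reference.py`).  Only the
residue identities relevant to variant naming are placed as in the targeted
protein, with codons chosen so the documented amino-acid changes are
single-nucleotide reachable; all other residues are arbitrary fillers.  It
is explicitly a stand-in, adequate because every statistic computed here
depends on window length, codon structure and substitution reachability —
not on the actual gene sequence.

## Validation problem sizes

The test suite runs the coverage Monte Carlo at the full 10^6 trials and the
end-to-end recovery at the full study conditions: six cycles at bottlenecks
(2000, 10000, 800, 75, 75, 40), one advantaged variant at fitness 2.8, 10^4
read pairs per cycle, error 0.003, fixed seeds.  Because initialising from
the fitted doping model would start any specific variant at below one
expected colony after the first 2,000-colony bottleneck (where drift, not
selection, decides its fate), the recovery run uses an explicit initial
mixture — wild type 89%, the advantaged variant at 1% (the same starting
frequency as the deterministic worked example), and four neutral variants at
2.5% each — so that recovery and monotonicity are tested where the
multinomial model makes sharp predictions.  Estimated per-cycle fractions
are required to fall inside central 99% binomial intervals of the realised
(post-bottleneck) truth for every variant at >= 1% truth frequency, and the
advantaged variant must be the unique strictly monotone riser among the
reported labels.  Other statistical tests (martingale means/variances,
chi-square goodness of fit, KS distributional identity) use 10^4-10^5
replicates with fixed seeds.

## Known limitations

* Inclusion-exclusion in float64 cannot resolve completion probabilities in
  the extreme lower tail; the Markov fallback covers it at O(n m) cost.
* The Smith-Waterman kernel is O(|q| x |r|) per read with full traceback;
  for much longer references a banded or vectorised aligner would be
  warranted.
* Doping is modelled as independent per-position Bernoulli substitution
  only; codon-level designs (NNK etc.) and synthesis-chemistry effects
  beyond the efficiency scalar are out of scope.
* Fitness is a per-protein-label scalar; epistasis between co-occurring
  mutations on one molecule is represented only insofar as the combined
  label carries its own fitness value.
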