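# Methods

This note records the models implemented in `lariatfold`, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical conventions used throughout.

## Composition statistics (`seq_metrics`)

MBP is computed from base proportions with the closed form

    MBP = 1 − [max(A−U,0) + max(C−G,0) + |max(U−A,0) − max(G−C,0)|]

after mapping T→U. Ambiguous bases (N and other IUPAC codes) are excluded
from both numerator and denominator of all composition fractions; the 5%
ambiguity cutoff applies only to lariat-mapping reads, so arbitrarily
ambiguous sequences can still be scored here as long as one unambiguous
base remains.

`mbp_matching_oracle` is an independent verifier: it maximizes the number
of disjoint {A–U, C–G, G–U} pairs over the base multiset by exhausting the
split of G between C–G and G–U pairing. The closed form and the oracle
agree on every composition with total count ≤ 40 (exhaustive grid in the
test suite). One consequence of directional G–U wobble is worth noting:
MBP is *not* invariant under reverse complement (`AAAATTCC` scores 0.5,
`GGAATTTT` scores 1.0, because the excess U in the latter can wobble-pair
with G). The formula is implemented exactly as stated; the asymmetry is
real and covered by tests.

Shuffling is mononucleotide (uniform seeded permutation): it preserves
composition exactly, which is the null the ensemble comparison needs.
Dinucleotide-preserving shuffles are deliberately out of scope.

The probability that a random k-mer is fully paired is taken as MBP^k
(position-wise independence). The relevant k are the sensor minimums 17,
22 and 33. A Monte-Carlo alternative (`kmer_fully_paired_prob_mc`) draws
k bases i.i.d. from the composition and tests full pairability of the
draw; it upper-bounds the closed form (pairability of a finite draw is
less strict than per-position pairing) and is provided for sensitivity
analysis.

## Structure statistics (`structure_stats`)

A dsRNA stretch is a maximal run of consecutively stacked pairs.  The
strict breaking rule is used: any departure from perfect stacking — a
1-nt bulge, an internal loop, a junction — terminates the stretch.  This
matches the mechanistic requirement of the sensors for uninterrupted
helix, and it is the conservative choice where tolerance for small bulges
was not specified.  Sensor sites are Σ floor(stretch length / threshold)
with the default panel OAS1→17, RIG-I→22, PKR→33 bp.

Folding is an injected contract (sequence → structure + energy), because
absolute MFE values depend on the predictor and its version:

* `ViennaFolder` wraps RNAfold via the ViennaRNA Python bindings for
  production use.
* `MaxPairFolder` is the built-in deterministic Nussinov-style
  pairing-maximization folder: minimum hairpin loop of 3 nt, {A–U, C–G,
  G–U} pairs, surrogate energy −1 per pair, deterministic traceback
  (unpaired-first, then smallest split). It agrees with exhaustive
  enumeration of nested structures on sequences ≤ 12 nt (tested) and makes
  every structure-derived statistic reproducible with no external binary.

Regions longer than 5,000 nt are skipped by the region-level folding
driver and written to a skip report; folding cost grows cubically and
comparisons across very different lengths are not meaningful anyway. Both
raw and length-normalized MFE are emitted.

Ensemble deviation is observed − mean(shuffled) over n = 10 shuffles by
default; negative values mean more structure than expected from
composition. With the pairing-maximization folder a homopolymer's
deviation is exactly 0 (all shuffles are the sequence itself).

## Alu classification (`alu_catalog`)

Orientation is the element's annotated strand in genome coordinates.
Whether two insertions are inverted relative to each other is
gene-strand-invariant, so gene strand is never consulted. Categories:
0 insertions → NONE, 1 → SINGLE, ≥2 all same strand → MULTI_SAME, ≥2 with
both strands present → IR.

An Alu is assigned to a region when at least 50% of the element's length
overlaps it (configurable; no standard value exists, so the default is
stated rather than inherited). Nested or overlapping Alus count as
separate insertions, and one Alu may be assigned to several overlapping
regions.

## Lariat mapping (`lariat_mapper`)

The filter chain and its thresholds: ≤5% ambiguous characters; genome
prefilter (end-to-end mappable reads discarded); exact, unique occurrence
of one intron's first-20-nt 5′SS key; retained prefix ≥ 20 nt; branch
alignment with ≤5 mismatches, ≤10% mismatch rate, at most one indel of
≤3 nt; same-gene, transcription-strand, inverted-order candidates only;
highest score wins (ties: smaller coordinate, then intron id); the call is
the final aligned base in transcription orientation.

Two ambiguities were resolved explicitly:

* "Trimmed portion ≥ 20 nt" is applied to the *retained prefix* — the
  segment that is re-mapped, hence the one whose mappability the rule
  protects. The alternative reading (rule on the removed suffix) is
  available behind `MapperConfig.prefix_rule_on_retained=False`.
* The branchpoint must fall inside the called intron (not merely
  downstream of its 5′SS within the gene); candidates ending outside the
  intron are dropped before scoring.

Scoring is +1 match, −1 mismatch, −2 gap open, −1 per gap base
(configurable; no published scheme exists for this step). Indels must be
internal — flanked by aligned bases on both sides — since an edge gap is a
clip, not an indel, and would silently absorb edge mismatches.

The built-in aligner finds candidate loci with edlib (C edit-distance
search in infix mode, band = max mismatches + max indel length) and then
re-scores each candidate window with an exhaustive enumeration of single-
indel placements under the constraint triple. It is intended for desk-
scale genomes (up to tens of megabases); externally aligned data can be
ingested as a SAM subset for the prefilter stage. Reads are assumed
strand-resolved (stranded library); reverse-complement 5′SS key search is
available as a config flag.

Both read-level and distinct-branchpoint counts are available from
`quantify` (`count_mode`), since published "lariat read" counts do not
state which collapsing was used. Fold changes between libraries are
computed on per-million-normalized counts with a configurable pseudocount
(default 0; 0-denominator cases are reported as infinite and flagged
rather than imputed).

`lariat_dsrna_sites` folds each intron with at least one call once, sums
per-sensor site counts over called introns, and normalizes per million
mapped reads.

## Alu-pair hybridization (`alu_hybrid`)

10,000 trials (default): sample one plus-strand and one minus-strand Alu
with probabilities proportional to their read representation (with
replacement), predict the intermolecular duplex, count sensor sites.
Failed predictor calls are recorded, tallied and excluded from the
summary distribution. Because the hybridizer contract is deterministic,
per-pair results are cached; on pools of ≤10 members this turns 10,000
trials into at most 100 predictor calls.

`DuplexFolder` wraps RNAduplex; the built-in
`MaxComplementHybridizer` slides one strand along the reverse complement
of the other (no gaps, intermolecular pairs only, G–U allowed), keeps the
offset with the most complementary positions (first offset on ties), and
reads stretches off the runs of consecutive complementary pairs. Two
exact reverse complements of length L therefore yield one stretch of L
and floor(L/threshold) sites per sensor.

## RIP-seq quantification (`ripseq_quant`)

RPKM = count / (length/10³) / (total/10⁶); TPM renormalizes RPKM to sum
to 10⁶ per library. IR Alu enrichment is the mean over sites of IP/total
coverage; zero-denominator sites are excluded and counted, never imputed.
The ratio direction is a named switch (`ip_over_total` default) because
axis conventions for such plots vary. The intron vs 3′UTR comparison is
Σ TPM(introns) / Σ TPM(3′UTRs) within each Alu category; empty strata are
omitted with a warning. Strand-aware counting is assumed done upstream.

## Synthetic data (`synthetic_data`)

The generator's job is ground truth, not realism:

* **Genome.** Single-intron genes (5′UTR | exon | intron | exon | 3′UTR in
  transcription order, both strands), uniform-random background in which
  no 20-mer occurs twice in either orientation. Uniqueness is enforced at
  generation time for background sequence; planted Alu copies are
  repetitive by construction, so the post-hoc validator
  (`validate_unique_kmers`) takes the planted Alu intervals as a mask.
  K-mers straddling an Alu/background junction share up to 19 fixed bases
  between element copies and are best-effort only — they fall inside the
  validator's mask as well.
* **Alu content.** Insertions are copies of the bundled 282-nt consensus
  Alu element (forward or reverse-complemented to realize SINGLE /
  MULTI_SAME / IR plans), separated by background spacers, optionally
  mutated at a per-base rate. An unmutated IR intron always contains a
  perfect-complement pair of full element length.
* **Branchpoints** are planted 30 nt upstream of the intron's 3′ end
  (within the 18–40 nt window typical of real branchpoints), always in
  background sequence so branch segments map uniquely.
* **Lariat reads** are (read_length − 20) genomic bases ending at the
  branchpoint followed by the intron's first 20 nt. Noise applies to the
  prefix only. Planted substitutions keep ≥5 nt from the prefix edges and
  ≥5 nt apart, and planted indels sit in the central half of the prefix:
  an edge or clustered event is alignment-equivalent to a smaller one, so
  constraint-boundary tests would otherwise be testing an ambiguous truth.
* **Counts.** Totals are gamma-Poisson (mean = expression × length/10³,
  variance μ + dμ²; d = 0 gives the exact mean). J2-IP coverage at IR
  sites is total × enrichment × mean-one gamma noise, which makes the
  per-site IP/total ratio an unbiased draw around the planted enrichment —
  a ratio of two independent count draws would carry a Jensen bias that no
  mean-ratio estimator should be asked to absorb. Defaults: expression
  100 reads/kb, dispersion 0.05, IP noise dispersion 0.05, enrichment 2.0.

What this does **not** emulate: Alu subfamily structure, realistic repeat
landscapes (only the planted copies repeat), position- or quality-dependent
sequencing error, fragment-level coverage profiles, splice isoforms, or
multi-intron genes. Passing the recovery tests therefore demonstrates the
correctness of the algorithms under their stated contracts, not their
performance on repetitive real genomes, where 5′SS keys and branch
segments need not be unique.

## Problem sizes and numerics

The recovery suite uses a 2-Mb genome with 25 genes and 500 simulated
reads, a scale at which the edlib-backed aligner resolves every locus
uniquely and the whole suite completes in about a minute; the exhaustive
MBP grid covers all ~135,000 compositions of total ≤ 40. Coordinates are
0-based half-open everywhere internally; 1-based only at GTF file
boundaries. All stochastic operations take integer seeds; reruns with the
same seed and config are byte-identical, and output files carry version,
seed and config hash in a comment header (no timestamps). Energies from
the built-in folder are surrogate pair counts, not thermodynamic values —
comparisons mixing predictors are meaningless by design and absolute MFE
distributions are out of scope.
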