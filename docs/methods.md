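# Methods

This note documents the models and procedures implemented in phagekit, the
parameter defaults and why they were chosen, what the synthetic data does
and does not emulate, and the numerical choices that affect results.

## Synthetic genomes

`synthgen.GenomeSpec` describes one genome: length (bp), G+C fraction, CDS
count, DTR length (bp) and optional homopolymer tracts. Defaults throughout
the examples, tests and the acceptance script follow the configuration of
the two O139-specific N4-like vibriophage genomes the package is built to
analyse: 69,278 bp, 34.6% G+C, 79 CDSs, a 1,974 bp direct terminal repeat
represented once at the 3' end (non-redundant form), and homopolymer tracts
up to 12 nt.

Construction: bases are drawn per-position with `P(G or C) = gc`; CDS
regions are rewritten as clean ORFs (ATG start, stop-free body, single
stop), with the per-base G+C of coding codons calibrated by inverting the
conditional expectation given "not a stop codon" — without this, excluding
the AT-rich stop codons inflates genome G+C by ~1.4 percentage points at
34.6% G+C. A build whose realized G+C deviates more than 0.5 pp from target
is resampled (bounded retries). CDSs are non-overlapping, ≥ 300 bp,
alternate strands, and keep intergenic gaps ≥ 50 bp so "intergenic" is
unambiguous; the DTR region is kept CDS-free so the repeat unit duplicates
no annotation. Homopolymer tracts are planted mid-gap with non-matching
flanking bases, so planted tract lengths are exact and maximal.

`diverge_pair` plants substitutions whose class is guaranteed at planting
time: synonymous/non-synonymous candidates are enumerated per codon from
translation table 11 (strand-aware), each codon is used at most once, and —
except for dedicated in-tract plantings — no substitution may sit inside a
≥ 6 nt homopolymer run of either genome, so post-filter totals equal
planted totals. Indels are 1–10 bp intergenic events by default. The two
gene-content differences seen between real sibling phage genomes (a CDS
present in only one genome) can be emulated with `cds_deletion=True`, which
removes one whole, event-free CDS; whether real small indels are of this
kind is not asserted — both modes are available.

Read simulation draws uniform start positions at `coverage × length /
read_length` reads, with optional uniform substitution errors. It does
not model platform-specific artifacts (no homopolymer-length errors, no
quality strings beyond a constant): the homopolymer-exclusion rule is
exercised through planted substitutions, not through simulated
pyrosequencing noise, so passing tests show the bookkeeping is right, not
that the error model of any instrument is reproduced.

## DTR detection

Mapping (`termini.map_reads`) is k-mer-seeded (k = 31, seeds every k bases)
exact/near-exact placement with a 90% identity floor. Reads that map
equally well at several positions are counted at *every* best position;
this is deliberate and is precisely what converts terminal redundancy into
a 2× pileup on the non-redundant reference.

Detection (`termini.detect_dtr`): the interior baseline is the median depth
over the central 50% of positions. A repeat is sought at each terminus
where the smoothed depth (moving average, window 201 bp by default, capped
at n/50) reaches `fold_min × interior` within the outer quarter of the
genome; `fold_min = 1.75` sits between the 1× interior and the true 2× of
a repeat, robust to sampling noise. The end-of-contig coverage ramp —
reads cannot straddle the reference end, so depth builds up over about one
read length — is skipped when locating the crossing, and its width serves
as the data-driven estimate of the boundary blur.

The inner boundary is placed at the maximum of the standardized excess
statistic S(b) = (Σ depth[b:j] − interior·(j−b)) / √(j−b), where j is the
threshold crossing. This is the optimal changepoint statistic for an
elevated terminal segment under independent noise: it is exactly maximal
at the step of a noise-free profile, and because it integrates over the
whole candidate region it is robust to the read-length-correlated local
dips that defeat walk-based or matched-filter boundary rules at 20–40×
coverage. A final short walk moves the boundary outward while the depth
just outside still exceeds 1.1× interior, undoing the half-ramp bias on
gradual boundaries; the walk is capped at half the observed ramp width.

The reported fold is the median depth of the run's established core (outer
ramp trimmed) over the interior median. It is a *measurement* with
substantial sampling noise — at 30× with 400 bp reads the repeat region is
covered by only ~300 reads, giving the region median a standard deviation
near 0.18 fold units — so detection does not re-threshold it; a call is
returned whenever the smoothed profile crossed the detection threshold and
the run passes the length sanity checks (≥ `min_length` = 100 bp, < half
the genome). Re-testing the measured median against 1.75 would reject
roughly one in eight true 2× repeats at this coverage for no inferential
gain.

Accuracy: across seeded simulations at the study configuration (69,278 bp,
1,974 bp repeat, 30×, 400 bp reads) recovered lengths fall within one read
length of truth in ≥ 19 of 20 runs; the residual error is dominated by the
ramp geometry, not by the statistic. For short repeats the signal itself
attenuates — a repeat shorter than the read length produces *no* depth
doubling, because no read fits inside the 5'-copy — so the varied-length
recovery property is exercised with 100 bp reads (smoothing window 101)
against repeats of 400–2,500 bp.

Terminal motif search is a bounded exhaustive scan (window 50 bp, unit
≥ 4 bp) over the three arrangements u·u (direct), u·reverse(u) (the
arrangement of the GATAGGGGATAG motif), and u·revcomp(u) (inverted repeat
proper); homopolymeric units are excluded as trivially self-similar.

## Restriction and topology

Recognition sites are IUPAC patterns matched on the top strand; a
non-palindromic site is also searched as its reverse complement.
Ambiguity codes in the *site* expand to their base sets; an N in the
*sequence* never matches (conservative). Twelve enzymes are built in so
the digestion experiments of the source analyses run out of the box; cut
offsets default to the canonical cut position where known, but all
topology evidence is fragment *counts*, which are offset-invariant.

Topology logic: every informative enzyme (≥ 1 site) showing n + 1
fragments ⇒ `linear_fixed`; every one showing max(n, 1) ⇒
`circular_or_permuted`; any mixture ⇒ `ambiguous` with the dissenting rows
listed. The cos test compares heated and unheated fragment multisets with
a 2% default length tolerance (gel resolution): identical ⇒ no cohesive
ends; exactly one fragment replaced by two summing to it ⇒ cos present;
anything else is refused as uninterpretable rather than guessed at.

## Genome comparison and SNP classification

Anchoring uses k-mers unique within *both* genomes (k = 21; at 70 kb and
34.6% G+C a random 21-mer is effectively unique), chained by the longest
strictly-increasing subsequence in both coordinates. Anchors on one
diagonal merge into gapless blocks; blocks shifted by an indel are trimmed
to prevent double-counted columns. Inter-anchor gaps ≤ 20 kb are closed by
optimal global alignment (match +1, mismatch −2, gap open −5, extend −1 —
near-identical genomes make the scores insensitive; determinism matters
more); larger gaps are reported as structural differences, not forced into
an alignment.

Each mismatch column yields one SNP (columns with N are skipped).
Homopolymer tracts are maximal single-base runs ≥ 6 nt; a SNP is excluded
if its position lies inside a tract of either genome — tract membership is
half-open, so a SNP immediately adjacent to a tract is kept. Reported
totals are post-filter; the pre-filter count is also carried in the
summary because the exclusion convention of published totals is not always
explicit.

Classification extracts the codon covering the SNP from each genome
through that genome's own annotation (so indel-shifted coordinates stay
correct) and compares amino acids under table 11. Adjacent SNPs in one
codon are judged jointly at codon level but counted as separate records.
A SNP coding in one genome and intergenic in the other is flagged
`discordant` and left out of the class partition. The affected-protein
count is the number of distinct locus tags carrying ≥ 1 non-synonymous
SNP.

## Proteome statistics and trees

Local protein alignment uses BLOSUM62 with gap open 11 / extend 1 (the
classic protein-search defaults) through Biopython's pairwise aligner;
E-values use the standard gapped-BLOSUM62 Karlin–Altschul constants
λ = 0.267, K = 0.041. These constants reproduce database-search behaviour
closely enough for display cutoffs (E ≤ 1e-5, identity ≥ 35%), but
absolute E-values differ from any particular search engine's composition
corrections; identity-based quantities (API) are insensitive to this.
Percent identity is counted over aligned residue pairs, gap columns
excluded — stated explicitly because published APIs rarely define the
denominator.

API is the mean identity of best hits passing both cutoffs, unidirectional
query → reference by default (matching the convention of comparing a
family against one reference genome); a reciprocal mode averages both
directions. Mean BSR averages, over each proteome's proteins, the best
cross-genome score divided by the self-score (0 when no hit passes the
E-value cutoff), then symmetrizes by averaging the two directions;
1 − mean BSR is the tree distance.

Neighbor joining is the canonical agglomeration with Q-criterion ties
broken by the lowest taxon-index pair (full determinism); the final three
lineages are star-joined, giving an unrooted tree whose tip-to-tip path
lengths reproduce any additive input matrix exactly (verified to 1e-9 up
to 8 taxa). Negative branch estimates are clamped to zero with a warning.
Bootstrap support is the fraction of replicate trees (columns or proteins
resampled with replacement; one seed, replicate streams drawn from it)
containing each internal bipartition of the full-data tree, reported as
percentages on internal nodes.

The progressive aligner builds a guide tree by NJ on pairwise k-mer
distances and merges profiles by global profile–profile alignment under
mean BLOSUM62 scores with affine gaps (open −10, extend −1). It is a
plain guide-tree progressive method: adequate for the well-conserved
protein families it is used on here (e.g. large terminase), with no
iterative refinement.

## Problem sizes used in validation

The test suite and acceptance script run entirely on synthetic data at the
study's own scale: one 69,278 bp genome pair for the SNP pipeline, twenty
seeded 30× simulations for DTR recovery, 100 random sequences for
digestion-oracle equivalence, 1,000 random kilobase sequences for the
homopolymer oracle, and additive matrices up to 8 taxa for NJ. These sizes
make every check exact or high-powered while keeping a full run in the
seconds-to-minutes range.

## Known limitations

- The read simulator has no platform error model; conclusions about
  homopolymer artifacts concern the exclusion rule, not error generation.
- `map_reads` is exact/near-exact placement without base qualities or
  paired ends; it is adequate for depth profiling, not a general mapper.
- The 5' terminus of a DTR genome is not independently resolved (as in the
  underlying wet-lab situation): detection reports per-end evidence, and a
  repeat is assumed identical at both ends when constructing redundant
  forms.
- GenBank parsing handles simple and complement locations only; join()
  locations (spliced/wrapped features) are rejected explicitly.
- E-values are scale stand-ins for search-engine statistics; trees from
  1 − mean BSR are dendrograms of proteome similarity, not phylogenies in
  the strict coalescent sense.
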