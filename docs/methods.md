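# Methods

`acascan` re-creates, as tested desk-scale machinery, the computational
workflow used to survey anti-CRISPR-associated (Aca) transcriptional
repressors across bacterial genomes: find family homologs, ask whether each
sits in an operon with anti-CRISPR (acr) genes, pull the operon promoter, and
look for the sigma70 core elements and inverted-repeat (IR) operator sites
that make Aca-mediated autorepression possible. Because the original survey
ran against multi-terabyte database snapshots that cannot be reproduced at
desk scale, every stage here is exercised on synthetic communities with
planted ground truth; the scientific claims the tests support are therefore
claims about the *machinery*, not re-measurements of database-era counts.

## Synthetic communities

The generator (`synthetic_data`) emulates the genomic structures the
analysis targets.

* **Background DNA** is i.i.d. per base with P(G)=P(C)=gc/2 (default
  gc = 0.5). This is the simplest null for intergenic sequence; real mobile
  genetic elements have skews, repeats and codon structure that this model
  deliberately omits, so passing tests show correct behaviour of the
  detectors given their model assumptions, not performance on real MGE
  backgrounds.
* **Background CDSs** are random stop-free ORFs (ATG + random sense codons +
  stop, 150–900 nt), giving the scanner and operon caller realistic
  negatives.
* **acr–aca operons**: 1–2 acr genes upstream of one aca on the coding
  strand, consecutive genes separated by 0–55 intervening bases (drawn
  uniformly), strand chosen at random per locus. **Solo aca** loci carry the
  promoter and the aca only; the placer keeps every solo aca at least 5.1 kb
  from any acr gene so "solo" is recoverable under the 5 kb neighborhood
  rule rather than an accident of layout.
* **Promoters** (400 bp, planted immediately upstream of the leader gene):
  a −10 hexamer ending 20 nt before the start codon, a −35 hexamer a
  15–19 nt spacer upstream (defaults TTGACA/TATAAT, spacer 17), and an IR
  whose left arm ends immediately 5′ of the −35 with its right arm inside
  the core spacer — so the IR span overlaps the core promoter and is an IR1
  by construction. An optional second IR with the same arm consensus sits
  entirely 5′ of the −35 (an IR2). `ir_mismatches` substitutions per IR are
  placed in random arm positions, so the arms stay within that many
  mismatches of perfect reverse complementarity.
* **Family members** are mutated copies of fixed synthetic reference
  proteins (invented sequences styled on small HTH repressors; they match no
  real accession) at a per-site substitution rate; `solo_mutation_rate`
  optionally makes solo members more divergent than associated ones, the
  pattern the family statistics are designed to expose.
* All randomness flows from one integer seed through `numpy` Generators;
  identical configs produce byte-identical FASTA/GFF3/manifest output.

## Homology scanning

Families are position-specific log-odds profiles over the 20 amino acids.
Per column, `score(a) = log2(((f_a + pc·bg_a)/(1 + pc))/bg_a)` with column
frequency `f_a`, pseudocount weight `pc` (default 1) and background `bg`
(uniform by default); columns more than half gaps are dropped. Applying the
pseudocount to frequencies rather than raw counts makes the profile depend
only on column composition, not on how many copies of a sequence the seed
alignment holds.

Scanning is ungapped: the profile slides over each CDS translation,
partial overlaps allowed (unaligned columns score 0 and reduce coverage),
and the best-scoring placement with coverage ≥ `min_coverage` (default 0.4)
is kept. Ungapped scanning keeps two useful exactness properties: the
profile consensus is provably the highest-scoring sequence, and scores are
independent of iteration order. Full profile-HMM machinery (Forward/Viterbi,
insert states) is out of scope.

Score thresholds are per family and calibrated empirically: the 99.9th
percentile of best-window scores on background-only synthetic genomes,
floored at 25 % of the profile's maximum achievable score. The floor is an
absolute bit-score filter in the spirit of the fixed bit-score ranges used
in field practice to prune ubiquitous HTH-domain false positives; the
empirical quantile alone has a heavy-tailed null that a finite calibration
sample underestimates.

Pairwise identity uses Biopython's global aligner (match +1, mismatch 0,
linear gap −1). Identity = matches over the columns between the first and
last position where both sequences align (internal gaps count in the
denominator). Because co-optimal alignments can differ in match count, the
pair is aligned in canonical (lexicographic) order, making identity exactly
symmetric; coverage is reported relative to the first argument (the
reference), capped at 1. Redundancy reduction is greedy incremental
clustering, longest sequence first, joining the first representative at or
above the identity threshold — 0.8 for proteins, 0.9 for nucleotide sets,
one algorithm for both alphabets.

## Genomic context

Coordinates are 0-based half-open internally; the GFF3 layer owns the
1-based inclusive conversion. An operon is a maximal run of same-strand CDS
with ≤ 55 strictly intervening bases between neighbours (overlaps merge);
an interposed opposite-strand CDS always breaks the run, since
transcriptional read-through across it is implausible. The leader is the
5′-most member on the coding strand.

Association of an aca-like gene: *acr-associated* if a labelled acr CDS
shares its operon; else *proximal* if one lies within ±5 kb (overlap by one
base suffices for neighborhood membership); else *solo*. The acr class
reported is the best present (known > candidate > putative). Any operonic
co-membership qualifies as associated regardless of gene order; order is
recorded so stricter filters can be layered on. The association network
counts, per acr-associated record, one edge increment between the aca
family and each distinct linked acr family.

## Promoter analysis

400 bp upstream of the operon leader is extracted coding-strand oriented
(clipped and flagged at contig edges). Core-promoter prediction is a
transparent consensus-matrix scan standing in for closed-source predictors:
hexamer PWMs from TTGACA/TATAAT with P(consensus base) = 0.8
(log2(0.8/0.25) ≈ +1.68 bits per matching base), spacers 15–19 nt penalised
0.5 bits per base away from 17, all placements inside the 3′-most 150 bases
scored, ties resolved toward the 3′-most −10 then the longest spacer.
Significance is an empirical null quantile (99th percentile of best scores
on random 150-mers, recalibrated per run from the stage sub-seed). Only the
relative placement of IRs versus the core matters downstream, so the
absolute calibration is not load-bearing.

IR detection enumerates every (position, arm, spacer) combination within
bounds (arm 4–10, spacer 0–12, ≤1 mismatch between the left arm and the
reverse complement of the right arm, by default) and reports only maximal
IRs: one whose one-base arm extension — outward (both arms grow away from
the spacer) or inward (both grow into it) — would violate the mismatch
budget or a bound. This suppresses nested sub-IRs, an ambiguity the
tolerant-palindrome formulation leaves open. At these default bounds random
sequence contains many IRs; the biological reading of an IR call rests on
conservation across promoters (the motif stage) and on planted-truth
comparisons in the tests, not on any single call. IR1/IR2 classification:
an IR whose span (left arm start → right arm end) overlaps the core span
(−35 start → −10 end) by ≥1 base is IR1; disjoint is IR2; without a core
call, unclassified.

Motif discovery is a strand-aware Gibbs site sampler (replacing EM-based
discovery): one site per sequence (OOPS) or at most one (ZOOPS), pseudocount
0.25 per base, both strands scored every sweep. In ZOOPS a no-site option
competes with weight equal to the total window count — a flat-odds prior
under which a background-like motif leaves a sequence out about half the
time. Every 10 sweeps a phase-shift move slides all sites together by up to
±3 columns when that raises the complete-data log-likelihood; without it the
sampler reliably converges one or two columns off register. The best of
`n_restarts` (default 3–5) by information content × site count is returned;
a width sweep (default 12–20) selects the maximal per-column information
content. Whether the original survey ran its discovery in OOPS or ZOOPS mode
is unstated; ZOOPS is the pipeline default (not every promoter need carry
the site), while planted-recovery benchmarks use OOPS because the planted
design has exactly one site per sequence. Motif significance is by
comparison against background-only runs (empirical null), not database
e-values; motif comparison maximises the mean per-column Pearson correlation
of frequency vectors over all offsets and both orientations, with ties
preferring forward orientation and small offsets.

## Family statistics

Per family, hits with coverage > 0.4 (strict, mirroring the ">40 %" filter)
are split into acr-associated versus solo (proximal excluded by default, as
the contrast is binary); protein length and identity-to-reference get means
with 95 % t-distribution confidence intervals (small per-group n makes the
normal approximation inappropriate) and an unpaired Welch t-test
(Welch–Satterthwaite df; the equal-variance flavour was not specified in the
source presentation, and Welch is the safer default). The statistic is
computed from the closed-form formulas with `scipy.stats.t` supplying tail
probabilities; `scipy.stats.ttest_ind` serves only as an independent
cross-check in tests.

Family relatedness uses neighbor joining on d = 1 − pairwise identity —
a documented stand-in for the multiple-alignment + approximate-ML treeing of
the original workflow, preserving the qualitative deliverable (family
grouping) with machinery that is exact on additive matrices. Q-criterion
ties break on the lexicographically smallest pair of subtree labels;
negative branch-length estimates are clamped to zero and flagged. Trees are
written as standard Newick (labels with spaces quoted) and round-trip
through standard readers.

## Pipeline and reproducibility

`analyze()` composes the stages in order (profiles → calibration → scan →
cluster → context → promoters → core/IR → motifs → network → statistics)
and emits a JSON-serialisable report with counts in and out of every filter.
Each stochastic stage derives a sub-seed as the first four bytes of
SHA-256("seed:stage"), so stages are individually reproducible and no two
stages share a stream. Reports contain no timestamps and serialise with
sorted keys; identical seeds give byte-identical reports.

Problem sizes used throughout the tests and the acceptance script — 10
contigs of 30 kb, 5 operons, 5 solo loci, 50 background CDS; 20 noisy-seed
replicates; 50 motif-recovery seeds; 1000 operon layouts; 200 IR oracle
sequences — were chosen as the smallest communities that exercise every
code path with non-trivial negatives, and are the package's stated study
conditions.

## Known limitations

* The i.i.d. background and random-ORF negatives understate the false-hit
  rates expected on real genomes rich in HTH-domain proteins; thresholds
  calibrated here are a methodology demonstration, not transferable cutoffs.
* Ungapped profile scanning cannot model indels within a family; strongly
  indel-divergent homologs would be missed.
* Identity-based NJ is not an ML phylogeny; branch lengths are identity
  distances, not substitution estimates.
* Database-era headline counts (thousands of non-redundant homologs, the
  15 % acr-associated fraction) depend on 2018–2020 database snapshots and
  are out of scope; nothing here attempts to reproduce them.
* Wet-lab validation (reporter assays of promoter repression) is entirely
  out of scope.
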