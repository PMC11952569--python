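# Methods

This note documents the models, statistics and design decisions behind
`kzfpcluster`, in the spirit of a methods supplement: what each component
assumes, which parameters matter, and what the synthetic data do and do not
establish about real assemblies.

## The cluster-expansion model

`simulate.SimulationConfig` describes a single linear genome (default 10 Mb)
containing one gene cluster (default 200 kb). The cluster is seeded with
`n_init_genes` KZFP genes (each carrying an explicit random 3′-exon DNA
sequence and a canonical C2H2 finger-array protein sequence with random
fingerprint residues) interleaved with LINE copies at `init_line_density`
copies/Mb; everything else is neutral sequence. Evolution proceeds in
discrete generations, each applying three steps in order:

1. **Insertion.** Every TE family gains `Poisson(insertion_rate)` new copies
   per generation genome-wide. A new copy lands inside the cluster with
   probability `cluster_bias`, otherwise uniformly in the cluster's
   complement — so the in-cluster probability is exactly `cluster_bias`,
   and setting it to the cluster's genome share yields a uniform null.
   Insertions never interrupt genes (positions inside genes are redrawn);
   they may fragment neutral sequence or existing TE copies, as real nested
   insertions do.
2. **NAHR.** Two TE copies can anchor a non-allelic homologous recombination
   event when they share family and orientation, lie within `max_pair_dist`
   (default 25 kb), and still provide microhomology: divergences within
   `microhomology_tol` (5 points) of each other and each below
   `max_anchor_div` (20 %) — old, decayed copies lose recombinogenic
   potential. Each eligible pair triggers independently with `p_nahr`; at
   most one event is applied per generation (the first triggered pair in
   coordinate order), which keeps intra-generation coordinates consistent
   and caps the event rate. A triggered event duplicates the span from the
   left anchor's start to the right anchor's start in tandem with
   probability `p_dup_given_nahr`, copying every contained gene and TE with
   its *current* divergence and sequences; otherwise the span is deleted and
   the right anchor survives as the hybrid copy.
3. **Mutation.** Every TE copy's percent divergence grows by a
   `Gamma(shape=2, mean=mu)` increment — a stochastic molecular clock that
   produces the genome-wide continuum of divergence against which tie
   groups are judged. Gene 3′-exon and finger-array sequences mutate per
   site with probability `exon_mu` (uniform substitution).

TE copies are annotation objects (family, strand, length, divergence), not
nucleotide sequences; modelling recombination at annotation resolution keeps
a 10 Mb, 3000-generation run under two seconds while preserving exactly the
quantities the analyses consume (coordinates, families, divergences, exon
sequences). An event log records every change; replaying it from the
initial state reproduces the final genome exactly, and the log yields the
length-conservation identity
`final = initial + Σ inserted + Σ duplicated − Σ deleted`.
For very large exploratory runs `log_mutations=False` drops the per-
generation mutation records (they dominate log size) and defers per-copy
divergence write-back to read-out; structural events are always logged.

### Default parameters and why

The defaults are the study conditions for the acceptance experiments; rates
are desk-scale free parameters, not estimates of mouse rates. They were
chosen from four analytic constraints on the tie-group statistic, then fixed:

- *Tie persistence*: twin copies born of one duplication drift apart by
  ≈ `mu·√age` points, which must stay below the tie tolerance ε = 0.2;
  with `mu = 0.005` and 3000 generations, late-run duplications stay tied.
- *Sparse continuum*: the resampling null needs genome-wide divergence gaps
  well above ε, bounding each family to a few dozen copies over the
  ~15-point divergence spread.
- *Outside pool*: the null draws from the family's genome-wide values, so a
  family must keep a substantial population outside the cluster
  (`cluster_bias = 0.15` with a genome 50× the cluster); otherwise
  resampling re-absorbs the locus ties. The 10 Mb genome also confines
  NAHR geometrically to the cluster — outside copies are too sparse to
  pair within 25 kb.
- *Lineage survival*: with near-balanced duplication/deletion, deletion
  extinguishes tie lineages as fast as duplication creates them;
  `p_dup_given_nahr = 0.8` gives the strong net expansion these loci
  actually show, while `p_nahr = 4·10⁻⁴` per pair keeps event counts
  moderate in most runs.

Three LTR families (named after ERV families enriched at the mouse Chr4
cluster) plus one background LINE family are simulated; the ancestral LINE
cohort deliberately reproduces a LINE-rich founding state.

### What the simulator does not model

Nucleotide-level breakpoints, selection and gene dosage effects, diploidy
and meiotic drive, gene conversion, inversion events, and hotspot
determination. Because initial LINE copies are born synchronized (all
divergence 0), the LINE family's locus divergences are trivially tied and
are excluded from tie-group testing; real loci violate this only in the
sense that their founding repeats also share age. Passing tests therefore
demonstrate internal consistency of the statistics and their power against
this model's duplication signature — not calibration against real mouse
rates.

## Fingerprint analysis

Fingers are matched N→C, non-overlapping, smallest spacers first, by
`C-x(2,4)-C-x(12)-H-x(3,5)-H` (the H-x(3/4/5)-H tail covers standard C2H2
spacing variation). The fingerprint is the residue 4-mer at helix positions
−1/+2/+3/+6, i.e. offsets −7/−5/−4/−1 from the first histidine. A finger
missing a zinc-coordinating C or H is a `chz_mutant` ("red"); an intact
scaffold with a mutation at −12 (F/Y), −3 (F) or +4 (L) is a
`structural_mutant` ("yellow"); chz takes precedence, and fingers whose −12
position precedes the sequence start are conservatively treated as
degenerate. Because the strict pattern cannot find C/H-mutant fingers, a
rescue pass scans gaps between or flanking canonical fingers whose size
matches one canonical ~28-residue period (±3) and places a candidate with
the neighbour's internal spacing, classifying it by the same rules.
Repertoires are compared by exact string equality of the `|`-joined
fingerprint array; mutant fingers are included by default (dropping them
would create false cross-assembly matches), with an intact-only mode
available.

## Enrichment and permutation statistics

Enrichment is the bp-density ratio of a family in the locus versus
genome-wide, computed on interval unions per family so fragmented or nested
annotations are not double-counted; it is scale-invariant and undefined
(flagged, not zero) for families absent genome-wide. Permutation tests
re-place intervals uniformly within an allowed space, preserving lengths
(and per-interval sequence assignment in `randomize_query` mode); the
statistic is union-overlap bp when randomizing a single locus and the count
of overlapping query intervals when randomizing a query set. The
+1-corrected empirical p-value avoids zero; the Z-score uses the
permutation null's mean and SD. Family selection uses the midpoint rule for
locus membership (an annotation is "in" the locus when its midpoint is),
requiring strictly more than 2 % of annotations and more than 10
annotations inside.

## Divergence tie groups

Tie groups are single-linkage chains of sorted divergence values with
consecutive gaps ≤ ε, reported at minimum size 3; ε defaults to 0.2
percentage points (±one RepeatMasker reporting step of 0.1 on each side)
and is a package choice, surfaced in all outputs, not a published value.
The test statistic is the tied fraction of locus copies; the null draws the
same number of values without replacement from the family's genome-wide
values — locus copies are genome copies, so this preserves the finite
population — with the +1-corrected p-value. The test is exact under
retrotransposition-only evolution (locus membership independent of age) and
is reported per family; it loses power when a family keeps too few copies
outside the locus, which is why the experiment driver requires a minimal
outside pool before testing a family.

## Gene blocks

Paralog labels come from single-linkage components of pairwise global
3′-exon identity at threshold 0.95 (a tunable package default; the
published analysis colored a clustalO guide tree by eye, which is not
reproducible as a rule). Alignment scoring is match +1 / mismatch −1, gap
open −2 / extend −0.5 (first gap residue costs the open score), end gaps
penalized; identity is matched columns over alignment columns of one
optimal alignment. Blocks are maximal repeated label substrings of length
≥ 3 occurring ≥ 2 times, counting reversed-order occurrences for inverted
duplications, with greedy non-overlapping occurrence selection; a block is
maximal when every one-label extension loses an occurrence, and shorter
blocks nested in longer ones are reported only when they have an occurrence
outside all longer-block occurrences (partial duplications).

## Contig curation and census

Contig filtering reads "largest alignment" as the largest *total* aligned bp
(contigs align in many fragments), assigns each contig to its best
chromosome, drops contigs whose reference footprint is fully contained in a
higher-priority kept contig's footprint (priority by total aligned bp, ties
by name), and flags a flip when most aligned bp are on the minus strand.
The census assigns each (species, unit) pair to exactly one of four
conservation categories by the unit's carrier set, counting units once or
weighting by copy number; the categories partition the totals by
construction.

## Numerical and testing notes

Coordinates are 0-based half-open everywhere internally; GFF and
RepeatMasker conversion happens at file boundaries only. All stochastic
components take explicit seeds; simulations are deterministic given
(config, seed), and replaying the event log is bit-identical to the original
run. Test problem sizes (100-seed conservation runs at 150 generations,
50-seed power runs at the default 3000 generations, 500-replicate
calibration at 200 permutations) were chosen so the full suite completes in
minutes on one CPU while keeping Monte-Carlo error well inside the asserted
bands. Brute-force oracles (exhaustive finger scan, repeated-substring
enumeration, Gotoh dynamic programming, pairwise contig containment,
pairwise tie chaining) are maintained in the test suite as independent
restatements of each definition.
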