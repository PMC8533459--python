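# Methods

This note documents the models and procedures implemented in `chemotri`,
the choices made where the design was genuinely open, and what the
synthetic fixture does and does not establish about real data.

## Data model and conventions

Coordinates are 1-based and inclusive (GFF3 convention) throughout; inputs
that look 0-based (start = 0) are rejected at parse time rather than
shifted.  Gene sequences are stored in transcript orientation
(reverse-complemented for `-` strand genes).  Clusters are exchanged as a
5-column TSV (`genome_id, cluster_id, region_label, core_type, genes`) with
core genes flagged by a leading `*` — a deliberately neutral interchange
format, since no machine-readable cluster format is standard across
annotation tools.  Free-text product labels are matched case-insensitively
against a small closed vocabulary (NR-PKS, R-PKS, CytP450, OMT,
monooxygenase, transporter, FAS-A/B); anything else is treated as
"unidentified", mirroring how most cluster genes are annotated in practice.

## Homology and the shared/specific partition

Cluster orthology is called on core genes with the reciprocal-best-hit
criterion: A and B pair iff each is the other's unique best-scoring match.
Scoring is global Needleman–Wunsch with affine gaps (match +1, mismatch −1,
first gap position −2, each further position −1), computed with
`Bio.Align.PairwiseAligner`; an independent Gotoh dynamic program in the
test suite pins the convention.  Identity is the fraction of identical
columns over all alignment columns.

Choices that were open:

* **Best-hit ties** are broken by higher identity, then lexicographic gene
  id, making the best hit always unique and the matching symmetric under
  swapping genomes.
* **RBH acceptance threshold** defaults to identity ≥ 0.7 — orthologs
  between two conspecific chemotypes are expected far above this, while
  global alignments of unrelated genes sit near 0.5.
* **Seeding.** Pairs whose 8-mer Jaccard distance exceeds 0.9 are treated
  as no-hits and never aligned, exactly as seeded database search tools
  refuse to extend seedless pairs.  True homolog pairs at a few percent
  divergence (distance ≈ 0.5) and even 15 %-diverged paralogs (≈ 0.84) are
  far inside the cutoff; unrelated ~3 kb pairs sit near 0.98.  This keeps a
  ~113-core comparison to seconds without affecting which best hits exist.
* **Global, not local, alignment**: fixture and real core genes enter as
  full-length gene models, so end-to-end alignment is the right objective.

A cluster without an RBH partner is *specific* only when the other
chemotype's raw reads give zero normalised coverage (RPKM) on its core
gene(s); any nonzero cross-coverage flags it *ambiguous* instead, so a
presence/absence claim is always backed by read-level absence evidence.

Synteny between a homologous cluster pair is reported as a TSV of gene
pairs at ≥ 90 % identity over ≥ 50 bp (the conventional plotting
thresholds), after flipping cluster B if the core genes disagree in
orientation.

## PKS classification and group placement

Domain strings are tokenised on both `-` and whitespace (published tables
mix the separators).  Classification: R-PKS iff any reducing domain
(KR/DH/ER); NR-PKS iff none and KS, AT and ACP all present; otherwise
"other".  TD is treated as a reductive release domain, distinct from TE
and not reducing.

Group placement replaces a maximum-likelihood phylogeny with
nearest-labelled-reference assignment under k-mer Jaccard distance
(k = 8 for nucleotide, k = 4 for amino-acid references): the downstream
filter consumes only the group label, not branch lengths.  The default
acceptance radius of 0.6 corresponds to roughly 6–7 % nucleotide divergence
from a reference — queries within a group's radiation land well inside,
unrelated sequences at distance ≈ 1.  A neighbor-joining tree
(`skbio.tree.nj`) over the same distances is written for visual sanity
checking only.  The NJ implementation is checked against additive matrices
from known trees.

## Candidate filter

The four hard criteria — shared between chemotypes, NR-PKS present,
CytP450 in the cluster, two ACP domains in the PKS — decide pass/fail.
Everything else that argues against a cluster is recorded as
*negative evidence*, not as an extra criterion: a cMT domain
(azaphilone/ß-orcinol-type chemistry), a missing TE, an in-cluster OMT
(not needed for olivetoric/physodic acid), a divergently transcribed R-PKS
neighbour (shared regulation with a different pathway), and group ∉ {I}.
This keeps the printed rule set authoritative while preserving the
per-cluster exclusion narrative.  The CytP450 criterion is evaluated
identically in both genomes: the candidate carries its CytP450 in both
chemotypes even though only the depsidone producer needs it.

The atranorin rule is separate: a shared cluster whose PKS carries
SAT-KS-AT-PT-ACP-cMT, placed in group IX, with CytP450 + OMT + transporter
in the cluster.  TE is treated as optional in this rule — the canonical
atranorin PKS architecture ends in TE, but domain callers may miss it and
the published architecture for this cluster omits it.  More than one match
is an error, not a choice.

The FAS detector takes known HexA/HexB homolog sequences as queries, finds
each query's best gene hit, and reports a locus only when the two hits are
adjacent (no intervening gene, intergenic gap ≤ 5000 bp — the orientation
is published but no distance, and fungal divergent promoters operate well
under this span) and divergently transcribed (`-` gene before `+` gene in
ascending coordinates).

## Expression

RPKM = raw / (library/10⁶) / (length/10³), with *library size = total reads
in the sample*, not total mapped reads.  Library sizes are not published;
they are recovered by least squares on the RPKM identity
(`L = Σx_i² / Σx_i·rpkm_i`, `x_i = raw_i·10⁹/length_i`), which reduces to
exact inversion for a single row.  One library size (~34.6 M reads)
reproduces all eight nonzero physodic RPKM values within ±0.02.  The
olivetoric column is internally inconsistent under any single library size
(different rows imply sizes ~40 % apart), so olivetoric values are used
only for rank order, never as numeric targets.

Read counting is exact-seed (31-mer) candidate lookup plus edit-distance
verification (edlib, both strands), appropriate for the error-free
simulated libraries quantified here: a read counts for the gene with its
unique best placement at ≥ 95 % identity; tied best placements are
discarded; everything else counts only toward the library size, so
`Σcounts + background + discarded = library_size` exactly.

Transcriptional activity: genes are ranked by RPKM (ties by id); the
"active" flag marks genes at ≥ 10× the within-cluster median RPKM — no
numeric activity rule is published, so the flag is a convention and every
cross-chemotype claim in the tests uses the threshold-free rank order
instead.

## Biosynthesis scheme

The model is combinatorial and structural only.  A ring is
(starter ∈ {2,4,6,8} carbons, extensions ∈ {3,4}); its side chain has
`starter + 2·(extensions−3) − 1` carbons — the formula is asserted rather
than published, but it is the unique linear rule consistent with the
C1/C3/C5/C7 enumeration, with "four extensions give a ß-keto side chain
two carbons longer", and with hexanoyl starters giving C5 (3 ext) and C7
(4 ext).  A depside is two rings plus the fixed A-carboxyl→B-4′-OH ester;
depsidonisation adds the A-C2-OH→B-5′-C ether and is idempotent-checked
(applying it twice is an error).  Starter sourcing encodes the host
dependence: C2 starters are the PKS default; longer starters require a
dedicated HexA/HexB metabolite FAS delivering acyl-ACP directly, so in a
FAS-less host those rings are flagged unreachable (the mechanism behind an
olivetoric-acid PKS yielding lecanoric acid in yeast).  No stereochemistry,
masses or kinetics — anything further would be invention.

## The synthetic fixture

The generator plants the complete published structure: 51 shared clusters
(8 NR-PKS with the published domain strings, companion genes and
phylogenetic groups; 14 R-PKS; 1 type-III PKS; 7 hybrid; 14 NRPS/NRPS-like;
5 terpene; 2 indole), five physodic-only clusters (R-PKS ×3, hybrid,
terpene) and one olivetoric-only terpene cluster, the ten-gene candidate
cluster at the published gene lengths, a divergent HexA/HexB pair
(5619/6285 bp, 800 bp apart — orientation is published, the distance is a
choice) and labelled group references.  Homologous genes differ by
substitution-only divergence (default 3 %), which keeps identity arithmetic
exact (mean pair identity ≈ 1 − d); an indel-rate hook exists but defaults
to 0.  NR-PKS cores are drawn at 2 % divergence from their group reference
so that even the second-genome copies (~5 % from the reference) place
firmly inside the 0.6 group radius.  Every tenth shared cluster in genome A
additionally carries a 15 %-diverged paralog of its core gene, registered
as an extra core, so reciprocal-best-hit matching actually has paralogy to
defeat.

Transcriptome counts are the published values divided by 1000 (RPKM is
scale-invariant, so normalised values are unchanged), with library sizes
calibrated from the published RPKM rows and scaled identically; reads are
error-free 150-mers drawn uniformly from gene bodies with random strand,
plus background reads from gene-free sequence.  The full published counts
are exercised through the count-table entry point, not read simulation.

What the fixture does **not** emulate: sequencing error, quality variation,
paired ends, splicing, indel divergence, assembly artefacts, contamination,
or genes split across contigs.  Passing on the fixture therefore
demonstrates the correctness of the comparative logic under the stated
model of divergence, not robustness to real-world read noise or annotation
error.

## Problem sizes and determinism

The default fixture compares 56 + 52 clusters (61 + 52 core genes after
decoys) with ~3 kb cores and simulates ~35 k + ~33 k reads; a full pipeline
run completes in well under a minute on one CPU.  All randomness flows from
a single integer seed through `numpy.random.default_rng`; identical seeds
produce byte-identical fixture files and pipeline outputs (logs excepted).

## Known limitations

* Group placement is nearest-reference assignment, not phylogenetics: it
  needs at least one reference per group and degrades gracefully to
  "unknown", but cannot discover new groups.
* Cross-genome absence evidence uses the same exact-seed counter as
  quantification, so it shares its blindness to highly diverged or
  rearranged homologs (anything < 95 % read identity counts as absent).
* The cluster-number bookkeeping in published summary tables is not fully
  self-consistent (e.g. per-genome NR-PKS tallies vs the eight shared
  NR-PKS clusters); the fixture follows the per-cluster catalog and the
  eight-cluster count.
* Library-size calibration assumes the printed RPKM values were computed
  from one library size per sample; where they were not (the olivetoric
  column), only rank statements are made.
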