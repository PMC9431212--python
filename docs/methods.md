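# Methods

This note documents the models, parameters, and design decisions behind
hydromine, and what the synthetic benchmark does and does not establish.

## Classification model

Hydrogenase function tracks the phylogeny of the catalytic subunit, so
class assignment is homology transfer from a class-labeled reference
catalog (HydDB-style: [NiFe] groups 1–4 and [FeFe] groups A–C with
subgroups).  Reference sequences follow the source-database convention:
full large subunits for [NiFe], H-domain only for [FeFe].  The default
reference header dialect is `id|metal|class` (e.g.
`WP_010890826.1|FeFe|A4`); `load_reference` accepts a custom header
parser for other dialects.

### Alignment engine

Internal search is Smith–Waterman over BLOSUM62 with gap open 11 /
extend 1 (Biopython's `PairwiseAligner`), i.e. the default scoring of
protein–protein BLAST, so identities are commensurate with ingested
BLAST tabular files.  Expect values use the Karlin–Altschul formula
`E = K·m·n·exp(−λS)` with the standard gapped constants K = 0.041,
λ = 0.267; `m` is the query length and `n` the total residue count of
the catalog.  The engine reports hits down to E ≤ 10.  Percent identity
is identities / alignment-length × 100, gap columns included.  For
large-scale or coordinate-level work, run `blastp -outfmt 6` externally
and ingest the table; downstream behavior is identical by construction.

`pairwise_identity` orders each pair canonically before aligning, so the
function is exactly symmetric even when co-optimal tracebacks differ.

### Class-specific identity thresholds

A hit is retained iff E ≤ 0.01 (inclusive) and its identity is strictly
greater than the minimum of the within-class pairwise-identity
distribution of the subject's class.  Rationale: classes differ widely
in internal diversity, so one global cutoff would be simultaneously too
permissive for tight classes and too strict for diverse ones.  All
within-class pairs are enumerated when a class has at most
`max_pairs_per_class` (default 5,000) pairs; larger classes use a
seeded uniform subsample, and the threshold table's provenance records
`full` vs `sampled` because the minimum is guaranteed only under full
enumeration.  Classes with a single entry fall back to a conservative
twilight-zone floor of 25% identity (configurable).

The same alignment engine and identity definition are used for the
threshold distributions and for query hits, keeping the two sides of
the comparison consistent.

### Sorting and voting

Hits are sorted best-first with the priority identity ↓, E-value ↑,
query length ↓, subject id ↑ (the last key only for determinism).
E-value ascending is the only reading under which "best first" is
coherent — a literal descending sort on E would rank the worst
alignments first.

The vote takes the top `k = 4` retained hits (fewer when thresholding
leaves fewer).  "Majority" is implemented as strict plurality: a label
wins only if its count strictly exceeds every other label's, so [2,1,1]
is a win and [2,2] or [1,1,1,1] falls back to the top hit's class with
`tie_broken = true`.  Voting granularity follows the hits: subgroup
labels are used when every voted hit carries one, otherwise the vote is
taken at group level; both levels appear in reports.  Votes spanning
metal types are legal but flagged (`mixed_metal_types`).

## Signature engine

Signatures use the PROSITE-style dialect of the hydrogenase literature:
dash-separated elements, `x` wildcard, `h` hydrophobic class,
`[A/B]` alternatives, `(n)` and `(n–m)` repeats.  The scanner reports
*every* distinct (start, end) occurrence — variable gaps enumerate all
admissible widths, overlaps and nestings included — because validators
consume presence per slot, and partial reporting could hide a valid
placement.  An `X` in the scanned sequence matches no element, the
wildcard included: unknown residues must not certify a metal-binding
site.  The hydrophobic class defaults to {A, V, L, I, M, F, W, Y}
(configurable in the catalog file).

Terminal-region constraints are qualitative in the literature, so they
are made operational with windows: N-terminal patterns scan the first
60 residues by default (signal peptides and P-loops sit near the
start; the HydF GTPase elements use wider per-pattern windows of
120–200), C-terminal patterns the last max(80, 40% of length) residues.
All windows are per-pattern configurable; matches are reported in
full-sequence coordinates.

The H-cluster P1/P2/P3 and [NiFe] L1/L2 strings ship as editable
consensus entries in `data/motif_catalog.yaml` rather than as code:
published motif catalogs differ in granularity, and validators reference
roles, not pattern strings, so alternative catalogs drop in without code
changes.  The synthetic generator plants whatever strings the active
catalog holds, which keeps the benchmark self-consistent under catalog
edits.

## Validation rules

- **[FeFe]**: `all_three` mode (default) requires ≥1 match in each of
  P1, P2, P3 — chosen because a catalytic subunit carrying only two of
  the three cannot coordinate a complete H cluster; `any_one` mode is
  retained for sensitivity analyses.
- **[NiFe]**: both Ni-ligating slots (L1 ∧ L2) on the large subunit, plus
  a neighborhood small subunit that is both annotated as such (keyword
  match against the local domain-annotation table; defaults include
  "small subunit" and IPR027394-like labels) and carries ≥1 small-subunit
  Fe–S ligand motif.  The conjunction mirrors the two-check design:
  annotation first, motif confirmation second.
- **Neighborhood**: ±5 genes on the same contig (configurable), wide
  enough to cover the largest template (the six-subunit Hyt cluster).
  Offsets are signed gene counts; contig edges truncate without error.
- **Templates**: 1a = large + small + optional cytochrome; B = monomeric;
  A3 = catalytic + diaphorase + thioredoxin-like; A4 = catalytic HytA +
  diaphorase HytB + four Fe–S subunits.  Role assignment is greedy
  nearest-first keyword matching, each neighbor filling at most one
  role; it is invariant to reversing contig orientation.  Missing roles
  (required or optional) produce warnings and downgrade a validated call
  to `validated_with_warnings` — they never reject, because subunit
  composition varies within classes and annotation tables are
  incomplete in real data.

## Diaphorase cofactor hypothesis

NuoF-like diaphorase subunits are profiled for two loops.  The
N-terminal Gly-rich loop types the subunit (A4-form `R-G-G-A-G-F-P` vs
A3-form `R-G-G-G-G-F-P`).  The first loop of the Rossmann fold sets the
cofactor hypothesis: Gly form `G-D-E-G-D-P-G` → NADP-associated, Ala
form `A-D-E-G-D-P-G` → NAD-associated, neither → undetermined.  The
hypothesis follows the Rossmann loop alone — deliberately, so that an
A3-type subunit carrying the Gly form (the known exception pattern in
some trimeric complexes) reads NADP-associated.  This is a sequence-level
hypothesis only; no structural modeling is attempted.

## Maturation survey

Detection is homology-first: every reported hit (E ≤ 10) of every query
maturase is inspected against the family profile, with no E-value gate
by default — the signatures decide, and an early gate could drop a
divergent but signature-complete homolog.  Verdicts: `detected` (all
required slots canonical), `candidate_atypical` (required slot satisfied
only by a configured atypical variant, e.g. the `C-x(4)-C-x(23-25)-C`
HydG-like triads), `absent`.  Paralogs at the best tier are all
reported, never collapsed.  HydG additionally carries a length range of
350–550 residues around the ~450-aa family norm.  The HypA–F profiles
are homology-only (their individual signatures are not modelled here),
so they carry explicit homology gates instead — identity ≥ 50% and
E ≤ 0.01 — because short spurious local alignments routinely reach high
column identity between unrelated proteins; HypB's optional P-loop slot
raises a GTPase flag when it matches.  Machinery completeness requires
every member `detected`; an atypical candidate does not complete a
machinery.

## Synthetic benchmark

The generator emulates the statistical structure the pipeline assumes,
fully determined by one seed (byte-identical files across runs):

- **Reference catalog**: per class, a motif-free random ancestor
  (default 300–320 aa) and 5 copies mutated at substitution rate 0.12 —
  diverse enough that class thresholds sit well below the identity of
  planted query subunits.  Separability is verified post hoc with the
  pipeline's own engine: minimum within-class identity must exceed the
  maximum *significant* between-class identity (alignments at E > 0.01
  in the catalog-sized search space count as 0) by ≥10 points, with
  bounded redraws.  Significance matters here because unrelated random
  proteins routinely share short local alignments of high column
  identity and negligible score, which never compete in hit selection.
- **Genomes**: planted catalytic subunits are in-class reference copies
  mutated at rate 0.03 with the required motifs spliced in (H-cluster
  motifs mid-sequence, terminal motifs inside their windows); neighbors
  follow the class templates with matching annotation labels; A4
  diaphorases carry the Gly loops, A3 the Ala loops unless configured as
  the exception; maturases are mutated family ancestors with profile
  motifs spliced in, rejection-sampled so a construction cannot silently
  change verdict tier (an atypical HydG must not also contain a
  canonical triad — stray Cys from wildcard draws could otherwise
  complete one); decoys are rejection-sampled to match no catalog
  pattern anywhere.  Gene coordinates are non-overlapping, 1-based,
  with 60-nt intergenic spacing, on both strands.
- **Default panel**: eight genomes, each with the minimal repertoire
  (1a pair, B singleton, A3 trio, A4 hexamer) plus one H-cluster-ablated
  A3 operon and one small-subunit-ablated 1a pair as planted negatives
  and four decoys.  Cytochrome presence, HydG status (intact vs atypical
  variant), HypA/HypB presence, and the A3 Gly-loop exception vary
  across genomes so that complete/incomplete machinery patterns and
  both cofactor labels are all exercised.  Twin-arginine signals are not
  planted by default, emulating their absence from acetogen uptake
  hydrogenases.

What passing on this benchmark shows: correctness of the decision rules,
thresholds, boundary semantics, coordinate arithmetic, and end-to-end
plumbing under the generator's assumptions.  What it does not show:
performance on real proteomes — the generator has no phylogenetic
autocorrelation, no domain architecture beyond the planted motifs, no
annotation noise, and class separability is enforced rather than
empirical.  Real-data runs should ingest real BLAST output and a real
HydDB export.

## Numerical and degenerate-input choices

- E-boundary inclusive (E = 0.01 retained), identity boundary strict
  (identity = threshold rejected).
- Zero-score local alignments return identity 0.0 (no-alignment
  sentinel); empty sequences are domain errors.
- Ties everywhere are broken deterministically (subject id, nearest
  neighbor first with upstream before downstream, first qualifying
  locus).
- Floats in intermediate TSVs are written in shortest round-trip form so
  staged (subcommand-chained) runs reproduce monolithic runs exactly.
- Problem sizes in the shipped tests and acceptance script (8 genomes ×
  ~30 genes, 4 reference classes × 5 entries) were chosen as the
  smallest panel that exercises every decision path of the method.

## Known limitations

- The internal search engine has no heuristic seeding; it is meant for
  desk-scale catalogs, with BLAST tabular ingestion as the path for
  real-scale searches.
- Karlin–Altschul constants are fixed at the standard gapped BLOSUM62
  values rather than estimated per search space.
- Profile HMMs and PROSITE weight-matrix profiles are out of scope; the
  signature engine handles exact pattern classes only.
- HypA–F detection is homology-gated only and will miss highly divergent
  homologs; supplying curated per-protein signatures via the profile
  YAML tightens it without code changes.
- Subunit role assignment uses annotation keywords, not sequence
  features, so it inherits the quality of the annotation table.
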