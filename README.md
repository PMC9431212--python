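# hydromine

Genome mining of **[NiFe]- and [FeFe]-hydrogenases** — the metalloenzymes
that interconvert H₂ with protons and electrons — in bacterial proteomes,
with functional classification, signature-based validation, gene-neighborhood
complex reconstruction, maturation-machinery surveys, and diaphorase
cofactor-loop profiling.  The package was built with anaerobic,
gas-fermenting acetogens (genus *Clostridium*) in mind, where hydrogenase
repertoires govern H₂ uptake, electron bifurcation, and formate-coupled
H₂ metabolism, but it applies to any proteome + gene-coordinate input.

## The method

Given a query proteome and a class-labeled catalog of hydrogenase
catalytic-subunit sequences (HydDB-style labels: [NiFe] groups 1–4,
[FeFe] groups A–C, with subgroups such as 1a, A3, A4), the pipeline runs:

1. **Alignment.** Each protein is locally aligned against every catalog
   entry (Smith–Waterman, BLOSUM62, gap open 11 / extend 1; Karlin–Altschul
   E-values).  Precomputed BLAST tabular output (outfmt 6/7) can be
   ingested instead, with identical downstream behavior.
2. **Hit selection.** Hits are sorted best-first (identity ↓, E-value ↑,
   query length ↓) and retained iff **E ≤ 0.01** and percent identity is
   **strictly greater** than a *class-specific* threshold: the minimum of
   the within-class pairwise-identity distribution of the subject's class,
   computed from the catalog itself.
3. **Class assignment.** The class shared by the strict plurality of the
   top four retained hits is assigned; ties (e.g. 2–2) resolve to the
   class of the top hit.
4. **Validation.**
   - An [FeFe] candidate validates iff its sequence carries the H-cluster
     metal-binding motifs **P1 ∧ P2 ∧ P3** (a candidate with only two of
     three is rejected).
   - A [NiFe] candidate additionally needs a *small subunit* in its gene
     neighborhood: a flanking gene annotated as such **and** carrying a
     small-subunit Fe–S ligand motif.  Twin-arginine export signals
     (`R-R-x-F-x-K`) are checked on small subunits and reported.
   - Flanking genes are matched to the class subunit template (e.g. the
     hexameric HytABCDE₁E₂ complex for group A4); missing accessory
     subunits downgrade to `validated_with_warnings`, never reject.
5. **Diaphorase profiling.** NuoF-like diaphorase subunits of bifurcating
   A3/A4 complexes are scanned for the N-terminal Gly-rich loop
   (`R-G-G-A-G-F-P` = A4-type, `R-G-G-G-G-F-P` = A3-type) and the Rossmann
   first loop, whose form tracks cofactor specificity:
   `G-D-E-G-D-P-G` → NADP-associated, `A-D-E-G-D-P-G` → NAD-associated.
6. **Maturation survey.** Known maturases are aligned against the
   proteome and every hit is inspected for the family signatures —
   radical-SAM Cys triads and C-terminal Fe–S ligands for HydE/HydG,
   the GTPase elements (`G-x(4)-G-K-[S/T]`, `h(4)-D-x(2)-G`, `[N/T]-K-x-D`)
   plus `C-x-H-x(46-53)-C-x(2)-C` for HydF — yielding per-genome verdicts
   (`detected` / `candidate_atypical` / `absent`) and machinery
   completeness for the [FeFe] (HydE,F,G) and [NiFe] (HypA–F) systems.

All signatures are PROSITE-style patterns (wildcards, alternatives,
variable-length gaps) scanned by an exact, exhaustively tested internal
engine; the motif catalog is an editable YAML file.

A seeded synthetic-data module generates reference catalogs with
controlled within/between-class identity, genomes with planted operons,
maturases, motif-ablated constructs and motif-free decoys, plus a truth
table — so the whole pipeline is testable offline.

## Worked example

```bash
hydromine synth --seed 42 --genomes 2 -o demo   # synthetic panel + run.yaml
cd demo && hydromine run -c run.yaml
```

prints

```
identified 12 candidates, validated 8 (reports in results)
```

Each genome plants six hydrogenase operons: four intact (a [NiFe] 1a
large+small pair, a monomeric [FeFe] B enzyme, a trimeric bifurcating A3
complex, a hexameric A4 complex) and two motif-ablated negatives — hence
6 identified and 4 validated per genome.  `results/validated.tsv` begins

```
genome_id  class            catalytic_locus  status                   small_subunit  subunit_roles                                            warnings
SYN01      [NiFe] Group 1a  SYN01_RS00010    validated_with_warnings  SYN01_RS00015  large_subunit=SYN01_RS00010;small_subunit=SYN01_RS00015  optional subunit role 'cytochrome' not found in neighborhood
SYN01      [FeFe] Group B   SYN01_RS00025    validated                               catalytic=SYN01_RS00025
SYN01      [FeFe] Group A3  SYN01_RS00035    validated                               catalytic=SYN01_RS00035;diaphorase=SYN01_RS00040;thioredoxin=SYN01_RS00045
```

— the uptake hydrogenase validates *with warnings* because this genome
lacks the optional cytochrome neighbor, while the bifurcating complexes
resolve all their template roles.  `results/diaphorase.tsv` labels their
cofactor-binding subunits:

```
genome_id  catalytic_locus  diaphorase_locus  nterm_loop  rossmann_loop  cofactor_hypothesis
SYN01      SYN01_RS00035    SYN01_RS00040     A3-type     A-type         NAD-associated
SYN01      SYN01_RS00070    SYN01_RS00060     A4-type     G-type         NADP-associated
```

and `results/summary.json` records the per-genome funnel and machinery
status (SYN01 is complete for the [FeFe] maturases but missing
HypA/HypB, so its [NiFe] machinery is incomplete).

Every stage is also available as its own subcommand (`thresholds`,
`search`, `classify`, `validate`, `maturation`) with file-in/file-out
semantics; `--hits blast.tsv` substitutes external BLAST output for the
internal search engine.

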