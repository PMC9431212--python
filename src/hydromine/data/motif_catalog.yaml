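# Bundled signature catalog for hydrogenase mining.
#
# Pattern dialect: dash-separated elements; x = any residue, h = the
# hydrophobic class below, [A/B] = alternatives, (n) / (n-m) = repeats.
# region: any | N-terminal | C-terminal; window: residues (omit for the
# built-in defaults: 60 for N-terminal, max(80, 40% of length) for
# C-terminal).
#
# The H-cluster P1/P2/P3 and [NiFe] L1/L2 entries are consensus strings
# assembled from the hydrogenase motif literature; they are deliberately
# kept in this editable file rather than in code, since published motif
# catalogs differ in granularity.  Validators reference roles, not
# pattern names, so alternative strings can be dropped in freely.

hydrophobic: AVLIMFWY

patterns:
  # ---- [FeFe] H-cluster metal-binding motifs (catalytic H-domain) ----
  - name: fefe_p1
    pattern: T-S-C-C-P-x-W
    role: h_cluster_p1
    source: H-cluster P1 consensus (editable)
  - name: fefe_p2
    pattern: M-P-C-x-x-K-x-x-E
    role: h_cluster_p2
    source: H-cluster P2 consensus (editable)
  - name: fefe_p3
    pattern: E-x-M-A-C-x-x-G-C-x-G-G
    role: h_cluster_p3
    source: H-cluster P3 consensus (editable)

  # ---- [NiFe] large-subunit Ni-ligating motifs ----
  - name: nife_l1
    pattern: R-x-C-G-x-C-x-x-x-H
    role: nife_l1
    source: L1 consensus (editable)
  - name: nife_l2
    pattern: D-P-C-x-x-C-x-x-H
    role: nife_l2
    source: L2 consensus (editable)

  # ---- [NiFe] small-subunit Fe-S cluster ligands ----
  - name: nife_small_fes
    pattern: C-x-x-C-x-x-x-C
    role: nife_small_fes
    source: small-subunit Fe-S ligand consensus (editable)

  # ---- Twin-arginine (Tat) export signal of uptake-hydrogenase small subunits ----
  - name: tat_signal
    pattern: R-R-x-F-x-K
    role: tat
    region: N-terminal
    window: 60
    source: twin-arginine signal peptide

  # ---- Radical SAM core (HydE / HydG) ----
  - name: radical_sam_cx3
    pattern: C-x(3)-C-x(2)-C
    role: radical_sam
    source: radical SAM CxxxCxxC signature
  - name: radical_sam_cx2
    pattern: C-x(2)-C-x(4)-C
    role: radical_sam
    source: radical SAM CxxCxxxxC signature

  # ---- HydE C-terminal Fe-S cluster (dispensable) ----
  - name: hyde_cterm
    pattern: C-x(7)-C-x(2)-C
    role: hyde_cterm
    region: C-terminal
    source: HydE C-terminal triad

  # ---- HydG C-terminal Fe-S cluster (essential); canonical + accepted forms ----
  - name: hydg_cterm_canonical
    pattern: C-x(2)-C-x(22)-C
    role: hydg_cterm
    region: C-terminal
    source: HydG C-terminal triad, canonical
  - name: hydg_cterm_cx5
    pattern: C-x(5)-C-x(19)-C
    role: hydg_cterm
    region: C-terminal
    source: HydG C-terminal triad, accepted variant

  # ---- HydG-like atypical C-terminal Cys patterns (candidate tier) ----
  - name: hydg_cterm_atypical_2325
    pattern: C-x(4)-C-x(23-25)-C
    role: hydg_cterm_variant
    region: C-terminal
    source: atypical HydG-like Cys pattern
  - name: hydg_cterm_atypical_2324
    pattern: C-x(4)-C-x(23-24)-C
    role: hydg_cterm_variant
    region: C-terminal
    source: atypical HydG-like Cys pattern

  # ---- HydF GTPase / Fe-S signatures ----
  - name: hydf_ploop
    pattern: G-x(4)-G-K-[S/T]
    role: hydf_ploop
    region: N-terminal
    window: 120
    source: Walker A P-loop (alpha/beta phosphate binding)
  - name: hydf_switch
    pattern: h(4)-D-x(2)-G
    role: hydf_switch
    region: N-terminal
    window: 160
    source: Walker B-like gamma-phosphate/Mg2+ element
  - name: hydf_nkxd
    pattern: "[N/T]-K-x-D"
    role: hydf_nkxd
    region: N-terminal
    window: 200
    source: nucleotide-specificity element
  - name: hydf_cterm
    pattern: C-x-H-x(46-53)-C-x(2)-C
    role: hydf_cterm
    region: C-terminal
    source: HydF C-terminal [4Fe-4S] ligand set

  # ---- HypB P-loop (GTPase evidence flag) ----
  - name: hypb_ploop
    pattern: G-x(4)-G-K-[S/T]
    role: hypb_ploop
    region: N-terminal
    window: 120
    source: Walker A P-loop

  # ---- Diaphorase (NuoF-like) N-terminal Gly-rich loops ----
  - name: diaphorase_nterm_a4
    pattern: R-G-G-A-G-F-P
    role: diaphorase_nterm_a4
    source: NuoF-like N-terminal loop, A4 form
  - name: diaphorase_nterm_a3
    pattern: R-G-G-G-G-F-P
    role: diaphorase_nterm_a3
    source: NuoF-like N-terminal loop, A3 form

  # ---- Rossmann-fold first-loop variants (cofactor-specificity proxy) ----
  - name: rossmann_loop_g
    pattern: G-D-E-G-D-P-G
    role: rossmann_loop_g
    source: Gly-form Rossmann first loop (NADP-associated)
  - name: rossmann_loop_a
    pattern: A-D-E-G-D-P-G
    role: rossmann_loop_a
    source: Ala-form Rossmann first loop (NAD-associated)
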