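# Methods

## The barrier surrogate

The package models the effect of an electrostatic perturbation on a
reaction barrier with a fixed-charge, frozen-geometry Coulomb surrogate.
Two structures of the same system — the reactant and the transition state
of the rate-limiting step — are partitioned into a QM region (the reacting
atoms, whose partial charges differ between the two states and encode the
reaction's charge flow) and a point-charge environment. The environment's
contribution to the barrier is taken to be

    E_int(state) = k_C Σ_i Σ_j q_i(state) q_j / r_ij ,
    ΔE‡ = E_int(TS1) − E_int(REACT),   ΔΔE‡ = ΔE‡(mut) − ΔE‡(wt),

with i over QM atoms, j over environment charges, k_C = 332.0637
kcal·Å·mol⁻¹·e⁻², vacuum dielectric (ε = 1) and no cutoffs — the sums are
exact at the system sizes involved. This is the electrostatic-embedding
term of a QM/MM single point; what it deliberately omits is the QM
density's polarization response to the perturbation, van-der-Waals terms,
geometry relaxation, entropy and solvation. Users who need true QM/MM
numbers can export every mutant with `write_qmmm_manifest` (a mutant PDB
plus an `x y z q` charge table per state, probe included) and run them
externally; the surrogate exists to *rank* perturbations by the physics the
scan is interrogating — differential stabilization of the
transition-state macrodipole — while remaining analytically testable.

Because geometries are frozen and (by default) environment charges are
state-independent, only the QM charge *shift* Δq couples to a perturbation.
ΔΔE‡ is therefore assembled term-by-term from the touched charges only
(removed side chains, re-charged atoms, added caps, the probe): the
wild-type sums cancel structurally rather than numerically, which makes a
null perturbation exactly zero, probe responses exactly linear and
antisymmetric in the probe charge, and the scan cost per residue
proportional to the residue, not the system.

With `include_env_env=True` the environment-internal terms touched by an
edit are added per state. They cancel from ΔΔE‡ whenever both states share
one environment charge set, which is the default setup; the option matters
only when the user supplies distinct per-state environment charges.

## The scan protocol

* **Shell**: every residue with at least one atom within 10 Å (default) of
  the active-site selection in the reactant geometry, excluding Gly, Ala
  and Pro (no side chain beyond Cβ to truncate, or a backbone-coupled
  ring), residues contributing atoms to the QM region, waters and ions.
* **Alanine truncation**: atoms beyond Cβ are deleted at fixed geometry.
  The default `ZERO_SIDECHAIN` mode simply drops their charges, so the
  net-charge change equals minus the summed side-chain charge exactly and
  no parameter tables are needed; `ALA_LIBRARY` instead re-charges the
  retained backbone + Cβ from a standard alanine library and caps Cβ with a
  third hydrogen placed 1.09 Å along the former Cβ→Cγ direction (no
  minimization — the method is frozen-geometry by construction).
* **Probe**: a bare ±1.0 e point charge (no size, no vdW) at the unweighted
  geometric center of the *wild-type* side chain's heavy atoms, computed on
  the reactant geometry and reused identically in the transition state.
  The geometric center stands in for the center of mass because side chains
  are almost entirely C/N/O. Reading "the mutated side chain's center" as
  the wild-type side chain is a deliberate choice; the alternative (the
  alanine stub's center) is reachable through `PROBE_ONLY` plus a custom
  position.
* **Distances**: each residue is reduced to the mass-weighted center of its
  charged group (carboxyl for Asp/Glu, Nζ for Lys, guanidinium
  Cζ/Nη1/Nη2/Nε for Arg) or of all side-chain heavy atoms otherwise,
  measured on the reactant geometry (configurable to TS1). The signed
  asymmetry delta_d = d(O_p) − d(S_DBT) is the organizing coordinate; its
  zero is the exact sign change of the probe response.
* **Ranking**: ascending in ΔΔE‡ per scan mode (most barrier-lowering
  first), ties broken by (chain, residue number); residues whose largest
  |ΔΔE‡| exceeds 1.0 kcal·mol⁻¹ (default) are labeled. Bulkiness in the
  plots is the side-chain heavy-atom count — reproducible and monotone with
  volume.

## Rate ↔ barrier conversion

ΔG‡ = R·T·ln(k_B·T/(h·k)) with transmission coefficient 1, R = 1.98720×10⁻³
kcal·mol⁻¹·K⁻¹ and k_B/h = 2.08366×10¹⁰ s⁻¹·K⁻¹. The default temperature is
310 K, the physiological value consistent with pairing a turnover of
1.6 min⁻¹ with a 20.4 kcal·mol⁻¹ barrier; it is configurable everywhere.

## Conservation grading

ConSurf-style 1–9 grades are computed without tree inference: per mapped
query column, sequences are weighted by the Henikoff position-based scheme
(gaps treated as a symbol class, so duplicated sequences share weight), the
weighted residue distribution (gaps excluded) is compared to a background —
the BLOSUM62 marginal amino-acid frequencies — by base-2 Jensen–Shannon
divergence, and scores are binned into nine equal-population grades with
9 = most conserved. Bin edges are score quantiles with a `score ≥ edge`
rule, so tied scores always share a grade; an alignment of identical
sequences grades 9 everywhere rather than being spread by rank. True
ConSurf grade exports are accepted as an alternative input (`parse_consurf`
keeps grade ranges such as 8–9 as min/max). The variability list reports
residues observed at the position at weighted frequency ≥ 0.02 (a chosen
floor; ConSurf states none), excluding the query's own residue.

Candidate filtering mirrors the scan logic. Alanine-scan hits (ΔΔE‡ <
−threshold) get non-charged replacements, preferring the position's
variability list and falling back to BLOSUM62 score ≥ 0; probe hits get
charged replacements of the probe's sign, flagged `risky` unless homologues
actually show such a residue there. Gly/Pro insertions and QM/catalytic
positions are never proposed.

## The synthetic fixtures

`make_toy_pair` builds an analytically solvable system: a five-atom QM core
in which an O_p-like oxygen gains Δq = 0.5 e of electron density (charge
−Δq) and an S-like sulfur loses it, 4.6 Å apart, with identical REACT/TS1
geometry. Residues are built from an idealized template library (zig-zag
heavy-atom side chains, fixture charges summing exactly to each residue's
formal charge) and placed with their reference point at *exactly*
prescribed distances to the two sites — the placement locus is a circle
around the inter-site axis, so distances are exact by construction and an
all-carbon side chain's probe site lands exactly at the prescribed point.
Every toy ships with an answer sheet of ΔΔE‡ values computed by a naive
O(N²) double loop written independently of the vectorized energetics code;
the two code paths agree to better than 1e-9 kcal·mol⁻¹ and the hand-value
k_C·(−0.5/3 + 0.5/5) = −22.1376 kcal·mol⁻¹ for a +1 e probe at 3 Å/5 Å is
reproduced exactly.

`make_dszc_like_case` assembles an end-to-end bundle of ~29 shell residues
mixing all four chemical classes: acidic residues planted near the
electron-gaining site (strong negative alanine-scan ΔΔE‡), apolar residues
planted near each site (strong probe response of one sign, exactly zero
alanine response), residues placed exactly equidistant (null in every
mode), plus polar/apolar fillers, and a 30-sequence alignment whose query
mirrors the structure and whose acidic positions vary into non-charged
alternatives. The generator verifies the planted margins against the
oracle before returning. What the fixtures do *not* emulate: realistic
stereochemistry, hydrogens, conformational diversity, charge transfer
beyond two sites, or alignment phylogeny — so passing tests demonstrate the
machinery and its exact laws, not predictive accuracy on real enzymes,
whose per-residue effects are an order of magnitude smaller and buried in
DFT-level physics the surrogate omits.

## Numerical choices and degenerate inputs

* Coulomb guard: any charge pair closer than 0.05 Å raises (a probe
  clashing with an atom); distances are exact Euclidean, float64.
* Charges above |2.5| e are rejected at parse time as misaligned tables;
  PDB/charge-table rows are matched by order with name/coordinate
  cross-checks, and a row-count mismatch is an error, not a truncation.
* Atoms present in only one state are recorded as orphans and excluded from
  all ΔΔE‡ sums; fewer than 50 % of environment atoms matching is treated
  as mispaired input.
* Per-residue scan failures (missing Cβ, clashes) are quarantined on the
  record and the scan continues; NaNs sink to the bottom of rankings.
* TSV outputs use fixed 6-decimal formatting, and per-residue work is
  order-independent, so serial and threaded runs are byte-identical.
* Problem sizes: the test-suite and acceptance fixtures use the toy (74
  atoms), the end-to-end case (~260 atoms, 29 residues), and 100 random
  systems of up to 500 atoms for the oracle cross-check — sizes at which
  exact summation and the naive oracle are both instantaneous.

## Known limitations

Fixed charges cannot capture polarization, charge transfer, or the
functional-dependent spread of true QM/MM numbers; the scan's rankings are
a screening signal, not barrier predictions. Protonation states are taken
as given (His counts as positive only when hinted). The conservation
grades are a reproducible stand-in for ConSurf's Bayesian phylogenetic
machinery and will differ from it in detail, particularly for small or
biased alignments; below ~5 homologues they are noise and the package warns
accordingly.
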