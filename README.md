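# tsscan

Transition-state macrodipole screening for enzyme engineering: a fast,
frozen-geometry electrostatic scan that ranks active-site residues by how
much their mutation would lower (or raise) a reaction's activation energy,
then filters the candidates by evolutionary plausibility.

## Who this is for

Computational enzymologists who have a pair of optimized stationary points
for a rate-limiting step — the reactant (`REACT`) and the transition state
(`TS1`) — with per-state partial charges, and who want a ranked shortlist of
point mutations expected to speed the enzyme up before committing to
expensive QM/MM single points or wet-lab mutagenesis. The motivating system
is DszC, the flavin-dependent monooxygenase that oxidizes dibenzothiophene
(DBT) in the bacterial 4S desulfurization pathway, but nothing in the code
is specific to it.

## The model

During the reaction, electron density flows onto the proximal peroxyl
oxygen of the C4a-hydroperoxyflavin (O_p) and off the substrate sulfur
(S_DBT), creating a dipole at the transition state that does not exist in
the reactant. Any fixed charge placed asymmetrically with respect to these
two atoms therefore stabilizes one state more than the other. The package
quantifies this with an electrostatic-embedding surrogate: the barrier
contribution of the environment is

    E_int(state) = k_C · Σ_{i∈QM} Σ_{j∈env} q_i(state) · q_j / r_ij
    ΔE‡  = E_int(TS1) − E_int(REACT)
    ΔΔE‡ = ΔE‡(mutant) − ΔE‡(wild type)

with k_C = 332.0637 kcal·Å·mol⁻¹·e⁻², ε = 1, no cutoffs, and frozen
wild-type geometries throughout. The QM-region charges differ between the
two states (they encode the charge flow); a negative ΔΔE‡ predicts a faster
mutant. Three perturbations are scanned for every residue with an atom
within 10 Å of the active site (Gly/Ala/Pro excepted):

* **alanine truncation** — side-chain atoms beyond Cβ and their charges are
  deleted, measuring the wild-type side chain's contribution to the barrier;
* **±1 e probe** — a unit point charge is additionally placed at the
  geometric center of the wild-type side chain's heavy atoms, testing
  whether a charged replacement of either sign would help.

Each scanned residue is located by its distances to the two reference atoms
(center of mass of the charged group for Asp/Glu/Lys/Arg, of all side-chain
heavy atoms otherwise); the asymmetry d(O_p) − d(S_DBT) organizes the
results, with the equidistant locus the exact zero-crossing of the probe
response. Candidates are finally filtered against homologue variability: a
1–9 conservation grade per position (Jensen–Shannon divergence from
background composition with Henikoff sequence weights, or a parsed ConSurf
export), non-charged replacements drawn from the observed variability or
from BLOSUM62-compatible residues, and charged replacements flagged risky
when homologues never show one. The Eyring relation
ΔG‡ = R·T·ln(k_B·T/(h·k)) links measured turnover numbers to barriers.

## Worked example

The package ships a generator for fully synthetic, analytically solvable
inputs, so the whole pipeline can be exercised without any external data:

```
$ tsscan eyring --kcat 1.6 --kcat-units per-min --temp 310
dG_act = 20.4 kcal/mol  (k = 0.0266667 s^-1, T = 310.0 K)

$ tsscan fixtures --seed 7 --outdir demo
wrote synthetic bundle (259 atoms, 29 shell residues) to demo

$ tsscan scan --config demo/config.yaml --output-dir demo/out
scanned 29 residues; 47 candidate mutations
```

The first command converts a turnover of 1.6 min⁻¹ (a typical slow
oxidoreductase) into its transition-state-theory barrier of 20.4 kcal·mol⁻¹.
The scan writes `scan.tsv`, one row per shell residue:

```
chain  resid  residue  class     ddE_ala     ddE_probe_pos  d_Op      d_SDBT    delta_d    labeled
A      101    ASP      NEGATIVE  -19.935437  -35.022887     4.199893  7.799933  -3.600040  True
A      102    GLU      NEGATIVE  -16.116330  -27.207624     4.799504  8.499570  -3.700066  True
```

Asp101 sits 4.2 Å from the oxygen that turns negative and 7.8 Å from the
sulfur that turns positive, so its carboxylate destabilizes the transition
state: deleting it (ΔΔE‡ = −19.9 kcal·mol⁻¹) or replacing it with a positive
charge (−35.0) is predicted to speed the toy reaction up. (The synthetic
charge shift is deliberately large; real side-chain contributions are a
couple of kcal·mol⁻¹.) `candidates.tsv` then crosses these hits with the
bundled homologue alignment:

```
chain  resid  wild_type  replacement  mutation  mode      provenance   ddE
A      101    D          N            D101N     ALA_SCAN  variability  -19.935437
A      101    D          Q            D101Q     ALA_SCAN  blosum       -19.935437
```

`D101N` is proposed because homologues actually show Asn at that position;
`D101Q` only passes the BLOSUM62 filter. Probe-mode candidates at positions
where homologues never carry a charge are flagged `risky`.

For real systems, point the config at your own PDB pairs and PQR (or plain
`x y z q` / `chain resid atomname q`) charge tables, and use
`tsscan prep` to export per-mutant PDBs and point-charge tables for an
external QM/MM engine if you want to replace the Coulomb surrogate with
true ONIOM single points.

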