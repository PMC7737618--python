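# elevator

Conformational analysis toolkit for elevator-type membrane transporters —
the Na⁺/H⁺ exchanger (CPA) fold in particular — for structural biologists
and simulators who want to quantify an inward↔outward "elevator" transition
from structures, elastic-network dynamics, trajectories and functional
assays, without any web services in the loop.

In an elevator transporter each protomer splits into a static,
interface-forming **dimerization domain** and a mobile 6-TM **core
(transport) domain** that carries the ion-binding site vertically across
the membrane. The package implements the complete computational chain used
to characterize that mechanism:

* **Structural-ensemble PCA** (`elevator.pca`). A matched set of
  structures is superposed on the dimerization domain of a reference and
  the 3M-dimensional Cα covariance is diagonalized. Each structure *i* is
  classified by its scalar projection onto principal axis *k*,
  p(i,k) = |T(i−0)| cos(PC_k ∧ T(i−0)) = T(i−0)·PC_k, where T(i−0) is the
  coordinate difference to a reference structure 0. PC1 is the
  inward–outward axis.
* **Elastic-network normal modes** (`elevator.enm`). Cα beads joined by
  harmonic springs (cutoff-ANM, or an ED-ENM-style parameterization with
  C_seq/s² sequence springs and (C_cart/r)⁶ distance springs). The 3M×3M
  Hessian eigenvectors give the intrinsic motions; overlap
  |v·d|/‖d‖ and cumulative overlap √Σo² against a transition vector
  measure how much of the conformational change the cheap modes encode.
  Per-residue fluctuations Σ‖v_m,i‖²/λ_m locate rigid "hinge" minima.
* **Transition pathways and elevator metrics** (`elevator.pathway`).
  Iterative normal-mode climbing toward a target state (modes recomputed
  each step, best-overlapping modes combined, Cα–Cα virtual bonds
  re-idealized), transition *coverage* as a PC1 projection ratio, and the
  **elevator shift**: membrane-normal displacement of the binding-site
  centroid after scaffold superposition.
* **Interface burial and conserved contacts** (`elevator.surface`).
  Shrake–Rupley SASA, buried surface area
  BSA = (SASA(A)+SASA(B)−SASA(A∪B))/2, and conservation-filtered
  (grades ≥ 8 of 9) inter-domain contact networks that expose the
  hydrophobic gates sealing the ion pathway on either side of the site.
* **Trajectory ion binding and densities** (`elevator.binding`). The 3 Å
  ion–carboxyl-oxygen distance criterion with minimum-image periodic
  distances, occupancy and bound-event segmentation, and voxelized
  densities in mol/L (OpenDX export).
* **Assay numerics** (`elevator.assays`). ACMA dequench percentage,
  Michaelis–Menten fits (v = V_max·S/(K_M+S), Levenberg–Marquardt) and
  4-parameter-logistic melting fits with ΔT_m.
* **Synthetic ground truth** (`elevator.synth`). Two-state toy elevators,
  noisy ensembles, ideal-gas ion trajectories at a stated concentration
  with a programmable bound fraction, and dose–response/melting curves —
  every generator a pure function of (parameters, seed).

## Worked example

Generate a two-state toy elevator (core shifted 5 Å along the membrane
normal), a noisy 6-member ensemble of both states, then run PCA, build a
transition pathway and measure the elevator shift:

```bash
elevator simulate ensemble --shift 5 --sigma 0.2 --n-per-state 3 --seed 11 --out ens
elevator pca --structures ens/ensemble.pdb --domains ens/domains.yaml --out pca
head -2 pca/variance.csv
#   component,eigenvalue_A2,variance_fraction
#   1,382.1873853302473,0.9748889781472401

elevator simulate elevator --shift 5 --seed 11 --out sim
elevator pathway --start sim/state_a.pdb --target sim/state_b.pdb \
    --domains sim/domains.yaml --out path
cat path/pathway.json
#   {"final_coverage": 1.0187766882470553, "n_frames": 7,
#    "stop_reason": "coverage 1.019 reached stop criterion 0.95"}

elevator shift --state-a sim/state_a.pdb --state-b sim/state_b.pdb \
    --domains sim/domains.yaml --out shift
#   elevator_shift_A 5.000
```

Reading: PC1 of the two-state ensemble carries 97% of the coordinate
variance (the elevator axis dominates the noise); six normal-mode steps
cover the full inward→outward transition; and the binding-site centroid
moves exactly the programmed 5.0 Å along the membrane normal once the
scaffold domains are superposed.

The same commands run on real inputs: deposited PDB/mmCIF structures, a
curated residue-correspondence TSV, a YAML domain definition, per-residue
conservation CSVs and trajectory CSV/multi-model-PDB files. See
`docs/methods.md` for the model details, defaults and limitations.

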