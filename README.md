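# hexanlo

Inverse design of hexaphyrin-based nonlinear-optical (NLO) switches.

Hexaphyrins are expanded porphyrins with six heterocycle rings and six meso
substitution sites (R1–R6). They interconvert between redox states and
π-conjugation topologies — the rectangular Hückel forms **26R**/**28R**, the
singly-twisted Möbius form **28M**, the dumbbell **26D** — whose first
hyperpolarizabilities differ by orders of magnitude, which makes them
candidate molecular switches for second-order nonlinear optics. This package
provides the desk-scale machinery of that design problem for computational
chemists working downstream of quantum-chemistry β tensors:

* **`nlo_tensor`** — hyper-Rayleigh-scattering (HRS) invariants of a β
  tensor: the orientational averages ⟨β²_ZZZ⟩ and ⟨β²_ZXX⟩, with

  β_HRS = √(⟨β²_ZZZ⟩ + ⟨β²_ZXX⟩),  DR = ⟨β²_ZZZ⟩/⟨β²_ZXX⟩,

  assuming only intrinsic SHG symmetry (β_ijk = β_ikj, no Kleinman
  symmetry), plus a Monte-Carlo rotational-averaging oracle and a JSON
  tensor dialect (`hexanlo-beta-v1`).
* **`contrast`** — the two switch figures of merit, the ratio
  β_HRS(ON)/β_HRS(OFF) and the difference β_HRS(ON) − β_HRS(OFF), with the
  OFF-state clamping rule (an OFF response below 10 a.u. replaces the
  denominator by 0.001 a.u., keeping centrosymmetric OFF states finite and
  comparable), reversal flags, and the ratio/difference correlation.
* **`chemspace`** — the meso-substitution compound space: substituent
  library (NO₂, CN, F, H, CH₃, OH, NH₂; PhF₅ in fixtures only), the FULL,
  A₂B₂C₂, A₃B₃ and A₂BC₂D site patterns, canonical structure keys such as
  `26R(NH2_OH_NH2)`, enumeration, and the formal-centrosymmetry rule
  (a 28R structure with a diagonal-symmetric substituent map is predicted
  C_i, hence β_HRS = 0).
* **`bfs`** — best-first (greedy site-by-site) contrast maximization with
  sweep convergence, caching, trajectory logging, and an exhaustive-search
  oracle. On additive (independent-site) landscapes one sweep is provably
  optimal; with inter-site couplings the result is a monotone lower bound on
  the exhaustive optimum.
* **`evaluators`** — pluggable property evaluators: a fixture evaluator
  replaying published DFT β_HRS tables, a seeded synthetic landscape with
  centrosymmetry cancellation and tunable couplings, and a file-based
  external-evaluator contract for real quantum-chemistry back ends.
* **`geometry`** — topology descriptors from XYZ geometries: torsional ring
  strain Φ_p (mean inter-ring plane dihedral), the signed π-conjugation
  index Π (positive Hückel, negative Möbius), inversion-center detection,
  and a synthetic macrocycle generator with exactly known descriptors.

What it deliberately does **not** do: compute β tensors or any other
electronic-structure quantity. DFT results enter only as plain-text fixture
tables or external-evaluator responses.

## Worked example

HRS invariants of a one-dimensional chromophore (only β_zzz = 1000 a.u.):

```bash
$ hexanlo hrs tensor.json
frequency_eV  beta_hrs  avg_zzz2  avg_zxx2  depolarization_ratio
0             414.039   142857    28571.4   5
```

β_HRS = 1000·√(6/35) ≈ 414.04 a.u. and DR = 5, the textbook values for a
single diagonal component. Contrast of the unsubstituted redox switch
28R → 26R from the packaged fixture tables:

```bash
$ hexanlo contrast --on-key "26R(H)" --off-key "28R(H)" --objective ratio
ratio      difference  clamped  reversed  objective  objective_value
2.347e+06  2347        True     False     ratio      2.347e+06
```

The OFF state is centrosymmetric (β_HRS stored as 0), so the clamp rule
fires: 2347/0.001 = 2.347×10⁶, and the difference is the full 2347 a.u. ON
response. A search over the 343-point A₂B₂C₂ space on a seeded synthetic
landscape:

```bash
$ hexanlo optimize --pattern A2B2C2 --objective ratio --evaluator synthetic --seed 7
best_key         best_objective  converged  evaluations  cache_hits
26R(OH_NH2_CH3)  7.64667e+06     True       25           18
```

25 structure evaluations out of 343 — the point of greedy inverse design —
and on this couplings-free landscape the result equals the exhaustive
optimum. Topology descriptors of a generated Möbius-like frame with six
30° inter-ring twists:

```bash
$ hexanlo descriptors m.xyz m.yaml
phi_p_deg  pi_index   topology  aromatic_by_pi  centrosymmetric
30         -0.421875  Moebius   False           False
```

Π = −cos⁶30° — the single orientation reversal of the Möbius loop makes the
overlap product negative.

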