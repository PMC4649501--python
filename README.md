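# pentaef

Structural analysis of penta-EF-hand (PEF) calcium-binding proteins —
Sorcin, PDCD6/Alg-2 and the calpain small-subunit dVI domain.

PEF proteins carry five helix-loop-helix EF-hand motifs per monomer, built
from eight α-helices A–H (EF1 = [A–B], EF2 = [C–D], EF3 = [D–E],
EF4 = [F–G], EF5 = [G–H]). Calcium binding to the high-affinity hands opens
EF1 and EF3 and tilts the long D-helix relative to the G-helix, exposing
the hydrophobic surfaces through which these proteins engage their targets.
`pentaef` quantifies every step of that story from coordinate files:

- **EF-hand opening angles** — the angle θ between the directed axes of an
  EF-hand's entering and exiting helices, each axis being the first
  principal component of the helix Cα trace (sign fixed N→C); the hD–hG
  angle reports the EF1–EF3 sub-domain movement, and apo→holo tables give
  Δθ = θ(holo) − θ(apo).
- **Rigid superposition** — Kabsch least-squares fits, per-region Cα RMSD
  after aligning on a reference region, inter-atomic distances and
  distance-criterion hydrogen bonds (N/O pairs ≤ 3.5 Å).
- **Calcium coordination geometry** — coordination spheres at a 2.9 Å
  Ca–O/N cutoff, classified against the ideal pentagonal bipyramid
  (two axial ligands at 180°, five equatorial at 72°) by exhaustive
  axial-pair search; EF-hand Ca²⁺ is canonically hepta-coordinated.
- **Solvent accessibility** — Shrake–Rupley SASA (1.4 Å probe, 960-point
  Fibonacci meshes), apo→holo relative-change filtering
  (100·ΔSASA/max(SASA_apo, 1 Å²) > 30% with a 5 Å² absolute guard),
  Hotpatch-like exposed hydrophobic patch clustering, and ePISA-style
  interface burial by ΔSASA on complex separation.
- **Binding-motif analysis** — scanning and position-frequency matrices for
  the degenerate phage-display consensus Φ/Gly/Met-Φ/Gly/Met-x-P
  (Φ = Trp/Tyr/Phe) and the acidic-Φ pattern, with per-condition
  (Ca²⁺ vs EDTA) enrichment.
- **SPR kinetics** — 1:1 Langmuir sensorgram simulation and statsmodels-style
  global fitting (`LangmuirModel(curves).fit()` → results with `summary()`),
  steady-state hyperbola fits and the Scatchard linearization
  (slope = −1/Kd).

A synthetic-data module generates ideal helices at prescribed mutual
angles, ideal coordination polyhedra, motif-planted peptide sets and noisy
sensorgrams, so the entire pipeline is testable without downloading any
structure. Real PDB/mmCIF files are read through the same code paths
(via `gemmi`, author residue numbering throughout).

## Worked example

Measure an EF1 opening from an apo/holo pair and fit an SPR affinity:

```python
from pentaef import (build_efhand_pair, efhand_angles, delta_table,
                     simulate_sensorgram, LangmuirModel)

apo, holo, anns, efd = build_efhand_pair(theta_apo=40.8, theta_holo=59.2)
rep_apo = efhand_angles(apo, "A", anns, efd, label="apo")
rep_holo = efhand_angles(holo, "A", anns, efd, label="holo")
delta = delta_table(rep_apo, rep_holo)
print(f"delta theta EF1 = {delta.ef_deltas['EF1']:+.1f} deg")

kd = 3.5e-6
curves = [simulate_sensorgram(kon=1e5, koff=1e5*kd, rmax=100.0, conc=f*kd,
                              noise_sd=2.0, seed=i)
          for i, f in enumerate((0.2, 0.5, 1.0, 2.0, 5.0))]
print(LangmuirModel(curves).fit().summary())
```

prints

```
delta theta EF1 = +18.4 deg

1:1 Langmuir kinetic fit
========================================
curves:         5  (3005 points)
kon  [1/(M s)]: 9.856e+04
koff [1/s]:     0.3501
Kd   [M]:       3.552e-06  (3.55 uM)
Rmax [RU]:      100.5
residual RMS per curve [RU]: 1.99, 1.89, 1.99, 1.99, 2.01
converged:      True
```

The +18.4° is the EF1 opening the generator was asked for, recovered by
axis fitting on the helix Cα traces; the fitted Kd recovers the simulated
3.5 μM affinity from five noisy concentration series.

The same operations are available from the shell via the `pef` CLI
(`pef efhands`, `pef metal-sites`, `pef sasa-diff`, `pef patches`,
`pef interface`, `pef motif-scan`, `pef enrich`, `pef spr-sim`,
`pef spr-fit`, `pef simulate`, `pef run-all`); selections are
`CHAIN:START-END` strings and outputs are TSV/JSON. `pef run-all` runs the
full apo/holo comparison and writes a provenance-stamped report bundle.

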