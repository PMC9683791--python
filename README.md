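# aldpkit

Structure-based analysis toolkit for ALDP (ABCD1), the peroxisomal
ATP-binding cassette transporter of very-long-chain fatty acyl-CoAs whose
dysfunction causes X-linked adrenoleukodystrophy (ALD). The package is
aimed at structural biologists and variant curators who want to connect a
transporter's conformational cycle, its substrate cavities, and its
disease-variant catalogue into one reproducible pipeline, together with
the supporting biochemistry (ATPase kinetics, nanoDSF thermal melts).

## What it computes

* **Conformational analysis.** Kabsch least-squares rigid superposition
  (SVD closed form, proper rotations only), per-residue Cα displacement
  maps between states, and inter-segment distance metrics. The gating
  motion of the transporter is summarised by the TM4–TM6 distance at the
  juxta-membrane region, measured as min Cα–Cα between configurable
  terminal windows of the two helices.
* **Substrate cavities.** Grid-based cavity detection: nodes farther than
  `probe + vdW` from every heavy atom are open; bulk solvent is removed by
  flood fill from the box boundary (6-connectivity); remaining clusters
  are cavities with volume `|nodes| · spacing³`, lining residues within a
  contact cutoff, and ligand maximal extent (largest heavy-atom pairwise
  distance) for substrate/pocket size comparisons.
* **Variant hotspots.** A residue reported mutated to ≥ 2 distinct amino
  acids is a *hotspot*; hotspots are classified spatially with a fixed
  precedence (cavity-lining > other TMD > NBD > C-terminal helix) into the
  three functional groups used to interpret ALD missense variants.
* **Kinetics & stability.** Michaelis–Menten fitting
  (v = V<sub>max</sub>·s/(K<sub>m</sub>+s)) by Hanes–Woolf-initialised
  nonlinear least squares with Jacobian standard errors; WT-normalised
  activity panels; melting temperatures from the extremum of the smoothed
  first derivative of the nanoDSF F350/F330 ratio.
* **Synthetic fixtures.** Every stage has a generator that plants known
  ground truth (ideal helix bundles with a recorded C2 operator, sealed
  cavity shells of analytic volume, variant tables with planted hotspot
  counts, kinetic and melt curves with known parameters), so the whole
  pipeline is testable offline.

## Worked example

Generate the bundled synthetic demo (all ground truths planted and
recorded in `truth.json`) and run the full pipeline:

```sh
$ aldpkit demo --out demo --seed 2
demo config written to demo/config.yaml
$ aldpkit run --config demo/config.yaml
       distances  ok
        cavities  ok       1 cavity(ies)
   ligand_extent  ok
        hotspots  ok       88 hotspots
  classification  ok       {'cavity_lining': 10, 'tmd_other': 35, 'nbd_and_ch': 43}
        kinetics  ok       vmax=193 km=0.17
            melt  ok       Tm=55.00 C
```

`demo/out/distances.tsv` holds the planted three-state TM4–TM6 gate
series (20.0 / 12.0 / 6.0 Å: open, substrate-bound, closed); the hotspot
summary reports 970 records over 232 affected residues of which 88 are
hotspots, classified 10 (cavity-lining) / 35 (other TMD) / 43 (NBD + CH);
the kinetics fit recovers the planted V<sub>max</sub> = 193 mol Pi
min⁻¹ mol⁻¹ protein and K<sub>m</sub> = 0.17 µM; the melt stage recovers
the planted T<sub>m</sub> = 55.0 °C. Individual stages are also available
as `aldpkit distances|cavities|extent|hotspots|classify|kinetics|melt`.

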