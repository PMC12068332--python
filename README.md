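# mitobrush

Coarse-grained polymer simulation of **bridging-mediated compaction of
mitotic chromosomes**.

During mitosis a loose, loop-decorated chromatin fiber ("bottlebrush",
the prophase state produced by condensin loop extrusion) folds into the
compact cylindrical chromatid seen in metaphase.  Loop extrusion alone
does not produce the cylinder without artificial confinement.  `mitobrush`
implements the alternative mechanism: condensins also act as *bridges* —
multivalent particles weakly attracted to chromatin everywhere and
strongly attracted to condensin loop anchors.  Switching this attraction
on collapses the bottlebrush into a **self-assembled cylinder (SAC)**
spontaneously, with no confining potential, while bridges condense into
separated clusters along the backbone through bridging-induced attraction
(there is *no* bridge–bridge attraction term in the energy).

The package is aimed at chromatin/polymer modellers who want a small,
fully scripted, reproducible implementation of this model with its
standard readouts.

## The model in brief

* Chromatin: bead–spring chain, 2 kbp per bead (bead diameter σ = length
  unit, k_BT = energy unit), tiled by consecutive loops drawn uniformly
  from 60–120 kbp; each loop closed by a looping-condensin spring at its
  two shared root beads (*n* loops → *n*+1 anchors).
* Chromatin–chromatin repulsion is a *bounded* soft core with barrier
  `2A`: the topoisomerase-II dial.  `A = 1 k_BT` ≈ free strand crossing
  (high enzyme activity); default `A = 4 k_BT` makes crossing rare.
* Bridges: spheres, one per attractive anchor by default, WCA-steric in
  phase 1, then `ε_weak = 3 k_BT` to chromatin and `ε_strong = 8 k_BT` to
  anchors (truncated LJ wells) in phase 2.
* Underdamped Langevin (BAOAB) dynamics, dt = 0.01 τ, γ = 1, periodic box
  with minimum-image interactions; fully seeded and bit-reproducible.
* Observables: gyration radius and acylindricity (λ₂ − λ₃ of the gyration
  tensor — zero for a perfect cylinder), chromosome length/width, contact
  probability P(s) and its power-law exponent (the SAC decays ≈ s^−0.5
  over 10–100 kbp), single-linkage bridge clusters, backbone contour and
  straightness, stretch–release elasticity, condensin-I/II knockout and
  common-fragile-site lesion scenarios.

See `docs/methods.md` for the full model description and design choices.

## Worked example

```python
import mitobrush as mb

cfg = mb.BottlebrushConfig(n_beads=600, seed=1)      # 1.2 Mbp chromatid
state = mb.build_bottlebrush(cfg)                    # prophase bottlebrush
state = mb.place_bridges(state, "auto", seed=1)      # one bridge per anchor
traj = mb.run_schedule(
    state, mb.ForceFieldParams(), mb.EngineParams(seed=1),
    mb.Schedule(phase1_steps=1000, phase2_steps=100_000, snapshot_every=3000),
)

shapes = mb.shape_series(traj)
print(f"Rg    {shapes.rg[0]:.2f} -> {shapes.rg[-1]:.2f}")
print(f"acyl  {shapes.acylindricity[0]:.2f} -> {shapes.acylindricity[-1]:.2f}")

profile = mb.fit_exponent(mb.contact_probability(traj, frames="final_quarter"))
print(f"P(s) ~ s^-{profile.fitted_exponent:.2f} over 10-100 kbp")
print(f"bridge clusters: {mb.cluster_bridges(traj.bridges[-1]).n_clusters}")
```

prints (exact values for these seeds):

```
Rg    10.62 -> 6.98
acyl  28.50 -> 7.29
P(s) ~ s^-0.70 over 10-100 kbp
bridge clusters: 10
```

The gyration radius drops by a third and the acylindricity falls as the
flexible brush condenses (single-frame shape values fluctuate; the
scenario reports average the final quarter of frames); the
contact-probability exponent is near the ≈ 0.5 characteristic of
compacted mitotic chromatids (0.46 replicate mean at the default
1000-bead scale); and the 15 bridges have condensed into a necklace of
separated clusters plus a few still-unbound particles — all without any
bridge–bridge attraction or confinement.

The same experiment from the shell:

```bash
mitobrush run --config my_config.yaml --seed 1 --out out/
mitobrush analyze --traj out/trajectory.h5 --out out/
mitobrush scenario wildtype --seeds 1,2,3 --out out_wt/
```

Every run writes a manifest (resolved configuration, seeds, version,
SHA-256 of outputs) sufficient to reproduce it.

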