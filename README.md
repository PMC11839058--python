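# myelindev

Depth-resolved cortical myelination trajectories: T1w/T2w ratio maps,
equivolumetric depth bins, a geodesic sensorimotor–association (S-A) axis,
penalized-smooth age-trajectory models with plateau detection, and
cross-species (human/macaque) developmental time alignment.

## The problem

Intracortical myelin content can be proxied in vivo by the ratio of a
T1-weighted to a co-registered T2-weighted MR volume. Across development,
myelination does not proceed uniformly: sensorimotor cortex matures before
association cortex, deep cortical layers before superficial ones, and
macaque development runs roughly four times faster than human. Testing
these claims requires a chain of non-trivial machinery — calibrated ratio
maps; depth compartments of equal tissue volume (the equi-volume
principle, which compensates cortical curvature); a cortical hierarchy
axis built from surface geodesic distances; penalized regression smooths
of age whose first derivative, with a simultaneous confidence band,
defines when growth plateaus; and a 4:1 age rescaling with
baseline-adjusted overlays for cross-species comparison.

`myelindev` implements that chain as a tested library, exercised
end-to-end on synthetic cortices with analytically known ground truth, so
every stage's recovery properties are measured rather than assumed.

## The core models

- **Equivolume depth.** For a column whose cross-sectional area varies
  linearly from the white-surface area `A_w` to the pial area `A_p`, the
  depth fraction enclosing volume fraction α is
  `ρ(α) = (−A_w + √((1−α)A_w² + αA_p²)) / (A_p − A_w)`; K bins of equal
  volume follow by slicing α. Bin 1 is deepest throughout.
- **S-A axis.** Per-vertex minimum geodesic distance (multi-source
  Dijkstra on the mesh edge graph) from k-means-subsampled seed vertices
  in association parcels; parcel means, ranked and split into equal
  thirds (association / middle / sensorimotor).
- **Trajectories.** `ratio = β₀ + β_sex·sex + f(age) + b_subject + ε`
  with `f` a rank-3 thin-plate regression spline (one penalized curvature
  term beside the {1, age} null space), smoothing by REML; the age effect
  is the signed partial R² of the smooth (full minus reduced model),
  FDR-corrected across parcels.
- **Plateaus.** Analytic first derivative with a simultaneous 95% band
  from coefficient-posterior draws; the plateau age is the earliest age
  from which growth is never again significant.
- **Species alignment.** human_age = s·macaque_age (default s = 4);
  baseline-adjusted trajectory overlays, plus a recovery harness that
  re-estimates s from the fitted trajectories.

## Worked example

```bash
python examples/04_plateau_detection.py
```

```
simultaneous critical multiplier m* = 2.441 (pointwise would be 1.96)
plateau flag: no-growth
detected plateau age: 5.17 years
true plateau onset  : 7.50 years (derivative falls below 1% of its initial value)
```

A saturating trajectory (150 subjects, ages 5–35 y, noise 10% of the
growth amplitude) is fitted with the rank-3 REML smooth; the simultaneous
band of its derivative needs a larger multiplier than the pointwise 1.96
because it must hold jointly over the whole age grid. Here the true
plateau (7.5 y) falls so close to the window start that the band never
clears zero — the unit is flagged as having plateaued at or before the
first observed age (5.17 y), within the ±15%-of-range tolerance the
recovery study uses.

The other examples cover the equivolume phantom (01), the geodesic axis
(02), trajectory fitting and signed partial R² (03), species scaling
(05) and the full pipeline (06), each printing a few numbers and what
they mean. The end-to-end pipeline is also available from the shell:

```bash
myelin-pipeline run --config config.json --out-dir results
```

writing `axis.csv`, `profiles.csv`, `effects.csv`, `plateaus.csv`,
`ground_truth.csv`, `summary.json` and a run log; identical configs give
byte-identical tables.

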