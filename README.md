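# endopolar

Quantification pipelines for imaging studies of invasive cancer-cell
polarity: where do MT1-MMP-loaded late endosomes/lysosomes sit relative
to the direction a cell is moving, how much of the cell surface is
covered by invadopodial markers such as TKS5 or FGD1, how much
pericellular collagen does a cell population cleave, and how deep do
cells invade into a 3D collagen gel.

The package is aimed at cell biologists who have calibrated multi-channel
TIFF/OME-TIFF stacks (pixel size in µm, z-step in µm, frame interval in
minutes) and want reproducible, scriptable versions of quantifications
that are usually done interactively in Fiji/ImageJ — plus a synthetic
scene generator that produces movies, colocalization fixtures,
degradation fields and invasion stacks with exported ground truth, so
every stage of the pipeline can be validated without any microscope.

## What it computes

**Endosome polarity in the nucleus-velocity frame.** Nuclei are
segmented (smoothing + Otsu + watershed split) and tracked by greedy
nearest-neighbour linking; per-interval speed (µm/min) and persistence
(net displacement / path length ∈ [0, 1]) are computed per trajectory.
Endosomes are detected by Laplacian-of-Gaussian enhancement with a
marker-controlled watershed, assigned to the nearest nucleus, and
re-expressed in polar coordinates (r, θ) with the origin at the nucleus
centroid and θ = 0° along the instantaneous velocity; θ ∈ (−180°, 180°],
so a spot directly ahead of the nucleus is at 0° and one directly behind
at 180°. Pooled angles feed a 12 × 30° rose histogram, the percentage of
endosomes in the frontal 120° sector, and Rao's spacing test of circular
uniformity,

U = ½ Σᵢ |Tᵢ − λ|,  λ = 360°/n,

where Tᵢ are the circular spacings of the sorted angles; the p-value is
Monte-Carlo (add-one smoothed, seedable).

**Colocalization.** Width-averaged linescans along user-drawn polylines
(default width 6 px, each channel normalized to max = 100) with Pearson
r and an OLS regression; thresholded Manders coefficients
M1 = Σ Aᵢ[Aᵢ>tA ∧ Bᵢ>tB] / Σ Aᵢ[Aᵢ>tA] (M2 symmetric); and the
normalized mean deviation product map
nMDPᵢ = (Aᵢ−Ā)(Bᵢ−B̄)/((A_max−Ā)(B_max−B̄)) ∈ [−1, 1].

**Scalar assays.** Invadopodia area ratio (marker-positive area over
cell area, components < 8 px discarded), degradation index (LoG-counted
collagen-cleavage spots per cell and field, control mean set to 100),
and 3D invasion fraction (share of nuclear signal at depth ≥ 30 µm in a
serial-section stack).

## Worked example

```python
import endopolar as ep

cfg = ep.SceneConfig(n_frames=40, endosomes_per_cell=20,
                     angular_model=("von_mises", 0.0, 1.5), seed=5)
scene, truth = ep.generate_polarity_movie(cfg)
pset, tracks = ep.run_polarity_assay(scene)

print(f"endosomes analysed: {pset.n}")
print(f"front 120° fraction: {ep.front_fraction(pset.angles):.1f}%")
rao = ep.rao_spacing_test(pset.detection_angles, seed=0)
print(f"Rao U = {rao.U:.1f}°, p = {rao.p_value:.4f}")
```

prints

```
endosomes analysed: 782
front 120° fraction: 72.1%
Rao U = 174.1°, p = 0.0001
```

The movie plants endosomes around a migrating nucleus with a von Mises
(µ = 0°, κ = 1.5) angular law, for which the true frontal-120° mass is
71.7%; the pipeline recovers 72.1% from this single movie's pixels, and
the spacing test rejects circular uniformity (p ≈ 10⁻⁴), i.e. the
endosomes are detectably polarized toward the front. A κ = 0 movie
instead yields ≈ 33% and a non-significant p.

The same functionality is exposed as CLI subcommands (`endopolar
simulate | polarity | invadopodia | linescan | coloc | degradation |
invasion`), each driven by a YAML config and writing CSV/JSON results
plus a provenance record.

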