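# lcn — quantification of the osteocyte lacunocanalicular network

Osteocytes sit in small cavities (lacunae, ~300–400 µm³) inside bone matrix
and reach each other through sub-micron channels (canaliculi, ~300 nm
diameter). This lacunocanalicular network (LCN) is the transport and
mechanosensing infrastructure of bone. `lcn` turns 3D confocal image stacks
of stained bone into a spatial network and computes the standard morphometry
of the field:

* **Can.Dn** [µm/µm³] — canalicular length per unit tissue volume,
* **Nd.Nr** [µm⁻³] — branching points (network nodes) per unit volume,
* **Nd.Dg** [–] — mean number of branches per node (lacunae not counted),
  evaluated in cubic subvolumes of 400 µm³,
* **Lc.V, Lc.St, Lc.Ob, Lc.Dg** — lacunar volume, stretch (1 − c/a),
  oblateness (2(b−c)/(a−c) − 1) from ellipsoid fits, and the number of
  primary canaliculi emanating from each lacuna,
* the cumulative node-degree distribution C(x) of "genuine" nodes
  (degree ≥ 3) and its exponential tail fit C(x) ≈ e^(−β(x−3)),
* region statistics separating dense, radially aligned ("ordered") network
  from sparser isotropic ("unordered") network,
* qBEI calibration mapping 8-bit backscattered-electron gray levels to
  calcium content (wt% Ca) via carbon/aluminum references.

Extraction follows the five-step procedure used in LCN studies: difference-
of-Gaussians adaptive binarization → thickness-based separation of lacunae
from canaliculi → topology-preserving 3D skeletonization → cubic smoothing
splines on skeleton branches → translation into a spatial graph with
lacuna/junction/endpoint nodes and canalicular edges (lengths in µm,
anisotropic voxels handled in physical units).

Because raw image data of this kind are rarely shareable, the package ships
a first-class synthetic phantom generator (`lcn.synth`) producing
ground-truthed image stacks with the statistical structure the analysis
assumes — ellipsoidal lacunae, tubular canaliculi at realistic densities, a
degree distribution with exponential tail, ordered/unordered regions,
mineral interface planes that interrupt the network, paired-limb cohorts of
two mouse-strain presets, and confocal-like blur and noise. Every
downstream stage is tested against this generator's known truth.

## Worked example

```python
import numpy as np

from lcn.synth import GeneratorParams, generate_ground_truth, rasterize, degrade
from lcn.extract import extract_network
from lcn.metrics import compute_subvolume_maps, cumulative_degree_fit, lacuna_morphometry

params = GeneratorParams(seed=1)  # 50x50x50 um^3 phantom at confocal voxel size
truth = generate_ground_truth(params)
stack = degrade(rasterize(truth, params), params)
result = extract_network(stack)

submap = compute_subvolume_maps(result.graph, params.domain_size_um)
fit = cumulative_degree_fit(result.graph)
lacunae = lacuna_morphometry(result.segmentation, result.graph)

print(f"true Can.Dn  = {truth.realized['can_dn']:.3f} um/um^3")
print(f"extracted    = {np.mean(submap.values('can_dn')):.3f} um/um^3")
print(f"true Nd.Nr   = {truth.realized['nd_nr']:.4f} /um^3")
print(f"extracted    = {np.mean(submap.values('nd_nr')):.4f} /um^3")
print(f"mean node degree: true {truth.realized['nd_dg']:.2f}, "
      f"extracted {result.graph.genuine_degrees().mean():.2f}")
print(f"degree-tail exponent beta = {fit.beta:.2f} over {fit.n_nodes} genuine nodes")
print(f"lacunae found: {len(lacunae)} (true {int(truth.realized['n_lacunae'])}); "
      f"Lc.V = {np.mean([s.volume_um3 for s in lacunae]):.0f} um^3, "
      f"Lc.Dg = {np.mean([s.degree for s in lacunae]):.1f}")
```

prints

```
true Can.Dn  = 0.226 um/um^3
extracted    = 0.195 um/um^3
true Nd.Nr   = 0.0498 /um^3
extracted    = 0.0410 /um^3
mean node degree: true 3.15, extracted 3.27
degree-tail exponent beta = 0.69 over 5342 genuine nodes
lacunae found: 4 (true 4); Lc.V = 315 um^3, Lc.Dg = 42.0
```

The phantom realizes canalicular density 0.226 µm/µm³ and node density
0.0498 µm⁻³ (targets 0.21 / 0.05, the measured scale for murine cortical
bone); the extraction recovers them to within its documented tolerances
(length −14 %, nodes −18 % here, mostly boundary and merging losses). Note
that the *fitted* tail exponent of the extracted network (0.69) is smaller
than the generator's degree parameter — junction merging at imaging
resolution fattens the degree tail, a bias worth remembering when
interpreting β from real image data (see `docs/methods.md`).

## Command line

```bash
lcn simulate --config config.yaml --out run/sim        # phantom + truth
lcn extract  --in run/sim/stack.tif --out run/ext      # stack -> graph
lcn metrics  --graph run/ext/graph.graphml --domain 50,50,50 --out run/met
lcn regions  --graph ... --mask mask.tif --domain ... --out run/reg
lcn qbei     --in qbei.tif --out run/qbei              # gray level -> wt% Ca
lcn compare  --n-per-group 3 --out run/cmp             # two-strain cohort t-tests
lcn report   --dir run                                 # collate manifests
```

Each subcommand writes a JSON manifest (parameters, seed, output checksums)
so a full run is auditable.

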