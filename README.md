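# dscircuit

A compartmental model and analysis toolkit for retinal direction
selectivity, built around the idea that a direction-selective ganglion cell
(DSGC) can compute motion direction from the *relative timing* of its
excitatory and inhibitory inputs, not only from their amplitudes.

Starburst amacrine cells co-release acetylcholine and GABA onto DSGCs with
different spatial footprints: cholinergic excitation reaches the cell from
all sides with its effective receptive field displaced ~50 µm toward the
stimulus, while GABAergic inhibition is dominated by null-side cells. For
preferred-direction motion excitation therefore *leads* inhibition (by
offset/velocity, ~50 ms at 1 mm/s); for null-direction motion the two
arrive together and cancel. This timing (E/I temporal offset) mechanism
operates in parallel with the classical amplitude mechanism, in which GABA
release probability itself is direction tuned.

The package is for computational neuroscientists who want to simulate,
dissect and quantify these mechanisms:

* `circuit_geometry` — procedural planar DSGC arbor, tri-receptor synapse
  placement, and moving-bar activation schedules with sigmoidal direction
  tuning of release probability `Pr(a)` and spatial offset (0° preferred,
  180° null):

      Pr(a)     = pPr + (nPr − pPr)·(1 − 0.98/(1 + e^((a−91.0)/25.0)))
      offset(a) = pOff − (pOff − nOff)·(1 − 0.98/(1 + e^((a−74.69)/24.36)))

* `biophysics` — Hodgkin–Huxley-type multicompartment cable model
  (region-specific Na/K densities, numba-compiled implicit solver), with
  current-clamp (spikes) and ideal-space-clamp voltage-clamp (EPSC/IPSC)
  recording modes.
* `ephys_analysis` — the field's standard statistics: Gaussian-kernel
  firing rates (σ = 25 ms), the vector-sum direction selectivity index
  DSI = |Σᵢ rᵢ·v̂ᵢ| / Σᵢ rᵢ with preferred angle from the resultant, 20–80%
  rise-fit onset latencies, E/I temporal offsets (inhibition minus
  excitation onset; negatives clamped to 0 for DSI), and early- versus
  peak-phase tuning with trial variability.
* `synthetic_data` — surrogate EPSC/IPSC pairs and Poisson spike trains
  with configured ground truth, for estimator validation.
* `experiments` / `dscircuit` CLI — mechanism-dissection and
  velocity-sweep protocols, plus `simulate`, `analyze` and `synth`
  subcommands.

## Worked example

```python
import numpy as np
from dscircuit import (default_model, default_transmitter_tuning,
                       simulate_bar_response, measure_ei_offset,
                       DirectionSeries, direction_selectivity_index)

cell, sites = default_model()
tuning = default_transmitter_tuning()

directions = [45.0 * k for k in range(8)]
counts = [simulate_bar_response(cell, sites, tuning, d, 1000.0,
                                trial_seed=k, noise=False).n_spikes
          for k, d in enumerate(directions)]
result = direction_selectivity_index(
    DirectionSeries(np.array(directions), np.array(counts, dtype=float)))
print("spike counts:", dict(zip(map(int, directions), counts)))
print(f"DSI = {result.dsi:.2f}, preferred angle = {result.preferred_angle_deg:.0f} deg")

est = measure_ei_offset(cell, sites, tuning, direction_deg=0.0,
                        velocity_um_s=1000.0, trials=200, seed=1)
print(f"preferred-direction E/I temporal offset = {est.offset_ms:.1f} ms")
```

prints

```
spike counts: {0: 11, 45: 12, 90: 6, 135: 3, 180: 2, 225: 4, 270: 8, 315: 8}
DSI = 0.34, preferred angle = 0 deg
preferred-direction E/I temporal offset = 48.2 ms
```

The bar moving along the preferred axis (0°) evokes ~5× more spikes than
null-direction motion, giving a DSI of 0.34 with the preferred angle
recovered exactly. The voltage-clamp protocol measures excitation leading
inhibition by ~48 ms for a 1 mm/s preferred-direction bar — the temporal
signature of the ~50 µm cholinergic receptive-field displacement
(offset = velocity × temporal offset).

Experiment protocols from the shell:

```
dscircuit experiment mechanism-dissection --trials 20 --seed 1 --out out/dissect
dscircuit experiment velocity-sweep --trials 20 --seed 1 --out out/sweep
dscircuit synth --seed 1 --out out/fixture && dscircuit analyze out/fixture
```

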