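# mackinetics

Single-pore kinetics of membrane attack complex (MAC) assembly from
time-lapse atomic force microscopy (AFM) movies.

The MAC is the terminal pore of the complement system: a membrane-bound
C5b-8 initiator complex recruits 18 copies of C9 to open an ~11 nm
transmembrane pore in a bacterial membrane. Time-lapse AFM of supported
bilayers resolves individual pores as they appear and grow, and shows that
assembly separates into two very different timescales — a slow insertion of
the *first* C9 and a fast oligomerisation of the remaining 17. This package
implements that analysis for researchers working on pore-forming proteins:

* **detection & tracking** — pores are found per frame by normalised 2D
  cross-correlation against a complete-pore template (threshold 0.6) and
  linked into tracks with a maximum linking distance (~30 px) and gap
  closing;
* **oligomerisation time** — each track's cropped average-height trace is
  Savitzky–Golay smoothed and fitted with the sigmoid
  `f(t) = A·tanh((t − t₀)/τ) + B`; the transition width `τ_olig = 3τ`
  (covering tanh(1.5) ≈ 90% of the amplitude) measures the time to add the
  17 propagating C9s, `τ₊ = τ_olig/17`;
* **initiation time** — the cumulative pore count is fitted with
  `A(1 − exp(−t/τ_init))`, the appearance curve of exponentially
  distributed first insertions;
* **kinetic model** — characteristic times convert to rate constants
  `k = 1/(τ·[C9])`; the occupancy distribution pₙ(t) of a growing pore
  obeys the linear birth chain `dp₁/dt = −k₊[C9]p₁`,
  `dpₙ/dt = k₊[C9](pₙ₋₁ − pₙ)`, with absorbing state n = 18, and the mean
  oligomer size grows at the constant rate `k₊[C9]` until absorption;
* **synthetic movies** — because raw AFM movie data of this kind is not
  publicly deposited, a first-class generator renders stochastic assembly
  trajectories (exponential initiation, Erlang propagation) as AFM-like
  height-map movies with known ground truth, so every stage is validated
  by parameter recovery.

## Worked example

Simulate a 500-frame, 256×256 px movie (2 nm/px, 6.5 s/frame) at the
measured MAC rate constants `k_init = 0.78 s⁻¹ mM⁻¹`,
`k₊ = 108 s⁻¹ mM⁻¹`, `[C9] = 1.4 µM`, and run the complete analysis:

```bash
mackinetics run-all --seed 0 --outdir demo_run
```

which prints (abridged):

```json
{
  "kinetics": {
    "tau_init_s": 1067.47,
    "tau_olig_s": 111.65,
    "tau_plus_s": 6.57,
    "k_init_per_s_mM": 0.669,
    "k_plus_per_s_mM": 108.76,
    "timescale_ratio": 162.5
  },
  "n_tracks_curated": 50,
  "oligomerization": {"n": 20, "tau_olig_mean_s": 111.65, "tau_olig_sem_s": 7.84}
}
```

Reading the numbers: the pipeline re-detected all 50 simulated pores,
measured a mean oligomerisation time of ~112 s over the isolated events
(so ~6.6 s per C9 addition), and an initiation time of ~1070 s — recovering
both generating rate constants (`k̂_init = 0.67`, `k̂₊ = 108.8 s⁻¹ mM⁻¹`)
within the stochastic scatter of a single movie containing 50 initiation
events. The timescale ratio τ_init/τ₊ ≈ 160 ≫ 1 is the signature that the
first C9 insertion is the kinetic bottleneck of MAC formation.

The same stages are available individually (`simulate`, `preprocess`,
`detect`, `track`, `fit-traces`, `kinetics`) and as a Python API built
around model/results pairs:

```python
import numpy as np
from mackinetics import solve_occupancy, growth_slope

occ = solve_occupancy(k_plus=108.0, c9=1.4e-3, times=np.linspace(0, 120, 241))
print(occ.mean_n[:3], growth_slope(occ))   # ⟨n⟩(t) and its early-time slope
```

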