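# mesosaxs

Bragg-peak fitting, mesophase identification and photoswitching-kinetics
analysis for 1D small-angle X-ray scattering (SAXS) of lyotropic lipid
mesophases.

Lipid/water systems assemble into ordered mesophases — multilamellar
stacks, bicontinuous cubics (Pn3m "double diamond", Im3m "primitive"),
inverse hexagonal — whose reduced SAXS curves show Bragg peaks at

    q_hkl = 2π·m / a,   m = n (lamellar),  √(h²+k²+l²) (cubic),  √(h²+hk+k²) (hexagonal)

with characteristic allowed-ratio sequences (lamellar 1:2:3…, Pn3m
√2:√3:√4:√6:√8:√9, Im3m √2:√4:√6:√8:√10:√12). Identifying which phase —
or which *coexistence* of phases — produced an observed peak list, and
extracting each lattice parameter `a` with an honest uncertainty, is the
routine but error-prone core of such experiments. Samples doped with
photoswitchable (azobenzene) amphiphiles add a second question: when the
switch isomerizes under illumination, how fast does one mesophase convert
into another?

`mesosaxs` is for experimentalists reducing such data. It provides:

* **`mesosaxs.phases`** — allowed-reflection tables generated from
  extinction rules, and lattice estimation by weighted through-origin
  regression of peak positions against spacing ratios.
* **`mesosaxs.peaks`** — peak detection and joint Gaussian +
  local-background fitting (lmfit), with residual-driven recovery of
  blended reflections.
* **`mesosaxs.indexing`** — combination search over candidate phase sets,
  ranking explanations by unexplained peaks *and* predicted-but-absent
  reflections, with uncertainty-aware lattice estimates and explicit
  reporting of near-degenerate alternatives.
* **`mesosaxs.kinetics`** — per-frame reflection tracking normalized to a
  spectator reference peak, onset/completion detection, and lamellar
  d(t) trending.
* **`mesosaxs.synthetic`** — a seeded generator of patterns and kinetic
  series with ground-truth sidecars.
* **`mesosaxs.io`** — 3-column ASCII curves, series manifests, and an
  NXcanSAS-inspired HDF5 result container.
* A CLI: `mesosaxs simulate | analyze | kinetics`.

## Worked example

Simulate a three-phase coexistence — a lamellar stack (a = 6.9 nm)
alongside Pn3m (11.6 nm) and Im3m (12.7 nm) cubics — with Poisson
counting noise, then run the full analysis chain:

```python
import warnings
from mesosaxs import (PhaseSpec, NoiseSpec, generate_pattern,
                      detect_peaks, fit_peaks, index_phases)
from mesosaxs.peaks import significant

pattern = generate_pattern(
    [PhaseSpec("lamellar", 6.9, amplitude=2000),
     PhaseSpec("Pn3m", 11.6, amplitude=1200),
     PhaseSpec("Im3m", 12.7, amplitude=800)],
    NoiseSpec(model="poisson", seed=1))

peaks = significant(fit_peaks(pattern, detect_peaks(pattern)))
ranked = index_phases(peaks, q_range=(pattern.q[0], pattern.q[-1]))

print(f"{len(peaks)} significant peaks")
top = ranked[0]
for name, est in sorted(top.phases.items()):
    print(f"  {name:9s} a = {est.a:6.2f} +/- {est.sigma_a:.2f} nm "
          f"({est.n_peaks} reflections)")
print(f"  unexplained peaks: {top.n_unexplained}")
```

Output:

```
12 significant peaks
  Im3m      a =  12.72 +/- 0.02 nm (5 reflections)
  Pn3m      a =  11.59 +/- 0.01 nm (3 reflections)
  lamellar  a =   6.90 +/- 0.00 nm (4 reflections)
  unexplained peaks: 0
```

Twelve fitted peaks (several reflections blend at this resolution and are
deconvolved jointly) are explained without remainder by exactly the three
generating phases, and each lattice parameter is recovered to well within
1%. Ranked alternatives below the top assignment show how unambiguous the
identification is — with sparse peak lists several cubic aspects can fit,
and the ranking keeps that visible instead of hiding it.

The same chain runs from the shell on directories of `.dat` curves:

```bash
mesosaxs simulate --out fixtures --seed 7
mesosaxs analyze  --manifest fixtures/static/manifest.csv  --out results
mesosaxs kinetics --manifest fixtures/kinetic/manifest.csv --out results \
    --lattice lamellar=6.9 --lattice Pn3m=11.6 --lattice Im3m=12.7
```

`analyze` writes a ranked-assignment JSON report, a CSV summary
(phase, a ± σ per pattern) and an HDF5 container per sample; `kinetics`
writes normalized intensity traces and an onset/completion summary.

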