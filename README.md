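# flimsort

Identify microplastic particles directly in environmental material — no
extraction step — from a single frequency-domain fluorescence-lifetime
(FD-FLIM) image. `flimsort` implements the complete evaluation chain for
pco.flim-style 5-layer lifetime stacks: per-pixel lifetimes from phase shift
and modulation index, spectral pre-analysis with ideal LP/BP emission
filters, Gaussian lifetime characterization of homogeneous calibration
samples, and a lifetime-window classification pipeline that separates a
target polymer (HDPE) from natural materials (spruce, grass, soil), reports
each material's relative share of the frame, and sizes individual particles.
A ground-truth scene simulator makes every stage testable without an
instrument.

## The physics in one paragraph

Under sinusoidally modulated excitation at frequency *f* (ω = 2π·*f*, here
30 MHz), a fluorophore's emission lags the excitation by a phase φ and is
demodulated by the index *M* = (b/a)/(B/A). For a single-exponential decay,

    τ_PH = tan(φ) / ω        τ_M = √(1/M² − 1) / ω

Each camera pixel measures intensity *I*, φ and *M*, giving two independent
per-pixel lifetime estimates — a 1004 × 1008 stack of five layers.
Lifetimes are material-characteristic on the ns scale: with a 495–550 nm
band-pass emitter, HDPE sits at 3.52 ± 0.21 ns and spruce at 1.40 ± 0.12 ns,
so the windows μ ± 3σ are disjoint and pixel membership classifies the
material. Grass emits only above 680 nm (chlorophyll *a*) and is removed
entirely by the band-pass filter; dim soil falls below the 10 % intensity
gate.

## Worked example

```python
import flimsort as fs

# synthetic chips-on-soil scene at 2x magnification (2.8 um/px)
spec = fs.experiment_iv_scene(seed=1)
stack, labels = fs.render_stack(spec)

materials = [
    fs.material_range(fs.GaussianFit(3.52, 0.21, 10**6), name="HDPE"),
    fs.material_range(fs.GaussianFit(1.40, 0.12, 10**6), name="spruce"),
]
result = fs.classify(stack, materials)
for name, m in result.materials.items():
    p = m.particles[-1]
    print(f"{name}: share {m.relative_share_percent:.2f} %  "
          f"tau {m.fit.mu:.2f} +/- {m.fit.sigma:.2f} ns  "
          f"smallest particle {p.height_um:.0f} x {p.width_um:.0f} um")
```

prints

```
HDPE: share 1.56 %  tau 3.52 +/- 0.21 ns  smallest particle 70 x 98 um
spruce: share 8.35 %  tau 1.40 +/- 0.12 ns  smallest particle 252 x 1176 um
```

The recovered shares match the labelled ground truth (1.57 % / 8.36 %) to
within the morphological edge loss, the lifetime statistics reproduce the
generating distributions, and the smallest HDPE chip — drawn at the 25 × 35
px detection limit — comes back at exactly its true 70 × 98 µm bounding box
(25 × 35 px at 2.8 µm/px).

The same pipeline is scriptable from the shell:

```bash
flimsort simulate --scene experiment4 --out sim/ --seed 1
flimsort fit --stack calib_hdpe.tif --name HDPE --out materials.csv
flimsort classify --stack sim/stack.tif --materials materials.csv --out results/
flimsort spectra rep1.csv rep2.csv --background bg.csv --filter BP495-550 --out peaks.csv
```

## Acceptance script

`scripts/acceptance.py` recomputes the package's reference check from
scratch — the phase round trip of the 3.75 ns calibration-slide lifetime at
30 MHz through the forward model and the phase-lifetime equation — and
writes the result as JSON:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

## Documentation

See `docs/methods.md` for the model assumptions, parameter defaults, the
synthetic-scene generator's scope, and numerical choices.
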