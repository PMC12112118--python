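# ohfate

Semiempirical prediction of pollutant fate during electrochemical advanced
oxidation (EAOP), for environmental chemists and process engineers who want
to know — before running a 5-hour electrolysis — how much pollutant will be
removed, what intermediates will build up, how much carbon ends up as CO₂,
and how toxic the treated water is along the way.

## The model

Anodic oxidation degrades organics through hydroxyl radicals (•OH) generated
at the electrode. •OH is too short-lived to measure directly, but it sits in
a fast recombination equilibrium with H₂O₂ (2 •OH ⇌ H₂O₂), so the normalised
radical level can be read off the easily measured peroxide curve:

    [•OH]*(t) = k · f(t),    f(t) = B₀ + B₁t + B₂t² + B₃t³

where f is a cubic smoothing of the measured normalised H₂O₂ series and the
proportionality factor k is a characteristic of the electrode that scales
linearly with current density j: k(j) = (6.48·10⁻¹² cm²/mA)·j + 8.55·10⁻¹².

Degradation is modelled as a lumped sequential chain of second-order steps —
for bisphenol A (BPA): parent → two-ring intermediates (P_tr) → one-ring
intermediates (P_or) → CO₂, with rate constants k_S, k_B, k_M in 1/(M·s):

    d[BPA]*/dt = −k_S·[BPA]*·[•OH]
    d[P_tr]*/dt = k_S·[BPA]*·[•OH] − k_B·[P_tr]*·[•OH]
    d[P_or]*/dt = k_B·[P_tr]*·[•OH] − k_M·[P_or]*·[•OH]
    d[CO₂]*/dt = k_M·[P_or]*·[•OH]

Mass is conserved exactly. In the radical exposure u(t) = ∫[•OH]dt the chain
is a linear decay cascade with a closed-form (Bateman) solution, which the
package uses as an exact oracle for its numerical trajectories. Rate
constants are estimated from measured pool profiles by bounded nonlinear
least squares (trust-region reflective), and the time-dependent toxicity of
the mixture is an additive toxic-unit sum over the pools, Toxicity%(t) =
100·(LC₅₀ᵣₑf/Mᵣₑf)·Σᵢ xᵢ*(t)·Mᵢ/LC₅₀ᵢ, built from per-compound molar masses
and 96-h Fathead Minnow LC₅₀ values.

## Worked example

```python
import numpy as np
import ohfate as of

sc = of.builtin_scenario("bpa15")           # BPA, 15 mA/cm2, 5 h
grid = np.linspace(0.0, 18000.0, 61)
traj = of.simulate_chain(sc.system, sc.constants, sc.profile, grid)
print(f"5-h BPA removal: {100 * of.removal_fraction(traj, 'BPA', 18000):.1f}%")

k20 = of.k_of_j(of.PRINTED_CURRENT_LAW, 20.0)
traj20 = of.simulate_chain(sc.system, sc.constants,
                           of.OhProfile(sc.poly, k20, 1.31e-4), grid)
pot = of.potencies_from_table(of.load_lc50_table(), sc.system.species_names)
tox = of.toxicity_profile(traj20, pot, of.ToxRecord("Bisphenol A", 228.29, 3.24))
peak, t_peak, reduction = of.toxicity_summary(grid, tox)
print(f"at 20 mA/cm2: toxicity peaks at {peak:.1f}% after {t_peak/3600:.1f} h, "
      f"5-h reduction {reduction:.1f}%")
```

prints

```
5-h BPA removal: 91.0%
at 20 mA/cm2: toxicity peaks at 104.3% after 0.6 h, 5-h reduction 93.6%
```

The removal reproduces the measured 92.3% endpoint to within the model's
error; the toxicity profile shows the characteristic biphasic shape — a
small early rise while the more potent two-ring intermediates accumulate,
then a steep decline as they mineralise.

The same pipeline is scriptable from the shell:

```sh
ohfate simulate bpa15 -o traj.csv
ohfate toxicity traj.csv bpa15 -o tox.csv
ohfate sweep bpa15 -j 2.5,5,10,15,20 -o sweep/
ohfate --seed 7 synth bpa15 --sigma 0.04 -o noisy.csv
ohfate fit-rates noisy.csv bpa15 -o fit.json
```

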