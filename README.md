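# deerfit

Analysis stack for resolving proton-coupled conformational equilibria of
membrane transporters from pulsed EPR distance measurements and structural
models.

Double electron–electron resonance (DEER/PELDOR) on pairs of nitroxide spin
labels reports the distribution P(r) of inter-label distances in the
1.5–8 nm range. For a proton-coupled transporter — an MFS-fold antiporter
cycling between inward-facing and occluded states, say — decays recorded on
the same labelled pair across a pH series encode how the conformer
populations titrate, and hence the pK and cooperativity of the protonation
events that drive alternating access. `deerfit` implements that entire
analysis, plus the structural side: predicting P(r) from a PDB model with
an accessible-volume spin-label model, and quantifying domain motions in
trajectories through orientation collective variables, salt-bridge series
and DEER-restraint energies.

## The model

A dipolar trace is

    V(t) = B(t) · [(1 − Δ) + Δ ∫ K(t, r) P(r) dr]

with the orientation-averaged point-dipole powder kernel
K(t, r) = ∫₀¹ cos[(1 − 3u²)·2πD·t/r³] du (D = 52.04 MHz·nm³, evaluated in
closed form via Fresnel integrals), a stretched-exponential intermolecular
background B(t) = exp(−κ t^(d/3)), and modulation depth Δ.

P(r) is a sum of Gaussians. Decays of the same pair under different
conditions are fitted **globally**: component centers r₀ₖ and widths σₖ are
shared across conditions (conformer geometry is condition-independent),
populations a_{c,k} are free per condition, and (κ, d, Δ) are free per
trace. The number of components is selected by BIC (AICc optional) and
pointwise 2σ confidence bands on P(r) follow from delta-method propagation
of the fit covariance (a seeded parametric bootstrap is available as a
cross-check).

State populations across pH are then fitted with a generalized Hill curve

    f(pH) = f_base + (f_acid − f_base) / (1 + 10^{n (pH − pK)})

whose midpoint pK and Hill coefficient n (n = 1 ⇒ independent protonation
events) summarize the conformational titration.

## Worked example

Simulate a two-state titration dataset (known truth), fit it globally, and
recover the pK:

```python
import numpy as np
import deerfit as df

spec = df.EquilibriumSpec(
    state_a=[df.GaussianComponent(3.0, 0.3, 1.0)],   # intracellular-closed
    state_b=[df.GaussianComponent(4.5, 0.3, 1.0)],   # inward-facing open
    pK=7.0, hill_n=1.0,
    pH_values=(5.0, 6.0, 6.5, 7.0, 7.5, 8.0, 9.0),
    noise_sigma=0.007, seed=42,
)
conditions, truth = df.generate_deer_dataset(spec)

result = df.fit_global(conditions, 2)
print("shared centers (nm):", np.round(result.centers, 3))
print("shared widths  (nm):", np.round(result.widths, 3))
for label, pops in zip(result.condition_labels, result.populations):
    print(f"{label:>6}: closed-state population = {pops[0]:.3f}")

fits = [(tr.meta["pH"], result, c) for c, tr in enumerate(conditions.traces)]
series = df.titrate_from_fits(fits, 0)
fit = df.hill_fit(series)
print(f"pK = {fit.pK:.2f} +/- {fit.pK_sigma2:.2f} (2 sigma)")
print(f"Hill n = {fit.n:.2f} +/- {fit.n_sigma2:.2f}")
```

Output:

```
shared centers (nm): [2.998 4.499]
shared widths  (nm): [0.298 0.301]
   pH5: closed-state population = 0.995
   pH6: closed-state population = 0.917
 pH6.5: closed-state population = 0.762
   pH7: closed-state population = 0.514
 pH7.5: closed-state population = 0.239
   pH8: closed-state population = 0.085
   pH9: closed-state population = 0.000
pK = 7.02 +/- 0.08 (2 sigma)
Hill n = 1.09 +/- 0.20
```

The global fit recovers the generating centers (3.0 / 4.5 nm) and widths
(0.3 nm) to a few thousandths of a nm, the per-pH populations follow the
Hill curve, and the titration fit returns the true pK of 7.0 with a Hill
coefficient consistent with 1 — independent protonation.

The same run is available from the shell:

```sh
deerfit run --out run1 --seed 42
```

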