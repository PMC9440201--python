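# Methods

This note records the models implemented in `deerfit`, the choices made
where the underlying methodology is genuinely open, and what the synthetic
validation studies do and do not demonstrate.

## Forward model

A four-pulse DEER decay is factorized as
V(t) = B(t)·[(1 − Δ) + Δ·∫K(t,r)P(r)dr], the standard separation of the
intramolecular dipolar signal from the intermolecular background.

**Kernel.** The powder-averaged point-dipole kernel
K(t,r) = ∫₀¹ cos[(1 − 3u²)·ω(r)·t] du with ω = 2πD/r³ and
D = 52.04 MHz·nm³ (nitroxide pair, ideal complete pump excitation;
orientation selection and excitation bandwidth are not modelled). The
integral is evaluated in closed form,
K = √(π/6x)·[cos x·C(q) + sin x·S(q)] with x = ωt, q = √(6x/π) and C, S
the Fresnel integrals (scipy.special.fresnel), with K → 1 as x → 0. A
fixed-node quadrature was rejected: at r = 1.5 nm and t = 6 µs the
integrand oscillates ≈ 90 periods over u ∈ [0, 1], where a few hundred
Gauss–Legendre nodes leave errors of order 0.1 while the closed form is
exact to machine precision (verified against a 10⁶-point Riemann sum;
max deviation ~1e-10 over a 20×20 (t, r) grid).

**Background.** Stretched exponential B(t) = exp(−κ·t^(d/3)), κ ≥ 0,
d ∈ [2, 3.5]. d = 3 is a homogeneous three-dimensional spin bath;
deviations describe restricted geometries, and nanodisc samples at acidic
pH show steeper decays (larger κ) from reversible particle clustering. By
default d is held at 3 and only κ is fitted: on traces of a few µs,
κ and d trade off almost perfectly (t^(d/3) vs κ near-degeneracy), and
releasing d costs precision on every other parameter without improving
the fit of d = 3 data. `vary_background_dim=True` releases it per trace.

**Units.** Time µs, distance nm, frequency MHz throughout the signal
model; structure coordinates are Å internally with nm at the distance
interface (exact ×0.1).

**Distance grid.** Default 1.5–8.0 nm, 0.02 nm step — the sensitivity
window of nitroxide DEER. Gaussian components are renormalized per
component on the grid, so populations keep their meaning even when a
component's tails are clipped at the grid edges.

## Global Gaussian fitting

Decays of one spin pair under several conditions are fitted jointly:
centers and widths shared, populations per condition, background and
modulation depth per trace. This mirrors the physical picture that
conformer geometry is condition-independent while occupancy is not.

- **Population parameterization.** Per-condition softmax over K − 1
  logits (last logit pinned to 0). Σₖ a_ck = 1 holds exactly, the
  optimization stays unconstrained and smooth, and population
  uncertainties follow from the softmax Jacobian. Logits are bounded at
  ±12 (populations ≥ ~6e-6) to keep the Jacobian finite.
- **Optimizer.** scipy.optimize.least_squares (TRF) with analytic
  Jacobians for all parameters; bounds r₀ ∈ grid range,
  σ ∈ [0.05, 1.5] nm, Δ ∈ [0.02, 0.8], κ ∈ [0, 20], d ∈ [2, 3.5].
- **Multi-start.** 8 restarts: centers seeded evenly over the grid
  interior, jittered by a seeded generator on later restarts; initial
  depths cycle over {0.3, 0.45, 0.2, 0.6}; lowest objective wins.
- **Model selection.** Information criterion on the concatenated
  residuals with per-trace Gaussian noise variance estimated from the
  fit: Σ_t N_t ln(RSS_t/N_t) + p·ln(ΣN_t) (BIC, default) or the AICc
  analogue. Candidate K = 1..K_max (default 4); ties break toward
  smaller K. Each K warm-starts from the best K−1 solution plus a small
  extra component at the largest center gap, which makes the objective
  non-increasing in K. The criterion choice is configurable because the
  original analysis protocol this emulates states only that *a*
  statistical criterion was used; BIC's parsimony matches the small
  component counts (1–3) typical of these data.
- **Degenerate traces.** A fitted modulation depth at its lower bound
  flags the trace as background-dominated (warning recorded in the
  result); P(r) is then unconstrained by the data.

**Uncertainty.** Parameter covariance is (JᵀWJ)⁻¹ (pseudo-inverse) with
per-trace weights 1/σ̂_t², σ̂_t estimated from the fit residuals with a
degrees-of-freedom correction. Pointwise 2σ bands on P(r) come from
first-order (delta-method) propagation through the mixture density; the
lower band is clipped at 0. By default the full covariance is used, so
correlations with background/depth parameters widen the band; inverting
the shape-parameter block alone (backgrounds treated as known) is
available. A seeded parametric bootstrap (simulate from the fitted model
at the estimated noise, refit warm-started, take pointwise SDs) provides
an independent band; on matched cases the two agree within a factor of
~2 in half-width, and the delta-method band's pointwise coverage of the
true P(r) measures 0.95–0.96 at nominal 0.954 in the 200-replicate
calibration study.

## Titration analysis

Populations vs pH are fitted with
f(pH) = f_base + (f_acid − f_base)/(1 + 10^{n(pH − pK)}); a single-site
protonation equilibrium is exactly the n = 1 member of this family, so
the recovered Hill coefficient reads directly as cooperativity. Both
plateaus are free by default (the emulated protocol does not state its
plateau handling; free plateaus are recorded in every report), and n can
be fixed (e.g. at 1). Weights are inverse-variance from the 2σ population
uncertainties, floored at 5% of the median uncertainty so a
near-noiseless point cannot dominate; equal uncertainties reduce exactly
to the unweighted fit. Fits report 2σ uncertainties from the weighted
Jacobian with residual variance scaling. The reported n is canonicalized
positive (the plateaus carry the direction); a constant series raises an
unidentifiability error rather than returning an arbitrary pK.

## Spin-label distance prediction

The rotamer ensemble of a methanethiosulfonate nitroxide label is
approximated by accessible-volume sampling: unpaired-electron candidates
at tether length L = 7.0 Å from CB, uniform over the cone of half-angle
90° about the CA→CB axis, with candidates within 2.5 Å of any heavy atom
outside the labelled residue rejected and survivors weighted uniformly
(2000 samples per site; all parameters configurable). Temperature
weighting reduces to uniform weights in this model. The sampling frame is
built from the residue's own N/CA/CB atoms, so clouds are exactly
invariant under rigid-body motion of the structure. Multi-model
structures pool per-model clouds with equal weights. This is a
deliberately simple stand-in for full rotamer-library energetics:
agreement with library-based predictions is qualitative, and the model's
role here is comparing predicted and fitted P(r) via the overlap
coefficient ∫min(P₁,P₂)dr.

Distance distributions between clouds deposit the weighted pairwise
distances by linear binning (exactly mean-preserving) and smooth with a
Gaussian (default σ = 0.05 nm, truncated at the grid edges).

## Conformational metrics

- **Domain split.** By-sequence (ordered residues halved, odd counts put
  the extra residue in the first/intracellular half) or by-z (median CA
  z within the domain; lower-z half intracellular when the membrane
  normal points to +z).
- **α/β angles.** α is the angle at the center of mass of the
  extracellular half of the whole protein between the centers of mass of
  the intracellular half-domains; β is the extracellular mirror image.
  Default all-atom mass-weighted centers (CA-only and geometric centers
  available — the emulated protocol does not state which was used).
- **Salt bridges.** Per-frame minimum over donor-N (Arg NE/NH1/NH2,
  Lys NZ) × acceptor-O (Asp OD1/OD2, Glu OE1/OE2) distances; centered
  moving average with edge truncation; formed fraction below a 4.0 Å
  cutoff (the conventional criterion; configurable). Frames with missing
  side-chain atoms become NaN entries, excluded from averages and
  reported.
- **Restraint energy.** E = Σ ½k(d − d_target)² with k in kcal/mol/Å²
  (default 10, the refinement value) and displacements in Å. The ½k
  convention is the standard harmonic form; `half_factor=False` gives
  k(Δd)² since a bare "force constant" does not disambiguate the two.
  Only this bookkeeping energy is computed — ensemble-restrained MD
  itself is out of scope.

## Synthetic data

Generators are pure functions of (parameters, seed); sub-seeds derive
deterministically per condition, and every generator returns a
machine-readable truth record. The default DEER emulation uses two
conformers at 3.0 and 4.5 nm (σ 0.3 nm) exchanging through a Hill
equilibrium, populations sweeping ~0.99→0.01 across pH 5→9 around
pK 7, Δ = 0.35, κ = 0.15 µs⁻¹ (tripled at acidic pH when the steep
nanodisc background is enabled), 3 µs traces of 300 points, and additive
white Gaussian noise (σ = 0.007 ⇒ SNR Δ/σ = 50). Not emulated: phase
errors, dead time, ESEEM artifacts, orientation selection, and
correlated noise — so passing recovery tests demonstrates correctness of
the estimators under the stated noise model, not robustness to
spectrometer artifacts, which are assumed to be handled upstream.

Toy structures are ideal poly-Ala helices (rise 1.5 Å, twist 100°/res,
CA radius 2.3 Å) on a circle, with N/CA/C/O/CB per residue; salt-bridge
trajectories place an Arg/Asp pair whose minimum N–O distance follows a
formed→broken step schedule exactly (± optional jitter along the contact
axis).

## Validation studies and problem sizes

`deerfit.validation` (exercised by the test suite and
`scripts/acceptance.py`) runs: kernel vs 10⁶-point Riemann oracle on a
20×20 (t,r) grid; noiseless single-site Hill recovery (returns n = 1.00);
50 seeded bimodal two-condition datasets at SNR 50 with model selection
over K ≤ 3 (center RMSE ~0.008 nm, population RMSE ~0.008, correct K in
100% of runs); 200-replicate 2σ-band coverage (~0.95); and 30-seed
end-to-end pK recovery (mean |Δ pK| ~0.007). K_max = 3 covers the under-
and over-fitting alternatives around the true K = 2 at these sizes.

## Known limitations

- No Tikhonov/model-free inversion; distributions far from a small
  Gaussian mixture are out of model.
- The delta-method band is first-order: strongly nonlinear regimes (very
  low SNR, overlapping components) should use the bootstrap band.
- The accessible-volume label model ignores rotamer energetics and
  tether flexibility beyond the cone constraint.
- Global fits assume per-trace white Gaussian noise of unknown constant
  variance.
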