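# Methods

`ciiros` is a mass-action kinetic model of electron transfer and reactive
oxygen species (ROS) production by mitochondrial respiratory Complex II
(succinate:ubiquinone oxidoreductase, SDH) in its assembled and disintegrated
states, together with a steady-state solver, sweep machinery along the
experimentally accessible axes, and a least-squares calibration harness.

## The model

### Reaction network

The network treats each redox centre of the enzyme as an independent
well-mixed pool (flavin, [2Fe-2S], [4Fe-4S], [3Fe-4S], heme b, the
Q-binding site), coupled by bimolecular electron-transfer reactions.  The
assembled enzyme carries reactions 1–29 plus a hydrogen-peroxide efflux step
(rid 30):

* **Dicarboxylate site (1–5).** Succinate binds oxidised FAD (1), hydride
  transfer reduces the flavin and oxidises succinate to fumarate (2),
  fumarate is released (3).  Fumarate can also form a dead-end complex with
  oxidised FAD (4), and succinate binds reduced FADH2 (5) — the *occupied*
  FADH2 state is catalytically shielded and produces no ROS.
* **One-electron relay (6–8 first electron, 14–16 second).** FADH2 gives one
  electron to [2Fe-2S], forming the semiquinone radical FADH•; the electron
  hops through [4Fe-4S] (thermodynamically uphill, hence always near
  equilibrium) to [3Fe-4S].  The second electron follows the same relay from
  FADH•.
* **The heme-b / Q-site thermodynamic cycle (9–13, 17–21).** Reduced
  [3Fe-4S]⁻ passes the first electron to the bound quinone either via heme b
  (9, 11) or directly (13); the bound semiquinone anion is protonated (12).
  The second electron follows the analogous triangle (17, 18, 21), the
  quinolate is protonated (19) and ubiquinol is released to the membrane
  pool (20) — the rate v20 is the SQR (succinate:quinone reductase) output.
* **Q pool and Complex III (10, 29).** Oxidised ubiquinone binds the Q site
  (10); Complex III is lumped into a single first-order oxidation of pool
  ubiquinol, v29 = k29·[QH2].  CIII inhibition is modelled by decreasing
  k29.
* **Inhibitor (27).** Atpenin A5 binds the empty Q site reversibly, in
  direct competition with ubiquinone.
* **ROS bypasses (22–26) and sinks (28, 30).** Unoccupied FADH2 reduces O2
  by two electrons to H2O2 (22, irreversible) or by one electron to
  superoxide (23, reversible); FADH• (24), [3Fe-4S]⁻ (25) and the bound
  semiquinone (26) produce superoxide reversibly.  Superoxide dismutates,
  two O2⁻ giving one H2O2 (28), and H2O2 leaves the matrix (30), so a true
  steady state exists.  The reported total H2O2 release is the identity
  vH2O2tot = v22 + v22d + v28, which at steady state equals v30.

Disintegration splits the enzyme into the soluble SDHA/SDHB subcomplex —
which keeps the dicarboxylate chemistry, the relay and the flavin/cluster
ROS bypasses (1d–8d, 14d–16d, 22d–25d) but has lost the quinone acceptor —
and the membrane SDHC/SDHD anchor, which keeps heme b and the Q site
(10d–12d, 18d–20d, 26d, 27d) but has no electron source.  The anchor's
reactions let it equilibrate with the Q/QH2 pool; in the absence of an
electron supply they carry zero net flux at every steady state reached from
oxidised initial conditions.  Both fragment families share the Q pool, O2,
superoxide, H2O2, succinate and fumarate with the assembled enzyme, giving
53 reactions and 48 dynamic species in the mixed network.

The published model this package re-implements states 35 ODEs and 15 moiety
conservation relations; its full reaction list lives in supplementary
material that is not reproduced in the main text.  The network
reconstructable from the main text has 53 reactions and 35 independent ODEs
but 13 conservation relations (six assembled pools, four SDHA/SDHB pools,
the anchor site pool, the anchor heme pool and the quinone pool).  The two
missing relations presumably involve species of the supplementary reaction
list that the main text does not name; the corresponding acceptance check is
left failing rather than padded with artificial species.

### Thermodynamic consistency

Equilibrium constants of electron transfers are never free parameters: each
is derived from the midpoint potentials of its donor and acceptor couples
through the Nernst relation, Keq = exp(n·ΔEm·F/RT), with RT/F = 25 mV.  This
guarantees the Wegscheider condition (unit product of equilibrium constants
around any closed cycle) globally and by construction — in particular
Keq13 = Keq9·Keq11 and Keq21 = Keq17·Keq18 for the two three-reaction loops
of the [3Fe-4S] ↔ heme b ↔ bound-Q cycle.  The [3Fe-4S] and bound-semiquinone
midpoints are back-computed from the published equilibrium constants
(Keq9 = 5.55×10⁻⁵, Keq11 = 2.72, Keq18 = 3.269×10⁶ at Em(b) = −185 mV), so
those values hold exactly, and `apply_em_b` moves only the heme midpoint:
Keq9/Keq17 scale by exp(+ΔEm/25), Keq11/Keq18 by exp(−ΔEm/25), Keq13/Keq21
stay put, and the cycles remain balanced for any Em(b).

RT/F = 25 mV exactly reproduces the published conversion factor
exp(221/25) = 6905 for the Em(b) = −185 → +36 mV shift.  Changing
`rt_over_f` re-derives all electron-transfer Keqs, but the three midpoints
above are calibrated at 25 mV.

### Parameters

Units: μM for concentrations, s⁻¹ and μM⁻¹s⁻¹ for rate constants, μM/s for
fluxes, mV for potentials.  No conversion to the experimental
pmol·min⁻¹·mg⁻¹ axis is attempted; a single scale factor can be applied
externally when plotting against experimental data.

Hard (printed) defaults: k22 = 0.027 and k23 = 0.019 μM⁻¹s⁻¹ (flavin ROS
catalytic constants), k29 = 1 s⁻¹ (basal CIII turnover; 0.005 s⁻¹ for
strong inhibition), CIIt = 235 μM (97 μM for the CIII-inhibition
comparison; 100 + 135/135 μM for the mixed assembled/disintegrated case),
Em(b) = −185 mV, and the three Keq values quoted above.  Everything else is
tagged `estimated` in `ciiros.params.PROVENANCE` and was chosen from
literature ranges, then calibrated — exactly as the original study
calibrated its own constants — so that the model reproduces the *printed*
steady-state outputs rather than any figure digitisation.  The decisive
calibrated choices:

* **Flavin one-electron midpoints (−145/−135 mV).**  The reduced heme-b
  level at saturating succinate (≈12 μM of 235, i.e. [3Fe-4S]⁻/[3Fe-4S] ≈
  970 via Keq9) together with a low basal flavin-site ROS rate forces the
  flavin couples well below the succinate/fumarate couple: electron
  pressure then transmits through a nearly *oxidised* flavin pool.  With
  higher flavin midpoints the two observations are mutually exclusive.
* **Fast intra-complex electron transfer (relay ≥ 10³, heme cycle
  10⁵–10⁶ μM⁻¹s⁻¹).**  Keeps the [3Fe-4S] ↔ b ↔ Q cycle at
  quasi-equilibrium, which is what makes v20 and vH2O2tot invariant (to
  ~10⁻⁸ relative) under the Em(b) shift while the heme poise swings from
  5% to 98% reduced.
* **Semiquinone protonation (k12 = 85 μM⁻¹s⁻¹ with H⁺ clamped at pH 7.2)**
  sets the bound-semiquinone level that anchors the [3Fe-4S] poise and
  hence the absolute reduced-heme concentration.
* **Succinate binding (Kd ≈ 280 μM at FAD, 60 μM at FADH2)** places the
  apparent Km of the SQR output in the few-hundred-μM range and the
  inhibited ROS optimum at subsaturating succinate.
* **Dismutation k28 = 2 μM⁻¹s⁻¹** (spontaneous-dismutation scale;
  submitochondrial particles retain little dispersed SOD).  The resulting
  superoxide level feeds the reverse one-electron flavin reactions, which
  is what makes k22 and k23 separately identifiable from total-H2O2 data.

Clamped boundary species: succinate and AA5 (the experimental axes), O2
(30 μM), H⁺ (pH 7.2) and fumarate (trace, 0.002 μM — an initial-rate assay
without added fumarate).  Clamping fumarate near zero matters: the
succinate/fumarate couple sets the thermodynamic ceiling of the whole
relay's reduction poise.

### Numerics

The ODE system is integrated with BDF (rate constants span ~10 decades).
Steady states are found by damped Newton iteration on the
conservation-reduced system: the state is parameterised on the affine
manifold fixed by the moiety totals, the step is controlled by Deuflhard's
affine-invariant natural-monotonicity test, and stalls switch to
pseudo-transient continuation.  Steps that cross the non-negative orthant
are clipped and the totals re-projected on convergence.  Rate laws are
evaluated in 80-bit extended precision: near-equilibrium transfers make the
net rate a ~10⁻⁹-relative difference of two huge unidirectional terms, and
double precision alone cannot reach the 10⁻⁹ μM/s residual tolerance.
Defaults: integrator rtol 10⁻⁸ / atol 10⁻¹² μM, Newton residual 10⁻⁹ μM/s,
all overridable.  Sweeps warm-start each point from the previous solution
and fall back to relaxation integration; failed points are flagged in the
result rather than dropped.

Curve classification calls a succinate response "bell" when an interior
maximum exceeds both endpoints by 5% relative (robust against solver
noise); otherwise a Michaelis–Menten fit by nonlinear least squares
(initialised from the half-max crossing — a double-reciprocal transform
would bias the low-signal points) labels it hyperbolic (relative rms misfit
≤ 5%) or sigmoid.  Peak positions are reported at the grid argmax of the
default 60-point log grid over 1–5000 μM, refined by a local quadratic in
log-substrate.  Whether the basal curves are "sigmoid" or "hyperbolic" in a
Hill-coefficient sense is deliberately not asserted; the classification
reports the monotone class together with the Michaelis-fit residual.

### Calibration harness and synthetic data

The experimental points of the original study exist only as figure symbols,
so the fitting module ships a synthetic-data generator instead of digitised
values.  Its default designs mirror the study's two calibration curves:
total H2O2 release versus AA5 at 100 μM succinate, and versus succinate at
0.05 μM AA5, with multiplicative Gaussian noise (default σ = 5%) and
clipping at zero.  The objective is the weighted sum of squared residuals
between measured points and model steady states; optimisation is bounded
local least squares (trust-region reflective) with optional seeded
multistart.  The default adjustable set follows the study's statement that
the largest adjustments hit the ROS catalytic constants and the Q-binding
constant: {k22, k23, k24, k25, k26, k10}.

What the generator does *not* emulate: systematic (non-Gaussian) assay
errors, unit conversion to pmol·min⁻¹·mg⁻¹, baseline drift, or
between-preparation variability.  Passing recovery tests therefore show
that the estimation machinery is correct and that the constants are
identifiable under the stated designs — not that real titrations would
constrain them equally well.  A single design (AA5 alone) leaves k22 and
k23 nearly collinear (both rates are proportional to unoccupied FADH2 and
differ mainly through the ½ dismutation stoichiometry); the dual design
plus the superoxide-mediated reverse fluxes breaks the degeneracy.

## Known limitations and divergences

* The exact supplementary reaction list of the published model was not
  available; the network here is a reconstruction from the main text.  It
  reproduces the printed structural counts except the conservation count
  (13 vs 15, see above).
* The published figure shows the apparent Vmax *and* Km of the SQR output
  both decreasing with AA5; this reconstruction reproduces the Vmax
  decrease, but its apparent Km increases (the textbook competitive
  pattern).  An alternative "scale k10" inhibition mode (sweep axis `k10`)
  is provided for the variant the study used in its mixed-state figure.
* Under very strong CIII inhibition (k29 = 0.01 s⁻¹) the net mainstream
  flow v6 develops a mild (~18%) interior maximum rather than staying
  strictly hyperbolic; at intermediate inhibition (k29 = 0.1 s⁻¹) the
  published unidirectional/net decomposition pattern holds as stated.
* Proton-motive force, pH dynamics, Complex I/III internal mechanisms,
  spatial diffusion and MPT-pore feedback are out of scope.
* Absolute ROS rates are in model units (μM/s); the experimental
  ~1000 pmol·min⁻¹·mg⁻¹ scale is not reproduced (unstated conversion).
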