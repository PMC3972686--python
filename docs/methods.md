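# Methods

## Model overview

One simulation run is one cell.  The cytosol is a cubic lattice with
single-site exclusion; one site holds one molecule or one complex.  The
reference geometry is 60×60×60 sites at Δx ≈ 20 nm (volume ≈ 1.7 fL), chosen
so that one molecule corresponds to one nanomolar: concentration tables read
directly as copy numbers.  A centered axis-aligned block (18×18×18 by
default) represents the mitochondrion.  Cytochrome c and Smac are placed
uniformly at random inside it and are confined there until outer-membrane
permeabilization; cytosolic molecules are excluded from the block until
release, after which the compartment opens.  Membrane-resident species
(tBid after translocation, tBid:Bax, Bcl2-bound membrane complexes, active
Bax dimers formed on the membrane) live on the one-site shell around the
block and move within it.  The z = 0 lattice face is the plasma membrane
and hosts the DISC adaptor field.  Walls are reflecting: moves off the
lattice are rejected, which conserves molecule number without wraparound
artifacts.

### Monte Carlo scheme

Each MC step corresponds to ΔT = 2×10⁻⁴ s and performs 2N random samples,
with N the number of entities (molecules plus DISC adaptors) present at
step start, so each entity is sampled on average twice — one diffusion and
one reaction opportunity.  A single uniform draw selects both the entity
and the move type (a fair coin between diffusion and reaction/switch).  N
is frozen for the step's budget even if reactions change the count
mid-step; entity selection always uses the current population.

* **Diffusion.**  With the mobility-class probability (P_diff = 0.1
  cytosolic and mitochondrial-interior, 0.01 membrane, 0 for apoptosome
  species) a uniformly chosen face neighbor (6 directions; 4 in-plane for
  the 2-D adaptor field) is targeted; the move succeeds only if the target
  is free, on-lattice, and inside the mover's allowed region.  The implied
  effective diffusion constant, in the convention D = P_diff·Δx²/ΔT, is
  0.2 µm²/s for cytosolic molecules.
* **Reaction.**  All rules applicable to the sampled molecule are collected
  — its unimolecular rules (unbinding, catalytic conversion, tBid
  translocation) plus one bimolecular rule per adjacent reaction partner —
  one is chosen uniformly, and it fires iff a uniform draw falls below its
  probability.  Uniform choice among applicable rules is the simplest rule
  consistent with the one-reaction-attempt-per-sample budget; it slightly
  discounts each channel when several compete at one site, identically
  across compared scenarios.
* **Parameter mapping.**  P_on = 10²·k_on (k_on in nM⁻¹s⁻¹),
  P_off = 10⁻⁴ s·k_off, P_cat = 10⁻⁴ s·k_cat.  Mapped probabilities above 1
  are configuration errors.  For a reversible pair the stationary state
  satisfies detailed balance through the ratio P_on/P_off; the test suite
  checks this against an exactly enumerated Markov chain on a 3×3×3
  lattice.

### Reaction network

Binding forms the complex at one site and frees the partner site; the
membrane-resident reactant keeps its site so membrane species never leave
the shell.  Catalysis is explicit — substrate binding, then a catalytic
conversion of the complex that keeps the enzyme at the complex site and
places the product on a random free allowed neighbor (the attempt is
rejected if none is free).  Unbinding works the same way.  Dimerization
(tBid:Bax + Bax → Bax₂* + tBid) puts the dimer at the complex site and
frees the activator into the cytosol, where tBid re-translocates on next
membrane contact (conversion probability 1 on the shell; no rate is
specified for translocation).  Each caspase-3-producing catalytic event is
tagged with its catalyst — caspase 8 (type 1) or caspase 9 (type 2) — and
the tags accumulate in per-cell provenance counters.

Release is all-or-none: once the active Bax-dimer count reaches the
configured threshold (default 10 at full scale), every cytochrome c and
Smac molecule becomes cytosolic in the same step; the rule fires at most
once.  Smac sequesters free XIAP only; it does not displace XIAP already
bound to a caspase (XIAP redistribution happens through unbinding).

### Rate constants

Two association constants are anchored: caspase 8–Bid, k_A = 1 nM⁻¹, and
caspase 8–procaspase 3, k_A = 1.67×10⁻⁴ nM⁻¹.  The remaining defaults are
reconstructions chosen to respect the network's qualitative regimes — the
cytochrome c–Apaf association is the low-probability rate-limiting step
(P_on = 10⁻⁴ against 10⁻² for ordinary bindings); post-apoptosome caspase
processing is fast (k_cat = 10 s⁻¹); the caspase 8–procaspase 3 channel has
both weak affinity and slow turnover (k_cat = 0.1 s⁻¹), so the type 1 route
is slow at nanomolar caspase 8; the direct Bid–Bax channel is three orders
of magnitude weaker than tBid–Bax; XIAP binds its three targets strongly
(k_on = 10⁻⁴ nM⁻¹s⁻¹) and unbinds at 10⁻² s⁻¹, slow but fast enough to
redistribute among procaspase 9, caspase 9, and caspase 3 over a full-length
run.  With these defaults a 1 nM caspase-8 cell releases cytochrome c after
a few ×10⁶ steps and dies through the type 2 route on the 10⁷-step scale,
while the type 1 route alone would need several ×10⁷ steps — matching the
regime in which the type 1/type 2 switch operates.  Every channel is
overridable per configuration.

### DISC model

Adaptor molecules occupy the plasma-membrane lattice (default density 10 %).
An adaptor is active while death-receptor–ligand bound; switching is
probabilistic (P_on, P_off per sampled reaction attempt — the death-ligand
induction knobs).  Active–active nearest-neighbor pairs lower the free
energy by E_DD (k_BT units, default −2), and adaptor diffusion is accepted
with the Metropolis probability min[1, exp(−ΔE/k_BT)], which drives
clustering of active adaptors.  An active adaptor with at least
`min_active_neighbors` active neighbors (default 1, i.e. cluster membership)
converts one procaspase 8 from a well-mixed pool (default 20) into active
caspase 8 with per-attempt probability P_c8 (default 10⁻⁴, the mapping of a
1 s⁻¹ catalytic rate), placed at the adaptor's membrane-adjacent lattice
site.  The pool is well-mixed rather than lattice-resident because only
aggregate caspase 8 output feeds the network.  Adaptor attempts are
scheduled inside the same 2N budget as molecular moves; a reaction attempt
on an active adaptor first draws generation, then deactivation, so brief
activations still carry one generation opportunity.

### Engine and reproducibility

A cell run is a single compiled kernel invocation seeded once; identical
(configuration, seed) pairs give identical trajectories.  Ensemble seeds
are spawned from a master seed with numpy's `SeedSequence`, so per-cell
results are independent of execution order.  Runs terminate when free
(unbound) active caspase 3 reaches its half-maximal count — 50 at full
scale, half of the 100 nM procaspase 3 pool — or at the step cap (default
10⁸); an option stops at first apoptosome formation for rate-scan studies.
Species counts, active-adaptor counts, and provenance counters are sampled
every `record_every` steps (default 10⁴) plus the initial and final states.

### Analysis conventions

Caspase 3 activation is reported normalized to the half-max count and
capped at 1; cells that stopped at half-max stay at 1 afterwards.  A cell
is type 1 (type 2) when the caspase-8 (caspase-9) share of its provenance
counters at the half-max event — or at the final step for censored cells —
is at least τ = 0.8, mixed otherwise, unclassified with no activation; the
threshold is configurable, as no quantitative boundary for "mixed" exists.
Summary tables use the population standard deviation (divide by n), the
descriptive convention; event-time means (release, first apoptosome) are
computed over cells where the event occurred, with the occurrence count
reported.  The early-time caspase-8 partitioning estimate integrates the
shared-enzyme competitive binding ODEs (association/dissociation only) with
LSODA and also reports the linear-regime ratio k_on,Bid·[Bid]₀ /
(k_on,proC3·[proC3]₀).

### Minimal loop network

Stimulus X₀ (fixed count) catalyzes X₃ → X₃* directly (k = 2×10⁻⁴, the
type 1 channel) and X₁ → X₁* (k = 1.0); X₁* drives the slow conversion
X₂ → X₂* (k = 10⁻⁷); X₂* catalyzes X₃ → X₃* (k = 10⁻¹).  All pairs are
conserved; X₃* production is attributed per channel.  The wiring is a
reconstruction of the published schematic (one direct slow type-1 channel,
a three-step type-2 cascade with the slow middle step, rate list in the
printed order); the builder accepts arbitrary channel lists for
alternatives.  Solvers: exact SSA (direct method); Euler–Maruyama on the
chemical Langevin equations with per-pair clamping to [0, total] (the zero-
noise limit is the deterministic Euler scheme, tested against an ODE
solver); and the hybrid scheme in which the slow channel fires as a Poisson
count with mean k·X₁*·X₂·δt (truncated to keep X₂ ≥ 0) while the other
channels use Euler–Maruyama.  Channel attribution accumulates the signed
Langevin increments, which is unbiased; rectifying the noise would inflate
whichever channel has the larger diffusion coefficient.  δt defaults to
0.01 with a runtime stability check (per-step drift must not exceed any
pool).

## Desk-scale fixtures

Full-scale scenarios need 10⁷–10⁸ steps per cell over 56–64 cells.  The
test suite and the acceptance script instead use `desk_*` presets: an 8×8×8
lattice with a 3×3×3 mitochondrion and proportionally reduced copy numbers
(procaspase 3 = 12, half-max 6; Bid 6, Bax 10, Bcl2 2, cytochrome c 6,
Smac 3, Apaf 12, procaspase 9 5, XIAP 3; release threshold 2), run for at
most 2×10⁵ steps with 32 cells per condition.  The higher density
accelerates encounters so the full signaling sequence — tBid production,
Bax dimerization, release, apoptosome nucleation, caspase 9/3 activation —
completes within the step budget while apoptosome formation remains the
dominant stochastic step.  Two desk-specific adjustments keep the
full-scale mechanisms in proportion: XIAP-complex residence is shortened
(k_off = 0.3 s⁻¹) by roughly the same factor as the run length, so XIAP
redistribution — the mechanism behind the XIAP/Smac orderings — still
occurs within a run; and the DISC ligand-dose ladder uses activation
probabilities (5×10⁻⁵, 6×10⁻⁴, 1.0) chosen so the three doses produce
clearly separated death fractions in a 10⁵-step, 10-adaptor fixture.  Desk
runs preserve the model's orderings (caspase-8 titration, rate scans,
energy scans), not its absolute times; absolute event times in MC steps are
only comparable within a fixture.  A volume-proportional `scale_config`
(lattice and copy numbers shrink together, preserving nM equivalents) is
provided separately for scaled replicas of the full presets.

What the desk fixtures do not emulate: extrinsic (expression-level)
cell-to-cell variability — all cells in an ensemble share one parameter
set, so observed variability is purely inherent; receptor–ligand binding
kinetics (the adaptor P_on/P_off switch stands in for it); and crowding
beyond single-site exclusion.  Passing desk-scale ordering tests therefore
demonstrates the model's regulatory logic, not quantitative agreement with
any particular cell line.

## Numerical choices and degenerate inputs

Concentration→count uses round-half-up.  Overfilled compartments, unknown
species/channels, out-of-range probabilities, and mapped probabilities
above 1 are configuration errors raised before stepping.  A mitochondrial
block of size 0 disables the compartment (used by small fixtures).
Unbinding/catalysis with no free allowed neighbor site is rejected (normal
outcome, like a blocked diffusion move).  Ties in rule selection are
resolved by the uniform draw itself; there is no rule priority.  The
adaptor Metropolis move counts pair energies excluding the moving adaptor's
own origin site.  RNG: one numba global stream per process, reseeded at
each cell-run entry from the per-cell seed (master-seed spawned, kept below
2³¹).

## Known limitations

* Appendix-level rate tables for every channel are reconstructions around
  two printed affinity anchors; quantitative full-scale times shift with
  the rate table, so cross-scenario orderings (which are robust) are the
  validated surface.
* One complex per site: a bound pair occupies the site of the reactant that
  kept it; no complex geometry.
* The DISC model omits explicit receptor–ligand binding, closed oligomers,
  and lipid-raft partitioning; caspase 6 feedback and XIAP-mediated
  degradation are not simulated.
* The per-sample kernel is serial (one cell per core); ensembles
  parallelize trivially by seed but the engine itself does not.
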