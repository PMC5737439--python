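# Methods

## Model definition

The system is a continuous-time Markov jump process on a 1-D lattice of
`L` sites (1 site = 1 bp).  Motors occupy `delta_m` contiguous sites,
roadblocks `delta_rb`; both are tracked by their leftmost site.  All
waiting times are exponential — rates are per second, and continuous time
avoids the update-order artifacts of discrete parallel schemes.

Events and rates:

* **Step.**  A motor advances its front by one site at `k_ip` on free
  track and `k_tp` when the step interacts with a roadblock (below).  A
  step onto a site held by another motor is forbidden; motors never
  overtake.
* **Initiation** (open boundary).  A new motor appears at sites
  `[0, delta_m)` at rate `k_in` whenever that footprint is motor-free.
  The initiation footprint is permanently roadblock-free (promoters are
  kept nucleosome-depleted in vivo).
* **Termination** (open boundary).  A motor whose front sits on the last
  site leaves the lattice in one unhindered step.  Termination never
  rate-limits; the model targets initiation-limited regimes.
* **Roadblock binding.**  Every leftmost position whose full footprint is
  free of motors and roadblocks accepts a roadblock at rate `k_b`,
  independently.  There is no spontaneous unbinding: roadblock loss is
  motor-driven.

### Interaction variants

* **`uniform`** — motors and roadblocks mutually exclude; the step onto a
  roadblock's first footprint site is slow (`k_tp`) and displaces it.
  With `delta_m = delta_rb = 1` on a ring this is exactly the Bus-Route
  Model, which is the regime this mode is used in.
* **`dyad`** — the transcription scenario.  The motor transcribes
  *through* the nucleosome: any step whose target lies in an intact
  footprint runs at `k_tp`; the histone complex is displaced when the
  motor front passes the central (dyad) site, at offset
  `floor(delta_rb/2)`; and the motor retains `k_tp` for the remaining
  `delta_rb - 1 - floor(delta_rb/2)` sites of the former footprint
  (per-motor traversal memory `slow_left` — threading through the
  displaced histones).  The net cost is exactly `delta_rb` slow steps
  per nucleosome, i.e. a through-nucleosome velocity of `k_tp`.  This is
  the microscopic realization that makes the analytic anchors hold:
  `k_tp` *is* the measured elongation rate through a nucleosome, the
  time to clear a footprint is `delta_rb/k_tp` (the effective rebinding
  time `tau_Delta` of the theory), and the bulk velocity once pelotons
  form is `k_tp`.  A "slow only at the single dyad site" variant was
  evaluated and rejected: it yields a through-nucleosome velocity of
  `~(delta_rb-1)/k_ip + 1/k_tp` per footprint (≈ 9.9 bp/s at the
  physiological rates), no significant speed differential between
  hindered and free motors, and hence essentially no peloton formation —
  inconsistent with every quantitative statement of the theory.

A motor may overlap a roadblock footprint in dyad mode but never an
intact dyad; binding requires the entire footprint to be motor-free, so
nucleosomes cannot assemble on top of a transcribing polymerase.

## Simulation algorithm

Gillespie's direct method over the full event catalogue.  Per-motor step
rates are updated locally after each event (the moved motor, the motor
behind it, and the motor immediately upstream of a fresh roadblock); this
is equivalent in law to full recomputation, and the equivalence is
checked against an independently hand-coded master-equation solution of
the Bus-Route chain on small rings (total-variation distance ~0.01 at
10^6 events).

Roadblock binding is sampled by thinning: attempts fall uniformly on
*all* leftmost positions at total rate `k_b * n_positions` and
inadmissible attempts are null events.  Thinning a Poisson process is
exact, and it keeps the cost per attempt at one footprint scan.

Realized events (`step`, `initiate`, `terminate`, `bind_roadblock`) are
logged with strictly increasing timestamps; evictions are implied by the
step that causes them.  Full configurations are snapshotted on a regular
grid (default 1 s at physiological rates) after a burn-in (default
`5 L / k_tp` for open systems, several transit times).  Snapshots are the
canonical source for density, gap, and peloton statistics; the event log
is replayed for velocity estimation and conservation checks.  A single
seeded NumPy generator drives everything; identical seeds give identical
event logs.

## Observables

* **Gaps** — empty sites strictly between consecutive motor footprints;
  *intra-peloton* if no intact roadblock interferes (uniform mode: no
  footprint overlap; dyad mode: no intact dyad in the gap),
  *trans-peloton* otherwise.  A peloton is a maximal run of motors linked
  by intra-peloton gaps.
* **Gap-law fits** — maximum-likelihood single geometric
  (`p = 1/(1+mean)`) and two-component geometric mixture via EM with ten
  seeded random restarts (best likelihood wins; components oriented so
  the larger `p`, i.e. the shorter gaps, is "intra").  Model preference
  is reported by BIC, with the likelihood-ratio statistic alongside;
  nothing is enforced.
* **Profiles** — per-site occupancy probabilities from the snapshot
  ensemble (a site counts as occupied when covered by a footprint).  The
  optional smoothing window of `delta_rb` sites removes the strong
  nucleosome-phasing oscillations imprinted near the promoter-proximal
  barrier (an edge-corrected moving average, so the fit region is not
  distorted).  Velocity `v_m(x)` is steps per second of front residence
  at `x`, accumulated by replaying the event log.  This estimator is
  robust at low density but note it is a *time-weighted (harmonic)*
  mean over passages: in regions where fast and slow motors mix it lies
  below the motor-averaged velocity.  It is, however, exactly the
  velocity that enters the continuity relation `rho_m(x) v(x) = J`, and
  therefore the one consistent with the relative density profile.
* **Relaxation length** — least-squares fit of `A - B exp(-x/x_p)` to a
  profile over the peloton-forming region, taken as the first
  `4 x_p` lattice points with `x_p` from the closed form.
* **Bursts** — counts of termination (or initiation) events in fixed
  windows; Fano factor = variance/mean of the counts (sample variance).
  The observation window is a free parameter conceptually, so the
  comparison tools report Fano as a function of window size; the
  default single-window summaries use 1 min, matching the per-minute
  scale of the effective telegraph rates.

## Telegraph comparison

The two-state promoter (off → on at `k_on`, on → off at `k_off`, Poisson
production at `k_tr` while on) is simulated exactly, and compared with
the lattice model's termination stream through Fano-vs-window curves and
a Kolmogorov–Smirnov statistic on interarrival times.  Distances are
reported, not thresholded: the mapping is an approximation with no
stated closeness criterion.  Closed-form telegraph noise expressions are
deliberately not transcribed; the simulator is the reference.

## Parameters

| symbol | meaning | preset `table1` |
|---|---|---|
| `delta_m` | motor (RNAP II) footprint | 35 bp |
| `delta_rb` | roadblock (nucleosome + linker) footprint | 167 bp |
| `k_ip` | elongation rate, bare DNA | 10 bp/s |
| `k_tp` | elongation rate through a nucleosome | 3 bp/s |
| `k_in` | initiation rate, highly induced genes | 0.6–3 pol/min |
| `k_b` | binding-attempt rate per admissible position | 0.02 /s |
| `tau` | roadblock equilibration time (analytics) | 0 s |
| `L` | gene length | 3000 bp |

`tau` conventions: the simulator realizes equilibration through the
binding process (`tau ~ 1/k_b`); the analytic layer takes `tau` as an
independent input so either convention can be tested.  The preset sets
`tau = 0` because histones rebind on a sub-minute timescale while
clearing a footprint takes about a minute — the shadow is
footprint-dominated (`Delta ~= delta_rb`, `tau_Delta = delta_rb/k_tp ~=
56 s`).

Run-length choices (package defaults, used by the tests and the
acceptance script): open-gene runs simulate 8 000–12 000 s with
2 000–3 000 s burn-in (two-plus transit times), giving ~10^5 step events
in the post-formation region — a ~1 % standard error on bulk velocity;
the exact-oracle check uses ~10^6 events on a 6-site ring; the Bus-Route
gap studies use rings of 100–1000 sites with 2 000–4 000 s of simulated
time and gap samples of ~10^4.

## What the simulations do and do not emulate

The generator reproduces the model's own idealizations: a single
homogeneous gene with sequence-independent rates, one roadblock species,
eviction as a single all-or-nothing event, no polymerase pausing or
backtracking, no supercoiling, no mRNA degradation, and no cell-to-cell
variability.  Agreement between simulation and closed forms therefore
validates the *theory's* approximations, not the model's biological
completeness; in-vivo comparisons (convoy imaging, nucleosome occupancy
maps, GRO-seq velocity maturation) are outside the package's scope.

## Known limitations

* **Post-formation coagulation at high initiation rates.**  The
  closed-form `n_p` and `x_p` describe the *initial* peloton formation
  and treat later peloton merging as negligibly slow.  At the
  physiological preset with `k_in = 3/min`, simulation shows this is not
  the case: the inter-peloton spacing (`~ v n_p/k_in ~ 235 bp`) barely
  exceeds the roadblock shadow (167 bp), so at most one nucleosome
  separates consecutive pelotons, and once a trailing peloton's leader
  displaces it nothing can rebind in the shrinking gap — merging becomes
  nearly deterministic.  Measured mean peloton size keeps growing along
  the gene (≈ 7 at the gene end vs `n_p = 3.8`), and the density
  profile relaxes over ~150 bp instead of `x_p = 279 bp`, because formed
  pelotons also have a spatial extent (`~ n_p delta_m`) comparable to
  `x_p` that the point-particle theory ignores.  One acceptance-style
  test asserts the theory's stated 15 %/20 % agreement bands and is left
  failing as the honest record of this discrepancy.  In the
  unit-footprint open system — where the point-particle assumptions hold
  — the fitted relaxation length does agree with the closed form
  (within ~13 % at `k_in/k_ip = 0.1`).
* **Bulk velocity slightly above `k_tp`.**  Roadblocks refill behind a
  moving peloton with small gaps (~10 bp at these rates), so the leader
  crosses ~5 % unhindered track; measured bulk velocities are
  3.1–3.4 bp/s against the idealized `v = k_tp = 3`.
* **Sub-Poissonian initiation at high rates.**  A motor occupies the
  initiation footprint for `~ delta_m/k_tp ~ 12 s`; at `k_in = 3/min`
  this dead time thins the initiation stream measurably (windowed Fano
  0.6–0.8).  Burst-contrast checks treat initiation as
  "at most Poisson" rather than exactly Poisson.
* The supplementary-level general expressions (flux, absolute densities,
  finite-gene aging corrections, the prefactor of the bulk-peloton
  scale) are not reproduced; where needed, the simulator is the
  reference.
* Exact master-equation solving is limited to unit footprints and small
  rings (state space `C(L,n)·2^(L-n)`).
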