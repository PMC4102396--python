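# Methods

## The model

`plantclock` implements a gene-regulatory ODE model of the *Arabidopsis
thaliana* circadian clock in which transcriptional regulation is almost
entirely repressive. Twelve transcribed genes are modelled — the morning
MYB factors *LHY* and *CCA1* (kept as separate variables with identical
regulatory targets), the PRR wave *PRR9* → *PRR7* → *PRR5* → *TOC1*, the
activator *RVE8*, and the evening genes *GI*, *NOX*, *LUX*, *ELF3*,
*ELF4* — together with the ELF3–ELF4 and GI–ZTL protein complexes and
constitutive ZTL and COP1 pools. The compiled wild-type system has 35
state variables (12 mRNAs, 18 protein pools, 2 complexes, 3 constitutive
species) and 119 rate parameters; Hill exponents are fixed integers
written into the network file and are not counted or fitted.

Transcription of gene *g* is a product of independent regulatory factors,

dM_g/dt = v_g · (1 + a_g·L) · Π_r K_r^h/(K_r^h + R^h) · Π_a (1 + s_a·A^h/(K_a^h + A^h)) − dm_g · M_g,

with L ∈ {0,1} the binary light signal, R repressor levels and A
activator levels. Multiplicative factoring makes every edge's effect
separable: the contribution of one regulator can be plotted or tested in
isolation, and "dead" terms are easy to spot with the sensitivity scan.
Repressors act through their nuclear protein; LHY and CCA1 act as a
summed pool ("LC") inside a single Hill term per target. The only
transcriptional activator is RVE8 (six targets: *PRR9*, *PRR5*, *TOC1*,
*GI*, *LUX*, *ELF4*); its multiplicative factor lies in [1, 1+s] and
equals 1 when RVE8 is absent, so removing RVE8 lowers every target at
every instant.

### The evening complex

EC is an algebraic activity, not a state variable:

EC = f(LUX_n + c_NOX·NOX_n) · g(E34_n + c_E3·ELF3_n),

with f, g Hill saturations (exponent 2) and c_NOX, c_E3 ∈ (0,1). LUX is
rate-limiting on one side and the ELF3–ELF4 complex on the other; NOX
and free ELF3 substitute with reduced efficacy. The product form is
smooth and satisfies both ablation conditions exactly: EC ≡ 0 when LUX
and NOX are absent, and when all ELF3 is absent. Because LUX_n and NOX_n
appear nowhere else, the *lux;nox* double knockout is state-for-state
identical to disabling EC in the wild-type network (a regression test
enforces this).

### Light inputs

Light is a hard binary step (no twilight); the integrator restarts at
every switch so acute responses keep exact timing. Light enters through

- one acute transcriptional term (on *PRR9*, amplitude `a_PRR9`),
- light-gated GI–ZTL complex association and dark-gated dissociation,
- dark-gated COP1 nuclear import, with COP1-mediated degradation of
  nuclear ELF3/GI and cytoplasmic ELF3,
- dark-gated ZTL-mediated degradation of cytoplasmic TOC1 and PRR5.

Per-compartment light-switched degradation rates (separate day/night
values) are supported by the network schema but unused in the canonical
file.

### Genotypes

Knockout zeroes transcription *and* translation; knockdown multiplies
transcription by (1−m); overexpression adds a constitutive,
light-independent transcription rate. Genotype strings follow corpus
conventions: lowercase gene names are knockouts (`"cca1;lhy"`), except
`rve8` alone, which is a 60% knockdown because RVE4/RVE6 partially cover
for RVE8; the `rve4;rve6;rve8` triple maps to a full RVE8 knockout.
`<gene>-ox` adds constitutive expression.

## Simulation protocol

Simulations entrain in light/dark cycles until the dawn-to-dawn state
change is below 1e-5 (relative max-norm), up to 50 cycles, then run the
experiment's light protocol from the entrained state. The integrator is
LSODA (stiff-capable) at rtol 1e-6/atol 1e-9: clock ODEs mix fast
light-switched degradation with slow transcription. Initial conditions
are 0.1 a.u. for every variable; entrainment erases them. States are
clipped at zero only for sub-1e-8 undershoot; anything larger raises an
error, separating round-off from genuine model bugs.

## Reference parameter set

The packaged `reference_params.csv` was produced by the package's own
tooling: a hand-constructed starting point (rates of order 0.1–3 h⁻¹,
Hill half-points of order the species' typical levels), a global
rescaling of all rate-dimension parameters to set the free-running
period, and a parallel-tempering run over the regulatory half-points,
activation strengths and a few turnover rates against qualitative
targets taken from the clock literature: entrainment in LD 12:12 with
LHY/CCA1 peaking at dawn, the PRR wave peaking in order through the day,
evening-gene peaks at dusk, a free-running period slightly above 24 h in
LL, a ~2 h period lengthening when RVE8 function is removed, a roughly
halved CCA1 peak in *lux*, a marginal effect in *nox*, and a further
at-least-halving in *lux;nox*. Sixteen parameters (the COP1 block, the
ZTL/GI protein machinery and the GI/TOC1 protein degradation rates) are
flagged hand-constrained and are excluded from fitting by default. The
reference set is one self-consistent point in a sloppy parameter space,
not a unique optimum — which is exactly why the fitting interface
returns ensembles.

## The cost function

For each time course with data x_i at times t_i and simulation y(t_i)
(linear interpolation of the dense solver output):

- Profile cost: both series are divided by their own mean over the
  course's time points; the cost is the mean squared difference of the
  normalized series. It is invariant to any per-course rescaling of data
  or simulation — experimental units are arbitrary.
- Scaling cost (per scale group): with r_k = mean(sim_k)/mean(data_k),
  the cost is the variance of log r_k within the group. It is zero iff
  the model preserves all relative levels in the group, and symmetric
  under fold changes up or down.
- Total: Σ_j w_j·C_profile_j + α·Σ_g C_scaling_g, with per-course
  weights w (default 1) and balance α (default 1.0, prominent in the
  config and CLI).

A dead simulated gene (zero mean) against non-trivial data scores the
worst-case normalized mismatch rather than being skipped, so knockouts
of measured genes are penalized, while a zero/negative *data* mean
excludes the course with a diagnostic. One simulation is shared per
(genotype, protocol) pair; a failed simulation makes the total infinite
with a diagnostic, so optimizers reject the point.

## Fitting

Seeding takes the best of `n_seeds` log-uniform draws (default 1000)
inside per-parameter bounds (default 1e-4 to 1e2). Parallel tempering
runs Metropolis chains at four temperatures (geometric ladder, ratio 3)
with Gaussian proposals in log-parameter space, step size adapted toward
~25% acceptance, replica-exchange swaps at a fixed interval, and all
temperatures multiplied by 0.7 between four stages. Out-of-bounds
proposals are rejected, so chains never hold invalid states; at zero
temperature the kernel reduces to strict greedy descent (tested).
`ensemble_fit` repeats the whole procedure with offset seeds and returns
the best n_select of n_runs (default 8 of 30) —
individually fitted parameters of models like this are sloppy, and only
ensemble predictions are trustworthy.

## Synthetic data

The generator emulates the statistical structure of the published
corpus: traces at 3 h resolution, individually normalized except within
declared scale groups, with multiplicative lognormal noise (expression
data are non-negative and span decades; additive Gaussian noise would be
the wrong error model and would fight the log-space scaling cost).
Hidden per-course normalization factors are lognormal with σ = 0.5;
grouped courses share one factor; optional sampling-time jitter corrupts
the measurement while times are recorded as nominal, mimicking
digitization error. The default design is a reduced-scale corpus — 12
courses over wild type, *cca1;lhy* and the *rve* triple in LD and
LD→LL, with one 3-member scale group — small enough for minutes-scale
recovery experiments. What passing recovery tests show is that the
pipeline (simulation → cost → tempering) can find parameters consistent
with data generated *by this model family*; they say nothing about
model misspecification against real plants, where no ground truth
exists and the corpus mixes labs, platforms and normalizations.

## Numerical choices and problem sizes

- Entrainment tolerance 1e-5 (relative, max-norm at dawn), well below
  cost-function sensitivity; reduced to 1e-3–1e-4 in fitting loops and
  unit tests, where speed matters and the cost is noise-dominated.
- Peak detection: discrete argmax with parabolic refinement, prominence
  threshold 5% of range, peaks closer than 6 h merged keeping the
  larger. Period = mean successive peak interval after discarding the
  first 24 h of constant conditions (transients); rhythmicity requires
  ≥3 peaks and a last/first cycle amplitude ratio ≥ 0.1.
- The recovery benchmark fits 5 free parameters on 4 wild-type LD
  courses with an 8-run ensemble at reduced budget (6 seeds, 2
  temperatures, 2×25 sweeps); these sizes keep the full experiment
  within a few minutes while still exercising every pipeline stage.

## Known limitations

- The canonical parameter set reproduces qualitative clock behaviour;
  it was not fitted to the published corpus (not redistributable here),
  so quantitative profile details (e.g. the secondary nightly *TOC1*
  shoulder) are not expected.
- NOX phase: with PRR7 as its only repressor, simulated *NOX* mRNA
  peaks later than its LUX-like evening phase in some conditions.
- Spectral light quality is not modelled; constant red/blue protocols
  are tagged but simulated as constant white light.
- No stochasticity, spatial structure, or ABA signalling; luciferase
  reporter kinetics are outside scope, so CAB::LUC-style period
  comparisons are not meaningful here.
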