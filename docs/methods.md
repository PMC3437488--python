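# Methods

## The material balance and its inversion

The core model treats the room as a single well-mixed compartment at
steady state over the sampling-averaged period. For each
aerodynamic-diameter bin and analyte (particle mass in μg/m³, bacterial
genomes and fungal calibrant-equivalent genomes in copies/m³):

    C = f · C_out + N · E / (Q + k · V)

Removal is by ventilation (`Q = AER·V`, m³/h) and first-order surface
deposition (`k·V`). The infiltration factor `f` bundles penetration,
filtration and deposition losses of outdoor-origin particles; it is
estimated as the per-bin indoor/outdoor ratio during vacant periods and
assumed unchanged during occupancy. The inversion
`E = (C − f·C_out)·(Q + k·V)/N` is algebraically exact; forward/inverse
round-trips hold to floating precision and are property-tested.

Assumptions worth keeping in mind: steady state (sampling periods much
longer than the ~10-minute residence time at AER 5.5/h), spatially
well-mixed air, no coagulation or bin-to-bin size shifting, and occupancy
as the only indoor source. The model deliberately does **not** separate
direct shedding from resuspension — both appear as `E`.

Negative inferred excesses (possible under measurement noise) are clamped
to zero and flagged `negative_clamped`; the raw value is retained in
`EmissionProfile.raw_e`. A negative source term has no physical meaning,
but discarding the sign silently would hide a diagnostic, hence the flag.

Because a single across-bin occupied/vacant ratio can be formed two ways,
`occupied_vacant_ratio` reports both the mean of per-bin ratios and the
ratio of bin sums, labelled; the two differ whenever the size distribution
changes with occupancy.

## Deposition loss-rate coefficients

The default pointwise model is a cubic in log–log space,
`log10 k = −0.407 + 1.232·X + 1.818·X² − 1.594·X³` with
`X = log10(dₚ/μm)`, representing measured deposition in a furnished,
ventilated room for 0.5–9 μm particles. Bin averages take particle mass
uniform in `log10 dₚ` within a stage and integrate `k(10^X)` by adaptive
quadrature (`scipy.integrate.quad`, relative tolerance 1e−8 — far tighter
than the 2-significant-figure precision of the coefficients themselves).
The six-stage grid (0.4–1.1, 1.1–2.1, 2.1–3.3, 3.3–4.7, 4.7–9, 9–20 μm)
yields 0.31, 0.79, 2.1, 4.4, 8.6 and 9.6 /h. Evaluating the cubic above
9 μm is an extrapolation; the module logs this rather than warning,
because the extrapolated top stage is the standard treatment and the
companion sensitivity analysis quantifies its cost.

The settling model is pure Stokes, `k = v_s/H` with
`v_s = ρ d² g / (18 μ)` and no slip correction. Slip correction changes
`v_s` by under ~2 % above 9 μm, and every sensitivity quantity computed
with this model is a ratio in which density, viscosity and room height
cancel exactly. Because `k ∝ dₚ²`, the log-uniform bin average has the
closed form `(d_hi² − d_lo²)/(2·ln(d_hi/d_lo))`; the implementation
carries both this closed form and the generic quadrature route, and a
test pins their agreement to 1e−6 relative. Moving the top-stage cap from
20 μm to 15 μm lowers the settling-based `k̄` by 29.4 %; to 25 μm raises
it by 33.3 %; propagated through the removal term with AER 5.5/h and
`k` 9.6/h, the induced emission-rate changes are −18.7 % and +21.1 % — an
approximately symmetric ±20 % structural uncertainty on the top-stage `E`.

## Air-exchange rate

A well-mixed tracer with no indoor source decays as
`C(t) = C_bg + (C₀−C_bg)·e^(−λt)` with λ equal to the AER. The fit is OLS
of `ln(C − C_bg)` on `t`; noiseless exponentials are recovered exactly for
any rate and background (property-tested), and replicate releases are
summarised as mean ± sample s.d. The background is a user-supplied
constant (ambient CO₂, ~400 ppm); no automatic changepoint or window
detection is attempted — the fit window is explicit.

## qPCR quantification

Ct triplicates are averaged arithmetically before conversion; if more
than one replicate fails to amplify the result is a `BelowDetection`
sentinel, never zero, because absent amplification bounds the quantity
rather than measuring it. The conversion chain is: standard curve →
calibrant-genome equivalents → × calibrant operons/genome → marker-gene
copies → ÷ community operons/genome → organism genomes. For bacteria the
community average is 4 operons/genome (calibrant 10). Fungal 18S copy
numbers are too variable and too poorly catalogued to support that last
division, so fungal quantities are *defined* as calibrant-equivalent
genomes (55 operons/genome) throughout the type system and never
converted to true genomes. Standard-curve fitting requires ≥3 dilution
points spanning ≥2 decades; efficiency `10^(−1/slope) − 1` is reported as
a fit diagnostic. Air concentrations scale the analysed aliquot (default
one quarter of the filter) to the whole filter and divide by sampled air
volume (flow × duration; default 28.3 L/min × 22.2 h = 37.70 m³).

## Taxa apportionment

Group emission rates are `E_group,i = E_total,i × fraction_i` per bin,
where `fraction_i` is the group's relative read abundance in bin *i*. The
overall group fraction pools reads across bins by default rather than
averaging per-bin fractions: at pyrosequencing depth (~60 reads/bin,
unevenly distributed) per-bin fractions are noisy and pooling weights
them by the information each bin actually carries; both conventions are
computed and returned. Default groups: skin/hair/nostrils =
{Propionibacterineae, Staphylococcus, Enterobacteriaceae,
Corynebacterineae}; oral cavity = {Pasteurellaceae, Fusobacterium,
Veillionella}. Staphylococcus has both skin and oral sources; it sits in
the skin group by default with a flag (`staph_in_oral`) to duplicate it
into the oral group. Bins whose sequencing library failed carry a
`failed_pcr` status and contribute nothing to group totals — they are
missing data, not zeros. Enrichment factors are simple indoor/outdoor
ratios of a group's overall fraction, undefined (and reported as such)
when the outdoor fraction is zero.

## Bacterial mass fraction

Genome concentrations convert to mass at 655 fg per cell (a literature
average for airborne bacteria; one genome ≡ one cell, so aggregated cells
are counted individually — an advantage of DNA-based counting). The
overall ppm fraction is mass-pooled (Σ bacterial / Σ PM over reporting
bins), which a mass fraction should be; per-bin values are reported
alongside, and the pooled value provably lies between the per-bin
extremes. No fungal analogue is provided: per-spore mass and 18S copy
number are both too variable to support one.

## The synthetic-data generator

`generate_scenario` builds a ground-truth classroom: V = 90 m³,
AER = 5.5/h, N = 4.7 occupants, the six-stage grid, `k` from the cubic
model. Default emission rates and outdoor concentrations were chosen
once, jointly, to reproduce the study conditions the pipeline is designed
for: mean occupied/vacant indoor ratios of ~15 (mass), ~170 (bacterial
genomes) and ~2.3 (fungal equivalents); a ~12× bacterial increase in the
largest stage; mass emissions majority >9 μm; bacterial emissions peaking
at 3–5 μm. Per-bin bacterial emission rates are back-calculated from the
published human-microflora table (group E ÷ its percent of total), giving
(0.46, 1.9, 5.0*, 15, 13.3, 1.7)×10⁶ genomes/h/person (*the failed-PCR
bin interpolated). Infiltration factors fall from 0.90 to 0.20 with size,
reflecting growing penetration and deposition losses.

`simulate_observations` draws: concentrations with mean-one multiplicative
lognormal noise (default CV 0.10 — no error model is established for
such measurements, and lognormal respects positivity across decades);
per-bin multinomial taxa counts at depth 60 (no overdispersion by
default); Ct triplicates from a perfect-efficiency standard curve with
additive Gaussian noise (σ 0.15 cycles); and six tracer decays (background
400 ppm, initial excess 1600 ppm, 20 samples over 0.5 h, CV 0.02). One
indoor size stage (2.1–3.3 μm) defaults to a failed sequencing library,
exercising the missing-bin pathway. All draws flow from a single
`numpy.random.default_rng` seed and are reproducible.

What the generator does *not* emulate: temporal dynamics (everything is
steady-state averaged), spatial inhomogeneity, correlated errors between
indoor and outdoor samplers, impactor particle bounce, DNA-extraction
efficiency variation, and chimeric or misclassified reads. Passing
recovery tests therefore validate the inference machinery under the
stated noise model, not the field accuracy of any particular instrument
chain.

Monte-Carlo checks run at 200 replicates of the six-bin scenario — enough
to pin a per-bin median to a few percent while keeping the full suite in
seconds. At CV 0.10 the per-bin median |relative error| of recovered
bacterial emission rates stays below 15 %; fungal recovery is
intrinsically noisier because the occupancy signal is only ~2.3× the
infiltrated background.

## Numerical and interface choices

- Bin grids are matched exactly across tables (half-open [d_lo, d_hi)
  μm); a mismatch is an error, never an interpolation.
- Units ride on profiles (μg vs copies, per m³ vs per h per person) and
  are set from the analyte; operations validate analyte and state (e.g.
  infiltration factors refuse non-vacant inputs).
- Quadrature failures report the offending bin; tracer fits name the
  first sample whose excess is non-positive.
- Logs go to stderr via the `bioemit` logger; results only to return
  values and files.

## Known limitations

Single-zone, single-`f` model: if occupancy alters infiltration (door
traffic) the vacant-period `f` biases `E`. The deposition cubic is an
empirical fit for one furnished room at one airspeed; its extrapolation
above 9 μm carries the quantified ±20 % top-stage uncertainty. Taxa
apportionment assumes read fractions are unbiased for genome fractions
(no 16S copy-number correction per taxon, no primer bias model). The
mass-fraction estimate inherits the fixed 655 fg/cell assumption
linearly.
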