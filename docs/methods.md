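# Methods

This note documents the models, estimators, defaults and known limitations
of `xbsolv`, module by module.

## Single-site ITC model (`xbsolv.itc`)

**Dilution model.** The instrument perfuses a constant-volume cell (V0);
after a cumulative injected volume ΔV the cell species is diluted to
X = X0·exp(−ΔV/V0) and the titrant accumulates to
M = C_syr·(1 − exp(−ΔV/V0)). This exponential-displacement convention is
the standard instrument model; the package validates it against a
micro-step finite-difference mixing simulation (10⁴ sub-injections) in the
test suite.

**Heat model.** The cumulative heat content is the Wiseman closed form
Q = (ΔH·V0/2)[α − √(α² − 4nMX)], α = nM + X + K_d, evaluated in the
cancellation-free form 4nMX/(α + √·) so that low-saturation heats do not
lose precision. The discriminant is non-negative for all K_d ≥ 0 by the
AM–GM inequality. The observed heat of injection i is

    ΔQ_i = Q_i − Q_{i−1} + (V_i/V0)·(Q_i + Q_{i−1})/2 + Q_off.

The displaced-volume correction uses the **mean** of the bracketing heat
contents (the expelled slab is half-reacted on average). A difference form
`(Q_i − Q_{i−1})/2` circulates in parts of the literature, most plausibly
as a transcription artifact of the mean form; it is available via
`displacement="printed"` and differs only by `(V_i/V0)·Q_{i−1}`.

**Global fit.** Parameters are [ln K_d, ΔH, n, Q_off(1..R)]: the three
thermodynamic parameters are shared across replicates, one offset per
replicate, Levenberg–Marquardt least squares on the pooled residuals. The
log parameterisation enforces K_d > 0. The first (small, 0.4 µL) injection
is modelled but excluded from the objective, as is universal ITC practice —
its heat suffers from syringe backlash; this is configurable. Initial
values: ΔH from the first large injection (complete binding assumed), n
from the cell/titrant molar ratio at the steepest heat drop, K_d = X0/10.

**Uncertainties.** Residual bootstrap (default 1000 resamples, seeded):
residuals are pooled across replicates, resampled onto the fitted curve and
refit. Replicate-level heteroscedasticity is ignored — a deliberate
simplification for synthetic i.i.d. noise. Uncertainty-from-baseline error
propagation as done by peak-integration pipelines is out of scope.

**Units.** Heats in µJ, volumes in µL, energies in kJ/mol,
R = 8.314 J mol⁻¹ K⁻¹; ΔG° = RT ln K_d (K_d in molar), −TΔS° = ΔG° − ΔH°.

**Default scheme.** The reverse-titration protocol used throughout the
examples: 287 µM titrant (protein) into 28.7 µM cell species (ligand),
200 µL cell, 15 injections (0.4 µL then 14 × 2.5 µL), 301 K. This gives a
Wiseman c ≈ 130 for K_d ≈ 0.22 µM — a well-conditioned sigmoid.

**Known data caveat.** For the tabulated chloro-ligand row shipped in
`data/table1_itc.csv`, the printed (K_d, ΔH) pair decomposes to
−TΔS = 18.24 kJ/mol whereas the printed value is 18.4; the printed row is
internally inconsistent at the 0.1–0.2 kJ/mol level (rounding of K_d and
ΔH). The acceptance test records this: every other row agrees to better
than 0.15 kJ/mol. The quoted experimental uncertainty on that entry is
±1.7 kJ/mol, so nothing scientific hinges on the discrepancy.

## Halogen-bond geometry (`xbsolv.geometry`)

All criteria are heavy-atom criteria: crystal structures of this resolution
carry no hydrogens. Defaults, all overridable:

| parameter | default | rationale |
| --- | --- | --- |
| vdW radii (X) | Cl 1.75, Br 1.85, I 1.98 Å | halogen electrostatic-surface radii |
| vdW radii (other) | Bondi (O 1.52, N 1.55, F 1.47 …) | makes Cl+O = 3.27 Å exact |
| XB distance slack | 0.3 Å | admits borderline contacts for inspection; `is_short_contact` still marks the strict sub-vdW criterion |
| min C–X···O angle | 140° | "nearly linear" without excluding real site geometry |
| water-bridge leg cutoff | 3.5 Å | hydrogen-bond heavy-atom distance |
| belt H-bond | d ≤ 3.6 Å, C–X···D ∈ [90°, 150°] | electronegative belt is perpendicular to C–X; near-180° is the σ-hole side |
| covalent C–X search | nearest C within 2.2 Å | longest relevant C–I bond ≈ 2.1 Å |

Fluorine is screened geometrically like the heavier halogens but has no
σ-hole; in the default XB halogen set it is excluded, while the
water-bridge scan includes it (F participates in water-mediated hydrogen
bonding). Alternate locations are collapsed to the highest-occupancy
conformer (ties → altloc 'A') at read time; waters with occupancy < 0.5 are
kept but flagged. Residue numbering follows PDB author numbering.

## Voxel solvation thermodynamics (`xbsolv.gist`)

**Grid.** Cubic voxels, 0.5 Å default, dims = ceil(extent/spacing) per
axis; binning is half-open [low, high). Binding-site analyses use a
16 × 17 × 14 Å box; single-water-site analyses a 6 × 6 × 6 Å cube.

**Translational entropy.** First-order expansion per voxel,
T·δS_trans(v) = −k_B·T·ρ(v)·V_voxel·ln g(v), g = ρ/ρ_bulk, with
ρ_bulk = 0.0329 Å⁻³ (ambient water) and empty voxels contributing zero. The
sign convention is chosen so the term vanishes in bulk and is negative at
ordered sites; the reported regional quantity −TΔS_tot =
−Σ(TS_trans + TS_rot) is therefore positive where water is ordered, the
convention in which binding-site water entropies are usually tabulated. A
first-order small-count correction (+k_B·T/(2·n_frames) per occupied voxel)
cancels the leading Jensen bias of n·ln n under Poisson counting, so an
ideal-bulk trajectory averages to zero at finite sampling; it is exact in
the large-mean limit and the bulk-null test operates in that regime.

**Orientational entropy.** Kozachenko–Leonenko nearest-neighbour estimator
in quaternion space. Distances are geodesic rotation angles honouring the
q/−q double cover; ball volumes use the exact SO(3) form
V(r) = 8π(r − sin r) (total 8π²), which removes the curvature bias that a
flat-space volume would introduce at realistic sample counts. Voxels with
fewer than two samples contribute zero. The estimator is validated against
dense-histogram integration of −k_B ∫ p ln(p/p_iso) in rotation-vector
space (10% agreement at n ≈ 6000 samples).

**Energies.** Rigid 3-site water (O–H 0.9572 Å, H–O–H 104.52°, charges
−0.834/+0.417 e, single O-site Lennard-Jones ε = 0.636 kJ/mol,
σ = 3.151 Å), point charges + LJ for the solute, molecule-based
minimum-image truncation at 8 Å (no Ewald — this is a toy potential for
bookkeeping validation, not a simulation engine). Each water–water pair
energy is split half/half between the partners' voxels; solute–water
energy goes to the water's voxel. Grid totals equal a direct double loop
exactly, which the tests assert to 1e−9.

**Uncertainties.** `region_block_series` reports the full-trajectory
estimate with a standard error from n contiguous frame blocks — the
standard block-averaging procedure. Block estimates carry larger
small-sample bias than the full estimate and are used only for the spread.

**What the synthetic trajectories do and do not show.** The bulk generator
draws independent uniform positions and isotropic orientations; the
ordered-site generator pins one water with Gaussian positional spread and
tangent-space-Gaussian orientations. These reproduce the *statistical*
structure the estimators assume (null density, planted order) but none of
the physics of real water — no hydrogen-bond network, no correlations
between frames, no realistic energy scale. Passing the null/ladder tests
therefore validates the estimators, not any simulation result; published
binding-site entropy tables from force-field MD are deliberately not a
reproduction target here and their values ship only as a packaged
reference table for correlation analyses.

## Energy ledger (`xbsolv.energetics`)

Interaction energies and the composite `Sum = ΣΔE − Solv` are exact
arithmetic; recomputation is checked against the stored integer-rounded
published column with a ±1.5 kJ/mol tolerance (three rounded terms plus a
rounded total). Correlations are unweighted 5-point Pearson coefficients.
Because a composite-vs-ΔG correlation can be read with the solvation term
subtracted once (the `Sum` column) or twice ("Sum − Solv"), the ledger
reports both variants rather than asserting either; with the packaged
tables they evaluate to R = 0.97 and R = 0.84 respectively.

Extra-point placement puts the σ-hole charge at
EP = X + d·(X − C)/|X − C| with d = 1.95/2.02/2.15 Å for Cl/Br/I
(QM-calibrated defaults). The EP charge itself is user-supplied: published
parameterisations do not print transferable charges, and guessing one would
suggest a fidelity the model does not have.

## NMR signal modelling (`xbsolv.nmr`)

CSPs are plain differences per residue and nucleus with a 0.01 ppm
reporting threshold. The correlation against |ΔΔH| takes the enthalpy
difference relative to a stated reference complex and returns NaN where a
residue's Δδ has no variance.

Interferograms follow S(t) = Σ S_k exp(iω_k t − κR_k t). The accordion
scale κ (relaxation-delay increment per evolution increment) is an explicit
parameter with no privileged value. Reverse-mode data (delay decremented)
are handled by the exact map *time-reverse and conjugate*, which converts
them to forward form with amplitudes conj(S_k·e^{iω_k T_max}); rates and
frequencies are unchanged, so one estimator serves both modes.

Poisson-gap schedules draw gap lengths from a Poisson law with a
sine-modulated rate (dense early, sparse late), always retain index 0, and
hit the requested count exactly by bisection on the rate multiplier with
identical re-seeding per trial — fully deterministic per seed.

Parameter recovery is variable-projection nonlinear least squares:
amplitudes are solved linearly for each candidate (ω, κR) set, the
optimiser runs on the nonlinear parameters with R bounded at zero, and
initial frequencies come from the K strongest well-separated peaks of the
zero-filled DFT spectrum, with three decay-rate starts spanning 0.5–8
linewidths. Sparse super-resolution reconstruction (as used by
accordion-NUS processing pipelines) is intentionally not reimplemented —
the signal model, not the estimator, is the published contract; a
least-squares fit recovers noiseless parameters exactly and is transparent
to test.

## Synthetic data (`xbsolv.synth`)

All generators are deterministic per seed. Defaults encode the study
conditions: the reverse titration scheme above; ITC noise of 1% of the
largest heat; interaction-site fixtures built to the interaction distances
reported for the halogen series (X···O 3.1–3.3 Å; water bridge legs ~3 Å;
nearest water 4.4 Å in the iodo complex, which is why it has no bridge);
idealised C–X bond lengths (1.35/1.74/1.90/2.10 Å for F/Cl/Br/I) are used
only to place the donor carbon and are never asserted. Written fixtures
carry provenance headers (generator parameters + seed).

## Test problem sizes

The statistical tests choose sizes where the tested effect is several times
its Monte-Carlo error: the bulk null uses ~57 waters × 800–1000 frames on a
1 Å entropy grid (per-voxel expected counts ≈ 25–35, well inside the
bias-correction regime); the confinement ladder uses 10 seeds × 250 frames
at 0.5 Å; ITC recovery studies use 30–50 seeded triplicates; the doublet
recovery study 60 noisy realisations. These are the package's own choices
of statistically sufficient sizes.

## Known limitations

- The ITC module fits a single-site model only; competitive, multi-site and
  ΔCp models, and raw-thermogram baseline integration, are out of scope.
- Geometry works on heavy atoms; protonation and hydrogen placement are the
  user's problem, and crystallographic symmetry mates are not expanded.
- The solvation grid computes first-order entropies with a toy potential;
  no Ewald electrostatics, no higher-order entropy terms, no end-state free
  energies.
- Electronic-structure calculations themselves (interaction energies,
  solvation free energies) are inputs, never computed here.
- The damped-sinusoid estimator assumes the component count K is known and
  components are separated by at least a few Rayleigh widths.
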