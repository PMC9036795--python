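# Methods

## Scope and data model

The package re-implements a two-armed analysis pipeline: whole-genome
comparison with a sketch-distance phylogeny, and a stationary ¹³C metabolic
flux analysis (MFA) of xylose assimilation.  All stages operate on plain-text
formats (PAF, nucmer show-coords tab dialect, FASTA, Newick, CSV/TSV, JSON);
parsed alignments live in pandas match tables with a single coordinate
convention (0-based, half-open, start < end, strand explicit), regardless of
the source dialect.

## Genome comparison

Matches are filtered on reference-span length (default ≥ 1000 bp) and mapping
quality (default > 0); a separate display threshold (10 kbp) mirrors
synteny-plot practice.  Per-chromosome identity is the match-length-weighted
mean of per-match identities, with *reference* span length as the weight —
query spans can differ through indels, and the summary is organized by
reference chromosome.  Coverage merges overlapping match intervals before
summing ("covered fraction" is a set property, so double-counted overlaps
would overstate it).  Contig assignment picks the chromosome holding the
largest summed matched reference length (ties broken by chromosome name),
orientation by the strand carrying the majority of matched bases, and order
by median reference position; assignments with < 50% support are flagged
ambiguous but still reported.  N50 is the length of the contig at which the
cumulative sorted-descending length first reaches half the assembly size.

## Sketch distances and tree

Sketches keep the s = 1000 smallest 64-bit hashes of canonical 21-mers
(lexicographic minimum of a k-mer and its reverse complement; windows
containing non-ACGT bases are skipped).  Hashing is a seeded splitmix64-style
finalizer over 2-bit-packed k-mer codes, vectorised in numpy — deterministic
for a fixed seed.  The distance is d = −ln(2j/(1+j))/k with j estimated on
the bottom-s sketch of the merged hash union; identical sketches give d = 0
and disjoint sketches are capped at d = 1 (the logarithm is undefined at
j = 0, and bounded distances keep tree fitting finite).

Branch lengths for a fixed topology minimize the Fitch–Margoliash criterion
Σ((d−p)/d)² (weights 1/d², the classical power-2 choice).  Path lengths are
linear in edge lengths, so the fit is a nonnegative least-squares problem
(NNLS); negative branch lengths are forbidden by construction — a documented
departure from implementations that allow them, chosen because negative
lengths have no interpretation as sketch distances.  A zero off-diagonal
distance would give an infinite weight; it is replaced by a configurable
epsilon (1e−6) with a warning.  Topology search adds taxa stepwise in a
seeded random ("jumbled") order at the criterion-minimizing branch, then runs
nearest-neighbor-interchange passes to convergence, keeping the best of 10
jumble rounds (seed 23893 by default).  NNI is complete for the small trees
this pipeline targets; an exhaustive enumeration oracle guards the search in
the test suite (all 15 topologies at n = 5), and additive matrices up to
n = 8 are recovered exactly in 100 seeded trials.

The 11-taxon preset distance matrix mirrors the study genus's structure: two
close sister-pair clades (two phaffii-like strains + kurtzmanii-like;
three pastoris-like strains + ulmi-like), a distant three-species clade, and
a far outgroup, at Mash-distance scale with 0.002 truncated-Gaussian noise.

## Stoichiometric model fixture

The packaged model (`data/central_carbon_xylose.csv`) is a **reconstruction**,
not the original supplementary file: compact central carbon metabolism with
carbon atom transitions — non-oxidative PPP (two transketolase steps and
transaldolase), oxidative PPP (G6P → 6-phosphogluconate → Ru5P + CO₂), upper
glycolysis run gluconeogenically to G6P and free glucose, lower glycolysis to
pyruvate, pyruvate dehydrogenase and carboxylase, a compact TCA cycle, a CO₂
pool with efflux, and a lumped biomass drain on ten precursors.  The
five-reaction xylose extension (xylose uptake, xylose reductase, xylitol
dehydrogenase, xylulokinase, xylitol efflux) is tagged as its own block and
keeps the original reaction numbers (R48, R49, R50, R59, R25) as aliases.
Simplifications: succinate/fumarate scrambling is omitted (the measured
metabolites sit in PPP and glycolysis, far from the TCA symmetry), cofactor
balancing is out of scope, and the biomass composition uses rounded
literature-scale precursor demands.  The model has 26 reactions over 21
balanced metabolites, rank 21, hence 5 net degrees of freedom; reversible
steps are parameterized as net + exchange fluxes.

Flux scenarios fix the five degrees of freedom through measured-rate-style
constraints (xylose uptake normalized to 1, xylitol efflux 0.1, glucose
efflux 0.05, biomass drain 0.15, and the oxidative-PPP flux at 0 or 0.08).
`sample_feasible_flux` returns a deterministic vertex of the constrained flux
polytope selected by a seeded random linear objective (HiGHS linear
programming).

## Labeling simulation

Steady-state (stationary) MFA only: the 10-day labeling experiment justifies
isotopic steady state.  The simulator uses the EMU decomposition: backward
from each measured metabolite, the minimal set of elementary metabolite units
is collected and layered by size; each layer is one dense linear solve, with
condensation reactions entering as convolutions of smaller EMUs.  The
exhaustive isotopomer oracle solves the full positional system (2ⁿ states per
metabolite, tensors of shape (2,)*n) by damped fixed-point iteration to
1e−14 and collapses to mass distributions; EMU and oracle agree to better
than 1e−8 on every network small enough for the oracle, which is the
package's primary correctness guarantee for the simulator.

Natural ¹³C abundance (0.0107) is included at unlabeled substrate positions
by default so simulated backbone MDVs are directly comparable to corrected
measured CIDs; it can be switched off for idealized calculations.  The
default tracer is 1-¹³C xylose: position 1 at isotopic purity 0.99, positions
2–5 at natural abundance.

Two numerical conventions matter at zero flux.  A pool with strictly zero
turnover (6-phosphogluconate when the oxidative PPP carries no flux) has an
undefined balance; the simulator reports it at natural background, which is
what the instrument sees for a relict pool.  For *fitting*, this creates a
discontinuity of the simulated MDVs in the fluxes, so the fitter adds an
infinitesimal natural-background dilution flux (1e−8) to every balance,
making the forward map continuous at negligible bias (≪ 1e−6 on any pool
with appreciable turnover); exact mode (dilution 0) is the default elsewhere.

## Isotope correction

Fragment ions of ethoxime/TMS-derivatized metabolites carry H, C, N, O, Si
(and potentially S) whose natural isotopes are deconvolved by nonnegative
least squares against the convolution matrix of the non-backbone atoms;
NNLS rather than matrix inversion because inversion can return negative
isotopologue abundances on noisy data, and the NNLS residual is exposed as a
QC quantity.  IUPAC abundances are packaged (²⁸/²⁹/³⁰Si = 0.92223 / 0.04685 /
0.03092; ¹³C = 0.0107, i.e. the 1.1% unlabeled-biomass baseline at one
decimal).  The truncation window defaults to K = n + 8 mass shifts: fragments
with five to seven silicons spread appreciable pattern mass to high shifts,
and the wider window keeps the truncated column tail below 1e−4 (a shorter
window of n + 4 leaves up to ~1% unaccounted).  Relative abundances follow
RAᵢ = 100·Aᵢ/ΣAᵢ over the corrected backbone areas.  The 50:50
¹²C/¹³C-methanol QC check compares a corrected CID against binomial(n, ½)
("Pascal's triangle" row n) with a configurable pass threshold (default 5
percentage points).

The packaged fragment table (`data/fragments_synthetic.csv`) is **synthetic**:
plausible ethoxime-TMS derivative compositions for the ten measured
metabolites, not the instrument's actual fragment list.

## Flux fitting and confidence intervals

The fit minimizes Σ((CID_sim − CID_meas)/SD)² with SDs floored at 0.1
percentage points (infinite weights otherwise).  Net fluxes are parameterized
on an orthonormal null-space basis of the stoichiometry augmented with the
fixed measured rates; exchange fluxes map a bounded coordinate x ∈ [0, 0.95]
through x/(1−x).  Nonnegativity of dependent irreversible fluxes is enforced
by penalty residuals (box bounds alone cannot express it).  The optimizer is
bounded trust-region least squares with seeded multi-start from feasible flux
vertices capped at a physiological scale, in two stages: a coarse stage with
1e−6 dilution smooths the near-zero-flux region, then a polish at the target
dilution.  On noise-free self-generated data the fit recovers all net fluxes
to better than 1e−3 relative with SSR ≤ 1e−8, and data generated with zero
oxidative-PPP flux yield a fitted oxidative-PPP flux below 2% of uptake.

Confidence intervals are percentile intervals over Monte-Carlo resamples:
each measured CID is perturbed by Gaussian noise at its SD, clipped at zero
and renormalized (a documented deviation from naive Gaussian resampling —
CIDs must stay distributions), and refit from the point estimate.  On the
small branch-network testbed the interval width matches the estimator's true
sampling spread to a few percent and the 95% intervals cover the true flux in
90–99% of 50 seeded replications.

## Bulk enrichment

Expected biomass ¹³C after an x-fold biomass increase on a labeled tracer
uses a two-pool mixture: new-carbon fraction f = (x−1)/x at the tracer's mean
per-carbon enrichment, the rest at the initial (natural) enrichment.  For
1-¹³C xylose at purity 0.99 and the measured 1.85-fold increase this model
gives ≈ 10.1% — higher than the bulk value the study measured (9%) and its
stated expectation (~5%).  The mixing model ignores respiratory fractionation,
CO₂ loss during biosynthesis, and carbon turnover, all of which push the true
value down; the discrepancy is surfaced rather than tuned away, because the
quantities needed to model those effects are not available.

## Synthetic data: what it does and does not emulate

The generators are first-class, seeded, and emit their ground truth beside
the data.  Genome pairs program a SNP rate (match identities equal the
realized substitution fraction), segment the reference into contigs, and
reverse-complement a chosen number of segments; the match table and FASTA are
mutually consistent by construction.  Not emulated: repeats, indels,
horizontal transfer, assembly errors — so contig-assignment recovery on these
genomes shows algorithmic correctness, not robustness to repeat-rich real
assemblies.  Tree distances are tree path lengths plus truncated Gaussian
noise; real sketch distances deviate from additivity in structured ways noise
does not capture.  MFA datasets convolve simulated backbone MDVs through each
fragment's correction matrix, scale to instrument-like areas (10⁶ with a
per-fragment lognormal-ish factor), and add Gaussian area noise — peak
integration errors, retention-time drift, and detector nonlinearity are not
modeled.  Passing tests therefore demonstrate internal consistency and
correct mathematics under the stated noise models, not instrument-level
robustness.

## Problem sizes in the shipped tests

Tree-search trials use 5–8 taxa with 2 jumble rounds (100 trials); the
11-taxon preset uses the full 10 rounds.  The oracle comparison runs 20
random flux draws on the 4-balanced-metabolite branch network.  End-to-end
fits use the full 26-reaction fixture with 3 restarts; interval calibration
runs 50 replications at 100 Monte-Carlo samples on the branch network with
one free net flux.  All sizes are package defaults chosen to exercise every
code path at interactive runtimes; the same code runs unchanged at larger
sizes.
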