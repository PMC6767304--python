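# Methods

`dmcminer` implements a drug-metabolite-cluster (DMC) workflow for
LC-MS^n metabolite identification: a prototype drug is expanded through
biotransformation templates into a generation-ranked candidate network,
candidates are screened in accurate-mass MS^1 data, confirmed against
ion-trap MS^n spectra, and every confirmed metabolite is promoted to a
new *cluster center* whose own neighbourhood is predicted in the next
round.  This note records the model, its assumptions, the defaults, and
the numerical choices.

## Mass arithmetic and ion conventions

All masses are monoisotopic sums over a packaged element table
(`data/atomic_masses.tsv`, CODATA/IUPAC values to >= 6 decimals).
Singly charged ±H ions follow the physical convention by default:
[M+H]+ = M + 1.0072765 Da, [M−H]− = M − 1.0072765 Da.  Published
negative-mode theoretical columns are sometimes tabulated as
M − m(H atom) − m(electron) instead; `IonConvention.paper_negative`
reproduces such values (e.g. C19H17O7−: 357.09688 under that convention
vs 357.09798 physically).  Correctness defaults to physical;
reproducibility of historical tables is preserved by the switch.

Reporting follows table practice: m/z to 5 decimals, ppm to 1 decimal,
rounding half away from zero.

## Formula decomposition

`decompose_mass` enumerates element counts C[0–30], H[0–50], O[0–20],
S[0–2], N[0–3] with branch-and-bound pruning on the residual mass,
keeping neutral formulas whose ±H ion lies within 5 ppm of the target
and whose ring-plus-double-bond equivalents (RDB = C − H/2 + N/2 + 1,
computed on the neutral composition) lie in [0, 15].  Candidates are
ordered by |ppm| ascending, ties broken by fewer heteroatoms, then Hill
string.  The constraint space is small enough (~4 × 10^5 combinations)
that tests check exact set equality against a vectorised full-grid
enumeration; the search window is widened by a relative 1e-4 so that
boundary candidates are never pruned before the exact ppm test.
An empty candidate list is a valid result.

## Biotransformation templates and cluster expansion

A template is an elemental gain/loss with metadata: phase, a terminal
flag, a per-path application cap, and an optional skeleton retag.  The
stock library covers oxidation (+O), di-oxidation (+O2), methylation
(+CH2), demethylation (−CH2, up to 3 per path — triple demethylation
products are observed), methoxylation (+CH2O), demethoxylation (−CH2O),
flavanone formation (+H2), chalcone formation (+H2, retagged),
carbonyl loss (−CO), methane loss (−CH4), glucuronidation (+C6H8O6) and
sulfation (+SO3).  Conjugations are terminal and limited to one per
path: phase-II products rarely re-enter phase-I chemistry, and the
composite conjugates seen in practice (e.g. methoxylation + sulfation)
remain reachable because conjugation is applied last.  All other
templates default to 2 applications per path.

Node identity is (elemental formula, skeleton tag).  Flavanone and
chalcone formation both add H2 yet are distinct metabolite classes with
different diagnostic ions, so they yield distinct nodes; conflating
them would collapse isomeric classes.  The graph is a directed
multigraph: a formula reachable along several routes keeps every
incoming edge, which is how cluster intersection is represented.

`expand` is an exact breadth-first enumeration of legal template
sequences out of each expandable center (applicability, per-path caps
counting the center's own history, terminal-last, absolute generation
cap — default 3, i.e. tertiary clusters).  From a fresh seed the
closure runs to the full generation cap; resuming an existing graph
defaults to one hop per call, so that after `promote_centers` the next
generation appears only around confirmed centers — one round of the
iterative workflow.  A node's stored path is a shortest one; its
generation is that path's length.

## MS^1 screening

HREIC: per MS^1 scan, intensities of peaks within ±5 ppm of a predicted
ion m/z are summed; apexes are 3-point local maxima above the polarity
threshold (10,000 negative / 40,000 positive), with no smoothing.
MMDF: a peak passes when, for some template, it lies within ±50 Da of
the template mass and its mass defect (fractional mass, mDa) lies
within ±50 mDa of the template defect.  Filtering is applied to
centroid peaks per scan; features are then grouped via the chromatogram
trace.

Templates are built per cluster center: each center contributes its own
(prototype, +glucuronide, +sulfate) triple with defects derived from
the neutral monoisotopic masses, so the filter tracks the network as it
grows.  Published prototype-filter defects are not always derivable
from the stated composition (a known 113.08 vs 105.25 mDa discrepancy
for the tetramethoxyflavone prototype); `center_defect` therefore
accepts a manual override for replaying historical settings, and the
auto-derived value is the default.

## MS^n confirmation

Fragment matching is nominal-mass with ±0.5 Th tolerance: the printed
MS^2/MS^3 strings and the emulated ion trap both operate on nominal
masses, while MS^1 matching stays ppm-based (hybrid trap/orbitrap
semantics).  Rules:

* neutral losses — CH3·, CH4, H2O, CO, OCH3·, SO3 (80), glucuronyl
  (176); both the exact and the nominal loss mass are accepted;
* the n × 15 methyl-ladder screen, with ladder depth measured from the
  root precursor across the whole tree (MS^3 re-isolation extends it);
* diagnostic product ions — 151+X for flavones with X ∈ {0, 14, 16,
  30} (config-extensible), 211 as MS^2 base peak for flavanones, 221
  (plus a minor 197) for chalcones.

Classification precedence: glucuronyl loss, SO3 loss, flavanone base
peak, chalcone 221, then flavone (151+X or ladder depth >= 2), else
unclassified.  Conjugate losses outrank DPIs because an intact
conjugate loss is unambiguous while DPIs can co-occur; the ladder
depth >= 2 requirement stops a single methyl loss — common to nearly
every methoxylated skeleton — from forcing a flavone call.  For
conjugates the aglycone sub-tree, when acquired, is classified
recursively and recorded as the inner skeleton.

A screen hit is *identified* when at least one of its MS^n trees
classifies as the class its reaction path predicts; *potential* when no
tree was acquired; *potential with a conflict flag* when trees exist
but the evidence is absent or contradictory.

## Pipeline

Rounds of expand(one hop from centers) → screen → confirm → promote run
until a round confirms nothing new or the generation cap is reached.
Records merge dual-polarity observations of one metabolite (two ion
entries, one record); isomers — same formula and skeleton tag at
retention times more than 0.3 min apart — become separate records
suffixed a/b/c by ascending retention time.  Reports are deterministic:
identical inputs and configuration produce byte-identical TSV.

## Synthetic ground truth

No public raw data exist for the in-vivo study this toolkit targets, so
validation is closed-loop on simulated runs.  The generator emulates
the stated acquisition: full-scan m/z 100–1000, Gaussian elution
(sigma 0.05 min), N(0, sigma_ppm) mass error (default 2 ppm, matching
the sub-5-ppm errors of the printed tables), data-dependent MS^2/MS^3
with optional parent-ion list, dynamic exclusion (repeat count 5,
repeat window 30 s, exclusion 60 s) and top-N fallback.  Planted
networks are parent-closed — a planted node's precursor node is always
planted — because iterative center promotion can only reach a node
through its confirmed parent.  Fragment spectra invert the confirmation
rules per class with fixed relative-intensity profiles (base peak 100,
minors 3–45) loosely patterned on observed spectra; the profiles are
configuration, not claims.  Background peaks are uniform in m/z, hence
uniform in mass defect, giving MMDF measurable rejection power; density
defaults to 200 peaks per scan with log-normal intensities mostly below
the MS^1 thresholds.  One polarity per generated run; dual-mode
workflows use paired runs.

What the simulation does not model: matrix effects and ion
suppression, isotopologue envelopes, profile-mode peak shapes,
chromatographic drift between runs, and positional isomerism beyond
the skeleton tag.  Passing closed-loop tests therefore demonstrates
the correctness of the data-mining chain under its own stated
fragmentation model, not instrument-level realism.

Benchmark sizes were chosen to keep the full suite fast while covering
every stage: the standard recovery experiment plants the prototype plus
20 metabolites over three generations in one 30-minute positive-mode
run (600 MS^1 scans); at 2 ppm error and zero background the pipeline
recovers all 21 nodes with exact generation assignment and no false
positives.

## Known limitations

* Only ±H single-charge ions; no adducts, no multiple charging, no
  isotope-pattern scoring.
* Center counts per generation on real data depend on which nodes an
  analyst confirms; the package reports them but ships no re-analysis
  of the original animal dataset (raw files are not deposited).
* Concentration gating of cluster propagation is not modeled; any
  identified node is promoted.
* Structure elucidation stops at the skeleton class; positional
  isomers share a node and are distinguished only chromatographically.
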