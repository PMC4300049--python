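# Methods

## DNA thermodynamics

Duplex and structure energetics follow the unified DNA nearest-neighbor
framework. The ten unique Watson–Crick stack increments (stored as all 16
top-strand dinucleotides in `data/nn_params.json`) carry (ΔH°, ΔS°) in
kcal/mol and cal/(mol·K); free energies are recomputed as ΔG(T) = ΔH − T·ΔS
at any evaluation temperature (default 37 °C), which matters because the
decreasing-temperature protocol is ordered by melting temperature, not by a
single-temperature ΔG. Loop penalties (hairpin, bulge, internal) are ΔG37
tables treated as purely entropic (ΔH = 0), extrapolated beyond tabulated
sizes with the Jacobson–Stockmayer form ΔG(n) = ΔG(x) + 2.44·R·T·ln(n/x).
Multibranch loops use a linear penalty a + b·(branches) with a = 3.4,
b = 0.4 kcal/mol (entropic); no published linear multibranch set exists for
DNA, so these are package choices of RNA-like magnitude. Bimolecular
structures add a duplex-initiation term (ΔH = 0.2, ΔS = −5.7) and, for two
identical strands, the C2-symmetry correction ΔS = −1.4. Perfect-duplex
energies (`duplex_energy`) additionally apply the per-end terminal-A·T
correction. Dangling ends, coaxial stacking and terminal mismatches are not
modeled; single-base bulges do not retain their flanking stack. The
parameter file's SHA-256 is logged at load and echoed into run manifests.

## MFE folding and co-folding

`mfe_fold` is a Zuker-style dynamic program (paired matrix V, multibranch
helper WM, external contour) over Watson–Crick pairs with minimum hairpin
size 3 and interior/bulge loops capped at 30 nt (the cap is a speed device;
structures whose loops fit under the cap are unaffected). The kernel is
compiled with numba; decision matrices recorded during the fill make the
traceback a cheap table walk, and the reported (ΔG, ΔH, ΔS) are recomputed
from the traced structure so ΔG = ΔH − T·ΔS holds to 1e−6 by construction.

`mfe_cofold` folds the concatenation of the two strands across a nick.
Hairpin/bulge/internal loops whose backbone path crosses the nick cost
nothing and are exempt from the minimum hairpin size and the loop cap (they
are exterior-like); multibranch loops keep their penalty even when nicked —
a deliberate simplification that keeps the recursion standard and the model
identical between the dynamic program and the exhaustive test oracle. The
initiation (+symmetry) term applies exactly once when the structure contains
an inter-strand pair; the DP handles this correctly by minimizing spanning
and non-spanning structures separately before comparing. Co-folding is
symmetric in strand order (inputs are canonicalized), and `cofold(a, a)`
covers the "fragment with an identical copy" case.

Ties between equal-energy structures are broken deterministically by the
traceback's fixed scan order (5'-most candidate first). The empty structure
(ΔG = 0) is returned whenever nothing folds below zero.

## Melting temperatures

Two-state model on the MFE structure's (ΔH, ΔS): unimolecular structures
melt at Tm = ΔH/ΔS; bimolecular ones at Tm = ΔH / (ΔS + R·ln(C_T/x)) with
x = 4 for two different strands, x = 1 for a self-pair, and C_T the total
strand concentration (default 0.4 µM per strand, the 20 pmol / 50 µL scale
of the validation experiments). Structures without pairs have no Tm. How
"the temperature needed to unfold" should be derived from free energy is
genuinely open; the two-state choice is documented, not forced.

## Assembly semantics

`folding_order` evaluates every unordered fragment pair including self-pairs
(k fragments → k(k+1)/2 co-folds) and ranks them by descending Tm with a
lexicographic tie-break. `check_base_protocol` classifies each event:
*designed* if it pairs a helper with one of its two designed adjacent mains;
otherwise *improper* when its Tm reaches the lowest designed-event Tm and
*harmless* below it — sub-threshold events occur only after every junction
has formed, when all fragments are already held in the growing complex. A
designed junction that produces no favorable duplex at all, or a junction
with no helper, is reported as a conflict in its own right. The improper
threshold is a documented design choice: the ordering principle is given by
the protocol, the cutoff is not.

`plan_protocol` partitions conflicting sets into contiguous genomic blocks:
junctions without a helper are mandatory cut points, and every conflicting
pair needs at least one cut strictly between its members — minimal cuts via
the classical earliest-right-endpoint interval-stabbing greedy (optimal for
contiguous partitions; exact minimization over arbitrary partitions would be
graph coloring). Self-pair conflicts and junctions that never hybridize
cannot be fixed by partitioning and mark the design infeasible; the
optimizer penalizes S (capped, default 8) rather than raising. S counts leaf
tubes plus binary merges, so one tube gives S = 1 and two tubes give S = 3.
Products of merged tubes are assumed duplex-protected; conflicts between
merge-level products are not re-checked.

## Optimizer

Mutation-only (μ+μ) evolution: every parent produces one child by one of
three equally likely operators; invalid moves are resampled within the drawn
operator (up to 20 times) before falling back to a parent copy. Succession
selects μ−1 individuals from the combined pool by proportional, linear-rank
or size-2 tournament selection, plus one preserved elite (whether the
original scheme was elitist is unstated; elitism makes the best-F trace
monotone and the runs easier to reason about). Steepest-ascent hill climbing
over the full single-step neighborhood refines the final best design by
default (placement of the climb inside the loop is configurable). Default
weights w_C = w_N = w_S = 1; oligo length bounds default to 20–80 nt (the
chemical-synthesis cap) with a 10-nt minimum helper overlap per junction
side. Initial cuts are sampled sequentially within feasibility windows
(valid by construction, approximately uniform); helper windows are centered
on their junction and clamped, with min_overlap room reserved before the
next junction so left-to-right placement cannot dead-end.

Pair energies are cached by sequence pair in the shared `EnergyModel`; a
mutation changes at most 3 oligos, so at most 3·(fragment count) pairs are
refolded per evaluation, and cached results are bit-identical to fresh ones.

## The mixture simulation and what it shows

`estimate_success_rate` draws a random 60–80 nt target (uniform base
composition), splits it uniformly subject to both mains lying in 20–40 nt,
takes the helper as the reverse complement of a window centered on the split
(length 20–40, clipped at the target ends — "centered" is the package's
reading of a loosely specified placement), and applies the base-protocol
check to the three strands; it reports the success fraction over 10000
seeded trials with a 95 % Wilson interval.

Under the threshold criterion described above, roughly 95 % of such mixtures
pass: a centered 20–40 nt helper gives both junction duplexes ≥ 10 bp
(Tm ≈ 40–70 °C), which outranks the 4–6 bp hairpins and chance cross-dimers
random 20–40-mers typically harbor (Tm ≲ 40 °C). The rate is extremely
sensitive to the correctness criterion: demanding instead that every
fragment be entirely free of favorable off-design structure at *any*
temperature sends the rate to ~0 %, but that stricter reading also condemns
the bench-validated 11-oligo set (whose oligos carry harmless sub-threshold
self-structure), so the threshold criterion is the one this package stands
behind. Reported success rates should therefore be compared across designs
under one fixed criterion, not read as absolute assembly probabilities; the
simulation also ignores hybridization kinetics, dangling-end stabilization
and ligase-side effects.

## Synthetic data and scope of the tests

Test fixtures are either the printed bench oligo sets (pinned by SHA-256) or
programmatically constructed designs. Several use an alphabet trick — coding
strands over {A, C} only, whose helpers are G/T-only — so that no off-design
Watson–Crick pair can exist and single-tube verdicts are exact by
construction; engineered conflicts insert a mixed-alphabet reverse-
complement repeat shared by two mains. These constructions make verdicts
deterministic but are far tamer than natural sequence: passing them shows
the machinery is correct, not that real genes assemble at any particular
rate. The folding engine is validated against an independently written
exhaustive enumeration oracle on strands and pairs up to 16 nt (beyond
which enumeration is infeasible); the property suites (round-trip
reconstruction, cache bit-identity, seeded reproducibility, monotone best-F)
replace the original multi-day optimization runs with minutes-scale checks:
the full published-scale run (200 individuals × 466 generations on a
~100-residue protein) is deliberately not reproduced.

## Numerical choices and degenerate inputs

Energies are float64 throughout; traceback candidate matching uses a 1e−6
tolerance. Empty structures are canonical for ΔG ≥ 0. Fitness of designs
whose helper windows repeat elsewhere in the coding strand (possible for
low-complexity peptides such as poly-Met/Trp) is computed with S at the
infeasibility cap instead of erroring, keeping the search connected.
Single-main designs have no junctions and are trivially single-tube.
`F_N` is 0 for k = 1 (N = N_main = N_min). Stop codons (default TAA,
configurable) terminate every design and are excluded from F_C, since usage
tables rarely report stop frequencies meaningfully.
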