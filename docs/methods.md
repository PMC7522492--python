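# Methods

## Strategy classification

For each cell with at least one incident chemical connection we form two
delta lists under the convention `delta = birth(pre) − birth(post)`
(minutes): *pre-role* deltas for connections where the cell is presynaptic
and *post-role* deltas where it is postsynaptic; together they partition
the cell's incident connections. The base label follows the sign of the
mean over all incident deltas: negative → N–P coupling, positive → P–N
coupling. P–N is terminal (a pure strategy). For N–P cells the refinements
are tested in order of strictness and the first that holds is attached:

1. **XNOR** — every presynaptic partner born strictly before the cell and
   every postsynaptic partner strictly after;
2. **XOR First Mover** — every presynaptic partner strictly before;
3. **XOR Second Mover** — every postsynaptic partner strictly after.

Two deliberate numerical choices:

* **Ties.** Bilateral L/R pairs are born the same minute, so exact-zero
  deltas occur. A same-minute partner counts as neither earlier nor later:
  its delta enters the mean as 0 but is excluded from the universal tests
  (otherwise every bilateral pair would spuriously break exclusivity). A
  mean of exactly zero is resolved by a policy label (default N–P) and
  logged.
* **Majority vs universal.** The base label is a mean-sign (majority)
  judgement; refinements are universal with zero tolerated violations. The
  `Policy` object exposes both choices (tie label; strict vs
  fraction-tolerant refinements) so alternative readings are testable, but
  the defaults above define the package's semantics, and the brute-force
  oracle used in the tests transcribes exactly these predicates from
  partner birth times.

Classification is deterministic and independent of record order. Duplicate
(pre, post, stability) rows collapse to one relationship by default: the
analysis concerns pairwise cell–cell relationships, not synapse counts.

An immediate consequence of the definitions, worth stating because it is
easy to misread: both endpoints of a single old→young connection see the
same negative delta, so *both* classify as maximally conforming N–P (XNOR)
cells; a cell is P–N only when its incident deltas are positive on average.

## Game machinery

A strategy profile is a 2×2 joint probability over (synaptic role × birth
order); its conformity is the mass on (presynaptic partner born first) +
(postsynaptic partner born second). The reference profile
(0.375/0.125/0.125/0.375) gives 0.75.

The payoff matrix for a presynaptic cell is parameterized by FREQ
(empirically observed frequency, in [0, 1]) and two non-negative milieu
estimates M (molecular) and N (neurophysiological); no estimation
procedure exists for M and N, so they are free configuration parameters
with a warning (not an error) when FREQ·(M+N) > 1 pushes utilities out of
[0, 1]. The (subsequent, random) entry is implemented literally as
FREQ/0.5 = 2·FREQ as printed in the source formulation; a switch
(`subsequent_random_literal=False`) selects the plausible intended reading
FREQ·0.5. Only the presynaptic cell's payoffs are defined; the
postsynaptic side's matrix is not specified in the source and is not
implemented.

## Growth simulator

`simulate_growth` introduces cells in birth order. Each newcomer makes
`max(1, Poisson(attach_rate))` connection attempts toward strictly
earlier-born cells. An attempt conforms to the newcomer's planted strategy
with probability `conformity`: N–P-family newcomers receive a connection
from an earlier-born N–P-family cell (negative delta for both ends);
P–N newcomers connect presynaptically toward an earlier-born cell,
preferring P–N elders, for whom the positive delta also conforms. A
non-conforming attempt inverts the direction and draws from all elders.
Partner choice is uniform by default; a `partner_kernel` hook accepts
alternative kernels (e.g. degree-preferential). Stability classes are
drawn i.i.d. from the configured mix (default 0.43/0.14/0.43
transient/developmental/stable). Every edge is recorded in the truth file
with its initiator and a conforming flag.

The strategy definitions impose structural requirements that pure
conforming attachment cannot produce: a *plain* N–P cell must carry both a
younger presynaptic partner and an older postsynaptic partner (otherwise
it satisfies a refinement), XOR-First an older postsynaptic partner, and
XOR-Second a younger presynaptic partner; cells at the extremes of the
birth order cannot realize some labels at all (the earliest-born cell has
no elders to connect out to; the latest has no juniors to receive from).
At partial conformity the random direction inversions supply these
minority edges naturally. At `conformity = 1.0` — where classification
must recover every planted label exactly — the simulator instead (a)
anchors the earliest- and latest-born tie groups to P–N, which is feasible
at both extremes and guarantees every interior cell a compatible partner;
(b) places the required definitional minority edges explicitly, choosing
targets whose own definitions tolerate them; and (c) tops up conforming
edges until every cell's mean delta has the sign its base label
prescribes. Repair edges are attributed to their younger endpoint, so no
edge ever involves a cell unborn at its initiator's birth time.

## Synthetic data

The generator emulates the statistical shape of the real developmental
data: birth times are drawn (whole minutes) uniformly within three burst
windows — 210–285, 285–345 and 365–400 min, weighted by window length —
leaving the 345–365 min window quiescent; a configurable fraction of cells
(default 0.5) is created as L/R pairs sharing a birth time and a planted
strategy, as real bilateral classes do. Planted strategies default to the
exclusive-label decomposition of the published population (plain N–P 7,
XOR-First 4, XOR-Second 10, XNOR 8, P–N 24, of 53), conformity defaults to
0.75, and the default attachment rate of 6 partners per newcomer gives
mean total degrees comparable to the analyzed connectome neighborhood
(most cells end with ≥ 8 incident connections, the threshold used when
scoring base-label recovery). Outputs are byte-identical under a fixed
seed.

What the generator does *not* emulate: per-animal variability across
reconstructions, synapse weights or per-timepoint dynamics, gap-junction
connectivity, spatial or lineage structure, and any correlation between a
cell's strategy and its birth time beyond what the growth rules induce.
Passing recovery tests on this data therefore demonstrate that the
classifier inverts the generative model under its stated noise — not that
real cells follow these strategies.

## Problem sizes and enumeration scales

The default study-condition dataset uses 60 cells (≈290 connections), the
planted-recovery checks 20 seeds at full conformity plus one fixed seed at
0.75, and the distributional checks on the stability mix use a ~10,000-edge
network. Oracle-equivalence testing enumerates all three-cell tables over
all birth assignments in {0, 1, 2} crossed with all 2⁶−1 edge subsets,
all 2¹²−1 edge subsets at four cells for representative birth patterns
(including ties and an all-tied degenerate case), and 400 seeded random
tables at five and six cells; exhaustive enumeration at six cells (2³⁰
subsets) is not attempted.

## Known limitations

* Family parsing is heuristic (strip trailing L/R/D/V while more than two
  characters remain, digits block stripping, plus an override table); an
  explicit `family` column in the catalog always wins. The published
  family table is shipped as a fixture rather than re-derived from names.
* The published per-strategy stability-class percentages have no derivable
  denominator (the P–N row alone exceeds 100%); the package instead
  reports, per strategy, the class composition of its cells' incident
  connections, which sums to 1 by construction.
* The analyzed population is the 53 printed cell classes; the pairwise
  matrix over them has 53² = 2,809 entries including the zero diagonal.
* Real birth-time tables and synapse tables can be supplied as CSV/TSV at
  the same schemas; no download is attempted by any code path.
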