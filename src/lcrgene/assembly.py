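"""Oligo construction and decreasing-temperature assembly planning.

A gene is assembled from *main chains* — oligos that tile the coding strand
without gaps or overlaps — and *helper chains*, oligos complementary to the
coding strand across each junction between adjacent mains, which hold the
mains together for ligation.  During assembly the mixture cools slowly from a
fully denaturing temperature, so duplexes form in descending melting-
temperature (Tm) order.  The protocol is *correct* when every duplex that
forms at or above the temperature of the weakest designed junction event is
itself a designed helper/main event; any other pair risks mis-assembly and is
a *conflict*.  Conflicting fragments are separated into different tubes
(complex protocol) whose products are merged by further base-protocol steps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .thermo import EnergyModel, revcomp

__all__ = [
    "Fragment",
    "GeneDesign",
    "JunctionMap",
    "AssemblyProtocol",
    "ConflictReport",
    "DesignConstraints",
    "build_fragments",
    "reconstruct",
    "infer_junctions",
    "folding_order",
    "check_base_protocol",
    "plan_protocol",
    "plan_protocol_fragments",
]

log = logging.getLogger(__name__)

_ACGT = frozenset("ACGT")


class DesignError(ValueError):
    """A design or fragment set violates the assembly invariants."""


@dataclass(frozen=True)
class DesignConstraints:
    """Chemical-synthesis and overlap bounds for designed oligos (nt)."""

    l_min: int = 20
    l_max: int = 80
    min_overlap: int = 10

    def __post_init__(self) -> None:
        if not (1 <= self.l_min <= self.l_max):
            raise DesignError("need 1 <= l_min <= l_max")
        if self.min_overlap < 1 or 2 * self.min_overlap > self.l_max:
            raise DesignError("min_overlap incompatible with l_max")


@dataclass(frozen=True)
class Fragment:
    """A single oligo, written 5'->3'.

    Mains are pieces of the coding strand and carry a 5' phosphate so ligase
    can seal their upstream nick; helpers are reverse complements of coding-
    strand windows and are not phosphorylated.
    """

    name: str
    sequence: str
    role: str  # "main" | "helper"
    phosphorylated: bool

    def __post_init__(self) -> None:
        if self.role not in ("main", "helper"):
            raise DesignError(f"unknown role {self.role!r}")
        bad = set(self.sequence) - _ACGT
        if bad:
            raise DesignError(
                f"fragment {self.name}: non-ACGT character(s) {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GeneDesign:
    """Coding strand plus the main-chain cuts and helper windows.

    ``cuts`` are 0-based positions splitting ``dna`` into k mains;
    ``helpers`` are 0-based half-open intervals on the coding strand whose
    reverse complements are the helper oligos.  Every internal junction must
    be covered by exactly one helper with at least ``min_overlap`` nt on each
    side, and helpers must not overlap one another.
    """

    dna: str
    cuts: tuple[int, ...]
    helpers: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "dna", self.dna.strip().upper())
        object.__setattr__(self, "cuts", tuple(sorted(self.cuts)))
        object.__setattr__(self, "helpers", tuple(sorted(self.helpers)))

    @property
    def n_main(self) -> int:
        return len(self.dna)

    @property
    def k(self) -> int:
        return len(self.cuts) + 1

    def main_intervals(self) -> list[tuple[int, int]]:
        bounds = (0,) + self.cuts + (len(self.dna),)
        return [(bounds[i], bounds[i + 1]) for i in range(len(bounds) - 1)]

    def validate(self, constraints: DesignConstraints = DesignConstraints()) -> None:
        c = constraints
        n = len(self.dna)
        if n == 0:
            raise DesignError("empty coding strand")
        bad = set(self.dna) - _ACGT
        if bad:
            raise DesignError(f"non-ACGT character(s) {sorted(bad)} in coding strand")
        if len(set(self.cuts)) != len(self.cuts):
            raise DesignError("duplicate cut positions")
        for cut in self.cuts:
            if not (0 < cut < n):
                raise DesignError(f"cut {cut} outside (0, {n})")
        for idx, (a, b) in enumerate(self.main_intervals()):
            length = b - a
            if not (c.l_min <= length <= c.l_max):
                raise DesignError(
                    f"main chain {idx + 1} has length {length}, "
                    f"bounds [{c.l_min}, {c.l_max}]"
                )
        prev_end = -1
        for s, e in self.helpers:
            if not (0 <= s < e <= n):
                raise DesignError(f"helper ({s}, {e}) outside coding strand")
            if not (c.l_min <= e - s <= c.l_max):
                raise DesignError(
                    f"helper ({s}, {e}) has length {e - s}, "
                    f"bounds [{c.l_min}, {c.l_max}]"
                )
            if s < prev_end:
                raise DesignError(f"helper ({s}, {e}) overlaps the previous helper")
            prev_end = e
        for cut in self.cuts:
            covering = [
                (s, e)
                for s, e in self.helpers
                if s <= cut - c.min_overlap and cut + c.min_overlap <= e
            ]
            if len(covering) != 1:
                raise DesignError(
                    f"junction at {cut} covered by {len(covering)} helper(s) "
                    f"with >= {c.min_overlap} nt on each side, need exactly 1"
                )
        for s, e in self.helpers:
            spanned = [cut for cut in self.cuts if s < cut < e]
            if len(spanned) != 1:
                raise DesignError(
                    f"helper ({s}, {e}) spans {len(spanned)} junction(s), "
                    "need exactly 1"
                )


@dataclass(frozen=True)
class JunctionMap:
    """Designed adjacency: which helper seals which main/main junction.

    ``covered`` maps a junction index (0-based, between main i and main i+1)
    to (helper name, left main name, right main name); ``uncovered`` lists
    junction indices with no helper (these can never assemble in one tube and
    force a tube boundary).  ``positions`` gives each fragment's slot on the
    genomic axis used for contiguous tube partitioning.
    """

    main_names: tuple[str, ...]
    covered: dict[int, tuple[str, str, str]]
    uncovered: tuple[int, ...]
    positions: dict[str, int]

    def designed_pairs(self) -> set[frozenset]:
        out: set[frozenset] = set()
        for helper, left, right in self.covered.values():
            out.add(frozenset((helper, left)))
            out.add(frozenset((helper, right)))
        return out


def build_fragments(
    design: GeneDesign,
    constraints: DesignConstraints = DesignConstraints(),
    prefix: str = "frag",
    validate: bool = True,
) -> list[Fragment]:
    """Oligos of a design: k phosphorylated mains + (k-1) helpers.

    Fragments are named ``{prefix}1..{prefix}{2k-1}`` in genomic order with
    mains at odd and helpers at even indices, matching the usual bench
    convention.
    """
    if validate:
        design.validate(constraints)
    mains = design.main_intervals()
    cut_to_helper = {}
    for s, e in design.helpers:
        for idx, cut in enumerate(design.cuts):
            if s < cut < e:
                cut_to_helper[idx] = (s, e)
    fragments: list[Fragment] = []
    for i, (a, b) in enumerate(mains):
        fragments.append(
            Fragment(f"{prefix}{2 * i + 1}", design.dna[a:b], "main", True)
        )
        if i in cut_to_helper:
            s, e = cut_to_helper[i]
            fragments.append(
                Fragment(f"{prefix}{2 * i + 2}", revcomp(design.dna[s:e]), "helper", False)
            )
    return fragments


def reconstruct(fragments: list[Fragment]) -> tuple[str, int]:
    """Concatenate the mains back into the coding strand and validate helpers.

    Mains are taken in list order.  Each helper's reverse complement must
    occur exactly once in the concatenation and span exactly one junction.
    Returns (coding strand, length in nt).
    """
    mains = [f for f in fragments if f.role == "main"]
    helpers = [f for f in fragments if f.role == "helper"]
    if not mains:
        raise DesignError("no main chains to reconstruct")
    dna = "".join(f.sequence for f in mains)
    cuts = []
    pos = 0
    for f in mains[:-1]:
        pos += len(f.sequence)
        cuts.append(pos)
    for h in helpers:
        window = revcomp(h.sequence)
        count = dna.count(window)
        if count == 0:
            raise DesignError(
                f"helper {h.name} matches no locus on the reconstructed strand"
            )
        if count > 1:
            raise DesignError(
                f"helper {h.name} matches {count} loci (repeat the design "
                "should have avoided)"
            )
        s = dna.index(window)
        e = s + len(window)
        spanned = [c for c in cuts if s < c < e]
        if len(spanned) != 1:
            raise DesignError(
                f"helper {h.name} spans {len(spanned)} junction(s), need exactly 1"
            )
    return dna, len(dna)


def infer_junctions(fragments: list[Fragment]) -> JunctionMap:
    """Designed adjacency of a fragment set (mains in list order)."""
    mains = [f for f in fragments if f.role == "main"]
    helpers = [f for f in fragments if f.role == "helper"]
    dna, _ = reconstruct(fragments)
    cuts = []
    pos = 0
    for f in mains[:-1]:
        pos += len(f.sequence)
        cuts.append(pos)
    covered: dict[int, tuple[str, str, str]] = {}
    positions: dict[str, int] = {}
    for i, m in enumerate(mains):
        positions[m.name] = i + 1
    for h in helpers:
        window = revcomp(h.sequence)
        s = dna.index(window)
        e = s + len(window)
        for idx, cut in enumerate(cuts):
            if s < cut < e:
                if idx in covered:
                    raise DesignError(
                        f"junction {idx} covered by {covered[idx][0]} and {h.name}"
                    )
                covered[idx] = (h.name, mains[idx].name, mains[idx + 1].name)
                positions[h.name] = idx + 1  # stays left of a cut at its junction
    uncovered = tuple(i for i in range(len(cuts)) if i not in covered)
    return JunctionMap(
        main_names=tuple(m.name for m in mains),
        covered=covered,
        uncovered=uncovered,
        positions=positions,
    )


def folding_order(
    fragments: list[Fragment], model: EnergyModel
) -> list[tuple[tuple[str, str], float]]:
    """All fragment pairs (self-pairs included) ranked by descending Tm.

    Pairs whose co-fold has no favorable structure are omitted.  Ties break
    lexicographically on the (sorted) pair names for determinism.
    """
    if not fragments:
        raise DesignError("no fragments")
    by_name = {f.name: f for f in fragments}
    if len(by_name) != len(fragments):
        raise DesignError("duplicate fragment names")
    names = sorted(by_name)
    events = []
    for i, a in enumerate(names):
        for b in names[i:]:
            tm = model.pair_tm(by_name[a].sequence, by_name[b].sequence)
            if tm is not None:
                events.append(((a, b), tm))
    events.sort(key=lambda ev: (-ev[1], ev[0]))
    return events


@dataclass(frozen=True)
class ConflictReport:
    """Outcome of the folding-order check.

    ``verdict`` is "correct" when the set can be assembled in one tube:
    every designed junction hybridizes and no undesigned pair melts at or
    above the weakest designed event.  ``conflicts`` lists offending pairs
    with reasons; ``details`` classifies every event.
    """

    verdict: str  # "correct" | "conflicting"
    conflicts: tuple[tuple[tuple[str, str], str], ...]
    details: tuple[tuple[tuple[str, str], float, str], ...]
    threshold: float | None

    @property
    def correct(self) -> bool:
        return self.verdict == "correct"


def check_base_protocol(
    fragments: list[Fragment],
    junctions: JunctionMap | None = None,
    model: EnergyModel | None = None,
    events: list[tuple[tuple[str, str], float]] | None = None,
) -> ConflictReport:
    """Walk folding events in descending Tm and classify each one.

    An event is *designed* when it pairs a helper with one of its two
    designed adjacent mains.  Any other event whose Tm reaches the lowest
    designed-event Tm is *improper* (it would form before assembly is
    complete); events below all designed events are harmless.  A designed
    junction with no favorable duplex at all, or with no helper, is reported
    as missing.
    """
    if model is None and events is None:
        raise DesignError("need an EnergyModel or a precomputed event list")
    if junctions is None:
        junctions = infer_junctions(fragments)
    if events is None:
        events = folding_order(fragments, model)
    designed = junctions.designed_pairs()
    seen_designed = {
        frozenset(pair) for pair, _ in events if frozenset(pair) in designed
    }
    designed_tms = [tm for pair, tm in events if frozenset(pair) in designed]
    threshold = min(designed_tms) if designed_tms else None

    conflicts: list[tuple[tuple[str, str], str]] = []
    details: list[tuple[tuple[str, str], float, str]] = []
    for pair, tm in events:
        if frozenset(pair) in designed:
            details.append((pair, tm, "designed-junction"))
        elif threshold is not None and tm >= threshold - 1e-9:
            details.append((pair, tm, "improper"))
            conflicts.append((pair, f"undesigned duplex at Tm {tm:.1f} C "
                                    f"outranks a designed junction"))
        else:
            details.append((pair, tm, "harmless"))
    for pair in designed - seen_designed:
        a, b = sorted(pair)
        conflicts.append(((a, b), "designed junction forms no favorable duplex"))
    for idx in junctions.uncovered:
        left = junctions.main_names[idx]
        right = junctions.main_names[idx + 1]
        conflicts.append(((left, right), f"junction {idx} has no helper"))
    verdict = "correct" if not conflicts else "conflicting"
    return ConflictReport(verdict, tuple(conflicts), tuple(details), threshold)


@dataclass(frozen=True)
class AssemblyProtocol:
    """Planned assembly: event order, conflicts, tube partition and S.

    ``tubes`` are leaf tubes (lists of fragment names, contiguous on the
    genomic axis); ``merge_tree`` is a left-deep binary tree over tube
    indices; ``S`` counts base-protocol executions = leaf tubes + merges.
    """

    events: tuple[tuple[tuple[str, str], float], ...]
    conflicts: tuple[tuple[tuple[str, str], str], ...]
    tubes: tuple[tuple[str, ...], ...]
    merge_tree: object
    S: int
    feasible: bool
    report: ConflictReport

    def __post_init__(self) -> None:
        if self.S < 1:
            raise DesignError("S must be >= 1")


def _stab_cuts(
    intervals: list[tuple[int, int]], mandatory: set[int]
) -> set[int]:
    """Minimal cut set stabbing every interval (earliest-right-end greedy)."""
    cuts = set(mandatory)
    for lo, hi in sorted(intervals, key=lambda iv: iv[1]):
        if not any(lo <= c <= hi for c in cuts):
            cuts.add(hi)
    return cuts


def plan_protocol_fragments(
    fragments: list[Fragment],
    junctions: JunctionMap | None = None,
    model: EnergyModel | None = None,
    max_tubes: int = 8,
) -> AssemblyProtocol:
    """Plan a base or complex protocol for an explicit fragment set.

    Conflict-free sets get one tube (S = 1).  Otherwise fragments are split
    into contiguous genomic blocks: junctions without a helper are mandatory
    cut points, and each conflicting pair needs at least one cut strictly
    between its members (minimal cuts by interval stabbing).  Self-pair
    conflicts and junctions that never hybridize cannot be fixed by
    partitioning and mark the design infeasible (the optimizer penalizes S
    rather than raising).
    """
    if junctions is None:
        junctions = infer_junctions(fragments)
    events = folding_order(fragments, model)
    report = check_base_protocol(fragments, junctions, model=None, events=events)
    k = len(junctions.main_names)
    feasible = True
    intervals: list[tuple[int, int]] = []
    mandatory = {idx + 1 for idx in junctions.uncovered}  # cut slot after main idx+1
    for pair, reason in report.conflicts:
        a, b = pair
        if "no helper" in reason:
            continue  # already a mandatory cut
        if "no favorable duplex" in reason:
            feasible = False
            continue
        pa = junctions.positions.get(a)
        pb = junctions.positions.get(b)
        if pa is None or pb is None:
            feasible = False
            continue
        lo, hi = min(pa, pb), max(pa, pb)
        if lo == hi:
            feasible = False  # self-conflict or same-slot pair: unpartitionable
            continue
        intervals.append((lo, hi - 1))
    cuts = _stab_cuts(intervals, mandatory)
    cuts = {c for c in cuts if 1 <= c <= k - 1}
    boundaries = sorted(cuts)
    n_tubes = len(boundaries) + 1
    if n_tubes > max_tubes:
        feasible = False
    tube_of_slot = {}
    tube = 0
    for slot in range(1, k + 1):
        tube_of_slot[slot] = tube
        if slot in cuts:
            tube += 1
    tubes: list[list[str]] = [[] for _ in range(n_tubes)]
    ordered = sorted(
        junctions.positions.items(),
        key=lambda kv: (kv[1], 0 if kv[0] in junctions.main_names else 1, kv[0]),
    )
    for name, slot in ordered:
        tubes[tube_of_slot[slot]].append(name)
    merge_tree: object = 0
    for t in range(1, n_tubes):
        merge_tree = (merge_tree, t)
    s = n_tubes + (n_tubes - 1)
    return AssemblyProtocol(
        events=tuple(events),
        conflicts=report.conflicts,
        tubes=tuple(tuple(t) for t in tubes),
        merge_tree=merge_tree,
        S=s,
        feasible=feasible,
        report=report,
    )


def plan_protocol(
    design: GeneDesign,
    model: EnergyModel,
    constraints: DesignConstraints = DesignConstraints(),
    prefix: str = "frag",
    max_tubes: int = 8,
) -> AssemblyProtocol:
    """Plan the assembly protocol of a design (see plan_protocol_fragments)."""
    fragments = build_fragments(design, constraints, prefix=prefix)
    junctions = infer_junctions(fragments)
    return plan_protocol_fragments(fragments, junctions, model, max_tubes)
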