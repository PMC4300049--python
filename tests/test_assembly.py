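"""Fragment construction, reconstruction, folding order and tube planning.

Several fixtures exploit an alphabet trick: a coding strand over {A, C} only
cannot form any Watson-Crick pair with itself or with another A/C strand, and
its helpers (G/T only) are equally inert, so the only favorable duplexes are
the designed helper/main overlaps.  That makes single-tube verdicts exact by
construction.
"""

import numpy as np
import pytest

from conftest import random_dna
from lcrgene.assembly import (
    DesignConstraints,
    DesignError,
    Fragment,
    GeneDesign,
    build_fragments,
    check_base_protocol,
    folding_order,
    infer_junctions,
    plan_protocol,
    plan_protocol_fragments,
    reconstruct,
)
from lcrgene.fixtures import load_fixture
from lcrgene.optimizer import EAConfig, init_population
from lcrgene.thermo import revcomp

# 60-nt A/C-only target; helper window (20, 40) occurs once
AC_TARGET = "CAAAACCCAAAACAAACCAAAACCAACCACCCCAACCCCACAACCAAAACCCAAACAAAC"
CLEAN_DESIGN = GeneDesign(AC_TARGET, (30,), ((20, 40),))

# same geometry with an engineered 15-nt reverse-complement repeat shared by
# the two mains, which outranks both designed junctions
_REPEAT = "GCTAGGACGTGATCC"
CONFLICT_DESIGN = GeneDesign(
    _REPEAT + AC_TARGET[15:45] + revcomp(_REPEAT), (30,), ((20, 40),)
)


def table1_design() -> GeneDesign:
    """The 276-nt bench-validated design, rebuilt from its printed oligos."""
    fx = load_fixture("ubp4_prime")
    dna, _ = reconstruct(list(fx.fragments))
    cuts = []
    pos = 0
    for f in fx.mains[:-1]:
        pos += len(f.sequence)
        cuts.append(pos)
    helpers = []
    for h in fx.helpers:
        w = revcomp(h.sequence)
        s = dna.index(w)
        helpers.append((s, s + len(w)))
    return GeneDesign(dna, tuple(cuts), tuple(helpers))


class TestBuildFragments:
    def test_direct_construction(self):
        frags = build_fragments(CLEAN_DESIGN)
        assert [f.role for f in frags] == ["main", "helper", "main"]
        assert [len(f) for f in frags] == [30, 20, 30]
        assert [f.phosphorylated for f in frags] == [True, False, True]
        assert frags[1].sequence == revcomp(AC_TARGET[20:40])

    def test_phosphorylation_marks_exactly_the_mains(self):
        fx = load_fixture("ubp4_prime")
        frags = build_fragments(table1_design(), prefix="Ubp4'")
        assert {f.name: f.sequence for f in frags} == {
            f.name: f.sequence for f in fx.fragments
        }
        phosphorylated = {f.name for f in frags if f.phosphorylated}
        assert phosphorylated == {f"Ubp4'{i}" for i in (1, 3, 5, 7, 9, 11)}

    def test_short_main_rejected(self):
        with pytest.raises(DesignError, match="main chain.*length 5"):
            design = GeneDesign(AC_TARGET[:45], (5,), ((0, 25),))
            design.validate(DesignConstraints(l_min=20, l_max=80, min_overlap=5))


class TestReconstruct:
    @pytest.mark.parametrize(
        "name,length",
        [("ubp4_prime", 276), ("ubp4_dprime_a", 540), ("ubp4_dprime_b", 543)],
    )
    def test_printed_sets_reassemble(self, name, length):
        fx = load_fixture(name)
        dna, n = reconstruct(list(fx.fragments))
        assert n == length and len(dna) == length

    def test_helper_matching_nowhere_rejected(self):
        frags = build_fragments(CLEAN_DESIGN)
        bogus = Fragment("h2", "GTGTGTGTGTGTGTGTGTGT", "helper", False)
        with pytest.raises(DesignError, match="matches no locus"):
            reconstruct(frags[:1] + [bogus] + frags[2:])

    def test_repeated_helper_locus_rejected(self):
        dna = "ACCA" * 15  # periodic: every window repeats
        frags = [
            Fragment("m1", dna[:30], "main", True),
            Fragment("m2", dna[30:], "main", True),
            Fragment("h1", revcomp(dna[20:40]), "helper", False),
        ]
        with pytest.raises(DesignError, match="matches 2 loci|matches \\d+ loci"):
            reconstruct(frags)

    def test_roundtrip_on_random_designs(self, rng):
        # reconstruct(build_fragments(d)) == d.dna for valid random designs
        config = EAConfig(population_size=20, seed=5)
        peptide = "".join("ARNDCQEGHILKMFPSTWYV"[i]
                          for i in rng.integers(0, 20, 40))
        pop = init_population(peptide, __import__("lcrgene").uniform_usage_table(),
                              config, rng)
        for design in pop.individuals:
            dna, n = reconstruct(build_fragments(design, config.constraints))
            assert dna == design.dna and n == design.n_main

    def test_total_nucleotides_within_bounds(self, rng):
        config = EAConfig(population_size=20, seed=6)
        peptide = "".join("ARNDCQEGHILKMFPSTWYV"[i]
                          for i in rng.integers(0, 20, 50))
        pop = init_population(peptide, __import__("lcrgene").uniform_usage_table(),
                              config, rng)
        for design in pop.individuals:
            frags = build_fragments(design, config.constraints)
            n = sum(len(f) for f in frags)
            n_min = design.n_main + (design.k - 1) * config.l_min
            assert n_min <= n <= 2 * design.n_main


class TestFoldingOrder:
    def test_pair_count_bound(self, model):
        frags = build_fragments(CLEAN_DESIGN)
        events = folding_order(frags, model)
        assert len(events) <= 6  # C(3,2) cross + 3 self

    def test_single_inert_fragment_yields_no_events(self, model):
        frags = [Fragment("m1", "ACACCAACCACAACCCACAA", "main", True)]
        assert folding_order(frags, model) == []

    def test_complementary_pair_ranks_first(self, model):
        s = "GACTGCATCGAGCTAGGCAT"
        frags = [
            Fragment("a", s, "main", True),
            Fragment("b", revcomp(s), "helper", False),
            Fragment("c", "A" * 20, "main", True),
        ]
        events = folding_order(frags, model)
        assert set(events[0][0]) == {"a", "b"}


class TestCheckBaseProtocol:
    def test_clean_two_main_design_is_correct(self, model):
        frags = build_fragments(CLEAN_DESIGN)
        report = check_base_protocol(frags, model=model)
        assert report.correct
        classes = {cls for _, _, cls in report.details}
        assert classes == {"designed-junction"}

    def test_engineered_repeat_is_flagged_with_pair(self, model):
        frags = build_fragments(CONFLICT_DESIGN)
        report = check_base_protocol(frags, model=model)
        assert not report.correct
        flagged = {frozenset(pair) for pair, _ in report.conflicts}
        assert frozenset(("frag1", "frag3")) in flagged  # the two mains

    def test_verdict_correct_iff_no_improper_event(self, model):
        for design in (CLEAN_DESIGN, CONFLICT_DESIGN):
            report = check_base_protocol(build_fragments(design), model=model)
            improper = any(cls == "improper" for _, _, cls in report.details)
            missing = any("duplex" in r or "helper" in r
                          for _, r in report.conflicts
                          if "outranks" not in r)
            assert report.correct == (not improper and not missing)


class TestPlanProtocol:
    def test_conflict_free_design_is_single_tube(self, model):
        proto = plan_protocol(CLEAN_DESIGN, model)
        assert proto.S == 1 and len(proto.tubes) == 1 and proto.feasible

    def test_midpoint_conflict_gives_two_tubes_one_merge(self, model):
        proto = plan_protocol(CONFLICT_DESIGN, model)
        assert len(proto.tubes) == 2 and proto.S == 3
        # brute force on the 3-fragment conflict graph: the only minimal
        # contiguous partition separating frag1 from frag3 is a cut at the
        # single junction, helper staying with the left main
        assert proto.tubes == (("frag1", "frag2"), ("frag3",))

    def test_no_improper_pair_co_resident(self, model):
        proto = plan_protocol(CONFLICT_DESIGN, model)
        tube_of = {n: t for t, names in enumerate(proto.tubes) for n in names}
        for (a, b), reason in proto.conflicts:
            if "outranks" in reason:
                assert tube_of[a] != tube_of[b]

    def test_uncovered_junction_forces_tube_boundary(self, model):
        # two abutting mains with no helper across their junction can never
        # assemble in one tube
        frags = [
            Fragment("m1", AC_TARGET[:30], "main", True),
            Fragment("m2", AC_TARGET[30:], "main", True),
        ]
        proto = plan_protocol_fragments(frags, model=model)
        assert len(proto.tubes) == 2 and proto.S == 3
        assert not proto.report.correct
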