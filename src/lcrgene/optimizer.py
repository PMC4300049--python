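"""Evolutionary search over (coding sequence, cuts, helpers) designs.

Each individual is a complete synthesis plan for one peptide: a synonymous-
codon choice for the coding strand, the cut positions splitting it into main
chains, and the helper windows.  Fitness is

    F = 1 / (1 + F_C + F_N + F_S)

with F_C the weighted RMS codon-usage deviation, F_N = w_N (N - N_min) /
(N_max - N_min) the normalized nucleotide cost (N = total oligo nucleotides,
N_min = N_main + (k-1) L_min, N_max = 2 N_main), and F_S = w_S (S - 1)^2 the
protocol-complexity penalty, S being the number of base-protocol executions.

The algorithm is mutation-only (mu + mu): every parent produces one child by
one of three operators (synonymous codon swap, +-1 cut shift, one-step helper
move), parents and offspring compete under proportional, linear-ranking or
k=2 tournament selection with one elite preserved, and a steepest-ascent hill
climb fine-tunes the final best design.  Pair energies are cached in the
shared EnergyModel, so a mutation (which touches at most 3 oligos) only
refolds the pairs whose sequences changed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from . import codon as _codon
from .assembly import (
    AssemblyProtocol,
    DesignConstraints,
    DesignError,
    GeneDesign,
    build_fragments,
    plan_protocol,
)
from .codon import CodonUsageTable, codon_deviation, reverse_translate, translate
from .thermo import EnergyModel

__all__ = [
    "EAConfig",
    "FitnessBreakdown",
    "Population",
    "init_population",
    "mutate",
    "evaluate_fitness",
    "select",
    "hill_climb",
    "run_ea",
]

log = logging.getLogger(__name__)

SELECTION_METHODS = ("proportional", "ranking", "tournament")


@dataclass(frozen=True)
class EAConfig:
    """Run configuration for the evolutionary search."""

    population_size: int = 50
    generations: int = 100
    selection: str = "tournament"
    tournament_k: int = 2
    w_c: float = 1.0
    w_n: float = 1.0
    w_s: float = 1.0
    l_min: int = 20
    l_max: int = 80
    min_overlap: int = 10
    seed: int = 0
    stop_codon: str | None = "TAA"
    mutation_retries: int = 20
    infeasible_s: int = 8
    max_tubes: int = 8
    hill_climb_final: bool = True
    hill_climb_max_rounds: int = 50

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if self.selection not in SELECTION_METHODS:
            raise ValueError(f"selection must be one of {SELECTION_METHODS}")
        if not (1 <= self.l_min <= self.l_max):
            raise ValueError("need 1 <= l_min <= l_max")
        if self.tournament_k < 2:
            raise ValueError("tournament_k must be >= 2")

    @property
    def constraints(self) -> DesignConstraints:
        return DesignConstraints(self.l_min, self.l_max, self.min_overlap)


@dataclass(frozen=True)
class FitnessBreakdown:
    """Components and composite of the multicriteria fitness."""

    f_c: float
    f_n: float
    f_s: float
    fitness: float
    n_total: int
    n_min: int
    n_max: int
    n_main: int
    k: int
    s: int
    feasible: bool = True


@dataclass
class Population:
    individuals: list[GeneDesign]
    fitnesses: list[FitnessBreakdown | None]
    generation: int = 0


def composite_fitness(f_c: float, f_n: float, f_s: float) -> float:
    return 1.0 / (1.0 + f_c + f_n + f_s)


def fitness_from_components(
    f_c: float, n_total: int, n_main: int, k: int, s: int, config: EAConfig,
    feasible: bool = True,
) -> FitnessBreakdown:
    n_min = n_main + (k - 1) * config.l_min
    n_max = 2 * n_main
    denom = n_max - n_min
    f_n = config.w_n * (n_total - n_min) / denom if denom > 0 else 0.0
    f_s = config.w_s * (s - 1) ** 2
    return FitnessBreakdown(
        f_c=f_c,
        f_n=f_n,
        f_s=f_s,
        fitness=composite_fitness(f_c, f_n, f_s),
        n_total=n_total,
        n_min=n_min,
        n_max=n_max,
        n_main=n_main,
        k=k,
        s=s,
        feasible=feasible,
    )


# ---------------------------------------------------------------------------
# construction

def _sample_cuts(n: int, config: EAConfig, rng: np.random.Generator) -> tuple[int, ...]:
    k_min = max(1, -(-n // config.l_max))
    k_max = n // config.l_min
    if k_max < k_min:
        raise DesignError(
            f"no fragmentation of {n} nt fits lengths "
            f"[{config.l_min}, {config.l_max}]"
        )
    k = int(rng.integers(k_min, k_max + 1))
    cuts = []
    prev = 0
    for i in range(1, k):
        remaining = k - i  # mains still to place after this cut
        lo = max(prev + config.l_min, n - remaining * config.l_max)
        hi = min(prev + config.l_max, n - remaining * config.l_min)
        cut = int(rng.integers(lo, hi + 1))
        cuts.append(cut)
        prev = cut
    return tuple(cuts)


def _sample_helpers(
    dna_len: int, cuts: tuple[int, ...], config: EAConfig, rng: np.random.Generator
) -> tuple[tuple[int, int], ...]:
    helpers = []
    prev_end = 0
    bounds = (0,) + cuts + (dna_len,)
    for idx, cut in enumerate(cuts):
        prev_cut = bounds[idx]
        next_cut = bounds[idx + 2]
        # keep min_overlap room clear before the next junction so that a
        # long helper cannot make the following one unplaceable
        next_limit = next_cut - (config.min_overlap if idx < len(cuts) - 1 else 0)
        base = max(prev_end, prev_cut)
        m = config.min_overlap
        len_lo = max(config.l_min, 2 * m)
        len_hi = min(config.l_max, next_limit - base)
        if base > cut - m or cut + m > next_limit or len_lo > len_hi:
            raise DesignError(
                f"cannot place a helper across junction at {cut} under the "
                "given length/overlap constraints"
            )
        length = int(rng.integers(len_lo, len_hi + 1))
        lo = max(base, cut + m - length)
        hi = min(cut - m, next_limit - length)
        start = min(max(cut - length // 2, lo), hi)  # centered, then clamped
        helpers.append((start, start + length))
        prev_end = start + length
    return tuple(helpers)


def init_population(
    peptide: str, table: CodonUsageTable, config: EAConfig,
    rng: np.random.Generator | None = None,
) -> Population:
    """Random initial population: uniform codons, cuts and helper windows."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    individuals = []
    for _ in range(config.population_size):
        dna = reverse_translate(peptide, rng, stop_codon=config.stop_codon)
        cuts = _sample_cuts(len(dna), config, rng)
        helpers = _sample_helpers(len(dna), cuts, config, rng)
        design = GeneDesign(dna, cuts, helpers)
        design.validate(config.constraints)
        individuals.append(design)
    return Population(individuals, [None] * len(individuals), generation=0)


# ---------------------------------------------------------------------------
# mutation

def _mutate_codon(design: GeneDesign, config: EAConfig, rng) -> GeneDesign:
    n_codons = len(design.dna) // 3
    skip_last = config.stop_codon is not None
    limit = n_codons - 1 if skip_last else n_codons
    if limit <= 0:
        return design
    pos = int(rng.integers(limit))
    old = design.dna[3 * pos : 3 * pos + 3]
    synonyms = _codon.AA_TO_CODONS[_codon.CODON_TO_AA[old]]
    new = synonyms[int(rng.integers(len(synonyms)))]
    dna = design.dna[: 3 * pos] + new + design.dna[3 * pos + 3 :]
    return GeneDesign(dna, design.cuts, design.helpers)


def _mutate_cut(design: GeneDesign, config: EAConfig, rng) -> GeneDesign:
    if not design.cuts:
        raise DesignError("no cuts to shift")
    idx = int(rng.integers(len(design.cuts)))
    delta = 1 if rng.integers(2) else -1
    cuts = list(design.cuts)
    cuts[idx] += delta
    return GeneDesign(design.dna, tuple(cuts), design.helpers)


_HELPER_MOVES = ("shorten", "extend", "move_left", "move_right")


def _mutate_helper(design: GeneDesign, config: EAConfig, rng) -> GeneDesign:
    if not design.helpers:
        raise DesignError("no helpers to adjust")
    idx = int(rng.integers(len(design.helpers)))
    s, e = design.helpers[idx]
    move = _HELPER_MOVES[int(rng.integers(4))]
    if move == "shorten":
        s, e = (s + 1, e) if rng.integers(2) else (s, e - 1)
    elif move == "extend":
        s, e = (s - 1, e) if rng.integers(2) else (s, e + 1)
    elif move == "move_left":
        s, e = s - 1, e - 1
    else:
        s, e = s + 1, e + 1
    helpers = list(design.helpers)
    helpers[idx] = (s, e)
    return GeneDesign(design.dna, design.cuts, tuple(helpers))


_OPERATORS = (_mutate_codon, _mutate_cut, _mutate_helper)


def mutate(parent: GeneDesign, config: EAConfig, rng: np.random.Generator) -> GeneDesign:
    """One mutated child: one of three operators, chosen with equal probability.

    The drawn operator is retried (bounded) until the child satisfies the
    design invariants; if no valid move exists the parent is returned
    unchanged.
    """
    op = _OPERATORS[int(rng.integers(3))]
    for _ in range(config.mutation_retries):
        try:
            child = op(parent, config, rng)
            child.validate(config.constraints)
            return child
        except DesignError:
            continue
    log.debug("mutation operator %s found no valid move; returning parent copy",
              op.__name__)
    return GeneDesign(parent.dna, parent.cuts, parent.helpers)


# ---------------------------------------------------------------------------
# evaluation

def evaluate_fitness(
    design: GeneDesign,
    table: CodonUsageTable,
    config: EAConfig,
    model: EnergyModel,
    return_protocol: bool = False,
):
    """FitnessBreakdown of a design (protocol planning included).

    Infeasible protocols are penalized through S capped at
    ``config.infeasible_s`` instead of raising, keeping the search connected.
    """
    f_c = codon_deviation(design.dna, table, config.w_c)
    try:
        protocol = plan_protocol(design, model, config.constraints,
                                 max_tubes=config.max_tubes)
        s = protocol.S if protocol.feasible else config.infeasible_s
        feasible = protocol.feasible
    except DesignError as exc:
        # e.g. a helper window repeated elsewhere in the coding strand:
        # penalize instead of raising so the search stays connected
        log.debug("protocol planning infeasible: %s", exc)
        protocol = None
        s = config.infeasible_s
        feasible = False
    fragments = build_fragments(design, config.constraints, validate=False)
    n_total = sum(len(f) for f in fragments)
    breakdown = fitness_from_components(
        f_c, n_total, design.n_main, design.k, s, config, feasible=feasible,
    )
    if return_protocol:
        return breakdown, protocol
    return breakdown


# ---------------------------------------------------------------------------
# selection

def select(
    fitness_values: list[float],
    n_select: int,
    config: EAConfig,
    rng: np.random.Generator,
) -> list[int]:
    """Indices of selected individuals (with replacement).

    proportional: probability ~ F; ranking: linear rank weights (worst = 1,
    best = mu); tournament: best of k uniform draws.  All-zero fitness under
    proportional falls back to uniform.
    """
    f = np.asarray(fitness_values, dtype=float)
    mu = len(f)
    if mu == 0:
        raise ValueError("empty pool")
    if config.selection == "proportional":
        total = f.sum()
        if total <= 0:
            log.warning("all-zero fitness; proportional selection falls back "
                        "to uniform")
            p = np.full(mu, 1.0 / mu)
        else:
            p = f / total
        return [int(i) for i in rng.choice(mu, size=n_select, p=p)]
    if config.selection == "ranking":
        order = np.argsort(f, kind="stable")  # worst first
        weights = np.empty(mu)
        weights[order] = np.arange(1, mu + 1, dtype=float)
        p = weights / weights.sum()
        return [int(i) for i in rng.choice(mu, size=n_select, p=p)]
    # tournament
    out = []
    for _ in range(n_select):
        contenders = rng.integers(0, mu, size=config.tournament_k)
        best = max(contenders, key=lambda i: (f[i], -i))
        out.append(int(best))
    return out


# ---------------------------------------------------------------------------
# hill climbing

def _neighbors(design: GeneDesign, config: EAConfig):
    skip_last = config.stop_codon is not None
    n_codons = len(design.dna) // 3 - (1 if skip_last else 0)
    for pos in range(n_codons):
        old = design.dna[3 * pos : 3 * pos + 3]
        for new in _codon.AA_TO_CODONS[_codon.CODON_TO_AA[old]]:
            if new != old:
                dna = design.dna[: 3 * pos] + new + design.dna[3 * pos + 3 :]
                yield GeneDesign(dna, design.cuts, design.helpers)
    for idx in range(len(design.cuts)):
        for delta in (-1, 1):
            cuts = list(design.cuts)
            cuts[idx] += delta
            yield GeneDesign(design.dna, tuple(cuts), design.helpers)
    for idx in range(len(design.helpers)):
        s, e = design.helpers[idx]
        for ns, ne in ((s + 1, e), (s, e - 1), (s - 1, e), (s, e + 1),
                       (s - 1, e - 1), (s + 1, e + 1)):
            helpers = list(design.helpers)
            helpers[idx] = (ns, ne)
            yield GeneDesign(design.dna, design.cuts, tuple(helpers))


def hill_climb(
    design: GeneDesign,
    table: CodonUsageTable,
    config: EAConfig,
    model: EnergyModel,
) -> tuple[GeneDesign, FitnessBreakdown]:
    """Steepest-ascent refinement over the single-step neighborhood.

    Repeats until no neighbor improves F; the returned fitness is always
    >= the input fitness.
    """
    current = design
    current_fit = evaluate_fitness(current, table, config, model)
    for _ in range(config.hill_climb_max_rounds):
        best_neighbor = None
        best_fit = current_fit
        for neighbor in _neighbors(current, config):
            try:
                neighbor.validate(config.constraints)
            except DesignError:
                continue
            fit = evaluate_fitness(neighbor, table, config, model)
            if fit.fitness > best_fit.fitness + 1e-12:
                best_neighbor, best_fit = neighbor, fit
        if best_neighbor is None:
            break
        current, current_fit = best_neighbor, best_fit
    return current, current_fit


# ---------------------------------------------------------------------------
# main loop

@dataclass
class GenerationStats:
    generation: int
    best_f: float
    mean_f: float
    cache_hit_rate: float


def run_ea(
    peptide: str,
    table: CodonUsageTable,
    config: EAConfig,
    model: EnergyModel | None = None,
):
    """Full optimization run; returns (best design, fitness, protocol, stats).

    All parents reproduce each generation; succession selects from the
    combined parent+offspring pool with one elite preserved.  Fully
    reproducible for a fixed config.seed.
    """
    if model is None:
        model = EnergyModel()
    rng = np.random.default_rng(config.seed)
    pop = init_population(peptide, table, config, rng)
    pop.fitnesses = [
        evaluate_fitness(d, table, config, model) for d in pop.individuals
    ]
    stats: list[GenerationStats] = []

    def record(gen: int) -> None:
        fs = [fb.fitness for fb in pop.fitnesses]
        total = model.cache_hits + model.cache_misses
        stats.append(GenerationStats(
            generation=gen,
            best_f=max(fs),
            mean_f=float(np.mean(fs)),
            cache_hit_rate=model.cache_hits / total if total else 0.0,
        ))

    record(0)
    for gen in range(1, config.generations + 1):
        children = [mutate(d, config, rng) for d in pop.individuals]
        child_fits = [
            evaluate_fitness(d, table, config, model) for d in children
        ]
        pool = pop.individuals + children
        pool_fits = pop.fitnesses + child_fits
        values = [fb.fitness for fb in pool_fits]
        elite = int(np.argmax(values))
        chosen = select(values, config.population_size - 1, config, rng)
        idxs = [elite] + chosen
        pop = Population(
            [pool[i] for i in idxs],
            [pool_fits[i] for i in idxs],
            generation=gen,
        )
        record(gen)
        log.info("generation %d: best F = %.4f, mean F = %.4f",
                 gen, stats[-1].best_f, stats[-1].mean_f)

    best_idx = int(np.argmax([fb.fitness for fb in pop.fitnesses]))
    best, best_fit = pop.individuals[best_idx], pop.fitnesses[best_idx]
    if config.hill_climb_final:
        best, best_fit = hill_climb(best, table, config, model)
    _, protocol = evaluate_fitness(best, table, config, model,
                                   return_protocol=True)
    return best, best_fit, protocol, stats
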