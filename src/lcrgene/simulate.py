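"""Monte-Carlo study: how often do random three-strand mixtures assemble?

Each trial draws a random target of 60-80 nt, splits it uniformly into two
main chains of 20-40 nt each, adds one helper complementary to a window
centered on the split, and asks whether the mixture passes the decreasing-
temperature folding-order check (one-tube base protocol).  Random sequences
almost always contain spurious self- or cross-complementarities that melt
above the weakest designed junction, so only a small fraction of mixtures
assemble correctly — the motivation for optimizing the fragment design at
all.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import binomtest

from .assembly import Fragment, JunctionMap, check_base_protocol
from .thermo import EnergyModel, revcomp

__all__ = ["MixtureTrialConfig", "random_mixture_trial", "estimate_success_rate"]

log = logging.getLogger(__name__)

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class MixtureTrialConfig:
    """Study conditions for the random-mixture simulation."""

    target_length_range: tuple[int, int] = (60, 80)
    fragment_length_range: tuple[int, int] = (20, 40)
    n_trials: int = 10000
    seed: int = 0

    def __post_init__(self) -> None:
        for lo, hi in (self.target_length_range, self.fragment_length_range):
            if not (0 < lo <= hi):
                raise ValueError("length ranges must be positive with min <= max")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")


def _draw_trial(config: MixtureTrialConfig, rng: np.random.Generator):
    """(target, split, helper window) honoring the length constraints."""
    lo_t, hi_t = config.target_length_range
    lo_f, hi_f = config.fragment_length_range
    for _ in range(1000):
        n = int(rng.integers(lo_t, hi_t + 1))
        split_lo = max(lo_f, n - hi_f)
        split_hi = min(hi_f, n - lo_f)
        if split_lo > split_hi:
            log.debug("target length %d admits no valid split; redrawing", n)
            continue
        split = int(rng.integers(split_lo, split_hi + 1))
        target = "".join(_BASES[rng.integers(0, 4, size=n)])
        h_len = int(rng.integers(lo_f, hi_f + 1))
        h_start = max(0, split - h_len // 2)  # centered on the split
        h_end = min(n, h_start + h_len)  # clipped to the target
        return target, split, (h_start, h_end)
    raise RuntimeError("no admissible split after 1000 redraws")


def random_mixture_trial(
    config: MixtureTrialConfig,
    rng: np.random.Generator,
    model: EnergyModel,
) -> bool:
    """One trial: True when the three-strand mixture assembles correctly."""
    target, split, (h_start, h_end) = _draw_trial(config, rng)
    fragments = [
        Fragment("m1", target[:split], "main", True),
        Fragment("m2", target[split:], "main", True),
        Fragment("h1", revcomp(target[h_start:h_end]), "helper", False),
    ]
    junctions = JunctionMap(
        main_names=("m1", "m2"),
        covered={0: ("h1", "m1", "m2")},
        uncovered=(),
        positions={"m1": 1, "m2": 2, "h1": 1},
    )
    report = check_base_protocol(fragments, junctions, model)
    return report.correct


def estimate_success_rate(
    config: MixtureTrialConfig,
    model: EnergyModel | None = None,
) -> tuple[float, tuple[float, float]]:
    """Success fraction over n_trials with a 95% Wilson binomial CI.

    Deterministic for a fixed config.seed.
    """
    if model is None:
        model = EnergyModel()
    rng = np.random.default_rng(config.seed)
    successes = 0
    for i in range(config.n_trials):
        if random_mixture_trial(config, rng, model):
            successes += 1
        if (i + 1) % 1000 == 0:
            log.info("trial %d/%d: %d successes", i + 1, config.n_trials, successes)
    ci = binomtest(successes, config.n_trials).proportion_ci(
        confidence_level=0.95, method="wilson"
    )
    fraction = successes / config.n_trials
    return fraction, (ci.low, ci.high)
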