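"""Packaged oligo sets from the Ubp4 protease gene-analogue syntheses.

Three bench-validated fragment sets are shipped: ``ubp4_prime`` (a 276-nt
analogue assembled from 11 oligos in one tube) and ``ubp4_dprime_a`` /
``ubp4_dprime_b`` (the two halves, 540 + 543 nt, of a 1083-nt analogue
assembled from 34 oligos in two tubes).  Odd-numbered rows are main chains
(phosphorylated), even-numbered rows helpers; the PCR primers in each set are
carried for completeness but never enter folding-order or reconstruction
computations.

Note: the published caption for the second set names rows a1-a15 while the
table itself lists 17 assembly rows; the rows are taken as authoritative.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources

from .assembly import Fragment

__all__ = ["FixtureSet", "load_fixture", "FIXTURE_NAMES"]

FIXTURE_NAMES = ("ubp4_prime", "ubp4_dprime_a", "ubp4_dprime_b")


@dataclass(frozen=True)
class FixtureSet:
    """A named oligo set: assembly fragments plus (excluded) PCR primers."""

    name: str
    fragments: tuple[Fragment, ...]
    pcr_primers: tuple[tuple[str, str], ...]

    @property
    def mains(self) -> tuple[Fragment, ...]:
        return tuple(f for f in self.fragments if f.role == "main")

    @property
    def helpers(self) -> tuple[Fragment, ...]:
        return tuple(f for f in self.fragments if f.role == "helper")


def load_fixture(name: str) -> FixtureSet:
    """Load a packaged fragment set by name (see FIXTURE_NAMES)."""
    if name not in FIXTURE_NAMES:
        raise KeyError(
            f"unknown fixture {name!r}; available: {', '.join(FIXTURE_NAMES)}"
        )
    ref = resources.files("lcrgene").joinpath(f"data/fixtures/{name}.tsv")
    fragments: list[Fragment] = []
    primers: list[tuple[str, str]] = []
    with ref.open() as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            if row["role"] == "primer":
                primers.append((row["name"], row["sequence"]))
            else:
                fragments.append(
                    Fragment(
                        row["name"],
                        row["sequence"],
                        row["role"],
                        row["phosphorylated"].lower() == "true",
                    )
                )
    return FixtureSet(name, tuple(fragments), tuple(primers))
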