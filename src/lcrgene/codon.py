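"""Codon-usage tables, reverse translation and the codon-frequency fitness term.

The designer scores how far a candidate coding sequence drifts from the host
organism's preferred codon usage.  Usage is expressed per amino acid: for each
codon *j* encoding amino acid *a*, ``C_rj`` is the required relative frequency
(synonymous frequencies sum to 1) and ``C_ij`` is the frequency observed in the
candidate sequence.  The deviation term is a weighted root-mean-square over the
codons actually used:

    F_C = w_C * sqrt( sum_j n_j * (C_rj - C_ij)**2 / n )

where ``n_j`` counts occurrences of codon *j* and ``n = sum_j n_j``.  Stop
codons are excluded (usage tables rarely report them meaningfully).
"""

from __future__ import annotations

import json
import math
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import pandas as pd
from Bio.Data import CodonTable as _BioCodonTable

__all__ = [
    "STANDARD_CODONS",
    "AA_TO_CODONS",
    "CODON_TO_AA",
    "STOP_CODONS",
    "CodonUsageTable",
    "load_usage_table",
    "uniform_usage_table",
    "reverse_translate",
    "translate",
    "codon_deviation",
    "codon_counts",
]

_STANDARD = _BioCodonTable.unambiguous_dna_by_id[1]

#: codon -> amino acid (sense codons only, standard genetic code)
CODON_TO_AA: dict[str, str] = dict(_STANDARD.forward_table)
STOP_CODONS: frozenset[str] = frozenset(_STANDARD.stop_codons)
STANDARD_CODONS: tuple[str, ...] = tuple(sorted(CODON_TO_AA))

AA_TO_CODONS: dict[str, tuple[str, ...]] = {}
for _c, _a in sorted(CODON_TO_AA.items()):
    AA_TO_CODONS.setdefault(_a, ())
    AA_TO_CODONS[_a] = AA_TO_CODONS[_a] + (_c,)

AMINO_ACIDS: frozenset[str] = frozenset(AA_TO_CODONS)

_SUM_TOL = 1e-9


class CodonTableError(ValueError):
    """Raised for malformed usage tables or sequences."""


@dataclass(frozen=True)
class CodonUsageTable:
    """Per-amino-acid relative codon frequencies for a host organism.

    ``frequencies`` maps every sense codon of the standard genetic code to its
    required frequency ``C_rj``; synonymous frequencies sum to 1.
    """

    frequencies: Mapping[str, float]

    def __post_init__(self) -> None:
        freqs = dict(self.frequencies)
        missing = [c for c in STANDARD_CODONS if c not in freqs]
        if missing:
            raise CodonTableError(f"missing codon(s): {', '.join(missing)}")
        extra = [c for c in freqs if c not in CODON_TO_AA]
        if extra:
            raise CodonTableError(f"unknown codon(s): {', '.join(sorted(extra))}")
        for aa, codons in AA_TO_CODONS.items():
            s = sum(freqs[c] for c in codons)
            if abs(s - 1.0) > 1e-6:
                raise CodonTableError(
                    f"frequencies for amino acid {aa} sum to {s:.6g}, expected 1"
                )
            for c in codons:
                if not (0.0 <= freqs[c] <= 1.0 + _SUM_TOL):
                    raise CodonTableError(f"frequency for {c} outside [0, 1]")
        object.__setattr__(self, "frequencies", freqs)

    def __getitem__(self, codon: str) -> float:
        return self.frequencies[codon]


def uniform_usage_table() -> CodonUsageTable:
    """Usage table with equal frequency for every synonymous codon."""
    freqs = {c: 1.0 / len(AA_TO_CODONS[aa]) for c, aa in CODON_TO_AA.items()}
    return CodonUsageTable(freqs)


def load_usage_table(source) -> CodonUsageTable:
    """Load a codon-usage table from TSV/CSV/JSON (path) or a DataFrame.

    Tabular input needs columns ``codon``, ``amino_acid`` and either
    ``frequency`` or ``count``; raw counts are normalized to per-amino-acid
    frequencies.  A JSON file may simply map codon -> frequency or count.
    """
    if isinstance(source, pd.DataFrame):
        df = source
    else:
        path = Path(source)
        if path.suffix.lower() == ".json":
            raw = json.loads(path.read_text())
            df = pd.DataFrame(
                {
                    "codon": list(raw),
                    "amino_acid": [CODON_TO_AA.get(c.upper(), "*") for c in raw],
                    "count": list(raw.values()),
                }
            )
        else:
            sep = "," if path.suffix.lower() == ".csv" else "\t"
            df = pd.read_csv(path, sep=sep, comment="#")
    cols = {c.lower(): c for c in df.columns}
    if "codon" not in cols:
        raise CodonTableError("usage table needs a 'codon' column")
    value_col = cols.get("frequency") or cols.get("count")
    if value_col is None:
        raise CodonTableError("usage table needs a 'frequency' or 'count' column")

    values: dict[str, float] = {}
    for _, row in df.iterrows():
        codon = str(row[cols["codon"]]).upper().replace("U", "T")
        if codon in STOP_CODONS:
            continue  # stop-codon rows tolerated, never used
        if codon not in CODON_TO_AA:
            raise CodonTableError(f"unknown codon {codon!r} in usage table")
        if "amino_acid" in cols:
            aa = str(row[cols["amino_acid"]]).strip().upper()
            if aa not in ("", "NAN") and aa != CODON_TO_AA[codon]:
                raise CodonTableError(
                    f"codon {codon} annotated as {aa}, standard code says "
                    f"{CODON_TO_AA[codon]}"
                )
        v = float(row[value_col])
        if v < 0:
            raise CodonTableError(f"negative value for codon {codon}")
        values[codon] = v

    missing = [c for c in STANDARD_CODONS if c not in values]
    if missing:
        raise CodonTableError(f"missing codon(s): {', '.join(missing)}")

    freqs: dict[str, float] = {}
    for aa, codons in AA_TO_CODONS.items():
        total = sum(values[c] for c in codons)
        if total <= 0:
            raise CodonTableError(f"all-zero usage for amino acid {aa}")
        for c in codons:
            freqs[c] = values[c] / total
    return CodonUsageTable(freqs)


def _check_peptide(peptide: str) -> str:
    p = peptide.strip().upper()
    if not p:
        raise CodonTableError("empty peptide")
    bad = sorted({ch for ch in p if ch not in AMINO_ACIDS})
    if bad:
        raise CodonTableError(f"invalid residue letter(s): {', '.join(bad)}")
    return p


def reverse_translate(peptide: str, rng, stop_codon: str | None = "TAA") -> str:
    """Encode a peptide in DNA, drawing each synonymous codon uniformly.

    ``rng`` is a ``numpy.random.Generator``.  A stop codon (default TAA) is
    appended; pass ``stop_codon=None`` for no stop.
    """
    p = _check_peptide(peptide)
    if stop_codon is not None and stop_codon.upper() not in STOP_CODONS:
        raise CodonTableError(f"{stop_codon!r} is not a stop codon")
    parts = []
    for aa in p:
        codons = AA_TO_CODONS[aa]
        parts.append(codons[int(rng.integers(len(codons)))])
    if stop_codon is not None:
        parts.append(stop_codon.upper())
    return "".join(parts)


def translate(dna: str, allow_terminal_stop: bool = True) -> str:
    """Standard-genetic-code translation of a coding DNA string.

    Internal stop codons raise; a single terminal stop is stripped when
    ``allow_terminal_stop``.
    """
    seq = dna.strip().upper()
    if len(seq) % 3 != 0:
        raise CodonTableError(f"length {len(seq)} not divisible by 3")
    bad = sorted({ch for ch in seq if ch not in "ACGT"})
    if bad:
        raise CodonTableError(f"non-ACGT character(s): {', '.join(bad)}")
    residues = []
    n_codons = len(seq) // 3
    for i in range(n_codons):
        codon = seq[3 * i : 3 * i + 3]
        if codon in STOP_CODONS:
            if i == n_codons - 1 and allow_terminal_stop:
                break
            raise CodonTableError(f"internal stop codon {codon} at codon {i}")
        residues.append(CODON_TO_AA[codon])
    return "".join(residues)


def codon_counts(dna: str) -> Counter:
    """Codon occurrence counts ``n_j`` of a CDS, stop codons excluded."""
    seq = dna.strip().upper()
    if len(seq) % 3 != 0:
        raise CodonTableError(f"length {len(seq)} not divisible by 3")
    counts: Counter = Counter()
    for i in range(0, len(seq), 3):
        codon = seq[i : i + 3]
        if codon not in STOP_CODONS:
            counts[codon] += 1
    return counts


def codon_deviation(dna_or_counts, table: CodonUsageTable, w_c: float = 1.0) -> float:
    """Weighted RMS deviation F_C between required and observed codon usage.

    Observed frequency ``C_ij`` is the count of codon *j* divided by the count
    of its amino acid in the sequence (same per-amino-acid normalization as the
    table's ``C_rj``).  Codons never used contribute nothing (``n_j = 0``).
    """
    if w_c < 0:
        raise ValueError("w_c must be non-negative")
    counts = (
        dna_or_counts if isinstance(dna_or_counts, Counter) else codon_counts(dna_or_counts)
    )
    n = sum(counts.values())
    if n == 0:
        raise CodonTableError("empty coding sequence (n = 0)")
    aa_totals: Counter = Counter()
    for codon, nj in counts.items():
        aa_totals[CODON_TO_AA[codon]] += nj
    ss = 0.0
    for codon, nj in counts.items():
        c_ij = nj / aa_totals[CODON_TO_AA[codon]]
        ss += nj * (table[codon] - c_ij) ** 2
    return w_c * math.sqrt(ss / n)
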