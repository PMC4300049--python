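"""Independent brute-force folding oracle for the tests.

Everything here is written from the model definition alone — its own JSON
parsing, its own loop classification and its own structure enumeration — so
that agreement with the dynamic program is a real two-route check, not a
tautology.
"""

from __future__ import annotations

import json
import math
from functools import lru_cache
from importlib import resources

R = 1.98720425864083e-3  # kcal/(mol*K)
T37 = 310.15
JS = 2.44

_COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}
_WC = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


def revcomp(seq: str) -> str:
    return "".join(_COMP[c] for c in reversed(seq))


@lru_cache(maxsize=1)
def raw_params() -> dict:
    text = resources.files("lcrgene").joinpath("data/nn_params.json").read_text()
    return json.loads(text)


def loop_dg37(table: dict, size: int) -> float:
    anchors = sorted(int(k) for k in table)
    below = [a for a in anchors if a <= size]
    if not below:
        raise ValueError(f"loop size {size} below smallest anchor")
    a = below[-1]
    g = float(table[str(a)])
    if size > a:
        g += JS * R * T37 * math.log(size / a)
    return g


def stack_hs(top_dinuc: str) -> tuple[float, float]:
    dh, ds = raw_params()["stacks"][top_dinuc]
    return dh, ds


def _children_map(pairs):
    ordered = sorted(pairs)
    kids = {p: [] for p in ordered}
    roots = []
    for p in ordered:
        parent = None
        for q in ordered:
            if q[0] < p[0] and p[1] < q[1]:
                if parent is None or (q[0] > parent[0]):
                    parent = q
        if parent is None:
            roots.append(p)
        else:
            kids[parent].append(p)
    return kids, roots


def oracle_score(seq, pairs, temperature, nick=-1, self_pair=False):
    """(dG, dH, dS) of one structure, classified from scratch."""
    p = raw_params()
    tk = temperature + 273.15
    dh = ds = 0.0

    def add_loop(dg37):
        nonlocal ds
        ds += -dg37 * 1000.0 / T37

    kids, _roots = _children_map(pairs)
    for (i, j), inner in kids.items():
        if (seq[i], seq[j]) not in _WC:
            raise ValueError("non-WC pair")
        nicked_hairpin = nick >= 0 and i < nick <= j
        if not inner:
            if not nicked_hairpin:
                add_loop(loop_dg37(p["hairpin_dG37"], j - i - 1))
        elif len(inner) == 1:
            k, l = inner[0]
            left, right = k - i - 1, j - l - 1
            nicked = nick >= 0 and (i < nick <= k or l < nick <= j)
            if nicked:
                pass
            elif left == 0 and right == 0:
                sdh, sds = stack_hs(seq[i] + seq[i + 1])
                dh += sdh
                ds += sds
            elif left == 0 or right == 0:
                add_loop(loop_dg37(p["bulge_dG37"], left + right))
            else:
                add_loop(loop_dg37(p["internal_dG37"], left + right))
        else:
            ml = p["multiloop"]
            add_loop(ml["a"] + ml["b"] * (len(inner) + 1))
    if nick >= 0 and any(i < nick <= j for i, j in pairs):
        dh += p["initiation"]["duplex"][0]
        ds += p["initiation"]["duplex"][1]
        if self_pair:
            ds += p["initiation"]["symmetry_dS"]
    return dh - tk * ds / 1000.0, dh, ds


def enumerate_structures(seq, nick=-1):
    """All pseudoknot-free WC pairings respecting the minimum hairpin size
    (waived for loops containing the nick).  Exponential; use for n <= 16."""
    n = len(seq)

    def gen(lo, hi):
        if lo >= hi:
            yield ()
            return
        yield from gen(lo + 1, hi)
        for j in range(lo + 1, hi + 1):
            if (seq[lo], seq[j]) not in _WC:
                continue
            for inner in gen(lo + 1, j - 1):
                for outer in gen(j + 1, hi):
                    yield ((lo, j),) + inner + outer

    for st in gen(0, n - 1):
        ok = True
        for i, j in st:
            if nick >= 0 and i < nick <= j:
                continue
            if j - i - 1 < 3 and not any(i < a and b < j for a, b in st):
                ok = False
                break
        if ok:
            yield st


def oracle_mfe(seq, temperature=37.0, nick=-1, self_pair=False):
    """Minimum free energy over the full structure ensemble (0 if none < 0)."""
    best = 0.0
    for st in enumerate_structures(seq, nick):
        dg, _, _ = oracle_score(seq, st, temperature, nick, self_pair)
        if dg < best:
            best = dg
    return best


def oracle_duplex(top, temperature=37.0):
    """Hand-summed perfect-duplex (dG, dH, dS) straight from the JSON file."""
    p = raw_params()
    dh, ds = p["initiation"]["duplex"]
    for end in (top[0], top[-1]):
        if end in "AT":
            dh += p["initiation"]["terminal_AT"][0]
            ds += p["initiation"]["terminal_AT"][1]
    for i in range(len(top) - 1):
        sdh, sds = stack_hs(top[i : i + 2])
        dh += sdh
        ds += sds
    if top == revcomp(top):
        ds += p["initiation"]["symmetry_dS"]
    tk = temperature + 273.15
    return dh - tk * ds / 1000.0, dh, ds
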