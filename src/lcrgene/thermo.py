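"""DNA nearest-neighbor thermodynamics and minimum-free-energy folding.

The model is the unified DNA nearest-neighbor framework: Watson-Crick stacks
carry tabulated (dH, dS) increments, loops carry length-dependent free-energy
penalties (treated as purely entropic so structures can be re-evaluated at any
temperature), multibranch loops a linear penalty, and bimolecular structures a
duplex-initiation term plus a symmetry correction for identical strands.
Dangling ends, coaxial stacking and terminal mismatches are not modeled.

Folding of one strand (:func:`mfe_fold`) and co-folding of a strand pair
(:func:`mfe_cofold`, concatenation-with-nick construction) share one dynamic
program in :mod:`lcrgene._zuker`.  Melting temperatures come from the
two-state model applied to the MFE structure's (dH, dS).
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np

from . import _zuker

__all__ = [
    "NNParameterSet",
    "load_parameters",
    "FoldResult",
    "duplex_energy",
    "mfe_fold",
    "mfe_cofold",
    "melting_temperature",
    "score_structure",
    "revcomp",
    "EnergyModel",
    "GAS_CONSTANT",
]

log = logging.getLogger(__name__)

GAS_CONSTANT = 1.98720425864083e-3  # kcal/(mol*K)
T37 = 310.15
_BASES = "ACGT"
_ENC = {b: i for i, b in enumerate(_BASES)}
_COMP = str.maketrans("ACGT", "TGCA")
_JS_COEFF = 2.44  # Jacobson-Stockmayer loop-extrapolation prefactor


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def _encode(seq: str) -> np.ndarray:
    s = seq.strip().upper()
    if not s:
        raise ValueError("empty sequence")
    try:
        return np.array([_ENC[c] for c in s], dtype=np.int8)
    except KeyError:
        bad = sorted({c for c in s if c not in _ENC})
        raise ValueError(f"non-ACGT character(s): {', '.join(bad)}") from None


def _expand_loop_table(table: dict[str, float], n: int, min_size: int) -> np.ndarray:
    """Dense dG37 array up to size ``n`` with logarithmic extrapolation."""
    sizes = sorted(int(k) for k in table)
    out = np.full(n + 1, np.inf)
    for size in range(min_size, n + 1):
        anchors = [s for s in sizes if s <= size]
        if not anchors:
            continue
        a = anchors[-1]
        g = float(table[str(a)])
        if size > a:
            g += _JS_COEFF * GAS_CONSTANT * T37 * math.log(size / a)
        out[size] = g
    return out


@dataclass(frozen=True)
class NNParameterSet:
    """Packaged nearest-neighbor parameters.

    ``stack_dh``/``stack_ds`` are 4x4 arrays indexed by the encoded top-strand
    dinucleotide of a Watson-Crick stack (A=0, C=1, G=2, T=3); loop tables are
    dG37 values in kcal/mol treated as entropic contributions.
    """

    stack_dh: np.ndarray
    stack_ds: np.ndarray
    hairpin_dg37: dict[str, float]
    bulge_dg37: dict[str, float]
    internal_dg37: dict[str, float]
    init_dh: float
    init_ds: float
    terminal_at_dh: float
    terminal_at_ds: float
    symmetry_ds: float
    ml_a: float
    ml_b: float
    ml_c: float
    loop_cap: int
    checksum: str
    name: str

    def loop_arrays(self, n: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        # bucket n so repeated folds of similar lengths share one table
        bucket = max(64, self.loop_cap, n)
        bucket = 1 << (bucket - 1).bit_length()
        key = (self.checksum, bucket)
        cached = _LOOP_CACHE.get(key)
        if cached is None:
            cap = self.loop_cap
            cached = (
                _expand_loop_table(self.hairpin_dg37, bucket, 3),
                _expand_loop_table(self.bulge_dg37, cap, 1),
                _expand_loop_table(self.internal_dg37, cap, 2),
            )
            _LOOP_CACHE[key] = cached
        return cached


_LOOP_CACHE: dict = {}


def load_parameters(path: str | Path | None = None) -> NNParameterSet:
    """Load the packaged (or a user-supplied) NN parameter file."""
    if path is None:
        ref = resources.files("lcrgene").joinpath("data/nn_params.json")
        text = ref.read_text()
    else:
        text = Path(path).read_text()
    checksum = hashlib.sha256(text.encode()).hexdigest()
    raw = json.loads(text)

    stack_dh = np.zeros((4, 4))
    stack_ds = np.zeros((4, 4))
    seen = set()
    for step, (dh, ds) in raw["stacks"].items():
        x, y = _ENC[step[0]], _ENC[step[1]]
        stack_dh[x, y] = dh
        stack_ds[x, y] = ds
        seen.add(step)
    if len(seen) != 16:
        raise ValueError(f"parameter file lists {len(seen)} stack steps, need 16")

    init = raw["initiation"]
    ml = raw.get("multiloop", {"a": 3.4, "b": 0.4, "c": 0.0})
    cap = int(raw.get("loop_cap", 30))
    if cap < 3:
        raise ValueError("loop_cap must be >= 3")
    params = NNParameterSet(
        stack_dh=stack_dh,
        stack_ds=stack_ds,
        hairpin_dg37=dict(raw["hairpin_dG37"]),
        bulge_dg37=dict(raw["bulge_dG37"]),
        internal_dg37=dict(raw["internal_dG37"]),
        init_dh=float(init["duplex"][0]),
        init_ds=float(init["duplex"][1]),
        terminal_at_dh=float(init["terminal_AT"][0]),
        terminal_at_ds=float(init["terminal_AT"][1]),
        symmetry_ds=float(init.get("symmetry_dS", -1.4)),
        ml_a=float(ml["a"]),
        ml_b=float(ml["b"]),
        ml_c=float(ml["c"]),
        loop_cap=cap,
        checksum=checksum,
        name=str(raw.get("name", "unnamed")),
    )
    log.info("loaded NN parameter set %s (sha256 %s)", params.name, checksum[:12])
    return params


_CAN_PAIR = np.zeros((4, 4), dtype=np.bool_)
for _a, _b in (("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")):
    _CAN_PAIR[_ENC[_a], _ENC[_b]] = True


@dataclass(frozen=True)
class FoldResult:
    """MFE secondary structure of a strand or strand pair.

    ``pairs`` are 0-based index pairs on the strand (or on the concatenation
    of the two strands for a co-fold, the second strand starting at ``nick``).
    ``dG`` is the free energy at ``temperature`` (Celsius); ``dH`` kcal/mol,
    ``dS`` cal/(mol K).  ``tm`` is the two-state melting temperature in
    Celsius, or None for a structure without pairs.
    """

    sequence: str
    pairs: tuple[tuple[int, int], ...]
    dG: float
    dH: float
    dS: float
    tm: float | None
    temperature: float
    nick: int = -1
    bimolecular: bool = False
    self_pair: bool = False

    @property
    def has_structure(self) -> bool:
        return bool(self.pairs)


def _loop_children(pairs):
    """Map each pair to its directly nested pairs; return (children, external)."""
    ordered = sorted(pairs)
    children: dict[tuple[int, int], list] = {p: [] for p in ordered}
    external = []
    stack: list[tuple[int, int]] = []
    for p in ordered:
        while stack and not (stack[-1][0] < p[0] and p[1] < stack[-1][1]):
            stack.pop()
        if stack:
            children[stack[-1]].append(p)
        else:
            external.append(p)
        stack.append(p)
    return children, external


def validate_structure(n: int, pairs, nick: int = -1) -> None:
    """Raise if ``pairs`` is not a valid pseudoknot-free structure."""
    seen: set[int] = set()
    for i, j in pairs:
        if not (0 <= i < j < n):
            raise ValueError(f"pair ({i}, {j}) out of range")
        if i in seen or j in seen:
            raise ValueError(f"base in two pairs near ({i}, {j})")
        seen.update((i, j))
    ordered = sorted(pairs)
    for a in range(len(ordered)):
        for b in range(a + 1, len(ordered)):
            i, j = ordered[a]
            k, l = ordered[b]
            if i < k < j < l:
                raise ValueError(f"pseudoknot between ({i},{j}) and ({k},{l})")
    for i, j in pairs:
        nicked = nick >= 0 and i < nick <= j
        if not nicked and j - i - 1 < 3:
            inner = [p for p in pairs if i < p[0] and p[1] < j]
            if not inner:
                raise ValueError(f"hairpin loop under 3 nt at ({i}, {j})")


def score_structure(
    seq: str,
    pairs,
    params: NNParameterSet,
    temperature: float,
    nick: int = -1,
    self_pair: bool = False,
) -> tuple[float, float, float, bool]:
    """(dG, dH, dS, bimolecular) of a given structure under the model.

    Loop classification: a pair with no nested pair closes a hairpin, with one
    nested pair a stack/bulge/internal loop, with several a multibranch loop
    (penalty a + b*(branches+1), unpaired free).  Loops whose backbone path
    crosses the nick cost nothing, except multibranch loops which keep their
    penalty.  Initiation (and the symmetry term for ``self_pair``) is added
    once when any pair spans the nick.
    """
    enc = _encode(seq)
    n = len(enc)
    tk = temperature + 273.15
    hp, bulge, internal = params.loop_arrays(n)

    def loop_ds(dg37: float) -> float:
        return -dg37 * 1000.0 / T37

    dh = 0.0
    ds = 0.0
    children, _external = _loop_children(pairs)
    bimolecular = any(i < nick <= j for i, j in pairs) if nick >= 0 else False
    for (i, j), kids in children.items():
        if not _CAN_PAIR[enc[i], enc[j]]:
            raise ValueError(f"non-Watson-Crick pair at ({i}, {j})")
        if len(kids) == 0:
            if not (nick >= 0 and i < nick <= j):
                dh += 0.0
                ds += loop_ds(hp[j - i - 1])
        elif len(kids) == 1:
            k, l = kids[0]
            nicked = nick >= 0 and ((i < nick <= k) or (l < nick <= j))
            l1, l2 = k - i - 1, j - l - 1
            if nicked:
                pass  # exterior-like, no penalty
            elif l1 == 0 and l2 == 0:
                dh += params.stack_dh[enc[i], enc[i + 1]]
                ds += params.stack_ds[enc[i], enc[i + 1]]
            elif l1 == 0 or l2 == 0:
                ds += loop_ds(bulge[l1 + l2])
            else:
                ds += loop_ds(internal[l1 + l2])
        else:
            penalty = params.ml_a + params.ml_b * (len(kids) + 1)
            ds += loop_ds(penalty)
    if bimolecular:
        dh += params.init_dh
        ds += params.init_ds
        if self_pair:
            ds += params.symmetry_ds
    dg = dh - tk * ds / 1000.0
    return dg, dh, ds, bimolecular


_G_CACHE: dict = {}


def _g_tables(params: NNParameterSet, n: int, temperature: float, loop_cap=None):
    tk = temperature + 273.15
    cap = params.loop_cap if loop_cap is None else loop_cap
    bucket = max(64, cap, n)
    bucket = 1 << (bucket - 1).bit_length()
    key = (params.checksum, round(temperature, 9), cap, bucket)
    cached = _G_CACHE.get(key)
    if cached is not None:
        return cached
    g_stack = params.stack_dh - tk * params.stack_ds / 1000.0
    hp = _expand_loop_table(params.hairpin_dg37, bucket, 3)
    bulge = _expand_loop_table(params.bulge_dg37, cap, 1)
    internal = _expand_loop_table(params.internal_dg37, cap, 2)
    scale = tk / T37  # entropic loops: dG(T) = dG37 * T/T37
    g_hp = np.where(np.isfinite(hp), hp * scale, _zuker.INF)
    g_bulge = np.where(np.isfinite(bulge), bulge * scale, _zuker.INF)
    g_internal = np.where(np.isfinite(internal), internal * scale, _zuker.INF)
    g_mla = params.ml_a * scale
    g_mlb = params.ml_b * scale
    cached = (g_stack, g_hp, g_bulge, g_internal, g_mla, g_mlb, cap)
    _G_CACHE[key] = cached
    return cached


_EPS = 1e-6


def _trace_v(i, j, V, Vt, Vk, Vl, WM, WMt, WMk, nick, out):
    out.append((int(i), int(j)))
    t = Vt[i, j]
    if t == _zuker.V_HAIRPIN:
        return
    if t == _zuker.V_INTERIOR:
        _trace_v(Vk[i, j], Vl[i, j], V, Vt, Vk, Vl, WM, WMt, WMk, nick, out)
        return
    if t == _zuker.V_MULTI:
        k = Vk[i, j]
        _trace_wm(i + 1, k, V, Vt, Vk, Vl, WM, WMt, WMk, nick, out)
        _trace_wm(k + 1, j - 1, V, Vt, Vk, Vl, WM, WMt, WMk, nick, out)
        return
    # V_NICK_FREE: interior pair inside one strand, nicked loop, zero penalty
    target = V[i, j]
    n = V.shape[0]
    for k in range(i + 1, j):
        for l in range(k + 1, j):
            if nick >= 0 and (k >= nick or l < nick):
                if abs(V[k, l] - target) < _EPS:
                    _trace_v(k, l, V, Vt, Vk, Vl, WM, WMt, WMk, nick, out)
                    return
    raise AssertionError("nick-free traceback failed")


def _trace_wm(i, j, V, Vt, Vk, Vl, WM, WMt, WMk, nick, out):
    while True:
        t = WMt[i, j]
        if t == _zuker.WM_TRIM_I:
            i += 1
        elif t == _zuker.WM_TRIM_J:
            j -= 1
        elif t == _zuker.WM_BRANCH:
            _trace_v(i, j, V, Vt, Vk, Vl, WM, WMt, WMk, nick, out)
            return
        else:
            k = WMk[i, j]
            _trace_wm(i, k, V, Vt, Vk, Vl, WM, WMt, WMk, nick, out)
            i = k + 1


def _trace_external(lo, hi, wpref, V, tables, nick, out):
    """Traceback of the external contour wpref over [lo, hi]."""
    Vt, Vk, Vl, WM, WMt, WMk = tables
    t = hi
    while t >= lo:
        base_prev = wpref[t - 1] if t - 1 >= lo else 0.0
        if abs(wpref[t] - base_prev) < _EPS:
            t -= 1
            continue
        hit = False
        for s in range(lo, t + 1):
            if V[s, t] >= _zuker.INF:
                continue
            base = wpref[s - 1] if s - 1 >= lo else 0.0
            if abs(base + V[s, t] - wpref[t]) < _EPS:
                _trace_v(s, t, V, Vt, Vk, Vl, WM, WMt, WMk, nick, out)
                t = s - 1
                hit = True
                break
        if not hit:
            t -= 1
    return out


def _trace_suffix(lo, hi, sbsuf, V, tables, nick, out):
    Vt, Vk, Vl, WM, WMt, WMk = tables
    q = lo
    while q <= hi:
        if abs(sbsuf[q] - sbsuf[q + 1]) < _EPS:
            q += 1
            continue
        hit = False
        for t in range(q, hi + 1):
            if V[q, t] >= _zuker.INF:
                continue
            if abs(V[q, t] + sbsuf[t + 1] - sbsuf[q]) < _EPS:
                _trace_v(q, t, V, Vt, Vk, Vl, WM, WMt, WMk, nick, out)
                q = t + 1
                hit = True
                break
        if not hit:
            q += 1
    return out


def _fold_engine(
    seq: str,
    params: NNParameterSet,
    temperature: float,
    nick: int,
    self_pair: bool,
    loop_cap=None,
) -> tuple[tuple[tuple[int, int], ...], float]:
    enc = _encode(seq)
    n = len(enc)
    g_stack, g_hp, g_bulge, g_internal, g_mla, g_mlb, cap = _g_tables(
        params, n, temperature, loop_cap
    )
    (V, Vt, Vk, Vl, WM, WMt, WMk, wpref, sbsuf,
     intra_best, span_best, span_p, span_q) = _zuker.fill(
        enc, nick, _CAN_PAIR, g_stack, g_hp, g_bulge, g_internal,
        g_mla, g_mlb, cap,
    )
    tk = temperature + 273.15
    candidates = [("empty", 0.0), ("intra", intra_best)]
    if nick >= 0 and span_best < _zuker.INF:
        g_init = params.init_dh - tk * params.init_ds / 1000.0
        if self_pair:
            g_init += -tk * params.symmetry_ds / 1000.0
        candidates.append(("span", span_best + g_init))
    best_route, best_g = min(candidates, key=lambda kv: kv[1])
    if best_g > -_EPS:
        return (), 0.0
    tables = (Vt, Vk, Vl, WM, WMt, WMk)
    out: list[tuple[int, int]] = []
    if best_route == "intra":
        if nick >= 0:
            _trace_external(0, nick - 1, wpref, V, tables, nick, out)
            _trace_external(nick, n - 1, wpref, V, tables, nick, out)
        else:
            _trace_external(0, n - 1, wpref, V, tables, nick, out)
    else:
        _trace_external(0, span_p - 1, wpref, V, tables, nick, out)
        _trace_v(span_p, span_q, V, tables[0], tables[1], tables[2],
                 WM, WMt, WMk, nick, out)
        _trace_suffix(span_q + 1, n - 1, sbsuf, V, tables, nick, out)
    return tuple(sorted(out)), best_g


def mfe_fold(
    strand: str,
    params: NNParameterSet,
    temperature: float = 37.0,
    loop_cap: int | None = None,
    strand_concentration: float = 0.4e-6,
) -> FoldResult:
    """Minimum-free-energy intramolecular structure of one strand.

    Returns the all-unpaired structure with dG = 0 when nothing folds
    favorably.
    """
    seq = strand.strip().upper()
    pairs, _ = _fold_engine(seq, params, temperature, -1, False, loop_cap)
    dg, dh, ds, _ = score_structure(seq, pairs, params, temperature)
    tm = melting_temperature_values(dh, ds, bimolecular=False, pairs=bool(pairs))
    return FoldResult(seq, pairs, dg, dh, ds, tm, temperature)


def mfe_cofold(
    strand_a: str,
    strand_b: str,
    params: NNParameterSet,
    temperature: float = 37.0,
    loop_cap: int | None = None,
    strand_concentration: float = 0.4e-6,
) -> FoldResult:
    """MFE structure of two strands (intra- plus inter-strand pairs).

    The strands are folded as a concatenation with a nick; ``strand_b`` may
    equal ``strand_a`` (a molecule pairing with an identical copy), in which
    case the duplex symmetry correction applies.
    """
    a = strand_a.strip().upper()
    b = strand_b.strip().upper()
    # symmetric by construction: canonical order
    if b < a:
        a, b = b, a
    self_pair = a == b
    seq = a + b
    nick = len(a)
    pairs, _ = _fold_engine(seq, params, temperature, nick, self_pair, loop_cap)
    dg, dh, ds, bimol = score_structure(
        seq, pairs, params, temperature, nick=nick, self_pair=self_pair
    )
    ct = strand_concentration if self_pair else 2.0 * strand_concentration
    tm = melting_temperature_values(
        dh, ds, bimolecular=bimol, pairs=bool(pairs),
        total_concentration=ct, self_complementary=self_pair,
    )
    return FoldResult(seq, pairs, dg, dh, ds, tm, temperature,
                      nick=nick, bimolecular=bimol, self_pair=self_pair)


def melting_temperature_values(
    dh: float,
    ds: float,
    *,
    bimolecular: bool,
    pairs: bool,
    total_concentration: float = 0.8e-6,
    self_complementary: bool = False,
) -> float | None:
    """Two-state melting temperature in Celsius from (dH, dS).

    Bimolecular: Tm = dH / (dS + R ln(C_T/x)) with x = 4 for two different
    strands and x = 1 for a strand with itself; unimolecular: Tm = dH/dS.
    Returns None for a structure without pairs.
    """
    if not pairs:
        return None
    if dh >= 0:
        raise ValueError(
            f"structure with pairs has non-negative dH = {dh:.3f} "
            "(corrupted parameters?)"
        )
    if bimolecular:
        x = 1.0 if self_complementary else 4.0
        denom = ds / 1000.0 + GAS_CONSTANT * math.log(total_concentration / x)
    else:
        denom = ds / 1000.0
    if denom >= 0:
        return None
    return dh / denom - 273.15


def melting_temperature(
    fold: FoldResult,
    strand_concentration: float = 0.4e-6,
    params: NNParameterSet | None = None,
) -> float | None:
    """Two-state Tm (Celsius) of an MFE structure; None when unpaired."""
    ct = strand_concentration if fold.self_pair else 2.0 * strand_concentration
    return melting_temperature_values(
        fold.dH, fold.dS, bimolecular=fold.bimolecular, pairs=fold.has_structure,
        total_concentration=ct, self_complementary=fold.self_pair,
    )


def duplex_energy(
    strand: str,
    complement: str | None = None,
    params: NNParameterSet | None = None,
    temperature: float = 37.0,
) -> tuple[float, float, float]:
    """(dG, dH, dS) of a perfect Watson-Crick duplex.

    ``complement`` defaults to the reverse complement of ``strand``; a
    non-complementary position raises.  Includes duplex initiation, the
    per-end terminal-AT correction and the symmetry term for
    self-complementary strands.
    """
    if params is None:
        params = load_parameters()
    top = strand.strip().upper()
    bottom = complement.strip().upper() if complement is not None else revcomp(top)
    if len(bottom) != len(top):
        raise ValueError("strands have different lengths")
    if revcomp(bottom) != top:
        for idx, (x, y) in enumerate(zip(top, revcomp(bottom))):
            if x != y:
                raise ValueError(f"non-complementary position {idx} in claimed duplex")
    enc = _encode(top)
    dh = params.init_dh
    ds = params.init_ds
    for end in (top[0], top[-1]):
        if end in "AT":
            dh += params.terminal_at_dh
            ds += params.terminal_at_ds
    for i in range(len(top) - 1):
        dh += params.stack_dh[enc[i], enc[i + 1]]
        ds += params.stack_ds[enc[i], enc[i + 1]]
    if top == revcomp(top):
        ds += params.symmetry_ds
    tk = temperature + 273.15
    return dh - tk * ds / 1000.0, dh, ds


class EnergyModel:
    """Folding context: parameters, temperature, concentration and a cache.

    The pair-energy cache maps (strand, strand) keys to FoldResults so that
    re-evaluating a mutated design only refolds pairs whose sequences changed.
    Cached values are the exact objects a fresh computation would produce.
    """

    def __init__(
        self,
        params: NNParameterSet | None = None,
        temperature: float = 37.0,
        strand_concentration: float = 0.4e-6,
        loop_cap: int | None = None,
        cache: bool = True,
    ) -> None:
        self.params = params if params is not None else load_parameters()
        self.temperature = temperature
        self.strand_concentration = strand_concentration
        self.loop_cap = loop_cap
        self.cache_enabled = cache
        self._cache: dict[tuple[str, str], FoldResult] = {}
        self.cache_hits = 0
        self.cache_misses = 0

    def fold(self, strand: str) -> FoldResult:
        return mfe_fold(strand, self.params, self.temperature, self.loop_cap,
                        self.strand_concentration)

    def cofold(self, strand_a: str, strand_b: str) -> FoldResult:
        a, b = sorted((strand_a.strip().upper(), strand_b.strip().upper()))
        key = (a, b)
        if self.cache_enabled and key in self._cache:
            self.cache_hits += 1
            return self._cache[key]
        self.cache_misses += 1
        result = mfe_cofold(a, b, self.params, self.temperature, self.loop_cap,
                            self.strand_concentration)
        if self.cache_enabled:
            self._cache[key] = result
        return result

    def pair_tm(self, strand_a: str, strand_b: str) -> float | None:
        return self.cofold(strand_a, strand_b).tm

    def clear_cache(self) -> None:
        self._cache.clear()
        self.cache_hits = 0
        self.cache_misses = 0
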