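"""RNA hairpin folding and miRNA-precursor evaluation.

Secondary structure is predicted with a Zuker-style interval dynamic program
under a *simplified* nearest-neighbour energy model: Watson-Crick and G:U
stacked-pair free energies plus length-dependent hairpin / bulge / internal
loop penalties and an affine multiloop cost.  Dangles, coaxial stacking and
sequence-dependent loop bonuses are deliberately omitted; the model is meant
to rank hairpin-forming candidates, not to reproduce full Turner-2004
energies.  The same energy function is exposed through
:func:`structure_energy`, and :func:`brute_force_mfe` enumerates every
pseudoknot-free structure of a short sequence, so the DP can be checked
against exhaustive enumeration.

Candidate precursors excised from the genome carry a long unstructured flank;
:func:`evaluate_precursor` therefore folds the window, trims it to the maximal
simple stem-loop that contains the mature sequence (the usual
precursor-boundary refinement step of de novo miRNA predictors), re-folds the
trimmed precursor and computes MFE (kcal/mol and kJ/mol), AMFE, MFEI and the
duplex-geometry checks on that precursor.

Units: energies are kcal/mol internally; the discovery filter applies the
kJ/mol threshold after multiplying by 4.184.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .util import encode, gc_percent

# --------------------------------------------------------------------------
# energy model
# --------------------------------------------------------------------------

KCAL_TO_KJ = 4.184
MIN_HAIRPIN = 3  # minimum unpaired bases in a hairpin loop
MAX_INTERIOR = 30  # maximum total unpaired bases in a bulge/internal loop
MAX_FOLD_LEN = 500

ML_CLOSE = 3.4  # multiloop initiation
ML_BRANCH = 0.4  # per branch, closing pair included
ML_UNPAIRED = 0.4  # per unpaired base inside a multiloop

_PAIRS = ("AU", "UA", "CG", "GC", "GU", "UG")
_PAIR_INDEX = {p: i for i, p in enumerate(_PAIRS)}
ALLOWED_PAIRS = frozenset(_PAIRS)

# Stacked-pair free energies, kcal/mol, keyed (outer pair, inner pair) where
# the outer pair is (seq[i], seq[j]) and the inner (seq[i+1], seq[j-1]).
# Values follow the standard Watson-Crick / wobble stacking table to two
# decimals; entries related by reading the duplex from the opposite strand
# (outer (a,b), inner (c,d)  <->  outer (d,c), inner (b,a)) are filled in by
# symmetry below.
_STACK_SEED = {
    ("AU", "AU"): -0.93,
    ("AU", "UA"): -1.10,
    ("UA", "AU"): -1.33,
    ("CG", "AU"): -2.11,
    ("CG", "UA"): -2.08,
    ("GC", "AU"): -2.35,
    ("GC", "UA"): -2.24,
    ("CG", "GC"): -2.36,
    ("GC", "GC"): -3.26,
    ("GC", "CG"): -3.42,
    ("AU", "GU"): -0.55,
    ("AU", "UG"): -1.36,
    ("UA", "GU"): -1.27,
    ("UA", "UG"): -1.00,
    ("CG", "GU"): -1.41,
    ("CG", "UG"): -2.11,
    ("GC", "GU"): -1.53,
    ("GC", "UG"): -2.51,
    ("GU", "GU"): -0.50,
    ("GU", "UG"): 0.47,
    ("UG", "GU"): 0.30,
}


def _complete_stack_table() -> dict[tuple[str, str], float]:
    table = dict(_STACK_SEED)
    for (a, b), (c, d) in [((o[0], o[1]), (i[0], i[1])) for o, i in _STACK_SEED]:
        mirror = (d + c, b + a)
        table.setdefault(mirror, _STACK_SEED[(a + b, c + d)])
    for outer in _PAIRS:
        for inner in _PAIRS:
            table.setdefault((outer, inner), -0.50)
    return table


STACK = _complete_stack_table()

_STACK_ARR = np.zeros((6, 6))
for _o, _i in STACK:
    _STACK_ARR[_PAIR_INDEX[_o], _PAIR_INDEX[_i]] = STACK[(_o, _i)]

# pair-type lookup over encoded bases (A=0,C=1,G=2,U=3); -1 = cannot pair
_PTYPE = np.full((5, 5), -1, dtype=np.int8)
for _p, _idx in _PAIR_INDEX.items():
    _a = "ACGU".index(_p[0])
    _b = "ACGU".index(_p[1])
    _PTYPE[_a, _b] = _idx

_HAIRPIN_TAB = {3: 5.4, 4: 5.6, 5: 5.7, 6: 5.4, 7: 6.0, 8: 5.5, 9: 6.4}
_BULGE_TAB = {1: 3.8, 2: 2.8, 3: 3.2, 4: 3.6, 5: 4.0, 6: 4.4}
_INTERNAL_TAB = {2: 0.5, 3: 1.8, 4: 1.1, 5: 2.0, 6: 1.9}
_LOOP_EXTRAP = 1.077  # 1.75 * R * T at 37 C, Jacobson-Stockmayer extrapolation


def _tabulated(tab: dict[int, float], n: int, n_max: int) -> float:
    if n in tab:
        return tab[n]
    return tab[n_max] + _LOOP_EXTRAP * math.log(n / n_max)


def hairpin_penalty(n_unpaired: int) -> float:
    """Free-energy cost of a hairpin loop with `n_unpaired` bases."""
    if n_unpaired < MIN_HAIRPIN:
        return math.inf
    return _tabulated(_HAIRPIN_TAB, n_unpaired, 9)


def bulge_penalty(n_unpaired: int) -> float:
    return _tabulated(_BULGE_TAB, n_unpaired, 6)


def internal_penalty(n_unpaired: int) -> float:
    return _tabulated(_INTERNAL_TAB, n_unpaired, 6)


def _interior_energy(n1: int, n2: int, outer_pt: int, inner_pt: int) -> float:
    """Energy of the two-pair motif: stack, bulge or internal loop."""
    if n1 + n2 > MAX_INTERIOR:
        return math.inf
    if n1 == 0 and n2 == 0:
        return _STACK_ARR[outer_pt, inner_pt]
    if n1 == 0 or n2 == 0:
        return bulge_penalty(n1 + n2)
    return internal_penalty(n1 + n2)


# penalty block used by the DP interior scan: PEN[r, c] with n1 = r and
# n2 = MAX_INTERIOR - c (columns aligned so that c indexes q = j-31 .. j-1)
_PEN = np.full((MAX_INTERIOR + 1, MAX_INTERIOR + 1), math.inf)
for _n1 in range(MAX_INTERIOR + 1):
    for _c in range(MAX_INTERIOR + 1):
        _n2 = MAX_INTERIOR - _c
        if _n1 + _n2 == 0 or _n1 + _n2 > MAX_INTERIOR:
            continue
        if _n1 == 0 or _n2 == 0:
            _PEN[_n1, _c] = bulge_penalty(_n1 + _n2)
        else:
            _PEN[_n1, _c] = internal_penalty(_n1 + _n2)

_HP_ARR = np.array([hairpin_penalty(n) for n in range(MAX_FOLD_LEN + 2)])


def _validate_rna(seq: str) -> np.ndarray:
    if not 1 <= len(seq) <= MAX_FOLD_LEN:
        raise ValueError(f"sequence length {len(seq)} outside 1..{MAX_FOLD_LEN}")
    si = encode(seq.upper())
    bad = np.nonzero(si > 3)[0]
    if bad.size:
        raise ValueError(f"invalid RNA base {seq[bad[0]]!r} at position {int(bad[0])}")
    return si


# --------------------------------------------------------------------------
# dynamic programming fold
# --------------------------------------------------------------------------


@dataclass
class _FoldMatrices:
    si: np.ndarray
    pt: np.ndarray
    V: np.ndarray
    WM: np.ndarray
    WM2: np.ndarray
    w: np.ndarray


def _fill(seq: str) -> _FoldMatrices:
    si = _validate_rna(seq)
    n = len(si)
    pt = _PTYPE[si[:, None], si[None, :]]
    inf = math.inf
    V = np.full((n, n), inf)
    WM = np.full((n, n), inf)
    WM2 = np.full((n, n), inf)
    K = MAX_INTERIOR + 1
    for span in range(MIN_HAIRPIN + 1, n):
        for i in range(n - span):
            j = i + span
            if pt[i, j] >= 0:
                best = _HP_ARR[span - 1]
                # stack onto the immediately enclosed pair
                if pt[i + 1, j - 1] >= 0 and (j - 1) - (i + 1) > MIN_HAIRPIN:
                    cand = _STACK_ARR[pt[i, j], pt[i + 1, j - 1]] + V[i + 1, j - 1]
                    if cand < best:
                        best = cand
                # bulge / internal loops: interior pair (p, q)
                r1, r2 = i + 1, min(i + K + 1, j)
                c1 = max(j - K, r1)
                if r2 > r1 and j > c1:
                    sub = V[r1:r2, c1:j] + _PEN[0 : r2 - r1, c1 - (j - K) : K]
                    cand = sub.min()
                    if cand < best:
                        best = cand
                # multiloop closure
                if j - 1 > i + 1:
                    cand = ML_CLOSE + ML_BRANCH + WM2[i + 1, j - 1]
                    if cand < best:
                        best = cand
                V[i, j] = best
            # multiloop accumulators (k splits region into WM + branch V)
            t = (WM[i, i:j] + V[i + 1 : j + 1, j]).min() + ML_BRANCH
            WM2[i, j] = min(WM2[i, j - 1] + ML_UNPAIRED, t)
            WM[i, j] = min(
                V[i, j] + ML_BRANCH,
                WM[i, j - 1] + ML_UNPAIRED,
                WM[i + 1, j] + ML_UNPAIRED,
                t,
            )
    w = np.zeros(n + 1)
    for j in range(n):
        best = w[j]
        if j >= MIN_HAIRPIN + 1:
            cand = (w[0 : j - MIN_HAIRPIN] + V[0 : j - MIN_HAIRPIN, j]).min()
            if cand < best:
                best = cand
        w[j + 1] = best
    return _FoldMatrices(si, pt, V, WM, WM2, w)


_EPS = 1e-6


def _traceback(m: _FoldMatrices) -> list[int]:
    n = len(m.si)
    partner = [-1] * n
    V, WM, WM2, w = m.V, m.WM, m.WM2, m.w
    pt = m.pt

    def trace_v(i: int, j: int) -> None:
        partner[i], partner[j] = j, i
        e = V[i, j]
        span = j - i
        if abs(e - _HP_ARR[span - 1]) < _EPS:
            return
        if pt[i + 1, j - 1] >= 0 and (j - 1) - (i + 1) > MIN_HAIRPIN:
            if abs(e - (_STACK_ARR[pt[i, j], pt[i + 1, j - 1]] + V[i + 1, j - 1])) < _EPS:
                trace_v(i + 1, j - 1)
                return
        # interior loops: scan p ascending, q descending (deterministic ties)
        for p in range(i + 1, min(i + MAX_INTERIOR + 2, j)):
            for q in range(j - 1, p + MIN_HAIRPIN, -1):
                n1, n2 = p - i - 1, j - q - 1
                if n1 + n2 == 0 or n1 + n2 > MAX_INTERIOR:
                    continue
                if V[p, q] == math.inf:
                    continue
                if abs(e - (_interior_energy(n1, n2, pt[i, j], pt[p, q]) + V[p, q])) < _EPS:
                    trace_v(p, q)
                    return
        trace_wm2(i + 1, j - 1)

    def trace_wm2(i: int, j: int) -> None:
        e = WM2[i, j]
        if j - 1 >= i and abs(e - (WM2[i, j - 1] + ML_UNPAIRED)) < _EPS:
            trace_wm2(i, j - 1)
            return
        for k in range(i + 1, j + 1):
            if WM[i, k - 1] < math.inf and V[k, j] < math.inf:
                if abs(e - (WM[i, k - 1] + V[k, j] + ML_BRANCH)) < _EPS:
                    trace_wm(i, k - 1)
                    trace_v(k, j)
                    return
        raise AssertionError("WM2 traceback failed")

    def trace_wm(i: int, j: int) -> None:
        e = WM[i, j]
        if V[i, j] < math.inf and abs(e - (V[i, j] + ML_BRANCH)) < _EPS:
            trace_v(i, j)
            return
        if j - 1 >= i and abs(e - (WM[i, j - 1] + ML_UNPAIRED)) < _EPS:
            trace_wm(i, j - 1)
            return
        if i + 1 <= j and abs(e - (WM[i + 1, j] + ML_UNPAIRED)) < _EPS:
            trace_wm(i + 1, j)
            return
        for k in range(i + 1, j + 1):
            if WM[i, k - 1] < math.inf and V[k, j] < math.inf:
                if abs(e - (WM[i, k - 1] + V[k, j] + ML_BRANCH)) < _EPS:
                    trace_wm(i, k - 1)
                    trace_v(k, j)
                    return
        raise AssertionError("WM traceback failed")

    j = n - 1
    while j >= 0:
        if abs(w[j + 1] - w[j]) < _EPS:
            j -= 1
            continue
        hit = None
        for i in range(0, j - MIN_HAIRPIN):
            if V[i, j] < math.inf and abs(w[j + 1] - (w[i] + V[i, j])) < _EPS:
                hit = i
                break
        if hit is None:  # numerical safety net; should not occur
            j -= 1
            continue
        trace_v(hit, j)
        j = hit - 1
    return partner


def fold_mfe(seq: str) -> tuple[str, float]:
    """Predict the minimum-free-energy structure of an RNA sequence.

    Returns ``(dot_bracket, mfe_kcal_per_mol)``.  The MFE is never positive:
    the open chain (all dots, 0 kcal/mol) is always admissible.  Raises
    ``ValueError`` for non-ACGU characters, naming the offending position.
    """
    seq = seq.upper().replace("T", "U")
    if len(seq) <= MIN_HAIRPIN + 1:
        _validate_rna(seq)
        return "." * len(seq), 0.0
    m = _fill(seq)
    mfe = float(m.w[len(seq)])
    if mfe >= 0.0:
        return "." * len(seq), 0.0
    partner = _traceback(m)
    db = "".join("(" if partner[k] > k else ")" if partner[k] >= 0 else "." for k in range(len(seq)))
    return db, mfe


def pair_table(db: str) -> list[int]:
    """Partner index per position (-1 if unpaired) from dot-bracket."""
    stack: list[int] = []
    partner = [-1] * len(db)
    for k, c in enumerate(db):
        if c == "(":
            stack.append(k)
        elif c == ")":
            i = stack.pop()
            partner[i], partner[k] = k, i
    if stack:
        raise ValueError("unbalanced brackets")
    return partner


# --------------------------------------------------------------------------
# explicit-structure energy + exhaustive enumeration (oracle support)
# --------------------------------------------------------------------------


def structure_energy(seq: str, pairs: frozenset | set | list) -> float:
    """Energy of an explicit pseudoknot-free structure under the same model.

    `pairs` is a collection of (i, j) index pairs, i < j.  Invalid pairs,
    hairpin loops below the minimum size or oversized interior loops give
    +inf.  This evaluator is deliberately independent of the DP recursions.
    """
    si = encode(seq.upper().replace("T", "U"))
    plist = sorted((min(i, j), max(i, j)) for i, j in pairs)
    for i, j in plist:
        if _PTYPE[si[i], si[j]] < 0 or j - i <= MIN_HAIRPIN:
            return math.inf
    # nestedness check + direct children per pair
    children: dict[tuple[int, int], list[tuple[int, int]]] = {p: [] for p in plist}
    root: list[tuple[int, int]] = []
    stack: list[tuple[int, int]] = []
    for p in plist:
        while stack and stack[-1][1] < p[0]:
            stack.pop()
        if stack:
            if p[1] > stack[-1][1]:
                return math.inf  # pseudoknot
            children[stack[-1]].append(p)
        else:
            root.append(p)
        stack.append(p)
    total = 0.0
    for (i, j), kids in children.items():
        if not kids:
            total += hairpin_penalty(j - i - 1)
        elif len(kids) == 1:
            (p, q) = kids[0]
            total += _interior_energy(
                p - i - 1, j - q - 1, _PTYPE[si[i], si[j]], _PTYPE[si[p], si[q]]
            )
        else:
            unpaired = (j - i - 1) - sum(q - p + 1 for p, q in kids)
            total += ML_CLOSE + ML_BRANCH * (len(kids) + 1) + ML_UNPAIRED * unpaired
        if math.isinf(total):
            return math.inf
    return total


def enumerate_structures(seq: str):
    """Yield every pseudoknot-free structure (as frozensets of pairs)."""
    si = encode(seq.upper().replace("T", "U"))
    n = len(si)
    from functools import lru_cache

    @lru_cache(maxsize=None)
    def region(i: int, j: int) -> tuple[frozenset, ...]:
        if j - i < MIN_HAIRPIN + 1:
            return (frozenset(),)
        out = list(region(i, j - 1))
        for k in range(i, j - MIN_HAIRPIN):
            if _PTYPE[si[k], si[j]] >= 0:
                for left in region(i, k - 1) if k > i else (frozenset(),):
                    for inner in region(k + 1, j - 1):
                        out.append(left | inner | {(k, j)})
        return tuple(out)

    yield from region(0, n - 1)


def brute_force_mfe(seq: str) -> float:
    """Exhaustive-enumeration MFE; only feasible for short sequences."""
    best = 0.0
    for pairs in enumerate_structures(seq):
        e = structure_energy(seq, pairs)
        if e < best:
            best = e
    return best


# --------------------------------------------------------------------------
# MFEI and precursor evaluation
# --------------------------------------------------------------------------


def mfei(mfe: float, length: int, gc_pct: float) -> tuple[float, float]:
    """AMFE and MFEI of a precursor.

    AMFE = (MFE / length) * 100 (kcal/mol per 100 nt); MFEI = |AMFE| / GC%.
    Both are reported to 4 decimals.
    """
    if length <= 0:
        raise ValueError("length must be positive")
    if gc_pct <= 0:
        raise ValueError("GC percentage must be positive")
    amfe = mfe / length * 100.0
    return round(amfe, 4), round(abs(amfe) / gc_pct, 4)


@dataclass
class HairpinEvaluation:
    """Folding metrics and duplex geometry of one candidate precursor."""

    precursor_seq: str
    structure: str
    mfe: float  # kcal/mol
    mfe_kj: float
    amfe: float
    gc_pct: float
    mfei: float
    mature_arm: str  # "5p" / "3p" / "?"
    mature_span: tuple[int, int]  # on the trimmed precursor, 0-based half-open
    star_span: tuple[int, int] | None
    valid_hairpin: bool
    reasons: list[str] = field(default_factory=list)
    window_offset: int = 0  # precursor start within the excised window


def _parents_and_children(partner: list[int]):
    pairs = [(i, partner[i]) for i in range(len(partner)) if partner[i] > i]
    parent: dict[tuple[int, int], tuple[int, int] | None] = {}
    nchildren: dict[tuple[int, int], int] = {p: 0 for p in pairs}
    stack: list[tuple[int, int]] = []
    for p in pairs:
        while stack and stack[-1][1] < p[0]:
            stack.pop()
        if stack:
            parent[p] = stack[-1]
            nchildren[stack[-1]] += 1
        else:
            parent[p] = None
        stack.append(p)
    return parent, nchildren


def stem_loop_span(
    partner: list[int], mature_span: tuple[int, int], *, max_gap: int = 8
) -> tuple[int, int] | None:
    """Span (i, j inclusive) of the maximal simple stem-loop holding the mature.

    Starts at the outermost pair involving a mature base and ascends enclosing
    pairs for as long as each parent directly encloses only this stem (no
    multiloop sibling branches) and the interior loop between parent and child
    leaves at most `max_gap` unpaired bases — larger gaps are treated as stem
    breaks so that unstructured flank is not absorbed into the precursor.
    None if the mature is entirely unpaired.
    """
    paired = [k for k in range(*mature_span) if 0 <= k < len(partner) and partner[k] >= 0]
    if not paired:
        return None
    # The mature may sporadically pair far-away flank bases; anchor on the
    # majority stem: the run of mature bases whose partners stay contiguous.
    clusters: list[list[int]] = [[paired[0]]]
    for k in paired[1:]:
        if abs(partner[k] - partner[clusters[-1][-1]]) <= max_gap + (k - clusters[-1][-1]):
            clusters[-1].append(k)
        else:
            clusters.append([k])
    best = max(clusters, key=len)
    anchor = None
    for k in best:
        p = (min(k, partner[k]), max(k, partner[k]))
        if anchor is None or (p[0] <= anchor[0] and p[1] >= anchor[1]):
            anchor = p
    parent, nchildren = _parents_and_children(partner)
    cur = anchor
    while True:
        up = parent.get(cur)
        if up is None or nchildren[up] != 1:
            break
        gap = (cur[0] - up[0] - 1) + (up[1] - cur[1] - 1)
        if gap > max_gap:
            break
        cur = up
    return cur


def validate_hairpin(
    partner: list[int],
    mature_span: tuple[int, int],
    *,
    min_paired_frac: float = 0.6,
    max_unpaired_mature: int = 4,
    max_asymmetry: int = 2,
) -> tuple[bool, list[str], tuple[int, int] | None, str]:
    """miRNA-like duplex geometry checks for a folded precursor.

    Returns (valid, reasons, star_span, arm).  The star span is derived from
    the pairing partners of the mature with the canonical 2-nt 3' overhang.
    """
    n = len(partner)
    ms, me = mature_span
    idx = [k for k in range(ms, me) if 0 <= k < n]
    paired = [k for k in idx if partner[k] >= 0]
    reasons: list[str] = []
    if not paired:
        return False, ["unpaired mature"], None, "?"
    partners = [partner[k] for k in paired]
    if any(ms <= p < me for p in partners) or not (
        all(p >= me for p in partners) or all(p < ms for p in partners)
    ):
        return False, ["loop overlap"], None, "?"
    arm = "5p" if partners[0] >= me else "3p"
    if len(paired) / len(idx) < min_paired_frac:
        reasons.append("unpaired mature")
    n_unpaired = len(idx) - len(paired)
    if n_unpaired > max_unpaired_mature:
        reasons.append("mature bulges")
    pmin, pmax = min(partners), max(partners)
    star_unpaired = sum(1 for k in range(pmin, pmax + 1) if partner[k] < 0)
    if abs(n_unpaired - star_unpaired) > max_asymmetry:
        reasons.append("asymmetric bulges")
    if arm == "5p":
        star = (pmin, min(pmax + 3, n))
    else:
        star = (max(pmin - 2, 0), pmax + 1)
    return not reasons, reasons, star, arm


def evaluate_precursor(window: str, mature_span: tuple[int, int]) -> HairpinEvaluation:
    """Fold an excised window, trim to the mature's stem-loop, and score it."""
    window = window.upper().replace("T", "U")
    db, _ = fold_mfe(window)
    partner = pair_table(db)
    span = stem_loop_span(partner, mature_span)
    if span is None:
        gc = gc_percent(window)
        return HairpinEvaluation(
            precursor_seq=window,
            structure=db,
            mfe=0.0,
            mfe_kj=0.0,
            amfe=0.0,
            gc_pct=round(gc, 4),
            mfei=0.0,
            mature_arm="?",
            mature_span=mature_span,
            star_span=None,
            valid_hairpin=False,
            reasons=["unpaired mature"],
        )
    lo, hi = span
    lo = min(lo, mature_span[0])
    hi = max(hi, mature_span[1] - 1)
    pre = window[lo : hi + 1]
    m2 = (mature_span[0] - lo, mature_span[1] - lo)
    db2, mfe_val = fold_mfe(pre)
    partner2 = pair_table(db2)
    gc = gc_percent(pre)
    if gc > 0:
        amfe, mfei_val = mfei(mfe_val, len(pre), gc)
    else:
        amfe, mfei_val = 0.0, 0.0
    valid, reasons, star, arm = validate_hairpin(partner2, m2)
    if gc == 0:
        valid = False
        reasons = reasons + ["zero GC"]
    return HairpinEvaluation(
        precursor_seq=pre,
        structure=db2,
        mfe=round(mfe_val, 4),
        mfe_kj=round(mfe_val * KCAL_TO_KJ, 4),
        amfe=amfe,
        gc_pct=round(gc, 4),
        mfei=mfei_val,
        mature_arm=arm,
        mature_span=m2,
        star_span=star,
        valid_hairpin=valid,
        reasons=reasons,
        window_offset=lo,
    )


# --------------------------------------------------------------------------
# precursor excision
# --------------------------------------------------------------------------


def excise_precursors(
    chrom_seq: str,
    start: int,
    end: int,
    strand: str,
    *,
    flank_near: int = 20,
    flank_far: int = 150,
) -> list[tuple[str, tuple[int, int], str, tuple[int, int]]]:
    """Candidate precursor windows around a uniquely mapped tag.

    Two windows are excised per hit: one with the tag as the 5p arm (short
    flank upstream in transcript orientation, long flank downstream) and the
    mirror with the tag as the 3p arm.  Windows are truncated at contig edges
    and returned as RNA in transcript orientation together with the mature
    span inside the window, the assumed arm, and the genomic interval.
    """
    tag_len = end - start
    out = []
    for arm in ("5p", "3p"):
        if (strand == "+") == (arm == "5p"):
            a = max(0, start - flank_near)
            b = min(len(chrom_seq), end + flank_far)
        else:
            a = max(0, start - flank_far)
            b = min(len(chrom_seq), end + flank_near)
        requested = tag_len + flank_near + flank_far
        # skip only when contig-edge truncation leaves too little context
        if b - a < min(tag_len + 15, requested):
            continue
        seq = chrom_seq[a:b]
        if strand == "-":
            from .util import revcomp

            seq = revcomp(seq)
            m0 = b - end
        else:
            m0 = start - a
        out.append((seq.replace("T", "U"), (m0, m0 + tag_len), arm, (a, b)))
    return out


def write_vienna(path, records) -> None:
    """Write (name, seq, structure, mfe) records in Vienna dot-bracket text."""
    with open(path, "w") as fh:
        for name, seq, db, e in records:
            fh.write(f">{name}\n{seq}\n{db} ({e:.2f})\n")
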