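"""Minimum-free-energy RNA secondary-structure prediction.

A simplified Turner-style nearest-neighbour model: helix stacking energies,
hairpin-loop initiation (minimum loop 3 nt) with AU/GU closing penalty,
bulge/internal-loop penalties with capped asymmetry, and an affine multiloop
penalty.  No dangles, coaxial stacking, or special tetraloop bonuses.  G:U
wobble pairs are allowed in stems.  The dynamic program is the classic
Zuker recursion (V / multiloop M / external W matrices) with loop size
bounded by ``energy.MAXLOOP``; the kernel is JIT-compiled with numba when
available and falls back to pure Python otherwise.

An alternative folding engine (e.g. a full thermodynamic package) can be
plugged in by passing ``backend=`` to :func:`fold`; the backend only needs
to return a dot-bracket string and an MFE.
"""

from __future__ import annotations

import shutil
import subprocess
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from . import energy as en

_EPS = 1e-6

try:  # pragma: no cover - exercised implicitly
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def _njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]
        return lambda f: f


@_njit(cache=False)
def _fold_kernel(s, stack, hp_loop, bu_loop, in_loop, pair_id, weak,
                 multi_close, multi_branch, multi_unpaired,
                 term_au, asym_pen, asym_max, maxloop):
    n = s.shape[0]
    INF = 1e9
    V = np.full((n, n), INF)
    M = np.full((n, n), INF)

    for d in range(4, n):  # j - i; min hairpin loop 3 => d >= 4
        for i in range(0, n - d):
            j = i + d
            pij = pair_id[s[i], s[j]]
            if pij >= 0:
                # hairpin closing (i, j)
                best = hp_loop[j - i - 1]
                if weak[pij] == 1:
                    best += term_au
                # stack / bulge / internal to inner pair (k, l)
                for k in range(i + 1, min(i + maxloop + 2, j - 4) + 1):
                    n1 = k - i - 1
                    for l in range(max(k + 4, j - 1 - (maxloop - n1)), j):
                        if V[k, l] >= INF:
                            continue
                        pkl = pair_id[s[k], s[l]]
                        if pkl < 0:
                            continue
                        n2 = j - l - 1
                        if n1 == 0 and n2 == 0:
                            e = V[k, l] + stack[pij, pkl]
                        elif n1 == 0 or n2 == 0:
                            e = V[k, l] + bu_loop[n1 + n2]
                        else:
                            a = asym_pen * abs(n1 - n2)
                            if a > asym_max:
                                a = asym_max
                            e = V[k, l] + in_loop[n1 + n2] + a
                        if e < best:
                            best = e
                # multiloop closed by (i, j)
                for k in range(i + 1, j - 1):
                    if M[i + 1, k] < INF and M[k + 1, j - 1] < INF:
                        e = multi_close + multi_branch + M[i + 1, k] + M[k + 1, j - 1]
                        if e < best:
                            best = e
                V[i, j] = best
            # M: at least one branch within i..j (multiloop context)
            best = INF
            if V[i, j] < INF:
                best = V[i, j] + multi_branch
            if M[i + 1, j] + multi_unpaired < best:
                best = M[i + 1, j] + multi_unpaired
            if M[i, j - 1] + multi_unpaired < best:
                best = M[i, j - 1] + multi_unpaired
            for k in range(i + 1, j):
                e = M[i, k] + M[k + 1, j]
                if e < best:
                    best = e
            M[i, j] = best

    # external: W[j] = best energy of prefix 0..j
    W = np.zeros(n)
    for j in range(n):
        best = W[j - 1] if j > 0 else 0.0
        for i in range(0, j):
            if V[i, j] < INF:
                left = W[i - 1] if i > 0 else 0.0
                if left + V[i, j] < best:
                    best = left + V[i, j]
        if V[0, j] < best:
            best = V[0, j]
        W[j] = best

    # traceback
    pairs = np.full(n, -1, dtype=np.int64)
    # explicit stack of (state, i, j): state 0 = V, 1 = M
    st_state = np.zeros(2 * n + 4, dtype=np.int64)
    st_i = np.zeros(2 * n + 4, dtype=np.int64)
    st_j = np.zeros(2 * n + 4, dtype=np.int64)
    top = 0

    j = n - 1
    while j >= 0:
        if j > 0 and W[j] >= W[j - 1] - 1e-6:
            j -= 1
            continue
        found = False
        for i in range(0, j):
            left = W[i - 1] if i > 0 else 0.0
            if V[i, j] < 1e9 and abs(left + V[i, j] - W[j]) < 1e-6:
                st_state[top] = 0
                st_i[top] = i
                st_j[top] = j
                top += 1
                j = i - 1
                found = True
                break
        if not found:
            if V[0, j] < 1e9 and abs(V[0, j] - W[j]) < 1e-6:
                st_state[top] = 0
                st_i[top] = 0
                st_j[top] = j
                top += 1
            j = -1

    while top > 0:
        top -= 1
        state = st_state[top]
        i = st_i[top]
        j = st_j[top]
        if state == 0:  # V(i, j)
            pairs[i] = j
            pairs[j] = i
            pij = pair_id[s[i], s[j]]
            target = V[i, j]
            hp = hp_loop[j - i - 1]
            if weak[pij] == 1:
                hp += term_au
            if abs(hp - target) < 1e-6:
                continue
            done = False
            for k in range(i + 1, min(i + maxloop + 2, j - 4) + 1):
                if done:
                    break
                n1 = k - i - 1
                for l in range(max(k + 4, j - 1 - (maxloop - n1)), j):
                    if V[k, l] >= 1e9:
                        continue
                    pkl = pair_id[s[k], s[l]]
                    if pkl < 0:
                        continue
                    n2 = j - l - 1
                    if n1 == 0 and n2 == 0:
                        e = V[k, l] + stack[pij, pkl]
                    elif n1 == 0 or n2 == 0:
                        e = V[k, l] + bu_loop[n1 + n2]
                    else:
                        a = asym_pen * abs(n1 - n2)
                        if a > asym_max:
                            a = asym_max
                        e = V[k, l] + in_loop[n1 + n2] + a
                    if abs(e - target) < 1e-6:
                        st_state[top] = 0
                        st_i[top] = k
                        st_j[top] = l
                        top += 1
                        done = True
                        break
            if done:
                continue
            for k in range(i + 1, j - 1):
                if M[i + 1, k] < 1e9 and M[k + 1, j - 1] < 1e9:
                    e = multi_close + multi_branch + M[i + 1, k] + M[k + 1, j - 1]
                    if abs(e - target) < 1e-6:
                        st_state[top] = 1
                        st_i[top] = i + 1
                        st_j[top] = k
                        top += 1
                        st_state[top] = 1
                        st_i[top] = k + 1
                        st_j[top] = j - 1
                        top += 1
                        break
        else:  # M(i, j)
            target = M[i, j]
            if V[i, j] < 1e9 and abs(V[i, j] + multi_branch - target) < 1e-6:
                st_state[top] = 0
                st_i[top] = i
                st_j[top] = j
                top += 1
                continue
            if abs(M[i + 1, j] + multi_unpaired - target) < 1e-6:
                st_state[top] = 1
                st_i[top] = i + 1
                st_j[top] = j
                top += 1
                continue
            if abs(M[i, j - 1] + multi_unpaired - target) < 1e-6:
                st_state[top] = 1
                st_i[top] = i
                st_j[top] = j - 1
                top += 1
                continue
            for k in range(i + 1, j):
                if abs(M[i, k] + M[k + 1, j] - target) < 1e-6:
                    st_state[top] = 1
                    st_i[top] = i
                    st_j[top] = k
                    top += 1
                    st_state[top] = 1
                    st_i[top] = k + 1
                    st_j[top] = j
                    top += 1
                    break

    mfe = W[n - 1] if n > 0 else 0.0
    if mfe > 0.0:
        mfe = 0.0
    return mfe, pairs


@dataclass(frozen=True)
class FoldResult:
    """An MFE structure: sequence, dot-bracket, energy and pairing partners.

    ``partner[k]`` is the 0-based pairing partner of position ``k`` or -1;
    ``pair_map`` exposes the same information 1-based.
    """

    seq: str
    structure: str
    mfe: float
    partner: tuple[int, ...] = field(repr=False)

    @property
    def pair_map(self) -> dict[int, int]:
        return {i + 1: p + 1 for i, p in enumerate(self.partner) if p >= 0}

    def __str__(self) -> str:  # ViennaRNA-style triplet
        return f"{self.seq}\n{self.structure} ({self.mfe:.2f})"


def pairs_to_dotbracket(partner: Sequence[int]) -> str:
    out = []
    for i, p in enumerate(partner):
        out.append("." if p < 0 else ("(" if p > i else ")"))
    return "".join(out)


def dotbracket_to_pairs(structure: str) -> list[int]:
    partner = [-1] * len(structure)
    stack: list[int] = []
    for i, c in enumerate(structure):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise ValueError("unbalanced dot-bracket string")
            j = stack.pop()
            partner[i], partner[j] = j, i
    if stack:
        raise ValueError("unbalanced dot-bracket string")
    return partner


def fold(seq: str, backend: Optional[Callable[[str], tuple[str, float]]] = None) -> FoldResult:
    """Predict the MFE structure of an RNA sequence.

    Parameters
    ----------
    seq:
        RNA (or DNA; T is coerced to U), alphabet ACGU(T), length at most
        ``energy.MAX_FOLD_LEN``.
    backend:
        Optional external engine returning ``(dot_bracket, mfe)``; when given
        the in-repo model is bypassed entirely.
    """
    rna = seq.upper().replace("T", "U")
    if not rna:
        raise ValueError("empty sequence")
    if len(rna) > en.MAX_FOLD_LEN:
        raise ValueError(f"sequence longer than {en.MAX_FOLD_LEN} nt")
    codes = en.encode(rna)  # validates alphabet
    if backend is not None:
        structure, mfe = backend(rna)
        return FoldResult(rna, structure, float(mfe), tuple(dotbracket_to_pairs(structure)))
    if len(rna) < 5:
        return FoldResult(rna, "." * len(rna), 0.0, tuple([-1] * len(rna)))
    mfe, pairs = _fold_kernel(
        codes, en.STACK, en.HAIRPIN_LOOP, en.BULGE_LOOP, en.INTERNAL_LOOP,
        en.PAIR_ID, en.IS_WEAK_PAIR,
        en.MULTI_CLOSE, en.MULTI_BRANCH, en.MULTI_UNPAIRED,
        en.TERMINAL_AU, en.ASYM_PENALTY, en.ASYM_MAX, en.MAXLOOP,
    )
    partner = tuple(int(p) for p in pairs)
    return FoldResult(rna, pairs_to_dotbracket(partner), round(float(mfe), 2), partner)


def structure_energy(seq: str, partner: Sequence[int]) -> float:
    """Score a given structure by loop decomposition under the same model.

    Independent of the DP: walks the structure, classifies each loop closed
    by a pair (hairpin, stack, bulge, internal, multiloop) and sums the
    table energies.  External bases are free.
    """
    rna = seq.upper().replace("T", "U")
    s = en.encode(rna)
    total = 0.0
    for i, j in [(i, p) for i, p in enumerate(partner) if p > i]:
        pij = en.PAIR_ID[s[i], s[j]]
        if pij < 0:
            raise ValueError(f"non-canonical pair {rna[i]}:{rna[j]} at {i + 1},{j + 1}")
        # children: pairs directly nested under (i, j)
        children = []
        k = i + 1
        while k < j:
            p = partner[k]
            if p > k:
                children.append((k, p))
                k = p + 1
            else:
                k += 1
        if not children:
            e = en.HAIRPIN_LOOP[j - i - 1]
            if en.IS_WEAK_PAIR[pij]:
                e += en.TERMINAL_AU
            total += e
        elif len(children) == 1:
            (k, l) = children[0]
            n1, n2 = k - i - 1, j - l - 1
            pkl = en.PAIR_ID[s[k], s[l]]
            if n1 == 0 and n2 == 0:
                total += en.STACK[pij, pkl]
            elif n1 == 0 or n2 == 0:
                total += en.BULGE_LOOP[n1 + n2]
            else:
                total += en.INTERNAL_LOOP[n1 + n2] + min(
                    en.ASYM_MAX, en.ASYM_PENALTY * abs(n1 - n2))
        else:
            unpaired = (j - i - 1) - sum(l - k + 1 for k, l in children)
            total += (en.MULTI_CLOSE + en.MULTI_BRANCH * (1 + len(children))
                      + en.MULTI_UNPAIRED * unpaired)
    return total


def is_single_hairpin(result: FoldResult) -> tuple[bool, Optional[tuple[int, int]]]:
    """Whether the structure is one stem-loop; returns the terminal loop span.

    True iff the structure contains exactly one terminal (hairpin) loop —
    which also rules out multiloop branching and side-by-side stems.  The
    span is 1-based inclusive over the unpaired terminal-loop bases.
    """
    partner = result.partner
    loops = [(i + 1, p - 1) for i, p in enumerate(partner)
             if p > i and all(partner[k] < 0 for k in range(i + 1, p))]
    if len(loops) != 1:
        return False, None
    lo, hi = loops[0]
    return True, (lo + 1, hi + 1)  # to 1-based


def arm_of(result: FoldResult, start: int, end: int) -> str:
    """Locate a 1-based inclusive interval relative to the terminal loop.

    Returns ``5p``, ``3p``, ``loop`` or ``spanning``; requires a
    single-hairpin fold.
    """
    ok, span = is_single_hairpin(result)
    if not ok:
        raise ValueError("not a single-hairpin structure")
    loop_lo, loop_hi = span
    if end < loop_lo:
        return "5p"
    if start > loop_hi:
        return "3p"
    if start >= loop_lo and end <= loop_hi:
        return "loop"
    return "spanning"


def rnafold_backend(seq: str) -> tuple[str, float]:
    """Fold with the external ViennaRNA ``RNAfold`` CLI (if on PATH).

    Usable as ``fold(seq, backend=rnafold_backend)`` and as an independent
    cross-check engine.
    """
    exe = shutil.which("RNAfold")
    if exe is None:
        raise RuntimeError("RNAfold executable not found on PATH")
    out = subprocess.run([exe, "--noPS"], input=seq + "\n", text=True,
                         capture_output=True, check=True).stdout.splitlines()
    line = out[1]
    structure = line.split()[0]
    mfe = float(line[line.rindex("(") + 1 : line.rindex(")")])
    return structure, mfe
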