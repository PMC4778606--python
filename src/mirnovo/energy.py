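"""Nearest-neighbour RNA energy parameters.

The parameter tables are shipped as plain-text TSVs under ``mirnovo/data``:
``stack_energies.tsv`` (helix stacking, outer pair x inner pair) and
``loop_energies.tsv`` (hairpin / bulge / internal loop initiation by size,
with Jacobson-Stockmayer log extrapolation beyond the tabulated range).

Bases are encoded A=0, C=1, G=2, U=3.  Pair types are indexed
AU=0, CG=1, GC=2, UA=3, GU=4, UG=5; anything else is not a pair (-1).
"""

from __future__ import annotations

import math
from importlib import resources

import numpy as np

RT = 0.6163  # kcal/mol at 37 C
JS_COEF = 1.75 * RT  # Jacobson-Stockmayer loop-entropy coefficient

#: multiloop closing penalty / per-branch penalty / per-unpaired-base penalty
MULTI_CLOSE = 3.4
MULTI_BRANCH = 0.4
MULTI_UNPAIRED = 0.0
#: penalty for a hairpin closed by an AU or GU pair
TERMINAL_AU = 0.5
#: internal-loop asymmetry penalty per unpaired-length difference, capped
ASYM_PENALTY = 0.5
ASYM_MAX = 3.0
#: largest bulge/internal loop the folding DP will consider
MAXLOOP = 30
#: longest sequence the folder accepts (precursor-scale RNA)
MAX_FOLD_LEN = 300

INF = 1e9

BASE_CODE = {"A": 0, "C": 1, "G": 2, "U": 3, "T": 3}
PAIR_NAMES = ["AU", "CG", "GC", "UA", "GU", "UG"]

# PAIR_ID[b1, b2] -> pair-type index or -1
PAIR_ID = -np.ones((4, 4), dtype=np.int64)
for _idx, _name in enumerate(PAIR_NAMES):
    PAIR_ID[BASE_CODE[_name[0]], BASE_CODE[_name[1]]] = _idx

#: pairs carrying the terminal AU/GU penalty when closing a hairpin
IS_WEAK_PAIR = np.array([1, 0, 0, 1, 1, 1], dtype=np.int64)  # AU, UA, GU, UG


def _load_stack() -> np.ndarray:
    table = np.full((6, 6), INF)
    text = resources.files("mirnovo.data").joinpath("stack_energies.tsv").read_text()
    rows = [ln.split("\t") for ln in text.splitlines() if ln and not ln.startswith("#")]
    header = rows[0][1:]
    for row in rows[1:]:
        i = PAIR_NAMES.index(row[0])
        for col, val in zip(header, row[1:]):
            table[i, PAIR_NAMES.index(col)] = float(val)
    return table


def _load_loops(n_max: int = MAX_FOLD_LEN + 2) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    hairpin = np.full(n_max, INF)
    bulge = np.full(n_max, INF)
    internal = np.full(n_max, INF)
    text = resources.files("mirnovo.data").joinpath("loop_energies.tsv").read_text()
    rows = [ln.split("\t") for ln in text.splitlines() if ln and not ln.startswith("#")]
    tab_max = 0
    for row in rows[1:]:
        n = int(row[0])
        tab_max = max(tab_max, n)
        hairpin[n], bulge[n], internal[n] = (float(v) for v in row[1:4])
    for n in range(tab_max + 1, n_max):
        extrap = JS_COEF * math.log(n / tab_max)
        hairpin[n] = hairpin[tab_max] + extrap
        bulge[n] = bulge[tab_max] + extrap
        internal[n] = internal[tab_max] + extrap
    return hairpin, bulge, internal


STACK = _load_stack()
HAIRPIN_LOOP, BULGE_LOOP, INTERNAL_LOOP = _load_loops()


def encode(seq: str) -> np.ndarray:
    """Encode an RNA/DNA string to the 0..3 integer alphabet."""
    try:
        return np.array([BASE_CODE[c] for c in seq.upper()], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"invalid base {exc} in sequence") from exc


def can_pair(a: str, b: str) -> bool:
    """True if two bases form a canonical (WC or G:U wobble) pair."""
    return PAIR_ID[BASE_CODE[a.upper()], BASE_CODE[b.upper()]] >= 0
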