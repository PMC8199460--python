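"""Performance and questionnaire metrics of the speller.

Selection-level throughput follows the standard information-theoretic
account of an N-alternative BCI: with accuracy ``P`` over ``N = 49``
menu cells (dummies included),

    B   = log2 N + P log2 P + (1 - P) log2[(1 - P)/(N - 1)]   bits/selection
    ITR = B / T                                               bits/min
    SR  = B / log2 N
    WSR = (2 SR - 1)/T  if SR > 0.5 else 0                    symbols/min

where ``T`` is the selection time in minutes.  WSR penalizes the
corrections an error forces and is the criterion used to pick the
per-subject sequence count (with a floor of three sequences).  The
output characters per minute (OCM) counts user-spelled characters only
(spaces included, fixed voice-command prefixes excluded).  SUS and Raw
NASA-TLX give the standard questionnaire scores.
"""

from __future__ import annotations

import math

from .rcp_engine import GRID_ITEMS, selection_duration


def _check_pn(P: float, N: int) -> None:
    if not 0.0 <= P <= 1.0:
        raise ValueError("P must lie in [0, 1]")
    if N < 2:
        raise ValueError("N must be >= 2")


def bits_per_selection(P: float, N: int = GRID_ITEMS) -> float:
    """Bits transmitted per selection (0 log 0 taken as 0 by continuity)."""
    _check_pn(P, N)
    b = math.log2(N)
    if P > 0.0:
        b += P * math.log2(P)
    if P < 1.0:
        b += (1.0 - P) * math.log2((1.0 - P) / (N - 1))
    return b


def itr(P: float, N: int, T_minutes: float) -> float:
    """Information transfer rate in bits per minute."""
    if T_minutes <= 0:
        raise ValueError("T_minutes must be positive")
    return bits_per_selection(P, N) / T_minutes


def symbol_rate(P: float, N: int = GRID_ITEMS) -> float:
    return bits_per_selection(P, N) / math.log2(N)


def wsr(P: float, N: int, T_minutes: float) -> float:
    """Written symbol rate in symbols per minute (0 at or below SR = 0.5)."""
    if T_minutes <= 0:
        raise ValueError("T_minutes must be positive")
    sr = symbol_rate(P, N)
    if sr <= 0.5:
        return 0.0
    return (2.0 * sr - 1.0) / T_minutes


def ocm(spelled_chars: int, spelling_minutes: float) -> float:
    """Output characters per minute.

    The caller counts user-spelled characters including spaces and
    excluding the predetermined voice-command prefixes.
    """
    if spelling_minutes <= 0:
        raise ValueError("spelling_minutes must be positive")
    if spelled_chars < 0:
        raise ValueError("spelled_chars must be >= 0")
    return spelled_chars / spelling_minutes


def spelled_character_count(sentence: str, prefix: str) -> int:
    """Characters that count toward OCM: the sentence minus its fixed
    command prefix, trailing whitespace ignored."""
    if not sentence.startswith(prefix):
        raise ValueError("sentence does not carry the expected command prefix")
    return len(sentence[len(prefix):].rstrip(" "))


def choose_sequences(curve: dict[int, float], timing, min_seq: int = 3,
                     n_items: int = GRID_ITEMS) -> int:
    """Sequence count maximizing the calibration WSR, floored at ``min_seq``.

    ``curve`` maps sequence count k to calibration accuracy P_k; the
    selection time for k uses pure flash time (14 k x SOA plus any
    configured pause).  Ties break toward the smallest k.
    """
    if not curve:
        raise ValueError("empty accuracy curve")
    best_k, best_w = None, -1.0
    for k in sorted(curve):
        w = wsr(curve[k], n_items, selection_duration(k, timing) / 60.0)
        if w > best_w:
            best_k, best_w = k, w
    assert best_k is not None
    return max(best_k, min_seq)


def sus_score(items) -> float:
    """System Usability Scale: ten 1-5 Likert items -> 0-100."""
    items = list(items)
    if len(items) != 10:
        raise ValueError("SUS has exactly ten items")
    if any(not 1 <= v <= 5 for v in items):
        raise ValueError("SUS items must lie in 1..5")
    total = 0
    for i, v in enumerate(items):
        total += (v - 1) if i % 2 == 0 else (5 - v)   # odd-numbered items positive
    return total * 2.5


def tlx_total(subscales) -> float:
    """Raw NASA-TLX total workload: mean of the six 0-100 subscales."""
    vals = list(subscales)
    if len(vals) != 6:
        raise ValueError("Raw NASA-TLX has exactly six subscales")
    if any(not 0 <= v <= 100 for v in vals):
        raise ValueError("subscales must lie in [0, 100]")
    return sum(vals) / 6.0
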