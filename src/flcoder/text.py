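"""Name normalization and fuzzy string matching.

Storefront names arrive in mixed case, with Catalan/Spanish diacritics,
apostrophes and stray punctuation; both keyword classification and
duplicate detection operate on a canonical form.
"""

from __future__ import annotations

import re
import unicodedata
from difflib import SequenceMatcher

_PUNCT_RE = re.compile(r"[^\w\s]|_", flags=re.UNICODE)
_WS_RE = re.compile(r"\s+")


def normalize_text(s: str) -> str:
    """Canonicalize free text: lower-case, strip accents, drop punctuation.

    "Cafetería El Niño" -> "cafeteria el nino"; apostrophes are removed
    without splitting the word ("McDonald's" -> "mcdonalds").
    """
    s = s.replace("'", "").replace("’", "").replace("ʼ", "")
    # NFKD first: compatibility forms may expand to fresh uppercase letters
    s = unicodedata.normalize("NFKD", s)
    s = "".join(ch for ch in s if not unicodedata.combining(ch))
    s = s.lower()
    s = _PUNCT_RE.sub(" ", s)
    return _WS_RE.sub(" ", s).strip()


def token_set_similarity(a: str, b: str) -> float:
    """Token-set string similarity in [0, 1] between two canonical names.

    The classic token-set ratio: split both names into word tokens, then
    score the shared-token core against each full token set with a
    sequence matcher and take the best.  Reordered tokens ("bar pepe" vs
    "pepe bar") score 1.0; a name that extends the other with extra
    tokens still scores highly through the shared core.
    """
    ta, tb = set(a.split()), set(b.split())
    if not ta or not tb:
        return 0.0
    inter = " ".join(sorted(ta & tb))
    only_a = " ".join(sorted(ta - tb))
    only_b = " ".join(sorted(tb - ta))
    combined_a = f"{inter} {only_a}".strip()
    combined_b = f"{inter} {only_b}".strip()
    return max(
        _ratio(inter, combined_a) if inter else 0.0,
        _ratio(inter, combined_b) if inter else 0.0,
        _ratio(combined_a, combined_b),
    )


def _ratio(x: str, y: str) -> float:
    if x == y:
        return 1.0
    if y < x:  # SequenceMatcher.ratio is argument-order dependent; canonicalize
        x, y = y, x
    return SequenceMatcher(None, x, y).ratio()
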