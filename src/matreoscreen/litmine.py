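"""Compound filtering over lifespan databases and abstract text.

Keeps compounds whose best reported mean lifespan extension exceeds a
threshold, then flags those whose abstracts mention extracellular-matrix
key terms.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

# ECM key terms searched in abstracts. Matching is token-prefix, so "TGF"
# also hits "TGFbeta"/"TGFB1"-style tokens.
DEFAULT_ECM_KEYWORDS = (
    "collagen",
    "ECM",
    "extracellular",
    "matrix",
    "proteoglycan",
    "hyaluronic",
    "hyaluronan",
    "TGF",
    "integrin",
    "TGFbeta",
)

_TOKEN_RE = re.compile(r"[A-Za-z0-9ß-ω]+")


@dataclass
class CompoundRecord:
    compound: str
    mean_lifespan_change_pct: float  # max across species/studies
    species: list[str] = field(default_factory=list)
    abstract_text: str = ""
    keyword_hits: int = 0
    matched_terms: list[str] = field(default_factory=list)
    ecm_linked: bool = False


def filter_lifespan(
    records: list[CompoundRecord], min_extension_pct: float = 5.0
) -> list[CompoundRecord]:
    """Keep records with lifespan change strictly above the threshold."""
    return [r for r in records if r.mean_lifespan_change_pct > min_extension_pct]


def keyword_hits(
    text: str,
    keywords: tuple[str, ...] | list[str] = DEFAULT_ECM_KEYWORDS,
    count_occurrences: bool = False,
) -> tuple[int, list[str]]:
    """Count keywords matched in text by case-insensitive token-prefix match.

    A keyword matches any word token that starts with it ("collagen"
    matches "collagens", "TGF" matches "TGFbeta"). By default each keyword
    counts at most once (distinct-keyword count); ``count_occurrences``
    switches to total matching tokens. Returns (count, matched keywords).
    """
    if not keywords:
        raise ValueError("keyword list is empty")
    tokens = [t.lower() for t in _TOKEN_RE.findall(text)]
    matched: list[str] = []
    total = 0
    for kw in keywords:
        kl = kw.lower()
        n = sum(1 for t in tokens if t.startswith(kl))
        if n:
            matched.append(kw)
            total += n
    count = total if count_occurrences else len(matched)
    return count, matched


def flag_ecm(
    records: list[CompoundRecord],
    keywords: tuple[str, ...] | list[str] = DEFAULT_ECM_KEYWORDS,
) -> list[CompoundRecord]:
    """Fill keyword_hits from abstracts and set ecm_linked = (hits >= 1)."""
    for r in records:
        r.keyword_hits, r.matched_terms = keyword_hits(r.abstract_text, keywords)
        r.ecm_linked = r.keyword_hits >= 1
    return records
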