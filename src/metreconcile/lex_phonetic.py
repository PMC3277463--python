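"""Name normalisation and phonetic matching for structure-less metabolites.

When a metabolite carries no structure, its name is the only evidence of
identity — but sources decorate names with stereo prefixes (``L-``,
``cis-``), locants (``7,8-``), case and spelling variants.  Normalisation
strips exactly the decorations that do not change chemical identity *for
matching purposes* (stereo distinctions are resolved later at the structure
level), and a phonetic encoder catches residual spelling variants
("coumarate" vs "cumarate").

Matches are never applied automatically: :func:`suggest_matches` only ranks
candidates for a curator, whose accepted mappings are fed back in as an
explicit input file.
"""

from __future__ import annotations

import re
import unicodedata
from collections import Counter
from dataclasses import dataclass, field
from fractions import Fraction

from .model import MetaboliteEntry, Resolution

#: Tokens that carry stereo/geometric information only.
STEREO_TOKENS = frozenset(
    {"cis", "trans", "l", "d", "dl", "alpha", "beta", "gamma", "omega",
     "r", "s", "e", "z", "sn", "n", "o", "p", "m", "sec", "tert"}
)

#: Non-chemistry words that appear in some source names.
STOPWORDS = frozenset({"use", "used", "for", "experiment", "compound", "the", "a", "an", "of"})

_GREEK = {
    "α": "alpha", "β": "beta", "γ": "gamma", "δ": "delta", "ε": "epsilon", "ω": "omega",
}

_LOCANT = re.compile(r"^\d+(,\d+)*'*$")


@dataclass(frozen=True)
class NormalizedName:
    """Ordered surviving tokens plus the tokens that were suppressed."""

    tokens: tuple[str, ...]
    suppressed: tuple[str, ...] = ()

    def multiset(self) -> Counter:
        return Counter(self.tokens)

    def render(self) -> str:
        return " ".join(self.tokens)

    def signature(self) -> str:
        """Order- and hyphenation-insensitive fingerprint.

        Sources disagree on whether substituent names are fused
        ("aminoimidazole") or hyphen-separated ("amino-...-imidazole"), so
        the fingerprint concatenates the sorted tokens without separators:
        fused and split writings of the same substituents coincide.
        """
        return "".join(sorted(self.tokens))

    def equivalent(self, other: "NormalizedName") -> bool:
        return self.multiset() == other.multiset() or self.signature() == other.signature()


def _spell_greek(text: str) -> str:
    return "".join(_GREEK.get(ch, ch) for ch in text)


def normalize_name(name: str, stopwords: frozenset[str] = STOPWORDS) -> NormalizedName:
    """Normalise a metabolite name for identity matching.

    Case-folds, spells out Greek letters, splits on punctuation, rewrites
    every ``<stem>ic acid`` to ``<stem>ate`` (before stopword removal, so
    ``acid`` never survives as a token), and suppresses stereo descriptors,
    bare numerals/locant groups and configured non-chemistry stopwords.
    Idempotent on its own rendered output.
    """
    if not name:
        raise ValueError("empty name")
    text = unicodedata.normalize("NFKC", _spell_greek(name)).lower()
    # "-ic acid" -> "-ate" before any token surgery
    text = re.sub(r"([a-z]+)ic(?:\s+|-)acid\b", r"\1ate", text)
    raw_tokens = [t for t in re.split(r"[\s\-_,;:()\[\]{}'\"/+]+", text) if t]

    kept: list[str] = []
    dropped: list[str] = []
    for tok in raw_tokens:
        if tok in STEREO_TOKENS or tok in stopwords or _LOCANT.match(tok):
            dropped.append(tok)
        else:
            kept.append(tok)
    if not kept:  # never erase a name completely
        kept, dropped = raw_tokens, []
    return NormalizedName(tokens=tuple(kept), suppressed=tuple(dropped))


# ---------------------------------------------------------------------------
# Phonetic encoding
#
# A compact metaphone-class encoder: consonant-skeleton codes with the usual
# Latinate collapses (C/K/Q -> K, PH -> F, X -> KS, soft G -> J, vowel and
# doubled-letter suppression).  Chemical names are mostly Latinate, so these
# rules fold the common transliteration variants ("coumarate"/"cumarate",
# "cysteine"/"cystein") onto one code.

_PHONETIC_DIGRAPHS = [
    ("ph", "F"), ("gh", "K"), ("ck", "K"), ("sch", "SK"), ("sh", "X"),
    ("ch", "K"), ("th", "T"), ("qu", "KW"), ("wh", "W"), ("kn", "N"),
    ("gn", "N"), ("wr", "R"), ("ae", "E"), ("oe", "E"),
]

_PHONETIC_SINGLE = {
    "b": "P", "c": "K", "d": "T", "f": "F", "g": "K", "h": "", "j": "J",
    "k": "K", "l": "L", "m": "M", "n": "N", "p": "P", "q": "K", "r": "R",
    "s": "S", "t": "T", "v": "F", "w": "W", "x": "KS", "y": "", "z": "S",
}

_VOWELS = set("aeiou")


def phonetic_key(token: str) -> str:
    """Deterministic phonetic code of a normalised token.

    Equal tokens always yield equal codes; near-homophones collapse.
    Digits are preserved verbatim (they distinguish e.g. ``f420`` species).
    """
    t = token.lower()
    # soft c/g before front vowels sound as S/J
    t = re.sub(r"c(?=[eiy])", "s", t)
    t = re.sub(r"g(?=[eiy])", "j", t)
    for dig, rep in _PHONETIC_DIGRAPHS:
        t = t.replace(dig, rep)
    out: list[str] = []
    for i, ch in enumerate(t):
        if ch.isdigit() or ch.isupper():
            out.append(ch)
        elif ch in _VOWELS:
            if i == 0:
                out.append("A")  # initial vowel class marker
        else:
            out.append(_PHONETIC_SINGLE.get(ch, ""))
    code = "".join(out)
    return re.sub(r"(.)\1+", r"\1", code)  # collapse runs


# ---------------------------------------------------------------------------
# Suggestion ranking

_EVIDENCE_PRIORITY = {"exact-normalized": 0, "phonetic": 1, "reaction-context": 2}


@dataclass(frozen=True, order=False)
class MatchSuggestion:
    """A ranked, curator-facing candidate identity for an unresolved entry."""

    candidate: str
    score: Fraction
    evidence: str
    rank: int = 0


def _best_name_score(query: MetaboliteEntry, cand: MetaboliteEntry) -> tuple[Fraction, str]:
    """Best (score, evidence) over all name pairs of query x candidate."""
    best = (Fraction(0), "phonetic")
    for qn in query.names:
        qnorm = normalize_name(qn)
        qms = qnorm.multiset()
        qcodes = Counter(phonetic_key(t) for t in qnorm.tokens)
        for cn in cand.names:
            cnorm = normalize_name(cn)
            if qnorm.equivalent(cnorm):
                return (Fraction(1), "exact-normalized")
            ccodes = Counter(phonetic_key(t) for t in cnorm.tokens)
            overlap = sum((qcodes & ccodes).values())
            denom = max(sum(qcodes.values()), sum(ccodes.values()))
            if denom:
                score = Fraction(overlap, denom)
                if score > best[0]:
                    best = (score, "phonetic")
    return best


def suggest_matches(
    query: MetaboliteEntry,
    resolved: list[MetaboliteEntry],
    k: int = 5,
    score_floor: Fraction = Fraction(1, 2),
) -> list[MatchSuggestion]:
    """Rank up to ``k`` resolved candidates for an unresolved metabolite.

    Score 1 for exact normalised-token-multiset equality; otherwise the
    fraction of tokens whose phonetic codes match.  Ties break by evidence
    priority then candidate id, so output is fully deterministic.  The
    result is advisory only.
    """
    if query.resolution is Resolution.FULL:
        raise ValueError("query already has resolution=full")
    scored = []
    for cand in resolved:
        if cand.resolution is not Resolution.FULL:
            raise ValueError(f"candidate {cand.id!r} is not fully resolved")
        score, evidence = _best_name_score(query, cand)
        if score >= score_floor:
            scored.append((score, evidence, cand.id))
    scored.sort(key=lambda t: (-t[0], _EVIDENCE_PRIORITY[t[1]], t[2]))
    return [
        MatchSuggestion(candidate=cid, score=s, evidence=ev, rank=i + 1)
        for i, (s, ev, cid) in enumerate(scored[:k])
    ]
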