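"""Wordlist ingestion and tonic-domain extraction.

The analysis domain is the tonic (first-syllable) vowel together with the
single intervocalic consonant that follows it.  This module parses segmented
wordlists and per-language segment feature tables, applies the vowel-length
normalization conventions used for Australian lexical data (two adjacent
identical short vowels, and /uwu/, /iji/ sequences, are treated as one long
vowel; geminates and pre-stopped sonorants are single multi-character
symbols), and tabulates the distribution of (vowel, consonant) string types
per language.
"""

from __future__ import annotations

import csv
import io
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

logger = logging.getLogger(__name__)

VOWEL = "vowel"
CONSONANT = "consonant"


class LexiconError(ValueError):
    """Raised for malformed wordlists or segment tables."""


@dataclass(frozen=True)
class Segment:
    """Feature bundle for one segment symbol."""

    symbol: str
    seg_class: str  # "vowel" | "consonant"
    length: Optional[str] = None  # "short" | "long" | None
    length_partner: Optional[str] = None
    place: Optional[str] = None
    manner: Optional[str] = None


class SegmentTable:
    """Phoneme inventory of one language: symbol -> feature bundle.

    Symbols may be multi-character (digraphs, geminates, pre-stopped
    sonorants); tokenization is greedy longest-match.  Every long vowel must
    name its short partner and vice versa; every consonant must carry place
    and manner labels.
    """

    def __init__(self, segments: Iterable[Segment]):
        self._segments: dict[str, Segment] = {}
        for seg in segments:
            if seg.symbol in self._segments:
                raise LexiconError(f"duplicate segment symbol {seg.symbol!r}")
            self._segments[seg.symbol] = seg
        self._validate()
        # longest-first ordering drives greedy tokenization
        self._symbols_by_length = sorted(
            self._segments, key=len, reverse=True
        )

    def _validate(self) -> None:
        for seg in self._segments.values():
            if seg.seg_class not in (VOWEL, CONSONANT):
                raise LexiconError(
                    f"{seg.symbol!r}: class must be vowel or consonant, "
                    f"got {seg.seg_class!r}"
                )
            if seg.seg_class == CONSONANT:
                if not seg.place or not seg.manner:
                    raise LexiconError(
                        f"consonant {seg.symbol!r} lacks place/manner labels"
                    )
            if seg.length in ("short", "long") and seg.length_partner:
                partner = self._segments.get(seg.length_partner)
                if partner is None:
                    raise LexiconError(
                        f"{seg.symbol!r}: length partner "
                        f"{seg.length_partner!r} not in table"
                    )
                if partner.length_partner != seg.symbol:
                    raise LexiconError(
                        f"length partnership {seg.symbol!r} <-> "
                        f"{seg.length_partner!r} is not symmetric"
                    )
            if seg.length == "long" and not seg.length_partner:
                raise LexiconError(
                    f"long vowel {seg.symbol!r} has no short partner"
                )

    def __contains__(self, symbol: str) -> bool:
        return symbol in self._segments

    def __getitem__(self, symbol: str) -> Segment:
        return self._segments[symbol]

    def __len__(self) -> int:
        return len(self._segments)

    @property
    def symbols(self) -> list[str]:
        return list(self._segments)

    def segments(self) -> list[Segment]:
        return list(self._segments.values())

    def is_vowel(self, symbol: str) -> bool:
        return self._segments[symbol].seg_class == VOWEL

    def is_consonant(self, symbol: str) -> bool:
        return self._segments[symbol].seg_class == CONSONANT

    def vowel_length_pairs(self) -> list[tuple[str, str]]:
        """(short, long) symbol pairs among partnered vowels."""
        pairs = []
        for seg in self._segments.values():
            if (
                seg.seg_class == VOWEL
                and seg.length == "short"
                and seg.length_partner
            ):
                pairs.append((seg.symbol, seg.length_partner))
        return pairs

    def tokenize(self, raw: str) -> list[str]:
        """Greedy longest-match tokenization of a contiguous form.

        The concatenation of the returned symbols equals ``raw``.  An
        unmatchable residue raises :class:`LexiconError` naming the
        position.
        """
        if not self._segments:
            raise LexiconError("empty segment table")
        out: list[str] = []
        i = 0
        while i < len(raw):
            for sym in self._symbols_by_length:
                if raw.startswith(sym, i):
                    out.append(sym)
                    i += len(sym)
                    break
            else:
                raise LexiconError(
                    f"cannot tokenize {raw!r}: no symbol matches at "
                    f"position {i} (residue {raw[i:]!r})"
                )
        return out


def tokenize(raw_form: str, table: SegmentTable) -> list[str]:
    """Module-level convenience wrapper for :meth:`SegmentTable.tokenize`."""
    return table.tokenize(raw_form)


@dataclass(frozen=True)
class Wordform:
    language_id: str
    segments: tuple[str, ...]

    def __post_init__(self):
        if not self.segments:
            raise LexiconError("empty wordform")


@dataclass
class Lexicon:
    language_id: str
    words: list[Wordform] = field(default_factory=list)

    def __post_init__(self):
        for w in self.words:
            if w.language_id != self.language_id:
                raise LexiconError(
                    f"wordform language {w.language_id!r} != lexicon "
                    f"language {self.language_id!r}"
                )

    def __len__(self) -> int:
        return len(self.words)


@dataclass(frozen=True)
class DomainInstance:
    """One tonic vowel + single post-tonic intervocalic consonant."""

    vowel: str
    vowel_length: str  # "short" | "long"
    consonant: str
    place: Optional[str]
    manner: Optional[str]


@dataclass
class DomainProfile:
    """Multiset of (vowel, consonant) string types with counts."""

    language_id: str
    counts: dict[tuple[str, str], int] = field(default_factory=dict)

    @property
    def n_instances(self) -> int:
        return sum(self.counts.values())

    def probabilities(self) -> dict[tuple[str, str], float]:
        n = self.n_instances
        return {s: c / n for s, c in self.counts.items()} if n else {}

    def tonic_vowels(self) -> set[str]:
        return {v for (v, _c) in self.counts}


def normalize_vowel_length(
    segments: Sequence[str], table: SegmentTable
) -> list[str]:
    """Rewrite short-vowel sequences as long vowels.

    Single left-to-right pass.  At each position, the triple V-glide-V
    (u-w-u or i-j-i with identical short flanking vowels) is checked before
    the pair of identical adjacent short vowels; either match emits the long
    partner and advances past the matched span.  Non-identical adjacent
    vowels are left untouched (hiatus).  Idempotent: long vowels are never
    re-matched.
    """
    glide_for = {"u": "w", "i": "j"}
    out: list[str] = []
    i = 0
    n = len(segments)

    def short_vowel(sym: str) -> bool:
        return (
            sym in table
            and table.is_vowel(sym)
            and table[sym].length == "short"
        )

    while i < n:
        s = segments[i]
        if short_vowel(s):
            partner = table[s].length_partner
            # /uwu/, /iji/ -> long vowel (triple before pair)
            if (
                s in glide_for
                and i + 2 < n
                and segments[i + 1] == glide_for[s]
                and segments[i + 2] == s
            ):
                if partner is None:
                    raise LexiconError(
                        f"no long partner for {s!r} required by "
                        f"{s}{glide_for[s]}{s} normalization"
                    )
                out.append(partner)
                i += 3
                continue
            # identical short vowel pair -> long vowel
            if i + 1 < n and segments[i + 1] == s:
                if partner is None:
                    raise LexiconError(
                        f"adjacent {s!r} {s!r} but no long partner in table"
                    )
                out.append(partner)
                i += 2
                continue
        out.append(s)
        i += 1
    return out


def extract_domain(
    word: Wordform, table: SegmentTable
) -> Optional[DomainInstance]:
    """Extract the tonic V + single intervocalic C, or None.

    The tonic vowel is the word's first vowel, at index i.  An instance is
    returned iff index i+1 holds exactly one consonant and index i+2 holds a
    vowel; clusters after the tonic vowel, vowel hiatus, and word-final
    consonants yield None.  Assumes segments already normalized by
    :func:`normalize_vowel_length`.
    """
    segs = word.segments
    i = next(
        (k for k, s in enumerate(segs) if table.is_vowel(s)), None
    )
    if i is None:
        logger.debug("word %r has no vowel", "".join(segs))
        return None
    if i + 2 >= len(segs):
        return None  # nothing, or no vowel, after the candidate consonant
    c, after = segs[i + 1], segs[i + 2]
    if not table.is_consonant(c) or not table.is_vowel(after):
        return None
    vseg, cseg = table[segs[i]], table[c]
    return DomainInstance(
        vowel=vseg.symbol,
        vowel_length=vseg.length or "short",
        consonant=cseg.symbol,
        place=cseg.place,
        manner=cseg.manner,
    )


def profile(lexicon: Lexicon, table: SegmentTable) -> DomainProfile:
    """Count (vowel, consonant) string types over a lexicon.

    Each word contributes at most one instance (the tonic syllable is
    unique); duplicate wordforms count separately (multiset semantics over
    the lexical list).  Vowel-length normalization is applied here.
    """
    prof = DomainProfile(language_id=lexicon.language_id)
    for word in lexicon.words:
        segs = normalize_vowel_length(word.segments, table)
        inst = extract_domain(
            Wordform(word.language_id, tuple(segs)), table
        )
        if inst is None:
            continue
        key = (inst.vowel, inst.consonant)
        prof.counts[key] = prof.counts.get(key, 0) + 1
    return prof


def filter_languages(
    profiles: Iterable[DomainProfile],
    tables: Mapping[str, SegmentTable],
    min_instances: int = 200,
) -> list[str]:
    """Language inclusion filter.

    Keep a language iff it has strictly more than ``min_instances`` domain
    instances and at least one short/long vowel pair with both members
    attested among its tonic vowels (some degree of tonic length contrast).
    """
    kept = []
    for prof in profiles:
        if prof.n_instances <= min_instances:
            logger.info(
                "excluding %s: %d domain instances (need > %d)",
                prof.language_id, prof.n_instances, min_instances,
            )
            continue
        table = tables[prof.language_id]
        tonic = prof.tonic_vowels()
        if not any(
            short in tonic and long_ in tonic
            for short, long_ in table.vowel_length_pairs()
        ):
            logger.info(
                "excluding %s: no tonic vowel length contrast attested",
                prof.language_id,
            )
            continue
        kept.append(prof.language_id)
    return kept


# ---------------------------------------------------------------------------
# File formats


def read_segment_table(source) -> SegmentTable:
    """Read a segment feature table from CSV.

    Columns: ``symbol,class,length,length_partner,place,manner``.  Empty
    cells mean "not applicable".  ``source`` is a path or an open text
    stream.
    """
    close = False
    if isinstance(source, (str, bytes)) or hasattr(source, "__fspath__"):
        source = open(source, encoding="utf-8", newline="")
        close = True
    try:
        reader = csv.DictReader(source)
        segs = []
        for row in reader:
            segs.append(
                Segment(
                    symbol=row["symbol"].strip(),
                    seg_class=row["class"].strip(),
                    length=row.get("length", "").strip() or None,
                    length_partner=row.get("length_partner", "").strip()
                    or None,
                    place=row.get("place", "").strip() or None,
                    manner=row.get("manner", "").strip() or None,
                )
            )
    finally:
        if close:
            source.close()
    return SegmentTable(segs)


def write_segment_table(table: SegmentTable, path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["symbol", "class", "length", "length_partner", "place", "manner"]
        )
        for seg in table.segments():
            writer.writerow(
                [
                    seg.symbol,
                    seg.seg_class,
                    seg.length or "",
                    seg.length_partner or "",
                    seg.place or "",
                    seg.manner or "",
                ]
            )


def read_lexicons(
    source,
    tables: Mapping[str, SegmentTable],
    segmented: bool = True,
) -> dict[str, Lexicon]:
    """Read wordlists from TSV: ``language_id<TAB>form``.

    Lines beginning with ``#`` are comments.  If ``segmented`` is true, the
    form is space-delimited segment symbols; otherwise the form is contiguous
    and tokenized greedily against the language's segment table.
    """
    close = False
    if isinstance(source, (str, bytes)) or hasattr(source, "__fspath__"):
        source = open(source, encoding="utf-8")
        close = True
    lexicons: dict[str, Lexicon] = {}
    try:
        for lineno, line in enumerate(source, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            try:
                lang, form = line.split("\t", 1)
            except ValueError:
                raise LexiconError(
                    f"line {lineno}: expected language_id<TAB>form"
                ) from None
            lang = lang.strip()
            table = tables.get(lang)
            if table is None:
                raise LexiconError(
                    f"line {lineno}: no segment table for language "
                    f"{lang!r}"
                )
            if segmented:
                segs = tuple(form.split())
                for s in segs:
                    if s not in table:
                        raise LexiconError(
                            f"line {lineno}: segment {s!r} not in the "
                            f"{lang!r} table"
                        )
            else:
                segs = tuple(table.tokenize(form.strip()))
            lexicons.setdefault(lang, Lexicon(lang)).words.append(
                Wordform(lang, segs)
            )
    finally:
        if close:
            source.close()
    return lexicons


def write_lexicons(lexicons: Mapping[str, Lexicon], path) -> None:
    """Write lexicons as segmented TSV (space-delimited symbols)."""
    with open(path, "w", encoding="utf-8") as fh:
        for lang in sorted(lexicons):
            for word in lexicons[lang].words:
                fh.write(f"{lang}\t{' '.join(word.segments)}\n")


def write_profiles(profiles: Iterable[DomainProfile], path) -> None:
    """Export profiles as CSV ``language_id,vowel,consonant,count``."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["language_id", "vowel", "consonant", "count"])
        for prof in profiles:
            for (v, c), n in sorted(prof.counts.items()):
                writer.writerow([prof.language_id, v, c, n])
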