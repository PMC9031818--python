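"""Entropy-based functional load of phonological contrasts.

The functional load (FL) of a contrast is the drop in entropy of a domain's
string-type distribution when the contrast is collapsed: with H the Shannon
entropy (base 2) of the (vowel, consonant) string types and H' the entropy
after every phoneme set of the contrast is merged to a single fresh symbol,

    fl      = H - H'            (bits)
    fl_norm = (H - H') / H      (dimensionless, 0 when H = 0)

Contrast constructors cover the three families of contrasts analysed here:
vowel length (FLV), post-tonic consonant manner (FLC), and post-tonic
consonant place (FLP).
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass
from typing import Iterable, Optional

from .lexicon import CONSONANT, VOWEL, DomainProfile, SegmentTable

logger = logging.getLogger(__name__)


class ContrastError(ValueError):
    """Raised for ill-formed contrast specifications."""


@dataclass(frozen=True)
class ContrastSpec:
    """A contrast: pairwise-disjoint phoneme sets acting on one slot.

    ``slot`` names the component of the (vowel, consonant) string the sets
    act on.  Collapsing replaces every member of each set by a per-set
    placeholder distinct from all other symbols.
    """

    name: str
    sets: tuple[frozenset[str], ...]
    slot: str  # "vowel" | "consonant"

    def __post_init__(self):
        if self.slot not in (VOWEL, CONSONANT):
            raise ContrastError(f"slot must be vowel or consonant: {self.slot!r}")
        seen: set[str] = set()
        for s in self.sets:
            if len(s) < 2:
                raise ContrastError(
                    f"contrast {self.name!r}: set {sorted(s)} has < 2 members"
                )
            if seen & s:
                raise ContrastError(
                    f"contrast {self.name!r}: overlapping sets at "
                    f"{sorted(seen & s)}"
                )
            seen |= s

    @staticmethod
    def make(name: str, sets: Iterable[Iterable[str]], slot: str) -> "ContrastSpec":
        return ContrastSpec(
            name=name, sets=tuple(frozenset(s) for s in sets), slot=slot
        )


@dataclass(frozen=True)
class FLResult:
    language_id: str
    contrast: str
    H: float
    H_collapsed: float
    fl: float
    fl_norm: float


def entropy(profile: DomainProfile) -> float:
    """Shannon entropy (bits) of the profile's string-type distribution."""
    n = profile.n_instances
    if n == 0:
        return 0.0
    h = 0.0
    for c in profile.counts.values():
        p = c / n
        h -= p * math.log2(p)
    return h


def collapse(profile: DomainProfile, contrast: ContrastSpec) -> DomainProfile:
    """Merge the contrast's phoneme sets to placeholders; sum counts.

    Only the contrast's slot is rewritten; the placeholder for set k is a
    private symbol that cannot collide with inventory symbols.  The total
    instance count is unchanged.
    """
    rewrite: dict[str, str] = {}
    for k, s in enumerate(contrast.sets):
        placeholder = f"⟨{contrast.name}:{k}⟩"  # ⟨name:k⟩
        for sym in s:
            rewrite[sym] = placeholder
    out = DomainProfile(language_id=profile.language_id)
    vowel_slot = contrast.slot == VOWEL
    for (v, c), n in profile.counts.items():
        if vowel_slot:
            key = (rewrite.get(v, v), c)
        else:
            key = (v, rewrite.get(c, c))
        out.counts[key] = out.counts.get(key, 0) + n
    return out


def functional_load(
    profile: DomainProfile, contrast: ContrastSpec
) -> FLResult:
    """FL of a contrast over a profile: entropy drop under collapse."""
    h = entropy(profile)
    h_c = entropy(collapse(profile, contrast))
    fl = max(h - h_c, 0.0)  # clip float round-off; merging cannot raise H
    if h > 0:
        fl_norm = fl / h
    else:
        logger.warning(
            "%s: zero entropy, normalized FL of %s defined as 0",
            profile.language_id, contrast.name,
        )
        fl_norm = 0.0
    return FLResult(
        language_id=profile.language_id,
        contrast=contrast.name,
        H=h,
        H_collapsed=h_c,
        fl=fl,
        fl_norm=fl_norm,
    )


def build_contrasts(
    table: SegmentTable,
) -> tuple[ContrastSpec, ContrastSpec, ContrastSpec]:
    """Construct the (FLV, FLC, FLP) contrasts from a segment table.

    FLV: one set {short, long} per partnered vowel quality.
    FLC: consonants sharing a place label, differing in manner.
    FLP: consonants sharing a manner label, differing in place.
    Singleton groups are dropped (a one-member set carries no contrast).
    """
    flv_sets = [
        frozenset(pair) for pair in table.vowel_length_pairs()
    ]

    by_place: dict[str, set[str]] = {}
    by_manner: dict[str, set[str]] = {}
    for seg in table.segments():
        if seg.seg_class != CONSONANT:
            continue
        if not seg.place or not seg.manner:
            raise ContrastError(
                f"consonant {seg.symbol!r} lacks place/manner labels"
            )
        by_place.setdefault(seg.place, set()).add(seg.symbol)
        by_manner.setdefault(seg.manner, set()).add(seg.symbol)

    flc_sets = [
        frozenset(g) for _p, g in sorted(by_place.items()) if len(g) >= 2
    ]
    flp_sets = [
        frozenset(g) for _m, g in sorted(by_manner.items()) if len(g) >= 2
    ]
    return (
        ContrastSpec("FLV", tuple(flv_sets), VOWEL),
        ContrastSpec("FLC", tuple(flc_sets), CONSONANT),
        ContrastSpec("FLP", tuple(flp_sets), CONSONANT),
    )


def write_fl_results(results: Iterable[FLResult], path) -> None:
    """CSV export: ``language_id,contrast,H,H_collapsed,fl,fl_norm``."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["language_id", "contrast", "H", "H_collapsed", "fl", "fl_norm"]
        )
        for r in results:
            writer.writerow(
                [r.language_id, r.contrast, f"{r.H:.10g}",
                 f"{r.H_collapsed:.10g}", f"{r.fl:.10g}", f"{r.fl_norm:.10g}"]
            )
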