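"""Synthetic trees, Brownian traits, and lexicons with controlled FL.

The generators emulate the shape of the study system: dated family trees of
around 90 languages, continuous traits evolving by (bi)variate Brownian
motion, and lexical lists whose tonic-domain distribution realises a
tunable trade-off between vowel-length informativeness and consonant-manner
informativeness.

The trade-off is a theta-mixture over (vowel length, consonant manner):
with probability 1 - theta a word's domain is drawn from distribution A
(length short/long equiprobable, manner fixed) and with probability theta
from distribution B (length fixed short, manner equiprobable between two
values).  In expectation the vowel-length FL is 1 bit at theta = 0 and 0 at
theta = 1, while the consonant-manner FL runs the opposite way; consonant
place is drawn independently of theta, so place FL carries no trade-off.
Evolving a latent trait by BM on a tree and mapping it through a logistic
function to per-language theta values yields whole families of lexicons
with heritable, negatively correlated FLV and FLC.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import dendropy
import numpy as np
import pandas as pd

from .lexicon import Lexicon, Segment, SegmentTable, Wordform

DEFAULT_N_WORDS_RANGE = (208, 3215)  # observed lexicon-size range emulated


class SimulationError(ValueError):
    """Raised for invalid generator specifications."""


# ---------------------------------------------------------------------------
# Trees


def yule_tree(
    n_tips: int,
    birth_rate: float = 1.0,
    seed: Optional[int] = None,
    label_format: str = "L{:03d}",
) -> dendropy.Tree:
    """Simulate a pure-birth (Yule) tree, ultrametric, bit-reproducible.

    Lineages split at rate ``birth_rate`` each; after the n-th tip arises
    the tree is grown for one further exponential waiting time and cut, so
    all tip depths are equal.  Tip labels follow ``label_format``.
    """
    if n_tips < 2:
        raise SimulationError("need at least 2 tips")
    if birth_rate <= 0:
        raise SimulationError("birth rate must be positive")
    rng = np.random.default_rng(seed)

    tree = dendropy.Tree()
    tree.is_rooted = True
    root = tree.seed_node
    # active lineages: (parent dendropy node, start time)
    active: list[tuple[dendropy.Node, float]] = [(root, 0.0), (root, 0.0)]
    t = 0.0
    while len(active) < n_tips:
        t += rng.exponential(1.0 / (birth_rate * len(active)))
        i = int(rng.integers(len(active)))
        parent, start = active.pop(i)
        node = dendropy.Node()
        node.edge.length = t - start
        parent.add_child(node)
        active.append((node, t))
        active.append((node, t))
    t += rng.exponential(1.0 / (birth_rate * n_tips))

    taxa = tree.taxon_namespace
    for k, (parent, start) in enumerate(active):
        leaf = dendropy.Node()
        leaf.edge.length = t - start
        leaf.taxon = taxa.new_taxon(label=label_format.format(k + 1))
        parent.add_child(leaf)
    return tree


# ---------------------------------------------------------------------------
# Brownian traits


@dataclass
class BMSpec:
    """Brownian-motion specification: rate matrix, root state, seed.

    ``rates`` is the trait covariance accrued per unit branch length
    (1x1 or 2x2, symmetric PSD); ``root`` the trait value(s) at the root.
    """

    rates: np.ndarray
    root: np.ndarray
    seed: Optional[int] = None
    trait_names: Optional[tuple[str, ...]] = None

    def __post_init__(self):
        self.rates = np.atleast_2d(np.asarray(self.rates, dtype=float))
        self.root = np.atleast_1d(np.asarray(self.root, dtype=float))
        k = self.rates.shape[0]
        if self.rates.shape != (k, k) or len(self.root) != k:
            raise SimulationError("rates/root dimension mismatch")
        if not np.allclose(self.rates, self.rates.T):
            raise SimulationError("rate matrix must be symmetric")
        eigvals = np.linalg.eigvalsh(self.rates)
        if eigvals.min() < -1e-12:
            raise SimulationError("rate matrix must be positive semi-definite")
        if self.trait_names is None:
            self.trait_names = tuple(
                f"trait{j + 1}" for j in range(k)
            )

    @property
    def k(self) -> int:
        return self.rates.shape[0]

    @property
    def correlation(self) -> float:
        """Implied cross-trait correlation (2-trait specs)."""
        if self.k != 2:
            raise SimulationError("correlation defined for 2-trait specs")
        return float(
            self.rates[0, 1] / np.sqrt(self.rates[0, 0] * self.rates[1, 1])
        )


def simulate_bm(
    tree: dendropy.Tree,
    spec: BMSpec,
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """Evolve traits along a tree by Brownian motion.

    Independent Gaussian increments with covariance ``rates * l`` are drawn
    on each branch of length l; the returned frame has one row per tip
    (indexed by tip label).  Tip values are jointly multivariate normal
    with covariance ``rates`` (traits) kron ``C`` (tree).
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    # PSD (possibly singular) rate matrix: scale the eigenbasis
    w, V = np.linalg.eigh(spec.rates)
    L = V * np.sqrt(np.clip(w, 0.0, None))
    values: dict[int, np.ndarray] = {}
    rows = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            base = spec.root.copy()
            length = node.edge.length or 0.0
        else:
            base = values[id(node.parent_node)]
            length = node.edge.length
            if length is None:
                raise SimulationError("branch without length")
        if length < 0:
            raise SimulationError("negative branch length")
        step = L @ rng.standard_normal(spec.k) * np.sqrt(length)
        val = base + step
        values[id(node)] = val
        if node.is_leaf():
            rows[node.taxon.label] = val
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=list(spec.trait_names)
    )


# ---------------------------------------------------------------------------
# Lexicons with a controlled FLV/FLC trade-off


def tradeoff_segment_table() -> SegmentTable:
    """Default inventory for the trade-off generator.

    One vowel length pair (a / aː), an onset-only bilabial stop, and
    stop/nasal pairs at two places (apical t/n, velar k/ng).  The velar
    nasal is the digraph ``ng``, so greedy tokenization is exercised.
    """
    return SegmentTable(
        [
            Segment("a", "vowel", length="short", length_partner="aː"),
            Segment("aː", "vowel", length="long", length_partner="a"),
            Segment("p", "consonant", place="bilabial", manner="stop"),
            Segment("t", "consonant", place="apical", manner="stop"),
            Segment("n", "consonant", place="apical", manner="nasal"),
            Segment("k", "consonant", place="velar", manner="stop"),
            Segment("ng", "consonant", place="velar", manner="nasal"),
        ]
    )


@dataclass
class TradeoffSpec:
    """One language's draw from the theta-mixture lexicon model.

    ``theta`` routes probability mass from the vowel-length contrast
    (theta = 0: length informative, manner not) to the consonant-manner
    contrast (theta = 1: manner informative, length not).  ``place_probs``
    is the theta-independent distribution over consonant places; the
    default puts all mass on one place so the endpoint entropies are the
    closed-form 1-bit values.
    """

    theta: float
    n_words: int
    language_id: str = "synth"
    inventory: SegmentTable = field(default_factory=tradeoff_segment_table)
    place_probs: Optional[Mapping[str, float]] = None
    manner_a: str = "stop"  # manner fixed under distribution A
    manner_b: str = "nasal"  # alternative manner under distribution B
    seed: Optional[int] = None

    def __post_init__(self):
        if not 0.0 <= self.theta <= 1.0:
            raise SimulationError("theta must lie in [0, 1]")
        if self.n_words < 1:
            raise SimulationError("n_words must be >= 1")
        pairs = self.inventory.vowel_length_pairs()
        if not pairs:
            raise SimulationError("inventory lacks a vowel length pair")
        self.vowel_pair = pairs[0]
        self._consonant_by_place = {}
        for seg in self.inventory.segments():
            if seg.seg_class == "consonant":
                self._consonant_by_place[(seg.place, seg.manner)] = seg.symbol
        places = sorted(
            {
                p
                for (p, m) in self._consonant_by_place
                if (p, self.manner_a) in self._consonant_by_place
                and (p, self.manner_b) in self._consonant_by_place
            }
        )
        if not places:
            raise SimulationError(
                f"inventory lacks a place with both manners "
                f"{self.manner_a!r} and {self.manner_b!r}"
            )
        if self.place_probs is None:
            self.place_probs = {places[0]: 1.0}
        for p in self.place_probs:
            if (p, self.manner_a) not in self._consonant_by_place or (
                p,
                self.manner_b,
            ) not in self._consonant_by_place:
                raise SimulationError(
                    f"place {p!r} lacks consonants for both manners"
                )

    def consonant(self, place: str, manner: str) -> str:
        return self._consonant_by_place[(place, manner)]


def tradeoff_string_probs(spec: TradeoffSpec) -> dict[tuple[str, str], float]:
    """Closed-form (vowel, consonant) string probabilities of the mixture."""
    short, long_ = spec.vowel_pair
    theta = spec.theta
    probs: dict[tuple[str, str], float] = {}
    for place, pp in spec.place_probs.items():
        ca = spec.consonant(place, spec.manner_a)
        cb = spec.consonant(place, spec.manner_b)
        # A: length equiprobable, manner_a; B: short, manner equiprobable
        add = {
            (short, ca): (1 - theta) / 2 + theta / 2,
            (long_, ca): (1 - theta) / 2,
            (short, cb): theta / 2,
        }
        for key, q in add.items():
            if q > 0:
                probs[key] = probs.get(key, 0.0) + pp * q
    return probs


def synth_lexicon(spec: TradeoffSpec) -> Lexicon:
    """Generate a lexicon of CVCV wordforms realising the theta-mixture.

    Each word is onset + tonic vowel + single intervocalic consonant +
    final short vowel, so the domain extractor recovers exactly the drawn
    (vowel, consonant) pair for every word.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_words
    short, long_ = spec.vowel_pair
    use_b = rng.random(n) < spec.theta
    long_vowel = ~use_b & (rng.random(n) < 0.5)
    alt_manner = use_b & (rng.random(n) < 0.5)
    places = sorted(spec.place_probs)
    pvec = np.array([spec.place_probs[p] for p in places], dtype=float)
    pvec = pvec / pvec.sum()
    place_idx = rng.choice(len(places), size=n, p=pvec)

    onset = "p" if "p" in spec.inventory else next(
        s.symbol
        for s in spec.inventory.segments()
        if s.seg_class == "consonant"
    )
    words = []
    for i in range(n):
        vowel = long_ if long_vowel[i] else short
        manner = spec.manner_b if alt_manner[i] else spec.manner_a
        consonant = spec.consonant(places[place_idx[i]], manner)
        words.append(
            Wordform(spec.language_id, (onset, vowel, consonant, short))
        )
    return Lexicon(language_id=spec.language_id, words=words)


# ---------------------------------------------------------------------------
# End-to-end: heritable trade-off across a family


def logistic(z: np.ndarray, loc: float = 0.0, scale: float = 1.0):
    return 1.0 / (1.0 + np.exp(-(np.asarray(z, dtype=float) - loc) / scale))


def evolve_tradeoff(
    tree: dendropy.Tree,
    bm_seed: Optional[int] = None,
    bm_rate: float = 1.0,
    loc: float = 0.0,
    scale: float = 1.0,
    n_words_range: tuple[int, int] = DEFAULT_N_WORDS_RANGE,
    place_probs: Optional[Mapping[str, float]] = None,
    inventory: Optional[SegmentTable] = None,
) -> tuple[dict[str, Lexicon], pd.Series]:
    """Evolve theta by BM + logistic mapping; generate one lexicon per tip.

    A latent trait evolves by univariate BM (rate ``bm_rate``, root at
    ``loc`` so the root theta is 1/2) and is mapped through a logistic
    function to per-tip theta values; each tip then draws a lexicon of
    uniformly sized word count from the theta-mixture.  Consonant place is
    uniform over the two places of the default inventory, independent of
    theta, giving place FL that carries no trade-off.  Returns the lexicons
    and the per-tip theta values (for diagnostics).
    """
    if inventory is None:
        inventory = tradeoff_segment_table()
    if place_probs is None:
        place_probs = {"apical": 0.5, "velar": 0.5}
    root_seq = np.random.SeedSequence(
        bm_seed if bm_seed is not None else np.random.SeedSequence().entropy
    )
    bm_rng = np.random.default_rng(root_seq.spawn(1)[0])
    latent = simulate_bm(
        tree,
        BMSpec(rates=[[bm_rate]], root=[loc], trait_names=("latent",)),
        rng=bm_rng,
    )["latent"]
    thetas = pd.Series(
        logistic(latent.to_numpy(), loc=loc, scale=scale),
        index=latent.index,
        name="theta",
    )
    lo, hi = n_words_range
    lexicons: dict[str, Lexicon] = {}
    for i, (lang, theta) in enumerate(thetas.items()):
        sub = np.random.default_rng(
            np.random.SeedSequence(root_seq.entropy, spawn_key=(1, i))
        )
        n_words = int(sub.integers(lo, hi + 1))
        spec = TradeoffSpec(
            theta=float(theta),
            n_words=n_words,
            language_id=str(lang),
            inventory=inventory,
            place_probs=place_probs,
            seed=int(sub.integers(2**31)),
        )
        lexicons[str(lang)] = synth_lexicon(spec)
    return lexicons, thetas
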