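"""End-to-end orchestration of the two studies.

Study 1: per-trait phylogenetic signal (Blomberg's K + permutation test)
over a tree sample.  Study 2: phylogenetic Pearson correlation between
trait pairs over the same sample.  Trait values are either computed from
raw lexicons (full pipeline) or ingested from a precomputed FL table, since
published per-language FL values are available even where raw lexicons are
not.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import yaml

from . import lexicon as lex
from .functional_load import build_contrasts
from .functional_load import functional_load as _functional_load
from .phylo_correlation import (
    correlate_over_sample,
    correlation_results_frame,
    correlation_summary_frame,
)
from .phylo_signal import (
    k_results_frame,
    k_summary_frame,
    signal_over_sample,
)
from .trees import read_trees

logger = logging.getLogger(__name__)

TRAITS = ("FLVu", "FLCu", "FLPu", "FLVn", "FLCn", "FLPn")
PAIRS = (
    ("FLVu", "FLCu"),
    ("FLVu", "FLPu"),
    ("FLVn", "FLCn"),
    ("FLVn", "FLPn"),
)


class ConfigError(ValueError):
    """Raised for invalid run configurations."""


@dataclass
class RunConfig:
    """Inputs and options of one pipeline run.

    Exactly one of ``lexicons`` (raw-wordlist mode, requires
    ``segment_tables``) or ``fl_table`` (precomputed-FL mode) must be set.
    ``segment_tables`` is a single CSV applied to every language or a
    directory of ``<language_id>.csv`` files.
    """

    trees: Optional[str] = None
    tree_format: str = "nexus"
    lexicons: Optional[str] = None
    segment_tables: Optional[str] = None
    fl_table: Optional[str] = None
    lexicons_segmented: bool = True
    min_instances: int = 200
    n_perm: int = 999
    seed: int = 0
    traits: Sequence[str] = TRAITS
    pairs: Sequence[tuple[str, str]] = PAIRS
    out_dir: str = "phylofl_out"

    def __post_init__(self):
        if (self.lexicons is None) == (self.fl_table is None):
            raise ConfigError(
                "exactly one of lexicons / fl_table must be supplied"
            )
        if self.lexicons is not None and self.segment_tables is None:
            raise ConfigError("raw-lexicon mode requires segment_tables")
        self.pairs = tuple(tuple(p) for p in self.pairs)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def _load_segment_tables(
    path: str, languages: Sequence[str]
) -> dict[str, lex.SegmentTable]:
    p = Path(path)
    if p.is_dir():
        tables = {}
        for lang in languages:
            f = p / f"{lang}.csv"
            if not f.exists():
                raise ConfigError(f"no segment table for {lang!r} at {f}")
            tables[lang] = lex.read_segment_table(f)
        return tables
    shared = lex.read_segment_table(p)
    return {lang: shared for lang in languages}


def compute_fl(
    config: RunConfig,
) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Trait table (six FL variables per retained language) + exclusions.

    Languages failing the inclusion filters (> ``min_instances`` domain
    instances, attested tonic length contrast) are excluded with a logged
    reason, never fatally.  Returns (trait table indexed by language id,
    list of (language_id, reason) exclusions).
    """
    if config.fl_table is not None:
        return ingest_fl_table(config.fl_table), []

    with open(config.lexicons, encoding="utf-8") as fh:
        languages = sorted(
            {
                line.split("\t", 1)[0].strip()
                for line in fh
                if line.strip() and not line.lstrip().startswith("#")
            }
        )
    tables = _load_segment_tables(config.segment_tables, languages)
    lexicons = lex.read_lexicons(
        config.lexicons, tables, segmented=config.lexicons_segmented
    )
    profiles = {
        lang: lex.profile(lexicons[lang], tables[lang]) for lang in languages
    }
    return fl_from_profiles(profiles, tables, config.min_instances)


def fl_from_profiles(
    profiles: dict[str, lex.DomainProfile],
    tables: dict[str, lex.SegmentTable],
    min_instances: int = 200,
) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Apply inclusion filters, then all six FL variables per language."""
    exclusions: list[tuple[str, str]] = []
    rows = {}
    for lang in sorted(profiles):
        prof = profiles[lang]
        table = tables[lang]
        if prof.n_instances <= min_instances:
            exclusions.append(
                (lang, f"{prof.n_instances} domain instances "
                       f"(need > {min_instances})")
            )
            continue
        tonic = prof.tonic_vowels()
        if not any(
            s in tonic and l in tonic
            for s, l in table.vowel_length_pairs()
        ):
            exclusions.append(
                (lang, "no tonic vowel length contrast attested")
            )
            continue
        flv, flc, flp = build_contrasts(table)
        row = {}
        for contrast in (flv, flc, flp):
            res = _functional_load(prof, contrast)
            row[f"{contrast.name}u"] = res.fl
            row[f"{contrast.name}n"] = res.fl_norm
        rows[lang] = row
    trait_table = pd.DataFrame.from_dict(rows, orient="index")
    if not trait_table.empty:
        trait_table = trait_table[list(TRAITS)]
    trait_table.index.name = "language_id"
    for lang, reason in exclusions:
        logger.info("excluded %s: %s", lang, reason)
    return trait_table, exclusions


def ingest_fl_table(path) -> pd.DataFrame:
    """Read a precomputed FL table.

    Accepts either the wide shape (columns ``language_id, FLVu ... FLPn``)
    or the long export shape (``language_id, contrast, H, H_collapsed, fl,
    fl_norm``), which is pivoted to wide.
    """
    df = pd.read_csv(path)
    if "contrast" in df.columns:
        wide = {}
        for _, row in df.iterrows():
            rec = wide.setdefault(row["language_id"], {})
            rec[f"{row['contrast']}u"] = row["fl"]
            rec[f"{row['contrast']}n"] = row["fl_norm"]
        out = pd.DataFrame.from_dict(wide, orient="index")
        out.index.name = "language_id"
        return out[[c for c in TRAITS if c in out.columns]]
    df = df.set_index("language_id")
    return df[[c for c in TRAITS if c in df.columns]]


def _write(df: pd.DataFrame, out_dir: str, name: str, index=False) -> str:
    os.makedirs(out_dir, exist_ok=True)
    path = os.path.join(out_dir, name)
    df.to_csv(path, index=index, float_format="%.10g")
    return path


def run_study1(
    config: RunConfig, trait_table: Optional[pd.DataFrame] = None, trees=None
) -> pd.DataFrame:
    """Phylogenetic signal for every configured trait over the tree sample.

    Writes ``signal_per_tree.csv`` and ``signal_summary.csv`` (per-trait
    mean K, sd K, max permutation p) to the output directory and returns
    the summary frame.  Deterministic under the configured seed.
    """
    if trait_table is None:
        trait_table, exclusions = compute_fl(config)
        _write_exclusions(exclusions, config.out_dir)
    if trees is None:
        trees = read_trees(config.trees, format=config.tree_format)
    results = [
        signal_over_sample(
            trait, trait_table, trees, n_perm=config.n_perm, seed=config.seed
        )
        for trait in config.traits
    ]
    _write(k_results_frame(results), config.out_dir, "signal_per_tree.csv")
    summary = k_summary_frame(results)
    _write(summary, config.out_dir, "signal_summary.csv")
    return summary


def run_study2(
    config: RunConfig, trait_table: Optional[pd.DataFrame] = None, trees=None
) -> pd.DataFrame:
    """Phylogenetic correlation for every configured pair over the sample.

    Writes ``correlation_per_tree.csv`` and ``correlation_summary.csv``
    (per-pair posterior-mean r, 95% equal-tail interval, p) and returns
    the summary frame.
    """
    if trait_table is None:
        trait_table, exclusions = compute_fl(config)
        _write_exclusions(exclusions, config.out_dir)
    if trees is None:
        trees = read_trees(config.trees, format=config.tree_format)
    results = [
        correlate_over_sample(x, y, trait_table, trees)
        for x, y in config.pairs
    ]
    _write(
        correlation_results_frame(results),
        config.out_dir,
        "correlation_per_tree.csv",
    )
    summary = correlation_summary_frame(results)
    _write(summary, config.out_dir, "correlation_summary.csv")
    return summary


def _write_exclusions(exclusions, out_dir: str) -> None:
    df = pd.DataFrame(exclusions, columns=["language_id", "reason"])
    _write(df, out_dir, "exclusions.csv")


def run_all(config: RunConfig) -> dict[str, pd.DataFrame]:
    """Full pipeline: FL computation (or ingestion), Study 1, Study 2."""
    trait_table, exclusions = compute_fl(config)
    _write_exclusions(exclusions, config.out_dir)
    _write(trait_table, config.out_dir, "fl_traits.csv", index=True)
    trees = read_trees(config.trees, format=config.tree_format)
    study1 = run_study1(config, trait_table=trait_table, trees=trees)
    study2 = run_study2(config, trait_table=trait_table, trees=trees)
    meta = pd.DataFrame(
        [{"seed": config.seed, "n_perm": config.n_perm,
          "n_trees": len(trees), "n_languages": len(trait_table)}]
    )
    _write(meta, config.out_dir, "run_metadata.csv")
    return {"traits": trait_table, "study1": study1, "study2": study2}
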