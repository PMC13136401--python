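"""Readers and writers for the external formats the pipeline consumes.

Formats
-------
* word embeddings in the fastText ``.vec`` text dialect: a header line
  ``"N D"`` followed by one ``word v1 ... vD`` line per word.  The first
  whitespace-delimited token is the word; words containing spaces are not
  supported.
* concept translation wordlists, anchor specifications and colexification
  edge lists as TSV;
* labeled square distance matrices as CSV (see :mod:`semscape.rdm`);
* run configuration as YAML.

Every reader rejects malformed input rather than silently repairing it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("semscape")

FLOAT_FMT = "%.10g"


class EmbeddingFormatError(ValueError):
    """Malformed .vec file (bad header, wrong row length, duplicate word)."""


class CoverageError(ValueError):
    """No language survives the coverage filter."""


class ConfigError(ValueError):
    """Invalid or incomplete run configuration."""


def log_stage(stage: str, **info) -> None:
    """One structured log line per pipeline stage."""
    fields = " ".join(f"{k}={v}" for k, v in sorted(info.items()))
    logger.info("stage=%s %s", stage, fields)


# ---------------------------------------------------------------------------
# embeddings
# ---------------------------------------------------------------------------

@dataclass
class EmbeddingTable:
    """One language's concept -> vector map.

    ``vectors`` maps concept_id to a real vector of length ``dim``.  All-zero
    vectors are rejected on construction: they have no direction and would
    poison every cosine downstream.
    """

    language: str
    dim: int
    vectors: dict[str, np.ndarray]
    missing: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.dim <= 0:
            raise EmbeddingFormatError(f"non-positive dimension {self.dim}")
        for word, v in self.vectors.items():
            v = np.asarray(v, dtype=float)
            if v.shape != (self.dim,):
                raise EmbeddingFormatError(
                    f"{self.language}: vector for {word!r} has length {v.size}, "
                    f"expected {self.dim}"
                )
            if not np.all(np.isfinite(v)):
                raise EmbeddingFormatError(f"{self.language}: non-finite vector for {word!r}")
            if np.allclose(v, 0.0):
                raise EmbeddingFormatError(f"{self.language}: all-zero vector for {word!r}")
            self.vectors[word] = v

    @property
    def concepts(self) -> list[str]:
        return list(self.vectors)

    def __contains__(self, concept: str) -> bool:
        return concept in self.vectors

    def matrix(self, concepts) -> np.ndarray:
        """Stack vectors for ``concepts`` (all must be present) into (n, dim)."""
        return np.stack([self.vectors[c] for c in concepts])

    def unit_matrix(self, concepts) -> np.ndarray:
        m = self.matrix(concepts)
        return m / np.linalg.norm(m, axis=1, keepdims=True)


def read_embeddings(path, restrict_to=None) -> EmbeddingTable:
    """Parse a ``.vec`` file, optionally keeping only ``restrict_to`` concepts.

    Concepts requested but absent from the file are recorded on the returned
    table's ``missing`` attribute.
    """
    path = Path(path)
    wanted = None if restrict_to is None else set(restrict_to)
    vectors: dict[str, np.ndarray] = {}
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise EmbeddingFormatError(f"{path}: malformed header {header!r}")
        try:
            n_rows, dim = int(header[0]), int(header[1])
        except ValueError as exc:
            raise EmbeddingFormatError(f"{path}: malformed header {header!r}") from exc
        if n_rows < 0 or dim <= 0:
            raise EmbeddingFormatError(f"{path}: malformed header {header!r}")
        for lineno, line in enumerate(fh, start=2):
            tokens = line.rstrip("\n").split()
            if not tokens:
                continue
            word = tokens[0]
            if len(tokens) - 1 != dim:
                raise EmbeddingFormatError(
                    f"{path}:{lineno}: row for {word!r} has {len(tokens) - 1} "
                    f"values, expected {dim}"
                )
            if word in vectors:
                raise EmbeddingFormatError(f"{path}:{lineno}: duplicate word {word!r}")
            if wanted is not None and word not in wanted:
                continue
            try:
                vectors[word] = np.array(tokens[1:], dtype=float)
            except ValueError as exc:
                raise EmbeddingFormatError(
                    f"{path}:{lineno}: non-numeric value in row for {word!r}"
                ) from exc
    missing: tuple[str, ...] = ()
    if wanted is not None:
        missing = tuple(sorted(wanted - set(vectors)))
        if missing:
            logger.info("read_embeddings %s: %d requested concepts missing", path.stem, len(missing))
    return EmbeddingTable(language=path.stem, dim=dim, vectors=vectors, missing=missing)


def write_embeddings(table: EmbeddingTable, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"{len(table.vectors)} {table.dim}\n")
        for word, v in table.vectors.items():
            vals = " ".join(FLOAT_FMT % x for x in v)
            fh.write(f"{word} {vals}\n")


def language_coverage_filter(tables, concepts, max_missing_frac=0.25) -> list[str]:
    """Retain languages whose missing-concept fraction is <= the threshold.

    Mirrors the study-design rule of dropping languages missing more than a
    quarter of the concept inventory; order of the input tables is preserved.
    """
    if not 0.0 <= max_missing_frac <= 1.0:
        raise ValueError("max_missing_frac must be in [0, 1]")
    concepts = list(concepts)
    if not concepts:
        raise ValueError("empty concept list")
    retained = []
    for t in tables:
        frac = sum(c not in t.vectors for c in concepts) / len(concepts)
        if frac <= max_missing_frac:
            retained.append(t.language)
        else:
            logger.info("coverage filter: excluding %s (missing %.1f%%)", t.language, 100 * frac)
    if not retained:
        raise CoverageError("no language passes the coverage filter")
    return retained


# ---------------------------------------------------------------------------
# wordlists / anchors / edge lists / tables
# ---------------------------------------------------------------------------

@dataclass
class WordList:
    """Concept translation rows (concept_id, language, wordform)."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"concept_id", "language", "wordform"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"wordlist needs columns {sorted(required)}")
        dup = self.table.duplicated(subset=["concept_id", "language"])
        if dup.any():
            raise ValueError("duplicate (concept_id, language) rows in wordlist")

    @property
    def concepts(self) -> list[str]:
        return sorted(self.table["concept_id"].unique())

    def available(self, language: str) -> set[str]:
        return set(self.table.loc[self.table["language"] == language, "concept_id"])


def read_wordlist(path) -> WordList:
    return WordList(pd.read_csv(path, sep="\t", dtype=str))


def write_wordlist(wl: WordList, path) -> None:
    wl.table.to_csv(path, sep="\t", index=False)


def read_anchor_spec(path) -> dict[str, list[str]]:
    """TSV with columns (dimension, concept_id) -> dict dimension -> anchors."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"dimension", "concept_id"}.issubset(df.columns):
        raise ValueError("anchor spec needs columns dimension, concept_id")
    spec: dict[str, list[str]] = {}
    for dim, grp in df.groupby("dimension", sort=False):
        spec[dim] = list(grp["concept_id"])
    for dim, anchors in spec.items():
        if not anchors:
            raise ValueError(f"dimension {dim!r} has no anchors")
    return spec


def write_anchor_spec(spec: dict[str, list[str]], path) -> None:
    rows = [(d, c) for d, anchors in spec.items() for c in anchors]
    pd.DataFrame(rows, columns=["dimension", "concept_id"]).to_csv(path, sep="\t", index=False)


def read_edge_list(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if not {"concept_a", "concept_b", "n_languages"}.issubset(df.columns):
        raise ValueError("edge list needs columns concept_a, concept_b, n_languages")
    return df


def write_edge_list(edges: pd.DataFrame, path) -> None:
    edges.to_csv(path, sep="\t", index=False)


def read_table(path, index_col=0) -> pd.DataFrame:
    """Generic labeled CSV table (climate profiles, coordinates, ratings...)."""
    return pd.read_csv(path, index_col=index_col)


def write_table(df: pd.DataFrame, path, index=True) -> None:
    df.to_csv(path, float_format=FLOAT_FMT, index=index)


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Parameters for an end-to-end synthetic pipeline run."""

    out_dir: str
    seed: int = 0
    # synthetic world
    n_families: int = 5
    langs_per_family: int = 6
    n_target_concepts: int = 60
    anchors_per_dim: int = 4
    embed_dim: int = 50
    noise_sd: float = 0.3
    planted_beta_climate: float = 0.5
    # model parameters
    k_neighbors: int = 100
    n_feature_words: int = 100
    n_null_iters: int = 200
    n_random_anchor_words: int = 13
    fdr_level: float = 0.05

    def __post_init__(self) -> None:
        positive = [
            "n_families", "langs_per_family", "n_target_concepts", "anchors_per_dim",
            "embed_dim", "k_neighbors", "n_feature_words", "n_null_iters",
            "n_random_anchor_words",
        ]
        for name in positive:
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if not 0 < self.fdr_level < 1:
            raise ConfigError("fdr_level must be in (0, 1)")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        if not self.out_dir:
            raise ConfigError("out_dir is required")

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path) -> RunConfig:
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    known = {f for f in RunConfig.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"{path}: unknown config keys {sorted(unknown)}")
    if "out_dir" not in raw:
        raise ConfigError(f"{path}: out_dir is required")
    return RunConfig(**raw)
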