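"""Readers, writers, configuration and checkpointing.

All on-disk formats are plain text: 2-column TSV edge lists (an optional third
weight column is ignored with a warning), 3-column TSV genetic-interaction
score tables, and labelled CSV/TSV matrices. Gene identifiers are opaque,
case-sensitive strings; unordered gene pairs are canonicalized as
(min, max) under lexicographic order.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml

logger = logging.getLogger("mvsl")

__all__ = [
    "GeneUniverse",
    "GIScoreTable",
    "RunConfig",
    "canonical_pair",
    "read_edge_list",
    "write_edge_list",
    "read_gi_table",
    "write_gi_table",
    "read_matrix",
    "write_matrix",
    "load_config",
    "save_checkpoint",
    "load_checkpoint",
]


def canonical_pair(a: str, b: str) -> tuple[str, str]:
    """Return the unordered pair (a, b) in canonical (lexicographic) order."""
    if a == b:
        raise ValueError(f"self-pair not allowed: {a!r}")
    return (a, b) if a < b else (b, a)


class GeneUniverse:
    """Ordered set of gene identifiers shared by every view graph.

    Row/column ``i`` of every adjacency matrix and of the node-feature matrix
    refers to ``genes[i]``.
    """

    def __init__(self, genes: Iterable[str]):
        genes = tuple(str(g) for g in genes)
        if len(set(genes)) != len(genes):
            raise ValueError("gene identifiers must be unique")
        if len(genes) < 2:
            raise ValueError("a gene universe needs at least 2 genes")
        self.genes: tuple[str, ...] = genes
        self.index_of: dict[str, int] = {g: i for i, g in enumerate(genes)}

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in self.index_of

    def __eq__(self, other: object) -> bool:
        return isinstance(other, GeneUniverse) and self.genes == other.genes

    def index(self, gene: str) -> int:
        return self.index_of[gene]

    def pair_indices(self, a: str, b: str) -> tuple[int, int]:
        """Indices of an unordered pair, canonicalized as (low, high)."""
        i, j = self.index_of[a], self.index_of[b]
        if i == j:
            raise ValueError(f"self-pair not allowed: {a!r}")
        return (i, j) if i < j else (j, i)

    def content_hash(self) -> str:
        h = hashlib.sha256("\n".join(self.genes).encode()).hexdigest()
        return h[:16]


@dataclass
class GIScoreTable:
    """Genetic-interaction scores for screened unordered gene pairs."""

    records: list[tuple[str, str, float]]

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        for a, b, _ in self.records:
            key = canonical_pair(a, b)
            if key in seen:
                raise ValueError(f"duplicate pair in GI table: {key}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.records)

    def genes(self) -> list[str]:
        """All distinct gene identifiers, in order of first appearance."""
        out: list[str] = []
        seen: set[str] = set()
        for a, b, _ in self.records:
            for g in (a, b):
                if g not in seen:
                    seen.add(g)
                    out.append(g)
        return out


# ----------------------------------------------------------------------------
# configuration


@dataclass
class RunConfig:
    """Training/evaluation configuration.

    Defaults follow the published architecture: two graph-convolution layers
    of 128 and 64 units, a 64/32/16 prediction head, Adam at learning rate
    1e-4, SL threshold -3 on genetic-interaction scores, and a raw p < 0.01
    cutoff for correlation networks.
    """

    sl_threshold: float = -3.0
    corr_alpha: float = 0.01
    gcn_dims: tuple[int, int] = (128, 64)
    head_dims: tuple[int, int, int] = (64, 32, 16)
    learning_rate: float = 0.0001
    max_epochs: int = 200
    patience: int = 20
    split_mode: str = "pair"
    train_fraction: float = 0.8
    cv_folds: int = 5
    precision_at_percent: float = 5.0
    seed: int = 0
    optimizer: str = "adam"
    weight_decay: float = 0.0
    dropout: float = 0.0
    batch_size: int | None = None
    val_fraction: float = 0.1

    def __post_init__(self) -> None:
        self.gcn_dims = tuple(int(d) for d in self.gcn_dims)  # type: ignore[assignment]
        self.head_dims = tuple(int(d) for d in self.head_dims)  # type: ignore[assignment]
        self.validate()

    def validate(self) -> None:
        if len(self.gcn_dims) != 2 or any(d <= 0 for d in self.gcn_dims):
            raise ValueError("gcn_dims must be two positive integers")
        if len(self.head_dims) != 3 or any(d <= 0 for d in self.head_dims):
            raise ValueError("head_dims must be three positive integers")
        if not np.isfinite(self.sl_threshold):
            raise ValueError("sl_threshold must be finite")
        if not 0.0 < self.corr_alpha < 1.0:
            raise ValueError("corr_alpha must lie in (0, 1)")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.max_epochs <= 0:
            raise ValueError("max_epochs must be positive")
        if self.patience <= 0:
            raise ValueError("patience must be positive")
        if self.split_mode not in ("pair", "gene"):
            raise ValueError("split_mode must be 'pair' or 'gene'")
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie in (0, 1)")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be at least 2")
        if not 0.0 < self.precision_at_percent <= 100.0:
            raise ValueError("precision_at_percent must lie in (0, 100]")
        if self.seed < 0:
            raise ValueError("seed must be non-negative")
        if self.optimizer not in ("adam", "sgd"):
            raise ValueError("optimizer must be 'adam' or 'sgd'")
        if self.weight_decay < 0:
            raise ValueError("weight_decay must be non-negative")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")
        if self.batch_size is not None and self.batch_size <= 0:
            raise ValueError("batch_size must be positive when given")
        if not 0.0 < self.val_fraction < 0.5:
            raise ValueError("val_fraction must lie in (0, 0.5)")


def load_config(path: str | Path | None) -> RunConfig:
    """Load a RunConfig from a flat YAML key-value file.

    Absent keys take the defaults above; unknown keys are a hard error
    (fail closed) so typos cannot silently fall back to defaults.
    """
    if path is None:
        return RunConfig()
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError(f"config must be a key-value mapping, got {type(raw).__name__}")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    try:
        return RunConfig(**raw)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"invalid config at {path}: {exc}") from exc


# ----------------------------------------------------------------------------
# edge lists


def read_edge_list(
    path: str | Path,
    universe: GeneUniverse | None = None,
    header: bool = False,
) -> list[tuple[str, str]]:
    """Read a 2-column TSV edge list into deduplicated canonical pairs.

    Self-edges are dropped with a warning. When a universe is given, pairs
    with any gene outside it are dropped (logged). ``header=True`` skips the
    first line; header presence is a flag, never sniffed.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if header:
        lines = lines[1:]
    rows = [(no, ln) for no, ln in enumerate(lines, start=1 + int(header)) if ln.strip()]
    if not rows:
        raise ValueError(f"{path}: empty edge list")

    pairs: list[tuple[str, str]] = []
    seen: set[tuple[str, str]] = set()
    extra_cols = 0
    self_edges = 0
    outside = 0
    for line_no, line in rows:
        fields = line.rstrip("\r\n").split("\t")
        if len(fields) < 2 or not fields[0] or not fields[1]:
            raise ValueError(f"{path}:{line_no}: malformed edge line: {line!r}")
        if len(fields) > 2:
            extra_cols += 1
        a, b = fields[0], fields[1]
        if a == b:
            self_edges += 1
            continue
        if universe is not None and (a not in universe or b not in universe):
            outside += 1
            continue
        key = canonical_pair(a, b)
        if key not in seen:
            seen.add(key)
            pairs.append(key)
    if extra_cols:
        logger.warning("%s: ignored extra columns on %d lines", path, extra_cols)
    if self_edges:
        logger.warning("%s: dropped %d self-edges", path, self_edges)
    if outside:
        logger.info("%s: dropped %d edges outside the gene universe", path, outside)
    return pairs


def write_edge_list(path: str | Path, pairs: Iterable[tuple[str, str]]) -> None:
    """Write canonical unordered pairs as a sorted 2-column TSV."""
    canon = sorted({canonical_pair(a, b) for a, b in pairs})
    with open(path, "w") as fh:
        for a, b in canon:
            fh.write(f"{a}\t{b}\n")


# ----------------------------------------------------------------------------
# GI score tables


def read_gi_table(path: str | Path, header: bool = False) -> GIScoreTable:
    """Read a 3-column TSV of (gene_a, gene_b, gi_score).

    Records with a non-finite score are rejected with a warning.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if header:
        lines = lines[1:]
    records: list[tuple[str, str, float]] = []
    bad = 0
    for line_no, line in enumerate(lines, start=1 + int(header)):
        if not line.strip():
            continue
        fields = line.rstrip("\r\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}:{line_no}: expected 3 columns, got {len(fields)}")
        try:
            score = float(fields[2])
        except ValueError as exc:
            raise ValueError(f"{path}:{line_no}: non-numeric score {fields[2]!r}") from exc
        if not np.isfinite(score):
            bad += 1
            continue
        records.append((fields[0], fields[1], score))
    if bad:
        logger.warning("%s: rejected %d records with non-finite scores", path, bad)
    if not records:
        raise ValueError(f"{path}: empty GI score table")
    return GIScoreTable(records)


def write_gi_table(path: str | Path, table: GIScoreTable) -> None:
    with open(path, "w") as fh:
        for a, b, s in table.records:
            fh.write(f"{a}\t{b}\t{s:.6g}\n")


# ----------------------------------------------------------------------------
# labelled matrices


def read_matrix(path: str | Path) -> tuple[list[str], list[str], np.ndarray, np.ndarray]:
    """Read a labelled CSV/TSV matrix.

    Returns (row_ids, col_ids, values, missing_mask). Delimiter is chosen by
    extension (.csv comma, otherwise tab). Missing cells (empty or NA) are
    NaN in ``values`` and True in ``missing_mask``.
    """
    import pandas as pd

    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    try:
        df = pd.read_csv(path, sep=sep, index_col=0)
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: malformed matrix: {exc}") from exc
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate row labels {dupes}")
    try:
        values = df.astype(float).to_numpy()
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric matrix cell: {exc}") from exc
    mask = ~np.isfinite(values)
    values = values.copy()
    values[mask] = np.nan
    return (list(map(str, df.index)), list(map(str, df.columns)), values, mask)


def write_matrix(
    path: str | Path,
    row_ids: Sequence[str],
    col_ids: Sequence[str],
    values: np.ndarray,
) -> None:
    import pandas as pd

    sep = "," if Path(path).suffix.lower() == ".csv" else "\t"
    pd.DataFrame(values, index=list(row_ids), columns=list(col_ids)).to_csv(path, sep=sep)


# ----------------------------------------------------------------------------
# checkpoints


def save_checkpoint(out_dir: str | Path, state, config: RunConfig,
                    universe: GeneUniverse, history: dict | None = None) -> None:
    """Write model weights (npz blob) plus a sidecar JSON with config,
    universe hash, seed and metric history."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    arrays = state.to_arrays()
    np.savez(out_dir / "weights.npz", **arrays)
    meta = {
        "config": dataclasses.asdict(config),
        "universe_hash": universe.content_hash(),
        "n_genes": len(universe),
        "seed": int(state.rng_seed),
        "history": history or {},
    }
    (out_dir / "checkpoint.json").write_text(json.dumps(meta, indent=2))


def load_checkpoint(out_dir: str | Path):
    """Load (ModelState, meta dict) written by :func:`save_checkpoint`."""
    from .model import ModelState

    out_dir = Path(out_dir)
    meta = json.loads((out_dir / "checkpoint.json").read_text())
    with np.load(out_dir / "weights.npz") as blob:
        arrays = {k: blob[k] for k in blob.files}
    state = ModelState.from_arrays(arrays, rng_seed=meta["seed"])
    return state, meta
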