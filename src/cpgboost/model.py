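"""Feature-matrix assembly and the gradient-boosted classifier.

One model is trained per target cell on the concatenated feature blocks
(84 sequence + 175 structural + 4m + 8(m-1) positional = 259 + 4m + 8(m-1)
columns for an m-cell dataset).  Training delegates to LightGBM, whose
gradient-based one-side sampling (GOSS) and exclusive feature bundling (EFB)
are enabled per its own defaults; `goss_select`, `efb_conflict`,
`efb_bundle` and `merge_bundles` below are standalone reference
implementations of those two strategies, tested against post-hoc oracles
but deliberately not wired into the delegated trainer.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .profiles import MultiCellDataset, STATE_UNKNOWN
from .positional import (
    positional_matrix,
    positional_feature_names,
    positional_feature_origins,
)
from .sequence import GenomeSequence, extract_window, ngram_matrix, sequence_feature_names
from .structural import TrackSet, structural_matrix

FEATURE_BLOCKS = ("seq", "str", "pos")


@dataclass
class FeatureMatrix:
    """Named feature columns keyed by (cell_id, chrom, pos), with labels.

    ``X`` is a DataFrame with a (cell_id, chrom, pos) MultiIndex; ``y`` is
    the aligned 0/1 label Series; ``blocks`` maps each column name to its
    feature family (seq/str/pos).
    """

    X: pd.DataFrame
    y: pd.Series
    blocks: dict = field(default_factory=dict)
    origins: dict = field(default_factory=dict)  # column -> cell of origin

    def __post_init__(self) -> None:
        if len(self.X) != len(self.y):
            raise ValueError("X and y length mismatch")
        if self.X.columns.duplicated().any():
            raise ValueError("duplicate feature columns")

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def select_blocks(self, blocks: Iterable[str]) -> "FeatureMatrix":
        keep = set(blocks)
        cols = [c for c in self.X.columns if self.blocks.get(c) in keep]
        return self.select_columns(cols)

    def select_columns(self, columns: Sequence[str]) -> "FeatureMatrix":
        cols = list(columns)
        return FeatureMatrix(
            self.X[cols], self.y,
            {c: self.blocks.get(c, "?") for c in cols},
            {c: self.origins[c] for c in cols if c in self.origins},
        )

    def to_tsv(self, path, manifest_path=None) -> None:
        out = self.X.copy()
        out.insert(0, "label", self.y.to_numpy())
        out.to_csv(path, sep="\t")
        if manifest_path is not None:
            manifest = pd.DataFrame(
                {"column": list(self.X.columns),
                 "block": [self.blocks.get(c, "?") for c in self.X.columns],
                 "origin": [self.origins.get(c, "") for c in self.X.columns]}
            )
            manifest.to_csv(manifest_path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, manifest_path=None) -> "FeatureMatrix":
        df = pd.read_csv(path, sep="\t", index_col=[0, 1, 2])
        y = df.pop("label")
        blocks, origins = {}, {}
        if manifest_path is not None:
            man = pd.read_csv(manifest_path, sep="\t").fillna({"origin": ""})
            blocks = dict(zip(man["column"], man["block"]))
            origins = {c: o for c, o in zip(man["column"], man.get("origin", []))
                       if isinstance(o, str) and o}
        return cls(df, y, blocks, origins)


def expected_n_features(m: int, blocks: Iterable[str] = FEATURE_BLOCKS) -> int:
    n = 0
    blocks = set(blocks)
    if "seq" in blocks:
        n += 84
    if "str" in blocks:
        n += 175
    if "pos" in blocks:
        n += 4 * m + 8 * (m - 1)
    return n


def build_matrix(
    dataset: MultiCellDataset,
    genome: GenomeSequence | None,
    tracks: TrackSet | None,
    cell_id: str,
    chroms: Sequence[str],
    blocks: Iterable[str] = FEATURE_BLOCKS,
    flank: int = 50,
    dedupe_absent_gap: bool = False,
) -> FeatureMatrix:
    """Assemble the feature matrix for the labeled sites of one target cell.

    One row per labeled site of ``cell_id`` on ``chroms``; columns are the
    requested blocks in seq, str, pos order; labels come from the profile's
    binarized states.
    """
    blocks = [b for b in FEATURE_BLOCKS if b in set(blocks)]
    if not blocks:
        raise ValueError("at least one feature block required")
    if "seq" in blocks and genome is None:
        raise ValueError("sequence block requested without a genome")
    if "str" in blocks and tracks is None:
        raise ValueError("structural block requested without tracks")
    profile = dataset.cell(cell_id)
    chroms = [c for c in chroms if c in profile.chroms]
    parts, index_rows, labels = [], [], []
    for chrom in chroms:
        pos_arr, state_arr = profile.labeled(chrom)
        if len(pos_arr) == 0:
            continue
        chunk = []
        if "seq" in blocks:
            windows = [extract_window(genome, chrom, int(p), flank) for p in pos_arr]
            chunk.append(ngram_matrix(windows))
        if "str" in blocks:
            chunk.append(structural_matrix(chrom, pos_arr, tracks))
        if "pos" in blocks:
            chunk.append(positional_matrix(dataset, cell_id, chrom, pos_arr,
                                           dedupe_absent_gap))
        parts.append(np.hstack(chunk))
        index_rows += [(cell_id, chrom, int(p)) for p in pos_arr]
        labels.append(state_arr)
    if not parts:
        raise ValueError(f"no labeled sites for cell {cell_id!r} on {list(chroms)}")
    names: list[str] = []
    block_of: dict[str, str] = {}
    origin_of: dict[str, str] = {}
    if "seq" in blocks:
        seq_names = sequence_feature_names()
        names += seq_names
        block_of.update({c: "seq" for c in seq_names})
    if "str" in blocks:
        str_names = tracks.feature_names()
        names += str_names
        block_of.update({c: "str" for c in str_names})
    if "pos" in blocks:
        pos_names = positional_feature_names(dataset.m)
        origins = positional_feature_origins(dataset, cell_id)
        names += pos_names
        block_of.update({c: "pos" for c in pos_names})
        origin_of.update(dict(zip(pos_names, origins)))
    index = pd.MultiIndex.from_tuples(index_rows, names=["cell_id", "chrom", "pos"])
    X = pd.DataFrame(np.vstack(parts), index=index, columns=names)
    y = pd.Series(np.concatenate(labels).astype(np.int8), index=index, name="label")
    return FeatureMatrix(X, y, block_of, origin_of)


# ---------------------------------------------------------------------------
# GOSS reference implementation


@dataclass(frozen=True)
class GossConfig:
    """Gradient-based one-side sampling: keep the top ``a_frac`` of samples
    by |gradient| plus a random ``b_frac`` (of the total) from the rest,
    up-weighted by (1-a)/b to keep the gradient sum unbiased."""

    a_frac: float = 0.2
    b_frac: float = 0.1
    amplify: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.a_frac <= 1.0 and 0.0 <= self.b_frac <= 1.0):
            raise ValueError("fractions must be in [0, 1]")
        if self.a_frac + self.b_frac > 1.0 + 1e-12:
            raise ValueError("a_frac + b_frac must be <= 1")


def goss_select(gradients: np.ndarray, cfg: GossConfig) -> tuple[np.ndarray, np.ndarray]:
    """(kept indices, per-sample weights) of one GOSS round.

    Top ceil(a*n) samples by |gradient| are kept with weight 1; ceil(b*n)
    are drawn uniformly from the remainder (weight (1-a)/b when amplify).
    """
    g = np.abs(np.asarray(gradients, dtype=np.float64))
    n = len(g)
    if n == 0:
        return np.array([], dtype=np.int64), np.array([])
    n_top = min(n, math.ceil(cfg.a_frac * n)) if cfg.a_frac > 0 else 0
    order = np.argsort(-g, kind="stable")
    top = order[:n_top]
    rest = order[n_top:]
    n_sample = min(len(rest), math.ceil(cfg.b_frac * n)) if cfg.b_frac > 0 else 0
    rng = np.random.default_rng(cfg.seed)
    sampled = rng.choice(rest, size=n_sample, replace=False) if n_sample else np.array([], dtype=np.int64)
    indices = np.concatenate([top, sampled]).astype(np.int64)
    weights = np.ones(len(indices))
    if cfg.amplify and cfg.b_frac > 0 and n_sample:
        weights[n_top:] = (1.0 - cfg.a_frac) / cfg.b_frac
    return indices, weights


# ---------------------------------------------------------------------------
# EFB reference implementation


@dataclass(frozen=True)
class BundlePlan:
    """Partition of the feature columns into exclusive bundles.

    ``sets`` lists column indices; every within-set pair respected the
    maximum conflict ``d`` when the plan was built.
    """

    sets: tuple[tuple[int, ...], ...]
    d: float


def efb_conflict(col_i: np.ndarray, col_j: np.ndarray) -> float:
    """Conflict weight of two feature columns: the fraction of rows where
    both are nonzero."""
    a = np.asarray(col_i)
    b = np.asarray(col_j)
    if a.shape != b.shape:
        raise ValueError("columns must have equal length")
    L = len(a)
    if L == 0:
        raise ValueError("empty columns")
    return float(np.count_nonzero((a != 0) & (b != 0)) / L)


def efb_bundle(columns: np.ndarray, d: float = 0.05) -> BundlePlan:
    """Greedily bundle nearly-exclusive sparse columns.

    Builds the conflict graph (edge weight = co-nonzero fraction), visits
    features in descending weighted-degree order (ties by column index) and
    assigns each to the first existing bundle whose total added conflict
    stays within ``d``, else opens a new bundle.
    """
    if d < 0:
        raise ValueError("d must be >= 0")
    X = np.asarray(columns)
    if X.ndim != 2:
        raise ValueError("expected a 2-D column matrix")
    n_feat = X.shape[1]
    nz = X != 0
    L = X.shape[0]
    # pairwise co-nonzero fractions
    w = (nz.astype(np.float64).T @ nz.astype(np.float64)) / max(L, 1)
    np.fill_diagonal(w, 0.0)
    degree = w.sum(axis=1)
    order = sorted(range(n_feat), key=lambda i: (-degree[i], i))
    sets: list[list[int]] = []
    for i in order:
        placed = False
        for s in sets:
            added = sum(w[i, j] for j in s)
            if added <= d:
                s.append(i)
                placed = True
                break
        if not placed:
            sets.append([i])
    return BundlePlan(sets=tuple(tuple(sorted(s)) for s in sets), d=d)


@dataclass(frozen=True)
class MergeResult:
    """Merged matrix plus the per-set value-range offsets needed to invert."""

    matrix: np.ndarray            # (n_rows, n_sets)
    plan: BundlePlan
    offsets: tuple[tuple[float, ...], ...]   # per set, offset of each member
    ranges: tuple[tuple[float, ...], ...]    # per set, max value of each member


def merge_bundles(columns: np.ndarray, plan: BundlePlan) -> MergeResult:
    """Collapse each bundle into one composite column via range offsets.

    Member values are shifted so their nonzero ranges are disjoint (the
    histogram-offset construction); zero stays the shared zero bin.  On the
    rare conflict row (several members nonzero) the member latest in the set
    wins.  Members must be non-negative and finite.
    """
    X = np.asarray(columns, dtype=np.float64)
    n_rows = X.shape[0]
    merged = np.zeros((n_rows, len(plan.sets)))
    offsets, ranges = [], []
    for si, members in enumerate(plan.sets):
        cum = 0.0
        offs, rngs = [], []
        col = np.zeros(n_rows)
        for f in members:
            v = X[:, f]
            if not np.isfinite(v).all() or (v < 0).any():
                raise ValueError("bundled columns must be finite and non-negative")
            vmax = float(v.max()) if n_rows else 0.0
            offs.append(cum)
            rngs.append(vmax)
            nz = v != 0
            col[nz] = v[nz] + cum
            cum += vmax
            if not np.isfinite(cum):
                raise ValueError("offset range overflow")
        merged[:, si] = col
        offsets.append(tuple(offs))
        ranges.append(tuple(rngs))
    return MergeResult(matrix=merged, plan=plan,
                       offsets=tuple(offsets), ranges=tuple(ranges))


def unmerge_bundles(result: MergeResult, n_features: int) -> np.ndarray:
    """Reconstruct the original columns from a merge (exact when no bundle
    had conflicting rows)."""
    n_rows = result.matrix.shape[0]
    X = np.zeros((n_rows, n_features))
    for si, members in enumerate(result.plan.sets):
        col = result.matrix[:, si]
        for f, off, rng in zip(members[::-1], result.offsets[si][::-1],
                               result.ranges[si][::-1]):
            hit = (col > off) & (col <= off + rng) & (col != 0)
            X[hit, f] = col[hit] - off
    return X


# ---------------------------------------------------------------------------
# Trainer (delegated boosting)


@dataclass
class ModelConfig:
    """LightGBM hyperparameters used throughout: 110 trees of depth <= 5
    with 22 leaves, learning rate 0.04."""

    n_trees: int = 110
    max_depth: int = 5
    num_leaves: int = 22
    learning_rate: float = 0.04
    threads: int = 8
    seed: int = 0
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if min(self.n_trees, self.max_depth, self.num_leaves, self.threads) < 1:
            raise ValueError("n_trees, max_depth, num_leaves, threads must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.num_leaves > 2 ** self.max_depth:
            raise ValueError("num_leaves must be <= 2**max_depth")


@dataclass
class TrainedModel:
    """Fitted booster plus the column manifest it was trained on."""

    booster: object
    feature_names: list[str]
    config: ModelConfig

    @property
    def split_counts(self) -> pd.Series:
        """Per-feature split participation counts (importance scores)."""
        imp = self.booster.feature_importance(importance_type="split")
        return pd.Series(imp, index=self.feature_names, name="split_count")

    def save(self, model_path, manifest_path) -> None:
        with open(model_path, "w") as fh:
            fh.write(self.booster.model_to_string())
        with open(manifest_path, "w") as fh:
            json.dump({"feature_names": self.feature_names,
                       "config": asdict(self.config)}, fh, indent=1)

    @classmethod
    def load(cls, model_path, manifest_path) -> "TrainedModel":
        import lightgbm as lgb

        with open(manifest_path) as fh:
            meta = json.load(fh)
        booster = lgb.Booster(model_file=str(model_path))
        cfg = ModelConfig(**{k: v for k, v in meta["config"].items()})
        return cls(booster=booster, feature_names=meta["feature_names"], config=cfg)


def _lgb_params(cfg: ModelConfig) -> dict:
    params = {
        "objective": "binary",
        "num_iterations": cfg.n_trees,
        "max_depth": cfg.max_depth,
        "num_leaves": cfg.num_leaves,
        "learning_rate": cfg.learning_rate,
        "num_threads": cfg.threads,
        "seed": cfg.seed,
        "deterministic": True,
        "force_row_wise": True,
        "verbosity": -1,
    }
    params.update(cfg.extra)
    return params


def train(matrix: FeatureMatrix, cfg: ModelConfig | None = None) -> TrainedModel:
    """Fit the binary booster on a feature matrix.

    Requires both classes present.  Reproducible for a fixed (seed,
    threads=1) configuration.
    """
    import lightgbm as lgb

    if cfg is None:
        cfg = ModelConfig()
    y = matrix.y.to_numpy()
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError(f"training labels contain a single class ({classes})")
    names = list(matrix.X.columns)
    data = lgb.Dataset(matrix.X.to_numpy(np.float64), label=y,
                       feature_name=[f"f{i}" for i in range(len(names))],
                       params={"verbosity": -1})
    booster = lgb.train(_lgb_params(cfg), data)
    return TrainedModel(booster=booster, feature_names=names, config=cfg)


def predict(model: TrainedModel, matrix: FeatureMatrix | pd.DataFrame) -> np.ndarray:
    """Methylation probabilities; columns are aligned to the training
    manifest by name, so column order is irrelevant."""
    X = matrix.X if isinstance(matrix, FeatureMatrix) else matrix
    missing = [c for c in model.feature_names if c not in X.columns]
    if missing:
        raise ValueError(f"prediction input lacks training columns {missing[:5]}...")
    aligned = X[model.feature_names].to_numpy(np.float64)
    return model.booster.predict(aligned)


def predict_states(model: TrainedModel, matrix, threshold: float = 0.5) -> np.ndarray:
    return (predict(model, matrix) >= threshold).astype(np.int8)


def aggregate_importance(models: Sequence[TrainedModel]) -> pd.Series:
    """Element-wise sum of per-cell split counts over identically-manifested
    models, sorted descending (ties stable by feature name)."""
    if not models:
        raise ValueError("no models to aggregate")
    names = models[0].feature_names
    for m in models[1:]:
        if m.feature_names != names:
            raise ValueError("models have different feature manifests")
    total = sum(m.split_counts for m in models)
    df = total.rename("importance").reset_index().rename(columns={"index": "feature"})
    df = df.sort_values(["importance", "feature"],
                        ascending=[False, True], kind="mergesort")
    return pd.Series(df["importance"].to_numpy(), index=df["feature"], name="importance")
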