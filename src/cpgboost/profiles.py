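"""Sparse per-cell CpG methylation profiles.

Single-cell bisulfite protocols (scBS-seq, scRRBS) observe only 1-40% of the
CpG sites of each cell, each with a handful of reads.  This module holds the
container types for such profiles and the bookkeeping operations around them:
reading/writing the TSV dialects, majority-vote binarization with a minimum
coverage filter, chromosome-holdout splitting, and the cross-cell overlap
summary (how many positions are observed, and observed consistently, in more
than one cell).

Coordinates are 1-based positions of the C in the CpG dinucleotide, forward
strand, assumed pre-collapsed across strands.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: state value for sites whose methylation status is unknown / excluded
STATE_UNKNOWN = -1

_PROFILE_COLUMNS = ["chrom", "pos", "meth_reads", "total_reads", "state"]


class ParseError(ValueError):
    """Malformed profile/track input; message carries the offending line."""


@dataclass(frozen=True)
class CpGRecord:
    """One observed CpG site in one cell.

    ``state`` is 0 (unmethylated), 1 (methylated) or ``STATE_UNKNOWN``.
    """

    chrom: str
    pos: int
    meth_reads: int = 0
    total_reads: int = 0
    state: int = STATE_UNKNOWN

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.meth_reads < 0 or self.total_reads < 0:
            raise ValueError("read counts must be non-negative")
        if self.meth_reads > self.total_reads:
            raise ValueError(
                f"meth_reads {self.meth_reads} > total_reads {self.total_reads} "
                f"at {self.chrom}:{self.pos}"
            )
        if self.state not in (0, 1, STATE_UNKNOWN):
            raise ValueError(f"state must be 0, 1 or {STATE_UNKNOWN}")


def binarize(meth_reads: int, total_reads: int, min_cov: int = 4) -> int:
    """Majority-vote binary state of one site, or ``STATE_UNKNOWN``.

    A site is usable only when covered by at least ``min_cov`` reads; the
    state is 1 when more than half the reads are methylated, 0 when fewer
    than half are.  Exact ties carry no majority and are excluded.
    """
    if meth_reads < 0 or total_reads < 0:
        raise ValueError("read counts must be non-negative")
    if meth_reads > total_reads:
        raise ValueError("meth_reads exceeds total_reads")
    if total_reads < min_cov:
        return STATE_UNKNOWN
    if 2 * meth_reads == total_reads:
        return STATE_UNKNOWN
    return 1 if 2 * meth_reads > total_reads else 0


def binarize_array(
    meth_reads: np.ndarray, total_reads: np.ndarray, min_cov: int = 4
) -> np.ndarray:
    """Vectorized :func:`binarize`."""
    meth = np.asarray(meth_reads, dtype=np.int64)
    total = np.asarray(total_reads, dtype=np.int64)
    if (meth < 0).any() or (total < 0).any():
        raise ValueError("read counts must be non-negative")
    if (meth > total).any():
        raise ValueError("meth_reads exceeds total_reads")
    state = np.full(meth.shape, STATE_UNKNOWN, dtype=np.int8)
    covered = total >= min_cov
    state[covered & (2 * meth > total)] = 1
    state[covered & (2 * meth < total)] = 0
    return state


@dataclass
class CellProfile:
    """All observed CpG sites of one cell, sorted per chromosome.

    ``sites`` has columns chrom, pos, meth_reads, total_reads, state and is
    sorted by (chrom, pos) with no duplicate positions within a chromosome.
    """

    cell_id: str
    sites: pd.DataFrame
    _labeled_cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        df = self.sites
        missing = [c for c in _PROFILE_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"profile table missing columns {missing}")
        df = df[_PROFILE_COLUMNS].copy()
        df["pos"] = df["pos"].astype(np.int64)
        df["meth_reads"] = df["meth_reads"].astype(np.int64)
        df["total_reads"] = df["total_reads"].astype(np.int64)
        df["state"] = df["state"].astype(np.int8)
        df = df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
        dup = df.duplicated(subset=["chrom", "pos"])
        if dup.any():
            first = df.loc[dup.idxmax()]
            raise ValueError(
                f"duplicate position {first.chrom}:{first.pos} in cell {self.cell_id}"
            )
        if (df["pos"] < 1).any():
            raise ValueError("positions must be >= 1")
        if (df["meth_reads"] > df["total_reads"]).any():
            raise ValueError("meth_reads exceeds total_reads")
        if not df["state"].isin([0, 1, STATE_UNKNOWN]).all():
            raise ValueError("states must be 0, 1 or unknown")
        self.sites = df

    @property
    def chroms(self) -> list[str]:
        return sorted(self.sites["chrom"].unique())

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def labeled(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        """(positions, states) of sites with a known state on ``chrom``.

        Positions are strictly increasing; this is the set the neighbor
        features are computed from.
        """
        cached = self._labeled_cache.get(chrom)
        if cached is None:
            sub = self.sites[
                (self.sites["chrom"] == chrom) & (self.sites["state"] != STATE_UNKNOWN)
            ]
            cached = (
                sub["pos"].to_numpy(np.int64),
                sub["state"].to_numpy(np.int8),
            )
            self._labeled_cache[chrom] = cached
        return cached

    def subset_chroms(self, chroms: Iterable[str]) -> "CellProfile":
        keep = set(chroms)
        return CellProfile(self.cell_id, self.sites[self.sites["chrom"].isin(keep)])


@dataclass
class MultiCellDataset:
    """m >= 1 cell profiles sharing a chromosome naming convention."""

    cells: list[CellProfile]

    def __post_init__(self) -> None:
        if len(self.cells) < 1:
            raise ValueError("dataset needs at least one cell")
        ids = [c.cell_id for c in self.cells]
        if len(set(ids)) != len(ids):
            raise ValueError("cell ids must be unique")

    @property
    def m(self) -> int:
        return len(self.cells)

    @property
    def cell_ids(self) -> list[str]:
        return [c.cell_id for c in self.cells]

    @property
    def chroms(self) -> list[str]:
        out: set[str] = set()
        for c in self.cells:
            out.update(c.chroms)
        return sorted(out)

    def cell(self, cell_id: str) -> CellProfile:
        for c in self.cells:
            if c.cell_id == cell_id:
                return c
        raise KeyError(f"no cell {cell_id!r} in dataset")

    def subset_chroms(self, chroms: Iterable[str]) -> "MultiCellDataset":
        chroms = list(chroms)
        return MultiCellDataset([c.subset_chroms(chroms) for c in self.cells])


# ---------------------------------------------------------------------------
# I/O


def _open_text(path, mode: str = "rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_profile(
    path,
    dialect: str = "counts",
    cell_id: str | None = None,
    min_cov: int = 4,
) -> CellProfile:
    """Read one cell's profile TSV.

    ``counts`` dialect: chrom, pos, meth_reads, total_reads (state derived by
    :func:`binarize` with ``min_cov``).  ``states`` dialect: chrom, pos, state.
    Lines starting with ``#`` are ignored; rows may arrive unsorted (they are
    sorted, never dropped); duplicate positions raise.
    """
    if dialect not in ("counts", "states"):
        raise ValueError(f"unknown dialect {dialect!r}")
    rows = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            try:
                if dialect == "counts":
                    if len(parts) < 4:
                        raise ValueError("expected 4 columns")
                    chrom, pos, meth, total = parts[0], int(parts[1]), int(parts[2]), int(parts[3])
                    state = binarize(meth, total, min_cov=min_cov)
                else:
                    if len(parts) < 3:
                        raise ValueError("expected 3 columns")
                    chrom, pos = parts[0], int(parts[1])
                    state = int(parts[2])
                    if state not in (0, 1, STATE_UNKNOWN):
                        raise ValueError(f"bad state {state}")
                    meth, total = 0, 0
                if pos < 1:
                    raise ValueError(f"bad position {pos}")
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
            rows.append((chrom, pos, meth, total, state))
    if cell_id is None:
        name = str(path)
        for suffix in (".gz", ".tsv", ".txt", ".bed"):
            if name.endswith(suffix):
                name = name[: -len(suffix)]
        cell_id = name.rsplit("/", 1)[-1]
    df = pd.DataFrame(rows, columns=_PROFILE_COLUMNS)
    try:
        return CellProfile(cell_id, df)
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_profile(profile: CellProfile, path, dialect: str = "counts") -> None:
    """Write a profile TSV; inverse of :func:`read_profile`."""
    if dialect not in ("counts", "states"):
        raise ValueError(f"unknown dialect {dialect!r}")
    with _open_text(path, "wt") as fh:
        for row in profile.sites.itertuples(index=False):
            if dialect == "counts":
                fh.write(f"{row.chrom}\t{row.pos}\t{row.meth_reads}\t{row.total_reads}\n")
            else:
                fh.write(f"{row.chrom}\t{row.pos}\t{row.state}\n")


# ---------------------------------------------------------------------------
# Chromosome-holdout split


@dataclass(frozen=True)
class SplitSpec:
    """Disjoint chromosome-name lists for train / test / validation."""

    train_chroms: tuple[str, ...]
    test_chroms: tuple[str, ...] = ()
    val_chroms: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        groups = [set(self.train_chroms), set(self.test_chroms), set(self.val_chroms)]
        for a in range(3):
            for b in range(a + 1, 3):
                overlap = groups[a] & groups[b]
                if overlap:
                    raise ValueError(f"split lists overlap on {sorted(overlap)}")


def default_split(prefix: str = "chr") -> SplitSpec:
    """The autosome holdout used throughout: odd chromosomes 1-11 train,
    even 2-12 test, 13-19 validation."""
    return SplitSpec(
        train_chroms=tuple(f"{prefix}{i}" for i in (1, 3, 5, 7, 9, 11)),
        test_chroms=tuple(f"{prefix}{i}" for i in (2, 4, 6, 8, 10, 12)),
        val_chroms=tuple(f"{prefix}{i}" for i in range(13, 20)),
    )


def split_dataset(
    dataset: MultiCellDataset, spec: SplitSpec
) -> tuple[MultiCellDataset, MultiCellDataset, MultiCellDataset]:
    """Partition every cell's sites by chromosome into (train, test, val).

    Sites on chromosomes in none of the three lists are dropped; the dropped
    count is logged, never silently swallowed.
    """
    listed = set(spec.train_chroms) | set(spec.test_chroms) | set(spec.val_chroms)
    dropped = sum(
        int((~c.sites["chrom"].isin(listed)).sum()) for c in dataset.cells
    )
    if dropped:
        logger.info("split_dataset: dropped %d sites on unlisted chromosomes", dropped)
    return (
        dataset.subset_chroms(spec.train_chroms),
        dataset.subset_chroms(spec.test_chroms),
        dataset.subset_chroms(spec.val_chroms),
    )


# ---------------------------------------------------------------------------
# Cross-cell overlap summary


@dataclass(frozen=True)
class OverlapStats:
    """Cross-cell position/state sharing summary.

    N counts distinct positions with a known state in at least one cell;
    N1/N2/N3 count positions shared in >=2 cells, sharing a state in >=2
    cells, and satisfying the all-cells concordance predicate.
    Pk = 100 * Nk / N.
    """

    N: int
    N1: int
    N2: int
    N3: int

    @property
    def P1(self) -> float:
        return 100.0 * self.N1 / self.N

    @property
    def P2(self) -> float:
        return 100.0 * self.N2 / self.N

    @property
    def P3(self) -> float:
        return 100.0 * self.N3 / self.N


def _default_n3_predicate(n_known: int, m: int, states: np.ndarray) -> bool:
    # concordant across the whole dataset: known in every cell, one state
    return n_known == m and len(np.unique(states)) == 1


def overlap_stats(
    dataset: MultiCellDataset,
    chroms: Sequence[str] | None = None,
    n3_predicate: Callable[[int, int, np.ndarray], bool] | None = None,
) -> OverlapStats:
    """Tabulate how often positions recur (and agree) across cells.

    ``n3_predicate(n_known, m, states)`` classifies a position for the N3
    count; the default requires the position known in all m cells with one
    common state.
    """
    if n3_predicate is None:
        n3_predicate = _default_n3_predicate
    m = dataset.m
    frames = []
    for c in dataset.cells:
        sub = c.sites[c.sites["state"] != STATE_UNKNOWN]
        if chroms is not None:
            sub = sub[sub["chrom"].isin(set(chroms))]
        frames.append(sub[["chrom", "pos", "state"]])
    known = pd.concat(frames, ignore_index=True)
    if known.empty:
        raise ValueError("no known sites in dataset (empty or fully filtered)")
    grouped = known.groupby(["chrom", "pos"], sort=False)["state"]
    N = grouped.ngroups
    N1 = N2 = N3 = 0
    for _, states in grouped:
        s = states.to_numpy()
        k = len(s)
        if k >= 2:
            N1 += 1
            if (s == 1).sum() >= 2 or (s == 0).sum() >= 2:
                N2 += 1
        if n3_predicate(k, m, s):
            N3 += 1
    return OverlapStats(N=N, N1=N1, N2=N2, N3=N3)
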