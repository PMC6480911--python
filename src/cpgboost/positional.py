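"""Cross-cell positional features.

The central idea: the methylation state of a CpG site is strongly correlated
with the states of its nearest observed neighbors — in the same cell and,
because methylation landscapes are partly shared, in the other cells of the
dataset.  For a target site (cell i, position p) two feature families are
extracted from every cell j's labeled sites G_j:

* the flanking block F(i,j): signed distances and states of the labeled
  sites immediately left and right of p in cell j (4 values).  When p itself
  is labeled in cell j the flanks are its rank-1 neighbors there, so the
  target's own label never enters its feature vector when j = i.
* the gap block D(i,j), j != i only: the four consecutive inter-site gaps
  and three states surrounding p in cell j (8 values).  For j = i this block
  would contain the target's own state, so it is forbidden.

Concatenated over cells this yields 4m + 8(m-1) features.  Missing neighbors
(chromosome boundaries, empty cells) are NaN — gradient-boosted trees route
missingness natively, and sentinel values would distort splits.  Distances
are raw signed base pairs (left negative).

The skip-k generalization used for the distance-decay analyses takes the
k-th nearest neighbor instead of the first (``rank_pair``), or all ranks
1..k on each side (``window``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .profiles import CellProfile, MultiCellDataset

MISSING = np.nan


@dataclass(frozen=True)
class NeighborPair:
    """k-th nearest labeled site on each side of a query position.

    Each side is a (pos, state) tuple or None when fewer than k labeled
    sites exist on that side.
    """

    left: tuple[int, int] | None
    right: tuple[int, int] | None


def neighbors(profile: CellProfile, chrom: str, pos: int, k: int = 1) -> NeighborPair:
    """The k-th labeled site strictly left / strictly right of ``pos``.

    A labeled site exactly at ``pos`` is never its own neighbor.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    pos_arr, state_arr = profile.labeled(chrom)
    first_ge = np.searchsorted(pos_arr, pos, side="left")
    first_gt = np.searchsorted(pos_arr, pos, side="right")
    li = first_ge - k
    ri = first_gt + (k - 1)
    left = (int(pos_arr[li]), int(state_arr[li])) if li >= 0 else None
    right = (int(pos_arr[ri]), int(state_arr[ri])) if ri < len(pos_arr) else None
    return NeighborPair(left=left, right=right)


def _at(pos_arr, state_arr, idx, query):
    """(signed distance, state) of site ``idx`` relative to ``query``; NaN out of range."""
    if 0 <= idx < len(pos_arr):
        return float(pos_arr[idx] - query), float(state_arr[idx])
    return MISSING, MISSING


def _gap(pos_arr, i, j):
    """pos[j] - pos[i]; NaN when either index is out of range."""
    if 0 <= i < len(pos_arr) and 0 <= j < len(pos_arr):
        return float(pos_arr[j] - pos_arr[i])
    return MISSING


def _locate(pos_arr: np.ndarray, pos: int) -> tuple[int, bool]:
    """(index of pos if present else index of left flank, present?)."""
    idx = int(np.searchsorted(pos_arr, pos, side="left"))
    present = idx < len(pos_arr) and pos_arr[idx] == pos
    return (idx, True) if present else (idx - 1, False)


def feature_F(
    dataset: MultiCellDataset, cell_i: str, cell_j: str, chrom: str, pos: int
) -> np.ndarray:
    """Flanking block: (dist_left, state_left, dist_right, state_right).

    If ``pos`` is labeled in cell j at index l, the flanks are sites l-1 and
    l+1 (the state at l itself is not used); otherwise they are the labeled
    sites bracketing ``pos``.  Distances are signed (left negative).
    """
    dataset.cell(cell_i)  # validate id
    profile_j = dataset.cell(cell_j)
    pos_arr, state_arr = profile_j.labeled(chrom)
    l, present = _locate(pos_arr, pos)
    if present:
        dl, sl = _at(pos_arr, state_arr, l - 1, pos)
        dr, sr = _at(pos_arr, state_arr, l + 1, pos)
    else:
        dl, sl = _at(pos_arr, state_arr, l, pos)
        dr, sr = _at(pos_arr, state_arr, l + 1, pos)
    return np.array([dl, sl, dr, sr])


def feature_D(
    dataset: MultiCellDataset,
    cell_i: str,
    cell_j: str,
    chrom: str,
    pos: int,
    dedupe_absent_gap: bool = False,
) -> np.ndarray:
    """Gap block in cell j around the target position (8 values).

    Present case (pos labeled in cell j at index l):
        (g(l-2,l-1), s[l-2], g(l-1,l), s[l], g(l,l+1), s[l], g(l+1,l+2), s[l+2])
    Absent case (flanks l < pos < l+1):
        (g(l-1,l), s[l-1], g(l,l+1), s[l+1], g(l,l+1), s[l], g(l+1,l+2), s[l+2])
    where g(a,b) = pos[b] - pos[a].  In the absent case the central gap
    appears in two slots by construction; ``dedupe_absent_gap`` masks the
    second occurrence to NaN.  Out-of-range indices yield NaN.

    For j = i the block would expose the target site's own state, so i == j
    raises.
    """
    if cell_i == cell_j:
        raise ValueError("gap block is undefined for the target cell itself "
                         "(it would leak the target site's own state)")
    dataset.cell(cell_i)
    profile_j = dataset.cell(cell_j)
    pos_arr, state_arr = profile_j.labeled(chrom)
    l, present = _locate(pos_arr, pos)

    def s(idx):
        return float(state_arr[idx]) if 0 <= idx < len(pos_arr) else MISSING

    if present:
        vec = [
            _gap(pos_arr, l - 2, l - 1), s(l - 2),
            _gap(pos_arr, l - 1, l), s(l),
            _gap(pos_arr, l, l + 1), s(l),
            _gap(pos_arr, l + 1, l + 2), s(l + 2),
        ]
    else:
        central = _gap(pos_arr, l, l + 1)
        vec = [
            _gap(pos_arr, l - 1, l), s(l - 1),
            central, s(l + 1),
            MISSING if dedupe_absent_gap else central, s(l),
            _gap(pos_arr, l + 1, l + 2), s(l + 2),
        ]
    return np.asarray(vec, dtype=np.float64)


_F_SLOTS = ("Pl", "Sl", "Pr", "Sr")
_D_SLOTS = ("g1", "s1", "g2", "s2", "g3", "s3", "g4", "s4")


def positional_feature_names(m: int) -> list[str]:
    """Column names of :func:`positional_vector` for an m-cell dataset.

    Names are relative to the target cell (``self``, then the other cells
    by lexicographic rank) so that every per-cell model shares one manifest;
    :func:`positional_feature_origins` maps columns back to absolute cell
    ids for a given target.
    """
    names = [f"pos_F_self_{s}" for s in _F_SLOTS]
    for r in range(1, m):
        names += [f"pos_F_o{r:02d}_{s}" for s in _F_SLOTS]
    for r in range(1, m):
        names += [f"pos_D_o{r:02d}_{s}" for s in _D_SLOTS]
    return names


def positional_feature_origins(dataset: MultiCellDataset, cell_i: str) -> list[str]:
    """Cell of origin of each positional column for one target cell."""
    others = sorted(c for c in dataset.cell_ids if c != cell_i)
    origins = [cell_i] * 4
    for j in others:
        origins += [j] * 4
    for j in others:
        origins += [j] * 8
    return origins


def positional_vector(
    dataset: MultiCellDataset, cell_i: str, chrom: str, pos: int,
    dedupe_absent_gap: bool = False,
) -> np.ndarray:
    """Full positional block of one site: 4m + 8(m-1) values.

    F blocks over every cell (target cell first, then lexicographic), D
    blocks over the other cells in the same order.
    """
    others = sorted(c for c in dataset.cell_ids if c != cell_i)
    parts = [feature_F(dataset, cell_i, cell_i, chrom, pos)]
    for j in others:
        parts.append(feature_F(dataset, cell_i, j, chrom, pos))
    for j in others:
        parts.append(feature_D(dataset, cell_i, j, chrom, pos, dedupe_absent_gap))
    return np.concatenate(parts)


def n_positional_features(m: int) -> int:
    return 4 * m + 8 * (m - 1)


# ---------------------------------------------------------------------------
# Vectorized extraction over many target positions


def _locate_batch(pos_arr: np.ndarray, queries: np.ndarray):
    idx = np.searchsorted(pos_arr, queries, side="left")
    present = np.zeros(len(queries), dtype=bool)
    inb = idx < len(pos_arr)
    present[inb] = pos_arr[idx[inb]] == queries[inb]
    left = np.where(present, idx, idx - 1)  # index of pos itself, or left flank
    return left, present


def _take_dist(pos_arr, idx, queries):
    out = np.full(len(idx), MISSING)
    ok = (idx >= 0) & (idx < len(pos_arr))
    out[ok] = pos_arr[idx[ok]] - queries[ok]
    return out


def _take_state(state_arr, idx):
    out = np.full(len(idx), MISSING)
    ok = (idx >= 0) & (idx < len(state_arr))
    out[ok] = state_arr[idx[ok]]
    return out


def _take_gap(pos_arr, i_idx, j_idx):
    out = np.full(len(i_idx), MISSING)
    ok = (i_idx >= 0) & (j_idx >= 0) & (i_idx < len(pos_arr)) & (j_idx < len(pos_arr))
    out[ok] = pos_arr[j_idx[ok]] - pos_arr[i_idx[ok]]
    return out


def feature_F_batch(profile_j: CellProfile, chrom: str, queries: np.ndarray) -> np.ndarray:
    """(n, 4) flanking blocks of many target positions against one cell."""
    queries = np.asarray(queries, dtype=np.int64)
    pos_arr, state_arr = profile_j.labeled(chrom)
    left, present = _locate_batch(pos_arr, queries)
    lidx = np.where(present, left - 1, left)
    ridx = left + 1
    return np.column_stack([
        _take_dist(pos_arr, lidx, queries),
        _take_state(state_arr, lidx),
        _take_dist(pos_arr, ridx, queries),
        _take_state(state_arr, ridx),
    ])


def feature_D_batch(
    profile_j: CellProfile, chrom: str, queries: np.ndarray,
    dedupe_absent_gap: bool = False,
) -> np.ndarray:
    """(n, 8) gap blocks of many target positions against one *other* cell.

    Caller is responsible for the j != i restriction (see :func:`feature_D`).
    """
    queries = np.asarray(queries, dtype=np.int64)
    pos_arr, state_arr = profile_j.labeled(chrom)
    left, present = _locate_batch(pos_arr, queries)
    n = len(queries)
    out = np.empty((n, 8))
    # present case, anchored at l = left
    lp = left
    pres = np.column_stack([
        _take_gap(pos_arr, lp - 2, lp - 1), _take_state(state_arr, lp - 2),
        _take_gap(pos_arr, lp - 1, lp), _take_state(state_arr, lp),
        _take_gap(pos_arr, lp, lp + 1), _take_state(state_arr, lp),
        _take_gap(pos_arr, lp + 1, lp + 2), _take_state(state_arr, lp + 2),
    ])
    central = _take_gap(pos_arr, left, left + 1)
    abs_ = np.column_stack([
        _take_gap(pos_arr, left - 1, left), _take_state(state_arr, left - 1),
        central, _take_state(state_arr, left + 1),
        np.full(n, MISSING) if dedupe_absent_gap else central,
        _take_state(state_arr, left),
        _take_gap(pos_arr, left + 1, left + 2), _take_state(state_arr, left + 2),
    ])
    out[present] = pres[present]
    out[~present] = abs_[~present]
    return out


def positional_matrix(
    dataset: MultiCellDataset, cell_i: str, chrom: str, queries: np.ndarray,
    dedupe_absent_gap: bool = False,
) -> np.ndarray:
    """(n, 4m + 8(m-1)) positional block for many sites of the target cell."""
    queries = np.asarray(queries, dtype=np.int64)
    others = sorted(c for c in dataset.cell_ids if c != cell_i)
    blocks = [feature_F_batch(dataset.cell(cell_i), chrom, queries)]
    for j in others:
        blocks.append(feature_F_batch(dataset.cell(j), chrom, queries))
    for j in others:
        blocks.append(feature_D_batch(dataset.cell(j), chrom, queries, dedupe_absent_gap))
    return np.hstack(blocks)


# ---------------------------------------------------------------------------
# skip-k features (distance-decay analyses)


def skip_k_feature_names(k1: int = 1, k2: int | None = None,
                         mode: str = "rank_pair") -> list[str]:
    if mode == "rank_pair":
        ranks = [k1]
    elif mode == "window":
        ranks = list(range(1, (k2 or 1) + 1))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    names = []
    for k in ranks:
        names += [f"skip_k{k}_Pl", f"skip_k{k}_Sl", f"skip_k{k}_Pr", f"skip_k{k}_Sr"]
    return names


def skip_k_features(
    profile: CellProfile, chrom: str, pos: int,
    k1: int = 1, k2: int | None = None, mode: str = "rank_pair",
) -> np.ndarray:
    """Neighbor states/distances at rank k1 (``rank_pair``) or all ranks
    1..k2 on each side (``window``); self-excluding, NaN when missing."""
    return skip_k_matrix(profile, chrom, np.asarray([pos]), k1, k2, mode)[0]


def skip_k_matrix(
    profile: CellProfile, chrom: str, queries: np.ndarray,
    k1: int = 1, k2: int | None = None, mode: str = "rank_pair",
) -> np.ndarray:
    """Vectorized :func:`skip_k_features` over many positions."""
    if mode == "rank_pair":
        ranks = [k1]
    elif mode == "window":
        if k2 is None or k2 < 1:
            raise ValueError("window mode needs k2 >= 1")
        ranks = list(range(1, k2 + 1))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if min(ranks) < 1:
        raise ValueError("rank must be >= 1")
    queries = np.asarray(queries, dtype=np.int64)
    pos_arr, state_arr = profile.labeled(chrom)
    first_ge = np.searchsorted(pos_arr, queries, side="left")
    first_gt = np.searchsorted(pos_arr, queries, side="right")
    blocks = []
    for k in ranks:
        lidx = first_ge - k
        ridx = first_gt + (k - 1)
        blocks.append(np.column_stack([
            _take_dist(pos_arr, lidx, queries),
            _take_state(state_arr, lidx),
            _take_dist(pos_arr, ridx, queries),
            _take_state(state_arr, ridx),
        ]))
    return np.hstack(blocks)
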