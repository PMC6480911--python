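"""Structural annotation features.

Each CpG site gets one column per annotation track: binary membership for
interval tracks (CpG islands, shores, shelves, TFBS, chromatin states,
histone marks, DNase hypersensitive sites) and a real value for per-position
score tracks (iHS selection statistic, evolutionary constraint score).  The
default manifest is 3 CGI-class + 144 TFBS + 15 chromatin-state + 10 histone
+ 1 DHS binary tracks plus the 2 score tracks: 175 features.

BED input is 0-based half-open; everything internal is 1-based closed point
queries, converted once at load time.  Missing scores are NaN, not 0 —
boosted trees route missing values natively and 0 is a meaningful score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

HISTONE_MARKS = (
    "H3K4me1", "H3K4me2", "H3K4me3", "H3K9ac", "H3K27ac",
    "H3K27me3", "H3K36me3", "H3K9me3", "H4K20me1", "H2AZ",
)


def default_manifest_names() -> list[tuple[str, str]]:
    """(name, kind) pairs of the default 175-track manifest, in column order."""
    names: list[tuple[str, str]] = [
        ("cgi", "binary_intervals"),
        ("cgi_shore", "binary_intervals"),
        ("cgi_shelf", "binary_intervals"),
    ]
    names += [(f"tfbs_{i:03d}", "binary_intervals") for i in range(1, 145)]
    names += [(f"chromstate_{i:02d}", "binary_intervals") for i in range(1, 16)]
    names += [(mark, "binary_intervals") for mark in HISTONE_MARKS]
    names.append(("dhs", "binary_intervals"))
    names.append(("ihs", "position_scores"))
    names.append(("constraint", "position_scores"))
    return names


def _merge_intervals(
    starts: np.ndarray, ends: np.ndarray, warn: str | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Merge overlapping/adjacent 1-based closed intervals; returns sorted arrays."""
    if len(starts) == 0:
        return starts.astype(np.int64), ends.astype(np.int64)
    order = np.argsort(starts, kind="mergesort")
    starts, ends = starts[order], ends[order]
    out_s, out_e = [starts[0]], [ends[0]]
    merged = False
    for s, e in zip(starts[1:], ends[1:]):
        if s <= out_e[-1] + 1:
            if s <= out_e[-1]:
                merged = True
            out_e[-1] = max(out_e[-1], e)
        else:
            out_s.append(s)
            out_e.append(e)
    if merged and warn:
        logger.warning("%s: overlapping intervals merged", warn)
    return np.asarray(out_s, dtype=np.int64), np.asarray(out_e, dtype=np.int64)


@dataclass
class AnnotationTrack:
    """One annotation track, queryable at 1-based point coordinates.

    ``intervals``: chrom -> (starts, ends), sorted non-overlapping 1-based
    closed.  ``scores``: chrom -> (positions, values), positions sorted.
    """

    name: str
    kind: str  # binary_intervals | position_scores
    intervals: dict = field(default_factory=dict)
    scores: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in ("binary_intervals", "position_scores"):
            raise ValueError(f"unknown track kind {self.kind!r}")

    @classmethod
    def from_intervals(cls, name: str, per_chrom: dict,
                       warn_on_merge: bool = False) -> "AnnotationTrack":
        """Build a binary track from {chrom: (starts, ends)} 1-based closed."""
        merged = {}
        for chrom, (s, e) in per_chrom.items():
            s = np.asarray(s, dtype=np.int64)
            e = np.asarray(e, dtype=np.int64)
            if (s < 1).any() or (e < s).any():
                raise ValueError(f"track {name}: bad interval coordinates on {chrom}")
            merged[chrom] = _merge_intervals(
                s, e, warn=f"track {name} ({chrom})" if warn_on_merge else None
            )
        return cls(name=name, kind="binary_intervals", intervals=merged)

    @classmethod
    def from_scores(cls, name: str, per_chrom: dict) -> "AnnotationTrack":
        """Build a score track from {chrom: (positions, values)} 1-based."""
        data = {}
        for chrom, (p, v) in per_chrom.items():
            p = np.asarray(p, dtype=np.int64)
            v = np.asarray(v, dtype=np.float64)
            order = np.argsort(p, kind="mergesort")
            p, v = p[order], v[order]
            if len(p) and (np.diff(p) == 0).any():
                raise ValueError(f"track {name}: duplicate score positions on {chrom}")
            data[chrom] = (p, v)
        return cls(name=name, kind="position_scores", scores=data)

    def query(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Vectorized point query: 0/1 for binary tracks, value/NaN for scores."""
        positions = np.asarray(positions, dtype=np.int64)
        if self.kind == "binary_intervals":
            out = np.zeros(len(positions), dtype=np.float64)
            if chrom in self.intervals:
                starts, ends = self.intervals[chrom]
                if len(starts):
                    idx = np.searchsorted(starts, positions, side="right") - 1
                    inside = idx >= 0
                    inside[inside] &= positions[inside] <= ends[idx[inside]]
                    out[inside] = 1.0
            return out
        out = np.full(len(positions), np.nan)
        if chrom in self.scores:
            pos_arr, val_arr = self.scores[chrom]
            if len(pos_arr):
                idx = np.searchsorted(pos_arr, positions)
                hit = (idx < len(pos_arr)) & (pos_arr[np.minimum(idx, len(pos_arr) - 1)] == positions)
                out[hit] = val_arr[idx[hit]]
        return out


def load_track(path, name: str, kind: str) -> AnnotationTrack:
    """Load a BED (binary_intervals) or bedGraph (position_scores) file.

    BED's 0-based half-open [start, end) becomes the 1-based closed
    [start+1, end] here; bedGraph rows expand to per-position scores.
    """
    ncol = 3 if kind == "binary_intervals" else 4
    try:
        df = pd.read_csv(
            path, sep=r"\s+", header=None, comment="#",
            usecols=range(ncol),
            names=["chrom", "start", "end", "value"][:ncol],
        )
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=["chrom", "start", "end", "value"][:ncol])
    if kind == "binary_intervals":
        if len(df) and ((df["start"] < 0).any() or (df["end"] <= df["start"]).any()):
            raise ValueError(f"{path}: bad BED coordinates")
        per_chrom = {
            chrom: (sub["start"].to_numpy() + 1, sub["end"].to_numpy())
            for chrom, sub in df.groupby("chrom")
        }
        return AnnotationTrack.from_intervals(name, per_chrom, warn_on_merge=True)
    if kind == "position_scores":
        if len(df) and ((df["start"] < 0).any() or (df["end"] <= df["start"]).any()):
            raise ValueError(f"{path}: bad bedGraph coordinates")
        per_chrom = {}
        for chrom, sub in df.groupby("chrom"):
            pos_chunks, val_chunks = [], []
            for s, e, v in zip(sub["start"], sub["end"], sub["value"]):
                pos_chunks.append(np.arange(s + 1, e + 1, dtype=np.int64))
                val_chunks.append(np.full(e - s, float(v)))
            per_chrom[chrom] = (np.concatenate(pos_chunks), np.concatenate(val_chunks))
        return AnnotationTrack.from_scores(name, per_chrom)
    raise ValueError(f"unknown track kind {kind!r}")


def derive_cgi_flanks(
    cgi: AnnotationTrack, shore_width: int = 2000, shelf_width: int = 2000
) -> tuple[AnnotationTrack, AnnotationTrack]:
    """Shore and shelf tracks from CGI intervals.

    Shores are the conventional 2 kb flanks on either side of an island,
    shelves the next 2 kb outward; both exclude positions inside any island,
    and shelves exclude shores.
    """

    def flanks(track_intervals, inner: int, outer: int):
        per_chrom = {}
        for chrom, (starts, ends) in track_intervals.items():
            fs, fe = [], []
            for s, e in zip(starts, ends):
                fs += [max(1, s - outer), e + inner + 1]
                fe += [max(1, s - inner - 1), e + outer]
            per_chrom[chrom] = (np.asarray(fs), np.asarray(fe))
        return per_chrom

    def subtract(track: AnnotationTrack, others: list[AnnotationTrack], name: str):
        per_chrom = {}
        for chrom, (starts, ends) in track.intervals.items():
            keep_s, keep_e = [], []
            for s, e in zip(starts, ends):
                segments = [(s, e)]
                for other in others:
                    os, oe = other.intervals.get(chrom, (np.array([]), np.array([])))
                    nxt = []
                    for a, b in segments:
                        cur = a
                        for s2, e2 in zip(os, oe):
                            if e2 < cur or s2 > b:
                                continue
                            if s2 > cur:
                                nxt.append((cur, s2 - 1))
                            cur = max(cur, e2 + 1)
                        if cur <= b:
                            nxt.append((cur, b))
                    segments = nxt
                for a, b in segments:
                    keep_s.append(a)
                    keep_e.append(b)
            if keep_s:
                per_chrom[chrom] = (np.asarray(keep_s), np.asarray(keep_e))
        return AnnotationTrack.from_intervals(name, per_chrom)

    raw_shore = AnnotationTrack.from_intervals(
        "cgi_shore", flanks(cgi.intervals, 0, shore_width)
    )
    shore = subtract(raw_shore, [cgi], "cgi_shore")
    raw_shelf = AnnotationTrack.from_intervals(
        "cgi_shelf", flanks(cgi.intervals, shore_width, shore_width + shelf_width)
    )
    shelf = subtract(raw_shelf, [cgi, shore], "cgi_shelf")
    return shore, shelf


@dataclass
class TrackSet:
    """Ordered annotation tracks; the order fixes the feature column order."""

    tracks: list[AnnotationTrack]

    def __post_init__(self) -> None:
        names = [t.name for t in self.tracks]
        if len(set(names)) != len(names):
            raise ValueError("track names must be unique")

    def __len__(self) -> int:
        return len(self.tracks)

    @property
    def names(self) -> list[str]:
        return [t.name for t in self.tracks]

    def feature_names(self) -> list[str]:
        return [f"str_{t.name}" for t in self.tracks]


def structural_vector(chrom: str, pos: int, tracks: TrackSet) -> np.ndarray:
    """Feature vector of one site, ordered by the manifest."""
    return structural_matrix(chrom, np.asarray([pos]), tracks)[0]


def structural_matrix(chrom: str, positions: np.ndarray, tracks: TrackSet) -> np.ndarray:
    """(n_sites, n_tracks) structural feature block for one chromosome."""
    positions = np.asarray(positions, dtype=np.int64)
    cols = [t.query(chrom, positions) for t in tracks.tracks]
    return np.column_stack(cols) if cols else np.zeros((len(positions), 0))


def load_manifest(path) -> TrackSet:
    """Load a track manifest TSV (name, kind, path), one track per row.

    Paths are resolved relative to the manifest file's directory.  Row order
    defines feature order.
    """
    import os

    base = os.path.dirname(os.path.abspath(str(path)))
    rows = pd.read_csv(path, sep="\t", header=None, comment="#",
                       names=["name", "kind", "path"])
    tracks = []
    for row in rows.itertuples(index=False):
        p = row.path if os.path.isabs(row.path) else os.path.join(base, row.path)
        tracks.append(load_track(p, row.name, row.kind))
    return TrackSet(tracks)
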