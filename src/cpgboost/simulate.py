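"""Synthetic sparse multi-cell methylome generator.

Emulates the statistical regime of single-cell bisulfite data so the whole
pipeline is testable offline: a random genome with CpG dinucleotides planted
at geometric gaps, a spatially correlated latent methylation landscape (a
symmetric two-state Markov chain in base-pair distance, so neighbor
agreement decays as (1 + (1-2q)^gap) / 2 toward 1/2), per-cell states that
copy the latent landscape with a concordance probability, sparse per-cell
observation (1-40% coverage in the real protocols), and shifted-Poisson
read depths with a small per-read error so the >= 4-read majority filter
has real work to do downstream.

Each component draws from its own child RNG stream of the master seed, so
fixtures are reproducible component-by-component.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .profiles import CellProfile, MultiCellDataset, binarize_array
from .sequence import GenomeSequence
from .structural import (
    AnnotationTrack,
    TrackSet,
    default_manifest_names,
    derive_cgi_flanks,
)


@dataclass(frozen=True)
class SimConfig:
    """Study-condition knobs of the simulator.

    Defaults describe a small but realistic sparse methylome: 5 cells over
    two 1-Mb chromosomes, one CpG per ~100 bp, coverage 30% per cell,
    cell-to-latent concordance 0.9, per-bp state-switch probability 0.001
    (neighbor agreement ~0.91 at 100 bp, ~0.5 beyond a few kb), mean read
    depth 6 with 1% per-read error.
    """

    m: int = 5
    n_chrom: int = 2
    chrom_len: int = 1_000_000
    mean_gap: float = 100.0
    switch_per_bp: float = 0.001
    concordance: float = 0.9
    coverage: float = 0.3
    depth_mean: float = 6.0
    read_error: float = 0.01
    cgi_enrichment: float = 6.0
    cgi_base_rate: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m < 1 or self.n_chrom < 1 or self.chrom_len < 10:
            raise ValueError("m, n_chrom, chrom_len out of range")
        if self.mean_gap < 2:
            raise ValueError("mean_gap must be >= 2")
        if not (0 <= self.switch_per_bp <= 0.5):
            raise ValueError("switch_per_bp must be in [0, 0.5]")
        if not (0.5 <= self.concordance <= 1.0):
            raise ValueError("concordance must be in [0.5, 1]")
        if not (0 < self.coverage <= 1.0):
            raise ValueError("coverage must be in (0, 1]")
        if self.depth_mean < 1:
            raise ValueError("depth_mean must be >= 1")
        if not (0 <= self.read_error < 0.5):
            raise ValueError("read_error must be in [0, 0.5)")


def _streams(cfg: SimConfig) -> dict:
    children = np.random.SeedSequence(cfg.seed).spawn(4)
    return {name: np.random.default_rng(ss)
            for name, ss in zip(("genome", "latent", "profiles", "tracks"), children)}


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def simulate_genome(cfg: SimConfig) -> tuple[dict, dict]:
    """Random genome with CpG dinucleotides planted at geometric gaps.

    Returns ({chrom: sequence}, {chrom: positions}); positions are the
    1-based coordinates of the planted C's and are exactly the CG
    dinucleotides present (accidental background CGs are scrubbed).
    """
    rng = _streams(cfg)["genome"]
    genome: dict[str, str] = {}
    positions: dict[str, np.ndarray] = {}
    p_gap = 1.0 / (cfg.mean_gap - 1.0) if cfg.mean_gap > 2 else 1.0
    for ci in range(1, cfg.n_chrom + 1):
        chrom = f"chr{ci}"
        seq = _BASES[rng.integers(0, 4, size=cfg.chrom_len)].copy()
        # plant CGs at gaps of 1 + Geometric(p) >= 2 (mean = mean_gap)
        n_draw = int(cfg.chrom_len / max(cfg.mean_gap, 2) * 1.5) + 16
        gaps = 1 + rng.geometric(p_gap, size=n_draw)
        pos = 2 + np.cumsum(gaps)  # 1-based C positions, first >= 4
        pos = pos[pos <= cfg.chrom_len - 1]
        seq[pos - 1] = ord("C")
        seq[pos] = ord("G")
        # scrub accidental CG dinucleotides (flip the G to A); planting
        # guarantees gaps >= 2 so planted pairs never touch
        is_cg = (seq[:-1] == ord("C")) & (seq[1:] == ord("G"))
        cg_pos = np.flatnonzero(is_cg) + 1  # 1-based C position
        accidental = np.setdiff1d(cg_pos, pos, assume_unique=False)
        seq[accidental] = ord("A")  # the G sits at index == 1-based C pos
        genome[chrom] = seq.tobytes().decode("ascii")
        positions[chrom] = pos.astype(np.int64)
    return genome, positions


def write_fasta(genome: dict, path, width: int = 70) -> None:
    """Plain-text FASTA output of a simulated genome."""
    with open(path, "w") as fh:
        for chrom in genome:
            fh.write(f">{chrom}\n")
            seq = genome[chrom]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def simulate_latent(cfg: SimConfig, positions: dict) -> dict:
    """Latent methylation landscape over the CpG positions.

    A symmetric two-state Markov chain in base-pair distance: over a gap of
    g bp the state flips with probability (1 - (1 - 2s)^g) / 2, s being the
    per-bp switch probability, so agreement decays smoothly to 1/2.
    """
    rng = _streams(cfg)["latent"]
    latent = {}
    s = cfg.switch_per_bp
    for chrom, pos in positions.items():
        n = len(pos)
        states = np.empty(n, dtype=np.int8)
        if n == 0:
            latent[chrom] = states
            continue
        states[0] = rng.integers(0, 2)
        gaps = np.diff(pos).astype(np.float64)
        p_flip = 0.5 * (1.0 - (1.0 - 2.0 * s) ** gaps)
        flips = rng.random(n - 1) < p_flip
        states[1:] = flips
        states = np.bitwise_xor.accumulate(states)
        latent[chrom] = states.astype(np.int8)
    return latent


def simulate_profiles(
    cfg: SimConfig, positions: dict, latent: dict | None = None
) -> MultiCellDataset:
    """Sparse per-cell read-count profiles over the CpG positions.

    Each cell copies the latent state with probability ``concordance``
    (else flips), observes each site with probability ``coverage``, draws
    depth 1 + Poisson(depth_mean - 1), and draws methylated read counts
    binomially with error ``read_error``.  States are the >= 4-read
    majority binarization of those counts.
    """
    if latent is None:
        latent = simulate_latent(cfg, positions)
    rng = _streams(cfg)["profiles"]
    cells = []
    for i in range(cfg.m):
        frames = []
        for chrom, pos in positions.items():
            n = len(pos)
            if n == 0:
                continue
            cell_state = np.where(
                rng.random(n) < cfg.concordance, latent[chrom], 1 - latent[chrom]
            ).astype(np.int8)
            observed = rng.random(n) < cfg.coverage
            n_obs = int(observed.sum())
            if n_obs == 0:
                continue
            depth = 1 + rng.poisson(cfg.depth_mean - 1.0, size=n_obs)
            p_meth = np.where(cell_state[observed] == 1,
                              1.0 - cfg.read_error, cfg.read_error)
            meth = rng.binomial(depth, p_meth)
            frames.append(pd.DataFrame({
                "chrom": chrom,
                "pos": pos[observed],
                "meth_reads": meth,
                "total_reads": depth,
                "state": binarize_array(meth, depth, min_cov=4),
            }))
        if not frames:
            frames = [pd.DataFrame(columns=["chrom", "pos", "meth_reads",
                                            "total_reads", "state"])]
        cells.append(CellProfile(f"cell{i:02d}", pd.concat(frames, ignore_index=True)))
    return MultiCellDataset(cells)


def _random_intervals(rng, chrom_len, n, min_len, max_len):
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    starts = rng.integers(1, max(2, chrom_len - max_len), size=n)
    lengths = rng.integers(min_len, max_len + 1, size=n)
    order = np.argsort(starts)
    return starts[order], np.minimum(starts[order] + lengths[order] - 1, chrom_len)


def simulate_tracks(
    cfg: SimConfig, positions: dict, latent: dict | None = None
) -> TrackSet:
    """The full 175-track annotation fixture.

    CGI intervals are tiled 2-kb windows accepted with a probability that
    grows with the window's unmethylated-latent fraction (strength
    ``cgi_enrichment``; 0 makes islands independent of the landscape, so
    structural features carry signal only when the knob is on).  Shores and
    shelves are derived from the islands with the conventional 2-kb flanks.
    The remaining binary tracks are random interval sets; the two score
    tracks carry Gaussian per-position scores on random subsets of the CpG
    positions (missing elsewhere).
    """
    if latent is None:
        latent = simulate_latent(cfg, positions)
    rng = _streams(cfg)["tracks"]
    chrom_lens = {chrom: cfg.chrom_len for chrom in positions}

    # CGI islands: tile the genome, enrich for unmethylated latent windows
    window = 2000
    base_rate = cfg.cgi_base_rate
    cgi_per_chrom = {}
    for chrom, pos in positions.items():
        starts, ends = [], []
        lat = latent[chrom]
        for w0 in range(1, chrom_lens[chrom] - window + 2, window):
            w1 = w0 + window - 1
            inside = (pos >= w0) & (pos <= w1)
            if inside.sum() >= 3:
                unmeth_frac = 1.0 - lat[inside].mean()
            else:
                unmeth_frac = 0.5
            p = base_rate * np.exp(cfg.cgi_enrichment * (unmeth_frac - 0.5))
            if rng.random() < min(p, 1.0):
                starts.append(w0)
                ends.append(w1)
        cgi_per_chrom[chrom] = (np.asarray(starts, dtype=np.int64),
                                np.asarray(ends, dtype=np.int64))
    cgi = AnnotationTrack.from_intervals("cgi", cgi_per_chrom)
    shore, shelf = derive_cgi_flanks(cgi)

    tracks: list[AnnotationTrack] = [cgi, shore, shelf]
    for name, kind in default_manifest_names()[3:]:
        if kind == "binary_intervals":
            if name.startswith("tfbs_"):
                n_iv, lo, hi = max(1, cfg.chrom_len // 50_000), 100, 400
            elif name.startswith("chromstate_"):
                n_iv, lo, hi = max(1, cfg.chrom_len // 30_000), 1000, 5000
            elif name == "dhs":
                n_iv, lo, hi = max(1, cfg.chrom_len // 40_000), 150, 600
            else:  # histone marks: broad domains
                n_iv, lo, hi = max(1, cfg.chrom_len // 60_000), 2000, 10_000
            per_chrom = {
                chrom: _random_intervals(rng, chrom_lens[chrom], n_iv, lo, hi)
                for chrom in positions
            }
            tracks.append(AnnotationTrack.from_intervals(name, per_chrom))
        else:  # ihs / constraint scores on a random half of the CpG positions
            scale = 1.0 if name == "ihs" else 2.0
            per_chrom = {}
            for chrom, pos in positions.items():
                keep = rng.random(len(pos)) < 0.5
                per_chrom[chrom] = (pos[keep],
                                    rng.normal(0.0, scale, size=int(keep.sum())))
            tracks.append(AnnotationTrack.from_scores(name, per_chrom))
    return TrackSet(tracks)


# ---------------------------------------------------------------------------
# Fixture directory


def write_tracks(tracks: TrackSet, outdir) -> str:
    """Write every track as BED/bedGraph plus a manifest TSV; returns the
    manifest path."""
    os.makedirs(outdir, exist_ok=True)
    rows = []
    for t in tracks.tracks:
        if t.kind == "binary_intervals":
            fname = f"{t.name}.bed"
            with open(os.path.join(outdir, fname), "w") as fh:
                for chrom, (starts, ends) in t.intervals.items():
                    for s, e in zip(starts, ends):
                        fh.write(f"{chrom}\t{s - 1}\t{e}\n")  # back to BED coords
        else:
            fname = f"{t.name}.bedgraph"
            with open(os.path.join(outdir, fname), "w") as fh:
                for chrom, (pos, val) in t.scores.items():
                    for p, v in zip(pos, val):
                        fh.write(f"{chrom}\t{p - 1}\t{p}\t{v:.10g}\n")
        rows.append((t.name, t.kind, fname))
    manifest = os.path.join(outdir, "manifest.tsv")
    pd.DataFrame(rows).to_csv(manifest, sep="\t", header=False, index=False)
    return manifest


def simulate_fixture(cfg: SimConfig, outdir) -> dict:
    """Emit a complete fixture directory: genome FASTA, per-cell profile
    TSVs, annotation tracks and manifest.  Returns the path map."""
    from .profiles import write_profile

    os.makedirs(outdir, exist_ok=True)
    genome, positions = simulate_genome(cfg)
    latent = simulate_latent(cfg, positions)
    dataset = simulate_profiles(cfg, positions, latent)
    tracks = simulate_tracks(cfg, positions, latent)

    fasta = os.path.join(outdir, "genome.fa")
    write_fasta(genome, fasta)
    profile_dir = os.path.join(outdir, "profiles")
    os.makedirs(profile_dir, exist_ok=True)
    profile_paths = []
    for cell in dataset.cells:
        p = os.path.join(profile_dir, f"{cell.cell_id}.tsv")
        write_profile(cell, p, dialect="counts")
        profile_paths.append(p)
    manifest = write_tracks(tracks, os.path.join(outdir, "tracks"))
    return {"fasta": fasta, "profiles": profile_paths, "track_manifest": manifest}


def simulated_genome_sequence(genome: dict) -> GenomeSequence:
    """In-memory GenomeSequence over a simulated genome mapping."""
    return GenomeSequence(genome)
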