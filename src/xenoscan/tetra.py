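"""Tetranucleotide-signature profiling and k-means contig binning.

Compositionally similar replicons share tetranucleotide (4-mer) usage, so
clustering the 256-dimensional frequency vectors of 2-kb windows groups
contigs by genome of origin — a standard check that co-assembled contigs
belong together.  Clustering is Lloyd's k-means (k-means++ seeding,
Euclidean distance on raw frequencies, max 20 iterations, deterministic
under a fixed seed); each contig is then assigned the majority cluster of
its windows.

All 256 tetramers are used as individual dimensions by default; an optional
canonical mode collapses each tetramer with its reverse complement into 136
strand-independent features.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import product
from pathlib import Path
from typing import Iterable, Sequence, Union

import numpy as np
from sklearn.cluster import KMeans

from .io import GenomeRecord, revcomp

__all__ = [
    "TETRAMERS",
    "TetraProfile",
    "ClusterResult",
    "window_tetra_freqs",
    "kmeans_cluster",
    "assign_contigs",
    "write_profiles_tsv",
    "write_assignments_tsv",
    "plot_profile_heatmap",
]

logger = logging.getLogger(__name__)

TETRAMERS: tuple[str, ...] = tuple("".join(p) for p in product("ACGT", repeat=4))

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass(frozen=True)
class TetraProfile:
    """Tetramer frequency vector of one window of one contig."""

    contig_id: str
    window_start: int
    freqs: np.ndarray  # 256 frequencies in TETRAMERS order, summing to 1 for N-free windows


@dataclass
class ClusterResult:
    k: int
    labels: np.ndarray  # per-profile cluster index
    centroids: np.ndarray  # (k, n_features)
    iterations: int
    seed: int
    profiles: list[TetraProfile]


def _tetramer_counts(seq: str) -> np.ndarray:
    """Counts of all overlapping 4-mers; any 4-mer containing N is dropped."""
    codes = np.array([_BASE_CODE.get(b, -1) for b in seq], dtype=np.int64)
    n = len(codes) - 3
    idx = codes[:n] * 64 + codes[1 : n + 1] * 16 + codes[2 : n + 2] * 4 + codes[3 : n + 3]
    valid = (
        (codes[:n] >= 0)
        & (codes[1 : n + 1] >= 0)
        & (codes[2 : n + 2] >= 0)
        & (codes[3 : n + 3] >= 0)
    )
    return np.bincount(idx[valid], minlength=256).astype(np.float64)


def window_tetra_freqs(
    contig: GenomeRecord, window: int = 2000, canonical: bool = False
) -> list[TetraProfile]:
    """Per-window tetramer frequency profiles over non-overlapping windows.

    A window of length ``w`` contains ``w - 3`` overlapping tetramers;
    tetramers containing ``N`` are dropped from numerator and denominator.
    Contigs shorter than one window are skipped with a logged warning
    (returning an empty list), as are trailing partial windows.
    """
    if window < 8:
        raise ValueError(f"window must be >= 8 bp, got {window}")
    n = len(contig)
    if n < window:
        logger.warning(
            "contig %s (%d bp) shorter than the %d bp window; skipped", contig.id, n, window
        )
        return []
    profiles: list[TetraProfile] = []
    for start in range(0, n - window + 1, window):
        counts = _tetramer_counts(contig.sequence[start : start + window])
        total = counts.sum()
        if total == 0:
            logger.warning("window %s:%d is all-N; skipped", contig.id, start)
            continue
        freqs = counts / total
        if canonical:
            freqs = _canonicalize(freqs)
        profiles.append(TetraProfile(contig.id, start, freqs))
    return profiles


def _canonical_index() -> tuple[np.ndarray, int]:
    canon: dict[str, int] = {}
    mapping = np.zeros(256, dtype=np.int64)
    for i, t in enumerate(TETRAMERS):
        key = min(t, revcomp(t))
        if key not in canon:
            canon[key] = len(canon)
        mapping[i] = canon[key]
    return mapping, len(canon)


def _canonicalize(freqs: np.ndarray) -> np.ndarray:
    mapping, n = _canonical_index()
    out = np.zeros(n)
    np.add.at(out, mapping, freqs)
    return out


def kmeans_cluster(
    profiles: Sequence[TetraProfile],
    k: int = 3,
    max_iter: int = 20,
    seed: int = 0,
    z_scale: bool = False,
) -> ClusterResult:
    """Cluster window profiles with Lloyd's k-means (k-means++ seeding).

    Euclidean distance on raw frequencies by default; ``z_scale`` standardises
    each feature first.  Deterministic given ``seed``; stops at convergence or
    after ``max_iter`` iterations.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if len(profiles) < k:
        raise ValueError(f"need at least k={k} profiles, got {len(profiles)}")
    X = np.vstack([p.freqs for p in profiles])
    if z_scale:
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        X = (X - X.mean(axis=0)) / sd
    km = KMeans(
        n_clusters=k,
        init="k-means++",
        n_init=1,
        max_iter=max_iter,
        random_state=seed,
        algorithm="lloyd",
    ).fit(X)
    return ClusterResult(
        k=k,
        labels=km.labels_.astype(np.int64),
        centroids=km.cluster_centers_,
        iterations=int(km.n_iter_),
        seed=seed,
        profiles=list(profiles),
    )


def assign_contigs(result: ClusterResult) -> dict[str, tuple[int, float]]:
    """Majority-vote cluster per contig, with the winning vote fraction.

    Ties break toward the lowest cluster index.
    """
    votes: dict[str, np.ndarray] = {}
    for profile, label in zip(result.profiles, result.labels):
        votes.setdefault(profile.contig_id, np.zeros(result.k, dtype=np.int64))[label] += 1
    out: dict[str, tuple[int, float]] = {}
    for cid, v in votes.items():
        best = int(np.argmax(v))  # argmax returns the first (lowest) index on ties
        out[cid] = (best, float(v[best] / v.sum()))
    return out


def write_profiles_tsv(profiles: Iterable[TetraProfile], path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        fh.write("contig\twindow_start\t" + "\t".join(TETRAMERS) + "\n")
        for p in profiles:
            fh.write(
                f"{p.contig_id}\t{p.window_start}\t"
                + "\t".join(f"{x:.6g}" for x in p.freqs)
                + "\n"
            )


def write_assignments_tsv(
    assignments: dict[str, tuple[int, float]],
    path: Union[str, Path],
    header_lines: Iterable[str] = (),
) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("contig\tcluster\tvote_fraction\n")
        for cid, (cluster, frac) in sorted(assignments.items()):
            fh.write(f"{cid}\t{cluster}\t{frac:.3f}\n")


def plot_profile_heatmap(result: ClusterResult, path: Union[str, Path]) -> None:
    """Window-by-tetramer frequency heatmap with rows ordered by cluster."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    order = np.argsort(result.labels, kind="stable")
    X = np.vstack([result.profiles[i].freqs for i in order])
    fig, ax = plt.subplots(figsize=(10, max(2, 0.05 * X.shape[0])))
    ax.imshow(X, aspect="auto", cmap="gray", interpolation="nearest")
    ax.set_xlabel("tetranucleotide")
    ax.set_ylabel("2 kb window (ordered by cluster)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
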