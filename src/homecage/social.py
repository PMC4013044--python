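"""Permutation-based inference of follow/avoid relationships from corner
entry sequences.

Pipeline: each animal is a letter; per-corner entry sequences are formed
from visit start times; adjacent ordered letter pairs are counted, keeping
only pairs whose entry-time gap lies in [1 s, 60 s]; a null distribution is
obtained by shuffling each corner's letters over that corner's fixed time
slots (so the same gap filter applies to the null) and the z-like score is

    score(first -> second) = (observed - permutation mean) / permutation SD

interpreted on a standard-normal scale: |score| > 2 maps to a two-sided
unadjusted p of 0.0455, and score > 3.5 to p < 0.0005.

Matrix axis convention: the first mouse of a pair indexes the *column*, the
second the *row*, so column-normalised matrices have unit column sums.

Cells whose permutation SD is zero (e.g. a corner visited by one animal
only) are given a score of 0 and flagged — no evidence either way.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import norm

from .errors import ConfigError, DataError
from .event_log import EventTable

MIN_GAP_S = 1.0
MAX_GAP_S = 60.0
DEFAULT_N_PERM = 100
WEAK_THRESHOLD = 2.0
STRONG_THRESHOLD = 3.5

MERGE_DUPLICATE_S = 1.0  # same mouse re-triggering the same corner within this gap


@dataclass
class CornerSequence:
    """Ordered entries into one corner: integer animal codes + entry times."""

    corner: int
    codes: np.ndarray  # int codes into the shared animal index
    times: np.ndarray  # entry times (t_start), non-decreasing

    def __len__(self) -> int:
        return len(self.codes)


@dataclass
class PairCountMatrix:
    """N x N counts of qualifying adjacent pairs; ``counts[second, first]``."""

    animals: List[str]
    counts: np.ndarray
    total_pairs: int  # qualifying pairs (sum of counts)
    total_adjacent: int  # adjacent pairs before the gap filter

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.animals, columns=self.animals)


@dataclass
class ScoreMatrix:
    """Permutation z-like scores with the null's per-cell mean and SD."""

    animals: List[str]
    scores: np.ndarray  # [second, first]
    perm_mean: np.ndarray
    perm_sd: np.ndarray
    observed: np.ndarray
    n_perm: int
    seed: Optional[int]
    zero_sd: np.ndarray = field(default=None)  # boolean mask of degenerate cells

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.scores, index=self.animals, columns=self.animals)


@dataclass
class Edge:
    source: str  # first mouse (leader)
    target: str  # second mouse (follower/avoider)
    score: float
    kind: str  # follow | avoid
    strength: str  # weak | strong


# ---------------------------------------------------------------------------
# Sequence construction


def build_sequences(table: EventTable) -> Dict[int, CornerSequence]:
    """One entry sequence per corner from visit start times.

    Ties in entry time keep stable input order; sub-second re-entries by
    the same mouse at the same corner are merged into the first entry
    (transponder re-contact artifacts).
    """
    index = {a: i for i, a in enumerate(table.animals)}
    df = table.df
    out: Dict[int, CornerSequence] = {}
    for corner in (1, 2, 3, 4):
        sub = df[df["corner"] == corner]
        codes = np.array([index[a] for a in sub["animal_id"]], dtype=np.int64)
        times = sub["t_start"].to_numpy(dtype=float)
        order = np.argsort(times, kind="stable")
        codes, times = codes[order], times[order]
        if len(codes) > 1:
            dup = (codes[1:] == codes[:-1]) & (np.diff(times) < MERGE_DUPLICATE_S)
            keep = np.concatenate([[True], ~dup])
            codes, times = codes[keep], times[keep]
        out[corner] = CornerSequence(corner=corner, codes=codes, times=times)
    return out


def _collapse_repeats(codes: np.ndarray, times: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Collapse consecutive same-letter runs to their first entry."""
    if len(codes) == 0:
        return codes, times
    keep = np.concatenate([[True], codes[1:] != codes[:-1]])
    return codes[keep], times[keep]


def _count_codes(
    codes: np.ndarray,
    times: np.ndarray,
    n_animals: int,
    min_gap: float,
    max_gap: float,
    drop_repeats: bool,
) -> Tuple[np.ndarray, int, int]:
    """Core pair counter on raw arrays; returns (matrix, qualifying, adjacent)."""
    if drop_repeats:
        codes, times = _collapse_repeats(codes, times)
    counts = np.zeros((n_animals, n_animals), dtype=np.int64)
    if len(codes) < 2:
        return counts, 0, 0
    gaps = times[1:] - times[:-1]
    mask = (gaps >= min_gap) & (gaps <= max_gap)
    firsts = codes[:-1][mask]
    seconds = codes[1:][mask]
    np.add.at(counts, (seconds, firsts), 1)
    return counts, int(mask.sum()), int(len(codes) - 1)


def count_pairs(
    seq: CornerSequence,
    animals: Sequence[str],
    min_gap: float = MIN_GAP_S,
    max_gap: float = MAX_GAP_S,
    drop_repeats: bool = False,
) -> PairCountMatrix:
    """Count qualifying adjacent ordered pairs in one corner sequence.

    A pair (first, second) qualifies when ``min_gap <= gap <= max_gap`` with
    the gap measured between entry times.  With ``drop_repeats`` consecutive
    same-letter runs are collapsed to their first entry before counting, so
    same-mouse pairs vanish from both the counts and (downstream) the null.
    """
    if min_gap > max_gap:
        raise ConfigError("min_gap must not exceed max_gap")
    counts, qualifying, adjacent = _count_codes(
        seq.codes, seq.times, len(animals), min_gap, max_gap, drop_repeats
    )
    return PairCountMatrix(
        animals=list(animals),
        counts=counts,
        total_pairs=qualifying,
        total_adjacent=adjacent,
    )


def sum_counts(matrices: Sequence[PairCountMatrix]) -> PairCountMatrix:
    """Element-wise sum of per-corner count matrices (same animal order)."""
    if not matrices:
        raise DataError("no matrices to sum")
    animals = matrices[0].animals
    counts = np.zeros_like(matrices[0].counts)
    total_pairs = total_adj = 0
    for m in matrices:
        if m.animals != animals:
            raise DataError("matrices have differing animal order")
        counts = counts + m.counts
        total_pairs += m.total_pairs
        total_adj += m.total_adjacent
    return PairCountMatrix(animals, counts, total_pairs, total_adj)


def normalize_by_first(counts: PairCountMatrix) -> Tuple[np.ndarray, List[str]]:
    """Column-stochastic version: each positive column sums to 1.

    Returns the normalised matrix and the list of animals (columns) with no
    qualifying pairs as first mouse, which stay all-zero.
    """
    mat = counts.counts.astype(float)
    sums = mat.sum(axis=0)
    flagged = [counts.animals[j] for j in range(mat.shape[1]) if sums[j] == 0]
    positive = sums > 0
    mat[:, positive] = mat[:, positive] / sums[positive]
    return mat, flagged


# ---------------------------------------------------------------------------
# Permutation null and scores


def permutation_scores(
    sequences: Dict[int, CornerSequence] | Sequence[CornerSequence],
    animals: Sequence[str],
    n_perm: int = DEFAULT_N_PERM,
    seed: Optional[int] = None,
    min_gap: float = MIN_GAP_S,
    max_gap: float = MAX_GAP_S,
    drop_repeats: bool = False,
    respect_gaps: bool = True,
) -> ScoreMatrix:
    """Permutation z-like scores pooled over corners.

    Observed pair counts are summed over corners; in each of ``n_perm``
    permutations every corner's letter multiset is shuffled independently
    over that corner's fixed time slots and the counts recomputed with the
    same gap filter (``respect_gaps=True``, the default).  With
    ``respect_gaps=False`` the gap filter is dropped in both observed and
    null counting (every adjacent pair qualifies).

    score = (observed - null mean) / null SD, with zero-SD cells set to 0
    and flagged on ``zero_sd``.
    """
    if n_perm < 2:
        raise ConfigError("n_perm must be >= 2")
    if isinstance(sequences, dict):
        seq_list = [sequences[k] for k in sorted(sequences)]
    else:
        seq_list = list(sequences)
    n = len(animals)
    lo, hi = (min_gap, max_gap) if respect_gaps else (-np.inf, np.inf)

    observed = np.zeros((n, n), dtype=np.int64)
    total_qualifying = 0
    for seq in seq_list:
        counts, q, _ = _count_codes(seq.codes, seq.times, n, lo, hi, drop_repeats)
        observed = observed + counts
        total_qualifying += q
    if total_qualifying == 0:
        raise DataError("no qualifying pairs in any corner sequence")

    rng = np.random.default_rng(seed)
    acc = np.zeros((n, n), dtype=float)
    acc_sq = np.zeros((n, n), dtype=float)
    for _ in range(n_perm):
        perm_counts = np.zeros((n, n), dtype=np.int64)
        for seq in seq_list:
            shuffled = rng.permutation(seq.codes)
            counts, _, _ = _count_codes(shuffled, seq.times, n, lo, hi, drop_repeats)
            perm_counts += counts
        acc += perm_counts
        acc_sq += perm_counts.astype(float) ** 2

    mean = acc / n_perm
    var = (acc_sq - n_perm * mean**2) / (n_perm - 1)
    var = np.maximum(var, 0.0)
    sd = np.sqrt(var)
    zero_sd = sd == 0
    scores = np.zeros((n, n), dtype=float)
    np.divide(observed - mean, sd, out=scores, where=~zero_sd)
    return ScoreMatrix(
        animals=list(animals),
        scores=scores,
        perm_mean=mean,
        perm_sd=sd,
        observed=observed.astype(float),
        n_perm=n_perm,
        seed=seed,
        zero_sd=zero_sd,
    )


def score_pvalue(z: float) -> float:
    """Two-sided standard-normal tail probability for a score."""
    if not np.isfinite(z):
        raise ValueError("score must be finite")
    return float(2.0 * norm.sf(abs(z)))


def classify_edges(
    scores: ScoreMatrix,
    weak: float = WEAK_THRESHOLD,
    strong: float = STRONG_THRESHOLD,
) -> Tuple[List[Edge], pd.DataFrame]:
    """Threshold the score matrix into directed follow/avoid edges.

    Off-diagonal cells with score > threshold are ``follow`` edges
    (source = first mouse, target = second); score < -threshold are
    ``avoid``.  The diagonal (repeat-entry tendency) is reported separately.
    """
    if weak <= 0 or strong <= 0:
        raise ConfigError("thresholds must be positive")
    if strong < weak:
        raise ConfigError("strong threshold must be >= weak threshold")
    edges: List[Edge] = []
    n = len(scores.animals)
    for j in range(n):  # first mouse (column)
        for i in range(n):  # second mouse (row)
            if i == j:
                continue
            z = scores.scores[i, j]
            if abs(z) <= weak:
                continue
            edges.append(
                Edge(
                    source=scores.animals[j],
                    target=scores.animals[i],
                    score=float(z),
                    kind="follow" if z > 0 else "avoid",
                    strength="strong" if abs(z) > strong else "weak",
                )
            )
    diagonal = pd.DataFrame(
        {
            "animal_id": scores.animals,
            "self_score": np.diag(scores.scores),
        }
    )
    return edges, diagonal


# ---------------------------------------------------------------------------
# Export


def export_network(
    edges: Sequence[Edge],
    annotations: pd.DataFrame,
    edges_path,
    nodes_path,
) -> None:
    """Write an edge-list TSV (source, target, score, kind, strength) and a
    node TSV (animal_id, preference, weight_g)."""
    required = {"animal_id", "preference", "weight_g"}
    missing = required - set(annotations.columns)
    if missing:
        raise DataError(f"node annotations missing column(s): {sorted(missing)}")
    known = set(annotations["animal_id"])
    for e in edges:
        if e.source not in known or e.target not in known:
            raise DataError(f"edge endpoint not annotated: {e.source} -> {e.target}")
    edge_frame = pd.DataFrame(
        [
            {
                "source": e.source,
                "target": e.target,
                "score": e.score,
                "kind": e.kind,
                "strength": e.strength,
            }
            for e in edges
        ],
        columns=["source", "target", "score", "kind", "strength"],
    )
    edge_frame.to_csv(edges_path, sep="\t", index=False)
    annotations[["animal_id", "preference", "weight_g"]].to_csv(
        nodes_path, sep="\t", index=False
    )


def read_network(edges_path, nodes_path) -> Tuple[List[Edge], pd.DataFrame]:
    """Parse files written by :func:`export_network`."""
    edge_frame = pd.read_csv(edges_path, sep="\t", dtype={"source": str, "target": str})
    edges = [
        Edge(
            source=r.source,
            target=r.target,
            score=float(r.score),
            kind=r.kind,
            strength=r.strength,
        )
        for r in edge_frame.itertuples(index=False)
    ]
    nodes = pd.read_csv(nodes_path, sep="\t", dtype={"animal_id": str})
    return edges, nodes


# ---------------------------------------------------------------------------
# Convenience driver


def score_table(
    table: EventTable,
    n_perm: int = DEFAULT_N_PERM,
    seed: Optional[int] = None,
    min_gap: float = MIN_GAP_S,
    max_gap: float = MAX_GAP_S,
    drop_repeats: bool = False,
) -> ScoreMatrix:
    """Sequences -> pooled permutation scores for a (pre-sliced) table."""
    sequences = build_sequences(table)
    return permutation_scores(
        sequences,
        table.animals,
        n_perm=n_perm,
        seed=seed,
        min_gap=min_gap,
        max_gap=max_gap,
        drop_repeats=drop_repeats,
    )
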