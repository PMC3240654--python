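"""Kimura two-parameter distances and group summaries.

The K2P model corrects the raw mismatch proportion for multiple hits
while keeping transitions (A↔G, C↔T) and transversions on separate
footings, which matters for animal mtDNA where transitions dominate.
With P and Q the transition and transversion proportions over the L
columns usable for a pair (pairwise deletion of gap/'N' columns),

    d = -1/2 ln[(1 - 2P - Q) sqrt(1 - 2Q)]

Distances are kept as substitutions/site internally; percent formatting
belongs to the reporting layer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import Alignment, InputError, _ENCODE_LUT

#: per-column pair classes used by the vectorised bootstrap machinery
MATCH, TRANSITION, TRANSVERSION, EXCLUDED = 0, 1, 2, 3


class UndefinedDistanceError(ValueError):
    """No usable columns remain after pairwise deletion."""


class SaturationError(ValueError):
    """The K2P log argument is non-positive; the distance is undefined."""


@dataclass(frozen=True)
class PairwiseK2P:
    """K2P distance between one pair of aligned sequences."""

    L: int
    s: int
    v: int
    d: float

    @property
    def P(self) -> float:
        return self.s / self.L

    @property
    def Q(self) -> float:
        return self.v / self.L


@dataclass
class DistanceMatrix:
    ids: list[str]
    d: np.ndarray
    L: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.d.shape != (n, n) or self.L.shape != (n, n):
            raise InputError("distance matrix shape does not match ids")

    @property
    def n(self) -> int:
        return len(self.ids)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.ids, columns=self.ids)

    def submatrix(self, indices: list[int]) -> "DistanceMatrix":
        ix = np.asarray(indices)
        return DistanceMatrix(
            ids=[self.ids[i] for i in indices],
            d=self.d[np.ix_(ix, ix)],
            L=self.L[np.ix_(ix, ix)],
        )


@dataclass
class GroupDistanceSummary:
    """Mean pairwise distance within or between population samples.

    The mean is over individual pairs (each individual weighted by its
    multiplicity, not one term per haplotype).  ``se_d`` is a
    site-bootstrap standard error: alignment columns are resampled with
    replacement B times and the mean recomputed on each replicate.
    """

    mode: str
    groups: tuple[str, ...]
    n_pairs: int
    mean_d: float
    se_d: float | None
    replicates: int
    seed: int | None


def k2p_from_counts(s: int, v: int, L: int) -> float:
    """Closed-form K2P distance from transition/transversion counts."""
    if L < 1:
        raise UndefinedDistanceError("no usable sites (L = 0)")
    P = s / L
    Q = v / L
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        raise SaturationError(
            f"K2P undefined at P={P:.4f}, Q={Q:.4f} (saturated pair)"
        )
    if s == 0 and v == 0:
        return 0.0
    return -0.5 * math.log(w1 * math.sqrt(w2))


def _encode(seq: str | np.ndarray) -> np.ndarray:
    if isinstance(seq, np.ndarray):
        return seq
    flat = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    codes = _ENCODE_LUT[flat]
    if (codes < 0).any():
        raise InputError("sequence contains characters outside A,C,G,T,-,N")
    return codes


def _pair_counts(a: np.ndarray, b: np.ndarray) -> tuple[int, int, int]:
    usable = (a < 4) & (b < 4)
    L = int(usable.sum())
    diff = usable & (a != b)
    ts = diff & (((a - b) % 2) == 0)
    s = int(ts.sum())
    v = int(diff.sum()) - s
    return s, v, L


def k2p(seq_a: str | np.ndarray, seq_b: str | np.ndarray) -> PairwiseK2P:
    """K2P distance for one pair, with pairwise deletion of gap/'N' columns."""
    a = _encode(seq_a)
    b = _encode(seq_b)
    if a.size != b.size:
        raise InputError("sequences differ in aligned length")
    s, v, L = _pair_counts(a, b)
    return PairwiseK2P(L=L, s=s, v=v, d=k2p_from_counts(s, v, L))


def distance_matrix(alignment: Alignment) -> DistanceMatrix:
    """All pairwise K2P distances over an alignment."""
    if alignment.n < 2:
        raise InputError("need at least 2 sequences")
    codes = alignment.codes()
    n = alignment.n
    d = np.zeros((n, n))
    L = np.zeros((n, n), dtype=int)
    np.fill_diagonal(L, alignment.length)
    for i in range(n):
        for j in range(i + 1, n):
            s, v, Lij = _pair_counts(codes[i], codes[j])
            try:
                dij = k2p_from_counts(s, v, Lij)
            except (UndefinedDistanceError, SaturationError) as exc:
                raise type(exc)(
                    f"pair ({alignment.ids[i]!r}, {alignment.ids[j]!r}): {exc}"
                ) from exc
            d[i, j] = d[j, i] = dij
            L[i, j] = L[j, i] = Lij
    return DistanceMatrix(ids=list(alignment.ids), d=d, L=L)


def pair_class_matrix(codes: np.ndarray, pairs: list[tuple[int, int]]) -> np.ndarray:
    """(n_pairs, length) matrix of per-column classes for given index pairs.

    Classes: MATCH, TRANSITION, TRANSVERSION, or EXCLUDED (gap/'N' in
    either member).  Site-bootstrap replicates reduce to one integer
    matrix-vector product per class against the column resampling weights.
    """
    out = np.empty((len(pairs), codes.shape[1]), dtype=np.int8)
    for r, (i, j) in enumerate(pairs):
        a, b = codes[i], codes[j]
        usable = (a < 4) & (b < 4)
        diff = usable & (a != b)
        ts = diff & (((a - b) % 2) == 0)
        row = np.full(codes.shape[1], EXCLUDED, dtype=np.int8)
        row[usable] = MATCH
        row[ts] = TRANSITION
        row[diff & ~ts] = TRANSVERSION
        out[r] = row
    return out


def bootstrap_pair_distances(
    class_matrix: np.ndarray, weights: np.ndarray
) -> np.ndarray:
    """K2P distance per pair on a column-resampled pseudo-alignment.

    ``weights[j]`` is how many times column j was drawn.  Raises
    :class:`UndefinedDistanceError` / :class:`SaturationError` exactly as
    the per-pair path does.
    """
    s = (class_matrix == TRANSITION).astype(np.int64) @ weights
    v = (class_matrix == TRANSVERSION).astype(np.int64) @ weights
    m = (class_matrix == MATCH).astype(np.int64) @ weights
    L = s + v + m
    if (L < 1).any():
        raise UndefinedDistanceError("a resampled pair has no usable sites")
    P = s / L
    Q = v / L
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if (w1 <= 0).any() or (w2 <= 0).any():
        raise SaturationError("a resampled pair is saturated")
    d = -0.5 * np.log(w1 * np.sqrt(w2))
    d[(s == 0) & (v == 0)] = 0.0
    return d


def _site_bootstrap_se(
    codes: np.ndarray,
    pairs: list[tuple[int, int]],
    B: int,
    seed: int,
    max_redraw_frac: float = 0.1,
) -> float:
    rng = np.random.default_rng(seed)
    class_matrix = pair_class_matrix(codes, pairs)
    length = codes.shape[1]
    p = np.full(length, 1.0 / length)
    means = np.empty(B)
    redraws = 0
    b = 0
    while b < B:
        weights = rng.multinomial(length, p)
        try:
            means[b] = float(bootstrap_pair_distances(class_matrix, weights).mean())
        except (UndefinedDistanceError, SaturationError):
            redraws += 1
            if redraws > max_redraw_frac * B:
                raise
            continue
        b += 1
    return float(means.std(ddof=1)) if B > 1 else 0.0


def _pairs_for_mode(
    alignment: Alignment, mode: str, group: str | None, groups: tuple[str, str] | None
) -> tuple[list[tuple[int, int]], tuple[str, ...]]:
    if mode == "within":
        if group is None:
            raise InputError("within-mode needs group=")
        idx = alignment.group_indices(group)
        if len(idx) < 2:
            raise InputError(f"group {group!r} has fewer than 2 members")
        return [(i, j) for a, i in enumerate(idx) for j in idx[a + 1 :]], (group,)
    if mode == "between":
        if groups is None:
            raise InputError("between-mode needs groups=(a, b)")
        ga, gb = groups
        idx_a = alignment.group_indices(ga)
        idx_b = alignment.group_indices(gb)
        if not idx_a or not idx_b:
            raise InputError(f"empty group among {groups!r}")
        return [(i, j) for i in idx_a for j in idx_b], (ga, gb)
    raise InputError(f"unknown mode {mode!r}")


def group_mean(
    alignment: Alignment,
    mode: str,
    *,
    group: str | None = None,
    groups: tuple[str, str] | None = None,
    bootstrap: int = 1000,
    seed: int = 0,
    matrix: DistanceMatrix | None = None,
) -> GroupDistanceSummary:
    """Mean pairwise K2P distance within a group or between two groups.

    ``bootstrap=0`` skips the (seeded) site-bootstrap standard error.
    A precomputed :func:`distance_matrix` may be passed to avoid
    recomputation; its ids must match the alignment.
    """
    pairs, group_names = _pairs_for_mode(alignment, mode, group, groups)
    if matrix is None:
        matrix = distance_matrix(alignment)
    elif matrix.ids != alignment.ids:
        raise InputError("matrix ids do not match alignment")
    mean_d = float(np.mean([matrix.d[i, j] for i, j in pairs]))
    se = None
    if bootstrap > 0:
        se = _site_bootstrap_se(alignment.codes(), pairs, bootstrap, seed)
    return GroupDistanceSummary(
        mode=mode,
        groups=group_names,
        n_pairs=len(pairs),
        mean_d=mean_d,
        se_d=se,
        replicates=bootstrap,
        seed=seed if bootstrap > 0 else None,
    )


def outgroup_distance(
    alignment: Alignment,
    outgroup_seq: str,
    *,
    group: str | None = None,
    outgroup_id: str = "outgroup",
    bootstrap: int = 1000,
    seed: int = 0,
) -> GroupDistanceSummary:
    """Mean K2P distance from an outgroup sequence to a group's members.

    ``group=None`` averages over every individual in the alignment.
    The outgroup must be aligned to the same columns.
    """
    if len(outgroup_seq) != alignment.length:
        raise InputError("outgroup sequence length does not match alignment")
    member_idx = (
        list(range(alignment.n)) if group is None else alignment.group_indices(group)
    )
    if not member_idx:
        raise InputError(f"group {group!r} has no members")
    combined = Alignment(
        ids=[alignment.ids[i] for i in member_idx] + [outgroup_id],
        seqs=[alignment.seqs[i] for i in member_idx] + [outgroup_seq.upper()],
        group=[alignment.group[i] for i in member_idx] + [None],
    )
    out_pos = combined.n - 1
    pairs = [(i, out_pos) for i in range(len(member_idx))]
    codes = combined.codes()
    dists = [
        k2p(codes[i], codes[j]).d for i, j in pairs
    ]
    se = None
    if bootstrap > 0:
        se = _site_bootstrap_se(codes, pairs, bootstrap, seed)
    return GroupDistanceSummary(
        mode="between",
        groups=(group if group is not None else "all", outgroup_id),
        n_pairs=len(pairs),
        mean_d=float(np.mean(dists)),
        se_d=se,
        replicates=bootstrap,
        seed=seed if bootstrap > 0 else None,
    )
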