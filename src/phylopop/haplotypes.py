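"""Haplotype collapsing, site classification and diagnostic substitutions.

These are the alignment summaries a population survey reports before any
model-based distance: how many distinct haplotypes the sample carries,
which columns vary (and whether by substitution or indel), which columns
are parsimony informative, Nei's haplotype diversity, and which columns
diagnostically separate two populations (fixed differences, plus
"nearly fixed" columns that become diagnostic after excusing a small
number of exception individuals).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np

from .io import Alignment, GAP_CODE, InputError, N_CODE


@dataclass
class Haplotype:
    sequence: str
    member_ids: list[str]

    @property
    def count(self) -> int:
        return len(self.member_ids)


@dataclass
class SiteClassification:
    """Per-column classification of an alignment.

    ``variable`` marks columns with ≥2 observed states ('N' never counts
    as a state; a gap does).  ``contains_gap`` marks variable columns where
    one of the states is a gap (indel columns).  ``parsimony_informative``
    marks columns with ≥2 states each carried by ≥2 individuals.
    """

    variable: np.ndarray
    contains_gap: np.ndarray
    parsimony_informative: np.ndarray

    @property
    def length(self) -> int:
        return self.variable.size

    @property
    def n_variable(self) -> int:
        return int(self.variable.sum())

    @property
    def n_indel(self) -> int:
        return int(self.contains_gap.sum())

    @property
    def n_parsimony_informative(self) -> int:
        return int(self.parsimony_informative.sum())

    def variable_columns(self) -> list[int]:
        """1-based indices of variable columns."""
        return [int(i) + 1 for i in np.flatnonzero(self.variable)]


@dataclass
class DiversityResult:
    n: int
    k: int
    freqs: np.ndarray
    h: float


@dataclass
class DiagnosticSites:
    """Columns separating two groups, 1-based, sorted ascending.

    ``fixed``: the groups share no state at the column.
    ``nearly_fixed``: not fixed, but the state sets become disjoint (and
    stay non-empty) after removing at most ``tolerance`` individuals in
    total.  ``states_by_group`` maps each listed column to the observed
    state multisets ``{group: {state: count}}``.
    """

    group_a: str
    group_b: str
    tolerance: int
    fixed: list[int]
    nearly_fixed: list[int]
    states_by_group: dict[int, dict[str, dict[str, int]]]


def collapse_haplotypes(alignment: Alignment) -> list[Haplotype]:
    """Group individuals by exact full-sequence identity.

    Gaps are ordinary states: sequences differing only at an indel column
    are distinct haplotypes.  Haplotypes are returned in order of first
    occurrence.
    """
    seen: dict[str, Haplotype] = {}
    for sid, seq in zip(alignment.ids, alignment.seqs):
        hap = seen.get(seq)
        if hap is None:
            seen[seq] = Haplotype(sequence=seq, member_ids=[sid])
        else:
            hap.member_ids.append(sid)
    return list(seen.values())


def classify_sites(alignment: Alignment) -> SiteClassification:
    codes = alignment.codes()
    n, length = codes.shape
    variable = np.zeros(length, dtype=bool)
    contains_gap = np.zeros(length, dtype=bool)
    informative = np.zeros(length, dtype=bool)
    for j in range(length):
        col = codes[:, j]
        col = col[col != N_CODE]
        states, counts = np.unique(col, return_counts=True)
        if states.size >= 2:
            variable[j] = True
            contains_gap[j] = bool((states == GAP_CODE).any())
            informative[j] = int((counts >= 2).sum()) >= 2
    return SiteClassification(variable, contains_gap, informative)


def haplotype_diversity(counts) -> DiversityResult:
    """Nei's unbiased haplotype diversity h = n(1 − Σ p_i²)/(n − 1).

    ``h`` is the small-sample-corrected probability that two individuals
    drawn without replacement carry different haplotypes: 0 for a
    monomorphic sample, 1 when every individual is unique.
    """
    counts = np.asarray(list(counts), dtype=float)
    if counts.size == 0 or (counts < 1).any():
        raise InputError("haplotype counts must all be >= 1")
    n = counts.sum()
    if n < 2:
        raise InputError("haplotype diversity needs at least 2 individuals")
    p = counts / n
    h = n / (n - 1.0) * (1.0 - float(p @ p))
    return DiversityResult(n=int(n), k=counts.size, freqs=p, h=h)


def _min_exceptions(count_a: dict[int, int], count_b: dict[int, int]) -> int | None:
    """Fewest individuals whose removal makes the state sets disjoint.

    For every state shared by both groups, all its carriers on one side
    must go; sides are chosen to minimise the total while leaving both
    groups with at least one remaining individual.  Returns None when no
    assignment keeps both groups non-empty.
    """
    shared = sorted(set(count_a) & set(count_b))
    if not shared:
        return 0
    best: int | None = None
    for sides in product((0, 1), repeat=len(shared)):
        rem_a = dict(count_a)
        rem_b = dict(count_b)
        cost = 0
        for state, side in zip(shared, sides):
            if side == 0:
                cost += rem_a.pop(state)
            else:
                cost += rem_b.pop(state)
        if rem_a and rem_b and (best is None or cost < best):
            best = cost
    return best


def diagnostic_sites(
    alignment: Alignment,
    group_a: str,
    group_b: str,
    tolerance: int = 2,
) -> DiagnosticSites:
    """Find fixed and nearly fixed differences between two populations.

    'N' is excluded from a column's state set so missing data cannot
    create spurious diagnoses; gaps are ordinary states.  ``tolerance``
    is the maximum total number of exception individuals a nearly fixed
    column may excuse.
    """
    idx_a = alignment.group_indices(group_a)
    idx_b = alignment.group_indices(group_b)
    if not idx_a or not idx_b:
        raise InputError(f"empty group among {group_a!r}, {group_b!r}")
    if set(idx_a) & set(idx_b):
        raise InputError("groups overlap")
    if tolerance < 0:
        raise InputError("tolerance must be >= 0")

    codes = alignment.codes()
    fixed: list[int] = []
    nearly: list[int] = []
    states_by_group: dict[int, dict[str, dict[str, int]]] = {}
    from .io import DECODE

    for j in range(alignment.length):
        col_a = codes[idx_a, j]
        col_b = codes[idx_b, j]
        col_a = col_a[col_a != N_CODE]
        col_b = col_b[col_b != N_CODE]
        if col_a.size == 0 or col_b.size == 0:
            continue
        count_a = {int(s): int(c) for s, c in zip(*np.unique(col_a, return_counts=True))}
        count_b = {int(s): int(c) for s, c in zip(*np.unique(col_b, return_counts=True))}
        removals = _min_exceptions(count_a, count_b)
        site = j + 1
        if removals == 0 and not (set(count_a) & set(count_b)):
            fixed.append(site)
        elif removals is not None and 0 < removals <= tolerance:
            nearly.append(site)
        else:
            continue
        states_by_group[site] = {
            group_a: {DECODE[s]: c for s, c in sorted(count_a.items())},
            group_b: {DECODE[s]: c for s, c in sorted(count_b.items())},
        }
    return DiagnosticSites(
        group_a=group_a,
        group_b=group_b,
        tolerance=tolerance,
        fixed=fixed,
        nearly_fixed=nearly,
        states_by_group=states_by_group,
    )
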