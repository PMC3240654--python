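"""Reading and writing aligned mtDNA data.

Two input dialects are supported: ordinary aligned FASTA, and the compact
polymorphic-site haplotype table used to publish short mtDNA surveys, in
which each haplotype is a row of states at the variable columns only
('.' = identical to the reference row, '-' = alignment gap) together with
per-locality individual counts.  A haplotype table plus a locality→group
map expands losslessly into a per-individual alignment, which is the
common currency of every downstream module.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

ALPHABET = frozenset("ACGTN-")

#: integer codes used throughout for vectorised column arithmetic
CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "-": 4, "N": 5}
DECODE = "ACGT-N"
GAP_CODE = CODE["-"]
N_CODE = CODE["N"]

_ENCODE_LUT = np.full(256, -1, dtype=np.int8)
for _c, _i in CODE.items():
    _ENCODE_LUT[ord(_c)] = _i


class AlignmentError(ValueError):
    """Sequences that should form an alignment do not (e.g. ragged lengths)."""


class InputError(ValueError):
    """Malformed or inconsistent user input (duplicate ids, empty file...)."""


class FormatError(ValueError):
    """A haplotype table violates the documented dialect."""


class MappingError(KeyError):
    """A locality has no group assignment."""


@dataclass
class Alignment:
    """A multiple sequence alignment with optional per-individual metadata.

    Attributes
    ----------
    ids
        Unique individual identifiers, in input order.
    seqs
        Equal-length uppercase strings over ``A C G T - N``.
    locality, group
        Optional per-individual labels (``None`` where unknown).  ``group``
        carries the population assignment (e.g. ``"EP"`` vs ``"CP+WP"``)
        used by the diagnostic-site and distance summaries.
    """

    ids: list[str]
    seqs: list[str]
    locality: list[str | None] = field(default=None)  # type: ignore[assignment]
    group: list[str | None] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.seqs):
            raise AlignmentError("ids and seqs differ in length")
        if not self.ids:
            raise InputError("empty alignment")
        if len(set(self.ids)) != len(self.ids):
            dupes = sorted({i for i in self.ids if self.ids.count(i) > 1})
            raise InputError(f"duplicate sequence ids: {dupes}")
        lengths = {len(s) for s in self.seqs}
        if len(lengths) != 1:
            raise AlignmentError(f"unequal sequence lengths: {sorted(lengths)}")
        for sid, s in zip(self.ids, self.seqs):
            bad = set(s) - ALPHABET
            if bad:
                raise AlignmentError(f"invalid characters {sorted(bad)} in {sid!r}")
        if self.locality is None:
            self.locality = [None] * len(self.ids)
        if self.group is None:
            self.group = [None] * len(self.ids)
        if len(self.locality) != len(self.ids) or len(self.group) != len(self.ids):
            raise AlignmentError("metadata length does not match number of sequences")

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def length(self) -> int:
        return len(self.seqs[0])

    def codes(self) -> np.ndarray:
        """(n, length) int8 matrix of state codes (see :data:`CODE`)."""
        flat = np.frombuffer("".join(self.seqs).encode(), dtype=np.uint8)
        return _ENCODE_LUT[flat].reshape(self.n, self.length)

    def group_indices(self, label: str) -> list[int]:
        return [i for i, g in enumerate(self.group) if g == label]

    def group_labels(self) -> list[str]:
        """Distinct group labels in first-occurrence order (``None`` dropped)."""
        seen: dict[str, None] = {}
        for g in self.group:
            if g is not None:
                seen.setdefault(g, None)
        return list(seen)

    def subset(self, indices: list[int]) -> "Alignment":
        return Alignment(
            ids=[self.ids[i] for i in indices],
            seqs=[self.seqs[i] for i in indices],
            locality=[self.locality[i] for i in indices],
            group=[self.group[i] for i in indices],
        )

    def with_groups(self, mapping: dict[str, str]) -> "Alignment":
        """Attach group labels keyed by sequence id."""
        missing = [i for i in self.ids if i not in mapping]
        if missing:
            raise MappingError(f"no group for ids: {missing}")
        return Alignment(
            ids=list(self.ids),
            seqs=list(self.seqs),
            locality=list(self.locality),
            group=[mapping[i] for i in self.ids],
        )


@dataclass
class HaplotypeTable:
    """A polymorphic-site haplotype table (dot-notation dialect).

    ``reference_pattern`` is the first row spelled out in full; later
    ``patterns`` keep '.' where they match it.  ``counts`` is the dense
    haplotype × locality matrix of individuals carrying each haplotype.
    ``total_length`` is the declared length of the underlying alignment,
    of which only the variable columns are printed.
    """

    names: list[str]
    reference_pattern: str
    patterns: list[str]
    counts: pd.DataFrame
    total_length: int
    positions: list[int] | None = None

    def __post_init__(self) -> None:
        if "." in self.reference_pattern:
            raise FormatError("reference pattern may not contain '.'")
        width = len(self.reference_pattern)
        for name, pat in zip(self.names, self.patterns):
            if len(pat) != width:
                raise FormatError(
                    f"pattern for {name!r} has length {len(pat)}, expected {width}"
                )
        if (self.counts.to_numpy() < 0).any():
            raise FormatError("negative haplotype count")
        if (self.counts.sum(axis=1) == 0).any():
            zero = self.counts.index[self.counts.sum(axis=1) == 0].tolist()
            raise FormatError(f"haplotypes with no individuals: {zero}")
        if self.total_length < width:
            raise FormatError("total_length shorter than the printed pattern")

    @property
    def n_haplotypes(self) -> int:
        return len(self.names)

    @property
    def n_individuals(self) -> int:
        return int(self.counts.to_numpy().sum())

    @property
    def localities(self) -> list[str]:
        return list(self.counts.columns)

    def resolved_patterns(self) -> list[str]:
        """Patterns with '.' replaced by the reference state."""
        out = []
        for pat in self.patterns:
            out.append(
                "".join(r if c == "." else c for c, r in zip(pat, self.reference_pattern))
            )
        return out


def read_fasta(path: str | Path) -> Alignment:
    """Read an aligned FASTA file (groups unset).

    Sequences are uppercased and RNA ``U`` is normalised to ``T``.
    Ragged record lengths raise :class:`AlignmentError`; duplicate ids or
    an empty file raise :class:`InputError`.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise InputError(f"no FASTA records in {path}")
    ids = [r.id for r in records]
    seqs = [str(r.seq).upper().replace("U", "T") for r in records]
    return Alignment(ids=ids, seqs=seqs)


def write_fasta(alignment: Alignment, path: str | Path, wrap: int = 70) -> None:
    """Write an alignment as wrapped FASTA; round-trips with :func:`read_fasta`."""
    records = [
        SeqRecord(Seq(s), id=i, description="") for i, s in zip(alignment.ids, alignment.seqs)
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=wrap)
        writer.write_file(records)


def parse_haplotype_table(path: str | Path) -> HaplotypeTable:
    """Parse a dot-notation polymorphic-site haplotype table.

    Dialect: optional ``#`` comment lines (``#length: <int>`` declares the
    full alignment length, ``#positions: <ints>`` optional 1-based site
    coordinates, metadata only); then a header line
    ``type<TAB>pattern<TAB><loc1><TAB><loc2>...``; the first data row is the
    reference with its pattern in full; later rows use ``.`` for identity
    and ``-`` for a gap.  Blank counts mean zero.
    """
    total_length: int | None = None
    positions: list[int] | None = None
    header: list[str] | None = None
    rows: list[list[str]] = []
    with open(path) as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if body.lower().startswith("length:"):
                    total_length = int(body.split(":", 1)[1])
                elif body.lower().startswith("positions:"):
                    positions = [int(x) for x in body.split(":", 1)[1].split()]
                continue
            cells = line.split("\t")
            if header is None:
                header = cells
                if len(header) < 3 or header[0] != "type" or header[1] != "pattern":
                    raise FormatError(
                        "header must be 'type<TAB>pattern<TAB><locality>...'"
                    )
                continue
            rows.append(cells)
    if header is None or not rows:
        raise FormatError(f"no haplotype rows in {path}")

    localities = header[2:]
    names, patterns, count_rows = [], [], []
    for cells in rows:
        if len(cells) < 2:
            raise FormatError(f"short row: {cells!r}")
        name, pattern = cells[0], cells[1]
        raw_counts = cells[2:]
        if len(raw_counts) > len(localities):
            raise FormatError(f"row {name!r} has more counts than localities")
        raw_counts += [""] * (len(localities) - len(raw_counts))
        counts = []
        for loc, cell in zip(localities, raw_counts):
            cell = cell.strip()
            if cell == "":
                counts.append(0)
                continue
            try:
                counts.append(int(cell))
            except ValueError as exc:
                raise FormatError(
                    f"non-integer count {cell!r} for {name!r} at {loc}"
                ) from exc
        bad = set(pattern) - set("ACGT-.")
        if bad:
            raise FormatError(f"invalid pattern characters {sorted(bad)} in {name!r}")
        names.append(name)
        patterns.append(pattern)
        count_rows.append(counts)

    reference = patterns[0]
    counts_df = pd.DataFrame(count_rows, index=names, columns=localities, dtype=int)
    return HaplotypeTable(
        names=names,
        reference_pattern=reference,
        patterns=patterns,
        counts=counts_df,
        total_length=total_length if total_length is not None else len(reference),
        positions=positions,
    )


def read_group_map(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV mapping (locality or sequence id) → group."""
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(f"group map rows need 2 columns, got {parts!r}")
            key, group = parts[0].strip(), parts[1].strip()
            if key in mapping and mapping[key] != group:
                raise FormatError(f"conflicting group for {key!r}")
            mapping[key] = group
    if not mapping:
        raise InputError(f"empty group map {path}")
    return mapping


def expand_table(
    table: HaplotypeTable,
    groups: dict[str, str],
    filler: str = "A",
) -> Alignment:
    """Expand a haplotype table into one sequence per sampled individual.

    The printed variable columns occupy the first columns of the
    reconstruction and a monomorphic run of ``filler`` pads the alignment
    to ``total_length``.  Identical invariant columns cancel from every
    pairwise comparison, so all distance and haplotype statistics are
    independent of both the filler base and the placement (asserted by the
    test suite).  Individuals are named ``<type>_<locality>_<k>`` in table
    row order, then locality column order.
    """
    if filler not in "ACGT":
        raise InputError(f"filler must be a plain base, got {filler!r}")
    missing = [loc for loc in table.localities if loc not in groups]
    if missing:
        raise MappingError(f"localities missing from group map: {missing}")
    pad = filler * (table.total_length - len(table.reference_pattern))
    ids, seqs, locs, grps = [], [], [], []
    resolved = table.resolved_patterns()
    for name, seq_core in zip(table.names, resolved):
        seq = seq_core + pad
        for loc in table.localities:
            for k in range(int(table.counts.at[name, loc])):
                ids.append(f"{name}_{loc}_{k + 1}")
                seqs.append(seq)
                locs.append(loc)
                grps.append(groups[loc])
    return Alignment(ids=ids, seqs=seqs, locality=locs, group=grps)


def write_tsv(frame: pd.DataFrame, path: str | Path, index_label: str | None = None) -> None:
    """Write a DataFrame as TSV (used for matrices and reports)."""
    frame.to_csv(path, sep="\t", index_label=index_label)
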