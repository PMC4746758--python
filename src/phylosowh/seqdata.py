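"""Multilocus alignment curation: reading, concatenation, occupancy profiling,
column filtering and partition bookkeeping.

A *supermatrix* is assembled from per-locus multiple sequence alignments by
concatenating the locus blocks side by side; any isolate that lacks a locus is
padded with the missing character ``?`` across that block.  Column occupancy
("completeness") is the fraction of isolates with a determined character in a
column; intron-like blocks that are mostly gap are removed by thresholding
this fraction (default: retain a column iff at least 10 % of isolates have
data, i.e. columns with *more than* 90 % missing data are excluded).

Missing-character convention: ``-``, ``?``, ``N`` and ``X`` count as missing;
all other IUPAC ambiguity codes (R, Y, S, W, K, M, B, D, H, V) count as
present, since the occupancy filter targets unalignable gap regions rather
than polymorphic base calls.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field, replace

import numpy as np
from Bio import AlignIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import AlignmentError, DataError, UsageError

#: nucleotide bitmasks (A=1, C=2, G=4, T=8) used by the likelihood engine
CHAR_MASKS: dict[str, int] = {
    "A": 1, "C": 2, "G": 4, "T": 8, "U": 8,
    "R": 1 | 4, "Y": 2 | 8, "S": 2 | 4, "W": 1 | 8,
    "K": 4 | 8, "M": 1 | 2,
    "B": 2 | 4 | 8, "D": 1 | 4 | 8, "H": 1 | 2 | 8, "V": 1 | 2 | 4,
    "N": 15, "X": 15, "?": 15, "-": 15,
}

MISSING_CHARS = frozenset("-?NX")
VALID_CHARS = frozenset(CHAR_MASKS)

MISSING = "?"


def _validate_chars(seq: str, where: str) -> None:
    bad = set(seq) - VALID_CHARS
    if bad:
        raise AlignmentError(f"unknown characters {sorted(bad)} in {where}")


@dataclass
class LocusAlignment:
    """One locus: equal-length sequences keyed by isolate id."""

    locus_name: str
    sequences: dict[str, str]
    coding: bool = False

    def __post_init__(self) -> None:
        if not self.sequences:
            raise AlignmentError(f"locus {self.locus_name!r} has no sequences")
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) != 1:
            raise AlignmentError(
                f"locus {self.locus_name!r}: ragged sequence lengths {sorted(lengths)}"
            )
        self.sequences = {k: v.upper() for k, v in self.sequences.items()}
        for iso, seq in self.sequences.items():
            _validate_chars(seq, f"locus {self.locus_name!r}, isolate {iso!r}")

    @property
    def length(self) -> int:
        return len(next(iter(self.sequences.values())))

    @property
    def isolates(self) -> list[str]:
        return list(self.sequences)


@dataclass
class Partition:
    """A named set of alignment columns (0-based internally)."""

    name: str
    indices: np.ndarray  # sorted 0-based column indices
    kind: str = "ribosomal"  # ribosomal | coding | codon1 | codon2 | codon3 | intron

    KINDS = ("ribosomal", "coding", "codon1", "codon2", "codon3", "intron")

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=np.int64)
        self.indices.sort()
        if self.kind not in self.KINDS:
            raise UsageError(f"unknown partition kind {self.kind!r}")
        if len(self.indices) and len(np.unique(self.indices)) != len(self.indices):
            raise DataError(f"partition {self.name!r} has duplicate columns")

    def __len__(self) -> int:
        return len(self.indices)


@dataclass
class PartitionScheme:
    """Disjoint named column sets covering the whole alignment."""

    partitions: list[Partition]

    def validate(self, n_columns: int) -> None:
        seen = np.concatenate([p.indices for p in self.partitions]) if self.partitions else np.array([], int)
        if len(seen) != n_columns or len(np.unique(seen)) != len(seen) or (
            len(seen) and (seen.min() < 0 or seen.max() >= n_columns)
        ):
            raise DataError("partitions are not a disjoint cover of the columns")

    def __iter__(self):
        return iter(self.partitions)

    def __len__(self) -> int:
        return len(self.partitions)

    def by_name(self, name: str) -> Partition:
        for p in self.partitions:
            if p.name == name:
                return p
        raise UsageError(f"no partition named {name!r}")

    def site_to_partition(self, n_columns: int) -> np.ndarray:
        """Per-column partition index."""
        out = np.full(n_columns, -1, dtype=np.int64)
        for i, p in enumerate(self.partitions):
            out[p.indices] = i
        return out


@dataclass
class MultiLocusAlignment:
    """Concatenated supermatrix with per-column locus provenance."""

    isolates: list[str]
    matrix: np.ndarray  # (n_isolates, L) of single characters, dtype '<U1'
    origin_locus: np.ndarray  # per-column locus name
    origin_pos: np.ndarray  # per-column 0-based position within its locus

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype="<U1")
        if self.matrix.shape[0] != len(self.isolates):
            raise DataError("matrix row count does not match isolate list")
        if len(self.origin_locus) != self.matrix.shape[1] or len(self.origin_pos) != self.matrix.shape[1]:
            raise DataError("column_origin does not cover every column exactly once")
        if len(set(self.isolates)) != len(self.isolates):
            raise DataError("duplicate isolate ids")

    @property
    def n_isolates(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_columns(self) -> int:
        return self.matrix.shape[1]

    def sequence(self, isolate: str) -> str:
        return "".join(self.matrix[self.isolates.index(isolate)])

    def presence(self) -> np.ndarray:
        """Boolean (isolate, column) matrix: True where a character is determined."""
        miss = np.isin(self.matrix, list(MISSING_CHARS))
        return ~miss

    def masks(self) -> np.ndarray:
        """uint8 bitmask matrix for the likelihood engine."""
        lut = np.zeros(128, dtype=np.uint8)
        for ch, m in CHAR_MASKS.items():
            lut[ord(ch)] = m
        codes = self.matrix.view(np.uint32).reshape(self.matrix.shape)
        return lut[codes]


@dataclass
class CompletenessProfile:
    """Per-column presence fractions plus per-isolate per-locus presence flags."""

    column_presence: np.ndarray  # (L,) fractions in [0, 1]
    isolate_locus_presence: dict[str, dict[str, bool]]

    def to_table(self) -> str:
        lines = ["column_index\tpresence_fraction"]
        for i, f in enumerate(self.column_presence, start=1):
            lines.append(f"{i}\t{f:.6g}")
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# I/O

def read_alignment(path, format: str = "fasta", locus_name: str | None = None,
                   coding: bool = False) -> LocusAlignment:
    """Read one aligned locus from FASTA or relaxed sequential PHYLIP."""
    if format not in ("fasta", "phylip"):
        raise UsageError(f"unsupported format {format!r}")
    schema = "fasta" if format == "fasta" else "phylip-relaxed"
    try:
        msa = AlignIO.read(str(path), schema)
    except ValueError as exc:
        raise AlignmentError(f"could not parse {path}: {exc}") from exc
    ids = [rec.id for rec in msa]
    if len(set(ids)) != len(ids):
        raise DataError(f"duplicate sequence ids in {path}")
    name = locus_name
    if name is None:
        name = re.sub(r"\.(fasta|fa|fna|phy|phylip)$", "", str(path).rsplit("/", 1)[-1])
    return LocusAlignment(name, {rec.id: str(rec.seq) for rec in msa}, coding=coding)


def write_alignment(aln: LocusAlignment | MultiLocusAlignment, path,
                    format: str = "fasta") -> None:
    """Write a locus or supermatrix to FASTA or relaxed sequential PHYLIP."""
    if format not in ("fasta", "phylip"):
        raise UsageError(f"unsupported format {format!r}")
    if isinstance(aln, MultiLocusAlignment):
        items = [(iso, "".join(row)) for iso, row in zip(aln.isolates, aln.matrix)]
    else:
        items = list(aln.sequences.items())
    msa = MultipleSeqAlignment(
        SeqRecord(Seq(seq), id=iso, description="") for iso, seq in items
    )
    schema = "fasta" if format == "fasta" else "phylip-relaxed"
    with open(path, "w") as fh:
        AlignIO.write(msa, fh, schema)


def _runs(indices: np.ndarray) -> list[tuple[int, int, int]]:
    """Greedy decomposition of a sorted index array into (start, stop, step) runs."""
    out = []
    i, n = 0, len(indices)
    while i < n:
        if i + 1 < n:
            step = int(indices[i + 1] - indices[i])
            j = i + 1
            while j + 1 < n and indices[j + 1] - indices[j] == step:
                j += 1
            if j == i + 1 and step != 1:
                out.append((int(indices[i]), int(indices[i]), 1))
                i += 1
                continue
            out.append((int(indices[i]), int(indices[j]), step))
            i = j + 1
        else:
            out.append((int(indices[i]), int(indices[i]), 1))
            i += 1
    return out


def write_partition_file(scheme: PartitionScheme, path) -> None:
    """RAxML-style partition file; columns are written 1-based."""
    with open(path, "w") as fh:
        for p in scheme:
            parts = []
            for a, b, step in _runs(p.indices):
                rng = f"{a + 1}-{b + 1}" if b > a else f"{a + 1}"
                if step == 3:
                    rng += "\\3"
                elif step != 1:  # uncommon stride: fall back to singletons
                    parts.extend(f"{x + 1}" for x in range(a, b + 1, step))
                    continue
                parts.append(rng)
            fh.write(f"DNA, {p.name} = {', '.join(parts)}\n")


_PART_RE = re.compile(r"^\s*DNA\s*,\s*(\S+)\s*=\s*(.+)$", re.IGNORECASE)


def read_partition_file(path) -> PartitionScheme:
    """Parse a RAxML-style partition file ("DNA, name = 1-500\\3" dialect)."""
    partitions = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            m = _PART_RE.match(line)
            if not m:
                raise DataError(f"unparseable partition line: {line!r}")
            name, spec = m.group(1), m.group(2)
            idx: list[int] = []
            for chunk in spec.split(","):
                chunk = chunk.strip()
                step = 1
                if "\\" in chunk:
                    chunk, stepstr = chunk.split("\\")
                    step = int(stepstr)
                if "-" in chunk:
                    a, b = chunk.split("-")
                    idx.extend(range(int(a) - 1, int(b), step))
                else:
                    idx.append(int(chunk) - 1)
            kind = "ribosomal"
            lname = name.lower()
            for k in ("codon1", "codon2", "codon3", "intron", "coding"):
                if k in lname:
                    kind = k
                    break
            partitions.append(Partition(name, np.array(idx), kind=kind))
    return PartitionScheme(partitions)


# ---------------------------------------------------------------------------
# Core operations

def concatenate(loci: list[LocusAlignment]) -> tuple[MultiLocusAlignment, PartitionScheme]:
    """Concatenate per-locus alignments into a supermatrix.

    The isolate set is the union over loci (sorted for determinism); an
    isolate absent from a locus receives ``?`` over that locus's columns.
    One base partition is created per locus, in input order.
    """
    if not loci:
        raise UsageError("concatenate requires at least one locus")
    names = [lo.locus_name for lo in loci]
    if len(set(names)) != len(names):
        raise DataError("duplicate locus names")
    isolates = sorted(set().union(*(lo.sequences.keys() for lo in loci)))
    total = sum(lo.length for lo in loci)
    matrix = np.full((len(isolates), total), MISSING, dtype="<U1")
    origin_locus = np.empty(total, dtype=object)
    origin_pos = np.empty(total, dtype=np.int64)
    partitions = []
    offset = 0
    for lo in loci:
        width = lo.length
        cols = np.arange(offset, offset + width)
        for iso, seq in lo.sequences.items():
            matrix[isolates.index(iso), offset:offset + width] = list(seq)
        origin_locus[cols] = lo.locus_name
        origin_pos[cols] = np.arange(width)
        partitions.append(Partition(lo.locus_name, cols,
                                    kind="coding" if lo.coding else "ribosomal"))
        offset += width
    aln = MultiLocusAlignment(isolates, matrix, origin_locus, origin_pos)
    return aln, PartitionScheme(partitions)


def completeness_profile(aln: MultiLocusAlignment) -> CompletenessProfile:
    """Per-column presence fraction and per-isolate per-locus presence flags."""
    if aln.n_columns == 0 or aln.n_isolates == 0:
        raise UsageError("empty alignment")
    pres = aln.presence()
    col_frac = pres.mean(axis=0)
    per_locus: dict[str, dict[str, bool]] = {}
    for locus in dict.fromkeys(aln.origin_locus):
        cols = aln.origin_locus == locus
        has = pres[:, cols].any(axis=1)
        per_locus[locus] = dict(zip(aln.isolates, has.tolist()))
    return CompletenessProfile(col_frac, per_locus)


def filter_columns(
    aln: MultiLocusAlignment,
    scheme: PartitionScheme,
    cutoff: float = 0.10,
) -> tuple[MultiLocusAlignment, PartitionScheme, np.ndarray]:
    """Remove low-occupancy columns.

    A column is retained iff its presence fraction is >= ``cutoff`` (strict
    exclusion of columns with more than ``1 - cutoff`` missing data).  Returns
    the filtered alignment, the partition scheme remapped through the
    surviving-column index map, and the array of retained original column
    indices (0-based).  Partitions left empty are dropped.
    """
    if not 0.0 <= cutoff <= 1.0:
        raise UsageError("cutoff must lie in [0, 1]")
    frac = aln.presence().mean(axis=0)
    keep = frac >= cutoff
    kept_idx = np.flatnonzero(keep)
    if len(kept_idx) == 0:
        raise DataError("occupancy filter removed every column")
    new_of_old = np.full(aln.n_columns, -1, dtype=np.int64)
    new_of_old[kept_idx] = np.arange(len(kept_idx))
    out = MultiLocusAlignment(
        list(aln.isolates),
        aln.matrix[:, kept_idx],
        aln.origin_locus[kept_idx],
        aln.origin_pos[kept_idx],
    )
    new_parts = []
    for p in scheme:
        surv = new_of_old[p.indices]
        surv = surv[surv >= 0]
        if len(surv):
            new_parts.append(Partition(p.name, surv, kind=p.kind))
    return out, PartitionScheme(new_parts), kept_idx


def codon_subpartition(
    scheme: PartitionScheme,
    locus: str,
    frame_offset: int = 0,
    origin_pos: np.ndarray | None = None,
) -> PartitionScheme:
    """Split a protein-coding locus partition into three codon-position partitions.

    Codon class of a column is ``(within-locus index - frame_offset) mod 3``.
    When ``origin_pos`` (the supermatrix column_origin positions) is supplied,
    the original within-locus coordinates are used, so columns removed by
    earlier filtering do not shift the reading frame; otherwise the rank of a
    column within the partition is used.
    """
    if frame_offset not in (0, 1, 2):
        raise UsageError("frame_offset must be 0, 1 or 2")
    target = scheme.by_name(locus)
    if target.kind != "coding":
        raise UsageError(f"partition {locus!r} is not protein-coding (kind={target.kind})")
    if origin_pos is not None:
        within = np.asarray(origin_pos)[target.indices]
    else:
        within = np.arange(len(target.indices))
    classes = (within - frame_offset) % 3
    new_parts = []
    for p in scheme:
        if p.name != locus:
            new_parts.append(p)
            continue
        for c in range(3):
            sel = target.indices[classes == c]
            new_parts.append(Partition(f"{locus}_codon{c + 1}", sel, kind=f"codon{c + 1}"))
    return PartitionScheme(new_parts)
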