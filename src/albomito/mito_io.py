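"""Sequence/table I/O, coordinate frames, and mutation-label notation.

This module defines the coordinate system and the positional mutation
notation used throughout the package, mirroring the conventions of
phylotree-style mitochondrial work on *Aedes albopictus*:

* positions ("np") are 1-based and refer to a named coordinate frame —
  either the Taiwan reference mitogenome (``reference_taiwan``) or the
  Rimini mitogenome #1 (``rimini_1``) that is used to number the
  haplogroup-tree mutations;
* a bare number denotes a transition; an explicit trailing base denotes a
  transversion to that base; ``.k`` denotes an insertion, ``d`` a deletion;
  ``h`` marks heteroplasmy and ``@`` an event that restores the reference
  base (a back mutation in reference-relative polarity).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("albomito")

# --------------------------------------------------------------------------
# Package-wide coordinate conventions (rimini_1 frame unless stated).
# --------------------------------------------------------------------------

#: Assayable window of the partial COI sequences surveyed in the literature.
COI_WINDOW: tuple[int, int] = (1450, 2600)
#: Assayable window of the partial ND5 sequences surveyed in the literature.
ND5_WINDOW: tuple[int, int] = (6950, 8200)
#: Length of the standard COI DNA-barcoding segment.
BARCODE_LENGTH: int = 658
#: Default start of the barcode window (5' end of COI); configurable because
#: the exact offset of the published barcode segment on the reference is a
#: package convention, not a published coordinate.
DEFAULT_BARCODE_START: int = 1490
#: Positions masked before any comparison: length variation in the poly-A
#: stretch beginning at np 3808 is not considered.
MASKED_POSITIONS: frozenset[int] = frozenset({3808})

VALID_BASES = frozenset("ACGT")
MISSING_CHARS = frozenset("N-")
SEQ_CHARS = VALID_BASES | MISSING_CHARS

TRANSITION_PARTNER = {"A": "G", "G": "A", "C": "T", "T": "C"}


class MitoIOError(ValueError):
    """Base error for malformed inputs."""


class MutationLabelError(MitoIOError):
    """Raised when a mutation label does not match the notation grammar."""


class FrameMismatchError(MitoIOError):
    """Raised when objects in different coordinate frames are mixed silently."""


# --------------------------------------------------------------------------
# Coordinate frames
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class CoordinateFrame:
    """A named 1-based coordinate system on a mitogenome.

    ``coding_end`` is the last np of the coding region in this frame; the
    control region runs from ``coding_end + 1`` to ``length``.
    """

    name: str
    length: int
    coding_end: int

    def coding_interval(self) -> tuple[int, int]:
        return (1, self.coding_end)


#: Taiwan reference mitogenome frame (coding region np 1-14893 of 16,665 bp).
REFERENCE_TAIWAN = CoordinateFrame("reference_taiwan", 16665, 14893)
#: Rimini mitogenome #1 frame used to number the tree mutations (coding
#: region np 1-14896; total length is a package convention large enough to
#: hold the highest annotated control-region position, np 17139).
RIMINI_1 = CoordinateFrame("rimini_1", 17200, 14896)

FRAMES = {f.name: f for f in (REFERENCE_TAIWAN, RIMINI_1)}


class FrameMap:
    """Monotone position map between two frames, built from an alignment.

    The published gap placements between the Taiwan reference and mitogenome
    #1 are not available, so no default map is shipped; callers supply the
    pairwise alignment they trust.
    """

    def __init__(self, frame_a: CoordinateFrame, frame_b: CoordinateFrame,
                 pairs: list[tuple[int, int]]):
        self.frame_a = frame_a
        self.frame_b = frame_b
        self._a_to_b = dict(pairs)
        self._b_to_a = {b: a for a, b in pairs}
        cols = sorted(self._a_to_b)
        if any(self._a_to_b[x] >= self._a_to_b[y]
               for x, y in zip(cols, cols[1:])):
            raise MitoIOError("frame map is not monotone")

    @classmethod
    def from_alignment(cls, frame_a: CoordinateFrame, frame_b: CoordinateFrame,
                       aligned_a: str, aligned_b: str) -> "FrameMap":
        if len(aligned_a) != len(aligned_b):
            raise MitoIOError("aligned sequences must have equal length")
        pairs = []
        pa = pb = 0
        for ca, cb in zip(aligned_a.upper(), aligned_b.upper()):
            if ca != "-":
                pa += 1
            if cb != "-":
                pb += 1
            if ca != "-" and cb != "-":
                pairs.append((pa, pb))
        return cls(frame_a, frame_b, pairs)

    def convert(self, position: int, source: CoordinateFrame) -> int:
        if source == self.frame_a:
            table = self._a_to_b
        elif source == self.frame_b:
            table = self._b_to_a
        else:
            raise FrameMismatchError(
                f"frame {source.name!r} is not part of this map")
        try:
            return table[position]
        except KeyError:
            raise MitoIOError(
                f"np {position} aligns to a gap; no counterpart position"
            ) from None


# --------------------------------------------------------------------------
# Mutation notation
# --------------------------------------------------------------------------


_MUTATION_RE = re.compile(
    r"^(?P<pos>\d+)"
    r"(?:(?P<base>[ACGT])|\.(?P<ins>\d+)|(?P<del>d))?"
    r"(?P<het>h)?"
    r"(?P<back>@)?$"
)

KIND_TRANSITION = "transition"
KIND_TRANSVERSION = "transversion"
KIND_INSERTION = "insertion"
KIND_DELETION = "deletion"


@dataclass(frozen=True)
class Mutation:
    """One substitution/indel event in positional notation.

    ``derived_base`` is set iff the event is a transversion (the notation
    only spells the base out when it is not the transition partner).
    ``recurrent`` is never parsed from a label; it is derived from the tree
    (the same position appearing on more than one branch).
    """

    position: int
    kind: str = KIND_TRANSITION
    derived_base: str | None = None
    insert_index: int | None = None
    heteroplasmic: bool = False
    back_mutation: bool = False
    recurrent: bool = False

    def __post_init__(self):
        if self.position < 1:
            raise MutationLabelError(f"position must be >= 1, got {self.position}")
        if (self.kind == KIND_TRANSVERSION) != (self.derived_base is not None):
            raise MutationLabelError(
                "derived_base must be given for transversions and only for them")
        if (self.kind == KIND_INSERTION) != (self.insert_index is not None):
            raise MutationLabelError(
                "insert_index must be given for insertions and only for them")

    @property
    def is_indel(self) -> bool:
        return self.kind in (KIND_INSERTION, KIND_DELETION)

    @property
    def is_substitution(self) -> bool:
        return self.kind in (KIND_TRANSITION, KIND_TRANSVERSION)

    def label(self) -> str:
        return format_mutation_label(self)


def parse_mutation_label(label: str) -> Mutation:
    """Parse one positional mutation label (``1578C``, ``14969``, ``7210@``,
    ``3808.1``, ``100d``, ``4890h`` ...)."""
    if not label:
        raise MutationLabelError("empty mutation label")
    m = _MUTATION_RE.match(label.strip())
    if m is None:
        # Name the offending token: first character that breaks the grammar.
        stripped = label.strip()
        head = re.match(r"\d+", stripped)
        offending = stripped[head.end():] if head else stripped
        raise MutationLabelError(
            f"malformed mutation label {label!r}: unexpected token {offending!r}")
    kind = KIND_TRANSITION
    derived = None
    insert_index = None
    if m.group("base"):
        kind = KIND_TRANSVERSION
        derived = m.group("base")
    elif m.group("ins") is not None:
        kind = KIND_INSERTION
        insert_index = int(m.group("ins"))
    elif m.group("del"):
        kind = KIND_DELETION
    return Mutation(
        position=int(m.group("pos")),
        kind=kind,
        derived_base=derived,
        insert_index=insert_index,
        heteroplasmic=bool(m.group("het")),
        back_mutation=bool(m.group("back")),
    )


def format_mutation_label(m: Mutation) -> str:
    """Inverse of :func:`parse_mutation_label` (recurrence is not notated)."""
    out = str(m.position)
    if m.kind == KIND_TRANSVERSION:
        out += m.derived_base
    elif m.kind == KIND_INSERTION:
        out += f".{m.insert_index}"
    elif m.kind == KIND_DELETION:
        out += "d"
    if m.heteroplasmic:
        out += "h"
    if m.back_mutation:
        out += "@"
    return out


# --------------------------------------------------------------------------
# Sequence records
# --------------------------------------------------------------------------


@dataclass
class MitoSequence:
    """A complete or partial mitogenome sequence.

    ``region_covered`` is the closed 1-based interval of frame positions the
    record spans; ``seq`` holds one character per position (alignment columns,
    so gaps are allowed and 'N'/'-' count as missing, not as states).
    """

    id: str
    seq: str
    region_covered: tuple[int, int]
    population: str = ""
    source: str = "synthetic"
    frame: str = RIMINI_1.name

    def __post_init__(self):
        self.seq = self.seq.upper()
        bad = set(self.seq) - SEQ_CHARS
        if bad:
            raise MitoIOError(
                f"record {self.id!r} contains non-nucleotide characters: "
                f"{sorted(bad)}")
        start, end = self.region_covered
        if start < 1 or end < start:
            raise MitoIOError(
                f"record {self.id!r}: invalid covered interval {self.region_covered}")
        if len(self.seq) != end - start + 1:
            raise MitoIOError(
                f"record {self.id!r}: sequence length {len(self.seq)} does not "
                f"match covered interval {self.region_covered}")

    def covers(self, position: int) -> bool:
        return self.region_covered[0] <= position <= self.region_covered[1]

    def base_at(self, position: int) -> str | None:
        """Observed base at a frame position, or None if uncovered/missing."""
        if not self.covers(position):
            return None
        b = self.seq[position - self.region_covered[0]]
        return b if b in VALID_BASES else None


def extract_coding_region(s: MitoSequence,
                          frame: CoordinateFrame | None = None) -> MitoSequence | None:
    """Restrict a record to the coding region of its frame.

    Returns ``None`` when the record does not overlap the coding interval
    (the empty-result signal). Idempotent.
    """
    frame = frame or FRAMES[s.frame]
    if frame.name != s.frame:
        raise FrameMismatchError(
            f"record {s.id!r} is in frame {s.frame!r}, not {frame.name!r}")
    lo, hi = frame.coding_interval()
    start, end = s.region_covered
    new_start, new_end = max(start, lo), min(end, hi)
    if new_start > new_end:
        return None
    return replace(
        s,
        seq=s.seq[new_start - start:new_end - start + 1],
        region_covered=(new_start, new_end),
    )


# --------------------------------------------------------------------------
# FASTA / table reading and writing
# --------------------------------------------------------------------------

_HEADER_KV = re.compile(r"(\w+)=(\S+)")


def _record_from_fasta(rec: SeqRecord, frame: str) -> MitoSequence:
    meta = dict(_HEADER_KV.findall(rec.description))
    seq = str(rec.seq).upper()
    if "window" in meta:
        try:
            start, end = (int(x) for x in meta["window"].split("-"))
        except ValueError:
            raise MitoIOError(
                f"record {rec.id!r}: malformed window {meta['window']!r}") from None
    else:
        start, end = 1, len(seq)
    population = meta.get("population", "")
    return MitoSequence(
        id=rec.id,
        seq=seq,
        region_covered=(start, end),
        population="" if population == "." else population,
        source=meta.get("source", "genbank"),
        frame=meta.get("frame", frame),
    )


def read_sequences(path: str | Path, format: str = "fasta",
                   frame: str = RIMINI_1.name) -> list[MitoSequence]:
    """Read mitogenome records from FASTA or a tab-separated table.

    FASTA headers may carry ``window=start-end``, ``population=...``,
    ``source=...`` and ``frame=...`` tokens in the description; the covered
    interval defaults to ``[1, len(seq)]``.
    """
    path = Path(path)
    if format == "fasta":
        records = [_record_from_fasta(r, frame) for r in SeqIO.parse(path, "fasta")]
    elif format == "table":
        df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
        required = {"id", "seq"}
        if not required <= set(df.columns):
            raise MitoIOError(f"table {path} must have columns {sorted(required)}")
        records = []
        for row in df.itertuples(index=False):
            seq = row.seq.upper()
            start = int(getattr(row, "start", 1) or 1)
            end = int(getattr(row, "end", start + len(seq) - 1) or
                      (start + len(seq) - 1))
            records.append(MitoSequence(
                id=row.id, seq=seq, region_covered=(start, end),
                population=getattr(row, "population", "") or "",
                source=getattr(row, "source", "genbank") or "genbank",
                frame=getattr(row, "frame", frame) or frame,
            ))
    else:
        raise MitoIOError(f"unknown sequence format {format!r}")
    if not records:
        raise MitoIOError(f"no sequence records found in {path}")
    seen: set[str] = set()
    for r in records:
        if r.id in seen:
            raise MitoIOError(f"duplicate sequence id {r.id!r} in {path}")
        seen.add(r.id)
    return records


def write_sequences(records: Iterable[MitoSequence], path: str | Path) -> None:
    """Write records as FASTA with window/population metadata in headers."""
    out = []
    for r in records:
        desc = (f"window={r.region_covered[0]}-{r.region_covered[1]} "
                f"population={r.population or '.'} source={r.source} "
                f"frame={r.frame}")
        out.append(SeqRecord(Seq(r.seq), id=r.id, description=desc))
    SeqIO.write(out, str(path), "fasta")


# --------------------------------------------------------------------------
# Packaged fixture tables
# --------------------------------------------------------------------------

_FIXTURES = {
    "table1": "table1.tsv",
    "table2": "table2.tsv",
    "tree": "haplogroup_tree.nwk",
    "branch_mutations": "branch_mutations.tsv",
}


def fixture_path(name: str) -> Path:
    try:
        fname = _FIXTURES[name]
    except KeyError:
        raise MitoIOError(
            f"unknown fixture {name!r}; available: {sorted(_FIXTURES)}") from None
    return Path(resources.files("albomito").joinpath("fixtures", fname))


def load_fixture_table(name: str) -> pd.DataFrame:
    """Load a packaged study table.

    ``table1``: the 27 sequenced mitogenomes with haplogroup labels,
    accessions and control-region repeat copy numbers ("N.D." -> NaN).
    ``table2``: per-population haplogroup counts from the published survey of
    1170 partial COI/ND5 sequences, with the printed 2-decimal frequencies
    kept as strings for cross-checking.
    """
    if name not in ("table1", "table2"):
        raise MitoIOError(f"unknown fixture table {name!r}")
    path = fixture_path(name)
    if name == "table1":
        df = pd.read_csv(path, sep="\t", na_values=["N.D."])
        df["type_i_repeats"] = df["type_i_repeats"].astype("Int64")
        df["type_ii_repeats"] = df["type_ii_repeats"].astype("Int64")
        return df
    df = pd.read_csv(path, sep="\t", dtype={"region": str, "population": str})
    count_cols = ["A1a1a1", "A1a2", "A1b", "A2", "A3", "others"]
    for c in count_cols + ["N"]:
        df[c] = df[c].astype(int)
    return df
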