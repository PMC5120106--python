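"""Control-region annotation: tandem-repeat arrays and conserved blocks.

The *A. albopictus* control region carries two tandem-repeat classes —
type I (~190 bp units) and type II (~42 bp units) — separated by conserved
sequence blocks (a poly-T stretch, a poly-T stretch followed by a GC-rich
block, and a short poly-A stretch) and an A+T-rich spacer of variable
length. Repeat copy number varies among mitogenomes and is the quantity
reported per sample.

Detection is a k-mer periodicity scan: for each candidate unit length p the
sequence is compared with itself shifted by p, maximal runs of windowed
identity above a threshold are extended greedily, and arrays are placed
left-most. A single-copy "array" has no periodicity signal, so copy numbers
in the conserved-block-delimited territories fall back to segment length
divided by the nominal unit length.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from .mito_io import MitoIOError, logger

#: Unit-length bands (bp) for the two repeat classes.
TYPE_I_BAND: tuple[int, int] = (150, 230)
TYPE_II_BAND: tuple[int, int] = (30, 55)
#: Default minimum identity between a unit and the unit one period away.
DEFAULT_MIN_IDENTITY: float = 0.80
#: Nominal unit lengths used when periodicity cannot resolve copy number.
NOMINAL_UNIT_I: int = 190
NOMINAL_UNIT_II: int = 42
#: Package default length of the A+T-rich spacer between the repeat regions.
DEFAULT_AT_SPACER: int = 150


@dataclass
class RepeatAnnotation:
    repeat_type: str | None  # "I" | "II" | None
    unit_length: int
    copies: int
    span: tuple[int, int]  # 1-based inclusive
    unit_consensus: str = ""
    per_copy_identity: list[float] = field(default_factory=list)
    estimated: bool = False  # True when copies came from the length fallback

    def __post_init__(self):
        if self.copies < 1:
            raise MitoIOError("repeat array must have at least one copy")


@dataclass(frozen=True)
class ConservedBlock:
    kind: str  # "polyT" | "polyT_GCrich" | "polyA"
    span: tuple[int, int]


@dataclass
class ControlRegionAnnotation:
    repeats: list[RepeatAnnotation]
    blocks: list[ConservedBlock]
    at_rich_span: tuple[int, int] | None
    warnings: list[str] = field(default_factory=list)

    @property
    def copies(self) -> tuple[int | None, int | None]:
        """(type I copies, type II copies) as reported per sample."""
        by_type = {r.repeat_type: r.copies for r in self.repeats}
        return (by_type.get("I"), by_type.get("II"))


# --------------------------------------------------------------------------
# Periodicity scan
# --------------------------------------------------------------------------


def _period_runs(arr: np.ndarray, p: int, min_identity: float):
    """Maximal runs of positions whose p-shifted window identity passes the
    threshold; yields (start, end) in 0-based match coordinates."""
    if len(arr) < 2 * p:
        return []
    m = (arr[:-p] == arr[p:]).astype(np.int32)
    if len(m) < p:
        return []
    win = np.convolve(m, np.ones(p, dtype=np.int32), mode="valid")
    good = win >= int(np.ceil(min_identity * p))
    runs, start = [], None
    for i, g in enumerate(good):
        if g and start is None:
            start = i
        elif not g and start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, len(good) - 1))
    return runs


def detect_tandem_repeats(seq: str,
                          unit_length_range: tuple[int, int],
                          min_copies: int = 2,
                          min_identity: float = DEFAULT_MIN_IDENTITY,
                          ) -> list[RepeatAnnotation]:
    """Maximal non-overlapping tandem arrays with unit length in the band.

    Deterministic: the period with the longest supporting run wins (ties to
    the shortest period), arrays are reported left-most first. Returns an
    empty list when no array is found.
    """
    seq = seq.upper()
    lo, hi = unit_length_range
    if len(seq) < 2 * lo:
        return []
    arr = np.frombuffer(seq.encode(), dtype="S1")
    candidates = []  # (run_len, p, start, end)
    for p in range(lo, min(hi, len(seq) // 2) + 1):
        for s, e in _period_runs(arr, p, min_identity):
            candidates.append((e - s, p, s, e))
    out: list[RepeatAnnotation] = []
    taken: list[tuple[int, int]] = []
    for run_len, p, s, e in sorted(candidates,
                                   key=lambda c: (-c[0], c[1], c[2])):
        span = _trim_span(arr, p, s, e, min_identity)
        if span is None:
            continue
        if any(span[0] <= t[1] and t[0] <= span[1] for t in taken):
            continue
        copies = int(round((span[1] - span[0] + 1) / p))
        if copies < min_copies:
            continue
        taken.append(span)
        ann = RepeatAnnotation(
            repeat_type=None, unit_length=p, copies=copies,
            span=(span[0] + 1, span[1] + 1))
        _fill_consensus(ann, seq)
        out.append(ann)
    out.sort(key=lambda a: a.span)
    return out


def _trim_span(arr: np.ndarray, p: int, s: int, e: int,
               min_identity: float) -> tuple[int, int] | None:
    """Exact 0-based array span for a windowed-identity run.

    Threshold runs overshoot into flanking sequence by up to (1-identity)*p
    positions on each side; the span is trimmed to the region of high local
    match density between the sequence and its p-shifted copy.
    """
    m = (arr[:-p] == arr[p:]).astype(np.float64)
    lo = max(0, s - p)
    hi = min(len(m), e + 2 * p)
    # penalised match profile: positions only pay off where the p-shifted
    # identity beats the threshold, so extending into flanks always loses
    seg = m[lo:hi] - min_identity
    prefix = np.concatenate(([0.0], np.cumsum(seg)))
    best = None  # (score, copies, start)
    c = 2
    while (c - 1) * p <= hi - lo:
        span_m = (c - 1) * p
        diffs = prefix[span_m:] - prefix[:-span_m]
        score = float(diffs.max())
        # right-most placement among ties: boundary bases shared with a
        # conserved-block homopolymer stay outside the array
        a_rel = int(np.nonzero(diffs >= score - 1e-9)[0][-1])
        if best is None or score > best[0] + 1e-9:
            best = (score, c, lo + a_rel)
        c += 1
    if best is None or best[0] <= 0:
        return None
    _, copies, a = best
    return (a, a + copies * p - 1)


def _fill_consensus(ann: RepeatAnnotation, seq: str) -> None:
    lo, hi = ann.span
    p = ann.unit_length
    units = [seq[lo - 1 + i * p: lo - 1 + (i + 1) * p]
             for i in range(ann.copies)]
    units = [u for u in units if len(u) == p]
    if not units:
        return
    cols = zip(*units)
    consensus = "".join(max(set(c), key=lambda b: (list(c).count(b), b))
                        for c in cols)
    ann.unit_consensus = consensus
    ann.per_copy_identity = [
        sum(a == b for a, b in zip(u, consensus)) / p for u in units]


def classify_repeat_types(annotations: list[RepeatAnnotation],
                          band_i: tuple[int, int] = TYPE_I_BAND,
                          band_ii: tuple[int, int] = TYPE_II_BAND,
                          ) -> list[RepeatAnnotation]:
    """Label arrays as type I (~190 bp band) or type II (~42 bp band);
    arrays outside both bands stay unlabelled."""
    for ann in annotations:
        if band_i[0] <= ann.unit_length <= band_i[1]:
            ann.repeat_type = "I"
        elif band_ii[0] <= ann.unit_length <= band_ii[1]:
            ann.repeat_type = "II"
        else:
            ann.repeat_type = None
    return annotations


# --------------------------------------------------------------------------
# Full control-region annotation
# --------------------------------------------------------------------------

_POLY_T = re.compile(r"T{10,}")
_POLY_T_GC = re.compile(r"T{8,}[GC]{12,}")
_POLY_A = re.compile(r"A{8,}")


def _span(m: re.Match) -> tuple[int, int]:
    return (m.start() + 1, m.end())


def annotate_control_region(seq: str,
                            unit_i: int = NOMINAL_UNIT_I,
                            unit_ii: int = NOMINAL_UNIT_II,
                            min_identity: float = DEFAULT_MIN_IDENTITY,
                            at_spacer: int = DEFAULT_AT_SPACER,
                            ) -> ControlRegionAnnotation:
    """Annotate a control-region sequence: conserved blocks, both repeat
    arrays with copy numbers, and the A+T-rich spacer.

    Expected layout (5'->3'): poly-T block, type I array, poly-T+GC-rich
    block, A+T-rich spacer, type II array, poly-A block. Missing features
    produce warnings and a partial annotation, never a silent failure.
    """
    seq = seq.upper()
    warnings: list[str] = []
    blocks: list[ConservedBlock] = []

    m_tgc = _POLY_T_GC.search(seq)
    m_t = None
    for cand in _POLY_T.finditer(seq):
        if m_tgc is None or cand.start() < m_tgc.start():
            m_t = cand
            break
    if m_t is not None:
        blocks.append(ConservedBlock("polyT", _span(m_t)))
    else:
        warnings.append("poly-T block not found")
    if m_tgc is not None:
        blocks.append(ConservedBlock("polyT_GCrich", _span(m_tgc)))
    else:
        warnings.append("poly-T + GC-rich block not found")
    m_a = None
    for cand in _POLY_A.finditer(seq):
        if m_tgc is None or cand.start() > m_tgc.end():
            m_a = cand
    if m_a is not None:
        blocks.append(ConservedBlock("polyA", _span(m_a)))
    else:
        warnings.append("poly-A block not found")

    repeats: list[RepeatAnnotation] = []

    # -- type I territory: between poly-T and poly-T+GC blocks
    if m_t is not None and m_tgc is not None:
        lo, hi = m_t.end(), m_tgc.start()  # 0-based half-open
        repeats += _annotate_territory(seq, lo, hi, TYPE_I_BAND, unit_i,
                                       min_identity, trailing=0,
                                       warnings=warnings, label="type I")
    else:
        warnings.append("type I territory not delimited; skipped")

    # -- type II territory: between poly-T+GC block and poly-A block,
    #    preceded by the A+T-rich spacer
    at_span = None
    if m_tgc is not None and m_a is not None:
        lo, hi = m_tgc.end(), m_a.start()
        found = _annotate_territory(seq, lo, hi, TYPE_II_BAND, unit_ii,
                                    min_identity, trailing=at_spacer,
                                    warnings=warnings, label="type II")
        repeats += found
        if found:
            at_span = (lo + 1, found[0].span[0] - 1)
        else:
            at_span = (lo + 1, hi)
    else:
        warnings.append("type II territory not delimited; skipped")

    classify_repeat_types(repeats)
    # boundary homopolymers can be claimed by both an array edge and a
    # conserved block; blocks win so the reported features never overlap
    for r in repeats:
        s, e = r.span
        for b in blocks:
            if b.span[0] <= s <= b.span[1]:
                s = b.span[1] + 1
            if b.span[0] <= e <= b.span[1]:
                e = b.span[0] - 1
        r.span = (s, e)
    for w in warnings:
        logger.warning("control region: %s", w)
    return ControlRegionAnnotation(repeats=repeats, blocks=blocks,
                                   at_rich_span=at_span, warnings=warnings)


def _annotate_territory(seq: str, lo: int, hi: int,
                        band: tuple[int, int], nominal_unit: int,
                        min_identity: float, trailing: int,
                        warnings: list[str], label: str,
                        ) -> list[RepeatAnnotation]:
    """Detect the repeat array inside a block-delimited territory.

    ``trailing`` is the nominal length of non-repeat spacer sharing the
    territory (0 when the blocks delimit the array exactly); it is only
    used for the single-copy fallback, where periodicity is silent.
    """
    if hi - lo < nominal_unit // 2:
        warnings.append(f"{label} territory too short for one unit")
        return []
    # pad a few bases: a unit starting/ending in T or A can donate its edge
    # to the neighbouring conserved-block homopolymer match
    pad = 8
    base = max(0, lo - pad)
    territory = seq[base:min(len(seq), hi + pad)]
    found = detect_tandem_repeats(territory, band,
                                  min_copies=2, min_identity=min_identity)
    if found:
        best = max(found, key=lambda a: a.span[1] - a.span[0])
        best.span = (best.span[0] + base, best.span[1] + base)
        return [best]
    copies = max(1, int(round((hi - lo - trailing) / nominal_unit)))
    warnings.append(
        f"{label} array shows no periodicity; copy number {copies} "
        f"estimated from territory length")
    span = (hi - copies * nominal_unit + 1, hi)
    return [RepeatAnnotation(repeat_type=None, unit_length=nominal_unit,
                             copies=copies, span=span, estimated=True)]


def repeats_to_bed(ann: ControlRegionAnnotation, name: str = "control_region",
                   ) -> str:
    """BED-like TSV (1-based inclusive) of arrays and conserved blocks."""
    lines = ["#chrom\tstart\tend\tfeature\tdetail"]
    for r in ann.repeats:
        lines.append(f"{name}\t{r.span[0]}\t{r.span[1]}\t"
                     f"repeat_type_{r.repeat_type or 'unknown'}\t"
                     f"unit={r.unit_length};copies={r.copies}")
    for b in ann.blocks:
        lines.append(f"{name}\t{b.span[0]}\t{b.span[1]}\t{b.kind}\t.")
    if ann.at_rich_span:
        lines.append(f"{name}\t{ann.at_rich_span[0]}\t{ann.at_rich_span[1]}"
                     f"\tAT_rich\t.")
    return "\n".join(lines) + "\n"
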