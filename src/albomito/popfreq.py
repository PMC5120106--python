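"""Population-level statistics: haplogroup frequency tables, COI barcode
p-distances and maximum intraspecific divergence.

The p-distance is the proportion of differing sites among pairwise
comparable sites (pairwise deletion: positions where either sequence is
missing, gapped or 'N' are excluded from numerator and denominator), the
convention used for DNA-barcoding divergence on the standard 658-bp COI
segment.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .haplotree import is_under, validate_haplogroup_name
from .mito_io import (
    BARCODE_LENGTH,
    DEFAULT_BARCODE_START,
    MitoIOError,
    MitoSequence,
    VALID_BASES,
    logger,
)

OTHERS = "others"
#: Table 2 survey columns, native order.
DEFAULT_SURVEY_COLUMNS: tuple[str, ...] = ("A1a1a1", "A1a2", "A1b", "A2", "A3")


def p_distance(a: str, b: str) -> float:
    """Proportion of differing sites among pairwise comparable sites."""
    if len(a) != len(b):
        raise MitoIOError(
            f"length mismatch: {len(a)} vs {len(b)}")
    aa = np.frombuffer(a.upper().encode(), dtype="S1")
    bb = np.frombuffer(b.upper().encode(), dtype="S1")
    valid = np.array([x.encode() for x in sorted(VALID_BASES)])
    comparable = np.isin(aa, valid) & np.isin(bb, valid)
    n = int(comparable.sum())
    if n == 0:
        raise MitoIOError("no comparable sites between sequences")
    return float((aa[comparable] != bb[comparable]).sum()) / n


def default_barcode_window() -> tuple[int, int]:
    return (DEFAULT_BARCODE_START, DEFAULT_BARCODE_START + BARCODE_LENGTH - 1)


def _window_slice(s: MitoSequence | str, window: tuple[int, int]) -> str | None:
    lo, hi = window
    if isinstance(s, str):
        return s[lo - 1:hi] if len(s) >= hi else None
    start, end = s.region_covered
    if start > lo or end < hi:
        return None
    return s.seq[lo - start:hi - start + 1]


def max_intraspecific_divergence(
        barcodes: Sequence[MitoSequence | str],
        window: tuple[int, int] | None = None) -> float:
    """Maximum pairwise p-distance over a barcode window.

    Sequences not fully covering the window are dropped; at least two usable
    sequences are required.
    """
    window = window or default_barcode_window()
    usable = []
    for s in barcodes:
        w = _window_slice(s, window)
        if w is None:
            sid = s.id if isinstance(s, MitoSequence) else "<str>"
            logger.warning("sequence %s does not cover the barcode window "
                           "%s; skipped", sid, window)
        else:
            usable.append(w)
    if len(usable) < 2:
        raise MitoIOError(
            f"need at least 2 sequences covering window {window}, "
            f"got {len(usable)}")
    return max(p_distance(x, y) for x, y in combinations(usable, 2))


def round_half_up(x: float, ndigits: int = 2) -> float:
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def _column_for_call(call: str, columns: Sequence[str]) -> str:
    if call == OTHERS:
        return OTHERS
    matches = [c for c in columns if is_under(call, c)]
    if matches:
        # nearest listed ancestor = the deepest matching column
        return max(matches, key=len)
    logger.info("call %r matches no survey column; counted as others", call)
    return OTHERS


def frequency_table(calls: pd.DataFrame,
                    columns: Sequence[str] = DEFAULT_SURVEY_COLUMNS,
                    ) -> pd.DataFrame:
    """Per-population haplogroup counts and 2-decimal frequencies.

    ``calls`` needs columns ``region``, ``population`` and ``call``; nested
    calls roll up to their nearest listed ancestor column, anything else to
    "others". Frequencies are rounded half-up to two decimals for display;
    raw fractions are count/N from the count columns.
    """
    for col in columns:
        validate_haplogroup_name(col)
    required = {"region", "population", "call"}
    if not required <= set(calls.columns):
        raise MitoIOError(f"calls table needs columns {sorted(required)}")
    if calls.empty:
        raise MitoIOError("empty calls table")
    work = calls.copy()
    work["_col"] = [_column_for_call(c, columns) for c in work["call"]]
    rows = []
    for (region, pop), grp in work.groupby(["region", "population"],
                                           sort=False):
        counts = grp["_col"].value_counts()
        n = len(grp)
        row = {"region": region, "population": pop, "N": n}
        for col in (*columns, OTHERS):
            k = int(counts.get(col, 0))
            row[col] = k
            row[f"{col}_freq"] = round_half_up(k / n)
        rows.append(row)
    return pd.DataFrame(rows)


def aggregate_by_region(ft: pd.DataFrame,
                        columns: Sequence[str] = DEFAULT_SURVEY_COLUMNS,
                        ) -> pd.DataFrame:
    """Regional subtotal rows: summed counts, recomputed frequencies."""
    cols = [*columns, OTHERS]
    rows = []
    for region, grp in ft.groupby("region", sort=False):
        n = int(grp["N"].sum())
        row = {"region": region, "population": "", "N": n}
        for col in cols:
            k = int(grp[col].sum())
            row[col] = k
            row[f"{col}_freq"] = round_half_up(k / n) if n else 0.0
        rows.append(row)
    return pd.DataFrame(rows)


def check_row_conservation(ft: pd.DataFrame,
                           columns: Sequence[str] = DEFAULT_SURVEY_COLUMNS,
                           ) -> bool:
    """Row conservation: haplogroup counts + others == N on every row."""
    cols = [*columns, OTHERS]
    sums = ft[cols].sum(axis=1)
    ok = (sums == ft["N"]).all()
    if not ok:
        bad = ft.loc[sums != ft["N"], "population"].tolist()
        raise MitoIOError(f"count conservation violated in rows: {bad}")
    return True


def count_distinct_haplotypes(seqs: Iterable[MitoSequence],
                              region: tuple[int, int] | None = None) -> int:
    """Number of distinct haplotypes over a region (full span by default)."""
    seen = set()
    for s in seqs:
        seen.add(_window_slice(s, region) if region else s.seq)
    return len(seen)
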