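"""Haplogroup assignment of partial COI/ND5 fragments from marker panels.

A fragment is scored against the diagnostic panel marker by marker
(``derived`` / ``ancestral`` / ``missing``; markers outside the covered
window are missing, as are heteroplasmic or ambiguous bases), then called
to the deepest haplogroup whose root-path markers are all satisfied and
none violated. Any violated marker on a path forces the conservative
"others" bucket for that path; absence markers require the ancestral state
to be *observed* — lack of coverage never supports a call.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .haplotree import MarkerPanel, PanelEntry, base_name, is_under
from .mito_io import (
    FrameMismatchError,
    KIND_TRANSVERSION,
    MitoIOError,
    MitoSequence,
    TRANSITION_PARTNER,
    logger,
)

OTHERS = "others"

__all__ = [
    "OTHERS", "FragmentRecord", "MarkerTally", "HaplogroupCall",
    "MarkerPanel", "observe_marker", "score_fragment", "classify_fragment",
    "classify_batch",
]


@dataclass
class FragmentRecord:
    """A partial COI or ND5 sequence with its covered window.

    ``truth`` carries the generating haplogroup for synthetic benchmark
    fragments and is never consulted by the classifier.
    """

    sequence: MitoSequence
    window: str = "COI"
    truth: str | None = None

    @property
    def id(self) -> str:
        return self.sequence.id

    @property
    def population(self) -> str:
        return self.sequence.population


@dataclass
class MarkerTally:
    satisfied: list[PanelEntry] = field(default_factory=list)
    violated: list[PanelEntry] = field(default_factory=list)
    unobservable: list[PanelEntry] = field(default_factory=list)


@dataclass(frozen=True)
class HaplogroupCall:
    fragment_id: str
    population: str
    call: str
    confidence: str  # "full" | "partial" | "none"
    supporting: tuple[str, ...] = ()
    conflicting: tuple[str, ...] = ()
    tie_with: tuple[str, ...] = ()

    def __post_init__(self):
        if self.call != OTHERS and (not self.supporting or self.conflicting):
            raise MitoIOError(
                f"call {self.call!r} must have supporting markers and no "
                "conflicts")


def _reference_base(reference, position: int) -> str:
    if isinstance(reference, MitoSequence):
        b = reference.base_at(position)
        if b is None:
            raise MitoIOError(
                f"reference does not resolve np {position}")
        return b
    try:
        return reference[position - 1].upper()
    except IndexError:
        raise MitoIOError(
            f"reference of length {len(reference)} does not cover np "
            f"{position}") from None


def observe_marker(fragment: FragmentRecord, entry: PanelEntry,
                   reference) -> str:
    """State of one marker in a fragment: derived / ancestral / missing.

    The derived state of a transition marker is the transition partner of
    the reference base; transversion markers spell their derived base out.
    Unexpected third bases count as missing, never as support.
    """
    pos = entry.mutation.position
    base = fragment.sequence.base_at(pos)
    if base is None:
        return "missing"
    ref = _reference_base(reference, pos)
    if entry.mutation.kind == KIND_TRANSVERSION:
        derived = entry.mutation.derived_base
    else:
        derived = TRANSITION_PARTNER[ref]
    if base == derived:
        return "derived"
    if base == ref:
        return "ancestral"
    return "missing"


def score_fragment(fragment: FragmentRecord, panel: MarkerPanel,
                   reference) -> dict[str, MarkerTally]:
    """Per-haplogroup tallies of satisfied / violated / unobservable
    stem markers.

    Presence markers are satisfied by the derived state, absence markers by
    the *observed* ancestral state; anything unobserved is unobservable.
    """
    if fragment.sequence.frame != panel.frame:
        raise FrameMismatchError(
            f"fragment {fragment.id!r} is in frame "
            f"{fragment.sequence.frame!r} but the panel is in "
            f"{panel.frame!r}")
    tallies: dict[str, MarkerTally] = {}
    for entry in panel.entries:
        tally = tallies.setdefault(entry.haplogroup, MarkerTally())
        state = observe_marker(fragment, entry, reference)
        if state == "missing":
            tally.unobservable.append(entry)
        elif (state == "derived") == (entry.mode == "presence"):
            tally.satisfied.append(entry)
        else:
            tally.violated.append(entry)
    return tallies


def _depth_key(name: str) -> tuple:
    return (len(base_name(name)), name != base_name(name), name)


def classify_fragment(fragment: FragmentRecord, panel: MarkerPanel,
                      reference) -> HaplogroupCall:
    """Deepest-satisfiable haplogroup call for one fragment.

    A haplogroup is satisfiable when at least one of its own stem markers is
    satisfied and no marker on its root path (its own or any panel
    ancestor's) is violated. Among satisfiable haplogroups the deepest is
    called; if two incomparable haplogroups are both maximal the shallower
    one is called with the tie recorded. No satisfiable haplogroup means
    "others".
    """
    tallies = score_fragment(fragment, panel, reference)
    candidates = []
    for hg, tally in tallies.items():
        if not tally.satisfied:
            continue
        path_violated = any(
            tallies[anc].violated for anc in tallies if is_under(hg, anc))
        if not path_violated:
            candidates.append(hg)
    if not candidates:
        violated = sorted({e.mutation.label()
                           for t in tallies.values() for e in t.violated})
        return HaplogroupCall(
            fragment_id=fragment.id, population=fragment.population,
            call=OTHERS, confidence="none", conflicting=tuple(violated))
    maximal = [h for h in candidates
               if not any(h != o and is_under(o, h) for o in candidates)]
    maximal.sort(key=_depth_key)
    call = maximal[0]
    ties = tuple(maximal[1:])
    if ties:
        logger.warning("fragment %s: incomparable haplogroups %s also "
                       "satisfied; calling the shallower %s",
                       fragment.id, list(ties), call)
    path_entries = panel.path_entries(call)
    supporting = tuple(
        e.mutation.label() for hg in tallies for e in tallies[hg].satisfied
        if is_under(call, hg))
    observable = all(
        e not in tallies[hg].unobservable
        for hg in tallies for e in panel.entries_for(hg)
        if is_under(call, hg)) and len(path_entries) > 0
    confidence = "full" if observable else "partial"
    return HaplogroupCall(
        fragment_id=fragment.id, population=fragment.population,
        call=call, confidence=confidence, supporting=supporting,
        tie_with=ties)


def classify_batch(fragments, panel: MarkerPanel, reference,
                   regions: dict[str, str] | None = None) -> pd.DataFrame:
    """Classify a batch of fragments; one row per fragment, input order.

    ``regions`` optionally maps population -> region label for downstream
    frequency tables.
    """
    fragments = list(fragments)
    if not fragments:
        raise MitoIOError("no fragments to classify")
    ids = [f.id for f in fragments]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise MitoIOError(f"duplicate fragment ids: {dupes}")
    rows = []
    for f in fragments:
        call = classify_fragment(f, panel, reference)
        rows.append({
            "id": call.fragment_id,
            "population": call.population,
            "region": (regions or {}).get(call.population, ""),
            "call": call.call,
            "confidence": call.confidence,
            "supporting": ",".join(call.supporting),
            "conflicting": ",".join(call.conflicting),
            "truth": f.truth if f.truth is not None else "",
        })
    df = pd.DataFrame(rows)
    summary = df["call"].value_counts().to_dict()
    logger.info("classified %d fragments: %s", len(df), summary)
    return df
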