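"""Haplogroup phylogeny: tree container, small parsimony, marker panels.

The haplogroup tree is a rooted tree whose nodes carry haplogroup names
(``A1``, ``A1a2a1``, motif-annotated subtypes like ``"A1b (Brazilian
motif)"``, or anonymous internals) and whose branches carry lists of
positional mutations. Mutations are numbered and polarised against a
reference mitogenome that is itself a leaf of the tree (Rim1, mitogenome
#1 of the study design): "presence of the transition at np X" in a sample
means carrying the non-reference base at X. Events on the reference's own
root path therefore restore the reference base and are written with the
``@`` suffix; such events are what make *absence* of a mutation diagnostic
(e.g. haplogroup A1a1a1, distinguished by the absence of the COI
transitions at nps 1536 and 2165).

Small parsimony uses Hartigan's generalisation of the Fitch algorithm so
that multifurcating nodes and missing leaf states (treated as the universal
state set, never forcing changes) are handled exactly.
"""

from __future__ import annotations

import itertools
import re
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import dendropy
import numpy as np
import pandas as pd

from .mito_io import (
    COI_WINDOW,
    KIND_TRANSITION,
    KIND_TRANSVERSION,
    MASKED_POSITIONS,
    MitoIOError,
    MitoSequence,
    Mutation,
    ND5_WINDOW,
    RIMINI_1,
    TRANSITION_PARTNER,
    VALID_BASES,
    fixture_path,
    logger,
    parse_mutation_label,
)

# --------------------------------------------------------------------------
# Haplogroup nomenclature
# --------------------------------------------------------------------------

_HG_BASE_RE = re.compile(r"^[A-Z]\d+([a-z]\d*)*$")
_MOTIF_RE = re.compile(r"^(?P<base>\S+) \((?P<motif>[^()]+)\)$")


def base_name(name: str) -> str:
    """Strip a motif annotation: ``"A1b (Brazilian motif)"`` -> ``"A1b"``."""
    m = _MOTIF_RE.match(name)
    return m.group("base") if m else name


def is_haplogroup_name(name: str) -> bool:
    """True for names following the nested nomenclature (motif suffix allowed)."""
    return bool(_HG_BASE_RE.match(base_name(name)))


def validate_haplogroup_name(name: str) -> str:
    if not is_haplogroup_name(name):
        raise MitoIOError(f"malformed haplogroup name {name!r}")
    return name


def is_under(child: str, parent: str) -> bool:
    """Nesting test: ``A1`` covers ``A1a2a1`` but not ``A11``.

    A child label extends the parent's label without continuing a digit run,
    so the alternating letter/digit structure is respected. A motif-annotated
    label nests strictly under its base label.
    """
    if child == parent:
        return True
    if parent != base_name(parent):
        # a motif-annotated subtype is terminal: nothing nests under it
        return False
    bc = base_name(child)
    if bc == parent:
        # child is a motif subtype of this base haplogroup
        return child != bc
    if not bc.startswith(parent):
        return False
    return not (parent[-1].isdigit() and bc[len(parent)].isdigit())


def haplogroup_members(labels: Iterable[str], group: str) -> int:
    """Count labels equal to ``group`` or nested under it."""
    validate_haplogroup_name(group)
    return sum(1 for lab in labels if is_under(lab, group))


# --------------------------------------------------------------------------
# Tree container
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class BranchEvent:
    """A mutation on a branch; annotation-only events (doubtful
    control-region mutations, heteroplasmies recorded as annotations,
    unplaceable insertions) are kept for display but excluded from
    scoring, simulation and marker panels."""

    mutation: Mutation
    annotation_only: bool = False

    @property
    def scorable(self) -> bool:
        m = self.mutation
        return (not self.annotation_only and m.is_substitution
                and not m.heteroplasmic)


class Node:
    __slots__ = ("name", "children", "parent", "events", "_auto")

    def __init__(self, name: str | None = None):
        self._auto = name is None
        self.name = name or ""
        self.children: list[Node] = []
        self.parent: Node | None = None
        self.events: list[BranchEvent] = []

    @property
    def is_leaf(self) -> bool:
        return not self.children

    @property
    def is_named_haplogroup(self) -> bool:
        return not self.is_leaf and is_haplogroup_name(self.name)

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    def depth(self) -> int:
        d, n = 0, self
        while n.parent is not None:
            d, n = d + 1, n.parent
        return d

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Node({self.name!r}, leaf={self.is_leaf})"


class HaplogroupTree:
    """Rooted haplogroup tree with per-branch mutation lists."""

    def __init__(self, root: Node, frame: str = RIMINI_1.name,
                 reference_leaf: str | None = None):
        self.root = root
        self.frame = frame
        self.reference_leaf = reference_leaf
        self._index = {}
        auto = itertools.count(1)
        for node in self.preorder():
            if not node.name:
                node.name = f"node{next(auto)}"
            if node.name in self._index:
                raise MitoIOError(f"duplicate node name {node.name!r} in tree")
            self._index[node.name] = node
        self._mark_recurrent()

    # -- traversal ---------------------------------------------------------

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            n = stack.pop()
            yield n
            stack.extend(reversed(n.children))

    def postorder(self) -> Iterator[Node]:
        out = list(self.preorder())
        return iter(reversed(out))

    def leaves(self) -> list[Node]:
        return [n for n in self.preorder() if n.is_leaf]

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    def find(self, name: str) -> Node:
        try:
            return self._index[name]
        except KeyError:
            raise MitoIOError(f"no node named {name!r} in tree") from None

    def path_to(self, name: str) -> list[Node]:
        """Nodes from root (exclusive) down to the named node (inclusive)."""
        node = self.find(name)
        path = []
        while node.parent is not None:
            path.append(node)
            node = node.parent
        return path[::-1]

    def named_haplogroups(self) -> list[Node]:
        nodes = [n for n in self.preorder() if n.is_named_haplogroup]
        return sorted(nodes, key=lambda n: (n.depth(), n.name))

    # -- mutation bookkeeping ---------------------------------------------

    def _mark_recurrent(self) -> None:
        counts = Counter(
            ev.mutation.position
            for node in self.preorder() for ev in node.events if ev.scorable)
        for node in self.preorder():
            node.events = [
                replace(ev, mutation=replace(ev.mutation, recurrent=True))
                if ev.scorable and counts[ev.mutation.position] > 1 else ev
                for ev in node.events
            ]

    def recurrent_positions(self) -> set[int]:
        return {ev.mutation.position for n in self.preorder()
                for ev in n.events if ev.scorable and ev.mutation.recurrent}

    def reference_diff(self, node_name: str) -> frozenset[int]:
        """Positions where the named node's haplotype differs from the
        reference leaf (reference-relative presence of each mutation)."""
        return self._diffs()[node_name]

    def _diffs(self) -> dict[str, frozenset[int]]:
        if getattr(self, "_diff_cache", None) is None:
            if self.reference_leaf is None:
                raise MitoIOError("tree has no reference leaf set")
            ref_path = self.path_to(self.reference_leaf)
            root_diff: set[int] = set()
            for node in ref_path:
                for ev in node.events:
                    if ev.scorable:
                        root_diff.symmetric_difference_update(
                            {ev.mutation.position})
            cache: dict[str, frozenset[int]] = {}

            def walk(node: Node, diff: set[int]):
                for ev in node.events:
                    if ev.scorable:
                        diff.symmetric_difference_update({ev.mutation.position})
                cache[node.name] = frozenset(diff)
                for c in node.children:
                    walk(c, set(diff))

            walk_root = set(root_diff)
            cache[self.root.name] = frozenset(walk_root)
            for c in self.root.children:
                walk(c, set(walk_root))
            self._diff_cache = cache
        return self._diff_cache

    def stem_marker_events(self, node: Node) -> list[tuple[BranchEvent, str]]:
        """Scorable, non-recurrent stem events classified as ``presence``
        (adds a difference from the reference) or ``absence`` (removes one)."""
        parent_diff = self._diffs()[node.parent.name] if node.parent else \
            self._diffs()[self.root.name]
        seen = set(parent_diff)
        out = []
        for ev in node.events:
            if not ev.scorable or ev.mutation.recurrent:
                continue
            pos = ev.mutation.position
            mode = "absence" if pos in seen else "presence"
            seen.symmetric_difference_update({pos})
            if ev.mutation.back_mutation != (mode == "absence"):
                logger.warning(
                    "event %s on branch %s: '@' flag disagrees with "
                    "reference-relative polarity", ev.mutation.label(), node.name)
            out.append((ev, mode))
        return out

    # -- I/O ---------------------------------------------------------------

    @classmethod
    def from_newick(cls, source: str | Path, mutations: str | Path | None = None,
                    frame: str = RIMINI_1.name,
                    reference_leaf: str | None = None) -> "HaplogroupTree":
        """Read a tree from Newick, optionally attaching a branch->mutation
        ledger (TSV with columns branch, mutation, annotation_only)."""
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        dtree = dendropy.Tree.get(data=text, schema="newick",
                                  suppress_internal_node_taxa=True,
                                  preserve_underscores=True)

        def convert(dnode) -> Node:
            label = dnode.taxon.label if dnode.taxon else dnode.label
            node = Node(label)
            for c in dnode.child_nodes():
                node.add_child(convert(c))
            return node

        tree = cls(convert(dtree.seed_node), frame=frame,
                   reference_leaf=reference_leaf)
        if mutations is not None:
            df = pd.read_csv(mutations, sep="\t", dtype=str)
            for row in df.itertuples(index=False):
                node = tree.find(row.branch)
                node.events.append(BranchEvent(
                    mutation=parse_mutation_label(row.mutation),
                    annotation_only=bool(int(row.annotation_only or 0)),
                ))
            tree._mark_recurrent()
            tree._diff_cache = None
        return tree

    @classmethod
    def load_fixture(cls) -> "HaplogroupTree":
        """The packaged 27-mitogenome haplogroup tree with its branch ledger."""
        return cls.from_newick(
            fixture_path("tree"), mutations=fixture_path("branch_mutations"),
            frame=RIMINI_1.name, reference_leaf="Rim1")

    def to_newick(self, include_mutations: bool = True) -> str:
        def quote(label: str) -> str:
            if re.match(r"^[\w.]+$", label):
                return label
            return "'" + label.replace("'", "''") + "'"

        def fmt(node: Node) -> str:
            label = "" if node._auto and not node.is_leaf else quote(node.name)
            comment = ""
            if include_mutations and node.events:
                labs = " ".join(ev.mutation.label() +
                                ("~" if ev.annotation_only else "")
                                for ev in node.events)
                comment = f"[&mutations={labs}]"
            if node.is_leaf:
                return label + comment
            inner = ",".join(fmt(c) for c in node.children)
            return f"({inner}){label}{comment}"

        return fmt(self.root) + ";"

    def branch_ledger(self) -> pd.DataFrame:
        rows = [
            {"branch": n.name, "mutation": ev.mutation.label(),
             "annotation_only": int(ev.annotation_only),
             "recurrent": int(ev.mutation.recurrent)}
            for n in self.preorder() for ev in n.events
        ]
        return pd.DataFrame(rows, columns=["branch", "mutation",
                                           "annotation_only", "recurrent"])

    def rerooted(self, name: str) -> "HaplogroupTree":
        """Return a copy rooted at the named node (events travel with the
        child side of each branch, so scoring input is preserved)."""
        import copy

        clone = copy.deepcopy(self)
        new_root = clone.find(name)
        chain = []
        n = new_root
        while n is not None:
            chain.append(n)
            n = n.parent
        orig_events = {id(n): n.events for n in chain}
        for child, parent in zip(chain, chain[1:]):
            parent.children.remove(child)
            child.children.append(parent)
            # the branch between child and parent keeps its events,
            # now attached to the (former) parent side
            parent.events = orig_events[id(child)]
            parent.parent = child
        new_root.parent = None
        new_root.events = []
        if new_root.children and name in [l.name for l in self.leaves()]:
            # rooting at a leaf: root on the edge above it so the leaf's
            # observed state keeps counting
            wrapper = Node()
            for c in new_root.children:
                c.parent = wrapper
                wrapper.children.append(c)
            new_root.children = []
            wrapper.children.insert(0, new_root)
            new_root.parent = wrapper
            new_root = wrapper
        return HaplogroupTree(new_root, frame=clone.frame,
                              reference_leaf=clone.reference_leaf)


# --------------------------------------------------------------------------
# Site patterns
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class SitePattern:
    """Observed bases at one reference position; None marks missing."""

    position: int
    states: dict  # taxon -> base | None

    def observed(self) -> set[str]:
        return {b for b in self.states.values() if b is not None}


def build_site_patterns(seqs: Sequence[MitoSequence],
                        masked: frozenset[int] = MASKED_POSITIONS,
                        region: tuple[int, int] | None = None,
                        ) -> list[SitePattern]:
    """Variable alignment columns from a set of frame-aligned records.

    Gaps and 'N' are missing; masked positions (the poly-A length-variant
    stretch at np 3808 by default) are dropped; only columns with at least
    two observed states are returned.
    """
    frames = {s.frame for s in seqs}
    if len(frames) > 1:
        raise MitoIOError(f"records mix coordinate frames: {sorted(frames)}")
    length = max(s.region_covered[1] for s in seqs)
    code = np.zeros(256, dtype=np.uint8)
    for i, b in enumerate("ACGT", start=1):
        code[ord(b)] = i
    mat = np.zeros((len(seqs), length), dtype=np.uint8)
    for i, s in enumerate(seqs):
        lo, hi = s.region_covered
        mat[i, lo - 1:hi] = code[np.frombuffer(s.seq.encode(), dtype=np.uint8)]
    lo, hi = region or (1, length)
    patterns = []
    sub = mat[:, lo - 1:hi]
    n_states = np.array([
        len(np.unique(col[col > 0])) for col in sub.T])
    bases = " ACGT"
    for off in np.nonzero(n_states >= 2)[0]:
        pos = lo + int(off)
        if pos in masked:
            continue
        col = sub[:, off]
        patterns.append(SitePattern(
            position=pos,
            states={s.id: (bases[c] if c else None)
                    for s, c in zip(seqs, col)}))
    return patterns


# --------------------------------------------------------------------------
# Small parsimony (Hartigan / Fitch)
# --------------------------------------------------------------------------

_FULL = frozenset(VALID_BASES)


@dataclass
class FitchResult:
    branch_mutations: dict  # node name -> list[Mutation]
    total_changes: int
    ambiguous_sites: set[int] = field(default_factory=set)
    skipped_sites: set[int] = field(default_factory=set)


def _hartigan_sets(tree: HaplogroupTree, states: dict) -> tuple[dict, int]:
    """Bottom-up pass: optimal state sets per node and the minimum number of
    changes. Missing leaves carry the universal set."""
    sets: dict[int, frozenset] = {}
    cost = 0
    for node in tree.postorder():
        if node.is_leaf:
            b = states.get(node.name)
            sets[id(node)] = frozenset((b,)) if b else _FULL
            continue
        counts: Counter = Counter()
        for c in node.children:
            for s in sets[id(c)]:
                counts[s] += 1
        k = max(counts.values())
        sets[id(node)] = frozenset(s for s, c in counts.items() if c == k)
        # Hartigan: a node with m children of which at most k agree on any
        # one state forces m - k changes below it
        cost += len(node.children) - k
    return sets, cost


def parsimony_score(patterns: Sequence[SitePattern],
                    tree: HaplogroupTree) -> int:
    """Total minimum number of state changes over all sites (unrooted
    parsimony length; invariant under rerooting and leaf order)."""
    _check_taxa(patterns, tree)
    total = 0
    for pat in patterns:
        if not pat.observed():
            continue
        _, cost = _hartigan_sets(tree, pat.states)
        total += cost
    return total


def _check_taxa(patterns: Sequence[SitePattern], tree: HaplogroupTree) -> None:
    leaves = set(tree.leaf_names())
    for pat in patterns:
        missing = leaves - set(pat.states)
        if missing:
            raise MitoIOError(
                f"np {pat.position}: no observation entry for leaves "
                f"{sorted(missing)}")


def fitch_assign(patterns: Sequence[SitePattern],
                 tree: HaplogroupTree) -> FitchResult:
    """Minimum-change assignment of per-site state transitions to branches.

    Sites needing two or more changes are flagged recurrent on every
    resulting mutation; a change back to a state carried by an ancestor of
    the branch is flagged as a back mutation. Equally parsimonious
    placements are resolved deterministically (alphabetical root state,
    parent-state propagation, which keeps changes as close to the root as a
    minimal assignment allows on unary chains); such sites are flagged
    ambiguous.
    """
    _check_taxa(patterns, tree)
    branch_mut: dict[str, list[Mutation]] = {}
    total = 0
    ambiguous: set[int] = set()
    skipped: set[int] = set()
    for pat in patterns:
        if not pat.observed():
            skipped.add(pat.position)
            logger.warning("np %d: all states missing; site skipped",
                           pat.position)
            continue
        sets, cost = _hartigan_sets(tree, pat.states)
        total += cost
        site_changes: list[tuple[Node, str, str]] = []
        amb = len(sets[id(tree.root)]) > 1

        def assign(node: Node, parent_state: str | None,
                   path_states: tuple[str, ...]):
            nonlocal amb
            opts = sets[id(node)]
            if parent_state is not None and parent_state in opts:
                state = parent_state
            else:
                state = min(opts)
                if len(opts) > 1:
                    amb = True
                if parent_state is not None:
                    site_changes.append((node, parent_state, state))
            for c in node.children:
                assign(c, state, path_states + (state,))

        assign(tree.root, None, ())
        recurrent = len(site_changes) > 1
        for node, from_state, to_state in site_changes:
            # a reversion: the derived state equals a state above the parent
            states_above = _ancestor_states(tree, sets, node, pat)
            is_back = to_state in states_above[:-1]
            if to_state == TRANSITION_PARTNER.get(from_state):
                mut = Mutation(position=pat.position, kind=KIND_TRANSITION,
                               back_mutation=is_back, recurrent=recurrent)
            else:
                mut = Mutation(position=pat.position, kind=KIND_TRANSVERSION,
                               derived_base=to_state, back_mutation=is_back,
                               recurrent=recurrent)
            branch_mut.setdefault(node.name, []).append(mut)
        if amb:
            ambiguous.add(pat.position)
    return FitchResult(branch_mutations=branch_mut, total_changes=total,
                       ambiguous_sites=ambiguous, skipped_sites=skipped)


def _ancestor_states(tree: HaplogroupTree, sets: dict, node: Node,
                     pat: SitePattern) -> list[str]:
    """States assigned along root -> node.parent under the same deterministic
    refinement used by fitch_assign."""
    chain = []
    n = node.parent
    while n is not None:
        chain.append(n)
        n = n.parent
    chain.reverse()
    states, parent_state = [], None
    for n in chain:
        opts = sets[id(n)]
        state = parent_state if (parent_state in opts) else min(opts)
        states.append(state)
        parent_state = state
    return states


# --------------------------------------------------------------------------
# Exhaustive most-parsimonious tree search (small taxon sets)
# --------------------------------------------------------------------------

MAX_EXHAUSTIVE_TAXA = 9


def _rooted_insertions(tree, leaf):
    yield (tree, leaf)
    if isinstance(tree, tuple):
        a, b = tree
        for na in _rooted_insertions(a, leaf):
            yield (na, b)
        for nb in _rooted_insertions(b, leaf):
            yield (a, nb)


def _enumerate_unrooted(taxa: Sequence[str]):
    """All unrooted binary topologies as rooted shapes over taxa[1:] hung
    below a pendant taxa[0] ((2n-5)!! of them)."""
    shapes = [taxa[1]]
    for t in taxa[2:]:
        shapes = [s2 for s in shapes for s2 in _rooted_insertions(s, t)]
    return shapes


def _score_shape(shape, pendant: str, patterns) -> int:
    def site_sets(tree, states):
        if isinstance(tree, str):
            b = states.get(tree)
            return (frozenset((b,)) if b else _FULL), 0
        (sa, ca), (sb, cb) = (site_sets(t, states) for t in tree)
        inter = sa & sb
        if inter:
            return inter, ca + cb
        return sa | sb, ca + cb + 1

    total = 0
    for pat in patterns:
        s, c = site_sets((pendant, shape), pat.states)
        total += c
    return total


def _shape_to_tree(shape, pendant: str) -> HaplogroupTree:
    def convert(t) -> Node:
        if isinstance(t, str):
            return Node(t)
        node = Node()
        for sub in t:
            node.add_child(convert(sub))
        return node

    root = Node()
    root.add_child(Node(pendant))
    root.add_child(convert(shape))
    return HaplogroupTree(root)


def unrooted_splits(tree: HaplogroupTree) -> frozenset:
    """Non-trivial leaf bipartitions, canonicalised for topology comparison."""
    leaves = frozenset(tree.leaf_names())
    splits = set()
    for node in tree.preorder():
        if node.parent is None or node.is_leaf:
            continue
        stack, under = [node], set()
        while stack:
            n = stack.pop()
            if n.is_leaf:
                under.add(n.name)
            stack.extend(n.children)
        side = frozenset(under)
        if 1 < len(side) < len(leaves) - 1:
            splits.add(min(side, leaves - side, key=sorted))
    return frozenset(splits)


def mp_search_exhaustive(patterns: Sequence[SitePattern],
                         taxa: Sequence[str]) -> list[HaplogroupTree]:
    """All most-parsimonious unrooted topologies on a small taxon set,
    found by exhaustive stepwise-addition enumeration.

    Deterministic output order (canonical newick of each best tree).
    """
    taxa = list(taxa)
    if len(taxa) > MAX_EXHAUSTIVE_TAXA:
        raise MitoIOError(
            f"{len(taxa)} taxa exceed the exhaustive-search bound "
            f"({MAX_EXHAUSTIVE_TAXA}); map mutations on a fixed topology "
            "instead")
    if len(taxa) < 3:
        raise MitoIOError("need at least 3 taxa")
    for pat in patterns:
        missing = set(taxa) - set(pat.states)
        if missing:
            raise MitoIOError(
                f"np {pat.position}: no observation for taxa {sorted(missing)}")
    pendant = taxa[0]
    if len(taxa) == 3:
        shapes = [(taxa[1], taxa[2])]
    else:
        shapes = _enumerate_unrooted(taxa)
    scored = [(_score_shape(s, pendant, patterns), s) for s in shapes]
    best = min(c for c, _ in scored)
    trees = [_shape_to_tree(s, pendant) for c, s in scored if c == best]
    return sorted(trees, key=lambda t: t.to_newick(include_mutations=False))


# --------------------------------------------------------------------------
# Diagnostic marker panels
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class PanelEntry:
    haplogroup: str
    mutation: Mutation
    mode: str  # "presence" | "absence"
    window: str
    interval: tuple[int, int]


@dataclass
class MarkerPanel:
    """Per-haplogroup diagnostic markers restricted to assayable windows.

    Entries are keyed by the haplogroup whose stem branch introduces each
    marker; a classifier evaluates the full root path by accumulating the
    entries of a haplogroup and of all its ancestors. ``not_distinguishable``
    lists named haplogroups with no in-window marker of their own.
    """

    entries: list[PanelEntry]
    frame: str = RIMINI_1.name
    windows: dict = field(default_factory=lambda: {"COI": COI_WINDOW,
                                                   "ND5": ND5_WINDOW})
    not_distinguishable: list[str] = field(default_factory=list)

    def haplogroups(self) -> list[str]:
        seen: dict[str, None] = {}
        for e in self.entries:
            seen.setdefault(e.haplogroup)
        return sorted(seen, key=lambda h: (len(base_name(h)), h))

    def entries_for(self, haplogroup: str) -> list[PanelEntry]:
        return [e for e in self.entries if e.haplogroup == haplogroup]

    def path_entries(self, haplogroup: str) -> list[PanelEntry]:
        """Entries of the haplogroup and of every panel ancestor."""
        return [e for e in self.entries if is_under(haplogroup, e.haplogroup)]

    def positions(self) -> set[int]:
        return {e.mutation.position for e in self.entries}

    def to_dataframe(self) -> pd.DataFrame:
        rows = [{"haplogroup": e.haplogroup, "marker": e.mutation.label(),
                 "mode": e.mode, "window": e.window,
                 "start": e.interval[0], "end": e.interval[1]}
                for e in self.entries]
        return pd.DataFrame(rows, columns=["haplogroup", "marker", "mode",
                                           "window", "start", "end"])


def derive_marker_panel(tree: HaplogroupTree,
                        windows: dict | None = None) -> MarkerPanel:
    """Diagnostic marker panel from the branch mutations of a haplogroup tree.

    For every named haplogroup, its stem-branch substitutions that fall in an
    assayable window become markers: events adding a difference from the
    reference are presence markers, events restoring the reference base
    (back mutations, e.g. nps 1536/2165 on the A1a1a1 stem) are absence
    markers. Recurrent, heteroplasmic and annotation-only events are
    excluded. Haplogroups without any in-window stem marker are reported as
    not distinguishable.
    """
    windows = windows or {"COI": COI_WINDOW, "ND5": ND5_WINDOW}
    entries: list[PanelEntry] = []
    orphans: list[str] = []
    for node in tree.named_haplogroups():
        found = False
        for ev, mode in tree.stem_marker_events(node):
            pos = ev.mutation.position
            for wname, (lo, hi) in windows.items():
                if lo <= pos <= hi:
                    entries.append(PanelEntry(
                        haplogroup=node.name, mutation=ev.mutation,
                        mode=mode, window=wname, interval=(lo, hi)))
                    found = True
                    break
        if not found:
            orphans.append(node.name)
            logger.info("haplogroup %s has no in-window diagnostic marker",
                        node.name)
    return MarkerPanel(entries=entries, frame=tree.frame, windows=dict(windows),
                       not_distinguishable=orphans)
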