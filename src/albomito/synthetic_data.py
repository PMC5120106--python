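"""Synthetic mitogenome data with the statistical structure the analyses
assume.

The generators produce (i) an A+T-rich root sequence, (ii) leaf mitogenomes
evolved along a haplogroup tree by applying each branch's mutation list —
homoplasy-free unless the fixture itself encodes recurrence — together with
a truth ledger, (iii) partial COI/ND5 fragments of the kind surveyed in the
literature, (iv) population samples drawn multinomially at specified
haplogroup frequencies (the published worldwide survey frequencies by
default), and (v) control-region sequences with chosen tandem-repeat copy
numbers. Every generator is fully determined by its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classifier import OTHERS, FragmentRecord
from .control_region import DEFAULT_AT_SPACER, NOMINAL_UNIT_I, NOMINAL_UNIT_II
from .haplotree import HaplogroupTree, MarkerPanel, Node
from .mito_io import (
    COI_WINDOW,
    KIND_DELETION,
    KIND_TRANSITION,
    KIND_TRANSVERSION,
    MitoIOError,
    MitoSequence,
    ND5_WINDOW,
    RIMINI_1,
    TRANSITION_PARTNER,
    logger,
)

#: Default base composition (A, C, G, T): A+T-rich, as in culicid mtDNA.
DEFAULT_COMPOSITION: tuple[float, float, float, float] = (0.40, 0.10, 0.10, 0.40)
#: Default transition fraction among simulated private mutations (the
#: observed mutation spectrum is strongly transition-dominated).
DEFAULT_TS_FRACTION: float = 0.9

_BASES = np.array(list("ACGT"))
_PURINES = {"A", "G"}


@dataclass
class SimulationConfig:
    """Bundle of generator settings; the defaults are the study conditions."""

    seed: int = 0
    root_length: int = RIMINI_1.length
    base_composition: tuple[float, float, float, float] = DEFAULT_COMPOSITION
    ts_fraction: float = DEFAULT_TS_FRACTION
    private_noise_rate: float = 0.0
    coi_window: tuple[int, int] = COI_WINDOW
    nd5_window: tuple[int, int] = ND5_WINDOW


@dataclass
class SimulatedGenomes:
    root_seq: str
    node_seqs: dict
    leaves: list[MitoSequence]
    ledger: pd.DataFrame
    frame: str = RIMINI_1.name


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)


def simulate_root(length: int,
                  composition: tuple[float, float, float, float] | None = None,
                  seed: int | np.random.Generator = 0) -> str:
    """Random root sequence with a given (A, C, G, T) composition."""
    if length < 1:
        raise MitoIOError("root length must be >= 1")
    comp = np.asarray(composition if composition is not None
                      else DEFAULT_COMPOSITION, dtype=float)
    if comp.shape != (4,) or (comp < 0).any() or abs(comp.sum() - 1) > 1e-9:
        raise MitoIOError(f"invalid base composition {composition!r}")
    rng = _rng(seed)
    return "".join(rng.choice(_BASES, size=length, p=comp))


def _apply_event(seq: list, mutation) -> None:
    i = mutation.position - 1
    if i >= len(seq):
        raise MitoIOError(
            f"np {mutation.position} beyond simulated length {len(seq)}")
    if mutation.kind == KIND_TRANSITION:
        seq[i] = TRANSITION_PARTNER[seq[i]]
    elif mutation.kind == KIND_TRANSVERSION:
        seq[i] = mutation.derived_base
    elif mutation.kind == KIND_DELETION:
        seq[i] = "-"
    # insertions are annotation-only: they cannot be placed without adding
    # alignment columns and are never applied


def simulate_along_tree(tree: HaplogroupTree,
                        root: str | None = None,
                        seed: int | np.random.Generator = 0,
                        length: int | None = None,
                        private_noise_rate: float = 0.0,
                        forbidden_positions: set[int] | frozenset[int] = frozenset(),
                        ts_fraction: float = DEFAULT_TS_FRACTION,
                        ) -> SimulatedGenomes:
    """Evolve sequences along a haplogroup tree from its branch mutations.

    Each node's haplotype is its parent's plus the branch events
    (transitions toggle between partners, transversions set the stated
    base, deletions gap the column; heteroplasmic, insertion and
    annotation-only events are skipped). Optional per-leaf private noise
    adds extra substitutions at positions outside ``forbidden_positions``
    (pass the marker-panel positions to keep diagnostics intact). The truth
    ledger records every applied event with its branch of origin.
    """
    rng = _rng(seed)
    length = length or RIMINI_1.length
    if root is None:
        root = simulate_root(length, seed=rng)
    seq = list(root.upper())
    # make transversion events visible: the ancestral base must belong to
    # the other purine/pyrimidine class than the stated derived base
    for node in tree.preorder():
        for ev in node.events:
            m = ev.mutation
            if ev.scorable and m.kind == KIND_TRANSVERSION:
                anc = "A" if m.derived_base not in _PURINES else "C"
                seq[m.position - 1] = anc
    root_seq = "".join(seq)

    node_seqs: dict[str, str] = {}
    rows = []

    def walk(node: Node, parent_seq: list):
        s = list(parent_seq)
        for ev in node.events:
            m = ev.mutation
            if not ev.scorable and m.kind != KIND_DELETION:
                continue
            if ev.annotation_only or m.heteroplasmic:
                continue
            _apply_event(s, m)
            rows.append({"branch": node.name, "position": m.position,
                         "mutation": m.label(), "private": False})
        node_seqs[node.name] = "".join(s)
        for c in node.children:
            walk(c, s)

    walk(tree.root, seq)
    node_seqs[tree.root.name] = root_seq

    leaves = []
    for leaf in tree.leaves():
        s = node_seqs[leaf.name]
        if private_noise_rate > 0:
            s_list = list(s)
            n_extra = rng.binomial(len(s_list), private_noise_rate)
            allowed = [p for p in range(1, len(s_list) + 1)
                       if p not in forbidden_positions and
                       s_list[p - 1] in TRANSITION_PARTNER]
            for pos in rng.choice(allowed, size=min(n_extra, len(allowed)),
                                  replace=False):
                pos = int(pos)
                old = s_list[pos - 1]
                if rng.random() < ts_fraction:
                    new = TRANSITION_PARTNER[old]
                else:
                    new = str(rng.choice(
                        [b for b in "ACGT"
                         if b != old and b != TRANSITION_PARTNER[old]]))
                s_list[pos - 1] = new
                rows.append({"branch": leaf.name, "position": pos,
                             "mutation": str(pos), "private": True})
            s = "".join(s_list)
            node_seqs[leaf.name] = s
        leaves.append(MitoSequence(
            id=leaf.name, seq=s, region_covered=(1, len(s)),
            source="synthetic", frame=tree.frame))
    ledger = pd.DataFrame(rows, columns=["branch", "position", "mutation",
                                         "private"])
    return SimulatedGenomes(root_seq=root_seq, node_seqs=node_seqs,
                            leaves=leaves, ledger=ledger, frame=tree.frame)


# --------------------------------------------------------------------------
# Fragments and populations
# --------------------------------------------------------------------------

_WINDOWS = {"COI": COI_WINDOW, "ND5": ND5_WINDOW}


def sample_fragments(genomes,
                     window: str | tuple[int, int] = "COI",
                     n_per_genome: int = 1,
                     length: int | None = None,
                     seed: int | np.random.Generator = 0,
                     population: str = "",
                     truth: dict | None = None) -> list[FragmentRecord]:
    """Cut partial-gene fragments out of full genomes.

    ``genomes`` maps name -> sequence (or is a list of MitoSequence).
    Fragments span the whole window unless ``length`` asks for shorter
    sub-windows at random offsets. Truth haplogroup labels, when supplied,
    ride along for benchmarking.
    """
    rng = _rng(seed)
    if isinstance(genomes, list):
        genomes = {s.id: s.seq for s in genomes}
    wname, (lo, hi) = _resolve_window(window)
    if hi < lo:
        raise MitoIOError(f"empty window {window!r}")
    out = []
    for name in genomes:
        seq = genomes[name]
        if len(seq) < hi:
            raise MitoIOError(
                f"window {wname} {lo}-{hi} outside genome {name!r} "
                f"(length {len(seq)})")
        for i in range(n_per_genome):
            if length is None or length >= hi - lo + 1:
                s, e = lo, hi
            elif length < 1:
                raise MitoIOError("fragment length must be >= 1")
            else:
                s = int(rng.integers(lo, hi - length + 2))
                e = s + length - 1
            fid = name if n_per_genome == 1 else f"{name}_f{i + 1}"
            out.append(FragmentRecord(
                sequence=MitoSequence(
                    id=fid, seq=seq[s - 1:e], region_covered=(s, e),
                    population=population, source="synthetic"),
                window=wname,
                truth=(truth or {}).get(name)))
    return out


def _resolve_window(window) -> tuple[str, tuple[int, int]]:
    if isinstance(window, str):
        try:
            return window, _WINDOWS[window]
        except KeyError:
            raise MitoIOError(f"unknown window {window!r}") from None
    return "custom", tuple(window)


@dataclass
class PopulationSpec:
    """One population of the survey: name, region, sample size and the
    generating haplogroup frequency vector (residual mass -> "others")."""

    population: str
    region: str
    n: int
    frequencies: dict  # haplogroup name (or "others") -> frequency

    def __post_init__(self):
        total = sum(self.frequencies.values())
        if total > 1 + 1e-9:
            raise MitoIOError(
                f"{self.population}: frequencies sum to {total} > 1")


def population_specs_from_survey(table2: pd.DataFrame) -> list[PopulationSpec]:
    """Generating specs at the published per-population frequencies
    (count/N from the survey table's counts)."""
    cols = ["A1a1a1", "A1a2", "A1b", "A2", "A3"]
    specs = []
    for row in table2.itertuples(index=False):
        freqs = {c: getattr(row, c) / row.N for c in cols
                 if getattr(row, c) > 0}
        specs.append(PopulationSpec(population=row.population,
                                    region=row.region, n=int(row.N),
                                    frequencies=freqs))
    return specs


def _others_haplotype(tree: HaplogroupTree, genomes: SimulatedGenomes,
                      n_mutations: int = 5) -> str:
    """A basal lineage carrying none of the panel markers: the root plus a
    few substitutions at positions used by no branch and no assay window."""
    used = {ev.mutation.position for n in tree.preorder() for ev in n.events}
    s = list(genomes.root_seq)
    placed = 0
    for pos in range(len(s) - 400, 0, -7):
        if placed >= n_mutations:
            break
        in_window = any(lo <= pos <= hi for lo, hi in _WINDOWS.values())
        if pos in used or in_window or s[pos - 1] not in TRANSITION_PARTNER:
            continue
        s[pos - 1] = TRANSITION_PARTNER[s[pos - 1]]
        placed += 1
    return "".join(s)


def simulate_population(specs: list[PopulationSpec],
                        tree: HaplogroupTree,
                        seed: int | np.random.Generator = 0,
                        window: str = "COI",
                        panel: MarkerPanel | None = None,
                        private_noise_rate: float = 0.0,
                        genomes: SimulatedGenomes | None = None,
                        ) -> tuple[list[FragmentRecord], pd.DataFrame]:
    """Draw population samples at specified haplogroup frequencies.

    Each individual's mitogenome is the haplotype of its drawn haplogroup's
    node (an unlisted basal lineage for the "others" residual), optionally
    perturbed by private noise away from marker sites, and is then reduced
    to a partial fragment of the requested window. Returns the fragments
    (truth-labelled) and a truth count table per population.
    """
    rng = _rng(seed)
    genomes = genomes or simulate_along_tree(tree, seed=rng)
    others_seq = _others_haplotype(tree, genomes)
    wname, (lo, hi) = _resolve_window(window)
    forbidden = frozenset(panel.positions()) if panel else frozenset()
    fragments: list[FragmentRecord] = []
    truth_rows = []
    for spec in specs:
        names = list(spec.frequencies)
        for hg in names:
            if hg != OTHERS and not any(
                    n.name == hg for n in tree.preorder()):
                raise MitoIOError(
                    f"{spec.population}: haplogroup {hg!r} not in tree")
        probs = [spec.frequencies[h] for h in names]
        resid = 1.0 - sum(probs)
        if resid > 1e-9 or OTHERS in names:
            if OTHERS not in names:
                names.append(OTHERS)
                probs.append(resid)
            else:
                probs[names.index(OTHERS)] += resid
        counts = rng.multinomial(spec.n, np.asarray(probs) / sum(probs)) \
            if spec.n > 0 else np.zeros(len(names), dtype=int)
        idx = 0
        for hg, k in zip(names, counts):
            truth_rows.append({"population": spec.population,
                               "region": spec.region, "haplogroup": hg,
                               "count": int(k)})
            base_seq = others_seq if hg == OTHERS else genomes.node_seqs[hg]
            for _ in range(int(k)):
                idx += 1
                s = base_seq
                if private_noise_rate > 0:
                    s = _perturb(s, private_noise_rate, forbidden, rng)
                fragments.append(FragmentRecord(
                    sequence=MitoSequence(
                        id=f"{spec.population}|{idx}", seq=s[lo - 1:hi],
                        region_covered=(lo, hi),
                        population=spec.population, source="synthetic"),
                    window=wname, truth=hg))
    truth = pd.DataFrame(truth_rows, columns=["population", "region",
                                              "haplogroup", "count"])
    logger.info("simulated %d fragments across %d populations",
                len(fragments), len(specs))
    return fragments, truth


def _perturb(seq: str, rate: float, forbidden: frozenset[int],
             rng: np.random.Generator) -> str:
    s = list(seq)
    n = rng.binomial(len(s), rate)
    if n == 0:
        return seq
    allowed = [p for p in range(1, len(s) + 1)
               if p not in forbidden and s[p - 1] in TRANSITION_PARTNER]
    for pos in rng.choice(allowed, size=min(n, len(allowed)), replace=False):
        s[int(pos) - 1] = TRANSITION_PARTNER[s[int(pos) - 1]]
    return "".join(s)


# --------------------------------------------------------------------------
# Control region
# --------------------------------------------------------------------------


def _break_runs(s: np.ndarray, max_run: int = 6) -> np.ndarray:
    """Cap homopolymer runs so random segments cannot mimic the conserved
    poly-T/poly-A blocks."""
    run = 1
    for i in range(1, len(s)):
        if s[i] == s[i - 1]:
            run += 1
            if run > max_run:
                s[i] = {"A": "C", "C": "A", "G": "T", "T": "G"}[s[i]]
                run = 1
        else:
            run = 1
    return s


def _random_segment(rng, length: int, comp) -> str:
    seg = rng.choice(_BASES, size=length, p=comp)
    return "".join(_break_runs(seg))


def simulate_control_region(n_i: int, n_ii: int,
                            unit_len_i: int = NOMINAL_UNIT_I,
                            unit_len_ii: int = NOMINAL_UNIT_II,
                            per_copy_noise: float = 0.0,
                            at_spacer_len: int = DEFAULT_AT_SPACER,
                            seed: int | np.random.Generator = 0,
                            ) -> tuple[str, dict]:
    """Control region with chosen repeat copy numbers.

    Layout (5'->3'): flank, poly-T block, type I array x n_i, poly-T +
    GC-rich block, A+T-rich spacer, type II array x n_ii, poly-A block,
    flank. ``per_copy_noise`` is the per-base substitution probability
    applied independently to every copy. Returns the sequence and the truth
    (copy numbers and unit sequences).
    """
    if n_i < 1 or n_ii < 1:
        raise MitoIOError("copy numbers must be >= 1")
    if not 0 <= per_copy_noise < 0.1:
        raise MitoIOError("per-copy noise must be in [0, 0.1)")
    rng = _rng(seed)
    unit_comp = (0.30, 0.20, 0.20, 0.30)
    at_comp = (0.42, 0.08, 0.08, 0.42)

    def noisy(unit: str) -> str:
        if per_copy_noise == 0:
            return unit
        u = list(unit)
        for i in range(len(u)):
            if rng.random() < per_copy_noise:
                u[i] = str(rng.choice([b for b in "ACGT" if b != u[i]]))
        return "".join(u)

    unit_i = _random_segment(rng, unit_len_i, unit_comp)
    unit_ii = _random_segment(rng, unit_len_ii, unit_comp)
    gc_block = "".join(rng.choice(np.array(["G", "C"]), size=20))
    parts = [
        _random_segment(rng, 25, at_comp),
        "T" * 12,
        "".join(noisy(unit_i) for _ in range(n_i)),
        "T" * 10 + gc_block,
        _random_segment(rng, at_spacer_len, at_comp),
        "".join(noisy(unit_ii) for _ in range(n_ii)),
        "A" * 10,
        _random_segment(rng, 25, at_comp),
    ]
    seq = "".join(parts)
    truth = {"n_i": n_i, "n_ii": n_ii, "unit_i": unit_i, "unit_ii": unit_ii,
             "length": len(seq)}
    return seq, truth
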