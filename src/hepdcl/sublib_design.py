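"""Mass-degeneracy-aware sublibrary design.

A full one-pot library of one core and n aldehydes contains members whose
monoisotopic masses coincide (isomeric aldehydes give literally identical
formulas), so single-run LC-MS cannot quantify them.  The remedy is to split
the aldehyde panel into sublibraries such that within each reaction mixture
every implied product (all mono- and bis-adducts over the subset) has a
unique mass, while across sublibraries every measurable aldehyde pair is
still realized at least once.

The covering design is produced by a deterministic greedy set cover: seed a
sublibrary with the lexicographically smallest uncovered pair, then grow it
with the aldehyde that covers the most still-uncovered pairs subject to the
no-degeneracy validation, ties broken by id.  Pairs that are degenerate
already in their own two-aldehyde context (e.g. positional isomers) are
degenerate in every larger context too and are reported as uncovered.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations_with_replacement
from typing import Dict, FrozenSet, List, Mapping, Optional, Sequence, Tuple

from .chemlib import BuildingBlock, LibraryMember, enumerate_library

Pair = Tuple[str, str]  # unordered, stored sorted; self-pairs allowed

__all__ = [
    "Sublibrary",
    "DesignReport",
    "validate_sublibrary",
    "design_sublibraries",
    "pair_coverage",
]


@dataclass(frozen=True)
class Sublibrary:
    id: int
    aldehyde_ids: FrozenSet[str]
    members: Tuple[LibraryMember, ...]

    def pairs(self) -> List[Pair]:
        ids = sorted(self.aldehyde_ids)
        return [tuple(p) for p in combinations_with_replacement(ids, 2)]


@dataclass(frozen=True)
class DesignReport:
    sublibraries: Tuple[Sublibrary, ...]
    covered_pairs: FrozenSet[Pair]
    uncovered_pairs: Mapping[Pair, str]  # pair -> reason

    def all_pairs(self) -> FrozenSet[Pair]:
        return frozenset(self.covered_pairs) | frozenset(self.uncovered_pairs)


def _canonical_pair(x: str, y: str) -> Pair:
    return (x, y) if x <= y else (y, x)


def validate_sublibrary(
    aldehyde_ids: Sequence[str],
    core: BuildingBlock,
    blocks: Mapping[str, BuildingBlock],
    tol: float,
) -> Tuple[bool, List[Tuple[str, str]]]:
    """Check that all implied member masses are pairwise > tol apart.

    Returns ``(ok, violating member-id pairs)``.  The implied members are
    all mono- and bis-adducts over the aldehyde subset.
    """
    if tol <= 0:
        raise ValueError("tol must be > 0")
    alds = [blocks[a] for a in sorted(set(aldehyde_ids))]
    members = sorted(enumerate_library(core, alds), key=lambda m: m.mono_mass)
    violations = []
    for a, b in zip(members, members[1:]):
        if b.mono_mass - a.mono_mass <= tol:
            violations.append((a.id, b.id))
    return (not violations, violations)


def design_sublibraries(
    aldehydes: Sequence[BuildingBlock],
    core: BuildingBlock,
    tol: float,
    max_size: int = 6,
    seed: Optional[int] = None,
) -> DesignReport:
    """Greedy covering design of non-degenerate sublibraries.

    Every pair of aldehydes (including self-pairs) that is not intrinsically
    mass-degenerate appears in at least one sublibrary; every sublibrary
    passes :func:`validate_sublibrary`.  The greedy order and tie-breaks are
    fully deterministic, so ``seed`` is accepted for interface symmetry with
    the stochastic stages but has no effect on the output.
    """
    if max_size < 2:
        raise ValueError("max_size must be >= 2")
    del seed  # deterministic by construction
    blocks = {a.id: a for a in aldehydes}
    ids = sorted(blocks)
    if not ids:
        raise ValueError("empty aldehyde list")

    def ok(subset: Sequence[str]) -> bool:
        return validate_sublibrary(subset, core, blocks, tol)[0]

    uncovered_reasons: Dict[Pair, str] = {}
    coverable: List[Pair] = []
    for x, y in combinations_with_replacement(ids, 2):
        context = [x] if x == y else [x, y]
        if ok(context):
            coverable.append((x, y))
        else:
            uncovered_reasons[(x, y)] = "mass-degenerate in every candidate context"

    covered: set = set()
    subs: List[Sublibrary] = []
    while True:
        remaining = [p for p in coverable if p not in covered]
        if not remaining:
            break
        seed_pair = min(remaining)
        subset = sorted(set(seed_pair))
        # grow while a valid addition covers new pairs
        while len(subset) < max_size:
            best_id, best_gain = None, 0
            for cand in ids:
                if cand in subset:
                    continue
                trial = sorted(subset + [cand])
                if not ok(trial):
                    continue
                gain = sum(
                    1
                    for p in (_canonical_pair(cand, other) for other in trial)
                    if p in coverable and p not in covered
                )
                if gain > best_gain:
                    best_id, best_gain = cand, gain
            if best_id is None:
                break
            subset.append(best_id)
            subset.sort()
        members = tuple(enumerate_library(core, [blocks[i] for i in subset]))
        sub = Sublibrary(
            id=len(subs) + 1, aldehyde_ids=frozenset(subset), members=members
        )
        subs.append(sub)
        covered.update(p for p in sub.pairs() if p in coverable)

    return DesignReport(
        sublibraries=tuple(subs),
        covered_pairs=frozenset(covered),
        uncovered_pairs=dict(uncovered_reasons),
    )


def pair_coverage(report: DesignReport) -> Dict[Pair, int]:
    """Count of sublibraries containing each pair; 0 for uncovered pairs."""
    counts: Dict[Pair, int] = {p: 0 for p in report.all_pairs()}
    for sub in report.sublibraries:
        for p in sub.pairs():
            counts[p] = counts.get(p, 0) + 1
    return counts
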