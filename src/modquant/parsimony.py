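"""Parsimony ("minimal pathway set") filtering of module calls.

For each sample, find the smallest set of modules whose combined ortholog
content explains every observed ortholog that occurs in at least one module —
an unweighted minimum set cover.  Modules that map observed orthologs but are
not needed by any minimal cover candidate set are flagged as redundant; this
suppresses artifact module calls caused by enzymes shared between modules
(a truly expressed module "lights up" other modules it shares enzymes with).

Exact mode solves the cover by branch-and-bound (optimal); greedy mode uses
the classical largest-new-coverage heuristic.  Observed orthologs found in no
module are reported as unexplained and excluded from the cover requirement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from .db import ModuleDB, ModuleDefinition, ortholog_universe
from .matrix import AbundanceMatrix
from .quantify import ModuleProfile

__all__ = [
    "ParsimonyResult",
    "module_ortholog_content",
    "min_pathway_set",
    "apply_parsimony",
]

#: Candidate-set size up to which mode="auto" uses the exact solver.
AUTO_EXACT_LIMIT = 20


def module_ortholog_content(module: ModuleDefinition) -> frozenset[str]:
    """All orthologs a module can use: union over steps, alternatives, members."""
    content: set[str] = set()
    for step in module.steps:
        for alt in step.alternatives:
            content.update(alt.members)
    return frozenset(content)


@dataclass(frozen=True)
class ParsimonyResult:
    """Minimal explaining module set for one sample.

    ``observed`` holds the explainable observed orthologs (those occurring in
    at least one module); ``unexplained`` the rest.  ``removed`` are modules
    that map >= 1 observed ortholog but are not in the minimal set.
    """

    sample: str
    observed: frozenset[str]
    unexplained: frozenset[str]
    kept: frozenset[str]
    removed: frozenset[str]
    method: str  # "exact" | "greedy"
    optimal: bool


def _greedy_cover(contents: dict[str, frozenset[str]], target: set[str]) -> list[str]:
    """Greedy set cover: largest new coverage first, ties by module id."""
    uncovered = set(target)
    kept: list[str] = []
    while uncovered:
        best_id, best_gain = None, 0
        for mid in sorted(contents):
            gain = len(contents[mid] & uncovered)
            if gain > best_gain:
                best_id, best_gain = mid, gain
        assert best_id is not None  # target subset of union(contents)
        kept.append(best_id)
        uncovered -= contents[best_id]
    return kept


def _exact_cover(contents: dict[str, frozenset[str]], target: set[str]) -> set[str]:
    """Minimum set cover by branch-and-bound, deterministic tie-breaking."""
    if not target:
        return set()
    best = set(_greedy_cover(contents, target))  # upper bound
    cover_by: dict[str, list[str]] = {
        o: sorted(mid for mid, c in contents.items() if o in c) for o in target
    }
    max_size = max(len(c) for c in contents.values())

    def dfs(uncovered: frozenset[str], chosen: tuple[str, ...]) -> None:
        nonlocal best
        if not uncovered:
            if len(chosen) < len(best):
                best = set(chosen)
            return
        if len(chosen) + math.ceil(len(uncovered) / max_size) >= len(best):
            return
        # branch on the hardest-to-cover ortholog
        pivot = min(uncovered, key=lambda o: (len(cover_by[o]), o))
        coverers = sorted(
            cover_by[pivot], key=lambda mid: (-len(contents[mid] & uncovered), mid)
        )
        for mid in coverers:
            dfs(uncovered - contents[mid], chosen + (mid,))

    dfs(frozenset(target), ())
    return best


def min_pathway_set(
    observed: Iterable[str],
    db: ModuleDB,
    mode: str = "auto",
    sample: str = "",
) -> ParsimonyResult:
    """Smallest module set explaining the observed orthologs.

    ``mode`` is "exact", "greedy" or "auto" (exact when there are at most
    ``AUTO_EXACT_LIMIT`` candidate modules).  Orthologs outside the database
    universe are reported as unexplained and never required to be covered.
    """
    if mode not in ("exact", "greedy", "auto"):
        raise ValueError(f"mode must be 'exact', 'greedy' or 'auto', got {mode!r}")
    observed = set(observed)
    universe = set(ortholog_universe(db))
    explainable = observed & universe
    unexplained = observed - universe

    contents = {m.id: module_ortholog_content(m) & explainable for m in db.modules}
    candidates = {mid: c for mid, c in contents.items() if c}

    if mode == "auto":
        mode = "exact" if len(candidates) <= AUTO_EXACT_LIMIT else "greedy"
    if mode == "exact":
        kept = frozenset(_exact_cover(candidates, explainable))
        optimal = True
    else:
        kept_list = _greedy_cover(candidates, explainable)
        kept = frozenset(kept_list)
        # a cover of size <= 1 cannot be beaten (empty target => empty cover)
        optimal = len(kept) <= 1
    removed = frozenset(candidates) - kept
    return ParsimonyResult(
        sample=sample,
        observed=frozenset(explainable),
        unexplained=frozenset(unexplained),
        kept=kept,
        removed=removed,
        method=mode,
        optimal=optimal,
    )


def apply_parsimony(
    profile: ModuleProfile,
    matrix: AbundanceMatrix,
    db: ModuleDB,
    mode: str = "auto",
) -> tuple[ModuleProfile, pd.DataFrame]:
    """Force modules outside each sample's minimal set to absent.

    Parsimony runs on the raw observed orthologs (pre-gate) and is then
    intersected with the coverage gate: a module stays present only if it
    passed the gate *and* belongs to the minimal explaining set.  Coverage
    and abundance grids are retained untouched for transparency.

    Returns the filtered profile and a tidy annotation table
    (sample, module, kept, method, optimal, reason).
    """
    new_present = profile.present.copy()
    rows = []
    for sample in profile.samples:
        col = matrix.data[sample]
        observed = set(col.index[col > 0])
        result = min_pathway_set(observed, db, mode=mode, sample=sample)
        content = {mid: module_ortholog_content(db[mid]) for mid in profile.modules}
        for mid in profile.modules:
            keep = mid in result.kept
            if not keep:
                new_present.loc[mid, sample] = False
            if keep:
                reason = "kept"
            elif content[mid] & result.observed:
                reason = "redundant_by_parsimony"
            else:
                reason = "no_observed_orthologs"
            rows.append((sample, mid, keep, result.method, result.optimal, reason))
    table = pd.DataFrame(
        rows, columns=["sample", "module", "kept", "method", "optimal", "reason"]
    )
    return profile.with_present(new_present), table
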