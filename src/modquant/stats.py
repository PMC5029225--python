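"""Two-group differential module analysis.

Module abundances are compared between two sample groups with the two-sided
Wilcoxon rank-sum (Mann–Whitney U) test — meta-omics abundances are
distribution-free and the test is robust to outliers — followed by
Benjamini–Hochberg FDR correction.  Modules failing a prevalence filter are
excluded *before* correction, so the BH family size m counts only informative
modules: uninformative modules would inflate the number of comparisons and
penalise true signals.

The U statistic is computed from midranks.  P-values are exact (full null
distribution of U via the standard count recurrence) when the pooled sample
size is small and there are no ties; otherwise a normal approximation with
tie-corrected variance and a 0.5 continuity correction is used.  The
continuity correction shrinks |U - mean| toward zero with a floor at zero, so
complete equality of the groups yields p = 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _sps

from .quantify import ModuleProfile

__all__ = [
    "EXACT_CUTOFF",
    "GroupDesign",
    "GroupComparison",
    "mann_whitney_u",
    "bh_fdr",
    "compare_groups",
    "comparisons_to_frame",
]

#: Largest pooled sample size for which the exact null distribution is used.
EXACT_CUTOFF = 25


class DesignError(ValueError):
    """Invalid sample-to-group design."""


@dataclass(frozen=True)
class GroupDesign:
    """Assignment of samples to exactly two groups.

    ``group_a`` is the reference group for effect direction (direction
    ``up_in_a`` means larger median in ``group_a``).
    """

    assignment: Mapping[str, str]
    group_a: str
    group_b: str

    def __post_init__(self):
        if self.group_a == self.group_b:
            raise DesignError("group_a and group_b must differ")
        labels = set(self.assignment.values())
        extra = labels - {self.group_a, self.group_b}
        if extra:
            raise DesignError(f"unknown group label(s) in assignment: {sorted(extra)}")
        if len(labels) != 2:
            raise DesignError("assignment must use exactly two distinct group labels")
        for grp in (self.group_a, self.group_b):
            if len(self.samples(grp)) < 2:
                raise DesignError(f"group {grp!r} has fewer than 2 samples")

    def samples(self, label: str) -> list[str]:
        """Samples assigned to ``label``, in assignment order."""
        return [s for s, g in self.assignment.items() if g == label]

    @property
    def all_samples(self) -> list[str]:
        return list(self.assignment)

    @classmethod
    def from_table(
        cls,
        table: Sequence[tuple[str, str]],
        group_a: str | None = None,
        group_b: str | None = None,
    ) -> "GroupDesign":
        """Build a design from (sample, group) pairs.

        When the group labels are not given, ``group_a`` is the label of the
        first sample and ``group_b`` the other label, in order of appearance.
        """
        assignment = {}
        for sample, group in table:
            if sample in assignment:
                raise DesignError(f"sample {sample!r} assigned twice")
            assignment[sample] = group
        labels = list(dict.fromkeys(assignment.values()))
        if len(labels) != 2:
            raise DesignError(
                f"expected exactly 2 group labels, found {len(labels)}: {labels}"
            )
        if group_a is None:
            group_a = labels[0]
        if group_b is None:
            group_b = labels[1] if labels[0] == group_a else labels[0]
        return cls(assignment, group_a, group_b)


@lru_cache(maxsize=None)
def _u_counts(n: int, m: int) -> np.ndarray:
    """Null distribution counts of the Mann-Whitney U statistic.

    ``counts[u]`` is the number of the C(n+m, n) equally likely group
    assignments with U = u, from the recurrence
    c(n, m, u) = c(n-1, m, u-m) + c(n, m-1, u).  Counts stay below 2**53 for
    n+m <= 25, so float64 arithmetic is exact.
    """
    if n == 0 or m == 0:
        return np.ones(1)
    counts = np.zeros(n * m + 1)
    left = _u_counts(n - 1, m)
    counts[m : m + left.size] += left
    right = _u_counts(n, m - 1)
    counts[: right.size] += right
    return counts


def mann_whitney_u(
    x: Sequence[float], y: Sequence[float], exact_cutoff: int = EXACT_CUTOFF
) -> tuple[float, float]:
    """Mann–Whitney U for ``x`` (first group) and two-sided p-value.

    Exact enumeration when ``len(x) + len(y) <= exact_cutoff`` and the pooled
    values are tie-free; otherwise normal approximation with tie-corrected
    variance and continuity correction.  The returned p lies in (0, 1].
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    n, m = x.size, y.size
    combined = np.concatenate([x, y])
    ranks = _sps.rankdata(combined)
    u_stat = float(ranks[:n].sum() - n * (n + 1) / 2)
    has_ties = np.unique(combined).size < n + m

    if n + m <= exact_cutoff and not has_ties:
        counts = _u_counts(n, m)
        total = counts.sum()
        u_int = int(round(u_stat))
        cdf = counts[: u_int + 1].sum() / total
        sf = counts[u_int:].sum() / total
        p = min(1.0, 2.0 * min(cdf, sf))
    else:
        total_n = n + m
        mean_u = n * m / 2.0
        _, tie_counts = np.unique(combined, return_counts=True)
        tie_term = float((tie_counts**3 - tie_counts).sum())
        var_u = n * m / 12.0 * ((total_n + 1) - tie_term / (total_n * (total_n - 1)))
        if var_u <= 0:
            p = 1.0
        else:
            z = max(abs(u_stat - mean_u) - 0.5, 0.0) / np.sqrt(var_u)
            p = min(1.0, 2.0 * float(_sps.norm.sf(z)))
    return u_stat, p


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted values, input order preserved.

    ``q_i = min_{j: p_(j) >= p_(i)} m * p_(j) / rank(j)``, capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a non-empty 1-d sequence")
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


@dataclass(frozen=True)
class GroupComparison:
    """Per-module two-group test result.

    ``tested`` is False for modules that failed the prevalence filter; such
    modules carry no p/q (NaN) and do not count toward the BH family size.
    """

    module: str
    name: str
    n_a: int
    n_b: int
    median_a: float
    median_b: float
    u_stat: float
    p: float
    q: float
    direction: str  # "up_in_a" | "up_in_b" | "none"
    tested: bool
    significant: bool


def _direction(median_a: float, median_b: float) -> str:
    if median_a > median_b:
        return "up_in_a"
    if median_a < median_b:
        return "up_in_b"
    return "none"


def compare_groups(
    profile: ModuleProfile,
    design: GroupDesign,
    min_prevalence: float = 0.2,
    alpha: float = 0.05,
    value: str = "abundance",
    exact_cutoff: int = EXACT_CUTOFF,
) -> list[GroupComparison]:
    """Differential module analysis between the design's two groups.

    Modules present (per the profile's coverage gate) in fewer than
    ``min_prevalence`` of *all* samples are excluded from testing and from
    the BH family.  Absent modules contribute abundance 0 (absence is
    informative), which is why the prevalence filter exists: all-zero noise
    modules would otherwise dilute the correction.  ``value`` selects the
    tested grid: "abundance" (default) or "coverage".
    """
    if not 0.0 <= min_prevalence <= 1.0:
        raise ValueError(f"min_prevalence must be in [0, 1], got {min_prevalence}")
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must be in [0, 1], got {alpha}")
    if value not in ("abundance", "coverage"):
        raise ValueError(f"value must be 'abundance' or 'coverage', got {value!r}")

    samples = profile.samples
    missing = [s for s in samples if s not in design.assignment]
    if missing:
        raise DesignError(f"profiled sample(s) without group assignment: {missing[:5]}")
    samples_a = [s for s in samples if design.assignment[s] == design.group_a]
    samples_b = [s for s in samples if design.assignment[s] == design.group_b]
    if len(samples_a) < 2 or len(samples_b) < 2:
        raise DesignError(
            f"each group needs >= 2 profiled samples "
            f"(got {len(samples_a)} vs {len(samples_b)})"
        )

    data = profile.abundance if value == "abundance" else profile.coverage
    prevalence = profile.present.mean(axis=1)
    tested_ids = [mid for mid in profile.modules if prevalence[mid] >= min_prevalence]
    if len(tested_ids) < 2:
        warnings.warn(
            f"only {len(tested_ids)} module(s) pass the prevalence filter; "
            "multiple-testing correction is degenerate",
            stacklevel=2,
        )

    p_tested: list[float] = []
    u_tested: dict[str, float] = {}
    for mid in tested_ids:
        row = data.loc[mid]
        u_stat, p = mann_whitney_u(
            row[samples_a].to_numpy(), row[samples_b].to_numpy(), exact_cutoff
        )
        u_tested[mid] = u_stat
        p_tested.append(p)
    q_tested = dict(zip(tested_ids, bh_fdr(p_tested))) if tested_ids else {}
    p_map = dict(zip(tested_ids, p_tested))

    results = []
    for mid in profile.modules:
        row = data.loc[mid]
        median_a = float(np.median(row[samples_a]))
        median_b = float(np.median(row[samples_b]))
        tested = mid in p_map
        p = p_map.get(mid, float("nan"))
        q = float(q_tested[mid]) if tested else float("nan")
        results.append(
            GroupComparison(
                module=mid,
                name=str(profile.info.loc[mid, "name"]),
                n_a=len(samples_a),
                n_b=len(samples_b),
                median_a=median_a,
                median_b=median_b,
                u_stat=u_tested.get(mid, float("nan")),
                p=p,
                q=q,
                direction=_direction(median_a, median_b),
                tested=tested,
                significant=bool(tested and q <= alpha),
            )
        )
    return results


def comparisons_to_frame(comparisons: Sequence[GroupComparison]) -> pd.DataFrame:
    """Tabulate comparisons, sorted by (q, p, module id); untested rows last."""
    frame = pd.DataFrame(
        {
            "module": [c.module for c in comparisons],
            "name": [c.name for c in comparisons],
            "n_a": [c.n_a for c in comparisons],
            "n_b": [c.n_b for c in comparisons],
            "median_a": [c.median_a for c in comparisons],
            "median_b": [c.median_b for c in comparisons],
            "U": [c.u_stat for c in comparisons],
            "p": [c.p for c in comparisons],
            "q": [c.q for c in comparisons],
            "direction": [c.direction for c in comparisons],
            "tested": [c.tested for c in comparisons],
            "significant": [c.significant for c in comparisons],
        }
    )
    sort_key = frame.assign(
        _q=frame["q"].fillna(np.inf), _p=frame["p"].fillna(np.inf)
    )
    frame = frame.loc[
        sort_key.sort_values(["_q", "_p", "module"], kind="stable").index
    ].reset_index(drop=True)
    return frame
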