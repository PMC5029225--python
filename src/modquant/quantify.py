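"""Map an ortholog abundance matrix onto a module database.

Per sample and module this produces:

* **coverage** — the fraction of the module's steps detected (step abundance
  > 0); an exact rational k/n_steps.
* **presence** — a strict gate ``coverage > threshold`` (a module must cover
  *more* than the user threshold to be called present).
* **abundance** — the mean (or median) step abundance over the *covered*
  steps only; 0 when no step is covered.

Aggregation semantics: within a complex the abundance is the minimum member
abundance (limiting subunit, AND); across a step's alternatives it is the
maximum (best available route, OR).  Both keep the result in the input's
abundance unit and avoid double-counting promiscuous enzymes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .db import ModuleDB, ModuleDefinition, OrthologComplex, Step, ortholog_universe
from .matrix import AbundanceMatrix

__all__ = [
    "DEFAULT_THRESHOLD",
    "ModuleProfile",
    "complex_abundance",
    "step_abundance",
    "quantify_module",
    "quantify_all",
]

#: Default coverage threshold for the presence gate.  The threshold is a user
#: parameter; 2/3 is the convention of reference-pathway-mapping tools.
DEFAULT_THRESHOLD = 2.0 / 3.0

_ESTIMATORS = ("mean", "median")


def complex_abundance(complex_: OrthologComplex, sample_abundances: Mapping[str, float]) -> float:
    """Abundance of a complex: minimum member abundance (0 if any member absent)."""
    return float(min(sample_abundances.get(m, 0.0) for m in complex_.members))


def step_abundance(step: Step, sample_abundances: Mapping[str, float]) -> float:
    """Abundance of a step: maximum over its alternative complexes.

    A step is *present* iff the result is > 0.
    """
    return max(complex_abundance(alt, sample_abundances) for alt in step.alternatives)


def quantify_module(
    module: ModuleDefinition,
    sample_abundances: Mapping[str, float],
    threshold: float = DEFAULT_THRESHOLD,
    estimator: str = "mean",
) -> tuple[float, bool, float]:
    """Quantify one module in one sample.

    Returns ``(coverage, present, abundance)``.  Coverage and abundance are
    reported regardless of the presence call so that a failed gate still
    shows what was measured.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    if estimator not in _ESTIMATORS:
        raise ValueError(f"estimator must be one of {_ESTIMATORS}, got {estimator!r}")
    step_values = [step_abundance(s, sample_abundances) for s in module.steps]
    covered = [v for v in step_values if v > 0.0]
    coverage = len(covered) / len(step_values)
    present = coverage > threshold
    if covered:
        abundance = float(np.mean(covered)) if estimator == "mean" else float(np.median(covered))
    else:
        abundance = 0.0
    return coverage, present, abundance


@dataclass
class ModuleProfile:
    """Per-sample module coverage, presence and abundance grids.

    All three DataFrames are module × sample, grid-complete over the input
    database and matrix.  ``info`` carries module metadata (name, hierarchy,
    n_steps) for self-describing outputs.
    """

    coverage: pd.DataFrame
    abundance: pd.DataFrame
    present: pd.DataFrame
    threshold: float
    estimator: str
    info: pd.DataFrame

    @property
    def modules(self) -> list[str]:
        return list(self.coverage.index)

    @property
    def samples(self) -> list[str]:
        return list(self.coverage.columns)

    def with_present(self, present: pd.DataFrame) -> "ModuleProfile":
        """Copy of the profile with a replaced presence grid (e.g. after parsimony)."""
        return replace(self, present=present)


def quantify_all(
    db: ModuleDB,
    matrix: AbundanceMatrix,
    threshold: float = DEFAULT_THRESHOLD,
    estimator: str = "mean",
) -> ModuleProfile:
    """Quantify every module of ``db`` in every sample of ``matrix``.

    Orthologs referenced by modules but absent from the matrix count as
    abundance 0 everywhere.  Matrix orthologs matching no module are reported
    in a warning (they are upstream signal the database cannot interpret).
    """
    if not matrix.samples:
        raise ValueError("abundance matrix has no samples")
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    if estimator not in _ESTIMATORS:
        raise ValueError(f"estimator must be one of {_ESTIMATORS}, got {estimator!r}")

    universe = set(ortholog_universe(db))
    unmatched = [o for o in matrix.orthologs if o not in universe]
    if unmatched:
        preview = ", ".join(unmatched[:10]) + (", ..." if len(unmatched) > 10 else "")
        warnings.warn(
            f"{len(unmatched)} matrix ortholog(s) match no module: {preview}",
            stacklevel=2,
        )

    module_ids = db.module_ids
    samples = matrix.samples
    cov = np.zeros((len(module_ids), len(samples)))
    abund = np.zeros_like(cov)
    pres = np.zeros(cov.shape, dtype=bool)
    for j, sample in enumerate(samples):
        sample_abundances = matrix.sample_abundances(sample)
        for i, module in enumerate(db.modules):
            c, p, a = quantify_module(module, sample_abundances, threshold, estimator)
            cov[i, j], pres[i, j], abund[i, j] = c, p, a

    info = pd.DataFrame(
        {
            "name": [m.name for m in db.modules],
            "hierarchy": ["/".join(m.hierarchy) for m in db.modules],
            "n_steps": [m.n_steps for m in db.modules],
        },
        index=pd.Index(module_ids, name="module"),
    )
    return ModuleProfile(
        coverage=pd.DataFrame(cov, index=module_ids, columns=samples),
        abundance=pd.DataFrame(abund, index=module_ids, columns=samples),
        present=pd.DataFrame(pres, index=module_ids, columns=samples),
        threshold=float(threshold),
        estimator=estimator,
        info=info,
    )
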