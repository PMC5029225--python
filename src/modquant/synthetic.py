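"""Synthetic module databases and abundance matrices with known ground truth.

Every stage of the workflow is testable without external data: the generators
plant module-level group differences (effect multipliers applied in one
group), optionally make modules share orthologs across module boundaries
(the mechanism behind artifact module calls in universal databases: a shared
enzyme from a truly expressed module also "lights up" modules that are not
there), and are bit-reproducible from (parameters, seed).

Noise is applied at the ortholog level, not the module level, so coverage
varies realistically across samples.  Defaults: lognormal with sigma 0.5 for
intensity-like data (e.g. spectral counts normalised to continuous scale),
negative binomial with dispersion 0.3 for count-like data.  These are
modelling choices of this package.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .db import ModuleDB, ModuleDefinition, OrthologComplex, Step, ortholog_universe
from .matrix import AbundanceMatrix
from .parsimony import module_ortholog_content
from .stats import GroupDesign

__all__ = [
    "SyntheticTruth",
    "generate_module_db",
    "generate_abundance",
    "make_worked_example",
]

LOGNORMAL_SIGMA = 0.5
NEGBINOM_DISPERSION = 0.3


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth of a simulated dataset.

    ``differential_modules`` maps module id to an effect multiplier (> 1
    means up in ``design.group_a``); ``decoy_modules`` are non-differential
    modules sharing at least one ortholog with a differential module — the
    candidates for artifact overrepresentation.
    """

    db: ModuleDB
    matrix: AbundanceMatrix
    design: GroupDesign
    differential_modules: dict[str, float]
    decoy_modules: frozenset[str]
    seed: int


def generate_module_db(
    n_modules: int,
    steps_range: tuple[int, int] = (2, 4),
    alts_range: tuple[int, int] = (1, 2),
    p_complex: float = 0.15,
    p_shared: float = 0.0,
    seed: int = 0,
) -> ModuleDB:
    """Random module database, deterministic per seed.

    Each step has a number of alternatives uniform in ``alts_range``; an
    alternative is a 2-member complex with probability ``p_complex``.  With
    probability ``p_shared`` a member is reused from a *previously generated*
    module (cross-module enzyme sharing); with ``p_shared=0`` module contents
    are pairwise disjoint, with ``p_shared=1`` every module after the first
    shares orthologs with earlier ones.
    """
    if n_modules < 1:
        raise ValueError("n_modules must be >= 1")
    for lo, hi, what in [(steps_range[0], steps_range[1], "steps_range"),
                         (alts_range[0], alts_range[1], "alts_range")]:
        if lo < 1 or hi < lo:
            raise ValueError(f"infeasible {what}: {(lo, hi)}")
    for p, what in [(p_complex, "p_complex"), (p_shared, "p_shared")]:
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{what} must be in [0, 1], got {p}")

    rng = np.random.default_rng(seed)
    counter = 0
    pool: list[str] = []  # orthologs of completed modules, for sharing
    modules = []
    for i in range(n_modules):
        n_steps = int(rng.integers(steps_range[0], steps_range[1] + 1))
        steps = []
        fresh: list[str] = []
        for _ in range(n_steps):
            n_alts = int(rng.integers(alts_range[0], alts_range[1] + 1))
            alternatives = []
            seen: set[frozenset[str]] = set()
            for _ in range(n_alts):
                for attempt in range(20):
                    size = 2 if rng.random() < p_complex else 1
                    members: list[str] = []
                    for _ in range(size):
                        use_shared = pool and rng.random() < p_shared and attempt < 3
                        if use_shared:
                            cand = pool[int(rng.integers(len(pool)))]
                            if cand in members:
                                cand = None
                        else:
                            cand = None
                        if cand is None:
                            counter += 1
                            cand = f"K{counter:05d}"
                            fresh.append(cand)
                        members.append(cand)
                    member_set = frozenset(members)
                    if member_set not in seen:
                        break
                else:  # pragma: no cover - fresh orthologs always break the loop
                    raise ValueError("could not generate distinct step alternatives")
                seen.add(member_set)
                alternatives.append(OrthologComplex(tuple(members)))
            steps.append(Step(tuple(alternatives)))
        module = ModuleDefinition(
            id=f"SM{i + 1:04d}",
            name=f"synthetic module {i + 1}",
            hierarchy=("synthetic",),
            steps=tuple(steps),
        )
        modules.append(module)
        pool.extend(sorted(module_ortholog_content(module)))
    return ModuleDB(tuple(modules), source=f"generate_module_db(seed={seed})")


def generate_abundance(
    db: ModuleDB,
    design: GroupDesign,
    differential: Mapping[str, float] | None = None,
    noise: str = "lognormal",
    base_scale: float = 100.0,
    dispersion: float | None = None,
    seed: int = 0,
) -> tuple[AbundanceMatrix, SyntheticTruth]:
    """Simulate an ortholog abundance matrix over ``db``'s universe.

    Each ortholog occurrence contributes
    ``base_scale * effect * noise`` per sample, where the module's effect
    multiplier applies only in ``design.group_a``; orthologs shared between
    modules sum the contributions of all containing modules — which is
    exactly the decoy-inflation artifact, by construction.
    """
    differential = dict(differential or {})
    unknown = set(differential) - set(db.module_ids)
    if unknown:
        raise ValueError(f"differential module(s) not in db: {sorted(unknown)}")
    if any(eff <= 0 for eff in differential.values()):
        raise ValueError("effect multipliers must be > 0")
    if noise not in ("lognormal", "negbinom"):
        raise ValueError(f"noise must be 'lognormal' or 'negbinom', got {noise!r}")
    if dispersion is None:
        dispersion = LOGNORMAL_SIGMA if noise == "lognormal" else NEGBINOM_DISPERSION
    if dispersion <= 0:
        raise ValueError(f"dispersion must be > 0, got {dispersion}")
    if base_scale <= 0:
        raise ValueError(f"base_scale must be > 0, got {base_scale}")

    samples = design.all_samples
    orthologs = list(ortholog_universe(db))
    index_of = {o: i for i, o in enumerate(orthologs)}
    values = np.zeros((len(orthologs), len(samples)))

    rng = np.random.default_rng(seed)
    for module in db.modules:
        effect = float(differential.get(module.id, 1.0))
        content = sorted(module_ortholog_content(module))
        rows = [index_of[o] for o in content]
        for j, sample in enumerate(samples):
            mu = base_scale * (effect if design.assignment[sample] == design.group_a else 1.0)
            if noise == "lognormal":
                draw = mu * rng.lognormal(0.0, dispersion, size=len(rows))
            else:
                size_param = 1.0 / dispersion
                draw = rng.negative_binomial(
                    size_param, size_param / (size_param + mu), size=len(rows)
                ).astype(float)
            values[rows, j] += draw

    matrix = AbundanceMatrix(pd.DataFrame(values, index=orthologs, columns=samples))
    diff_content = [
        module_ortholog_content(db[mid]) for mid, eff in differential.items() if eff != 1.0
    ]
    decoys = frozenset(
        m.id
        for m in db.modules
        if m.id not in differential
        and any(module_ortholog_content(m) & c for c in diff_content)
    )
    truth = SyntheticTruth(
        db=db,
        matrix=matrix,
        design=design,
        differential_modules=differential,
        decoy_modules=decoys,
        seed=seed,
    )
    return matrix, truth


def _module(mid: str, name: str, hierarchy: tuple[str, ...], *steps: str) -> ModuleDefinition:
    return ModuleDefinition(
        id=mid,
        name=name,
        hierarchy=hierarchy,
        steps=tuple(
            Step(tuple(OrthologComplex(tuple(alt.split("+"))) for alt in s.split(",")))
            for s in steps
        ),
    )


# Hand-written worked-example values: 12 orthologs x 8 samples (4 healthy vs
# 4 disease).  MF0001/MF0002/MF0003 carry a planted ~4x up-shift in the
# healthy group; MF0004/MF0005 are null; XD9001 is a decoy whose two steps are
# both orthologs of MF0001, so it inherits MF0001's signal without existing.
# Values are tie-free within each module's per-sample abundance vector so the
# exact rank-sum path applies throughout.
_WORKED_SAMPLES = ("H1", "H2", "H3", "H4", "D1", "D2", "D3", "D4")
_WORKED_VALUES = {
    "K00001": (8.0, 9.0, 10.0, 11.0, 2.0, 2.5, 3.0, 1.5),
    "K00002": (12.0, 11.5, 10.5, 9.5, 2.2, 2.8, 1.8, 3.2),
    "K00003": (7.5, 8.5, 9.2, 10.4, 2.1, 1.9, 2.6, 2.4),
    "K00004": (6.0, 7.0, 5.5, 6.5, 1.0, 1.3, 0.8, 1.4),
    "K00005": (5.0, 4.5, 5.8, 6.2, 1.1, 0.9, 1.25, 0.75),
    "K00006": (4.0, 4.8, 5.2, 4.4, 1.0, 0.6, 1.2, 0.9),
    "K00007": (3.6, 4.2, 3.9, 4.7, 0.8, 1.1, 0.7, 1.0),
    "K00008": (5.1, 4.6, 5.5, 4.9, 1.3, 0.95, 1.05, 0.85),
    "K00009": (3.0, 1.5, 4.2, 2.1, 3.6, 2.6, 1.1, 4.6),
    "K00010": (2.4, 3.8, 1.7, 3.5, 1.9, 4.1, 3.1, 2.2),
    "K00011": (2.1, 2.6, 3.1, 1.8, 2.3, 2.9, 1.6, 3.3),
    "K00012": (0.0, 1.4, 0.0, 2.6, 1.1, 0.0, 2.7, 0.0),
}


def make_worked_example() -> tuple[ModuleDB, AbundanceMatrix, GroupDesign]:
    """Fixed, human-readable fixture used throughout the documentation.

    Six modules (one enzyme-sharing decoy), 12 orthologs, 8 samples (4
    healthy vs 4 disease).  Values are hand-written and byte-stable: calling
    this twice yields identical objects and serialisations.
    """
    db = ModuleDB(
        (
            _module(
                "MF0001",
                "pyruvate to butyrate fermentation",
                ("saccharolytic fermentation", "SCFA production"),
                "K00001",
                "K00002",
                "K00003",
            ),
            _module(
                "MF0002",
                "mucin degradation",
                ("polysaccharide degradation",),
                "K00004",
                "K00005",
            ),
            _module(
                "MF0003",
                "proteolytic fermentation",
                ("amino-acid degradation",),
                "K00006",
                "K00007",
                "K00008",
            ),
            _module(
                "MF0004",
                "hydrogen metabolism",
                ("gas metabolism",),
                "K00009",
                "K00010",
            ),
            _module(
                "MF0005",
                "lactate utilization",
                ("cross-feeding",),
                "K00011",
                "K00012",
            ),
            _module(
                "XD9001",
                "plant carbon fixation (synthetic decoy)",
                ("off-biome", "plant metabolism"),
                "K00002",
                "K00003",
            ),
        ),
        source="make_worked_example()",
    )
    matrix = AbundanceMatrix(
        pd.DataFrame(
            {s: [vals[j] for vals in _WORKED_VALUES.values()] for j, s in enumerate(_WORKED_SAMPLES)},
            index=list(_WORKED_VALUES),
        )
    )
    design = GroupDesign(
        assignment={s: ("healthy" if s.startswith("H") else "disease") for s in _WORKED_SAMPLES},
        group_a="healthy",
        group_b="disease",
    )
    return db, matrix, design
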