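"""TSV/JSON readers and writers for the command-line workflow.

All outputs are UTF-8 TSV with Unix newlines, '.' decimal separator, and
floats formatted to 6 significant digits so that reruns on identical inputs
are byte-identical.  Booleans are written as 1/0, missing values as "NA".
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .matrix import AbundanceMatrix
from .quantify import ModuleProfile
from .stats import GroupComparison, GroupDesign, comparisons_to_frame
from .synthetic import SyntheticTruth

__all__ = [
    "fmt_float",
    "read_groups_tsv",
    "write_groups_tsv",
    "write_profile",
    "write_comparison",
    "write_map_coloring",
    "write_parsimony",
    "write_truth_json",
]

FLOAT_FMT = "%.6g"


def fmt_float(value: float) -> str:
    if isinstance(value, float) and math.isnan(value):
        return "NA"
    return FLOAT_FMT % value


def _fmt_cell(value) -> str:
    if isinstance(value, (bool, np.bool_)):
        return "1" if value else "0"
    if isinstance(value, (float, np.floating)):
        return fmt_float(float(value))
    return str(value)


def _write_frame(frame: pd.DataFrame, path, index_name: str | None = None) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        columns = list(frame.columns)
        if index_name is not None:
            fh.write("\t".join([index_name] + [str(c) for c in columns]) + "\n")
            for idx, row in frame.iterrows():
                fh.write("\t".join([str(idx)] + [_fmt_cell(v) for v in row]) + "\n")
        else:
            fh.write("\t".join(str(c) for c in columns) + "\n")
            for _, row in frame.iterrows():
                fh.write("\t".join(_fmt_cell(v) for v in row) + "\n")


def read_groups_tsv(path, group_a: str | None = None, group_b: str | None = None) -> GroupDesign:
    """Read a sample-to-group TSV (``sample<TAB>group``, header optional)."""
    pairs: list[tuple[str, str]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\r\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValueError(
                    f"{path}: line {lineno}: expected 2 tab-separated fields, got {len(fields)}"
                )
            if lineno == 1 and fields[0].lower() == "sample":
                continue
            pairs.append((fields[0], fields[1]))
    return GroupDesign.from_table(pairs, group_a=group_a, group_b=group_b)


def write_groups_tsv(design: GroupDesign, path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("sample\tgroup\n")
        for sample, group in design.assignment.items():
            fh.write(f"{sample}\t{group}\n")


def write_profile(profile: ModuleProfile, out_dir) -> list[str]:
    """Write coverage.tsv, abundance.tsv, presence.tsv and module_info.tsv."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, frame in [
        ("coverage.tsv", profile.coverage),
        ("abundance.tsv", profile.abundance),
        ("presence.tsv", profile.present),
    ]:
        _write_frame(frame, out_dir / name, index_name="module")
        written.append(name)
    _write_frame(profile.info, out_dir / "module_info.tsv", index_name="module")
    written.append("module_info.tsv")
    return written


def write_comparison(comparisons: Sequence[GroupComparison], path) -> pd.DataFrame:
    """Write comparison.tsv, rows sorted by (q, p, module id)."""
    frame = comparisons_to_frame(comparisons)
    _write_frame(frame, path)
    return frame


def coloring_epsilon(profile: ModuleProfile) -> float:
    """Pseudo-abundance guard for log-ratios with a zero median.

    One tenth of the smallest positive abundance in the profile (1.0 when the
    profile has no positive abundance at all).
    """
    values = profile.abundance.to_numpy()
    positive = values[values > 0]
    return float(positive.min() / 10.0) if positive.size else 1.0


def write_map_coloring(
    comparisons: Sequence[GroupComparison], profile: ModuleProfile, path
) -> float:
    """Write map_coloring.tsv: per-module signed effect for map visualisation.

    The signed effect is log2(median_a / median_b) with zero medians replaced
    by the epsilon guard; positive means up in group A.  Returns the epsilon
    used so callers can log it.
    """
    eps = coloring_epsilon(profile)
    frame = comparisons_to_frame(comparisons)
    effects = []
    for _, row in frame.iterrows():
        ma = row["median_a"] if row["median_a"] > 0 else eps
        mb = row["median_b"] if row["median_b"] > 0 else eps
        effects.append(math.log2(ma / mb))
    out = pd.DataFrame(
        {
            "module": frame["module"],
            "hierarchy": [
                str(profile.info.loc[m, "hierarchy"]) for m in frame["module"]
            ],
            "log2_effect": effects,
            "q": frame["q"],
            "significant": frame["significant"],
        }
    )
    _write_frame(out, path)
    return eps


def write_parsimony(table: pd.DataFrame, path) -> None:
    """Write parsimony.tsv (sample, module, kept, method, optimal, reason)."""
    _write_frame(table, path)


def write_truth_json(truth: SyntheticTruth, path) -> None:
    payload = {
        "seed": truth.seed,
        "group_a": truth.design.group_a,
        "group_b": truth.design.group_b,
        "differential_modules": dict(sorted(truth.differential_modules.items())),
        "decoy_modules": sorted(truth.decoy_modules),
        "n_modules": len(truth.db),
        "n_orthologs": len(truth.matrix.orthologs),
        "n_samples": len(truth.matrix.samples),
    }
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
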