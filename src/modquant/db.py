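"""Metabolic module database: data model, flat-file parser/writer, validation.

A *module* is a curated set of tightly related enzymatic functions that
together represent a cellular process with defined input and output
metabolites (e.g. "pyruvate to butyrate fermentation").  It is modelled as an
ordered list of *steps*; each step is satisfiable by any of several
alternative enzymes (OR), and each alternative may be a multi-subunit
*complex* whose members are all required jointly (AND).

The flat-file format (suggested extension ``.gmd``) is a block format:

.. code-block:: text

    # comment lines start with '#'
    MF0001<TAB>pyruvate to butyrate fermentation<TAB>fermentation/SCFA production
    K00001
    K00002,K00003+K00004
    ///

One header line per module (``id<TAB>name[<TAB>hierarchy]``, hierarchy
categories joined by ``/``), then one step per line where ``,`` separates
alternatives and ``+`` joins complex members, terminated by ``///``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import IO, Iterable, Union

__all__ = [
    "OrthologComplex",
    "Step",
    "ModuleDefinition",
    "ModuleDB",
    "ModuleDBError",
    "ModuleDBParseError",
    "parse_module_db",
    "write_module_db",
    "read_module_db",
    "ortholog_universe",
]

# characters that would break the line-oriented grammar
_FORBIDDEN_IN_IDENT = set(",+/")
_LINE_BREAKS = set("\n\r\v\f\x1c\x1d\x1e\x85\u2028\u2029")


class ModuleDBError(ValueError):
    """Invalid module database content (invariant violation)."""


class ModuleDBParseError(ModuleDBError):
    """Syntax or consistency error while parsing a module flat file."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


def _check_identifier(token: str, kind: str) -> None:
    if not token:
        raise ModuleDBError(f"empty {kind}")
    if any(c.isspace() for c in token):
        raise ModuleDBError(f"{kind} {token!r} contains whitespace")
    if set(token) & _FORBIDDEN_IN_IDENT:
        raise ModuleDBError(f"{kind} {token!r} contains a reserved character (one of ',+/')")
    if token.startswith("#"):
        raise ModuleDBError(f"{kind} {token!r} starts with '#'")


def _check_text(text: str, kind: str) -> None:
    if "\t" in text or (set(text) & _LINE_BREAKS):
        raise ModuleDBError(f"{kind} {text!r} contains a tab or line break")


@dataclass(frozen=True)
class OrthologComplex:
    """One alternative of a step: a set of orthologs all required jointly.

    Abundance semantics are AND (limiting subunit): the complex abundance is
    the minimum member abundance.  A singleton complex is the plain
    single-enzyme case.
    """

    members: tuple[str, ...]

    def __post_init__(self):
        if len(self.members) < 1:
            raise ModuleDBError("complex must have at least one member")
        for m in self.members:
            _check_identifier(m, "ortholog identifier")
        if len(set(self.members)) != len(self.members):
            raise ModuleDBError(f"duplicate member in complex {self.members!r}")

    @property
    def member_set(self) -> frozenset[str]:
        return frozenset(self.members)


@dataclass(frozen=True)
class Step:
    """One enzymatic stage of a module: OR over alternative complexes."""

    alternatives: tuple[OrthologComplex, ...]

    def __post_init__(self):
        if len(self.alternatives) < 1:
            raise ModuleDBError("step must have at least one alternative")
        seen: set[frozenset[str]] = set()
        for alt in self.alternatives:
            if alt.member_set in seen:
                raise ModuleDBError(
                    f"duplicate alternative {sorted(alt.member_set)!r} within a step"
                )
            seen.add(alt.member_set)


@dataclass(frozen=True)
class ModuleDefinition:
    """An identified, named, hierarchically classified ordered list of steps."""

    id: str
    name: str
    hierarchy: tuple[str, ...] = ()
    steps: tuple[Step, ...] = ()

    def __post_init__(self):
        _check_identifier(self.id, "module id")
        _check_text(self.name, "module name")
        for cat in self.hierarchy:
            if not cat:
                raise ModuleDBError("empty hierarchy category")
            if "/" in cat:
                raise ModuleDBError(f"hierarchy category {cat!r} contains '/'")
            _check_text(cat, "hierarchy category")
        if len(self.steps) < 1:
            raise ModuleDBError(f"module {self.id!r} has no steps")

    @property
    def n_steps(self) -> int:
        return len(self.steps)


@dataclass(frozen=True)
class ModuleDB:
    """Ordered collection of modules with pairwise distinct ids."""

    modules: tuple[ModuleDefinition, ...] = ()
    source: str = field(default="<memory>", compare=False)

    def __post_init__(self):
        seen: set[str] = set()
        for m in self.modules:
            if m.id in seen:
                raise ModuleDBError(f"duplicate module id {m.id!r}")
            seen.add(m.id)

    def __len__(self) -> int:
        return len(self.modules)

    def __iter__(self):
        return iter(self.modules)

    def __getitem__(self, module_id: str) -> ModuleDefinition:
        for m in self.modules:
            if m.id == module_id:
                return m
        raise KeyError(module_id)

    @property
    def module_ids(self) -> list[str]:
        return [m.id for m in self.modules]


def ortholog_universe(db: ModuleDB) -> tuple[str, ...]:
    """Union of all complex members over all modules, sorted lexicographically."""
    universe: set[str] = set()
    for module in db.modules:
        for step in module.steps:
            for alt in step.alternatives:
                universe.update(alt.members)
    return tuple(sorted(universe))


def _parse_step(line: str, lineno: int) -> Step:
    alternatives = []
    for alt_tok in line.split(","):
        if not alt_tok:
            raise ModuleDBParseError("empty alternative in step", lineno)
        members = alt_tok.split("+")
        if any(not m for m in members):
            raise ModuleDBParseError("empty complex member in step", lineno)
        try:
            alternatives.append(OrthologComplex(tuple(members)))
        except ModuleDBError as exc:
            raise ModuleDBParseError(str(exc), lineno) from exc
    try:
        return Step(tuple(alternatives))
    except ModuleDBError as exc:
        raise ModuleDBParseError(str(exc), lineno) from exc


def parse_module_db(source: Union[str, IO[str], Iterable[str]], name: str = "<stream>") -> ModuleDB:
    """Parse a module flat file into a :class:`ModuleDB`.

    ``source`` may be a string, an open text stream, or an iterable of lines.
    Unix and Windows newlines are both accepted.  Blank lines and lines
    starting with ``#`` are ignored.  Errors are hard and carry line numbers.
    """
    if isinstance(source, str):
        lines = source.splitlines()
    elif hasattr(source, "read"):
        lines = source.read().splitlines()
    else:
        lines = [ln.rstrip("\n") for ln in source]

    modules: list[ModuleDefinition] = []
    id_lines: dict[str, int] = {}
    header: tuple[str, str, tuple[str, ...], int] | None = None
    steps: list[Step] = []

    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\r")
        if not line.strip() or line.startswith("#"):
            continue
        if line.strip() == "///":
            if header is None:
                raise ModuleDBParseError("terminator '///' outside a module block", lineno)
            if not steps:
                raise ModuleDBParseError(
                    f"module {header[0]!r} has no steps (empty module)", lineno
                )
            try:
                modules.append(
                    ModuleDefinition(header[0], header[1], header[2], tuple(steps))
                )
            except ModuleDBError as exc:
                raise ModuleDBParseError(str(exc), header[3]) from exc
            header, steps = None, []
            continue
        if header is None:
            if "\t" not in line:
                raise ModuleDBParseError(
                    "step line before any module header "
                    "(expected 'id<TAB>name[<TAB>hierarchy]')",
                    lineno,
                )
            fields = line.split("\t")
            if len(fields) > 3:
                raise ModuleDBParseError(
                    f"module header has {len(fields)} tab-separated fields (max 3)", lineno
                )
            mod_id, mod_name = fields[0], fields[1]
            hierarchy = tuple(fields[2].split("/")) if len(fields) > 2 and fields[2] else ()
            if mod_id in id_lines:
                raise ModuleDBParseError(
                    f"duplicate module id {mod_id!r} "
                    f"(first declared at line {id_lines[mod_id]})",
                    lineno,
                )
            try:
                _check_identifier(mod_id, "module id")
                _check_text(mod_name, "module name")
                for cat in hierarchy:
                    if not cat:
                        raise ModuleDBError("empty hierarchy category")
            except ModuleDBError as exc:
                raise ModuleDBParseError(str(exc), lineno) from exc
            id_lines[mod_id] = lineno
            header = (mod_id, mod_name, hierarchy, lineno)
            continue
        steps.append(_parse_step(line, lineno))

    if header is not None:
        raise ModuleDBParseError(
            f"unterminated module {header[0]!r} (missing '///')", header[3]
        )
    return ModuleDB(tuple(modules), source=name)


def write_module_db(db: ModuleDB) -> str:
    """Serialise a :class:`ModuleDB` to the flat format.

    Round-trip guarantee: ``parse_module_db(write_module_db(db)) == db``
    (ids, names, hierarchy and step/alternative/member order preserved).
    An empty database serialises to the empty string.
    """
    blocks = []
    for module in db.modules:
        head = f"{module.id}\t{module.name}"
        if module.hierarchy:
            head += "\t" + "/".join(module.hierarchy)
        lines = [head]
        for step in module.steps:
            lines.append(",".join("+".join(alt.members) for alt in step.alternatives))
        lines.append("///")
        blocks.append("\n".join(lines))
    return "\n".join(blocks) + ("\n" if blocks else "")


def read_module_db(path) -> ModuleDB:
    """Read a module flat file from ``path`` (UTF-8)."""
    with open(path, encoding="utf-8") as fh:
        return parse_module_db(fh, name=str(path))
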