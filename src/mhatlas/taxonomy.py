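"""DESDE-LTC main-type-of-care taxonomy.

The DESDE-LTC instrument classifies the basic stable inputs of care (BSICs)
of a service by "main type of care" (MTC) codes arranged in a tree: a
single-letter main branch (residential, day, outpatient, accessibility,
information, self-help) followed by a dot-separated numeric path, e.g.
``R2.1``. The packaged registry carries the instrument's 91 codes; all
computation is registry-driven so a revised registry file can be swapped in
without code changes.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Mapping

__all__ = [
    "MTCCode",
    "CodeRegistry",
    "CodeQualifiers",
    "RegistryError",
    "UnknownCodeError",
    "load_registry",
    "parse_code",
    "branch_group",
]

_CODE_RE = re.compile(r"^([A-Za-z])(\d+(?:\.\d+)*)$")


class RegistryError(ValueError):
    """The registry file violates the registry schema or tree invariants."""


class UnknownCodeError(KeyError):
    """A code string is not present in the registry.

    Carries the nearest ancestors of the requested code that *are* present,
    to help locate typos.
    """

    def __init__(self, code: str, ancestors: tuple[str, ...] = ()):
        self.code = code
        self.ancestors = ancestors
        hint = f"; nearest ancestors present: {', '.join(ancestors)}" if ancestors else ""
        super().__init__(f"unknown MTC code {code!r}{hint}")

    def __str__(self) -> str:  # KeyError quotes its arg; keep the message readable
        return self.args[0]


@dataclass(frozen=True, order=True)
class MTCCode:
    """A single main-type-of-care code: branch letter plus numeric path."""

    branch: str
    path: tuple[int, ...]
    label: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        if len(self.branch) != 1 or not self.branch.isalpha():
            raise ValueError(f"branch must be a single letter, got {self.branch!r}")
        if not self.path or any(s <= 0 for s in self.path):
            raise ValueError(f"path segments must be positive integers, got {self.path!r}")

    @property
    def depth(self) -> int:
        return len(self.path)

    @property
    def code(self) -> str:
        """Canonical string form, e.g. ``R2.1``."""
        return self.branch + ".".join(str(s) for s in self.path)

    @property
    def parent_code(self) -> str | None:
        """Code string one path segment shorter; None for a top-level code."""
        if self.depth == 1:
            return None
        return self.branch + ".".join(str(s) for s in self.path[:-1])

    def __str__(self) -> str:
        return self.code


def _split_code(text: str) -> tuple[str, tuple[int, ...]]:
    m = _CODE_RE.match(text.strip())
    if m is None:
        raise ValueError(f"malformed MTC code {text!r} (expected letter + dotted integers)")
    return m.group(1).upper(), tuple(int(s) for s in m.group(2).split("."))


@dataclass
class CodeRegistry:
    """A validated collection of MTC codes plus qualifier vocabularies."""

    instrument_name: str
    version: str
    branches: dict[str, str]  # branch letter -> label
    codes: dict[str, MTCCode]  # canonical code string -> code
    qualifiers: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for s, code in self.codes.items():
            if s != code.code:
                raise RegistryError(f"registry key {s!r} does not match code {code.code!r}")
            if code.branch not in self.branches:
                raise RegistryError(f"code {s} uses undeclared branch {code.branch!r}")
            parent = code.parent_code
            if parent is not None and parent not in self.codes:
                raise RegistryError(f"orphan code {s}: parent {parent} missing from registry")

    def __len__(self) -> int:
        return len(self.codes)

    def __iter__(self) -> Iterator[MTCCode]:
        return iter(self.codes.values())

    def __contains__(self, text: str) -> bool:
        try:
            self.get(text)
        except (UnknownCodeError, ValueError):
            return False
        return True

    def get(self, text: str) -> MTCCode:
        """Look up a code string (branch letter case-insensitive)."""
        branch, path = _split_code(text)
        canonical = branch + ".".join(str(s) for s in path)
        try:
            return self.codes[canonical]
        except KeyError:
            ancestors = []
            for k in range(len(path) - 1, 0, -1):
                anc = branch + ".".join(str(s) for s in path[:k])
                if anc in self.codes:
                    ancestors.append(anc)
            raise UnknownCodeError(canonical, tuple(ancestors)) from None

    def branch_codes(self, branch: str) -> list[MTCCode]:
        branch = branch.upper()
        return sorted(c for c in self.codes.values() if c.branch == branch)

    def ancestors(self, code: MTCCode | str) -> list[MTCCode]:
        """Chain of ancestors from the code's parent up to its main-branch top."""
        code = self.get(str(code)) if not isinstance(code, MTCCode) else code
        out = []
        cur = code.parent_code
        while cur is not None:
            parent = self.codes[cur]
            out.append(parent)
            cur = parent.parent_code
        return out


@dataclass(frozen=True)
class CodeQualifiers:
    """Descriptor axes attached to an MTC assignment; values are registry-declared."""

    user_status: str | None = None
    care_typology: str | None = None
    intensity: str | None = None
    time_of_stay: str | None = None
    mobility: str | None = None

    def validate(self, registry: CodeRegistry) -> "CodeQualifiers":
        for axis in ("user_status", "care_typology", "intensity", "time_of_stay", "mobility"):
            value = getattr(self, axis)
            if value is None:
                continue
            declared = registry.qualifiers.get(axis, [])
            if value not in declared:
                raise ValueError(
                    f"undeclared {axis} value {value!r}; declared: {declared}"
                )
        return self


def _packaged_registry_path() -> Path:
    return Path(str(resources.files("mhatlas").joinpath("data/desde_ltc_registry.json")))


def load_registry(source: str | Path | None = None) -> CodeRegistry:
    """Load and validate a code registry.

    With no argument, loads the packaged DESDE-LTC registry (91 codes).
    Raises :class:`RegistryError` on duplicate codes, orphan parents or
    undeclared branches.
    """
    path = Path(source) if source is not None else _packaged_registry_path()
    with open(path) as fh:
        raw = json.load(fh)
    for key in ("instrument", "version", "branches", "codes"):
        if key not in raw:
            raise RegistryError(f"registry file missing required field {key!r}")
    branches = {b["letter"]: b["label"] for b in raw["branches"]}
    codes: dict[str, MTCCode] = {}
    for entry in raw["codes"]:
        branch, p = _split_code(entry["code"])
        code = MTCCode(branch=branch, path=p, label=entry.get("label", ""))
        if code.code in codes:
            raise RegistryError(f"duplicate code {code.code} in registry file")
        declared_parent = entry.get("parent")
        if declared_parent is not None and declared_parent != code.parent_code:
            raise RegistryError(
                f"code {code.code}: declared parent {declared_parent!r} "
                f"inconsistent with path-derived parent {code.parent_code!r}"
            )
        codes[code.code] = code
    return CodeRegistry(
        instrument_name=raw["instrument"],
        version=raw["version"],
        branches=branches,
        codes=codes,
        qualifiers=dict(raw.get("qualifiers", {})),
    )


def parse_code(text: str, registry: CodeRegistry) -> MTCCode:
    """Parse a code string against a registry (case-insensitive branch letter)."""
    if not text or not text.strip():
        raise ValueError("empty MTC code string")
    return registry.get(text)


def branch_group(code: MTCCode | str, registry: CodeRegistry | None = None) -> str:
    """Top-level branch letter of a code — the aggregation level for
    'different types of care available' indicators."""
    if isinstance(code, MTCCode):
        return code.branch
    if registry is not None:
        return registry.get(code).branch
    branch, _ = _split_code(code)
    return branch


def group_by_branch(codes: Iterable[MTCCode | str]) -> dict[str, list[str]]:
    """Group code strings by their main branch."""
    out: dict[str, list[str]] = {}
    for c in codes:
        s = c.code if isinstance(c, MTCCode) else str(c)
        out.setdefault(branch_group(s if not isinstance(c, MTCCode) else c), []).append(s)
    return out
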