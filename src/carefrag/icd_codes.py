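"""ICD-9/ICD-10 code pattern compilation and matching.

Patterns come in three shapes:

* exact codes ("496", "J44.1") — match the single code;
* trailing-wildcard stems ("J45.x", "493.0x", "J44.*") — match the stem
  itself plus any extension;
* positional wildcards ("250.x2") — the lowercase "x" matches exactly one
  arbitrary character, every other character is literal, and the total
  (dotless) length must agree.

Codes and patterns are normalized before matching: dots stripped, letters
uppercased. A pattern only ever matches codes of its own code system
(``icd9`` vs ``icd10``); the system is carried explicitly, never inferred
from the shape of the code.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import pandas as pd
import yaml

from .errors import PatternError, VocabularyError

CODE_SYSTEMS = ("icd9", "icd10")

_WILDCARDS = ("x", "*")


def normalize_code(code: str) -> str:
    """Strip dots and uppercase. Matching happens on this form."""
    return code.replace(".", "").strip().upper()


@dataclass(frozen=True)
class CodePattern:
    """A compiled diagnosis-code pattern.

    ``raw`` is preserved verbatim so that rendering a compiled pattern
    reproduces the vocabulary entry exactly.
    """

    raw: str
    code_system: str
    kind: str = field(compare=False)  # "exact" | "prefix" | "mask"
    stem: str = field(compare=False)  # normalized stem (prefix/exact) or mask with "\0" holes

    def matches(self, code: str, code_system: str | None = None) -> bool:
        if code_system is not None and code_system != self.code_system:
            return False
        norm = normalize_code(code)
        if self.kind == "exact":
            return norm == self.stem
        if self.kind == "prefix":
            return norm.startswith(self.stem)
        # mask: fixed length, "\0" marks a free position
        if len(norm) != len(self.stem):
            return False
        return all(m == "\0" or m == c for m, c in zip(self.stem, norm))


def compile_pattern(raw: str, code_system: str) -> CodePattern:
    """Compile a raw pattern string into a :class:`CodePattern`.

    Raises :class:`PatternError` for an empty pattern, an unknown code
    system, or a wildcard in an unsupported position (leading wildcard,
    ``*`` anywhere but last).
    """
    if code_system not in CODE_SYSTEMS:
        raise PatternError(f"unknown code system {code_system!r}")
    body = raw.replace(".", "").strip()
    if not body:
        raise PatternError("empty pattern")
    if "*" in body[:-1]:
        raise PatternError(f"pattern {raw!r}: '*' is only supported in trailing position")
    if body[0] in _WILDCARDS:
        raise PatternError(f"pattern {raw!r}: leading wildcard is not supported")

    if body[-1] in _WILDCARDS:
        stem = body[:-1]
        if "x" in stem:
            # e.g. "250.xx" — interior holes plus open tail is not a shape
            # the vocabulary uses; reject rather than guess.
            raise PatternError(f"pattern {raw!r}: mixed interior and trailing wildcards")
        return CodePattern(raw=raw, code_system=code_system, kind="prefix", stem=stem.upper())
    if "x" in body:
        mask = "".join("\0" if c == "x" else c.upper() for c in body)
        return CodePattern(raw=raw, code_system=code_system, kind="mask", stem=mask)
    return CodePattern(raw=raw, code_system=code_system, kind="exact", stem=body.upper())


def code_matches(code: str, code_system: str, pattern: CodePattern) -> bool:
    """True iff ``code`` (of ``code_system``) is in the pattern's denotation."""
    return pattern.matches(code, code_system)


@dataclass(frozen=True)
class CodeSet:
    name: str
    patterns: tuple[CodePattern, ...]

    def __post_init__(self):
        if not self.patterns:
            raise VocabularyError(f"code set {self.name!r} is empty")

    def matches(self, code: str, code_system: str) -> bool:
        return any(p.matches(code, code_system) for p in self.patterns)


class Vocabulary:
    """Named collection of :class:`CodeSet` objects loaded from YAML."""

    def __init__(self, code_sets: Mapping[str, CodeSet]):
        self._sets = dict(code_sets)

    def __contains__(self, name: str) -> bool:
        return name in self._sets

    def __getitem__(self, name: str) -> CodeSet:
        try:
            return self._sets[name]
        except KeyError:
            raise VocabularyError(f"unknown code set {name!r}") from None

    def names(self) -> list[str]:
        return sorted(self._sets)

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, Mapping[str, list[str]]]) -> "Vocabulary":
        sets = {}
        for name, by_system in mapping.items():
            patterns = []
            for system, raws in by_system.items():
                for raw in raws:
                    patterns.append(compile_pattern(str(raw), system))
            sets[name] = CodeSet(name=name, patterns=tuple(patterns))
        return cls(sets)

    @classmethod
    def from_yaml(cls, path) -> "Vocabulary":
        with open(path, encoding="utf-8") as fh:
            return cls.from_mapping(yaml.safe_load(fh))


def default_vocabulary() -> Vocabulary:
    """The vocabulary shipped with the package (every rule's code list)."""
    ref = resources.files("carefrag.data").joinpath("code_sets.yaml")
    return Vocabulary.from_mapping(yaml.safe_load(ref.read_text(encoding="utf-8")))


def any_match(
    diagnosis_rows: pd.DataFrame,
    code_set: CodeSet,
    *,
    rank: str | None = None,
    visit_type: str | None = None,
    date_from=None,
    date_to=None,
) -> pd.DataFrame:
    """Subset of ``diagnosis_rows`` matching any pattern of ``code_set``.

    Optional filters restrict on diagnosis rank, the visit type of the
    attached visit (requires a ``visit_type`` column, normally merged in
    from the visits table), and an inclusive date window. Input row order
    is preserved.
    """
    df = diagnosis_rows
    if df.empty:
        return df
    mask = pd.Series(False, index=df.index)
    norm = df["code"].map(normalize_code)
    for pat in code_set.patterns:
        sys_ok = df["code_system"] == pat.code_system
        if pat.kind == "exact":
            mask |= sys_ok & (norm == pat.stem)
        elif pat.kind == "prefix":
            mask |= sys_ok & norm.str.startswith(pat.stem)
        else:
            mask |= sys_ok & norm.map(pat.matches)
    if rank is not None:
        mask &= df["rank"] == rank
    if visit_type is not None:
        if "visit_type" not in df.columns:
            raise VocabularyError("visit_type filter requires a visit_type column")
        mask &= df["visit_type"] == visit_type
    if date_from is not None:
        mask &= df["date"] >= pd.Timestamp(date_from)
    if date_to is not None:
        mask &= df["date"] <= pd.Timestamp(date_to)
    return df[mask]
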