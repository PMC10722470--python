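"""Versioned keyword/ICD-10 computational phenotypes and their compilation.

A computational phenotype here is a purely lexical rule set: keyword phrases
(with SQL-LIKE ``%`` wildcards) matched against whole word tokens of clinical
note text, plus ICD-10-CM code patterns matched against recorded diagnosis
codes. Rule sets are versioned by effective date so the phenotype active at
any point of an observation window can be reassembled exactly.

Matching semantics
------------------
* Text is lowercased and split on non-alphanumeric boundaries; the matching
  unit is the word token (so ``anal`` never fires on ``analysis``, and
  ``abuse`` does not fire on ``abusive``).
* A hyphenated phrase like ``trans-sexual`` is therefore a two-token phrase.
* ``%`` matches any run of zero or more characters *within* a single token
  (``traffic%`` matches ``trafficking``); there is no single-character
  wildcard.
* Multi-word phrases match consecutive tokens.
* Patterns may be scoped to one sex; patients of unknown sex receive the
  union of all scopes.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from datetime import date
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import yaml
from pydantic import BaseModel, Field, field_validator

from .ehr_model import Sex, normalize_code

__all__ = [
    "SexScope",
    "MatchMode",
    "KeywordPattern",
    "CodePattern",
    "RuleSetVersion",
    "RuleSet",
    "RuleSetDelta",
    "RulesetConfigError",
    "compile_keyword",
    "tokenize",
    "load_ruleset_config",
    "assemble_ruleset_as_of",
    "diff_rulesets",
    "default_ruleset_path",
    "load_default_ruleset_versions",
]

#: Date from which code patterns are additionally evaluated as keyword
#: phrases against diagnosis *description* text (the "simplified to key
#: phrase" behavior switch).
CODE_DESCRIPTION_KEYWORDS_FROM = date(2019, 10, 1)

_TOKEN_RE = re.compile(r"[a-z0-9]+")
_PATTERN_TOKEN_RE = re.compile(r"[a-z0-9%]+")


class SexScope(str, Enum):
    ANY = "any"
    MALE_ONLY = "male_only"
    FEMALE_ONLY = "female_only"

    def applies_to(self, sex: Sex) -> bool:
        # Unknown sex receives the union of all scopes (conservative
        # sensitivity: never drop a pattern for lack of demographics).
        if sex == Sex.UNKNOWN or self == SexScope.ANY:
            return True
        if self == SexScope.MALE_ONLY:
            return sex == Sex.MALE
        return sex == Sex.FEMALE


class MatchMode(str, Enum):
    EXACT = "exact"
    PREFIX = "prefix"


class RulesetConfigError(ValueError):
    """Invalid ruleset configuration or version history."""


def tokenize(text: str) -> List[Tuple[str, int, int]]:
    """Lowercased word tokens of *text* with [start, end) character offsets."""
    return [(m.group(0), m.start(), m.end()) for m in _TOKEN_RE.finditer(text.lower())]


def canonical_phrase(raw: str) -> str:
    """Canonical key of a keyword phrase: its token sequence joined by spaces."""
    return " ".join(_PATTERN_TOKEN_RE.findall(raw.lower()))


class CompiledKeyword:
    """A keyword phrase compiled to a predicate over token sequences."""

    def __init__(self, raw: str):
        phrase = canonical_phrase(raw)
        if not phrase:
            raise RulesetConfigError(f"keyword pattern {raw!r} is empty after normalization")
        self.raw = raw
        self.tokens = phrase.split(" ")
        for tok in self.tokens:
            if not tok.replace("%", ""):
                raise RulesetConfigError(
                    f"keyword pattern {raw!r} contains a bare wildcard token; it would match everything"
                )
        # Literal tokens compare by equality; wildcard tokens via regex.
        self._regexes: List[Optional[re.Pattern]] = []
        for tok in self.tokens:
            if "%" in tok:
                rx = ".*".join(re.escape(part) for part in tok.split("%"))
                self._regexes.append(re.compile(rx))
            else:
                self._regexes.append(None)
        self.has_wildcard = any(rx is not None for rx in self._regexes)

    def _token_matches(self, i: int, token: str) -> bool:
        rx = self._regexes[i]
        return token == self.tokens[i] if rx is None else rx.fullmatch(token) is not None

    def matches_at(self, tokens: Sequence[str], pos: int) -> bool:
        k = len(self.tokens)
        if pos + k > len(tokens):
            return False
        return all(self._token_matches(i, tokens[pos + i]) for i in range(k))

    def matches(self, tokens: Sequence[str]) -> bool:
        """True if the phrase matches some run of consecutive tokens."""
        return any(self.matches_at(tokens, p) for p in range(len(tokens) - len(self.tokens) + 1))

    def matches_text(self, text: str) -> bool:
        return self.matches([t for t, _, _ in tokenize(text)])

    def find_first(self, text: str) -> Optional[Tuple[int, int]]:
        """[start, end) span of the first match window in *text*, or None."""
        toks = tokenize(text)
        names = [t for t, _, _ in toks]
        k = len(self.tokens)
        for p in range(len(names) - k + 1):
            if self.matches_at(names, p):
                return toks[p][1], toks[p + k - 1][2]
        return None


def compile_keyword(raw: str) -> CompiledKeyword:
    """Compile a keyword phrase (optionally with ``%`` wildcards) to a matcher."""
    return CompiledKeyword(raw)


class KeywordPattern(BaseModel):
    model_config = {"frozen": True}

    raw: str
    sex_scope: SexScope = SexScope.ANY
    effective_from: date
    source_tag: str = ""

    @field_validator("raw")
    @classmethod
    def _norm(cls, v: str) -> str:
        v = v.lower().strip()
        if not canonical_phrase(v):
            raise ValueError("keyword pattern empty after normalization")
        return v

    @property
    def canonical(self) -> str:
        return canonical_phrase(self.raw)

    @property
    def has_wildcard(self) -> bool:
        return "%" in self.raw

    @property
    def key(self) -> Tuple[str, SexScope]:
        return (self.canonical, self.sex_scope)


class CodePattern(BaseModel):
    model_config = {"frozen": True}

    raw_code: str
    description: str = ""
    match_mode: MatchMode = MatchMode.PREFIX
    effective_from: date
    source_tag: str = ""

    @field_validator("raw_code")
    @classmethod
    def _check(cls, v: str) -> str:
        norm = normalize_code(v)
        if not norm or not norm.isalnum():
            raise ValueError(f"code pattern {v!r} empty or non-alphanumeric after normalization")
        return v

    @property
    def normalized(self) -> str:
        return normalize_code(self.raw_code)

    def matches_code(self, recorded: str) -> bool:
        norm = normalize_code(recorded)
        if self.match_mode == MatchMode.EXACT:
            return norm == self.normalized
        return norm.startswith(self.normalized)


@dataclass
class _KeywordRemoval:
    pattern: str
    sex_scope: SexScope = SexScope.ANY


@dataclass
class RuleSetVersion:
    version_id: str
    effective_from: date
    added_keywords: List[KeywordPattern] = field(default_factory=list)
    removed_keywords: List[_KeywordRemoval] = field(default_factory=list)
    added_codes: List[CodePattern] = field(default_factory=list)
    removed_codes: List[str] = field(default_factory=list)


@dataclass
class RuleSet:
    """The phenotype active as of a date: deduplicated keywords and codes."""

    as_of: date
    active_keywords: Dict[Tuple[str, SexScope], KeywordPattern]
    active_codes: Dict[str, CodePattern]
    code_descriptions_as_keywords: bool = False
    collapsed_duplicates: int = 0

    def __post_init__(self):
        self._matchers: Dict[Sex, "RuleSetMatcher"] = {}
        self._desc_matchers: Dict[str, CompiledKeyword] = {}

    def keywords_for_sex(self, sex: Sex) -> List[KeywordPattern]:
        return [kw for kw in self.active_keywords.values() if kw.sex_scope.applies_to(sex)]

    def matcher_for_sex(self, sex: Sex) -> "RuleSetMatcher":
        if sex not in self._matchers:
            self._matchers[sex] = RuleSetMatcher(self.keywords_for_sex(sex))
        return self._matchers[sex]

    def match_codes(self, recorded: str) -> List[CodePattern]:
        norm = normalize_code(recorded)
        hits = []
        for cp in self.active_codes.values():
            if cp.match_mode == MatchMode.EXACT:
                if norm == cp.normalized:
                    hits.append(cp)
            elif norm.startswith(cp.normalized):
                hits.append(cp)
        return hits

    def match_code_descriptions(self, description: str) -> List[Tuple[CodePattern, Tuple[int, int]]]:
        """Code patterns whose description phrase matches free description text."""
        if not self.code_descriptions_as_keywords or not description:
            return []
        hits = []
        for cp in self.active_codes.values():
            if not cp.description:
                continue
            ck = self._desc_matchers.get(cp.normalized)
            if ck is None:
                ck = compile_keyword(cp.description)
                self._desc_matchers[cp.normalized] = ck
            span = ck.find_first(description)
            if span is not None:
                hits.append((cp, span))
        return hits


class RuleSetMatcher:
    """Token-indexed matcher over a set of keyword patterns.

    Single-token literal patterns resolve by dictionary lookup; multi-token
    phrases are bucketed by their (literal) first token; patterns whose first
    token carries a wildcard are the only ones scanned per position.
    """

    def __init__(self, patterns: Sequence[KeywordPattern]):
        self._lit_single: Dict[str, List[Tuple[KeywordPattern, CompiledKeyword]]] = {}
        self._lit_first: Dict[str, List[Tuple[KeywordPattern, CompiledKeyword]]] = {}
        self._wild_first: List[Tuple[KeywordPattern, CompiledKeyword]] = []
        for kw in patterns:
            ck = compile_keyword(kw.raw)
            first = ck.tokens[0]
            if "%" in first:
                self._wild_first.append((kw, ck))
            elif len(ck.tokens) == 1:
                self._lit_single.setdefault(first, []).append((kw, ck))
            else:
                self._lit_first.setdefault(first, []).append((kw, ck))

    def match_text(self, text: str) -> List[Tuple[KeywordPattern, int, int, str]]:
        """All matching patterns with the first-hit span of each.

        Returns (pattern, start, end, matched_text) tuples, one per pattern,
        in first-hit order.
        """
        toks = tokenize(text)
        names = [t for t, _, _ in toks]
        hits: Dict[Tuple[str, SexScope], Tuple[KeywordPattern, int, int]] = {}
        for pos, tok in enumerate(names):
            for kw, ck in self._lit_single.get(tok, ()):
                hits.setdefault(kw.key, (kw, toks[pos][1], toks[pos][2]))
            for kw, ck in self._lit_first.get(tok, ()):
                if kw.key not in hits and ck.matches_at(names, pos):
                    end = toks[pos + len(ck.tokens) - 1][2]
                    hits[kw.key] = (kw, toks[pos][1], end)
            for kw, ck in self._wild_first:
                if kw.key not in hits and ck.matches_at(names, pos):
                    end = toks[pos + len(ck.tokens) - 1][2]
                    hits[kw.key] = (kw, toks[pos][1], end)
        out = sorted(hits.values(), key=lambda h: (h[1], h[0].canonical))
        return [(kw, s, e, text[s:e]) for kw, s, e in out]


# ---------------------------------------------------------------------------
# Configuration loading and assembly


def default_ruleset_path() -> Path:
    """Path of the packaged default phenotype configuration."""
    return Path(resources.files("ehrsentry").joinpath("data/table1_default.yaml"))


def _parse_keyword_entry(entry, effective_from: date, source_tag: str) -> KeywordPattern:
    if isinstance(entry, str):
        return KeywordPattern(raw=entry, effective_from=effective_from, source_tag=source_tag)
    return KeywordPattern(
        raw=entry["pattern"],
        sex_scope=SexScope(entry.get("sex_scope", "any")),
        effective_from=effective_from,
        source_tag=entry.get("source_tag", source_tag),
    )


def _parse_removal_entry(entry) -> _KeywordRemoval:
    if isinstance(entry, str):
        return _KeywordRemoval(pattern=canonical_phrase(entry))
    return _KeywordRemoval(
        pattern=canonical_phrase(entry["pattern"]),
        sex_scope=SexScope(entry.get("sex_scope", "any")),
    )


def load_ruleset_config(path: Union[str, Path, None] = None) -> List[RuleSetVersion]:
    """Load a versioned ruleset configuration (YAML) into an ordered history.

    With no *path* the packaged default configuration is loaded. The full
    history is validated on load: version ids unique, effective dates
    strictly increasing, and every removal must reference a pattern active at
    its date.
    """
    if path is None:
        path = default_ruleset_path()
    with Path(path).open("r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    raw_versions = (doc or {}).get("versions") or []
    if not raw_versions:
        raise RulesetConfigError("no versions defined")

    versions: List[RuleSetVersion] = []
    seen_ids = set()
    for rv in raw_versions:
        vid = str(rv["id"])
        if vid in seen_ids:
            raise RulesetConfigError(f"duplicate version_id {vid!r}")
        seen_ids.add(vid)
        eff = rv["effective_from"]
        if isinstance(eff, str):
            eff = date.fromisoformat(eff)
        versions.append(
            RuleSetVersion(
                version_id=vid,
                effective_from=eff,
                added_keywords=[_parse_keyword_entry(e, eff, vid) for e in rv.get("add_keywords") or []],
                removed_keywords=[_parse_removal_entry(e) for e in rv.get("remove_keywords") or []],
                added_codes=[
                    CodePattern(
                        raw_code=e["code"],
                        description=e.get("description", ""),
                        match_mode=MatchMode(e.get("match_mode", "prefix")),
                        effective_from=eff,
                        source_tag=e.get("source_tag", vid),
                    )
                    for e in rv.get("add_codes") or []
                ],
                removed_codes=[normalize_code(c) for c in rv.get("remove_codes") or []],
            )
        )

    versions.sort(key=lambda v: v.effective_from)
    for a, b in zip(versions, versions[1:]):
        if b.effective_from <= a.effective_from:
            raise RulesetConfigError(
                f"version effective dates must be strictly increasing; "
                f"{b.version_id!r} ({b.effective_from}) does not follow {a.version_id!r} ({a.effective_from})"
            )
    # Replaying the whole history validates every removal.
    assemble_ruleset_as_of(versions, versions[-1].effective_from)
    return versions


def load_default_ruleset_versions() -> List[RuleSetVersion]:
    return load_ruleset_config(None)


def assemble_ruleset_as_of(
    versions: Sequence[RuleSetVersion],
    as_of: date,
    code_descriptions_from: date = CODE_DESCRIPTION_KEYWORDS_FROM,
) -> RuleSet:
    """Assemble the active phenotype as of *as_of* (inclusive boundary).

    The active set is the union of all additions effective on or before
    *as_of*, minus removals effective on or before that date. Duplicate
    additions collapse silently (counted in ``collapsed_duplicates``). A
    sex-scoped removal of a pattern active for all sexes narrows it to the
    opposite scope.
    """
    if not versions:
        raise RulesetConfigError("no versions defined")
    ordered = sorted(versions, key=lambda v: v.effective_from)
    if as_of < ordered[0].effective_from:
        raise RulesetConfigError(
            f"ruleset not yet defined: {as_of} precedes first version ({ordered[0].effective_from})"
        )

    keywords: Dict[Tuple[str, SexScope], KeywordPattern] = {}
    codes: Dict[str, CodePattern] = {}
    collapsed = 0
    for ver in ordered:
        if ver.effective_from > as_of:
            break
        for kw in ver.added_keywords:
            if kw.key in keywords:
                collapsed += 1
            else:
                keywords[kw.key] = kw
        for rm in ver.removed_keywords:
            collapsed_key = (rm.pattern, rm.sex_scope)
            if rm.sex_scope == SexScope.ANY:
                matching = [k for k in keywords if k[0] == rm.pattern]
                if not matching:
                    raise RulesetConfigError(
                        f"version {ver.version_id!r} removes {rm.pattern!r}, which is not active"
                    )
                for k in matching:
                    del keywords[k]
            else:
                if collapsed_key in keywords:
                    del keywords[collapsed_key]
                elif (rm.pattern, SexScope.ANY) in keywords:
                    old = keywords.pop((rm.pattern, SexScope.ANY))
                    narrowed = (
                        SexScope.FEMALE_ONLY if rm.sex_scope == SexScope.MALE_ONLY else SexScope.MALE_ONLY
                    )
                    kept = old.model_copy(update={"sex_scope": narrowed})
                    keywords[kept.key] = kept
                else:
                    raise RulesetConfigError(
                        f"version {ver.version_id!r} removes {rm.pattern!r} "
                        f"({rm.sex_scope.value}), which is not active for that scope"
                    )
        for cp in ver.added_codes:
            if cp.normalized in codes:
                collapsed += 1
            else:
                codes[cp.normalized] = cp
        for norm in ver.removed_codes:
            if norm not in codes:
                raise RulesetConfigError(
                    f"version {ver.version_id!r} removes code {norm!r}, which is not active"
                )
            del codes[norm]

    return RuleSet(
        as_of=as_of,
        active_keywords=keywords,
        active_codes=codes,
        code_descriptions_as_keywords=as_of >= code_descriptions_from,
        collapsed_duplicates=collapsed,
    )


# ---------------------------------------------------------------------------
# Diffing


@dataclass
class RuleSetDelta:
    keywords_added: List[KeywordPattern]
    keywords_removed: List[KeywordPattern]
    codes_added: List[CodePattern]
    codes_removed: List[CodePattern]

    @property
    def scope_changes(self) -> List[Tuple[str, SexScope, SexScope]]:
        """Phrases present on both sides under different sex scopes."""
        removed = {kw.canonical: kw.sex_scope for kw in self.keywords_removed}
        changes = []
        for kw in self.keywords_added:
            if kw.canonical in removed and removed[kw.canonical] != kw.sex_scope:
                changes.append((kw.canonical, removed[kw.canonical], kw.sex_scope))
        return changes

    def is_empty(self) -> bool:
        return not (self.keywords_added or self.keywords_removed or self.codes_added or self.codes_removed)

    def to_dict(self) -> dict:
        return {
            "keywords_added": [
                {"pattern": kw.raw, "sex_scope": kw.sex_scope.value} for kw in self.keywords_added
            ],
            "keywords_removed": [
                {"pattern": kw.raw, "sex_scope": kw.sex_scope.value} for kw in self.keywords_removed
            ],
            "codes_added": [{"code": cp.raw_code, "match_mode": cp.match_mode.value} for cp in self.codes_added],
            "codes_removed": [
                {"code": cp.raw_code, "match_mode": cp.match_mode.value} for cp in self.codes_removed
            ],
            "scope_changes": [
                {"pattern": raw, "from": old.value, "to": new.value} for raw, old, new in self.scope_changes
            ],
        }


def diff_rulesets(a: RuleSet, b: RuleSet) -> RuleSetDelta:
    """Structured delta turning ruleset *a* into ruleset *b*."""
    kw_keys = sorted(set(b.active_keywords) - set(a.active_keywords))
    kw_gone = sorted(set(a.active_keywords) - set(b.active_keywords))
    code_keys = sorted(set(b.active_codes) - set(a.active_codes))
    code_gone = sorted(set(a.active_codes) - set(b.active_codes))
    return RuleSetDelta(
        keywords_added=[b.active_keywords[k] for k in kw_keys],
        keywords_removed=[a.active_keywords[k] for k in kw_gone],
        codes_added=[b.active_codes[k] for k in code_keys],
        codes_removed=[a.active_codes[k] for k in code_gone],
    )


def apply_delta(a: RuleSet, delta: RuleSetDelta) -> RuleSet:
    """Apply *delta* to *a*; ``apply_delta(a, diff_rulesets(a, b))`` equals *b*."""
    keywords = dict(a.active_keywords)
    for kw in delta.keywords_removed:
        keywords.pop(kw.key, None)
    for kw in delta.keywords_added:
        keywords[kw.key] = kw
    codes = dict(a.active_codes)
    for cp in delta.codes_removed:
        codes.pop(cp.normalized, None)
    for cp in delta.codes_added:
        codes[cp.normalized] = cp
    return RuleSet(
        as_of=a.as_of,
        active_keywords=keywords,
        active_codes=codes,
        code_descriptions_as_keywords=a.code_descriptions_as_keywords,
    )
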