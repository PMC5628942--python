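"""Boolean keyword query language: parsing and evaluation.

Query syntax (case-insensitive matching throughout):

* a space between operands denotes AND;
* an uppercase, standalone ``OR`` separates alternatives (lowercase
  ``or`` is an ordinary search term);
* parentheses group clauses;
* quoted spans (single or double quotes) are matched as exact
  consecutive-token phrases rather than independent words.

Inside an OR group, an alternative written as several unquoted words
("finish line", "San Francisco") is treated as a phrase: requiring mere
co-occurrence would make "San Francisco" match any text containing both
words anywhere, which contradicts the evident intent of such operands.

Matching is token based.  Text is lowercased and split into maximal
runs of Unicode letters and digits; every other character (including
``#``, ``@``, punctuation and underscore) is a separator, so ``#sf``
matches the term ``sf`` and the quoted operand ``'214'`` does not match
``62148``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence, Union

__all__ = [
    "Term",
    "Phrase",
    "And",
    "Or",
    "FilterRule",
    "KeywordSets",
    "RuleParseError",
    "tokenize",
    "parse_rule",
    "parse_operand",
    "render",
    "matches",
    "matches_any",
    "joint_match",
    "load_rules",
]

_TOKEN_RE = re.compile(r"[^\W_]+", re.UNICODE)


def tokenize(text: str) -> list[str]:
    """Lowercase *text* and split it into letter/digit tokens.

    >>> tokenize("Plane crash at SFO!")
    ['plane', 'crash', 'at', 'sfo']
    >>> tokenize("#PrayForBoston RT @cnn")
    ['prayforboston', 'rt', 'cnn']
    """
    return _TOKEN_RE.findall(text.lower())


# --------------------------------------------------------------------------
# AST


@dataclass(frozen=True)
class Term:
    token: str

    def __post_init__(self) -> None:
        if not self.token or self.token != self.token.lower() or _TOKEN_RE.fullmatch(self.token) is None:
            raise ValueError(f"invalid term token: {self.token!r}")


@dataclass(frozen=True)
class Phrase:
    tokens: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "tokens", tuple(self.tokens))
        if not self.tokens:
            raise ValueError("empty phrase")
        for tok in self.tokens:
            if not tok or tok != tok.lower() or _TOKEN_RE.fullmatch(tok) is None:
                raise ValueError(f"invalid phrase token: {tok!r}")


@dataclass(frozen=True)
class And:
    children: tuple["FilterRule", ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "children", tuple(self.children))
        if len(self.children) < 2:
            raise ValueError("AND requires at least two children")


@dataclass(frozen=True)
class Or:
    children: tuple["FilterRule", ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "children", tuple(self.children))
        if len(self.children) < 2:
            raise ValueError("OR requires at least two children")


FilterRule = Union[Term, Phrase, And, Or]


@dataclass(frozen=True)
class KeywordSets:
    """Operand sets for joint event+location matching."""

    event_terms: tuple[FilterRule, ...]
    location_terms: tuple[FilterRule, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "event_terms", tuple(self.event_terms))
        object.__setattr__(self, "location_terms", tuple(self.location_terms))
        if not self.event_terms or not self.location_terms:
            raise ValueError("both keyword sets must be non-empty")

    @classmethod
    def from_words(cls, event_words: Iterable[str], location_words: Iterable[str]) -> "KeywordSets":
        return cls(
            tuple(parse_operand(w) for w in event_words),
            tuple(parse_operand(w) for w in location_words),
        )


# --------------------------------------------------------------------------
# Parser


class RuleParseError(ValueError):
    """Raised on malformed rule text; carries the character position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


@dataclass(frozen=True)
class _Lexeme:
    kind: str  # LPAREN | RPAREN | OR | WORD | QUOTED
    value: str
    pos: int


def _lex(text: str) -> list[_Lexeme]:
    out: list[_Lexeme] = []
    i, n = 0, len(text)
    while i < n:
        ch = text[i]
        if ch.isspace():
            i += 1
        elif ch == "(":
            out.append(_Lexeme("LPAREN", ch, i))
            i += 1
        elif ch == ")":
            out.append(_Lexeme("RPAREN", ch, i))
            i += 1
        elif ch in "'\"":
            j = text.find(ch, i + 1)
            if j < 0:
                raise RuleParseError("unbalanced quote", i)
            out.append(_Lexeme("QUOTED", text[i + 1 : j], i))
            i = j + 1
        else:
            j = i
            while j < n and not text[j].isspace() and text[j] not in "()'\"":
                j += 1
            word = text[i:j]
            if word == "OR":
                out.append(_Lexeme("OR", word, i))
            else:
                out.append(_Lexeme("WORD", word, i))
            i = j
    return out


class _Parser:
    def __init__(self, lexemes: list[_Lexeme], length: int):
        self.lexemes = lexemes
        self.i = 0
        self.length = length

    def peek(self) -> _Lexeme | None:
        return self.lexemes[self.i] if self.i < len(self.lexemes) else None

    def next(self) -> _Lexeme:
        lex = self.lexemes[self.i]
        self.i += 1
        return lex

    # item := ( node, is_bare_word )
    def parse_primary(self) -> tuple[FilterRule, bool]:
        lex = self.peek()
        if lex is None:
            raise RuleParseError("unexpected end of rule", self.length)
        if lex.kind == "LPAREN":
            self.next()
            node = self.parse_group(lex.pos)
            closing = self.peek()
            if closing is None or closing.kind != "RPAREN":
                raise RuleParseError("unbalanced parenthesis", lex.pos)
            self.next()
            return node, False
        if lex.kind == "QUOTED":
            self.next()
            toks = tokenize(lex.value)
            if not toks:
                raise RuleParseError("quoted span has no searchable tokens", lex.pos)
            return Phrase(tuple(toks)), False
        if lex.kind == "WORD":
            self.next()
            toks = tokenize(lex.value)
            if not toks:
                raise RuleParseError(f"word {lex.value!r} has no searchable tokens", lex.pos)
            if len(toks) == 1:
                return Term(toks[0]), True
            return Phrase(tuple(toks)), True
        raise RuleParseError(f"unexpected {lex.value!r}", lex.pos)

    def parse_group(self, start: int) -> FilterRule:
        """Parse OR-separated alternatives; adjacency within each binds to AND
        (or collapses to a phrase, see module docstring)."""
        alternatives: list[list[tuple[FilterRule, bool]]] = [[]]
        while True:
            lex = self.peek()
            if lex is None or lex.kind == "RPAREN":
                break
            if lex.kind == "OR":
                self.next()
                alternatives.append([])
                continue
            alternatives[-1].append(self.parse_primary())
        for alt in alternatives:
            if not alt:
                raise RuleParseError("empty OR alternative", start)
        if len(alternatives) == 1:
            return self._combine_adjacent(alternatives[0])
        branches = [self._collapse_alternative(alt) for alt in alternatives]
        return Or(tuple(branches))

    @staticmethod
    def _combine_adjacent(items: list[tuple[FilterRule, bool]]) -> FilterRule:
        if len(items) == 1:
            return items[0][0]
        return And(tuple(node for node, _ in items))

    @staticmethod
    def _collapse_alternative(items: list[tuple[FilterRule, bool]]) -> FilterRule:
        if len(items) == 1:
            return items[0][0]
        if all(bare for _, bare in items):
            toks: list[str] = []
            for node, _ in items:
                toks.extend([node.token] if isinstance(node, Term) else node.tokens)
            return Phrase(tuple(toks))
        return And(tuple(node for node, _ in items))


def parse_rule(rule_text: str) -> FilterRule:
    """Parse one boolean keyword rule into its AST.

    >>> parse_rule("Boston (explosion OR terrorist)")
    And(children=(Term(token='boston'), Or(children=(Term(token='explosion'), Term(token='terrorist')))))
    """
    lexemes = _lex(rule_text)
    if not lexemes:
        raise RuleParseError("empty rule", 0)
    parser = _Parser(lexemes, len(rule_text))
    node = parser.parse_group(0)
    trailing = parser.peek()
    if trailing is not None:
        raise RuleParseError("unbalanced parenthesis", trailing.pos)
    return node


def parse_operand(word: str) -> FilterRule:
    """Parse a single keyword operand (one term or one phrase)."""
    node = parse_rule(word)
    if not isinstance(node, (Term, Phrase)):
        raise RuleParseError(f"expected a single operand, got a compound rule: {word!r}", 0)
    return node


def render(rule: FilterRule) -> str:
    """Pretty-print an AST back to rule text; ``parse_rule(render(r)) == r``."""
    if isinstance(rule, Term):
        return rule.token
    if isinstance(rule, Phrase):
        return "'" + " ".join(rule.tokens) + "'"
    if isinstance(rule, And):
        return " ".join(
            f"({render(c)})" if isinstance(c, (And, Or)) else render(c) for c in rule.children
        )
    if isinstance(rule, Or):
        # bare-word adjacency inside an OR alternative reads as a phrase,
        # so AND children must keep their parentheses to round-trip
        return "(" + " OR ".join(
            f"({render(c)})" if isinstance(c, (And, Or)) else render(c) for c in rule.children
        ) + ")"
    raise TypeError(f"not a rule node: {rule!r}")


# --------------------------------------------------------------------------
# Evaluation


def _phrase_in(needle: Sequence[str], haystack: Sequence[str]) -> bool:
    k = len(needle)
    if k == 0 or k > len(haystack):
        return False
    target = tuple(needle)
    return any(tuple(haystack[i : i + k]) == target for i in range(len(haystack) - k + 1))


def _eval(rule: FilterRule, tokens: Sequence[str], token_set: frozenset[str]) -> bool:
    if isinstance(rule, Term):
        return rule.token in token_set
    if isinstance(rule, Phrase):
        if len(rule.tokens) == 1:
            return rule.tokens[0] in token_set
        return _phrase_in(rule.tokens, tokens)
    if isinstance(rule, And):
        return all(_eval(c, tokens, token_set) for c in rule.children)
    if isinstance(rule, Or):
        return any(_eval(c, tokens, token_set) for c in rule.children)
    raise TypeError(f"not a rule node: {rule!r}")


def matches(rule: FilterRule, text: str) -> bool:
    """True iff *text* satisfies *rule* under token-based matching."""
    tokens = tokenize(text)
    return _eval(rule, tokens, frozenset(tokens))


def matches_any(rules: Sequence[FilterRule], text: str) -> bool:
    """Disjunction over a rule list (an event with several rule lines
    includes a message if any line matches); empty list matches nothing."""
    tokens = tokenize(text)
    token_set = frozenset(tokens)
    return any(_eval(r, tokens, token_set) for r in rules)


def joint_match(keywords: KeywordSets, text: str) -> bool:
    """True iff *text* contains at least one event operand AND at least
    one location operand."""
    tokens = tokenize(text)
    token_set = frozenset(tokens)
    return any(_eval(r, tokens, token_set) for r in keywords.event_terms) and any(
        _eval(r, tokens, token_set) for r in keywords.location_terms
    )


def load_rules(path) -> list[FilterRule]:
    """Load rules from a plain-text file, one rule per line; blank lines
    and ``#`` comments are skipped."""
    out = []
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.append(parse_rule(line))
    return out
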