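"""Independent brute-force reference implementations used to check the
package's evaluators.  These deliberately take a different route from
the production code (string search over a space-joined token stream,
linear scans) so agreement is meaningful."""

import random

from tweetwatch.rules import And, Or, Phrase, Term, tokenize


def oracle_matches(rule, text):
    """Evaluate a rule by substring search over the joined token stream."""
    haystack = " " + " ".join(tokenize(text)) + " "
    return _eval(rule, haystack)


def _eval(rule, haystack):
    if isinstance(rule, Term):
        return f" {rule.token} " in haystack
    if isinstance(rule, Phrase):
        return " " + " ".join(rule.tokens) + " " in haystack
    if isinstance(rule, And):
        return all(_eval(c, haystack) for c in rule.children)
    if isinstance(rule, Or):
        return any(_eval(c, haystack) for c in rule.children)
    raise TypeError(rule)


ORACLE_VOCAB = ["boston", "bomb", "finish", "line", "sf", "214", "x2", "news", "a", "b"]


def random_rule(rng: random.Random, depth=0):
    kinds = ["TERM", "PHRASE"] if depth >= 4 else ["TERM", "PHRASE", "AND", "OR"]
    kind = rng.choice(kinds)
    if kind == "TERM":
        return Term(rng.choice(ORACLE_VOCAB))
    if kind == "PHRASE":
        return Phrase(tuple(rng.choice(ORACLE_VOCAB) for _ in range(rng.randint(1, 3))))
    children = tuple(random_rule(rng, depth + 1) for _ in range(rng.randint(2, 3)))
    return And(children) if kind == "AND" else Or(children)


_SEPARATORS = [" ", "  ", ", ", "! ", " #", " @", "-", ". "]


def random_text(rng: random.Random, max_tokens=12):
    n = rng.randint(0, max_tokens)
    parts = []
    for _ in range(n):
        word = rng.choice(ORACLE_VOCAB)
        if rng.random() < 0.3:
            word = word.upper()
        parts.append(word)
        parts.append(rng.choice(_SEPARATORS))
    return "".join(parts)


def oracle_milestone_minute(counts60, percent):
    """Linear scan for the first minute reaching percent% of the
    first-hour cumulative total; None when the hour is empty."""
    total = sum(counts60)
    if total == 0:
        return None
    running = 0
    for minute, c in enumerate(counts60, start=1):
        running += c
        if running * 100.0 >= percent * total - 1e-9:
            return minute
    return 60


def oracle_first_threshold_minute(counts, threshold):
    for minute, c in enumerate(counts, start=1):
        if c >= threshold:
            return minute
    return None
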