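"""Distinct arrangements of a multiset of labels, in lexicographic order."""

from __future__ import annotations

from collections import Counter
from math import factorial
from typing import Iterator, Sequence


def n_distinct_arrangements(labels: Sequence) -> int:
    n = len(labels)
    out = factorial(n)
    for c in Counter(labels).values():
        out //= factorial(c)
    return out


def distinct_arrangements(labels: Sequence) -> Iterator[tuple]:
    """Yield every distinct ordering of ``labels`` exactly once
    (lexicographic; no n! blow-up for repeated labels)."""
    counter = Counter(labels)
    keys = sorted(counter)
    n = len(labels)
    prefix: list = []

    def rec() -> Iterator[tuple]:
        if len(prefix) == n:
            yield tuple(prefix)
            return
        for k in keys:
            if counter[k]:
                counter[k] -= 1
                prefix.append(k)
                yield from rec()
                prefix.pop()
                counter[k] += 1

    return rec()
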