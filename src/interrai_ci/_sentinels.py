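"""Sentinel values shared across the package.

Three sentinels are distinguishable from every legal numeric code:

* ``MISSING`` — the item was not assessed / the cell is empty.
* ``UNCERTAIN`` — the assessor recorded the instrument's explicit
  "uncertain" code (only legal for items whose coding declares one).
* ``NOT_CALCULABLE`` — a statistic whose defining formula degenerates
  (e.g. a zero marginal in a 2x2 table, zero score variance).
"""

from __future__ import annotations


class Sentinel:
    """A named singleton; identity comparison only, never equal to a number."""

    __slots__ = ("name",)

    def __init__(self, name: str) -> None:
        self.name = name

    def __repr__(self) -> str:
        return self.name

    def __reduce__(self):  # keep identity through pickling
        return (_lookup, (self.name,))

    def __bool__(self) -> bool:
        raise TypeError(f"{self.name} has no truth value; test identity explicitly")


MISSING = Sentinel("MISSING")
UNCERTAIN = Sentinel("UNCERTAIN")
NOT_CALCULABLE = Sentinel("NOT_CALCULABLE")

_REGISTRY = {s.name: s for s in (MISSING, UNCERTAIN, NOT_CALCULABLE)}


def _lookup(name: str) -> Sentinel:
    return _REGISTRY[name]


def is_missing(value) -> bool:
    return value is MISSING


def is_sentinel(value) -> bool:
    return isinstance(value, Sentinel)
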