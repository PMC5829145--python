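"""Specification of the tree graph a tree lives in.

The hierarchy of discrete time-tree graphs is parametrised by a *family*
and, for the top levels, a maximum event-interval length ``m``:

* ``NNI`` — plain rooted-tree nearest-neighbour-interchange graph; no
  timing information at all.
* ``RNNI`` — ranked trees: every node (leaves included) carries a distinct
  integer time; all event intervals have length 1.
* ``RNNIu`` — ranked ultrametric trees: all leaves sampled at time 0, the
  n-1 internal nodes are totally ranked; all intervals have length 1.
* ``DtT_m`` (m >= 2) — discrete time-trees: ranked trees whose event
  intervals carry integer lengths in [1, m].
* ``DtTu_m`` (m >= 2) — the ultrametric restriction of ``DtT_m``.

``RNNI`` and ``RNNIu`` are the m = 1 levels of the hierarchy, so a
:class:`SpaceSpec` for them always has ``m == 1``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

__all__ = ["Family", "SpaceSpec"]


class Family(enum.Enum):
    NNI = "nni"
    RNNI = "rnni"
    RNNIU = "rnniu"
    DTT = "dtt"
    DTTU = "dttu"


# Families whose leaves are all fixed at time 0 (only internal nodes ranked).
_ULTRAMETRIC = frozenset({Family.RNNIU, Family.DTTU})
# Families whose trees carry interval lengths that may exceed 1.
_LENGTHED = frozenset({Family.DTT, Family.DTTU})


@dataclass(frozen=True)
class SpaceSpec:
    """Which graph a tree belongs to: family plus maximum interval length."""

    family: Family
    m: int = 1

    def __post_init__(self) -> None:
        if not isinstance(self.family, Family):
            raise TypeError(f"family must be a Family, got {self.family!r}")
        if self.family in _LENGTHED:
            if self.m < 2:
                raise ValueError(f"{self.family.value} requires m >= 2, got m={self.m}")
        else:
            # NNI carries no lengths; RNNI/RNNIu are the m = 1 level.
            if self.m != 1:
                raise ValueError(f"{self.family.value} fixes m = 1, got m={self.m}")

    # -- convenience constructors -------------------------------------

    @classmethod
    def nni(cls) -> "SpaceSpec":
        return cls(Family.NNI)

    @classmethod
    def rnni(cls) -> "SpaceSpec":
        return cls(Family.RNNI)

    @classmethod
    def rnniu(cls) -> "SpaceSpec":
        return cls(Family.RNNIU)

    @classmethod
    def dtt(cls, m: int) -> "SpaceSpec":
        return cls(Family.DTT, m)

    @classmethod
    def dttu(cls, m: int) -> "SpaceSpec":
        return cls(Family.DTTU, m)

    @classmethod
    def from_name(cls, name: str, m: int | None = None) -> "SpaceSpec":
        """Build a spec from a CLI-style name (nni, rnni, rnniu, dtt, dttu)."""
        family = Family(name.lower())
        if family in _LENGTHED:
            if m is None:
                raise ValueError(f"{name} requires an explicit m >= 2")
            return cls(family, m)
        if m not in (None, 1):
            raise ValueError(f"{name} does not take m (got m={m})")
        return cls(family)

    # -- structural predicates ----------------------------------------

    @property
    def is_ultrametric(self) -> bool:
        return self.family in _ULTRAMETRIC

    @property
    def is_ranked(self) -> bool:
        """True for every family with rank structure (everything but NNI)."""
        return self.family is not Family.NNI

    @property
    def has_lengths(self) -> bool:
        return self.family in _LENGTHED

    def n_intervals(self, n: int) -> int:
        """Number of event intervals of a tree on n leaves in this space."""
        if self.family is Family.NNI:
            return 0
        return n - 1 if self.is_ultrametric else 2 * n - 2

    def __str__(self) -> str:
        if self.has_lengths:
            return f"{self.family.value}_{self.m}"
        return self.family.value
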