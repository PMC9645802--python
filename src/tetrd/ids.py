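"""Vocabulary-typed integer identifiers.

Mesh elements, species, kinetic processes and ranks are all indexed by small
nonnegative integers.  Using bare ints invites silent cross-wiring (passing a
triangle index where a tetrahedron index is expected), so every public
signature in the package takes one of the typed id classes below.  Ids of
different kinds never compare equal and refuse arithmetic with each other;
raw integers appear only at I/O boundaries.
"""

from __future__ import annotations


class EntityId(int):
    """Base class for typed nonnegative integer ids.

    Subclasses are distinct types: ``TetId(3) == TriId(3)`` is ``False``.
    """

    __slots__ = ()

    def __new__(cls, value: int):
        if cls is EntityId:
            raise TypeError("instantiate a concrete id kind, not EntityId")
        v = int(value)
        if v < 0:
            raise ValueError(f"{cls.__name__} must be nonnegative, got {v}")
        return super().__new__(cls, v)

    def __eq__(self, other) -> bool:
        if isinstance(other, EntityId) and type(other) is not type(self):
            return False
        return int(self) == int(other)

    def __ne__(self, other) -> bool:
        return not self.__eq__(other)

    def __hash__(self) -> int:
        return hash((type(self).__name__, int(self)))

    def __repr__(self) -> str:
        return f"{type(self).__name__}({int(self)})"


class TetId(EntityId):
    """Local (process-wide) tetrahedron index."""
    __slots__ = ()


class GlobalTetId(EntityId):
    """Global tetrahedron index, identical across partitions."""
    __slots__ = ()


class TriId(EntityId):
    """Surface-triangle index."""
    __slots__ = ()


class VertId(EntityId):
    """Mesh vertex index."""
    __slots__ = ()


class SpeciesId(EntityId):
    """Index of a species (or channel state) within a model."""
    __slots__ = ()


class ProcId(EntityId):
    """Kinetic-process index."""
    __slots__ = ()


class RankId(EntityId):
    """Emulated MPI rank index."""
    __slots__ = ()
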