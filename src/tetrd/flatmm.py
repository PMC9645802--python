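"""Fixed-shape contiguous multimap (the flat-multimap container).

A multimap from small nonnegative integer keys to sequences of values, stored
in exactly two contiguous arrays:

* ``a2ab`` — offsets, one entry per key plus a terminal sentinel;
* ``ab2c`` — all values, concatenated in key order.

The values of key ``a`` occupy ``ab2c[a2ab[a] : a2ab[a+1]]``.  For example the
map ``{0: [a, b, c], 2: [d]}`` over a key space of size 4 stores
``a2ab = [0, 3, 3, 4, 4]``: key 0 yields ``ab2c[0:3]``, key 1 is empty because
``a2ab[1] == a2ab[2]``.

Shape is fixed at construction — the container never grows.  Lookup is two
offset reads and returns a zero-copy view.  This layout backs every
fixed-shape key->values table in the simulator (tet->neighbor faces,
vertex->membrane triangles, process->dependents ...), trading mutability for
locality and exactly two allocations.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np


class FlatMultimap:
    """Immutable integer-keyed multimap over two flat arrays."""

    __slots__ = ("a2ab", "ab2c", "num_keys")

    def __init__(self, a2ab: np.ndarray, ab2c: np.ndarray):
        a2ab = np.asarray(a2ab)
        self.a2ab = a2ab
        self.ab2c = np.asarray(ab2c)
        self.num_keys = len(a2ab) - 1
        if a2ab[0] != 0 or a2ab[-1] != len(self.ab2c):
            raise ValueError("a2ab must start at 0 and end at len(ab2c)")
        if np.any(np.diff(a2ab) < 0):
            raise ValueError("a2ab must be nondecreasing")

    @classmethod
    def from_pairs(
        cls,
        pairs: Iterable[tuple[int, object]],
        num_keys: int,
        dtype=None,
    ) -> "FlatMultimap":
        """Build from (key, value) pairs; values of a key keep insertion order."""
        buckets: list[list] = [[] for _ in range(num_keys)]
        for k, v in pairs:
            k = int(k)
            if not 0 <= k < num_keys:
                raise KeyError(f"key {k} outside declared key space [0, {num_keys})")
            buckets[k].append(v)
        counts = np.fromiter((len(b) for b in buckets), dtype=np.int64, count=num_keys)
        a2ab = np.zeros(num_keys + 1, dtype=np.int64)
        np.cumsum(counts, out=a2ab[1:])
        flat = [v for b in buckets for v in b]
        ab2c = np.asarray(flat, dtype=dtype) if flat else np.empty(0, dtype=dtype)
        return cls(a2ab, ab2c)

    @classmethod
    def from_lists(cls, lists: Sequence[Sequence], dtype=None) -> "FlatMultimap":
        """Build from one value-list per key (index = key)."""
        return cls.from_pairs(
            ((k, v) for k, vals in enumerate(lists) for v in vals), len(lists), dtype
        )

    def __getitem__(self, key: int) -> np.ndarray:
        """Zero-copy view of the values of ``key``."""
        k = int(key)
        if not 0 <= k < self.num_keys:
            raise KeyError(f"key {k} outside key space [0, {self.num_keys})")
        return self.ab2c[self.a2ab[k] : self.a2ab[k + 1]]

    def bounds(self, key: int) -> tuple[int, int]:
        k = int(key)
        if not 0 <= k < self.num_keys:
            raise KeyError(f"key {k} outside key space [0, {self.num_keys})")
        return int(self.a2ab[k]), int(self.a2ab[k + 1])

    def __len__(self) -> int:
        return self.num_keys

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, FlatMultimap)
            and np.array_equal(self.a2ab, other.a2ab)
            and np.array_equal(self.ab2c, other.ab2c)
        )

    def __repr__(self) -> str:
        return f"FlatMultimap(keys={self.num_keys}, values={len(self.ab2c)})"
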