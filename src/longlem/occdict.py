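"""Diagonal-keyed dictionaries for live match tracking.

During a long-match query every text suffix currently inside the
tracked suffix-array interval is stored under its diagonal key
``suffix - window_start`` (left extension decrements both, so the key
is stable) with the pattern end position of its longest match as the
value.  Two interchangeable implementations are provided:

* :class:`HashedOccDict` -- a hash map, expected O(1) per operation;
* :class:`OrderedOccDict` -- an AVL-tree map, worst-case O(log size)
  per operation, for callers wanting a deterministic bound.
"""

from __future__ import annotations

__all__ = ["InternalConsistencyError", "HashedOccDict", "OrderedOccDict", "make_occ_dict"]


class InternalConsistencyError(Exception):
    """A key the algorithm relies on is missing: signals a bug, not bad input."""


class HashedOccDict:
    """Hash-backed mapping with operation counting."""

    def __init__(self, counters=None):
        self._data = {}
        self.counters = counters if counters is not None else {}

    def _count(self):
        self.counters["dict"] = self.counters.get("dict", 0) + 1

    def insert(self, key: int, value: int) -> None:
        self._count()
        self._data[key] = value

    def pop(self, key: int) -> int:
        self._count()
        try:
            return self._data.pop(key)
        except KeyError:
            raise InternalConsistencyError(f"missing diagonal key {key}") from None

    def get(self, key: int):
        self._count()
        return self._data.get(key)

    def __len__(self) -> int:
        return len(self._data)

    def __contains__(self, key) -> bool:
        return key in self._data

    def items(self):
        return self._data.items()


class _Node:
    __slots__ = ("key", "value", "left", "right", "height")

    def __init__(self, key, value):
        self.key = key
        self.value = value
        self.left = None
        self.right = None
        self.height = 1


def _h(node):
    return node.height if node else 0


def _update(node):
    node.height = 1 + max(_h(node.left), _h(node.right))


def _rotate_right(y):
    x = y.left
    y.left = x.right
    x.right = y
    _update(y)
    _update(x)
    return x


def _rotate_left(x):
    y = x.right
    x.right = y.left
    y.left = x
    _update(x)
    _update(y)
    return y


def _rebalance(node):
    _update(node)
    bal = _h(node.left) - _h(node.right)
    if bal > 1:
        if _h(node.left.left) < _h(node.left.right):
            node.left = _rotate_left(node.left)
        return _rotate_right(node)
    if bal < -1:
        if _h(node.right.right) < _h(node.right.left):
            node.right = _rotate_right(node.right)
        return _rotate_left(node)
    return node


class OrderedOccDict:
    """AVL-tree mapping: worst-case O(log size) insert / pop / get."""

    def __init__(self, counters=None):
        self._root = None
        self._size = 0
        self.counters = counters if counters is not None else {}

    def _count(self):
        self.counters["dict"] = self.counters.get("dict", 0) + 1

    def insert(self, key: int, value: int) -> None:
        self._count()
        self._root = self._insert(self._root, key, value)

    def _insert(self, node, key, value):
        if node is None:
            self._size += 1
            return _Node(key, value)
        if key == node.key:
            node.value = value
            return node
        if key < node.key:
            node.left = self._insert(node.left, key, value)
        else:
            node.right = self._insert(node.right, key, value)
        return _rebalance(node)

    def get(self, key: int):
        self._count()
        node = self._root
        while node is not None:
            if key == node.key:
                return node.value
            node = node.left if key < node.key else node.right
        return None

    def pop(self, key: int) -> int:
        self._count()
        found = []
        self._root = self._delete(self._root, key, found)
        if not found:
            raise InternalConsistencyError(f"missing diagonal key {key}")
        self._size -= 1
        return found[0]

    def _delete(self, node, key, found):
        if node is None:
            return None
        if key < node.key:
            node.left = self._delete(node.left, key, found)
        elif key > node.key:
            node.right = self._delete(node.right, key, found)
        else:
            found.append(node.value)
            if node.left is None:
                return node.right
            if node.right is None:
                return node.left
            succ = node.right
            while succ.left is not None:
                succ = succ.left
            node.key, node.value = succ.key, succ.value
            dummy = []
            node.right = self._delete(node.right, succ.key, dummy)
        return _rebalance(node)

    def __len__(self) -> int:
        return self._size

    def __contains__(self, key) -> bool:
        node = self._root
        while node is not None:
            if key == node.key:
                return True
            node = node.left if key < node.key else node.right
        return False

    def items(self):
        out = []

        def walk(node):
            if node is None:
                return
            walk(node.left)
            out.append((node.key, node.value))
            walk(node.right)

        walk(self._root)
        return out


def make_occ_dict(mode: str = "hashed", counters=None):
    if mode == "hashed":
        return HashedOccDict(counters)
    if mode == "ordered":
        return OrderedOccDict(counters)
    raise ValueError(f"unknown dict mode {mode!r}")
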