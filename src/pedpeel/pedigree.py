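"""Pedigree container, generation ordering and family (mate-pair) structure.

A pedigree is a list of ``(id, sire, dam)`` records. Unknown parents are
denoted ``"0"``. After construction every individual either has both parents
known or is a founder: parents that appear only in the sire/dam columns are
auto-added as founders, and an individual recorded with exactly one known
parent gets a private anonymous founder for the missing slot (so two
offspring of the same sire with unknown dams are half-sibs, not full sibs).
"""

from __future__ import annotations

from dataclasses import dataclass, field

UNKNOWN = "0"


class PedigreeError(ValueError):
    """Raised for malformed pedigrees (cycles, duplicate ids)."""


@dataclass(frozen=True)
class Family:
    """A mate pair and its shared offspring."""

    sire: int
    dam: int
    children: tuple[int, ...]


@dataclass
class Pedigree:
    """An acyclic pedigree with generation indices and family structure.

    Attributes
    ----------
    ids
        Individual identifiers in input order (auto-added founders included).
    sire, dam
        Parent indices per individual; ``-1`` for founders (both or neither
        parent is ``-1``).
    generation
        Longest-path depth from founders; ``generation[child] >
        generation[parent]`` for every known parent.
    """

    ids: list[str]
    sire: list[int]
    dam: list[int]
    generation: list[int] = field(init=False)
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._index = {name: i for i, name in enumerate(self.ids)}
        if len(self._index) != len(self.ids):
            seen: set[str] = set()
            for name in self.ids:
                if name in seen:
                    raise PedigreeError(f"duplicate individual id: {name!r}")
                seen.add(name)
        self.generation = self._generations()

    # ------------------------------------------------------------------
    @classmethod
    def from_records(cls, records: list[tuple[str, str, str]]) -> "Pedigree":
        """Build a pedigree from ``(id, sire, dam)`` string triples."""
        names = [r[0] for r in records]
        seen = set()
        for n in names:
            if n in seen:
                raise PedigreeError(f"duplicate individual id: {n!r}")
            seen.add(n)
        ids: list[str] = []
        known = set()
        # implicit founders first, in order of first mention as a parent
        for ind, s, d in records:
            for parent in (s, d):
                if parent != UNKNOWN and parent not in seen and parent not in known:
                    ids.append(parent)
                    known.add(parent)
        ids.extend(names)
        index = {name: i for i, name in enumerate(ids)}
        sire = [-1] * len(ids)
        dam = [-1] * len(ids)
        anon = 0
        for ind, s, d in records:
            i = index[ind]
            if s == UNKNOWN and d == UNKNOWN:
                continue
            if s == UNKNOWN or d == UNKNOWN:
                # private anonymous founder for the missing slot
                anon += 1
                name = f"__anon{anon}__{ind}"
                ids.append(name)
                index[name] = len(ids) - 1
                sire.append(-1)
                dam.append(-1)
                if s == UNKNOWN:
                    s = name
                else:
                    d = name
            sire[i] = index[s]
            dam[i] = index[d]
        return cls(ids=ids, sire=sire, dam=dam)

    # ------------------------------------------------------------------
    def _generations(self) -> list[int]:
        n = len(self.ids)
        gen = [-1] * n
        state = [0] * n  # 0 unvisited, 1 on stack, 2 done

        for start in range(n):
            if state[start] == 2:
                continue
            stack = [start]
            while stack:
                i = stack[-1]
                if state[i] == 2:
                    stack.pop()
                    continue
                state[i] = 1
                pending = []
                for par in (self.sire[i], self.dam[i]):
                    if par >= 0 and state[par] != 2:
                        if state[par] == 1:
                            raise PedigreeError(
                                f"pedigree cycle detected involving {self.ids[par]!r}"
                            )
                        pending.append(par)
                if pending:
                    stack.extend(pending)
                    continue
                parents = [p for p in (self.sire[i], self.dam[i]) if p >= 0]
                gen[i] = 0 if not parents else 1 + max(gen[p] for p in parents)
                state[i] = 2
                stack.pop()
        return gen

    # ------------------------------------------------------------------
    def __len__(self) -> int:
        return len(self.ids)

    def index_of(self, name: str) -> int:
        return self._index[name]

    def is_founder(self, i: int) -> bool:
        return self.sire[i] < 0

    @property
    def founders(self) -> list[int]:
        return [i for i in range(len(self.ids)) if self.sire[i] < 0]

    def peeling_order(self) -> list[int]:
        """Topological order: parents before offspring.

        Deterministic: sorted by (generation, input position). The peel-up
        pass uses the exact reverse of this list.
        """
        return sorted(range(len(self.ids)), key=lambda i: (self.generation[i], i))

    def families(self) -> list[Family]:
        """Mate pairs ``(sire, dam)`` with their shared children.

        Ordered by the (common) generation of the children then by first
        appearance, which makes a family-wise sweep a valid peel-down order.
        """
        groups: dict[tuple[int, int], list[int]] = {}
        order: list[tuple[int, int]] = []
        for i in range(len(self.ids)):
            if self.sire[i] < 0:
                continue
            key = (self.sire[i], self.dam[i])
            if key not in groups:
                groups[key] = []
                order.append(key)
            groups[key].append(i)
        fams = [Family(s, d, tuple(groups[(s, d)])) for (s, d) in order]
        fams.sort(key=lambda f: (self.generation[f.children[0]], f.children[0]))
        return fams

    def ancestors(self, i: int) -> set[int]:
        """All ancestors of ``i`` (used by property tests)."""
        out: set[int] = set()
        stack = [p for p in (self.sire[i], self.dam[i]) if p >= 0]
        while stack:
            j = stack.pop()
            if j in out:
                continue
            out.add(j)
            stack.extend(p for p in (self.sire[j], self.dam[j]) if p >= 0)
        return out
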