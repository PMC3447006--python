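"""Pedigree storage, relatedness queries, and Wright's path-method inbreeding.

A :class:`Pedigree` holds one :class:`PedigreeRecord` per individual and
answers the lineage questions a closed breeding experiment needs: is a plant
inbred, are two plants relatives, and what is the average inbreeding
coefficient of a line at a given generation.

Inbreeding coefficients are computed by Wright's path-counting method:

    F_X = sum over common ancestors A, over pairs of non-overlapping paths
          from X's dam and sire up to A, of (1/2)^(n1 + n2 + 1) * (1 + F_A)

where ``n1`` and ``n2`` are the path lengths (in meioses) from each parent to
A.  Transmission is treated as disomic for every ploidy, i.e. tetraploids are
scored with the same path rules as diploids.  Path enumeration is exponential
in pedigree depth, which is fine for the short (few-generation) experimental
pedigrees this package targets.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from typing import Iterable, Iterator

from .errors import (
    DanglingParentError,
    DuplicateIdError,
    PedigreeCycleError,
    PedigreeError,
    UnknownIdError,
)

#: Sentinel written for an unknown parent; empty string is accepted on input.
UNKNOWN_PARENT = "0"

CSV_COLUMNS = [
    "id",
    "dam",
    "sire",
    "maternal_family",
    "line",
    "generation",
    "ploidy",
    "fertile",
]


def _is_unknown(parent_id: str) -> bool:
    return parent_id == UNKNOWN_PARENT or parent_id == ""


@dataclass(frozen=True, slots=True)
class PedigreeRecord:
    """One individual's parentage and experimental bookkeeping.

    ``dam_id``/``sire_id`` use :data:`UNKNOWN_PARENT` when the parent is not
    recorded; founders have both parents unknown.
    """

    id: str
    dam_id: str
    sire_id: str
    maternal_family: str
    line: str
    generation: int
    ploidy: int
    fertile: bool

    @property
    def is_founder(self) -> bool:
        return _is_unknown(self.dam_id) and _is_unknown(self.sire_id)

    def known_parents(self) -> tuple[str, ...]:
        return tuple(
            p for p in (self.dam_id, self.sire_id) if not _is_unknown(p)
        )


class Pedigree:
    """A validated, acyclic collection of :class:`PedigreeRecord`."""

    def __init__(self) -> None:
        self._records: dict[str, PedigreeRecord] = {}
        self._f_cache: dict[str, float] = {}
        self._paths_cache: dict[str, tuple[tuple[str, ...], ...]] = {}

    # -- construction --------------------------------------------------

    @classmethod
    def from_records(cls, records: Iterable[PedigreeRecord]) -> "Pedigree":
        """Build and fully validate a pedigree; row order does not matter."""
        ped = cls()
        for rec in records:
            if rec.id in ped._records:
                raise DuplicateIdError(f"duplicate individual id {rec.id!r}")
            if _is_unknown(rec.id):
                raise PedigreeError(
                    f"individual id may not be the unknown sentinel {rec.id!r}"
                )
            ped._records[rec.id] = rec
        ped._validate()
        return ped

    def add(self, rec: PedigreeRecord) -> None:
        """Append one individual whose known parents are already present.

        Used by the simulator, which grows pedigrees generation by
        generation; the ordering requirement makes cycles impossible and
        keeps cached coefficients valid (adding descendants never changes
        the inbreeding of existing individuals).
        """
        if rec.id in self._records:
            raise DuplicateIdError(f"duplicate individual id {rec.id!r}")
        for parent in rec.known_parents():
            if parent not in self._records:
                raise DanglingParentError(
                    f"{rec.id!r} references absent parent {parent!r}"
                )
            if self._records[parent].generation >= rec.generation:
                raise PedigreeError(
                    f"parent {parent!r} does not precede {rec.id!r} "
                    "in generation order"
                )
        self._records[rec.id] = rec

    def _validate(self) -> None:
        for rec in self._records.values():
            for parent in rec.known_parents():
                if parent not in self._records:
                    raise DanglingParentError(
                        f"{rec.id!r} references absent parent {parent!r}"
                    )
        # explicit cycle check (self-parentage, swapped generations, ...)
        state: dict[str, int] = {}  # 1 = on stack, 2 = done

        def visit(start: str) -> None:
            stack = [(start, iter(self._records[start].known_parents()))]
            state[start] = 1
            while stack:
                node, parents = stack[-1]
                advanced = False
                for p in parents:
                    if state.get(p) == 1:
                        raise PedigreeCycleError(
                            f"{p!r} is its own ancestor"
                        )
                    if p not in state:
                        state[p] = 1
                        stack.append((p, iter(self._records[p].known_parents())))
                        advanced = True
                        break
                if not advanced:
                    state[node] = 2
                    stack.pop()

        for rec_id in self._records:
            if rec_id not in state:
                visit(rec_id)
        for rec in self._records.values():
            for parent in rec.known_parents():
                if self._records[parent].generation >= rec.generation:
                    raise PedigreeError(
                        f"parent {parent!r} of {rec.id!r} must belong to an "
                        "earlier generation"
                    )

    # -- basic access --------------------------------------------------

    def __len__(self) -> int:
        return len(self._records)

    def __contains__(self, individual_id: str) -> bool:
        return individual_id in self._records

    def __iter__(self) -> Iterator[PedigreeRecord]:
        return iter(self._records.values())

    def record(self, individual_id: str) -> PedigreeRecord:
        try:
            return self._records[individual_id]
        except KeyError:
            raise UnknownIdError(f"no individual {individual_id!r}") from None

    # -- relatedness ---------------------------------------------------

    def ancestors(self, individual_id: str, max_depth: int | None = None) -> set[str]:
        """Ids of all known ancestors within ``max_depth`` meioses (the
        individual itself is not included)."""
        self.record(individual_id)
        out: set[str] = set()
        frontier = [individual_id]
        depth = 0
        while frontier and (max_depth is None or depth < max_depth):
            nxt: list[str] = []
            for node in frontier:
                for p in self._records[node].known_parents():
                    if p not in out:
                        out.add(p)
                        nxt.append(p)
            frontier = nxt
            depth += 1
        return out

    def are_relatives(
        self, a: str, b: str, max_depth: int | None = None
    ) -> bool:
        """True iff ``a`` and ``b`` share a known ancestor (or one is an
        ancestor of the other) within ``max_depth`` generations.

        ``max_depth=None`` searches the whole pedigree, the appropriate
        default for an experiment only a handful of generations deep.
        """
        if max_depth is not None and max_depth < 1:
            raise ValueError("max_depth must be >= 1")
        anc_a = self.ancestors(a, max_depth) | {a}
        anc_b = self.ancestors(b, max_depth) | {b}
        if a == b:
            return True
        return not anc_a.isdisjoint(anc_b)

    # -- inbreeding ----------------------------------------------------

    def _paths_up(self, individual_id: str) -> tuple[tuple[str, ...], ...]:
        """Every ancestral path ``(individual, ..., ancestor)``, including the
        length-0 path to the individual itself."""
        cached = self._paths_cache.get(individual_id)
        if cached is not None:
            return cached
        rec = self._records[individual_id]
        paths: list[tuple[str, ...]] = [(individual_id,)]
        for parent in rec.known_parents():
            for tail in self._paths_up(parent):
                paths.append((individual_id,) + tail)
        result = tuple(paths)
        self._paths_cache[individual_id] = result
        return result

    def inbreeding_coefficient(self, individual_id: str) -> float:
        """Wright's path-method F for one individual.

        Distinct loops through the same common ancestor each contribute a
        term; two paths of one loop may share only the common ancestor
        itself.
        """
        rec = self.record(individual_id)
        cached = self._f_cache.get(individual_id)
        if cached is not None:
            return cached
        if _is_unknown(rec.dam_id) or _is_unknown(rec.sire_id):
            self._f_cache[individual_id] = 0.0
            return 0.0
        dam_paths: dict[str, list[tuple[str, ...]]] = {}
        for path in self._paths_up(rec.dam_id):
            dam_paths.setdefault(path[-1], []).append(path)
        total = 0.0
        for path in self._paths_up(rec.sire_id):
            ancestor = path[-1]
            partners = dam_paths.get(ancestor)
            if not partners:
                continue
            f_anc = self.inbreeding_coefficient(ancestor)
            interior = set(path[:-1])
            for other in partners:
                if interior.isdisjoint(other[:-1]):
                    n_meioses = len(path) + len(other) - 1  # n1 + n2 + 1
                    total += 0.5 ** n_meioses * (1.0 + f_anc)
        total = min(total, 1.0)
        self._f_cache[individual_id] = total
        return total

    def mean_line_inbreeding(
        self,
        line: str,
        generation: int,
        fertile_only: bool = True,
    ) -> float:
        """Arithmetic mean F over one line's individuals at one generation.

        Sterile plants are excluded by default, matching the convention of
        dropping sterile individuals from all summary statistics.
        """
        members = [
            rec
            for rec in self._records.values()
            if rec.line == line
            and rec.generation == generation
            and (rec.fertile or not fertile_only)
        ]
        if not members:
            raise PedigreeError(
                f"no individuals in line {line!r} at generation {generation}"
                + (" (fertile only)" if fertile_only else "")
            )
        return sum(self.inbreeding_coefficient(r.id) for r in members) / len(
            members
        )


# -- CSV I/O -----------------------------------------------------------


def read_pedigree(path) -> Pedigree:
    """Read a pedigree CSV (columns ``id,dam,sire,maternal_family,line,
    generation,ploidy,fertile``).  Unknown parents may be coded ``0`` or
    left empty; row order is irrelevant."""
    records = []
    with open(path, newline="", encoding="utf-8") as handle:
        reader = csv.DictReader(handle)
        missing = set(CSV_COLUMNS) - set(reader.fieldnames or [])
        if missing:
            raise PedigreeError(
                f"pedigree CSV missing columns: {sorted(missing)}"
            )
        for row in reader:
            records.append(
                PedigreeRecord(
                    id=row["id"].strip(),
                    dam_id=UNKNOWN_PARENT
                    if _is_unknown(row["dam"].strip())
                    else row["dam"].strip(),
                    sire_id=UNKNOWN_PARENT
                    if _is_unknown(row["sire"].strip())
                    else row["sire"].strip(),
                    maternal_family=row["maternal_family"].strip(),
                    line=row["line"].strip(),
                    generation=int(row["generation"]),
                    ploidy=int(row["ploidy"]),
                    fertile=row["fertile"].strip().lower()
                    in {"1", "true", "t", "yes"},
                )
            )
    return Pedigree.from_records(records)


def write_pedigree(ped: Pedigree, path) -> None:
    """Write the pedigree CSV consumed by :func:`read_pedigree`."""
    with open(path, "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle)
        writer.writerow(CSV_COLUMNS)
        for rec in ped:
            writer.writerow(
                [
                    rec.id,
                    rec.dam_id,
                    rec.sire_id,
                    rec.maternal_family,
                    rec.line,
                    rec.generation,
                    rec.ploidy,
                    1 if rec.fertile else 0,
                ]
            )


def relabelled(ped: Pedigree, mapping: dict[str, str]) -> Pedigree:
    """Return a copy of ``ped`` with ids renamed via ``mapping`` (missing
    keys keep their id).  Utility for invariance checks."""

    def rename(identifier: str) -> str:
        if _is_unknown(identifier):
            return identifier
        return mapping.get(identifier, identifier)

    return Pedigree.from_records(
        replace(
            rec,
            id=rename(rec.id),
            dam_id=rename(rec.dam_id),
            sire_id=rename(rec.sire_id),
        )
        for rec in ped
    )
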