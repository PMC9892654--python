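"""Exact two-level Boolean minimization by the Quine-McCluskey procedure.

A response group's observed binary expression patterns form the minterms of
a Boolean function over the panel's biomarkers; minimizing that function
yields the group's compact expression signatures.  Minimization here is
exact: prime implicants are generated by the tabular Quine-McCluskey
procedure; the coverage chart is then reduced by iterated essential-prime
extraction and row/column dominance, and any residual cyclic core is
resolved exactly by branch-and-bound set cover (the optimum Petrick's
method defines, computed without the exponential product expansion).  Among
minimum-cardinality covers the one with fewest specified literals is
chosen, with a final lexicographic tie-break, so the answer is
deterministic and unique.

Terms use the field's prime notation: ``A'`` means biomarker A low (0),
``A`` high (1), and an unspecified (don't-care) variable may be either.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property
from typing import Iterable, Sequence

#: Literal value marking an unspecified (don't-care) variable in a term.
DONT_CARE = None

_MAX_VARS = 20


@dataclass(frozen=True)
class BooleanTerm:
    """A product term: per-variable literal in {0, 1, DONT_CARE}.

    An all-don't-care term is the constant-1 function of its arity.
    """

    literals: tuple[int | None, ...]

    @property
    def n_vars(self) -> int:
        return len(self.literals)

    @cached_property
    def n_specified(self) -> int:
        return sum(1 for lit in self.literals if lit is not DONT_CARE)

    def sort_key(self) -> tuple[int, ...]:
        # 0 < 1 < don't-care per position; gives a stable total order
        return tuple(2 if lit is DONT_CARE else lit for lit in self.literals)

    def covers(self, assignment: Sequence[int]) -> bool:
        """True iff the term evaluates to 1 on a fully specified assignment."""
        if len(assignment) != self.n_vars:
            raise ValueError(
                f"assignment length {len(assignment)} != n_vars {self.n_vars}"
            )
        return all(
            lit is DONT_CARE or lit == bit
            for lit, bit in zip(self.literals, assignment)
        )

    def render(self, names: Sequence[str] | None = None, sep: str = "·") -> str:
        """Human-readable product, e.g. ``A'·C`` (prime = complemented/low)."""
        if names is None:
            names = [chr(ord("A") + i) for i in range(self.n_vars)]
        if len(names) != self.n_vars:
            raise ValueError("names length does not match n_vars")
        parts = [
            f"{name}{'′' if lit == 0 else ''}"
            for name, lit in zip(names, self.literals)
            if lit is not DONT_CARE
        ]
        return sep.join(parts) if parts else "1"


@dataclass(frozen=True)
class SopFunction:
    """A sum-of-products: OR over a set of product terms.

    The empty term set is the constant-0 function.
    """

    n_vars: int
    terms: frozenset[BooleanTerm]

    def __post_init__(self) -> None:
        for t in self.terms:
            if t.n_vars != self.n_vars:
                raise ValueError("term arity does not match n_vars")

    def evaluate(self, assignment: Sequence[int]) -> int:
        if len(assignment) != self.n_vars:
            raise ValueError(
                f"assignment length {len(assignment)} != n_vars {self.n_vars}"
            )
        return int(any(t.covers(assignment) for t in self.terms))

    def sorted_terms(self) -> list[BooleanTerm]:
        return sorted(self.terms, key=BooleanTerm.sort_key)

    def render(self, names: Sequence[str] | None = None) -> str:
        if not self.terms:
            return "0"
        return " + ".join(t.render(names) for t in self.sorted_terms())


def _to_int(bits: Sequence[int]) -> int:
    value = 0
    for i, b in enumerate(bits):
        if b not in (0, 1):
            raise ValueError(f"minterm bits must be 0/1, got {b!r}")
        value |= int(b) << i
    return value


def _term_from_pair(value: int, mask: int, n_vars: int) -> BooleanTerm:
    lits: list[int | None] = []
    for i in range(n_vars):
        if mask >> i & 1:
            lits.append(value >> i & 1)
        else:
            lits.append(DONT_CARE)
    return BooleanTerm(tuple(lits))


def prime_implicants(minterm_ints: set[int], n_vars: int) -> list[tuple[int, int]]:
    """Quine-McCluskey tabular pass: all prime implicants as (value, mask).

    ``mask`` has a 1-bit for each specified variable; two implicants merge
    when they share a mask and differ in exactly one specified bit.
    """
    current: set[tuple[int, int]] = {(m, (1 << n_vars) - 1) for m in minterm_ints}
    primes: set[tuple[int, int]] = set()
    while current:
        merged: set[tuple[int, int]] = set()
        used: set[tuple[int, int]] = set()
        by_mask: dict[int, list[tuple[int, int]]] = {}
        for t in current:
            by_mask.setdefault(t[1], []).append(t)
        for mask, terms in by_mask.items():
            by_count: dict[int, list[int]] = {}
            for value, _ in terms:
                by_count.setdefault(bin(value).count("1"), []).append(value)
            for c in sorted(by_count):
                for v1 in by_count[c]:
                    for v2 in by_count.get(c + 1, ()):
                        diff = v1 ^ v2
                        if diff & (diff - 1) == 0:  # single-bit difference
                            merged.add((v1 & ~diff, mask & ~diff))
                            used.add((v1, mask))
                            used.add((v2, mask))
        primes |= current - used
        current = merged
    return sorted(primes)


def _core_cover(
    chart: dict[int, frozenset[int]],
    cover_of: dict[int, frozenset[int]],
    cost_of: dict[int, tuple],
) -> frozenset[int]:
    """Exact minimum cover of a cyclic chart core by branch and bound.

    Minimizes the lexicographic cost (number of primes, total specified
    literals, term sort keys).  Branches on the row with fewest covering
    primes; prunes on a covering-capacity lower bound for the primary
    (cardinality) objective, so every minimum-cardinality cover is still
    reached and the secondary keys are optimized among them.
    """
    max_cover = max(len(c) for c in cover_of.values())
    best: dict = {"size": len(cover_of) + 1, "cost": None, "cover": None}

    def cost(chosen: frozenset[int]) -> tuple:
        lits = sum(cost_of[i][0] for i in chosen)
        lex = tuple(sorted(cost_of[i][1] for i in chosen))
        return (len(chosen), lits, lex)

    def search(uncovered: frozenset[int], chosen: frozenset[int]) -> None:
        if not uncovered:
            c = cost(chosen)
            if best["cost"] is None or c < best["cost"]:
                best["cost"] = c
                best["size"] = len(chosen)
                best["cover"] = chosen
            return
        bound = len(chosen) + -(-len(uncovered) // max_cover)
        if bound > best["size"]:
            return
        pivot = min(
            uncovered, key=lambda m: (len(chart[m]), m)
        )
        for i in sorted(chart[pivot], key=lambda i: (cost_of[i], i)):
            if i not in chosen:
                search(uncovered - cover_of[i], chosen | {i})

    search(frozenset(chart), frozenset())
    assert best["cover"] is not None
    return best["cover"]


def minimize(minterms: Iterable[Sequence[int]], n_vars: int) -> SopFunction:
    """Minimum SOP cover of a minterm set by the Quine-McCluskey procedure.

    The result is logically equivalent to the minterm set, consists only of
    prime implicants, and has the fewest terms; among equal-cardinality
    covers, the fewest total specified literals, then lexicographic order.
    An empty set gives constant 0; the full set gives constant 1.
    """
    if n_vars < 1 or n_vars > _MAX_VARS:
        raise ValueError(f"n_vars must lie in [1, {_MAX_VARS}], got {n_vars}")
    ints: set[int] = set()
    for mt in minterms:
        if len(mt) != n_vars:
            raise ValueError(f"minterm {tuple(mt)} has length != n_vars={n_vars}")
        v = _to_int(mt)
        if v in ints:
            raise ValueError(f"duplicate minterm {tuple(mt)}")
        ints.add(v)
    if not ints:
        return SopFunction(n_vars, frozenset())
    if len(ints) == 1 << n_vars:
        return SopFunction(n_vars, frozenset({BooleanTerm((DONT_CARE,) * n_vars)}))

    primes = prime_implicants(ints, n_vars)

    def covers_int(term: tuple[int, int], m: int) -> bool:
        value, mask = term
        return (m & mask) == value

    chart = {
        m: set(i for i, p in enumerate(primes) if covers_int(p, m))
        for m in ints
    }
    lit_count = [bin(p[1]).count("1") for p in primes]
    selected: set[int] = set()
    # iterate essential extraction with row/column dominance until the chart
    # stabilises; what survives is the cyclic core, solved exactly below
    changed = True
    while changed and chart:
        changed = False
        # essential primes: sole coverers of some remaining minterm
        essentials = {next(iter(opts)) for opts in chart.values() if len(opts) == 1}
        if essentials:
            selected |= essentials
            chart = {
                m: opts for m, opts in chart.items()
                if not any(covers_int(primes[e], m) for e in essentials)
            }
            changed = True
            continue
        # row dominance: a minterm whose options are a superset of another's
        # is covered automatically; drop the weaker constraint
        rows = sorted(chart, key=lambda m: len(chart[m]))
        dropped_rows: set[int] = set()
        for i, a in enumerate(rows):
            if a in dropped_rows:
                continue
            for b in rows[:i]:
                if b not in dropped_rows and chart[b] <= chart[a] and a != b:
                    dropped_rows.add(a)
                    break
        if dropped_rows:
            chart = {m: o for m, o in chart.items() if m not in dropped_rows}
            changed = True
        # column dominance: a prime whose remaining cover is contained in a
        # no-costlier prime's cover can be dropped without losing optimality
        active = sorted({i for opts in chart.values() for i in opts})
        col_cover = {
            i: frozenset(m for m in chart if i in chart[m]) for i in active
        }
        dropped_cols: set[int] = set()
        for q in active:
            if q in dropped_cols:
                continue
            for p in active:
                if p == q or p in dropped_cols:
                    continue
                if col_cover[q] < col_cover[p] and lit_count[p] <= lit_count[q]:
                    dropped_cols.add(q)
                    break
                if col_cover[q] == col_cover[p] and (
                    (lit_count[p], p) < (lit_count[q], q)
                ):
                    dropped_cols.add(q)
                    break
        if dropped_cols:
            chart = {m: opts - dropped_cols for m, opts in chart.items()}
            changed = True
    best = frozenset(selected)
    if chart:
        frozen = {m: frozenset(opts) for m, opts in chart.items()}
        active = sorted({i for opts in frozen.values() for i in opts})
        cover_of = {
            i: frozenset(m for m in frozen if i in frozen[m]) for i in active
        }
        cost_of = {
            i: (lit_count[i], _term_from_pair(*primes[i], n_vars).sort_key())
            for i in active
        }
        best |= _core_cover(frozen, cover_of, cost_of)
    terms = frozenset(_term_from_pair(*primes[i], n_vars) for i in best)
    return SopFunction(n_vars, terms)
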