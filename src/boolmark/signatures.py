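"""Binarization, truth tables, expression signatures and response prediction.

Phase 2 of the framework.  Biomarker abundances are discretized per feature:
under the ``median`` scheme each feature row is divided by its median across
samples and thresholded at 1 (high = 1, low = 0; a value exactly at the
median maps low by default).  Under the ``quantile_band`` scheme a value
below the low quantile (default 30%) is 0, above the high quantile (default
70%) is 1, and anything in between is INDETERMINATE — used when calling
response classes for new cohorts whose mid-range expression should not force
a bit either way.

The distinct bit-patterns observed within a response group form the minterms
of that group's Boolean function; Quine-McCluskey minimization collapses
them into a small set of product terms — the group's expression signatures.
A new sample is assigned every group with at least one matching signature;
matching uses consistent-with semantics, i.e. an INDETERMINATE sample bit
satisfies either literal value.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .data_io import CLASSES, ExpressionMatrix, ResponseLabels
from .minimize import DONT_CARE, BooleanTerm, minimize

#: Bit value for cells between the quantile cut-offs.
INDETERMINATE = -1

SCHEMA_VERSION = 1


@dataclass
class BinarizedMatrix:
    """Discretized biomarker table: bits in {0, 1, INDETERMINATE}."""

    feature_ids: list[str]
    sample_ids: list[str]
    bits: np.ndarray  # int8, features x samples
    scheme: str  # "median" or "quantile_band(low,high)"

    def sample_bits(self, sample_id: str) -> tuple[int, ...]:
        j = self.sample_ids.index(sample_id)
        return tuple(int(b) for b in self.bits[:, j])


@dataclass(frozen=True)
class Signature:
    id: int
    term: BooleanTerm
    coverage: float  # fraction of the group's samples satisfying the term


@dataclass
class SignatureSet:
    """Minimized expression signatures of one response group."""

    group: str
    signatures: list[Signature]
    feature_ids: list[str]

    def terms(self) -> list[BooleanTerm]:
        return [s.term for s in self.signatures]


def binarize(
    m: ExpressionMatrix,
    scheme: str = "median",
    low_q: float = 0.3,
    high_q: float = 0.7,
    tie_value: int = 0,
) -> BinarizedMatrix:
    """Discretize each feature row of an imputed matrix.

    ``median``: divide the row by its median (which must be positive) and
    threshold at 1; exact ties map to ``tie_value``.  ``quantile_band``:
    0 below the ``low_q`` quantile, 1 above the ``high_q`` quantile
    (linear-interpolation sample quantiles), INDETERMINATE between.
    """
    if m.missing_mask.any():
        raise ValueError("matrix contains missing values; impute first")
    bits = np.empty(m.values.shape, dtype=np.int8)
    if scheme == "median":
        for r, fid in enumerate(m.feature_ids):
            row = m.values[r]
            med = float(np.median(row))
            if med <= 0:
                raise ValueError(
                    f"feature {fid!r} has non-positive median {med}; "
                    "median binarization undefined"
                )
            norm = row / med
            bits[r] = np.where(norm > 1, 1, np.where(norm < 1, 0, tie_value))
        label = "median"
    elif scheme == "quantile_band":
        if not 0 <= low_q < high_q <= 1:
            raise ValueError("require 0 <= low_q < high_q <= 1")
        for r in range(m.n_features):
            row = m.values[r]
            lo = np.quantile(row, low_q)
            hi = np.quantile(row, high_q)
            bits[r] = np.where(
                row < lo, 0, np.where(row > hi, 1, INDETERMINATE)
            )
        label = f"quantile_band({low_q},{high_q})"
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    return BinarizedMatrix(
        feature_ids=list(m.feature_ids),
        sample_ids=list(m.sample_ids),
        bits=bits,
        scheme=label,
    )


def group_truth_table(
    b: BinarizedMatrix, labels: ResponseLabels, group: str
) -> tuple[set[tuple[int, ...]], dict[tuple[int, ...], float]]:
    """Distinct bit-patterns of a group's samples, with pattern frequencies.

    Patterns become the minterms of the group's Boolean function; bits must
    be fully determined (median-scheme discovery direction).  Frequencies
    are pattern sample-counts divided by the group size and sum to 1.
    """
    if group not in CLASSES:
        raise ValueError(f"unknown group {group!r}; expected one of {CLASSES}")
    aligned = labels.aligned_to(b.sample_ids)
    idx = aligned.group_indices()[group]
    if idx.size == 0:
        raise ValueError(f"group {group} has no samples")
    sub = b.bits[:, idx]
    if (sub == INDETERMINATE).any():
        raise ValueError(
            "INDETERMINATE bits in the discovery direction; "
            "use the median scheme for signature derivation"
        )
    counts: dict[tuple[int, ...], int] = {}
    for j in range(sub.shape[1]):
        pattern = tuple(int(x) for x in sub[:, j])
        counts[pattern] = counts.get(pattern, 0) + 1
    freq = {p: c / idx.size for p, c in counts.items()}
    return set(counts), freq


def match(sample_bits: Sequence[int], term: BooleanTerm) -> bool:
    """Consistent-with match of a (possibly indeterminate) sample to a term.

    Every specified literal must be satisfied; a DONT_CARE literal always
    is; an INDETERMINATE sample bit satisfies either literal value.
    """
    if len(sample_bits) != term.n_vars:
        raise ValueError(
            f"sample has {len(sample_bits)} bits, term expects {term.n_vars}"
        )
    for bit, lit in zip(sample_bits, term.literals):
        if lit is DONT_CARE or bit == INDETERMINATE:
            continue
        if bit != lit:
            return False
    return True


def derive_signatures(
    b: BinarizedMatrix, labels: ResponseLabels
) -> dict[str, SignatureSet]:
    """Minimize each group's observed patterns into expression signatures.

    Signature IDs are assigned in ascending term order; coverage is the
    fraction of the group's samples matching the term (a sample may count
    toward several signatures).  Jointly, a group's signatures cover every
    sample of that group.  A bit-pattern observed in more than one group is
    reported with a warning (the resulting signatures overlap).
    """
    aligned = labels.aligned_to(b.sample_ids)
    present = [c for c in CLASSES if aligned.counts()[c] > 0]
    tables = {g: group_truth_table(b, labels, g) for g in present}
    for g1, g2 in [(a, c) for i, a in enumerate(present) for c in present[i + 1:]]:
        shared = tables[g1][0] & tables[g2][0]
        if shared:
            warnings.warn(
                f"{len(shared)} bit-pattern(s) occur in both {g1} and {g2}; "
                "their signatures will overlap",
                stacklevel=2,
            )
    out: dict[str, SignatureSet] = {}
    n_vars = len(b.feature_ids)
    for g in present:
        minterms, _ = tables[g]
        sop = minimize(minterms, n_vars)
        idx = aligned.group_indices()[g]
        group_bits = [tuple(int(x) for x in b.bits[:, j]) for j in idx]
        sigs = []
        for i, term in enumerate(sop.sorted_terms(), start=1):
            cov = sum(match(bits, term) for bits in group_bits) / len(group_bits)
            sigs.append(Signature(id=i, term=term, coverage=cov))
        out[g] = SignatureSet(group=g, signatures=sigs,
                              feature_ids=list(b.feature_ids))
    return out


def predict_response(
    sample_bits: Sequence[int], signature_sets: dict[str, SignatureSet]
) -> tuple[set[str], list[tuple[str, int]]]:
    """All groups with at least one matching signature, plus the matches.

    A singleton set is an unambiguous call; an empty set is an explicit
    no-call; multi-group results are reported as-is.
    """
    groups: set[str] = set()
    matches: list[tuple[str, int]] = []
    for g, sset in signature_sets.items():
        for sig in sset.signatures:
            if match(sample_bits, sig.term):
                groups.add(g)
                matches.append((g, sig.id))
    return groups, matches


# ---------------------------------------------------------------------------
# serialization

def signatures_to_json(signature_sets: dict[str, SignatureSet]) -> str:
    any_set = next(iter(signature_sets.values()))
    payload = {
        "schema_version": SCHEMA_VERSION,
        "feature_ids": any_set.feature_ids,
        "groups": {
            g: [
                {
                    "id": s.id,
                    "literals": [
                        "-" if lit is DONT_CARE else int(lit)
                        for lit in s.term.literals
                    ],
                    "term": s.term.render(sset.feature_ids),
                    "coverage": s.coverage,
                }
                for s in sset.signatures
            ]
            for g, sset in signature_sets.items()
        },
    }
    return json.dumps(payload, indent=2, ensure_ascii=False)


def signatures_from_json(text: str) -> dict[str, SignatureSet]:
    payload = json.loads(text)
    if payload.get("schema_version") != SCHEMA_VERSION:
        raise ValueError("unsupported signature schema version")
    feature_ids = payload["feature_ids"]
    out = {}
    for g, sigs in payload["groups"].items():
        signatures = [
            Signature(
                id=s["id"],
                term=BooleanTerm(
                    tuple(
                        DONT_CARE if lit == "-" else int(lit)
                        for lit in s["literals"]
                    )
                ),
                coverage=s["coverage"],
            )
            for s in sigs
        ]
        out[g] = SignatureSet(group=g, signatures=signatures,
                              feature_ids=list(feature_ids))
    return out
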