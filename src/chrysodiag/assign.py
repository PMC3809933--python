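"""Distance-based species assignment and fixed-clock divergence dating.

Pairwise distances (p, JC69 or K80, with pairwise deletion of gap/ambiguous
columns) feed two consumers: a classical neighbour-joining tree emitted for
inspection, and a nearest-type-isolate assignment with cross-locus
concordance — a query is called a species only when every testable locus
agrees on it.

Node heights in expected substitutions/site convert to calendar years by a
strict molecular clock (default 3e-9 substitutions/site/yr, the standard
eurotiomycete rate): years = height / rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .io import SequenceRecord

__all__ = [
    "DistanceMatrix",
    "ClockParams",
    "LocusCall",
    "AssignmentResult",
    "pairwise_distance",
    "nj_tree",
    "assign_by_types",
    "node_height_to_years",
    "divergence_time_estimate",
]


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        finite = np.isfinite(v)
        if not np.allclose(
            np.where(finite, v, 0.0), np.where(finite.T, v.T, 0.0), atol=1e-12
        ):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.diagonal(v) != 0):
            raise ValueError("diagonal must be zero")
        if np.any(v[finite] < 0):
            raise ValueError("distances must be non-negative")
        self.values = v

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.labels.index(a), self.labels.index(b)])


@dataclass(frozen=True)
class ClockParams:
    subst_rate_per_site_per_year: float = 3e-9

    def __post_init__(self) -> None:
        if self.subst_rate_per_site_per_year <= 0:
            raise ValueError("clock rate must be > 0")


_PURINES = frozenset("AG")


def _site_arrays(a: str, b: str) -> tuple[np.ndarray, np.ndarray]:
    if len(a) != len(b):
        raise ValueError("sequences must be aligned to equal length")
    aa = np.frombuffer(a.encode(), dtype="S1")
    bb = np.frombuffer(b.encode(), dtype="S1")
    plain = np.frombuffer(b"ACGT", dtype="S1")
    keep = np.isin(aa, plain) & np.isin(bb, plain)  # pairwise deletion
    return aa[keep], bb[keep]


def _pair_distance(a: str, b: str, model: str) -> tuple[float, int]:
    aa, bb = _site_arrays(a, b)
    n = aa.size
    if n == 0:
        return math.nan, 0
    diff = aa != bb
    p = float(diff.mean())
    if model == "p":
        return p, n
    if model == "JC69":
        if p >= 0.75:
            return math.nan, n
        return -0.75 * math.log1p(-4.0 * p / 3.0), n
    if model == "K80":
        purine = np.isin(aa, np.frombuffer(b"AG", dtype="S1"))
        purine_b = np.isin(bb, np.frombuffer(b"AG", dtype="S1"))
        ts = float((diff & (purine == purine_b)).mean())  # transitions
        tv = float((diff & (purine != purine_b)).mean())
        w1 = 1.0 - 2.0 * ts - tv
        w2 = 1.0 - 2.0 * tv
        if w1 <= 0 or w2 <= 0:
            return math.nan, n
        return -0.5 * math.log(w1) - 0.25 * math.log(w2), n
    raise ValueError(f"unknown distance model {model!r}")


def pairwise_distance(
    records: Sequence[SequenceRecord], model: str = "JC69"
) -> DistanceMatrix:
    """All-pairs distances with pairwise deletion of gap/ambiguous columns.

    Saturated pairs (p >= 3/4 under JC69; non-positive logs under K80) get
    NaN — an undefined-distance marker, not an error.
    """
    labels = [r.id for r in records]
    n = len(records)
    vals = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d, _ = _pair_distance(records[i].residues, records[j].residues, model)
            vals[i, j] = vals[j, i] = d
    return DistanceMatrix(labels, vals)


# ---------------------------------------------------------------------------
# Neighbour joining


def nj_tree(matrix: DistanceMatrix) -> str:
    """Classical neighbour joining; returns an unrooted newick string.

    Agglomeration uses the standard Q-criterion; equal Q values break to the
    lexicographically lowest label pair (internal nodes rank by their
    smallest constituent leaf label), so output is deterministic.
    """
    n = len(matrix.labels)
    if n < 3:
        raise ValueError("need at least three taxa")
    if not np.all(np.isfinite(matrix.values)):
        raise ValueError("cannot build a tree from undefined distances")
    # active nodes: (sort_key, newick_fragment)
    nodes: list[tuple[str, str]] = [(lab, lab) for lab in matrix.labels]
    d = matrix.values.astype(float).copy()

    def fmt(x: float) -> str:
        return f"{x:.10g}"

    while len(nodes) > 3:
        m = len(nodes)
        totals = d.sum(axis=1)
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * d[i, j] - totals[i] - totals[j]
                pair_key = tuple(sorted((nodes[i][0], nodes[j][0])))
                cand = (q, pair_key, i, j)
                if best is None or cand[:2] < best[:2]:
                    best = cand
        _, _, i, j = best
        li = 0.5 * d[i, j] + (totals[i] - totals[j]) / (2 * (m - 2))
        lj = d[i, j] - li
        new_key = min(nodes[i][0], nodes[j][0])
        new_frag = (
            f"({nodes[i][1]}:{fmt(li)},{nodes[j][1]}:{fmt(lj)})"
        )
        new_row = 0.5 * (d[i] + d[j] - d[i, j])
        keep = [x for x in range(m) if x not in (i, j)]
        d2 = np.zeros((m - 1, m - 1))
        d2[:-1, :-1] = d[np.ix_(keep, keep)]
        d2[-1, :-1] = d2[:-1, -1] = new_row[keep]
        d = d2
        nodes = [nodes[x] for x in keep] + [(new_key, new_frag)]

    # resolve the final three nodes around a central vertex (closed form)
    (ka, fa), (kb, fb), (kc, fc) = nodes
    la = 0.5 * (d[0, 1] + d[0, 2] - d[1, 2])
    lb = 0.5 * (d[0, 1] + d[1, 2] - d[0, 2])
    lc = 0.5 * (d[0, 2] + d[1, 2] - d[0, 1])
    parts = sorted(
        [(ka, f"{fa}:{fmt(la)}"), (kb, f"{fb}:{fmt(lb)}"), (kc, f"{fc}:{fmt(lc)}")]
    )
    return "(" + ",".join(p for _, p in parts) + ");"


# ---------------------------------------------------------------------------
# Assignment


@dataclass(frozen=True)
class LocusCall:
    locus: str
    species: str | None  # None when untestable
    distance: float = math.nan
    margin: float = math.nan  # runner-up species distance minus best
    ambiguous: bool = False
    untestable: bool = False


@dataclass(frozen=True)
class AssignmentResult:
    query_id: str
    per_locus: tuple[LocusCall, ...]
    overall: str  # species | "discordant" | "untestable"


def assign_by_types(
    queries_by_locus: Mapping[str, Sequence[SequenceRecord]],
    types_by_locus: Mapping[str, Sequence[SequenceRecord]],
    type_species: Mapping[str, str],
    model: str = "JC69",
    min_overlap: int = 50,
) -> list[AssignmentResult]:
    """Assign queries to the species of their nearest type isolate, per locus,
    with a cross-locus concordance verdict.

    A locus is untestable for a query when fewer than ``min_overlap``
    comparable (pairwise-kept) sites remain against every type.  Equidistant
    nearest species break to the lexicographically first and are flagged
    ambiguous.  The overall call is a species only if all testable loci
    agree; "discordant" otherwise; "untestable" when no locus is testable.
    """
    for locus, types in types_by_locus.items():
        missing = [t.id for t in types if t.id not in type_species]
        if missing:
            raise ValueError(f"type isolates without species: {missing}")
    query_ids: dict[str, dict[str, SequenceRecord]] = {}
    for locus, qs in queries_by_locus.items():
        for q in qs:
            query_ids.setdefault(q.id, {})[locus] = q

    results = []
    for qid, per_locus_seq in query_ids.items():
        locus_calls: list[LocusCall] = []
        for locus, q in sorted(per_locus_seq.items()):
            types = list(types_by_locus.get(locus, ()))
            best_by_species: dict[str, float] = {}
            for t in types:
                dist, n_sites = _pair_distance(q.residues, t.residues, model)
                if n_sites < min_overlap or math.isnan(dist):
                    continue
                sp = type_species[t.id]
                if sp not in best_by_species or dist < best_by_species[sp]:
                    best_by_species[sp] = dist
            if not best_by_species:
                locus_calls.append(LocusCall(locus, None, untestable=True))
                continue
            ranked = sorted(best_by_species.items(), key=lambda kv: (kv[1], kv[0]))
            best_sp, best_d = ranked[0]
            if len(ranked) > 1:
                margin = ranked[1][1] - best_d
                ambiguous = ranked[1][1] == best_d
            else:
                margin, ambiguous = math.inf, False
            locus_calls.append(
                LocusCall(locus, best_sp, best_d, margin, ambiguous)
            )
        testable = [c.species for c in locus_calls if not c.untestable]
        if not testable:
            overall = "untestable"
        elif len(set(testable)) == 1:
            overall = testable[0]
        else:
            overall = "discordant"
        results.append(AssignmentResult(qid, tuple(locus_calls), overall))
    return results


# ---------------------------------------------------------------------------
# Clock conversion and divergence dating


def node_height_to_years(
    height_subs_per_site: float, clock: ClockParams = ClockParams()
) -> float:
    """Convert a node height (expected substitutions/site) to years under a
    strict clock: years = height / rate."""
    if height_subs_per_site < 0:
        raise ValueError("node height cannot be negative")
    return height_subs_per_site / clock.subst_rate_per_site_per_year


def divergence_time_estimate(
    alignment,
    species_a: str,
    species_b: str,
    clock: ClockParams = ClockParams(),
    model: str = "p",
    net: bool = True,
) -> tuple[float, float]:
    """Estimate the split time of two species as T = d / (2 * rate).

    Per locus, d is the mean between-species pairwise distance; with
    ``net`` (default) the mean within-species diversities are subtracted
    (net divergence d_a = d_xy - (d_x + d_y)/2) so that within-species
    polymorphism does not inflate the estimate.  Returns (T_hat, SE) where
    the Monte-Carlo standard error is taken across loci.
    """
    per_locus_T = []
    for locus in alignment.loci:
        ra = alignment.records_for_species(locus, species_a)
        rb = alignment.records_for_species(locus, species_b)
        if not ra or not rb:
            continue
        between = [
            _pair_distance(x.residues, y.residues, model)[0] for x in ra for y in rb
        ]
        d = float(np.nanmean(between))
        if net:
            for recs in (ra, rb):
                within = [
                    _pair_distance(x.residues, y.residues, model)[0]
                    for i, x in enumerate(recs)
                    for y in recs[i + 1 :]
                ]
                if within:
                    d -= 0.5 * float(np.nanmean(within))
        per_locus_T.append(d / (2.0 * clock.subst_rate_per_site_per_year))
    if not per_locus_T:
        raise ValueError("no locus with sequences for both species")
    t = np.asarray(per_locus_T)
    se = float(t.std(ddof=1) / math.sqrt(t.size)) if t.size > 1 else math.nan
    return float(t.mean()), se
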