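"""In-silico PCR: primer binding, amplicon prediction and species calls.

Binding follows the allele-specific PCR logic the assays are designed
around: a site qualifies only when the 3'-terminal clamp (last ``clamp``
bases of the primer) matches perfectly, and at most ``max_total_mismatches``
mismatches occur overall.  Forward primers are scanned against the plus
strand, reverse primers against the minus strand; both are given 5'->3'.

IUPAC ambiguity codes in the template count as a match whenever the primer
base is among the code's set (optimistic for sensitivity); such positions
are tallied in ``BindingSite.ambiguous_matches`` so callers can flag them.

Species calls enforce the no-overlap contract of a clean species-specific
panel: exactly one positive assay names the species, no positives is
"other", and anything else is a "conflict".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import IUPAC_CODES, PrimerTableRow
from .primers import reverse_complement

__all__ = [
    "Tolerance",
    "BindingSite",
    "AmpliconResult",
    "SpeciesCall",
    "find_binding_sites",
    "amplify",
    "classify_isolates",
]

_MASK = {b: sum(1 << "ACGT".index(x) for x in bases) for b, bases in IUPAC_CODES.items()}
_MASK["-"] = 0


@dataclass(frozen=True)
class Tolerance:
    """Mismatch tolerance: at most ``max_total_mismatches`` over the whole
    primer, and none at all within the 3'-terminal ``clamp`` bases."""

    max_total_mismatches: int = 2
    clamp: int = 3


@dataclass(frozen=True)
class BindingSite:
    template_id: str
    strand: str  # "+" (forward primer) or "-" (reverse primer)
    interval: tuple[int, int]  # 0-based half-open on the plus strand
    total_mismatches: int
    three_prime_mismatches: int
    ambiguous_matches: int = 0


@dataclass(frozen=True)
class AmpliconResult:
    set_name: str
    template_id: str
    start: int
    end: int
    forward_site: BindingSite
    reverse_site: BindingSite

    @property
    def length(self) -> int:
        """5' end to 5' end, inclusive of both primers."""
        return self.end - self.start


@dataclass(frozen=True)
class SpeciesCall:
    isolate_id: str
    positives: frozenset[str]
    call: str  # species name | "other" | "conflict"
    untested: frozenset[str] = frozenset()


def _encode(seq: str) -> np.ndarray:
    try:
        return np.array([_MASK[c] for c in seq], dtype=np.uint8)
    except KeyError as e:  # pragma: no cover - templates are validated on ingest
        raise ValueError(f"unexpected template character {e.args[0]!r}") from None


def find_binding_sites(
    template: str,
    primer: str,
    strand: str,
    tolerance: Tolerance = Tolerance(),
    template_id: str = "",
) -> list[BindingSite]:
    """All qualifying binding sites of a 5'->3' primer on an ungapped template.

    A primer longer than the template yields an empty list.
    """
    if strand not in ("forward", "reverse"):
        raise ValueError(f"bad strand {strand!r}")
    if set(primer) - set("ACGT"):
        raise ValueError("primer must be pure A/C/G/T")
    Lp, Lt = len(primer), len(template)
    if Lp > Lt or Lp == 0:
        return []
    # orient the primer along the plus strand
    plus_primer = primer if strand == "forward" else reverse_complement(primer)
    tmask = _encode(template)
    pmask = _encode(plus_primer)
    pexact = np.array([1 << "ACGT".index(c) for c in plus_primer], dtype=np.uint8)
    # clamp positions, expressed along the plus-strand orientation
    k = min(tolerance.clamp, Lp)
    clamp_idx = np.arange(Lp - k, Lp) if strand == "forward" else np.arange(k)
    out: list[BindingSite] = []
    strides = np.lib.stride_tricks.sliding_window_view(tmask, Lp)
    match = (strides & pmask) != 0
    ambiguous = match & ((strides & ~pexact) != 0)
    mismatches = (~match).sum(axis=1)
    clamp_ok = match[:, clamp_idx].all(axis=1)
    hits = np.nonzero((mismatches <= tolerance.max_total_mismatches) & clamp_ok)[0]
    for i in hits:
        out.append(
            BindingSite(
                template_id=template_id,
                strand="+" if strand == "forward" else "-",
                interval=(int(i), int(i) + Lp),
                total_mismatches=int(mismatches[i]),
                three_prime_mismatches=0,
                ambiguous_matches=int(ambiguous[i].sum()),
            )
        )
    return out


def amplify(
    template: str,
    primer_set: PrimerTableRow,
    tolerance: Tolerance = Tolerance(),
    length_bounds: tuple[int, int] = (50, 2000),
    template_id: str = "",
) -> list[AmpliconResult]:
    """Predicted amplicons of a primer pair on one template.

    Every forward-site/reverse-site combination with the forward 5' end
    upstream of the reverse 5' end and product length within
    ``length_bounds`` yields an amplicon; length is measured 5' end to
    5' end inclusive of both primers.
    """
    fsites = find_binding_sites(
        template, primer_set.forward_5to3, "forward", tolerance, template_id
    )
    rsites = find_binding_sites(
        template, primer_set.reverse_5to3, "reverse", tolerance, template_id
    )
    lo, hi = length_bounds
    out: list[AmpliconResult] = []
    for f in fsites:
        for r in rsites:
            if f.interval[0] >= r.interval[1] - 1:
                continue
            length = r.interval[1] - f.interval[0]
            if lo <= length <= hi:
                out.append(
                    AmpliconResult(
                        set_name=primer_set.set_name,
                        template_id=template_id,
                        start=f.interval[0],
                        end=r.interval[1],
                        forward_site=f,
                        reverse_site=r,
                    )
                )
    return out


def classify_isolates(
    panel: Sequence,
    primer_sets: Sequence[PrimerTableRow],
    tolerance: Tolerance = Tolerance(),
    length_bounds: tuple[int, int] = (50, 2000),
) -> tuple[list[SpeciesCall], pd.DataFrame | None]:
    """Run every assay on every isolate and call species.

    ``panel`` items need ``isolate_id`` and ``sequences`` (locus -> DNA)
    attributes; ``true_species`` when present feeds the assay x true-species
    positive-rate matrix returned alongside the calls.  An isolate missing
    an assay's locus is recorded as untested for it, never positive.
    """
    target_of = {ps.set_name: ps.target_species for ps in primer_sets}
    calls: list[SpeciesCall] = []
    truth_known = all(getattr(p, "true_species", None) is not None for p in panel)
    pos_counts: dict[tuple[str, str], int] = {}
    n_by_species: dict[str, int] = {}
    for iso in panel:
        positives: set[str] = set()
        untested: set[str] = set()
        for ps in primer_sets:
            seq = iso.sequences.get(ps.locus)
            if seq is None:
                untested.add(ps.set_name)
                continue
            if amplify(seq, ps, tolerance, length_bounds, template_id=iso.isolate_id):
                positives.add(ps.set_name)
        if len(positives) == 1:
            call = target_of[next(iter(positives))]
        elif not positives:
            call = "other"
        else:
            call = "conflict"
        calls.append(
            SpeciesCall(
                isolate_id=iso.isolate_id,
                positives=frozenset(positives),
                call=call,
                untested=frozenset(untested),
            )
        )
        if truth_known:
            sp = iso.true_species
            n_by_species[sp] = n_by_species.get(sp, 0) + 1
            for name in positives:
                pos_counts[(name, sp)] = pos_counts.get((name, sp), 0) + 1
    matrix = None
    if truth_known and panel:
        species = sorted(n_by_species)
        matrix = pd.DataFrame(
            [
                [pos_counts.get((ps.set_name, sp), 0) / n_by_species[sp] for sp in species]
                for ps in primer_sets
            ],
            index=[ps.set_name for ps in primer_sets],
            columns=species,
        )
    return calls, matrix
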