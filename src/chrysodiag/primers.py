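"""Species-specific primer enumeration, scoring and pair selection.

The design rule mirrors allele-specific PCR: a primer's 3'-terminal base sits
on a diagnostic site, so polymerase extension only proceeds on the target
species' allele.  Candidate primers are enumerated at every feasible length
ending on a diagnostic column, then paired under the amplicon-length window
(100-200 bp by default, the range the published assays occupy) and ranked by
a weighted score.

Only one primer of a pair must be anchored on a diagnostic site; the
companion primer is a plain locus-specific oligo.  Anchoring both is a score
bonus, not a constraint — some loci simply do not carry two diagnostic
columns within amplicon range.

Melting temperatures come either from the Wallace 2+4 rule or from
nearest-neighbour thermodynamics (Allawi & SantaLucia parameters via
Biopython) at the salt/primer concentrations recorded in
``NN_CONDITIONS``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from Bio.SeqUtils import MeltingTemp as _mt

from .io import PrimerTableRow, SequenceRecord
from .sites import DiagnosticSite

__all__ = [
    "Primer",
    "PrimerPairCandidate",
    "PrimerConstraints",
    "ScoringWeights",
    "NN_CONDITIONS",
    "gc_content",
    "melting_temperature",
    "reverse_complement",
    "consensus_sequence",
    "enumerate_candidates",
    "pair_and_select",
    "design_primer_sets",
]

log = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: Conditions used by the nearest-neighbour Tm model (Allawi & SantaLucia
#: stacking table; SantaLucia 1998 salt correction on the entropy).
NN_CONDITIONS = {
    "Na_mM": 50.0,
    "dnac1_nM": 250.0,
    "dnac2_nM": 0.0,
    "saltcorr": 5,
}


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def gc_content(sequence: str) -> float:
    """(#G + #C) / length of a pure A/C/G/T sequence."""
    if not sequence:
        raise ValueError("empty sequence")
    bad = set(sequence) - set("ACGT")
    if bad:
        raise ValueError(f"ambiguous base(s) {sorted(bad)} in primer sequence")
    return (sequence.count("G") + sequence.count("C")) / len(sequence)


def melting_temperature(sequence: str, method: str = "wallace") -> float:
    """Primer melting temperature in Celsius.

    ``wallace``: 2(A+T) + 4(G+C).  ``nn``: nearest-neighbour thermodynamics
    under :data:`NN_CONDITIONS`; requires length >= 8.
    """
    gc_content(sequence)  # alphabet check
    if method == "wallace":
        at = sequence.count("A") + sequence.count("T")
        gc = sequence.count("G") + sequence.count("C")
        return float(2 * at + 4 * gc)
    if method == "nn":
        if len(sequence) < 8:
            raise ValueError("nearest-neighbour Tm needs length >= 8")
        return float(
            _mt.Tm_NN(
                sequence,
                nn_table=_mt.DNA_NN3,
                Na=NN_CONDITIONS["Na_mM"],
                dnac1=NN_CONDITIONS["dnac1_nM"],
                dnac2=NN_CONDITIONS["dnac2_nM"],
                saltcorr=NN_CONDITIONS["saltcorr"],
            )
        )
    raise ValueError(f"unknown Tm method {method!r}")


@dataclass(frozen=True)
class Primer:
    """An oligo with its anchor interval on the locus reference (0-based,
    half-open, plus-strand coordinates)."""

    sequence_5to3: str
    strand: str  # "forward" | "reverse"
    template_anchor: tuple[int, int]
    locus: str
    tm_celsius: float
    gc_fraction: float
    anchored_site: DiagnosticSite | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("forward", "reverse"):
            raise ValueError(f"bad strand {self.strand!r}")
        start, end = self.template_anchor
        if end - start != len(self.sequence_5to3):
            raise ValueError("anchor interval length must equal primer length")
        if self.anchored_site is not None:
            col = self.anchored_site.column
            if self.strand == "forward":
                ok = end - 1 == col and self.sequence_5to3[-1] == self.anchored_site.target_allele
            else:
                ok = start == col and self.sequence_5to3[-1] == reverse_complement(
                    self.anchored_site.target_allele
                )
            if not ok:
                raise ValueError("3'-terminal base does not sit on the anchored site")

    def __len__(self) -> int:
        return len(self.sequence_5to3)


@dataclass(frozen=True)
class PrimerPairCandidate:
    forward: Primer
    reverse: Primer
    amplicon_length: int
    target_species: str
    score: float

    def to_table_row(self, set_name: str, cycles: int = 35) -> PrimerTableRow:
        return PrimerTableRow(
            set_name=set_name,
            target_species=self.target_species,
            forward_5to3=self.forward.sequence_5to3,
            reverse_5to3=self.reverse.sequence_5to3,
            amplicon_length=self.amplicon_length,
            cycles=cycles,
        )


@dataclass(frozen=True)
class PrimerConstraints:
    """Length, Tm and amplicon windows.  Length defaults span the range the
    published assay primers occupy (17-29 nt)."""

    min_len: int = 17
    max_len: int = 29
    tm_min: float | None = None
    tm_max: float | None = None
    tm_method: str = "wallace"
    amplicon_min: int = 100
    amplicon_max: int = 200


@dataclass(frozen=True)
class ScoringWeights:
    tm_balance: float = 1.0
    gc_mid: float = 1.0
    both_anchored: float = 0.5
    dimer_penalty: float = 0.5


def consensus_sequence(records: Sequence[SequenceRecord]) -> str:
    """Majority base per column; ties broken to the alphabetically first
    base; gap/ambiguity characters are ignored where a plain base exists."""
    if not records:
        raise ValueError("no records for consensus")
    L = len(records[0])
    cols = []
    for i in range(L):
        counts: dict[str, int] = {}
        for r in records:
            ch = r.residues[i]
            if ch in "ACGT":
                counts[ch] = counts.get(ch, 0) + 1
        if not counts:
            cols.append("N")
            continue
        best = max(sorted(counts), key=lambda b: counts[b])
        cols.append(best)
    return "".join(cols)


def _make_primer(seq, strand, anchor, locus, site, constraints) -> Primer | None:
    if set(seq) - set("ACGT"):
        return None
    tm = melting_temperature(seq, constraints.tm_method)
    if constraints.tm_min is not None and tm < constraints.tm_min:
        return None
    if constraints.tm_max is not None and tm > constraints.tm_max:
        return None
    return Primer(
        sequence_5to3=seq,
        strand=strand,
        template_anchor=anchor,
        locus=locus,
        tm_celsius=tm,
        gc_fraction=gc_content(seq),
        anchored_site=site,
    )


def enumerate_candidates(
    consensus: str,
    locus: str,
    sites: Iterable[DiagnosticSite],
    constraints: PrimerConstraints = PrimerConstraints(),
) -> list[Primer]:
    """All primers whose 3'-terminal base sits on a diagnostic site.

    Forward primers read the plus strand ending at the site column; reverse
    primers read the minus strand, likewise ending on the site.  Sites too
    close to a sequence edge for any feasible length are skipped with a log
    entry.
    """
    out: list[Primer] = []
    L = len(consensus)
    for site in sites:
        if site.locus != locus:
            raise ValueError(
                f"site at {site.locus}:{site.column} does not belong to locus {locus!r}"
            )
        col = site.column
        made = 0
        template = consensus[:col] + site.target_allele + consensus[col + 1 :]
        for n in range(constraints.min_len, constraints.max_len + 1):
            if col - n + 1 >= 0:
                p = _make_primer(
                    template[col - n + 1 : col + 1],
                    "forward",
                    (col - n + 1, col + 1),
                    locus,
                    site,
                    constraints,
                )
                if p:
                    out.append(p)
                    made += 1
            if col + n <= L:
                p = _make_primer(
                    reverse_complement(template[col : col + n]),
                    "reverse",
                    (col, col + n),
                    locus,
                    site,
                    constraints,
                )
                if p:
                    out.append(p)
                    made += 1
        if made == 0:
            log.info(
                "no feasible primer for site %s:%d (%s): too close to an edge "
                "or outside the Tm window",
                locus,
                col,
                site.target_species,
            )
    out.sort(key=lambda p: (p.locus, p.template_anchor, p.strand))
    return out


def _three_prime_dimer_run(a: str, b: str) -> int:
    """Longest suffix of ``a`` that is reverse-complementary to a window of
    ``b`` — a cheap 3'-dimer propensity measure."""
    target = reverse_complement(b)
    for k in range(min(len(a), len(b)), 0, -1):
        if a[-k:] in target:
            return k
    return 0


def _pair_score(f: Primer, r: Primer, weights: ScoringWeights) -> float:
    s = 0.0
    s -= weights.tm_balance * abs(f.tm_celsius - r.tm_celsius) / 10.0
    s -= weights.gc_mid * (abs(f.gc_fraction - 0.5) + abs(r.gc_fraction - 0.5))
    if f.anchored_site is not None and r.anchored_site is not None:
        s += weights.both_anchored
    dimer = max(
        _three_prime_dimer_run(f.sequence_5to3, r.sequence_5to3),
        _three_prime_dimer_run(r.sequence_5to3, r.sequence_5to3),
        _three_prime_dimer_run(f.sequence_5to3, f.sequence_5to3),
    )
    s -= weights.dimer_penalty * dimer / 10.0
    return s


@dataclass(frozen=True)
class PairSelection:
    pair: PrimerPairCandidate | None
    reason: str = ""


def _companions(consensus, locus, strand, lo, hi, constraints) -> list[Primer]:
    """Unanchored companion primers whose 5' end lies in [lo, hi)."""
    out = []
    L = len(consensus)
    for five in range(max(0, lo), min(hi, L)):
        for n in range(constraints.min_len, constraints.max_len + 1):
            if strand == "forward":
                start, end = five, five + n
                if end > L:
                    continue
                seq = consensus[start:end]
            else:
                start, end = five - n + 1, five + 1
                if start < 0:
                    continue
                seq = reverse_complement(consensus[start:end])
            p = _make_primer(seq, strand, (start, end), locus, None, constraints)
            if p:
                out.append(p)
    return out


def pair_and_select(
    candidates: Sequence[Primer],
    consensus_by_locus: Mapping[str, str] | None = None,
    constraints: PrimerConstraints = PrimerConstraints(),
    weights: ScoringWeights = ScoringWeights(),
    target_species: str | None = None,
) -> PairSelection:
    """Select the best primer pair for one species from anchored candidates.

    Amplicon length is measured 5' end to 5' end, inclusive of both primers
    (``reverse.anchor.end - forward.anchor.start``).  When a consensus is
    supplied, unanchored companion primers are enumerated so that a single
    anchored primer suffices.  Ties break deterministically: higher score,
    then shorter amplicon, then lexicographic forward and reverse sequence.
    """
    cands = list(candidates)
    if target_species is None:
        species = {c.anchored_site.target_species for c in cands if c.anchored_site}
        if len(species) > 1:
            raise ValueError("candidates span multiple target species")
        target_species = next(iter(species)) if species else "unknown"
    if not cands:
        return PairSelection(None, "no anchored candidates")

    best: tuple | None = None
    by_locus: dict[str, list[Primer]] = {}
    for c in cands:
        by_locus.setdefault(c.locus, []).append(c)

    def consider(f: Primer, r: Primer) -> None:
        nonlocal best
        amp = r.template_anchor[1] - f.template_anchor[0]
        if not (constraints.amplicon_min <= amp <= constraints.amplicon_max):
            return
        if f.template_anchor[0] >= r.template_anchor[1] - 1:
            return
        score = _pair_score(f, r, weights)
        key = (-score, amp, f.sequence_5to3, r.sequence_5to3)
        if best is None or key < best[0]:
            best = (key, PrimerPairCandidate(f, r, amp, target_species, score))

    for locus, group in by_locus.items():
        fwd = [c for c in group if c.strand == "forward"]
        rev = [c for c in group if c.strand == "reverse"]
        for f in fwd:
            for r in rev:
                consider(f, r)
        cons = (consensus_by_locus or {}).get(locus)
        if cons is not None:
            # companions are enumerated once per locus and filtered by the
            # 5'-end window each anchored primer implies
            comp_rev = _companions(cons, locus, "reverse", 0, len(cons), constraints)
            comp_fwd = _companions(cons, locus, "forward", 0, len(cons), constraints)
            for f in fwd:
                lo = f.template_anchor[0] + constraints.amplicon_min - 1
                hi = f.template_anchor[0] + constraints.amplicon_max
                for r in comp_rev:
                    if lo <= r.template_anchor[1] - 1 < hi:
                        consider(f, r)
            for r in rev:
                lo = r.template_anchor[1] - constraints.amplicon_max
                hi = r.template_anchor[1] - constraints.amplicon_min
                for f in comp_fwd:
                    if lo <= f.template_anchor[0] <= hi:
                        consider(f, r)
    if best is None:
        return PairSelection(
            None,
            f"no pair within amplicon window [{constraints.amplicon_min}, "
            f"{constraints.amplicon_max}]",
        )
    return PairSelection(best[1])


def design_primer_sets(
    alignment,
    catalog: Mapping[str, list[DiagnosticSite]],
    constraints: PrimerConstraints = PrimerConstraints(),
    weights: ScoringWeights = ScoringWeights(),
    cycles: int = 35,
) -> tuple[list[PrimerTableRow], dict[str, PairSelection]]:
    """Design one assay per species from a diagnostic-site catalog.

    The design template is the target-species consensus per locus.  Returns
    assay-table rows for every species with a feasible pair plus the full
    per-species selection report.
    """
    rows: list[PrimerTableRow] = []
    report: dict[str, PairSelection] = {}
    for sp in sorted(catalog):
        sites = catalog[sp]
        if not sites:
            report[sp] = PairSelection(None, "no diagnostic sites")
            continue
        loci = sorted({s.locus for s in sites})
        consensus_by_locus = {
            locus: consensus_sequence(alignment.records_for_species(locus, sp))
            for locus in loci
        }
        cands: list[Primer] = []
        for locus in loci:
            cands.extend(
                enumerate_candidates(
                    consensus_by_locus[locus],
                    locus,
                    [s for s in sites if s.locus == locus],
                    constraints,
                )
            )
        sel = pair_and_select(
            cands, consensus_by_locus, constraints, weights, target_species=sp
        )
        report[sp] = sel
        if sel.pair is not None:
            set_name = f"{sel.pair.forward.locus}_{sp.capitalize()}"
            rows.append(sel.pair.to_table_row(set_name, cycles=cycles))
    return rows, report
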