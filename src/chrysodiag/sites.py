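"""Discovery of species-diagnostic alignment columns.

A column is diagnostic for a target species when every target sequence
carries the same unambiguous base and that base appears in no non-target
sequence — the property that lets an allele-specific primer anchored there
detect exactly one species of a cryptic complex.

Fixation within the target species is required: a column polymorphic in the
target cannot anchor a reliable assay.  Specificity is preferred over
sensitivity throughout: a non-target IUPAC ambiguity code whose expansion
contains the target allele disqualifies the column.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import IUPAC_CODES, MultiLocusAlignment

__all__ = ["DiagnosticSite", "ScanOptions", "find_diagnostic_sites", "diagnostic_catalog"]

_ACGT = frozenset("ACGT")


@dataclass(frozen=True)
class DiagnosticSite:
    """An alignment column fixed for ``target_allele`` in the target species
    and absent from all counted non-target sequences."""

    locus: str
    column: int  # 0-based
    target_species: str
    target_allele: str
    other_alleles: frozenset[str]
    n_target: int
    n_other: int
    low_support: bool = False

    def __post_init__(self) -> None:
        if self.target_allele in self.other_alleles:
            raise ValueError("target allele cannot also be a non-target allele")


@dataclass(frozen=True)
class ScanOptions:
    """Options for the column scan.

    allow_missing
        When False (default) a column containing any gap or ambiguity code in
        a counted sequence is skipped.  When True those sequences are ignored
        at that column, provided at least ``min_target_depth`` target and one
        non-target sequence remain — except that a non-target ambiguity code
        compatible with the target allele still disqualifies the column.
    min_target_depth
        Below this many target sequences a site is flagged ``low_support``,
        not rejected (per-species samples can be small).
    outgroup_species / include_outgroups
        Sequences of species named in ``outgroup_species`` are excluded from
        the scan unless ``include_outgroups`` is set; the published design
        procedure only contrasted the four in-complex species.
    """

    allow_missing: bool = False
    min_target_depth: int = 2
    outgroup_species: frozenset[str] = frozenset()
    include_outgroups: bool = False


def _seq_matrix(records) -> np.ndarray:
    return np.frombuffer(
        "".join(r.residues for r in records).encode(), dtype="S1"
    ).reshape(len(records), -1)


def find_diagnostic_sites(
    alignment: MultiLocusAlignment,
    target_species: str,
    options: ScanOptions = ScanOptions(),
) -> list[DiagnosticSite]:
    """Scan every locus for columns diagnostic of ``target_species``.

    Returns sites sorted by (locus, column).
    """
    if target_species not in set(alignment.partition.values()):
        raise ValueError(f"unknown target species {target_species!r}")
    excluded = set() if options.include_outgroups else set(options.outgroup_species)
    sites: list[DiagnosticSite] = []
    for locus in alignment.loci:
        target_recs = alignment.records_for_species(locus, target_species)
        other_recs = [
            r
            for r in alignment.records[locus]
            if alignment.partition.get(r.id) not in (None, target_species)
            and alignment.partition[r.id] not in excluded
        ]
        if not target_recs or not other_recs:
            continue
        tmat = _seq_matrix(target_recs)
        omat = _seq_matrix(other_recs)
        sites.extend(
            _scan_locus(locus, target_species, tmat, omat, options)
        )
    sites.sort(key=lambda s: (s.locus, s.column))
    return sites


def _scan_locus(locus, target_species, tmat, omat, options) -> list[DiagnosticSite]:
    acgt = np.frombuffer(b"ACGT", dtype="S1")
    t_plain = np.isin(tmat, acgt)
    o_plain = np.isin(omat, acgt)
    out: list[DiagnosticSite] = []
    for col in range(tmat.shape[1]):
        tcol, ocol = tmat[:, col], omat[:, col]
        tok, ook = t_plain[:, col], o_plain[:, col]
        if not options.allow_missing:
            if not (tok.all() and ook.all()):
                continue
        else:
            if int(tok.sum()) < options.min_target_depth or not ook.any():
                continue
        t_bases = set(tcol[tok].tobytes().decode())
        if len(t_bases) != 1:
            continue
        allele = next(iter(t_bases))
        o_bases = set(ocol[ook].tobytes().decode())
        if allele in o_bases:
            continue
        if options.allow_missing:
            # ambiguity codes in non-target sequences: compatible -> disqualify
            codes = set(ocol[~ook].tobytes().decode()) - {"-"}
            if any(allele in IUPAC_CODES[c] for c in codes):
                continue
        n_target = int(tok.sum())
        out.append(
            DiagnosticSite(
                locus=locus,
                column=col,
                target_species=target_species,
                target_allele=allele,
                other_alleles=frozenset(o_bases),
                n_target=n_target,
                n_other=int(ook.sum()),
                low_support=n_target < options.min_target_depth,
            )
        )
    return out


def diagnostic_catalog(
    alignment: MultiLocusAlignment,
    species: list[str] | None = None,
    options: ScanOptions = ScanOptions(),
) -> dict[str, list[DiagnosticSite]]:
    """Per-species diagnostic sites; the union of per-species scans."""
    if species is None:
        excluded = set() if options.include_outgroups else set(options.outgroup_species)
        species = [s for s in alignment.species if s not in excluded]
    return {sp: find_diagnostic_sites(alignment, sp, options) for sp in species}


def catalog_to_rows(catalog: dict[str, list[DiagnosticSite]]) -> list[dict]:
    """Flatten a catalog for TSV export."""
    rows = []
    for sp in sorted(catalog):
        for s in catalog[sp]:
            rows.append(
                {
                    "locus": s.locus,
                    "column": s.column,
                    "species": sp,
                    "allele": s.target_allele,
                    "other_alleles": "".join(sorted(s.other_alleles)),
                    "n_target": s.n_target,
                    "n_other": s.n_other,
                    "low_support": s.low_support,
                }
            )
    return rows
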