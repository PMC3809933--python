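"""Synthetic data with the statistical structure of the Chrysogenum complex.

Generates (a) multilocus alignments for a four-species cryptic complex that
diverged ~0.75 Myr ago under a fixed molecular clock of 3e-9
substitutions/site/yr, with distant outgroup species splitting ~2.75 Myr ago
and low within-species polymorphism, and (b) location-structured isolate
panels with multinomial species proportions and ~1:1 mating types — the two
kinds of input every downstream stage of the pipeline consumes.

Sequences evolve by a Jukes-Cantor process along a fixed species tree whose
branch lengths are years x rate.  Within-species variation is added as
independent private mutations per isolate (expected pairwise diversity
``within_species_polymorphism``), not a coalescent: the goal is testable
structure, not demographic realism.  All randomness flows from a single
integer-seeded numpy generator, so output is byte-identical across runs and
platforms for a fixed config.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import MultiLocusAlignment, SequenceRecord

__all__ = [
    "ComplexSimConfig",
    "PanelSimConfig",
    "PanelIsolate",
    "simulate_locus_alignments",
    "simulate_isolate_panel",
    "panel_to_dataframe",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")

#: Default node ages in years: complex radiation ~0.75 Myr ago, the two
#: within-complex clades ~0.47/0.45 Myr, outgroup split ~2.75 Myr.
DEFAULT_HEIGHTS = {
    "outgroup_split": 2.75e6,
    "complex_root": 7.5e5,
    "clade_0": 4.7e5,
    "clade_1": 4.5e5,
}


@dataclass
class ComplexSimConfig:
    """Configuration of the synthetic species complex.

    ``clades`` fixes the within-complex topology
    ``((rubens,floreyi),(chrysogenum,chainii))`` by default; the branching
    order of the real complex is not resolved with confidence, so it is
    configurable rather than hard-coded.  Species not covered by ``clades``
    hang directly from the complex root (star fallback).
    """

    species_names: tuple[str, ...] = ("chrysogenum", "rubens", "chainii", "floreyi")
    outgroup_names: tuple[str, ...] = ("flavigenum",)
    clades: tuple[tuple[str, str], ...] = (
        ("rubens", "floreyi"),
        ("chrysogenum", "chainii"),
    )
    tree_heights_years: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_HEIGHTS)
    )
    subst_rate_per_site_per_year: float = 3e-9
    locus_lengths: dict[str, int] = field(
        default_factory=lambda: {"benA": 480, "trpC": 520, "crt1": 560, "ITS": 440}
    )
    n_isolates_per_species: int = 10
    within_species_polymorphism: float = 1e-3
    seed: int = 0

    def validate(self) -> None:
        h = self.tree_heights_years
        root = h.get("complex_root", 0.0)
        if root <= 0:
            raise ValueError("complex_root height must be positive")
        if self.outgroup_names and h.get("outgroup_split", 0.0) <= root:
            raise ValueError("outgroup_split must exceed complex_root")
        for i in range(len(self.clades)):
            ch = h.get(f"clade_{i}", root / 2)
            if not (0 < ch < root):
                raise ValueError(f"clade_{i} height must lie in (0, complex_root)")
        if self.subst_rate_per_site_per_year <= 0:
            raise ValueError("substitution rate must be > 0")
        for locus, L in self.locus_lengths.items():
            if L < 50:
                raise ValueError(f"locus {locus!r}: length {L} < 50")
        if self.within_species_polymorphism < 0:
            raise ValueError("within-species polymorphism must be >= 0")
        covered = [s for pair in self.clades for s in pair]
        if len(covered) != len(set(covered)):
            raise ValueError("a species appears in more than one clade")


@dataclass
class PanelSimConfig:
    """Location-structured isolate panel: multinomial species proportions per
    location and Bernoulli mating types."""

    locations: tuple[str, ...]
    n_isolates: dict[str, int]
    species_proportions: dict[str, dict[str, float]]
    mating_ratio: float = 0.5
    seed: int = 0
    #: species backing the "other" category; None = every species the
    #: proportions never name (set this to the outgroup names when the panel
    #: should emulate non-complex Penicillium)
    other_species: tuple[str, ...] | None = None

    def validate(self) -> None:
        for loc in self.locations:
            if self.n_isolates.get(loc, 0) < 0:
                raise ValueError(f"negative isolate count at {loc!r}")
            props = self.species_proportions[loc]
            total = sum(props.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"proportions at {loc!r} sum to {total}, not 1")
            if any(p < 0 for p in props.values()):
                raise ValueError(f"negative proportion at {loc!r}")
        if not (0.0 < self.mating_ratio < 1.0):
            raise ValueError("mating_ratio must lie in (0, 1)")


@dataclass(frozen=True)
class PanelIsolate:
    isolate_id: str
    location: str
    true_species: str  # "other" for outgroup-derived isolates
    source_id: str  # isolate in the complex alignment the sequences came from
    sequences: Mapping[str, str]  # locus -> ungapped DNA
    mating_type: str  # "MAT1-1" or "MAT1-2"


def _jc_evolve(seq_idx: np.ndarray, d_subs_per_site: float, rng: np.random.Generator) -> np.ndarray:
    """Evolve a base-index array along a branch of expected length ``d``
    substitutions/site under Jukes-Cantor."""
    if d_subs_per_site <= 0:
        return seq_idx.copy()
    p_change = 0.75 * (1.0 - np.exp(-4.0 * d_subs_per_site / 3.0))
    out = seq_idx.copy()
    hit = rng.random(out.size) < p_change
    n = int(hit.sum())
    if n:
        # uniform choice among the three other bases
        out[hit] = (out[hit] + rng.integers(1, 4, size=n)) % 4
    return out


def _species_paths(config: ComplexSimConfig) -> dict[str, list[tuple[str, float]]]:
    """Per-species path from the grand root to the tip, as a list of
    (child-node name, branch duration in years)."""
    h = config.tree_heights_years
    root = h["complex_root"]
    grand = h.get("outgroup_split", root) if config.outgroup_names else root
    clade_of = {s: i for i, pair in enumerate(config.clades) for s in pair}
    paths: dict[str, list[tuple[str, float]]] = {}
    stem = [("complex_root", grand - root)] if grand > root else []
    for sp in config.species_names:
        if sp in clade_of:
            i = clade_of[sp]
            ch = h.get(f"clade_{i}", root / 2)
            paths[sp] = stem + [(f"clade_{i}", root - ch), (f"tip_{sp}", ch)]
        else:
            paths[sp] = stem + [(f"tip_{sp}", root)]
    for og in config.outgroup_names:
        paths[og] = [(f"tip_{og}", grand)]
    return paths


def simulate_locus_alignments(
    config: ComplexSimConfig,
) -> tuple[MultiLocusAlignment, dict[str, str]]:
    """Simulate ungapped per-locus alignments for the complex plus outgroups.

    Returns the alignment and the truth partition (isolate id -> species).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    rate = config.subst_rate_per_site_per_year
    paths = _species_paths(config)
    all_species = list(config.species_names) + list(config.outgroup_names)
    d_private = config.within_species_polymorphism / 2.0

    records: dict[str, list[SequenceRecord]] = {}
    partition: dict[str, str] = {}
    for locus, L in config.locus_lengths.items():
        root_seq = rng.integers(0, 4, size=L)
        # share ancestral segments: evolve along the path per species, caching
        # prefix nodes so sister species share their clade ancestor
        cache: dict[tuple[str, ...], np.ndarray] = {(): root_seq}
        recs: list[SequenceRecord] = []
        for sp in all_species:
            prefix: tuple[str, ...] = ()
            seq = root_seq
            for node, dur in paths[sp]:
                nxt = prefix + (node,)
                if nxt not in cache:
                    cache[nxt] = _jc_evolve(cache[prefix], dur * rate, rng)
                seq = cache[nxt]
                prefix = nxt
            for k in range(config.n_isolates_per_species):
                iso = f"{sp}_{k:02d}"
                iso_seq = _jc_evolve(seq, d_private, rng)
                recs.append(
                    SequenceRecord(
                        id=iso,
                        residues=_BASES[iso_seq].tobytes().decode(),
                        locus=locus,
                        species_label=sp,
                    )
                )
                partition[iso] = sp
        records[locus] = recs
    mla = MultiLocusAlignment(list(config.locus_lengths), records, dict(partition))
    return mla, partition


def simulate_isolate_panel(
    config: PanelSimConfig, complex_alignment: MultiLocusAlignment
) -> list[PanelIsolate]:
    """Draw a location-structured panel from the simulated complex.

    Species counts per location are multinomial; ``"other"`` draws from
    outgroup-species isolates; mating types are Bernoulli(mating_ratio) coded
    MAT1-1 with probability ``mating_ratio``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    partition = complex_alignment.partition
    by_species: dict[str, list[str]] = {}
    for iso, sp in partition.items():
        by_species.setdefault(sp, []).append(iso)
    for pool in by_species.values():
        pool.sort()
    seq_of: dict[str, dict[str, str]] = {}
    for locus in complex_alignment.loci:
        for rec in complex_alignment.records[locus]:
            seq_of.setdefault(rec.id, {})[locus] = rec.ungapped()

    complex_species = set()
    for loc in config.locations:
        complex_species |= set(config.species_proportions[loc])
    complex_species.discard("other")
    unknown = complex_species - set(by_species)
    if unknown:
        raise ValueError(f"proportions reference unknown species: {sorted(unknown)}")
    if config.other_species is not None:
        missing = set(config.other_species) - set(by_species)
        if missing:
            raise ValueError(f"other_species not in alignment: {sorted(missing)}")
        other_pool = sorted(
            iso for iso, sp in partition.items() if sp in config.other_species
        )
    else:
        other_pool = sorted(
            iso for iso, sp in partition.items() if sp not in complex_species
        )

    panel: list[PanelIsolate] = []
    for loc in config.locations:
        n = config.n_isolates.get(loc, 0)
        if n == 0:
            continue
        cats = sorted(config.species_proportions[loc])
        probs = np.array([config.species_proportions[loc][c] for c in cats])
        counts = rng.multinomial(n, probs)
        assignments = [c for c, k in zip(cats, counts) for _ in range(int(k))]
        rng.shuffle(assignments)  # interleave species within the location
        for k, cat in enumerate(assignments):
            pool = other_pool if cat == "other" else by_species[cat]
            if not pool:
                raise ValueError(f"no source isolates available for {cat!r}")
            src = pool[int(rng.integers(len(pool)))]
            mating = "MAT1-1" if rng.random() < config.mating_ratio else "MAT1-2"
            panel.append(
                PanelIsolate(
                    isolate_id=f"{loc}_{k:03d}",
                    location=loc,
                    true_species=cat,
                    source_id=src,
                    sequences=dict(seq_of[src]),
                    mating_type=mating,
                )
            )
    return panel


def panel_to_dataframe(panel: Sequence[PanelIsolate]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "isolate_id": [p.isolate_id for p in panel],
            "location": [p.location for p in panel],
            "true_species": [p.true_species for p in panel],
            "source_id": [p.source_id for p in panel],
            "mating_type": [p.mating_type for p in panel],
        }
    )
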