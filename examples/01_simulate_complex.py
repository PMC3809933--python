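"""Simulate a four-species cryptic complex and look at its divergence.

Builds the default synthetic Chrysogenum-like complex (four species split
~0.75 Myr ago plus a distant outgroup, four loci, clock 3e-9
substitutions/site/yr, low within-species polymorphism) and reports how far
apart the species ended up.
"""

import numpy as np

from chrysodiag import ComplexSimConfig, simulate_locus_alignments

cfg = ComplexSimConfig(n_isolates_per_species=5, seed=1)
mla, truth = simulate_locus_alignments(cfg)

print(f"loci: {mla.loci}")
print(f"isolates: {len(mla.isolate_ids())} across species {mla.species}")


def mean_p(sp1, sp2):
    ds = []
    for locus in mla.loci:
        for a in mla.records_for_species(locus, sp1):
            for b in mla.records_for_species(locus, sp2):
                ds.append(sum(x != y for x, y in zip(a.residues, b.residues)) / len(a))
    return float(np.mean(ds))


print(f"\nmean p-distance rubens vs chrysogenum:  {mean_p('rubens', 'chrysogenum'):.4f}")
print(f"mean p-distance rubens vs floreyi:      {mean_p('rubens', 'floreyi'):.4f}")
print(f"mean p-distance rubens vs flavigenum:   {mean_p('rubens', 'flavigenum'):.4f}")
print(
    "\nThe cross-complex distance sits near 2 x rate x 0.75 Myr = 0.0045 "
    "substitutions/site,\nsister species are closer, and the outgroup is "
    "several-fold farther — the structure\nevery downstream stage assumes."
)
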