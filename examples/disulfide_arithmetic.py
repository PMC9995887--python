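"""Cysteine census and disulfide-bridge capacity for the two families.

Counts domain cysteines on the zero-mutation templates and maps the
published conserved positions onto the canonical bridge template.
"""

from pa2c import (
    GeneratorConfig,
    compute_profile,
    make_protein,
    max_bridge_count,
    retained_bridges,
)

cfg = GeneratorConfig(mutation_rate=0.0)
for clade in ("alpha", "pla2like"):
    profile = compute_profile(make_protein(clade, cfg))
    n = profile.n_cys_domain
    print(f"{clade:<9} domain cysteines: {n:>2}  ->  max bridges: {max_bridge_count(n)}")

retained = retained_bridges({140, 166, 167, 192})
print(f"\nconserved positions {{140, 166, 167, 192}} retain: "
      + ", ".join(f"C{a}-C{b}" for a, b in retained))
print(
    "\nCanonical sPLA2: 12 cysteines / 6 bridges.  PLA2-like: 6 cysteines, "
    "at most 3 bridges, of which only the two bridges anchoring helix 1 to "
    "the calcium loop and helix 2 are conserved."
)
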