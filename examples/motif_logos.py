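"""Information-content logos of the calcium-binding and catalytic motifs.

Extracts the calcium-loop matches from a synthetic canonical family and
prints per-column information content in bits: anchored literal columns
approach log2(20) ~ 4.32 bits, wildcard columns carry much less.
"""

from pa2c import GeneratorConfig, logo_from_block, make_family, scan

family = make_family(GeneratorConfig(seed=3))
canonical = [r for r in family.records if r.true_clade in ("alpha", "beta")]
blocks = [
    m.matched
    for record in canonical
    for m in scan(record)
    if m.pattern == "CA_CANON"
]
logo = logo_from_block(blocks)

print(f"calcium-loop block: {len(blocks)} sequences x {len(logo.information)} columns")
print("pos  consensus  IC(bits)")
for j, ic in enumerate(logo.information, start=1):
    top = logo.frequencies.iloc[j - 1].idxmax()
    print(f"{j:>3}  {top:^9}  {ic:6.3f}")
print(
    "\nColumns fixed by the motif (Y,G,K,Y,C,G,...,G,C) sit near the "
    "4.32-bit maximum; the four wildcard positions drift with mutation."
)
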