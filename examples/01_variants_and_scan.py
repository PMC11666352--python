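"""Parse variant names, apply them to the Taq reference, size up the scan.

Run:  python examples/01_variants_and_scan.py
"""

from taqdesign import (ScanSpec, TAQ_COMBINATORIAL_SITES, apply_variant,
                       count_scan, parse_variant, taq_reference)

ref = taq_reference()
print(f"Reference: {ref.id}, {len(ref)} residues")

v = parse_variant("E507Q-D578S-I614M", ref)
mutated = apply_variant(ref, v)
print(f"{v.name}: {len(v)} substitutions; residue 507 {ref.residue_at(507)} -> "
      f"{mutated.residue_at(507)}")

# the constrained in-silico scan: all singles, doubles/triples at 21 sites
counts = count_scan(ref, ScanSpec(TAQ_COMBINATORIAL_SITES, 3))
print(f"Scan size: {counts['singles']:,} singles + {counts['doubles']:,} doubles "
      f"+ {counts['triples']:,} triples = {counts['total']:,} variants")
# ~9.2 million candidate enzymes screened without ever materializing the list
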