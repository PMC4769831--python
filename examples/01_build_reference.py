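"""Build a targeted RRBS reference from a genome.

Digests a synthetic genome at CCGG, size-selects fragments, models end
repair and adapter ligation on both strands, and writes the converted
(three-letter) reference plus its coordinate metadata.
"""

from pathlib import Path

import tracerrbs as t

genome = t.synthetic_genome(200_000, seed=1)
bundle = t.build_reference([genome], s_min=40, s_max=250)
paths = t.write_reference(bundle, Path("scratch_example_reference"))

frag = bundle.fragments[0]
top = bundle.by_entry_id[f"{frag.fragment_id}:top"]
print(f"genome: {genome.name}, {genome.length:,} bp")
print(f"fragments in 40-250 bp window: {len(bundle.fragments):,}")
print(f"alignable entries (2 per fragment): {len(bundle.entries):,}")
print(f"first fragment: {frag.fragment_id} ({frag.length} bp)")
print(f"  repaired top strand: {top.repaired_seq[:20]}...{top.repaired_seq[-5:]}")
print(f"  fill-in C at entry index {top.artificial_c_index} -> genomic "
      f"position {top.genomic_position(top.artificial_c_index)}")
print(f"wrote {paths['fasta']} and {paths['metadata']}")
# The fill-in cytosine lands on the downstream CCGG's CpG: a real genomic
# CpG that receives non-biological, always-unmethylated evidence unless
# excluded during calling.
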