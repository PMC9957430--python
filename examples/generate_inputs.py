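"""Write the complete synthetic input suite to disk.

Produces LAD BEDs per timepoint, histone-mark peak BEDs, lamin and TSS
bedGraphs, mark count tracks, a gene table, a connections TSV, FISH
coordinate tables, and truth.json with every generating parameter.
Regeneration from the same seed is bit-identical.
"""

import sys

import ladscape as L

outdir = sys.argv[1] if len(sys.argv) > 1 else "synthetic_inputs"
ds = L.generate(seed=1, outdir=outdir)
paths = sorted(p.name for p in __import__("pathlib").Path(outdir).glob("*"))
print(f"wrote {len(paths)} files to {outdir}/:")
for name in paths:
    print(" ", name)
print("truth.json holds the generating parameters (rates, fractions, effect sizes)")
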