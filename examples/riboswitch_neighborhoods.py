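"""Cobalamin riboswitch filtering and genomic context assignment.

Filters covariance-model hits at the 1e-6 E-value cutoff, then maps two
riboswitch loci onto a miniature genome annotation and reports the flanking
genes and the functional category of each locus.
"""

import pandas as pd

from cobashare.io_formats import RiboswitchHit
from cobashare.riboswitch_context import (
    GeneFeature, assign_context, filter_riboswitch_hits, riboswitch_counts,
)

hits = [
    RiboswitchHit("read1", "Cobalamin", 1e-9, "+"),
    RiboswitchHit("read2", "Cobalamin", 1e-8, "-"),
    RiboswitchHit("read3", "AdoCbl_riboswitch", 1e-7, "+"),
    RiboswitchHit("read4", "Cobalamin", 1e-4, "+"),   # fails the cutoff
]
kept = filter_riboswitch_hits(hits)
print(f"hits kept at E <= 1e-6: {len(kept)} of {len(hits)}")
print("raw per-model counts (not length-normalized):",
      riboswitch_counts(kept))

genes = [
    GeneFeature("genome1", "cobN", 1200, 2600, "+", "cobaltochelatase CobN"),
    GeneFeature("genome1", "btuF", 5200, 6100, "-", "vitamin B12 ABC "
                "transporter substrate-binding protein"),
    GeneFeature("genome1", "hyp1", 9000, 9400, "-", None),
]
loci = pd.DataFrame({
    "seqid": ["genome1", "genome1"],
    "start": [900, 6500], "end": [1050, 6650],
    "strand": ["+", "-"], "name": ["rs1", "rs2"],
})
function_map = {"cobN": "cobamide_biosynthesis", "btuF": "abc_transport"}

for ctx in assign_context(loci, genes, window_bp=5000,
                          function_map=function_map):
    down = [(g.gene_id, g.distance) for g in ctx.downstream_genes]
    print(f"\nriboswitch {ctx.start}-{ctx.end} ({ctx.strand}): "
          f"category {ctx.functional_category}")
    print(f"  downstream (on riboswitch strand): {down}")
# Each locus is labeled by its nearest same-strand downstream gene — the gene
# a 5'-UTR riboswitch most plausibly regulates.
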