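"""Build an ELI-D1-style candidate set.

Intersects a toy selection of high-ELI genes with three decidualization
pathway sets and annotates the result with decidualization fold changes.
"""

import pandas as pd

from invascope import genesets
from invascope.genesets import GeneSet, GeneSetCollection

eli_genes = GeneSet("ELI", ("ADCY7", "CREB1", "EP300", "F2R", "PPARA", "TGFB1", "MYC"))
pathways = GeneSetCollection([
    GeneSet("CAMP_PKA_SIGNALING", ("ADCY7", "CREB1", "EP300", "PRKAR1A")),
    GeneSet("PROGESTERONE_SIGNALING", ("PPARA", "NCOA2", "PGR")),
    GeneSet("PROSTAGLANDIN_BIOSYNTHESIS", ("F2R", "PTGS2")),
])

eli_d1, overlap = genesets.build_eli_d1(eli_genes, pathways)
print("ELI-D1 members:", ", ".join(eli_d1.members))
print("\nper-pathway overlap (a gene counts once per pathway it belongs to):")
print(overlap.to_string(index=False))

fc = pd.DataFrame({
    "gene": ["ADCY7", "CREB1", "EP300", "F2R", "PPARA"],
    "log2fc": [-1.4, -0.9, -1.1, -0.7, -1.8],
    "p_adj": [1e-4, 2e-3, 5e-4, 0.01, 1e-5],
})
ann = genesets.annotate_decidual_fc(eli_d1, fc)
print("\nannotated with decidualization fold changes (negative = down in dESFs):")
print(ann.to_string(index=False))
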