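"""Project contig read depth onto a reference through alignment blocks.

A contig whose reads map at 60x aligns to two reference regions; its depth
is split equally (30x each). A second contig's block that is fully
contained in the first one (length rate 0.5 < 0.8) is removed by the block
filter before projection, while its short distal block survives.
"""

import numpy as np

import copyvar as cv
from copyvar.depth import bin_depth

contigs = {
    "ctg1": bin_depth(np.full(1000, 60.0), bin_size=250, chrom="ctg1"),
    "ctg2": bin_depth(np.full(500, 20.0), bin_size=250, chrom="ctg2"),
}
blocks = [
    cv.AlignmentBlock("ctg1", 0, 1000, "chr1", 0, 1000),      # region 1
    cv.AlignmentBlock("ctg1", 0, 1000, "chr1", 2000, 3000),   # region 2
    cv.AlignmentBlock("ctg2", 0, 500, "chr1", 0, 500),        # overlaps region 1
    cv.AlignmentBlock("ctg2", 0, 100, "chr1", 5000, 5100),    # tiny redundant block
]

kept = cv.filter_alignment_blocks(blocks)
print(f"{len(kept)}/{len(blocks)} alignment blocks survive filtering")

ref = cv.project_contig_depth(contigs, kept, {"chr1": 6000}, bin_size=250)
track = cv.compute_cn_index(ref["chr1"])
print("reference bin depths:", np.round(track.depths, 1).tolist())
print("CN_index:            ", np.round(track.cn_index, 2).tolist())
# ctg1's 60x is split across its two reference regions (bins 0-3 and 8-11
# get 30x each); ctg2's contained block was filtered out, so only its
# 100 bp distal block contributes (100 x 20 / 250 = 8x in bin 20);
# uncovered bins stay at depth 0.
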