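import numpy as np
import pytest

from peakrep.genome import build_partition
from peakrep.intervals import GenomicInterval


@pytest.fixture
def toy_partition():
    """1000-bp chromosome: exon [0,200), intron [100,400), intergenic rest.

    With priority exon > intron the resolved occupancy is exon 200,
    intron 200, intergenic 600.
    """
    return build_partition(
        {
            "exon": [GenomicInterval("chr1", 0, 200)],
            "intron": [GenomicInterval("chr1", 100, 400)],
        },
        priority=("exon", "intron"),
        genome_sizes={"chr1": 1000},
    )


def paint_genome(class_sets, priority, genome_sizes):
    """Per-base brute-force oracle for the priority partition.

    Returns chrom -> array of class labels (intergenic where unclaimed).
    """
    painted = {}
    for chrom, length in genome_sizes.items():
        arr = np.full(length, "intergenic", dtype=object)
        claimed = np.zeros(length, dtype=bool)
        for cls_label in priority:
            for iv in class_sets.get(cls_label, []):
                if iv.chrom != chrom:
                    continue
                take = ~claimed[iv.start : iv.end]
                idx = np.arange(iv.start, iv.end)[take]
                arr[idx] = cls_label
                claimed[idx] = True
        painted[chrom] = arr
    return painted
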