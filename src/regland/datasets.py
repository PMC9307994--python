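"""Small bundled fixtures.

``toy_pcre_fixture`` loads a hand-derived six-interval classification
example: two TSS points (10,000 and 50,000), one exon (30,000-31,000)
and six candidate intervals. By the 2 kb TSS rule the expected
partition is two promoters (edge distances 0 and 1,100 bp), three
enhancers (distances 3,500 / 9,500 / 20,000 bp) and one interval
discarded for exon overlap.
"""

from __future__ import annotations

from importlib import resources

from .cre import GeneModel
from .genome import GenomeAssembly, GenomicInterval
from .io import read_bed, read_chrom_sizes

__all__ = ["toy_pcre_fixture"]


def toy_pcre_fixture() -> tuple[
    GenomeAssembly, list[GenomicInterval], GeneModel
]:
    """Load the bundled toy classification fixture.

    Returns the toy assembly, the six merged candidate intervals, and
    the gene model (TSS points plus the single exon).
    """
    root = resources.files("regland") / "data" / "pcre_toy"
    with resources.as_file(root) as path:
        assembly = read_chrom_sizes(path / "toy.chrom.sizes", "toy")
        merged = read_bed(path / "merged.bed", assembly)
        tss = read_bed(path / "tss.bed", assembly)
        exons = read_bed(path / "exons.bed", assembly)
    return assembly, merged, GeneModel.from_beds(tss, exons)
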