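"""Synthetic reconstruction of the barley HvSAP16 promoter genotyping target.

The validated reference assay for this toolkit genotypes an A/T SNP in the
promoter of the barley (*Hordeum vulgare*) stress-associated-protein gene
HvSAP16 with an 83-bp amplicon: two tagged allele-specific primers designed
on the reverse-complement strand with the SNP at the penultimate 3' position,
and an untagged common reverse primer reading the given strand.

The genomic fragment itself is not redistributed here; this module carries a
SYNTHETIC stand-in template assembled to be exactly consistent with the
published assay: it embeds the real common-primer site, the real
reverse-complement allele-primer site around the [A/T] SNP, and the real
83-bp amplicon geometry, while the spacer and outer flanks are synthetic
filler. Running the designer on this target must reproduce the published
oligo set exactly; the unit tests assert that.
"""

from __future__ import annotations

from .aspdesign import SnpTarget

__all__ = [
    "HVSAP16_F1",
    "HVSAP16_F2",
    "HVSAP16_R",
    "HVSAP16_F1_GENE_PART",
    "HVSAP16_F2_GENE_PART",
    "HVSAP16_AMPLICON_BP",
    "hvsap16_target",
]

# published oligos (tag lower case, barcode upper, gene part upper)
HVSAP16_F1 = "ccagctgaacggtTCGACCAGACGATGTTGGACAAGCTTCTC"
HVSAP16_F2 = "ccagctgaacggtACCTGCAGACGATGTTGGACAAGCTTCAC"
HVSAP16_R = "GCACATTTGTACTGAGGATGGTAG"
HVSAP16_F1_GENE_PART = HVSAP16_F1[19:]
HVSAP16_F2_GENE_PART = HVSAP16_F2[19:]
HVSAP16_AMPLICON_BP = 83

# given-strand image of the allele-primer site: reverse complement of the
# allele-1 gene part, with the SNP base at index 1 of the block
_ASP_BLOCK_ALLELE1 = "GAGAAGCTTGTCCAACATCGTCT"

# synthetic filler (AT-rich so it offers no competing primer sites; the
# homopolymer run upstream of the SNP block reflects that the given-strand
# 3' context of this site is unsuitable for a forward design, forcing the
# reverse-complement design the published assay uses)
_UPSTREAM_FLANK = "TTGACTATTGACATTCATGAAAAA"
_SPACER = "TTTTT" + "TGATCTAGTTCAATGCTTATCAGATT" + "AAAAA"
_DOWNSTREAM_FLANK = (
    "TAGTTAGATTCAATGTTAGCATTGATTAGTTCAATG"
    "TTAGATTCATTGACTTAGTTCAATGATT"
)


def hvsap16_synthetic_template() -> str:
    """The synthetic given-strand template with allele 1 ('A') written in."""
    spacer = _SPACER
    assert len(spacer) == HVSAP16_AMPLICON_BP - len(HVSAP16_R) - len(_ASP_BLOCK_ALLELE1)
    return _UPSTREAM_FLANK + HVSAP16_R + spacer + _ASP_BLOCK_ALLELE1 + _DOWNSTREAM_FLANK


def hvsap16_target() -> SnpTarget:
    """The synthetic HvSAP16 A/T design target (alleles read on the given strand)."""
    template = hvsap16_synthetic_template()
    snp_position = len(_UPSTREAM_FLANK) + len(HVSAP16_R) + len(_SPACER) + 1
    return SnpTarget(template=template, snp_position=snp_position, alleles=("A", "T"))
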