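"""Allele-specific primer design: reference reproduction and self-consistency.

The revalidation helpers here deliberately share no code with the designer:
they re-derive every constraint (amplicon bounds, Tm windows, per-position
primer identity, concentration ratios) from the raw design output.
"""

from __future__ import annotations

import numpy as np
import pytest

from asq.aspdesign import (
    AssayDesign,
    DesignParams,
    NoReversePrimerError,
    SnpTarget,
    assemble_assay,
    candidate_placements,
    design_allele_primers,
    design_reverse_primer,
    discrimination_score,
)
from asq.assaykit import export_assay
from asq.thermo import NO_MG_BUFFER, Oligo, melting_temperature
from asq.universal import build_universal_set, reverse_complement
from .conftest import F1, F2, R, make_random_target


def revalidate(design: AssayDesign, params: DesignParams | None = None) -> None:
    """Independent re-check of a finished design against its own contract."""
    params = params or DesignParams()
    lo, hi = params.amplicon_window
    assert lo <= design.amplicon_length <= hi

    gene_parts = [p.gene_part for p in design.allele_primers]
    assert len({len(g) for g in gene_parts}) == 1
    diffs = [
        i for i in range(len(gene_parts[0]))
        if len({g[i] for g in gene_parts}) > 1
    ]
    offset = design.allele_primers[0].snp_offset
    assert diffs == [len(gene_parts[0]) - offset]

    # every primer's gene part must anneal on its strand of the template
    template = design.target.template
    for primer in design.allele_primers:
        strand_seq = template if primer.strand == "+" else reverse_complement(template)
        expected_allele = primer.allele if primer.strand == "+" else reverse_complement(primer.allele)
        assert primer.gene_part[len(primer.gene_part) - offset] == expected_allele
        probe = primer.gene_part[: len(primer.gene_part) - offset] + "." + primer.gene_part[len(primer.gene_part) - offset + 1 :]
        import re

        assert re.search(probe, strand_seq), "gene part does not anneal on its strand"

    # reverse primer: anneals opposite the allele primers, Tm matched
    rev = design.reverse_primer
    span_seq = template[rev.span[0] : rev.span[1]]
    if design.allele_primers[0].strand == "-":
        assert rev.sequence == span_seq
    else:
        assert rev.sequence == reverse_complement(span_seq)
    fwd_tms = [
        melting_temperature(Oligo(g, params.asp_concentration), params.buffer)
        for g in gene_parts
    ]
    rev_tm = melting_temperature(Oligo(rev.sequence, rev.concentration), params.buffer)
    assert abs(rev_tm - float(np.mean(fwd_tms))) <= params.reverse_tm_tolerance + 1e-9

    # stoichiometry: the common primer outnumbers each allele primer >= 3x
    for primer in design.allele_primers:
        assert rev.concentration / primer.concentration >= 3

    # barcodes pair one-to-one with probes
    probe_barcodes = [p.barcode for p in design.universal_set.probes]
    for i, primer in enumerate(design.allele_primers):
        assert primer.barcode == probe_barcodes[i]

    for score in design.discrimination.values():
        assert score > 0


class TestSnpTarget:
    def test_bracket_notation(self):
        notation = "T" * 70 + "[A/G]" + "C" * 70
        target = SnpTarget.from_bracket(notation)
        assert target.snp_position == 70
        assert target.alleles == ("A", "G")
        assert target.template[70] == "A"

    def test_iupac_code_defines_alleles(self):
        template = "ACGT" * 20 + "W" + "TGCA" * 20
        target = SnpTarget(template=template, snp_position=80, alleles=None)
        assert target.alleles == ("A", "T")

    def test_insufficient_flank(self):
        with pytest.raises(ValueError, match="flank"):
            SnpTarget(template="ACGTACGTAC", snp_position=5, alleles=("A", "T"))

    def test_duplicate_alleles(self):
        with pytest.raises(ValueError, match="distinct"):
            SnpTarget(template="ACGT" * 40, snp_position=80, alleles=("A", "A"))


class TestReferenceAssay:
    def test_top_placement_is_reverse_strand_penultimate(self, hvsap16):
        top = candidate_placements(hvsap16)[0]
        assert top.strand == "-"
        assert top.snp_offset == 2
        assert top.gene_parts["A"].endswith("CTTCTC")
        assert top.gene_parts["T"].endswith("CTTCAC")

    def test_allele_primers_match_published(self, hvsap16, universal_set):
        placement = candidate_placements(hvsap16)[0]
        primers = design_allele_primers(hvsap16, placement, universal_set)
        assert [p.full_sequence for p in primers] == [F1, F2]

    def test_reverse_primer_and_amplicon_match_published(self, hvsap16, universal_set):
        placement = candidate_placements(hvsap16)[0]
        rev = design_reverse_primer(hvsap16, placement, universal_set)
        assert rev.sequence == R
        design = assemble_assay(hvsap16, universal_set)
        assert design.amplicon_length == 83

    def test_end_to_end_design_revalidates(self, hvsap16):
        revalidate(assemble_assay(hvsap16))

    def test_design_is_deterministic(self, hvsap16):
        a = export_assay(assemble_assay(hvsap16), "json")
        b = export_assay(assemble_assay(hvsap16), "json")
        assert a == b


class TestPlacementRules:
    def test_homopolymer_context_demotes_placements(self):
        # a 5-A run just 5' of the SNP sits inside every given-strand gene
        # part, so the clean reverse-strand placements must all outrank the
        # given-strand ones regardless of offset preference
        left = "GCATCGGATCTACGGTCAGCTAGCATGCGATCAGGCTAGGATCCTAGCGATCAGGCTTACGAAAAA"
        right = "CTGATCGGACTACGGATCAGCTTGACCTAGGATCGATCCGGATTCAGGCATGCATCCGGATTACGG"
        template = left + "G" + right
        target = SnpTarget(template=template, snp_position=len(left), alleles=("G", "C"))
        placements = candidate_placements(target)
        flags = [p.clean for p in placements]
        assert flags == sorted(flags, reverse=True)  # clean placements first
        assert placements[0].strand == "-"
        assert any(not p.clean for p in placements if p.strand == "+")

    def test_capacity_error(self, universal_set):
        template = "ACGT" * 40
        target = SnpTarget(template=template, snp_position=80, alleles=("A", "T", "G"))
        placement = candidate_placements(target)[0]
        with pytest.raises(ValueError, match="probes"):
            design_allele_primers(target, placement, universal_set)

    def test_flank_too_short_for_amplicon(self, universal_set):
        # SNP 10 nt from one end: no room for a 50 bp amplicon on that side
        rng = np.random.default_rng(11)
        bases = "".join(np.random.default_rng(5).choice(list("ACGT"), size=80))
        template = bases + "A" + "GCGC"
        target = SnpTarget(template=template, snp_position=80, alleles=("A", "T"))
        placements = [p for p in candidate_placements(target) if p.strand == "+"]
        assert placements, "need a given-strand placement for this test"
        with pytest.raises(NoReversePrimerError):
            design_reverse_primer(target, placements[0], universal_set)


class TestDiscrimination:
    def test_rejects_own_allele(self, hvsap16):
        design = assemble_assay(hvsap16)
        with pytest.raises(ValueError, match="own allele"):
            discrimination_score(design.allele_primers[0], "A")

    def test_positive_for_reference_pair(self, hvsap16):
        design = assemble_assay(hvsap16)
        assert discrimination_score(design.allele_primers[0], "T") > 0
        assert discrimination_score(design.allele_primers[1], "A") > 0

    def test_independent_of_tag_and_barcode(self, hvsap16):
        design = assemble_assay(hvsap16)
        primer = design.allele_primers[0]
        from dataclasses import replace

        relabeled = replace(primer, barcode="TGCAGG")
        assert discrimination_score(primer, "T") == discrimination_score(relabeled, "T")


class TestRandomTargets:
    def test_designs_revalidate_on_random_targets(self):
        rng = np.random.default_rng(2024)
        produced = 0
        for _ in range(200):
            target = make_random_target(rng)
            try:
                design = assemble_assay(target)
            except Exception:
                continue
            produced += 1
            revalidate(design)
        assert produced >= 150  # realistic random targets are mostly designable

    def test_strand_flip_maps_design(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            target = make_random_target(rng)
            flipped = SnpTarget(
                template=reverse_complement(target.template),
                snp_position=len(target.template) - 1 - target.snp_position,
                alleles=tuple(reverse_complement(a) for a in target.alleles),
            )
            try:
                d1 = assemble_assay(target)
                d2 = assemble_assay(flipped)
            except Exception:
                continue
            assert sorted(p.full_sequence for p in d1.allele_primers) == sorted(
                p.full_sequence for p in d2.allele_primers
            )
            assert d1.reverse_primer.sequence == d2.reverse_primer.sequence
            assert d1.amplicon_length == d2.amplicon_length
            return
        pytest.skip("no designable pair among the sampled targets")
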