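"""Allele-specific primer and amplicon design.

Designs the allele-specific half of the assay for one polymorphic site:
2-4 tagged forward primers (one per allele) whose allele-discriminating base
sits at the penultimate position from the 3' end (with a documented fallback
window of positions 2-12), plus one untagged common reverse primer placed so
the amplicon is 50-100 bp.

A forward primer is ``tag (13) + barcode (6) + gene_part (~20-25)``; the gene
part is the only template-annealing portion, so its melting temperature is
tuned without the tag, in magnesium-free buffer at the primer working
concentration -- the condition under which the 55-56 deg C design window is
defined. Primers for the different alleles share the gene part except at the
allele position, and are paired one-to-one with the universal probes whose
barcodes they carry.

Coordinates are 0-based half-open on the given (input) strand throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .thermo import Buffer, NO_MG_BUFFER, Oligo, melting_temperature, mismatch_ddg
from .universal import UniversalSet, build_universal_set, reverse_complement

__all__ = [
    "SnpTarget",
    "DesignParams",
    "Placement",
    "AllelePrimer",
    "ReversePrimer",
    "AssayDesign",
    "NoPlacementError",
    "NoReversePrimerError",
    "candidate_placements",
    "design_allele_primers",
    "design_reverse_primer",
    "discrimination_score",
    "assemble_assay",
]

_COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G"}
_IUPAC_ALLELES = {
    "R": ("A", "G"), "Y": ("C", "T"), "S": ("C", "G"), "W": ("A", "T"),
    "K": ("G", "T"), "M": ("A", "C"), "B": ("C", "G", "T"), "D": ("A", "G", "T"),
    "H": ("A", "C", "T"), "V": ("A", "C", "G"), "N": ("A", "C", "G", "T"),
}
MIN_FLANK = 60


class NoPlacementError(RuntimeError):
    """No allele-primer placement satisfies the melting-temperature window."""


class NoReversePrimerError(RuntimeError):
    """No common reverse primer satisfies the amplicon and hygiene constraints."""


@dataclass(frozen=True)
class SnpTarget:
    """A template sequence with one marked polymorphic site.

    ``alleles`` are single bases read on the given strand. They may be given
    explicitly or left as ``None`` when the template carries an IUPAC
    ambiguity code at ``snp_position``.
    """

    template: str
    snp_position: int
    alleles: tuple[str, ...] = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        seq = self.template.upper()
        object.__setattr__(self, "template", seq)
        if not 0 <= self.snp_position < len(seq):
            raise ValueError(f"snp_position {self.snp_position} outside template of length {len(seq)}")
        alleles = self.alleles
        if alleles is None:
            code = seq[self.snp_position]
            if code not in _IUPAC_ALLELES:
                raise ValueError(
                    f"no alleles given and template base {code!r} at the polymorphic "
                    "site is not an IUPAC ambiguity code"
                )
            alleles = _IUPAC_ALLELES[code]
        alleles = tuple(a.upper() for a in alleles)
        if not 2 <= len(alleles) <= 4:
            raise ValueError(f"2-4 alleles required, got {alleles}")
        if len(set(alleles)) != len(alleles):
            raise ValueError(f"alleles must be distinct, got {alleles}")
        if any(a not in "ACGT" for a in alleles):
            raise ValueError(f"only single-base alleles are supported, got {alleles}")
        object.__setattr__(self, "alleles", alleles)
        left = self.snp_position
        right = len(seq) - 1 - self.snp_position
        if max(left, right) < MIN_FLANK:
            raise ValueError(
                f"need >= {MIN_FLANK} nt of flank on at least one side of the site "
                f"(got {left} and {right})"
            )

    @classmethod
    def from_bracket(cls, notation: str) -> "SnpTarget":
        """Parse inline bracket notation, e.g. ``"ACCT[A/T]GGAC..."``.

        The first listed allele is written into the stored template.
        """
        start = notation.find("[")
        end = notation.find("]")
        if start == -1 or end == -1 or end < start:
            raise ValueError("bracket notation requires one [X/Y/...] site")
        alleles = tuple(a.strip().upper() for a in notation[start + 1 : end].split("/"))
        template = notation[:start] + alleles[0] + notation[end + 1 :]
        return cls(template=template, snp_position=start, alleles=alleles)


@dataclass(frozen=True)
class DesignParams:
    """Tunable primer-design thresholds (all temperatures in deg C)."""

    gene_part_tm_min: float = 55.0  # extend the gene part until mean Tm reaches this
    gene_part_tm_target: float = 55.5
    tm_hard_min: float = 52.0
    tm_hard_max: float = 60.0
    min_gene_part: int = 18
    max_gene_part: int = 28
    asp_concentration: float = 100.0  # nM, per allele primer
    reverse_concentration: float = 500.0  # nM; >= 3-5x the allele primers
    reverse_tm_tolerance: float = 1.0
    amplicon_window: tuple[int, int] = (50, 100)
    amplicon_hard_window: tuple[int, int] = (40, 150)
    min_offset: int = 2  # penultimate
    max_offset: int = 12  # 3'-critical window
    max_run: int = 4
    gc_min: float = 0.30
    gc_max: float = 0.70
    max_3prime_complementarity: int = 7  # reject at >= 8
    buffer: Buffer = NO_MG_BUFFER


@dataclass(frozen=True)
class Placement:
    """One candidate (strand, offset, gene-part) choice for the allele primers.

    ``strand`` is "+" when the primers read the given strand and "-" when they
    are designed on the reverse complement. ``asp_span`` is the given-strand
    half-open interval covered by the gene part; the amplicon always ends at
    the gene part's 5'-most given-strand coordinate on the side away from the
    reverse primer.
    """

    strand: str
    snp_offset: int
    gene_parts: dict[str, str]  # given-strand allele -> gene part (primer strand, 5'->3')
    tm_mean: float
    tm_by_allele: dict[str, float]
    min_ddg: float
    clean: bool
    asp_span: tuple[int, int]


def _strand_view(target: SnpTarget, strand: str) -> tuple[str, int, dict[str, str]]:
    """Template, SNP index and given->strand allele map for one strand."""
    if strand == "+":
        return target.template, target.snp_position, {a: a for a in target.alleles}
    rc = reverse_complement(target.template)
    pos = len(target.template) - 1 - target.snp_position
    return rc, pos, {a: _COMPLEMENT[a] for a in target.alleles}


def _has_long_run(seq: str, max_run: int) -> bool:
    run, prev = 0, ""
    for c in seq:
        run = run + 1 if c == prev else 1
        prev = c
        if run > max_run:
            return True
    return False


def candidate_placements(target: SnpTarget, params: DesignParams | None = None) -> list[Placement]:
    """Enumerate and rank allele-primer placements on both strands.

    For each strand and each allele offset 2..12 from the 3' end, the gene
    part is grown from the 3' end until its mean across-allele Tm (no Mg, at
    the primer concentration) reaches the design minimum; placements whose Tm
    cannot be brought inside the 52-60 deg C hard window are dropped. Ranking:
    homopolymer-clean placements first, then smaller offset (penultimate
    preferred), then larger worst-case off-allele destabilization, then Tm
    closest to target, then the given strand.
    """
    params = params or DesignParams()
    placements: list[Placement] = []
    for strand in ("+", "-"):
        stemplate, spos, allele_map = _strand_view(target, strand)
        n = len(stemplate)
        for offset in range(params.min_offset, params.max_offset + 1):
            end3 = spos + offset - 1  # 3'-terminal index on this strand
            if end3 >= n:
                continue
            chosen = None
            for length in range(params.min_gene_part, params.max_gene_part + 1):
                start = end3 - length + 1
                if start < 0:
                    break
                window = stemplate[start : end3 + 1]
                core = window[:spos - start] + window[spos - start + 1 :]
                if any(c not in "ACGT" for c in core):
                    break  # ambiguity inside the annealing region
                parts = {
                    given: window[: spos - start] + allele_map[given] + window[spos - start + 1 :]
                    for given in target.alleles
                }
                tms = {
                    given: melting_temperature(
                        Oligo(part, params.asp_concentration), params.buffer
                    )
                    for given, part in parts.items()
                }
                mean_tm = sum(tms.values()) / len(tms)
                chosen = (parts, tms, mean_tm)
                if mean_tm >= params.gene_part_tm_min:
                    break
            if chosen is None:
                continue
            parts, tms, mean_tm = chosen
            if not params.tm_hard_min <= mean_tm <= params.tm_hard_max:
                continue
            ddgs = [
                mismatch_ddg(parts[a], offset, allele_map[b])
                for a in target.alleles
                for b in target.alleles
                if a != b
            ]
            clean = not any(_has_long_run(p, params.max_run) for p in parts.values())
            length = len(next(iter(parts.values())))
            if strand == "+":
                span = (end3 - length + 1, end3 + 1)
            else:
                span = (n - 1 - end3, n - 1 - end3 + length)
            placements.append(
                Placement(
                    strand=strand,
                    snp_offset=offset,
                    gene_parts=parts,
                    tm_mean=mean_tm,
                    tm_by_allele=tms,
                    min_ddg=min(ddgs),
                    clean=clean,
                    asp_span=span,
                )
            )
    if not placements:
        raise NoPlacementError(
            f"no placement achieves a gene-part Tm inside "
            f"{params.tm_hard_min}-{params.tm_hard_max} deg C"
        )
    placements.sort(
        key=lambda p: (
            not p.clean,
            p.snp_offset,
            -round(p.min_ddg, 9),
            round(abs(p.tm_mean - params.gene_part_tm_target), 9),
            p.strand != "+",
        )
    )
    return placements


@dataclass(frozen=True)
class AllelePrimer:
    """A tagged allele-specific forward primer."""

    allele: str  # given-strand allele this primer amplifies
    gene_part: str
    snp_offset: int
    tag: str
    barcode: str
    strand: str
    concentration: float = 100.0

    @property
    def full_sequence(self) -> str:
        return self.tag + self.barcode + self.gene_part


@dataclass(frozen=True)
class ReversePrimer:
    """The untagged common primer on the strand opposite the allele primers.

    ``span`` is the 0-based half-open given-strand interval it anneals over.
    """

    sequence: str
    span: tuple[int, int]
    concentration: float = 500.0


def design_allele_primers(
    target: SnpTarget, placement: Placement, universal_set: UniversalSet
) -> list[AllelePrimer]:
    """One tagged primer per allele; primer *i* carries the barcode of probe *i*."""
    if len(target.alleles) > len(universal_set.probes):
        raise ValueError(
            f"{len(target.alleles)} alleles but the universal set has only "
            f"{len(universal_set.probes)} probes"
        )
    return [
        AllelePrimer(
            allele=allele,
            gene_part=placement.gene_parts[allele],
            snp_offset=placement.snp_offset,
            tag=universal_set.tag,
            barcode=probe.barcode,
            strand=placement.strand,
        )
        for allele, probe in zip(target.alleles, universal_set.probes)
    ]


def _three_prime_clash(candidate: str, others: list[str], limit: int) -> bool:
    """True when the candidate's 3' tail of length > ``limit`` could prime on
    any other oligo (reverse complement of the tail appears in it)."""
    tail = candidate[-(limit + 1) :]
    probe = reverse_complement(tail)
    return any(probe in other.upper() for other in others)


def design_reverse_primer(
    target: SnpTarget,
    placement: Placement,
    universal_set: UniversalSet | None = None,
    params: DesignParams | None = None,
) -> ReversePrimer:
    """Scan the opposite strand for the common reverse primer.

    Candidates are enumerated over amplicon lengths inside the window and
    primer lengths 18-28, rejecting extreme GC, homopolymer runs, overlap with
    the allele-primer footprint, and >= 8 nt of 3'-end complementarity to any
    other oligo in the reaction; among survivors with Tm within the tolerance
    of the gene-part Tm the one with the closest Tm wins, then the shortest
    amplicon.
    """
    params = params or DesignParams()
    template = target.template
    n = len(template)
    lo, hi = params.amplicon_window
    fwd_tm = placement.tm_mean
    other_oligos = [universal_set.tag.upper() + p.barcode.upper() + placement.gene_parts[a]
                    for a, p in zip(target.alleles, universal_set.probes)] if universal_set else \
                   list(placement.gene_parts.values())

    best = None
    reject = {"flank": 0, "gc": 0, "run": 0, "clash": 0, "tm": 0}
    for amplicon_len in range(lo, hi + 1):
        for length in range(params.min_gene_part, params.max_gene_part + 1):
            if placement.strand == "-":
                # allele primers on the reverse complement: the common primer
                # reads the given strand, left of the site
                amp_end = placement.asp_span[1]
                rev_start = amp_end - amplicon_len
                rev_end = rev_start + length
                if rev_start < 0 or rev_end > placement.asp_span[0]:
                    reject["flank"] += 1
                    continue
                seq = template[rev_start:rev_end]
                span = (rev_start, rev_end)
            else:
                amp_start = placement.asp_span[0]
                amp_end = amp_start + amplicon_len
                rev_end = amp_end
                rev_start = rev_end - length
                if amp_end > n or rev_start < placement.asp_span[1]:
                    reject["flank"] += 1
                    continue
                seq = reverse_complement(template[rev_start:rev_end])
                span = (rev_start, rev_end)
            if any(c not in "ACGT" for c in seq):
                continue
            gc = (seq.count("G") + seq.count("C")) / len(seq)
            if not params.gc_min <= gc <= params.gc_max:
                reject["gc"] += 1
                continue
            if _has_long_run(seq, params.max_run):
                reject["run"] += 1
                continue
            if _three_prime_clash(seq, other_oligos, params.max_3prime_complementarity):
                reject["clash"] += 1
                continue
            tm = melting_temperature(Oligo(seq, params.reverse_concentration), params.buffer)
            dt = abs(tm - fwd_tm)
            if dt > params.reverse_tm_tolerance:
                reject["tm"] += 1
                continue
            key = (round(dt, 6), amplicon_len, length)
            if best is None or key < best[0]:
                best = (key, ReversePrimer(sequence=seq, span=span,
                                           concentration=params.reverse_concentration))
    if best is None:
        binding = max(reject, key=reject.get)
        raise NoReversePrimerError(
            f"no feasible common reverse primer for amplicon window {params.amplicon_window}; "
            f"most frequently binding constraint: {binding} (rejections: {reject})"
        )
    return best[1]


def discrimination_score(primer: AllelePrimer, off_allele: str) -> float:
    """Free-energy penalty (kcal/mol) of priming the ``off_allele`` template.

    ``off_allele`` is read on the given strand; it is complemented when the
    primer was designed on the reverse strand. Depends only on the gene part,
    never on the tag or barcode.
    """
    off = off_allele.upper()
    if primer.strand == "-":
        off = _COMPLEMENT[off]
    primer_base = primer.gene_part[len(primer.gene_part) - primer.snp_offset]
    if off == primer_base:
        raise ValueError(f"off-allele {off_allele!r} is the primer's own allele")
    return mismatch_ddg(primer.gene_part, primer.snp_offset, off)


@dataclass(frozen=True)
class AssayDesign:
    """A complete designed assay: oligos, amplicon, stoichiometry, scores."""

    target: SnpTarget
    allele_primers: tuple[AllelePrimer, ...]
    reverse_primer: ReversePrimer
    universal_set: UniversalSet
    amplicon_span: tuple[int, int]
    concentrations: dict[str, float]  # nM per oligo name
    discrimination: dict[str, float] = field(default_factory=dict)

    @property
    def amplicon_length(self) -> int:
        return self.amplicon_span[1] - self.amplicon_span[0]

    @property
    def amplicon_sequence(self) -> str:
        return self.target.template[self.amplicon_span[0] : self.amplicon_span[1]]


def assemble_assay(
    target: SnpTarget,
    universal_set: UniversalSet | None = None,
    params: DesignParams | None = None,
) -> AssayDesign:
    """End-to-end design: placement -> allele primers -> reverse primer.

    Placements are tried in rank order until one admits a feasible reverse
    primer. Default per-oligo concentrations follow the validated recipe:
    allele primers 100 nM each, common reverse primer 500 nM (>= 3-5x the
    allele primers so the tagged primers, not the reverse primer, limit the
    reaction), probes 300 nM, quencher 600 nM. Deterministic for fixed inputs.
    """
    params = params or DesignParams()
    if universal_set is None:
        default_barcodes = ("TCGACC", "ACCTGC", "TGCAGG", "AGGTCG")
        default_dyes = ("FAM", "HEX", "Cy3", "Cy5")
        k = max(2, len(target.alleles))
        universal_set = build_universal_set(
            barcodes=default_barcodes[:k], dyes=default_dyes[:k]
        )
    last_error: Exception | None = None
    for placement in candidate_placements(target, params):
        try:
            reverse = design_reverse_primer(target, placement, universal_set, params)
        except NoReversePrimerError as err:
            last_error = err
            continue
        primers = design_allele_primers(target, placement, universal_set)
        if placement.strand == "-":
            amplicon = (reverse.span[0], placement.asp_span[1])
        else:
            amplicon = (placement.asp_span[0], reverse.span[1])
        length = amplicon[1] - amplicon[0]
        hard_lo, hard_hi = params.amplicon_hard_window
        if not hard_lo <= length <= hard_hi:
            raise NoReversePrimerError(
                f"amplicon of {length} bp outside the hard window {params.amplicon_hard_window}"
            )
        lo, hi = params.amplicon_window
        if not lo <= length <= hi:
            warnings.warn(f"amplicon of {length} bp outside the preferred window {lo}-{hi}")
        discrimination = {
            f"{p.allele}|{off}": discrimination_score(p, off)
            for p in primers
            for off in target.alleles
            if off != p.allele
        }
        concentrations = {
            **{f"ASP-{p.allele}": p.concentration for p in primers},
            "ASP-R": reverse.concentration,
            **{f"UP-{pr.dye_label}": pr.concentration for pr in universal_set.probes},
            "Uni-Q": universal_set.quencher.concentration,
        }
        return AssayDesign(
            target=target,
            allele_primers=tuple(primers),
            reverse_primer=reverse,
            universal_set=universal_set,
            amplicon_span=amplicon,
            concentrations=concentrations,
            discrimination=discrimination,
        )
    raise NoReversePrimerError(
        f"no placement admits a common reverse primer; last failure: {last_error}"
    )
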