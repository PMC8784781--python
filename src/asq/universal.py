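"""The template-independent detector mixture: universal probes and quencher.

A universal set consists of 2-4 fluorophore-labeled universal probes (UPs),
each a 19-mer made of a shared 13-bp tag plus a unique 6-bp barcode with the
dye on the 5' end, and a single quencher oligo (Uni-Q) that is the exact
reverse complement of the tag with the quencher on its 3' end. Hybridization
of Uni-Q to an unincorporated probe brings dye and quencher into FRET
proximity (dark); probes incorporated into amplicons escape quenching. The
3'-quencher also blocks polymerase extension of Uni-Q.

The design rules enforced here: the 19-mer probes must melt >= 10 deg C above
the 13-mer quencher (so the quencher releases probes at the annealing step of
the second PCR round but recaptures them at the read step), the quencher must
melt below the second-round annealing temperature, and the quencher must be
at least as concentrated as all probes combined (complete quenching of the
unincorporated pool).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

from Bio.Seq import Seq

from .barcodes import hamming, DEFAULT_MIN_HAMMING
from .thermo import Buffer, Oligo, PCR_BUFFER, melting_temperature

__all__ = [
    "UniversalProbe",
    "QuencherOligo",
    "UniversalSet",
    "UniversalSetValidation",
    "reverse_complement",
    "build_universal_set",
    "validate_universal_set",
    "order_sheet_tsv",
    "order_sheet_fasta",
]

TAG_LENGTH = 13
DEFAULT_TAG = "ccagctgaacggt"
DEFAULT_PROBE_CONC_NM = 300.0
# quencher concentration as a multiple of the summed probe concentration;
# the validated recipe uses exactly the sum (0.6 uM against two 0.3 uM
# probes), the design rule being "at least the same, up to double"
DEFAULT_QUENCHER_MULTIPLIER = 1.0
MIN_PROBE_QUENCHER_TM_GAP = 10.0  # deg C
DEFAULT_ANNEALING_C = 62.0

_IUPAC = set("ACGTRYSWKMBDHVN")


def reverse_complement(sequence: str) -> str:
    """IUPAC-aware reverse complement, preserving case."""
    bad = sorted({c for c in sequence.upper() if c not in _IUPAC})
    if bad:
        raise ValueError(f"invalid nucleotide characters: {bad!r}")
    return str(Seq(sequence).reverse_complement())


@dataclass(frozen=True)
class UniversalProbe:
    """5'-dye 19-mer: shared tag + unique barcode."""

    dye_label: str
    tag: str
    barcode: str
    concentration: float = DEFAULT_PROBE_CONC_NM

    def __post_init__(self) -> None:
        if len(self.tag) != TAG_LENGTH:
            raise ValueError(f"tag must be {TAG_LENGTH} nt, got {len(self.tag)}")
        if len(self.barcode) != 6:
            raise ValueError(f"barcode must be 6 nt, got {len(self.barcode)}")

    @property
    def sequence(self) -> str:
        return self.tag + self.barcode


@dataclass(frozen=True)
class QuencherOligo:
    """3'-quencher 13-mer, reverse complement of the probe tag."""

    sequence: str
    quencher_label: str = "BHQ1"
    concentration: float = 2 * DEFAULT_PROBE_CONC_NM


def _has_long_run(seq: str, max_run: int = 4) -> bool:
    run, prev = 0, ""
    for c in seq:
        run = run + 1 if c == prev else 1
        prev = c
        if run > max_run:
            return True
    return False


def _check_tag(tag: str) -> None:
    if len(tag) != TAG_LENGTH:
        raise ValueError(f"tag must be exactly {TAG_LENGTH} nt, got {len(tag)}")
    seq = tag.upper()
    bad = sorted({c for c in seq if c not in "ACGT"})
    if bad:
        raise ValueError(f"tag contains non-ACGT characters: {bad!r}")
    gc = (seq.count("G") + seq.count("C")) / len(seq)
    if not 0.5 <= gc <= 0.7:
        raise ValueError(f"tag GC fraction {gc:.2f} outside the accepted 0.50-0.70 window")
    if _has_long_run(seq):
        raise ValueError("tag contains a homopolymer run longer than 4")


@dataclass(frozen=True)
class UniversalSet:
    tag: str
    probes: tuple[UniversalProbe, ...]
    quencher: QuencherOligo

    def __post_init__(self) -> None:
        if not 2 <= len(self.probes) <= 4:
            raise ValueError(f"a universal set carries 2-4 probes, got {len(self.probes)}")
        for p in self.probes:
            if p.tag != self.tag:
                raise ValueError(f"probe {p.dye_label} does not share the set tag")
        expected = reverse_complement(self.tag)
        if self.quencher.sequence.upper() != expected.upper():
            raise ValueError("quencher sequence is not the reverse complement of the tag")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, payload: dict) -> "UniversalSet":
        probes = tuple(UniversalProbe(**p) for p in payload["probes"])
        quencher = QuencherOligo(**payload["quencher"])
        return cls(tag=payload["tag"], probes=probes, quencher=quencher)


def build_universal_set(
    tag: str = DEFAULT_TAG,
    barcodes: tuple[str, ...] = ("TCGACC", "ACCTGC"),
    dyes: tuple[str, ...] = ("FAM", "HEX"),
    quencher_label: str = "BHQ1",
    probe_concentration: float = DEFAULT_PROBE_CONC_NM,
    quencher_multiplier: float = DEFAULT_QUENCHER_MULTIPLIER,
    min_hamming: int = DEFAULT_MIN_HAMMING,
) -> UniversalSet:
    """Assemble a universal probe/quencher set.

    Each probe is ``tag + barcode`` with its dye; the quencher sequence is the
    reverse complement of the tag, at ``quencher_multiplier`` times the summed
    probe concentration (default 1x: two probes at 300 nM give Uni-Q 600 nM,
    the validated recipe; raise the multiplier up to 2 for a darker
    background).
    """
    _check_tag(tag)
    if len(barcodes) != len(dyes):
        raise ValueError(f"{len(barcodes)} barcodes but {len(dyes)} dyes")
    if not 2 <= len(barcodes) <= 4:
        raise ValueError(f"2-4 barcodes required, got {len(barcodes)}")
    if len(set(d.upper() for d in dyes)) != len(dyes):
        raise ValueError(f"duplicate dye labels: {dyes}")
    if quencher_multiplier < 1:
        raise ValueError("quencher multiplier must be >= 1 (full quenching of the probe pool)")
    upper = [b.upper() for b in barcodes]
    if len(set(upper)) != len(upper):
        raise ValueError(f"duplicate barcodes: {barcodes}")
    for i, a in enumerate(upper):
        for b in upper[i + 1 :]:
            d = hamming(a, b)
            if d < min_hamming:
                raise ValueError(
                    f"barcodes {a} and {b} differ at only {d} positions (< {min_hamming})"
                )
    probes = tuple(
        UniversalProbe(dye_label=dye, tag=tag, barcode=bc, concentration=probe_concentration)
        for dye, bc in zip(dyes, barcodes)
    )
    quencher = QuencherOligo(
        sequence=reverse_complement(tag),
        quencher_label=quencher_label,
        concentration=quencher_multiplier * probe_concentration * len(probes),
    )
    return UniversalSet(tag=tag, probes=probes, quencher=quencher)


@dataclass(frozen=True)
class UniversalSetValidation:
    """Per-oligo melting temperatures and the pass/fail design checks."""

    probe_tm: dict[str, float]
    quencher_tm: float
    tm_gap: float
    tm_gap_ok: bool
    quencher_below_annealing: bool
    quencher_concentration_ok: bool

    @property
    def all_ok(self) -> bool:
        return self.tm_gap_ok and self.quencher_below_annealing and self.quencher_concentration_ok


def validate_universal_set(
    uset: UniversalSet,
    buffer: Buffer = PCR_BUFFER,
    protocol_annealing: float = DEFAULT_ANNEALING_C,
) -> UniversalSetValidation:
    """Check the thermodynamic and stoichiometric design rules of a set.

    Each oligo's Tm is its self-duplex value at its working concentration
    under ``buffer``. Checks: (a) min probe Tm exceeds the quencher Tm by at
    least 10 deg C, (b) the quencher melts below the second-round annealing
    temperature, (c) the quencher is at least as concentrated as the summed
    probes.
    """
    probe_tm = {
        p.dye_label: melting_temperature(Oligo(p.sequence, p.concentration), buffer)
        for p in uset.probes
    }
    quencher_tm = melting_temperature(
        Oligo(uset.quencher.sequence, uset.quencher.concentration), buffer
    )
    gap = min(probe_tm.values()) - quencher_tm
    return UniversalSetValidation(
        probe_tm=probe_tm,
        quencher_tm=quencher_tm,
        tm_gap=gap,
        tm_gap_ok=gap >= MIN_PROBE_QUENCHER_TM_GAP,
        quencher_below_annealing=quencher_tm < protocol_annealing,
        quencher_concentration_ok=uset.quencher.concentration
        >= sum(p.concentration for p in uset.probes),
    )


def _probe_name(i: int, probe: UniversalProbe) -> str:
    return f"UP-{i}_5{probe.dye_label}"


def order_sheet_tsv(uset: UniversalSet) -> str:
    """Synthesis order sheet: one row per oligo with modification labels."""
    lines = ["name\tsequence\tmodification\tconcentration_nM"]
    for i, p in enumerate(uset.probes, start=1):
        lines.append(f"{_probe_name(i, p)}\t{p.sequence}\t5'-{p.dye_label}\t{p.concentration:g}")
    q = uset.quencher
    lines.append(f"UniQ_3{q.quencher_label}\t{q.sequence}\t3'-{q.quencher_label}\t{q.concentration:g}")
    return "\n".join(lines) + "\n"


def order_sheet_fasta(uset: UniversalSet) -> str:
    records = []
    for i, p in enumerate(uset.probes, start=1):
        records.append(f">{_probe_name(i, p)}\n{p.sequence}")
    q = uset.quencher
    records.append(f">UniQ_3{q.quencher_label}\n{q.sequence}")
    return "\n".join(records) + "\n"
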