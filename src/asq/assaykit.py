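"""Reaction stoichiometry, thermal protocol, and assay serialization.

The mix calculator reproduces the validated two-premix PCR cocktail
(allele-specific primers at 0.1 uM with the common reverse primer at 0.5 uM;
universal probes at 0.3 uM with the quencher at 0.6 uM; 3 mM MgCl2) for 5 or
10 ul reactions, and the thermal-protocol generator emits the two-round
program: a low-annealing first round in which the allele-specific primers
select their template, and a higher-annealing second round in which the
universal probes enter the amplicons, each cycle ending with a 55 deg C step
where the quencher recaptures unincorporated probes and fluorescence is read.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

from .aspdesign import AllelePrimer, AssayDesign, ReversePrimer, SnpTarget
from .thermo import NO_MG_BUFFER, Oligo, PCR_BUFFER, duplex_energies, melting_temperature
from .universal import UniversalSet

__all__ = [
    "Quantity",
    "MixSpec",
    "MixComponent",
    "InfeasibleRecipeError",
    "compute_mix",
    "default_mix_specs",
    "default_mix",
    "ThermalStep",
    "CyclingBlock",
    "ThermalProtocol",
    "default_protocol",
    "export_assay",
    "design_to_dict",
    "design_from_dict",
]

# unit families: conversions are allowed only inside a family
_FAMILIES = {
    "mM": ("molar", 1e-3),
    "uM": ("molar", 1e-6),
    "nM": ("molar", 1e-9),
    "units/ul": ("activity", 1.0),
    "ng/ul": ("mass_conc", 1.0),
    "x": ("fold", 1.0),
}


@dataclass(frozen=True)
class Quantity:
    """A value with an explicit unit tag; no implicit cross-family conversion."""

    value: float
    unit: str

    def __post_init__(self) -> None:
        if self.unit not in _FAMILIES:
            raise ValueError(f"unknown unit {self.unit!r}; known: {sorted(_FAMILIES)}")

    @property
    def family(self) -> str:
        return _FAMILIES[self.unit][0]

    def in_base(self) -> float:
        return self.value * _FAMILIES[self.unit][1]

    def ratio(self, other: "Quantity") -> float:
        """Dimensionless self/other; both quantities must share a unit family."""
        if self.family != other.family:
            raise ValueError(f"incompatible units {self.unit!r} vs {other.unit!r}")
        return self.in_base() / other.in_base()


@dataclass(frozen=True)
class MixSpec:
    """One species in the recipe: stock and target final concentration.

    Species sharing a physical pre-mix carry the same ``group`` label; they
    are pipetted together, so their (identical) volume is counted once.
    """

    name: str
    stock: Quantity
    final: Quantity
    group: str | None = None


@dataclass(frozen=True)
class MixComponent:
    name: str
    stock: Quantity
    final: Quantity
    volume: float  # ul
    group: str | None = None


class InfeasibleRecipeError(ValueError):
    """A requested final concentration cannot be reached from its stock."""


def compute_mix(
    specs: list[MixSpec], total_volume: float, template_volume: float
) -> tuple[list[MixComponent], float]:
    """Per-component volumes for a reaction of ``total_volume`` ul.

    Each species needs ``volume = (final/stock) * total_volume``; grouped
    species must agree on that volume (a pre-mix is one pipetting step).
    Returns the component list and the water volume that fills the reaction
    to ``total_volume`` after the DNA template; volumes conserve the total
    exactly. Raises :class:`InfeasibleRecipeError` when a final concentration
    exceeds its stock or the volumes overflow the reaction.
    """
    if not total_volume > template_volume > 0:
        raise ValueError(
            f"need total_volume > template_volume > 0, got {total_volume} and {template_volume}"
        )
    components: list[MixComponent] = []
    group_volume: dict[str, float] = {}
    pipetted = 0.0
    for spec in specs:
        ratio = spec.final.ratio(spec.stock)
        if ratio > 1:
            raise InfeasibleRecipeError(
                f"{spec.name}: final {spec.final.value} {spec.final.unit} exceeds "
                f"stock {spec.stock.value} {spec.stock.unit}"
            )
        volume = ratio * total_volume
        if spec.group is not None:
            if spec.group in group_volume:
                if abs(group_volume[spec.group] - volume) > 1e-9:
                    raise InfeasibleRecipeError(
                        f"{spec.name}: volume {volume:.6g} ul disagrees with its "
                        f"pre-mix {spec.group!r} ({group_volume[spec.group]:.6g} ul); "
                        "re-formulate the pre-mix stocks"
                    )
            else:
                group_volume[spec.group] = volume
                pipetted += volume
        else:
            pipetted += volume
        components.append(MixComponent(spec.name, spec.stock, spec.final, volume, spec.group))
    water = total_volume - template_volume - pipetted
    if water < -1e-9:
        raise InfeasibleRecipeError(
            f"component volumes ({pipetted:.4g} ul) plus template ({template_volume} ul) "
            f"overflow the {total_volume} ul reaction"
        )
    return components, max(water, 0.0)


def default_mix_specs(n_probes: int = 2) -> list[MixSpec]:
    """The validated cocktail recipe (concentrations per final reaction)."""
    um = lambda v: Quantity(v, "uM")
    specs = [
        MixSpec("GoTaq buffer", Quantity(5, "x"), Quantity(1, "x")),
        MixSpec("MgCl2", Quantity(25, "mM"), Quantity(3.0, "mM")),
        MixSpec("dNTP", Quantity(2, "mM"), Quantity(0.2, "mM")),
        MixSpec("ASP-F1", um(1), um(0.1), group="ASPs pre-mix"),
        MixSpec("ASP-F2", um(1), um(0.1), group="ASPs pre-mix"),
        MixSpec("ASP-R", um(5), um(0.5), group="ASPs pre-mix"),
    ]
    dyes = ["FAM", "HEX", "Cy3", "Cy5"][:n_probes]
    for dye in dyes:
        specs.append(MixSpec(f"UP-{dye}", um(3), um(0.3), group="UPs pre-mix"))
    specs.append(MixSpec("Uni-Q", um(6), um(0.6), group="UPs pre-mix"))
    specs.append(MixSpec("Taq polymerase", Quantity(5, "units/ul"), Quantity(0.04, "units/ul")))
    return specs


def default_mix(total_volume: float = 10.0, template_volume: float | None = None, n_probes: int = 2):
    """Cocktail for a 10 ul (default) or scaled reaction.

    ``template_volume`` defaults to a fifth of the reaction (2 ul at 10 ul,
    1 ul at 5 ul). Returns ``(components, water_volume, template_volume)``.
    """
    if template_volume is None:
        template_volume = total_volume / 5.0
    components, water = compute_mix(default_mix_specs(n_probes), total_volume, template_volume)
    return components, water, template_volume


@dataclass(frozen=True)
class ThermalStep:
    temperature: float  # deg C
    duration: float  # seconds
    note: str = ""


@dataclass(frozen=True)
class CyclingBlock:
    """Repeat steps ``first..last`` (0-based, inclusive) ``repeats`` times."""

    first: int
    last: int
    repeats: int


@dataclass(frozen=True)
class ThermalProtocol:
    steps: tuple[ThermalStep, ...]
    blocks: tuple[CyclingBlock, ...]
    read_points: tuple[int, ...]  # step indices with a fluorescence read

    def __post_init__(self) -> None:
        n = len(self.steps)
        for b in self.blocks:
            if not (0 <= b.first <= b.last < n):
                raise ValueError(f"cycling block {b} references missing steps")
            if b.repeats < 1:
                raise ValueError(f"cycling block repeat count must be >= 1, got {b.repeats}")
        for r in self.read_points:
            if not 0 <= r < n:
                raise ValueError(f"read point {r} references a missing step")

    def total_seconds(self) -> float:
        repeat = {i: 1 for i in range(len(self.steps))}
        for b in self.blocks:
            for i in range(b.first, b.last + 1):
                repeat[i] *= b.repeats
        return sum(s.duration * repeat[i] for i, s in enumerate(self.steps))

    def to_dict(self) -> dict:
        return {
            "steps": [[s.temperature, s.duration, s.note] for s in self.steps],
            "blocks": [[b.first, b.last, b.repeats] for b in self.blocks],
            "read_points": list(self.read_points),
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "ThermalProtocol":
        return cls(
            steps=tuple(ThermalStep(*s) for s in payload["steps"]),
            blocks=tuple(CyclingBlock(*b) for b in payload["blocks"]),
            read_points=tuple(payload["read_points"]),
        )


def default_protocol(
    first_round_cycles: int = 10,
    second_round_cycles: int = 30,
    include_optional_extension: bool = True,
) -> ThermalProtocol:
    """The two-round genotyping program.

    Round one anneals at 55 deg C so the allele-specific primers select their
    template; round two anneals at 62 deg C, favoring universal-probe entry
    into the tagged amplicons, and ends each cycle with a 55 deg C step where
    the quencher binds all unincorporated probes and the plate is read.
    """
    if first_round_cycles < 1 or second_round_cycles < 1:
        raise ValueError("cycle counts must be >= 1")
    steps = [
        ThermalStep(94, 120, "initial denaturation"),
        ThermalStep(94, 10, "first-round denaturation"),
        ThermalStep(55, 20, "first-round annealing"),
        ThermalStep(68, 20, "first-round extension"),
        ThermalStep(94, 10, "second-round denaturation"),
        ThermalStep(62, 20, "second-round annealing-extension"),
    ]
    if include_optional_extension:
        steps.append(ThermalStep(68, 20, "second-round extension (optional)"))
    read_index = len(steps)
    steps.append(ThermalStep(55, 30, "cooling, extension and microplate read"))
    blocks = (
        CyclingBlock(1, 3, first_round_cycles),
        CyclingBlock(4, read_index, second_round_cycles),
    )
    return ThermalProtocol(steps=tuple(steps), blocks=blocks, read_points=(read_index,))


# --- assay serialization -------------------------------------------------


def design_to_dict(design: AssayDesign) -> dict:
    return {
        "target": {
            "template": design.target.template,
            "snp_position": design.target.snp_position,
            "alleles": list(design.target.alleles),
        },
        "allele_primers": [
            {
                "allele": p.allele,
                "gene_part": p.gene_part,
                "snp_offset": p.snp_offset,
                "tag": p.tag,
                "barcode": p.barcode,
                "strand": p.strand,
                "concentration": p.concentration,
            }
            for p in design.allele_primers
        ],
        "reverse_primer": {
            "sequence": design.reverse_primer.sequence,
            "span": list(design.reverse_primer.span),
            "concentration": design.reverse_primer.concentration,
        },
        "universal_set": design.universal_set.to_dict(),
        "amplicon_span": list(design.amplicon_span),
        "concentrations": dict(design.concentrations),
        "discrimination": dict(design.discrimination),
    }


def design_from_dict(payload: dict) -> AssayDesign:
    target = SnpTarget(
        template=payload["target"]["template"],
        snp_position=payload["target"]["snp_position"],
        alleles=tuple(payload["target"]["alleles"]),
    )
    primers = tuple(AllelePrimer(**p) for p in payload["allele_primers"])
    reverse = ReversePrimer(
        sequence=payload["reverse_primer"]["sequence"],
        span=tuple(payload["reverse_primer"]["span"]),
        concentration=payload["reverse_primer"]["concentration"],
    )
    return AssayDesign(
        target=target,
        allele_primers=primers,
        reverse_primer=reverse,
        universal_set=UniversalSet.from_dict(payload["universal_set"]),
        amplicon_span=tuple(payload["amplicon_span"]),
        concentrations=dict(payload["concentrations"]),
        discrimination=dict(payload["discrimination"]),
    )


def _oligo_rows(design: AssayDesign):
    for i, p in enumerate(design.allele_primers, start=1):
        yield f"ASP-F{i}", p.full_sequence, p.gene_part, p.concentration, f"5'-tag+{p.barcode}"
    yield "ASP-R", design.reverse_primer.sequence, design.reverse_primer.sequence, \
        design.reverse_primer.concentration, "untagged common reverse"
    for i, probe in enumerate(design.universal_set.probes, start=1):
        yield f"UP-{i}", probe.sequence, probe.sequence, probe.concentration, f"5'-{probe.dye_label}"
    q = design.universal_set.quencher
    yield "Uni-Q", q.sequence, q.sequence, q.concentration, f"3'-{q.quencher_label}"


def export_assay(design: AssayDesign, format: str = "json") -> str:
    """Serialize a design: lossless ``json``, a Tm/dG-annotated ``tsv`` sheet,
    or ``fasta`` with modification labels in the headers."""
    if format == "json":
        return json.dumps(design_to_dict(design), indent=2, sort_keys=True) + "\n"
    if format == "tsv":
        lines = ["name\tsequence\ttm_mg_C\ttm_no_mg_C\tdg37_kcal_mol\tconcentration_nM\tnote"]
        for name, seq, anneal, conc, note in _oligo_rows(design):
            tm_mg = melting_temperature(Oligo(anneal, conc), PCR_BUFFER)
            tm_no = melting_temperature(Oligo(anneal, conc), NO_MG_BUFFER)
            dg = duplex_energies(anneal).dg37
            lines.append(f"{name}\t{seq}\t{tm_mg:.1f}\t{tm_no:.1f}\t{dg:.1f}\t{conc:g}\t{note}")
        return "\n".join(lines) + "\n"
    if format == "fasta":
        records = []
        for name, seq, _, _, note in _oligo_rows(design):
            records.append(f">{name} {note}\n{seq}")
        return "\n".join(records) + "\n"
    raise ValueError(f"unknown export format {format!r}; use json, tsv or fasta")
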