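"""Nearest-neighbor DNA duplex thermodynamics.

Implements the unified nearest-neighbor model for short DNA duplexes:
enthalpy/entropy summation over dinucleotide propagation steps plus terminal
initiation penalties, concentration-dependent melting temperature with
monovalent- and magnesium-ion corrections, and single internal-mismatch
destabilization scoring (the quantity that drives allele discrimination in
allele-specific PCR).

Conventions
-----------
* ``dH`` in kcal/mol, ``dS`` in cal/(mol K), ``dG37`` in kcal/mol.
* ``dG37`` is the standard-state (1 M strand, 1 M NaCl-equivalent) value
  ``dH - 310.15*dS/1000``; buffer ions affect only the melting temperature.
* Temperatures are degrees Celsius externally, Kelvin internally.
* The two-state melting temperature uses the ``CT/4`` convention for a
  non-self-complementary oligo hybridizing to its complement.
* Monovalent salt enters as an entropic correction
  ``dS' = dS + 0.368*(N-1)*ln[mono]``; magnesium uses the Owczarzy (2008)
  inverse-temperature correction, with the ``sqrt([Mg])/[mono]`` ratio
  deciding which ionic regime applies.

Parameter sets are stored as plain-text TSV files under ``asq/data`` so an
alternative table can be swapped in via :func:`load_nn_table`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

__all__ = [
    "Oligo",
    "Buffer",
    "ThermoResult",
    "NNTable",
    "load_nn_table",
    "duplex_energies",
    "melting_temperature",
    "mismatch_ddg",
]

GAS_CONSTANT = 1.987  # cal/(mol K)
T37_KELVIN = 310.15

_COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G"}
MIN_DUPLEX_LENGTH = 6


@dataclass(frozen=True)
class Oligo:
    """A single-stranded DNA oligonucleotide at a working concentration.

    Parameters
    ----------
    sequence:
        DNA over {A, C, G, T}, case-insensitive.
    concentration:
        Total strand concentration in nM.
    """

    sequence: str
    concentration: float = 100.0


@dataclass(frozen=True)
class Buffer:
    """Ionic conditions of the hybridization buffer (mM)."""

    monovalent: float = 50.0
    magnesium: float = 0.0

    def __post_init__(self) -> None:
        if self.monovalent <= 0:
            raise ValueError(f"monovalent cation concentration must be > 0, got {self.monovalent}")
        if self.magnesium < 0:
            raise ValueError(f"magnesium concentration must be >= 0, got {self.magnesium}")


# the standard PCR buffer of the assay: 50 mM K+, 3 mM Mg2+
PCR_BUFFER = Buffer(monovalent=50.0, magnesium=3.0)
# the same buffer without magnesium (gene-part design condition)
NO_MG_BUFFER = Buffer(monovalent=50.0, magnesium=0.0)


@dataclass(frozen=True)
class ThermoResult:
    """Duplex thermodynamics: dH (kcal/mol), dS (cal/mol/K), dG37 (kcal/mol),
    and optionally the melting temperature (deg C) under a stated buffer."""

    dh: float
    ds: float
    dg37: float
    tm: float | None = None


class NNTable:
    """Nearest-neighbor parameter set.

    Holds Watson-Crick propagation entries keyed by the top-strand
    dinucleotide, per-terminal-base initiation terms, and internal-mismatch
    entries keyed ``"XY/WZ"`` (top 5'->3' / bottom 3'->5').
    """

    def __init__(
        self,
        propagation: dict[str, tuple[float, float]],
        initiation: dict[str, tuple[float, float]],
        mismatch: dict[str, tuple[float, float]],
    ) -> None:
        missing = [a + b for a in "ACGT" for b in "ACGT" if a + b not in propagation]
        if missing:
            raise ValueError(f"incomplete propagation table, missing steps: {missing}")
        for step, params in propagation.items():
            twin = _COMPLEMENT[step[1]] + _COMPLEMENT[step[0]]
            if propagation[twin] != params:
                raise ValueError(f"propagation table breaks reverse-complement symmetry at {step}/{twin}")
        self.propagation = propagation
        self.initiation = initiation
        self.mismatch = mismatch

    def wc_step(self, step: str) -> tuple[float, float]:
        return self.propagation[step]

    def mismatch_step(self, top: str, bottom: str) -> tuple[float, float]:
        """Look up a step with >= 1 non-Watson-Crick pair.

        ``top`` is read 5'->3', ``bottom`` 3'->5'. Falls back to the
        strand-swap equivalent key ``rev(bottom)/rev(top)``.
        """
        key = f"{top}/{bottom}"
        hit = self.mismatch.get(key) or self.mismatch.get(f"{bottom[::-1]}/{top[::-1]}")
        if hit is None:
            raise KeyError(f"no internal-mismatch parameters for step {key}")
        return hit


def _read_param_file(name: str) -> dict[str, tuple[float, float]]:
    out: dict[str, tuple[float, float]] = {}
    text = resources.files("asq.data").joinpath(name).read_text()
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, dh, ds = line.split("\t")
        out[key] = (float(dh), float(ds))
    return out


@lru_cache(maxsize=None)
def load_nn_table(
    wc_file: str = "nn_unified_1998.tsv",
    mismatch_file: str = "nn_internal_mismatch.tsv",
) -> NNTable:
    """Load a nearest-neighbor parameter set from the packaged data files."""
    raw = _read_param_file(wc_file)
    propagation = {k: v for k, v in raw.items() if not k.startswith("init_")}
    initiation = {k.removeprefix("init_"): v for k, v in raw.items() if k.startswith("init_")}
    return NNTable(propagation, initiation, _read_param_file(mismatch_file))


def _clean_sequence(sequence: str) -> str:
    seq = sequence.upper()
    bad = sorted({c for c in seq if c not in "ACGT"})
    if bad:
        raise ValueError(f"sequence contains non-ACGT characters: {bad!r}")
    if len(seq) < MIN_DUPLEX_LENGTH:
        raise ValueError(
            f"sequence of length {len(seq)} too short for nearest-neighbor evaluation "
            f"(minimum {MIN_DUPLEX_LENGTH})"
        )
    return seq


def _sum_energies(seq: str, table: NNTable) -> tuple[float, float]:
    dh, ds = 0.0, 0.0
    for i in range(len(seq) - 1):
        h, s = table.wc_step(seq[i : i + 2])
        dh += h
        ds += s
    for terminal in (seq[0], seq[-1]):
        h, s = table.initiation[terminal]
        dh += h
        ds += s
    return dh, ds


def duplex_energies(sequence: str, table: NNTable | None = None) -> ThermoResult:
    """Thermodynamics of the perfect duplex of ``sequence`` with its complement.

    Returns summed propagation energies plus initiation terms at the 1 M
    reference state; ``dG37 = dH - 310.15*dS/1000``. ``tm`` is left unset --
    use :func:`melting_temperature` for the concentration- and
    buffer-dependent quantity.
    """
    seq = _clean_sequence(sequence)
    table = table or load_nn_table()
    dh, ds = _sum_energies(seq, table)
    return ThermoResult(dh=dh, ds=ds, dg37=dh - T37_KELVIN * ds / 1000.0)


def _salt_corrected_entropy(ds: float, n_bases: int, monovalent_mm: float) -> float:
    return ds + 0.368 * (n_bases - 1) * math.log(monovalent_mm / 1000.0)


def _owczarzy_magnesium_tm(tm_1m: float, seq: str, buffer: Buffer) -> float:
    """Owczarzy (2008) inverse-Tm correction for Mg2+/monovalent mixtures.

    ``tm_1m`` is the Kelvin melting temperature at the 1 M reference state.
    The ratio sqrt([Mg])/[mono] selects the regime: below 0.22 monovalent
    ions dominate (Owczarzy 2004 equation); between 0.22 and 6 the magnesium
    equation with monovalent-modified coefficients a, d, g applies; above 6
    magnesium alone governs.
    """
    mg = buffer.magnesium / 1000.0
    mono = buffer.monovalent / 1000.0
    f_gc = (seq.count("G") + seq.count("C")) / len(seq)
    ratio = math.sqrt(mg) / mono
    if ratio < 0.22:
        ln_m = math.log(mono)
        inv = 1.0 / tm_1m + (4.29 * f_gc - 3.95) * 1e-5 * ln_m + 9.40e-6 * ln_m**2
        return 1.0 / inv

    a, b, c, d = 3.92e-5, -9.11e-6, 6.26e-5, 1.42e-5
    e, f, g = -4.82e-4, 5.25e-4, 8.31e-5
    if ratio < 6.0:
        ln_m = math.log(mono)
        a *= 0.843 - 0.352 * math.sqrt(mono) * ln_m
        d *= 1.279 - 4.03e-3 * ln_m - 8.03e-3 * ln_m**2
        g *= 0.486 - 0.258 * ln_m + 5.25e-3 * ln_m**3
    ln_mg = math.log(mg)
    n_bp = len(seq)
    inv = (
        1.0 / tm_1m
        + a
        + b * ln_mg
        + f_gc * (c + d * ln_mg)
        + (1.0 / (2.0 * (n_bp - 1))) * (e + f * ln_mg + g * ln_mg**2)
    )
    return 1.0 / inv


def melting_temperature(oligo: Oligo, buffer: Buffer = PCR_BUFFER, table: NNTable | None = None) -> float:
    """Two-state melting temperature (deg C) of an oligo against its complement.

    ``Tm = dH*1000 / (dS' + R*ln(CT/4)) - 273.15`` with the monovalent
    entropic correction applied to dS when the buffer has no magnesium, and
    the Owczarzy (2008) correction applied on top of the 1 M Tm otherwise.
    """
    if oligo.concentration <= 0:
        raise ValueError(f"oligo concentration must be > 0 nM, got {oligo.concentration}")
    seq = _clean_sequence(oligo.sequence)
    table = table or load_nn_table()
    dh, ds = _sum_energies(seq, table)
    ct = oligo.concentration * 1e-9
    ln_ct = GAS_CONSTANT * math.log(ct / 4.0)
    if buffer.magnesium > 0:
        tm_1m = dh * 1000.0 / (ds + ln_ct)
        return _owczarzy_magnesium_tm(tm_1m, seq, buffer) - 273.15
    ds_corr = _salt_corrected_entropy(ds, len(seq), buffer.monovalent)
    return dh * 1000.0 / (ds_corr + ln_ct) - 273.15


def _duplex_dg37_with_mismatch(seq: str, position: int, template_base: str, table: NNTable) -> float:
    """dG37 of ``seq`` against a complement whose base opposite ``position``
    (0-based index into seq) is ``template_base`` (may be non-complementary)."""
    bottom = [_COMPLEMENT[c] for c in seq]
    bottom[position] = template_base
    dh, ds = 0.0, 0.0
    for i in range(len(seq) - 1):
        top = seq[i : i + 2]
        bot = bottom[i] + bottom[i + 1]
        if bot == _COMPLEMENT[top[0]] + _COMPLEMENT[top[1]]:
            h, s = table.wc_step(top)
        else:
            h, s = table.mismatch_step(top, bot)
        dh += h
        ds += s
    for terminal in (seq[0], seq[-1]):
        h, s = table.initiation[terminal]
        dh += h
        ds += s
    return dh - T37_KELVIN * ds / 1000.0


MAX_MISMATCH_OFFSET = 12  # the 3'-proximal window critical for primer binding


def mismatch_ddg(
    gene_part: str,
    position_from_3prime: int,
    off_allele_base: str,
    table: NNTable | None = None,
) -> float:
    """Destabilization (kcal/mol) of the primer/template duplex when the
    template carries the alternative allele.

    ``position_from_3prime`` counts from the primer 3' terminus (1 = terminal,
    2 = penultimate) and must lie in the 3'-proximal 1..12 window.
    ``off_allele_base`` is the alternative allele read on the primer strand;
    the template then presents its complement, creating a
    ``primer_base . complement(off_allele)`` mismatch. Positive values mean
    the off-allele duplex is less stable (better allele discrimination).
    """
    seq = _clean_sequence(gene_part)
    if not 1 <= position_from_3prime <= MAX_MISMATCH_OFFSET:
        raise ValueError(
            f"position_from_3prime must be in 1..{MAX_MISMATCH_OFFSET}, got {position_from_3prime}"
        )
    if position_from_3prime > len(seq) - 1:
        raise ValueError("mismatch position has no 5' neighbor within the primer")
    off = off_allele_base.upper()
    if off not in "ACGT":
        raise ValueError(f"off-allele base must be one of ACGT, got {off_allele_base!r}")
    table = table or load_nn_table()
    idx = len(seq) - position_from_3prime
    primer_base = seq[idx]
    if off == primer_base:
        return 0.0
    matched = duplex_energies(seq, table).dg37
    mismatched = _duplex_dg37_with_mismatch(seq, idx, _COMPLEMENT[off], table)
    return mismatched - matched
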