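"""6-bp barcode catalog: linguistic complexity ranking and set selection.

Each fluorophore-bearing universal probe is distinguished by a 6-bp barcode
appended to the shared 13-bp tag. Barcodes are ranked by linguistic sequence
complexity (LC) -- the product over word sizes of the observed-to-maximal
subword vocabulary ratio -- and sets of 2-4 barcodes are chosen so that every
pair differs at >= 4 of the 6 positions (robust optical/enzymatic
discrimination) while the full 19-mer probes keep closely matched melting
temperatures.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from functools import lru_cache
from itertools import product

from .thermo import Buffer, Oligo, PCR_BUFFER, melting_temperature

__all__ = [
    "Barcode",
    "BarcodeCatalog",
    "NoSolutionError",
    "linguistic_complexity",
    "build_catalog",
    "hamming",
    "select_barcode_set",
]

BARCODE_LENGTH = 6
DEFAULT_MIN_HAMMING = 4
DEFAULT_MAX_TM_RANGE = 1.5  # deg C, matches the spread of the validated probe set
DEFAULT_PROBE_CONC_NM = 300.0


class NoSolutionError(RuntimeError):
    """No barcode set satisfies the requested constraints."""


@dataclass(frozen=True)
class Barcode:
    sequence: str
    lc: float


@dataclass(frozen=True)
class BarcodeCatalog:
    """Barcodes ordered by descending LC, ties broken lexicographically."""

    entries: tuple[Barcode, ...]

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def sequences(self) -> list[str]:
        return [b.sequence for b in self.entries]


def _lc_fraction(kmer: str) -> Fraction:
    length = len(kmer)
    score = Fraction(1)
    for k in range(1, length + 1):
        observed = len({kmer[i : i + k] for i in range(length - k + 1)})
        score *= Fraction(observed, min(4**k, length - k + 1))
    return score


def linguistic_complexity(kmer: str) -> float:
    """Linguistic complexity of a DNA word, in (0, 1].

    ``LC = prod_{k=1..L} U_k`` with ``U_k`` the number of distinct k-mers
    observed divided by the maximum achievable, ``min(4^k, L-k+1)``. LC is 1
    exactly when every subword vocabulary is saturated.
    """
    seq = kmer.upper()
    if not seq:
        raise ValueError("empty sequence")
    bad = sorted({c for c in seq if c not in "ACGT"})
    if bad:
        raise ValueError(f"sequence contains non-ACGT characters: {bad!r}")
    return float(_lc_fraction(seq))


@lru_cache(maxsize=None)
def _ranked_hexamers() -> tuple[tuple[str, Fraction], ...]:
    scored = [("".join(p), _lc_fraction("".join(p))) for p in product("ACGT", repeat=BARCODE_LENGTH)]
    scored.sort(key=lambda item: (-item[1], item[0]))
    return tuple(scored)


def build_catalog(mode: str = "top") -> BarcodeCatalog:
    """Enumerate and rank all 4^6 = 4,096 hexamer barcodes.

    ``mode="all"`` returns the complete ranked catalog; ``mode="top"`` keeps
    only the barcodes attaining the maximal LC score (for hexamers these are
    exactly the words with all four bases present and all five dinucleotides
    distinct).
    """
    if mode not in ("top", "all"):
        raise ValueError(f"mode must be 'top' or 'all', got {mode!r}")
    ranked = _ranked_hexamers()
    if mode == "top":
        best = ranked[0][1]
        ranked = tuple(item for item in ranked if item[1] == best)
    return BarcodeCatalog(tuple(Barcode(seq, float(lc)) for seq, lc in ranked))


def hamming(a: str, b: str) -> int:
    """Number of positions at which two equal-length words differ."""
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    return sum(x != y for x, y in zip(a.upper(), b.upper()))


def _has_long_run(seq: str, max_run: int = 4) -> bool:
    run, prev = 0, ""
    for c in seq:
        run = run + 1 if c == prev else 1
        prev = c
        if run > max_run:
            return True
    return False


def select_barcode_set(
    catalog: BarcodeCatalog,
    m: int,
    tag: str,
    buffer: Buffer = PCR_BUFFER,
    min_hamming: int = DEFAULT_MIN_HAMMING,
    max_tm_range: float = DEFAULT_MAX_TM_RANGE,
    probe_concentration: float = DEFAULT_PROBE_CONC_NM,
) -> list[Barcode]:
    """Choose ``m`` barcodes with pairwise Hamming distance >= ``min_hamming``
    whose full 19-mer (tag+barcode) melting temperatures span <= ``max_tm_range``.

    Deterministic: candidates are sorted by full-probe Tm; a window of width
    ``max_tm_range`` slides over that ordering and within each window a
    Hamming-feasible set is grown greedily in lexicographic order. Barcodes
    creating a homopolymer run longer than 4 across the tag-barcode junction
    are screened out. Raises :class:`NoSolutionError` naming the binding
    constraint when the search fails.
    """
    if not 2 <= m <= 4:
        raise ValueError(f"m must be in 2..4, got {m}")
    if len(catalog) == 0:
        raise NoSolutionError("empty catalog")
    if min_hamming > BARCODE_LENGTH:
        raise NoSolutionError(
            f"min_hamming={min_hamming} exceeds the barcode length {BARCODE_LENGTH}: "
            "no two hexamers can differ at more positions than they have"
        )

    candidates = [b for b in catalog if not _has_long_run(tag.upper() + b.sequence)]
    if len(candidates) < m:
        raise NoSolutionError("tag-junction homopolymer screening left fewer candidates than requested")
    with_tm = sorted(
        (
            (melting_temperature(Oligo(tag + b.sequence, probe_concentration), buffer), b)
            for b in candidates
        ),
        key=lambda item: (item[0], item[1].sequence),
    )
    for start in range(len(with_tm)):
        tm_low = with_tm[start][0]
        window = [b for tm, b in with_tm[start:] if tm - tm_low <= max_tm_range]
        if len(window) < m:
            continue
        chosen: list[Barcode] = []
        for b in sorted(window, key=lambda x: x.sequence):
            if all(hamming(b.sequence, c.sequence) >= min_hamming for c in chosen):
                chosen.append(b)
                if len(chosen) == m:
                    return chosen
    raise NoSolutionError(
        f"no set of {m} barcodes with pairwise Hamming >= {min_hamming} fits inside a "
        f"{max_tm_range} degC probe-Tm window; the Tm-range constraint is binding"
    )
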