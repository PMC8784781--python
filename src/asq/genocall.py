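"""Genotype calling from end-point fluorescence plates or amplification curves.

A bi-allelic end-point plate carries two dye channels per well (e.g. FAM for
allele 1 and HEX for allele 2). Calling proceeds in three steps: subtract the
mean no-template-control (NTC) signal per dye, compute the allele-ratio
statistic ``theta = dye1 / (dye1 + dye2)`` on the normalized intensities, and
classify wells either by fixed theta thresholds or by k-means clustering of
the two-dye scatter. Wells whose total background-subtracted signal does not
clear a floor proportional to the NTC noise are reported as ``no_call``
rather than guessed.

Real-time curves are reduced to end points by removing a linear baseline
fitted on the early cycles and averaging the final cycles; the same caller
then applies, so allele discrimination can equally be computed at any chosen
read cycle.

The plate and curve simulators generate the cluster geometry such data shows
in practice -- homozygote clusters on each dye axis, heterozygotes on the
diagonal, NTCs at the origin, and sigmoid amplification curves whose signal
rises after roughly 20-25 cycles -- with known truth labels for scoring.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

__all__ = [
    "PlateLayout",
    "EndpointPlate",
    "CurveSet",
    "GenotypeCall",
    "read_endpoint",
    "write_endpoint",
    "normalize",
    "call_genotypes",
    "endpoint_from_curves",
    "simulate_plate",
    "simulate_curves",
    "calls_to_frame",
    "plot_plate",
]

CLASSES = ("allele1", "allele2", "heterozygous", "ntc", "no_call")
DEFAULT_THETA_LOW = 0.35
DEFAULT_THETA_HIGH = 0.65
DEFAULT_SIGNAL_K = 5.0  # signal floor, in summed per-dye NTC standard deviations


@dataclass(frozen=True)
class PlateLayout:
    """Well -> sample label; NTC wells are flagged separately."""

    samples: dict[str, str]
    ntc_wells: frozenset[str] = frozenset()

    @classmethod
    def from_samples(cls, labels: dict[str, str], ntc_label: str = "NTC") -> "PlateLayout":
        ntc = frozenset(w for w, s in labels.items() if s.upper() == ntc_label)
        return cls(samples=dict(labels), ntc_wells=ntc)

    def is_ntc(self, well: str) -> bool:
        return well in self.ntc_wells


@dataclass
class EndpointPlate:
    """Per-well, per-dye relative fluorescence units (RFU)."""

    wells: dict[str, dict[str, float]]
    ntc_sd: dict[str, float] = field(default_factory=dict)  # set by normalize()

    @property
    def dyes(self) -> tuple[str, ...]:
        first = next(iter(self.wells.values()))
        return tuple(sorted(first))

    def __post_init__(self) -> None:
        dye_sets = {frozenset(v) for v in self.wells.values()}
        if len(dye_sets) > 1:
            raise ValueError("all wells must share the same dye set")
        for well, channels in self.wells.items():
            for dye, rfu in channels.items():
                if rfu < 0:
                    raise ValueError(f"negative RFU {rfu} in well {well}, dye {dye}")


@dataclass
class CurveSet:
    """Per-well, per-dye fluorescence trace over cycles 1..N."""

    curves: dict[str, dict[str, np.ndarray]]

    @property
    def n_cycles(self) -> int:
        first = next(iter(self.curves.values()))
        return len(next(iter(first.values())))

    @property
    def dyes(self) -> tuple[str, ...]:
        first = next(iter(self.curves.values()))
        return tuple(sorted(first))

    def __post_init__(self) -> None:
        lengths = {
            len(trace) for well in self.curves.values() for trace in well.values()
        }
        if len(lengths) > 1:
            raise ValueError(f"unequal cycle counts across wells: {sorted(lengths)}")


@dataclass(frozen=True)
class GenotypeCall:
    well: str
    sample: str
    call: str  # one of CLASSES
    theta: float | None
    signal: float
    confidence: str


def read_endpoint(csv_text: str, layout: PlateLayout | None = None) -> EndpointPlate:
    """Parse an end-point plate from CSV.

    Two dialects are accepted: long (columns Well, Dye, RFU) and wide
    (column Well plus one column per dye). Duplicate (well, dye) rows and
    negative RFU are parse errors carrying the offending row.
    """
    frame = pd.read_csv(io.StringIO(csv_text))
    frame.columns = [str(c).strip() for c in frame.columns]
    cols = {c.lower(): c for c in frame.columns}
    if "well" not in cols:
        raise ValueError(f"plate CSV needs a Well column, got {list(frame.columns)}")
    wells: dict[str, dict[str, float]] = {}
    if "dye" in cols and "rfu" in cols:  # long dialect
        triples = zip(frame[cols["well"]], frame[cols["dye"]], frame[cols["rfu"]])
        for row_number, (well, dye, rfu) in enumerate(triples, start=2):
            well, dye, rfu = str(well), str(dye), float(rfu)
            if rfu < 0:
                raise ValueError(f"row {row_number}: negative RFU {rfu}")
            channels = wells.setdefault(well, {})
            if dye in channels:
                raise ValueError(f"row {row_number}: duplicate entry for well {well}, dye {dye}")
            channels[dye] = rfu
    else:  # wide dialect
        dye_cols = [c for c in frame.columns if c.lower() != "well"]
        if not dye_cols:
            raise ValueError("wide-format plate CSV needs one column per dye")
        if frame[cols["well"]].duplicated().any():
            dup = frame[cols["well"]][frame[cols["well"]].duplicated()].iloc[0]
            raise ValueError(f"duplicate well row: {dup}")
        for _, row in frame.iterrows():
            well = str(row[cols["well"]])
            channels = {}
            for dye in dye_cols:
                rfu = float(row[dye])
                if rfu < 0:
                    raise ValueError(f"well {well}: negative RFU {rfu} for dye {dye}")
                channels[dye] = rfu
            wells[well] = channels
    return EndpointPlate(wells=wells)


def write_endpoint(plate: EndpointPlate, dialect: str = "long") -> str:
    """Serialize a plate back to CSV (inverse of :func:`read_endpoint`)."""
    if dialect == "long":
        rows = [
            {"Well": w, "Dye": d, "RFU": rfu}
            for w, channels in plate.wells.items()
            for d, rfu in sorted(channels.items())
        ]
        return pd.DataFrame(rows).to_csv(index=False)
    if dialect == "wide":
        rows = [{"Well": w, **channels} for w, channels in plate.wells.items()]
        return pd.DataFrame(rows).to_csv(index=False)
    raise ValueError(f"unknown dialect {dialect!r}")


def normalize(plate: EndpointPlate, layout: PlateLayout) -> EndpointPlate:
    """Subtract the per-dye mean NTC signal, clamping at zero.

    The per-dye NTC standard deviation is attached to the result for use as
    the calling noise floor.
    """
    ntc_wells = [w for w in plate.wells if layout.is_ntc(w)]
    if not ntc_wells:
        raise ValueError("NTC normalization requires at least one NTC well in the layout")
    dyes = plate.dyes
    means = {
        d: float(np.mean([plate.wells[w][d] for w in ntc_wells])) for d in dyes
    }
    sds = {d: float(np.std([plate.wells[w][d] for w in ntc_wells], ddof=0)) for d in dyes}
    normalized = {
        well: {d: max(rfu - means[d], 0.0) for d, rfu in channels.items()}
        for well, channels in plate.wells.items()
    }
    return EndpointPlate(wells=normalized, ntc_sd=sds)


def _grade(theta: float, t_lo: float, t_hi: float) -> str:
    margin = min(abs(theta - t_lo), abs(theta - t_hi))
    return "high" if margin >= 0.15 else "low"


def call_genotypes(
    plate: EndpointPlate,
    layout: PlateLayout,
    mode: str = "threshold",
    theta_low: float = DEFAULT_THETA_LOW,
    theta_high: float = DEFAULT_THETA_HIGH,
    signal_k: float = DEFAULT_SIGNAL_K,
    n_clusters: int = 3,
    seed: int = 0,
) -> list[GenotypeCall]:
    """Call genotypes on a normalized bi-allelic plate.

    ``theta = dye1/(dye1+dye2)`` with dyes taken in sorted name order (FAM
    before HEX). Threshold mode: allele1 at ``theta >= theta_high``, allele2
    at ``theta <= theta_low``, heterozygous between, all conditioned on total
    signal clearing ``signal_k`` times the summed per-dye NTC standard
    deviation, otherwise ``no_call``. Cluster mode k-means the two-dye
    scatter of callable wells into ``n_clusters`` (3 with heterozygotes, 2
    for pure-line panels) and labels clusters by centroid theta, falling back
    to threshold mode when clustering degenerates. NTC wells are always
    class ``ntc``.
    """
    dyes = plate.dyes
    if len(dyes) != 2:
        raise ValueError(
            f"bi-allelic calling requires exactly 2 dyes, got {len(dyes)}: {dyes} "
            "(3-4 dye multiplex calling is not supported)"
        )
    if mode not in ("threshold", "cluster"):
        raise ValueError(f"mode must be 'threshold' or 'cluster', got {mode!r}")
    d1, d2 = dyes
    floor = signal_k * sum(plate.ntc_sd.get(d, 0.0) for d in dyes)

    def base_call(well: str) -> GenotypeCall:
        sample = layout.samples.get(well, well)
        x, y = plate.wells[well][d1], plate.wells[well][d2]
        signal = x + y
        if layout.is_ntc(well):
            return GenotypeCall(well, sample, "ntc", None, signal, "high")
        if signal < floor or signal <= 0:
            return GenotypeCall(well, sample, "no_call", None, signal, "low")
        theta = x / signal
        if theta >= theta_high:
            cls = "allele1"
        elif theta <= theta_low:
            cls = "allele2"
        else:
            cls = "heterozygous"
        return GenotypeCall(well, sample, cls, theta, signal, _grade(theta, theta_low, theta_high))

    calls = {w: base_call(w) for w in plate.wells}
    if mode == "cluster":
        callable_wells = [
            w for w, c in calls.items() if c.call not in ("ntc", "no_call")
        ]
        if len(callable_wells) >= n_clusters:
            points = np.array(
                [[plate.wells[w][d1], plate.wells[w][d2]] for w in callable_wells]
            )
            km = KMeans(n_clusters=n_clusters, n_init=10, random_state=seed).fit(points)
            centroids = km.cluster_centers_
            sizes = np.bincount(km.labels_, minlength=n_clusters)
            theta_c = centroids[:, 0] / np.maximum(centroids.sum(axis=1), 1e-12)
            order = np.argsort(-theta_c)
            if n_clusters == 3:
                labels_for = {order[0]: "allele1", order[1]: "heterozygous", order[2]: "allele2"}
            else:
                labels_for = {order[0]: "allele1", order[-1]: "allele2"}
            degenerate = (sizes == 0).any() or len(np.unique(np.round(theta_c, 6))) < n_clusters
            if not degenerate:
                for w, k in zip(callable_wells, km.labels_):
                    old = calls[w]
                    calls[w] = GenotypeCall(
                        w, old.sample, labels_for[k], old.theta, old.signal, old.confidence
                    )
            # else: keep threshold calls (documented fallback)
    return [calls[w] for w in sorted(calls)]


def endpoint_from_curves(
    curves: CurveSet,
    baseline_window: tuple[int, int] = (3, 15),
    summary_cycles: int = 3,
    summary_end: int | None = None,
) -> EndpointPlate:
    """Collapse amplification curves to an end-point plate.

    Per well and dye, a straight line fitted to the baseline window (cycle
    numbers, 1-based, inclusive) is subtracted and the last ``summary_cycles``
    cycles up to ``summary_end`` (default: the final cycle) are averaged;
    negative end points clamp to zero. Choosing an earlier ``summary_end``
    reads the plate "at any cycle".
    """
    n = curves.n_cycles
    end = summary_end if summary_end is not None else n
    if not 1 <= baseline_window[0] < baseline_window[1] <= n:
        raise ValueError(f"baseline window {baseline_window} outside 1..{n}")
    if end - summary_cycles + 1 <= baseline_window[1]:
        raise ValueError("summary window overlaps the baseline window")
    if end > n:
        raise ValueError(f"summary end {end} beyond the {n}-cycle run")
    cycles = np.arange(1, n + 1, dtype=float)
    b0, b1 = baseline_window
    base_mask = (cycles >= b0) & (cycles <= b1)
    wells: dict[str, dict[str, float]] = {}
    for well, channels in curves.curves.items():
        out = {}
        for dye, trace in channels.items():
            trace = np.asarray(trace, dtype=float)
            slope, intercept = np.polyfit(cycles[base_mask], trace[base_mask], 1)
            corrected = trace - (intercept + slope * cycles)
            endpoint = float(np.mean(corrected[end - summary_cycles : end]))
            out[dye] = max(endpoint, 0.0)
        wells[well] = out
    return EndpointPlate(wells=wells)


# --- simulators ----------------------------------------------------------

DEFAULT_CENTROIDS = {
    "allele1": (9000.0, 500.0),
    "allele2": (500.0, 9000.0),
    "heterozygous": (4500.0, 4500.0),
    "ntc": (0.0, 0.0),
}
DEFAULT_PROPORTIONS = {"allele1": 0.3, "allele2": 0.3, "heterozygous": 0.3, "ntc": 0.1}
DEFAULT_BASELINE_RFU = 300.0
DEFAULT_NOISE_SD = 400.0
DEFAULT_NTC_SD = 50.0


def _well_names(n: int) -> list[str]:
    names = [f"{row}{col}" for row in "ABCDEFGHIJKLMNOP" for col in range(1, 25)]
    if n > len(names):
        raise ValueError(f"at most {len(names)} wells supported, requested {n}")
    return names[:n]


def simulate_plate(
    n_wells: int = 96,
    proportions: dict[str, float] | None = None,
    centroids: dict[str, tuple[float, float]] | None = None,
    noise_sd: float = DEFAULT_NOISE_SD,
    ntc_sd: float = DEFAULT_NTC_SD,
    baseline: float = DEFAULT_BASELINE_RFU,
    dyes: tuple[str, str] = ("FAM", "HEX"),
    seed: int = 0,
) -> tuple[EndpointPlate, PlateLayout, dict[str, str]]:
    """Simulate a raw (un-normalized) bi-allelic end-point plate.

    Wells are assigned classes by rounding the requested proportions to
    counts; intensities are bivariate normal draws around
    ``baseline + centroid`` (NTC wells scatter with ``ntc_sd`` around the
    baseline alone), clamped at zero. Returns the plate, a layout flagging
    the NTC wells, and the truth labels. Reproducible for a fixed seed.
    """
    if noise_sd <= 0 or ntc_sd <= 0:
        raise ValueError("noise SDs must be > 0")
    if n_wells <= 0:
        raise ValueError("n_wells must be > 0")
    proportions = proportions or dict(DEFAULT_PROPORTIONS)
    centroids = centroids or {k: DEFAULT_CENTROIDS[k] for k in proportions}
    if any(p < 0 for p in proportions.values()) or sum(proportions.values()) <= 0:
        raise ValueError(f"invalid class proportions {proportions}")
    rng = np.random.default_rng(seed)
    classes = sorted(proportions)
    total = sum(proportions.values())
    counts = {c: int(round(proportions[c] / total * n_wells)) for c in classes}
    # fix rounding drift on the largest class
    drift = n_wells - sum(counts.values())
    counts[max(classes, key=lambda c: counts[c])] += drift
    labels: list[str] = [c for c in classes for _ in range(counts[c])]
    rng.shuffle(labels)
    names = _well_names(n_wells)
    wells, truth, sample_labels = {}, {}, {}
    for well, cls in zip(names, labels):
        sd = ntc_sd if cls == "ntc" else noise_sd
        cx, cy = centroids.get(cls, (0.0, 0.0))
        x = max(baseline + cx + rng.normal(0, sd), 0.0)
        y = max(baseline + cy + rng.normal(0, sd), 0.0)
        wells[well] = {dyes[0]: x, dyes[1]: y}
        truth[well] = cls
        sample_labels[well] = "NTC" if cls == "ntc" else f"S{well}"
    layout = PlateLayout.from_samples(sample_labels)
    return EndpointPlate(wells=wells), layout, truth


def simulate_curves(
    n_wells: int = 24,
    cq_by_class: dict[str, float] | None = None,
    plateau: float = 9000.0,
    slope: float = 1.5,
    noise_sd: float = 50.0,
    baseline: float = DEFAULT_BASELINE_RFU,
    n_cycles: int = 40,
    off_dye_fraction: float = 0.03,
    proportions: dict[str, float] | None = None,
    dyes: tuple[str, str] = ("FAM", "HEX"),
    seed: int = 0,
) -> tuple[CurveSet, PlateLayout, dict[str, str]]:
    """Simulate amplification curves as 4-parameter logistics plus noise.

    Per class, the on-allele dye follows
    ``baseline + plateau / (1 + exp(-(cycle - cq)/slope))`` (both dyes at
    half plateau for heterozygotes), the off dye stays at baseline times a
    small bleed-through fraction, and Gaussian noise is added everywhere.
    Default inflection points sit at cycles 24 (FAM) and 23 (HEX), so the
    fluorescence rise is registered after the first ~20-25 cycles.
    """
    if noise_sd <= 0:
        raise ValueError("noise SD must be > 0")
    if n_cycles < 30:
        raise ValueError(f"need >= 30 cycles for a usable end point, got {n_cycles}")
    cq_by_class = cq_by_class or {"allele1": 24.0, "allele2": 23.0, "heterozygous": 24.0}
    proportions = proportions or {"allele1": 0.375, "allele2": 0.375, "heterozygous": 0.125, "ntc": 0.125}
    rng = np.random.default_rng(seed)
    classes = sorted(proportions)
    total = sum(proportions.values())
    counts = {c: int(round(proportions[c] / total * n_wells)) for c in classes}
    counts[max(classes, key=lambda c: counts[c])] += n_wells - sum(counts.values())
    labels = [c for c in classes for _ in range(counts[c])]
    rng.shuffle(labels)
    cycles = np.arange(1, n_cycles + 1, dtype=float)

    def logistic(cq: float, amp: float) -> np.ndarray:
        return amp / (1.0 + np.exp(-(cycles - cq) / slope))

    curves, truth, sample_labels = {}, {}, {}
    for well, cls in zip(_well_names(n_wells), labels):
        amp1 = amp2 = 0.0
        if cls == "allele1":
            amp1 = plateau
        elif cls == "allele2":
            amp2 = plateau
        elif cls == "heterozygous":
            amp1 = amp2 = plateau / 2.0
        cq1 = cq_by_class.get("allele1", 24.0) if cls != "heterozygous" else cq_by_class["heterozygous"]
        cq2 = cq_by_class.get("allele2", 23.0) if cls != "heterozygous" else cq_by_class["heterozygous"]
        trace1 = baseline + logistic(cq1, amp1) + amp2 * off_dye_fraction + rng.normal(0, noise_sd, n_cycles)
        trace2 = baseline + logistic(cq2, amp2) + amp1 * off_dye_fraction + rng.normal(0, noise_sd, n_cycles)
        curves[well] = {dyes[0]: np.maximum(trace1, 0.0), dyes[1]: np.maximum(trace2, 0.0)}
        truth[well] = cls
        sample_labels[well] = "NTC" if cls == "ntc" else f"S{well}"
    layout = PlateLayout.from_samples(sample_labels)
    return CurveSet(curves=curves), layout, truth


def calls_to_frame(calls: list[GenotypeCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "well": c.well,
                "sample": c.sample,
                "call": c.call,
                "theta": c.theta,
                "signal": c.signal,
                "confidence": c.confidence,
            }
            for c in calls
        ]
    )


def plot_plate(plate: EndpointPlate, calls: list[GenotypeCall], path: str) -> None:
    """Two-dye scatter of a normalized plate, colored by call (NTC black)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    colors = {
        "allele1": "tab:red",
        "allele2": "tab:blue",
        "heterozygous": "tab:green",
        "ntc": "black",
        "no_call": "tab:gray",
    }
    d1, d2 = plate.dyes
    fig, ax = plt.subplots(figsize=(5, 5))
    by_call: dict[str, list[tuple[float, float]]] = {}
    for c in calls:
        by_call.setdefault(c.call, []).append(
            (plate.wells[c.well][d1], plate.wells[c.well][d2])
        )
    for cls, pts in sorted(by_call.items()):
        xs, ys = zip(*pts)
        ax.scatter(xs, ys, label=cls, c=colors.get(cls, "tab:purple"),
                   marker="^" if cls == "heterozygous" else "o")
    ax.set_xlabel(f"{d1} (normalized RFU)")
    ax.set_ylabel(f"{d2} (normalized RFU)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
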