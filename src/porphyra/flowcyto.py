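"""Flow-cytometry processing: gating, doublet removal, peak calling, genome size.

The workflow mirrors routine propidium-iodide flow cytometry with an internal
reference standard co-chopped with the sample:

1. a region of interest in the FL x SSC cytogram isolates intact nuclei
   (:func:`gate_events`);
2. aggregates are removed in the FL vs pulse-height cytogram
   (:func:`filter_doublets`);
3. nuclei subpopulations are called on the fluorescence pulse-integral (FL)
   axis as a 1-D Gaussian mixture with BIC model selection
   (:func:`call_peaks`);
4. the peak of the internal standard (known 2C DNA content, acquired at a
   fixed target channel) anchors the fluorescence-to-picogram conversion
   (:func:`identify_standard`, :func:`estimate_genome_size`);
5. minor peaks at twice a major peak's fluorescence are G2-phase nuclei and
   are excluded from genome-size reporting (:func:`label_g2`);
6. quality control on peak CVs and replicate agreement (:func:`qc_sample`).

Event tables are plain pandas DataFrames with columns ``fl``, ``pulse_height``,
``ssc``, ``fsc``, ``time`` on a linear 0-1023 FL channel scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture

__all__ = [
    "EventTable",
    "FLHistogram",
    "NucleiPeak",
    "StandardRef",
    "GenomeSizeCall",
    "GatingError",
    "NoPeaksError",
    "StandardNotFoundError",
    "read_event_csv",
    "read_histogram_csv",
    "gate_events",
    "filter_doublets",
    "build_histogram",
    "call_peaks",
    "call_peaks_events",
    "identify_standard",
    "estimate_genome_size",
    "label_g2",
    "qc_sample",
    "analyze_sample",
]

EVENT_COLUMNS = ("fl", "pulse_height", "ssc", "fsc", "time")

#: linear FL channel range of the acquisition
CHANNEL_MAX = 1023.0


class GatingError(ValueError):
    """Raised when a gate is degenerate or retains no events."""


class NoPeaksError(ValueError):
    """Raised when no nuclei peak can be called from the FL signal."""


class StandardNotFoundError(ValueError):
    """Raised when no peak lies near the expected standard channel."""


@dataclass
class EventTable:
    """Per-sample list-mode events (one row per detected particle)."""

    sample_id: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in EVENT_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"event table missing columns: {missing}")
        if len(self.data) < 1:
            raise ValueError("event table must contain at least one event")
        if (self.data["fl"] < 0).any():
            raise ValueError("fl must be non-negative")

    def __len__(self) -> int:
        return len(self.data)


@dataclass
class FLHistogram:
    """Pre-binned FL histogram (``len(counts) == len(bin_edges) - 1``)."""

    bin_edges: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.counts = np.asarray(self.counts)
        if len(self.counts) != len(self.bin_edges) - 1:
            raise ValueError("need len(counts) == len(bin_edges) - 1")
        if (np.diff(self.bin_edges) <= 0).any():
            raise ValueError("bin_edges must be strictly increasing")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class NucleiPeak:
    """One fitted nuclei subpopulation on the FL axis."""

    mean_fl: float
    cv: float  # percent, 100 * sigma / mean
    count: int
    proportion: float
    phase: str = "unknown"  # one of G1, G2, standard, unknown


@dataclass
class StandardRef:
    """Internal reference standard of known 2C DNA content."""

    name: str
    dna_2c: float  # picograms
    expected_channel: float = 720.0

    def __post_init__(self) -> None:
        if self.dna_2c <= 0:
            raise ValueError("dna_2c must be positive")


@dataclass
class GenomeSizeCall:
    """Genome sizes (pg) for the non-standard G1 peaks of one sample."""

    sample_id: str
    section_type: str
    sizes_pg: list[float]
    cvs: list[float]
    qc_pass: bool = True
    notes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.sizes_pg) != len(self.cvs):
            raise ValueError("sizes_pg and cvs must have equal length")
        if any(s <= 0 for s in self.sizes_pg):
            raise ValueError("genome sizes must be positive")


# ---------------------------------------------------------------------------
# I/O


def read_event_csv(path, sample_id: str | None = None) -> EventTable:
    """Read a CSV event table with columns fl, pulse_height, ssc, fsc, time."""
    df = pd.read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    sid = sample_id if sample_id is not None else str(path)
    return EventTable(sample_id=sid, data=df[list(EVENT_COLUMNS)].copy())


def read_histogram_csv(path) -> FLHistogram:
    """Read a two-column CSV histogram (bin_edge, count).

    The file holds one row per bin edge; the count column of the final edge
    must be empty or zero.
    """
    df = pd.read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    edges = df["bin_edge"].to_numpy(dtype=float)
    counts = df["count"].to_numpy(dtype=float)[:-1]
    return FLHistogram(bin_edges=edges, counts=counts.astype(int))


# ---------------------------------------------------------------------------
# Gating and doublet discrimination


def gate_events(
    events: EventTable,
    fl_range: tuple[float, float],
    ssc_range: tuple[float, float],
) -> EventTable:
    """Keep events inside a rectangular region of the FL x SSC cytogram."""
    lo_fl, hi_fl = fl_range
    lo_ssc, hi_ssc = ssc_range
    for v in (lo_fl, hi_fl, lo_ssc, hi_ssc):
        if not math.isfinite(v):
            raise GatingError("gate bounds must be finite")
    if hi_fl <= lo_fl or hi_ssc <= lo_ssc:
        raise GatingError("gate region has zero area")
    d = events.data
    mask = (
        (d["fl"] >= lo_fl)
        & (d["fl"] <= hi_fl)
        & (d["ssc"] >= lo_ssc)
        & (d["ssc"] <= hi_ssc)
    )
    if not mask.any():
        raise GatingError(
            f"gate retained no events in sample {events.sample_id}; "
            "region is probably mis-set"
        )
    return EventTable(events.sample_id, d[mask].reset_index(drop=True))


def filter_doublets(
    events: EventTable, max_ratio: float | None = None
) -> tuple[EventTable, float]:
    """Remove aggregates via the FL / pulse-height ratio.

    Singlet nuclei have FL roughly proportional to pulse height; a doublet
    carries twice the integral at an unchanged height, so its ratio is about
    double the singlet ratio.  Events with ``fl / pulse_height > max_ratio``
    are discarded.  When *max_ratio* is ``None`` an adaptive threshold of
    1.5x the median ratio is used.  Returns the filtered table and the
    removed fraction.
    """
    d = events.data
    if (d["pulse_height"] <= 0).any():
        raise ValueError("pulse_height must be positive for doublet filtering")
    ratio = d["fl"] / d["pulse_height"]
    if max_ratio is None:
        max_ratio = 1.5 * float(ratio.median())
    keep = ratio <= max_ratio
    removed_fraction = 1.0 - keep.mean()
    if not keep.any():
        raise ValueError(
            f"doublet filter removed every event in sample {events.sample_id}"
        )
    return EventTable(events.sample_id, d[keep].reset_index(drop=True)), float(
        removed_fraction
    )


def build_histogram(events: EventTable, n_bins: int = 512) -> FLHistogram:
    """Bin the FL channel of an event table into an :class:`FLHistogram`."""
    edges = np.linspace(0.0, CHANNEL_MAX, n_bins + 1)
    counts, _ = np.histogram(events.data["fl"].to_numpy(), bins=edges)
    return FLHistogram(bin_edges=edges, counts=counts)


# ---------------------------------------------------------------------------
# Peak calling


def _fit_best_gmm(values: np.ndarray, max_components: int) -> GaussianMixture:
    """BIC-selected 1-D Gaussian mixture with quantile-based initialisation.

    All initial parameters are supplied explicitly, so the fit is fully
    deterministic given the data.
    """
    x = values.reshape(-1, 1)
    spread = max(float(values.std()), 1e-3)
    best, best_bic = None, np.inf
    k_max = min(max_components, len(np.unique(values)))
    for k in range(1, k_max + 1):
        q = np.quantile(values, (np.arange(k) + 0.5) / k)
        sigma = max(spread / (2.0 * k), 1e-3)
        gm = GaussianMixture(
            n_components=k,
            covariance_type="full",
            weights_init=np.full(k, 1.0 / k),
            means_init=q.reshape(-1, 1),
            precisions_init=np.full((k, 1, 1), 1.0 / sigma**2),
            max_iter=500,
            reg_covar=1e-6,
            random_state=0,
        )
        gm.fit(x)
        bic = gm.bic(x)
        if bic < best_bic:
            best, best_bic = gm, bic
    assert best is not None
    return best


def _merge_close(
    comps: list[tuple[float, float, float]], min_separation: float
) -> list[tuple[float, float, float]]:
    """Merge mixture components whose mean ratio is below 1 + min_separation.

    Components are (mean, sd, weight); merging is moment-matched.
    """
    comps = sorted(comps)
    merged: list[tuple[float, float, float]] = []
    for mean, sd, w in comps:
        if merged and mean <= merged[-1][0] * (1.0 + min_separation):
            m0, s0, w0 = merged[-1]
            wt = w0 + w
            m = (w0 * m0 + w * mean) / wt
            var = (w0 * (s0**2 + (m0 - m) ** 2) + w * (sd**2 + (mean - m) ** 2)) / wt
            merged[-1] = (m, math.sqrt(var), wt)
        else:
            merged.append((mean, sd, w))
    return merged


def call_peaks(
    hist: FLHistogram,
    min_proportion: float = 0.02,
    min_separation: float = 0.10,
    max_components: int = 6,
    debris_cutoff: float = 20.0,
    max_peak_cv: float = 20.0,
    min_events: int = 500,
) -> list[NucleiPeak]:
    """Call nuclei peaks from a binned FL histogram.

    Bins below *debris_cutoff* (low-channel debris) are excluded before a
    Gaussian mixture with 1..*max_components* components is fitted and
    selected by BIC.  Components closer than *min_separation* in mean ratio
    are merged; components below *min_proportion* of gated events or broader
    than *max_peak_cv* percent CV are dropped.  Peaks are returned sorted by
    mean fluorescence with phase ``unknown``.
    """
    centers = 0.5 * (hist.bin_edges[:-1] + hist.bin_edges[1:])
    keep = centers >= debris_cutoff
    values = np.repeat(centers[keep], hist.counts[keep].astype(int))
    if len(values) < min_events:
        raise NoPeaksError(
            f"only {len(values)} events above debris cutoff "
            f"(minimum {min_events})"
        )
    return _call_from_values(
        values, min_proportion, min_separation, max_components, max_peak_cv
    )


def call_peaks_events(
    events: EventTable,
    min_proportion: float = 0.02,
    min_separation: float = 0.10,
    max_components: int = 6,
    debris_cutoff: float = 20.0,
    max_peak_cv: float = 20.0,
    min_events: int = 500,
) -> list[NucleiPeak]:
    """As :func:`call_peaks` but fitted directly on event FL values."""
    fl = events.data["fl"].to_numpy(dtype=float)
    values = fl[fl >= debris_cutoff]
    if len(values) < min_events:
        raise NoPeaksError(
            f"only {len(values)} events above debris cutoff "
            f"(minimum {min_events})"
        )
    return _call_from_values(
        values, min_proportion, min_separation, max_components, max_peak_cv
    )


def _call_from_values(
    values: np.ndarray,
    min_proportion: float,
    min_separation: float,
    max_components: int,
    max_peak_cv: float,
) -> list[NucleiPeak]:
    gm = _fit_best_gmm(values, max_components)
    # signal check: featureless (uniform) FL must not be reported as peaks
    n = len(values)
    span = float(values.max() - values.min())
    if span > 0:
        bic_uniform = 2.0 * n * math.log(span) + 2.0 * math.log(n)
        if gm.bic(values.reshape(-1, 1)) >= bic_uniform:
            raise NoPeaksError("no nuclei detected: FL signal is featureless")
    comps = [
        (float(m[0]), float(math.sqrt(c[0, 0])), float(w))
        for m, c, w in zip(gm.means_, gm.covariances_, gm.weights_)
    ]
    merged = _merge_close(comps, min_separation)
    peaks = []
    for mean, sd, w in merged:
        if mean <= 0:
            continue
        cv = 100.0 * sd / mean
        if w < min_proportion or cv > max_peak_cv:
            continue
        peaks.append(
            NucleiPeak(
                mean_fl=mean,
                cv=cv,
                count=int(round(w * n)),
                proportion=w,
                phase="unknown",
            )
        )
    if not peaks:
        raise NoPeaksError("no nuclei detected")
    peaks.sort(key=lambda p: p.mean_fl)
    return peaks


# ---------------------------------------------------------------------------
# Standard identification, genome size, G2 labelling, QC


def identify_standard(
    peaks: Sequence[NucleiPeak],
    std: StandardRef,
    tolerance: float = 0.15,
) -> tuple[NucleiPeak, list[NucleiPeak]]:
    """Split peaks into (standard peak, sample peaks).

    The standard is the peak nearest ``std.expected_channel`` provided its
    relative deviation is within *tolerance*.
    """
    if len(peaks) < 2:
        raise StandardNotFoundError(
            "need at least two peaks to separate standard from sample"
        )
    devs = [abs(p.mean_fl - std.expected_channel) / std.expected_channel for p in peaks]
    i = int(np.argmin(devs))
    if devs[i] > tolerance:
        raise StandardNotFoundError(
            f"standard not found: nearest peak at channel "
            f"{peaks[i].mean_fl:.1f} deviates {100 * devs[i]:.1f}% from "
            f"expected {std.expected_channel}"
        )
    standard = replace(peaks[i], phase="standard")
    sample = [p for j, p in enumerate(peaks) if j != i]
    return standard, sample


def estimate_genome_size(
    sample_peak: NucleiPeak, standard_peak: NucleiPeak, std: StandardRef
) -> float:
    """Genome size in pg: (sample mean FL / standard mean FL) x standard 2C."""
    if standard_peak.mean_fl <= 0 or sample_peak.mean_fl <= 0:
        raise ValueError("peak means must be positive")
    return sample_peak.mean_fl / standard_peak.mean_fl * std.dna_2c


def label_g2(
    peaks: Sequence[NucleiPeak],
    ratio_tol: float = 0.07,
    max_g2_proportion: float = 0.25,
) -> list[NucleiPeak]:
    """Label G2-phase peaks among sample peaks; everything else becomes G1.

    A peak is G2 when its mean is twice another peak's mean (within
    *ratio_tol* relative) AND its proportion is at most *max_g2_proportion*
    of that peak's proportion.  A 2x peak of comparable abundance is instead
    a distinct ploidy (mixoploid candidate) and stays G1.

    In multi-ploidy samples the two small G2 companions of adjacent G1 peaks
    can be fitted as a single component between their doubled channels; a
    minor peak inside ``[2 m_i, 2 m_j]`` (within *ratio_tol*) for adjacent
    peaks i, j whose proportion is at most *max_g2_proportion* of the
    smaller partner's is therefore also labelled G2.
    """
    means = [p.mean_fl for p in peaks]
    if means != sorted(means):
        raise ValueError("peaks must be sorted by mean_fl")
    out = []
    for j, p in enumerate(peaks):
        others = [q for i, q in enumerate(peaks) if i != j]
        is_g2 = any(
            abs(p.mean_fl / (2.0 * q.mean_fl) - 1.0) <= ratio_tol
            and p.proportion <= max_g2_proportion * q.proportion
            for q in others
        ) or any(
            2.0 * lo.mean_fl * (1.0 - ratio_tol)
            <= p.mean_fl
            <= 2.0 * hi.mean_fl * (1.0 + ratio_tol)
            and p.proportion
            <= max_g2_proportion * min(lo.proportion, hi.proportion)
            for lo, hi in zip(others, others[1:])
        )
        out.append(replace(p, phase="G2" if is_g2 else "G1"))
    return out


def qc_sample(
    call: GenomeSizeCall,
    max_cv: float = 5.0,
    replicate_sizes: Sequence[float] | None = None,
    max_replicate_cv: float = 6.0,
) -> GenomeSizeCall:
    """Quality control: peak CVs and (optionally) between-replicate CV.

    *replicate_sizes* are genome-size estimates of the same isolate from
    independent measurements; their CV (sd/mean, percent) must not exceed
    *max_replicate_cv*.
    """
    if not call.sizes_pg:
        raise ValueError("call carries no genome sizes")
    ok = all(cv <= max_cv for cv in call.cvs)
    notes = list(call.notes)
    if replicate_sizes is not None and len(replicate_sizes) >= 2:
        arr = np.asarray(replicate_sizes, dtype=float)
        rep_cv = 100.0 * arr.std(ddof=1) / arr.mean()
        notes.append(f"replicate_cv={rep_cv:.2f}%")
        ok = ok and rep_cv <= max_replicate_cv
    return replace(call, qc_pass=ok, notes=notes)


def analyze_sample(
    events: EventTable,
    std: StandardRef,
    section_type: str = "vegetative",
    fl_gate: tuple[float, float] = (1.0, CHANNEL_MAX),
    ssc_gate: tuple[float, float] = (-5.0, 10.0),
    doublet_max_ratio: float | None = None,
    standard_tolerance: float = 0.15,
    max_cv: float = 5.0,
    **peak_kwargs,
) -> tuple[list[NucleiPeak], GenomeSizeCall]:
    """Full single-sample chain: gate, de-doublet, call peaks, size G1 peaks.

    Returns all labelled peaks (standard included) and the
    :class:`GenomeSizeCall` built from the non-standard G1 peaks.
    """
    gated = gate_events(events, fl_gate, ssc_gate)
    singlets, _ = filter_doublets(gated, doublet_max_ratio)
    peaks = call_peaks_events(singlets, **peak_kwargs)
    standard, sample_peaks = identify_standard(peaks, std, standard_tolerance)
    labelled = label_g2(sample_peaks)
    g1 = [p for p in labelled if p.phase == "G1"]
    if not g1:
        raise NoPeaksError(f"no G1 sample peak in {events.sample_id}")
    sizes = [estimate_genome_size(p, standard, std) for p in g1]
    call = GenomeSizeCall(
        sample_id=events.sample_id,
        section_type=section_type,
        sizes_pg=sizes,
        cvs=[p.cv for p in g1],
    )
    call = qc_sample(call, max_cv=max_cv)
    return [standard] + labelled, call
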