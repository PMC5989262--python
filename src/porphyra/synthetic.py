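"""Ground-truthed synthetic cohorts: blades, genotypes, flow-cytometry events.

The generator encodes the life-history rules observed in *Porphyra*
gametophytes so that every upstream caller can be scored exactly:

- blades carry up to four sections (vegetative, zygotospores, female and male
  gametes); section ploidies follow the cytotype drawn for the blade;
- zygotospores double the highest vegetative ploidy (3x blades -> 6x,
  4x -> 8x, mixoploids -> double of the higher line);
- group-2 blades emit gametes of the blade ploidy and/or lower ploidies;
  multiploid (Mp) gamete sections carry {p, 2p, 3p} from spontaneous
  chromosome multiplication;
- mixoploid blades mix two vegetative cell lines (default 50/50);
- genotypes draw ploidy-many allele copies per locus i.i.d. from
  lineage-specific pools; only the distinct-allele phenotype is exposed and
  loci are masked at a configurable missing rate;
- flow samples are Gaussian FL peaks (one per section G1 ploidy, channel
  proportional to ploidy x the 0.1 pg 1x-equivalent), G2 companions at twice
  the channel, an internal standard at channel 720 (2C = 1.96 pg), and
  exponential low-channel debris.

:func:`study_cohort` builds the fixed design of the reference survey:
122 blades (47 *P. linearis*, 35 *P. umbilicalis*, 40 *P. dioica*) yielding
217 flow analyses, and 121 multilocus genotypes partitioned into 19
(species x ploidy-signature) groups, with the *P. linearis* lineage pools
constructed at the reported differentiation (G_ST 0.27 between the 3x and 4x
lineages, 0.17 between 3x and the 3x/4x mixoploids).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .flowcyto import EventTable, StandardRef
from .genotypes import LocusDef, PolyploidGenotype

__all__ = [
    "FlowParams",
    "SimConfig",
    "BladeTruth",
    "FlowSampleTruth",
    "Cohort",
    "default_loci",
    "simulate_lineages",
    "expected_gst",
    "simulate_blade",
    "simulate_genotype",
    "simulate_flow_sample",
    "simulate_cohort",
    "study_cohort",
    "STUDY_SPECIES",
    "write_cohort",
]

STUDY_SPECIES = ("P_linearis", "P_umbilicalis", "P_dioica")

CYTOTYPE_VEG = {1: [3], 2: [4], 3: [3], 4: [4], 5: [2, 3], 6: [3, 4], 7: [2, 4]}

#: gamete-ploidy patterns available to cytotype-4 (tetraploid, group 2) blades;
#: Mp patterns carry the {p, 2p, 3p} multiploid signature
C4_GAMETE_PATTERNS: list[tuple[list[int], bool]] = [
    ([2, 4], False),
    ([3, 4], False),
    ([2, 3, 4], False),
    ([4, 8, 12], True),
    ([3, 6, 9], True),
]


@dataclass
class FlowParams:
    """Flow-cytometry acquisition model parameters."""

    events_per_sample: int = 2000
    peak_cv_pct: float = 4.0
    debris_fraction: float = 0.10
    g2_fraction: float = 0.08
    standard_fraction: float = 0.20
    doublet_fraction: float = 0.0
    standard_channel: float = 720.0
    standard_2c_pg: float = 1.96
    debris_scale: float = 6.0

    def standard_ref(self) -> StandardRef:
        return StandardRef(
            name="S_lycopersicum",
            dna_2c=self.standard_2c_pg,
            expected_channel=self.standard_channel,
        )


@dataclass
class SimConfig:
    """Study conditions for a synthetic cohort.

    Defaults reproduce the survey conditions: a 0.2 pg base (2x) genome
    size, an internal standard of 2C = 1.96 pg acquired at channel 720,
    ~2,000 nuclei per sample at ~4% peak CV, 11 microsatellite loci, and the
    reported lineage differentiation within *P. linearis*.
    """

    seed: int = 0
    species: tuple[str, ...] = STUDY_SPECIES
    n_blades: dict[str, int] = field(
        default_factory=lambda: {
            "P_linearis": 47,
            "P_umbilicalis": 35,
            "P_dioica": 40,
        }
    )
    cytotype_proportions: dict[str, dict[int, float]] = field(
        default_factory=lambda: {
            "P_linearis": {1: 0.375, 2: 0.175, 3: 0.05, 5: 0.125, 6: 0.225, 7: 0.05},
            "P_umbilicalis": {1: 0.17, 2: 0.40, 3: 0.17, 4: 0.20, 5: 0.06},
            "P_dioica": {1: 0.03, 2: 0.42, 4: 0.55},
        }
    )
    lineage_gst_3x_4x: float = 0.27
    lineage_gst_3x_mx: float = 0.17
    n_loci: int = 11
    alleles_per_locus: int = 6
    shared_allele_mass: float = 0.25
    missing_rate: float = 0.05
    base_1x_pg: float = 0.1
    mix_proportion: float = 0.5
    mp_probability: float = 0.3
    gamete_section_prob: float = 0.7
    zygotospore_section_prob: float = 0.4
    flow: FlowParams = field(default_factory=FlowParams)

    def __post_init__(self) -> None:
        for sp, props in self.cytotype_proportions.items():
            total = sum(props.values())
            if abs(total - 1.0) > 1e-6:
                raise ValueError(f"cytotype proportions for {sp} sum to {total}")
        for rate in (self.missing_rate, self.flow.debris_fraction,
                     self.flow.g2_fraction, self.flow.doublet_fraction):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must lie in [0, 1]")


@dataclass
class BladeTruth:
    """Ground truth for one blade."""

    blade_id: str
    species: str
    lineage: str
    cytotype: int | None  # None for blades sampled without a vegetative section
    section_ploidies: dict[str, list[int]]
    mp: bool = False
    genotype_ploidy: int | None = None
    group_id: str | None = None
    signature: str = ""


@dataclass
class FlowSampleTruth:
    """Ground truth for one flow sample: component channels and labels."""

    sample_id: str
    blade_id: str
    section_type: str
    g1_channels: dict[int, float]  # ploidy -> channel
    labels: np.ndarray | None = None  # per-event component label


@dataclass
class Cohort:
    """A fully ground-truthed synthetic cohort."""

    config: SimConfig
    blades: list[BladeTruth]
    genotypes: list[PolyploidGenotype]
    dosage_truth: dict[str, dict[str, dict[float, int]]]
    loci: list[LocusDef]
    pools: dict[tuple[str, str], dict[str, tuple[np.ndarray, np.ndarray]]]
    expected_gst: dict[tuple[str, str, str], float]
    rule_table: dict[tuple[str, str], str]

    def flow_samples(self) -> Iterable[tuple[EventTable, FlowSampleTruth]]:
        """Yield (events, truth) per blade section, reproducibly seeded."""
        idx = 0
        for blade in self.blades:
            for section, ploidies in sorted(blade.section_ploidies.items()):
                rng = np.random.default_rng([self.config.seed, 7001, idx])
                idx += 1
                yield simulate_flow_sample(
                    ploidies,
                    self.config,
                    rng,
                    sample_id=f"{blade.blade_id}:{section}",
                    blade_id=blade.blade_id,
                    section_type=section,
                )

    def n_flow_analyses(self) -> int:
        return sum(len(b.section_ploidies) for b in self.blades)


def default_loci(n_loci: int = 11) -> list[LocusDef]:
    """Microsatellite panel: alternating di-/tri-nucleotide repeats."""
    out = []
    for i in range(n_loci):
        unit = 2 if i % 2 == 0 else 3
        lo = 100 + 15 * i
        out.append(LocusDef(name=f"L{i + 1:02d}", repeat_unit=unit,
                            size_range=(lo, lo + 120)))
    return out


# ---------------------------------------------------------------------------
# Lineage allele pools


def expected_gst(f: np.ndarray, g: np.ndarray) -> float:
    """Parametric G_ST of two frequency vectors (equal group weights)."""
    hs = 1.0 - 0.5 * (np.sum(f**2) + np.sum(g**2))
    m = 0.5 * (f + g)
    ht = 1.0 - float(np.sum(m**2))
    if ht == 0:
        return 0.0
    return float((ht - hs) / ht)


def _two_lineage_freqs(
    target: float, n_alleles: int, shared_mass: float
) -> tuple[np.ndarray, np.ndarray]:
    """Mirrored two-allele mixture with a shared tail hitting a target G_ST.

    Alleles 0 and 1 carry mass ``1 - shared_mass`` split (q, 1-q) in lineage
    A and (1-q, q) in lineage B; the remaining alleles share ``shared_mass``
    uniformly in both.  q is solved so the parametric G_ST equals *target*.
    """
    w = 1.0 - shared_mass
    n_tail = n_alleles - 2
    tail = np.full(n_tail, shared_mass / n_tail) if n_tail else np.array([])

    def build(q: float) -> tuple[np.ndarray, np.ndarray]:
        f = np.concatenate([[w * q, w * (1 - q)], tail])
        g = np.concatenate([[w * (1 - q), w * q], tail])
        return f, g

    gmax = expected_gst(*build(1.0))
    if target > gmax + 1e-9:
        raise ValueError(
            f"target G_ST {target} infeasible: maximum {gmax:.3f} with "
            f"shared mass {shared_mass}"
        )
    if target <= 0:
        return build(0.5)
    if target >= gmax:
        return build(1.0)
    q = brentq(lambda x: expected_gst(*build(x)) - target, 0.5, 1.0)
    return build(q)


def _single_pool_freqs(n_alleles: int) -> np.ndarray:
    """Skewed frequency profile giving gene diversity near 0.5."""
    raw = np.array([0.65, 0.15, 0.08, 0.06, 0.04, 0.02][:n_alleles])
    return raw / raw.sum()


def simulate_lineages(
    cfg: SimConfig,
) -> tuple[
    dict[tuple[str, str], dict[str, tuple[np.ndarray, np.ndarray]]],
    dict[tuple[str, str, str], float],
]:
    """Construct lineage-specific allele frequency pools per species.

    Species receive disjoint allele ranges (strong between-species
    differentiation).  Within *P. linearis* three pools are built: the 3x and
    4x lineages as mirrored mixtures at ``cfg.lineage_gst_3x_4x``, and the
    mixoploid pool as the convex combination of the two whose parametric
    G_ST against the 3x pool equals ``cfg.lineage_gst_3x_mx``.  Returns the
    pools and the realized expected pairwise G_ST values.
    """
    loci = default_loci(cfg.n_loci)
    pools: dict[tuple[str, str], dict[str, tuple[np.ndarray, np.ndarray]]] = {}
    realized: dict[tuple[str, str, str], float] = {}
    for s_idx, species in enumerate(cfg.species):
        allele_sets = {}
        for l_idx, l in enumerate(loci):
            base = l.size_range[0] + s_idx * 40
            alleles = base + l.repeat_unit * np.arange(cfg.alleles_per_locus)
            allele_sets[l.name] = alleles.astype(float)
        if species == "P_linearis":
            f3, f4 = _two_lineage_freqs(
                cfg.lineage_gst_3x_4x, cfg.alleles_per_locus, cfg.shared_allele_mass
            )

            def mix_gst(alpha: float) -> float:
                fm = alpha * f3 + (1 - alpha) * f4
                return expected_gst(f3, fm)

            if cfg.lineage_gst_3x_mx <= 0:
                alpha = 1.0
            else:
                alpha = brentq(
                    lambda a: mix_gst(a) - cfg.lineage_gst_3x_mx, 0.0, 1.0
                )
            fm = alpha * f3 + (1 - alpha) * f4
            for lineage, f in (("3x", f3), ("4x", f4), ("mx", fm)):
                pools[(species, lineage)] = {
                    name: (alleles, f.copy()) for name, alleles in allele_sets.items()
                }
            realized[(species, "3x", "4x")] = expected_gst(f3, f4)
            realized[(species, "3x", "mx")] = expected_gst(f3, fm)
            realized[(species, "4x", "mx")] = expected_gst(f4, fm)
        else:
            f = _single_pool_freqs(cfg.alleles_per_locus)
            pools[(species, "main")] = {
                name: (alleles, f.copy()) for name, alleles in allele_sets.items()
            }
    return pools, realized


# ---------------------------------------------------------------------------
# Blades


def _zygospore_section(veg: Sequence[int]) -> list[int]:
    """Zygotospore samples mix blade cells with zygotospores at 2x the
    highest vegetative ploidy."""
    top = max(veg)
    return sorted({top, 2 * top})


def simulate_blade(
    cfg: SimConfig, species: str, blade_id: str, rng: np.random.Generator
) -> BladeTruth:
    """Draw a cytotype and build cytotype-consistent section ploidies."""
    props = cfg.cytotype_proportions[species]
    cts = sorted(props)
    cytotype = int(rng.choice(cts, p=[props[c] for c in cts]))
    veg = CYTOTYPE_VEG[cytotype]
    sections: dict[str, list[int]] = {"vegetative": list(veg)}
    mp = False
    if cytotype in (1, 2):
        if rng.random() < cfg.gamete_section_prob:
            sections["male_gamete"] = list(veg)
    elif cytotype == 3:
        sections["male_gamete"] = [2, 3]
    elif cytotype == 4:
        if rng.random() < cfg.mp_probability:
            pattern, mp = C4_GAMETE_PATTERNS[3 + int(rng.integers(2))]
        else:
            pattern, mp = C4_GAMETE_PATTERNS[int(rng.integers(3))]
        sections["male_gamete"] = list(pattern)
    else:  # mixoploids: gametes from both lines
        if rng.random() < cfg.gamete_section_prob:
            sections["male_gamete"] = list(veg)
    if rng.random() < cfg.zygotospore_section_prob:
        sections["zygotospore"] = _zygospore_section(veg)
    lineage = _lineage_of(species, cytotype)
    return BladeTruth(
        blade_id=blade_id,
        species=species,
        lineage=lineage,
        cytotype=cytotype,
        section_ploidies=sections,
        mp=mp,
        genotype_ploidy=max(veg),
    )


def _lineage_of(species: str, cytotype: int | None) -> str:
    if species != "P_linearis":
        return "main"
    if cytotype in (1, 3):
        return "3x"
    if cytotype in (2, 4):
        return "4x"
    return "mx"


# ---------------------------------------------------------------------------
# Genotypes


def simulate_genotype(
    blade: BladeTruth,
    pools: Mapping[tuple[str, str], Mapping[str, tuple[np.ndarray, np.ndarray]]],
    cfg: SimConfig,
    rng: np.random.Generator,
) -> tuple[PolyploidGenotype, dict[str, dict[float, int]]]:
    """Draw ploidy-many allele copies per locus; expose only the phenotype.

    Dosage (the per-allele copy count) is recorded as ground truth; loci are
    masked as missing at ``cfg.missing_rate``.
    """
    pool = pools[(blade.species, blade.lineage)]
    m = blade.genotype_ploidy or max(blade.section_ploidies["vegetative"])
    loci_map: dict[str, tuple[float, ...]] = {}
    dosage: dict[str, dict[float, int]] = {}
    for name, (alleles, freqs) in sorted(pool.items()):
        counts = rng.multinomial(m, freqs)
        shown = tuple(sorted(float(a) for a, c in zip(alleles, counts) if c > 0))
        dosage[name] = {float(a): int(c) for a, c in zip(alleles, counts) if c > 0}
        if rng.random() < cfg.missing_rate:
            loci_map[name] = ()
        else:
            loci_map[name] = shown
    g = PolyploidGenotype(
        individual_id=blade.blade_id,
        species=blade.species,
        section_type="vegetative",
        loci=loci_map,
        ploidy=m,
        signature=blade.signature,
    )
    return g, dosage


# ---------------------------------------------------------------------------
# Flow samples


def _g1_weights(ploidies: Sequence[int], mix_proportion: float) -> np.ndarray:
    k = len(ploidies)
    if k == 1:
        return np.array([1.0])
    if k == 2:
        return np.array([mix_proportion, 1.0 - mix_proportion])
    # multi-ploidy gamete sections: base ploidy dominates
    w = np.array([0.5, 0.3, 0.2][:k] + [0.1] * max(0, k - 3))
    return w / w.sum()


def simulate_flow_sample(
    section_ploidies: Sequence[int],
    cfg: SimConfig,
    rng: np.random.Generator,
    sample_id: str = "sample",
    blade_id: str = "",
    section_type: str = "vegetative",
) -> tuple[EventTable, FlowSampleTruth]:
    """Emit an event table for one blade section.

    Components: one Gaussian per G1 ploidy (channel = ploidy x 1x-pg x
    channel-per-pg), a G2 companion at twice each G1 channel, the internal
    standard, exponential debris, and optional doublets (doubled FL at
    unchanged pulse height).  Per-event component labels are returned in the
    truth record.
    """
    fp = cfg.flow
    chan_per_pg = fp.standard_channel / fp.standard_2c_pg
    ploidies = sorted(set(section_ploidies))
    g1_chan = {p: p * cfg.base_1x_pg * chan_per_pg for p in ploidies}

    comps: list[tuple[str, float, float]] = []  # (label, channel, weight)
    sample_mass = 1.0 - fp.debris_fraction - fp.standard_fraction
    weights = _g1_weights(ploidies, cfg.mix_proportion)
    for p, w in zip(ploidies, weights):
        w_tot = sample_mass * w
        comps.append((f"g1:{p}", g1_chan[p], w_tot * (1.0 - fp.g2_fraction)))
        if fp.g2_fraction > 0:
            comps.append((f"g2:{p}", 2.0 * g1_chan[p], w_tot * fp.g2_fraction))
    comps.append(("standard", fp.standard_channel, fp.standard_fraction))
    comps.append(("debris", 0.0, fp.debris_fraction))

    labels_pool = [c[0] for c in comps]
    counts = rng.multinomial(fp.events_per_sample, [c[2] for c in comps])
    fl_parts, label_parts = [], []
    for (label, chan, _), n in zip(comps, counts):
        if n == 0:
            continue
        if label == "debris":
            fl = rng.exponential(fp.debris_scale, size=n) + 1.0
        else:
            fl = rng.normal(chan, fp.peak_cv_pct / 100.0 * chan, size=n)
        fl_parts.append(np.clip(fl, 0.5, 1023.0))
        label_parts.extend([label] * n)
    fl = np.concatenate(fl_parts)
    labels = np.array(label_parts)

    height = fl / 1.2 * (1.0 + rng.normal(0.0, 0.03, size=len(fl)))
    if fp.doublet_fraction > 0:
        n_dbl = int(round(fp.doublet_fraction * len(fl)))
        pick = rng.choice(np.flatnonzero(labels != "debris"), size=n_dbl)
        fl = np.concatenate([fl, 2.0 * fl[pick]])
        height = np.concatenate([height, height[pick]])
        labels = np.concatenate([labels, np.array(["doublet"] * n_dbl)])
    n = len(fl)
    ssc = np.where(
        labels == "debris",
        rng.normal(1.3, 0.3, size=n),
        rng.normal(2.5, 0.2, size=n),
    )
    fsc = rng.normal(2.2, 0.25, size=n)
    order = rng.permutation(n)
    data = pd.DataFrame(
        {
            "fl": fl[order],
            "pulse_height": np.maximum(height[order], 0.1),
            "ssc": ssc[order],
            "fsc": fsc[order],
            "time": np.arange(n, dtype=float),
        }
    )
    truth = FlowSampleTruth(
        sample_id=sample_id,
        blade_id=blade_id,
        section_type=section_type,
        g1_channels=g1_chan,
        labels=labels[order],
    )
    assert set(labels) <= set(labels_pool) | {"doublet"}
    return EventTable(sample_id=sample_id, data=data), truth


# ---------------------------------------------------------------------------
# Cohorts


def simulate_cohort(cfg: SimConfig) -> Cohort:
    """Random cohort drawn from the configured cytotype proportions."""
    rng = np.random.default_rng([cfg.seed, 11])
    pools, realized = simulate_lineages(cfg)
    blades: list[BladeTruth] = []
    for species in cfg.species:
        for i in range(cfg.n_blades[species]):
            blade = simulate_blade(cfg, species, f"{species}_{i + 1:03d}", rng)
            blade.signature = _signature_of(blade)
            blades.append(blade)
    genotypes, dosage = [], {}
    grng = np.random.default_rng([cfg.seed, 13])
    rule_table: dict[tuple[str, str], str] = {}
    for blade in blades:
        g, dtruth = simulate_genotype(blade, pools, cfg, grng)
        genotypes.append(g)
        dosage[g.individual_id] = dtruth
        key = (blade.species, blade.signature)
        rule_table.setdefault(key, f"{blade.species}:{blade.signature}")
        blade.group_id = rule_table[key]
    return Cohort(
        config=cfg,
        blades=blades,
        genotypes=genotypes,
        dosage_truth=dosage,
        loci=default_loci(cfg.n_loci),
        pools=pools,
        expected_gst=realized,
        rule_table=rule_table,
    )


def _signature_of(blade: BladeTruth) -> str:
    veg = blade.section_ploidies.get("vegetative", [])
    if len(veg) >= 2:
        return "Mx " + "/".join(f"{p}x" for p in veg)
    if blade.mp:
        base = min(blade.section_ploidies.get("male_gamete", veg or [0]))
        return f"Mp {base}x"
    if veg:
        return f"{veg[0]}x"
    # blades sampled without a vegetative section
    parts = []
    gam = sorted(
        set(blade.section_ploidies.get("male_gamete", []))
        | set(blade.section_ploidies.get("female_gamete", []))
    )
    if gam:
        parts.append("Gametes " + ", ".join(f"{p}x" for p in gam))
    zp = blade.section_ploidies.get("zygotospore")
    if zp:
        parts.append(f"Zp {max(zp)}x")
    return " + ".join(parts)


# ---------------------------------------------------------------------------
# Fixed survey design

# blade composition per species: classified cytotype counts plus auxiliary
# blades sampled without a vegetative section (zygotospore- or gamete-only),
# and the number of flow analyses (sections) performed per species
_STUDY_BLADES = {
    "P_linearis": dict(
        analyses=71,
        cytotypes=[(1, 15), (2, 7), (3, 2), (5, 5), (6, 9), (7, 2)],
        aux=[
            ("zygotospore", [6]),
            ("zygotospore", [6]),
            ("zygotospore", [3, 6]),
            ("zygotospore", [8]),
            ("zygotospore", [8]),
            ("male_gamete", [2]),
            ("male_gamete", [3]),
        ],
    ),
    "P_umbilicalis": dict(
        analyses=69,
        cytotypes=[(1, 6), (2, 14), (3, 6), (4, 7), (5, 2)],
        aux=[],
    ),
    "P_dioica": dict(
        analyses=77,
        cytotypes=[(1, 1), (2, 13), (4, 17)],
        aux=[
            ("zygotospore", [8]),
            ("zygotospore", [8]),
            ("zygotospore", [8]),
            ("zygotospore", [8]),
            ("zygotospore", [4, 8]),
            ("zygotospore", [4, 8]),
            ("zygotospore", [4, 8]),
            ("male_gamete", [2]),
            ("male_gamete", [3]),
        ],
    ),
}

# genotype groups: group id -> list of (ploidy signature, count, lineage, ploidy)
_STUDY_GENOTYPE_GROUPS: list[tuple[str, str, list[tuple[str, int, str, int]]]] = [
    ("P_linearis", "G01", [("3x", 15, "3x", 3)]),
    ("P_linearis", "G02", [("4x", 7, "4x", 4)]),
    ("P_linearis", "G03", [("Mx 2x/3x", 3, "mx", 3), ("Mx 2x/4x", 1, "mx", 4)]),
    ("P_linearis", "G04", [("Mx 3x/4x", 8, "mx", 4)]),
    ("P_linearis", "G05", [("3x + Zp 6x", 1, "3x", 6), ("Zp 6x", 2, "3x", 6)]),
    ("P_linearis", "G06", [("Mx 2x/3x + Zp 6x", 2, "mx", 6)]),
    (
        "P_linearis",
        "G07",
        [("Mx 2x/4x + Zp 8x", 1, "mx", 8), ("Mx 3x/4x + Zp 8x", 1, "mx", 8)],
    ),
    ("P_umbilicalis", "G08", [("4x", 23, "main", 4)]),
    ("P_umbilicalis", "G09", [("3x", 10, "main", 3)]),
    (
        "P_umbilicalis",
        "G10",
        [
            ("Mp 3x", 1, "main", 3),
            ("4x + Gametes 2x, 4x", 2, "main", 4),
            ("Mx 2x/3x + Zp 6x", 1, "main", 6),
            ("Gametes 2x + Zp 6x", 1, "main", 6),
            ("Zp 8x", 1, "main", 8),
        ],
    ),
    ("P_dioica", "G11", [("4x", 21, "main", 4)]),
    ("P_dioica", "G12", [("3x", 2, "main", 3)]),
    ("P_dioica", "G13", [("Mp 4x", 3, "main", 4)]),
    ("P_dioica", "G14", [("Mp 3x", 5, "main", 3)]),
    ("P_dioica", "G15", [("Mp 3x, 4x", 1, "main", 4)]),
    ("P_dioica", "G16", [("Zp 8x", 4, "main", 8)]),
    ("P_dioica", "G17", [("4x + Zp 8x", 3, "main", 8)]),
    ("P_dioica", "G18", [("Gametes 2x + Zp 8x", 1, "main", 8)]),
    ("P_dioica", "G19", [("Gametes 3x + Zp 8x", 1, "main", 8)]),
]


def _study_blades_for(species: str, cfg: SimConfig) -> list[BladeTruth]:
    """Deterministic blade list with exact cytotype counts and section
    allocations summing to the per-species analysis totals."""
    design = _STUDY_BLADES[species]
    blades: list[BladeTruth] = []
    i = 0
    c4_rotation = 0
    for cytotype, count in design["cytotypes"]:
        for _ in range(count):
            i += 1
            veg = CYTOTYPE_VEG[cytotype]
            sections: dict[str, list[int]] = {"vegetative": list(veg)}
            mp = False
            if cytotype == 3:
                sections["male_gamete"] = [2, 3]
            elif cytotype == 4:
                pattern, mp = C4_GAMETE_PATTERNS[c4_rotation % len(C4_GAMETE_PATTERNS)]
                c4_rotation += 1
                sections["male_gamete"] = list(pattern)
            blade = BladeTruth(
                blade_id=f"{species}_B{i:03d}",
                species=species,
                lineage=_lineage_of(species, cytotype),
                cytotype=cytotype,
                section_ploidies=sections,
                mp=mp,
                genotype_ploidy=max(veg),
            )
            blade.signature = _signature_of(blade)
            blades.append(blade)
    for section, ploidies in design["aux"]:
        i += 1
        blade = BladeTruth(
            blade_id=f"{species}_B{i:03d}",
            species=species,
            lineage="main" if species != "P_linearis" else "3x",
            cytotype=None,
            section_ploidies={section: list(ploidies)},
            genotype_ploidy=max(ploidies),
        )
        blade.signature = _signature_of(blade)
        blades.append(blade)
    # pad with optional sections (gametes of the blade ploidy, then mixed
    # zygotospore samples) until the species analysis total is met
    target = design["analyses"]
    deficit = target - sum(len(b.section_ploidies) for b in blades)
    if deficit < 0:
        raise ValueError(f"{species}: mandatory sections exceed analysis total")
    for b in blades:
        if deficit == 0:
            break
        if b.cytotype is not None and "male_gamete" not in b.section_ploidies:
            b.section_ploidies["male_gamete"] = list(
                b.section_ploidies["vegetative"]
            )
            deficit -= 1
    for b in blades:
        if deficit == 0:
            break
        if b.cytotype is not None and "zygotospore" not in b.section_ploidies:
            b.section_ploidies["zygotospore"] = _zygospore_section(
                b.section_ploidies["vegetative"]
            )
            deficit -= 1
    if deficit != 0:
        raise ValueError(f"{species}: cannot reach {target} analyses")
    return blades


def study_cohort(seed: int = 0, cfg: SimConfig | None = None) -> Cohort:
    """The fixed survey design with ground truth.

    122 blades (47 / 35 / 40 across the three species) with section
    allocations summing to 217 flow analyses, and 121 genotypes partitioned
    into 19 (species x ploidy signature) groups.  Blade composition and group
    sizes are deterministic; *seed* drives only the stochastic layers (allele
    draws, missing-data masks, flow events).
    """
    cfg = cfg if cfg is not None else SimConfig()
    cfg.seed = seed
    pools, realized = simulate_lineages(cfg)
    blades: list[BladeTruth] = []
    for species in STUDY_SPECIES:
        blades.extend(_study_blades_for(species, cfg))

    genotypes: list[PolyploidGenotype] = []
    dosage: dict[str, dict[str, dict[float, int]]] = {}
    rule_table: dict[tuple[str, str], str] = {}
    grng = np.random.default_rng([cfg.seed, 17])
    idx = 0
    for species, group_id, entries in _STUDY_GENOTYPE_GROUPS:
        for signature, count, lineage, ploidy in entries:
            rule_table[(species, signature)] = group_id
            for _ in range(count):
                idx += 1
                stub = BladeTruth(
                    blade_id=f"{species}_gt{idx:03d}",
                    species=species,
                    lineage=lineage,
                    cytotype=None,
                    section_ploidies={},
                    genotype_ploidy=ploidy,
                    group_id=group_id,
                    signature=signature,
                )
                g, dtruth = simulate_genotype(stub, pools, cfg, grng)
                genotypes.append(g)
                dosage[g.individual_id] = dtruth
    return Cohort(
        config=cfg,
        blades=blades,
        genotypes=genotypes,
        dosage_truth=dosage,
        loci=default_loci(cfg.n_loci),
        pools=pools,
        expected_gst=realized,
        rule_table=rule_table,
    )


# ---------------------------------------------------------------------------
# Output


def write_cohort(cohort: Cohort, outdir, events: bool = False) -> None:
    """Write a cohort to disk: blade manifest CSV, GenAlEx genotype CSV,
    ground-truth JSON, and (optionally) one events CSV per flow sample."""
    from pathlib import Path

    from .genotypes import write_genalex_csv

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for b in cohort.blades:
        for section, ploidies in sorted(b.section_ploidies.items()):
            rows.append(
                dict(
                    blade_id=b.blade_id,
                    species=b.species,
                    section_type=section,
                    sample_id=f"{b.blade_id}:{section}",
                )
            )
    pd.DataFrame(rows).to_csv(out / "blades.csv", index=False)
    write_genalex_csv(cohort.genotypes, out / "genotypes.csv", cohort.loci)
    truth = {
        "seed": cohort.config.seed,
        "expected_gst": {
            "|".join(k): v for k, v in cohort.expected_gst.items()
        },
        "blades": [
            {
                "blade_id": b.blade_id,
                "species": b.species,
                "lineage": b.lineage,
                "cytotype": b.cytotype,
                "sections": b.section_ploidies,
                "mp": b.mp,
                "signature": b.signature,
            }
            for b in cohort.blades
        ],
        "dosage": {
            ind: {locus: {str(a): c for a, c in d.items()} for locus, d in per.items()}
            for ind, per in cohort.dosage_truth.items()
        },
    }
    with open(out / "ground_truth.json", "w") as fh:
        json.dump(truth, fh, indent=1)
    if events:
        ev_dir = out / "events"
        ev_dir.mkdir(exist_ok=True)
        for table, _ in cohort.flow_samples():
            name = table.sample_id.replace(":", "_") + ".csv"
            table.data.to_csv(ev_dir / name, index=False)
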