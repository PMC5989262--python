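"""Ratio-based ploidy assignment and cytotype classification.

Genome sizes form a near-arithmetic grid: once the smallest gamete genome
size is anchored at the base ploidy (2x, because genotyping shows two or more
alleles per locus even in gametes), every other size is assigned the integer
multiple of the 1x-equivalent it is nearest to.  Blades are then classified
into cytotypes from the ploidies of their sections:

==========  =====================================================  =====
cytotype    definition                                             group
==========  =====================================================  =====
C1          vegetative 3x, gametes 3x                                1
C2          vegetative 4x, gametes 4x                                1
C3          vegetative 3x, gametes of lower ploidy (2x, 3x)          2
C4          vegetative 4x, gametes 2x/3x/4x and/or multiploid        2
C5          mixoploid vegetative 2x/3x                               3
C6          mixoploid vegetative 3x/4x                               3
C7          mixoploid vegetative 2x/4x                               3
==========  =====================================================  =====

Two cell lines run through the ploidy series: line 1 (2x-4x-8x, plus 12x
gametes) and line 2 (3x-6x, plus 9x gametes).  Zygotospores, the product of
fertilisation, double the highest vegetative ploidy of the blade.  Gamete
sections containing a ploidy together with its triple (e.g. 3x, 6x, 9x) carry
multiploid ("Mp") gametes attributed to spontaneous chromosome multiplication.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from statistics import median
from typing import Iterable, Mapping, Sequence

from .flowcyto import GenomeSizeCall

__all__ = [
    "GAMETE_SECTIONS",
    "SECTION_TYPES",
    "PloidyCall",
    "BaseCalibration",
    "CytotypeProfile",
    "CytotypeFrequencies",
    "CalibrationError",
    "assign_ploidy",
    "calibrate_base",
    "assign_cell_line",
    "detect_mp",
    "build_profile",
    "classify_cytotype",
    "expected_zygotospore_ploidy",
    "summarize_cytotype_frequencies",
]

SECTION_TYPES = ("vegetative", "zygotospore", "female_gamete", "male_gamete")
GAMETE_SECTIONS = ("female_gamete", "male_gamete")

CYTOTYPE_GROUP = {1: 1, 2: 1, 3: 2, 4: 2, 5: 3, 6: 3, 7: 3}
MIXOPLOID_CYTOTYPE = {(2, 3): 5, (3, 4): 6, (2, 4): 7}


class CalibrationError(ValueError):
    """Raised when the base ploidy cannot be calibrated."""


@dataclass
class PloidyCall:
    """Integer ploidies (x-multiples) for the G1 peaks of one section sample."""

    sample_id: str
    section_type: str
    ploidies: list[int]
    genome_sizes_pg: list[float]
    flags: set[str] = field(default_factory=set)
    unassigned: list[tuple[float, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.ploidies) != len(self.genome_sizes_pg):
            raise ValueError("ploidies and genome_sizes_pg must match in length")


@dataclass
class BaseCalibration:
    """Anchor of the ploidy grid: ``base_size_pg`` corresponds to ``base_ploidy``."""

    base_size_pg: float
    base_ploidy: int = 2

    def __post_init__(self) -> None:
        if self.base_size_pg <= 0:
            raise ValueError("base_size_pg must be positive")
        if self.base_ploidy < 1:
            raise ValueError("base_ploidy must be >= 1")

    @property
    def unit_pg(self) -> float:
        """Genome size of a single chromosome-set equivalent (1x)."""
        return self.base_size_pg / self.base_ploidy


@dataclass
class CytotypeProfile:
    """Per-blade collection of section ploidy calls and derived cytotype."""

    blade_id: str
    species: str
    sections: dict[str, PloidyCall] = field(default_factory=dict)
    cytotype: int | None = None
    group: int | None = None
    cell_lines: set[int] = field(default_factory=set)
    notation: str = ""
    unclassified_reason: str | None = None

    def vegetative_ploidies(self) -> list[int]:
        call = self.sections.get("vegetative")
        return sorted(set(call.ploidies)) if call else []

    def gamete_ploidies(self) -> list[int]:
        out: set[int] = set()
        for sec in GAMETE_SECTIONS:
            call = self.sections.get(sec)
            if call:
                out.update(call.ploidies)
        return sorted(out)

    def all_ploidies(self) -> list[int]:
        out: set[int] = set()
        for call in self.sections.values():
            out.update(call.ploidies)
        return sorted(out)


@dataclass
class CytotypeFrequencies:
    """Per-species cytotype/group counts and percentages over classified blades."""

    species: str
    n_total: int
    n_classified: int
    cytotype_counts: dict[int, int]
    group_counts: dict[int, int]

    def cytotype_pct(self, cytotype: int) -> float:
        if self.n_classified == 0:
            return float("nan")
        return 100.0 * self.cytotype_counts.get(cytotype, 0) / self.n_classified

    def group_pct(self, group: int) -> float:
        if self.n_classified == 0:
            return float("nan")
        return 100.0 * self.group_counts.get(group, 0) / self.n_classified


# ---------------------------------------------------------------------------
# Ploidy assignment and base calibration


def assign_ploidy(
    size_pg: float, cal: BaseCalibration, rel_tol: float = 0.15
) -> int | None:
    """Nearest integer multiple of the 1x unit, or ``None`` if off-grid.

    The call is accepted only when the deviation from the grid point is at
    most ``rel_tol * size_pg``; deviations of observed means from the grid
    reach several percent, hence the permissive default.
    """
    if size_pg <= 0:
        raise ValueError("size_pg must be positive")
    p = max(1, round(size_pg / cal.unit_pg))
    if abs(size_pg - p * cal.unit_pg) <= rel_tol * size_pg:
        return int(p)
    return None


def calibrate_base(
    all_calls: Iterable[GenomeSizeCall],
    base_ploidy: int = 2,
    gap_ratio: float = 1.25,
) -> BaseCalibration:
    """Anchor the grid at the smallest gamete genome-size cluster.

    All sizes from gamete sections are pooled and single-linkage clustered
    on the sorted axis (a new cluster starts when consecutive sizes differ by
    more than *gap_ratio*); the base is the median of the lowest cluster and
    is assigned *base_ploidy* (2x by default, since gametes are not haploid).
    """
    sizes: list[float] = []
    for call in all_calls:
        if call.section_type in GAMETE_SECTIONS:
            sizes.extend(call.sizes_pg)
    if not sizes:
        raise CalibrationError(
            "no gamete-section genome sizes available; "
            "supply a manual BaseCalibration"
        )
    sizes.sort()
    cluster = [sizes[0]]
    for prev, cur in zip(sizes, sizes[1:]):
        if cur > prev * gap_ratio:
            break
        cluster.append(cur)
    return BaseCalibration(base_size_pg=float(median(cluster)), base_ploidy=base_ploidy)


# ---------------------------------------------------------------------------
# Cell lines, Mp gametes, cytotype classification


def assign_cell_line(ploidies: Iterable[int]) -> set[int]:
    """Cell-line membership of a ploidy set.

    Line 1 is the 2x-4x-8x series (12x gametes are triplicated 4x, hence
    line 1); line 2 is the 3x-6x series (9x gametes are triplicated 3x).
    """
    ps = set(ploidies)
    if not ps:
        raise ValueError("ploidies must be non-empty")
    lines: set[int] = set()
    if ps & {2, 4, 8, 12}:
        lines.add(1)
    if ps & {3, 6, 9}:
        lines.add(2)
    return lines


def detect_mp(section_ploidies: Sequence[int]) -> bool:
    """True when a gamete section carries multiploid (Mp) gametes.

    A pair {p, 2p} alone is indistinguishable from a G1/G2 doublet, so Mp is
    only called when some ploidy is accompanied by its triple (e.g. 3x with
    9x, or 4x with 12x), the signature of chromosome triplication.
    """
    ps = set(section_ploidies)
    return any(3 * p in ps for p in ps)


def _fmt(ploidies: Sequence[int]) -> str:
    return ", ".join(f"{p}x" for p in ploidies)


def build_profile(
    blade_id: str,
    species: str,
    section_calls: Mapping[str, PloidyCall],
) -> CytotypeProfile:
    """Assemble and classify a blade profile from per-section ploidy calls."""
    profile = CytotypeProfile(
        blade_id=blade_id, species=species, sections=dict(section_calls)
    )
    return classify_cytotype(profile)


def classify_cytotype(profile: CytotypeProfile) -> CytotypeProfile:
    """Classify a blade into cytotypes C1-C7 and groups 1-3 (in place).

    A blade is mixoploid (group 3) when its vegetative section carries two
    G1 ploidies.  Single-line 3x/4x blades fall into group 1 when all their
    gametes match the blade ploidy and group 2 otherwise.  Blades without a
    vegetative section, or vegetative 2x only (never observed as a pure
    blade), are left unclassified with an explicit reason.
    """
    veg = profile.vegetative_ploidies()
    gametes = profile.gamete_ploidies()
    mp = any(
        detect_mp(profile.sections[s].ploidies)
        for s in GAMETE_SECTIONS
        if s in profile.sections
    )

    cytotype: int | None = None
    reason: str | None = None
    if not veg:
        reason = "no vegetative section"
    elif len(veg) >= 2:
        cytotype = MIXOPLOID_CYTOTYPE.get(tuple(veg))  # type: ignore[arg-type]
        if cytotype is None:
            reason = f"unrecognised mixoploid combination {_fmt(veg)}"
    elif veg == [3]:
        cytotype = 1 if set(gametes) <= {3} else 3
    elif veg == [4]:
        cytotype = 2 if set(gametes) <= {4} else 4
    elif veg == [2]:
        reason = "exclusively diploid vegetative blade (never observed); check calls"
    else:
        reason = f"vegetative ploidy {_fmt(veg)} outside the 2x-4x blade range"

    profile.cytotype = cytotype
    profile.group = CYTOTYPE_GROUP.get(cytotype) if cytotype else None
    profile.unclassified_reason = reason
    ploidies = profile.all_ploidies()
    profile.cell_lines = assign_cell_line(ploidies) if ploidies else set()
    profile.notation = _notation(profile, mp)
    return profile


def _notation(profile: CytotypeProfile, mp: bool) -> str:
    """Notation grammar: '/' joins coexisting vegetative ploidies (Mx),
    ',' joins alternative gamete ploidies, '+' joins distinct cell types,
    with Mx/Mp/Zp prefixes."""
    parts: list[str] = []
    veg = profile.vegetative_ploidies()
    if veg:
        core = "/".join(f"{p}x" for p in veg)
        parts.append(f"Mx {core}" if len(veg) >= 2 else core)
    gametes = profile.gamete_ploidies()
    if gametes and (not veg or set(gametes) != set(veg)):
        prefix = "Mp " if mp else "Gametes "
        parts.append(prefix + _fmt(gametes))
    zp = profile.sections.get("zygotospore")
    if zp and zp.ploidies:
        parts.append("Zp " + _fmt(sorted(set(zp.ploidies))))
    return " + ".join(parts)


def expected_zygotospore_ploidy(profile: CytotypeProfile) -> int:
    """Zygotospores double the highest vegetative ploidy of the blade.

    A 3x blade yields 6x zygotospores, a 4x blade 8x; in mixoploids only the
    highest vegetative line contributes (2x/3x blades yield 6x).
    """
    veg = profile.vegetative_ploidies()
    if not veg:
        raise ValueError("vegetative ploidies unknown")
    return 2 * max(veg)


def summarize_cytotype_frequencies(
    profiles: Iterable[CytotypeProfile],
) -> dict[str, CytotypeFrequencies]:
    """Per-species cytotype and group incidence over classified blades."""
    by_species: dict[str, list[CytotypeProfile]] = {}
    for p in profiles:
        by_species.setdefault(p.species, []).append(p)
    out: dict[str, CytotypeFrequencies] = {}
    for species, plist in by_species.items():
        classified = [p for p in plist if p.cytotype is not None]
        ccounts: dict[int, int] = {}
        gcounts: dict[int, int] = {}
        for p in classified:
            ccounts[p.cytotype] = ccounts.get(p.cytotype, 0) + 1
            gcounts[p.group] = gcounts.get(p.group, 0) + 1
        out[species] = CytotypeFrequencies(
            species=species,
            n_total=len(plist),
            n_classified=len(classified),
            cytotype_counts=ccounts,
            group_counts=gcounts,
        )
    return out
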