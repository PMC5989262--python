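"""Dosage-ambiguous microsatellite genotypes: I/O, binning, groups.

In a polyploid, capillary genotyping reveals only the *phenotype* of a locus:
the set of distinct allele sizes present, with copy numbers (dosage) unknown.
A genotype here is therefore individual x locus -> allele multiset.  The
module reads GenAlEx-style CSVs and long-format TSVs, snaps fragment sizes to
a per-locus repeat-unit grid, bounds ploidy from below by the maximum number
of distinct alleles at any locus, cross-checks that bound against the
flow-cytometric ploidy, partitions genotypes into analysis groups by
(species, ploidy signature), and imputes missing loci by random draws from
the group allele pool.
"""

from __future__ import annotations

import csv
import math
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "LocusDef",
    "PolyploidGenotype",
    "GroupAssignment",
    "GenotypeParseError",
    "read_loci_yaml",
    "read_genotypes",
    "read_genalex_csv",
    "read_long_tsv",
    "write_genalex_csv",
    "write_long_tsv",
    "fit_grid_offset",
    "bin_alleles",
    "max_allele_ploidy",
    "concordance_check",
    "assign_groups",
    "impute_missing",
]

MAX_PLOIDY = 12


class GenotypeParseError(ValueError):
    """Raised on malformed genotype files, with the offending line number."""


@dataclass
class LocusDef:
    name: str
    repeat_unit: int
    size_range: tuple[int, int] = (50, 400)

    def __post_init__(self) -> None:
        if self.repeat_unit < 1:
            raise ValueError("repeat_unit must be >= 1")


@dataclass
class PolyploidGenotype:
    """One multilocus genotype; ``loci[name]`` is a sorted allele tuple.

    An empty tuple means the locus is missing.  ``ploidy`` and ``signature``
    are annotations attached from the flow-cytometric side.
    """

    individual_id: str
    species: str
    section_type: str = ""
    loci: dict[str, tuple[float, ...]] = field(default_factory=dict)
    ploidy: int | None = None
    signature: str = ""
    flags: list[str] = field(default_factory=list)

    def scored_loci(self) -> list[str]:
        return [name for name, alleles in self.loci.items() if alleles]


@dataclass
class GroupAssignment:
    """Partition of genotypes into analysis groups.

    Every genotype id appears either in ``assignments`` or in ``unassigned``
    (with a reason), never in both.
    """

    assignments: dict[str, str] = field(default_factory=dict)
    unassigned: dict[str, str] = field(default_factory=dict)

    def members(self, group_id: str) -> list[str]:
        return [i for i, g in self.assignments.items() if g == group_id]


# ---------------------------------------------------------------------------
# I/O


def read_loci_yaml(path) -> list[LocusDef]:
    """Read a loci config YAML: a list of {name, repeat_unit, size_range}."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    out = []
    for item in raw:
        out.append(
            LocusDef(
                name=str(item["name"]),
                repeat_unit=int(item["repeat_unit"]),
                size_range=tuple(item.get("size_range", (50, 400))),
            )
        )
    return out


def read_genotypes(path, loci: Sequence[LocusDef] | None = None) -> list[PolyploidGenotype]:
    """Dispatch on extension: ``.csv`` -> GenAlEx dialect, ``.tsv`` -> long format."""
    p = str(path)
    if p.endswith(".tsv"):
        return read_long_tsv(path, loci)
    return read_genalex_csv(path, loci)


def _parse_allele(cell: str, lineno: int) -> float | None:
    cell = cell.strip()
    if cell in ("", "0", "0.0"):
        return None
    try:
        v = float(cell)
    except ValueError:
        raise GenotypeParseError(f"line {lineno}: non-numeric allele {cell!r}") from None
    if v <= 0:
        raise GenotypeParseError(f"line {lineno}: non-positive allele {cell!r}")
    return v


def read_genalex_csv(path, loci: Sequence[LocusDef] | None = None) -> list[PolyploidGenotype]:
    """Read a GenAlEx-style polyploid CSV.

    Layout: row 1 = ``n_loci, n_samples, ...``; row 2 = title; row 3 =
    ``Sample, Pop`` followed by each locus name heading a block of allele
    columns (continuation columns left blank); data rows hold variable
    numbers of allele sizes per locus, blank or 0 meaning unused and a fully
    blank block meaning the locus is missing.
    """
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh))
    if len(rows) < 4:
        raise GenotypeParseError("file too short for GenAlEx layout")
    try:
        n_loci = int(rows[0][0])
        n_samples = int(rows[0][1])
    except (IndexError, ValueError):
        raise GenotypeParseError("line 1: expected 'n_loci,n_samples,...'") from None
    header = rows[2]
    known = {l.name for l in loci} if loci else None
    # locus blocks: (name, start column, width)
    blocks: list[tuple[str, int, int]] = []
    for j in range(2, len(header)):
        name = header[j].strip()
        if name:
            if known is not None and name not in known:
                raise GenotypeParseError(f"line 3: unknown locus name {name!r}")
            blocks.append([name, j, 0])  # type: ignore[list-item]
    for k, (name, start, _) in enumerate(blocks):
        end = blocks[k + 1][1] if k + 1 < len(blocks) else len(header)
        blocks[k] = (name, start, end - start)
    if len(blocks) != n_loci:
        raise GenotypeParseError(
            f"line 3: header declares {len(blocks)} loci, line 1 says {n_loci}"
        )
    genotypes: list[PolyploidGenotype] = []
    for i, row in enumerate(rows[3:], start=4):
        if not any(c.strip() for c in row):
            continue
        ind, pop = row[0].strip(), row[1].strip()
        loci_map: dict[str, tuple[float, ...]] = {}
        for name, start, width in blocks:
            alleles = []
            for j in range(start, start + width):
                if j < len(row):
                    v = _parse_allele(row[j], i)
                    if v is not None:
                        alleles.append(v)
            loci_map[name] = tuple(sorted(alleles))
        genotypes.append(
            PolyploidGenotype(individual_id=ind, species=pop, loci=loci_map)
        )
    if len(genotypes) != n_samples:
        raise GenotypeParseError(
            f"found {len(genotypes)} genotype rows, line 1 declares {n_samples}"
        )
    return genotypes


def read_long_tsv(path, loci: Sequence[LocusDef] | None = None) -> list[PolyploidGenotype]:
    """Read a long-format TSV: individual, species, section, locus, alleles.

    ``alleles`` is semicolon-separated; an empty field records a missing
    locus.  One row per individual x locus.
    """
    known = {l.name for l in loci} if loci else None
    table: dict[str, PolyploidGenotype] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: k for k, name in enumerate(header)}
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            ind = parts[idx["individual"]]
            locus = parts[idx["locus"]]
            if known is not None and locus not in known:
                raise GenotypeParseError(f"line {lineno}: unknown locus name {locus!r}")
            raw = parts[idx["alleles"]].strip() if "alleles" in idx else ""
            alleles = tuple(
                sorted(
                    v
                    for v in (_parse_allele(c, lineno) for c in raw.split(";") if c.strip())
                    if v is not None
                )
            )
            if ind not in table:
                table[ind] = PolyploidGenotype(
                    individual_id=ind,
                    species=parts[idx["species"]] if "species" in idx else "",
                    section_type=parts[idx["section"]] if "section" in idx else "",
                )
            table[ind].loci[locus] = alleles
    return list(table.values())


def write_genalex_csv(
    genotypes: Sequence[PolyploidGenotype],
    path,
    loci: Sequence[LocusDef],
    max_alleles: int = 6,
    title: str = "porphyra genotypes",
) -> None:
    """Write genotypes in the GenAlEx dialect read by :func:`read_genalex_csv`."""
    pops = sorted({g.species for g in genotypes})
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow([len(loci), len(genotypes), len(pops)] + [
            sum(g.species == p for g in genotypes) for p in pops
        ])
        w.writerow([title, ""] + pops)
        header = ["Sample", "Pop"]
        for l in loci:
            header.extend([l.name] + [""] * (max_alleles - 1))
        w.writerow(header)
        for g in genotypes:
            row = [g.individual_id, g.species]
            for l in loci:
                alleles = list(g.loci.get(l.name, ()))[:max_alleles]
                row.extend([f"{a:g}" for a in alleles] + [""] * (max_alleles - len(alleles)))
            w.writerow(row)


def write_long_tsv(genotypes: Sequence[PolyploidGenotype], path) -> None:
    with open(path, "w") as fh:
        fh.write("individual\tspecies\tsection\tlocus\talleles\n")
        for g in genotypes:
            for locus, alleles in sorted(g.loci.items()):
                fh.write(
                    f"{g.individual_id}\t{g.species}\t{g.section_type}\t{locus}\t"
                    + ";".join(f"{a:g}" for a in alleles)
                    + "\n"
                )


# ---------------------------------------------------------------------------
# Binning


def fit_grid_offset(sizes: Sequence[float], repeat_unit: int) -> float:
    """Least-squares offset of the allele grid ``offset + k * repeat_unit``.

    The residuals of fragment sizes modulo the repeat unit live on a circle;
    the circular mean minimises the summed squared circular distance.
    """
    u = float(repeat_unit)
    theta = 2.0 * math.pi * (np.asarray(sizes, dtype=float) % u) / u
    s, c = np.sin(theta).mean(), np.cos(theta).mean()
    return (math.atan2(s, c) * u / (2.0 * math.pi)) % u


def bin_alleles(
    g: PolyploidGenotype,
    loci: Sequence[LocusDef],
    offsets: Mapping[str, float] | None = None,
    flag_frac: float = 0.45,
) -> PolyploidGenotype:
    """Snap alleles to the nearest repeat-unit grid point per locus.

    *offsets* maps locus name to a grid offset, typically fitted across the
    whole dataset with :func:`fit_grid_offset`; when absent, the offset is
    fitted from this genotype's own alleles.  An allele further than
    ``flag_frac * repeat_unit`` from its nearest grid point is kept unbinned
    and flagged.  Alleles identical after binning are collapsed; the
    operation is idempotent.
    """
    new_loci: dict[str, tuple[float, ...]] = dict(g.loci)
    flags = list(g.flags)
    for l in loci:
        alleles = g.loci.get(l.name)
        if not alleles:
            continue
        u = float(l.repeat_unit)
        if offsets is not None and l.name in offsets:
            off = offsets[l.name]
        else:
            off = fit_grid_offset(alleles, l.repeat_unit)
        binned = []
        for a in alleles:
            grid = off + round((a - off) / u) * u
            if abs(a - grid) > flag_frac * u:
                flags.append(f"{l.name}:{a:g}:off-grid")
                binned.append(float(a))
            else:
                binned.append(float(round(grid)))
        new_loci[l.name] = tuple(sorted(set(binned)))
    return replace(g, loci=new_loci, flags=flags)


# ---------------------------------------------------------------------------
# Ploidy cross-checks and grouping


def max_allele_ploidy(g: PolyploidGenotype) -> int:
    """Maximum number of distinct alleles at any locus: a lower ploidy bound."""
    counts = [len(set(a)) for a in g.loci.values() if a]
    if not counts:
        raise ValueError(f"genotype {g.individual_id} has no scored loci")
    return max(counts)


def concordance_check(g: PolyploidGenotype, flow_ploidy: int) -> bool:
    """Pass iff the allele-count ploidy bound does not exceed the flow call.

    Failure indicates a miscalled ploidy or cross-contamination; passing does
    not prove the flow ploidy since dosage hides copies.
    """
    return max_allele_ploidy(g) <= flow_ploidy


def assign_groups(
    genotypes: Iterable[PolyploidGenotype],
    rule_table: Mapping[tuple[str, str], str],
) -> GroupAssignment:
    """Deterministic (species, ploidy signature) -> group partition.

    Signatures use the same '/', ',', '+' grammar as cytotype notation.
    Genotypes whose (species, signature) key is absent from *rule_table* are
    reported unassigned.
    """
    ga = GroupAssignment()
    for g in genotypes:
        key = (g.species, g.signature)
        if key in rule_table:
            ga.assignments[g.individual_id] = rule_table[key]
        else:
            ga.unassigned[g.individual_id] = (
                f"no rule for species={g.species!r} signature={g.signature!r}"
            )
    return ga


def impute_missing(
    genotypes: Sequence[PolyploidGenotype],
    seed: int,
) -> tuple[list[PolyploidGenotype], list[str]]:
    """Fill missing loci by random draws from the group allele pool.

    For each locus, the pool is every allele observed across the group
    (phenotype occurrences, with multiplicity).  A missing locus receives
    the group's modal distinct-allele count of draws, sampled with
    replacement; the phenotype is their distinct set.  Reproducible under
    *seed*.  Loci missing in every member are left missing and reported.
    """
    rng = np.random.default_rng(seed)
    locus_names = sorted({name for g in genotypes for name in g.loci})
    pools: dict[str, list[float]] = {}
    modal: dict[str, int] = {}
    for name in locus_names:
        pool: list[float] = []
        counts: list[int] = []
        for g in genotypes:
            alleles = g.loci.get(name, ())
            if alleles:
                pool.extend(alleles)
                counts.append(len(set(alleles)))
        pools[name] = pool
        if counts:
            modal[name] = Counter(counts).most_common(1)[0][0]
    warnings: list[str] = []
    out: list[PolyploidGenotype] = []
    for g in genotypes:
        new_loci = dict(g.loci)
        for name in locus_names:
            if new_loci.get(name, ()):
                continue
            pool = pools[name]
            if not pool:
                warnings.append(f"locus {name} missing in all group members")
                continue
            draws = rng.choice(pool, size=modal[name], replace=True)
            new_loci[name] = tuple(sorted(set(float(a) for a in draws)))
        out.append(replace(g, loci=new_loci))
    return out, warnings
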