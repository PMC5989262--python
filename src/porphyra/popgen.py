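"""Population-genetic statistics for dosage-ambiguous polyploid genotypes.

Allele frequencies are estimated either naively (each distinct allele of an
individual weighted equally, the "phenotype frequency" convention) or by
maximum likelihood under polysomic inheritance: an EM algorithm integrates
over the hidden allele dosages given each individual's observed allele set
and total ploidy.  Diversity is summarised as the number of alleles, the
effective number of alleles ``1 / sum(p^2)``, and gene diversities Hs / Ht
with the Nei & Chesser (1983) small-sample corrections.  Differentiation is
reported as Nei's G_ST ``(Ht - Hs) / Ht`` and Jost's D
``(k / (k - 1)) (Ht - Hs) / (1 - Hs)``.  Individual-level analyses use an
allele-sharing distance feeding neighbour-joining trees and a PCA of
allele-presence indicators.
"""

from __future__ import annotations

import io
import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from skbio import DistanceMatrix as _SkbioDM
from skbio.tree import nj as _skbio_nj

from .genotypes import PolyploidGenotype

__all__ = [
    "AlleleFreqs",
    "DiversityReport",
    "DifferentiationMatrix",
    "IndividualDistanceMatrix",
    "allele_freqs_naive",
    "allele_freqs_ml",
    "exact_coverage_prob",
    "diversity",
    "nei_gst",
    "jost_d",
    "pairwise_differentiation",
    "individual_distances",
    "nj_tree",
    "pca_allelic",
]


@dataclass
class AlleleFreqs:
    """Per-locus allele frequencies of one group."""

    group_id: str
    freqs: dict[str, dict[float, float]]
    sample_sizes: dict[str, int]
    method: str = "naive"
    converged: bool = True
    loglik: dict[str, float] = field(default_factory=dict)
    #: per-locus gene-copy counts (sum of ploidies of scored individuals);
    #: set by the EM estimator, where the gene copy is the sampling unit
    gene_copies: dict[str, int] | None = None

    def loci(self) -> list[str]:
        return sorted(self.freqs)


@dataclass
class DiversityReport:
    """Diversity statistics per locus and averaged over loci."""

    group_ids: list[str]
    per_locus: pd.DataFrame  # columns: locus, num, eff_num, hs, ht, n_harmonic
    dropped_loci: list[str] = field(default_factory=list)
    flags: list[str] = field(default_factory=list)

    def _mean_sd(self, col: str) -> tuple[float, float]:
        v = self.per_locus[col].to_numpy(dtype=float)
        return float(v.mean()), float(v.std(ddof=1)) if len(v) > 1 else 0.0

    @property
    def num(self) -> float:
        return self._mean_sd("num")[0]

    @property
    def eff_num(self) -> float:
        return self._mean_sd("eff_num")[0]

    @property
    def hs(self) -> float:
        return self._mean_sd("hs")[0]

    @property
    def ht(self) -> float:
        return self._mean_sd("ht")[0]

    def summary(self) -> dict[str, tuple[float, float]]:
        return {c: self._mean_sd(c) for c in ("num", "eff_num", "hs", "ht")}


@dataclass
class DifferentiationMatrix:
    """Pairwise Nei G_ST / Jost's D between groups."""

    group_ids: list[str]
    gst: pd.DataFrame
    d: pd.DataFrame
    per_locus: dict[tuple[str, str], pd.DataFrame] = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)


@dataclass
class IndividualDistanceMatrix:
    ids: list[str]
    values: np.ndarray  # square, symmetric, zero diagonal; NaN = no shared loci

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


# ---------------------------------------------------------------------------
# Allele frequencies


def allele_freqs_naive(
    genotypes: Sequence[PolyploidGenotype], group_id: str = ""
) -> AlleleFreqs:
    """Phenotype-frequency estimate: each individual's distinct alleles get
    equal weight summing to one, then frequencies are averaged over the
    individuals scored at the locus."""
    if not genotypes:
        raise ValueError("need at least one genotype")
    locus_names = sorted({n for g in genotypes for n in g.loci})
    freqs: dict[str, dict[float, float]] = {}
    sizes: dict[str, int] = {}
    for name in locus_names:
        acc: dict[float, float] = {}
        n = 0
        for g in genotypes:
            alleles = set(g.loci.get(name, ()))
            if not alleles:
                continue
            n += 1
            w = 1.0 / len(alleles)
            for a in alleles:
                acc[a] = acc.get(a, 0.0) + w
        if n == 0:
            continue  # empty across the group; dropped
        freqs[name] = {a: v / n for a, v in acc.items()}
        sizes[name] = n
    return AlleleFreqs(group_id=group_id, freqs=freqs, sample_sizes=sizes, method="naive")


def exact_coverage_prob(
    p: np.ndarray, subset: Sequence[int], n: int, within: Sequence[int]
) -> float:
    """P(n iid draws from p all fall in *within* and cover every index of
    *subset*), by inclusion-exclusion over the missed part of *subset*."""
    p_within = float(sum(p[i] for i in within))
    total = 0.0
    sub = list(subset)
    for r in range(len(sub) + 1):
        for miss in itertools.combinations(sub, r):
            total += (-1.0) ** r * (p_within - sum(p[i] for i in miss)) ** n
    return total


def allele_freqs_ml(
    genotypes: Sequence[PolyploidGenotype],
    ploidies: Mapping[str, int] | None = None,
    group_id: str = "",
    max_iter: int = 1000,
    tol: float = 1e-8,
    return_trace: bool = False,
) -> AlleleFreqs | tuple[AlleleFreqs, dict[str, list[float]]]:
    """Maximum-likelihood allele frequencies with dosage correction (EM).

    Model: at each locus an individual of ploidy ``m`` carries ``m`` allele
    copies drawn independently from the group frequencies (polysomic random
    union); only the set of distinct alleles is observed.  The E-step
    computes the expected dosage of each observed allele conditional on the
    observed set and the total ploidy; the M-step renormalises expected
    counts.  Initialisation is uniform over observed alleles, so the fit is
    deterministic.  The log-likelihood is non-decreasing across iterations.

    *ploidies* maps individual id to ploidy; when absent, ``g.ploidy`` is
    used (falling back to the number of distinct alleles if unknown).
    """
    if not genotypes:
        raise ValueError("need at least one genotype")

    def ploidy_of(g: PolyploidGenotype, shown: int) -> int:
        m = ploidies.get(g.individual_id) if ploidies else g.ploidy
        if m is None:
            m = shown
        return max(int(m), shown)

    locus_names = sorted({n for g in genotypes for n in g.loci})
    freqs: dict[str, dict[float, float]] = {}
    sizes: dict[str, int] = {}
    copies: dict[str, int] = {}
    logliks: dict[str, float] = {}
    traces: dict[str, list[float]] = {}
    converged_all = True
    for name in locus_names:
        obs: list[tuple[tuple[int, ...], int]] = []
        alleles = sorted({a for g in genotypes for a in g.loci.get(name, ())})
        index = {a: i for i, a in enumerate(alleles)}
        for g in genotypes:
            shown = sorted(set(g.loci.get(name, ())))
            if not shown:
                continue
            obs.append(
                (tuple(index[a] for a in shown), ploidy_of(g, len(shown)))
            )
        if not obs:
            continue
        k = len(alleles)
        p = np.full(k, 1.0 / k)
        trace: list[float] = []
        converged = False
        for _ in range(max_iter):
            counts = np.zeros(k)
            ll = 0.0
            for subset, m in obs:
                denom = exact_coverage_prob(p, subset, m, subset)
                denom = max(denom, 1e-300)
                ll += math.log(denom)
                for a in subset:
                    rest = [b for b in subset if b != a]
                    num = m * p[a] * exact_coverage_prob(p, rest, m - 1, subset)
                    counts[a] += num / denom
            trace.append(ll)
            new_p = counts / counts.sum()
            if np.max(np.abs(new_p - p)) < tol:
                p = new_p
                converged = True
                break
            p = new_p
        converged_all = converged_all and converged
        freqs[name] = {a: float(p[index[a]]) for a in alleles}
        sizes[name] = len(obs)
        copies[name] = sum(m for _, m in obs)
        logliks[name] = trace[-1]
        traces[name] = trace
    out = AlleleFreqs(
        group_id=group_id,
        freqs=freqs,
        sample_sizes=sizes,
        method="ml",
        converged=converged_all,
        loglik=logliks,
        gene_copies=copies,
    )
    if return_trace:
        return out, traces
    return out


# ---------------------------------------------------------------------------
# Diversity and differentiation


def _harmonic_mean(values: Sequence[int]) -> float:
    return len(values) / sum(1.0 / v for v in values)


def diversity(
    freqs: AlleleFreqs | Sequence[AlleleFreqs],
) -> DiversityReport:
    """Num, Eff_num, Hs, Ht per locus with small-sample corrections.

    For ``k`` groups of (harmonic mean) sample size ``n``:
    ``Hs = n / (n - 1) * (1 - mean_g sum_a p_ga^2)`` and
    ``Ht = 1 - sum_a pbar_a^2 + Hs / (n k)`` with ``pbar`` the unweighted
    mean frequency across groups (Nei & Chesser 1983).  The sampling unit
    matches the frequency estimator: gene copies (individuals x ploidy) for
    the EM dosage-corrected frequencies, individuals for naive phenotype
    frequencies, whose per-individual weights make the phenotype the sampled
    unit.  With a single group ``Ht = Hs``.  Loci unscored in any group are
    dropped and reported.
    """
    groups = [freqs] if isinstance(freqs, AlleleFreqs) else list(freqs)
    if not groups:
        raise ValueError("need at least one group")
    k = len(groups)
    common = sorted(set.intersection(*(set(g.freqs) for g in groups)))
    all_loci = sorted(set.union(*(set(g.freqs) for g in groups)))
    dropped = [l for l in all_loci if l not in common]
    rows = []
    flags: list[str] = []
    use_copies = all(g.gene_copies is not None for g in groups)
    for name in common:
        per_group = [g.freqs[name] for g in groups]
        if use_copies:
            sizes = [g.gene_copies[name] for g in groups]
        else:
            sizes = [g.sample_sizes[name] for g in groups]
        n_tilde = _harmonic_mean(sizes)
        alleles = sorted(set().union(*per_group))
        mat = np.array([[pg.get(a, 0.0) for a in alleles] for pg in per_group])
        within = float(np.mean(np.sum(mat**2, axis=1)))
        hs_raw = 1.0 - within
        if n_tilde > 1:
            hs = n_tilde / (n_tilde - 1.0) * hs_raw
        else:
            hs = hs_raw
            flags.append(f"{name}: sample size 1, Hs uncorrected")
        pbar = mat.mean(axis=0)
        if k == 1:
            ht = hs
        else:
            ht = 1.0 - float(np.sum(pbar**2)) + hs / (n_tilde * k)
        num = int(np.sum(pbar > 0))
        eff_num = 1.0 / float(np.sum(pbar**2))
        rows.append(
            dict(locus=name, num=num, eff_num=eff_num, hs=hs, ht=ht, n_harmonic=n_tilde)
        )
    if not rows:
        raise ValueError("no locus scored in every group")
    return DiversityReport(
        group_ids=[g.group_id for g in groups],
        per_locus=pd.DataFrame(rows),
        dropped_loci=dropped,
        flags=flags,
    )


def nei_gst(hs: float, ht: float) -> float:
    """Nei's coefficient of gene differentiation ``(Ht - Hs) / Ht``."""
    if ht < 0:
        raise ValueError("ht must be non-negative")
    if ht == 0:
        return float("nan")
    return (ht - hs) / ht


def jost_d(hs: float, ht: float, k: int = 2) -> float:
    """Jost's allelic differentiation ``(k/(k-1)) (Ht - Hs) / (1 - Hs)``."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if hs >= 1:
        return float("nan")
    return (k / (k - 1.0)) * (ht - hs) / (1.0 - hs)


def pairwise_differentiation(
    groups: Mapping[str, Sequence[PolyploidGenotype]],
    dosage_corrected: bool = False,
    ploidies: Mapping[str, int] | None = None,
) -> DifferentiationMatrix:
    """Pairwise G_ST and Jost's D over all group pairs.

    Hs and Ht come from the two groups of the pair only; both are averaged
    over loci first and the statistic applied to the means (per-locus values
    are retained).  With *dosage_corrected* the EM frequencies are used.
    Negative estimates from the unbiased corrections are reported as
    computed.  Pairs without a shared scored locus are reported missing.
    """
    ids = list(groups)
    flags: list[str] = []
    freq_cache: dict[str, AlleleFreqs] = {}
    for gid in ids:
        members = groups[gid]
        if len(members) < 2:
            flags.append(f"group {gid}: fewer than 2 individuals")
        if dosage_corrected:
            freq_cache[gid] = allele_freqs_ml(members, ploidies, group_id=gid)
        else:
            freq_cache[gid] = allele_freqs_naive(members, group_id=gid)
    n = len(ids)
    gst = np.zeros((n, n))
    d = np.zeros((n, n))
    per_locus: dict[tuple[str, str], pd.DataFrame] = {}
    for i, j in itertools.combinations(range(n), 2):
        try:
            rep = diversity([freq_cache[ids[i]], freq_cache[ids[j]]])
        except ValueError:
            gst[i, j] = gst[j, i] = np.nan
            d[i, j] = d[j, i] = np.nan
            flags.append(f"pair ({ids[i]}, {ids[j]}): no shared scored loci")
            continue
        g = nei_gst(rep.hs, rep.ht)
        dj = jost_d(rep.hs, rep.ht, k=2)
        gst[i, j] = gst[j, i] = g
        d[i, j] = d[j, i] = dj
        pl = rep.per_locus.copy()
        pl["gst"] = [nei_gst(h, t) for h, t in zip(pl["hs"], pl["ht"])]
        pl["jost_d"] = [jost_d(h, t, 2) for h, t in zip(pl["hs"], pl["ht"])]
        per_locus[(ids[i], ids[j])] = pl
    return DifferentiationMatrix(
        group_ids=ids,
        gst=pd.DataFrame(gst, index=ids, columns=ids),
        d=pd.DataFrame(d, index=ids, columns=ids),
        per_locus=per_locus,
        flags=flags,
    )


# ---------------------------------------------------------------------------
# Individual-level analyses


def individual_distances(
    genotypes: Sequence[PolyploidGenotype],
) -> IndividualDistanceMatrix:
    """Allele-sharing distance between genotype pairs.

    Per locus scored in both individuals:
    ``1 - |A intersect B| / max(|A|, |B|)``, averaged over loci; in [0, 1].
    Pairs with no shared scored locus get NaN.
    """
    if len(genotypes) < 2:
        raise ValueError("need at least two genotypes")
    ids = [g.individual_id for g in genotypes]
    n = len(genotypes)
    vals = np.zeros((n, n))
    sets = [
        {name: frozenset(a) for name, a in g.loci.items() if a} for g in genotypes
    ]
    for i, j in itertools.combinations(range(n), 2):
        shared = sets[i].keys() & sets[j].keys()
        if not shared:
            vals[i, j] = vals[j, i] = np.nan
            continue
        ds = [
            1.0 - len(sets[i][l] & sets[j][l]) / max(len(sets[i][l]), len(sets[j][l]))
            for l in shared
        ]
        vals[i, j] = vals[j, i] = float(np.mean(ds))
    return IndividualDistanceMatrix(ids=ids, values=vals)


def nj_tree(dist: IndividualDistanceMatrix) -> str:
    """Neighbour-joining tree (Saitou & Nei) as a Newick string.

    Requires a complete symmetric matrix with at least three taxa; missing
    pairs abort with the list of offending pairs.
    """
    if len(dist.ids) < 3:
        raise ValueError("neighbour joining needs at least 3 taxa")
    if np.isnan(dist.values).any():
        missing = [
            (dist.ids[i], dist.ids[j])
            for i, j in zip(*np.where(np.isnan(np.triu(dist.values))))
        ]
        raise ValueError(f"distance matrix incomplete for pairs: {missing}")
    dm = _SkbioDM(dist.values, ids=dist.ids)
    tree = _skbio_nj(dm)
    buf = io.StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue().strip()


def pca_allelic(
    genotypes: Sequence[PolyploidGenotype],
) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of allele-presence indicators across individuals.

    The design matrix has one 0/1 column per (locus, allele), columns sorted
    lexicographically and mean-centered; scores come from the SVD.  Each axis
    is oriented so that its first non-zero loading is positive.  Missing data
    must be imputed beforehand.  Returns (scores, explained-variance
    fractions); a constant matrix yields all-zero scores.
    """
    columns = sorted(
        {(name, a) for g in genotypes for name, alleles in g.loci.items() for a in alleles}
    )
    col_index = {c: i for i, c in enumerate(columns)}
    X = np.zeros((len(genotypes), len(columns)))
    for r, g in enumerate(genotypes):
        for name, alleles in g.loci.items():
            for a in alleles:
                X[r, col_index[(name, a)]] = 1.0
    X -= X.mean(axis=0)
    u, s, vt = np.linalg.svd(X, full_matrices=False)
    total = float(np.sum(s**2))
    if total < 1e-12:
        scores = np.zeros_like(u)
        explained = np.zeros(len(s))
    else:
        for j in range(vt.shape[0]):
            nz = np.nonzero(np.abs(vt[j]) > 1e-12)[0]
            if len(nz) and vt[j, nz[0]] < 0:
                vt[j] *= -1.0
                u[:, j] *= -1.0
        scores = u * s
        explained = s**2 / total
    frame = pd.DataFrame(
        scores,
        index=[g.individual_id for g in genotypes],
        columns=[f"PC{j + 1}" for j in range(scores.shape[1])],
    )
    return frame, explained
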