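"""Per-genome count profiles and nonparametric group comparisons.

Group differences in PDZ protein/domain counts (habitat, oxygen requirement,
Gram stain, kingdom) are assessed with the Wilcoxon–Mann–Whitney rank-sum
test, one-sided by default with significance at p < 0.05; genome-size trends
with Spearman rank correlation.  The rank-sum test enumerates the exact null
distribution for small tie-free samples and otherwise uses the tie-corrected
normal approximation with continuity correction.
"""

from __future__ import annotations

import enum
import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .architecture import ProteinArchitecture
from .io_formats import (
    GenomeMetadata,
    Gram,
    Habitat,
    Kingdom,
    Localization,
    LocalizationRecord,
    Oxygen,
)

__all__ = [
    "GenomeProfile",
    "Alternative",
    "Method",
    "RankSumResult",
    "GroupComparison",
    "build_profiles",
    "rank_sum_test",
    "exact_rank_sum_p",
    "compare_groups",
    "size_trend",
    "localization_fractions",
    "write_profiles",
    "write_comparisons",
    "SIGNIFICANCE_LEVEL",
]

#: Significance rule used throughout: reject when p < 0.05.
SIGNIFICANCE_LEVEL = 0.05


@dataclass(frozen=True)
class GenomeProfile:
    """Derived PDZ counts and localization tallies for one genome.

    ``n_pdz_domains`` sums tandem counts over proteins; ``n_multidomain``
    counts PDZ proteins with at least one non-PDZ domain — proteins with
    repetitive PDZ domains alone are not counted as multidomain.
    """

    metadata: GenomeMetadata
    n_pdz_proteins: int
    n_pdz_domains: int
    n_multidomain: int
    loc_counts: Mapping[Localization, int]

    def __post_init__(self) -> None:
        if self.n_pdz_proteins > 0 and self.n_pdz_domains < self.n_pdz_proteins:
            raise ValueError("domain count cannot be below protein count")
        if self.n_multidomain > self.n_pdz_proteins:
            raise ValueError("multidomain count cannot exceed protein count")
        if sum(self.loc_counts.values()) != self.n_pdz_proteins:
            raise ValueError("localization counts must sum to the protein count")


class Alternative(enum.Enum):
    GREATER = "GREATER"  # first sample tends larger
    LESS = "LESS"
    TWO_SIDED = "TWO_SIDED"


class Method(enum.Enum):
    EXACT = "EXACT"
    NORMAL = "NORMAL"


@dataclass(frozen=True)
class RankSumResult:
    U: float  # Mann-Whitney statistic of the first sample
    n1: int
    n2: int
    z: float
    p: float
    alternative: Alternative
    method: Method

    def __post_init__(self) -> None:
        if not (0 <= self.U <= self.n1 * self.n2):
            raise ValueError("U out of range")
        if not (0 <= self.p <= 1):
            raise ValueError("p out of range")

    @property
    def significant(self) -> bool:
        return self.p < SIGNIFICANCE_LEVEL


def build_profiles(
    architectures: Mapping[str, ProteinArchitecture],
    localizations: Iterable[LocalizationRecord],
    metadata: Sequence[GenomeMetadata],
    protein_to_genome: Mapping[str, str],
) -> list[GenomeProfile]:
    """One profile per genome in ``metadata`` (zero counts where no PDZ
    protein maps there); proteins mapping to unknown genomes raise."""
    loc_by_prot = {r.protein_id: r.category for r in localizations}
    taxa = {m.taxon_id for m in metadata}
    per_genome: dict[str, list[ProteinArchitecture]] = {t: [] for t in taxa}
    orphans = []
    for pid, arch in architectures.items():
        taxon = protein_to_genome.get(pid)
        if taxon not in taxa:
            orphans.append(pid)
        else:
            per_genome[taxon].append(arch)
    if orphans:
        raise ValueError(f"proteins mapped to unknown genomes: {sorted(orphans)}")

    profiles = []
    for m in sorted(metadata, key=lambda m: m.taxon_id):
        archs = [a for a in per_genome[m.taxon_id] if a.has_pdz]
        loc_counts = {cat: 0 for cat in Localization}
        for a in archs:
            loc_counts[loc_by_prot.get(a.protein_id, Localization.NAN)] += 1
        profiles.append(
            GenomeProfile(
                metadata=m,
                n_pdz_proteins=len(archs),
                n_pdz_domains=sum(a.tandem_pdz_count for a in archs),
                n_multidomain=sum(1 for a in archs if a.non_pdz_domain_ids),
                loc_counts=loc_counts,
            )
        )
    return profiles


# ---------------------------------------------------------------------------
# Wilcoxon-Mann-Whitney rank-sum test
# ---------------------------------------------------------------------------


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """Mann-Whitney U of the first sample via midranks."""
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    r1 = ranks[: len(x)].sum()
    return r1 - len(x) * (len(x) + 1) / 2.0


def exact_rank_sum_p(
    x: Sequence[float], y: Sequence[float], alternative: Alternative | str
) -> float:
    """Brute-force oracle: exact tail probability of the observed rank sum
    over all C(n1+n2, n1) group labelings of the pooled sample.

    Handles ties through midranks on the actual pooled values.  Limited to
    n1+n2 <= 14.
    """
    alternative = Alternative(alternative) if isinstance(alternative, str) else alternative
    x, y = np.asarray(x, float), np.asarray(y, float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both samples must be non-empty")
    if n1 + n2 > 14:
        raise ValueError("exact enumeration limited to n1+n2 <= 14")
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    us = np.array(
        [sum(ranks[list(c)]) - n1 * (n1 + 1) / 2.0
         for c in itertools.combinations(range(n1 + n2), n1)]
    )
    eps = 1e-9
    if alternative is Alternative.GREATER:
        return float(np.mean(us >= u_obs - eps))
    if alternative is Alternative.LESS:
        return float(np.mean(us <= u_obs + eps))
    p = 2 * min(np.mean(us >= u_obs - eps), np.mean(us <= u_obs + eps))
    return float(min(1.0, p))


def rank_sum_test(
    x: Sequence[float],
    y: Sequence[float],
    alternative: Alternative | str = Alternative.TWO_SIDED,
    method: Method | str | None = None,
) -> RankSumResult:
    """Wilcoxon-Mann-Whitney rank-sum test.

    By default uses exact enumeration of rank assignments when n1+n2 <= 12
    and there are no ties, otherwise the normal approximation with
    tie-corrected variance and a 0.5 continuity correction.  ``method``
    forces one path (EXACT requires a tie-free sample with n1+n2 <= 12).
    ``alternative`` GREATER means the first sample tends larger.
    """
    alternative = Alternative(alternative) if isinstance(alternative, str) else alternative
    if isinstance(method, str):
        method = Method(method.upper())
    x, y = np.asarray(x, float), np.asarray(y, float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    u = _u_statistic(x, y)

    use_exact = n1 + n2 <= 12 and not has_ties if method is None else method is Method.EXACT
    if use_exact and (n1 + n2 > 12 or has_ties):
        raise ValueError("exact method requires a tie-free sample with n1+n2 <= 12")
    if use_exact:
        # exact: ranks are 1..N, enumerate placements of sample-1 ranks
        n = n1 + n2
        u_obs = u
        us = np.array(
            [sum(c) - n1 * (n1 + 1) / 2.0
             for c in itertools.combinations(range(1, n + 1), n1)],
            dtype=float,
        )
        if alternative is Alternative.GREATER:
            p = float(np.mean(us >= u_obs))
        elif alternative is Alternative.LESS:
            p = float(np.mean(us <= u_obs))
        else:
            p = float(min(1.0, 2 * min(np.mean(us >= u_obs), np.mean(us <= u_obs))))
        mu = n1 * n2 / 2.0
        sd = math.sqrt(n1 * n2 * (n + 1) / 12.0)
        z = (u - mu) / sd if sd > 0 else 0.0
        return RankSumResult(U=u, n1=n1, n2=n2, z=z, p=p,
                             alternative=alternative, method=Method.EXACT)

    n = n1 + n2
    mu = n1 * n2 / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var = n1 * n2 * (n + 1) / 12.0 - n1 * n2 * tie_term / (12.0 * n * (n - 1))
    if var <= 0:
        # all observations identical: no evidence either way
        return RankSumResult(U=u, n1=n1, n2=n2, z=0.0, p=1.0,
                             alternative=alternative, method=Method.NORMAL)
    sd = math.sqrt(var)
    if alternative is Alternative.GREATER:
        z = (u - mu - 0.5) / sd
        p = float(sps.norm.sf(z))
    elif alternative is Alternative.LESS:
        z = (u - mu + 0.5) / sd
        p = float(sps.norm.cdf(z))
    else:
        z = (u - mu - math.copysign(0.5, u - mu)) / sd if u != mu else 0.0
        p = float(min(1.0, 2 * sps.norm.sf(abs(z))))
    return RankSumResult(U=u, n1=n1, n2=n2, z=z, p=p,
                         alternative=alternative, method=Method.NORMAL)


# ---------------------------------------------------------------------------
# Group comparisons
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GroupComparison:
    grouping: str
    left_label: str
    right_label: str
    result: RankSumResult
    p_adjusted: float | None = None


#: Habitat complexity ordering used for adjacent-pair comparisons; the
#: directional null is "the right-side group is higher".
HABITAT_ORDER = [
    Habitat.SPECIALIZED,
    Habitat.HOST_ASSOCIATED,
    Habitat.MULTIPLE,
    Habitat.AQUATIC,
    Habitat.TERRESTRIAL,
]


def _measure_values(profiles: Sequence[GenomeProfile], measure: str) -> list[float]:
    if measure == "proteins":
        return [float(p.n_pdz_proteins) for p in profiles]
    if measure == "domains":
        return [float(p.n_pdz_domains) for p in profiles]
    raise ValueError(f"unknown measure {measure!r}")


def compare_groups(
    profiles: Sequence[GenomeProfile],
    grouping: str,
    measure: str = "domains",
    one_sided: bool = True,
    all_pairs: bool = False,
    adjust: bool = False,
    min_group: int = 2,
) -> list[GroupComparison]:
    """Rank-sum comparisons of per-genome counts between phenotype groups.

    ``grouping`` is one of ``habitat`` (adjacent pairs of the complexity
    ordering, or all pairs with ``all_pairs``), ``oxygen`` (non-aerobic vs
    aerobic), ``gram`` (positive vs negative), ``kingdom`` (archaea vs
    eubacteria and fungi vs eubacteria).  Tests are one-sided by default
    with the alternative that the right-side group is higher.  NA-phenotype
    genomes are excluded; groups below ``min_group`` genomes are skipped.
    Optional Benjamini-Hochberg adjustment across the returned list.
    """
    import logging

    logger = logging.getLogger(__name__)

    def genomes_where(pred) -> list[GenomeProfile]:
        return [p for p in profiles if pred(p.metadata)]

    pairs: list[tuple[str, list[GenomeProfile], str, list[GenomeProfile]]] = []
    if grouping == "habitat":
        order = HABITAT_ORDER
        groups = {
            h: genomes_where(lambda m, h=h: m.habitat is h) for h in order
        }
        seq = (
            list(itertools.combinations(order, 2)) if all_pairs
            else list(zip(order[:-1], order[1:]))
        )
        for lo, hi in seq:
            pairs.append((lo.value, groups[lo], hi.value, groups[hi]))
    elif grouping == "oxygen":
        non_aerobic = genomes_where(
            lambda m: m.oxygen in (Oxygen.ANAEROBIC, Oxygen.FACULTATIVE)
        )
        aerobic = genomes_where(lambda m: m.oxygen is Oxygen.AEROBIC)
        pairs.append(("NON_AEROBIC", non_aerobic, "AEROBIC", aerobic))
    elif grouping == "gram":
        pairs.append(
            (
                "POSITIVE",
                genomes_where(lambda m: m.gram is Gram.POSITIVE),
                "NEGATIVE",
                genomes_where(lambda m: m.gram is Gram.NEGATIVE),
            )
        )
    elif grouping == "kingdom":
        eub = genomes_where(lambda m: m.kingdom is Kingdom.EUBACTERIA)
        for other in (Kingdom.ARCHAEA, Kingdom.FUNGI):
            pairs.append(
                (other.value, genomes_where(lambda m, o=other: m.kingdom is o),
                 Kingdom.EUBACTERIA.value, eub)
            )
    else:
        raise ValueError(f"unknown grouping {grouping!r}")

    alternative = Alternative.LESS if one_sided else Alternative.TWO_SIDED
    out: list[GroupComparison] = []
    for left_label, left, right_label, right in pairs:
        if len(left) < min_group or len(right) < min_group:
            logger.warning(
                "skipping %s %s vs %s: group below %d genomes",
                grouping, left_label, right_label, min_group,
            )
            continue
        res = rank_sum_test(
            _measure_values(left, measure), _measure_values(right, measure), alternative
        )
        out.append(GroupComparison(grouping, left_label, right_label, res))

    if adjust and out:
        ps = [c.result.p for c in out]
        m = len(ps)
        order = np.argsort(ps)
        adj = np.empty(m)
        prev = 1.0
        for rank_idx in range(m - 1, -1, -1):
            i = order[rank_idx]
            val = min(prev, ps[i] * m / (rank_idx + 1))
            adj[i] = val
            prev = val
        out = [
            GroupComparison(c.grouping, c.left_label, c.right_label, c.result, float(adj[i]))
            for i, c in enumerate(out)
        ]
    return out


def size_trend(profiles: Sequence[GenomeProfile], kingdom: Kingdom) -> tuple[float, float]:
    """Spearman rank correlation between genome size (Mb) and the number of
    PDZ proteins within one kingdom; returns (rho, two-sided p)."""
    sub = [p for p in profiles if p.metadata.kingdom is kingdom]
    if len(sub) < 4:
        raise ValueError(f"need at least 4 genomes in {kingdom.value}, got {len(sub)}")
    sizes = [p.metadata.genome_size_mb for p in sub]
    counts = [p.n_pdz_proteins for p in sub]
    if len(set(sizes)) == 1 or len(set(counts)) == 1:
        raise ValueError("constant input; correlation undefined")
    rho, p = sps.spearmanr(sizes, counts)
    return float(rho), float(p)


def localization_fractions(
    profiles: Sequence[GenomeProfile], partition: str = "kingdom",
    skip_empty: bool = False,
) -> pd.DataFrame:
    """Fractions of TM/SP/TMSP/CYT among proteins with known localization,
    per partition value (``kingdom`` or ``gram``), plus an ``ALL`` row.

    Rows sum to 1; partitions with zero known-category proteins raise, or
    are dropped when ``skip_empty`` is set (small cohorts may lack, e.g.,
    fungal proteins entirely).
    """
    if partition not in ("kingdom", "gram"):
        raise ValueError(f"unknown partition {partition!r}")
    known = [Localization.TM, Localization.SP, Localization.TMSP, Localization.CYT]

    def label(p: GenomeProfile) -> str:
        return getattr(p.metadata, partition).value

    groups: dict[str, list[GenomeProfile]] = {}
    for p in profiles:
        groups.setdefault(label(p), []).append(p)
    groups["ALL"] = list(profiles)

    rows = {}
    for name in sorted(groups):
        counts = np.array(
            [sum(p.loc_counts.get(cat, 0) for p in groups[name]) for cat in known], float
        )
        total = counts.sum()
        if total == 0:
            if skip_empty:
                continue
            raise ValueError(f"partition {name!r} has no proteins with known localization")
        rows[name] = counts / total
    if not rows:
        raise ValueError("no partition has proteins with known localization")
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=[c.value for c in known]
    ).sort_index()


# ---------------------------------------------------------------------------
# TSV artifacts
# ---------------------------------------------------------------------------


def write_profiles(profiles: Sequence[GenomeProfile], path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(
            "taxon_id\tkingdom\tphylum\tgram\thabitat\toxygen\tgenome_size_mb\t"
            "n_pdz_proteins\tn_pdz_domains\tn_multidomain\tTM\tSP\tTMSP\tCYT\tNaN\n"
        )
        for p in sorted(profiles, key=lambda p: p.metadata.taxon_id):
            m = p.metadata
            lc = p.loc_counts
            fh.write(
                f"{m.taxon_id}\t{m.kingdom.value}\t{m.phylum}\t{m.gram.value}\t"
                f"{m.habitat.value}\t{m.oxygen.value}\t{m.genome_size_mb:.6g}\t"
                f"{p.n_pdz_proteins}\t{p.n_pdz_domains}\t{p.n_multidomain}\t"
                f"{lc.get(Localization.TM, 0)}\t{lc.get(Localization.SP, 0)}\t"
                f"{lc.get(Localization.TMSP, 0)}\t{lc.get(Localization.CYT, 0)}\t"
                f"{lc.get(Localization.NAN, 0)}\n"
            )


def write_comparisons(comparisons: Sequence[GroupComparison], path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("grouping\tleft\tright\tn_left\tn_right\tU\tz\tp\tmethod\tsignificant\tp_adjusted\n")
        for c in comparisons:
            r = c.result
            adj = f"{c.p_adjusted:.6g}" if c.p_adjusted is not None else ""
            fh.write(
                f"{c.grouping}\t{c.left_label}\t{c.right_label}\t{r.n1}\t{r.n2}\t"
                f"{r.U:.6g}\t{r.z:.6g}\t{r.p:.6g}\t{r.method.value}\t{int(r.significant)}\t{adj}\n"
            )
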