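"""Per-site variation, SNP distances, and synapomorphy accounting.

Conventions (all configurable where noted):

* Only the four unambiguous bases A, C, G, T carry information.  Gaps are
  missing data — never a fifth state — and IUPAC ambiguity codes are
  treated as missing by default (``ambiguity="missing"``).  With
  ``ambiguity="intersect"`` two characters count as different only if
  their IUPAC state sets are disjoint, so R vs A matches while R vs C
  differs.
* A synapomorphic column between groups G and H is one where every
  covering member of G carries one identical unambiguous base, every
  covering member of H carries a different identical unambiguous base,
  and at least ``min_coverage_fraction`` of each group covers the column
  (default 1.0: shared by *all* individuals studied).
* Columns are 0-based internally; reported 1-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from statistics import mean as _mean
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

from .datamodel import (
    ConfigError,
    GcpsrError,
    IUPAC_STATES,
    LocusAlignment,
    UNAMBIGUOUS,
)

__all__ = [
    "SiteClassification",
    "SynapomorphyReport",
    "GroupDistance",
    "GroupDistanceSummary",
    "classify_sites",
    "variability_summary",
    "pairwise_snp_distance",
    "group_distance",
    "count_synapomorphies",
]


@dataclass
class SiteClassification:
    """Classification of one alignment column.

    ``column`` is 1-based.  ``informative`` means at least two states are
    each carried by at least two sequences (parsimony-informative).
    ``coverage`` counts sequences with an unambiguous base at the column.
    """

    column: int
    site_class: str  # "invariant" | "variable"
    informative: bool
    coverage: int


@dataclass
class SynapomorphyReport:
    """Columns diagnostic between two specimen groups at one locus."""

    locus_name: str
    group_a: Set[str]
    group_b: Set[str]
    sites: List[Tuple[int, str, str]]  # (1-based column, state_A, state_B)

    @property
    def count(self) -> int:
        return len(self.sites)

    @property
    def columns(self) -> List[int]:
        return [c for c, _, _ in self.sites]


@dataclass
class GroupDistance:
    """Cross-pair SNP distance statistics between two groups at one locus."""

    locus_name: str
    group_a: Set[str]
    group_b: Set[str]
    min: int
    max: int
    mean: float
    n_pairs: int
    excluded_pairs: List[Tuple[str, str]]  # zero-overlap pairs, reported not dropped
    total_synapomorphies: int


@dataclass
class GroupDistanceSummary:
    """Per-locus distances plus totals over the loci where both groups occur."""

    per_locus: List[GroupDistance]
    skipped_loci: List[str]

    @property
    def total_min(self) -> int:
        return sum(d.min for d in self.per_locus)

    @property
    def total_max(self) -> int:
        return sum(d.max for d in self.per_locus)

    @property
    def total_mean(self) -> float:
        return sum(d.mean for d in self.per_locus)

    @property
    def total_synapomorphies(self) -> int:
        return sum(d.total_synapomorphies for d in self.per_locus)


def _is_unambiguous(ch: str) -> bool:
    return ch in UNAMBIGUOUS


def _differs(a: str, b: str, ambiguity: str) -> Optional[bool]:
    """Whether two characters differ; None when the comparison is missing."""
    if ambiguity == "missing":
        if a in UNAMBIGUOUS and b in UNAMBIGUOUS:
            return a != b
        return None
    # intersect mode: difference only when the IUPAC state sets are disjoint
    sa, sb = IUPAC_STATES[a], IUPAC_STATES[b]
    if not sa or not sb:
        return None
    return sa.isdisjoint(sb)


def classify_sites(aln: LocusAlignment) -> List[SiteClassification]:
    """Classify every column as invariant or variable.

    A column is ``variable`` iff at least two distinct unambiguous bases
    occur among the sequences covering it; gaps, N and ambiguity codes
    never create variability by themselves.
    """
    if len(aln) < 2:
        raise ConfigError("classify_sites needs an alignment with >= 2 sequences")
    out: List[SiteClassification] = []
    seqs = list(aln.sequences.values())
    for col in range(aln.length):
        counts: Dict[str, int] = {}
        for seq in seqs:
            ch = seq[col]
            if ch in UNAMBIGUOUS:
                counts[ch] = counts.get(ch, 0) + 1
        coverage = sum(counts.values())
        variable = len(counts) >= 2
        informative = sum(1 for c in counts.values() if c >= 2) >= 2
        out.append(
            SiteClassification(
                column=col + 1,
                site_class="variable" if variable else "invariant",
                informative=informative,
                coverage=coverage,
            )
        )
    return out


def variability_summary(aln: LocusAlignment) -> Dict[str, float]:
    """Percent variable and percent parsimony-informative sites.

    Denominator: columns covered by at least two unambiguous bases (a
    column seen in fewer than two sequences cannot show variation).
    """
    sites = classify_sites(aln)
    assessable = [s for s in sites if s.coverage >= 2]
    n = len(assessable)
    n_var = sum(1 for s in assessable if s.site_class == "variable")
    n_inf = sum(1 for s in assessable if s.informative)
    return {
        "locus": aln.locus_name,
        "columns": aln.length,
        "assessable": n,
        "variable": n_var,
        "informative": n_inf,
        "percent_variable": 100.0 * n_var / n if n else 0.0,
        "percent_informative": 100.0 * n_inf / n if n else 0.0,
    }


def pairwise_snp_distance(
    aln: LocusAlignment, a: str, b: str, ambiguity: str = "missing"
) -> Tuple[int, int]:
    """SNP distance and overlap between two specimens.

    Returns ``(distance, overlap)``: the number of columns where both carry
    comparable bases and they differ, and the number of columns where both
    carry comparable (unambiguous, in the default mode) bases.
    """
    sa, sb = aln[a], aln[b]
    distance = overlap = 0
    for ca, cb in zip(sa, sb):
        diff = _differs(ca, cb, ambiguity)
        if diff is None:
            continue
        overlap += 1
        if diff:
            distance += 1
    return distance, overlap


def _check_groups(G: Set[str], H: Set[str]) -> None:
    if not G or not H:
        raise ConfigError("groups must be non-empty")
    if G & H:
        raise ConfigError(f"groups overlap: {sorted(G & H)}")


def count_synapomorphies(
    aln: LocusAlignment,
    G: Iterable[str],
    H: Iterable[str],
    min_coverage_fraction: float = 1.0,
) -> SynapomorphyReport:
    """Columns where G and H are each uniform for different bases.

    With the default ``min_coverage_fraction=1.0`` every member of each
    group must carry an unambiguous base at the column; relax for
    fungarium-grade partial sequences.
    """
    G, H = set(G), set(H)
    _check_groups(G, H)
    g_seqs = [aln[s] for s in sorted(G) if s in aln]
    h_seqs = [aln[s] for s in sorted(H) if s in aln]
    sites: List[Tuple[int, str, str]] = []
    if g_seqs and h_seqs:
        for col in range(aln.length):
            ga = {s[col] for s in g_seqs if s[col] in UNAMBIGUOUS}
            hb = {s[col] for s in h_seqs if s[col] in UNAMBIGUOUS}
            if len(ga) != 1 or len(hb) != 1 or ga == hb:
                continue
            cov_g = sum(1 for s in g_seqs if s[col] in UNAMBIGUOUS)
            cov_h = sum(1 for s in h_seqs if s[col] in UNAMBIGUOUS)
            if (
                cov_g >= min_coverage_fraction * len(g_seqs)
                and cov_h >= min_coverage_fraction * len(h_seqs)
            ):
                sites.append((col + 1, next(iter(ga)), next(iter(hb))))
    return SynapomorphyReport(aln.locus_name, G, H, sites)


def group_distance(
    alns: Sequence[LocusAlignment],
    G: Iterable[str],
    H: Iterable[str],
    ambiguity: str = "missing",
    min_coverage_fraction: float = 1.0,
) -> GroupDistanceSummary:
    """Per-locus min/max/mean cross-pair SNP distances and totals.

    Cross pairs with zero overlap are excluded from the statistics but
    listed in ``excluded_pairs``.  Loci where either group has no member
    with sequence data are skipped and flagged in ``skipped_loci``.
    """
    G, H = set(G), set(H)
    _check_groups(G, H)
    per_locus: List[GroupDistance] = []
    skipped: List[str] = []
    for aln in alns:
        g_here = sorted(s for s in G if s in aln)
        h_here = sorted(s for s in H if s in aln)
        if not g_here or not h_here:
            skipped.append(aln.locus_name)
            continue
        dists: List[int] = []
        excluded: List[Tuple[str, str]] = []
        for a in g_here:
            for b in h_here:
                d, ov = pairwise_snp_distance(aln, a, b, ambiguity=ambiguity)
                if ov == 0:
                    excluded.append((a, b))
                else:
                    dists.append(d)
        if not dists:
            skipped.append(aln.locus_name)
            continue
        syn = count_synapomorphies(
            aln, set(g_here), set(h_here), min_coverage_fraction
        )
        per_locus.append(
            GroupDistance(
                locus_name=aln.locus_name,
                group_a=G,
                group_b=H,
                min=min(dists),
                max=max(dists),
                mean=_mean(dists),
                n_pairs=len(dists),
                excluded_pairs=excluded,
                total_synapomorphies=syn.count,
            )
        )
    return GroupDistanceSummary(per_locus=per_locus, skipped_loci=skipped)
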