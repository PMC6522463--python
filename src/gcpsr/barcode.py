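"""Diagnostic-SNP discovery and single-locus determination.

Reproduces the ITS screening workflow: find the alignment columns that are
synapomorphic between two labelled groups of a reference panel, optionally
check their stability against a wider panel, and classify query sequences
(possibly partial, pre-aligned to the panel coordinates) by the states
they carry at those columns.

Classification uses a unanimity rule, not a majority vote: one conflicting
diagnostic site signals introgression or instability and is grounds for
caution, so the query comes back UNDETERMINED rather than averaged over.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from .datamodel import (
    ConfigError,
    CoordinateError,
    LocusAlignment,
    UNAMBIGUOUS,
)
from .variation import count_synapomorphies

__all__ = [
    "UNDETERMINED",
    "DiagnosticSite",
    "ClassificationResult",
    "find_diagnostic_sites",
    "classify_specimen",
    "classify_panel",
]

UNDETERMINED = "UNDETERMINED"


@dataclass
class DiagnosticSite:
    """One alignment column diagnostic between two labels.

    ``column`` is 1-based.  ``stable`` is False when any wider-panel
    sequence carrying one of the two labels violates the state — the SNP
    may be uninformative on a wider geographic scale.
    """

    locus_name: str
    column: int
    state_by_label: Dict[str, str]
    stable: bool = True

    def __post_init__(self):
        if len(self.state_by_label) < 2:
            raise ConfigError("a diagnostic site needs >= 2 mapped labels")
        states = list(self.state_by_label.values())
        if len(set(states)) != len(states):
            raise ConfigError("diagnostic states must differ between labels")


@dataclass
class ClassificationResult:
    """Determination of one query from its diagnostic-site states."""

    query_id: str
    label: str  # a panel label, or UNDETERMINED
    sites_used: List[int] = field(default_factory=list)
    reason: Optional[str] = None  # no_coverage | conflicting_sites | ambiguous_base

    @property
    def determined(self) -> bool:
        return self.label != UNDETERMINED


def find_diagnostic_sites(
    aln: LocusAlignment,
    label_map: Mapping[str, Optional[str]],
    a_label: str,
    b_label: str,
    wider_panel: Optional[LocusAlignment] = None,
    wider_label_map: Optional[Mapping[str, Optional[str]]] = None,
    min_coverage_fraction: float = 1.0,
) -> List[DiagnosticSite]:
    """Columns diagnostic between two labels of a reference panel.

    Exactly the synapomorphic columns between the two label groups; each
    site is marked ``stable=False`` if any wider-panel sequence labelled
    ``a_label`` or ``b_label`` carries an unambiguous base violating its
    label's state.  ``min_coverage_fraction`` relaxes the per-group
    coverage a column needs, for panels containing partial
    (fungarium-grade) sequences.
    """
    ga = {s for s, l in label_map.items() if l == a_label and s in aln}
    gb = {s for s, l in label_map.items() if l == b_label and s in aln}
    if not ga:
        raise ConfigError(f"no panel specimen labelled {a_label!r}")
    if not gb:
        raise ConfigError(f"no panel specimen labelled {b_label!r}")
    rep = count_synapomorphies(aln, ga, gb, min_coverage_fraction)
    sites = [
        DiagnosticSite(aln.locus_name, col, {a_label: sa, b_label: sb})
        for col, sa, sb in rep.sites
    ]
    if wider_panel is not None:
        if wider_panel.length != aln.length:
            raise CoordinateError(
                "wider panel must share the panel's alignment coordinates"
            )
        wmap = wider_label_map if wider_label_map is not None else label_map
        for site in sites:
            idx = site.column - 1
            for sid in wider_panel.specimens:
                lab = wmap.get(sid)
                if lab not in (a_label, b_label):
                    continue
                ch = wider_panel[sid][idx]
                if ch in UNAMBIGUOUS and ch != site.state_by_label[lab]:
                    site.stable = False
                    break
    return sites


def classify_specimen(
    query: str,
    sites: Sequence[DiagnosticSite],
    panel_length: Optional[int] = None,
    query_id: str = "query",
) -> ClassificationResult:
    """Determine a query from the diagnostic sites it covers.

    The query must be pre-aligned to panel coordinates (gaps for missing
    stretches).  A label is assigned iff the query covers at least one
    diagnostic site with an unambiguous base and every covered site votes
    for the same label; otherwise the result is UNDETERMINED with reason
    ``no_coverage`` (all sites gapped or beyond the sequence),
    ``ambiguous_base`` (covered only by ambiguity codes) or
    ``conflicting_sites`` (covered sites disagree, or a base matches no
    label).
    """
    query = str(query).upper().replace("U", "T")
    if panel_length is not None and len(query) > panel_length:
        raise CoordinateError(
            f"query {query_id!r} is longer ({len(query)}) than the panel "
            f"alignment ({panel_length})"
        )
    votes: List[Tuple[int, Optional[str]]] = []  # (column, voted label|None)
    n_ambiguous = 0
    for site in sites:
        idx = site.column - 1
        ch = query[idx] if idx < len(query) else "-"
        if ch == "-":
            continue
        if ch not in UNAMBIGUOUS:
            n_ambiguous += 1
            continue
        voted = None
        for lab, base in site.state_by_label.items():
            if ch == base:
                voted = lab
                break
        votes.append((site.column, voted))
    if not votes:
        reason = "ambiguous_base" if n_ambiguous else "no_coverage"
        return ClassificationResult(query_id, UNDETERMINED, [], reason)
    labels = {v for _, v in votes}
    if None in labels or len(labels) != 1:
        return ClassificationResult(
            query_id, UNDETERMINED, [c for c, _ in votes], "conflicting_sites"
        )
    return ClassificationResult(
        query_id, labels.pop(), [c for c, _ in votes], None
    )


def classify_panel(
    queries: LocusAlignment,
    sites: Sequence[DiagnosticSite],
) -> List[ClassificationResult]:
    """Classify every sequence of an aligned query set."""
    return [
        classify_specimen(
            queries[sid], sites, panel_length=queries.length, query_id=sid
        )
        for sid in queries.specimens
    ]
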