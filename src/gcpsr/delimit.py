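"""Five-criteria phylospecies delimitation with a lumping recommender.

The recognition rules, evaluated for every candidate label of a
:class:`~gcpsr.datamodel.SpeciesHypothesis`:

monophyly
    The candidate is resolved as monophyletic (with adequate node support,
    or with supports absent) in the combined-data tree *and* in at least
    one single-locus tree; reciprocity additionally requires its sister
    candidate, when resolvable, to be monophyletic in the same trees.
genealogical
    No single-locus tree contains a supported split incompatible with the
    candidate's genealogical exclusivity.
distinctness
    The candidate differs from its sister (or nearest) candidate by at
    least ``min_snp_per_locus`` SNPs at every locus with adequate
    coverage (default 3, the ">2 SNPs" reading of the empirical rule for
    closely related phylospecies).
minimal_sampling
    At least ``n_min`` specimens (default 3).
polygenic_differentiation
    At least one synapomorphic SNP, shared by all individuals studied,
    against the comparator at a strict majority of the highly variable
    loci (by default 3 of ITS, EF1a, RPB1, RPB2).

The model/results interface follows the fit-and-summarize idiom:
``GCPSRDelimitation(...).fit()`` returns :class:`DelimitationResults`
whose ``report`` carries per-candidate evidence and merge
recommendations.
"""

from __future__ import annotations

import math
from collections import Counter
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple, Union

from .datamodel import (
    ConfigError,
    GeneTree,
    LocusAlignment,
    PartitionScheme,
    SisterUndefinedError,
    SpeciesHypothesis,
)
from .report import (
    FAIL,
    NOT_ASSESSABLE,
    PASS,
    CandidateReport,
    CriterionResult,
    DelimitationReport,
)
from .treeops import (
    DEFAULT_SUPPORT_THRESHOLD,
    is_contradicted,
    monophyly_status,
    sister_group,
)
from .variation import count_synapomorphies, group_distance

__all__ = [
    "criterion_monophyly",
    "criterion_genealogical",
    "criterion_distinctness",
    "criterion_minimal_sampling",
    "criterion_polygenic_differentiation",
    "GCPSRDelimitation",
    "DelimitationResults",
    "delimit",
]


def criterion_monophyly(
    gene_trees: Sequence[GeneTree],
    concat_tree: Optional[GeneTree],
    G: Set[str],
    support_threshold: float = DEFAULT_SUPPORT_THRESHOLD,
    sister: Optional[Set[str]] = None,
    reciprocal: bool = True,
) -> CriterionResult:
    """Reciprocal monophyly in the combined tree and >=1 single-locus tree."""
    evidence: Dict = {"trees": [t.locus_name for t in gene_trees]}
    if concat_tree is not None:
        evidence["trees"].append(concat_tree.locus_name)
    if len(G) < 2:
        evidence["note"] = "fewer than two specimens; monophyly undefined"
        return CriterionResult("monophyly", NOT_ASSESSABLE, evidence)
    if concat_tree is None or not gene_trees:
        evidence["note"] = "combined-data tree or gene trees missing"
        return CriterionResult("monophyly", NOT_ASSESSABLE, evidence)

    check_sister = reciprocal and sister is not None and len(sister) >= 2
    if reciprocal and not check_sister:
        evidence["warning"] = (
            "sister candidate unresolvable or a single specimen; "
            "reciprocity degraded to focal-only"
        )

    def resolved(tree: GeneTree, grp: Set[str]) -> Tuple[bool, Dict]:
        st = monophyly_status(tree, grp, support_threshold)
        return st.resolved(support_threshold), {
            "status": st.status,
            "support": st.support,
        }

    concat_ok, concat_ev = resolved(concat_tree, G)
    evidence["concat"] = concat_ev
    if check_sister:
        sis_ok, sis_ev = resolved(concat_tree, sister)
        evidence["concat_sister"] = sis_ev
        concat_ok = concat_ok and sis_ok

    per_locus: Dict[str, Dict] = {}
    any_gene_ok = False
    for gt in gene_trees:
        ok, ev = resolved(gt, G)
        if check_sister:
            s_ok, s_ev = resolved(gt, sister)
            ev["sister"] = s_ev
            ok = ok and s_ok
        per_locus[gt.locus_name] = ev
        any_gene_ok = any_gene_ok or ok
    evidence["per_locus"] = per_locus
    verdict = PASS if (concat_ok and any_gene_ok) else FAIL
    return CriterionResult("monophyly", verdict, evidence)


def criterion_genealogical(
    gene_trees: Sequence[GeneTree],
    G: Set[str],
    support_threshold: float = DEFAULT_SUPPORT_THRESHOLD,
) -> CriterionResult:
    """Exclusivity not contradicted by any individual data partition."""
    evidence: Dict = {"trees": [t.locus_name for t in gene_trees]}
    per_locus: Dict[str, Dict] = {}
    informative = 0
    contradicted = False
    for gt in gene_trees:
        leaves = set(gt.leaf_labels())
        if len(G & leaves) < 2 or not (leaves - G):
            per_locus[gt.locus_name] = {"informative": False}
            continue
        informative += 1
        res = is_contradicted(gt, G, support_threshold)
        per_locus[gt.locus_name] = {
            "informative": True,
            "contradicted": res.contradicted,
            "witnesses": [
                {"split": list(w), "support": s} for w, s in res.witnesses
            ],
        }
        contradicted = contradicted or res.contradicted
    evidence["per_locus"] = per_locus
    if informative == 0:
        evidence["note"] = "no tree contains two or more group members"
        return CriterionResult("genealogical", NOT_ASSESSABLE, evidence)
    return CriterionResult(
        "genealogical", FAIL if contradicted else PASS, evidence
    )


def criterion_distinctness(
    alns: Sequence[LocusAlignment],
    G: Set[str],
    H: Optional[Set[str]],
    min_snp_per_locus: int = 3,
    ambiguity: str = "missing",
) -> CriterionResult:
    """Minimum cross-pair distance >= min_snp_per_locus at every locus."""
    evidence: Dict = {
        "loci": [a.locus_name for a in alns],
        "min_snp_per_locus": min_snp_per_locus,
    }
    if not H:
        evidence["note"] = "no comparator candidate available"
        return CriterionResult("distinctness", NOT_ASSESSABLE, evidence)
    summary = group_distance(alns, G, H, ambiguity=ambiguity)
    evidence["comparator_members"] = sorted(H)
    evidence["per_locus"] = {
        d.locus_name: {
            "min": d.min,
            "max": d.max,
            "mean": round(d.mean, 4),
            "synapomorphies": d.total_synapomorphies,
        }
        for d in summary.per_locus
    }
    evidence["skipped_loci"] = summary.skipped_loci
    evidence["total_min"] = summary.total_min
    if not summary.per_locus:
        evidence["note"] = "no locus covers both groups"
        return CriterionResult("distinctness", NOT_ASSESSABLE, evidence)
    ok = all(d.min >= min_snp_per_locus for d in summary.per_locus)
    return CriterionResult("distinctness", PASS if ok else FAIL, evidence)


def criterion_minimal_sampling(G: Set[str], n_min: int = 3) -> CriterionResult:
    """At least n_min (optimally three or more) different specimens."""
    evidence = {"n": len(G), "n_min": n_min, "trees": [], "loci": []}
    return CriterionResult(
        "minimal_sampling", PASS if len(G) >= n_min else FAIL, evidence
    )


def criterion_polygenic_differentiation(
    alns: Sequence[LocusAlignment],
    partition: PartitionScheme,
    G: Set[str],
    H: Optional[Set[str]],
    min_coverage_fraction: float = 1.0,
) -> CriterionResult:
    """>=1 shared (synapomorphic) SNP at a strict majority of the highly
    variable loci, against the nearest/sister candidate."""
    hv = [a for a in alns if a.locus_name in partition.highly_variable]
    evidence: Dict = {
        "highly_variable": sorted(partition.highly_variable),
        "loci": [a.locus_name for a in hv],
    }
    if not H:
        evidence["note"] = "no comparator candidate available"
        return CriterionResult(
            "polygenic_differentiation", NOT_ASSESSABLE, evidence
        )
    counts: Dict[str, int] = {}
    for aln in hv:
        if not ({s for s in G if s in aln} and {s for s in H if s in aln}):
            continue
        counts[aln.locus_name] = count_synapomorphies(
            aln, G & set(aln.specimens), H & set(aln.specimens),
            min_coverage_fraction,
        ).count
    evidence["comparator_members"] = sorted(H)
    evidence["synapomorphies"] = counts
    missing = sorted(partition.highly_variable - set(counts))
    if missing:
        evidence["missing_loci"] = missing
    if not counts:
        evidence["note"] = "no highly variable locus covers both groups"
        return CriterionResult(
            "polygenic_differentiation", NOT_ASSESSABLE, evidence
        )
    n_diff = sum(1 for c in counts.values() if c >= 1)
    ok = n_diff > len(counts) / 2  # strict majority
    evidence["loci_with_synapomorphy"] = n_diff
    evidence["loci_assessed"] = len(counts)
    return CriterionResult(
        "polygenic_differentiation", PASS if ok else FAIL, evidence
    )


class DelimitationResults:
    """Results of a fitted :class:`GCPSRDelimitation`.

    Attributes
    ----------
    report : DelimitationReport
        Per-candidate criterion verdicts (for the final, post-merge set of
        candidates), merge recommendations in terms of the original
        labels, and the parameters used.
    n_merge_rounds : int
        Number of merges the recommender performed.
    """

    def __init__(
        self,
        model: "GCPSRDelimitation",
        report: DelimitationReport,
        n_merge_rounds: int,
        final_hypothesis: SpeciesHypothesis,
    ):
        self.model = model
        self.report = report
        self.n_merge_rounds = n_merge_rounds
        self.final_hypothesis = final_hypothesis

    @property
    def merge_recommendations(self) -> List[List[str]]:
        return self.report.merge_recommendations

    @property
    def labels(self) -> List[str]:
        return self.report.labels

    def overall(self, label: str) -> str:
        return self.report.candidate(label).overall

    def summary(self) -> str:
        lines = [self.report.summary()]
        lines.append("parameters:")
        for k, v in sorted(self.report.parameters.items()):
            lines.append(f"  {k} = {v}")
        return "\n".join(lines) + "\n"

    def save(self, path) -> None:
        from .io import write_report

        write_report(self.report, path)


class GCPSRDelimitation:
    """Genealogical-concordance species delimitation model.

    Parameters
    ----------
    alignments : mapping locus -> LocusAlignment, or sequence
    gene_trees : mapping locus -> GeneTree, or sequence
        Single-locus trees with node supports.
    concat_tree : GeneTree or None
        Combined-data tree.
    hypothesis : SpeciesHypothesis
        Candidate species assignment of the specimens.
    partition : PartitionScheme, optional
        Defaults to the five-locus morel scheme with ITS, EF1a, RPB1 and
        RPB2 highly variable.
    support_threshold : float
        Node support needed for a split to count as resolved/contradicting.
    min_snp_per_locus : int
        Distinctness threshold (">2 SNPs" rule => 3).
    n_min : int
        Minimal sampling threshold.
    min_coverage_fraction : float
        Fraction of each group that must cover a column for it to count as
        a synapomorphy (relax for fungarium-grade partial sequences).
    reciprocal : bool
        Whether the monophyly criterion also checks the sister candidate.
    """

    def __init__(
        self,
        alignments: Union[Mapping[str, LocusAlignment], Sequence[LocusAlignment]],
        gene_trees: Union[Mapping[str, GeneTree], Sequence[GeneTree]],
        concat_tree: Optional[GeneTree],
        hypothesis: SpeciesHypothesis,
        partition: Optional[PartitionScheme] = None,
        support_threshold: float = DEFAULT_SUPPORT_THRESHOLD,
        min_snp_per_locus: int = 3,
        n_min: int = 3,
        min_coverage_fraction: float = 1.0,
        reciprocal: bool = True,
        ambiguity: str = "missing",
    ):
        if isinstance(alignments, Mapping):
            alignments = list(alignments.values())
        if isinstance(gene_trees, Mapping):
            gene_trees = list(gene_trees.values())
        self.alignments: List[LocusAlignment] = list(alignments)
        self.gene_trees: List[GeneTree] = list(gene_trees)
        self.concat_tree = concat_tree
        self.hypothesis = hypothesis
        self.partition = partition or PartitionScheme(
            loci=[a.locus_name for a in self.alignments],
            highly_variable={
                a.locus_name for a in self.alignments if a.locus_name != "LSU"
            },
        )
        if not 0.0 <= support_threshold <= 1.0:
            raise ConfigError("support_threshold must be in [0, 1]")
        if not hypothesis.labels:
            raise ConfigError("hypothesis contains no candidate labels")
        self.support_threshold = support_threshold
        self.min_snp_per_locus = int(min_snp_per_locus)
        self.n_min = int(n_min)
        self.min_coverage_fraction = float(min_coverage_fraction)
        self.reciprocal = bool(reciprocal)
        self.ambiguity = ambiguity

    @classmethod
    def from_files(
        cls,
        alignment_paths: Mapping[str, str],
        tree_paths: Mapping[str, str],
        concat_tree_path: Optional[str],
        hypothesis_path: str,
        partition_path: Optional[str] = None,
        **params,
    ) -> "GCPSRDelimitation":
        """Build the model from per-locus FASTA/Newick files and the TSV
        specimen table."""
        from . import io as gio

        alns = {
            locus: gio.read_locus_alignment(path, locus)
            for locus, path in alignment_paths.items()
        }
        trees = {
            locus: gio.read_gene_tree(path, locus)
            for locus, path in tree_paths.items()
        }
        concat = (
            gio.read_gene_tree(concat_tree_path, "concat")
            if concat_tree_path
            else None
        )
        hyp = gio.read_hypothesis(hypothesis_path)
        partition = (
            gio.read_partition(partition_path) if partition_path else None
        )
        return cls(alns, trees, concat, hyp, partition=partition, **params)

    @classmethod
    def from_dataset(cls, dataset, **params) -> "GCPSRDelimitation":
        """Build the model from a :class:`~gcpsr.simulate.SimulatedDataset`."""
        return cls(
            dataset.alignments,
            dataset.gene_trees,
            dataset.concat_tree,
            dataset.hypothesis,
            **params,
        )

    # -- comparator selection ------------------------------------------------

    def _nearest_candidate(
        self, hyp: SpeciesHypothesis, label: str
    ) -> Optional[str]:
        """Nearest other candidate by total mean cross-pair distance."""
        G = hyp.members(label)
        best: Optional[Tuple[float, str]] = None
        for other in hyp.labels:
            if other == label:
                continue
            summary = group_distance(
                self.alignments, G, hyp.members(other), ambiguity=self.ambiguity
            )
            if not summary.per_locus:
                continue
            key = (summary.total_mean, other)
            if best is None or key < best:
                best = key
        return best[1] if best else None

    def _comparator(self, hyp: SpeciesHypothesis, label: str) -> Optional[str]:
        """Sister candidate from the combined tree, else nearest by distance."""
        G = hyp.members(label)
        if self.concat_tree is not None and len(hyp.labels) > 1:
            try:
                sis = sister_group(self.concat_tree, G)
            except SisterUndefinedError:
                sis = None
            if sis:
                labels = {hyp.label_of(s) for s in sis}
                labels.discard(None)
                if len(labels) == 1:
                    lab = labels.pop()
                    if lab != label and sis <= hyp.members(lab):
                        return lab
        return self._nearest_candidate(hyp, label)

    # -- evaluation ----------------------------------------------------------

    def _evaluate_candidate(
        self, hyp: SpeciesHypothesis, label: str
    ) -> CandidateReport:
        G = hyp.members(label)
        comparator = self._comparator(hyp, label)
        H = hyp.members(comparator) if comparator else None
        criteria = [
            criterion_monophyly(
                self.gene_trees,
                self.concat_tree,
                G,
                self.support_threshold,
                sister=H,
                reciprocal=self.reciprocal,
            ),
            criterion_genealogical(
                self.gene_trees, G, self.support_threshold
            ),
            criterion_distinctness(
                self.alignments,
                G,
                H,
                self.min_snp_per_locus,
                ambiguity=self.ambiguity,
            ),
            criterion_minimal_sampling(G, self.n_min),
            criterion_polygenic_differentiation(
                self.alignments,
                self.partition,
                G,
                H,
                self.min_coverage_fraction,
            ),
        ]
        return CandidateReport(label, sorted(G), comparator, criteria)

    def evaluate(
        self, hypothesis: Optional[SpeciesHypothesis] = None
    ) -> List[CandidateReport]:
        """One evaluation pass over every candidate (no merging)."""
        hyp = hypothesis or self.hypothesis
        return [self._evaluate_candidate(hyp, lab) for lab in sorted(hyp.labels)]

    # -- merge recommender ---------------------------------------------------

    def _merge_partner(
        self,
        cand: CandidateReport,
        failing: Set[str],
        hyp: SpeciesHypothesis,
    ) -> Optional[str]:
        """Partner label for a failing candidate.

        Sources, in order: candidate labels named in contradiction
        witnesses (most frequent first); the comparator when the candidate
        shares zero synapomorphies with it.  The partner must itself be
        failing — a candidate passing all assessable criteria is never
        dragged into a merge.
        """
        gen = cand.criterion("genealogical")
        tally: Counter = Counter()
        for locus_ev in gen.evidence.get("per_locus", {}).values():
            for w in locus_ev.get("witnesses", []):
                for leaf in w["split"]:
                    lab = hyp.label_of(leaf)
                    if lab is not None and lab != cand.label:
                        tally[lab] += 1
        for lab, _n in sorted(tally.items(), key=lambda kv: (-kv[1], kv[0])):
            if lab in failing:
                return lab
        poly = cand.criterion("polygenic_differentiation")
        if poly.verdict == FAIL:
            counts = poly.evidence.get("synapomorphies", {})
            if counts and all(c == 0 for c in counts.values()):
                comp = cand.comparator
                if comp in failing:
                    return comp
        return None

    @staticmethod
    def _distinctness_key(cand: CandidateReport) -> Tuple[float, str]:
        total = cand.criterion("distinctness").evidence.get("total_min")
        return (float(total) if total is not None else math.inf, cand.label)

    def fit(self) -> DelimitationResults:
        """Evaluate all candidates, merging failing ones until stable.

        Failing candidates are processed by ascending total distinctness
        (lexicographic tie-break); each round merges one failing candidate
        with its partner and re-evaluates.  The loop terminates after at
        most (number of labels - 1) merges.
        """
        hyp = self.hypothesis
        origin: Dict[str, Set[str]] = {lab: {lab} for lab in hyp.labels}
        n_rounds = 0
        max_rounds = len(hyp.labels) - 1
        while True:
            candidates = self.evaluate(hyp)
            failing = {c.label for c in candidates if c.overall == FAIL}
            if not failing or n_rounds >= max_rounds:
                break
            merged = False
            for cand in sorted(
                (c for c in candidates if c.label in failing),
                key=self._distinctness_key,
            ):
                partner = self._merge_partner(cand, failing - {cand.label}, hyp)
                if partner is None:
                    continue
                keep, absorb = sorted([cand.label, partner])
                hyp = hyp.merged(keep, absorb)
                origin[keep] = origin[keep] | origin.pop(absorb)
                n_rounds += 1
                merged = True
                break
            if not merged:
                break
        report = DelimitationReport(
            candidates=candidates,
            merge_recommendations=[
                sorted(s) for s in origin.values() if len(s) >= 2
            ],
            parameters={
                "support_threshold": self.support_threshold,
                "min_snp_per_locus": self.min_snp_per_locus,
                "n_min": self.n_min,
                "min_coverage_fraction": self.min_coverage_fraction,
                "reciprocal": self.reciprocal,
                "ambiguity": self.ambiguity,
                "loci": [a.locus_name for a in self.alignments],
                "highly_variable": sorted(self.partition.highly_variable),
            },
        )
        return DelimitationResults(self, report, n_rounds, hyp)


def delimit(
    hypothesis: SpeciesHypothesis,
    alignments,
    gene_trees,
    concat_tree: Optional[GeneTree],
    **params,
) -> DelimitationReport:
    """Functional wrapper: evaluate the five criteria and recommend merges."""
    model = GCPSRDelimitation(
        alignments, gene_trees, concat_tree, hypothesis, **params
    )
    return model.fit().report
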