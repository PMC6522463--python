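"""Readers and writers for alignments, trees, specimen tables and reports.

File formats are deliberately plain: aligned FASTA (one file per locus),
Newick with optional node supports, a TSV specimen table, a small JSON
partition config, and JSON delimitation reports with a text summary
alongside.
"""

from __future__ import annotations

import json
import os
from typing import Dict, List, Optional, Union

import dendropy
from Bio import SeqIO

from .datamodel import (
    AlignmentError,
    ConfigError,
    DuplicateIdError,
    GeneTree,
    LocusAlignment,
    PartitionScheme,
    SpeciesHypothesis,
    SpecimenRecord,
    SupportValueError,
    TreeFormatError,
)
from .report import DelimitationReport

PathLike = Union[str, "os.PathLike[str]"]

__all__ = [
    "read_locus_alignment",
    "write_locus_alignment",
    "read_gene_tree",
    "write_gene_tree",
    "read_specimen_table",
    "write_specimen_table",
    "read_hypothesis",
    "read_partition",
    "write_partition",
    "write_report",
    "read_report",
]


def read_locus_alignment(path: PathLike, locus_name: str) -> LocusAlignment:
    """Read one aligned FASTA file into a :class:`LocusAlignment`.

    Characters are uppercased and U is mapped to T.  Raises
    :class:`AlignmentError` for unequal record lengths,
    :class:`DuplicateIdError` for repeated ids, and
    :class:`AlphabetError` (naming the 1-based column) for characters
    outside the IUPAC nucleotide set plus ``-``.
    """
    sequences: Dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in sequences:
            raise DuplicateIdError(
                f"{path}: duplicate specimen id {rec.id!r}"
            )
        sequences[rec.id] = str(rec.seq)
    if not sequences:
        raise AlignmentError(f"{path}: no FASTA records found")
    return LocusAlignment(locus_name, sequences)


def write_locus_alignment(aln: LocusAlignment, path: PathLike) -> None:
    with open(path, "w") as fh:
        for sid, seq in aln.sequences.items():
            fh.write(f">{sid}\n{seq}\n")


def _parse_support(raw: Optional[str], where: str) -> Optional[float]:
    """Normalize a node-label support string to [0, 1], or None."""
    if raw is None or raw == "":
        return None
    try:
        val = float(raw)
    except ValueError:
        return None  # non-numeric internal labels are clade names, not supports
    if not 0.0 <= val <= 100.0:
        raise SupportValueError(
            f"{where}: support {val} outside [0, 100]"
        )
    if val > 1.0:  # percentage-style (bootstrap) support
        val /= 100.0
    return val


def _extract_supports(tree: dendropy.Tree, where: str) -> None:
    """Attach ``node.support`` from node labels or branch annotations.

    Both common Newick dialects are accepted: numeric internal-node labels
    (MrBayes/RAxML style) and ``[&support=...]``/``[&posterior=...]``
    comment annotations.  Values printed as percentages are divided by 100.
    """
    for node in tree.preorder_node_iter():
        support: Optional[float] = None
        for key in ("support", "posterior", "prob"):
            ann = node.annotations.get_value(key, None)
            if ann is None:
                ann = node.edge.annotations.get_value(key, None)
            if ann is not None:
                support = _parse_support(str(ann), where)
                break
        if support is None and not node.is_leaf():
            support = _parse_support(node.label, where)
        node.support = support


def read_gene_tree(
    path: PathLike, locus_name: str, rooted: bool = False
) -> GeneTree:
    """Read a Newick tree; numeric internal labels become supports."""
    try:
        tree = dendropy.Tree.get(
            path=str(path),
            schema="newick",
            suppress_internal_node_taxa=True,
            extract_comment_metadata=True,
            preserve_underscores=True,
        )
    except (dendropy.utility.error.DataParseError, ValueError) as exc:
        raise TreeFormatError(f"{path}: cannot parse Newick ({exc})") from exc
    if not tree.leaf_nodes():
        raise TreeFormatError(f"{path}: empty tree")
    _extract_supports(tree, str(path))
    return GeneTree(locus_name, tree, rooted=rooted)


def parse_gene_tree(
    newick: str, locus_name: str, rooted: bool = False
) -> GeneTree:
    """As :func:`read_gene_tree`, but from a Newick string."""
    try:
        tree = dendropy.Tree.get(
            data=newick,
            schema="newick",
            suppress_internal_node_taxa=True,
            extract_comment_metadata=True,
            preserve_underscores=True,
        )
    except (dendropy.utility.error.DataParseError, ValueError) as exc:
        raise TreeFormatError(f"cannot parse Newick ({exc})") from exc
    if not tree.leaf_nodes():
        raise TreeFormatError("empty tree")
    _extract_supports(tree, "<string>")
    return GeneTree(locus_name, tree, rooted=rooted)


def write_gene_tree(gt: GeneTree, path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write(gt.as_newick() + "\n")


_TABLE_COLUMNS = ["specimen_id", "candidate_label", "year", "prior_name", "source"]


def read_specimen_table(path: PathLike) -> List[SpecimenRecord]:
    """Read the TSV specimen table (header: specimen_id, candidate_label,
    year, prior_name, source; trailing columns optional)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    if "specimen_id" not in df.columns:
        raise ConfigError(f"{path}: missing 'specimen_id' column")
    records: List[SpecimenRecord] = []
    for _, row in df.iterrows():
        year = row.get("year", "")
        records.append(
            SpecimenRecord(
                specimen_id=row["specimen_id"],
                candidate_label=row.get("candidate_label", "") or None,
                year=int(year) if year else None,
                prior_name=row.get("prior_name", "") or None,
                source=row.get("source", "") or None,
            )
        )
    return records


def write_specimen_table(records: List[SpecimenRecord], path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_TABLE_COLUMNS) + "\n")
        for r in records:
            fh.write(
                "\t".join(
                    [
                        r.specimen_id,
                        r.candidate_label or "",
                        str(r.year) if r.year is not None else "",
                        r.prior_name or "",
                        r.source or "",
                    ]
                )
                + "\n"
            )


def read_hypothesis(path: PathLike) -> SpeciesHypothesis:
    """Build a :class:`SpeciesHypothesis` from the specimen table."""
    records = read_specimen_table(path)
    return SpeciesHypothesis(
        {r.specimen_id: r.candidate_label for r in records}
    )


def read_partition(path: PathLike) -> PartitionScheme:
    """Partition config: JSON with keys ``loci`` and ``highly_variable``."""
    with open(path) as fh:
        data = json.load(fh)
    try:
        return PartitionScheme(
            loci=list(data["loci"]),
            highly_variable=set(data.get("highly_variable", [])),
        )
    except KeyError as exc:
        raise ConfigError(f"{path}: missing key {exc}") from exc


def write_partition(partition: PartitionScheme, path: PathLike) -> None:
    with open(path, "w") as fh:
        json.dump(
            {
                "loci": partition.loci,
                "highly_variable": sorted(partition.highly_variable),
            },
            fh,
            indent=2,
        )
        fh.write("\n")


def write_report(report: DelimitationReport, path: PathLike) -> None:
    """Write the JSON report plus a text summary at ``<path>.txt``.

    The JSON is byte-stable for identical inputs (no timestamps) and
    round-trips losslessly through :func:`read_report`.
    """
    with open(path, "w") as fh:
        fh.write(report.to_json())
        fh.write("\n")
    with open(str(path) + ".txt", "w") as fh:
        fh.write(report.summary())


def read_report(path: PathLike) -> DelimitationReport:
    with open(path) as fh:
        return DelimitationReport.from_json(fh.read())
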