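"""Core domain types for multilocus phylospecies recognition.

The package works with four kinds of objects: per-locus multiple sequence
alignments (:class:`LocusAlignment`), leaf-labelled phylogenies with node
support (:class:`GeneTree`), specimen metadata (:class:`SpecimenRecord`),
and a candidate species partition (:class:`SpeciesHypothesis`).  All
coordinates are 0-based internally; user-facing reports are 1-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set

import dendropy

__all__ = [
    "GcpsrError",
    "AlignmentError",
    "AlphabetError",
    "DuplicateIdError",
    "UnknownSpecimenError",
    "TreeFormatError",
    "SupportValueError",
    "SisterUndefinedError",
    "CoordinateError",
    "ConfigError",
    "IUPAC_STATES",
    "UNAMBIGUOUS",
    "ALPHABET",
    "LocusAlignment",
    "SpecimenRecord",
    "GeneTree",
    "PartitionScheme",
    "SpeciesHypothesis",
]


class GcpsrError(Exception):
    """Base class for all package errors."""


class AlignmentError(GcpsrError):
    """Sequences in a FASTA file are not aligned (unequal lengths)."""


class AlphabetError(GcpsrError):
    """A sequence contains a character outside the IUPAC nucleotide set."""


class DuplicateIdError(GcpsrError):
    """Two records in one locus share a specimen id."""


class UnknownSpecimenError(GcpsrError):
    """A specimen id was requested that the alignment does not contain."""


class TreeFormatError(GcpsrError):
    """A Newick file could not be parsed or is empty."""


class SupportValueError(GcpsrError):
    """A node support value lies outside [0, 100]."""


class SisterUndefinedError(GcpsrError):
    """The focal group is not monophyletic, so no sister clade exists.

    Callers should fall back to the nearest candidate by total SNP
    distance (see :func:`gcpsr.variation.group_distance`).
    """


class CoordinateError(GcpsrError):
    """A query sequence does not fit the panel's alignment coordinates."""


class ConfigError(GcpsrError):
    """Invalid run configuration (thresholds, hypotheses, simulation)."""


# IUPAC nucleotide ambiguity codes -> set of unambiguous states.
# Gap ('-') carries the empty set: it is missing data, never a fifth state.
IUPAC_STATES: Dict[str, frozenset] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
    "-": frozenset(),
}

UNAMBIGUOUS = frozenset("ACGT")
ALPHABET = frozenset(IUPAC_STATES)


class LocusAlignment:
    """One aligned locus: specimen-indexed, equal-length IUPAC sequences.

    Parameters
    ----------
    locus_name : str
        Identifier of the locus (e.g. ``"ITS"``).
    sequences : mapping of str -> str
        Specimen id to aligned sequence.  Sequences are uppercased and
        U is mapped to T on construction; all must have equal length and
        use only IUPAC nucleotide codes plus ``-``.
    """

    def __init__(self, locus_name: str, sequences: Dict[str, str]):
        self.locus_name = str(locus_name)
        norm: Dict[str, str] = {}
        length: Optional[int] = None
        for sid, seq in sequences.items():
            if sid in norm:
                raise DuplicateIdError(
                    f"duplicate specimen id {sid!r} in locus {locus_name!r}"
                )
            s = str(seq).upper().replace("U", "T")
            if length is None:
                length = len(s)
            elif len(s) != length:
                raise AlignmentError(
                    f"locus {locus_name!r}: sequence {sid!r} has length "
                    f"{len(s)}, expected {length}"
                )
            for pos, ch in enumerate(s):
                if ch not in ALPHABET:
                    raise AlphabetError(
                        f"locus {locus_name!r}, specimen {sid!r}: illegal "
                        f"character {ch!r} at column {pos + 1}"
                    )
            norm[sid] = s
        self.sequences: Dict[str, str] = norm
        self.length: int = length or 0

    @property
    def specimens(self) -> List[str]:
        return list(self.sequences)

    def __len__(self) -> int:
        return len(self.sequences)

    def __contains__(self, specimen_id: str) -> bool:
        return specimen_id in self.sequences

    def __getitem__(self, specimen_id: str) -> str:
        try:
            return self.sequences[specimen_id]
        except KeyError:
            raise UnknownSpecimenError(
                f"specimen {specimen_id!r} not in locus {self.locus_name!r}"
            ) from None

    def column(self, i: int) -> Dict[str, str]:
        """Characters of 0-based column *i*, keyed by specimen."""
        return {sid: seq[i] for sid, seq in self.sequences.items()}

    def subset(self, specimen_ids: Iterable[str]) -> "LocusAlignment":
        ids = list(specimen_ids)
        return LocusAlignment(self.locus_name, {s: self[s] for s in ids})

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, LocusAlignment)
            and self.locus_name == other.locus_name
            and self.sequences == other.sequences
        )

    def __repr__(self) -> str:
        return (
            f"LocusAlignment({self.locus_name!r}, {len(self)} specimens x "
            f"{self.length} columns)"
        )


@dataclass
class SpecimenRecord:
    """Metadata for one specimen (one row of the specimen table)."""

    specimen_id: str
    year: Optional[int] = None
    prior_name: Optional[str] = None
    candidate_label: Optional[str] = None
    source: Optional[str] = None  # "fresh" | "fungarium"

    def __post_init__(self):
        if not self.specimen_id:
            raise ConfigError("specimen_id must be non-empty")
        if self.year is not None and self.year < 1800:
            raise ConfigError(
                f"specimen {self.specimen_id!r}: implausible year {self.year}"
            )


class GeneTree:
    """A leaf-labelled phylogeny for one locus, with optional node supports.

    Wraps a :class:`dendropy.Tree`.  Supports live on internal nodes as the
    attribute ``node.support`` (float in [0, 1] or ``None``).  Trees are
    treated as unrooted unless ``rooted=True`` (consensus trees from
    Bayesian analyses carry no root information).
    """

    def __init__(self, locus_name: str, tree: dendropy.Tree, rooted: bool = False):
        self.locus_name = str(locus_name)
        self.tree = tree
        self.rooted = bool(rooted)
        labels = self.leaf_labels()
        if len(set(labels)) != len(labels):
            raise TreeFormatError(
                f"tree {locus_name!r} has duplicate leaf labels"
            )
        for node in tree.preorder_internal_node_iter():
            if not hasattr(node, "support"):
                node.support = None
            if node.support is not None and not 0.0 <= node.support <= 1.0:
                raise SupportValueError(
                    f"tree {locus_name!r}: support {node.support} outside [0, 1]"
                )

    def leaf_labels(self) -> List[str]:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]

    @property
    def n_leaves(self) -> int:
        return len(self.tree.leaf_nodes())

    def clone(self) -> "GeneTree":
        t = self.tree.clone(depth=1)
        for src, dst in zip(
            self.tree.preorder_node_iter(), t.preorder_node_iter()
        ):
            dst.support = getattr(src, "support", None)
        return GeneTree(self.locus_name, t, rooted=self.rooted)

    def as_newick(self) -> str:
        """Newick string with supports written as internal-node labels."""
        t = self.tree.clone(depth=1)
        for src, dst in zip(
            self.tree.preorder_node_iter(), t.preorder_node_iter()
        ):
            if not dst.is_leaf():
                sup = getattr(src, "support", None)
                dst.label = None if sup is None else f"{sup:g}"
        has_lengths = any(
            e.length is not None for e in self.tree.preorder_edge_iter()
        )
        return t.as_string(
            schema="newick",
            suppress_rooting=True,
            suppress_edge_lengths=not has_lengths,
            unquoted_underscores=True,
        ).strip()

    def __repr__(self) -> str:
        return f"GeneTree({self.locus_name!r}, {self.n_leaves} leaves)"


@dataclass
class PartitionScheme:
    """The loci of the study and the subset treated as highly variable.

    Defaults follow the morel five-locus design: ITS, EF1a, RPB1 and RPB2
    are the variable loci used for polygenic differentiation; LSU is the
    conserved anchor.
    """

    loci: List[str] = field(
        default_factory=lambda: ["ITS", "LSU", "RPB1", "RPB2", "EF1a"]
    )
    highly_variable: Set[str] = field(
        default_factory=lambda: {"ITS", "EF1a", "RPB1", "RPB2"}
    )

    def __post_init__(self):
        self.highly_variable = set(self.highly_variable)
        if not self.highly_variable <= set(self.loci):
            extra = self.highly_variable - set(self.loci)
            raise ConfigError(
                f"highly_variable loci {sorted(extra)} not in loci list"
            )


class SpeciesHypothesis:
    """A partition of specimen ids into candidate species labels.

    Specimens mapped to ``None`` (or an empty label on read) are explicitly
    unassigned: they are carried through reports but take part in no
    candidate.  Leaves present in trees but absent here (published
    reference accessions) are treated as non-members with their own labels.
    """

    def __init__(self, assignment: Dict[str, Optional[str]]):
        self.assignment: Dict[str, Optional[str]] = {}
        for sid, label in assignment.items():
            if not sid:
                raise ConfigError("empty specimen id in hypothesis")
            if label is not None and label == "":
                label = None
            self.assignment[str(sid)] = label

    @property
    def labels(self) -> List[str]:
        """Candidate labels in first-appearance order."""
        seen: List[str] = []
        for lab in self.assignment.values():
            if lab is not None and lab not in seen:
                seen.append(lab)
        return seen

    def members(self, label: str) -> Set[str]:
        return {s for s, l in self.assignment.items() if l == label}

    def label_of(self, specimen_id: str) -> Optional[str]:
        return self.assignment.get(specimen_id)

    @property
    def specimens(self) -> List[str]:
        return list(self.assignment)

    def merged(self, keep: str, absorb: str) -> "SpeciesHypothesis":
        """A new hypothesis with label *absorb* relabelled to *keep*."""
        return SpeciesHypothesis(
            {
                s: (keep if l == absorb else l)
                for s, l in self.assignment.items()
            }
        )

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, SpeciesHypothesis)
            and self.assignment == other.assignment
        )

    def __repr__(self) -> str:
        return (
            f"SpeciesHypothesis({len(self.assignment)} specimens, "
            f"{len(self.labels)} labels)"
        )
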