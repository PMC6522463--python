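"""Multispecies-coalescent simulation of multilocus datasets.

Generates gene trees under the multispecies coalescent on a species tree
whose branch lengths are in coalescent units (time scaled so that two
lineages within one panmictic species coalesce at rate 1), then evolves
nucleotide sequences along them under Jukes-Cantor with per-site scaled
mutation rate ``theta`` (mutation rate ``theta/2`` per site per coalescent
unit, so the expected within-species pairwise difference per site is
``theta``).  An infinite-sites switch exists for oracle tests.

Datasets carry their true gene trees (all supports 1.0), the true species
assignment, and optionally a neighbour-joining tree on the concatenated
SNP distances standing in for the combined-data phylogeny.  Partial
sequences emulating degraded fungarium DNA are truncations from either
end, mimicking half-locus sequencing.

All randomness flows from a single integer seed through
``numpy.random.default_rng``; per-locus streams are derived from
``(seed, locus_index)`` so every output is reproducible across platforms.
"""

from __future__ import annotations

import io as _io
import json
import os
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Set, Tuple, Union

import dendropy
import numpy as np

from .datamodel import (
    ConfigError,
    GeneTree,
    LocusAlignment,
    PartitionScheme,
    SpeciesHypothesis,
)

__all__ = [
    "LocusConfig",
    "SimulationConfig",
    "SimulatedDataset",
    "simulate_gene_tree",
    "simulate_alignment",
    "simulate_dataset",
    "apply_partial_sequences",
    "plant_synapomorphies",
    "concatenation_tree",
    "make_fixture",
    "FIXTURE_NAMES",
]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class LocusConfig:
    """One simulated locus: name, alignment length, per-site theta."""

    name: str
    length: int
    theta: float

    def __post_init__(self):
        if self.length < 1:
            raise ConfigError(f"locus {self.name!r}: length must be >= 1")
        if self.theta < 0:
            raise ConfigError(f"locus {self.name!r}: theta must be >= 0")


# Five-locus design with the empirical variability hierarchy of morel
# studies: ITS most variable, LSU least; lengths sum to ~3.6 kb.
DEFAULT_LOCI: Tuple[LocusConfig, ...] = (
    LocusConfig("ITS", 600, 0.05),
    LocusConfig("LSU", 800, 0.006),
    LocusConfig("RPB1", 750, 0.02),
    LocusConfig("RPB2", 800, 0.018),
    LocusConfig("EF1a", 550, 0.03),
)


@dataclass
class SimulationConfig:
    """Full specification of one simulated multilocus dataset.

    ``species_tree`` is Newick with branch lengths in coalescent units
    (a single leaf, e.g. ``"X:1.0;"``, simulates one panmictic species).
    ``partial_fraction`` of the sequences at each locus are truncated to a
    contiguous window anchored at one end.
    """

    species_tree: str
    samples_per_species: Dict[str, int]
    loci: Sequence[LocusConfig] = DEFAULT_LOCI
    partial_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self):
        self.loci = tuple(
            lc if isinstance(lc, LocusConfig) else LocusConfig(**lc)
            for lc in self.loci
        )
        if not 0.0 <= self.partial_fraction < 1.0:
            raise ConfigError("partial_fraction must be in [0, 1)")
        if sum(self.samples_per_species.values()) < 1:
            raise ConfigError("at least one sample is required")
        if any(n < 0 for n in self.samples_per_species.values()):
            raise ConfigError("negative sample count")

    def specimen_ids(self) -> Dict[str, List[str]]:
        """Deterministic specimen ids per species: ``A01, A02, ...``."""
        return {
            sp: [f"{sp}{i + 1:02d}" for i in range(n)]
            for sp, n in self.samples_per_species.items()
        }

    def locus(self, name: str) -> LocusConfig:
        for lc in self.loci:
            if lc.name == name:
                return lc
        raise ConfigError(f"unknown locus {name!r}")

    def to_dict(self) -> Dict:
        return {
            "species_tree": self.species_tree,
            "samples_per_species": dict(self.samples_per_species),
            "loci": [
                {"name": l.name, "length": l.length, "theta": l.theta}
                for l in self.loci
            ],
            "partial_fraction": self.partial_fraction,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: Dict) -> "SimulationConfig":
        return cls(
            species_tree=d["species_tree"],
            samples_per_species=dict(d["samples_per_species"]),
            loci=[LocusConfig(**l) for l in d.get("loci", [])] or DEFAULT_LOCI,
            partial_fraction=d.get("partial_fraction", 0.0),
            seed=d.get("seed", 0),
        )


@dataclass
class SimulatedDataset:
    """Alignments, true gene trees and the true species assignment."""

    alignments: Dict[str, LocusAlignment]
    gene_trees: Dict[str, GeneTree]
    hypothesis: SpeciesHypothesis
    config: SimulationConfig
    concat_tree: Optional[GeneTree] = None

    def write(self, outdir: Union[str, os.PathLike]) -> None:
        """Write per-locus FASTA, true Newick trees, the truth table TSV
        and the config (reproducibility block)."""
        from . import io as gio

        os.makedirs(outdir, exist_ok=True)
        for name, aln in self.alignments.items():
            gio.write_locus_alignment(aln, os.path.join(outdir, f"{name}.fasta"))
        for name, gt in self.gene_trees.items():
            gio.write_gene_tree(gt, os.path.join(outdir, f"{name}.nwk"))
        if self.concat_tree is not None:
            gio.write_gene_tree(
                self.concat_tree, os.path.join(outdir, "concat.nwk")
            )
        with open(os.path.join(outdir, "truth.tsv"), "w") as fh:
            fh.write("specimen_id\tcandidate_label\tyear\tprior_name\tsource\n")
            for sid, lab in self.hypothesis.assignment.items():
                fh.write(f"{sid}\t{lab or ''}\t\t\t\n")
        with open(os.path.join(outdir, "config.json"), "w") as fh:
            json.dump(self.config.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")


def _rng_for(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), int(stream)])


def _species_ages(sp_tree: dendropy.Tree) -> None:
    """Annotate ``node.age_`` bottom-up; leaves are contemporaneous at 0."""
    for node in sp_tree.postorder_node_iter():
        if node.is_leaf():
            node.age_ = 0.0
        else:
            ages = []
            for ch in node.child_nodes():
                if ch.edge.length is None:
                    raise ConfigError(
                        "species tree needs branch lengths in coalescent units"
                    )
                ages.append(ch.age_ + ch.edge.length)
            node.age_ = max(ages)


def _coalesce_interval(
    pool: List[dendropy.Node],
    t0: float,
    t1: Optional[float],
    rng: np.random.Generator,
) -> List[dendropy.Node]:
    """Coalesce lineages at rate k(k-1)/2 within [t0, t1); t1=None => root."""
    pool = list(pool)
    t = t0
    while len(pool) > 1:
        k = len(pool)
        wait = rng.exponential(2.0 / (k * (k - 1)))
        if t1 is not None and t + wait > t1:
            break
        t += wait
        i = int(rng.integers(k))
        j = int(rng.integers(k - 1))
        if j >= i:
            j += 1
        a, b = pool[i], pool[j]
        for idx in sorted((i, j), reverse=True):
            pool.pop(idx)
        parent = dendropy.Node()
        parent.age_ = t
        parent.support = 1.0
        parent.add_child(a)
        parent.add_child(b)
        pool.append(parent)
    return pool


def simulate_gene_tree(
    config: SimulationConfig,
    locus: Union[str, int] = 0,
    rng: Optional[np.random.Generator] = None,
) -> GeneTree:
    """Sample one gene tree under the multispecies coalescent.

    Within each species-tree branch, the lineages present coalesce at rate
    k(k-1)/2 per coalescent time unit; lineages left over at the top of a
    branch are handed to the parent population, and everything merges above
    the root.  Leaf labels carry the species of origin (``A01`` is the
    first sample of species ``A``); internal nodes get support 1.0 (this is
    the true tree).  Branch lengths are in coalescent units.
    """
    locus_name = locus if isinstance(locus, str) else config.loci[locus].name
    locus_index = next(
        i for i, lc in enumerate(config.loci) if lc.name == locus_name
    )
    if rng is None:
        rng = _rng_for(config, 2 * locus_index)
    sp_tree = dendropy.Tree.get(
        data=config.species_tree, schema="newick", preserve_underscores=True
    )
    _species_ages(sp_tree)
    ids = config.specimen_ids()
    taxon_ns = dendropy.TaxonNamespace()
    pools: Dict[int, List[dendropy.Node]] = {}
    for node in sp_tree.postorder_node_iter():
        if node.is_leaf():
            sp = node.taxon.label
            pool: List[dendropy.Node] = []
            for sid in ids.get(sp, []):
                leaf = dendropy.Node(taxon=taxon_ns.new_taxon(sid))
                leaf.age_ = 0.0
                leaf.support = None
                pool.append(leaf)
        else:
            pool = []
            for ch in node.child_nodes():
                pool.extend(pools[id(ch)])
        t1 = None if node.parent_node is None else node.parent_node.age_
        pools[id(node)] = _coalesce_interval(pool, node.age_, t1, rng)
    root_pool = pools[id(sp_tree.seed_node)]
    if not root_pool:
        raise ConfigError("zero samples everywhere")
    root = root_pool[0]
    tree = dendropy.Tree(taxon_namespace=taxon_ns, seed_node=root)
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            node.edge.length = node.parent_node.age_ - node.age_
    tree.is_rooted = True
    return GeneTree(locus_name, tree, rooted=True)


def simulate_alignment(
    tree: GeneTree,
    length: int,
    theta: float,
    seed: Union[int, np.random.Generator] = 0,
    model: str = "jc",
) -> LocusAlignment:
    """Evolve sequences along a gene tree from a uniform root sequence.

    ``model="jc"`` is finite-sites Jukes-Cantor (recurrent substitution
    allowed, matching the homoplasy seen at real loci); ``"infinite"``
    gives each mutation a fresh column and errors out if the alignment is
    too short to hold them all.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    if model not in ("jc", "infinite"):
        raise ConfigError(f"unknown substitution model {model!r}")
    rate = theta / 2.0  # per site per coalescent unit
    root_seq = rng.integers(0, 4, size=length)
    seqs: Dict[str, np.ndarray] = {}
    next_col = [0]

    def evolve(parent_seq: np.ndarray, node: dendropy.Node) -> np.ndarray:
        b = node.edge.length
        if b is None:
            raise ConfigError("gene tree is missing branch lengths")
        seq = parent_seq.copy()
        if model == "jc":
            p = 0.75 * (1.0 - np.exp(-4.0 / 3.0 * rate * b))
            hits = np.nonzero(rng.random(length) < p)[0]
            if hits.size:
                seq[hits] = (seq[hits] + rng.integers(1, 4, size=hits.size)) % 4
        else:
            n_mut = rng.poisson(rate * b * length)
            if next_col[0] + n_mut > length:
                raise ConfigError(
                    "infinite-sites model: alignment too short for the "
                    "mutations drawn"
                )
            for _ in range(n_mut):
                col = next_col[0]
                next_col[0] += 1
                seq[col] = (seq[col] + 1) % 4
        return seq

    def walk(node: dendropy.Node, seq: np.ndarray) -> None:
        if node.is_leaf():
            seqs[node.taxon.label] = seq
            return
        for ch in node.child_nodes():
            walk(ch, evolve(seq, ch))

    walk(tree.tree.seed_node, root_seq)
    return LocusAlignment(
        tree.locus_name,
        {sid: "".join(_BASES[s]) for sid, s in sorted(seqs.items())},
    )


def apply_partial_sequences(
    aln: LocusAlignment,
    fraction: float,
    rng: np.random.Generator,
) -> LocusAlignment:
    """Truncate a fraction of sequences to one contiguous end window.

    Mimics half-locus sequencing of degraded fungarium DNA: each affected
    sequence keeps 35-55% of its columns anchored at a random end, the
    rest becoming gaps.
    """
    ids = sorted(aln.specimens)
    n_affect = int(round(fraction * len(ids)))
    affected = set(
        rng.choice(np.array(ids, dtype=object), size=n_affect, replace=False)
    )
    out: Dict[str, str] = {}
    for sid in aln.specimens:
        seq = aln[sid]
        if sid in affected:
            keep = int(round(rng.uniform(0.35, 0.55) * aln.length))
            keep = max(1, keep)
            if rng.integers(2) == 0:  # keep the 5' end
                seq = seq[:keep] + "-" * (aln.length - keep)
            else:
                seq = "-" * (aln.length - keep) + seq[-keep:]
        out[sid] = seq
    return LocusAlignment(aln.locus_name, out)


def simulate_dataset(
    config: SimulationConfig, build_concat: bool = True
) -> SimulatedDataset:
    """Simulate gene trees and alignments for every configured locus.

    The true species hypothesis maps each specimen to its species of
    origin.  When ``build_concat`` is set and at least three specimens
    exist, a neighbour-joining tree on the summed per-locus SNP distances
    is attached as the combined-data phylogeny (supports absent).
    """
    alignments: Dict[str, LocusAlignment] = {}
    gene_trees: Dict[str, GeneTree] = {}
    for i, lc in enumerate(config.loci):
        gt = simulate_gene_tree(config, lc.name, rng=_rng_for(config, 2 * i))
        aln = simulate_alignment(
            gt, lc.length, lc.theta, seed=_rng_for(config, 2 * i + 1)
        )
        if config.partial_fraction > 0:
            aln = apply_partial_sequences(
                aln, config.partial_fraction, _rng_for(config, 1000 + i)
            )
        gene_trees[lc.name] = gt
        alignments[lc.name] = aln
    hypothesis = SpeciesHypothesis(
        {
            sid: sp
            for sp, sids in config.specimen_ids().items()
            for sid in sids
        }
    )
    concat = None
    if build_concat and len(hypothesis.specimens) >= 3:
        concat = concatenation_tree(list(alignments.values()))
    return SimulatedDataset(alignments, gene_trees, hypothesis, config, concat)


def concatenation_tree(
    alns: Sequence[LocusAlignment], locus_name: str = "concat"
) -> GeneTree:
    """Neighbour-joining tree on summed per-locus SNP distances.

    A topology-only stand-in for a combined-data phylogeny; node supports
    are absent.
    """
    from skbio import DistanceMatrix
    from skbio.tree import nj

    from .variation import pairwise_snp_distance

    ids = sorted({sid for aln in alns for sid in aln.specimens})
    if len(ids) < 3:
        raise ConfigError("concatenation tree needs >= 3 specimens")
    mat = np.zeros((len(ids), len(ids)))
    for i, a in enumerate(ids):
        for j in range(i + 1, len(ids)):
            b = ids[j]
            d = 0
            for aln in alns:
                if a in aln and b in aln:
                    dd, ov = pairwise_snp_distance(aln, a, b)
                    if ov:
                        d += dd
            mat[i, j] = mat[j, i] = d
    tree = nj(DistanceMatrix(mat, ids))
    buf = _io.StringIO()
    tree.write(buf)
    from .io import parse_gene_tree

    return parse_gene_tree(buf.getvalue(), locus_name, rooted=False)


def plant_synapomorphies(
    dataset: SimulatedDataset,
    G: Set[str],
    H: Set[str],
    per_locus_counts: Dict[str, int],
    states: Tuple[str, str] = ("C", "T"),
) -> SimulatedDataset:
    """Overwrite columns so G and H are uniformly different at each one.

    For each locus, ``per_locus_counts[locus]`` evenly spaced columns are
    overwritten: every member of G gets ``states[0]`` and every member of
    H gets ``states[1]``.  Counting synapomorphies afterwards returns at
    least the planted number.  Planting is deterministic and idempotent
    for the same counts and states.
    """
    if states[0] == states[1]:
        raise ConfigError("planted states must differ")
    new_alns = dict(dataset.alignments)
    for locus, count in per_locus_counts.items():
        if count == 0:
            continue
        aln = dataset.alignments[locus]
        if count > aln.length:
            raise ConfigError(
                f"cannot plant {count} synapomorphies in {aln.length} columns"
            )
        cols = [int(i * aln.length / count) for i in range(count)]
        seqs = dict(aln.sequences)
        for sid in list(G) + list(H):
            if sid not in seqs:
                continue
            chars = list(seqs[sid])
            base = states[0] if sid in G else states[1]
            for c in cols:
                chars[c] = base
            seqs[sid] = "".join(chars)
        new_alns[locus] = LocusAlignment(locus, seqs)
    return SimulatedDataset(
        alignments=new_alns,
        gene_trees=dict(dataset.gene_trees),
        hypothesis=dataset.hypothesis,
        config=dataset.config,
        concat_tree=dataset.concat_tree,
    )


# ---------------------------------------------------------------------------
# Canned fixtures


FIXTURE_NAMES = (
    "clean_two_species",
    "ils_radiation",
    "single_specimen",
    "partial_fungarium",
    "four_label_one_species",
)


def _zero_theta_loci() -> Tuple[LocusConfig, ...]:
    return tuple(replace(lc, theta=0.0) for lc in DEFAULT_LOCI)


def make_fixture(name: str, seed: Optional[int] = None) -> SimulatedDataset:
    """Deterministic canned datasets with documented expected outcomes.

    clean_two_species
        Two species split 20 coalescent units ago, five samples each.
        Expected: both candidates pass all five criteria; no merges.
    ils_radiation
        Three species with short internal branches (heavy incomplete
        lineage sorting); gene trees routinely conflict.
    single_specimen
        Deeply diverged pair with one species sampled once.  Expected:
        the singleton fails minimal sampling only and is never merged.
    partial_fungarium
        Two labels separated by planted diagnostic sites on otherwise
        invariant loci; ITS carries exactly one diagnostic SNP in its 3'
        half and half of the specimens are truncated to the 5' half.
        Expected: truncated ITS queries come back UNDETERMINED
        (no_coverage).
    four_label_one_species
        Twelve samples of one panmictic species split over four candidate
        labels.  Expected: the recommender lumps all four into one merge
        set.
    """
    if name == "clean_two_species":
        cfg = SimulationConfig(
            species_tree="(A:20.0,B:20.0);",
            samples_per_species={"A": 5, "B": 5},
            seed=2019 if seed is None else seed,
        )
        return simulate_dataset(cfg)
    if name == "ils_radiation":
        cfg = SimulationConfig(
            species_tree="((A:1.0,B:1.0):0.5,C:1.5);",
            samples_per_species={"A": 4, "B": 4, "C": 4},
            seed=1952 if seed is None else seed,
        )
        return simulate_dataset(cfg)
    if name == "single_specimen":
        cfg = SimulationConfig(
            species_tree="(A:20.0,B:20.0);",
            samples_per_species={"A": 5, "B": 1},
            seed=1909 if seed is None else seed,
        )
        return simulate_dataset(cfg)
    if name == "partial_fungarium":
        cfg = SimulationConfig(
            species_tree="(A:20.0,B:20.0);",
            samples_per_species={"A": 4, "B": 4},
            loci=_zero_theta_loci(),
            seed=1890 if seed is None else seed,
        )
        ds = simulate_dataset(cfg, build_concat=False)
        ga = {s for s, l in ds.hypothesis.assignment.items() if l == "A"}
        gb = {s for s, l in ds.hypothesis.assignment.items() if l == "B"}
        # single ITS2-like diagnostic SNP; a handful elsewhere
        its = ds.alignments["ITS"]
        seqs = dict(its.sequences)
        col = int(0.75 * its.length)  # 3' half, adjacent to the rDNA core
        for sid in list(ga) + list(gb):
            chars = list(seqs[sid])
            chars[col] = "C" if sid in ga else "T"
            seqs[sid] = "".join(chars)
        ds.alignments["ITS"] = LocusAlignment("ITS", seqs)
        ds = plant_synapomorphies(
            ds, ga, gb, {"LSU": 3, "RPB1": 5, "RPB2": 5, "EF1a": 8}
        )
        # truncate half the specimens to the 5' half of ITS (degraded DNA)
        its = ds.alignments["ITS"]
        half = its.length // 2
        seqs = dict(its.sequences)
        for sid in ("A03", "A04", "B03", "B04"):
            seqs[sid] = seqs[sid][:half] + "-" * (its.length - half)
        ds.alignments["ITS"] = LocusAlignment("ITS", seqs)
        ds.concat_tree = concatenation_tree(list(ds.alignments.values()))
        return ds
    if name == "four_label_one_species":
        cfg = SimulationConfig(
            species_tree="X:1.0;",
            samples_per_species={"X": 12},
            seed=2012 if seed is None else seed,
        )
        ds = simulate_dataset(cfg)
        ids = cfg.specimen_ids()["X"]
        labels = {
            sid: f"L{i // 3 + 1}" for i, sid in enumerate(ids)
        }  # L1..L4, three specimens each
        ds.hypothesis = SpeciesHypothesis(labels)
        return ds
    raise ConfigError(
        f"unknown fixture {name!r}; choose from {', '.join(FIXTURE_NAMES)}"
    )
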