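"""Desk-scale synthetic virus/host communities.

Generates communities carrying the two signals the host-prediction method
exploits: (i) viruses of the same genus draw their genes from a shared,
genus-specific gene pool, so they share significantly more protein clusters
with each other than with viruses of other genera; and (ii) a fraction of
viruses carry a near-verbatim fragment of one of their hosts' genomes, so
virus-host nucleotide alignment recovers true pairs.  Host genomes and
intergenic virus sequence additionally carry a genus-specific 4-mer
compositional bias so that k-mer-based sequence features are informative
about the genus.

All outputs are deterministic functions of the parameter set, including the
integer seed.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ParameterError
from .sequence_io import SeqRecord, write_fasta

RANKS = ("phylum", "class", "order", "family", "genus")

_AA = "ACDEFGHIKLMNPQRSTVWY"
_NT = "ACGT"

#: codons per amino acid for back-translation (standard code, stops excluded)
_CODONS = {
    "A": ["GCT", "GCC", "GCA", "GCG"],
    "C": ["TGT", "TGC"],
    "D": ["GAT", "GAC"],
    "E": ["GAA", "GAG"],
    "F": ["TTT", "TTC"],
    "G": ["GGT", "GGC", "GGA", "GGG"],
    "H": ["CAT", "CAC"],
    "I": ["ATT", "ATC", "ATA"],
    "K": ["AAA", "AAG"],
    "L": ["TTA", "TTG", "CTT", "CTC", "CTA", "CTG"],
    "M": ["ATG"],
    "N": ["AAT", "AAC"],
    "P": ["CCT", "CCC", "CCA", "CCG"],
    "Q": ["CAA", "CAG"],
    "R": ["CGT", "CGC", "CGA", "CGG", "AGA", "AGG"],
    "S": ["TCT", "TCC", "TCA", "TCG", "AGT", "AGC"],
    "T": ["ACT", "ACC", "ACA", "ACG"],
    "V": ["GTT", "GTC", "GTA", "GTG"],
    "W": ["TGG"],
    "Y": ["TAT", "TAC"],
}
_STOP_CODONS = ("TAA", "TAG", "TGA")


class TaxonomyTree:
    """A five-rank (phylum..genus) taxonomy.

    ``nodes`` maps a taxon name to its ``(rank, parent)`` pair; phyla have
    parent ``None``.  Names are unique across the whole tree.
    """

    ranks = RANKS

    def __init__(self, nodes: dict[str, tuple[str, str | None]]):
        self.nodes = dict(nodes)
        for name, (rank, parent) in self.nodes.items():
            if rank not in RANKS:
                raise ParameterError(f"unknown rank {rank!r} for taxon {name!r}")
            if rank != "phylum":
                if parent not in self.nodes:
                    raise ParameterError(f"taxon {name!r} has unknown parent {parent!r}")

    @property
    def genera(self) -> list[str]:
        return [n for n, (r, _) in self.nodes.items() if r == "genus"]

    def taxa_at(self, rank: str) -> list[str]:
        return [n for n, (r, _) in self.nodes.items() if r == rank]

    def parent(self, name: str) -> str | None:
        return self.nodes[name][1]

    def rank_of(self, name: str) -> str:
        return self.nodes[name][0]

    def lineage(self, genus: str) -> dict[str, str]:
        """Full lineage of a genus as a rank -> taxon mapping."""
        if self.nodes[genus][0] != "genus":
            raise ParameterError(f"{genus!r} is not a genus")
        out: dict[str, str] = {}
        name: str | None = genus
        while name is not None:
            rank, parent = self.nodes[name]
            out[rank] = name
            name = parent
        if set(out) != set(RANKS):
            raise ParameterError(f"broken lineage for {genus!r}")
        return out

    def ancestor_at(self, name: str, rank: str) -> str:
        """The ancestor of ``name`` at ``rank`` (possibly itself)."""
        cur: str | None = name
        while cur is not None:
            r, parent = self.nodes[cur]
            if r == rank:
                return cur
            cur = parent
        raise ParameterError(f"{name!r} has no ancestor at rank {rank!r}")

    def add_lineage(self, lineage: dict[str, str]) -> None:
        """Insert a (possibly partially novel) phylum..genus path."""
        parent: str | None = None
        for rank in RANKS:
            name = lineage[rank]
            if name in self.nodes:
                if self.nodes[name][0] != rank:
                    raise ParameterError(f"taxon {name!r} already present at another rank")
            else:
                self.nodes[name] = (rank, parent)
            parent = name


def generate_taxonomy(
    n_genera: int,
    fanout_per_rank: int | Sequence[int] = 2,
    rng_seed: int = 0,
) -> TaxonomyTree:
    """Build a taxonomy whose leaves are exactly ``n_genera`` genera.

    ``fanout_per_rank`` is the number of children merged per parent when
    collapsing upward (genus->family, family->order, order->class,
    class->phylum); a scalar applies to every step.  Child ``i`` at a rank
    is assigned to parent ``i // fanout``, so the tree is enumerable by
    hand.  The seed is accepted for interface uniformity; construction is
    deterministic.
    """
    if n_genera < 1:
        raise ParameterError("n_genera must be >= 1")
    if isinstance(fanout_per_rank, int):
        fanouts = [fanout_per_rank] * 4
    else:
        fanouts = list(fanout_per_rank)
        if len(fanouts) != 4:
            raise ParameterError("fanout_per_rank needs one entry per collapse step (4)")
    if any(f < 1 for f in fanouts):
        raise ParameterError("fanout_per_rank must be >= 1")

    counts = [n_genera]
    for f in fanouts:
        counts.append(max(1, math.ceil(counts[-1] / f)))
    # counts: genus, family, order, class, phylum
    nodes: dict[str, tuple[str, str | None]] = {}
    rank_order = list(reversed(RANKS))  # genus..phylum
    for level, rank in enumerate(rank_order):
        for i in range(counts[level]):
            if rank == "phylum":
                parent = None
            else:
                parent_rank = rank_order[level + 1]
                parent = f"{parent_rank}_{i // fanouts[level]}"
            nodes[f"{rank}_{i}"] = (rank, parent)
    return TaxonomyTree(nodes)


@dataclass
class CommunityParams:
    """Parameters of a synthetic virus/host community.

    Defaults describe a community of 5 genera with 2 hosts and 20 viruses
    each; every virus carries 10 genes from its genus pool of 30 plus 2
    noise genes from a community-wide pool, and half the viruses carry a
    500 bp host-derived fragment.
    """

    n_genera: int = 5
    hosts_per_genus: int = 2
    viruses_per_genus: int = 20
    genes_per_genus_pool: int = 30
    genes_per_virus: int = 10
    shared_noise_genes: int = 2
    global_noise_pool: int = 60
    gene_len_aa: int = 120
    host_genome_len: int = 100_000
    virus_genome_len: int = 15_000
    fragment_insert_prob: float = 0.5
    fragment_len: int = 500
    point_mutation_rate: float = 0.02
    known_pair_fraction: float = 0.75
    composition_bias: float = 3.0
    rng_seed: int = 7

    def __post_init__(self) -> None:
        counts = (
            self.n_genera,
            self.hosts_per_genus,
            self.viruses_per_genus,
            self.genes_per_genus_pool,
            self.genes_per_virus,
            self.gene_len_aa,
            self.host_genome_len,
            self.virus_genome_len,
            self.fragment_len,
        )
        if any(c < 1 for c in counts):
            raise ParameterError("all counts must be >= 1")
        if self.shared_noise_genes < 0 or self.global_noise_pool < 0:
            raise ParameterError("noise gene counts must be >= 0")
        for p in (self.fragment_insert_prob, self.point_mutation_rate, self.known_pair_fraction):
            if not 0.0 <= p <= 1.0:
                raise ParameterError("probabilities must be in [0, 1]")
        if self.fragment_len >= self.virus_genome_len:
            raise ParameterError("fragment_len must be < virus_genome_len")
        if self.genes_per_virus > self.genes_per_genus_pool:
            raise ParameterError("gene pool smaller than genes_per_virus")
        if self.shared_noise_genes > self.global_noise_pool:
            raise ParameterError("global noise pool smaller than shared_noise_genes")


@dataclass
class Community:
    """In-memory result of :func:`generate_community`."""

    params: CommunityParams
    tree: TaxonomyTree
    hosts: list[SeqRecord]
    viruses: list[SeqRecord]
    proteins: list[SeqRecord]
    truth: pd.DataFrame  # virus_id, host_id, phylum..genus
    known_pairs: pd.DataFrame  # virus_id, host_id
    protein_sources: pd.DataFrame  # protein_id, gene_id, genome_id
    host_taxonomy: pd.DataFrame  # host_id, phylum..genus

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write all artifacts to ``outdir``; returns the path map."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "hosts": outdir / "hosts.fasta",
            "viruses": outdir / "viruses.fasta",
            "proteins": outdir / "proteins.fasta",
            "truth": outdir / "truth.tsv",
            "known_pairs": outdir / "known_pairs.tsv",
            "protein_sources": outdir / "protein_sources.tsv",
            "host_taxonomy": outdir / "host_taxonomy.tsv",
        }
        write_fasta(self.hosts, paths["hosts"])
        write_fasta(self.viruses, paths["viruses"])
        write_fasta(self.proteins, paths["proteins"])
        self.truth.to_csv(paths["truth"], sep="\t", index=False)
        self.known_pairs.to_csv(paths["known_pairs"], sep="\t", index=False)
        self.protein_sources.to_csv(paths["protein_sources"], sep="\t", index=False)
        self.host_taxonomy.to_csv(paths["host_taxonomy"], sep="\t", index=False)
        return paths


def _mutate_protein(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    chars = list(seq)
    hit = rng.random(len(chars)) < rate
    for i in np.flatnonzero(hit):
        choices = _AA.replace(chars[i], "")
        chars[i] = choices[rng.integers(len(choices))]
    return "".join(chars)


def _mutate_dna(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    chars = list(seq)
    hit = rng.random(len(chars)) < rate
    for i in np.flatnonzero(hit):
        choices = _NT.replace(chars[i], "")
        chars[i] = choices[rng.integers(len(choices))]
    return "".join(chars)


def _random_protein(length: int, rng: np.random.Generator) -> str:
    body = rng.integers(0, len(_AA), size=length - 1)
    return "M" + "".join(_AA[i] for i in body)


def _back_translate(prot: str, rng: np.random.Generator) -> str:
    codons = [_CODONS[aa][rng.integers(len(_CODONS[aa]))] for aa in prot]
    codons.append(_STOP_CODONS[rng.integers(3)])
    return "".join(codons)


_FOURMERS = ["".join(p) for p in itertools.product(_NT, repeat=4)]


def _biased_dna(length: int, probs: np.ndarray, rng: np.random.Generator) -> str:
    """Sample DNA by concatenating 4-mers from a genus-specific distribution."""
    n = length // 4 + 1
    idx = rng.choice(len(_FOURMERS), size=n, p=probs)
    return "".join(_FOURMERS[i] for i in idx)[:length]


def generate_community(params: CommunityParams, tree: TaxonomyTree) -> Community:
    """Generate a full community: genomes, proteins and ground-truth tables.

    Every virus is assigned a single true host within its genus; a subset
    of ``known_pair_fraction`` of the viruses has that interaction recorded
    in the known-pairs table (the rest are the query/test viruses).
    """
    genera = tree.genera
    if len(genera) < params.n_genera:
        raise ParameterError(
            f"taxonomy has {len(genera)} genera, need {params.n_genera}"
        )
    genera = genera[: params.n_genera]
    rng = np.random.default_rng(params.rng_seed)

    # gene pools: genus-specific + community-wide noise pool
    noise_pool = {
        f"noise_g{i}": _random_protein(params.gene_len_aa, rng)
        for i in range(params.global_noise_pool)
    }
    genus_pools: dict[str, dict[str, str]] = {}
    for g in genera:
        genus_pools[g] = {
            f"{g}_gene{i}": _random_protein(params.gene_len_aa, rng)
            for i in range(params.genes_per_genus_pool)
        }

    # genus-specific 4-mer composition bias
    genus_probs: dict[str, np.ndarray] = {}
    for g in genera:
        w = 1.0 + params.composition_bias * rng.random(len(_FOURMERS))
        genus_probs[g] = w / w.sum()

    hosts: list[SeqRecord] = []
    host_tax_rows: list[dict[str, str]] = []
    hosts_by_genus: dict[str, list[SeqRecord]] = {g: [] for g in genera}
    for gi, g in enumerate(genera):
        lineage = tree.lineage(g)
        for j in range(params.hosts_per_genus):
            hid = f"host_{gi}_{j}"
            seq = _biased_dna(params.host_genome_len, genus_probs[g], rng)
            rec = SeqRecord(id=hid, sequence=seq, role="host")
            hosts.append(rec)
            hosts_by_genus[g].append(rec)
            host_tax_rows.append({"host_id": hid, **{r: lineage[r] for r in RANKS}})

    viruses: list[SeqRecord] = []
    proteins: list[SeqRecord] = []
    truth_rows: list[dict[str, str]] = []
    source_rows: list[dict[str, str]] = []
    noise_ids = sorted(noise_pool)
    for gi, g in enumerate(genera):
        pool_ids = sorted(genus_pools[g])
        lineage = tree.lineage(g)
        for v in range(params.viruses_per_genus):
            vid = f"virus_{gi}_{v}"
            host_rec = hosts_by_genus[g][rng.integers(len(hosts_by_genus[g]))]
            gene_ids = [
                pool_ids[i]
                for i in rng.choice(len(pool_ids), size=params.genes_per_virus, replace=False)
            ]
            if params.shared_noise_genes:
                gene_ids += [
                    noise_ids[i]
                    for i in rng.choice(
                        len(noise_ids), size=params.shared_noise_genes, replace=False
                    )
                ]
            prots: list[str] = []
            for idx, gene_id in enumerate(gene_ids):
                template = genus_pools[g].get(gene_id, noise_pool.get(gene_id))
                prot = _mutate_protein(template, params.point_mutation_rate, rng)
                pid = f"{vid}_{idx}"
                proteins.append(SeqRecord(id=pid, sequence=prot, role="protein"))
                source_rows.append({"protein_id": pid, "gene_id": gene_id, "genome_id": vid})
                prots.append(prot)

            blocks = [_back_translate(p, rng) for p in prots]
            if rng.random() < params.fragment_insert_prob:
                start = rng.integers(0, len(host_rec.sequence) - params.fragment_len + 1)
                frag = host_rec.sequence[start : start + params.fragment_len]
                blocks.append(_mutate_dna(frag, params.point_mutation_rate, rng))
            content = sum(len(b) for b in blocks)
            if content >= params.virus_genome_len:
                raise ParameterError(
                    "gene content exceeds virus_genome_len; increase genome length"
                )
            spare = params.virus_genome_len - content
            cuts = np.sort(rng.integers(0, spare + 1, size=len(blocks)))
            gaps = np.diff(np.concatenate([[0], cuts, [spare]]))
            pieces: list[str] = []
            for gap, block in zip(gaps, blocks):
                pieces.append(_biased_dna(int(gap), genus_probs[g], rng))
                pieces.append(block)
            pieces.append(_biased_dna(int(gaps[-1]), genus_probs[g], rng))
            genome = "".join(pieces)
            viruses.append(SeqRecord(id=vid, sequence=genome, role="virus"))
            truth_rows.append(
                {"virus_id": vid, "host_id": host_rec.id, **{r: lineage[r] for r in RANKS}}
            )

    truth = pd.DataFrame(truth_rows, columns=["virus_id", "host_id", *RANKS])
    n_known = int(round(params.known_pair_fraction * len(truth)))
    known_idx = np.sort(rng.choice(len(truth), size=n_known, replace=False))
    known_pairs = truth.iloc[known_idx][["virus_id", "host_id"]].reset_index(drop=True)
    return Community(
        params=params,
        tree=tree,
        hosts=hosts,
        viruses=viruses,
        proteins=proteins,
        truth=truth,
        known_pairs=known_pairs,
        protein_sources=pd.DataFrame(source_rows, columns=["protein_id", "gene_id", "genome_id"]),
        host_taxonomy=pd.DataFrame(host_tax_rows, columns=["host_id", *RANKS]),
    )
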