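"""Synthetic-data generator for the whole marker workflow.

Produces, from one seed: an ultrametric species tree, conserved single-copy
loci evolved on it under Jukes-Cantor with per-locus and per-site rate
multipliers (substitutions only, no indels, so the true alignments are
column-exact), genome assemblies embedding each retained locus copy in
nonconserved background sequence, planted species-specific insertions
(i.i.d. uniform DNA present in exactly one taxon), and truth tables for
downstream recovery tests.

Defaults emulate a small panel of closely related fruit-fly-style taxa:
8 taxa on a shallow radiation (root-to-tip 0.02 substitutions/site, so
conserved loci stay within the harvesting and cross-matching identity
radii across the whole panel), 50 loci of ~600 bp with modest among-locus
rate spread (Gamma shape 6) and strong within-locus site heterogeneity
(Gamma shape 0.5), 10% per-(locus,taxon) dropout to create occupancy
structure, and one 1-kb unique insertion per taxon for the diagnostic
screen.
"""
from __future__ import annotations

import random
from dataclasses import dataclass, field

import dendropy
import numpy as np

from .seqio import Genome, Tree, reverse_complement
from .supermatrix import LocusAlignment

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimConfig:
    n_taxa: int = 8
    tree_mode: str = "yule"  # or "balanced"
    # shallow radiation: conserved loci must stay inside the harvesting and
    # cross-matching identity radii across the whole panel (the defining
    # property of conserved single-copy markers)
    tree_depth: float = 0.02  # expected substitutions/site, root to tip
    n_loci: int = 50
    locus_length_mean: float = 600.0
    locus_length_sd: float = 100.0
    per_locus_rate_shape: float = 6.0  # gamma shape of locus rate multiplier
    per_site_rate_shape: float = 0.5  # gamma shape of site rate multiplier
    dropout_prob: float = 0.1
    background_length: int = 60_000
    n_unique_regions: int = 1
    unique_length: int = 1000
    reverse_strand_prob: float = 0.5
    # probes: None -> one whole-root-sequence probe per locus; else tiled
    probe_tile_length: int | None = None
    probe_tile_step: int | None = None
    # decoy mode: copy each unique region of taxon i into taxon (i+1) with
    # this per-site mutation rate (None disables)
    decoy_divergence: float | None = None
    # plant an extra copy of the first `duplicated_loci` loci in taxon 0
    duplicated_loci: int = 0
    seed: int = 0

    def validate(self) -> None:
        if self.n_taxa < 2:
            raise ValueError("n_taxa must be >= 2")
        if not 0 <= self.dropout_prob <= 1:
            raise ValueError("dropout_prob must be in [0,1]")
        for name in ("tree_depth", "per_locus_rate_shape", "per_site_rate_shape"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class TruthTables:
    true_tree: Tree
    locus_presence: dict[str, dict[str, bool]]  # locus -> taxon -> present
    locus_coords: dict[tuple[str, str], tuple[str, int, int, str]]
    unique_regions: dict[str, list[tuple[str, int, int]]]
    true_site_rates: dict[str, np.ndarray]  # per-locus per-site rate (x locus rate)
    locus_rates: dict[str, float]
    decoy_coords: dict[tuple[str, str], tuple[str, int, int]] = field(
        default_factory=dict
    )


@dataclass
class ProbeSet:
    probes: dict[str, str]
    probe_to_locus: dict[str, str]
    marker_label: str = "BUSCO-like"

    def __post_init__(self) -> None:
        missing = set(self.probes) - set(self.probe_to_locus)
        if missing:
            raise ValueError(f"probes without locus mapping: {sorted(missing)[:3]}")


# ---------------------------------------------------------------------------
# Trees


def _balanced_tree(taxa: list[str], depth: float) -> Tree:
    """Ultrametric tree from recursive halving; every split divides the
    remaining time in two, so all root-to-tip paths equal `depth`."""
    ns = dendropy.TaxonNamespace()
    t = dendropy.Tree(taxon_namespace=ns)

    def attach(node, labels, remaining):
        half = remaining / 2.0
        mid = (len(labels) + 1) // 2
        for part in (labels[:mid], labels[mid:]):
            if len(part) == 1:
                child = node.new_child(edge_length=remaining)
                child.taxon = ns.new_taxon(part[0])
            else:
                child = node.new_child(edge_length=half)
                attach(child, part, remaining - half)

    attach(t.seed_node, taxa, depth)
    return Tree(t)


def _yule_tree(taxa: list[str], depth: float, rng: random.Random) -> Tree:
    from dendropy.model import birthdeath

    t = birthdeath.birth_death_tree(
        birth_rate=1.0,
        death_rate=0.0,
        num_extant_tips=len(taxa),
        rng=rng,
    )
    # the process stops at the n-th speciation, leaving a zero-length cherry;
    # sample the tree one exponential waiting time later (same increment on
    # every tip edge keeps it ultrametric)
    extra = rng.expovariate(len(taxa))
    for leaf in t.leaf_node_iter():
        leaf.edge.length = (leaf.edge.length or 0.0) + extra
    # rename leaves deterministically, rescale root-to-tip depth
    leaves = sorted(t.leaf_node_iter(), key=lambda n: n.taxon.label)
    ns = dendropy.TaxonNamespace()
    for leaf, label in zip(leaves, taxa):
        leaf.taxon = ns.new_taxon(label)
    t.taxon_namespace = ns
    tree = Tree(t)
    cur = max(tree.root_to_tip_depths().values())
    if cur > 0 and depth > 0:
        scale = depth / cur
        for e in t.preorder_edge_iter():
            if e.length is not None:
                e.length *= scale
    elif depth == 0:
        for e in t.preorder_edge_iter():
            if e.length is not None:
                e.length = 0.0
    return tree


def simulate_tree(config: SimConfig, rng: random.Random) -> Tree:
    taxa = [f"t{i + 1:02d}" for i in range(config.n_taxa)]
    if config.tree_mode == "balanced":
        return _balanced_tree(taxa, config.tree_depth)
    if config.tree_mode == "yule":
        return _yule_tree(taxa, config.tree_depth, rng)
    raise ValueError(f"unknown tree_mode {config.tree_mode!r}")


# ---------------------------------------------------------------------------
# Sequence evolution (Jukes-Cantor, substitutions only)


def _random_dna(rng: np.random.Generator, n: int) -> np.ndarray:
    return BASES[rng.integers(0, 4, size=n)]


def _jc_mutate(
    seq: np.ndarray, branch: float, site_rates: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Evolve one branch under JC: per-site substitution probability
    p = 3/4 (1 - exp(-4/3 * b * r))."""
    p = 0.75 * (1.0 - np.exp(-4.0 / 3.0 * branch * site_rates))
    hit = rng.random(seq.size) < p
    out = seq.copy()
    if hit.any():
        # substitute with one of the three other bases
        idx = np.searchsorted(BASES, out[hit])
        shift = rng.integers(1, 4, size=int(hit.sum()))
        out[hit] = BASES[(idx + shift) % 4]
    return out


def _evolve_locus(
    tree: Tree, root_seq: np.ndarray, site_rates: np.ndarray, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    seqs: dict[int, np.ndarray] = {id(tree.dtree.seed_node): root_seq}
    out: dict[str, np.ndarray] = {}
    for node in tree.dtree.preorder_node_iter():
        if node.parent_node is None:
            cur = root_seq
        else:
            parent = seqs[id(node.parent_node)]
            cur = _jc_mutate(parent, node.edge.length or 0.0, site_rates, rng)
            seqs[id(node)] = cur
        if node.is_leaf():
            out[node.taxon.label] = cur
    return out


# ---------------------------------------------------------------------------
# Dataset assembly


def simulate_dataset(
    config: SimConfig,
) -> tuple[list[Genome], ProbeSet, list[LocusAlignment], TruthTables]:
    """Generate genomes, probes, true per-locus alignments and truth tables.

    The returned alignments contain only taxa that retained the locus
    (dropout removes rows and genome copies together); the full species
    tree and per-site rates are exposed for recovery tests.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    pyrng = random.Random(config.seed)
    tree = simulate_tree(config, pyrng)
    taxa = sorted(tree.leaf_labels)

    locus_ids = [f"L{i + 1:04d}" for i in range(config.n_loci)]
    locus_rates = {}
    site_rates = {}
    roots = {}
    alignments: dict[str, dict[str, str]] = {}
    presence: dict[str, dict[str, bool]] = {}

    shape_l = config.per_locus_rate_shape
    shape_s = config.per_site_rate_shape
    for lid in locus_ids:
        L = max(100, int(round(rng.normal(config.locus_length_mean, config.locus_length_sd))))
        r_locus = float(rng.gamma(shape_l, 1.0 / shape_l)) if shape_l > 0 else 1.0
        r_sites = (
            rng.gamma(shape_s, 1.0 / shape_s, size=L) if shape_s > 0 else np.ones(L)
        )
        rates = r_locus * r_sites
        root = _random_dna(rng, L)
        leaf_seqs = _evolve_locus(tree, root, rates, rng)
        keep = {t: bool(rng.random() >= config.dropout_prob) for t in taxa}
        if not any(keep.values()):  # never lose a locus entirely
            keep[taxa[int(rng.integers(len(taxa)))]] = True
        locus_rates[lid] = r_locus
        site_rates[lid] = rates
        roots[lid] = root
        presence[lid] = keep
        alignments[lid] = {
            t: leaf_seqs[t].tobytes().decode() for t in taxa if keep[t]
        }

    # probes = root sequences (optionally tiled)
    probes: dict[str, str] = {}
    probe_map: dict[str, str] = {}
    for lid in locus_ids:
        root_str = roots[lid].tobytes().decode()
        if config.probe_tile_length:
            step = config.probe_tile_step or config.probe_tile_length
            j = 0
            for off in range(0, max(1, len(root_str) - config.probe_tile_length + 1), step):
                pid = f"{lid}_p{j}"
                probes[pid] = root_str[off : off + config.probe_tile_length]
                probe_map[pid] = lid
                j += 1
        else:
            pid = f"{lid}_p0"
            probes[pid] = root_str
            probe_map[pid] = lid
    probe_set = ProbeSet(probes=probes, probe_to_locus=probe_map)

    # unique regions: i.i.d. uniform DNA, one owner taxon each
    unique_seqs: dict[str, list[str]] = {
        t: [
            _random_dna(rng, config.unique_length).tobytes().decode()
            for _ in range(config.n_unique_regions)
        ]
        for t in taxa
    }

    genomes: list[Genome] = []
    locus_coords: dict[tuple[str, str], tuple[str, int, int, str]] = {}
    unique_coords: dict[str, list[tuple[str, int, int]]] = {t: [] for t in taxa}
    decoy_coords: dict[tuple[str, str], tuple[str, int, int]] = {}

    min_gap = 50
    for ti, taxon in enumerate(taxa):
        features: list[tuple[str, str, str, str]] = []  # (kind, name, seq, strand)
        for lid in locus_ids:
            if not presence[lid][taxon]:
                continue
            seq = alignments[lid][taxon]
            strand = "-" if rng.random() < config.reverse_strand_prob else "+"
            features.append(("locus", lid, seq, strand))
        if ti == 0:
            for lid in locus_ids[: config.duplicated_loci]:
                if presence[lid][taxon]:
                    features.append(("dup", lid, alignments[lid][taxon], "+"))
        for ui, useq in enumerate(unique_seqs[taxon]):
            features.append(("unique", f"U{ui}", useq, "+"))
        if config.decoy_divergence is not None and config.n_unique_regions > 0:
            donor = taxa[(ti - 1) % len(taxa)]
            src = unique_seqs[donor][0]
            arr = np.frombuffer(src.encode(), dtype=np.uint8).copy()
            hit = rng.random(arr.size) < config.decoy_divergence
            idx = np.searchsorted(BASES, arr[hit])
            arr[hit] = BASES[(idx + rng.integers(1, 4, size=int(hit.sum()))) % 4]
            features.append(("decoy", f"decoy_from_{donor}", arr.tobytes().decode(), "+"))

        n_feat = len(features)
        if config.background_length < (n_feat + 1) * min_gap:
            raise ValueError(
                f"{taxon}: background_length {config.background_length} too small "
                f"for {n_feat} features; increase background_length"
            )
        order = list(range(n_feat))
        rng.shuffle(order)
        # split background into n_feat+1 gaps of >= min_gap bp
        free = config.background_length - (n_feat + 1) * min_gap
        cuts = np.sort(rng.integers(0, free + 1, size=n_feat)) if n_feat else np.array([], dtype=int)
        gap_sizes = np.diff(np.concatenate([[0], cuts, [free]])) + min_gap

        parts: list[str] = []
        pos = 0
        contig = "c1"
        for gi, fi in enumerate(order):
            gap = _random_dna(rng, int(gap_sizes[gi])).tobytes().decode()
            parts.append(gap)
            pos += len(gap)
            kind, name, seq, strand = features[fi]
            emb = reverse_complement(seq) if strand == "-" else seq
            start, end = pos, pos + len(emb)
            if kind == "locus":
                locus_coords[(name, taxon)] = (contig, start, end, strand)
            elif kind == "unique":
                unique_coords[taxon].append((contig, start, end))
            elif kind == "decoy":
                decoy_coords[(name, taxon)] = (contig, start, end)
            parts.append(emb)
            pos = end
        parts.append(_random_dna(rng, int(gap_sizes[-1] if n_feat else config.background_length)).tobytes().decode())
        genomes.append(Genome(taxon=taxon, contigs={contig: "".join(parts)}))

    truth = TruthTables(
        true_tree=tree,
        locus_presence=presence,
        locus_coords=locus_coords,
        unique_regions=unique_coords,
        true_site_rates=site_rates,
        locus_rates=locus_rates,
        decoy_coords=decoy_coords,
    )
    loci = [
        LocusAlignment(lid, alignments[lid], "NT") for lid in locus_ids
    ]
    return genomes, probe_set, loci, truth


def make_cds_set(
    genomes: list[Genome], truth: TruthTables
) -> dict[str, dict[str, str]]:
    """Per-taxon CDS records: the taxon's locus copies plus planted unique
    regions, extracted from the genome forward strand. Record ids encode
    (taxon, source feature, contig:start-end) and parse back exactly."""
    by_taxon = {g.taxon: g for g in genomes}
    out: dict[str, dict[str, str]] = {t: {} for t in by_taxon}
    for (lid, taxon), (contig, start, end, _strand) in truth.locus_coords.items():
        seq = by_taxon[taxon].contigs[contig][start:end]
        out[taxon][f"{taxon}|locus={lid}|{contig}:{start}-{end}"] = seq
    for taxon, regions in truth.unique_regions.items():
        for i, (contig, start, end) in enumerate(regions):
            seq = by_taxon[taxon].contigs[contig][start:end]
            out[taxon][f"{taxon}|unique=U{i}|{contig}:{start}-{end}"] = seq
    return out


def parse_cds_id(record_id: str) -> tuple[str, str, str, int, int]:
    """Invert make_cds_set ids -> (taxon, feature, contig, start, end)."""
    taxon, feat, loc = record_id.split("|")
    feat = feat.split("=", 1)[1]
    contig, span = loc.rsplit(":", 1)
    start, end = span.split("-")
    return taxon, feat, contig, int(start), int(end)
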