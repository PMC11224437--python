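"""In-silico locus harvesting from assemblies against a probe set.

A seed-and-extend matcher (exact k-mer seeds on both strands, ungapped
extension) locates probe hits; hits are grouped per locus, loci hitting
multiple regions (putative duplicates) or regions claimed by several loci
are dropped, and survivors are extracted with flanking sequence (default
400 bp each side), truncated at contig ends.

N never matches any base. All genomic intervals are 0-based half-open on
the forward strand; minus-strand captures are reported after
reverse-complementing, i.e. in probe orientation.
"""
from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from typing import NamedTuple

from .seqio import Genome, reverse_complement
from .simulate import ProbeSet
from .supermatrix import LocusAlignment

log = logging.getLogger(__name__)

DEFAULT_K = 15
DEFAULT_MIN_IDENTITY = 0.85
DEFAULT_MIN_COVERAGE = 0.8
DEFAULT_JOIN_DIST = 100
DEFAULT_FLANK = 400


class RawHit(NamedTuple):
    probe_id: str
    contig_id: str
    start: int  # genomic, 0-based half-open
    end: int
    strand: str  # '+' or '-'
    identity: float
    q_start: int  # matched span in probe coordinates
    q_end: int


@dataclass
class CapturedLocus:
    locus_id: str
    taxon: str
    contig_id: str
    start: int  # probe-match core, genomic forward coords
    end: int
    strand: str
    left_flank: int  # attained flank lengths, in probe orientation
    right_flank: int
    sequence: str  # probe-oriented (reverse-complemented for '-')
    probe_offset: int  # probe coordinate of sequence position 0
    truncated: bool = False

    def __post_init__(self) -> None:
        if len(self.sequence) != (self.end - self.start) + self.left_flank + self.right_flank:
            raise ValueError(
                f"{self.locus_id}/{self.taxon}: sequence length inconsistent with "
                "core + flanks"
            )


@dataclass
class DropRecord:
    taxon: str
    locus_id: str
    reason: str  # DUPLICATE_LOCUS or SHARED_REGION
    detail: str = ""


def build_kmer_index(genome: Genome, k: int) -> dict[str, list[tuple[str, int]]]:
    index: dict[str, list[tuple[str, int]]] = defaultdict(list)
    for cid, seq in genome.contigs.items():
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            if "N" not in kmer:
                index[kmer].append((cid, i))
    return index


def _ungapped_hit(
    query: str, contig: str, offset: int
) -> tuple[int, int, int, int, float] | None:
    """Align query at fixed offset (no gaps), clipping at contig ends.

    Returns (g_start, g_end, q_start, q_end, identity) over the aligned span.
    """
    q_start = max(0, -offset)
    q_end = min(len(query), len(contig) - offset)
    if q_end <= q_start:
        return None
    g_start, g_end = offset + q_start, offset + q_end
    span = q_end - q_start
    matches = sum(
        1
        for a, b in zip(query[q_start:q_end], contig[g_start:g_end])
        if a == b and a != "N"
    )
    return g_start, g_end, q_start, q_end, matches / span


def match_probes(
    genome: Genome,
    probes: ProbeSet,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
    k: int = DEFAULT_K,
    index: dict[str, list[tuple[str, int]]] | None = None,
) -> list[RawHit]:
    """Find probe hits by exact k-mer seeding + ungapped extension.

    A hit is reported iff identity >= min_identity over an aligned span
    covering >= min_coverage of the probe. Overlapping hits of one probe on
    one contig are merged, keeping the best-identity hit.
    """
    if not 8 <= k <= 31:
        raise ValueError("k must be in [8, 31]")
    if not (0 < min_identity <= 1 and 0 < min_coverage <= 1):
        raise ValueError("identity/coverage must be in (0, 1]")
    for pid, seq in probes.probes.items():
        if len(seq) < k:
            raise ValueError(f"probe {pid} shorter than k={k}")
    if index is None:
        index = build_kmer_index(genome, k)

    hits: list[RawHit] = []
    for pid, probe in probes.probes.items():
        plen = len(probe)
        for strand in "+-":
            query = probe if strand == "+" else reverse_complement(probe)
            offsets: dict[str, set[int]] = defaultdict(set)
            for j in range(plen - k + 1):
                kmer = query[j : j + k]
                if "N" in kmer:
                    continue
                for cid, pos in index.get(kmer, ()):
                    offsets[cid].add(pos - j)
            for cid, offs in offsets.items():
                contig = genome.contigs[cid]
                for off in sorted(offs):
                    res = _ungapped_hit(query, contig, off)
                    if res is None:
                        continue
                    g0, g1, q0, q1, ident = res
                    if ident < min_identity or (q1 - q0) / plen < min_coverage:
                        continue
                    if strand == "-":
                        # convert oriented-query span to probe coordinates
                        q0, q1 = plen - q1, plen - q0
                    hits.append(RawHit(pid, cid, g0, g1, strand, ident, q0, q1))

    return _merge_probe_hits(hits)


def _merge_probe_hits(hits: list[RawHit]) -> list[RawHit]:
    """Merge overlapping hits of the same probe on the same contig,
    keeping the best-identity representative."""
    out: list[RawHit] = []
    grouped: dict[tuple[str, str], list[RawHit]] = defaultdict(list)
    for h in hits:
        grouped[(h.probe_id, h.contig_id)].append(h)
    for key in sorted(grouped):
        cluster: list[RawHit] = []
        end = -1
        for h in sorted(grouped[key], key=lambda h: (h.start, h.end)):
            if cluster and h.start >= end:
                out.append(max(cluster, key=lambda x: x.identity))
                cluster = []
                end = -1
            cluster.append(h)
            end = max(end, h.end)
        if cluster:
            out.append(max(cluster, key=lambda x: x.identity))
    return out


def _merge_regions(
    hits: list[RawHit], join_dist: int
) -> list[list[RawHit]]:
    """Group hits (same locus, same contig, pre-sorted) whose genomic
    intervals lie within join_dist of each other."""
    groups: list[list[RawHit]] = []
    cur: list[RawHit] = []
    end = None
    for h in sorted(hits, key=lambda h: (h.start, h.end)):
        if cur and h.start > end + join_dist:
            groups.append(cur)
            cur = []
        cur.append(h)
        end = h.end if end is None or h.end > end else end
    if cur:
        groups.append(cur)
    return groups


def dedupe_and_extract(
    hits: list[RawHit],
    genome: Genome,
    probes: ProbeSet,
    flank: int = DEFAULT_FLANK,
    join_dist: int = DEFAULT_JOIN_DIST,
) -> tuple[list[CapturedLocus], list[DropRecord]]:
    """Group hits by locus, drop duplicated/shared loci, extract with flanks.

    A locus is dropped for this taxon if its probes hit more than one
    distinct contig region (DUPLICATE_LOCUS) or if one region is claimed by
    more than one locus (SHARED_REGION). Flanks are truncated at contig ends.
    """
    by_locus: dict[str, list[RawHit]] = defaultdict(list)
    for h in hits:
        by_locus[probes.probe_to_locus[h.probe_id]].append(h)

    drops: list[DropRecord] = []
    regions: dict[str, tuple[str, int, int, list[RawHit]]] = {}
    for lid in sorted(by_locus):
        per_contig: list[tuple[str, list[RawHit]]] = []
        for cid in sorted({h.contig_id for h in by_locus[lid]}):
            chits = [h for h in by_locus[lid] if h.contig_id == cid]
            per_contig += [(cid, g) for g in _merge_regions(chits, join_dist)]
        if len(per_contig) > 1:
            drops.append(
                DropRecord(genome.taxon, lid, "DUPLICATE_LOCUS",
                           f"{len(per_contig)} regions")
            )
            continue
        cid, group = per_contig[0]
        regions[lid] = (cid, min(h.start for h in group), max(h.end for h in group), group)

    # cross-locus shared-region exclusion
    shared: set[str] = set()
    items = sorted(regions.items())
    for i, (lid_a, (ca, sa, ea, _)) in enumerate(items):
        for lid_b, (cb, sb, eb, _) in items[i + 1 :]:
            if ca == cb and sa < eb and sb < ea:
                shared.update((lid_a, lid_b))
    for lid in sorted(shared):
        drops.append(DropRecord(genome.taxon, lid, "SHARED_REGION"))
        del regions[lid]

    captured: list[CapturedLocus] = []
    for lid, (cid, rs, re_, group) in sorted(regions.items()):
        contig = genome.contigs[cid]
        best = max(group, key=lambda h: (h.identity, -(h.end - h.start)))
        strand = best.strand
        left_gen = min(flank, rs)
        right_gen = min(flank, len(contig) - re_)
        raw = contig[rs - left_gen : re_ + right_gen]
        if strand == "-":
            seq = reverse_complement(raw)
            left_fl, right_fl = right_gen, left_gen
            anchor_q = best.q_start + (best.end - re_)
        else:
            seq = raw
            left_fl, right_fl = left_gen, right_gen
            anchor_q = best.q_start + (rs - best.start)
        captured.append(
            CapturedLocus(
                locus_id=lid,
                taxon=genome.taxon,
                contig_id=cid,
                start=rs,
                end=re_,
                strand=strand,
                left_flank=left_fl,
                right_flank=right_fl,
                sequence=seq,
                probe_offset=anchor_q - left_fl,
                truncated=left_gen < flank or right_gen < flank,
            )
        )
    return captured, drops


@dataclass
class CaptureResult:
    loci: dict[str, dict[str, CapturedLocus]]  # locus -> taxon -> capture
    counts: dict[str, int]  # taxon -> captured locus count
    drops: list[DropRecord]


def capture_all(
    genomes: list[Genome],
    probes: ProbeSet,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
    k: int = DEFAULT_K,
    flank: int = DEFAULT_FLANK,
    join_dist: int = DEFAULT_JOIN_DIST,
) -> CaptureResult:
    """Run match + dedupe/extract per genome; tabulate per-taxon counts."""
    loci: dict[str, dict[str, CapturedLocus]] = defaultdict(dict)
    counts: dict[str, int] = {}
    drops: list[DropRecord] = []
    for genome in genomes:
        hits = match_probes(genome, probes, min_identity, min_coverage, k)
        captured, gdrops = dedupe_and_extract(hits, genome, probes, flank, join_dist)
        drops.extend(gdrops)
        counts[genome.taxon] = len(captured)
        for c in captured:
            loci[c.locus_id][c.taxon] = c
    return CaptureResult(loci=dict(loci), counts=counts, drops=drops)


def anchor_align(
    captured: dict[str, CapturedLocus], probes: ProbeSet | None = None
) -> LocusAlignment:
    """Columnize captured copies of one locus by probe-match offset.

    Valid when sequences differ only by substitutions (no indels): every
    sequence position maps to a probe-frame coordinate via probe_offset, and
    columns outside a taxon's attainable flanks are gap-filled. Output is
    column-exact under the simulator's no-indel model.
    """
    if not captured:
        raise ValueError("no captured copies to align")
    lids = {c.locus_id for c in captured.values()}
    if len(lids) > 1:
        raise ValueError(f"mixed loci in anchor_align: {sorted(lids)}")
    lo = min(c.probe_offset for c in captured.values())
    hi = max(c.probe_offset + len(c.sequence) for c in captured.values())
    rows = {}
    for taxon, c in captured.items():
        pre = c.probe_offset - lo
        post = hi - (c.probe_offset + len(c.sequence))
        rows[taxon] = "-" * pre + c.sequence + "-" * post
    aln = LocusAlignment(next(iter(lids)), rows, "NT")
    aln.frame_offset = lo  # probe coordinate of column 0
    return aln


# ---------------------------------------------------------------------------
# Brute-force oracle (small genomes only; used by tests and cross-checks)


def brute_force_hits(
    genome: Genome,
    probes: ProbeSet,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
) -> list[RawHit]:
    """Sliding-window Hamming scan over every offset and both strands.

    Independent of the k-mer matcher; quadratic, for genomes <= ~50 kb.
    Full-coverage windows only are scanned at interior offsets plus clipped
    windows at the ends, which suffices for ungapped hits at the same
    identity/coverage thresholds.
    """
    hits: list[RawHit] = []
    for pid, probe in probes.probes.items():
        plen = len(probe)
        for strand in "+-":
            query = probe if strand == "+" else reverse_complement(probe)
            for cid, contig in genome.contigs.items():
                for off in range(-plen + 1, len(contig)):
                    res = _ungapped_hit(query, contig, off)
                    if res is None:
                        continue
                    g0, g1, q0, q1, ident = res
                    if ident < min_identity or (q1 - q0) / plen < min_coverage:
                        continue
                    if strand == "-":
                        q0, q1 = plen - q1, plen - q0
                    hits.append(RawHit(pid, cid, g0, g1, strand, ident, q0, q1))
    return _merge_probe_hits(hits)
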