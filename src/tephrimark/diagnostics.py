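"""Species-specific diagnostic-marker screen.

Pipeline: coding sequences of the target species are fragmented into 200-bp
windows at a 50-bp step; windows are searched against every panel genome
(both strands, mismatch-tolerant); windows with hits only in the target
genome are species-specific and merged into candidate regions; primers are
designed exhaustively within each region (Wallace-rule Tm 53-60 degC, GC
40-60%, 100-200 bp products); candidate pairs are verified by in-silico PCR
against the whole panel and classified UNIQUE (one target band, none
elsewhere), SIZE_DISCRIMINABLE (off-target bands all differ in size),
NON_SPECIFIC, or FAILED.
"""
from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .capture import build_kmer_index, match_probes
from .seqio import Genome, reverse_complement
from .simulate import ProbeSet

log = logging.getLogger(__name__)

DEFAULT_WINDOW = 200
DEFAULT_STEP = 50


@dataclass(frozen=True)
class Fragment:
    taxon: str
    source_cds_id: str
    offset: int  # 0-based start in the CDS
    sequence: str

    @property
    def fragment_id(self) -> str:
        return f"{self.source_cds_id}:{self.offset}"


def fragment_windows(
    cds_id: str, sequence: str, taxon: str, w: int = DEFAULT_WINDOW, s: int = DEFAULT_STEP
) -> list[Fragment]:
    """Sliding windows at offsets 0, s, 2s, ... while offset + w <= length;
    a CDS shorter than w yields no fragments."""
    if w <= 0 or s <= 0:
        raise ValueError("window and step must be positive")
    L = len(sequence)
    if L < w:
        log.debug("%s: length %d < window %d, no fragments", cds_id, L, w)
        return []
    return [
        Fragment(taxon, cds_id, off, sequence[off : off + w])
        for off in range(0, L - w + 1, s)
    ]


@dataclass
class HitReport:
    fragments: list[Fragment]
    counts: dict[str, dict[str, int]]  # fragment_id -> genome taxon -> hit count
    skipped: list[str] = field(default_factory=list)  # fragments containing N


def cross_match(
    fragments: list[Fragment],
    genomes: list[Genome],
    min_identity: float = 0.9,
    min_coverage: float = 0.9,
    k: int = 15,
) -> HitReport:
    """Count seed-and-extend hits of each fragment in each panel genome
    (both strands). Fragments containing N are skipped with a log entry."""
    clean, skipped = [], []
    for f in fragments:
        (skipped if "N" in f.sequence else clean).append(f)
    for f in skipped:
        log.info("cross_match: skipping fragment %s (contains N)", f.fragment_id)
    counts: dict[str, dict[str, int]] = {
        f.fragment_id: {} for f in clean
    }
    probe_set = ProbeSet(
        probes={f.fragment_id: f.sequence for f in clean},
        probe_to_locus={f.fragment_id: f.fragment_id for f in clean},
        marker_label="diagnostic-fragments",
    )
    for genome in genomes:
        index = build_kmer_index(genome, k)
        hits = match_probes(
            genome, probe_set, min_identity, min_coverage, k, index=index
        )
        per_frag: dict[str, int] = defaultdict(int)
        for h in hits:
            per_frag[h.probe_id] += 1
        for f in clean:
            counts[f.fragment_id][genome.taxon] = per_frag.get(f.fragment_id, 0)
    return HitReport(
        fragments=clean, counts=counts, skipped=[f.fragment_id for f in skipped]
    )


@dataclass
class SpecificRegion:
    taxon: str
    source_cds_id: str
    start: int  # 0-based half-open in the CDS
    end: int
    sequence: str


def select_specific(
    report: HitReport, target: str
) -> tuple[list[Fragment], list[SpecificRegion]]:
    """Keep fragments with >= 1 hit in the target genome and 0 hits in every
    other panel genome; merge overlapping/adjacent survivors into maximal
    specific regions. Region sequences are stitched from the overlapping
    windows."""
    panel = set()
    for per in report.counts.values():
        panel.update(per)
    if panel == {target}:
        log.warning("select_specific: panel contains only the target genome; "
                    "every fragment is trivially specific")
    keep: list[Fragment] = []
    for f in report.fragments:
        per = report.counts[f.fragment_id]
        if per.get(target, 0) >= 1 and all(
            c == 0 for t, c in per.items() if t != target
        ):
            keep.append(f)

    regions: list[SpecificRegion] = []
    by_cds: dict[str, list[Fragment]] = defaultdict(list)
    for f in keep:
        by_cds[f.source_cds_id].append(f)
    for cds_id in sorted(by_cds):
        frags = sorted(by_cds[cds_id], key=lambda f: f.offset)
        cur = [frags[0]]
        for f in frags[1:]:
            last = cur[-1]
            if f.offset <= last.offset + len(last.sequence):
                cur.append(f)
            else:
                regions.append(_stitch(cur))
                cur = [f]
        regions.append(_stitch(cur))
    return keep, regions


def _stitch(frags: list[Fragment]) -> SpecificRegion:
    start = frags[0].offset
    seq = frags[0].sequence
    for f in frags[1:]:
        seq += f.sequence[start + len(seq) - f.offset :]
    return SpecificRegion(
        taxon=frags[0].taxon,
        source_cds_id=frags[0].source_cds_id,
        start=start,
        end=start + len(seq),
        sequence=seq,
    )


# ---------------------------------------------------------------------------
# Primer design


@dataclass
class PrimerConstraints:
    min_len: int = 18
    max_len: int = 27
    gc_min: float = 40.0
    gc_max: float = 60.0
    tm_min: float = 53.0
    tm_max: float = 60.0
    max_tm_diff: float = 3.0
    max_run: int = 4
    product_min: int = 100
    product_max: int = 200
    require_gc_clamp: bool = False  # 3'-terminal base in {G,C}


@dataclass
class PrimerPair:
    fwd: str  # 5'->3' on the plus strand of the region
    rev: str  # 5'->3' on the opposite strand
    tm_fwd: float
    tm_rev: float
    gc_fwd: float
    gc_rev: float
    product_size: int
    fwd_start: int  # region coordinates, 0-based
    rev_end: int  # half-open end of the product in the region
    template: tuple[str, str] = ("", "")  # (taxon, region/fragment id)


def wallace_tm(seq: str) -> float:
    """Wallace rule: Tm = 2(A+T) + 4(G+C) degC."""
    at = sum(seq.count(b) for b in "AT")
    gc = sum(seq.count(b) for b in "GC")
    return 2.0 * at + 4.0 * gc


def gc_percent(seq: str) -> float:
    return 100.0 * sum(seq.count(b) for b in "GC") / len(seq)


def _max_run(seq: str) -> int:
    best = run = 1
    for a, b in zip(seq, seq[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best


def _primer_ok(seq: str, c: PrimerConstraints) -> tuple[bool, str]:
    if "N" in seq:
        return False, "contains_N"
    gc = gc_percent(seq)
    if not c.gc_min <= gc <= c.gc_max:
        return False, "gc"
    tm = wallace_tm(seq)
    if not c.tm_min <= tm <= c.tm_max:
        return False, "tm"
    if _max_run(seq) > c.max_run:
        return False, "run"
    return True, ""


def design_primers(
    region: str,
    constraints: PrimerConstraints | None = None,
    template: tuple[str, str] = ("", ""),
    max_pairs: int | None = None,
) -> list[PrimerPair]:
    """Exhaustively enumerate primer pairs within a region.

    Forward primers are plus-strand substrings; reverse primers are the
    reverse complement of substrings further 3'. Filters: length 18-27 nt,
    GC 40-60%, Wallace Tm 53-60 degC, pair deltaTm <= 3, no mononucleotide
    run > 4, product 100-200 bp. Ranked by |mean pair Tm - 57| then product
    centrality. Returns [] with per-filter rejection counts logged if
    nothing passes.
    """
    c = constraints or PrimerConstraints()
    L = len(region)
    rejections: dict[str, int] = defaultdict(int)
    if L < c.product_min:
        raise ValueError(
            f"region length {L} below minimum product size {c.product_min}"
        )
    # single-primer candidates: (start, end) substrings passing filters
    cands: list[tuple[int, int, float, float]] = []  # start, end, tm, gc
    for start in range(L):
        for ln in range(c.min_len, c.max_len + 1):
            end = start + ln
            if end > L:
                break
            sub = region[start:end]
            ok, why = _primer_ok(sub, c)
            if not ok:
                rejections[why] += 1
                continue
            cands.append((start, end, wallace_tm(sub), gc_percent(sub)))

    pairs: list[PrimerPair] = []
    # index candidates by end position for product pairing
    by_end: dict[int, list[tuple[int, int, float, float]]] = defaultdict(list)
    for cand in cands:
        by_end[cand[1]].append(cand)
    for fs, fe, tmf, gcf in cands:
        fwd = region[fs:fe]
        if c.require_gc_clamp and fwd[-1] not in "GC":
            rejections["gc_clamp"] += 1
            continue
        for prod in range(c.product_min, c.product_max + 1):
            re_ = fs + prod
            if re_ > L:
                break
            for rs, _, tmr, gcr in by_end.get(re_, ()):
                if rs < fe:  # primers must not overlap
                    rejections["overlap"] += 1
                    continue
                if abs(tmf - tmr) > c.max_tm_diff:
                    rejections["tm_diff"] += 1
                    continue
                rev = reverse_complement(region[rs:re_])
                if c.require_gc_clamp and rev[-1] not in "GC":
                    rejections["gc_clamp"] += 1
                    continue
                pairs.append(
                    PrimerPair(
                        fwd=fwd,
                        rev=rev,
                        tm_fwd=tmf,
                        tm_rev=tmr,
                        gc_fwd=gcf,
                        gc_rev=gcr,
                        product_size=prod,
                        fwd_start=fs,
                        rev_end=re_,
                        template=template,
                    )
                )
    if not pairs:
        log.info("design_primers: no pairs passed; rejections=%s", dict(rejections))
    mid = (c.product_min + c.product_max) / 2.0
    pairs.sort(
        key=lambda p: (
            abs((p.tm_fwd + p.tm_rev) / 2.0 - 57.0),
            abs(p.product_size - mid),
            p.fwd_start,
        )
    )
    return pairs[:max_pairs] if max_pairs else pairs


# ---------------------------------------------------------------------------
# In-silico PCR


@dataclass
class Amplicon:
    taxon: str
    contig: str
    start: int  # 0-based half-open, outer primer bounds
    end: int

    @property
    def size(self) -> int:
        return self.end - self.start


@dataclass
class AmpliconReport:
    primer_pair: PrimerPair
    target: str
    amplicons: dict[str, list[Amplicon]]  # taxon -> amplicons
    verdict: str  # UNIQUE | SIZE_DISCRIMINABLE | NON_SPECIFIC | FAILED


def _binding_sites(
    contig_arr: np.ndarray, primer: str, max_mismatch: int, three_prime_exact: int
) -> tuple[np.ndarray, np.ndarray]:
    """Annealing positions of a primer on one contig.

    Returns (plus_starts, minus_starts): plus sites run left-to-right
    (primer 3' at start+len-1, extension rightward); minus sites are where
    the primer anneals to the plus strand's complement pointing leftward
    (window equals reverse complement of the primer; primer 3' maps to the
    window's first base). N in the template never matches.
    """
    L = len(primer)
    if contig_arr.size < L:
        empty = np.empty(0, dtype=int)
        return empty, empty
    windows = sliding_window_view(contig_arr, L)
    n_mask = windows == ord("N")

    q = np.frombuffer(primer.encode(), dtype=np.uint8)
    mism = (windows != q) | n_mask
    ok_plus = (mism.sum(axis=1) <= max_mismatch) & ~mism[:, L - three_prime_exact :].any(axis=1)

    qrc = np.frombuffer(reverse_complement(primer).encode(), dtype=np.uint8)
    mism_rc = (windows != qrc) | n_mask
    ok_minus = (mism_rc.sum(axis=1) <= max_mismatch) & ~mism_rc[:, :three_prime_exact].any(axis=1)

    return np.nonzero(ok_plus)[0], np.nonzero(ok_minus)[0]


def insilico_pcr(
    pair: PrimerPair,
    genomes: list[Genome],
    target: str,
    max_mismatch: int = 2,
    three_prime_exact: int = 3,
    size_window: tuple[int, int] = (50, 2000),
    size_margin: int = 10,
) -> AmpliconReport:
    """Predict amplicons and classify specificity for the target taxon.

    An amplicon is a convergent pair of binding sites — one primer annealed
    plus-oriented, the other minus-oriented downstream — with product size
    inside size_window; both (fwd, rev) and (rev, fwd) orientations are
    considered. Verdicts follow band semantics: UNIQUE = exactly one target
    amplicon, none elsewhere; SIZE_DISCRIMINABLE = one target amplicon and
    every off-target amplicon differing in size by >= size_margin;
    FAILED = no target amplicon; otherwise NON_SPECIFIC.
    """
    lo, hi = size_window
    amplicons: dict[str, list[Amplicon]] = {}
    for genome in genomes:
        found: set[tuple[str, int, int]] = set()
        for contig, seq in genome.contigs.items():
            arr = np.frombuffer(seq.encode(), dtype=np.uint8)
            sites = {
                "fwd": _binding_sites(arr, pair.fwd, max_mismatch, three_prime_exact),
                "rev": _binding_sites(arr, pair.rev, max_mismatch, three_prime_exact),
            }
            lens = {"fwd": len(pair.fwd), "rev": len(pair.rev)}
            for a, b in (("fwd", "rev"), ("rev", "fwd")):
                plus_a = sites[a][0]
                minus_b = sites[b][1]
                for i in plus_a:
                    for j in minus_b:
                        if j < i + lens[a]:
                            continue  # divergent or overlapping, no product
                        size = int(j) + lens[b] - int(i)
                        if lo <= size <= hi:
                            found.add((contig, int(i), int(j) + lens[b]))
        amplicons[genome.taxon] = [
            Amplicon(genome.taxon, c, s, e) for c, s, e in sorted(found)
        ]

    target_amps = amplicons.get(target, [])
    off = [a for t, amps in amplicons.items() if t != target for a in amps]
    if len(target_amps) == 0:
        verdict = "FAILED"
    elif len(target_amps) == 1 and not off:
        verdict = "UNIQUE"
    elif len(target_amps) == 1 and all(
        abs(a.size - target_amps[0].size) >= size_margin for a in off
    ):
        verdict = "SIZE_DISCRIMINABLE"
    else:
        verdict = "NON_SPECIFIC"
    return AmpliconReport(
        primer_pair=pair, target=target, amplicons=amplicons, verdict=verdict
    )


# ---------------------------------------------------------------------------
# Panel screen


@dataclass
class ScreenParams:
    window: int = DEFAULT_WINDOW
    step: int = DEFAULT_STEP
    min_identity: float = 0.9
    min_coverage: float = 0.9
    k: int = 15
    constraints: PrimerConstraints = field(default_factory=PrimerConstraints)
    max_mismatch: int = 2
    three_prime_exact: int = 3
    size_window: tuple[int, int] = (50, 2000)
    size_margin: int = 10
    pairs_per_region: int = 3  # candidate pairs verified per specific region
    max_reported: int = 10


def screen_panel(
    cds_sets: dict[str, dict[str, str]],
    genomes: list[Genome],
    target: str,
    params: ScreenParams | None = None,
) -> list[AmpliconReport]:
    """Full diagnostic screen for one target taxon.

    fragment -> cross_match -> select_specific -> design_primers ->
    insilico_pcr; only pairs with verdict UNIQUE or SIZE_DISCRIMINABLE are
    returned, UNIQUE first, best-ranked primer pairs first within a verdict.
    """
    p = params or ScreenParams()
    if target not in {g.taxon for g in genomes}:
        raise ValueError(f"target {target} not in genome panel")
    fragments: list[Fragment] = []
    for cds_id, seq in cds_sets.get(target, {}).items():
        fragments.extend(fragment_windows(cds_id, seq, target, p.window, p.step))
    if not fragments:
        return []
    report = cross_match(fragments, genomes, p.min_identity, p.min_coverage, p.k)
    _, regions = select_specific(report, target)

    results: list[AmpliconReport] = []
    for region in sorted(regions, key=lambda r: r.end - r.start, reverse=True):
        if len(region.sequence) < p.constraints.product_min:
            continue
        pairs = design_primers(
            region.sequence,
            p.constraints,
            template=(target, f"{region.source_cds_id}:{region.start}-{region.end}"),
            max_pairs=p.pairs_per_region,
        )
        for pair in pairs:
            rep = insilico_pcr(
                pair,
                genomes,
                target,
                p.max_mismatch,
                p.three_prime_exact,
                p.size_window,
                p.size_margin,
            )
            if rep.verdict in ("UNIQUE", "SIZE_DISCRIMINABLE"):
                results.append(rep)
        if len(results) >= p.max_reported:
            break
    results.sort(key=lambda r: 0 if r.verdict == "UNIQUE" else 1)
    return results[: p.max_reported]
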