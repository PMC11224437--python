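"""Trimming, occupancy filtering, concatenation and summary statistics.

Mirrors the standard supermatrix workflow: per-locus alignments are trimmed
by gap fraction, filtered by taxon occupancy (at least tau of the panel),
concatenated with '?' padding for absent taxa, and summarised AMAS-style
(locus lengths, parsimony-informative sites, missing data).
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

log = logging.getLogger(__name__)

MISSING_CHARS = frozenset("-?")
NT_STATES = frozenset("ACGT")
AA_STATES = frozenset("ACDEFGHIKLMNPQRSTVWY")


@dataclass
class LocusAlignment:
    """A per-locus alignment: taxon -> equal-length sequence rows."""

    locus_id: str
    rows: dict[str, str]
    alphabet: str = "NT"  # NT or AA

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError(f"{self.locus_id}: alignment has no rows")
        lens = {len(s) for s in self.rows.values()}
        if len(lens) > 1:
            raise ValueError(f"{self.locus_id}: ragged rows {sorted(lens)}")

    @property
    def length(self) -> int:
        return len(next(iter(self.rows.values())))

    @property
    def taxa(self) -> list[str]:
        return list(self.rows)

    def present_taxa(self) -> list[str]:
        """Taxa whose row contains at least one non-missing character."""
        return [
            t for t, s in self.rows.items()
            if any(c not in MISSING_CHARS for c in s)
        ]

    def states(self) -> frozenset[str]:
        return NT_STATES if self.alphabet == "NT" else AA_STATES

    def column(self, i: int) -> list[str]:
        return [s[i] for s in self.rows.values()]


@dataclass
class Supermatrix:
    rows: dict[str, str]
    partitions: list[tuple[str, int, int]]  # (locus_id, start, end) 1-based incl.
    alphabet: str = "NT"

    @property
    def n_sites(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0

    def slice_locus(self, locus_id: str) -> LocusAlignment:
        for lid, start, end in self.partitions:
            if lid == locus_id:
                return LocusAlignment(
                    lid,
                    {t: s[start - 1 : end] for t, s in self.rows.items()},
                    self.alphabet,
                )
        raise KeyError(locus_id)


@dataclass
class MatrixStats:
    n_loci: int
    mean_locus_len: float
    median_locus_len: float
    n_sites: int
    n_PIS: int
    pct_PIS: float
    pct_missing: float


def trim_columns(aln: LocusAlignment, max_gap_frac: float) -> LocusAlignment:
    """Drop columns whose gap/missing fraction exceeds ``max_gap_frac``.

    The fraction is computed over the taxa present in the alignment. A column
    provenance map (kept original column indices) is attached as
    ``aln.kept_columns``.
    """
    if not 0 <= max_gap_frac <= 1:
        raise ValueError("max_gap_frac must be in [0,1]")
    n = len(aln.rows)
    kept: list[int] = []
    for i in range(aln.length):
        gaps = sum(1 for c in aln.column(i) if c in MISSING_CHARS)
        if gaps / n <= max_gap_frac:
            kept.append(i)
    if not kept:
        log.warning("%s: all columns removed by trimming", aln.locus_id)
        out = LocusAlignment(aln.locus_id, {t: "" for t in aln.rows}, aln.alphabet)
    else:
        out = LocusAlignment(
            aln.locus_id,
            {t: "".join(s[i] for i in kept) for t, s in aln.rows.items()},
            aln.alphabet,
        )
    out.kept_columns = kept  # type: ignore[attr-defined]
    return out


def occupancy_threshold(n_taxa: int, tau: float) -> int:
    """Minimum taxon count for 'at least tau' occupancy (ceil, literal)."""
    return math.ceil(tau * n_taxa)


def filter_occupancy(
    loci: list[LocusAlignment], all_taxa: list[str], tau: float
) -> list[LocusAlignment]:
    """Keep loci present (non-empty row) in >= ceil(tau * |panel|) taxa."""
    if not 0 < tau <= 1:
        raise ValueError("tau must be in (0, 1]")
    need = occupancy_threshold(len(all_taxa), tau)
    panel = set(all_taxa)
    return [
        a for a in loci
        if sum(1 for t in a.present_taxa() if t in panel) >= need
    ]


def concatenate(
    loci: list[LocusAlignment], all_taxa: list[str]
) -> tuple[Supermatrix, list[tuple[str, int, int]]]:
    """Concatenate loci over the full panel, padding absent taxa with '?'."""
    ids = [a.locus_id for a in loci]
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate locus ids in concatenation")
    norm = [t.strip() for t in all_taxa]
    if len(norm) != len(set(norm)):
        raise ValueError("taxon name collision after normalization")
    parts: list[tuple[str, int, int]] = []
    chunks: dict[str, list[str]] = {t: [] for t in norm}
    pos = 1
    for aln in loci:
        L = aln.length
        parts.append((aln.locus_id, pos, pos + L - 1))
        pos += L
        for t in norm:
            chunks[t].append(aln.rows.get(t, "?" * L))
    matrix = Supermatrix(
        rows={t: "".join(c) for t, c in chunks.items()},
        partitions=parts,
        alphabet=loci[0].alphabet if loci else "NT",
    )
    return matrix, parts


def _informative_column(col: list[str], states: frozenset[str]) -> bool:
    counts: dict[str, int] = {}
    for c in col:
        if c in states:
            counts[c] = counts.get(c, 0) + 1
    return sum(1 for v in counts.values() if v >= 2) >= 2


def count_PIS(obj: LocusAlignment | Supermatrix) -> int:
    """Parsimony-informative sites: columns with >=2 states each in >=2 rows.

    Gaps, '?' and ambiguity codes (e.g. N) are not states.
    """
    if isinstance(obj, Supermatrix):
        rows = list(obj.rows.values())
        states = NT_STATES if obj.alphabet == "NT" else AA_STATES
        length = obj.n_sites
    else:
        rows = list(obj.rows.values())
        states = obj.states()
        length = obj.length
    n = 0
    for i in range(length):
        if _informative_column([s[i] for s in rows], states):
            n += 1
    return n


def summarize(loci: list[LocusAlignment], matrix: Supermatrix) -> MatrixStats:
    """AMAS-style matrix statistics.

    Missing data counts both '-' and '?' cells over the full taxa x sites
    grid; PIS percentage is over concatenated sites.
    """
    lens = [a.length for a in loci]
    n_sites = matrix.n_sites
    n_taxa = len(matrix.rows)
    missing = sum(
        sum(1 for c in s if c in MISSING_CHARS) for s in matrix.rows.values()
    )
    n_pis = count_PIS(matrix)
    return MatrixStats(
        n_loci=len(loci),
        mean_locus_len=float(np.mean(lens)) if lens else 0.0,
        median_locus_len=float(np.median(lens)) if lens else 0.0,
        n_sites=n_sites,
        n_PIS=n_pis,
        pct_PIS=100.0 * n_pis / n_sites if n_sites else 0.0,
        pct_missing=100.0 * missing / (n_taxa * n_sites) if n_sites and n_taxa else 0.0,
    )
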