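"""Iterative homology search to closure ("self-referencing" hit set).

Finding every family member in a new genome with a single similarity
search fails when members form a divergence chain: a copy within reach of
another copy but beyond reach of the original query is missed. The
closure search therefore iterates — hits from one round become queries
for the next — until no novel member appears. Local search itself is a
self-contained seed-and-extend: exact k-mer seeds on both strands,
diagonal clustering, then banded local alignment refinement of each
candidate region.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import edlib

from .classify import ClassifierParams, _aligner
from .element_scan import ElementAnnotation, ScanParams, scan_elements
from .sequences import GenomeSequence, revcomp
from .tsd import FlankTooShortError, TsdCall, TsdParams, find_tsd

Span = tuple[int, int]


@dataclass(frozen=True)
class ClosureParams:
    """Thresholds for local search and the closure novelty rule.

    A hit is *novel* (and becomes a query for the next round) unless it is
    at least ``dedupe_identity`` identical over at least ``dedupe_coverage``
    of its length to an existing member — this is what makes the final set
    "self-referencing" without accumulating duplicates.
    """

    min_identity: float = 0.70
    min_hit_len: int = 100
    report_min_len: int = 350
    merge_gap: int = 50
    max_iterations: int = 20
    seed_k: int = 11
    dedupe_identity: float = 0.95
    dedupe_coverage: float = 0.90

    def __post_init__(self) -> None:
        if self.report_min_len < self.min_hit_len:
            raise ValueError("report_min_len must be >= min_hit_len")
        if not 0 < self.min_identity <= 1:
            raise ValueError("min_identity must be in (0,1]")


@dataclass(frozen=True)
class Hit:
    span: Span
    strand: str
    query: str
    identity: float
    iteration_found: int = 0

    @property
    def length(self) -> int:
        return self.span[1] - self.span[0]


@dataclass
class HitSet:
    genome_id: str
    hits: list[Hit] = field(default_factory=list)
    converged: bool = True

    def spans(self) -> set[tuple[int, int, str]]:
        return {(h.span[0], h.span[1], h.strand) for h in self.hits}


def _index_kmers(seq: str, k: int) -> dict[str, list[int]]:
    index: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        if "N" not in kmer:
            index.setdefault(kmer, []).append(i)
    return index


def _cluster_diagonals(matches: list[tuple[int, int]], qlen: int
                       ) -> list[tuple[int, int]]:
    """Group (gpos, qpos) seed matches into candidate genome windows."""
    if not matches:
        return []
    matches = sorted((g - q, g) for g, q in matches)
    clusters: list[list[tuple[int, int]]] = [[matches[0]]]
    for diag, g in matches[1:]:
        pd_, pg = clusters[-1][-1]
        if abs(diag - pd_) <= 40 and abs(g - pg) <= max(200, qlen):
            clusters[-1].append((diag, g))
        else:
            clusters.append([(diag, g)])
    windows = []
    for cl in clusters:
        gs = [g for _, g in cl]
        windows.append((min(gs) - qlen, max(gs) + qlen))
    return windows


def _local_align(query: str, window: str, params: ClosureParams
                 ) -> Optional[tuple[int, int, float]]:
    """Best local alignment of query vs window: (wstart, wend, identity)."""
    scoring = ClassifierParams()
    aligner = _aligner(scoring, mode="local")
    alignments = aligner.align(window, query)
    if len(alignments) == 0:
        return None
    best = alignments[0]
    blocks_w, blocks_q = best.aligned
    if len(blocks_w) == 0:
        return None
    matches = cols = 0
    for (sw, ew), (sq, _eq) in zip(blocks_w, blocks_q):
        cols += ew - sw
        matches += sum(window[sw + i] == query[sq + i] for i in range(ew - sw))
    if cols == 0:
        return None
    wstart, wend = int(blocks_w[0][0]), int(blocks_w[-1][1])
    return wstart, wend, matches / cols


def _merge_hits(hits: list[Hit], merge_gap: int) -> list[Hit]:
    merged: list[Hit] = []
    for h in sorted(hits, key=lambda h: (h.strand, h.span[0], h.span[1])):
        if merged and merged[-1].strand == h.strand \
                and h.span[0] - merged[-1].span[1] <= merge_gap:
            prev = merged[-1]
            merged[-1] = replace(
                prev,
                span=(prev.span[0], max(prev.span[1], h.span[1])),
                identity=max(prev.identity, h.identity),
                iteration_found=min(prev.iteration_found, h.iteration_found),
            )
        else:
            merged.append(h)
    merged.sort(key=lambda h: (h.span[0], h.strand))
    return merged


def local_search(
    queries: Mapping[str, str],
    genome: GenomeSequence,
    params: ClosureParams = ClosureParams(),
    iteration: int = 0,
) -> HitSet:
    """Seed-and-extend search of all queries against both genome strands."""
    if not queries:
        raise ValueError("no queries given")
    index = _index_kmers(genome.residues, params.seed_k)
    raw: list[Hit] = []
    for qname in sorted(queries):
        qseq = queries[qname].upper()
        for strand in "+-":
            q = qseq if strand == "+" else revcomp(qseq)
            matches = []
            for qpos in range(0, len(q) - params.seed_k + 1, 2):
                for gpos in index.get(q[qpos : qpos + params.seed_k], ()):
                    matches.append((gpos, qpos))
            for ws, we in _cluster_diagonals(matches, len(q)):
                ws, we = max(0, ws), min(len(genome), we)
                result = _local_align(q, genome.residues[ws:we], params)
                if result is None:
                    continue
                hs, he, identity = result
                if identity >= params.min_identity \
                        and (he - hs) >= params.min_hit_len:
                    raw.append(Hit((ws + hs, ws + he), strand, qname,
                                   round(identity, 6), iteration))
    return HitSet(genome.id, _merge_hits(raw, params.merge_gap))


def _hit_sequence(genome: GenomeSequence, hit: Hit) -> str:
    seq = genome.residues[hit.span[0] : hit.span[1]]
    return seq if hit.strand == "+" else revcomp(seq)


def _is_duplicate(seq: str, members: Sequence[str], params: ClosureParams) -> bool:
    for member in members:
        shorter, longer = sorted((seq, member), key=len)
        res = edlib.align(shorter, longer, mode="HW", task="distance")
        dist = res["editDistance"]
        if dist < 0:
            continue
        identity = 1 - dist / len(shorter)
        coverage = len(shorter) / len(longer)
        if identity >= params.dedupe_identity and coverage >= params.dedupe_coverage:
            return True
    return False


def closure_search(
    seed_queries: Mapping[str, str],
    genome: GenomeSequence,
    params: ClosureParams = ClosureParams(),
) -> HitSet:
    """Iterate local search until the query set is self-referencing.

    Each round searches with the current query set and promotes novel hit
    sequences (per the dedupe rule) to queries. Stops at a fixed point —
    a round contributing no novel member — or at ``max_iterations``, in
    which case the result is flagged unconverged. The final hit set is
    invariant to seed ordering.
    """
    if not seed_queries:
        raise ValueError("no seed queries given")
    queries: dict[str, str] = {f"seed:{k}": v.upper()
                               for k, v in sorted(seed_queries.items())}
    members: list[str] = []
    final = HitSet(genome.id, [])
    converged = False
    for iteration in range(params.max_iterations):
        final = local_search(queries, genome, params, iteration)
        novel = 0
        for hit in sorted(final.hits, key=lambda h: (h.span[0], h.strand)):
            seq = _hit_sequence(genome, hit)
            if len(seq) < params.min_hit_len or _is_duplicate(seq, members, params):
                continue
            members.append(seq)
            queries[f"hit:{hit.span[0]}-{hit.span[1]}{hit.strand}"] = seq
            novel += 1
        if novel == 0:
            converged = True
            break
    final.converged = converged
    return final


@dataclass(frozen=True)
class ReportedElement:
    annotation: ElementAnnotation
    tsd: Optional[TsdCall]
    identity_to_nearest: float
    nearest_reference: Optional[str]


def report_elements(
    hits: HitSet,
    genome: GenomeSequence,
    params: ClosureParams = ClosureParams(),
    scan_params: ScanParams = ScanParams(),
    tsd_params: TsdParams = TsdParams(),
    references: Optional[Mapping[str, str]] = None,
) -> list[ReportedElement]:
    """Structural typing + TSD detection for hits above the report cutoff.

    Each retained hit is scanned for the full-length structure (5' motif
    through poly(A) tail) in element orientation, and its flanks searched
    for a target site duplication; the TSD is reported as absent (ND) when
    flanks are too short or no qualifying repeat exists.
    """
    from .classify import pairwise_identity

    out = []
    for hit in hits.hits:
        if hit.length < params.report_min_len:
            continue
        oriented = _hit_sequence(genome, hit)
        anns = scan_elements(GenomeSequence("hit", oriented), scan_params)
        full = [a for a in anns if a.structural_class == "full_length"
                and a.strand == "+"]
        if full:
            structural = "full_length"
        elif hit.length >= scan_params.partial_min_len:
            structural = "partial"
        else:
            structural = "fragment"
        try:
            tsd = find_tsd(genome, hit.span, tsd_params)
        except FlankTooShortError:
            tsd = None
        identity, nearest = hit.identity, hit.query
        if references:
            scored = sorted(
                ((pairwise_identity(oriented, seq)[0], name)
                 for name, seq in references.items()),
                key=lambda t: (-t[0], t[1]))
            identity, nearest = scored[0]
        ann = ElementAnnotation(
            genome_id=genome.id, span=hit.span, strand=hit.strand,
            motif_span=(hit.span[0], hit.span[0] + len(scan_params.motif)),
            structural_class=structural)
        out.append(ReportedElement(ann, tsd, round(identity, 4), nearest))
    return out
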