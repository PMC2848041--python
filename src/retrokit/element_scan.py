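"""Structural discovery of Sadhu-like non-LTR retroelement copies.

A canonical full-length element starts at a conserved 5' motif
(consensus CAATCGTTSC), carries a C/T-rich polypyrimidine patch shortly
downstream, and terminates roughly 900 bp later in a 3' poly(A) tract.
The scanner finds motif hits on both strands, pairs each with a
downstream poly(A) tail, and classifies the implied copy as full-length,
partial (shorter than the canonical span but still substantial) or a
bare motif fragment.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .sequences import IUPAC, GenomeSequence, revcomp

Span = tuple[int, int]


@dataclass(frozen=True)
class ScanParams:
    """Tunable thresholds for structural element discovery.

    ``motif`` is an IUPAC pattern; the default allows one mismatch since
    the motif is a family consensus, not an invariant. ``full_length_span``
    operationalizes the "approximately 900 bp" canonical element length.
    """

    motif: str = "CAATCGTTSC"
    motif_max_mismatch: int = 1
    polypyrimidine_min_len: int = 15
    polypyrimidine_min_purity: float = 0.9
    polypyrimidine_window: int = 120
    polya_min_len: int = 6
    polya_min_purity: float = 0.8
    polya_window: int = 60
    full_length_span: tuple[int, int] = (700, 1100)
    partial_min_len: int = 350

    def __post_init__(self) -> None:
        if not self.motif or set(self.motif) - set(IUPAC):
            raise ValueError(f"motif {self.motif!r} is not an IUPAC DNA pattern")
        if not 0 <= self.motif_max_mismatch < len(self.motif):
            raise ValueError("motif_max_mismatch must be in [0, motif length)")
        if not self.full_length_span[0] < self.full_length_span[1]:
            raise ValueError("full_length_span min must be < max")
        for purity in (self.polya_min_purity, self.polypyrimidine_min_purity):
            if not 0 < purity <= 1:
                raise ValueError("purity thresholds must lie in (0, 1]")


@dataclass(frozen=True)
class ElementAnnotation:
    """A located candidate element on the forward strand of a genome.

    Spans are 0-based half-open in forward-strand coordinates regardless
    of ``strand``; feature sub-spans (motif, polypyrimidine, poly(A)) are
    in the same frame.
    """

    genome_id: str
    span: Span
    strand: str
    motif_span: Span
    motif_mismatches: int = 0
    polypyrimidine_span: Optional[Span] = None
    polya_span: Optional[Span] = None
    structural_class: str = "fragment"
    name: Optional[str] = None

    @property
    def length(self) -> int:
        return self.span[1] - self.span[0]


def _motif_table(motif: str) -> list[frozenset]:
    return [frozenset(IUPAC[c]) for c in motif]


def _mismatches(window: str, table: list[frozenset]) -> int:
    # genome 'N' matches nothing, including motif N positions
    return sum(1 for base, allowed in zip(window, table)
               if base == "N" or base not in allowed)


def _window_mismatch_counts(seq: str, motif: str) -> np.ndarray:
    """Vectorized per-window motif mismatch counts (genome N matches nothing)."""
    m = len(motif)
    n = len(seq)
    if n < m:
        return np.zeros(0, dtype=np.int64)
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    counts = np.zeros(n - m + 1, dtype=np.int64)
    for j, pattern_char in enumerate(motif):
        allowed = [ord(b) for b in IUPAC[pattern_char]]
        col = arr[j : n - m + 1 + j]
        match = np.zeros(col.shape, dtype=bool)
        for code in allowed:
            match |= col == code
        counts += ~match
    return counts


def find_motif_sites(
    genome: GenomeSequence, params: ScanParams = ScanParams()
) -> list[tuple[int, str, int]]:
    """Locate motif occurrences on both strands.

    Returns ``(position, strand, mismatches)`` triples where ``position``
    is the forward-strand start of the matched window, sorted by position
    with '+' before '-'.
    """
    seq = genome.residues
    hits: list[tuple[int, str, int]] = []
    fwd_counts = _window_mismatch_counts(seq, params.motif)
    # a '-'-strand motif occurrence reads as the reverse complement of the
    # pattern on the forward strand
    rev_counts = _window_mismatch_counts(seq, revcomp(params.motif))
    for i in np.nonzero(fwd_counts <= params.motif_max_mismatch)[0]:
        hits.append((int(i), "+", int(fwd_counts[i])))
    for i in np.nonzero(rev_counts <= params.motif_max_mismatch)[0]:
        hits.append((int(i), "-", int(rev_counts[i])))
    hits.sort(key=lambda h: (h[0], h[1]))
    return hits


def find_polya(
    genome: GenomeSequence,
    search_span: Span,
    params: ScanParams = ScanParams(),
) -> Optional[Span]:
    """Longest A-anchored A-rich window inside ``search_span``.

    The tail model is a decayed homopolymer: the longest window that
    starts and ends on an A (a run extension, never a window padded with
    foreign bases), has length >= ``polya_min_len`` and A fraction >=
    ``polya_min_purity``. Ties go to the leftmost window. Returns ``None``
    when no window qualifies.
    """
    start, end = search_span
    if start > end:
        raise ValueError(f"inverted span [{start},{end})")
    start, end = max(0, start), min(len(genome), end)
    sub = genome.residues[start:end]
    n = len(sub)
    if n < params.polya_min_len:
        return None
    is_a = np.frombuffer(sub.encode(), dtype=np.uint8) == ord("A")
    prefix = np.concatenate([[0], np.cumsum(is_a)])
    for length in range(n, params.polya_min_len - 1, -1):
        counts = prefix[length:] - prefix[:-length] if length < n else prefix[-1:] - prefix[:1]
        anchored = is_a[: n - length + 1] & is_a[length - 1 :]
        ok = np.nonzero(anchored
                        & (counts >= params.polya_min_purity * length))[0]
        if ok.size:
            i = int(ok[0])
            return (start + i, start + i + length)
    return None


def _candidate_tails(seq: str, start: int, end: int, params: ScanParams) -> list[Span]:
    """Maximal A-run clusters in seq[start:end) that qualify as tails.

    Runs of >=3 A's separated by gaps of <=2 non-A bases are merged, the
    cluster trimmed to terminal A's, then filtered on length and purity.
    """
    runs: list[Span] = []
    i = start
    while i < end:
        if seq[i] == "A":
            j = i
            while j < end and seq[j] == "A":
                j += 1
            if j - i >= 3:
                runs.append((i, j))
            i = j
        else:
            i += 1
    merged: list[Span] = []
    for run in runs:
        if merged and run[0] - merged[-1][1] <= 2:
            merged[-1] = (merged[-1][0], run[1])
        else:
            merged.append(run)
    tails = []
    for s, e in merged:
        if e - s >= params.polya_min_len:
            frac = seq[s:e].count("A") / (e - s)
            if frac >= params.polya_min_purity:
                tails.append((s, e))
    return tails


def _polypyrimidine(seq: str, start: int, end: int, params: ScanParams) -> Optional[Span]:
    sub = seq[start:end]
    n = len(sub)
    if n < params.polypyrimidine_min_len:
        return None
    is_py = np.frombuffer(sub.encode(), dtype=np.uint8)
    is_py = (is_py == ord("C")) | (is_py == ord("T"))
    prefix = np.concatenate([[0], np.cumsum(is_py)])
    for length in range(n, params.polypyrimidine_min_len - 1, -1):
        counts = prefix[length:] - prefix[:-length] if length < n else prefix[-1:] - prefix[:1]
        ok = np.nonzero(counts >= params.polypyrimidine_min_purity * length)[0]
        if ok.size:
            i = int(ok[0])
            return (start + i, start + i + length)
    return None


def _scan_forward(seq: str, genome_id: str, params: ScanParams) -> list[ElementAnnotation]:
    """Scan one orientation; returns annotations with '+' strand placeholders."""
    m = len(params.motif)
    full_min, full_max = params.full_length_span
    out: list[ElementAnnotation] = []
    counts = _window_mismatch_counts(seq, params.motif)
    for p in np.nonzero(counts <= params.motif_max_mismatch)[0]:
        p, mm = int(p), int(counts[p])
        search_end = min(len(seq), p + full_max)
        tails = _candidate_tails(seq, p + m, search_end, params)
        full = [t for t in tails if full_min <= t[1] - p <= full_max]
        partial = [t for t in tails
                   if params.partial_min_len <= t[1] - p < full_min]
        pyr = _polypyrimidine(
            seq, p + m, min(len(seq), p + m + params.polypyrimidine_window), params
        )
        if full:
            # prefer the strongest (longest) tail: genuine tails outlast
            # chance A-rich runs in the element body
            tail = max(full, key=lambda t: (t[1] - t[0], -t[0]))
            out.append(ElementAnnotation(
                genome_id, (p, tail[1]), "+", (p, p + m), mm,
                polypyrimidine_span=pyr, polya_span=tail,
                structural_class="full_length"))
        elif partial:
            tail = max(partial, key=lambda t: (t[1] - t[0], -t[0]))
            out.append(ElementAnnotation(
                genome_id, (p, tail[1]), "+", (p, p + m), mm,
                polypyrimidine_span=pyr, polya_span=tail,
                structural_class="partial"))
        else:
            out.append(ElementAnnotation(
                genome_id, (p, p + m), "+", (p, p + m), mm,
                polypyrimidine_span=pyr, structural_class="fragment"))
    return out


def _mirror(ann: ElementAnnotation, length: int) -> ElementAnnotation:
    def flip(span: Optional[Span]) -> Optional[Span]:
        if span is None:
            return None
        return (length - span[1], length - span[0])

    return replace(
        ann,
        span=flip(ann.span),
        strand="-",
        motif_span=flip(ann.motif_span),
        polypyrimidine_span=flip(ann.polypyrimidine_span),
        polya_span=flip(ann.polya_span),
    )


def _resolve_overlaps(anns: list[ElementAnnotation]) -> list[ElementAnnotation]:
    """Greedy per-strand non-overlap resolution: longest wins, then leftmost."""
    kept: list[ElementAnnotation] = []
    for ann in sorted(anns, key=lambda a: (-a.length, a.span[0], a.strand)):
        clash = any(
            k.strand == ann.strand
            and k.span[0] < ann.span[1]
            and ann.span[0] < k.span[1]
            for k in kept
        )
        if not clash:
            kept.append(ann)
    kept.sort(key=lambda a: (a.span[0], a.strand))
    return kept


def scan_elements(
    genome: GenomeSequence, params: ScanParams = ScanParams()
) -> list[ElementAnnotation]:
    """Discover candidate elements on both strands of ``genome``.

    Each motif hit is paired with the strongest downstream in-strand
    poly(A) tail whose implied element length is canonical (full_length)
    or at least ``partial_min_len`` (partial); motif hits with no such
    tail become fragments. Annotations never overlap on the same strand
    (longest wins, then leftmost).
    """
    if not genome.residues:
        return []
    fwd = _scan_forward(genome.residues, genome.id, params)
    n = len(genome.residues)
    rev = [
        _mirror(a, n) for a in _scan_forward(revcomp(genome.residues), genome.id, params)
    ]
    return _resolve_overlaps(fwd + rev)


# ---------------------------------------------------------------------------
# output


def write_gff3(annotations: Iterable[ElementAnnotation], path: str | Path) -> None:
    """GFF3 export; internal 0-based half-open spans become 1-based closed."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, a in enumerate(annotations, 1):
            eid = a.name or f"element{i}"
            fh.write("\t".join([
                a.genome_id, "retrokit", "mobile_genetic_element",
                str(a.span[0] + 1), str(a.span[1]), ".", a.strand, ".",
                f"ID={eid};structural_class={a.structural_class}",
            ]) + "\n")
            children = [("sequence_motif", a.motif_span),
                        ("polypyrimidine_tract", a.polypyrimidine_span),
                        ("polyA_sequence", a.polya_span)]
            for j, (ftype, span) in enumerate(children):
                if span is None:
                    continue
                fh.write("\t".join([
                    a.genome_id, "retrokit", ftype,
                    str(span[0] + 1), str(span[1]), ".", a.strand, ".",
                    f"ID={eid}.{j};Parent={eid}",
                ]) + "\n")


def annotations_to_frame(annotations: Iterable[ElementAnnotation]) -> pd.DataFrame:
    rows = []
    for a in annotations:
        rows.append({
            "genome": a.genome_id,
            "start": a.span[0],
            "end": a.span[1],
            "strand": a.strand,
            "length": a.length,
            "structural_class": a.structural_class,
            "motif_start": a.motif_span[0],
            "motif_mismatches": a.motif_mismatches,
            "polypyrimidine": a.polypyrimidine_span is not None,
            "polya": a.polya_span is not None,
            "name": a.name or "",
        })
    return pd.DataFrame(
        rows,
        columns=["genome", "start", "end", "strand", "length",
                 "structural_class", "motif_start", "motif_mismatches",
                 "polypyrimidine", "polya", "name"],
    )
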