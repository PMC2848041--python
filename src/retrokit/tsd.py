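"""Target site duplication (TSD) detection and nicking-site consensus.

Non-LTR retroelements integrate by target-primed reverse transcription
(TPRT): two staggered nicks on the target DNA leave a short direct repeat
— the TSD — flanking the new insertion. Given an element span, the
detector searches both flanks for the maximal direct repeat whose left
copy ends near the element start and whose right copy starts near the
element end. The nicking-site extractor then cuts the fixed windows used
for integration-site sequence logos: nine bases 5' of the left TSD copy,
the first seven bases of the repeat, and nine bases 3' of the right copy.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .sequences import GenomeSequence, revcomp

Span = tuple[int, int]


class FlankTooShortError(ValueError):
    """Raised when a locus has too little flanking sequence on one side."""


@dataclass(frozen=True)
class TsdParams:
    """Search window for flanking direct repeats.

    Defaults cover the 7-18 bp range observed across the family; repeats
    are exact by default because sequenced pre-insertion (empty) alleles
    carry a single identical copy of the duplicated target. The
    ``boundary_slack`` absorbs the poly(A)/TSD boundary ambiguity: many
    TSDs begin with adenines and blend into the element's tail.
    """

    min_len: int = 7
    max_len: int = 18
    max_mismatch: int = 0
    boundary_slack: int = 3

    def __post_init__(self) -> None:
        if not 0 < self.min_len <= self.max_len:
            raise ValueError("need 0 < min_len <= max_len")
        if self.boundary_slack < 0 or self.max_mismatch < 0:
            raise ValueError("slack and mismatch must be >= 0")


@dataclass(frozen=True)
class TsdCall:
    """A detected flanking direct repeat (both copies, forward-strand spans)."""

    left_span: Span
    right_span: Span
    repeat_seq: str
    mismatches: int = 0

    @property
    def length(self) -> int:
        return self.left_span[1] - self.left_span[0]


@dataclass(frozen=True)
class NickContext:
    """Sequence windows around one insertion used for nicking-site logos."""

    five_prime_nick: str   # 9-mer immediately 5' of the left TSD copy
    tsd_prefix: str        # first <=7 nt of the repeat
    three_prime_nick: str  # 9-mer immediately 3' of the right TSD copy


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def find_tsd(
    genome: GenomeSequence,
    element_span: Span,
    params: TsdParams = TsdParams(),
) -> Optional[TsdCall]:
    """Maximal direct repeat flanking ``element_span``.

    The left copy must end within ``boundary_slack`` of the element start
    and the right copy start within ``boundary_slack`` of the element end.
    Among qualifying repeats the longest wins; ties break by fewer
    mismatches, then smaller total boundary offset, then leftmost left
    copy. Returns ``None`` when no repeat of at least ``min_len`` exists.
    """
    estart, eend = element_span
    seq = genome.residues
    if not (0 <= estart < eend <= len(seq)):
        raise ValueError(f"element span [{estart},{eend}) outside genome")
    if estart - params.boundary_slack < params.min_len:
        raise FlankTooShortError(
            f"left flank of {genome.id!r} shorter than min_len + slack")
    if len(seq) - (eend + params.boundary_slack) < params.min_len:
        raise FlankTooShortError(
            f"right flank of {genome.id!r} shorter than min_len + slack")

    best: Optional[tuple[int, int, int, int, TsdCall]] = None
    slack = params.boundary_slack
    for length in range(params.max_len, params.min_len - 1, -1):
        for left_end in range(estart - slack, estart + slack + 1):
            if left_end - length < 0 or left_end > eend:
                continue
            left = seq[left_end - length : left_end]
            for right_start in range(eend - slack, eend + slack + 1):
                if right_start + length > len(seq) or right_start < estart:
                    continue
                right = seq[right_start : right_start + length]
                mm = _hamming(left, right)
                if mm > params.max_mismatch:
                    continue
                offset = abs(left_end - estart) + abs(right_start - eend)
                key = (-length, mm, offset, left_end - length)
                call = TsdCall(
                    (left_end - length, left_end),
                    (right_start, right_start + length),
                    left, mm)
                if best is None or key < best[:4]:
                    best = (*key, call)
        if best is not None and -best[0] == length:
            # longer repeats were exhausted; the current length is maximal
            return best[4]
    return best[4] if best else None


def extract_nick_contexts(
    genome: GenomeSequence,
    element_span: Span,
    tsd: TsdCall,
    strand: str = "+",
) -> NickContext:
    """The three logo windows for one insertion, element-orientation normalized.

    For a '-'-strand element the windows are read off the reverse
    complement so that "5' of the left copy" is 5' in element orientation.
    """
    seq = genome.residues
    if strand == "-":
        n = len(seq)
        flip = lambda s: (n - s[1], n - s[0])
        return extract_nick_contexts(
            genome.reverse_complement(),
            flip(element_span),
            TsdCall(flip(tsd.right_span), flip(tsd.left_span),
                    revcomp(tsd.repeat_seq), tsd.mismatches),
            "+")
    ls, le = tsd.left_span
    rs, re_ = tsd.right_span
    if ls < 9:
        raise FlankTooShortError("need 9 bp 5' of the left TSD copy")
    if len(seq) - re_ < 9:
        raise FlankTooShortError("need 9 bp 3' of the right TSD copy")
    return NickContext(
        five_prime_nick=seq[ls - 9 : ls],
        tsd_prefix=tsd.repeat_seq[:7],
        three_prime_nick=seq[re_ : re_ + 9],
    )


@dataclass(frozen=True)
class ConsensusProfile:
    """Per-position base counts and information content for one logo window."""

    counts: pd.DataFrame  # index = position, columns = A,C,G,T
    n_sequences: int

    @property
    def information_bits(self) -> np.ndarray:
        """2 + sum_b p_b log2 p_b per column (0*log0 = 0), in [0, 2]."""
        p = self.counts.to_numpy(dtype=float) / self.n_sequences
        with np.errstate(divide="ignore", invalid="ignore"):
            h = np.where(p > 0, p * np.log2(p), 0.0)
        return 2.0 + h.sum(axis=1)

    def modal_base(self, position: int) -> tuple[str, int]:
        row = self.counts.iloc[position]
        base = row.idxmax()  # pandas idxmax is first-wins -> A<C<G<T ties
        return str(base), int(row.max())


def _profile(windows: Sequence[str]) -> ConsensusProfile:
    lengths = {len(w) for w in windows}
    if len(lengths) != 1:
        raise ValueError(f"mixed window lengths: {sorted(lengths)}")
    (width,) = lengths
    counts = pd.DataFrame(0, index=range(width), columns=list("ACGT"))
    for w in windows:
        for i, base in enumerate(w.upper()):
            if base in "ACGT":
                counts.loc[i, base] += 1
    return ConsensusProfile(counts, len(windows))


def build_site_consensus(
    contexts: Sequence[NickContext],
) -> tuple[ConsensusProfile, ConsensusProfile, ConsensusProfile]:
    """Count matrices for the 5' nick, TSD prefix and 3' nick windows.

    All contexts must have uniform window lengths (TSD prefixes shorter
    than 7, from repeats under 7 bp, would raise — by construction
    repeats are at least 7 bp so prefixes are uniform).
    """
    if not contexts:
        raise ValueError("need at least one context")
    five = _profile([c.five_prime_nick for c in contexts])
    prefix = _profile([c.tsd_prefix for c in contexts])
    three = _profile([c.three_prime_nick for c in contexts])
    return five, prefix, three


def profiles_to_frame(
    profiles: tuple[ConsensusProfile, ConsensusProfile, ConsensusProfile],
) -> pd.DataFrame:
    """Logo-ready long table: window, position, base counts, bits."""
    rows = []
    for name, prof in zip(("five_prime_nick", "tsd_prefix", "three_prime_nick"),
                          profiles):
        bits = prof.information_bits
        for pos in prof.counts.index:
            row = {"window": name, "position": int(pos)}
            row.update({b: int(prof.counts.loc[pos, b]) for b in "ACGT"})
            row["bits"] = float(bits[pos])
            rows.append(row)
    return pd.DataFrame(rows)
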