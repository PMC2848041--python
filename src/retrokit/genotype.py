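"""Filled/empty insertion-site genotyping across strains.

A TPRT insertion leaves the filled allele (flank + TSD + element + TSD +
flank) and, in strains predating the event, the pre-insertion allele with
a single copy of the target site. Given a filled reference locus and its
TSD call, the pre-insertion sequence is reconstructed exactly; strain
sequences are then genotyped by whole-locus edit distance against the
filled and reconstructed-empty models. A locus that is empty in some
strains and filled in others is a recent, polymorphic insertion; a locus
filled in every strain is fixed in the sample.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import edlib
import pandas as pd

from .sequences import GenomeSequence
from .tsd import TsdCall

FILLED = "filled"
EMPTY_CLEAN = "empty_clean"
EMPTY_OTHER = "empty_other"
UNDETERMINED = "undetermined"

RECENT = "recent_polymorphic"
FIXED = "fixed_in_sample"


@dataclass(frozen=True)
class SiteGenotype:
    strain: str
    locus: str
    state: str
    reconstructed_preinsertion: Optional[str] = None
    notes: str = ""


def predict_empty_site(
    filled_locus: GenomeSequence,
    element_span: tuple[int, int],
    tsd: TsdCall,
) -> str:
    """Reconstruct the pre-insertion allele of a filled locus.

    Excises the element together with the right-hand TSD copy, leaving
    5' flank + a single TSD copy + 3' flank — the structure sequenced
    empty sites show. Exact inverse of the TPRT insertion model.
    """
    seq = filled_locus.residues
    estart, eend = element_span
    if not (0 <= tsd.left_span[0] < tsd.left_span[1] <= tsd.right_span[0]
            < tsd.right_span[1] <= len(seq)):
        raise ValueError("TSD spans inconsistent with locus")
    if abs(tsd.left_span[1] - estart) > 6 or abs(tsd.right_span[0] - eend) > 6:
        raise ValueError("TSD spans inconsistent with element span")
    return seq[: tsd.left_span[1]] + seq[tsd.right_span[1] :]


def _edit_fraction(a: str, b: str) -> float:
    if not a or not b:
        return 1.0
    res = edlib.align(a, b, mode="NW", task="distance")
    return res["editDistance"] / max(len(a), len(b))


def _flank_present(flank: str, strain_seq: str, max_fraction: float = 0.1) -> bool:
    if len(flank) < 20:
        return False
    res = edlib.align(flank, strain_seq, mode="HW", task="distance",
                      k=int(max_fraction * len(flank)))
    return res["editDistance"] != -1


def genotype_site(
    strain_seq: GenomeSequence,
    filled_ref: GenomeSequence,
    element_span: tuple[int, int],
    tsd: TsdCall,
    tolerance: float = 0.02,
) -> SiteGenotype:
    """Classify one strain's locus as filled, clean empty, other, or unknown.

    The strain sequence is compared by normalized edit distance to the
    filled reference and to the reconstructed pre-insertion allele; the
    closer model wins if it scores within ``tolerance``. When neither
    fits, presence of both flanks indicates a non-TPRT absence
    (empty_other); absence of flank alignment leaves the call
    undetermined.
    """
    empty_model = predict_empty_site(filled_ref, element_span, tsd)
    d_filled = _edit_fraction(strain_seq.residues, filled_ref.residues)
    d_empty = _edit_fraction(strain_seq.residues, empty_model)
    locus = filled_ref.id
    strain = strain_seq.source_tag or strain_seq.id
    if min(d_filled, d_empty) <= tolerance:
        if d_filled <= d_empty:
            return SiteGenotype(strain, locus, FILLED,
                                notes=f"edit_fraction={d_filled:.4f}")
        return SiteGenotype(strain, locus, EMPTY_CLEAN,
                            reconstructed_preinsertion=empty_model,
                            notes=f"edit_fraction={d_empty:.4f}")
    left_flank = filled_ref.residues[: tsd.left_span[0]]
    right_flank = filled_ref.residues[tsd.right_span[1] :]
    if (_flank_present(left_flank, strain_seq.residues)
            and _flank_present(right_flank, strain_seq.residues)):
        return SiteGenotype(
            strain, locus, EMPTY_OTHER,
            notes=f"flanks present; best edit_fraction="
                  f"{min(d_filled, d_empty):.4f}")
    return SiteGenotype(strain, locus, UNDETERMINED,
                        notes="no model or flank alignment")


@dataclass
class PresenceMatrix:
    """Strains x loci grid of genotype states (strings)."""

    states: pd.DataFrame  # index = strains, columns = loci
    provenance: str = "sequence"

    def __post_init__(self) -> None:
        valid = {FILLED, EMPTY_CLEAN, EMPTY_OTHER, UNDETERMINED}
        bad = set(self.states.to_numpy().ravel()) - valid
        if bad:
            raise ValueError(f"invalid genotype states: {sorted(bad)}")

    @classmethod
    def from_genotypes(cls, genotypes: list[SiteGenotype]) -> "PresenceMatrix":
        frame = pd.DataFrame(
            [(g.strain, g.locus, g.state) for g in genotypes],
            columns=["strain", "locus", "state"],
        ).pivot(index="strain", columns="locus", values="state")
        return cls(frame.fillna(UNDETERMINED))


def call_insertion_age(matrix: PresenceMatrix) -> pd.DataFrame:
    """Label each locus recent (polymorphic) or fixed in the sampled strains.

    A locus with at least one clean empty site and at least one filled
    strain segregates, so the insertion postdates the strains' common
    ancestor; a locus filled in every determined strain is fixed in the
    sample. Undetermined/other cells are ignored but counted in the
    completeness column.
    """
    if matrix.states.shape[0] < 2:
        raise ValueError("need at least 2 strains")
    rows = []
    for locus in matrix.states.columns:
        col = matrix.states[locus]
        n_filled = int((col == FILLED).sum())
        n_empty = int((col == EMPTY_CLEAN).sum())
        n_other = int(col.isin([EMPTY_OTHER, UNDETERMINED]).sum())
        if n_filled + n_empty == 0:
            raise ValueError(f"locus {locus!r}: all cells undetermined")
        if n_empty >= 1 and n_filled >= 1:
            label = RECENT
        elif n_empty == 0:
            label = FIXED
        else:
            # empty in every determined strain: segregates relative to the
            # filled reference haplotype the locus was defined from
            label = RECENT
        rows.append({"locus": locus, "label": label, "n_filled": n_filled,
                     "n_empty_clean": n_empty, "n_unscored": n_other})
    return pd.DataFrame(rows)
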