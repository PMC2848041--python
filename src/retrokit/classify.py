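"""Subfamily classification and nomenclature for retroelement copies.

Every candidate is related to a reference panel of named full-length
elements. A structurally full-length candidate is a subfamily *member*;
a shorter copy aligning above an identity threshold to a unique best
full-length element is *derived* from it (suffix ``d``); anything else is
attached to its nearest full-length match as a *like* element (suffix
``L``). Names follow the SadhuX-#, SadhuX-#dK, SadhuXLK convention.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from typing import Mapping, Optional, Sequence

from Bio import Align

MEMBER = "member_full_length"
DERIVED = "derived"
LIKE = "like"
UNCLASSIFIED = "unclassified"


@dataclass(frozen=True)
class ClassifierParams:
    """Identity thresholds and alignment scoring for classification.

    ``derived_min_identity`` follows the family definition of a derivative
    (>75% identity to a unique full-length element); ``unique_margin`` is
    the best-vs-second-best identity gap required to call the best match
    unique. ``min_like_aligned`` is the minimum aligned length for a
    meaningful nearest-match assignment.
    """

    derived_min_identity: float = 0.75
    unique_margin: float = 0.02
    min_like_aligned: int = 50
    match_score: float = 1.0
    mismatch_score: float = -1.0
    gap_open: float = -5.0
    gap_extend: float = -1.0

    def __post_init__(self) -> None:
        if not 0 < self.derived_min_identity < 1:
            raise ValueError("derived_min_identity must be in (0,1)")
        if self.unique_margin < 0:
            raise ValueError("unique_margin must be >= 0")


@dataclass(frozen=True)
class SubfamilyAssignment:
    element_ref: str
    relation: str                 # member_full_length | derived | like | unclassified
    nearest_full_length: Optional[str]
    identity: float
    aligned_len: int
    subfamily: Optional[str] = None
    assigned_name: Optional[str] = None


def _aligner(params: ClassifierParams, mode: str = "global") -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.match_score = params.match_score
    aligner.mismatch_score = params.mismatch_score
    aligner.open_gap_score = params.gap_open
    aligner.extend_gap_score = params.gap_extend
    if mode == "global":
        # free terminal gaps: overhangs are not penalized, matching how
        # uncorrected distances are computed on trimmed alignments
        aligner.end_gap_score = 0.0
    return aligner


def align_stats(a: str, b: str, params: ClassifierParams = ClassifierParams()
                ) -> tuple[float, int, object]:
    """Global alignment (free end gaps); returns (identity, aligned_len, alignment).

    Identity is matches over columns where both sequences have a residue;
    internal gap columns are excluded from the denominator.
    """
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    a, b = a.upper(), b.upper()
    alignment = _aligner(params).align(a, b)[0]
    blocks_a, blocks_b = alignment.aligned
    matches = 0
    cols = 0
    for (sa, ea), (sb, _eb) in zip(blocks_a, blocks_b):
        cols += ea - sa
        matches += sum(a[sa + i] == b[sb + i] for i in range(ea - sa))
    identity = matches / cols if cols else 0.0
    return identity, cols, alignment


def pairwise_identity(a: str, b: str, params: ClassifierParams = ClassifierParams()
                      ) -> tuple[float, int]:
    """Uncorrected fractional identity between two sequences.

    Co-optimal alignments can differ in which one the aligner reports, so
    the pair is canonicalized (lexicographic order) before aligning;
    identity(a, b) == identity(b, a) exactly.
    """
    x, y = sorted((a.upper(), b.upper()))
    identity, cols, _ = align_stats(x, y, params)
    return identity, cols


def classify_element(
    candidate_name: str,
    candidate_seq: str,
    structural_class: str,
    full_set: Mapping[str, str],
    params: ClassifierParams = ClassifierParams(),
) -> SubfamilyAssignment:
    """Relate one candidate to the named full-length reference panel.

    The reference panel must have unique names. Candidates that are
    themselves structurally full-length become members of the subfamily of
    their best match; others are derived (identity above threshold to a
    unique best match) or like (attached to the best pairwise match).
    """
    if not full_set:
        raise ValueError("reference panel is empty")
    names = list(full_set)
    if len(set(names)) != len(names):
        raise ValueError("duplicate names in reference panel")
    # the nearest reference is the best-scoring pairwise alignment (the
    # identity of a short spurious match is meaningless on its own);
    # identity thresholds are then applied to the best-scoring match
    scored = []
    for name in sorted(names):
        x, y = sorted((candidate_seq.upper(), full_set[name].upper()))
        identity, cols, alignment = align_stats(x, y, params)
        scored.append((float(alignment.score), identity, cols, name))
    scored.sort(key=lambda t: (-t[0], t[3]))
    eligible = [s for s in scored if s[2] >= params.min_like_aligned]
    if not eligible:
        _, best_id, best_cols, _ = scored[0]
        return SubfamilyAssignment(candidate_name, UNCLASSIFIED, None,
                                   best_id, best_cols)
    _, best_id, best_cols, best_name = eligible[0]
    second_id = eligible[1][1] if len(eligible) > 1 else 0.0

    if structural_class == "full_length":
        return SubfamilyAssignment(candidate_name, MEMBER, best_name,
                                   best_id, best_cols)
    unique = (best_id - second_id) >= params.unique_margin or len(eligible) == 1
    if best_id > params.derived_min_identity and unique:
        return SubfamilyAssignment(candidate_name, DERIVED, best_name,
                                   best_id, best_cols)
    return SubfamilyAssignment(candidate_name, LIKE, best_name,
                               best_id, best_cols)


_NAME_RE = re.compile(
    r"^(?P<family>.*?)(?P<subfamily>\d+)"
    r"(?:-(?P<element>\d+)(?:d(?P<derived>\d+))?|L(?P<like>\d+))$"
)


def parse_name(name: str) -> dict:
    """Parse SadhuX-#, SadhuX-#dK or SadhuXLK back into its parts."""
    m = _NAME_RE.match(name)
    if not m:
        raise ValueError(f"unparseable element name: {name!r}")
    d = m.groupdict()
    if d["like"] is not None:
        relation, index = LIKE, int(d["like"])
        element = None
    elif d["derived"] is not None:
        relation, index = DERIVED, int(d["derived"])
        element = int(d["element"])
    else:
        relation, index = MEMBER, int(d["element"])
        element = int(d["element"])
    return {"family": d["family"], "subfamily": int(d["subfamily"]),
            "element": element, "relation": relation, "index": index}


def assign_names(
    assignments: Sequence[SubfamilyAssignment],
    family_prefix: str = "Sadhu",
    subfamily_of: Optional[Mapping[str, str]] = None,
) -> list[SubfamilyAssignment]:
    """Generate collision-free family nomenclature in input order.

    ``subfamily_of`` maps reference full-length names to subfamily labels;
    when omitted, labels are parsed from the reference names themselves
    (e.g. ``Sadhu5-1`` -> subfamily ``5``).
    """

    def subfamily_label(ref: str) -> str:
        if subfamily_of is not None:
            return str(subfamily_of[ref])
        return str(parse_name(ref)["subfamily"])

    member_counter: dict[str, int] = {}
    derived_counter: dict[str, int] = {}
    like_counter: dict[str, int] = {}
    member_name: dict[str, str] = {}
    out: list[SubfamilyAssignment] = []
    for a in assignments:
        if a.relation == MEMBER:
            sub = a.subfamily or subfamily_label(a.nearest_full_length)
            k = member_counter.get(sub, 0) + 1
            member_counter[sub] = k
            name = f"{family_prefix}{sub}-{k}"
            member_name[a.element_ref] = name
            out.append(replace(a, subfamily=sub, assigned_name=name))
        elif a.relation == DERIVED:
            base = member_name.get(a.nearest_full_length, a.nearest_full_length)
            k = derived_counter.get(base, 0) + 1
            derived_counter[base] = k
            sub = subfamily_label(a.nearest_full_length)
            out.append(replace(a, subfamily=sub, assigned_name=f"{base}d{k}"))
        elif a.relation == LIKE:
            sub = subfamily_label(a.nearest_full_length)
            k = like_counter.get(sub, 0) + 1
            like_counter[sub] = k
            out.append(replace(a, subfamily=sub,
                               assigned_name=f"{family_prefix}{sub}L{k}"))
        else:
            out.append(a)
    names = [a.assigned_name for a in out if a.assigned_name]
    if len(names) != len(set(names)):
        raise ValueError("name collision in assignment batch")
    return out


def subfamily_consensus(
    members: Sequence[str],
    anchor: Optional[str] = None,
    params: ClassifierParams = ClassifierParams(),
) -> str:
    """Plurality consensus via star alignment of members to an anchor.

    The anchor defaults to the longest member. Each member is globally
    aligned to the anchor and its residues projected onto anchor columns;
    insertions relative to the anchor do not create columns. Per column,
    the plurality residue wins (ties resolved in A<C<G<T order); columns
    where no member has a residue are dropped.
    """
    if not members:
        raise ValueError("need at least one member sequence")
    members = [m.upper() for m in members]
    if anchor is None:
        anchor = max(members, key=len)
    columns = [{b: 0 for b in "ACGT"} for _ in range(len(anchor))]
    for member in members:
        _, _, alignment = align_stats(anchor, member, params)
        blocks_a, blocks_b = alignment.aligned
        for (sa, ea), (sb, _eb) in zip(blocks_a, blocks_b):
            for i in range(ea - sa):
                base = member[sb + i]
                if base in "ACGT":
                    columns[sa + i][base] += 1
    consensus = []
    for col in columns:
        total = sum(col.values())
        if total == 0:
            continue  # all-gap column
        consensus.append(max("ACGT", key=lambda b: col[b]))
    return "".join(consensus)
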