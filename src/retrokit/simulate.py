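"""Synthetic genomes, element families and strain panels with ground truth.

The generator emulates the data the annotation pipeline assumes: TPRT
insertions flanked by exact 7-16 bp target site duplications and 3'
poly(A) tails; ~900 bp full-length elements opening with the CAATCGTTSC
motif and a polypyrimidine patch; 5'-truncated, chimeric (template
switch), early-polyadenylated and internally deleted derivatives; neutral
point divergence under a Jukes-Cantor substitution process; and strain
panels segregating ancestral (fixed) versus recent (polymorphic)
insertions. Every planted event carries a machine-readable truth record.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .sequences import GenomeSequence
from .tsd import TsdCall

BASES = "ACGT"

DERIVATIVE_MODES = (
    "five_prime_truncation",
    "template_switch",
    "early_polyA",
    "internal_deletion",
)


@dataclass(frozen=True)
class SimParams:
    """Study conditions for the simulator.

    Defaults mirror the family biology: 900 bp elements (+/- jitter),
    TSD lengths uniform on [7,16], a 12 bp poly(A) tail, within-subfamily
    divergence of 0.10 substitutions/site and between-subfamily divergence
    of 0.30, an AT-rich base composition, and an 8-strain panel with 4
    ancestral and 3 recent insertion loci where a recent insertion is
    present in a strain with probability 0.5.
    """

    seed: int = 0
    genome_len: int = 20_000
    base_composition: tuple[float, float, float, float] = (0.32, 0.18, 0.18, 0.32)
    n_subfamilies: int = 3
    within_subfamily_divergence: float = 0.10
    between_subfamily_divergence: float = 0.30
    element_len: int = 900
    element_len_jitter: int = 60
    tail_len: int = 12
    polypyrimidine_len: int = 20
    tsd_len_range: tuple[int, int] = (7, 16)
    derivative_mode_probs: tuple[float, float, float, float] = (0.4, 0.2, 0.2, 0.2)
    n_strains: int = 8
    n_ancestral_loci: int = 4
    n_recent_loci: int = 3
    p_recent_insertion: float = 0.5
    strain_divergence: float = 0.01
    flank_len: int = 400

    def __post_init__(self) -> None:
        if not math.isclose(sum(self.base_composition), 1.0, abs_tol=1e-9):
            raise ValueError("base composition must sum to 1")
        if not math.isclose(sum(self.derivative_mode_probs), 1.0, abs_tol=1e-9):
            raise ValueError("derivative mode probabilities must sum to 1")
        if self.within_subfamily_divergence < 0 or self.between_subfamily_divergence < 0:
            raise ValueError("divergences must be >= 0")


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one planted insertion event."""

    event_id: str
    genome_id: str
    span: tuple[int, int]
    tsd: str
    pre_insertion: str
    mode: str  # "full_length" or a derivative mode
    parent_id: str
    subfamily: int


def random_dna(n: int, rng: np.random.Generator,
               composition: Sequence[float] = (0.25, 0.25, 0.25, 0.25)) -> str:
    return "".join(rng.choice(list(BASES), size=n, p=list(composition)))


def mutate(seq: str, divergence: float, rng: np.random.Generator) -> str:
    """Apply Jukes-Cantor point substitutions at ``divergence`` subs/site.

    The realized per-site substitution probability is
    p = 3/4 (1 - exp(-4d/3)), the JC expected fraction of differing sites
    after a branch of length d.
    """
    if divergence == 0:
        return seq
    p = 0.75 * (1.0 - math.exp(-4.0 * divergence / 3.0))
    chars = list(seq)
    hit = np.nonzero(rng.random(len(chars)) < p)[0]
    for i in hit:
        current = chars[i]
        options = [b for b in BASES if b != current]
        chars[i] = options[rng.integers(0, 3)]
    return "".join(chars)


def jc_expected_difference(d_total: float) -> float:
    """Expected p-distance between two sequences separated by ``d_total``."""
    return 0.75 * (1.0 - math.exp(-4.0 * d_total / 3.0))


def make_ancestral_element(params: SimParams, rng: np.random.Generator) -> str:
    """A scannable full-length element: motif + polypyrimidine + body + tail."""
    if params.element_len < 100:
        raise ValueError("element_len must be >= 100")
    motif = "CAATCGTT" + ("C", "G")[rng.integers(0, 2)] + "C"  # S in {C,G}
    pyr = "".join(rng.choice(["C", "T"], size=params.polypyrimidine_len,
                             p=[0.5, 0.5]))
    length = params.element_len + int(
        rng.integers(-params.element_len_jitter, params.element_len_jitter + 1))
    body_len = max(0, length - len(motif) - len(pyr) - params.tail_len)
    body = random_dna(body_len, rng, params.base_composition)
    return motif + pyr + body + "A" * params.tail_len


def simulate_tprt_insertion(
    genome: GenomeSequence,
    element: str,
    position: int,
    tsd_len: int,
    event_id: str = "event",
    parent_id: str = "",
    subfamily: int = 0,
    mode: str = "full_length",
) -> tuple[GenomeSequence, TruthRecord]:
    """Insert ``element`` at ``position`` under the TPRT staggered-cut model.

    The target bases ``genome[position - tsd_len : position]`` are
    duplicated around the inserted element, exactly as two staggered nicks
    would leave them; flanks are untouched and the pre-insertion sequence
    is stored in the truth record.
    """
    if not 7 <= tsd_len <= 18:
        raise ValueError("tsd_len must be in [7, 18]")
    seq = genome.residues
    if position - tsd_len < 9 or position > len(seq) - 9:
        raise ValueError("position too close to contig edge for TPRT model")
    tsd = seq[position - tsd_len : position]
    new = seq[:position] + element + tsd + seq[position:]
    truth = TruthRecord(
        event_id=event_id,
        genome_id=genome.id,
        span=(position, position + len(element)),
        tsd=tsd,
        pre_insertion=seq,
        mode=mode,
        parent_id=parent_id,
        subfamily=subfamily,
    )
    return GenomeSequence(genome.id, new, genome.source_tag), truth


def planted_tsd_call(truth: TruthRecord) -> TsdCall:
    """The TsdCall corresponding to a planted insertion, from truth."""
    start, end = truth.span
    k = len(truth.tsd)
    return TsdCall((start - k, start), (end, end + k), truth.tsd, 0)


def derive_element(parent: str, mode: str, rng: np.random.Generator,
                   params: SimParams = SimParams()) -> str:
    """A structurally degraded copy of ``parent`` under one derivative mode.

    - five_prime_truncation: drop a random 5' fraction, keep the tail
      (incomplete reverse transcription);
    - template_switch: prepend 10-30 bp of foreign sequence to a
      5'-truncated copy (chimeric insertion);
    - early_polyA: truncate 3' and re-polyadenylate (early termination);
    - internal_deletion: remove an internal block.
    """
    if len(parent) < 200:
        raise ValueError("parent must be >= 200 bp")
    if mode == "five_prime_truncation":
        cut = int(rng.integers(len(parent) // 4, (3 * len(parent)) // 4))
        return parent[cut:]
    if mode == "template_switch":
        cut = int(rng.integers(len(parent) // 4, (3 * len(parent)) // 4))
        foreign = random_dna(int(rng.integers(10, 31)), rng,
                             params.base_composition)
        return foreign + parent[cut:]
    if mode == "early_polyA":
        cut = int(rng.integers(len(parent) // 3, (2 * len(parent)) // 3))
        return parent[:cut] + "A" * params.tail_len
    if mode == "internal_deletion":
        start = int(rng.integers(50, len(parent) // 2))
        size = int(rng.integers(50, len(parent) // 3))
        return parent[:start] + parent[start + size:]
    raise ValueError(f"unknown derivative mode: {mode!r}")


def make_subfamily_ancestors(params: SimParams, rng: np.random.Generator
                             ) -> list[str]:
    """One ancestor per subfamily, diverged from a family founder."""
    founder = make_ancestral_element(params, rng)
    ancestors = []
    for _ in range(params.n_subfamilies):
        anc = mutate(founder, params.between_subfamily_divergence / 2, rng)
        # keep diagnostic structure intact after mutation
        anc = founder[:10] + anc[10:-params.tail_len] + "A" * params.tail_len
        ancestors.append(anc)
    return ancestors


def simulate_genome(
    params: SimParams,
    rng: np.random.Generator,
    n_elements: int,
    divergence: Optional[float] = None,
    genome_id: str = "sim",
    include_derivatives: bool = False,
) -> tuple[GenomeSequence, list[TruthRecord]]:
    """A genome with ``n_elements`` planted TPRT insertions plus truth.

    Elements are subfamily-ancestor copies mutated at ``divergence``
    (default: the within-subfamily divergence), inserted at well-separated
    positions with fresh TSDs. Truth spans are in final coordinates.
    """
    if divergence is None:
        divergence = params.within_subfamily_divergence
    ancestors = make_subfamily_ancestors(params, rng)
    background = random_dna(params.genome_len, rng, params.base_composition)
    margin = 40
    gap = (len(background) - 2 * margin) // max(1, n_elements)
    if gap < 60:
        raise ValueError("genome too short for the requested element count")
    inserts = []
    for i in range(n_elements):
        sub = int(rng.integers(0, params.n_subfamilies))
        element = mutate(ancestors[sub], divergence, rng)
        if include_derivatives and rng.random() < 0.3:
            mode = str(rng.choice(DERIVATIVE_MODES,
                                  p=list(params.derivative_mode_probs)))
            element = derive_element(element, mode, rng, params)
        else:
            mode = "full_length"
        pos = margin + i * gap + int(rng.integers(0, max(1, gap - 60)))
        tsd_len = int(rng.integers(params.tsd_len_range[0],
                                   params.tsd_len_range[1] + 1))
        inserts.append((pos, tsd_len, element, sub, mode))

    pieces = []
    truths = []
    prev = 0
    offset = 0
    for i, (pos, k, element, sub, mode) in enumerate(inserts):
        tsd = background[pos - k : pos]
        pieces.append(background[prev:pos])
        pieces.append(element + tsd)
        start = pos + offset
        truths.append(TruthRecord(
            event_id=f"{genome_id}.e{i}",
            genome_id=genome_id,
            span=(start, start + len(element)),
            tsd=tsd,
            pre_insertion="",
            mode=mode,
            parent_id=f"subfamily{sub}.ancestor",
            subfamily=sub,
        ))
        offset += len(element) + k
        prev = pos
    pieces.append(background[prev:])
    return GenomeSequence(genome_id, "".join(pieces)), truths


@dataclass
class RadiationLocus:
    """One insertion locus across a strain panel, with the filled reference."""

    locus_id: str
    reference: GenomeSequence       # filled reference haplotype (no divergence)
    element_span: tuple[int, int]
    tsd: TsdCall
    strains: dict[str, GenomeSequence]
    truth_label: str                # realized: recent_polymorphic | fixed_in_sample
    filled_in: frozenset


@dataclass
class RadiationPanel:
    loci: list[RadiationLocus]
    strain_names: list[str]

    def truth_frame(self) -> pd.DataFrame:
        rows = [
            {"locus": loc.locus_id, "label": loc.truth_label,
             "n_filled": len(loc.filled_in), "tsd": loc.tsd.repeat_seq}
            for loc in self.loci
        ]
        return pd.DataFrame(rows)


def simulate_radiation(params: SimParams = SimParams()) -> RadiationPanel:
    """A strain panel segregating ancestral (fixed) and recent insertions.

    Each locus is an independent genomic region. Ancestral insertions are
    present in every strain; recent insertions are present in a random
    strain subset (probability ``p_recent_insertion`` per strain, with the
    first strain acting as the filled reference carrier). Per-strain
    point mutations accumulate at ``strain_divergence``. The truth label
    records the *realized* sample pattern: a recent insertion that
    happens to be carried by every sampled strain is fixed in the sample.
    Fully reproducible from ``params.seed``.
    """
    if params.n_strains < 2:
        raise ValueError("need at least 2 strains")
    rng = np.random.default_rng(params.seed)
    strains = [f"strain{i + 1:02d}" for i in range(params.n_strains)]
    ancestors = make_subfamily_ancestors(params, rng)
    loci: list[RadiationLocus] = []
    n_total = params.n_ancestral_loci + params.n_recent_loci
    for li in range(n_total):
        locus_id = f"locus{li + 1:02d}"
        ancestral = li < params.n_ancestral_loci
        flank = random_dna(2 * params.flank_len, rng, params.base_composition)
        pos = params.flank_len
        sub = int(rng.integers(0, params.n_subfamilies))
        element = mutate(ancestors[sub], params.within_subfamily_divergence, rng)
        tsd_len = int(rng.integers(params.tsd_len_range[0],
                                   params.tsd_len_range[1] + 1))
        empty = GenomeSequence(locus_id, flank)
        filled, truth = simulate_tprt_insertion(
            empty, element, pos, tsd_len, event_id=locus_id,
            parent_id=f"subfamily{sub}.ancestor", subfamily=sub)
        if ancestral:
            carriers = set(strains)
        else:
            carriers = {s for s in strains
                        if rng.random() < params.p_recent_insertion}
            carriers.add(strains[0])  # the reference strain carries it
        strain_seqs = {}
        for s in strains:
            base = filled.residues if s in carriers else empty.residues
            strain_seqs[s] = GenomeSequence(
                locus_id, mutate(base, params.strain_divergence, rng),
                source_tag=s)
        label = ("fixed_in_sample" if carriers == set(strains)
                 else "recent_polymorphic")
        loci.append(RadiationLocus(
            locus_id=locus_id,
            reference=filled,
            element_span=truth.span,
            tsd=planted_tsd_call(truth),
            strains=strain_seqs,
            truth_label=label,
            filled_in=frozenset(carriers),
        ))
    return RadiationPanel(loci, strains)
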