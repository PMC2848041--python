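"""End-to-end annotation: scan -> TSD -> classify -> tree -> report.

``run_annotate`` composes the library stages over one or more input
genomes and writes a reproducible report bundle (GFF3, TSV tables, a
newick tree, nicking-site consensus matrices and the serialized run
configuration). All randomness flows from a single seed; identical reruns
produce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import classify as _classify
from .element_scan import (ElementAnnotation, ScanParams, annotations_to_frame,
                           scan_elements, write_gff3)
from .phylo import DistanceMatrix, neighbor_joining
from .sequences import GenomeSequence, read_fasta
from .tsd import (FlankTooShortError, TsdParams, build_site_consensus,
                  extract_nick_contexts, find_tsd, profiles_to_frame)


class PipelineError(RuntimeError):
    """A stage failure; carries the failing stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    fasta: str
    out_dir: str
    seed: int = 0
    family_prefix: str = "Sadhu"
    references: Optional[str] = None  # FASTA of named full-length elements
    scan: ScanParams = field(default_factory=ScanParams)
    tsd: TsdParams = field(default_factory=TsdParams)
    classifier: _classify.ClassifierParams = field(
        default_factory=_classify.ClassifierParams)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        raw = json.loads(text)
        scan = raw.pop("scan", {})
        tsd = raw.pop("tsd", {})
        clf = raw.pop("classifier", {})
        for block in (scan,):
            if "full_length_span" in block:
                block["full_length_span"] = tuple(block["full_length_span"])
        return cls(**raw, scan=ScanParams(**scan), tsd=TsdParams(**tsd),
                   classifier=_classify.ClassifierParams(**clf))


def run_annotate(config: RunConfig) -> dict:
    """Run the full annotation workflow; returns a summary dict.

    Stage failures raise :class:`PipelineError` naming the stage, after
    removing any partial outputs.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        return _run_annotate(config, out, written)
    except PipelineError:
        for path in written:
            path.unlink(missing_ok=True)
        raise


def _run_annotate(config: RunConfig, out: Path, written: list[Path]) -> dict:
    genomes = read_fasta(config.fasta)
    if not genomes:
        raise PipelineError("ingest", f"no sequences in {config.fasta}")

    # --- structural scan
    annotations: list[tuple[GenomeSequence, ElementAnnotation]] = []
    for genome in genomes:
        for ann in scan_elements(genome, config.scan):
            annotations.append((genome, ann))

    # --- TSD detection + nicking contexts for full-length copies
    tsd_rows = []
    contexts = []
    for genome, ann in annotations:
        if ann.structural_class != "full_length":
            continue
        try:
            call = find_tsd(genome, ann.span, config.tsd)
        except FlankTooShortError:
            call = None
        if call is None:
            tsd_rows.append({"genome": genome.id, "start": ann.span[0],
                             "end": ann.span[1], "tsd": "ND", "length": 0})
            continue
        tsd_rows.append({"genome": genome.id, "start": ann.span[0],
                         "end": ann.span[1], "tsd": call.repeat_seq,
                         "length": call.length})
        try:
            contexts.append(
                extract_nick_contexts(genome, ann.span, call, ann.strand))
        except FlankTooShortError:
            pass

    # --- classification against a reference panel (optional)
    assign_rows = []
    if config.references:
        refs = {g.id: g.residues for g in read_fasta(config.references)}
        if not refs:
            raise PipelineError("classify", "empty reference FASTA")
        assignments = []
        for genome, ann in annotations:
            seq = genome.slice(*ann.span)
            assignments.append(_classify.classify_element(
                f"{genome.id}:{ann.span[0]}-{ann.span[1]}", seq,
                ann.structural_class, refs, config.classifier))
        named = _classify.assign_names(assignments, config.family_prefix)
        assign_rows = [dataclasses.asdict(a) for a in named]

    # --- divergence + tree over full-length element sequences
    newick = None
    full = [(f"{g.id}_{a.span[0]}", g.slice(*a.span))
            for g, a in annotations if a.structural_class == "full_length"]
    if len(full) >= 3:
        import numpy as np

        n = len(full)
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                ident, _ = _classify.pairwise_identity(
                    full[i][1], full[j][1], config.classifier)
                d[i, j] = d[j, i] = 1 - ident
        dm = DistanceMatrix(tuple(name for name, _ in full), d)
        newick = neighbor_joining(dm).newick()

    # --- outputs
    def emit(path: Path, writer) -> None:
        writer(path)
        written.append(path)

    config_json = config.to_json()
    # hash the analysis parameters only, so reruns into a different
    # directory remain byte-identical
    param_blob = json.dumps({
        "seed": config.seed,
        "family_prefix": config.family_prefix,
        "scan": dataclasses.asdict(config.scan),
        "tsd": dataclasses.asdict(config.tsd),
        "classifier": dataclasses.asdict(config.classifier),
    }, sort_keys=True)
    digest = hashlib.sha256(param_blob.encode()).hexdigest()[:12]
    header = f"# retrokit config {digest}\n"

    emit(out / "elements.gff3",
         lambda p: write_gff3([a for _, a in annotations], p))
    frame = annotations_to_frame([a for _, a in annotations])
    emit(out / "elements.tsv",
         lambda p: p.write_text(header + frame.to_csv(sep="\t", index=False)))
    emit(out / "tsd.tsv", lambda p: p.write_text(
        header + pd.DataFrame(
            tsd_rows, columns=["genome", "start", "end", "tsd", "length"]
        ).to_csv(sep="\t", index=False)))
    if contexts:
        profiles = build_site_consensus(contexts)
        emit(out / "site_consensus.tsv", lambda p: p.write_text(
            header + profiles_to_frame(profiles).to_csv(sep="\t", index=False)))
    if assign_rows:
        emit(out / "classification.tsv", lambda p: p.write_text(
            header + pd.DataFrame(assign_rows).to_csv(sep="\t", index=False)))
    if newick:
        emit(out / "tree.nwk", lambda p: p.write_text(newick + "\n"))
    emit(out / "config.json", lambda p: p.write_text(config_json))

    return {
        "n_genomes": len(genomes),
        "n_annotations": len(annotations),
        "n_full_length": len(full),
        "n_tsd_detected": sum(1 for r in tsd_rows if r["tsd"] != "ND"),
        "config_hash": digest,
        "outputs": [str(p) for p in written],
    }
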