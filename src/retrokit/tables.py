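"""Bundled curated tables and reconstruction helpers.

Four small TSV fixtures transcribe the published family tables: the
A. thaliana element catalogue (nomenclature and genome positions), the 14
A. thaliana insertion loci with their target site duplications and
nicking-site windows, the Sadhu5 strain presence/absence panel, and the
A. lyrata element table. Transcription quirks of the source are preserved
verbatim (e.g. the orphan Sadhu9L3 identifier in the TSD table, asterisked
presence marks, and "Short"/"Long" flanking-product entries whose meaning
was never defined — the latter are mapped to undetermined, not guessed).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .genotype import EMPTY_CLEAN, FILLED, UNDETERMINED, PresenceMatrix
from .sequences import GenomeSequence

#: synthetic element body used when rebuilding a TSD locus from its printed
#: flanking strings: conserved motif + G homopolymer body + poly(A) tail
ELEMENT_STUB = "CAATCGTTGC" + "G" * 40 + "A" * 12

PANEL_LOCI = ("Sadhu5-1", "Sadhu5-1d1", "Sadhu5-1d2", "Sadhu5-2")


def _read(name: str) -> pd.DataFrame:
    ref = resources.files("retrokit.data").joinpath(name)
    with ref.open("r") as fh:
        return pd.read_csv(fh, sep="\t", dtype=str, keep_default_na=False)


def load_tsd_sites() -> pd.DataFrame:
    """The 14 A. thaliana insertion loci: 5' nick, TSD, 3' nick strings."""
    frame = _read("athaliana_tsd_sites.tsv")
    bad = frame[frame["five_prime_nick"].str.len() != 9]
    if not bad.empty:
        raise ValueError(f"malformed five_prime_nick in rows {list(bad.index)}")
    bad = frame[frame["three_prime_nick"].str.len() != 9]
    if not bad.empty:
        raise ValueError(f"malformed three_prime_nick in rows {list(bad.index)}")
    return frame


def load_strain_panel() -> pd.DataFrame:
    """The Sadhu5 presence/absence panel across 24 natural strains (verbatim)."""
    return _read("sadhu5_strain_panel.tsv")


def load_alyrata_elements() -> pd.DataFrame:
    """The A. lyrata element table (>350 bp members)."""
    frame = _read("alyrata_elements.tsv")
    return frame


def load_athaliana_elements() -> pd.DataFrame:
    """The A. thaliana element catalogue (nomenclature + positions)."""
    return _read("athaliana_elements.tsv")


def _cell_state(value: str) -> str:
    value = value.strip()
    if value in ("X", "X*"):
        return FILLED
    if value == "ES":
        return EMPTY_CLEAN
    return UNDETERMINED  # blank, "Short", "Long": assay outcome undefined


def panel_to_matrix(panel: pd.DataFrame | None = None) -> PresenceMatrix:
    """Collapse the three PCR assays per locus into one genotype state.

    A clean empty-site product (ES) in any assay marks the strain empty;
    otherwise any positive product (X / X*) marks it filled; strains with
    only blank/undefined entries stay undetermined.
    """
    if panel is None:
        panel = load_strain_panel()
    states = {}
    for locus in PANEL_LOCI:
        cols = [f"{locus}_int", f"{locus}_5", f"{locus}_3"]
        locus_states = []
        for _, row in panel.iterrows():
            cells = [_cell_state(row[c]) for c in cols]
            if EMPTY_CLEAN in cells:
                locus_states.append(EMPTY_CLEAN)
            elif FILLED in cells:
                locus_states.append(FILLED)
            else:
                locus_states.append(UNDETERMINED)
        states[locus] = locus_states
    frame = pd.DataFrame(states, index=list(panel["strain"]))
    return PresenceMatrix(frame, provenance="fixture")


def reconstruct_tsd_locus(row: pd.Series) -> tuple[GenomeSequence, tuple[int, int]]:
    """Rebuild one insertion locus from its printed flanking strings.

    The locus is 5'nick + TSD + element stub + TSD + 3'nick, with the
    element span covering the stub. This is exactly the filled-site
    structure the TPRT model predicts around each catalogued element.
    """
    nick5, tsd, nick3 = (row["five_prime_nick"], row["tsd"],
                         row["three_prime_nick"])
    seq = nick5 + tsd + ELEMENT_STUB + tsd + nick3
    start = len(nick5) + len(tsd)
    return (GenomeSequence(str(row["element"]), seq),
            (start, start + len(ELEMENT_STUB)))


def load_fixture_tables() -> dict[str, pd.DataFrame]:
    """All bundled tables, schema-validated."""
    return {
        "athaliana_elements": load_athaliana_elements(),
        "tsd_sites": load_tsd_sites(),
        "strain_panel": load_strain_panel(),
        "alyrata_elements": load_alyrata_elements(),
    }
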