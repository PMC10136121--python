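"""Packaged datasets.

``load_table1`` returns the transcription of the published cnidarian
residue survey: 18 species (16 cnidarians plus the C. elegans anaerobic
and H. sapiens aerobic references) by the 5 panel sites, with "-" cells
as MISSING.
"""

from __future__ import annotations

from importlib import resources

from .io import CharacterMatrix, read_character_matrix

__all__ = ["load_table1", "TABLE1_REFERENCE_SPECIES", "table1_cnidarians"]

#: Non-cnidarian reference rows included in the survey table.
TABLE1_REFERENCE_SPECIES = ("Caenorhabditis elegans", "Homo sapiens")


def load_table1() -> CharacterMatrix:
    ref = resources.files("rqscreen").joinpath("data/table1.tsv")
    with ref.open("rt") as fh:
        return read_character_matrix(fh)


def table1_cnidarians(matrix: CharacterMatrix | None = None) -> tuple[str, ...]:
    """Names of the cnidarian rows (everything but the two references)."""
    if matrix is None:
        matrix = load_table1()
    return tuple(s for s in matrix.species if s not in TABLE1_REFERENCE_SPECIES)
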