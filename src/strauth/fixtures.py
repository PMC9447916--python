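"""Packaged reference data for the CellCheck Mouse 19 panel.

Three small CSVs ship with the package:

``panel.csv``
    Marker metadata — chromosome, known allele range (the repeat counts
    observed at each locus across laboratory mouse lines), and the multiplex
    primer pair for each of the 19 markers.
``colgfp_reference.csv``
    The 19-marker reference profile of the Col-GFP HSC hepatic stellate cell
    line (Cellosaurus CVCL_B7MI).
``similarity_table.csv``
    The published 18-marker comparison of Col-GFP HSC against its seven most
    similar mouse lines in the Cellosaurus STR database (marker 9-2 is not
    typed in any of the database lines, so it is absent from this table).
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

from .profile_model import MarkerDefinition, STRProfile, load_panel, load_profiles

__all__ = [
    "load_reference_panel",
    "load_colgfp_profile",
    "load_similarity_profiles",
    "materialize_fixtures",
    "FIXTURE_FILES",
]

FIXTURE_FILES = ("panel.csv", "colgfp_reference.csv", "similarity_table.csv")


def _open(name: str):
    return resources.files("strauth.data").joinpath(name).open("r", encoding="utf-8")


def load_reference_panel() -> list[MarkerDefinition]:
    """The 19 CellCheck mouse panel markers with known allele ranges and primers."""
    with _open("panel.csv") as fh:
        return load_panel(fh)


def load_colgfp_profile() -> STRProfile:
    """The full 19-marker Col-GFP HSC reference profile."""
    with _open("colgfp_reference.csv") as fh:
        profile = load_profiles(fh)[0]
    profile.accession = "CVCL_B7MI"
    return profile


def load_similarity_profiles() -> list[STRProfile]:
    """All eight columns of the published comparison table, query first."""
    with _open("similarity_table.csv") as fh:
        return load_profiles(fh)


def materialize_fixtures(out_dir) -> list[Path]:
    """Copy the packaged CSV fixtures into ``out_dir``; returns written paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for name in FIXTURE_FILES:
        target = out / name
        with _open(name) as fh:
            target.write_text(fh.read(), encoding="utf-8")
        written.append(target)
    return written
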