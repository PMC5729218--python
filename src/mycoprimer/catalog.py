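"""Bundled ITS1 primer catalog.

Ships the nine primers used throughout the worked examples: four published
("literature") ITS1-region primers that have dominated mycobiome studies,
and five custom-designed ones (four forward from the 3' 18S design window,
one reverse from the 5.8S region).
"""

from __future__ import annotations

from importlib import resources

from .thermo import Oligo


def bundled_primers(origin: str | None = None) -> list[Oligo]:
    """The bundled primer set, optionally filtered by origin
    ('literature' or 'custom')."""
    text = (
        resources.files("mycoprimer").joinpath("data/its1_primers.tsv").read_text()
    )
    oligos = []
    for line in text.splitlines()[1:]:
        if not line.strip():
            continue
        name, direction, seq, org = line.split("\t")
        if origin is None or org == origin:
            oligos.append(Oligo(name, seq, direction))
    return oligos


def primer(name: str) -> Oligo:
    """Look up one bundled primer by name (e.g. 'ITS1-30F')."""
    for o in bundled_primers():
        if o.name == name:
            return o
    raise KeyError(f"no bundled primer named {name!r}")
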