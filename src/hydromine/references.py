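"""Packaged reference enzymes and their catalytic annotations.

The package ships the full-length *Ideonella sakaiensis* PET hydrolase
(IsPETase, UniProt A0A0K8P6T7 / GenBank GAP38373.1), the canonical query
for PET-hydrolase mining.  Its catalytic triad is Ser160/Asp206/His237 on
full-length (signal-peptide-included) numbering, with the S238 gatekeeper
adjacent to the catalytic histidine and the class-II extra disulfide
C203-C239.
"""

from __future__ import annotations

from importlib import resources

from .mining import TriadSpec
from .sequence_core import ProteinRecord, read_fasta

ISPETASE_TRIAD = {"ser": 160, "asp": 206, "his": 237}
ISPETASE_GATEKEEPER = 238
ISPETASE_DISULFIDE_PAIR = (203, 239)

__all__ = [
    "ISPETASE_TRIAD",
    "ISPETASE_GATEKEEPER",
    "ISPETASE_DISULFIDE_PAIR",
    "ispetase",
    "ispetase_triad_spec",
]


def ispetase() -> ProteinRecord:
    """The packaged full-length IsPETase record."""
    path = resources.files("hydromine.data").joinpath("ispetase.fasta")
    with resources.as_file(path) as p:
        rec = read_fasta(p, source="reference")[0]
    return rec


def ispetase_triad_spec() -> TriadSpec:
    """Catalytic-triad anchors S160/D206/H237 on the packaged reference."""
    rec = ispetase()
    return TriadSpec(
        reference_id=rec.id,
        ser_pos=ISPETASE_TRIAD["ser"],
        asp_pos=ISPETASE_TRIAD["asp"],
        his_pos=ISPETASE_TRIAD["his"],
        reference=rec,
    )
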