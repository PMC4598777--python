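"""Bundled protein sequence fixtures.

The bundled FASTA files are *synthetic stand-ins* for the three neutrophil
azurophilic-granule proteins studied by the pipeline (cathepsin G,
azurocidin, neutrophil elastase). Each stand-in is engineered to satisfy the
documented anchors of the real proteins in unprocessed-chain numbering —
for cathepsin G: the catalytic triad His64/Asp108/Ser201, the single
N-glycosylation sequon at Asn71 inside the chymotryptic peptide GSNINVTL
(67-74), methionines at 35/110/152/242, deamidation-prone Gln163/Asn208,
six mature-chain cysteines (three disulfides), and the C-terminal
IRTTMR(238-243)/IRTTMRS(238-244) truncation variants. Real UniProt FASTA
files (P08311, P20160, P08246) can be substituted transparently.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

from Bio import SeqIO

__all__ = ["load_fasta", "bundled_sequence", "NCG", "AZUROCIDIN", "NE"]

NCG = "synthetic_ncg"
AZUROCIDIN = "synthetic_azurocidin"
NE = "synthetic_ne"


def load_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an {id: sequence} mapping."""
    with open(path) as fh:
        records = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def bundled_sequence(name: str) -> str:
    """Return one bundled stand-in sequence by fixture name."""
    ref = resources.files("glycoprofiler.data") / f"{name}.fasta"
    with resources.as_file(ref) as path:
        if not path.exists():
            raise FileNotFoundError(
                f"bundled fixture {name!r} missing; reinstall the package or "
                f"provide a FASTA via load_fasta()"
            )
        records = load_fasta(path)
    return next(iter(records.values()))
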