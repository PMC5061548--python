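"""Packaged African elephant TP53/TP53RTG repertoire table.

Transcription of the published summary of the African elephant (loxAfr3)
TP53 gene and its 19 retrogenes: locus scaffold, coding potential and ORF
size. Five retrogenes carry no intact reading frame.
"""

from __future__ import annotations

from .repertoire import GeneRecord

# gene id, scaffold, coding potential, ORF length (aa)
_TABLE1_ROWS = (
    ("TP53", "47", True, 392),
    ("TP53RTG1", "175", False, None),
    ("TP53RTG2", "217", True, 134),
    ("TP53RTG3", "406", True, 79),
    ("TP53RTG4", "627", True, 134),
    ("TP53RTG5", "221", True, 162),
    ("TP53RTG6", "76", True, 123),
    ("TP53RTG7", "208", False, None),
    ("TP53RTG8", "294", True, 210),
    ("TP53RTG9", "786", False, None),
    ("TP53RTG10", "221", True, 210),
    ("TP53RTG11", "281", True, 203),
    ("TP53RTG12", "825", True, 180),
    ("TP53RTG13", "458", False, None),
    ("TP53RTG14", "928", True, 210),
    ("TP53RTG15", "656", True, 210),
    ("TP53RTG16", "378", False, None),
    ("TP53RTG17", "552", True, 111),
    ("TP53RTG18", "498", True, 111),
    ("TP53RTG19", "342", True, 210),
)


def load_table1_fixture() -> list[GeneRecord]:
    """The packaged 20-record African elephant TP53/TP53RTG repertoire."""
    return [
        GeneRecord(
            gene_id=gid,
            contig=f"scaffold_{scaf}",
            is_retrogene=(gid != "TP53"),
            coding_potential=coding,
            orf_length_aa=orf,
        )
        for gid, scaf, coding, orf in _TABLE1_ROWS
    ]
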