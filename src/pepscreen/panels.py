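"""The 20-peptide MGMT tiling panel.

O-6-methylguanine-DNA methyltransferase (MGMT, NCBI AAP36645.1) is tiled into
twenty overlapping 20-mers at a 10-residue offset for serological screening of
anti-MGMT autoantibodies.  Start coordinates below are the array design
coordinates; end coordinates are derived from the sequence lengths (two design
spans are internally off by one residue and are corrected here).  MGMT-05 and
MGMT-06 are 19-mers in the design; the terminal MGMT-20 is a 17-mer truncated
at residue 206.
"""

from __future__ import annotations

from .tiling import PeptideTile, ProteinRecord, assemble_from_tiles

# (name, 1-based start, sequence)
MGMT_PEPTIDES: tuple[tuple[str, int, str], ...] = (
    ("MGMT-01", 1, "MDKDCEMKRTTLDSPLGKLE"),
    ("MGMT-02", 11, "TLDSPLGKLELSGCEQGLHE"),
    ("MGMT-03", 21, "LSGCEQGLHEIKLLGKGTSA"),
    ("MGMT-04", 31, "IKLLGKGTSAADAVEVPAPA"),
    ("MGMT-05", 41, "ADAVEVPAPAAVLGGPELM"),
    ("MGMT-06", 51, "AVLGGPELMQCTAWLNAYF"),
    ("MGMT-07", 60, "QCTAWLNAYFHQPEAIEEFP"),
    ("MGMT-08", 70, "HQPEAIEEFPVPALHHPVFQ"),
    ("MGMT-09", 80, "VPALHHPVFQQESFTRQVLW"),
    ("MGMT-10", 90, "QESFTRQVLWKLLKVVKFGE"),
    ("MGMT-11", 100, "KLLKVVKFGEVISYQQLAAL"),
    ("MGMT-12", 110, "VISYQQLAALAGNPKAARAV"),
    ("MGMT-13", 120, "AGNPKAARAVGGAMRGNPVP"),
    ("MGMT-14", 130, "GGAMRGNPVPILIPCHRVVC"),
    ("MGMT-15", 140, "ILIPCHRVVCSSGAVGNYSG"),
    ("MGMT-16", 150, "SSGAVGNYSGGLAVKEWLLA"),
    ("MGMT-17", 160, "GLAVKEWLLAHEGHRLGKPG"),
    ("MGMT-18", 170, "HEGHRLGKPGLGGSSGLAGA"),
    ("MGMT-19", 180, "LGGSSGLAGAWLKGAGATSG"),
    ("MGMT-20", 190, "WLKGAGATSGSPPAGRN"),
)

MGMT_PANEL_NAMES: tuple[str, ...] = tuple(name for name, _, _ in MGMT_PEPTIDES)

# the five peptides with elevated glioma-vs-healthy response used for pooled
# serostatus, longitudinal tracking and the IHC association
MGMT_TOP_PEPTIDES: tuple[str, ...] = (
    "MGMT-02",
    "MGMT-04",
    "MGMT-07",
    "MGMT-10",
    "MGMT-18",
)


def mgmt_panel() -> list[PeptideTile]:
    """The MGMT array panel as a list of :class:`PeptideTile`."""
    return [
        PeptideTile(
            index=i + 1,
            start=start,
            end=start + len(seq) - 1,
            sequence=seq,
            name=name,
        )
        for i, (name, start, seq) in enumerate(MGMT_PEPTIDES)
    ]


def mgmt_antigen() -> ProteinRecord:
    """The 206-residue MGMT antigen, overlap-assembled from the panel."""
    return assemble_from_tiles(mgmt_panel(), protein_id="MGMT")
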