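"""Small conveniences shared by the analysis drivers and tests."""

from __future__ import annotations

from importlib import resources

from thermoshift.hydropathy import ProteinSequence, read_fasta

__all__ = ["load_p65_sequence"]


def load_p65_sequence() -> ProteinSequence:
    """The bundled 551-aa p65/RelA sequence.

    This is a synthetic stand-in reconstructed offline for the canonical
    human RELA entry (see the FASTA header for the landmark checks);
    isolated positions may deviate from the database sequence.
    """
    ref = resources.files("thermoshift.data").joinpath("rela_p65_synthetic.fasta")
    with ref.open("r", encoding="utf-8") as handle:
        return read_fasta(handle)[0]
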