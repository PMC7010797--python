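# MmCpn validation data (not bundled)

Two acceptance checks validate this tool against the originally published
cysteine-less MmCpn chaperonin design. The sequences involved — the
543-residue *Methanococcus maripaludis* MmCpn wild-type query and the extant
donor orthologs (*Methanococcus thermolithotrophicus*, *Thermococcus sp.
4557*, *Haloarcula hispanica*, and the rest of the homolog set) — come from
that study's supplementary material and are not redistributed here.

To enable those checks, place a plain multi-FASTA at

    data/mmcpn/supplementary_sequences.fasta

with the MmCpn wild-type sequence as the **first** record and the homolog
set as the remaining records. Then run:

    python -m pytest tests/test_acceptance.py -k published

Without this file the two checks fail with a message pointing here; all
other tests are self-contained and run on synthetic data.
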