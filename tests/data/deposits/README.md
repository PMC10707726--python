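Place the deposited TsaBgl coordinate files here as text (PDB or mmCIF):

    8WFT.pdb  8WFU.pdb  8WFV.pdb  8WFW.pdb

e.g. from https://files.rcsb.org/download/8WFT.pdb — the deposit-dependent
checks in tests/test_acceptance.py activate when these files are present.
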