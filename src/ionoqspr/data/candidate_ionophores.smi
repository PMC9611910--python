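# Diphenylphosphoryl acetamide candidate ionophores (SMILES encoded from IUPAC names).
# substance_2 is reconstructed: the printed name duplicates substance_1 (butane-1,4-diyl);
# encoded here with the intermediate pentane-1,5-diyl linker of the 1-2-3 series.
O=P(c1ccccc1)(c1ccccc1)CC(=O)CN(CCCCCCCC)CCCCN(CCCCCCCC)CC(=O)CP(=O)(c1ccccc1)c1ccccc1 substance_1
O=P(c1ccccc1)(c1ccccc1)CC(=O)CN(CCCCCCCC)CCCCCN(CCCCCCCC)CC(=O)CP(=O)(c1ccccc1)c1ccccc1 substance_2
O=P(c1ccccc1)(c1ccccc1)CC(=O)CN(CCCCCCCC)CCCCCCN(CCCCCCCC)CC(=O)CP(=O)(c1ccccc1)c1ccccc1 substance_3
O=C(CP(=O)(c1ccccc1)c1ccccc1)N1CCN(CC1)C(=O)CP(=O)(c1ccccc1)c1ccccc1 substance_4
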