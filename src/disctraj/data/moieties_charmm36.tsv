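# CHARMM36 lipid atom-name -> moiety class mapping for DOPC / DOPS.
# First matching row wins; exact names precede globs so e.g. glycerol C2
# is headgroup_carbon while chain C2x atoms fall through to chain_carbon.
# residue_name	atom_name_glob	class
DOPC	N	amine_nitrogen
DOPC	C11	headgroup_carbon
DOPC	C12	headgroup_carbon
DOPC	C13	headgroup_carbon
DOPC	C14	headgroup_carbon
DOPC	C15	headgroup_carbon
DOPC	C1	headgroup_carbon
DOPC	C2	headgroup_carbon
DOPC	C3	headgroup_carbon
DOPC	P	phosphate
DOPC	O11	phosphate
DOPC	O12	phosphate
DOPC	O13	phosphate
DOPC	O14	phosphate
DOPC	O21	ester_oxygen
DOPC	O22	ester_oxygen
DOPC	O31	ester_oxygen
DOPC	O32	ester_oxygen
DOPC	C2*	chain_carbon
DOPC	C3*	chain_carbon
DOPC	H*	other
DOPS	N	amine_nitrogen
DOPS	C11	headgroup_carbon
DOPS	C12	headgroup_carbon
DOPS	C13	carboxylate
DOPS	O13A	carboxylate
DOPS	O13B	carboxylate
DOPS	C1	headgroup_carbon
DOPS	C2	headgroup_carbon
DOPS	C3	headgroup_carbon
DOPS	P	phosphate
DOPS	O11	phosphate
DOPS	O12	phosphate
DOPS	O13	phosphate
DOPS	O14	phosphate
DOPS	O21	ester_oxygen
DOPS	O22	ester_oxygen
DOPS	O31	ester_oxygen
DOPS	O32	ester_oxygen
DOPS	C2*	chain_carbon
DOPS	C3*	chain_carbon
DOPS	H*	other
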