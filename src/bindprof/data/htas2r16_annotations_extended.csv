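chain,res_seq,res_name,bw,mutations,ec50_affected,region,notes
A,86,GLU,3.33,E86Q;E86D,true,upper_extracellular,EC50 ratio 2.9-5.7 (Q) and 7.9-18.4 (D)
A,89,ASN,3.36,N89A,true,upper_extracellular,mutation abolishes activity for all three agonists
A,93,PHE,3.40,F93A,true,upper_extracellular,EC50 decreased 19-55 fold
A,177,GLN,5.39,Q177N;Q177E;Q177A,false,upper_extracellular,EC50 ratio only 0.9-2.9
A,181,HIS,5.43,H181T;H181L,true,upper_extracellular,H181T ratio 2-8.5; H181L abolishes response for 2/3 ligands
A,240,PHE,6.52,F240Y;F240W;F240L,true,upper_extracellular,Y/W ratio 6.5-11; L abolishes activity
A,243,ILE,6.55,I243L;I243V;I243A,true,upper_extracellular,L/V ratio 2.0-5.2; A abolishes response
A,85,TRP,3.32,W85R,false,upper_extracellular,extended set: reduces maximum response
A,59,LEU,2.53,L59A,false,upper_extracellular,extended set: response reduced to 64%
A,236,PHE,6.48,F236A,false,upper_extracellular,extended set: response reduced to 2%
A,262,GLU,7.39,E262D;E262A,true,upper_extracellular,extended set: E262A abolishes activation
A,265,VAL,7.42,V265A,false,upper_extracellular,extended set: response reduced to 5%
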