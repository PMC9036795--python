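metabolite,fragment_formula,n_backbone_carbons,rt,adduct
GLC,C23H56NO6Si5,6,14.2,[M+H]+
G6P,C26H67NO9PSi6,6,22.4,[M+H]+
F6P,C26H67NO9PSi6,6,22.1,[M+H]+
PG6,C26H65NO10PSi6,6,23.9,[M+H]+
X5P,C22H56NO8PSi5,5,20.6,[M+H]+
R5P,C22H56NO8PSi5,5,20.9,[M+H]+
S7P,C30H75NO11PSi7,7,25.3,[M+H]+
E4P,C18H45NO7PSi4,4,18.7,[M+H]+
PG3,C12H32O7PSi3,3,16.0,[M+H]+
XOL,C20H53O5Si5,5,15.1,[M+H]+
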