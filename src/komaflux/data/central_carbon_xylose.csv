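# Central carbon metabolism of K. phaffii plus the xylose oxidoreductase extension.
# Reconstruction: compact PPP/glycolysis/TCA stoichiometry with carbon atom
# transitions; the xylose_extension block carries the five added reactions
# (aliases R48/R49/R50/R59/R25). Reversibles are parameterized net+exchange.
id,equation,reversible,type,block,alias
RPE,RU5P (abcde) <-> X5P (abcde),1,N,base_model,
RPI,RU5P (abcde) <-> R5P (abcde),1,N,base_model,
TKT1,X5P (abcde) + R5P (fghij) <-> S7P (abfghij) + GAP (cde),1,N,base_model,
TAL,S7P (abcdefg) + GAP (hij) <-> F6P (abchij) + E4P (defg),1,N,base_model,
TKT2,X5P (abcde) + E4P (fghi) <-> F6P (abfghi) + GAP (cde),1,N,base_model,
PGI,G6P (abcdef) <-> F6P (abcdef),1,N,base_model,
G6PDH,G6P (abcdef) -> PG6 (abcdef),0,N,base_model,
GND,PG6 (abcdef) -> RU5P (bcdef) + CO2 (a),0,N,base_model,
FBA,GAP (abc) + GAP (def) <-> F6P (cbadef),1,N,base_model,
GAPDH,GAP (abc) <-> PG3 (abc),1,N,base_model,
ENO,PG3 (abc) <-> PEP (abc),1,N,base_model,
PYK,PEP (abc) -> PYR (abc),0,N,base_model,
G6PASE,G6P (abcdef) -> GLC (abcdef),0,N,base_model,
GLCOUT,GLC (abcdef) -> GLC_ext (abcdef),0,N,base_model,
PDH,PYR (abc) -> ACA (bc) + CO2 (a),0,N,base_model,
PYC,PYR (abc) + CO2 (d) -> OAA (abcd),0,N,base_model,
CS,OAA (abcd) + ACA (ef) -> CIT (dcbfea),0,N,base_model,
IDH,CIT (abcdef) -> AKG (abcde) + CO2 (f),0,N,base_model,
TCA,AKG (abcde) -> OAA (bcde) + CO2 (a),0,N,base_model,
CO2OUT,CO2 (a) -> CO2_ext (a),0,N,base_model,
BIOMASS,0.30 G6P + 0.12 R5P + 0.06 E4P + 0.10 GAP + 0.60 PG3 + 0.40 PEP + 0.80 PYR + 1.30 ACA + 0.90 OAA + 0.40 AKG -> BIOMASS,0,B,base_model,
XYLUP,XYL_ext (abcde) -> XYL (abcde),0,N,xylose_extension,R48
XR,XYL (abcde) -> XOL (abcde),0,N,xylose_extension,R49
XDH,XOL (abcde) -> XUL (abcde),0,N,xylose_extension,R50
XK,XUL (abcde) -> X5P (abcde),0,N,xylose_extension,R59
XOLOUT,XOL (abcde) -> XOL_ext (abcde),0,N,xylose_extension,R25
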