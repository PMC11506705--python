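# PRM quantification panel for the seven human somatic linker-histone (H1)
# subtypes: one proteotypic peptide per subtype, as published for this assay.
# Positions are 1-based inclusive, counting the initiator Met as residue 1.
# Note: the H1.1 peptide is a doubly miscleaved tryptic species (starts KK);
# miscleaved siblings listed under miscleaved_forms are quantified against
# their own external light-peptide curves and summed into the subtype total.
# Label positions reflect the SIS synthesis chemistry (K+8, L/I+7, A+4).

name = "human-H1-somatic"

[accessions]
P07305 = "H1.0"
Q02539 = "H1.1"
P16403 = "H1.2"
P16402 = "H1.3"
P10412 = "H1.4"
P16401 = "H1.5"
Q92522 = "H1X"

[[peptide]]
sequence = "YSDMIVAAIQAEK"
subtype = "H1.0"
enzyme = "trypsin"
start = 28
end = 40
label_positions = [13]
precursor_charge = 2
transitions = ["y4+1", "y5+1", "y6+1", "y7+1"]
oxidation_correction = true

[[peptide]]
sequence = "KKPAGPSVSELIVQAASSSK"
subtype = "H1.1"
enzyme = "trypsin"
start = 37
end = 56
missed_cleavages = 2
label_positions = [20]
precursor_charge = 3
transitions = ["y5+1", "y6+1", "y7+1", "y8+1"]

[[peptide]]
sequence = "TAPAAPAAAPPAE"
subtype = "H1.2"
enzyme = "glu_c"
start = 4
end = 16
label_positions = [2]
precursor_charge = 2
transitions = ["y4+1", "y5+1", "y6+1", "b4+1"]

[[peptide]]
sequence = "TAPLAPTIPAPAE"
subtype = "H1.3"
enzyme = "glu_c"
start = 4
end = 16
label_positions = [4]
precursor_charge = 2
transitions = ["y4+1", "y5+1", "y6+1", "b4+1"]

[[peptide]]
sequence = "TAPAAPAAPAPAE"
subtype = "H1.4"
enzyme = "glu_c"
start = 4
end = 16
label_positions = [2]
precursor_charge = 2
transitions = ["y4+1", "y5+1", "y7+1", "b4+1"]

[[peptide]]
sequence = "ATGPPVSELITK"
subtype = "H1.5"
enzyme = "trypsin"
start = 38
end = 49
label_positions = [12]
precursor_charge = 2
transitions = ["y4+1", "y5+1", "y6+1", "y7+1"]

[[peptide]]
sequence = "ALVQNDTLLQVK"
subtype = "H1X"
enzyme = "trypsin"
start = 95
end = 106
label_positions = [12]
precursor_charge = 2
transitions = ["y4+1", "y5+1", "y6+1", "y7+1"]
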