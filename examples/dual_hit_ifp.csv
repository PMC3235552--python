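complex,residue,interaction_type
hit8_H4R,D3.32,ionic_protein_anion
hit8_H4R,F7.39,aromatic_face_to_face
hit8_H4R,Y3.33,aromatic_face_to_face
hit8_H4R,Y6.51,aromatic_face_to_face
hit8_5HT3AR,E129,ionic_protein_anion
hit8_5HT3AR,Y234,aromatic_face_to_face
hit8_5HT3AR,W183,aromatic_face_to_face
hit8_5HT3AR,Y153,aromatic_face_to_face
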