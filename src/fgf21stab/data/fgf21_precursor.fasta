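>FGF21_HUMAN Q9NSA1 fibroblast growth factor 21 precursor (209 aa, signal peptide 1-28)
MDSDETGFEHSGLWVSVLAGLLLGACQAHPIPDSSPLLQFGGQVRQRYLYTDDAQQTEAH
LEIREDGTVGGAADQSPESLLQLKALKPGVIQILGVKTSRFLCQRPDGALYGSLHFDPEA
CSFRELLLEDGYNVYQSEAHGLPLHLPGNKSPHRDPAPRGPARFLPLPGLPPALPEPPGI
LAPQPPDVGSSDPLSMVGPSQGRSPSYAS
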