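>P02666 Beta-casein precursor (Bos taurus), UniProt canonical (A2); repository fixture, precursor numbering
MKVLILACLVALALARELEELNVPGEIVESLSSSEESITRINKKIEKFQSEEQQQTEDEL
QDKIHPFAQTQSLVYPFPGPIPNSLPQNIPPLTQTPVVVPPFLQPEVMGVSKVKEAMAPK
HKEMPFPKYPVEPFTESQSLTLTDVENLHLPLPLLQSWMHQPHQPLPPTVMFPPQSVLSL
SQSKVLPVPQKAVPYPQRDMPIQAFLLYQEPVLGPVRGPFPIIV
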