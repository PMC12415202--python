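>A4_dCache_1UR synthetic scaffold; uracil distal + SCFA proximal pocket residues at published A4 numbering
PRLSQLLFLDEGLIQLKPLIYGKTRMVQGKKERQIGIWVDLPVESLAVIKYMGFLILGDA
GLFRFNAVADKGAFHNNGNNDGARPVAIFPVLMYIETRSTGAEVMRGMPRVKLRLRPILL
SIGDAFFRFVGLAYTIMHAKCFEATSRTLGNKSETSDLLWYEFGEFPARPYSTCGYRNMN
LTNSTMKGRLNLQPAVFELATIMNDLKCAEVEADRMQIQLAMRSYPPGIIETENIHLHEF
AQKFADYYEIRKGLNGQIHGLLMSPGEQVSLHYKAMIGRKAVASSPELIAPDSAAAKAQV
CEFDDAPEEL
>McpX_like_dCache_1AM synthetic scaffold; amine-family distal pocket (placeholder residues) on the common dCache_1 scaffold
PRLSQLLFLDEGLIQLKPLIYGKTRMVQGKKERQIGIWVDLPVESLAVIKYMGFLILGDA
GLFRFNAVADKGAFHNNGNNDGARPVAIFPVLMYIETRSTGAEVMRGMPRVKLRLDPILL
SIGDAFFRYVGLAYTIMHAKCFEAASRTLGNKSETSDLLWYEFGEFPARPYSTCGYRWMY
LTNSTMKGRLNLQPAVFELATIMNDLKCAEVEADRMQIQLAMRSSPPGIIETENIHLLEF
AQKFADYYEIRKGLNGQIHGLLMSPGEQVSLHFKAMIGREAVASSPELIAPDSAAAKAQV
CEFDDAPEEL
>PctA_like_dCache_1AA synthetic scaffold; amino-acid-family distal pocket (placeholder residues) + SCFA proximal pocket
PRLSQLLFLDEGLIQLKPLIYGKTRMVQGKKERQIGIWVDLPVESLAVIKYMGFLILGDA
GLFRFNAVADKGAFHNNGNNDGARPVAIFPVLMYIETRSTGAEVMRGMPRVKLRLYPILL
SIGDAFFRYVGLAYTIMHAKCFEASSRTLGNKSETSDLLWYEFGEFPARPYSTCGYRTMW
LTNSTMKGRLNLQPAVFELATIMNDLKCAEVEADRMQIQLAMRSYPPGIIETENIHLHEF
AQKFADYYEIRKGLNGQIHGLLMSPGEQVSLHYKAMIGRKAVASSPELIAPDSAAAKAQV
CEFDDAPEEL
>McpH_like_dCache_1PU synthetic scaffold; purine-family distal pocket (placeholder residues) on the common dCache_1 scaffold
PRLSQLLFLDEGLIQLKPLIYGKTRMVQGKKERQIGIWVDLPVESLAVIKYMGFLILGDA
GLFRFNAVADKGAFHNNGNNDGARPVAIFPVLMYIETRSTGAEVMRGMPRVKLRLNPILL
SIGDAFFRFVGLAYTIMHAKCFEADSRTLGNKSETSDLLWYEFGEFPARPYSTCGYRSMF
LTNSTMKGRLNLQPAVFELATIMNDLKCAEVEADRMQIQLAMRSGPPGIIETENIHLMEF
AQKFADYYEIRKGLNGQIHGLLMSPGEQVSLHWKAMIGRQAVASSPELIAPDSAAAKAQV
CEFDDAPEEL
>K1_sCache_2 synthetic scaffold; SCCA pocket residues Y101/W103/L114/M135/Y153/F155/K166 at published K1 numbering
GNVNTVAAQYEPDLIISKKTRLASLAEENSNSFGDEEYGRSEIKRYSQASMGGVQQDKPT
ILHSLVQVDEITLVTGVKWERIFQDDVASKNKGEMPTSRDYYWCPCETSVLAWLALLLLV
EMKIDESLRSVLRVMELYEIASGVRTQNASNAYRFPGLSTTAGITKAKWLTLAGANIPPR
VVNSG
>FHS_sCache_3_3 synthetic scaffold; formate pocket placeholder positions (external provenance)
LQLYKVNTNAPANSEPGTITARDVTGPFDFSDILVNNLWKQLAKAVNTIAKDKYRLADAQ
LGDLAEILMTLHSAYVTLGAILGLEAFYHALRENDATRQKYSVSSMSDYLVILRQLEKQK
KAPLYFGLESLGKLPLQNPTRSYVRPEIETEREPVYGEIPLCESATVGIVARPNE
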