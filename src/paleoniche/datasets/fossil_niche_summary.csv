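species,n_fossils,pct_within_realized,pct_within_potential
Actinemys marmorata,4,100.0,100.0
Apalone ferox,2,0.0,100.0
Apalone spinifera,6,16.7,66.7
Chelydra serpentina,22,63.6,77.3
Chrysemys picta,14,42.9,92.9
Clemmys guttata,1,100.0,100.0
Deirochelys reticularia,4,25.0,100.0
Emydoidea blandingii,7,42.9,85.7
Kinosternon subrubrum,3,66.7,100.0
Malaclemys terrapin,1,100.0,100.0
Pseudemys concinna,5,20.0,80.0
Pseudemys floridana,3,33.3,100.0
Pseudemys nelsoni,3,33.3,100.0
Sternotherus minor,1,100.0,100.0
Sternotherus odoratus,4,50.0,75.0
Terrapene carolina,41,56.1,87.8
Terrapene ornata,5,60.0,100.0
Trachemys scripta,15,26.7,80.0
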