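subset,variable,n,mean_mess,max_mess
total,BIO10,48,-79.6,-218.0
total,BIO2,7,-26.4,-61.6
total,BIO5,5,-45.7,-85.4
total,BIO8,4,-206.0,-814.3
total,BIO4,3,-27.2,-58.7
total,BIO6,1,-1.6,-1.6
total,BIO17,1,-7.9,-7.9
total,BIO13,1,-25.3,-25.3
total,BIO12,1,-7.5,-7.5
total,BIO19,1,-16.4,-16.4
outside modern potential niche,BIO10,18,-125.5,-218.0
outside modern potential niche,BIO5,1,-24.0,-24.0
within modern potential niche,BIO10,30,-52.1,-149.2
within modern potential niche,BIO2,7,-26.4,-61.6
within modern potential niche,BIO5,4,-51.1,-85.4
within modern potential niche,BIO8,4,-206.0,-814.3
within modern potential niche,BIO4,3,-27.2,-58.7
within modern potential niche,BIO6,1,-1.6,-1.6
within modern potential niche,BIO17,1,-7.9,-7.9
within modern potential niche,BIO13,1,-25.3,-25.3
within modern potential niche,BIO12,1,-7.5,-7.5
within modern potential niche,BIO19,1,-16.4,-16.4
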