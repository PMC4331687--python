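# Sentence-internal abbreviations: a detected sentence ending with one of
# these is merged with the following sentence.  One entry per line, final
# period included.  User-extensible.
var.
sp.
cv.
syn.
spp.
subsp.
cf.
e.g.
i.e.
etc.
et al.
Fig.
fig.
ca.
approx.
vs.
no.
No.
resp.
Dr.
St.
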