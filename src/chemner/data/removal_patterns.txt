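# False-positive removal patterns, one anchored regular expression per line
# (full-match against the mention text).  User-extensible.
# Citation-like spans: volume(issue), page-page
\d+\(\d+\),\s*\d+\s*-\s*\d+
# Hyphenated single-letter enumerations: 1-D, 2-D
\d+\s*-\s*[A-Za-z](?:\s*,\s*\d+\s*-\s*[A-Za-z])+
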