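# Character normalization map: variant<TAB>canonical, one pair per line.
# Strictly 1:1 (single code point to single code point) so every character
# offset in the original text stays valid after normalization.
≧	≥
≦	≤
∗	*
﹡	*
≃	≅
（	(
）	)
［	[
］	]
｛	{
｝	}
：	:
；	;
，	,
．	.
％	%
＋	+
＝	=
＜	<
＞	>
～	~
－	-
–	-
—	-
−	-
‐	-
‑	-
’	'
‘	'
“	"
”	"
Ｃ	C
Ｈ	H
Ｏ	O
Ｎ	N
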