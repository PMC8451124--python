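alias	alpha2
usa	US
u s a	US
united states of america	US
america	US
uk	GB
u k	GB
great britain	GB
england	GB
scotland	GB
wales	GB
northern ireland	GB
peoples r china	CN
peoples republic of china	CN
pr china	CN
republic of korea	KR
korea	KR
south korea	KR
democratic peoples republic of korea	KP
viet nam	VN
russian federation	RU
czech republic	CZ
slovak republic	SK
the netherlands	NL
holland	NL
ivory coast	CI
cote divoire	CI
republic of cote d'ivoire	CI
dem rep congo	CD
dr congo	CD
drc	CD
congo kinshasa	CD
democratic republic of congo	CD
republic of the congo	CG
congo brazzaville	CG
cape verde	CV
swaziland	SZ
the gambia	GM
united republic of tanzania	TZ
republic of south africa	ZA
rsa	ZA
arab republic of egypt	EG
libyan arab jamahiriya	LY
macedonia	MK
burma	MM
brunei darussalam	BN
lao pdr	LA
laos pdr	LA
syrian arab republic	SY
iran islamic republic	IR
islamic republic of iran	IR
republic of ireland	IE
uae	AE
kingdom of saudi arabia	SA
trinidad tobago	TT
bosnia herzegovina	BA
bosnia and herceg	BA
sao tome e principe	ST
st helena	SH
republic of benin	BJ
republic of niger	NE
federal republic of nigeria	NG
republic of kenya	KE
republic of uganda	UG
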